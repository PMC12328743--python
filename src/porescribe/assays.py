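"""Bulk assay normalizations.

Carboxyfluorescein liposome-leakage readings are expressed as percent
leakage on a two-point scale: the detergent (Triton X-100) lysis control
defines 100% and the buffer-only control defines 0%.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LeakageMeasurement", "LeakageResult", "normalize_leakage"]


@dataclass(frozen=True)
class LeakageMeasurement:
    """Fluorescence readings (arbitrary units, common scale)."""

    fluorescence_sample: float
    fluorescence_buffer: float
    fluorescence_triton: float


@dataclass(frozen=True)
class LeakageResult:
    percent: float
    in_range: bool  # False when outside [0, 100]: quenching/scatter artefact


def normalize_leakage(m: LeakageMeasurement) -> LeakageResult:
    """Percent leakage = 100 (F_sample - F_buffer) / (F_triton - F_buffer).

    Values outside [0, 100] are returned unclipped but flagged, so
    quenching or scatter artefacts stay visible.
    """
    span = m.fluorescence_triton - m.fluorescence_buffer
    if span == 0:
        raise ValueError("Triton and buffer fluorescence are equal: degenerate scale")
    pct = 100.0 * (m.fluorescence_sample - m.fluorescence_buffer) / span
    return LeakageResult(pct, 0.0 <= pct <= 100.0)
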