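"""Synthetic generators for every input the analysis chain consumes.

Each generator is a pure function of its configuration and seed, so test
fixtures and acceptance runs are reproducible bit-for-bit.  The trace
simulator emulates the statistical structure of a peptide-addition bilayer
recording: pore insertions arrive as a homogeneous Poisson process, each
insertion adds a persistent conductance drawn i.i.d. from a configurable
amplitude distribution (lognormal by default, matching the broad
right-tailed conductance histograms such recordings show), and white
Gaussian noise rides on the Ohmic staircase current.  Pores never close by
default; an optional flicker mode exists for robustness exercises only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .peptide import ChargeStatePeakSet, predict_charge_ladder
from .ranking import MultimerMetricsTable
from .trace import CurrentTrace

__all__ = [
    "AmplitudeModel",
    "TraceSimConfig",
    "GroundTruth",
    "simulate_trace",
    "simulate_iv",
    "simulate_metrics_table",
    "simulate_spectrum",
]


@dataclass(frozen=True)
class AmplitudeModel:
    """Step-conductance distribution: 'lognormal' (median_nS, sigma) or
    'fixed' (median_nS only)."""

    distribution: str = "lognormal"
    median_nS: float = 10.8
    sigma: float = 0.35

    def __post_init__(self):
        if self.distribution not in ("lognormal", "fixed"):
            raise ValueError(f"unknown amplitude distribution {self.distribution!r}")
        if self.median_nS <= 0:
            raise ValueError("median_nS must be positive")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.distribution == "fixed":
            return np.full(n, self.median_nS)
        return np.exp(rng.normal(np.log(self.median_nS), self.sigma, size=n))


@dataclass(frozen=True)
class TraceSimConfig:
    """Defaults mirror the recording conditions the analysis targets:
    50 mV holding potential, step conductances with a 10.8 nS median, and a
    noise floor that keeps the step signal-to-noise ratio well above 5."""

    sampling_rate_hz: float = 5000.0
    duration_s: float = 60.0
    holding_voltage_mV: float = 50.0
    baseline_noise_sd_pA: float = 10.0
    insertion_rate_per_s: float = 1 / 3
    amplitude_model: AmplitudeModel = field(default_factory=AmplitudeModel)
    seed: int = 0
    flicker_close_rate_per_s: float = 0.0  # off by default: pores persist

    def __post_init__(self):
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.baseline_noise_sd_pA < 0 or self.insertion_rate_per_s < 0:
            raise ValueError("noise sd and insertion rate must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    event_times_s: np.ndarray
    event_conductances_nS: np.ndarray

    @property
    def final_total_conductance_nS(self) -> float:
        return float(np.sum(self.event_conductances_nS))

    @property
    def n_events(self) -> int:
        return int(self.event_times_s.size)


def simulate_trace(config: TraceSimConfig) -> tuple[CurrentTrace, GroundTruth]:
    """Poisson insertion staircase plus Gaussian noise.

    current(t) = V * sum_{events <= t} G_k + noise, in pA (mV * nS).
    """
    rng = np.random.default_rng(config.seed)
    n_events = rng.poisson(config.insertion_rate_per_s * config.duration_s)
    times = np.sort(rng.uniform(0.0, config.duration_s, size=n_events))
    amps = config.amplitude_model.draw(n_events, rng)

    n_samples = int(round(config.duration_s * config.sampling_rate_hz))
    t = np.arange(n_samples) / config.sampling_rate_hz
    # conductance staircase: cumulative amplitude of events at or before t
    cum = np.concatenate([[0.0], np.cumsum(amps)])
    current = config.holding_voltage_mV * cum[np.searchsorted(times, t, side="right")]
    if config.flicker_close_rate_per_s > 0 and n_events:
        close = rng.exponential(1 / config.flicker_close_rate_per_s, size=n_events)
        open_mask = t[:, None] < (times + close)[None, :]
        stepped = (t[:, None] >= times[None, :]) & open_mask
        current = config.holding_voltage_mV * (stepped * amps).sum(axis=1)
    if config.baseline_noise_sd_pA > 0:
        current = current + rng.normal(0.0, config.baseline_noise_sd_pA, size=n_samples)
    trace = CurrentTrace(
        samples=current,
        sampling_rate_hz=config.sampling_rate_hz,
        holding_voltage_mV=config.holding_voltage_mV,
        metadata={"seed": config.seed, "salt": "150 mM KCl", "filter_history": []},
    )
    return trace, GroundTruth(times, amps)


def simulate_iv(
    levels_nS: Sequence[float],
    reversal_mV: float,
    voltages_mV: Sequence[float],
    noise_sd_pA: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Ohmic I/V point sets, one per conductance level:
    I = G * (V - reversal) + noise.

    Returns a tidy frame with columns voltage_mV, current_pA, level_label.
    """
    voltages = np.asarray(voltages_mV, dtype=float)
    if np.unique(voltages).size < 2:
        raise ValueError("need at least two distinct voltages")
    rng = np.random.default_rng(seed)
    rows = []
    for j, g in enumerate(levels_nS, start=1):
        current = g * (voltages - reversal_mV)
        if noise_sd_pA > 0:
            current = current + rng.normal(0.0, noise_sd_pA, size=voltages.size)
        rows.append(
            pd.DataFrame(
                {"voltage_mV": voltages, "current_pA": current, "level_label": f"G{j}"}
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_metrics_table(
    n_range: Sequence[int],
    peak_n: int,
    peak_score: float = 0.75,
    width: float = 4.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    round_label: str = "round1",
    baseline: float = 0.2,
) -> MultimerMetricsTable:
    """Single-peaked stoichiometry-vs-confidence table.

    ipTM and pTM follow a Gaussian bump centred at peak_n (pTM slightly
    above ipTM, as multimer predictors typically report) plus optional
    Gaussian noise, clipped to [0, 1]; mean pLDDT tracks the same profile
    on its 0-100 scale.
    """
    ns = np.asarray(list(n_range), dtype=int)
    if peak_n not in ns:
        raise ValueError("peak_n must lie within n_range")
    rng = np.random.default_rng(seed)
    bump = np.exp(-((ns - peak_n) ** 2) / (2 * width**2))
    iptm = baseline + (peak_score - baseline) * bump
    ptm = np.clip(iptm + 0.05, 0.0, 1.0)
    plddt = 55.0 + 30.0 * bump
    if noise_sd > 0:
        iptm = iptm + rng.normal(0, noise_sd, ns.size)
        ptm = ptm + rng.normal(0, noise_sd, ns.size)
        plddt = plddt + rng.normal(0, 100 * noise_sd, ns.size)
    frame = pd.DataFrame(
        {
            "n": ns,
            "iptm": np.clip(iptm, 0.0, 1.0),
            "ptm": np.clip(ptm, 0.0, 1.0),
            "mean_plddt": np.clip(plddt, 0.0, 100.0),
            "round_label": round_label,
        }
    )
    return MultimerMetricsTable(frame)


def simulate_spectrum(
    mass_da: float,
    charges: Sequence[int] = (3, 4, 5, 6),
    mz_noise_sd_th: float = 0.0,
    seed: Optional[int] = None,
    proton_mass: float = 1.007,
) -> ChargeStatePeakSet:
    """Charge-state ladder with Gaussian m/z jitter."""
    ladder = predict_charge_ladder(mass_da, charges, proton_mass)
    rng = np.random.default_rng(seed)
    peaks = tuple(
        (z, mz + (rng.normal(0.0, mz_noise_sd_th) if mz_noise_sd_th > 0 else 0.0))
        for z, mz in ladder.peaks
    )
    return ChargeStatePeakSet(peaks)
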