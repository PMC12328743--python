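"""Peptide mass arithmetic, ESI charge-state deconvolution and hydropathy analysis.

The mature TMcin bacteriocin is a 52-residue peptide with an N-terminal
transmembrane helix and a C-terminal amphipathic hairpin pinned by a single
disulfide bond.  This module provides the sequence-level computations used to
characterise it: monoisotopic mass (with disulfide correction), the
charge-ladder deconvolution used for quadrupole ESI spectra, hydrophobic
residue fractions, Kyte-Doolittle sliding-window hydropathy, and the
Eisenberg hydrophobic moment.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from pyteomics.mass import std_aa_mass

__all__ = [
    "PeptideRecord",
    "ChargeStatePeakSet",
    "DeconvolutionResult",
    "HydropathyProfile",
    "HydrophobicFraction",
    "AMINO_ACIDS",
    "DEFAULT_HYDROPHOBIC_SET",
    "PROTON_MASS_PAPER",
    "PROTON_MASS_PHYSICAL",
    "WATER_MONO",
    "HYDROGEN_MONO",
    "TMCIN_G1905_SEQUENCE",
    "TMCIN_G1905_DISULFIDE",
    "monoisotopic_mass",
    "predict_charge_ladder",
    "deconvolute",
    "hydrophobic_fraction",
    "hydropathy_profile",
    "max_hydrophobic_span",
    "hydrophobic_moment",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Hydrophobic classification that reproduces the 65% figure on the mature
#: TMcin sequence (34/52).  Configurable in every operation that uses it.
DEFAULT_HYDROPHOBIC_SET = frozenset("AFGILMVW")

#: Proton mass as printed in the deconvolution protocol ("paper mode").
PROTON_MASS_PAPER = 1.007
#: CODATA proton mass, for "physical mode".
PROTON_MASS_PHYSICAL = 1.00728

WATER_MONO = 18.010565
HYDROGEN_MONO = 1.0078250319

#: Mature TMcin-G1905 peptide (52 residues) and its disulfide bridge.
TMCIN_G1905_SEQUENCE = "AWFVVLLAAILVFATAIFAGLTIWCVVNQHGKFTGNWNWHIKGVSLDVECKR"
TMCIN_G1905_DISULFIDE = (25, 50)


@dataclass(frozen=True)
class PeptideRecord:
    """A peptide sequence with optional disulfide pairings (1-based indices)."""

    id: str
    sequence: str
    disulfide_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        seq = self.sequence
        for pos, aa in enumerate(seq, start=1):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"unknown residue code {aa!r} at position {pos} in {self.id!r}"
                )
        seen: set[int] = set()
        for a, b in self.disulfide_pairs:
            if a == b:
                raise ValueError(f"disulfide pair ({a}, {b}) references a single residue")
            for idx in (a, b):
                if not 1 <= idx <= len(seq):
                    raise ValueError(f"disulfide index {idx} out of range 1..{len(seq)}")
                if seq[idx - 1] != "C":
                    raise ValueError(
                        f"disulfide index {idx} is {seq[idx - 1]!r}, not cysteine"
                    )
                if idx in seen:
                    raise ValueError(f"residue {idx} participates in two disulfides")
                seen.add(idx)

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def tmcin_g1905(cls) -> "PeptideRecord":
        """The mature TMcin-G1905 peptide with its Cys25-Cys50 disulfide."""
        return cls("TMcin-G1905", TMCIN_G1905_SEQUENCE, (TMCIN_G1905_DISULFIDE,))


@dataclass(frozen=True)
class ChargeStatePeakSet:
    """ESI peaks as (charge, m/z) pairs with unique positive charges."""

    peaks: tuple[tuple[int, float], ...]

    def __post_init__(self):
        charges = [z for z, _ in self.peaks]
        if any(z <= 0 or int(z) != z for z in charges):
            raise ValueError("charges must be positive integers")
        if len(set(charges)) != len(charges):
            raise ValueError("duplicate charge states in peak set")
        if any(mz <= 0 for _, mz in self.peaks):
            raise ValueError("m/z values must be positive")

    @property
    def charges(self) -> tuple[int, ...]:
        return tuple(z for z, _ in self.peaks)

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(mz for _, mz in self.peaks)


@dataclass(frozen=True)
class DeconvolutionResult:
    per_charge_masses: tuple[float, ...]
    mean_mass: float
    sd: Optional[float]  # None for a single peak (sample sd undefined)
    charges_used: tuple[int, ...]


@dataclass(frozen=True)
class HydropathyProfile:
    """Sliding-window mean hydropathy; scores[j] is the window starting at
    0-based residue j, centred on residue j + window//2 (0-based)."""

    window: int
    scores: np.ndarray
    scale_name: str = "kyte-doolittle"

    @property
    def centers(self) -> np.ndarray:
        """1-based center residue position of each window."""
        return np.arange(len(self.scores)) + self.window // 2 + 1


@dataclass(frozen=True)
class HydrophobicFraction:
    count: int
    length: int
    percent: float
    percent_rounded: int


def monoisotopic_mass(peptide: PeptideRecord) -> float:
    """Monoisotopic mass in Da: residue masses + one water, minus two
    hydrogens per disulfide bond."""
    total = sum(std_aa_mass[aa] for aa in peptide.sequence) + WATER_MONO
    total -= 2 * HYDROGEN_MONO * len(peptide.disulfide_pairs)
    return total


def predict_charge_ladder(
    mass: float,
    charges: Iterable[int],
    proton_mass: float = PROTON_MASS_PAPER,
) -> ChargeStatePeakSet:
    """Expected m/z ladder for a neutral mass: mz_i = (M + i*m_p) / i."""
    charges = tuple(charges)
    if mass <= 0:
        raise ValueError("mass must be positive")
    if not charges:
        raise ValueError("at least one charge state required")
    if any(z <= 0 for z in charges):
        raise ValueError("charges must be positive")
    return ChargeStatePeakSet(
        tuple((z, (mass + z * proton_mass) / z) for z in charges)
    )


def deconvolute(
    peaks: ChargeStatePeakSet,
    proton_mass: float = PROTON_MASS_PAPER,
) -> DeconvolutionResult:
    """Charge-state deconvolution: M_i = (m/z_i - m_p) * i, with the
    arithmetic mean and the sample (n-1) standard deviation across peaks.

    With a single peak the standard deviation is undefined and returned as
    ``None``.
    """
    if not peaks.peaks:
        raise ValueError("empty peak set")
    masses = tuple((mz - proton_mass) * z for z, mz in peaks.peaks)
    mean = sum(masses) / len(masses)
    if len(masses) > 1:
        sd = math.sqrt(sum((m - mean) ** 2 for m in masses) / (len(masses) - 1))
    else:
        sd = None
    return DeconvolutionResult(masses, mean, sd, peaks.charges)


def hydrophobic_fraction(
    peptide: PeptideRecord,
    hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC_SET,
) -> HydrophobicFraction:
    """Percentage of residues belonging to ``hydrophobic_set``.

    Reported unrounded and rounded to the nearest integer (half-up).
    """
    hs = frozenset(hydrophobic_set)
    if not hs or not hs <= AMINO_ACIDS:
        raise ValueError("hydrophobic_set must be a non-empty subset of the 20 codes")
    count = sum(1 for aa in peptide.sequence if aa in hs)
    pct = 100.0 * count / len(peptide)
    return HydrophobicFraction(count, len(peptide), pct, int(math.floor(pct + 0.5)))


def hydropathy_profile(peptide: PeptideRecord, window: int = 19) -> HydropathyProfile:
    """Sliding-window mean Kyte-Doolittle hydropathy."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if window > len(peptide):
        raise ValueError(
            f"window {window} exceeds sequence length {len(peptide)}"
        )
    vals = np.array([KYTE_DOOLITTLE[aa] for aa in peptide.sequence])
    scores = np.convolve(vals, np.full(window, 1.0 / window), mode="valid")
    return HydropathyProfile(window=window, scores=scores)


def max_hydrophobic_span(
    profile: HydropathyProfile, threshold: float = 1.6
) -> Optional[tuple[int, int]]:
    """Longest run of window centers scoring >= threshold, expanded to the
    full window extent; 1-based inclusive interval, or None.

    Run-length ties break toward the N-terminus.
    """
    above = profile.scores >= threshold
    if not above.any():
        return None
    best_start = best_len = 0
    run_start = None
    padded = np.concatenate([above, [False]])
    for j, flag in enumerate(padded):
        if flag and run_start is None:
            run_start = j
        elif not flag and run_start is not None:
            run_len = j - run_start
            if run_len > best_len:  # strict: ties keep the earlier run
                best_start, best_len = run_start, run_len
            run_start = None
    half = profile.window // 2
    start_center = best_start + half + 1  # 1-based
    end_center = best_start + best_len - 1 + half + 1
    return (start_center - half, end_center + half)


def hydrophobic_moment(
    segment: str | Sequence[str],
    periodicity_deg: float = 100.0,
    scale: dict[str, float] = KYTE_DOOLITTLE,
) -> float:
    """Eisenberg hydrophobic moment |sum h_k exp(i k delta)| / N.

    delta = 100 deg for an alpha helix, 180 deg for a beta strand.
    """
    seq = "".join(segment)
    if len(seq) < 2:
        raise ValueError("segment must have at least two residues")
    delta = math.radians(periodicity_deg)
    total = sum(scale[aa] * cmath.exp(1j * k * delta) for k, aa in enumerate(seq))
    return abs(total) / len(seq)
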