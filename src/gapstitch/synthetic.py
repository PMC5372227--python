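"""Synthetic proteins, deconvoluted spectra, and fragment strings.

The generator emulates the data a top-down pipeline hands to the assembler:
each simulated spectrum is the deconvoluted fragment-mass list of a
contiguous stretch of a known protein, with peaks at cumulative residue-mass
prefix sums (no ion-type constant — offset differences cancel any constant,
and this keeps ground truth exact), per-site dropout, small Gaussian mass
error, and occasional exact ±1 Da shifts mimicking monoisotopic-assignment
errors of deconvolution. Fragment strings are non-overlapping substrings of
the protein with known separating subsequences and random orientation
flips, standing in for aggregated de novo sequence fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chem import STANDARD_RESIDUES, WATER, residue_mass, reverse, sequence_mass
from .params import Params
from .spectra import DeconvolutedSpectrum, Peak
from .tagging import Tag

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_protein",
    "simulate_spectra",
    "simulate_fragment_strings",
    "glue_tags_to_string",
    "DeNovoString",
]

# I excluded from random proteins: tags canonicalize I to L, so ground-truth
# string comparisons stay exact without I/L rewriting.
_SIM_ALPHABET = "".join(aa for aa in STANDARD_RESIDUES if aa != "I")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generator; one seed fixes everything.

    Defaults describe a clean, well-covered top-down experiment on a
    mid-sized protein: full-length precursor windows, 80% chance each
    cleavage site produces a fragment peak, 1 mDa Gaussian mass error
    (well inside the 4 mDa tag tolerance), no ±1 Da errors unless asked
    for, log-normal intensities, and an even chance that a fragment string
    is handed over in reversed orientation.
    """

    protein_length: int = 300
    n_spectra: int = 200
    coverage: float = 0.8  # per-cleavage-site probability of a peak
    mass_error_sd: float = 0.001  # Da; << epsilon
    p_shift: float = 0.0  # probability of an exact ±1 Da error per peak
    intensity_model: str = "lognormal"  # or "uniform"
    intensity_sigma: float = 1.0
    min_window: Optional[int] = None  # None: every spectrum spans the protein
    fragment_lengths: tuple[int, ...] = (40, 40, 40, 40)
    gap_lengths: tuple[int, ...] = (8, 12, 16)
    flip_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.coverage, self.p_shift, self.flip_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if len(self.gap_lengths) != len(self.fragment_lengths) - 1:
            raise ValueError("need one gap length between each fragment pair")


@dataclass
class GroundTruth:
    """What the generator actually did, for exact downstream checks."""

    protein: str
    #: per fragment: (start, end) half-open protein coordinates and whether
    #: the emitted string is reversed
    fragment_positions: list[tuple[int, int]] = field(default_factory=list)
    fragment_reversed: list[bool] = field(default_factory=list)
    #: substrings separating consecutive fragments, and their residue masses
    separating_strings: list[str] = field(default_factory=list)
    separating_masses: list[float] = field(default_factory=list)
    #: per spectrum: (window_start, window_end) protein coordinates
    windows: list[tuple[int, int]] = field(default_factory=list)


def simulate_protein(length: int, seed: int = 0) -> str:
    """Uniform random protein over 19 letters (I folded into L); deterministic."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_SIM_ALPHABET), size=length))


def _prefix_masses(window: str) -> np.ndarray:
    return np.cumsum([residue_mass(aa) for aa in window])


def simulate_spectra(
    protein: str, config: SimulationConfig
) -> tuple[list[DeconvolutedSpectrum], GroundTruth]:
    """Deconvoluted spectra of contiguous windows of *protein*.

    Each spectrum emits, per interior cleavage site of its window and with
    probability ``coverage``, a peak at the prefix residue-mass sum, plus
    Gaussian mass error and (with probability ``p_shift``) an exact ±1 Da
    shift. The precursor mass is the window mass plus water.
    """
    rng = np.random.default_rng(config.seed)
    n = len(protein)
    min_window = config.min_window if config.min_window is not None else n
    min_window = min(min_window, n)
    truth = GroundTruth(protein=protein)
    spectra = []
    for s in range(config.n_spectra):
        wlen = int(rng.integers(min_window, n + 1))
        wstart = int(rng.integers(0, n - wlen + 1))
        window = protein[wstart : wstart + wlen]
        prefixes = _prefix_masses(window)
        precursor = float(prefixes[-1]) + WATER
        peaks = []
        for i in range(wlen - 1):  # interior cleavage sites
            if rng.random() >= config.coverage:
                continue
            mass = float(prefixes[i]) + float(rng.normal(0.0, config.mass_error_sd))
            if config.p_shift and rng.random() < config.p_shift:
                mass += 1.0 if rng.random() < 0.5 else -1.0
            if config.intensity_model == "lognormal":
                intensity = float(rng.lognormal(0.0, config.intensity_sigma))
            else:
                intensity = float(rng.uniform(0.5, 1.5))
            if mass > 0:
                peaks.append(Peak(mass, intensity))
        spectra.append(
            DeconvolutedSpectrum(
                spectrum_id=f"sim{s}", precursor_mass=precursor, peaks=peaks
            )
        )
        truth.windows.append((wstart, wstart + wlen))
    return spectra, truth


def simulate_fragment_strings(
    protein: str, config: SimulationConfig
) -> tuple[list[str], GroundTruth]:
    """Cut non-overlapping fragment strings with known separating substrings.

    Fragments of the configured lengths are placed left to right with the
    configured gaps, starting at a random feasible position; each emitted
    string is reversed with probability ``flip_probability``. True
    separating masses are the residue-mass sums of the gap substrings.
    """
    rng = np.random.default_rng(config.seed + 1)
    total = sum(config.fragment_lengths) + sum(config.gap_lengths)
    slack = len(protein) - total
    if slack < 0:
        raise ValueError(
            f"fragments + gaps ({total} residues) exceed protein length {len(protein)}"
        )
    start = int(rng.integers(0, slack + 1))
    truth = GroundTruth(protein=protein)
    strings = []
    pos = start
    for idx, flen in enumerate(config.fragment_lengths):
        frag = protein[pos : pos + flen]
        flipped = bool(rng.random() < config.flip_probability)
        strings.append(reverse(frag) if flipped else frag)
        truth.fragment_positions.append((pos, pos + flen))
        truth.fragment_reversed.append(flipped)
        pos += flen
        if idx < len(config.gap_lengths):
            gap = protein[pos : pos + config.gap_lengths[idx]]
            truth.separating_strings.append(gap)
            truth.separating_masses.append(sequence_mass(gap))
            pos += config.gap_lengths[idx]
    return strings, truth


@dataclass(frozen=True)
class DeNovoString:
    """A short de novo string obtained by gluing overlapping tags."""

    sequence: str
    offset: float


def glue_tags_to_string(
    t1: Tag, t2: Tag, params: Params | None = None
) -> Optional[DeNovoString]:
    """Glue two k-tags that overlap by k-1 residues into a (k+1)-mer.

    Succeeds when ``t2``'s sequence continues ``t1``'s by one residue and
    ``t2``'s offset exceeds ``t1``'s by the mass of ``t1``'s first residue
    (within ``2 * epsilon``); the merged string inherits the smallest
    contributing offset. Returns ``None`` on any mismatch.
    """
    params = params or Params()
    k = params.k
    if len(t1.sequence) != k or len(t2.sequence) != k:
        raise ValueError(f"both tags must have length k={k}")
    if t1.sequence[1:] != t2.sequence[:-1]:
        return None
    expected = residue_mass(t1.sequence[0])
    if abs((t2.offset - t1.offset) - expected) > 2 * params.epsilon:
        return None
    return DeNovoString(
        sequence=t1.sequence + t2.sequence[-1],
        offset=min(t1.offset, t2.offset),
    )
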