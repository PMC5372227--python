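"""Deconvoluted spectra: the msalign reader and preprocessing.

Input spectra are assumed to be already deisotoped and charge-state
deconvoluted (e.g. by MS-Deconv): every peak is a neutral monoisotopic
fragment mass. Preprocessing removes water-loss ions and reflects each peak
about the precursor mass so that prefix- and suffix-type ion series
reinforce each other in the spectrum graph.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path as _Path
from typing import Iterable, Iterator, TextIO

from .chem import WATER
from .params import Params

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "DeconvolutedSpectrum",
    "read_msalign",
    "write_msalign",
    "read_peak_list",
    "remove_water_loss",
    "reflect_peaks",
    "preprocess",
]

#: Two peaks closer than this (Da) are merged after reflection, keeping the
#: higher intensity. Tight enough not to merge real neighbours.
MERGE_TOLERANCE = 1e-5


@dataclass(frozen=True)
class Peak:
    """Neutral monoisotopic fragment mass with an abundance."""

    mass: float
    intensity: float = 1.0
    reflected: bool = False

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"peak mass must be positive, got {self.mass}")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class DeconvolutedSpectrum:
    """A deconvoluted MS/MS spectrum: neutral fragment masses + precursor mass."""

    spectrum_id: str
    precursor_mass: float | None
    peaks: list[Peak] = field(default_factory=list)
    activation: str | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mass)

    def masses(self) -> list[float]:
        return [p.mass for p in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------------------
# I/O


def _parse_msalign_blocks(handle: TextIO) -> Iterator[tuple[dict, list, int]]:
    header: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    in_block = False
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            in_block, header, peaks = True, {}, []
            continue
        if line == "END IONS":
            if in_block:
                yield header, peaks, lineno
            in_block = False
            continue
        if not in_block:
            continue
        if "=" in line:
            key, _, value = line.partition("=")
            header[key.strip().upper()] = value.strip()
        else:
            fields = line.replace("\t", " ").split()
            try:
                mass = float(fields[0])
                intensity = float(fields[1]) if len(fields) > 1 else 1.0
            except (ValueError, IndexError):
                raise ValueError(
                    f"malformed peak line {lineno}: {line!r}"
                ) from None
            peaks.append((mass, intensity))


def read_msalign(path: str | _Path) -> list[DeconvolutedSpectrum]:
    """Read an msalign file (BEGIN IONS/END IONS blocks) into spectra.

    Each block carries ``ID``/``SCANS`` and ``PRECURSOR_MASS`` headers and one
    ``mass <tab> intensity <tab> charge`` line per peak (the charge column is
    ignored — masses are already neutral). Blocks without a precursor mass
    are skipped with a warning; an unparsable peak line raises ``ValueError``
    naming the line number.
    """
    spectra: list[DeconvolutedSpectrum] = []
    n_skipped = 0
    with open(path) as handle:
        for header, peak_tuples, lineno in _parse_msalign_blocks(handle):
            sid = header.get("ID") or header.get("SCANS") or f"block@{lineno}"
            prec = header.get("PRECURSOR_MASS")
            if prec is None:
                logger.warning("spectrum %s has no precursor mass; skipped", sid)
                n_skipped += 1
                continue
            spectra.append(
                DeconvolutedSpectrum(
                    spectrum_id=str(sid),
                    precursor_mass=float(prec),
                    peaks=[Peak(m, i) for m, i in peak_tuples],
                    activation=header.get("ACTIVATION"),
                )
            )
    logger.info("read %d spectra (%d skipped) from %s", len(spectra), n_skipped, path)
    return spectra


def write_msalign(spectra: Iterable[DeconvolutedSpectrum], path: str | _Path) -> None:
    """Write spectra in the msalign block dialect understood by read_msalign."""
    with open(path, "w") as out:
        for spec in spectra:
            out.write("BEGIN IONS\n")
            out.write(f"ID={spec.spectrum_id}\n")
            if spec.activation:
                out.write(f"ACTIVATION={spec.activation}\n")
            if spec.precursor_mass is not None:
                out.write(f"PRECURSOR_MASS={spec.precursor_mass:.5f}\n")
            for p in spec.peaks:
                out.write(f"{p.mass:.5f}\t{p.intensity:.2f}\t1\n")
            out.write("END IONS\n")


def read_peak_list(
    path: str | _Path, precursor_mass: float, spectrum_id: str = "peaklist"
) -> DeconvolutedSpectrum:
    """Read a plain two-column ``mass intensity`` text file as one spectrum."""
    peaks = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            peaks.append(Peak(float(fields[0]), float(fields[1]) if len(fields) > 1 else 1.0))
    return DeconvolutedSpectrum(spectrum_id, precursor_mass, peaks)


# ---------------------------------------------------------------------------
# Preprocessing


def remove_water_loss(spec: DeconvolutedSpectrum, tol: float = 0.008) -> DeconvolutedSpectrum:
    """Eliminate water-loss ions.

    A peak ``p`` is removed when some peak ``q`` with
    ``mass(q) - mass(p)`` within *tol* of the water mass is at least as
    intense as ``p``; the parent ``q`` is kept. Removing a peak more intense
    than its putative parent would destroy signal, so such pairs are left
    alone.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    masses = spec.masses()
    keep = []
    for p in spec.peaks:
        target = p.mass + WATER
        lo = bisect_left(masses, target - tol)
        hi = bisect_right(masses, target + tol)
        is_loss = any(spec.peaks[j].intensity >= p.intensity for j in range(lo, hi))
        if not is_loss:
            keep.append(p)
    return replace(spec, peaks=keep)


def reflect_peaks(spec: DeconvolutedSpectrum) -> DeconvolutedSpectrum:
    """Add, for every peak, its reflection about the precursor mass.

    The reflected peak has mass ``precursor_mass - mass`` and the same
    intensity, and is flagged; reflections with non-positive mass are
    discarded. Duplicate masses (within 1e-5 Da) are merged keeping the
    higher intensity, preferring the original (non-reflected) peak on ties.
    No ion-type constant is applied: any constant common to a pair of tags
    cancels in their offset difference downstream.
    """
    if spec.precursor_mass is None:
        raise ValueError(f"spectrum {spec.spectrum_id} has no precursor mass")
    mirrored = [
        Peak(spec.precursor_mass - p.mass, p.intensity, reflected=True)
        for p in spec.peaks
        if spec.precursor_mass - p.mass > 0
    ]
    merged: list[Peak] = []
    for p in sorted(spec.peaks + mirrored, key=lambda q: (q.mass, q.reflected)):
        if merged and p.mass - merged[-1].mass <= MERGE_TOLERANCE:
            if p.intensity > merged[-1].intensity:
                merged[-1] = p
        else:
            merged.append(p)
    return replace(spec, peaks=merged)


def preprocess(spec: DeconvolutedSpectrum, params: Params | None = None) -> DeconvolutedSpectrum:
    """Water-loss elimination followed by peak reflection.

    Losses are removed on the original peaks first so that a loss artifact is
    not duplicated by its own reflection.
    """
    params = params or Params()
    out = spec
    if params.remove_water_losses:
        out = remove_water_loss(out, tol=2 * params.epsilon)
    if params.reflect:
        out = reflect_peaks(out)
    return out
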