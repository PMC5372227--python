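"""Gap-mass estimation from a string-convolution output.

The offset differences produced by string convolution are scaled by
``10**h`` and rounded (scaled differences), and independently rounded to the
nearest integer Da (binned differences). Candidate gaps are binned
differences within ``[0, Gmax]`` of multiplicity at least ``Bmin``; among
those of maximal multiplicity the one with the best three-bin score
``Score(db) = mu(db) + mu(db-1) + mu(db+1)`` wins (this absorbs the
well-known +/-1 Da deconvolution errors), and the winning bin's modal
scaled difference, divided back by ``10**h``, is the reported estimate. The
estimate is accepted only if the contributing tags jointly cover enough of
both strings (the ``Amin`` support rule, with its neighbour-bin fallback).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

from .convolution import OffsetDifferenceSpectrum, string_convolution
from .params import Params
from .tagging import TagSet

__all__ = [
    "BinnedHistogram",
    "GapEstimate",
    "SupportResult",
    "round_half_away",
    "bin_differences",
    "refine_bin",
    "score_binned",
    "select_candidate",
    "support_check",
    "estimate_gap",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


@dataclass
class BinnedHistogram:
    """Scaled and binned offset differences with multiplicities and back-links."""

    h: int
    #: scaled difference (round(d * 10**h)) -> multiplicity
    scaled: dict[int, int] = field(default_factory=dict)
    #: binned difference (integer Da) -> multiplicity
    binned: dict[int, int] = field(default_factory=dict)
    #: binned -> {scaled -> multiplicity}; each scaled value maps to one bin
    scaled_by_bin: dict[int, dict[int, int]] = field(default_factory=dict)
    #: binned -> (window positions supported in s1, in s2); only filled when
    #: the convolution carried provenance
    support: dict[int, tuple[set[int], set[int]]] = field(default_factory=dict)

    def total_multiplicity(self) -> int:
        return sum(self.binned.values())


def bin_differences(conv: OffsetDifferenceSpectrum, h: int = 4) -> BinnedHistogram:
    """Scale (by ``10**h``) and bin (to integer Da) the raw differences.

    Negative differences are allowed at this stage; the non-negativity
    filter belongs to candidate selection.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    hist = BinnedHistogram(h=h)
    scale = 10.0**h
    for d, m in conv.counts.items():
        ds = round_half_away(d * scale)
        db = round_half_away(ds / scale)
        hist.scaled[ds] = hist.scaled.get(ds, 0) + m
        hist.binned[db] = hist.binned.get(db, 0) + m
        per_bin = hist.scaled_by_bin.setdefault(db, {})
        per_bin[ds] = per_bin.get(ds, 0) + m
        contribs = conv.provenance.get(d)
        if contribs:
            sup = hist.support.setdefault(db, (set(), set()))
            for c in contribs:
                if c.pos1 is not None:
                    sup[0].add(c.pos1)
                if c.pos2 is not None:
                    sup[1].add(c.pos2)
    return hist


def refine_bin(hist: BinnedHistogram, db: int, h: int) -> float:
    """Modal scaled difference of bin *db*, on the Da scale (ties: smallest)."""
    per_bin = hist.scaled_by_bin[db]
    best_ds = min(per_bin, key=lambda ds: (-per_bin[ds], ds))
    return best_ds / 10.0**h


def score_binned(db: int, hist: BinnedHistogram) -> int:
    """Three-bin score ``mu(db) + mu(db-1) + mu(db+1)``; absent bins count 0."""
    return (
        hist.binned.get(db, 0)
        + hist.binned.get(db - 1, 0)
        + hist.binned.get(db + 1, 0)
    )


def select_candidate(
    hist: BinnedHistogram, params: Params | None = None
) -> Optional[tuple[float, int]]:
    """Pick the candidate gap estimate ``(d_hat, d_hat_binned)`` from a histogram.

    Bins are filtered to ``0 <= db <= Gmax`` and ``mu >= Bmin``; among the
    filtered bins of maximal multiplicity the top three-bin score wins (ties:
    smallest bin); within the winning bin the scaled difference of highest
    multiplicity (ties: smallest) is refined into the estimate. Returns
    ``None`` when no bin survives the filters.
    """
    params = params or Params()
    eligible = [
        db
        for db, mu in hist.binned.items()
        if 0 <= db <= params.g_max and mu >= params.b_min
    ]
    if not eligible:
        return None
    bmax = max(hist.binned[db] for db in eligible)
    at_bmax = [db for db in eligible if hist.binned[db] == bmax]
    winner = min(at_bmax, key=lambda db: (-score_binned(db, hist), db))
    return refine_bin(hist, winner, hist.h), winner


@dataclass(frozen=True)
class SupportResult:
    accepted: bool
    count1: int
    count2: int
    via_neighbor: Optional[int] = None  # neighbour bin that rescued acceptance


def _counts(hist: BinnedHistogram, db: int) -> tuple[int, int]:
    sup = hist.support.get(db)
    return (len(sup[0]), len(sup[1])) if sup else (0, 0)


def support_check(
    db: int, hist: BinnedHistogram, params: Params | None = None
) -> SupportResult:
    """Amin support rule on the tags contributing to bin *db*.

    With ``m* = Amin - k + 1``: accept when both strings have at least ``m*``
    distinct supporting tag windows, or one has ``m* + 1`` and the other
    ``m* - 1`` (either assignment). Failing that, when both have at least
    ``m* - 1``, accept if a neighbouring bin (``db - 1`` or ``db + 1``)
    occurred and is supported by at least ``m* - 1`` and ``m*`` windows for
    the two strings (either assignment).
    """
    params = params or Params()
    m = params.m_star
    n1, n2 = _counts(hist, db)

    def primary(a: int, b: int) -> bool:
        return (a >= m and b >= m) or (a >= m + 1 and b >= m - 1) or (b >= m + 1 and a >= m - 1)

    if primary(n1, n2):
        return SupportResult(True, n1, n2)
    if n1 >= m - 1 and n2 >= m - 1:
        for nb in (db - 1, db + 1):
            if nb not in hist.binned:
                continue
            c1, c2 = _counts(hist, nb)
            if (c1 >= m - 1 and c2 >= m) or (c1 >= m and c2 >= m - 1):
                return SupportResult(True, n1, n2, via_neighbor=nb)
    return SupportResult(False, n1, n2)


@dataclass(frozen=True)
class GapEstimate:
    """An accepted gap-mass estimate between two fragment strings."""

    estimate: float  # d_hat, Da
    binned: int  # d_hat rounded to integer Da
    score: int  # three-bin score of the accepted bin
    support1: int  # distinct supporting tag windows in s1
    support2: int  # distinct supporting tag windows in s2
    multiplicity: int = 0  # mu of the accepted bin

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "binned": self.binned,
            "score": self.score,
            "support": [self.support1, self.support2],
            "multiplicity": self.multiplicity,
        }


def estimate_gap(
    s1: str,
    s2: str,
    tagset: TagSet,
    params: Params | None = None,
    report: dict | None = None,
) -> Optional[GapEstimate]:
    """Estimate the mass of the gap separating *s1* (before) and *s2* (after).

    Runs string convolution, binning, candidate selection and the support
    check; returns the accepted estimate or ``None`` when the hypothesis
    that the two strings are ordered disjoint fragments of one protein is
    rejected. If *report* is given, it is filled with an auditable account
    of the decision.
    """
    params = params or Params()
    conv = string_convolution(s1, s2, tagset, params)
    hist = bin_differences(conv, params.h)
    candidate = select_candidate(hist, params)
    if report is not None:
        report.update(
            {
                "s1": s1,
                "s2": s2,
                "total_multiplicity": hist.total_multiplicity(),
                "candidate": None,
                "accepted": False,
            }
        )
    if candidate is None:
        return None
    d_hat, db = candidate
    sup = support_check(db, hist, params)
    if report is not None:
        report["candidate"] = {
            "estimate": d_hat,
            "binned": db,
            "multiplicity": hist.binned[db],
            "score": score_binned(db, hist),
            "support": [sup.count1, sup.count2],
            "via_neighbor": sup.via_neighbor,
        }
    if not sup.accepted:
        return None
    est = GapEstimate(
        estimate=d_hat,
        binned=db,
        score=score_binned(db, hist),
        support1=sup.count1,
        support2=sup.count2,
        multiplicity=hist.binned[db],
    )
    if report is not None:
        report["accepted"] = True
    return est


def write_report(report: dict, path) -> None:
    """Dump a gap-estimation report as JSON."""
    with open(path, "w") as out:
        json.dump(report, out, indent=2)
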