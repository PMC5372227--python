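"""Tag convolution and its generalization to amino-acid strings.

Tag convolution of two k-mers collects the offset differences of all tag
pairs matching them, with multiplicities. String convolution ``T(s1, s2)``
iterates over all k-mer pairs of the two strings, shifting each tag
convolution so that a pair of tags truly generated by two disjoint
occurrences of ``s1`` (before) and ``s2`` (after) inside one protein
contributes exactly the mass of the subsequence separating them; the
reversed-copies route ``tau(rev(s2), rev(s1))`` is accumulated analogously
and merged, which makes the result invariant under reversing and swapping
the two strings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path as _Path
from typing import Iterator, NamedTuple

from .chem import reverse, sequence_mass
from .params import Params
from .tagging import TagSet

__all__ = [
    "Contribution",
    "OffsetDifferenceSpectrum",
    "tag_convolution",
    "string_convolution",
    "validate_sequence_position",
    "PositionCheck",
]


class Contribution(NamedTuple):
    """Provenance of one offset difference: source spectrum and the k-mer
    window start positions (0-based) in s1 and s2 it supports."""

    spectrum_id: str
    pos1: int | None
    pos2: int | None


class OffsetDifferenceSpectrum:
    """Multiset of offset differences with multiplicities and provenance.

    Raw differences are kept exact (no rounding); grouping only merges
    float-identical values. Binning to scaled/integer resolution is a
    separate, later step.
    """

    def __init__(self) -> None:
        self.counts: dict[float, int] = {}
        self.provenance: dict[float, list[Contribution]] = {}

    def add(self, d: float, contribution: Contribution | None = None, m: int = 1) -> None:
        self.counts[d] = self.counts.get(d, 0) + m
        if contribution is not None:
            self.provenance.setdefault(d, []).append(contribution)

    def items(self) -> list[tuple[float, int]]:
        return sorted(self.counts.items())

    def total_multiplicity(self) -> int:
        return sum(self.counts.values())

    def shift(self, delta: float) -> "OffsetDifferenceSpectrum":
        out = OffsetDifferenceSpectrum()
        for d, m in self.counts.items():
            out.counts[d + delta] = out.counts.get(d + delta, 0) + m
        for d, contribs in self.provenance.items():
            out.provenance.setdefault(d + delta, []).extend(contribs)
        return out

    def merge(self, other: "OffsetDifferenceSpectrum") -> "OffsetDifferenceSpectrum":
        out = OffsetDifferenceSpectrum()
        for src in (self, other):
            for d, m in src.counts.items():
                out.counts[d] = out.counts.get(d, 0) + m
            for d, contribs in src.provenance.items():
                out.provenance.setdefault(d, []).extend(contribs)
        return out

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OffsetDifferenceSpectrum):
            return NotImplemented
        return self.counts == other.counts

    def to_tsv(self, path: str | _Path) -> None:
        with open(path, "w", newline="") as out:
            writer = csv.writer(out, delimiter="\t")
            writer.writerow(["difference", "multiplicity"])
            for d, m in self.items():
                writer.writerow([f"{d:.6f}", m])


def _tag_pairs(
    w1: str, w2: str, tagset: TagSet, same_spectrum_only: bool
) -> Iterator[tuple[str, float, float]]:
    """Yield (spectrum_id of t2, o(t1), o(t2)) over tag pairs matching (w1, w2)."""
    by_spec_1 = tagset.by_sequence(w1)
    by_spec_2 = tagset.by_sequence(w2)
    if not by_spec_1 or not by_spec_2:
        return
    if same_spectrum_only:
        for sid, offsets1 in by_spec_1.items():
            offsets2 = by_spec_2.get(sid)
            if not offsets2:
                continue
            for o1 in offsets1:
                for o2 in offsets2:
                    yield sid, o1, o2
    else:
        all2 = [(sid, o) for sid, offs in by_spec_2.items() for o in offs]
        for offsets1 in by_spec_1.values():
            for o1 in offsets1:
                for sid2, o2 in all2:
                    yield sid2, o1, o2


def tag_convolution(
    w1: str,
    w2: str,
    tagset: TagSet,
    same_spectrum_only: bool = True,
) -> OffsetDifferenceSpectrum:
    """Offset differences ``o(t2) - o(t1)`` over all tag pairs matching (w1, w2).

    With *same_spectrum_only* (the top-down default) only tags originating
    from the same spectrum may pair. Raw differences are recorded exactly.
    """
    if len(w1) != len(w2):
        raise ValueError("tag convolution requires k-mers of equal length")
    out = OffsetDifferenceSpectrum()
    for sid, o1, o2 in _tag_pairs(w1, w2, tagset, same_spectrum_only):
        out.add(o2 - o1, Contribution(sid, None, None))
    return out


def _accumulate_route(
    out: OffsetDifferenceSpectrum,
    a: str,
    b: str,
    tagset: TagSet,
    params: Params,
    pos_map,
) -> None:
    """Accumulate tau(a, b): all k-mer pairs of a and b, each shifted by
    -Mass(a-suffix from the k-mer start) - Mass(b-prefix before the k-mer)."""
    k = params.k
    for i in range(len(a) - k + 1):
        shift_a = -sequence_mass(a[i:])
        wa = a[i : i + k]
        for j in range(len(b) - k + 1):
            delta = shift_a - sequence_mass(b[:j])
            wb = b[j : j + k]
            for sid, o1, o2 in _tag_pairs(wa, wb, tagset, params.same_spectrum_only):
                pos1, pos2 = pos_map(i, j)
                out.add(o2 - o1 + delta, Contribution(sid, pos1, pos2))


def string_convolution(
    s1: str, s2: str, tagset: TagSet, params: Params | None = None
) -> OffsetDifferenceSpectrum:
    """T(s1, s2): shifted tag convolutions over all k-mer pairs, both routes.

    The direct route pairs k-mers of ``s1`` with k-mers of ``s2``; the
    reversed route pairs k-mers of ``rev(s2)`` with k-mers of ``rev(s1)``
    (picking up tags read off suffix-type ion series). Both are merged by
    summing multiplicities of exactly-equal raw differences. Provenance maps
    every contribution back to window positions in the original s1 and s2.
    """
    params = params or Params()
    k = params.k
    if len(s1) < k or len(s2) < k:
        raise ValueError(f"both strings must have length >= k={k}")
    out = OffsetDifferenceSpectrum()
    _accumulate_route(out, s1, s2, tagset, params, lambda i, j: (i, j))
    e, f = len(s1), len(s2)
    _accumulate_route(
        out,
        reverse(s2),
        reverse(s1),
        tagset,
        params,
        lambda i, j: (e - j - k, f - i - k),
    )
    return out


class PositionCheck(NamedTuple):
    """Outcome of the single-position de novo sequence-validation check."""

    top_difference: float  # refined estimate from the top bin's modal scaled value
    top_binned: int
    multiplicity: int
    runner_up_multiplicity: int
    margin: float  # multiplicity / runner-up multiplicity (inf if unrivaled)


def validate_sequence_position(
    s: str, i: int, tagset: TagSet, params: Params | None = None
) -> PositionCheck:
    """Check one position of a candidate de novo sequence.

    Computes ``T(s[:i-1], s[i:])`` (1-based *i*, which must satisfy
    ``k < i <= n - k``), bins the differences, and reports the most frequent
    binned difference together with the ratio of its multiplicity to the
    runner-up's. For a correct sequence the residue mass of ``s[i]`` should
    clearly dominate; the caller chooses the cutoff.
    """
    from .gap_estimation import bin_differences, refine_bin

    params = params or Params()
    n = len(s)
    if not (params.k < i <= n - params.k):
        raise ValueError(
            f"position {i} out of validatable range ({params.k} < i <= {n - params.k})"
        )
    conv = string_convolution(s[: i - 1], s[i:], tagset, params)
    hist = bin_differences(conv, params.h)
    if not hist.binned:
        raise ValueError("no offset differences: the tag set does not cover the string")
    ranked = sorted(hist.binned.items(), key=lambda kv: (-kv[1], kv[0]))
    top_db, top_mu = ranked[0]
    runner = ranked[1][1] if len(ranked) > 1 else 0
    return PositionCheck(
        top_difference=refine_bin(hist, top_db, params.h),
        top_binned=top_db,
        multiplicity=top_mu,
        runner_up_multiplicity=runner,
        margin=top_mu / runner if runner else float("inf"),
    )
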