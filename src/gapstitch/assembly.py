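"""Iterative assembly of fragment strings into gapped paths.

A gapped path alternates sequence fragments (each possibly reversed
relative to its input string) and gaps annotated with estimated masses.
Two paths are joined by trying, for each of the four orientation
combinations in turn, to append the second to the first, then to embed the
second into a sufficiently large gap of the first, then the first into the
second; the first success wins and the remaining combinations are never
examined.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path as _Path
from typing import Iterable, Optional

from Bio import SeqIO

from .chem import reverse as _rev
from .chem import sequence_mass
from .gap_estimation import GapEstimate, estimate_gap
from .params import Params
from .tagging import TagSet

logger = logging.getLogger(__name__)

__all__ = [
    "Fragment",
    "Gap",
    "GappedPath",
    "try_append",
    "try_embed",
    "join_pair",
    "assemble",
    "read_fragment_strings",
    "render_text",
]


@dataclass(frozen=True)
class Fragment:
    """A sequence fragment within a gapped path, as oriented in the path."""

    sequence: str
    reversed_: bool = False
    source_id: str = ""
    offset: float = 0.0  # mass offset of the fragment start from the path origin

    @property
    def mass(self) -> float:
        return sequence_mass(self.sequence)


@dataclass(frozen=True)
class Gap:
    """An estimated gap between two fragments of a gapped path."""

    estimate: float
    binned: int
    score: int = 0
    support1: int = 0
    support2: int = 0
    derived: bool = False  # remainder gap created by embedding, not estimated

    @classmethod
    def from_estimate(cls, est: GapEstimate) -> "Gap":
        return cls(est.estimate, est.binned, est.score, est.support1, est.support2)


@dataclass
class GappedPath:
    """Alternating fragments and gaps; starts and ends with a fragment."""

    segments: list[Fragment | Gap] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_alternation()
        self._recompute_offsets()

    def _check_alternation(self) -> None:
        if not self.segments or not isinstance(self.segments[0], Fragment):
            raise ValueError("a gapped path must start with a fragment")
        if not isinstance(self.segments[-1], Fragment):
            raise ValueError("a gapped path must end with a fragment")
        for a, b in zip(self.segments, self.segments[1:]):
            if isinstance(a, Gap) and isinstance(b, Gap):
                raise ValueError("two adjacent gaps are not allowed")

    def _recompute_offsets(self) -> None:
        offset = 0.0
        out: list[Fragment | Gap] = []
        for seg in self.segments:
            if isinstance(seg, Fragment):
                out.append(replace(seg, offset=offset))
                offset += seg.mass
            else:
                out.append(seg)
                offset += seg.estimate
        self.segments = out

    @property
    def fragments(self) -> list[Fragment]:
        return [s for s in self.segments if isinstance(s, Fragment)]

    @property
    def gaps(self) -> list[Gap]:
        return [s for s in self.segments if isinstance(s, Gap)]

    @property
    def total_mass(self) -> float:
        """Sum of fragment masses and gap estimates."""
        return sum(f.mass for f in self.fragments) + sum(g.estimate for g in self.gaps)

    @property
    def first_fragment(self) -> Fragment:
        return self.fragments[0]

    @property
    def last_fragment(self) -> Fragment:
        return self.fragments[-1]

    def reversed_copy(self) -> "GappedPath":
        segs: list[Fragment | Gap] = []
        for seg in reversed(self.segments):
            if isinstance(seg, Fragment):
                segs.append(
                    Fragment(_rev(seg.sequence), not seg.reversed_, seg.source_id)
                )
            else:
                segs.append(seg)
        return GappedPath(segs)

    @classmethod
    def from_string(cls, sequence: str, source_id: str = "") -> "GappedPath":
        return cls([Fragment(sequence, False, source_id)])

    def to_dict(self) -> dict:
        return {
            "fragments": [
                {
                    "sequence": f.sequence,
                    "reversed": f.reversed_,
                    "source_id": f.source_id,
                    "offset": f.offset,
                    "original": _rev(f.sequence) if f.reversed_ else f.sequence,
                }
                for f in self.fragments
            ],
            "gaps": [
                {
                    "estimate": g.estimate,
                    "binned": g.binned,
                    "score": g.score,
                    "support": [g.support1, g.support2],
                    "derived": g.derived,
                }
                for g in self.gaps
            ],
            "total_mass": self.total_mass,
        }


def render_text(path: GappedPath) -> str:
    """Human-readable rendering, e.g. ``ABC —[1583.842]→ DEF``."""
    parts = []
    for seg in path.segments:
        if isinstance(seg, Fragment):
            parts.append(seg.sequence + ("(rev)" if seg.reversed_ else ""))
        else:
            parts.append(f"—[{seg.estimate:.4f}]→")
    return " ".join(parts)


def _estimate(s1: str, s2: str, tagset: TagSet, params: Params, cache: dict | None):
    if cache is None:
        return estimate_gap(s1, s2, tagset, params)
    key = (s1, s2)
    if key not in cache:
        cache[key] = estimate_gap(s1, s2, tagset, params)
    return cache[key]


def try_append(
    g1: GappedPath,
    g2: GappedPath,
    tagset: TagSet,
    params: Params | None = None,
    cache: dict | None = None,
) -> Optional[GappedPath]:
    """Append *g2* after *g1* if a gap between their facing fragments is accepted."""
    params = params or Params()
    est = _estimate(
        g1.last_fragment.sequence, g2.first_fragment.sequence, tagset, params, cache
    )
    if est is None:
        return None
    return GappedPath(g1.segments + [Gap.from_estimate(est)] + g2.segments)


def _ppm_tol(a: float, b: float, ppm: float) -> float:
    return ppm * 1e-6 * max(abs(a), abs(b))


def try_embed(
    g1: GappedPath,
    g2: GappedPath,
    tagset: TagSet,
    params: Params | None = None,
    cache: dict | None = None,
) -> Optional[GappedPath]:
    """Embed *g2* into the first sufficiently large gap of *g1* that accepts it.

    A gap can accommodate *g2* when its estimate is at least the total mass
    of *g2* (fragments plus internal gaps), up to the ppm tolerance. The
    leading sub-gap is estimated between the fragment preceding the host gap
    and the first fragment of *g2*; the placement is rejected when the tail
    of *g2* would overlap the fragment following the host gap (offset
    comparison at ``eps_abs`` ppm). The remainder becomes a trailing
    sub-gap, clamped at zero when within tolerance.
    """
    params = params or Params()
    g2_mass = g2.total_mass
    for idx, seg in enumerate(g1.segments):
        if not isinstance(seg, Gap):
            continue
        if seg.estimate + _ppm_tol(seg.estimate, g2_mass, params.eps_abs_ppm) < g2_mass:
            continue  # not large enough to accommodate g2
        before: Fragment = g1.segments[idx - 1]  # type: ignore[assignment]
        after: Fragment = g1.segments[idx + 1]  # type: ignore[assignment]
        est = _estimate(
            before.sequence, g2.first_fragment.sequence, tagset, params, cache
        )
        if est is None:
            continue
        # overlap check on mass offsets from g1's origin
        end_of_g2 = before.offset + before.mass + est.estimate + g2_mass
        start_of_after = before.offset + before.mass + seg.estimate
        trailing = start_of_after - end_of_g2
        tol = _ppm_tol(end_of_g2, start_of_after, params.eps_abs_ppm)
        if trailing < -tol:
            continue  # g2's tail would overlap the fragment after the gap
        trailing_gap = Gap(
            estimate=max(trailing, 0.0),
            binned=round(max(trailing, 0.0)),
            derived=True,
        )
        segs = (
            g1.segments[:idx]
            + [Gap.from_estimate(est)]
            + g2.segments
            + [trailing_gap]
            + g1.segments[idx + 1 :]
        )
        return GappedPath(segs)
    return None


def join_pair(
    g1: GappedPath,
    g2: GappedPath,
    tagset: TagSet,
    params: Params | None = None,
    cache: dict | None = None,
) -> Optional[GappedPath]:
    """Try the four orientation combinations; first successful merge wins.

    For each combination (direct/direct, direct/reversed, reversed/direct,
    reversed/reversed) the order of attempts is: append the second path to
    the first, embed the second into the first, embed the first into the
    second. Later combinations are never evaluated after a success.
    """
    params = params or Params()
    combos = (
        (g1, g2),
        (g1, g2.reversed_copy()),
        (g1.reversed_copy(), g2),
        (g1.reversed_copy(), g2.reversed_copy()),
    )
    for a, b in combos:
        merged = try_append(a, b, tagset, params, cache)
        if merged is None:
            merged = try_embed(a, b, tagset, params, cache)
        if merged is None:
            merged = try_embed(b, a, tagset, params, cache)
        if merged is not None:
            return merged
    return None


def assemble(
    strings: Iterable[str],
    tagset: TagSet,
    params: Params | None = None,
    ids: Iterable[str] | None = None,
) -> list[GappedPath]:
    """Iteratively merge input fragment strings into gapped paths.

    Paths are initialized one per input string and scanned pairwise in
    deterministic order (ascending index pairs); the scan restarts after
    every successful merge and stops when a full scan yields no merge.
    Strings shorter than ``k`` are passed through unmerged with a warning.
    """
    params = params or Params()
    strings = list(strings)
    ids = list(ids) if ids is not None else [f"s{i}" for i in range(len(strings))]
    if len(ids) != len(strings):
        raise ValueError("ids must match strings one-to-one")

    paths: list[GappedPath] = []
    short: list[GappedPath] = []
    for s, sid in zip(strings, ids):
        p = GappedPath.from_string(s, sid)
        if len(s) < params.k:
            logger.warning("string %s shorter than k=%d; passed through", sid, params.k)
            short.append(p)
        else:
            paths.append(p)

    cache: dict = {}
    merged_any = True
    while merged_any:
        merged_any = False
        for i in range(len(paths)):
            for j in range(i + 1, len(paths)):
                merged = join_pair(paths[i], paths[j], tagset, params, cache)
                if merged is not None:
                    paths[i] = merged
                    del paths[j]
                    merged_any = True
                    break
            if merged_any:
                break
    return paths + short


def coverage_percent(n_covered: int, n_total: int) -> float:
    """Percentage of a protein's residues covered by a gapped string, to 0.1%."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_covered / n_total, 1)


def read_fragment_strings(path: str | _Path) -> tuple[list[str], list[str]]:
    """Read fragment strings from FASTA or one-per-line text.

    Returns ``(strings, ids)``; for plain text the ids are line numbers.
    """
    path = _Path(path)
    with open(path) as handle:
        first = handle.read(1)
    if first == ">":
        records = list(SeqIO.parse(str(path), "fasta"))
        return [str(r.seq).upper() for r in records], [r.id for r in records]
    strings, ids = [], []
    with open(path) as handle:
        for n, line in enumerate(handle, start=1):
            s = line.strip().upper()
            if s:
                strings.append(s)
                ids.append(f"line{n}")
    return strings, ids


def paths_to_json(paths: Iterable[GappedPath], path: str | _Path) -> None:
    with open(path, "w") as out:
        json.dump([p.to_dict() for p in paths], out, indent=2)
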