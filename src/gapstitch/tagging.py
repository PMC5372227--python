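"""Spectrum graphs and k-tag generation.

A spectrum graph has one vertex per peak, scored by the peak intensity, and
a directed edge between two peaks whenever their mass difference matches a
residue mass within ``2 * epsilon``. From each weakly connected component a
single directed path maximizing the sum of vertex scores is extracted
(exact dynamic program over the DAG), and every window of ``k`` consecutive
edges on such a path yields a k-tag: the window's residue string plus an
offset equal to the mass of the window's first peak.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path as _Path
from typing import Iterable, Iterator

import numpy as np

from .chem import RESIDUE_MASSES
from .params import Params
from .spectra import DeconvolutedSpectrum, preprocess

__all__ = [
    "SpectrumGraph",
    "GraphPath",
    "Tag",
    "TagSet",
    "build_graph",
    "optimal_paths",
    "tags_from_path",
    "generate_tags",
]

# I dropped so an isobaric I/L spacing produces one canonical edge labeled L.
_EDGE_RESIDUES = sorted(
    ((aa, m) for aa, m in RESIDUE_MASSES.items() if aa != "I"), key=lambda t: t[0]
)


@dataclass
class SpectrumGraph:
    """DAG over the peaks of one spectrum; edges go from lower to higher mass."""

    spectrum_id: str
    masses: list[float]
    scores: list[float]
    #: (u, w, residue label); u < w by construction, sorted for determinism.
    edges: list[tuple[int, int, str]]

    def in_edges(self) -> dict[int, list[tuple[int, str]]]:
        incoming: dict[int, list[tuple[int, str]]] = defaultdict(list)
        for u, w, label in self.edges:
            incoming[w].append((u, label))
        return incoming


@dataclass
class GraphPath:
    """A directed path through a spectrum graph, with its edge residue labels."""

    spectrum_id: str
    peak_masses: list[float]
    labels: list[str]

    def __len__(self) -> int:  # length in edges
        return len(self.labels)


@dataclass(frozen=True)
class Tag:
    """A k-tag: residue string + mass offset of its leftmost peak."""

    sequence: str
    offset: float
    spectrum_id: str = ""

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("tag offset must be non-negative")


class TagSet:
    """Tags indexed by residue string and grouped by source spectrum."""

    def __init__(self, tags: Iterable[Tag] = ()) -> None:
        self.tags: list[Tag] = []
        # sequence -> spectrum_id -> offsets
        self._index: dict[str, dict[str, list[float]]] = {}
        for t in tags:
            self.add(t)

    def add(self, tag: Tag) -> None:
        self.tags.append(tag)
        self._index.setdefault(tag.sequence, {}).setdefault(tag.spectrum_id, []).append(
            tag.offset
        )

    def kmers(self) -> set[str]:
        """K(T): the set of distinct tag residue strings."""
        return set(self._index)

    def by_sequence(self, w: str) -> dict[str, list[float]]:
        """spectrum_id -> offsets of tags whose string is *w* (empty if none)."""
        return self._index.get(w, {})

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self) -> Iterator[Tag]:
        return iter(self.tags)

    def to_tsv(self, path: str | _Path) -> None:
        with open(path, "w", newline="") as out:
            writer = csv.writer(out, delimiter="\t")
            writer.writerow(["spectrum_id", "sequence", "offset"])
            for t in self.tags:
                writer.writerow([t.spectrum_id, t.sequence, f"{t.offset:.6f}"])

    @classmethod
    def from_tsv(cls, path: str | _Path) -> "TagSet":
        tags = []
        with open(path) as handle:
            reader = csv.reader(handle, delimiter="\t")
            header = next(reader, None)
            if header and header[0] != "spectrum_id":  # headerless file
                tags.append(Tag(header[1], float(header[2]), header[0]))
            for row in reader:
                if row:
                    tags.append(Tag(row[1], float(row[2]), row[0]))
        return cls(tags)


def build_graph(spec: DeconvolutedSpectrum, epsilon: float = 0.004) -> SpectrumGraph:
    """Construct the spectrum graph of a (preprocessed) spectrum.

    An edge ``u -> w`` labeled with residue ``r`` is created whenever
    ``m(w) - m(u)`` is within ``2 * epsilon`` of the residue mass of ``r``.
    Several residues may label parallel edges if the tolerance admits them;
    the isobaric I/L pair yields a single edge labeled L.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    masses = np.asarray(spec.masses(), dtype=float)
    scores = [p.intensity for p in spec.peaks]
    edges: list[tuple[int, int, str]] = []
    tol = 2.0 * epsilon
    for label, rmass in _EDGE_RESIDUES:
        targets = masses + rmass
        lo = np.searchsorted(masses, targets - tol, side="left")
        hi = np.searchsorted(masses, targets + tol, side="right")
        for u in np.nonzero(hi > lo)[0]:
            for w in range(int(lo[u]), int(hi[u])):
                if w != u:
                    edges.append((int(u), int(w), label))
    edges.sort()
    return SpectrumGraph(spec.spectrum_id, list(map(float, masses)), scores, edges)


def _components(n: int, edges: list[tuple[int, int, str]]) -> list[int]:
    """Union-find roots: weakly connected components (direction-blind)."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, w, _ in edges:
        ru, rw = find(u), find(w)
        if ru != rw:
            parent[max(ru, rw)] = min(ru, rw)
    return [find(v) for v in range(n)]


def optimal_paths(graph: SpectrumGraph) -> list[GraphPath]:
    """One maximum-score directed path per weakly connected component.

    The dynamic program processes vertices in mass order; ties between
    equal-score paths are broken by the smaller starting-peak mass, then
    lexicographically by the edge-label string. Single-vertex components
    yield a length-0 path (discarded by tag derivation downstream).
    """
    n = len(graph.masses)
    if n == 0:
        return []
    incoming = graph.in_edges()
    # best[v]: (score, start_mass, labels tuple, parent vertex, parent label)
    best: list[tuple[float, float, tuple[str, ...], int | None, str | None]] = [
        (graph.scores[v], graph.masses[v], (), None, None) for v in range(n)
    ]
    for v in range(n):
        for u, label in incoming[v]:
            s_u, start_u, labels_u, _, _ = best[u]
            cand = (s_u + graph.scores[v], start_u, labels_u + (label,), u, label)
            cur = best[v]
            if cand[0] > cur[0] or (
                cand[0] == cur[0] and (cand[1], cand[2]) < (cur[1], cur[2])
            ):
                best[v] = cand

    roots = _components(n, graph.edges)
    champion: dict[int, int] = {}
    for v in range(n):
        r = roots[v]
        if r not in champion:
            champion[r] = v
        else:
            c = champion[r]
            if best[v][0] > best[c][0] or (
                best[v][0] == best[c][0]
                and (best[v][1], best[v][2]) < (best[c][1], best[c][2])
            ):
                champion[r] = v

    paths = []
    for v in sorted(champion.values()):
        vertices = [v]
        labels: list[str] = []
        while best[vertices[-1]][3] is not None:
            labels.append(best[vertices[-1]][4])  # type: ignore[arg-type]
            vertices.append(best[vertices[-1]][3])  # type: ignore[arg-type]
        vertices.reverse()
        labels.reverse()
        paths.append(
            GraphPath(graph.spectrum_id, [graph.masses[u] for u in vertices], labels)
        )
    return paths


def tags_from_path(path: GraphPath, k: int) -> list[Tag]:
    """All k-tags of a path: one per window of *k* consecutive edges."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [
        Tag("".join(path.labels[i : i + k]), path.peak_masses[i], path.spectrum_id)
        for i in range(len(path.labels) - k + 1)
    ]


def generate_tags(
    spectra: Iterable[DeconvolutedSpectrum], params: Params | None = None
) -> TagSet:
    """Full tagging pipeline: preprocess, graph, optimal paths, k-tags."""
    params = params or Params()
    tagset = TagSet()
    for spec in spectra:
        prepped = preprocess(spec, params)
        graph = build_graph(prepped, params.epsilon)
        for path in optimal_paths(graph):
            for tag in tags_from_path(path, params.k):
                tagset.add(tag)
    return tagset
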