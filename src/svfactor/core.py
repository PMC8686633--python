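"""Core domain types and the structural-variant matching/merging engine.

Structural variants (SVs) from different pipelines rarely agree to the base
pair, so call sets are compared with a breakpoint-distance predicate: two
records match when they sit on the same contig, are of the same type, and
both their start and end coordinates lie within ``max_dist`` base pairs of
each other.  Multi-call-set merging clusters records by single-linkage
connected components over cross-set matches and annotates every cluster
with a support vector recording which input sets contributed a member.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple, Sequence

log = logging.getLogger(__name__)

#: SV types handled by the pipeline.  Translocations/breakends (BND, TRA)
#: and raw copy-number segments are rejected at parse time.
SV_TYPES = ("DEL", "INS", "DUP", "INV")
_SV_TYPE_SET = frozenset(SV_TYPES)


class FactorKey(NamedTuple):
    """Labels one call set within the sample x center x replicate x mapper
    x postproc factorial design."""

    sample: str
    center: str
    replicate: str
    mapper: str
    postproc: str

    def validate(self) -> "FactorKey":
        if not all(self):
            raise ValueError(f"FactorKey fields must be non-empty: {self}")
        return self

    def label(self) -> str:
        return "|".join(self)


#: Names of the four within-sample factors, in canonical order.
FACTOR_NAMES = ("center", "replicate", "mapper", "postproc")


@dataclass(slots=True)
class SVRecord:
    """One structural-variant call.

    Coordinates follow the VCF convention: 1-based, inclusive.  For
    insertions ``end == start`` (the insertion point), and the length is
    carried entirely by ``svlen``.
    """

    contig: str
    start: int
    end: int
    svtype: str
    svlen: int | None = None
    id: str = ""
    read_support: int | None = None
    source_index: int | None = None

    def __post_init__(self) -> None:
        if self.svtype not in _SV_TYPE_SET:
            raise ValueError(f"unsupported SVTYPE {self.svtype!r} (record {self.id!r})")
        if self.svtype == "INS":
            if self.end != self.start:
                raise ValueError(f"INS record {self.id!r} must have end == start")
            if self.svlen is None:
                raise ValueError(f"INS record {self.id!r} requires an explicit SVLEN")
        elif self.end < self.start:
            raise ValueError(f"record {self.id!r} has end < start")
        if self.svlen is not None:
            self.svlen = abs(int(self.svlen))
            if self.svlen <= 0:
                raise ValueError(f"record {self.id!r} has non-positive SVLEN")

    @property
    def coords(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)


def sv_size(r: SVRecord) -> int:
    """Length of the variant in base pairs.

    An explicit SVLEN wins (caller-emitted lengths are authoritative for
    imprecise calls); otherwise the reference span ``end - start`` is used.
    """
    if r.svlen is not None:
        return r.svlen
    return r.end - r.start


@dataclass(frozen=True)
class MergeConfig:
    """Parameters of the pairwise breakpoint-distance match.

    ``min_size`` is the size floor applied to inputs before merging;
    ``strict_min_size`` selects "> min_size" (used with the 30 bp floor of
    intermediate merges) versus ">= min_size" (the 50 bp floor of final,
    union and truth-comparison merges).
    """

    max_dist: int = 1000
    require_same_type: bool = True
    min_size: int = 50
    strict_min_size: bool = False

    def __post_init__(self) -> None:
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        if self.min_size < 0:
            raise ValueError("min_size must be >= 0")


#: Merge parameters for intermediate concordance stages (">30 bp" floor).
INTERMEDIATE_MERGE = MergeConfig(max_dist=1000, require_same_type=True,
                                 min_size=30, strict_min_size=True)
#: Merge parameters for final/union/truth merges ("minimum 50 bp" floor).
FINAL_MERGE = MergeConfig(max_dist=1000, require_same_type=True,
                          min_size=50, strict_min_size=False)


def match(a: SVRecord, b: SVRecord, cfg: MergeConfig) -> bool:
    """True iff ``a`` and ``b`` describe the same event under ``cfg``.

    The distance is measured pairwise from the beginnings and from the ends
    of the two records; both must be within ``cfg.max_dist``.  Symmetric
    and reflexive.
    """
    if a.contig != b.contig:
        return False
    if cfg.require_same_type and a.svtype != b.svtype:
        return False
    return (abs(a.start - b.start) <= cfg.max_dist
            and abs(a.end - b.end) <= cfg.max_dist)


def filter_size(records: Iterable[SVRecord], min_size: int,
                strict: bool = False) -> list[SVRecord]:
    """Apply a size floor: keep ``sv_size > min_size`` when ``strict``,
    else ``sv_size >= min_size``."""
    if strict:
        return [r for r in records if sv_size(r) > min_size]
    return [r for r in records if sv_size(r) >= min_size]


@dataclass
class CallSet:
    """An ordered collection of SV records from one pipeline configuration."""

    key: FactorKey | str
    records: list[SVRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.contig, r.start, r.end))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SVRecord]:
        return iter(self.records)

    @property
    def label(self) -> str:
        return self.key.label() if isinstance(self.key, FactorKey) else str(self.key)


@dataclass
class MergedRecord:
    """One cluster of matched records with its support annotation.

    ``support_vector`` is a bit string of length n (the input-set count);
    bit i is '1' iff at least one member came from input set i.
    """

    representative: SVRecord
    members: list[SVRecord]
    support_vector: str

    @property
    def support(self) -> int:
        return self.support_vector.count("1")

    @property
    def sources(self) -> frozenset[int]:
        return frozenset(m.source_index for m in self.members)


@dataclass
class MergedSet:
    """Result of merging several call sets: clusters plus input bookkeeping."""

    inputs: list[str]
    clusters: list[MergedRecord]
    config: MergeConfig

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    def representatives(self) -> list[SVRecord]:
        return [c.representative for c in self.clusters]

    def supports(self) -> list[int]:
        return [c.support for c in self.clusters]


class _UnionFind:
    __slots__ = ("parent", "size")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]


def merge_callsets(sets: Sequence[CallSet], cfg: MergeConfig | None = None) -> MergedSet:
    """Merge call sets into clusters of matching records.

    Builds a graph whose nodes are all records (after the ``cfg`` size
    floor) and whose edges connect pairs from *different* input sets that
    satisfy :func:`match`; clusters are the connected components
    (single linkage).  Two records of the same set may still end up in one
    cluster via a bridge from another set.  The representative of a cluster
    is the member with the smallest coordinates among those from the lowest
    contributing source index.  Deterministic for a fixed input order.
    """
    if not sets:
        raise ValueError("no call sets to merge")
    cfg = cfg or FINAL_MERGE

    flat: list[SVRecord] = []
    for si, cs in enumerate(sets):
        for r in filter_size(cs.records, cfg.min_size, cfg.strict_min_size):
            flat.append(replace(r, source_index=si))

    order = sorted(range(len(flat)), key=lambda i: flat[i].coords)
    uf = _UnionFind(len(flat))

    # |start_a - start_b| <= max_dist is necessary for a match, so a sliding
    # window over records sorted by (contig, start) enumerates all candidate
    # pairs without a quadratic scan.
    lo = 0
    for pos in range(len(order)):
        i = order[pos]
        ri = flat[i]
        while lo < pos and (flat[order[lo]].contig != ri.contig
                            or ri.start - flat[order[lo]].start > cfg.max_dist):
            lo += 1
        for qos in range(lo, pos):
            j = order[qos]
            rj = flat[j]
            if ri.source_index != rj.source_index and match(ri, rj, cfg):
                uf.union(i, j)

    groups: dict[int, list[SVRecord]] = {}
    for i in order:  # coordinate order => members come out sorted
        groups.setdefault(uf.find(i), []).append(flat[i])

    clusters = []
    for members in groups.values():
        srcs = sorted({m.source_index for m in members})
        rep = min((m for m in members if m.source_index == srcs[0]),
                  key=lambda m: m.coords)
        vec = "".join("1" if s in srcs else "0" for s in range(len(sets)))
        clusters.append(MergedRecord(representative=rep, members=members,
                                     support_vector=vec))
    clusters.sort(key=lambda c: c.representative.coords)
    return MergedSet(inputs=[cs.label for cs in sets], clusters=clusters, config=cfg)


def filter_support(m: MergedSet, k: int, mode: str = "at_least") -> MergedSet:
    """Keep clusters whose support is ``>= k`` (``at_least``) or ``== k``
    (``exactly``); order preserved."""
    if not 1 <= k <= m.n_inputs:
        raise ValueError(f"support threshold {k} out of range 1..{m.n_inputs}")
    if mode == "at_least":
        keep = [c for c in m.clusters if c.support >= k]
    elif mode == "exactly":
        keep = [c for c in m.clusters if c.support == k]
    else:
        raise ValueError(f"unknown support filter mode {mode!r}")
    return MergedSet(inputs=list(m.inputs), clusters=keep, config=m.config)


def filter_regions(records: Iterable[SVRecord], regions) -> list[SVRecord]:
    """Keep records whose span overlaps >= 1 bp of a region (bedtools
    intersect default).  ``regions`` maps contig -> IntervalTree with
    0-based half-open intervals (see :func:`svfactor.vcfio.read_bed`).
    For insertions the single-base insertion point must fall in a region.
    """
    kept = []
    for r in records:
        tree = regions.get(r.contig)
        if tree is None:
            continue
        # VCF [start, end] inclusive -> 0-based half-open [start-1, end)
        hi = r.start if r.svtype == "INS" else r.end
        if tree.overlap(r.start - 1, hi):
            kept.append(r)
    return kept


class RecordIndex:
    """Sorted per-contig index for 'does any record here match r?' queries."""

    def __init__(self, records: Iterable[SVRecord]) -> None:
        by_contig: dict[str, list[SVRecord]] = {}
        for r in records:
            by_contig.setdefault(r.contig, []).append(r)
        self._index: dict[str, tuple[list[int], list[SVRecord]]] = {}
        for contig, recs in by_contig.items():
            recs.sort(key=lambda r: r.start)
            self._index[contig] = ([r.start for r in recs], recs)

    def matches(self, r: SVRecord, cfg: MergeConfig) -> bool:
        entry = self._index.get(r.contig)
        if entry is None:
            return False
        starts, recs = entry
        lo = bisect_left(starts, r.start - cfg.max_dist)
        hi = bisect_right(starts, r.start + cfg.max_dist)
        return any(match(r, recs[i], cfg) for i in range(lo, hi))

    def count_matching(self, records: Iterable[SVRecord], cfg: MergeConfig) -> int:
        return sum(1 for r in records if self.matches(r, cfg))
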