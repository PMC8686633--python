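"""Concordance analyses: truth-set overlap, family structure and consensus.

These operations quantify how well short-read SV calls agree with an
independent higher-sensitivity call set (long-read based), with the call
sets of related samples (two parents and monozygotic twins, who share
germline genotypes), and with each other across mappers.  Overlap is always
the same breakpoint-distance predicate used for merging, counted from the
query side: a query record "overlaps" when it matches at least one subject
record.  Multiple query records may match the same subject record unless
the strict one-to-one mode is requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._util import percent
from .core import (CallSet, FINAL_MERGE, MergeConfig, MergedSet, RecordIndex,
                   SVRecord, filter_size, match, merge_callsets)


def _query_records(query) -> list[SVRecord]:
    if isinstance(query, MergedSet):
        return query.representatives()
    if isinstance(query, CallSet):
        return list(query.records)
    return list(query)


def _overlap_flags(records, truth_index: RecordIndex, cfg: MergeConfig,
                   one_to_one: bool = False) -> list[bool]:
    if not one_to_one:
        return [truth_index.matches(r, cfg) for r in records]
    # strict mode: each truth record may absorb one query record
    used: set[int] = set()
    flags = []
    for r in records:
        entry = truth_index._index.get(r.contig)
        hit = False
        if entry is not None:
            starts, recs = entry
            from bisect import bisect_left, bisect_right
            lo = bisect_left(starts, r.start - cfg.max_dist)
            hi = bisect_right(starts, r.start + cfg.max_dist)
            for i in range(lo, hi):
                if (r.contig, id(recs[i])) in used:
                    continue
                if match(r, recs[i], cfg):
                    used.add((r.contig, id(recs[i])))
                    hit = True
                    break
        flags.append(hit)
    return flags


@dataclass
class TruthComparison:
    """Query-side overlap of a call set or merged set with a truth set."""

    n_query: int
    n_overlap: int
    per_record_overlap: list[bool]
    rate_by_support: dict[int, float] = field(default_factory=dict)
    counts_by_support: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def overlap_percent(self) -> float:
        return percent(self.n_overlap, self.n_query) if self.n_query else 0.0

    def monotone_in_support(self) -> bool:
        """Whether the overlap rate is non-decreasing in support level."""
        rates = [self.rate_by_support[k] for k in sorted(self.rate_by_support)]
        return all(a <= b for a, b in zip(rates, rates[1:]))


def truth_overlap(query, truth: CallSet, cfg: MergeConfig = FINAL_MERGE,
                  one_to_one: bool = False) -> TruthComparison:
    """Fraction of query records matching the truth set, by support level.

    Truth records below the ``cfg`` size floor are excluded before
    comparison.  When ``query`` is a merged set, the per-support-level
    rates are reported as well (published gradients run from low overlap at
    support 1 to high overlap at full support).
    """
    truth_records = filter_size(truth.records, cfg.min_size, cfg.strict_min_size)
    if not truth_records:
        warnings.warn("empty truth set: all overlap rates are 0")
    index = RecordIndex(truth_records)
    records = _query_records(query)
    flags = _overlap_flags(records, index, cfg, one_to_one)

    comparison = TruthComparison(n_query=len(records), n_overlap=sum(flags),
                                 per_record_overlap=flags)
    if isinstance(query, MergedSet):
        by_support: dict[int, list[bool]] = {}
        for cluster, flag in zip(query.clusters, flags):
            by_support.setdefault(cluster.support, []).append(flag)
        for k, fl in sorted(by_support.items()):
            comparison.counts_by_support[k] = (sum(fl), len(fl))
            comparison.rate_by_support[k] = percent(sum(fl), len(fl))
    return comparison


@dataclass
class FamilySingletonReport:
    """Proband singletons split into family-shared vs proband-unique."""

    n_singletons: int
    n_family_shared: int
    shared_truth_overlap: int
    unique_truth_overlap: int

    @property
    def n_unique(self) -> int:
        return self.n_singletons - self.n_family_shared

    @property
    def shared_percent(self) -> float:
        return percent(self.n_family_shared, self.n_singletons) if self.n_singletons else 0.0

    @property
    def unique_percent(self) -> float:
        return percent(self.n_unique, self.n_singletons) if self.n_singletons else 0.0

    @property
    def shared_truth_percent(self) -> float:
        return percent(self.shared_truth_overlap, self.n_family_shared) \
            if self.n_family_shared else 0.0

    @property
    def unique_truth_percent(self) -> float:
        return percent(self.unique_truth_overlap, self.n_unique) if self.n_unique else 0.0


def family_singleton_overlap(proband_singletons, relative_singletons: list,
                             truth: CallSet | None = None,
                             cfg: MergeConfig = FINAL_MERGE) -> FamilySingletonReport:
    """Partition proband singletons by recurrence in relatives' singletons.

    A proband singleton is "family-shared" iff it matches at least one
    singleton of *any* relative; recurrence across relatives distinguishes
    systematic artifacts (or shared real variants missed elsewhere) from
    sample-private noise.  Each partition is additionally scored against
    the truth set when one is given.
    """
    proband = _query_records(proband_singletons)
    relatives: list[SVRecord] = []
    for rel in relative_singletons:
        relatives.extend(_query_records(rel))
    rel_index = RecordIndex(relatives)
    shared_flags = [rel_index.matches(r, cfg) for r in proband]

    shared_truth = unique_truth = 0
    if truth is not None:
        truth_index = RecordIndex(
            filter_size(truth.records, cfg.min_size, cfg.strict_min_size))
        for r, shared in zip(proband, shared_flags):
            if truth_index.matches(r, cfg):
                if shared:
                    shared_truth += 1
                else:
                    unique_truth += 1
    return FamilySingletonReport(n_singletons=len(proband),
                                 n_family_shared=sum(shared_flags),
                                 shared_truth_overlap=shared_truth,
                                 unique_truth_overlap=unique_truth)


def parental_support_rate(twin_callsets: list[CallSet],
                          parent_callsets: list[CallSet],
                          cfg: MergeConfig = FINAL_MERGE) -> pd.DataFrame:
    """Mendelian-style consistency: per twin call set, the percentage of
    records found in at least one parental call set.

    Twins inherit every germline variant from a parent, so (absent de novo
    events) any twin call unsupported by the union of all parental call
    sets is suspect.
    """
    parent_union: list[SVRecord] = []
    for cs in parent_callsets:
        parent_union.extend(cs.records)
    index = RecordIndex(parent_union)
    rows = []
    for cs in twin_callsets:
        n = len(cs.records)
        hit = index.count_matching(cs.records, cfg)
        rows.append({"callset": cs.label, "n_records": n,
                     "parent_supported": hit,
                     "percent": percent(hit, n) if n else 0.0})
    return pd.DataFrame(rows)


def pairwise_overlap_matrix(callsets: list[CallSet],
                            cfg: MergeConfig = FINAL_MERGE) -> pd.DataFrame:
    """Asymmetric percent-overlap matrix: entry (i, j) is the percentage of
    set i's records that match at least one record of set j.

    The diagonal is exactly 100 (every record matches itself).  Rows of
    empty sets are emitted as missing.  A symmetric Jaccard variant is not
    computed here; callers needing one can derive it from the counts.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two call sets")
    labels = [cs.label for cs in callsets]
    indexes = [RecordIndex(cs.records) for cs in callsets]
    mat = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for i, ci in enumerate(callsets):
        if not len(ci.records):
            continue  # row stays NaN
        for j in range(len(callsets)):
            if i == j:
                mat.iloc[i, j] = 100.0
                continue
            hit = indexes[j].count_matching(ci.records, cfg)
            mat.iloc[i, j] = percent(hit, len(ci.records))
    return mat


def filter_min_read_support(records, min_reads: int = 1) -> list[SVRecord]:
    """Keep genotyped records with at least ``min_reads`` supporting reads."""
    kept = []
    for r in records:
        if r.read_support is None:
            raise ValueError(f"record {r.id!r} has no read_support annotation")
        if r.read_support >= min_reads:
            kept.append(r)
    return kept


def supp_vec_histogram(m: MergedSet) -> tuple[dict[int, int], dict[str, int]]:
    """Histogram of cluster support levels plus per-input marginal counts.

    Returns ``(support_counts, input_marginals)`` where ``input_marginals``
    counts, for each input set, how many clusters it participates in.
    """
    support_counts: dict[int, int] = {k: 0 for k in range(1, m.n_inputs + 1)}
    marginals: dict[str, int] = {label: 0 for label in m.inputs}
    for c in m.clusters:
        support_counts[c.support] += 1
        for i, bit in enumerate(c.support_vector):
            if bit == "1":
                marginals[m.inputs[i]] += 1
    return support_counts, marginals


@dataclass
class ConsensusResult:
    """Intersection of per-mapper call sets with its truth concordance."""

    mappers: tuple[str, ...]
    records: list[SVRecord]
    truth_overlap_count: int

    @property
    def count(self) -> int:
        return len(self.records)

    @property
    def truth_overlap_percent(self) -> float:
        return percent(self.truth_overlap_count, self.count) if self.count else 0.0


def consensus_mappers(per_mapper: dict[str, CallSet], subset,
                      truth: CallSet | None = None,
                      cfg: MergeConfig = FINAL_MERGE) -> ConsensusResult:
    """Records supported by every mapper of ``subset``, scored against truth.

    Intersecting mappers trades sensitivity for precision: independent
    false positives of individual mappers rarely co-occur, so the
    intersection is enriched for true calls.
    """
    subset = tuple(subset)
    for label in subset:
        if label not in per_mapper:
            raise KeyError(f"unknown mapper label {label!r}")
    sets = [per_mapper[label] for label in subset]
    if len(sets) == 1:
        records = list(sets[0].records)
    else:
        merged = merge_callsets(sets, cfg)
        records = [c.representative for c in merged.clusters
                   if c.support == len(sets)]
    hits = 0
    if truth is not None:
        index = RecordIndex(filter_size(truth.records, cfg.min_size,
                                        cfg.strict_min_size))
        hits = index.count_matching(records, cfg)
    return ConsensusResult(mappers=subset, records=records,
                           truth_overlap_count=hits)
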