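"""Factorial stratification: isolating the variability of one factor.

To measure how much one factor (mapper, sequencing center, replicate, or
dedup/recal post-processing) contributes to call-set variability, records
must first be concordant across *all other* factors: each non-target factor
is collapsed in turn by merging its level call sets and keeping only
clusters supported by every level (full concordance).  A final union merge
across the target factor's levels then partitions the surviving calls by
support level — a cluster supported by a single level is a "singleton"
attributable to that level alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import percent
from .core import (CallSet, FACTOR_NAMES, FactorKey, FINAL_MERGE,
                   INTERMEDIATE_MERGE, MergeConfig, MergedSet,
                   filter_support, merge_callsets)

#: Per-target order in which the non-target factors are collapsed.
#: Collapse order can matter under single-linkage merging, so it is fixed
#: (and configurable through StratificationPlan).
DEFAULT_STAGE_ORDER: dict[str, tuple[str, ...]] = {
    "mapper": ("postproc", "replicate", "center"),
    "center": ("postproc", "mapper", "replicate"),
    "replicate": ("postproc", "mapper", "center"),
    "postproc": ("mapper", "replicate", "center"),
}

_WILDCARD = "*"


@dataclass(frozen=True)
class StratificationPlan:
    """How to isolate one factor: collapse order and merge parameters."""

    target_factor: str
    order: tuple[str, ...] = ()
    intermediate_cfg: MergeConfig = INTERMEDIATE_MERGE
    final_cfg: MergeConfig = FINAL_MERGE

    def __post_init__(self) -> None:
        if self.target_factor not in FACTOR_NAMES:
            raise ValueError(f"unknown target factor {self.target_factor!r}")
        order = self.order or DEFAULT_STAGE_ORDER[self.target_factor]
        object.__setattr__(self, "order", tuple(order))
        expected = set(FACTOR_NAMES) - {self.target_factor}
        if set(self.order) != expected:
            raise ValueError(
                f"stage order {self.order} must contain exactly the non-target "
                f"factors {sorted(expected)}")


@dataclass
class StratificationResult:
    """Per-factor merged set after concordance filtering on all others."""

    sample: str
    target_factor: str
    levels: list[str]
    merged: MergedSet
    partitions: dict[int, list] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.merged)

    def singletons(self) -> list:
        return self.partitions.get(1, [])

    @property
    def singleton_fraction(self) -> float:
        return len(self.singletons()) / self.total if self.total else 0.0

    def singletons_for_level(self, level: str) -> list:
        """Singleton clusters whose single supporting input is ``level``."""
        i = self.levels.index(level)
        return [c for c in self.singletons() if c.support_vector[i] == "1"]


def _group_collapsing(callsets: dict[FactorKey, CallSet],
                      factor: str) -> dict[FactorKey, list[tuple[str, CallSet]]]:
    """Group call sets by their key with ``factor`` wildcarded."""
    groups: dict[FactorKey, list[tuple[str, CallSet]]] = {}
    for key, cs in callsets.items():
        shared = key._replace(**{factor: _WILDCARD})
        groups.setdefault(shared, []).append((getattr(key, factor), cs))
    for members in groups.values():
        members.sort(key=lambda t: t[0])
    return groups


def concordant_reduce(grouped: list[CallSet], required_support: int,
                      cfg: MergeConfig, key: FactorKey | str = "reduced") -> CallSet:
    """Merge the level call sets of one factor and keep full-concordance calls.

    Returns the cluster representatives of clusters supported by at least
    ``required_support`` of the inputs as a new call set labeled ``key``.
    """
    if len(grouped) != required_support:
        raise ValueError(
            f"full concordance of {required_support} levels requested but "
            f"{len(grouped)} call sets supplied for {key}")
    merged = merge_callsets(grouped, cfg)
    kept = filter_support(merged, required_support, "at_least")
    return CallSet(key=key, records=list(kept.representatives()))


def check_complete_factorial(callsets: dict[FactorKey, CallSet]) -> dict[str, list[str]]:
    """Verify the full factorial is present; return the observed levels.

    Raises ValueError naming the first absent FactorKey otherwise.
    """
    if not callsets:
        raise ValueError("no call sets supplied")
    levels = {f: sorted({getattr(k, f) for k in callsets}) for f in FACTOR_NAMES}
    samples = sorted({k.sample for k in callsets})
    for s in samples:
        for c in levels["center"]:
            for r in levels["replicate"]:
                for m in levels["mapper"]:
                    for p in levels["postproc"]:
                        key = FactorKey(s, c, r, m, p)
                        if key not in callsets:
                            raise ValueError(f"incomplete factorial: missing call set {key}")
    return levels


def stratify(callsets: dict[FactorKey, CallSet],
             plan: StratificationPlan) -> StratificationResult:
    """Run the full stratification for one sample and one target factor.

    ``callsets`` holds the complete factorial for a single sample (72 sets
    in the 3 centers x 3 replicates x 4 mappers x 2 postproc design).  Each
    stage in ``plan.order`` collapses one non-target factor via
    :func:`concordant_reduce`; downstream stages operate on the surviving
    cluster representatives.  The final union merge across the target
    factor's levels applies ``plan.final_cfg`` (the 50 bp floor) and the
    result is partitioned by support level.
    """
    samples = {k.sample for k in callsets}
    if len(samples) != 1:
        raise ValueError(f"stratify() expects call sets of one sample, got {sorted(samples)}")
    sample = samples.pop()
    levels = check_complete_factorial(callsets)

    current = dict(callsets)
    for factor in plan.order:
        n_levels = len(levels[factor])
        nxt: dict[FactorKey, CallSet] = {}
        for shared, members in _group_collapsing(current, factor).items():
            reduced = concordant_reduce([cs for _, cs in members], n_levels,
                                        plan.intermediate_cfg, key=shared)
            nxt[shared] = reduced
        current = nxt

    target_levels = levels[plan.target_factor]
    ordered = []
    for lvl in target_levels:
        (key,) = [k for k in current if getattr(k, plan.target_factor) == lvl]
        ordered.append(current[key])
    merged = merge_callsets(ordered, plan.final_cfg)

    partitions = {k: [] for k in range(1, len(target_levels) + 1)}
    for cluster in merged.clusters:
        partitions[cluster.support].append(cluster)
    return StratificationResult(sample=sample, target_factor=plan.target_factor,
                                levels=target_levels, merged=merged,
                                partitions=partitions)


def support_summary(res: StratificationResult | MergedSet | dict[int, int]) -> pd.DataFrame:
    """Counts and percentages of clusters per support level.

    Accepts a stratification result, a merged set, or a plain mapping of
    support level -> count (so published tallies can be summarised the same
    way).  Percentages are reported to two decimals (round-half-even).  An
    empty result yields zero percentages with a warning.
    """
    import warnings

    if isinstance(res, dict):
        counts = {int(k): int(v) for k, v in res.items()}
    else:
        merged = res.merged if isinstance(res, StratificationResult) else res
        counts = {k: 0 for k in range(1, merged.n_inputs + 1)}
        for c in merged.clusters:
            counts[c.support] += 1
    total = sum(counts.values())
    rows = []
    for k in sorted(counts):
        if total:
            pct = percent(counts[k], total)
        else:
            pct = 0.0
        rows.append({"support": k, "count": counts[k], "percent": pct})
    if not total:
        warnings.warn("support_summary of an empty merged set: percentages set to 0")
    return pd.DataFrame(rows)
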