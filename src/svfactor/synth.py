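"""Synthetic quartet call-set generator.

The raw data behind the factorial study design (a family quartet — two
parents and monozygotic twins — sequenced in triplicate at three centers,
mapped four ways, post-processed two ways: 288 call sets) are access
restricted, so every pipeline stage here is exercised on simulated call
sets with a fully known truth.

The generator draws a set of well-separated true SV loci with population
allele frequencies, assigns Hardy-Weinberg parental genotypes and a
Mendelian child genotype (both twins carry the child genotype), and then
emits one call set per factorial cell with a controllable error structure:

* per-factor multiplicative detection sensitivities and a per-record
  replicate drop probability (false negatives);
* private false positives (Poisson count per call set, positions far from
  any true locus);
* recurrent false-positive pools per mapper and per center level — fixed
  coordinates shared by every call set of that level, the minimal
  mechanism that makes level-specific singletons recur across family
  members the way systematic artifacts do;
* per-mapper Gaussian breakpoint jitter, truncated by default at the merge
  distance so a jittered true call still matches its locus.

Loci (and pool coordinates) are separated by more than twice the maximum
SV size plus twice the merge distance, so distinct loci can never merge
and every emitted record is unambiguously a true positive or a labeled
false positive.  All outputs are deterministic functions of the seed (and,
for call sets, of the factor key).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._util import stable_hash
from .core import CallSet, FactorKey, SVRecord

TWINS = ("LCL5", "LCL6")
PARENTS = ("LCL7", "LCL8")
SAMPLES = TWINS + PARENTS


def _default_type_probs() -> dict[str, float]:
    # deletion-dominated mix as seen in short-read germline call sets
    return {"DEL": 0.63, "INS": 0.18, "DUP": 0.08, "INV": 0.11}


def _ones(levels) -> dict[str, float]:
    return {lvl: 1.0 for lvl in levels}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic quartet factorial.

    Defaults emulate the study conditions: the 4 x 3 x 3 x 2 within-sample
    factorial, a deletion-dominated type mix, SV sizes log-uniform on
    50-10,000 bp (most mass at 100-1000 bp), and near-one per-call-set
    sensitivities — detection failures must be rare per call set for a
    realistic fraction of loci to survive full-concordance stratification,
    because the simulator draws them independently per call set.
    """

    genome: tuple[tuple[str, int], ...] = (("chr1", 10_000_000), ("chr2", 10_000_000))
    n_loci: int = 500
    type_probs: dict[str, float] = field(default_factory=_default_type_probs)
    size_range: tuple[int, int] = (50, 10_000)  # log-uniform
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    min_locus_separation: int = 25_000
    mappers: tuple[str, ...] = ("BWA-MEM", "Bowtie2", "Isaac", "Stampy")
    centers: tuple[str, ...] = ("Center1", "Center2", "Center3")
    replicates: tuple[str, ...] = ("Rep1", "Rep2", "Rep3")
    postprocs: tuple[str, ...] = ("dedup", "recal")
    base_sensitivity: float = 0.98
    mapper_sensitivity: dict[str, float] | None = None
    center_sensitivity: dict[str, float] | None = None
    postproc_sensitivity: dict[str, float] | None = None
    replicate_noise: float = 0.005
    private_fp_rate: float = 30.0
    recurrent_fp_pools: dict[str, dict[str, int]] | None = None
    jitter_sd: dict[str, float] | None = None
    truncate_jitter: bool = True
    max_dist: int = 1000
    longread_sensitivity: dict[str, float] = field(default_factory=lambda: {
        "DEL": 0.95, "INS": 0.90, "DUP": 0.85, "INV": 0.90})
    longread_fp_rate: float = 20.0
    longread_jitter_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mapper_sensitivity is None:
            # mild per-mapper structure: the split-read-blind mapper misses more
            self.mapper_sensitivity = {m: s for m, s in zip(
                self.mappers, (1.0, 0.97, 0.99, 0.995))} if len(self.mappers) == 4 \
                else _ones(self.mappers)
        if self.center_sensitivity is None:
            self.center_sensitivity = {c: s for c, s in zip(
                self.centers, (0.99, 0.995, 1.0))} if len(self.centers) == 3 \
                else _ones(self.centers)
        if self.postproc_sensitivity is None:
            self.postproc_sensitivity = _ones(self.postprocs)
        if self.jitter_sd is None:
            self.jitter_sd = {m: 50.0 for m in self.mappers}
        if self.recurrent_fp_pools is None:
            # ~2% of loci per mapper level, ~1% per center level: keeps the
            # default singleton mix dominated by detection variability with a
            # visible recurrent-artifact component, as in real call sets
            self.recurrent_fp_pools = {
                "mapper": {m: max(1, self.n_loci // 50) for m in self.mappers},
                "center": {c: max(1, self.n_loci // 100) for c in self.centers},
            }
        self.recurrent_fp_pools.setdefault("mapper", {})
        self.recurrent_fp_pools.setdefault("center", {})
        total_p = sum(self.type_probs.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ValueError("type_probs must sum to 1")
        for name, prob in (("base_sensitivity", self.base_sensitivity),
                           ("replicate_noise", self.replicate_noise)):
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_locus_separation <= 2 * self.size_range[1] + 2 * self.max_dist:
            raise ValueError(
                "min_locus_separation must exceed 2*max size + 2*max_dist so "
                "distinct loci can never merge")

    def factorial_keys(self, sample: str) -> list[FactorKey]:
        return [FactorKey(sample, c, r, m, p)
                for c in self.centers for r in self.replicates
                for m in self.mappers for p in self.postprocs]


@dataclass
class TruthTable:
    """Simulated ground truth: loci, quartet genotypes, artifact pools."""

    loci: list[SVRecord]
    allele_freq: np.ndarray
    genotypes: dict[str, np.ndarray]  # sample -> (n_loci, 2) array of 0/1
    fp_pools: dict[tuple[str, str], list[SVRecord]]  # (factor, level) -> records
    config: SimulationConfig

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def carriers(self, sample: str) -> np.ndarray:
        """Boolean mask of loci where ``sample`` carries >= 1 alternate allele."""
        return self.genotypes[sample].sum(axis=1) > 0

    def positions_by_contig(self) -> dict[str, np.ndarray]:
        """Sorted start positions of all loci and pool records per contig,
        for rejection-sampling false positives away from them."""
        pos: dict[str, list[int]] = {}
        records = list(self.loci)
        for pool in self.fp_pools.values():
            records.extend(pool)
        for r in records:
            pos.setdefault(r.contig, []).append(r.start)
        return {c: np.sort(np.asarray(v)) for c, v in pos.items()}


def _draw_separated_positions(cfg: SimulationConfig, n: int,
                              rng: np.random.Generator) -> list[tuple[str, int]]:
    """n positions with pairwise gaps >= min_locus_separation, spread over
    the genome proportionally to contig length."""
    sep = cfg.min_locus_separation
    max_size = cfg.size_range[1]
    total = sum(length for _, length in cfg.genome)
    counts = []
    assigned = 0
    for idx, (contig, length) in enumerate(cfg.genome):
        if idx == len(cfg.genome) - 1:
            k = n - assigned
        else:
            k = int(round(n * length / total))
        counts.append(k)
        assigned += k
    out: list[tuple[str, int]] = []
    for (contig, length), k in zip(cfg.genome, counts):
        if k == 0:
            continue
        slack = length - k * sep - max_size
        if slack <= 0:
            raise ValueError(
                f"genome too small: contig {contig} cannot host {k} loci at "
                f"separation {sep}")
        offsets = np.sort(rng.uniform(0, slack, size=k))
        for j, off in enumerate(offsets):
            out.append((contig, int(off) + j * sep + 1))
    return out


def _draw_records(cfg: SimulationConfig, positions, rng: np.random.Generator,
                  id_prefix: str) -> list[SVRecord]:
    types = list(cfg.type_probs)
    probs = np.asarray([cfg.type_probs[t] for t in types])
    lo, hi = np.log(cfg.size_range[0]), np.log(cfg.size_range[1])
    records = []
    for i, (contig, start) in enumerate(positions):
        svtype = types[rng.choice(len(types), p=probs)]
        size = int(round(np.exp(rng.uniform(lo, hi))))
        size = min(max(size, cfg.size_range[0]), cfg.size_range[1])
        end = start if svtype == "INS" else start + size
        records.append(SVRecord(contig=contig, start=start, end=end,
                                svtype=svtype, svlen=size,
                                id=f"{id_prefix}{i:06d}"))
    return records


def simulate_truth(cfg: SimulationConfig) -> TruthTable:
    """Draw the quartet ground truth (loci, genotypes) and artifact pools.

    Parental genotypes follow Hardy-Weinberg at each locus's allele
    frequency; the child receives one allele from each parent; the
    monozygotic twins share the child genotype.  Pool coordinates are drawn
    under the same global separation constraint as the loci so that no pool
    record can ever merge with a true locus or with another pool.
    """
    rng = np.random.default_rng([cfg.seed, stable_hash("truth")])
    pool_sizes = [(factor, level, size)
                  for factor in ("mapper", "center")
                  for level, size in sorted(cfg.recurrent_fp_pools[factor].items())]
    n_pool = sum(size for _, _, size in pool_sizes)
    positions = _draw_separated_positions(cfg, cfg.n_loci + n_pool, rng)
    positions = [positions[i] for i in rng.permutation(len(positions))]

    loci = _draw_records(cfg, positions[:cfg.n_loci], rng, "locus")
    fp_pools: dict[tuple[str, str], list[SVRecord]] = {}
    offset = cfg.n_loci
    for factor, level, size in pool_sizes:
        recs = _draw_records(cfg, positions[offset:offset + size], rng,
                             f"fp_{factor}_{level}_")
        fp_pools[(factor, level)] = recs
        offset += size

    lo_f, hi_f = cfg.allele_freq_range
    freqs = rng.uniform(lo_f, hi_f, size=cfg.n_loci)
    genotypes: dict[str, np.ndarray] = {}
    for parent in PARENTS:
        genotypes[parent] = (rng.random((cfg.n_loci, 2)) < freqs[:, None]).astype(np.int8)
    child = np.empty((cfg.n_loci, 2), dtype=np.int8)
    for j, parent in enumerate(PARENTS):
        picked = rng.integers(0, 2, size=cfg.n_loci)
        child[:, j] = genotypes[parent][np.arange(cfg.n_loci), picked]
    for twin in TWINS:
        genotypes[twin] = child.copy()
    return TruthTable(loci=loci, allele_freq=freqs, genotypes=genotypes,
                      fp_pools=fp_pools, config=cfg)


def _jitter_record(r: SVRecord, sd: float, rng: np.random.Generator,
                   max_dist: int, truncate: bool) -> SVRecord:
    if sd <= 0:
        return replace(r)
    d1, d2 = rng.normal(0.0, sd, size=2)
    if truncate:
        d1 = float(np.clip(d1, -max_dist, max_dist))
        d2 = float(np.clip(d2, -max_dist, max_dist))
    start = max(1, r.start + int(round(d1)))
    if r.svtype == "INS":
        return replace(r, start=start, end=start)
    end = max(start + 1, r.end + int(round(d2)))
    return replace(r, start=start, end=end, svlen=end - start)


def _draw_false_positives(truth: TruthTable, n: int, rng: np.random.Generator,
                          id_prefix: str) -> list[SVRecord]:
    """Random records whose starts sit > 2*max_dist from any truth or pool
    coordinate, so they can never match (even a jittered copy of) a labeled
    event."""
    cfg = truth.config
    occupied = truth.positions_by_contig()
    contigs = [c for c, _ in cfg.genome]
    lengths = np.asarray([length for _, length in cfg.genome], dtype=float)
    weights = lengths / lengths.sum()
    sep = 2 * cfg.max_dist + 1
    out: list[tuple[str, int]] = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 200 * (n + 1):
            raise RuntimeError("false-positive rejection sampling did not converge")
        ci = rng.choice(len(contigs), p=weights)
        contig = contigs[ci]
        pos = int(rng.integers(1, int(lengths[ci]) - cfg.size_range[1]))
        occ = occupied.get(contig)
        if occ is not None and len(occ):
            k = np.searchsorted(occ, pos)
            near = []
            if k > 0:
                near.append(occ[k - 1])
            if k < len(occ):
                near.append(occ[k])
            if any(abs(pos - q) < sep for q in near):
                continue
        out.append((contig, pos))
    return _draw_records(cfg, out, rng, id_prefix)


def simulate_callset(truth: TruthTable, key: FactorKey,
                     cfg: SimulationConfig | None = None) -> CallSet:
    """Emit one call set of the factorial with the configured error model.

    Each truth locus carried by ``key.sample`` is emitted with probability
    ``base x mapper x center x postproc x (1 - replicate_noise)``; emitted
    breakpoints receive per-mapper jitter.  Private false positives
    (Poisson) and the full recurrent pools of the key's mapper and center
    level are appended; pool records keep their fixed coordinates in every
    call set, the signature of a systematic artifact.  Deterministic per
    (seed, key).
    """
    cfg = cfg or truth.config
    key = key.validate()
    rng = np.random.default_rng([cfg.seed, stable_hash("callset", *key)])
    p_emit = (cfg.base_sensitivity
              * cfg.mapper_sensitivity[key.mapper]
              * cfg.center_sensitivity[key.center]
              * cfg.postproc_sensitivity[key.postproc]
              * (1.0 - cfg.replicate_noise))
    carried = truth.carriers(key.sample)
    emitted = carried & (rng.random(truth.n_loci) < p_emit)
    sd = cfg.jitter_sd[key.mapper]

    records = [_jitter_record(truth.loci[i], sd, rng, cfg.max_dist,
                              cfg.truncate_jitter)
               for i in np.flatnonzero(emitted)]
    n_private = int(rng.poisson(cfg.private_fp_rate))
    if n_private:
        records.extend(_draw_false_positives(
            truth, n_private, rng, f"fp_private_{key.label()}_"))
    for factor, level in (("mapper", key.mapper), ("center", key.center)):
        records.extend(replace(r) for r in truth.fp_pools.get((factor, level), []))
    return CallSet(key=key, records=records)


def simulate_sample_callsets(truth: TruthTable, sample: str,
                             cfg: SimulationConfig | None = None
                             ) -> dict[FactorKey, CallSet]:
    """The complete within-sample factorial (72 call sets by default)."""
    cfg = cfg or truth.config
    return {key: simulate_callset(truth, key, cfg)
            for key in cfg.factorial_keys(sample)}


def simulate_longread(truth: TruthTable, sample: str,
                      cfg: SimulationConfig | None = None) -> CallSet:
    """A higher-sensitivity long-read-style call set for ``sample``.

    Per-type sensitivities are applied to the carried loci (long-read
    callers are weakest on duplications), breakpoints get small jitter, and
    a Poisson number of false positives is appended.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, stable_hash("longread", sample)])
    carried = np.flatnonzero(truth.carriers(sample))
    records = []
    for i in carried:
        locus = truth.loci[i]
        if rng.random() < cfg.longread_sensitivity.get(locus.svtype, 1.0):
            records.append(_jitter_record(locus, cfg.longread_jitter_sd, rng,
                                          cfg.max_dist, cfg.truncate_jitter))
    n_fp = int(rng.poisson(cfg.longread_fp_rate))
    if n_fp:
        records.extend(_draw_false_positives(truth, n_fp, rng,
                                             f"fp_longread_{sample}_"))
    return CallSet(key=f"longread|{sample}", records=records)


def end_to_end_recovery(cfg: SimulationConfig, sample: str = "LCL5",
                        target_factors=("mapper", "center", "replicate", "postproc")
                        ) -> dict:
    """Simulate, stratify every target factor, and compare to the truth.

    Returns a nested report with, per target factor: total clusters,
    support-level counts, singleton counts per level next to the configured
    recurrent pool sizes, and the truth-overlap rate by support level
    against the simulated long-read set.
    """
    from .concordance import truth_overlap
    from .stratify import StratificationPlan, stratify

    truth = simulate_truth(cfg)
    callsets = simulate_sample_callsets(truth, sample, cfg)
    longread = simulate_longread(truth, sample, cfg)

    report: dict = {"sample": sample, "n_loci": cfg.n_loci,
                    "n_carried": int(truth.carriers(sample).sum()),
                    "factors": {}}
    for factor in target_factors:
        res = stratify(callsets, StratificationPlan(target_factor=factor))
        singles_per_level = {lvl: len(res.singletons_for_level(lvl))
                             for lvl in res.levels}
        pools = cfg.recurrent_fp_pools.get(factor, {})
        comparison = truth_overlap(res.merged, longread)
        report["factors"][factor] = {
            "total": res.total,
            "support_counts": {k: len(v) for k, v in res.partitions.items()},
            "singletons_per_level": singles_per_level,
            "configured_pools": dict(pools),
            "truth_overlap_by_support": dict(comparison.rate_by_support),
        }
    return report
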