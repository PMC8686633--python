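"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

from svfactor.core import CallSet, MergeConfig, SVRecord, match

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")
from svfactor.synth import SimulationConfig


def rec(contig="chr1", start=1000, end=None, svtype="DEL", svlen=None, **kw):
    """Terse SVRecord constructor for fixtures."""
    if svtype == "INS":
        end = start
        svlen = svlen or 100
    elif end is None:
        end = start + (svlen or 500)
    return SVRecord(contig=contig, start=start, end=end, svtype=svtype,
                    svlen=svlen, **kw)


def brute_force_partition(sets, cfg: MergeConfig):
    """Independent merge oracle: enumerate all cross-set pairs, form the edge
    list, and compute connected components by repeated set union.

    Returns a frozenset of frozensets of (set_index, record_index) node ids.
    """
    nodes = [(si, ri) for si, cs in enumerate(sets) for ri in range(len(cs.records))]
    comps = [{n} for n in nodes]

    def find(n):
        for c in comps:
            if n in c:
                return c
        raise AssertionError

    for a in nodes:
        for b in nodes:
            if a >= b or a[0] == b[0]:
                continue
            if match(sets[a[0]].records[a[1]], sets[b[0]].records[b[1]], cfg):
                ca, cb = find(a), find(b)
                if ca is not cb:
                    comps.remove(cb)
                    ca |= cb
    return frozenset(frozenset(c) for c in comps)


def merged_partition(merged, sets):
    """Express a MergedSet's clusters in the oracle's node-id vocabulary.

    Record identity is recovered by (source_index, id) lookup, so input
    records must carry unique ids within each set.
    """
    lookup = {}
    for si, cs in enumerate(sets):
        for ri, r in enumerate(cs.records):
            lookup[(si, r.id)] = (si, ri)
    return frozenset(
        frozenset(lookup[(m.source_index, m.id)] for m in c.members)
        for c in merged.clusters)


def random_callsets(rng: random.Random, n_sets=3, max_records=5, span=20000,
                    jitter=1000):
    """Small random call sets with unique ids, for oracle comparisons."""
    sets = []
    anchors = [rng.randrange(1000, span) for _ in range(max_records)]
    for si in range(n_sets):
        records = []
        for ri in range(rng.randint(0, max_records)):
            base = rng.choice(anchors)
            start = max(1, base + rng.randint(-jitter, jitter))
            size = rng.randint(60, 400)
            svtype = rng.choice(["DEL", "INS", "DUP", "INV"])
            end = start if svtype == "INS" else start + size
            records.append(SVRecord(contig=rng.choice(["chr1", "chr2"]),
                                    start=start, end=end, svtype=svtype,
                                    svlen=size, id=f"s{si}r{ri}"))
        sets.append(CallSet(key=f"set{si}", records=records))
    return sets


def unit_sim_config(**overrides) -> SimulationConfig:
    """A small, noiseless simulation config; tests override what they study."""
    mappers = overrides.pop("mappers", ("BWA-MEM", "Bowtie2", "Isaac", "Stampy"))
    defaults = dict(
        genome=(("chr1", 10_000_000), ("chr2", 10_000_000)),
        n_loci=200,
        mappers=mappers,
        base_sensitivity=1.0,
        mapper_sensitivity={m: 1.0 for m in mappers},
        center_sensitivity={c: 1.0 for c in ("Center1", "Center2", "Center3")},
        postproc_sensitivity={p: 1.0 for p in ("dedup", "recal")},
        replicate_noise=0.0,
        private_fp_rate=0.0,
        recurrent_fp_pools={"mapper": {}, "center": {}},
        jitter_sd={m: 0.0 for m in mappers},
        longread_sensitivity={t: 1.0 for t in ("DEL", "INS", "DUP", "INV")},
        longread_fp_rate=0.0,
        longread_jitter_sd=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def no_floor():
    """Merge config with no size floor, for small hand-built fixtures."""
    return MergeConfig(max_dist=1000, require_same_type=True, min_size=0)
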