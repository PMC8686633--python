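"""Tests for truth overlap, family structure and consensus analyses."""

import random

import pytest

from svfactor.concordance import (consensus_mappers, family_singleton_overlap,
                                  filter_min_read_support,
                                  pairwise_overlap_matrix,
                                  parental_support_rate, supp_vec_histogram,
                                  truth_overlap)
from svfactor.core import CallSet, MergeConfig, merge_callsets
from svfactor.synth import (simulate_callset, simulate_longread,
                            simulate_truth)
from svfactor.core import FactorKey

from conftest import random_callsets, rec, unit_sim_config

NOFLOOR = MergeConfig(max_dist=1000, min_size=0)


class TestTruthOverlap:
    def test_query_equals_truth_is_total(self):
        records = [rec(start=1000 + 20000 * i, id=f"r{i}") for i in range(10)]
        cmp_ = truth_overlap(CallSet("q", records), CallSet("t", records), NOFLOOR)
        assert cmp_.overlap_percent == 100.0

    def test_disjoint_contigs_zero(self):
        q = CallSet("q", [rec(contig="chr9", id="x")])
        t = CallSet("t", [rec(contig="chr1", id="y")])
        assert truth_overlap(q, t, NOFLOOR).overlap_percent == 0.0

    def test_empty_truth_warns(self):
        q = CallSet("q", [rec(id="x")])
        with pytest.warns(UserWarning):
            cmp_ = truth_overlap(q, CallSet("t", []), NOFLOOR)
        assert cmp_.n_overlap == 0

    def test_injected_fp_rate_recovered(self):
        # jittered true calls + 10% labeled false positives: overlap ~ 90%
        cfg = unit_sim_config(n_loci=400, seed=9, private_fp_rate=0.0,
                              jitter_sd={m: 100.0 for m in
                                         ("BWA-MEM", "Bowtie2", "Isaac", "Stampy")})
        truth = simulate_truth(cfg)
        key = FactorKey("LCL5", "Center1", "Rep1", "BWA-MEM", "dedup")
        query = simulate_callset(truth, key, cfg)
        n_true = len(query)
        n_fp = round(n_true / 9)  # ~10% of the final mix
        fp = [rec(start=9_000_000 + 30000 * i, contig="chr2", id=f"fp{i}")
              for i in range(n_fp)]
        mixed = CallSet("mixed", list(query.records) + fp)
        lr = simulate_longread(truth, "LCL5", cfg)
        got = truth_overlap(mixed, lr, NOFLOOR).overlap_percent
        expected = 100 * n_true / (n_true + n_fp)
        assert got == pytest.approx(expected, abs=3.0)

    def test_rate_by_support_from_merged_query(self):
        shared = [rec(start=1000 + 20000 * i, id=f"s{i}") for i in range(5)]
        only_a = [rec(start=500000 + 20000 * i, id=f"a{i}") for i in range(5)]
        m = merge_callsets([CallSet("a", shared + only_a), CallSet("b", shared)],
                           NOFLOOR)
        cmp_ = truth_overlap(m, CallSet("t", shared), NOFLOOR)
        assert cmp_.rate_by_support == {1: 0.0, 2: 100.0}
        assert cmp_.monotone_in_support()


class TestFamilySingletons:
    def test_identical_relatives_fully_shared(self):
        records = [rec(start=1000 + 20000 * i, id=f"r{i}") for i in range(10)]
        rep = family_singleton_overlap(records, [records], cfg=NOFLOOR)
        assert rep.shared_percent == 100.0

    def test_empty_relatives_nothing_shared(self):
        records = [rec(id="x")]
        rep = family_singleton_overlap(records, [[]], cfg=NOFLOOR)
        assert rep.n_family_shared == 0
        assert rep.unique_percent == 100.0

    def test_published_sharing_arithmetic(self):
        # 696 proband singletons of which 417 recur in relatives -> 59.91%
        proband = [rec(start=1000 + 20000 * i, id=f"p{i}") for i in range(696)]
        relatives = [proband[:417]]
        rep = family_singleton_overlap(proband, relatives, cfg=NOFLOOR)
        assert rep.n_family_shared == 417
        assert rep.shared_percent == pytest.approx(59.91)

    def test_partition_is_exact(self):
        rng = random.Random(21)
        sets = random_callsets(rng, n_sets=3, max_records=15)
        rep = family_singleton_overlap(sets[0].records,
                                       [sets[1].records, sets[2].records],
                                       cfg=NOFLOOR)
        assert rep.n_family_shared + rep.n_unique == rep.n_singletons


class TestParentalSupport:
    def test_superset_parents_full_support(self):
        twin = CallSet("twin", [rec(start=1000 + 20000 * i, id=f"t{i}")
                                for i in range(5)])
        parents = [CallSet("p", twin.records + [rec(start=900000, id="extra")])]
        df = parental_support_rate([twin], parents, NOFLOOR)
        assert df["percent"].tolist() == [100.0]

    def test_disjoint_parents_zero(self):
        twin = CallSet("twin", [rec(id="t")])
        parents = [CallSet("p", [rec(start=700000, id="p")])]
        df = parental_support_rate([twin], parents, NOFLOOR)
        assert df["percent"].tolist() == [0.0]

    def test_mendelian_simulation_full_support_at_zero_jitter(self):
        # every twin call is inherited, parents detect everything:
        # parental support is exactly 100%
        cfg = unit_sim_config(n_loci=150, seed=31)
        truth = simulate_truth(cfg)
        twin_sets, parent_sets = [], []
        for center in cfg.centers:
            for rep_ in cfg.replicates:
                for s in ("LCL5", "LCL6"):
                    twin_sets.append(simulate_callset(
                        truth, FactorKey(s, center, rep_, "BWA-MEM", "dedup"), cfg))
                for s in ("LCL7", "LCL8"):
                    parent_sets.append(simulate_callset(
                        truth, FactorKey(s, center, rep_, "BWA-MEM", "dedup"), cfg))
        df = parental_support_rate(twin_sets, parent_sets, NOFLOOR)
        assert (df["percent"] == 100.0).all()


class TestPairwiseMatrix:
    def test_identical_sets_all_100(self):
        records = [rec(start=1000 + 20000 * i, id=f"r{i}") for i in range(4)]
        mat = pairwise_overlap_matrix([CallSet("a", records),
                                       CallSet("b", records)], NOFLOOR)
        assert (mat == 100.0).all().all()

    def test_disjoint_sets_zero_off_diagonal(self):
        mat = pairwise_overlap_matrix(
            [CallSet("a", [rec(id="x")]),
             CallSet("b", [rec(start=800000, id="y")])], NOFLOOR)
        assert mat.loc["a", "b"] == 0.0
        assert mat.loc["a", "a"] == 100.0

    def test_nested_sets_asymmetric(self):
        inner = [rec(start=1000 + 20000 * i, id=f"r{i}") for i in range(5)]
        outer = inner + [rec(start=700000 + 20000 * i, id=f"o{i}")
                         for i in range(5)]
        mat = pairwise_overlap_matrix([CallSet("A", inner), CallSet("B", outer)],
                                      NOFLOOR)
        assert mat.loc["A", "B"] == 100.0
        assert mat.loc["B", "A"] == 50.0  # |A| / |B|


class TestReadSupportFilter:
    def test_threshold(self):
        records = [rec(start=1000 + 20000 * i, id=str(s), read_support=s)
                   for i, s in enumerate([0, 1, 5])]
        assert [r.id for r in filter_min_read_support(records, 1)] == ["1", "5"]
        assert filter_min_read_support(records[:1], 1) == []
        assert filter_min_read_support(records, 0) == records

    def test_missing_annotation_is_an_error(self):
        with pytest.raises(ValueError, match="naked"):
            filter_min_read_support([rec(id="naked")], 1)


class TestSuppVecHistogram:
    def test_single_input_all_mass_at_one(self):
        m = merge_callsets([CallSet("only", [rec(start=1000 + 20000 * i, id=str(i))
                                             for i in range(7)])], NOFLOOR)
        counts, marginals = supp_vec_histogram(m)
        assert counts == {1: 7}
        assert marginals == {"only": 7}

    def test_identical_inputs_full_support(self):
        records = [rec(start=1000 + 20000 * i, id=f"r{i}") for i in range(4)]
        m = merge_callsets([CallSet(l, records) for l in "abc"], NOFLOOR)
        counts, marginals = supp_vec_histogram(m)
        assert counts == {1: 0, 2: 0, 3: 4}
        assert all(v == 4 for v in marginals.values())

    def test_matches_bitstring_recount(self):
        rng = random.Random(17)
        sets = random_callsets(rng, n_sets=4, max_records=12)
        m = merge_callsets(sets, NOFLOOR)
        counts, marginals = supp_vec_histogram(m)
        # independent recount straight from the SUPP_VEC strings
        vecs = [c.support_vector for c in m.clusters]
        for k in counts:
            assert counts[k] == sum(1 for v in vecs if v.count("1") == k)
        for i, label in enumerate(m.inputs):
            assert marginals[label] == sum(1 for v in vecs if v[i] == "1")


class TestConsensusMappers:
    def test_single_mapper_identity(self):
        cs = CallSet("bwa", [rec(start=1000 + 20000 * i, id=f"r{i}")
                             for i in range(6)])
        res = consensus_mappers({"bwa": cs}, ["bwa"], cfg=NOFLOOR)
        assert res.count == 6

    def test_disjoint_mappers_empty_intersection(self):
        a = CallSet("a", [rec(id="x")])
        b = CallSet("b", [rec(start=900000, id="y")])
        res = consensus_mappers({"a": a, "b": b}, ["a", "b"], cfg=NOFLOOR)
        assert res.count == 0

    def test_unknown_mapper_rejected(self):
        with pytest.raises(KeyError):
            consensus_mappers({"a": CallSet("a", [])}, ["nope"], cfg=NOFLOOR)

    def test_intersection_removes_independent_fps(self):
        # two mappers with ~20% independent FPs: the intersection keeps the
        # shared true calls and drops (nearly) all FPs
        rng = random.Random(23)
        true = [rec(start=10000 + 30000 * i, id=f"t{i}") for i in range(100)]
        sets = {}
        for name, offset in (("A", 5_000_000), ("B", 7_000_000)):
            keep = [r for r in true if rng.random() < 0.9]
            fps = [rec(start=offset + 30000 * j, id=f"{name}fp{j}")
                   for j in range(20)]
            sets[name] = CallSet(name, keep + fps)
        truth = CallSet("truth", true)
        res = consensus_mappers(sets, ["A", "B"], truth, NOFLOOR)
        assert res.count <= min(len(sets["A"]), len(sets["B"]))
        assert res.truth_overlap_percent == 100.0  # all FPs eliminated
        assert res.count == pytest.approx(100 * 0.9 * 0.9, abs=15)
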