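"""Shifting score, scaled-cumulative K-S test and FDR calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cageforge import sim
from cageforge.cluster import cluster_dist
from cageforge.consensus import build_consensus
from cageforge.ctss import CtssTable
from cageforge.shifting import (fdr_adjust, group_cumulatives, ks_compare,
                                score_shifting, shifting_score)


def brute_bh(p):
    """max over the tail of p * m / rank, clipped at 1 (step-up definition)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    adj = [p[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m):
        out[order[i]] = min(1.0, min(adj[i:]))
    return out


def independent_ks_p(D, n1, n2, terms=50):
    ne = n1 * n2 / (n1 + n2)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * D
    return 2 * sum((-1) ** (j - 1) * math.exp(-2 * j * j * lam * lam)
                   for j in range(1, terms + 1))


class TestShiftingScore:
    def test_identical_profiles_score_zero(self):
        F = np.array([10.0, 30.0, 60.0])
        assert shifting_score(F, F.copy()) == 0.0

    def test_fully_disjoint_profiles_score_one(self):
        # lower group entirely upstream of the higher group
        F1 = np.array([50.0, 50.0, 50.0])
        F2 = np.array([0.0, 0.0, 100.0])
        assert shifting_score(F1, F2) == 1.0

    def test_forty_sixty_vs_hundred_scores_0_4(self):
        # L: 40 units at pos 5 + 60 at pos 20; H: 100 at pos 20 — at least
        # 40% of L's initiation is outside H's region
        F_L = np.array([40.0, 100.0])
        F_H = np.array([0.0, 100.0])
        assert shifting_score(F_L, F_H) == pytest.approx(0.4)

    def test_downstream_shift_caught_by_reverse_scan(self):
        # L initiates downstream of H: forward scan never sees L ahead,
        # the 3'->5' scan does
        F_L = np.array([0.0, 0.0, 50.0])
        F_H = np.array([100.0, 100.0, 100.0])
        assert shifting_score(F_L, F_H) == pytest.approx(1.0)

    def test_symmetric_under_group_exchange(self):
        F1 = np.array([10.0, 40.0, 70.0])
        F2 = np.array([30.0, 50.0, 90.0])
        assert shifting_score(F1, F2) == shifting_score(F2, F1)

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                    min_size=1, max_size=30).filter(
               lambda v: sum(a for a, _ in v) > 0 and sum(b for _, b in v) > 0),
           st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=60)
    def test_scale_invariant_and_bounded(self, increments, scale):
        F1 = np.cumsum([float(a) for a, _ in increments])
        F2 = np.cumsum([float(b) for _, b in increments])
        s = shifting_score(F1, F2)
        assert s <= 1.0 + 1e-12
        assert shifting_score(F1 * scale, F2 * scale) == pytest.approx(s)


class TestKsCompare:
    def test_equal_cumulatives_give_p_one(self):
        F = np.array([5.0, 9.0, 20.0])
        D, p = ks_compare(F, F.copy(), 100, 100)
        assert D == 0 and p == 1.0

    def test_matches_independent_series_evaluation(self):
        F1 = np.array([0.2, 1.0])
        F2 = np.array([0.0, 1.0])
        D, p = ks_compare(F1, F2, 100, 100)
        assert D == pytest.approx(0.2)
        assert p == pytest.approx(independent_ks_p(0.2, 100, 100), abs=1e-10)
        assert p == pytest.approx(0.0314, abs=5e-4)

    def test_p_monotone_decreasing_in_D(self):
        ps = []
        for D in (0.05, 0.1, 0.2, 0.4, 0.8):
            F1 = np.array([D, 1.0])
            F2 = np.array([0.0, 1.0])
            ps.append(ks_compare(F1, F2, 200, 200)[1])
        assert ps == sorted(ps, reverse=True)

    def test_non_monotone_cumulative_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            ks_compare(np.array([5.0, 3.0]), np.array([1.0, 2.0]), 10, 10)

    def test_null_p_values_roughly_uniform(self):
        # both groups resampled from one profile: p should be ~U(0,1)
        # wide support keeps ties rare, the regime where the asymptotic
        # two-sample formula is calibrated; coarse supports make it
        # conservative (p too large), never anti-conservative
        rng = np.random.default_rng(17)
        profile = rng.dirichlet(np.full(4000, 5.0))
        ps = []
        for _ in range(2000):
            c1 = rng.multinomial(1000, profile)
            c2 = rng.multinomial(1000, profile)
            _, p = ks_compare(np.cumsum(c1).astype(float),
                              np.cumsum(c2).astype(float), 1000, 1000)
            ps.append(p)
        ps = np.sort(ps)
        grid = (np.arange(1, 2001) - 0.5) / 2000
        assert np.abs(ps - grid).max() < 0.05


class TestFdrAdjust:
    def test_step_up_arithmetic_by_hand(self):
        got = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 0.0])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=200)
    def test_matches_brute_force_definition(self, ps):
        assert np.allclose(fdr_adjust(ps), brute_bh(np.array(ps)))


def _shift_dataset(seed=13, n_promoters=500, n_shift=50, depth=None,
                   shift_offset=40):
    specs = sim.generate_promoterome(
        seed=seed, n_promoters=n_promoters, sharp_fraction=0.5, alpha=1.25,
        n_samples=2, shift_fraction=n_shift / n_promoters,
        shift_offset=shift_offset, genome_length=250_000, min_expression=1)
    # equalize expression so every promoter gets ~500 tags
    for s in specs:
        s.per_sample_expression = np.full(2, 100.0)
    depth = depth or 500 * n_promoters
    table, truth, _ = sim.generate_ctss(specs, seed=seed,
                                        depth_per_sample=depth,
                                        noise_rate=0.0,
                                        genome_length=250_000)
    return specs, table, truth


class TestScoreShifting:
    def test_group_cumulatives_additive_and_total_matches(self):
        recs = [("chr1", 10, "+"), ("chr1", 20, "+")]
        counts = np.array([[3.0, 3.0, 1.0], [0.0, 0.0, 5.0]])
        t = CtssTable.from_records(recs, counts, ["a", "b", "c"])
        t.normalized = True
        ccs = build_consensus({s: cluster_dist(t, s, 20) for s in t.sample_ids},
                              t, tpm_threshold=0.5, max_gap=50)
        pos, F1, F2 = group_cumulatives(ccs[0], t, ["a", "b"], ["c"])
        assert F1.tolist() == [6.0, 6.0]
        assert F2.tolist() == [1.0, 6.0]

    def test_planted_shifts_detected_with_few_false_calls(self):
        specs, table, truth = _shift_dataset()
        ntab = table.with_signal(table.data[table.sample_ids]
                                 .to_numpy(dtype=float), normalized=True)
        clusters = {s: cluster_dist(ntab, s, 20) for s in ntab.sample_ids}
        ccs = build_consensus(clusters, ntab, tpm_threshold=5, max_gap=100)
        res = score_shifting(ccs, ntab, ["sample_1"], ["sample_2"],
                             raw_table=table, score_min=0.6, fdr_max=0.01)
        # map consensus calls back to planted truth by span overlap
        planted = truth[(truth["sample"] == "sample_2")]
        planted = {(r.chrom, r.strand, r.anchor): r.shifted
                   for r in planted.itertuples()}
        by_id = {row.consensus_id: row for row in res.itertuples()}
        index = {cc.id: cc for cc in ccs}
        calls = {}
        for cid, row in by_id.items():
            cc = index[cid]
            for key in planted:
                chrom, strand, anchor = key
                if (chrom == cc.chrom and strand == cc.strand
                        and cc.start - 60 <= anchor <= cc.end + 60):
                    calls[key] = calls.get(key, False) or bool(row.is_shifting)
        tp = sum(1 for k, v in planted.items() if v and calls.get(k, False))
        fp = sum(1 for k, v in planted.items() if not v and calls.get(k, False))
        n_planted = sum(planted.values())
        assert tp / n_planted >= 0.9
        assert fp <= 1

    def test_zero_signal_promoters_skipped(self):
        recs = [("chr1", 10, "+")]
        t = CtssTable.from_records(recs, np.array([[5.0, 0.0]]), ["a", "b"])
        t.normalized = True
        ccs = build_consensus({s: cluster_dist(t, s, 20) for s in t.sample_ids},
                              t, tpm_threshold=0.5, max_gap=50)
        res = score_shifting(ccs, t, ["a"], ["b"])
        assert len(res) == 0 and res.attrs["skipped"] == [ccs[0].id]

    def test_call_thresholds(self):
        # high score + low fdr -> shifting; high fdr -> not
        specs, table, _ = _shift_dataset(n_promoters=60, n_shift=20,
                                         depth=30_000)
        ntab = table.with_signal(table.data[table.sample_ids]
                                 .to_numpy(dtype=float), normalized=True)
        clusters = {s: cluster_dist(ntab, s, 20) for s in ntab.sample_ids}
        ccs = build_consensus(clusters, ntab, tpm_threshold=5, max_gap=100)
        res = score_shifting(ccs, ntab, ["sample_1"], ["sample_2"],
                             raw_table=table)
        for row in res.itertuples():
            assert row.is_shifting == (row.fdr <= 0.01
                                       and row.shifting_score >= 0.6)
            if row.fdr <= 0.01 and not row.is_shifting:
                assert row.pattern == "complex"
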