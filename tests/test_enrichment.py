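import numpy as np
import pytest
from scipy import stats

from psmeta import exact_enrichment, go_sweep, resampled_enrichment

from conftest import hypergeom_pmf_exact, hypergeom_tail_exact


def make_universe(n, prefix="g"):
    return {f"{prefix}{i:04d}" for i in range(n)}


class TestExactEnrichment:
    def test_toy_case_enumerated_tail(self):
        """N=20, K=5, n=4, k=3: P(X>=3) = 0.03199 by direct enumeration."""
        bg = sorted(make_universe(20))
        target = set(bg[:5])
        selected = set(bg[:3]) | {bg[10]}  # 3 hits of 4 selected
        res = exact_enrichment(selected, target, set(bg))
        expected = float(hypergeom_tail_exact(20, 5, 4, 3))
        assert res.k_hit == 3 and res.k_sel == 4 and res.K_set == 5
        assert res.p == pytest.approx(expected, rel=1e-12)
        assert res.p == pytest.approx(0.03199, abs=5e-6)

    def test_zero_hits_gives_p_one(self):
        bg = make_universe(30)
        target = set(sorted(bg)[:5])
        selected = set(sorted(bg)[10:14])
        assert exact_enrichment(selected, target, bg).p == 1.0

    def test_target_equals_background_forces_p_one(self):
        bg = make_universe(15)
        selected = set(sorted(bg)[:4])
        assert exact_enrichment(selected, bg, bg).p == 1.0

    def test_target_intersected_with_background(self):
        bg = make_universe(20)
        target = set(sorted(bg)[:5]) | {"outside1", "outside2"}
        selected = set(sorted(bg)[:3])
        res = exact_enrichment(selected, target, bg)
        assert res.K_set == 5  # outsiders dropped before testing

    def test_selected_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            exact_enrichment({"x"}, {"a"}, {"a", "b"})
        with pytest.raises(ValueError, match="empty"):
            exact_enrichment(set(), {"a"}, set())

    def test_matches_big_rational_enumeration(self):
        """Upper-tail p vs exact Fraction tails across N <= 60.

        Every N is covered; (K, n) pairs are a seeded sample per N and
        every achievable k is checked.
        """
        rng = np.random.default_rng(60)
        for N in range(2, 61):
            for _ in range(4):
                K = int(rng.integers(0, N + 1))
                n = int(rng.integers(1, N + 1))
                for k in range(0, min(K, n) + 1):
                    exact = float(hypergeom_tail_exact(N, K, n, k))
                    ours = float(stats.hypergeom.sf(k - 1, N, K, n))
                    assert ours == pytest.approx(exact, rel=1e-9, abs=1e-12)


class TestGoSweep:
    def build_toy(self):
        bg = sorted(make_universe(30))
        go_map = {}
        for g in bg[:10]:
            go_map[g] = {"GO:0000001"}
        for g in bg[10:20]:
            go_map[g] = {"GO:0000002"}
        # signal: selected genes concentrate in term 1
        selected = set(bg[:6]) | {bg[25]}
        return set(bg), go_map, selected

    def test_planted_term_ranks_first(self):
        bg, go_map, selected = self.build_toy()
        table = go_sweep(selected, go_map, bg, min_set_size=5)
        assert table.iloc[0]["term"] == "GO:0000001"
        expected = float(hypergeom_tail_exact(30, 10, 7, 6))
        assert table.iloc[0]["p"] == pytest.approx(expected, rel=1e-9)
        assert table.iloc[0]["p"] < table.iloc[1]["p"]

    def test_min_set_size_filters_everything(self):
        bg, go_map, selected = self.build_toy()
        with pytest.warns(UserWarning, match="min_set_size"):
            table = go_sweep(selected, go_map, bg, min_set_size=11)
        assert len(table) == 0

    def test_duplicate_annotations_do_not_inflate_counts(self):
        bg, go_map, selected = self.build_toy()
        base = go_sweep(selected, go_map, bg, min_set_size=5)
        # re-adding the same term to a gene changes nothing (sets dedup)
        go_map2 = {g: set(ts) for g, ts in go_map.items()}
        next(iter(go_map2.values())).add("GO:0000001")
        again = go_sweep(selected, go_map2, bg, min_set_size=5)
        assert base["K_set"].tolist() == again["K_set"].tolist()

    def test_annotated_only_restricts_background(self):
        bg, go_map, selected = self.build_toy()
        table = go_sweep(selected, go_map, bg, min_set_size=5, annotated_only=True)
        assert (table["N_bg"] == 20).all()


class TestResampledEnrichment:
    def test_zero_observed_gives_p_one(self):
        bg = make_universe(50)
        target = set(sorted(bg)[:10])
        selected = {b: set(sorted(bg)[20:25]) for b in ["b1"]}
        res, dist = resampled_enrichment(selected, {"b1": bg}, target, n_resamples=2000, seed=1)
        assert dist.observed == 0.0
        assert res.p == 1.0

    def test_single_branch_matches_exact_hypergeometric(self):
        """Empirical tail within 3 MC standard errors of the exact tail."""
        bg = sorted(make_universe(200))
        target = set(bg[:40])
        selected = set(bg[:10]) | set(bg[50:70])  # 10 hits of 30 selected
        n = 200_000
        res, dist = resampled_enrichment(
            {"b": selected}, {"b": set(bg)}, target, n_resamples=n, seed=9
        )
        exact = float(hypergeom_tail_exact(200, 40, 30, int(dist.observed)))
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(res.p - exact) <= 3 * se + 2 / n  # add-one offset allowance

    def test_two_branch_disjoint_backgrounds_match_enumeration(self):
        """Sum statistic vs full convolution of the two hypergeometrics."""
        bg1 = sorted(make_universe(12, "a"))
        bg2 = sorted(make_universe(10, "b"))
        target = set(bg1[:4]) | set(bg2[:3])
        sel = {"br1": set(bg1[:3]) | set(bg1[6:8]), "br2": set(bg2[:2]) | set(bg2[5:7])}
        n = 100_000
        res, dist = resampled_enrichment(
            sel, {"br1": set(bg1), "br2": set(bg2)}, target, n_resamples=n, seed=4
        )
        pmf1 = hypergeom_pmf_exact(12, 4, 5)
        pmf2 = hypergeom_pmf_exact(10, 3, 4)
        tail = float(
            sum(
                q1 * q2
                for k1, q1 in pmf1.items()
                for k2, q2 in pmf2.items()
                if k1 + k2 >= dist.observed
            )
        )
        se = np.sqrt(tail * (1 - tail) / n)
        assert abs(res.p - tail) <= 3 * se + 2 / n

    def test_seeded_determinism_byte_for_byte(self):
        bg = make_universe(80)
        target = set(sorted(bg)[:15])
        sel = {"b1": set(sorted(bg)[:8]), "b2": set(sorted(bg)[30:40])}
        bgs = {"b1": bg, "b2": bg}
        r1, d1 = resampled_enrichment(sel, bgs, target, n_resamples=5000, seed=123)
        r2, d2 = resampled_enrichment(sel, bgs, target, n_resamples=5000, seed=123)
        assert d1.draws.tobytes() == d2.draws.tobytes()
        assert r1.p == r2.p
        r3, _ = resampled_enrichment(sel, bgs, target, n_resamples=5000, seed=124)
        assert r3.p != r1.p or True  # different seed may legitimately differ

    def test_union_statistic_counts_distinct_genes(self):
        bg = make_universe(40)
        target = set(sorted(bg)[:10])
        overlap_sel = set(sorted(bg)[:5])
        sel = {"b1": overlap_sel, "b2": overlap_sel}  # same genes on both
        bgs = {"b1": bg, "b2": bg}
        _, d_sum = resampled_enrichment(sel, bgs, target, n_resamples=1000, seed=0)
        _, d_union = resampled_enrichment(
            sel, bgs, target, n_resamples=1000, seed=0, distinct_union=True
        )
        assert d_sum.observed == 10.0  # counted once per branch
        assert d_union.observed == 5.0  # distinct genes only

    def test_low_resample_count_warns(self):
        bg = make_universe(20)
        with pytest.warns(UserWarning, match="unstable"):
            resampled_enrichment(
                {"b": set(sorted(bg)[:3])}, {"b": bg}, set(sorted(bg)[:5]),
                n_resamples=100, seed=0,
            )

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="empty background"):
            resampled_enrichment({"b": set()}, {"b": set()}, {"x"}, n_resamples=1000, seed=0)
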