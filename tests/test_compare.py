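"""Profile correlations, position sets, KS contrasts, permutation tests."""

import numpy as np
import pandas as pd
import pytest

import timscan as ts
from timscan.alphabet import AA20
from timscan.compare import PositionProfile
from conftest import make_landscape


def profile(values, position=1, wt="A"):
    return PositionProfile(
        position=position, wt_residue=wt, values=pd.Series(values, index=list(AA20))
    )


class TestProfileCorrelation:
    def test_identical_profiles(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20)
        assert ts.profile_correlation(profile(v), profile(v, wt="L")) == pytest.approx(1.0)

    def test_negated_profile(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=20)
        r = ts.profile_correlation(profile(v), profile(-v, wt="L"))
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        """From-scratch cov/(sd*sd) over the shared 19-value outcome set."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            x, y = rng.normal(size=(2, 20))
            p, q = profile(x, wt="A"), profile(y, wt="A")
            keep = [i for i, aa in enumerate(AA20) if aa != "A"]
            xs, ys = x[keep], y[keep]
            expected = float(
                np.mean((xs - xs.mean()) * (ys - ys.mean())) / (xs.std() * ys.std())
            )
            assert ts.profile_correlation(p, q) == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance_and_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 20))
        p, q = profile(x), profile(y, wt="C")
        r = ts.profile_correlation(p, q)
        assert ts.profile_correlation(q, p) == pytest.approx(r, abs=1e-12)
        scaled = profile(3.0 * x + 1.7)
        assert ts.profile_correlation(scaled, q) == pytest.approx(r, abs=1e-12)

    def test_zero_variance_undefined(self):
        r = ts.profile_correlation(profile(np.ones(20)), profile(np.arange(20.0), wt="L"))
        assert r is None

    def test_wt_policy_excludes_both_wt_residues(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 20))
        p, q = profile(x, wt="A"), profile(y, wt="C")
        keep = [i for i, aa in enumerate(AA20) if aa not in "AC"]
        expected = float(np.corrcoef(x[keep], y[keep])[0, 1])
        assert ts.profile_correlation(p, q) == pytest.approx(expected, abs=1e-12)
        full = float(np.corrcoef(x, y)[0, 1])
        assert ts.profile_correlation(p, q, policy="include_all_20") == pytest.approx(
            full, abs=1e-12
        )

    def test_vectorized_agrees_with_scalar(self, trio_rho_half):
        lands, maps = trio_rho_half
        a, b = lands["orthoA"], lands["orthoB"]
        pairs = ts.build_position_set(a, b, "aligned", alignment=maps[("orthoA", "orthoB")])
        dist = ts.correlation_distribution(a, b, pairs, "aligned")
        pa = ts.position_profiles(a)
        pb = ts.position_profiles(b)
        scalars = [
            ts.profile_correlation(pa[i], pb[j]) for i, j in pairs
        ]
        scalars = np.array([r for r in scalars if r is not None])
        assert np.allclose(np.sort(dist.r_values), np.sort(scalars), atol=1e-12)


class TestBuildPositionSet:
    def test_identical_wt_enumeration(self):
        a = make_landscape(np.zeros((3, 20)) + np.arange(20), wt_aa=list("ALG"))
        b = make_landscape(np.zeros((3, 20)) + np.arange(20), wt_aa=list("LAG"))
        pairs = ts.build_position_set(a, b, "identical_wt")
        assert set(pairs) == {(1, 2), (2, 1), (3, 3)}

    def test_aligned_set_size(self, trio_rho_half):
        lands, maps = trio_rho_half
        pairs = ts.build_position_set(
            lands["orthoA"], lands["orthoB"], "aligned",
            alignment=maps[("orthoA", "orthoB")],
        )
        assert len(pairs) == 80

    def test_set_algebra(self, trio_rho_half):
        lands, maps = trio_rho_half
        a, b = lands["orthoA"], lands["orthoB"]
        amap = maps[("orthoA", "orthoB")]
        aligned = set(ts.build_position_set(a, b, "aligned", alignment=amap))
        nonid = set(ts.build_position_set(a, b, "aligned_nonidentical", alignment=amap))
        identical = set(ts.build_position_set(a, b, "identical_wt"))
        null = set(ts.build_position_set(a, b, "null_all_pairs"))
        assert nonid <= aligned
        assert not (nonid & identical)
        for label_set in (aligned, nonid, identical):
            assert label_set <= null

    def test_fourfold_matches_same_cell(self, trio_rho_half):
        lands, _ = trio_rho_half
        a, b = lands["orthoA"], lands["orthoB"]
        pairs = ts.build_position_set(a, b, "fourfold")
        # identity layout: same (quadrant, offset) means same position index
        assert set(pairs) == {(p, p) for p in a.positions()}

    def test_unknown_label(self, trio_rho_half):
        lands, _ = trio_rho_half
        with pytest.raises(ValueError, match="unknown set label"):
            ts.build_position_set(lands["orthoA"], lands["orthoB"], "bogus")


class TestKS:
    def test_identical_samples_zero_statistic(self):
        x = np.linspace(-1, 1, 50)
        d, p = ts.compare_distributions_ks(x, x)
        assert d == 0.0

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="fewer than 5"):
            ts.compare_distributions_ks(np.array([0.1, 0.2]), np.linspace(0, 1, 100))

    def test_null_pvalues_roughly_uniform(self):
        """KS p-values under the null are themselves uniform."""
        from scipy import stats as sps

        rng = np.random.default_rng(9)
        # unequal sizes keep the discrete KS statistic fine-grained enough
        # for its p-values to look continuous
        pvals = [
            ts.compare_distributions_ks(rng.normal(size=137), rng.normal(size=211))[1]
            for _ in range(300)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestBeneficialFractionTest:
    def test_observed_fraction(self):
        s = np.full((4, 20), -1.0)
        s[0, :2] = 0.1  # position 1: 2 of 19 substitutions beneficial
        land = make_landscape(s, wt_aa=list("WWWW"))
        res = ts.beneficial_fraction_test(land, [1], n_perm=100, seed=0)
        assert res.observed == pytest.approx(2 / 19)

    def test_maximal_separation(self):
        s = np.vstack([np.full((5, 20), 0.5), np.full((15, 20), -0.9)])
        land = make_landscape(s, wt_aa=["W"] * 20)
        res = ts.beneficial_fraction_test(land, [1, 2, 3, 4, 5], n_perm=2000, seed=1)
        assert res.observed == 1.0
        assert res.p_value <= 2 / 2001

    def test_subset_equals_all_rejected(self):
        land = make_landscape(np.random.default_rng(0).normal(size=(6, 20)))
        with pytest.raises(ValueError, match="no null contrast"):
            ts.beneficial_fraction_test(land, range(1, 7))

    def test_null_calibration_quick(self):
        """Random subsets of a homogeneous landscape give ~uniform p."""
        rng = np.random.default_rng(10)
        hits = 0
        trials = 200
        for _ in range(trials):
            land = make_landscape(rng.normal(-0.2, 0.3, size=(120, 20)), rng=rng)
            subset = rng.choice(np.arange(1, 121), size=40, replace=False)
            res = ts.beneficial_fraction_test(
                land, subset, n_perm=500, seed=int(rng.integers(2**31))
            )
            hits += res.p_value < 0.05
        assert 0.01 <= hits / trials <= 0.09


class TestTransformative:
    def test_identical_wt_everywhere_empty(self):
        a = make_landscape(np.random.default_rng(0).normal(size=(4, 20)), wt_aa=list("ALGW"))
        b = make_landscape(np.random.default_rng(1).normal(size=(4, 20)), wt_aa=list("ALGW"))
        amap = ts.AlignmentMap(
            pairs=pd.DataFrame(
                {"pos_a": [1, 2, 3, 4], "aa_a": list("ALGW"),
                 "pos_b": [1, 2, 3, 4], "aa_b": list("ALGW")}
            )
        )
        tset, summary = ts.transformative_analysis(a, b, amap)
        assert summary["n_transformative"] == 0
        assert len(tset.mutations) == 0

    def test_toy_enumeration(self):
        sa = np.zeros((2, 20))
        sa[0, list(AA20).index("V")] = 0.1  # A position 1, mutation to V
        a = make_landscape(sa, wt_aa=list("AL"), orthologue="A")
        b = make_landscape(np.zeros((2, 20)), wt_aa=list("VL"), orthologue="B")
        amap = ts.AlignmentMap(
            pairs=pd.DataFrame(
                {"pos_a": [1, 2], "aa_a": list("AL"), "pos_b": [1, 2], "aa_b": list("VL")}
            )
        )
        tset, summary = ts.transformative_analysis(a, b, amap)
        from_a = tset.mutations[tset.mutations.orthologue == "A"]
        assert from_a[["position", "target"]].values.tolist() == [[1, "V"]]
        assert from_a.s.iloc[0] == pytest.approx(0.1)

    def test_planted_detrimental_fraction_recovered(self):
        """31% of transformative cells planted below -0.5 are recovered."""
        rng = np.random.default_rng(11)
        n = 100
        wt_a = np.array(list(AA20))[rng.choice(20, size=n)]
        shift = rng.choice(19, size=n)
        wt_b = np.array(
            [AA20[(list(AA20).index(a) + 1 + s) % 20] for a, s in zip(wt_a, shift)]
        )
        sa = rng.normal(-0.2, 0.1, size=(n, 20))
        detrimental = rng.random(n) < 0.31
        for i in range(n):
            j = list(AA20).index(wt_b[i])
            sa[i, j] = -0.8 if detrimental[i] else 0.0
        a = make_landscape(sa, wt_aa=wt_a, orthologue="A")
        b = make_landscape(np.full((n, 20), -0.2), wt_aa=wt_b, orthologue="B")
        amap = ts.AlignmentMap(
            pairs=pd.DataFrame(
                {"pos_a": np.arange(1, n + 1), "aa_a": wt_a,
                 "pos_b": np.arange(1, n + 1), "aa_b": wt_b}
            )
        )
        tset, summary = ts.transformative_analysis(a, b, amap)
        from_a = tset.mutations[tset.mutations.orthologue == "A"]
        assert len(from_a) == n
        assert (from_a.s < -0.5).mean() == pytest.approx(detrimental.mean())


class TestFrameworkProperties:
    def test_fourfold_rho_one_mode_at_one(self):
        lands, _ = ts.simulate_landscape_trio(
            ts.LandscapeTrioConfig(n_positions=80, rho=1.0, seed=12)
        )
        a, b = lands["orthoA"], lands["orthoB"]
        pairs = ts.build_position_set(a, b, "fourfold")
        dist = ts.correlation_distribution(a, b, pairs, "fourfold",
                                           policy="include_all_20")
        assert np.allclose(dist.r_values, 1.0)
        assert dist.mode == pytest.approx(0.95, abs=0.051)

    def test_replicate_baseline_exceeds_cross_orthologue(self):
        """A noisy re-measurement of a landscape correlates with it better
        than a diverged orthologue does."""
        rng = np.random.default_rng(13)
        lands, maps = ts.simulate_landscape_trio(
            ts.LandscapeTrioConfig(n_positions=80, rho=0.6, seed=14)
        )
        a, b = lands["orthoA"], lands["orthoB"]
        rep_table = a.table.copy()
        rep_table["s"] = rep_table.s + rng.normal(0, 0.1, size=len(rep_table))
        replicate = ts.FitnessLandscape(table=rep_table)
        pairs = ts.build_position_set(a, b, "aligned", alignment=maps[("orthoA", "orthoB")])
        r_rep = ts.mean_profile_correlation(a, replicate, pairs)
        r_cross = ts.mean_profile_correlation(a, b, pairs)
        assert r_rep > r_cross
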