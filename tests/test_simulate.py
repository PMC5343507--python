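"""Synthetic-data generator: growth counts, reads, trios, MSAs."""

import numpy as np
import pandas as pd
import pytest

import timscan as ts
from timscan.alphabet import AA20, STOP
from timscan.simulate import ConfigurationError


class TestSimulationConfig:
    def test_rejects_empty_timepoints(self):
        with pytest.raises(ConfigurationError):
            ts.SimulationConfig(timepoints=())

    def test_rejects_nonincreasing_timepoints(self):
        with pytest.raises(ConfigurationError):
            ts.SimulationConfig(timepoints=(0.0, 1.0, 1.0))

    def test_rejects_negative_depth(self):
        with pytest.raises(ConfigurationError):
            ts.SimulationConfig(depth_per_timepoint=-1)

    def test_rejects_unknown_noise_model(self):
        with pytest.raises(ConfigurationError):
            ts.SimulationConfig(noise_model="gaussian")


class TestGrowthCounts:
    def test_neutral_variants_constant_log_ratio(self, small_design):
        """With all true s = 0 and noise off the mutant/WT ratio never moves."""
        true_s = {
            (int(p), o): 0.0
            for p in small_design.positions.position
            for o in ts.OUTCOME_CLASSES
        }
        cfg = ts.SimulationConfig(
            design=small_design,
            true_s=true_s,
            noise_model="none",
            timepoints=(0.0, 1.0, 2.0, 3.0),
            seed=0,
        )
        counts = ts.simulate_growth_counts(cfg)
        wt = counts.wt_series(1)
        pos = int(small_design.positions.position.iloc[0])
        mut = counts.variant_series(1, pos, "A")
        ratio = mut / wt
        assert np.allclose(ratio, ratio[0])
        rf = ts.raw_fitness(mut, wt, counts.timepoints)
        assert rf.w == pytest.approx(0.0, abs=1e-12)

    def test_exact_doubling_advantage(self, small_design):
        """True w = 1 doubles the mutant/WT ratio every WT doubling."""
        pos = int(small_design.positions.position.iloc[0])
        true_s = {
            (int(p), o): 0.0
            for p in small_design.positions.position
            for o in ts.OUTCOME_CLASSES
        }
        true_s[(pos, "A")] = 1.0
        cfg = ts.SimulationConfig(
            design=small_design,
            true_s=true_s,
            noise_model="none",
            timepoints=(0.0, 1.0, 2.0, 3.0),
            seed=0,
        )
        counts = ts.simulate_growth_counts(cfg)
        ratio = counts.variant_series(1, pos, "A") / counts.wt_series(1)
        assert np.allclose(ratio / ratio[0], [1.0, 2.0, 4.0, 8.0])

    def test_molecule_conservation(self, small_counts, small_design):
        """Multinomial sampling conserves the drawn total per time point."""
        totals = small_counts.total_per_timepoint(1)
        assert np.allclose(totals, 2000)

    def test_seed_determinism(self, small_design):
        cfg = dict(
            design=small_design,
            depth_per_timepoint=1000,
            timepoints=(0.0, 1.0, 2.0, 3.0),
            seed=42,
        )
        a = ts.simulate_growth_counts(ts.SimulationConfig(**cfg))
        b = ts.simulate_growth_counts(ts.SimulationConfig(**cfg))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.wt_counts, b.wt_counts)

    def test_truth_records_stop_at_minus_one(self, small_counts):
        stops = small_counts.truth[small_counts.truth.outcome == STOP]
        assert len(stops) == 10
        assert np.allclose(stops.s_true, -1.0)

    def test_recovery_correlation(self):
        """At depth 1e5 the estimator tracks the truth closely."""
        cfg = ts.SimulationConfig(depth_per_timepoint=1e5, seed=5)
        counts = ts.simulate_growth_counts(cfg)
        land = ts.estimate_landscape(counts, counts.design)
        merged = land.table.merge(counts.truth, on=["library", "position", "outcome"])
        ok = merged.s.notna()
        r = np.corrcoef(merged.s[ok], merged.s_true[ok])[0, 1]
        assert r >= 0.95


class TestEmitReads:
    def test_round_trip_single_variant(self, small_design):
        pos = int(small_design.positions.position.iloc[2])
        counts = ts.CountTimeSeries(
            counts=pd.DataFrame(
                {
                    "library": 1,
                    "position": pos,
                    "outcome": ["A"] * 2,
                    "codon": "GCC",
                    "timepoint": [0.0, 1.0],
                    "count": [7, 4],
                }
            ),
            wt_counts=pd.DataFrame(
                {"library": 1, "timepoint": [0.0, 1.0], "count": [10, 10]}
            ),
            timepoints=(0.0, 1.0),
        )
        recs = ts.emit_reads(counts, small_design, seed=1)
        cts, report = ts.process_reads(recs, small_design)
        assert report.passed == report.total == 31
        assert cts.variant_series(1, pos, "A").tolist() == [7.0, 4.0, 0.0, 0.0]

    def test_barcode_collision_rejected(self, small_counts, small_design):
        bad = {t: "AAAAAA" for t in small_design.barcode_map}
        with pytest.raises(ValueError, match="collision"):
            ts.emit_reads(small_counts, small_design, barcodes=bad)

    def test_corruption_fractions(self, small_design):
        """0.1 corruption split over three channels: each rejection reason
        lands within 3 s.d. of its binomial expectation."""
        n = 10000
        counts = ts.CountTimeSeries(
            counts=pd.DataFrame(
                {
                    "library": [1],
                    "position": [int(small_design.positions.position.iloc[0])],
                    "outcome": ["A"],
                    "codon": ["GCC"],
                    "timepoint": [0.0],
                    "count": [n],
                }
            ),
            wt_counts=pd.DataFrame({"library": [1], "timepoint": [0.0], "count": [0]}),
            timepoints=(0.0,),
        )
        recs = ts.emit_reads(counts, small_design, corruption=0.1, seed=9)
        _, report = ts.process_reads(recs, small_design)
        p = 0.1 / 3
        sd = np.sqrt(p * (1 - p) / n)
        for reason in ("quality", "barcode", "reference"):
            frac = report.rejected_by_reason[reason] / n
            assert abs(frac - p) < 3 * sd, (reason, frac)

    def test_planted_mmei_variant_flagged(self, small_design):
        """A variant codon creating TCCAAC in context is caught by the
        MmeI filter."""
        window = small_design.window_nt(1)
        lo, _ = small_design.window_residue_range(1)
        # find a position/codon whose substitution creates the site
        planted = None
        for off in range(len(window) // 3):
            for codon in ("AAC", "TCC", "CAA"):
                mutated = window[: off * 3] + codon + window[off * 3 + 3 :]
                wt_codon = window[off * 3 : off * 3 + 3]
                if codon != wt_codon and ts.contains_mmei_site(mutated):
                    planted = (lo + off, codon)
                    break
            if planted:
                break
        assert planted is not None
        pos, codon = planted
        counts = ts.CountTimeSeries(
            counts=pd.DataFrame(
                {
                    "library": [1],
                    "position": [pos],
                    "outcome": [ts.translate_codon(codon)],
                    "codon": [codon],
                    "timepoint": [0.0],
                    "count": [5],
                }
            ),
            wt_counts=pd.DataFrame({"library": [1], "timepoint": [0.0], "count": [0]}),
            timepoints=(0.0,),
        )
        recs = ts.emit_reads(counts, small_design, seed=0)
        _, report = ts.process_reads(recs, small_design)
        assert report.rejected_by_reason["mmei"] == 5


class TestLandscapeTrio:
    def test_rho_out_of_range(self):
        with pytest.raises(ConfigurationError):
            ts.LandscapeTrioConfig(rho=1.5)

    def test_rho_one_perfect_correlation(self):
        lands, maps = ts.simulate_landscape_trio(
            ts.LandscapeTrioConfig(n_positions=20, rho=1.0, seed=3)
        )
        a, b = lands["orthoA"], lands["orthoB"]
        pairs = ts.build_position_set(a, b, "aligned", alignment=maps[("orthoA", "orthoB")])
        dist = ts.correlation_distribution(a, b, pairs, policy="include_all_20")
        assert np.allclose(dist.r_values, 1.0)

    def test_rho_zero_mean_near_zero(self):
        lands, maps = ts.simulate_landscape_trio(
            ts.LandscapeTrioConfig(n_positions=500, rho=0.0, seed=4)
        )
        a, b = lands["orthoA"], lands["orthoB"]
        pairs = ts.build_position_set(a, b, "aligned", alignment=maps[("orthoA", "orthoB")])
        dist = ts.correlation_distribution(a, b, pairs, policy="include_all_20")
        se = dist.r_values.std(ddof=1) / np.sqrt(len(dist.r_values))
        assert abs(dist.r_values.mean()) < 3 * se + 1e-9

    def test_rho_recovers_mixing_weight(self):
        """Mean profile correlation estimates rho (Monte-Carlo check)."""
        lands, maps = ts.simulate_landscape_trio(
            ts.LandscapeTrioConfig(n_positions=1000, rho=0.36, seed=5)
        )
        a, b = lands["orthoA"], lands["orthoB"]
        pairs = ts.build_position_set(a, b, "aligned", alignment=maps[("orthoA", "orthoB")])
        dist = ts.correlation_distribution(a, b, pairs, policy="include_all_20")
        se = dist.r_values.std(ddof=1) / np.sqrt(len(dist.r_values))
        assert abs(dist.r_values.mean() - 0.36) < 3 * se

    def test_mean_correlation_monotone_in_rho(self):
        means = []
        for rho in (0.0, 0.25, 0.5, 0.75, 1.0):
            lands, maps = ts.simulate_landscape_trio(
                ts.LandscapeTrioConfig(n_positions=200, rho=rho, seed=6)
            )
            a, b = lands["orthoA"], lands["orthoB"]
            pairs = ts.build_position_set(
                a, b, "aligned", alignment=maps[("orthoA", "orthoB")]
            )
            dist = ts.correlation_distribution(a, b, pairs, policy="include_all_20")
            means.append(dist.r_values.mean())
        assert all(b > a for a, b in zip(means, means[1:]))


class TestSimulateMSA:
    def test_pure_column_fully_conserved(self):
        profiles = np.zeros((3, 20))
        profiles[:, 0] = 1.0  # all alanine
        msa = ts.simulate_msa(profiles, n_sequences=50, seed=0)
        column = [str(rec.seq[1]) for rec in msa]
        assert ts.wt_conservation(column, "A") == 1.0

    def test_uniform_column_low_information(self):
        profiles = np.full((1, 20), 1 / 20)
        msa = ts.simulate_msa(profiles, n_sequences=10000, seed=1)
        column = [str(rec.seq[0]) for rec in msa]
        assert ts.information_content(column) <= 0.05

    def test_wt_conservation_recovers_profile(self):
        profiles = np.full((1, 20), 0.4 / 19)
        profiles[0, list(AA20).index("W")] = 0.6
        msa = ts.simulate_msa(profiles, n_sequences=5000, seed=2)
        column = [str(rec.seq[0]) for rec in msa]
        cons = ts.wt_conservation(column, "W")
        se = np.sqrt(0.6 * 0.4 / 5000)
        assert abs(cons - 0.6) < 3 * se

    def test_unnormalized_profile_rejected(self):
        with pytest.raises(ValueError, match="not normalized"):
            ts.simulate_msa(np.full((1, 20), 0.1), n_sequences=10)
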