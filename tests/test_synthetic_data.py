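"""Hidden-population simulator and RDS sampling process."""

import json

import numpy as np
import pytest

import kpsize as kp
from kpsize.capture_data import AggregateCaptureTable, read_capture_histories
from kpsize.rds_weights import RDSSample, rds2_proportion
from kpsize.synthetic_data import (
    SyntheticConfig,
    combined_capture_records,
    emit_study_files,
    simulate_population,
    simulate_rds,
)


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="probability vector"):
            SyntheticConfig(class_weights=(0.5, 0.4))

    def test_capture_probs_shape_checked(self):
        with pytest.raises(ValueError, match="K x J"):
            SyntheticConfig(class_weights=(1.0,), capture_probs=((0.1, 0.2),))

    def test_probability_bounds_checked(self):
        with pytest.raises(ValueError):
            SyntheticConfig(
                class_weights=(1.0,), capture_probs=((0.1, 0.2, 1.2),)
            )


class TestSimulatePopulation:
    def test_zero_probabilities_capture_nobody(self):
        cfg = SyntheticConfig(
            true_size=500, class_weights=(1.0,), capture_probs=((0.0, 0.0, 0.0),), seed=0
        )
        t = simulate_population(cfg)
        assert t.n_ever_captured == 0

    def test_homogeneous_ever_captured_fraction_matches_closed_form(self):
        # P(captured at least once) = 1 - (1-p)^J = 0.657 at p=0.3, J=3
        cfg = SyntheticConfig(
            true_size=10_000, class_weights=(1.0,), capture_probs=((0.3, 0.3, 0.3),), seed=7
        )
        t = simulate_population(cfg)
        p_ever = 1 - 0.7**3
        se = np.sqrt(p_ever * (1 - p_ever) / 10_000)
        assert t.n_ever_captured / 10_000 == pytest.approx(p_ever, abs=3 * se)

    def test_independent_sources_uncorrelated(self):
        cfg = SyntheticConfig(
            true_size=10_000, class_weights=(1.0,), capture_probs=((0.3, 0.3, 0.3),), seed=11
        )
        t = simulate_population(cfg)
        corr = np.corrcoef(t.captures.T)
        off = corr[np.triu_indices(3, 1)]
        assert np.abs(off).max() < 3.0 / np.sqrt(10_000)

    def test_positive_dependence_inflates_overlap(self):
        base = dict(true_size=20_000, class_weights=(1.0,), capture_probs=((0.3, 0.3, 0.3),))
        t0 = simulate_population(SyntheticConfig(**base, dependence_logodds=0.0, seed=3))
        t1 = simulate_population(SyntheticConfig(**base, dependence_logodds=1.5, seed=3))
        overlap0 = (t0.captures[:, 0] & t0.captures[:, 1]).sum()
        overlap1 = (t1.captures[:, 0] & t1.captures[:, 1]).sum()
        assert overlap1 > overlap0

    def test_turnover_breaks_closure_in_both_directions(self):
        cfg = SyntheticConfig(true_size=5000, turnover_fraction=0.3, seed=4)
        t = simulate_population(cfg)
        first_only = (t.captures[:, 0] == 1) & (t.captures[:, 1:] == 0).all(axis=1)
        assert first_only.sum() > 0

    def test_fixed_seed_bit_identical(self):
        a = simulate_population(SyntheticConfig(seed=42))
        b = simulate_population(SyntheticConfig(seed=42))
        assert np.array_equal(a.captures, b.captures)
        assert np.array_equal(a.degrees, b.degrees)
        assert np.array_equal(a.service, b.service)


class TestSimulateRds:
    def test_single_seed_no_coupons_yields_just_the_seed(self):
        cfg = SyntheticConfig(
            true_size=200, n_seeds=1, n_coupons=0, sample_size=50,
            replace_depleted_seeds=False, seed=0,
        )
        sample = simulate_rds(simulate_population(cfg))
        assert len(sample) == 1
        assert sample.n_seeds == 1

    def test_structural_bounds_on_waves_and_size(self):
        cfg = SyntheticConfig(true_size=3000, sample_size=835, n_seeds=9, n_coupons=3, seed=1)
        sample = simulate_rds(simulate_population(cfg))
        assert len(sample) <= 835
        assert sample.max_wave >= 1
        assert sample.data["id"].is_unique  # without replacement

    def test_target_larger_than_population_rejected(self):
        cfg = SyntheticConfig(true_size=100, sample_size=150, seed=0)
        with pytest.raises(ValueError, match="exceeds population"):
            simulate_rds(simulate_population(cfg))

    def test_equal_degrees_make_weighting_irrelevant(self):
        cfg = SyntheticConfig(
            true_size=2000, mean_degree=6.0, degree_dispersion=1e9, sample_size=300, seed=5
        )
        t = simulate_population(cfg)
        t.degrees[:] = 6  # force constant reported degrees
        sample = simulate_rds(t)
        w = rds2_proportion(sample, "service_used", scheme="rds2").estimate
        u = rds2_proportion(sample, "service_used", scheme="unweighted").estimate
        assert w == pytest.approx(u, abs=1e-12)

    def test_fixed_seed_bit_identical(self):
        cfg = SyntheticConfig(true_size=1000, sample_size=200, seed=8)
        t = simulate_population(cfg)
        a = simulate_rds(t, seed=99)
        b = simulate_rds(t, seed=99)
        assert a.data.equals(b.data)


class TestEmitStudyFiles:
    def test_round_trip_and_truth_bookkeeping(self, tmp_path):
        cfg = SyntheticConfig(true_size=1000, sample_size=200, seed=2)
        t = simulate_population(cfg)
        sample = simulate_rds(t)
        paths = emit_study_files(t, sample, tmp_path)
        records, sources = read_capture_histories(paths["capture_histories"])
        assert sources == cfg.sources
        table = AggregateCaptureTable.from_csv(paths["aggregate_table"], cfg.sources)
        assert table.n_observed == len(records)
        back = RDSSample.from_csv(paths["rds"])
        assert len(back) == len(sample)
        truth = json.loads(paths["truth"].read_text())
        assert truth["true_size"] == 1000

    def test_rds_column_reflects_survey_membership(self, tmp_path):
        cfg = SyntheticConfig(true_size=1000, sample_size=200, seed=3)
        t = simulate_population(cfg)
        sample = simulate_rds(t)
        recs = combined_capture_records(t, sample)
        j = cfg.sources.index("rds")
        n_rds = sum(r.indicators[j] for r in recs)
        assert n_rds == len(sample)

    def test_town_scale_margins_near_targets(self):
        # default config emulates ~564/546/408 captures out of N=2700
        cfg = SyntheticConfig(seed=13)
        t = simulate_population(cfg)
        sample = simulate_rds(t)
        table = kp.aggregate_histories(combined_capture_records(t, sample), cfg.sources)
        assert table.marginal("keychain") == pytest.approx(564, rel=0.1)
        assert table.marginal("bangle") == pytest.approx(546, rel=0.1)
        assert table.marginal("rds") == 408
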