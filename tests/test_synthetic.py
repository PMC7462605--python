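"""Ground-truth generator: determinism, calibration, scan and hunt structure."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from huntniche import association, synthetic
from huntniche.synthetic import (GroupConfig, SimulationConfig,
                                 calibrate_mixture_weight,
                                 generate_individuals, generate_party_scans)


@pytest.fixture(scope="module")
def default_truth_sim():
    """~3000 hunts under the default (large group effect) truth."""
    cfg = small_config(seed=3, n_days=150, hunt_rate_per_day=20.0,
                       relocations_per_day=50)
    return synthetic.simulate(cfg)


class TestConfigValidation:
    def test_requires_exactly_two_groups(self):
        with pytest.raises(ValueError, match="2 groups"):
            SimulationConfig(groups=[GroupConfig("A", 5, 2)])

    def test_rejects_bad_probabilities_and_counts(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            SimulationConfig(p_intergroup_day=1.5)
        with pytest.raises(ValueError, match="counts"):
            SimulationConfig(n_days=0)

    def test_rejects_unknown_coefficient_category(self):
        with pytest.raises(ValueError, match="true_coefficients"):
            SimulationConfig(true_coefficients={"duiker": {}, "colobus": {}})


class TestDeterminism:
    def test_identical_config_and_seed_give_byte_identical_tables(self, tmp_path):
        cfg = small_config(seed=11, n_days=20)
        a = synthetic.simulate(small_config(seed=11, n_days=20))
        b = synthetic.simulate(cfg)
        for table in ("relocations", "scans", "hunts", "individuals"):
            csv_a = getattr(a, table).to_csv(index=False)
            csv_b = getattr(b, table).to_csv(index=False)
            assert csv_a == csv_b, table

    def test_different_seeds_differ(self):
        a = synthetic.simulate(small_config(seed=1, n_days=15))
        b = synthetic.simulate(small_config(seed=2, n_days=15))
        assert not a.relocations.equals(b.relocations)


class TestOverlapCalibration:
    def test_disjoint_ranges_reach_zero_overlap(self):
        cfg = small_config(range_centers=[(0.0, 0.0), (100.0, 0.0)],
                           overlap_target=0.0, n_days=30,
                           relocations_per_day=80)
        res = synthetic.simulate(cfg)
        assert res.realized_overlap == 0.0

    def test_identical_ranges_overlap_almost_fully(self):
        cfg = small_config(range_centers=[(0.0, 0.0), (0.0, 0.0)],
                           overlap_target=1.0, n_days=30,
                           relocations_per_day=80)
        res = synthetic.simulate(cfg)
        assert res.realized_overlap > 0.9

    def test_default_geometry_hits_065_target(self):
        cfg = small_config(n_days=60, relocations_per_day=100)
        res = synthetic.simulate(cfg)
        assert res.realized_overlap == pytest.approx(0.65, abs=0.10)

    def test_unreachable_target_reports_achieved_value(self):
        # identical centres overlap almost fully whatever the weight
        cfg = small_config(range_centers=[(0.0, 0.0), (0.0, 0.0)],
                           overlap_target=0.2)
        with pytest.raises(ValueError, match="closest achievable"):
            calibrate_mixture_weight(cfg)


class TestPartyScans:
    def test_no_intergroup_days_no_mixed_scans(self):
        cfg = small_config(p_intergroup_day=0.0, n_days=40)
        inds = generate_individuals(cfg)
        scans = generate_party_scans(cfg, inds)
        group_of = inds.set_index("individual_id")["group_id"]
        per_scan = scans.groupby("scan_id")["individual_id"].apply(
            lambda ids: group_of[ids].nunique())
        assert (per_scan == 1).all()

    def test_full_cohesion_gives_within_group_sri_of_one(self):
        cfg = small_config(
            n_days=25, p_intergroup_day=0.0,
            groups=[GroupConfig("Ekalakala", 5, 2, cohesion=1.0),
                    GroupConfig("Kokoalongo", 6, 3, cohesion=1.0)])
        inds = generate_individuals(cfg)
        scans = generate_party_scans(cfg, inds)
        sri = association.compute_sri(scans)
        for g in ("EK", "KO"):
            ids = [i for i in sri.individual_ids if i.startswith(g)]
            block = sri.values.loc[ids, ids].to_numpy()
            off_diag = block[~np.eye(len(ids), dtype=bool)]
            assert np.all(off_diag == 1.0)

    def test_intergroup_day_rate_within_binomial_bounds(self):
        p = 0.31
        cfg = small_config(n_days=1000, p_intergroup_day=p, scans_per_day=4)
        inds = generate_individuals(cfg)
        scans = generate_party_scans(cfg, inds)
        group_of = inds.set_index("individual_id")["group_id"]
        df = scans.copy()
        df["day"] = pd.to_datetime(df["timestamp"]).dt.normalize()
        mixed_scan = df.groupby(["day", "scan_id"])["individual_id"].apply(
            lambda ids: group_of[ids].nunique() > 1)
        frac = mixed_scan.groupby("day").any().mean()
        half_width = 2.576 * np.sqrt(p * (1 - p) / 1000)   # 99% binomial
        assert abs(frac - p) < half_width

    def test_every_scan_has_at_least_one_individual(self):
        cfg = small_config(
            n_days=30,
            groups=[GroupConfig("Ekalakala", 2, 1, cohesion=0.05),
                    GroupConfig("Kokoalongo", 2, 1, cohesion=0.05)])
        scans = generate_party_scans(cfg, generate_individuals(cfg))
        assert (scans.groupby("scan_id").size() >= 1).all()
        expected = cfg.n_days  # at least scans_per_day * n_days scan ids
        assert scans["scan_id"].nunique() >= expected


class TestHuntGeneration:
    def test_zero_coefficients_give_uniform_prey_frequencies(self):
        cfg = small_config(seed=5, n_days=150, hunt_rate_per_day=20.0,
                           relocations_per_day=50,
                           true_coefficients={"duiker": {}, "squirrel": {}})
        res = synthetic.simulate(cfg)
        n = len(res.hunts)
        assert n > 2500
        freqs = res.hunts["prey"].value_counts(normalize=True)
        se3 = 3 * np.sqrt((1 / 3) * (2 / 3) / n)
        for cat in synthetic.PREY_CATEGORIES:
            assert abs(freqs[cat] - 1 / 3) < se3

    def test_group_b_frequencies_match_closed_form_softmax(self, default_truth_sim):
        hunts = default_truth_sim.hunts
        sub = hunts[hunts["catcher_group"] == "Kokoalongo"]
        eta = np.array([0.0, -3.25 + 4.5, -3.3 + 5.0])
        expect = np.exp(eta) / np.exp(eta).sum()
        freqs = sub["prey"].value_counts(normalize=True)
        n = len(sub)
        for cat, p in zip(synthetic.PREY_CATEGORIES, expect):
            se3 = 3 * np.sqrt(p * (1 - p) / n)
            assert abs(freqs.get(cat, 0.0) - p) < se3 + 0.01

    def test_group_a_modal_prey_is_anomalure(self, default_truth_sim):
        hunts = default_truth_sim.hunts
        sub = hunts[hunts["catcher_group"] == "Ekalakala"]
        assert sub["prey"].value_counts().idxmax() == "anomalure"

    def test_generated_covariates_are_non_degenerate(self, default_truth_sim):
        from conftest import analysis_covariates
        cov = analysis_covariates(default_truth_sim).dropna()
        for c in ("n_available_males", "n_available_females",
                  "mean_association", "usage_difference", "sin_date",
                  "cos_date"):
            assert np.isfinite(cov[c]).all()
            assert cov[c].std(ddof=1) > 0


def test_roundtrip_through_csv_and_yaml_config(tmp_path):
    cfg = small_config(seed=9, n_days=15)
    res = synthetic.simulate(cfg)
    out = synthetic.write_outputs(res, tmp_path / "sim")
    hunts = pd.read_csv(out / "hunts.csv")
    assert set(hunts.columns) >= {"hunt_id", "timestamp", "x_km", "y_km",
                                  "prey", "catcher_group", "success"}
    import json
    truth = json.loads((out / "truth.json").read_text())
    assert truth["true_coefficients"]["duiker"]["group"] == 4.5

    yaml_path = tmp_path / "cfg.yaml"
    yaml_path.write_text(
        "seed: 9\nn_days: 15\nscans_per_day: 8\nrelocations_per_day: 60\n"
        "hunt_rate_per_day: 2.0\n"
        "groups:\n"
        "  - {group_id: Ekalakala, n_adults: 13, n_males: 5, cohesion: 0.68}\n"
        "  - {group_id: Kokoalongo, n_adults: 20, n_males: 7, cohesion: 0.5}\n")
    cfg2 = synthetic.load_config(yaml_path)
    res2 = synthetic.simulate(cfg2)
    assert res2.hunts.to_csv(index=False) == res.hunts.to_csv(index=False)
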