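"""Synthetic-data generator: cohort design, panel grid, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from inflamsig import simulate as sim
from inflamsig.regression import ols_fit

from conftest import single_cohort_config


class TestSubjects:
    def test_default_cohort_sizes_and_age_ranges(self):
        subj = sim.generate_subjects(seed=0)
        counts = subj.groupby(["cohort", "group"]).size()
        assert counts[("aging", "case")] == 60
        assert counts[("aging", "control")] == 29
        assert counts[("hiv", "case")] == 24
        assert counts[("hiv", "control")] == 45
        assert counts[("hcv", "case")] == 14
        assert counts[("hcv", "control")] == 11
        old = subj[(subj.cohort == "aging") & (subj.group == "case")]
        assert old.age.between(61, 90).all()
        young = subj[(subj.cohort == "aging") & (subj.group == "control")]
        assert young.age.between(22, 33).all()

    def test_serostatus_invariants(self):
        subj = sim.generate_subjects(seed=3)
        assert (subj[subj.hiv == 1].cohort == "hiv").all()
        assert (subj[subj.hiv == 1].group == "case").all()
        assert (subj[subj.hcv == 1].cohort == "hcv").all()

    def test_empty_config(self):
        empty = sim.CohortSpec(0, 0, (20, 30), (20, 30))
        subj = sim.generate_subjects(
            sim.CohortConfig(aging=empty, hiv=empty, hcv=empty), seed=0
        )
        assert len(subj) == 0

    def test_deterministic_per_seed(self):
        a = sim.generate_subjects(seed=42)
        b = sim.generate_subjects(seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = sim.generate_subjects(seed=43)
        assert not a.equals(c)

    @pytest.mark.parametrize(
        "bad",
        [
            sim.CohortSpec(-1, 0, (20, 30), (20, 30)),
            sim.CohortSpec(5, 5, (30, 20), (20, 30)),
        ],
    )
    def test_invalid_config_raises(self, bad):
        with pytest.raises(ValueError):
            sim.generate_subjects(sim.CohortConfig(aging=bad), seed=0)


class TestPanel:
    def test_baseline_grid_is_12_by_7(self, small_panel):
        assert len(small_panel) == 84
        grid = small_panel.groupby(["cell_type", "signaling_param"]).size()
        assert (grid == 1).all()
        assert small_panel.feature_id.is_unique

    def test_pathway_mapping(self, panel):
        sig = panel[panel.signaling_param != "none"]
        for _, row in sig.drop_duplicates("signaling_param").iterrows():
            assert row.pathway == sim.PATHWAY_OF[row.signaling_param]
        assert set(sig.pathway) == {"PSD", "PSAV", "MAPK", "STAT"}

    def test_default_panel_totals(self, panel):
        assert len(panel) == 357
        assert (panel.modality == "baseline_signaling").sum() == 84

    def test_empty_analytes(self):
        cfg = sim.PanelConfig(serum_analytes=())
        assert (
            sim.generate_panel(cfg).modality == "serum_protein"
        ).sum() == 0

    def test_unknown_param_rejected(self):
        with pytest.raises(ValueError, match="unknown signaling"):
            sim.generate_panel(sim.PanelConfig(signaling_params=("pFOO",)))


class TestMeasurements:
    def test_null_case_is_centered_noise(self, small_panel):
        subj = sim.generate_subjects(single_cohort_config(200), seed=5)
        ds = sim.simulate_measurements(subj, small_panel, seed=5)
        means = ds.measurements.mean(axis=0)
        se = 1.0 / np.sqrt(len(subj))
        assert (means.abs() < 3 * se).mean() > 0.95

    def test_within_block_spearman_matches_loading(self, small_panel):
        # single-factor loading 0.9 -> Pearson 0.81, Spearman ~ the same
        subj = sim.generate_subjects(single_cohort_config(200), seed=6)
        fids = small_panel.feature_id.tolist()
        comm = sim.CommunitySpec(
            {f: "block" for f in fids[:10]}, {f: 0.9 for f in fids[:10]}
        )
        ds = sim.simulate_measurements(subj, small_panel, community_spec=comm, seed=6)
        block = ds.measurements[fids[:10]].to_numpy()
        rho = spearmanr(block).statistic
        off = rho[np.triu_indices(10, k=1)]
        assert abs(off.mean() - 0.81) < 0.05

    def test_block_correlation_converges_to_lambda_squared(self, small_panel):
        subj = sim.generate_subjects(single_cohort_config(1000), seed=13)
        fids = small_panel.feature_id.tolist()[:8]
        for lam in (0.5, 0.8):
            comm = sim.CommunitySpec(
                {f: "b" for f in fids}, {f: lam for f in fids}
            )
            ds = sim.simulate_measurements(
                subj, small_panel.iloc[:8], community_spec=comm, seed=13
            )
            corr = np.corrcoef(ds.measurements.to_numpy(), rowvar=False)
            off = corr[np.triu_indices(8, k=1)]
            assert abs(off.mean() - lam**2) < 0.03

    def test_loading_outside_unit_interval_rejected(self, small_panel):
        f = small_panel.feature_id.iloc[0]
        with pytest.raises(ValueError, match="loadings"):
            sim.CommunitySpec({f: "b"}, {f: 1.2})

    def test_planted_beta_ci_coverage(self, small_panel):
        # 95% CI for a planted 1-SD age effect should cover ~95% of seeds
        fid = small_panel.feature_id.iloc[0]
        effects = [sim.EffectSpec(fid, "age", 1.0)]
        hits = 0
        n_rep = 100
        for s in range(n_rep):
            subj = sim.generate_subjects(single_cohort_config(100), seed=s)
            ds = sim.simulate_measurements(subj, small_panel, effects, seed=s)
            age = subj.age.to_numpy(dtype=float)
            age_z = (age - age.mean()) / age.std(ddof=1)
            X = np.column_stack([np.ones(100), age_z])
            y = ds.measurements[fid].to_numpy()
            betas, resid = ols_fit(y, X)
            sigma2 = resid @ resid / (100 - 2)
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            hits += abs(betas[1] - 1.0) <= 1.96 * se
        assert hits >= 93

    def test_determinism(self, subjects, small_panel):
        a = sim.simulate_measurements(subjects, small_panel, seed=9)
        b = sim.simulate_measurements(subjects, small_panel, seed=9)
        pd.testing.assert_frame_equal(a.measurements, b.measurements)


class TestLongitudinal:
    def test_viral_load_closed_form(self, hcv_longitudinal):
        vl = hcv_longitudinal.viral_load
        pre = vl[vl.timepoint == "pre"].viral_load
        assert (pre == 1e6).all()
        wk1 = vl[vl.timepoint == "wk1"].viral_load.iloc[0]
        assert wk1 == pytest.approx(1e6 * np.exp(-2.0), rel=1e-12)
        post = vl[vl.timepoint == "post"].viral_load
        assert (post == 15.0).all()  # floored at the detection limit

    def test_complete_panel(self, hcv_longitudinal):
        per_tp = hcv_longitudinal.subjects.groupby("timepoint").size()
        assert set(per_tp.index) == set(sim.TIMEPOINTS)
        assert (per_tp == 14).all()

    def test_null_spec_pre_post_identical_up_to_noise(self, subjects, panel):
        spec = sim.LongitudinalSpec(improve_delta=0.0, pulse_amplitude=0.0)
        ds = sim.simulate_longitudinal_hcv(subjects, panel, spec=spec, seed=2)
        pre = ds.at_timepoint("pre").measurements.to_numpy()
        post = ds.at_timepoint("post").measurements.to_numpy()
        diff = (post - pre).mean(axis=0)
        se = (post - pre).std(axis=0, ddof=1) / np.sqrt(14)
        assert (np.abs(diff) < 3 * se).mean() > 0.95

    def test_planted_improvement_magnitude(self, hcv_longitudinal, panel):
        planted = sim.default_improve_features(panel)
        assert len(planted) == 13
        pre = hcv_longitudinal.at_timepoint("pre").measurements[planted]
        post = hcv_longitudinal.at_timepoint("post").measurements[planted]
        diff = post.to_numpy() - pre.to_numpy()
        mean = diff.mean(axis=0)
        se = diff.std(axis=0, ddof=1) / np.sqrt(14)
        assert (np.abs(mean - 1.5) <= 3 * se).all()

    def test_requires_hcv_cases(self, panel):
        no_hcv = sim.generate_subjects(
            sim.CohortConfig(hcv=sim.CohortSpec(0, 5, (20, 30), (20, 30))),
            seed=0,
        )
        with pytest.raises(ValueError, match="no HCV cases"):
            sim.simulate_longitudinal_hcv(no_hcv, panel, seed=0)
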