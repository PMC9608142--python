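"""Bootstrap, pvcVPC, NPDE and goodness-of-fit diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pmbpk.data import DoseEvent, EventTable, Observation, SubjectRecord
from pmbpk.diagnostics import (
    _simulate_matrix,
    bootstrap,
    gof_table,
    npde,
    pvc_vpc,
)
from pmbpk.estimation import PopPKModel
from pmbpk.synthetic import StudyDesign, fixture_final_model, generate_study


class TestBootstrap:
    def test_identity_resample_reproduces_final_estimates(self, fit34):
        n = len(fit34.model.table)
        boot = bootstrap(fit34, indices=[np.arange(n)])
        rep = boot.replicates.iloc[0]
        for label, value in fit34.params.items():
            assert rep[label] == pytest.approx(value, rel=1e-3, abs=1e-6)

    def test_same_seed_bit_reproducible(self, fit34):
        a = bootstrap(fit34, n_replicates=3, seed=101)
        b = bootstrap(fit34, n_replicates=3, seed=101)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_percentiles_ordered_and_failures_counted(self, fit34):
        boot = bootstrap(fit34, n_replicates=12, seed=7)
        s = boot.summary()
        assert (s["p2.5"] <= s["median"]).all()
        assert (s["median"] <= s["p97.5"]).all()
        assert boot.n_failed + len(boot.replicates) == 12

    def test_reporting_scale_summary(self, fit34):
        boot = bootstrap(fit34, n_replicates=4, seed=3)
        s = boot.summary(reporting=True)
        assert "omega_cl_percent" in s.index
        assert s.loc["omega_cl_percent", "estimate"] == pytest.approx(
            100 * np.sqrt(fit34.spec.omega2["cl"])
        )


def _homogeneous_table(n=40, seed=4):
    """Identical design and covariates for every subject."""
    spec = fixture_final_model()
    rng = np.random.default_rng(seed)
    doses = tuple(DoseEvent(12.0 * i, 100.0, 1.0) for i in range(5))
    times = np.array([47.5, 50.0, 51.0, 55.0])
    subjects = []
    from pmbpk.model import concentration, individual_params

    for i in range(n):
        eta = {
            "cl": rng.normal(0, np.sqrt(spec.omega2["cl"])),
            "v": rng.normal(0, np.sqrt(spec.omega2["v"])),
        }
        f = concentration(
            individual_params(spec, {"crcl": 78.49}, eta), doses, times
        )
        y = f * (1 + spec.sigma_prop * rng.standard_normal(len(times)))
        subjects.append(
            SubjectRecord(
                id=f"H{i}",
                doses=doses,
                observations=tuple(
                    Observation(t, max(float(c), 0.11)) for t, c in zip(times, y)
                ),
                covariates={"crcl": 78.49},
            )
        )
    return EventTable(tuple(subjects)), spec


class TestVPC:
    def test_homogeneous_design_correction_is_identity(self):
        """With one time point per bin and identical subjects, the correction
        is the identity (pvcVPC reduces to VPC) up to the Monte Carlo noise
        of the simulation-estimated SD ratio."""
        table, spec = _homogeneous_table()
        model = PopPKModel(table, spec)
        res = pvc_vpc(model, spec, n_sim=1500, bins=4, seed=8)
        des = model.design
        tad = np.array([47.5 - 36.0, 2.0, 3.0, 7.0])  # times after last dose start
        for b in range(4):
            sel = res.table[res.table.bin == b]
            edge_lo, edge_hi = sel.tad_lower.iloc[0], sel.tad_upper.iloc[0]
            col = np.where((tad > edge_lo) & (tad <= edge_hi))[0]
            assert len(col) == 1
            raw = des.obs_y[:, col[0]]
            for p in (5.0, 50.0, 95.0):
                obs_p = sel[sel.percentile == p].observed.iloc[0]
                assert obs_p == pytest.approx(np.percentile(raw, p), rel=0.08)

    def test_median_curve_nonnegative_and_table_complete(self, fit34):
        res = pvc_vpc(fit34, n_sim=150, bins=4, seed=2)
        assert (res.table.observed >= 0).all()
        assert set(res.table.percentile) == {5.0, 50.0, 95.0}
        assert res.table.n_obs.min() >= 5

    def test_thin_bins_are_merged(self, fit34):
        res = pvc_vpc(fit34, n_sim=60, bins=30, seed=2)
        assert res.table.n_obs.min() >= 5


class TestNPDE:
    def test_length_matches_observation_count(self, fit34):
        res = npde(fit34, n_sim=300, seed=5)
        assert len(res.npde) == fit34.model.design.n_obs

    def test_single_observation_reduces_to_marginal_rank(self):
        """With one sample per subject, decorrelation is a scalar rescale and
        the NPDE is the normal quantile of the marginal rank."""
        spec = fixture_final_model()
        rng = np.random.default_rng(11)
        subjects = []
        for i in range(15):
            conc = float(rng.uniform(1, 8))
            subjects.append(
                SubjectRecord(
                    id=f"S{i}",
                    doses=(DoseEvent(0.0, 100.0, 1.0),),
                    observations=(Observation(2.0, conc),),
                    covariates={"crcl": float(rng.uniform(40, 120))},
                )
            )
        table = EventTable(tuple(subjects))
        model = PopPKModel(table, spec)
        K = 400
        res = npde(model, spec, n_sim=K, seed=21)
        sims = _simulate_matrix(model, spec, K, np.random.default_rng(21))
        for i in range(15):
            y = table.subjects[i].observations[0].concentration
            less = int((sims[:, i, 0] < y).sum())
            lo = stats.norm.ppf(max(less / (K + 1), 1 / (2 * K)))
            hi = stats.norm.ppf(min((less + 1) / (K + 1), 1 - 1 / (2 * K)))
            assert lo - 1e-9 <= res.npde[i] <= hi + 1e-9

    def test_calibrated_moments_on_model_simulated_data(self, final_model):
        """Under the true model the NPDE have mean 0 and variance 1."""
        table = generate_study(StudyDesign(n_subjects=125), final_model, seed=31)
        model = PopPKModel(table, final_model)
        res = npde(model, final_model, n_sim=1000, seed=17)
        n = len(res.npde)
        assert n >= 480  # 500 samples minus the occasional censored trough
        assert abs(np.mean(res.npde)) < 3.0 / np.sqrt(n)
        assert abs(np.var(res.npde, ddof=1) - 1.0) < 3.0 * np.sqrt(2.0 / (n - 1))


class TestGOF:
    def test_noise_free_data_gives_null_residuals(self, final_model):
        quiet = final_model.with_updates(omega2={}, sigma_prop=1e-12)
        table = generate_study(StudyDesign(n_subjects=10), quiet, seed=23)
        # evaluate with a small residual SD: with a large proportional sigma
        # the conditional mode shifts slightly off zero by construction (the
        # log-variance term rewards lower predictions)
        eval_spec = final_model.with_updates(sigma_prop=0.01)
        model = PopPKModel(table, eval_spec)
        labels = {"theta_cl", "theta_v", "crcl_on_cl", "omega2_cl", "omega2_v",
                  "sigma_prop"}
        res = model.fit(init=eval_spec, fixed=labels, compute_se=False)
        frame = gof_table(res)
        assert np.allclose(frame.CWRES, 0.0, atol=1e-3)
        # empirical Bayes modes collapse to zero, so IPRED equals PRED
        np.testing.assert_allclose(frame.IPRED, frame.PRED, rtol=1e-3)
        assert {"TAD"} <= set(frame.columns)

    def test_well_specified_fit_has_standardised_residuals(self, fit34):
        frame = gof_table(fit34)
        inside = np.mean(np.abs(frame.CWRES) <= 2.0)
        assert inside >= 0.90
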