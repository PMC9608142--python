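"""FOCE-I objective, fitting, and standard errors.

The FOCE-I objective is checked against an independent adaptive-quadrature
evaluation of the marginal likelihood on toy data, and against the
extended-least-squares deviance in the degenerate no-random-effects case.
"""

import numpy as np
import pytest
from scipy import integrate, stats

from pmbpk.data import DoseEvent, EventTable, Observation, SubjectRecord
from pmbpk.estimation import (
    PopPKModel,
    _ParamPacker,
    standard_errors,
    to_reporting_scale,
)
from pmbpk.model import (
    CovariateLink,
    ModelSpec,
    concentration,
    individual_params,
)
from pmbpk.synthetic import StudyDesign, generate_study


def quadrature_ofv(spec, table):
    """-2 log marginal likelihood minus n*log(2pi), by adaptive quadrature.

    Independent of the FOCE code path: brute-force integration over the
    (single) random effect per subject.
    """
    assert spec.eta_names == ("cl",)
    sd = np.sqrt(spec.omega2["cl"])
    total = 0.0
    for subj in table:
        times = np.array([o.time for o in subj.observations])
        y = np.array([o.concentration for o in subj.observations])

        def integrand(eta):
            params = individual_params(spec, subj.covariates, {"cl": eta})
            f = concentration(params, subj.doses, times)
            v = spec.residual_var(f)
            loglik = -0.5 * np.sum((y - f) ** 2 / v + np.log(2 * np.pi * v))
            return np.exp(loglik) * stats.norm.pdf(eta, 0.0, sd)

        lik, _ = integrate.quad(integrand, -8 * sd, 8 * sd, limit=200)
        total += -2.0 * np.log(lik) - len(y) * np.log(2 * np.pi)
    return total


def _toy_table():
    subjects = []
    for i, (crcl, obs) in enumerate(
        [(60.0, [(2.0, 5.1), (6.0, 2.4)]), (100.0, [(2.0, 3.2), (6.0, 1.1)])]
    ):
        subjects.append(
            SubjectRecord(
                id=f"T{i}",
                doses=(DoseEvent(0.0, 100.0, 1.0),),
                observations=tuple(Observation(t, c) for t, c in obs),
                covariates={"crcl": crcl},
            )
        )
    return EventTable(tuple(subjects))


def _toy_spec(theta_cl=2.0):
    # moderate variability keeps the conditional likelihood close to
    # Gaussian in eta, where the FOCE linearisation is accurate
    return ModelSpec(
        theta={"cl": theta_cl, "v": 15.0},
        omega2={"cl": 0.04},
        sigma_prop=0.2,
        links=(CovariateLink("cl", "crcl", reference=80.0, coefficient=0.5),),
    )


class TestFoceObjective:
    def test_delta_ofv_matches_quadrature_oracle(self):
        """FOCE-I OFV differences agree with brute-force marginal likelihood."""
        table = _toy_table()
        spec_a = _toy_spec(theta_cl=2.0)
        spec_b = _toy_spec(theta_cl=2.6)
        model = PopPKModel(table, spec_a)
        delta_foce = model.foce_objective(spec_b) - model.foce_objective(spec_a)
        delta_oracle = quadrature_ofv(spec_b, table) - quadrature_ofv(spec_a, table)
        assert delta_foce == pytest.approx(delta_oracle, abs=0.5)

    def test_degenerate_no_bsv_equals_extended_least_squares(self):
        table = _toy_table()
        spec = _toy_spec().with_updates(omega2={})
        ofv = PopPKModel(table, spec).foce_objective()
        expected = 0.0
        for subj in table:
            times = np.array([o.time for o in subj.observations])
            y = np.array([o.concentration for o in subj.observations])
            f = concentration(
                individual_params(spec, subj.covariates), subj.doses, times
            )
            v = spec.residual_var(f)
            expected += np.sum((y - f) ** 2 / v + np.log(v))
        assert ofv == pytest.approx(expected, rel=1e-10)

    def test_duplicating_subjects_doubles_ofv(self):
        table = _toy_table()
        doubled = EventTable(
            tuple(table.subjects)
            + tuple(
                SubjectRecord(s.id + "_copy", s.doses, s.observations, s.covariates)
                for s in table.subjects
            )
        )
        spec = _toy_spec()
        one = PopPKModel(table, spec).foce_objective()
        two = PopPKModel(doubled, spec).foce_objective()
        assert two == pytest.approx(2 * one, rel=1e-8)


class TestFit:
    def test_noise_free_self_consistency(self, final_model):
        """With no noise and no BSV the typical values are recovered ~exactly."""
        quiet = final_model.with_updates(omega2={}, sigma_prop=1e-12)
        table = generate_study(StudyDesign(n_subjects=20), quiet, seed=13)
        target = quiet.with_updates(sigma_prop=0.01)
        init = target.with_updates(
            theta={"cl": 1.4, "v": 11.0},
            links=(CovariateLink("cl", "crcl", reference=78.49, coefficient=0.4),),
        )
        res = PopPKModel(table, target).fit(
            init=init, fixed={"sigma_prop"}, compute_se=False
        )
        assert res.params["theta_cl"] == pytest.approx(1.72, rel=1e-3)
        assert res.params["theta_v"] == pytest.approx(14.4, rel=1e-3)
        assert res.params["crcl_on_cl"] == pytest.approx(0.681, abs=1e-3)

    def test_ofv_not_worse_than_initial(self, final_model):
        table = generate_study(StudyDesign(n_subjects=30), final_model, seed=17)
        model = PopPKModel(table, final_model)
        init = final_model.with_updates(theta={"cl": 1.0, "v": 10.0})
        ofv_init = model.foce_objective(init)
        res = model.fit(init=init, compute_se=False)
        assert res.ofv <= ofv_init + 1e-6

    def test_fit_at_fixed_values_reports_diagnostics(self, fit34):
        frame = fit34.predictions()
        assert {"ID", "TIME", "DV", "PRED", "IPRED", "CWRES"} <= set(frame.columns)
        assert len(frame) == fit34.model.design.n_obs
        assert np.isfinite(fit34.ofv)

    def test_reporting_scale_roundtrip(self, final_model, study34):
        packer = _ParamPacker(final_model)
        series = packer.natural(final_model)
        import pandas as pd

        natural = pd.Series(series, index=packer.labels)
        rep = to_reporting_scale(natural)
        assert rep["omega_cl_percent"] == pytest.approx(32.6)
        assert rep["sigma_prop_percent"] == pytest.approx(37.9)
        assert rep["theta_cl"] == pytest.approx(1.72)


def _flat_infusion_table(n, seed, sigma_add=0.4, cl=1.5, v=12.0):
    """Subjects observed late in a very long infusion: f ~ R0/CL analytic."""
    rng = np.random.default_rng(seed)
    r0 = 10.0  # mg/h
    subjects = []
    for i in range(n):
        f = r0 / cl * (1 - np.exp(-cl * 200.0 / v))
        y = f + sigma_add * rng.standard_normal()
        subjects.append(
            SubjectRecord(
                id=f"F{i}",
                doses=(DoseEvent(0.0, r0 * 300.0, 300.0),),
                observations=(Observation(200.0, float(y)),),
            )
        )
    return EventTable(tuple(subjects))


class TestStandardErrors:
    def test_matches_closed_form_fisher_information(self):
        """SE of CL from steady-infusion data vs the analytic information.

        At t >> t1/2 the prediction is R0/CL, so I(CL) = n (R0/CL^2)^2 / s^2
        and SE = s CL^2 / (R0 sqrt(n)).
        """
        n, sigma, r0 = 50, 0.4, 10.0
        table = _flat_infusion_table(n, seed=3, sigma_add=sigma)
        spec = ModelSpec(
            theta={"cl": 1.5, "v": 12.0},
            error_model="additive",
            sigma_add=sigma,
        )
        res = PopPKModel(table, spec).fit(
            fixed={"theta_v", "sigma_add"}, compute_se=True
        )
        cl_hat = res.params["theta_cl"]
        closed_form = sigma * cl_hat**2 / (r0 * np.sqrt(n))
        assert res.bse["theta_cl"] == pytest.approx(closed_form, rel=0.05)
        # the standalone recomputation agrees with the fit-time SEs
        frame = standard_errors(res)
        assert frame.loc["theta_cl", "se"] == pytest.approx(
            res.bse["theta_cl"], rel=1e-6
        )

    def test_rse_shrinks_with_sample_size(self):
        ses = {}
        for n in (25, 100):
            table = _flat_infusion_table(n, seed=5)
            spec = ModelSpec(
                theta={"cl": 1.5, "v": 12.0}, error_model="additive", sigma_add=0.4
            )
            res = PopPKModel(table, spec).fit(
                fixed={"theta_v", "sigma_add"}, compute_se=True
            )
            ses[n] = res.bse["theta_cl"]
        assert ses[100] / ses[25] == pytest.approx(0.5, rel=0.25)

    def test_duplicated_covariate_link_inflates_condition_number(self, final_model):
        table = generate_study(StudyDesign(n_subjects=25), final_model, seed=19)
        link = final_model.links[0]
        degenerate = final_model.with_updates(links=(link, link))
        model = PopPKModel(table, degenerate)
        packer = _ParamPacker(degenerate)
        _, _, cond = model._standard_errors(degenerate, packer)
        assert np.isinf(cond) or cond > 1e5
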