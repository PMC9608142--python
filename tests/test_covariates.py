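"""Stepwise covariate selection: thresholds, screening and recovery.

Threshold logic is exercised against a stubbed fitting backend with known
OFV drops; the end-to-end search is validated on synthetic data where the
renal-function covariate truly drives clearance.
"""

import numpy as np
import pytest

from pmbpk.covariates import (
    CovariateCandidate,
    backward_elimination,
    correlation_screen,
    forward_selection,
    stepwise_search,
)
from pmbpk.data import DoseEvent, EventTable, Observation, SubjectRecord
from pmbpk.estimation import PopPKModel
from pmbpk.model import ModelSpec
from pmbpk.synthetic import StudyDesign, generate_study


# ---------------------------------------------------------------------------
# Stub backend with known OFV drops per covariate
# ---------------------------------------------------------------------------


class FakeFit:
    def __init__(self, spec, ofv, converged=True):
        self.spec = spec
        self.ofv = ofv
        self.converged = converged


def make_stub_table(covs: dict[str, list[float]]) -> EventTable:
    n = len(next(iter(covs.values())))
    subjects = []
    for i in range(n):
        subjects.append(
            SubjectRecord(
                id=f"X{i}",
                doses=(DoseEvent(0.0, 100.0, 1.0),),
                observations=(Observation(2.0, 3.0),),
                covariates={k: v[i] for k, v in covs.items()},
            )
        )
    return EventTable(tuple(subjects))


def stub_fitter(drops: dict[str, float], base_ofv: float = 1000.0):
    """OFV = base - sum of the (additive) drop of each included covariate."""

    def fit_fn(spec, table, init=None, **kwargs):
        ofv = base_ofv - sum(drops.get(l.covariate, 0.0) for l in spec.links)
        return FakeFit(spec, ofv)

    return fit_fn


@pytest.fixture()
def stub_setup():
    rng = np.random.default_rng(0)
    table = make_stub_table(
        {
            "a": list(rng.uniform(50, 100, 8)),
            "b": list(rng.uniform(30, 60, 8)),
        }
    )
    spec = ModelSpec(theta={"cl": 2.0, "v": 10.0}, sigma_prop=0.3)
    return table, spec


class TestForwardThreshold:
    def test_adds_strong_then_weak_candidate(self, stub_setup):
        table, spec = stub_setup
        fit_fn = stub_fitter({"a": 10.0, "b": 4.5})
        base = fit_fn(spec, table)
        cands = [CovariateCandidate("a", "cl"), CovariateCandidate("b", "cl")]
        log = []
        res = forward_selection(base, table, cands, fit_fn=fit_fn, log=log)
        added = [l.covariate for l in res.spec.links]
        assert added == ["a", "b"]  # 10 > 3.84 first, then 4.5 > 3.84

    def test_no_candidate_clears_threshold(self, stub_setup):
        table, spec = stub_setup
        fit_fn = stub_fitter({"a": 2.0, "b": 3.0})
        base = fit_fn(spec, table)
        cands = [CovariateCandidate("a", "cl"), CovariateCandidate("b", "cl")]
        res = forward_selection(base, table, cands, fit_fn=fit_fn)
        assert res.spec.links == ()

    def test_redundant_candidate_not_added(self, stub_setup):
        # second covariate adds nothing once the first is in
        table, spec = stub_setup

        def fit_fn(spec, table, init=None, **kwargs):
            names = {l.covariate for l in spec.links}
            ofv = 1000.0 - (10.0 if names else 0.0)
            return FakeFit(spec, ofv)

        base = fit_fn(spec, table)
        cands = [CovariateCandidate("a", "cl"), CovariateCandidate("b", "cl")]
        res = forward_selection(base, table, cands, fit_fn=fit_fn)
        assert len(res.spec.links) == 1


class TestBackwardThreshold:
    def test_spurious_forward_addition_is_eliminated(self, stub_setup):
        """A 4.5-point covariate passes p<0.05 forward but fails p<0.01."""
        table, spec = stub_setup
        fit_fn = stub_fitter({"a": 10.0, "b": 4.5})
        base = fit_fn(spec, table)
        cands = [CovariateCandidate("a", "cl"), CovariateCandidate("b", "cl")]
        fwd = forward_selection(base, table, cands, fit_fn=fit_fn)
        assert {l.covariate for l in fwd.spec.links} == {"a", "b"}
        final = backward_elimination(fwd, table, fit_fn=fit_fn)
        assert [l.covariate for l in final.spec.links] == ["a"]

    def test_empty_link_set_is_noop(self, stub_setup):
        table, spec = stub_setup
        fit_fn = stub_fitter({})
        base = fit_fn(spec, table)
        final = backward_elimination(base, table, fit_fn=fit_fn)
        assert final is base


class TestScreen:
    def test_constant_covariate_excluded(self, stub_setup):
        table0, spec = stub_setup
        table = make_stub_table(
            {"a": [1.0] * 8, "b": list(np.linspace(30, 60, 8))}
        )
        fit_fn = stub_fitter({})
        base = fit_fn(spec, table)
        cands = [CovariateCandidate("a", "cl"), CovariateCandidate("b", "cl")]
        with pytest.warns(RuntimeWarning, match="constant"):
            kept = correlation_screen(table, cands, base, fit_fn=fit_fn)
        assert [c.covariate for c in kept] == ["b"]

    def test_collinear_pair_keeps_stronger_member(self, stub_setup):
        _, spec = stub_setup
        rng = np.random.default_rng(1)
        a = rng.uniform(50, 100, 10)
        table = make_stub_table({"a": list(a), "b": list(200.0 / a)})
        fit_fn = stub_fitter({"a": 12.0, "b": 5.0})
        base = fit_fn(spec, table)
        cands = [CovariateCandidate("a", "cl"), CovariateCandidate("b", "cl")]
        kept = correlation_screen(table, cands, base, fit_fn=fit_fn)
        assert [c.covariate for c in kept] == ["a"]

    def test_independent_pair_survives_without_fits(self, stub_setup):
        table, spec = stub_setup

        def exploding_fit(*a, **k):  # pragma: no cover - must not be called
            raise AssertionError("no univariate fit needed below threshold")

        base = FakeFit(spec, 1000.0)
        cands = [CovariateCandidate("a", "cl"), CovariateCandidate("b", "cl")]
        kept = correlation_screen(table, cands, base, fit_fn=exploding_fit)
        assert len(kept) == 2


def test_stepwise_recovers_renal_link_on_synthetic_data(final_model):
    """Screen + forward + backward select CrCL-on-CL and nothing else.

    Serum creatinine is strongly anticorrelated with CrCL by construction,
    so the screen must drop it; weight does not drive clearance in the
    generating model, so backward elimination must leave only CrCL.
    """
    table = generate_study(StudyDesign(n_subjects=60), final_model, seed=29)
    base_spec = final_model.with_updates(links=())
    base_fit = PopPKModel(table, base_spec).fit(compute_se=False, polish=False)
    cands = [
        CovariateCandidate("crcl", "cl"),
        CovariateCandidate("scr", "cl"),
        CovariateCandidate("weight", "cl"),
    ]
    final, log = stepwise_search(
        base_fit, table, cands, compute_se=False, polish=False
    )
    assert [(l.covariate, l.parameter) for l in final.spec.links] == [("crcl", "cl")]
    assert final.ofv <= base_fit.ofv
    # screen must have dropped one of the collinear renal markers
    screen_drops = log[(log.stage == "screen") & log.decision.str.startswith("dropped")]
    assert set(screen_drops.covariate) <= {"crcl", "scr"}
    assert len(screen_drops) == 1
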