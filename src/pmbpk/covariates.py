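"""Stepwise covariate model building.

The procedure mirrors standard pharmacometric practice: a Pearson
collinearity screen between candidate covariates (keeping, within each
correlated pair, the one whose univariate addition lowers the objective
more), forward selection adding the best candidate while the OFV drop
exceeds 3.84 (chi-square, p < 0.05, 1 df), then backward elimination
removing covariates whose single removal costs no more than 6.63
(p < 0.01).

Continuous covariates enter as power functions centred at the study
median; binary covariates as multiplicative factors.  Qualitative
retention criteria (precision gain, unexplained-variability drop) are
reported in the step log but never applied automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import EventTable
from .estimation import PopPKModel, PopPKResults
from .model import CovariateLink, ModelSpec

__all__ = [
    "CovariateCandidate",
    "StepRecord",
    "correlation_screen",
    "forward_selection",
    "backward_elimination",
    "stepwise_search",
]

FORWARD_THRESHOLD = 3.84   # chi2(1), p < 0.05
BACKWARD_THRESHOLD = 6.63  # chi2(1), p < 0.01


@dataclass(frozen=True)
class CovariateCandidate:
    """A covariate/parameter pair to be tested.

    ``form`` is chosen automatically when building the link: power for
    continuous covariates (centred at the study median), factor for 0/1
    indicators.
    """

    covariate: str
    parameter: str

    def build_link(self, table: EventTable) -> CovariateLink:
        values = table.covariate_frame()[self.covariate].to_numpy(dtype=float)
        unique = np.unique(values)
        if set(np.round(unique, 12)) <= {0.0, 1.0}:
            return CovariateLink(
                parameter=self.parameter,
                covariate=self.covariate,
                form="factor",
                reference=1.0,
                coefficient=1.0,
            )
        return CovariateLink(
            parameter=self.parameter,
            covariate=self.covariate,
            form="power",
            reference=float(np.median(values)),
            coefficient=0.0,
        )


@dataclass
class StepRecord:
    """One decision in the stepwise log."""

    stage: str           # "screen" | "forward" | "backward"
    covariate: str
    parameter: str
    delta_ofv: float
    decision: str
    omega2_target: float | None = None
    extras: dict = field(default_factory=dict)


def _fit_with(
    spec: ModelSpec, table: EventTable, init: ModelSpec | None = None, **kwargs
) -> PopPKResults:
    return PopPKModel(table, spec).fit(init=init, **kwargs)


def _spec_with_link(spec: ModelSpec, link: CovariateLink) -> ModelSpec:
    return spec.with_updates(links=spec.links + (link,))


def _spec_without_link(spec: ModelSpec, index: int) -> ModelSpec:
    links = tuple(l for i, l in enumerate(spec.links) if i != index)
    return spec.with_updates(links=links)


def _univariate_delta(
    base_fit: PopPKResults,
    table: EventTable,
    cand: CovariateCandidate,
    fit_fn,
    **fit_kwargs,
) -> tuple[float, PopPKResults | None]:
    """OFV drop from adding one candidate to the fitted base model."""
    link = cand.build_link(table)
    spec = _spec_with_link(base_fit.spec, link)
    try:
        res = fit_fn(spec, table, init=spec, **fit_kwargs)
    except Exception as exc:  # noqa: BLE001 - candidate failures are survivable
        warnings.warn(
            f"candidate {cand.covariate} on {cand.parameter} failed to fit: {exc}",
            RuntimeWarning,
            stacklevel=2,
        )
        return -np.inf, None
    if not res.converged:
        return -np.inf, None
    return base_fit.ofv - res.ofv, res


def correlation_screen(
    table: EventTable,
    candidates: list[CovariateCandidate],
    base_fit: PopPKResults,
    threshold: float = 0.5,
    fit_fn=_fit_with,
    log: list[StepRecord] | None = None,
    **fit_kwargs,
) -> list[CovariateCandidate]:
    """Drop the weaker member of each strongly correlated covariate pair.

    Pearson correlations are computed across subjects; for every pair with
    ``|r| >= threshold`` only the candidate whose univariate addition to
    the base model lowers the OFV more is kept.  Zero-variance covariates
    are excluded with a warning.
    """
    if len(candidates) < 2:
        return list(candidates)
    log = log if log is not None else []
    frame = table.covariate_frame()

    kept = []
    for cand in candidates:
        values = frame[cand.covariate].to_numpy(dtype=float)
        if np.std(values) == 0.0:
            warnings.warn(
                f"covariate {cand.covariate!r} is constant; excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            log.append(
                StepRecord("screen", cand.covariate, cand.parameter, np.nan,
                           "excluded (zero variance)")
            )
            continue
        kept.append(cand)

    deltas: dict[CovariateCandidate, float] = {}

    def delta(c: CovariateCandidate) -> float:
        if c not in deltas:
            deltas[c], _ = _univariate_delta(base_fit, table, c, fit_fn, **fit_kwargs)
        return deltas[c]

    dropped: set[CovariateCandidate] = set()
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            if a in dropped or b in dropped or a.covariate == b.covariate:
                continue
            r = np.corrcoef(
                frame[a.covariate].to_numpy(dtype=float),
                frame[b.covariate].to_numpy(dtype=float),
            )[0, 1]
            if abs(r) < threshold:
                continue
            loser, winner = (a, b) if delta(a) < delta(b) else (b, a)
            dropped.add(loser)
            log.append(
                StepRecord(
                    "screen", loser.covariate, loser.parameter, delta(loser),
                    f"dropped (|r|={abs(r):.2f} with {winner.covariate}, "
                    f"weaker univariate dOFV)",
                )
            )
    survivors = [c for c in kept if c not in dropped]
    for c in survivors:
        log.append(StepRecord("screen", c.covariate, c.parameter,
                              deltas.get(c, np.nan), "retained"))
    return survivors


def forward_selection(
    base_fit: PopPKResults,
    table: EventTable,
    candidates: list[CovariateCandidate],
    threshold: float = FORWARD_THRESHOLD,
    fit_fn=_fit_with,
    log: list[StepRecord] | None = None,
    **fit_kwargs,
) -> PopPKResults:
    """Iteratively add the candidate with the largest OFV drop > threshold."""
    log = log if log is not None else []
    current = base_fit
    remaining = list(candidates)
    while remaining:
        results = []
        for cand in remaining:
            d, res = _univariate_delta(current, table, cand, fit_fn, **fit_kwargs)
            if res is None:
                log.append(StepRecord("forward", cand.covariate, cand.parameter,
                                      np.nan, "skipped (non-convergent)"))
                continue
            results.append((d, cand, res))
        if not results:
            break
        d_best, cand_best, res_best = max(results, key=lambda t: t[0])
        for d, cand, _ in results:
            if cand is not cand_best:
                log.append(StepRecord("forward", cand.covariate, cand.parameter,
                                      d, "not selected this round"))
        if d_best > threshold:
            w2 = res_best.spec.omega2.get(cand_best.parameter)
            log.append(StepRecord("forward", cand_best.covariate,
                                  cand_best.parameter, d_best,
                                  f"added (dOFV {d_best:.2f} > {threshold})",
                                  omega2_target=w2))
            current = res_best
            remaining = [c for c in remaining if c is not cand_best]
        else:
            log.append(StepRecord("forward", cand_best.covariate,
                                  cand_best.parameter, d_best,
                                  f"stopped (best dOFV {d_best:.2f} <= {threshold})"))
            break
    return current


def backward_elimination(
    fit_result: PopPKResults,
    table: EventTable,
    threshold: float = BACKWARD_THRESHOLD,
    fit_fn=_fit_with,
    log: list[StepRecord] | None = None,
    protected: tuple[int, ...] = (),
    **fit_kwargs,
) -> PopPKResults:
    """Remove covariates whose single removal costs <= threshold OFV points.

    One link is removed at a time (the cheapest first); the procedure
    repeats until every remaining link's removal penalty exceeds the
    threshold.  ``protected`` link indices (relative to the incoming spec's
    link tuple) are never tested for removal.
    """
    log = log if log is not None else []
    current = fit_result
    protected_links = {current.spec.links[i] for i in protected}
    while True:
        links = current.spec.links
        removable = [i for i, l in enumerate(links) if l not in protected_links]
        if not removable:
            break
        trials = []
        for i in removable:
            reduced = _spec_without_link(current.spec, i)
            try:
                res = fit_fn(reduced, table, init=reduced, **fit_kwargs)
            except Exception:  # noqa: BLE001
                continue
            if not res.converged:
                continue
            penalty = res.ofv - current.ofv
            trials.append((penalty, i, res))
        if not trials:
            break
        penalty, i, res = min(trials, key=lambda t: t[0])
        link = links[i]
        if penalty <= threshold:
            log.append(StepRecord("backward", link.covariate, link.parameter,
                                  penalty,
                                  f"removed (dOFV {penalty:.2f} <= {threshold})"))
            current = res
        else:
            for penalty, i, _ in trials:
                link = links[i]
                log.append(StepRecord("backward", link.covariate, link.parameter,
                                      penalty,
                                      f"retained (dOFV {penalty:.2f} > {threshold})"))
            break
    return current


def stepwise_search(
    base_fit: PopPKResults,
    table: EventTable,
    candidates: list[CovariateCandidate],
    screen_threshold: float = 0.5,
    forward_threshold: float = FORWARD_THRESHOLD,
    backward_threshold: float = BACKWARD_THRESHOLD,
    fit_fn=_fit_with,
    **fit_kwargs,
) -> tuple[PopPKResults, pd.DataFrame]:
    """Screen, forward-select and backward-eliminate; returns (fit, step log)."""
    log: list[StepRecord] = []
    survivors = correlation_screen(
        table, candidates, base_fit, screen_threshold, fit_fn, log, **fit_kwargs
    )
    fwd = forward_selection(
        base_fit, table, survivors, forward_threshold, fit_fn, log, **fit_kwargs
    )
    protected = tuple(range(len(base_fit.spec.links)))
    final = backward_elimination(
        fwd, table, backward_threshold, fit_fn, log, protected=protected,
        **fit_kwargs,
    )
    frame = pd.DataFrame(
        [
            {
                "stage": r.stage,
                "covariate": r.covariate,
                "parameter": r.parameter,
                "delta_ofv": r.delta_ofv,
                "decision": r.decision,
                "omega2_target": r.omega2_target,
            }
            for r in log
        ]
    )
    return final, frame
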