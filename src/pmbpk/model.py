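"""Structural PK model: closed-form infusion kinetics and covariate links.

One- and two-compartment intravenous-infusion models with first-order
elimination, written as analytic superpositions of single-infusion
solutions (linear kinetics) so that Monte Carlo simulation of 10^5 virtual
subjects needs no ODE integration.

Parameters are log-normal across subjects: an individual's parameter is
``theta * (covariate/reference)^exponent * exp(eta)`` where ``eta`` is the
subject's random effect (variance ``omega^2``).  Residual variability is
additive, proportional or combined.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "StructuralParams",
    "CovariateLink",
    "ModelSpec",
    "individual_params",
    "concentration",
    "steady_state_auc24",
    "conc_profile_1cmt",
    "conc_profile_2cmt",
]

_ERROR_MODELS = ("additive", "proportional", "combined")


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural parameters (all strictly positive).

    ``q`` and ``v2`` (inter-compartmental clearance and peripheral volume)
    are only used by the two-compartment model.
    """

    cl: float
    v: float
    q: float | None = None
    v2: float | None = None

    def __post_init__(self) -> None:
        for name in ("cl", "v"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("q", "v2"):
            val = getattr(self, name)
            if val is not None and not val > 0:
                raise ValueError(f"{name} must be > 0 when present")


@dataclass(frozen=True)
class CovariateLink:
    """A covariate effect on a structural parameter.

    ``power`` links multiply by ``(covariate/reference)^coefficient``
    (continuous covariates, centred at a study reference such as the median
    creatinine clearance).  ``factor`` links multiply by
    ``coefficient^covariate`` where the covariate is a 0/1 indicator.
    """

    parameter: str
    covariate: str
    form: str = "power"
    reference: float = 1.0
    coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("power", "factor"):
            raise ValueError(f"unknown link form {self.form!r}")
        if not self.reference > 0:
            raise ValueError("link reference must be > 0")
        if self.form == "factor" and not self.coefficient > 0:
            raise ValueError("factor link coefficient must be > 0")

    def factor_for(self, value):
        """Multiplicative factor contributed for covariate value(s)."""
        value = np.asarray(value, dtype=float)
        if self.form == "power":
            if np.any(value <= 0):
                raise ValueError(
                    f"covariate {self.covariate!r} must be positive for a "
                    f"power link"
                )
            return (value / self.reference) ** self.coefficient
        return np.asarray(self.coefficient, dtype=float) ** value


@dataclass(frozen=True)
class ModelSpec:
    """Full model definition: structure, typical values, random effects, error.

    Attributes
    ----------
    n_compartments : 1 or 2
    theta : mapping of structural parameter name -> typical value
        Requires ``cl`` and ``v`` (plus ``q`` and ``v2`` for 2 compartments).
    omega2 : mapping of parameter name -> between-subject variance
        Exponential (log-normal) random-effect model; parameters absent from
        the map carry no random effect.
    error_model : "additive" | "proportional" | "combined"
    sigma_add : additive residual SD (mg/L)
    sigma_prop : proportional residual SD (fraction)
    links : covariate links applied before the random effect
    """

    n_compartments: int = 1
    theta: Mapping[str, float] = field(default_factory=dict)
    omega2: Mapping[str, float] = field(default_factory=dict)
    error_model: str = "proportional"
    sigma_add: float = 0.0
    sigma_prop: float = 0.0
    links: tuple[CovariateLink, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", dict(self.theta))
        object.__setattr__(self, "omega2", dict(self.omega2))
        object.__setattr__(self, "links", tuple(self.links))
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        required = ("cl", "v") if self.n_compartments == 1 else ("cl", "v", "q", "v2")
        for name in required:
            if name not in self.theta:
                raise ValueError(f"theta missing required parameter {name!r}")
            if not self.theta[name] > 0:
                raise ValueError(f"theta[{name!r}] must be > 0")
        for name, w2 in self.omega2.items():
            if name not in self.theta:
                raise ValueError(f"omega2 names unknown parameter {name!r}")
            if w2 < 0:
                raise ValueError("omega2 must be >= 0")
        if self.error_model not in _ERROR_MODELS:
            raise ValueError(f"error_model must be one of {_ERROR_MODELS}")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("residual SDs must be >= 0")
        uses_add = self.error_model in ("additive", "combined")
        uses_prop = self.error_model in ("proportional", "combined")
        active = (uses_add and self.sigma_add > 0) or (uses_prop and self.sigma_prop > 0)
        if not active:
            raise ValueError("at least one residual component must be > 0")
        for link in self.links:
            if link.parameter not in self.theta:
                raise ValueError(
                    f"link targets unknown parameter {link.parameter!r}"
                )

    # -- parameter bookkeeping -------------------------------------------

    @property
    def structural_names(self) -> tuple[str, ...]:
        return ("cl", "v") if self.n_compartments == 1 else ("cl", "v", "q", "v2")

    @property
    def eta_names(self) -> tuple[str, ...]:
        """Parameters carrying a random effect, in a stable order."""
        return tuple(n for n in self.structural_names if self.omega2.get(n, 0.0) > 0)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(l.covariate for l in self.links))

    def residual_sd(self, f):
        """Residual SD at prediction(s) ``f`` under the error model."""
        f = np.asarray(f, dtype=float)
        var = self.residual_var(f)
        return np.sqrt(var)

    def residual_var(self, f):
        f = np.asarray(f, dtype=float)
        var = np.zeros_like(f)
        if self.error_model in ("additive", "combined"):
            var = var + self.sigma_add**2
        if self.error_model in ("proportional", "combined"):
            var = var + (self.sigma_prop * f) ** 2
        return var

    def with_updates(self, **kwargs) -> "ModelSpec":
        return replace(self, **kwargs)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_compartments": self.n_compartments,
            "theta": dict(self.theta),
            "omega2": dict(self.omega2),
            "error_model": self.error_model,
            "sigma_add": self.sigma_add,
            "sigma_prop": self.sigma_prop,
            "links": [
                {
                    "parameter": l.parameter,
                    "covariate": l.covariate,
                    "form": l.form,
                    "reference": l.reference,
                    "coefficient": l.coefficient,
                }
                for l in self.links
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        links = tuple(CovariateLink(**lk) for lk in d.get("links", ()))
        return cls(
            n_compartments=int(d.get("n_compartments", 1)),
            theta={k: float(v) for k, v in d.get("theta", {}).items()},
            omega2={k: float(v) for k, v in d.get("omega2", {}).items()},
            error_model=d.get("error_model", "proportional"),
            sigma_add=float(d.get("sigma_add", 0.0)),
            sigma_prop=float(d.get("sigma_prop", 0.0)),
            links=links,
        )

    def to_yaml(self, path=None) -> str | None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "ModelSpec":
        if isinstance(source, str) and "\n" in source:
            fh = io.StringIO(source)
        else:
            fh = open(source)
        with fh:
            return cls.from_dict(yaml.safe_load(fh))


def typical_params(spec: ModelSpec, covariates: Mapping) -> dict:
    """Typical-value parameters after covariate links, before random effects.

    ``covariates`` maps covariate name to a scalar or an array of subject
    values; outputs broadcast accordingly.
    """
    out = {}
    for name in spec.structural_names:
        val = np.asarray(spec.theta[name], dtype=float)
        for link in spec.links:
            if link.parameter != name:
                continue
            if link.covariate not in covariates:
                raise KeyError(
                    f"covariate {link.covariate!r} required by the model is missing"
                )
            val = val * link.factor_for(covariates[link.covariate])
        out[name] = val
    return out


def individual_params(
    spec: ModelSpec, covariates: Mapping, eta: Mapping | None = None
) -> StructuralParams:
    """Individual parameters: covariate factors first, then ``exp(eta)``."""
    eta = eta or {}
    tp = typical_params(spec, covariates)
    vals = {name: float(tp[name] * np.exp(eta.get(name, 0.0))) for name in tp}
    if spec.n_compartments == 1:
        return StructuralParams(cl=vals["cl"], v=vals["v"])
    return StructuralParams(cl=vals["cl"], v=vals["v"], q=vals["q"], v2=vals["v2"])


# ---------------------------------------------------------------------------
# Closed-form concentration profiles (vectorized over subjects)
# ---------------------------------------------------------------------------


def conc_profile_1cmt(cl, v, dose_t0, dose_amt, dose_dur, times):
    """One-compartment infusion concentrations by superposition.

    All inputs broadcast: ``cl``, ``v`` have shape ``(n,)`` (or scalars),
    dose arrays shape ``(n, d)`` (padded doses may use ``amount = 0``) and
    ``times`` shape ``(n, m)`` or ``(m,)``.  Returns shape ``(n, m)``
    (or ``(m,)`` for scalar parameters).

    During an infusion of rate ``R0`` started at ``t0``:
    ``C = (R0/CL) (1 - e^{-k (t - t0)})`` with ``k = CL/V``; after the
    infusion ends the accumulated amount decays mono-exponentially.
    """
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    scalar_params = cl.ndim == 0
    cl2 = np.atleast_1d(cl)[:, None, None]  # (n,1,1)
    v2 = np.atleast_1d(v)[:, None, None]
    t0 = np.atleast_2d(np.asarray(dose_t0, dtype=float))[:, None, :]  # (n,1,d)
    amt = np.atleast_2d(np.asarray(dose_amt, dtype=float))[:, None, :]
    dur = np.atleast_2d(np.asarray(dose_dur, dtype=float))[:, None, :]
    t = np.asarray(times, dtype=float)
    if t.ndim == 1:
        t = t[None, :]
    t = t[:, :, None]  # (n,m,1)

    k = cl2 / v2
    tau = t - t0
    te = np.minimum(np.maximum(tau, 0.0), dur)
    rise = -np.expm1(-k * te)  # 1 - e^{-k te}, accurate for small k te
    decay = np.exp(-k * np.maximum(tau - dur, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rate_over_cl = np.where(amt > 0, amt / dur / cl2, 0.0)
    conc = (rate_over_cl * rise * decay).sum(axis=-1)
    if scalar_params:
        return conc[0] if np.asarray(times).ndim == 1 else conc
    return conc


def conc_profile_2cmt(cl, v, q, v2, dose_t0, dose_amt, dose_dur, times):
    """Two-compartment infusion concentrations (central compartment).

    Standard bi-exponential solution with macro rate constants ``alpha``,
    ``beta`` from ``k10 = CL/V1``, ``k12 = Q/V1``, ``k21 = Q/V2``.
    Broadcasting as in :func:`conc_profile_1cmt`.
    """
    cl = np.asarray(cl, dtype=float)
    scalar_params = cl.ndim == 0
    cl_a = np.atleast_1d(cl)[:, None, None]
    v1_a = np.atleast_1d(np.asarray(v, dtype=float))[:, None, None]
    q_a = np.atleast_1d(np.asarray(q, dtype=float))[:, None, None]
    v2_a = np.atleast_1d(np.asarray(v2, dtype=float))[:, None, None]
    t0 = np.atleast_2d(np.asarray(dose_t0, dtype=float))[:, None, :]
    amt = np.atleast_2d(np.asarray(dose_amt, dtype=float))[:, None, :]
    dur = np.atleast_2d(np.asarray(dose_dur, dtype=float))[:, None, :]
    t = np.asarray(times, dtype=float)
    if t.ndim == 1:
        t = t[None, :]
    t = t[:, :, None]

    k10 = cl_a / v1_a
    k12 = q_a / v1_a
    k21 = q_a / v2_a
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s**2 - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    # Impulse-response coefficients of the central compartment.
    c_alpha = (alpha - k21) / (alpha - beta)
    c_beta = (k21 - beta) / (alpha - beta)

    tau = t - t0
    te = np.minimum(np.maximum(tau, 0.0), dur)
    post = np.maximum(tau - dur, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r0_over_v1 = np.where(amt > 0, amt / dur / v1_a, 0.0)
        term_a = c_alpha / alpha * (-np.expm1(-alpha * te)) * np.exp(-alpha * post)
        term_b = c_beta / beta * (-np.expm1(-beta * te)) * np.exp(-beta * post)
    conc = (r0_over_v1 * (term_a + term_b)).sum(axis=-1)
    if scalar_params:
        return conc[0] if np.asarray(times).ndim == 1 else conc
    return conc


def concentration(params: StructuralParams, doses, t):
    """Concentration (mg/L) at time(s) ``t`` for one subject.

    ``doses`` is a sequence of :class:`DoseEvent`; times before the first
    dose return 0.  Linear kinetics: doses superpose.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    doses = list(doses)
    t0 = np.array([[d.time for d in doses]])
    amt = np.array([[d.amount for d in doses]])
    dur = np.array([[d.infusion_duration for d in doses]])
    if params.q is None:
        out = conc_profile_1cmt(
            np.array([params.cl]), np.array([params.v]), t0, amt, dur, t_arr[None, :]
        )[0]
    else:
        out = conc_profile_2cmt(
            np.array([params.cl]),
            np.array([params.v]),
            np.array([params.q]),
            np.array([params.v2]),
            t0,
            amt,
            dur,
            t_arr[None, :],
        )[0]
    return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def steady_state_auc24(params: StructuralParams, daily_dose_mg: float) -> float:
    """Steady-state 24-h AUC (mg·h/L): ``daily dose / CL``.

    Exact for linear kinetics at steady state, independent of volume terms;
    serves as the closed-form oracle for trapezoidal AUC computations.
    """
    if daily_dose_mg <= 0:
        raise ValueError("daily dose must be > 0")
    return daily_dose_mg / params.cl
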