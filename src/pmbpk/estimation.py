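"""FOCE-I estimation of population PK models.

:class:`PopPKModel` binds a :class:`~pmbpk.model.ModelSpec` to an
:class:`~pmbpk.data.EventTable`; :meth:`PopPKModel.fit` maximises the
first-order conditional (with interaction) approximation to the marginal
likelihood and returns a :class:`PopPKResults` carrying estimates, standard
errors, empirical Bayes etas, per-observation diagnostics and a
``summary()`` table.

The objective per subject is the linearised -2 log marginal likelihood at
the subject's conditional eta mode::

    OFV_i = log|C_i| + r_i' C_i^{-1} r_i,
    C_i   = diag(v(f(eta_hat))) + G Omega G',
    r_i   = y_i - f(eta_hat) + G eta_hat,

with ``G = df/deta`` at the mode and the residual variance ``v`` evaluated
at the conditional prediction (the "interaction" part).  The additive
``n log(2pi)`` constant is excluded, so only OFV differences are meaningful
across implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .data import EventTable
from .model import (
    ModelSpec,
    conc_profile_1cmt,
    conc_profile_2cmt,
    typical_params,
)

__all__ = ["PopPKModel", "PopPKResults", "foce_objective", "fit"]

_VAR_FLOOR = 1e-10
_ETA_TOL = 1e-8
_FD_H = 1e-4


# ---------------------------------------------------------------------------
# Packed design
# ---------------------------------------------------------------------------


class _Design:
    """Padded array view of an EventTable (below-LOQ observations dropped)."""

    def __init__(self, table: EventTable, covariate_names: tuple[str, ...]):
        table.require_covariates(covariate_names)
        subs = table.subjects
        self.ids = [s.id for s in subs]
        self.n = len(subs)
        m = max(s.n_quantified for s in subs)
        d = max(len(s.doses) for s in subs)
        self.obs_t = np.zeros((self.n, m))
        self.obs_y = np.zeros((self.n, m))
        self.mask = np.zeros((self.n, m), dtype=bool)
        self.dose_t0 = np.zeros((self.n, d))
        self.dose_amt = np.zeros((self.n, d))
        self.dose_dur = np.ones((self.n, d))
        self.cov: dict[str, np.ndarray] = {
            name: np.array([float(s.covariates[name]) for s in subs])
            for name in covariate_names
        }
        n_blq = 0
        for i, s in enumerate(subs):
            obs = [o for o in s.observations if not o.below_loq]
            n_blq += len(s.observations) - len(obs)
            if not obs:
                raise ValueError(
                    f"subject {s.id} has no quantifiable observations"
                )
            self.obs_t[i, : len(obs)] = [o.time for o in obs]
            self.obs_y[i, : len(obs)] = [o.concentration for o in obs]
            self.mask[i, : len(obs)] = True
            for j, dose in enumerate(s.doses):
                self.dose_t0[i, j] = dose.time
                self.dose_amt[i, j] = dose.amount
                self.dose_dur[i, j] = dose.infusion_duration
        self.n_obs = int(self.mask.sum())
        self.n_blq = n_blq


# ---------------------------------------------------------------------------
# Parameter packing (estimation scale <-> ModelSpec)
# ---------------------------------------------------------------------------


class _ParamPacker:
    """Maps a ModelSpec to a flat estimation-scale vector and back.

    Positive parameters (typical values, factor-link coefficients, variance
    terms) are log-transformed; power-link exponents are unconstrained.
    """

    def __init__(self, spec: ModelSpec, fixed: set[str] | frozenset[str] = frozenset()):
        entries: list[tuple[str, object, str, str]] = []  # (kind, key, label, scale)
        for name in spec.structural_names:
            entries.append(("theta", name, f"theta_{name}", "log"))
        for i, link in enumerate(spec.links):
            label = f"{link.covariate}_on_{link.parameter}"
            scale = "identity" if link.form == "power" else "log"
            entries.append(("link", i, label, scale))
        for name in spec.eta_names:
            entries.append(("omega2", name, f"omega2_{name}", "log"))
        if spec.error_model in ("additive", "combined"):
            entries.append(("sigma", "add", "sigma_add", "log"))
        if spec.error_model in ("proportional", "combined"):
            entries.append(("sigma", "prop", "sigma_prop", "log"))
        unknown = fixed - {e[2] for e in entries}
        if unknown:
            raise ValueError(f"unknown fixed parameter(s): {sorted(unknown)}")
        self.entries = [e for e in entries if e[2] not in fixed]
        self.labels = [e[2] for e in self.entries]

    def _natural_value(self, spec: ModelSpec, kind: str, key) -> float:
        if kind == "theta":
            return spec.theta[key]
        if kind == "link":
            return spec.links[key].coefficient
        if kind == "omega2":
            return spec.omega2[key]
        return spec.sigma_add if key == "add" else spec.sigma_prop

    def natural(self, spec: ModelSpec) -> np.ndarray:
        return np.array(
            [self._natural_value(spec, k, key) for k, key, _, _ in self.entries]
        )

    def pack(self, spec: ModelSpec) -> np.ndarray:
        vals = self.natural(spec)
        out = np.empty_like(vals)
        for i, (_, _, _, scale) in enumerate(self.entries):
            out[i] = np.log(vals[i]) if scale == "log" else vals[i]
        return out

    def unpack(self, x: np.ndarray, base: ModelSpec) -> ModelSpec:
        vals = np.empty_like(x)
        for i, (_, _, _, scale) in enumerate(self.entries):
            vals[i] = np.exp(x[i]) if scale == "log" else x[i]
        return self.update(vals, base)

    def update(self, natural_vals: np.ndarray, base: ModelSpec) -> ModelSpec:
        theta = dict(base.theta)
        omega2 = dict(base.omega2)
        links = list(base.links)
        sigma_add, sigma_prop = base.sigma_add, base.sigma_prop
        for val, (kind, key, _, _) in zip(natural_vals, self.entries):
            if kind == "theta":
                theta[key] = float(val)
            elif kind == "link":
                links[key] = links[key].__class__(
                    parameter=links[key].parameter,
                    covariate=links[key].covariate,
                    form=links[key].form,
                    reference=links[key].reference,
                    coefficient=float(val),
                )
            elif kind == "omega2":
                omega2[key] = float(val)
            elif key == "add":
                sigma_add = float(val)
            else:
                sigma_prop = float(val)
        return base.with_updates(
            theta=theta,
            omega2=omega2,
            links=tuple(links),
            sigma_add=sigma_add,
            sigma_prop=sigma_prop,
        )


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


class PopPKModel:
    """A population PK model bound to a dataset, in the estimator-object style.

    Parameters
    ----------
    table : EventTable
        The dataset (below-LOQ observations are excluded from the
        likelihood).
    spec : ModelSpec
        Structural/stochastic model definition; its parameter values serve
        as the default initial estimates for :meth:`fit`.
    """

    def __init__(self, table: EventTable, spec: ModelSpec):
        self.table = table
        self.spec = spec
        self.design = _Design(table, spec.covariate_names)
        self._eta_cache: np.ndarray | None = None

    @classmethod
    def from_csv(cls, path, spec: ModelSpec, column_map=None) -> "PopPKModel":
        from .data import read_event_table

        return cls(read_event_table(path, column_map), spec)

    # -- concentration kernel -------------------------------------------

    def _conc(self, spec: ModelSpec, eta: np.ndarray | None) -> np.ndarray:
        """Predicted concentrations (n, m) at eta (n, q) (None = zeros)."""
        des = self.design
        tp = typical_params(spec, des.cov)
        vals = {
            name: np.broadcast_to(np.asarray(tp[name], dtype=float), (des.n,))
            for name in spec.structural_names
        }
        if eta is not None and eta.size:
            vals = dict(vals)
            for j, name in enumerate(spec.eta_names):
                vals[name] = vals[name] * np.exp(eta[:, j])
        if spec.n_compartments == 1:
            return conc_profile_1cmt(
                vals["cl"], vals["v"], des.dose_t0, des.dose_amt, des.dose_dur,
                des.obs_t,
            )
        return conc_profile_2cmt(
            vals["cl"], vals["v"], vals["q"], vals["v2"],
            des.dose_t0, des.dose_amt, des.dose_dur, des.obs_t,
        )

    # -- conditional objective and eta modes ----------------------------

    def _cond_obj(self, spec: ModelSpec, eta: np.ndarray, omega2_vec) -> np.ndarray:
        """Per-subject conditional -2 log-likelihood plus eta prior (n,)."""
        f = self._conc(spec, eta)
        v = np.maximum(spec.residual_var(f), _VAR_FLOOR)
        res = self.design.obs_y - f
        terms = np.where(self.design.mask, np.log(v) + res**2 / v, 0.0)
        out = terms.sum(axis=1)
        if eta.size:
            out = out + (eta**2 / omega2_vec).sum(axis=1)
        return out

    def _eta_modes(self, spec: ModelSpec, eta0: np.ndarray) -> np.ndarray:
        """Batched damped-Newton search for each subject's eta mode.

        Finite-difference gradient/Hessian on the q-dimensional conditional
        objective, with per-subject backtracking; converges when the step
        falls below 1e-8.  Started from the better of ``eta0`` and zero.
        """
        n = self.design.n
        q = len(spec.eta_names)
        if q == 0:
            return np.zeros((n, 0))
        omega2_vec = np.array([spec.omega2[p] for p in spec.eta_names])

        def g(e):
            return self._cond_obj(spec, e, omega2_vec)

        zero = np.zeros((n, q))
        g_start = g(eta0)
        g_zero = g(zero)
        eta = np.where((g_zero < g_start)[:, None], zero, eta0).copy()
        g0 = np.minimum(g_start, g_zero)

        h = _FD_H
        eye = np.eye(q)
        for _ in range(60):
            grad = np.zeros((n, q))
            hess = np.zeros((n, q, q))
            gp = np.zeros((q, n))
            gm = np.zeros((q, n))
            for j in range(q):
                gp[j] = g(eta + h * eye[j])
                gm[j] = g(eta - h * eye[j])
                grad[:, j] = (gp[j] - gm[j]) / (2 * h)
                hess[:, j, j] = (gp[j] - 2 * g0 + gm[j]) / h**2
            for j in range(q):
                for k in range(j + 1, q):
                    gpp = g(eta + h * (eye[j] + eye[k]))
                    gpm = g(eta + h * (eye[j] - eye[k]))
                    gmp = g(eta - h * (eye[j] - eye[k]))
                    gmm = g(eta - h * (eye[j] + eye[k]))
                    hjk = (gpp - gpm - gmp + gmm) / (4 * h**2)
                    hess[:, j, k] = hjk
                    hess[:, k, j] = hjk
            # Regularize to positive definite (eigenvalue floor).
            w, vmat = np.linalg.eigh(hess)
            w = np.maximum(w, 1e-6)
            hess_pd = vmat @ (w[..., None] * np.swapaxes(vmat, -1, -2))
            step = -np.linalg.solve(hess_pd, grad[..., None])[..., 0]
            # Trust region: etas are unit-scale log deviations, cap the step.
            norm = np.abs(step).max(axis=1, keepdims=True)
            step = step * np.where(norm > 2.0, 2.0 / np.maximum(norm, 1e-300), 1.0)

            alpha = np.ones(n)
            accepted = np.zeros(n, dtype=bool)
            g_new = g0.copy()
            for _bt in range(12):
                trial = eta + np.where(accepted, 0.0, alpha)[:, None] * step
                g_try = g(trial)
                better = (g_try <= g0 + 1e-12) & ~accepted
                g_new = np.where(better, g_try, g_new)
                eta = np.where(better[:, None], trial, eta)
                accepted |= better
                alpha = np.where(accepted, alpha, alpha * 0.5)
                if accepted.all():
                    break
            step_size = np.where(accepted, np.abs(step).max(axis=1) * alpha, 0.0)
            g0 = g_new
            if step_size.max() < _ETA_TOL:
                break
        return eta

    # -- FOCE-I objective ------------------------------------------------

    def _ofv_terms(self, spec: ModelSpec, eta_hat: np.ndarray):
        """Linearised per-subject OFV plus the pieces needed for diagnostics."""
        des = self.design
        mask = des.mask
        f_hat = self._conc(spec, eta_hat)
        v_hat = np.maximum(spec.residual_var(f_hat), _VAR_FLOOR)
        q = len(spec.eta_names)
        if q == 0:
            res = np.where(mask, des.obs_y - f_hat, 0.0)
            v = np.where(mask, v_hat, 1.0)
            ofv_i = (np.where(mask, np.log(v), 0.0) + res**2 / v).sum(axis=1)
            cwres = np.where(mask, res / np.sqrt(v), np.nan)
            return ofv_i, f_hat, cwres

        h = _FD_H
        eye = np.eye(q)
        G = np.zeros(f_hat.shape + (q,))
        for j in range(q):
            fp = self._conc(spec, eta_hat + h * eye[j])
            fm = self._conc(spec, eta_hat - h * eye[j])
            G[..., j] = (fp - fm) / (2 * h)
        G = np.where(mask[..., None], G, 0.0)
        omega2_vec = np.array([spec.omega2[p] for p in spec.eta_names])
        GOG = np.einsum("nmj,j,nkj->nmk", G, omega2_vec, G)
        v = np.where(mask, v_hat, 1.0)
        m = mask.shape[1]
        C = GOG + np.einsum("nm,mk->nmk", v, np.eye(m))
        r = np.where(mask, des.obs_y - f_hat + np.einsum("nmj,nj->nm", G, eta_hat), 0.0)
        L = np.linalg.cholesky(C)
        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
        z = np.linalg.solve(L, r[..., None])[..., 0]
        ofv_i = logdet + (z**2).sum(axis=1)
        cwres = np.where(mask, z, np.nan)
        return ofv_i, f_hat, cwres

    def foce_objective(self, spec: ModelSpec | None = None) -> float:
        """FOCE-I objective function value at the given parameter values."""
        spec = spec or self.spec
        q = len(spec.eta_names)
        eta0 = (
            self._eta_cache
            if self._eta_cache is not None and self._eta_cache.shape == (self.design.n, q)
            else np.zeros((self.design.n, q))
        )
        eta_hat = self._eta_modes(spec, eta0)
        self._eta_cache = eta_hat
        ofv_i, _, _ = self._ofv_terms(spec, eta_hat)
        return float(ofv_i.sum())

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        init: ModelSpec | None = None,
        fixed: set[str] | frozenset[str] = frozenset(),
        compute_se: bool = True,
        maxfev: int = 4000,
        fatol: float = 1e-4,
        xatol: float = 1e-4,
        polish: bool = True,
    ) -> "PopPKResults":
        """Minimise the FOCE-I objective over (theta, omega^2, sigma).

        Positivity is enforced by log-transforming all positive parameters;
        power-law covariate exponents are unconstrained.  The outer search
        is quasi-Newton (coarse-step L-BFGS-B) followed, when ``polish`` is
        true, by Nelder-Mead restarts (robust to the small finite-difference
        noise of the inner eta optimisation) stopping when the simplex OFV
        spread falls below ``fatol``.  ``polish=False`` keeps only the
        quasi-Newton stage — appropriate for warm-started refits such as
        bootstrap replicates.

        Parameters named in ``fixed`` (labels as in ``results.params``)
        are held at their values in ``init``/the model spec.
        """
        base = init or self.spec
        packer = _ParamPacker(base, frozenset(fixed))
        x0 = packer.pack(base)
        self._eta_cache = None

        if len(x0) == 0:
            # Everything fixed: evaluate at the given values.
            return self._finalize(base, packer, converged=True, nfev=0,
                                  compute_se=False)

        def objective(x):
            spec = packer.unpack(x, base)
            try:
                return self.foce_objective(spec)
            except (np.linalg.LinAlgError, FloatingPointError, ValueError):
                return 1e12

        # Two-stage outer search: quasi-Newton (L-BFGS-B on the transformed
        # scale, coarse finite-difference gradient matched to the inner-loop
        # noise) followed by Nelder-Mead polish with restarts; a fresh
        # simplex around the incumbent escapes premature collapse.
        opt = None
        nfev = 0
        x_cur = x0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            qn = optimize.minimize(
                objective,
                x0,
                method="L-BFGS-B",
                options={"eps": 1e-4, "maxfun": maxfev, "ftol": 1e-10, "gtol": 1e-6},
            )
            nfev += int(qn.nfev)
            if np.isfinite(qn.fun) and qn.fun < objective(x0):
                x_cur = qn.x
            if not polish:
                opt = qn
            for _attempt in range(4 if polish else 0):
                opt_try = optimize.minimize(
                    objective,
                    x_cur,
                    method="Nelder-Mead",
                    options={
                        "maxfev": maxfev,
                        "fatol": fatol,
                        "xatol": xatol,
                        "adaptive": True,
                    },
                )
                nfev += int(opt_try.nfev)
                gain = np.inf if opt is None else opt.fun - opt_try.fun
                if opt is None or opt_try.fun < opt.fun:
                    opt = opt_try
                x_cur = opt.x
                if gain < 0.01:
                    break
        final_spec = packer.unpack(opt.x, base)
        converged = bool(opt.success)
        if not converged:
            warnings.warn(
                f"outer optimisation did not converge: {opt.message}",
                RuntimeWarning,
                stacklevel=2,
            )
        return self._finalize(final_spec, packer, converged, nfev, compute_se)

    def _finalize(
        self,
        final_spec: ModelSpec,
        packer: _ParamPacker,
        converged: bool,
        nfev: int,
        compute_se: bool,
    ) -> "PopPKResults":
        ofv = self.foce_objective(final_spec)
        eta_hat = self._eta_cache
        ofv_i, ipred, cwres = self._ofv_terms(final_spec, eta_hat)
        pred = self._conc(final_spec, None)

        boundary = [
            f"omega2_{name}"
            for name in final_spec.eta_names
            if final_spec.omega2[name] < 1e-6
        ]
        if boundary:
            warnings.warn(
                f"variance estimate(s) near zero boundary: {boundary}",
                RuntimeWarning,
                stacklevel=2,
            )

        se = rse = None
        cond = np.nan
        cov = None
        if compute_se:
            se, cov, cond = self._standard_errors(final_spec, packer)
            est = packer.natural(final_spec)
            with np.errstate(divide="ignore", invalid="ignore"):
                rse = 100.0 * se / np.abs(est)

        return PopPKResults(
            model=self,
            spec=final_spec,
            packer=packer,
            ofv=ofv,
            eta=eta_hat,
            pred=pred,
            ipred=ipred,
            cwres=cwres,
            se=se,
            rse_percent=rse,
            cov=cov,
            condition_number=cond,
            converged=converged,
            n_function_evals=nfev,
            boundary_flags=tuple(boundary),
        )

    def _standard_errors(self, spec: ModelSpec, packer: _ParamPacker):
        """FD Hessian of the OFV on the natural scale (the R-matrix route).

        Covariance = 2 H^{-1} (OFV is -2 log L); condition number is the
        eigenvalue ratio of the correlation-scaled Hessian.
        """
        x = packer.natural(spec)
        p = len(x)
        steps = np.maximum(1e-5, 1e-3 * np.abs(x))

        def f(v):
            try:
                return self.foce_objective(packer.update(v, spec))
            except (np.linalg.LinAlgError, ValueError):
                return np.nan

        H = np.empty((p, p))
        f0 = f(x)
        for i in range(p):
            ei = np.zeros(p)
            ei[i] = steps[i]
            H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
        for i in range(p):
            for j in range(i + 1, p):
                ei = np.zeros(p)
                ej = np.zeros(p)
                ei[i] = steps[i]
                ej[j] = steps[j]
                hij = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * steps[i] * steps[j])
                H[i, j] = H[j, i] = hij

        se = np.full(p, np.nan)
        cov = None
        cond = np.inf
        if np.all(np.isfinite(H)):
            diag = np.diag(H)
            if np.all(diag > 0):
                d = 1.0 / np.sqrt(diag)
                Hs = H * np.outer(d, d)
                eig = np.linalg.eigvalsh(Hs)
                cond = float(eig[-1] / eig[0]) if eig[0] > 0 else np.inf
            try:
                cov = 2.0 * np.linalg.inv(H)
                dvar = np.diag(cov)
                if np.all(dvar > 0):
                    se = np.sqrt(dvar)
                else:
                    cov = None
            except np.linalg.LinAlgError:
                cov = None
        if cov is None:
            warnings.warn(
                "Hessian not positive definite; standard errors unavailable",
                RuntimeWarning,
                stacklevel=2,
            )
        return se, cov, cond


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class PopPKResults:
    """Fit output: estimates, uncertainties, empirical Bayes etas, diagnostics."""

    model: PopPKModel
    spec: ModelSpec
    packer: _ParamPacker
    ofv: float
    eta: np.ndarray
    pred: np.ndarray
    ipred: np.ndarray
    cwres: np.ndarray
    se: np.ndarray | None
    rse_percent: np.ndarray | None
    cov: np.ndarray | None
    condition_number: float
    converged: bool
    n_function_evals: int
    boundary_flags: tuple[str, ...] = ()

    @property
    def params(self) -> pd.Series:
        """Estimates on the natural scale (theta, link coefficients, omega^2, sigma)."""
        return pd.Series(self.packer.natural(self.spec), index=self.packer.labels)

    @property
    def bse(self) -> pd.Series:
        se = self.se if self.se is not None else np.full(len(self.packer.labels), np.nan)
        return pd.Series(se, index=self.packer.labels)

    @property
    def omega_percent(self) -> pd.Series:
        """Between-subject variability as 100*sqrt(omega^2), by parameter."""
        return pd.Series(
            {p: 100.0 * np.sqrt(self.spec.omega2[p]) for p in self.spec.eta_names}
        )

    @property
    def sigma_percent(self) -> float:
        """Proportional residual SD as a percentage."""
        return 100.0 * self.spec.sigma_prop

    def eta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.eta,
            index=self.model.design.ids,
            columns=[f"eta_{p}" for p in self.spec.eta_names],
        )

    def predictions(self) -> pd.DataFrame:
        """Per-observation table: ID, TIME, DV, PRED, IPRED, CWRES."""
        des = self.model.design
        rows = []
        for i, sid in enumerate(des.ids):
            for j in range(des.mask.shape[1]):
                if not des.mask[i, j]:
                    continue
                rows.append(
                    {
                        "ID": sid,
                        "TIME": des.obs_t[i, j],
                        "DV": des.obs_y[i, j],
                        "PRED": self.pred[i, j],
                        "IPRED": self.ipred[i, j],
                        "CWRES": self.cwres[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        rows = []
        est = self.params
        se = self.bse
        rse = (
            self.rse_percent
            if self.rse_percent is not None
            else np.full(len(est), np.nan)
        )
        for i, label in enumerate(est.index):
            rows.append(
                f"{label:<22s} {est.iloc[i]:>12.4g} {se.iloc[i]:>12.4g} "
                f"{rse[i]:>9.1f}"
            )
        lines = [
            "Population PK model fit (FOCE-I)",
            "=" * 58,
            f"Subjects: {self.model.design.n}    Observations: {self.model.design.n_obs}"
            f"    (below LOQ excluded: {self.model.design.n_blq})",
            f"OFV: {self.ofv:.3f}    converged: {self.converged}"
            f"    condition number: {self.condition_number:.3g}",
            "-" * 58,
            f"{'parameter':<22s} {'estimate':>12s} {'SE':>12s} {'RSE%':>9s}",
            *rows,
            "-" * 58,
        ]
        for p in self.spec.eta_names:
            lines.append(f"omega_{p} (%)           {self.omega_percent[p]:>12.1f}")
        if self.spec.error_model in ("proportional", "combined"):
            lines.append(f"sigma_prop (%)         {self.sigma_percent:>12.1f}")
        if self.boundary_flags:
            lines.append(f"boundary flags: {', '.join(self.boundary_flags)}")
        return "\n".join(lines)


def to_reporting_scale(values):
    """Convert natural-scale estimates to the conventional reporting scale.

    Variance terms ``omega2_x`` become ``omega_x_percent`` (100*sqrt) and
    residual SDs ``sigma_*`` become ``sigma_*_percent`` (x100); typical
    values and link coefficients pass through.  Accepts a Series (one
    estimate set) or a DataFrame (e.g. bootstrap replicates, column-wise).
    """
    out = {}
    frame = values if isinstance(values, pd.DataFrame) else values.to_frame().T
    for label in frame.columns:
        col = frame[label]
        if label.startswith("omega2_"):
            out[f"omega_{label[7:]}_percent"] = 100.0 * np.sqrt(col)
        elif label.startswith("sigma_"):
            out[f"{label}_percent"] = 100.0 * col
        else:
            out[label] = col
    result = pd.DataFrame(out)
    return result if isinstance(values, pd.DataFrame) else result.iloc[0]


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def foce_objective(spec: ModelSpec, table: EventTable) -> float:
    """FOCE-I OFV of ``spec`` on ``table`` (no fitting)."""
    return PopPKModel(table, spec).foce_objective()


def fit(
    spec: ModelSpec,
    table: EventTable,
    init: ModelSpec | None = None,
    seed: int | None = None,
    **kwargs,
) -> PopPKResults:
    """Fit ``spec`` to ``table`` by FOCE-I.  ``seed`` is accepted for API
    symmetry with the stochastic stages; the estimator is deterministic."""
    del seed
    return PopPKModel(table, spec).fit(init=init, **kwargs)


def standard_errors(fit_result: PopPKResults) -> pd.DataFrame:
    """(Re)compute SEs, RSE% and the condition number for a converged fit.

    Useful when the fit was run with ``compute_se=False``; returns a frame
    indexed by parameter label with the condition number in ``attrs``.
    """
    model = fit_result.model
    se, cov, cond = model._standard_errors(fit_result.spec, fit_result.packer)
    est = fit_result.packer.natural(fit_result.spec)
    with np.errstate(divide="ignore", invalid="ignore"):
        rse = 100.0 * se / np.abs(est)
    frame = pd.DataFrame(
        {"estimate": est, "se": se, "rse_percent": rse},
        index=fit_result.packer.labels,
    )
    frame.attrs["condition_number"] = cond
    frame.attrs["cov"] = cov
    return frame
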