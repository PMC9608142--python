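"""Model evaluation: nonparametric bootstrap, pvcVPC, NPDE and GOF tables.

All stochastic procedures take an explicit seed and are bit-reproducible
for the same seed.  Simulation replicates reuse the fitted dataset's design
(dose history, sampling times, covariates) and draw new between-subject
random effects and residual errors from the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import PopPKModel, PopPKResults
from .model import ModelSpec

__all__ = [
    "BootstrapResult",
    "VPCResult",
    "NPDEResult",
    "bootstrap",
    "pvc_vpc",
    "npde",
    "gof_table",
]


# ---------------------------------------------------------------------------
# Shared simulation kernel
# ---------------------------------------------------------------------------


def _simulate_matrix(
    model: PopPKModel, spec: ModelSpec, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulated observations, shape (n_sim, n_subjects, m); masked cells 0.

    New etas and residual errors per replicate; the design (doses, times,
    covariates) is the dataset's own.
    """
    des = model.design
    n, m = des.obs_y.shape
    q = len(spec.eta_names)
    eta_sd = np.sqrt([spec.omega2[p] for p in spec.eta_names]) if q else None

    out = np.empty((n_sim, n, m))
    chunk = max(1, 200_000 // max(n, 1))
    uses_add = spec.error_model in ("additive", "combined")
    uses_prop = spec.error_model in ("proportional", "combined")
    for start in range(0, n_sim, chunk):
        k = min(chunk, n_sim - start)
        f = np.empty((k, n, m))
        for r in range(k):
            eta = (
                rng.standard_normal((n, q)) * eta_sd
                if q
                else np.zeros((n, 0))
            )
            f[r] = model._conc(spec, eta)
        y = f.copy()
        if uses_prop:
            y *= 1.0 + spec.sigma_prop * rng.standard_normal((k, n, m))
        if uses_add:
            y += spec.sigma_add * rng.standard_normal((k, n, m))
        out[start : start + k] = y
    return np.where(des.mask[None, :, :], out, 0.0)


def _time_after_last_dose(model: PopPKModel) -> np.ndarray:
    """TAD for each (subject, obs) cell relative to the last dose start."""
    des = model.design
    tad = np.zeros_like(des.obs_t)
    for i in range(des.n):
        starts = des.dose_t0[i][des.dose_amt[i] > 0]
        for j in range(des.obs_t.shape[1]):
            t = des.obs_t[i, j]
            prior = starts[starts <= t]
            tad[i, j] = t - prior.max() if prior.size else t
    return tad


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Replicate estimates and their percentile summary.

    ``bias_percent`` is (replicate median - final estimate)/final x 100,
    per parameter.
    """

    replicates: pd.DataFrame
    final_estimates: pd.Series
    n_requested: int
    n_failed: int

    @property
    def median(self) -> pd.Series:
        return self.replicates.median()

    def percentile(self, q: float) -> pd.Series:
        return self.replicates.quantile(q / 100.0)

    @property
    def bias_percent(self) -> pd.Series:
        return (self.median - self.final_estimates) / self.final_estimates * 100.0

    def summary(self, reporting: bool = False) -> pd.DataFrame:
        """Percentile table; ``reporting=True`` converts variance terms to
        the conventional percent scale (omega% = 100*sqrt(omega2)) first,
        so bias is measured on the scale estimates are reported on."""
        reps, est = self.replicates, self.final_estimates
        if reporting:
            from .estimation import to_reporting_scale

            reps = to_reporting_scale(reps)
            est = to_reporting_scale(est)
        med = reps.median()
        return pd.DataFrame(
            {
                "estimate": est,
                "p2.5": reps.quantile(0.025),
                "median": med,
                "p97.5": reps.quantile(0.975),
                "bias_percent": (med - est) / est * 100.0,
            }
        )


def bootstrap(
    fit_result: PopPKResults,
    n_replicates: int = 1000,
    seed: int = 0,
    indices: list[np.ndarray] | None = None,
    **fit_kwargs,
) -> BootstrapResult:
    """Nonparametric bootstrap with the subject as the sampling unit.

    Each replicate resamples subjects with replacement to the original
    subject count and refits the final model, initialising at the final
    estimates.  Non-convergent replicates are excluded and counted (a
    warning is raised when more than 5% fail).  ``indices`` overrides the
    random resampling with explicit subject-position arrays (testing hook).
    """
    model = fit_result.model
    table = model.table
    n = len(table)
    rng = np.random.default_rng(seed)
    if indices is None:
        indices = [rng.integers(0, n, size=n) for _ in range(n_replicates)]
    else:
        n_replicates = len(indices)

    fit_kwargs.setdefault("compute_se", False)
    fit_kwargs.setdefault("polish", False)  # warm-started quasi-Newton refits
    rows = []
    n_failed = 0
    for idx in indices:
        rep_table = table.subset(np.asarray(idx))
        try:
            rep = PopPKModel(rep_table, fit_result.spec).fit(
                init=fit_result.spec, **fit_kwargs
            )
        except Exception:  # noqa: BLE001 - replicate failures are expected
            n_failed += 1
            continue
        if not rep.converged:
            n_failed += 1
            continue
        rows.append(rep.params)
    if n_failed > 0.05 * n_replicates:
        warnings.warn(
            f"{n_failed}/{n_replicates} bootstrap replicates failed to converge",
            RuntimeWarning,
            stacklevel=2,
        )
    replicates = pd.DataFrame(rows).reset_index(drop=True)
    return BootstrapResult(
        replicates=replicates,
        final_estimates=fit_result.params,
        n_requested=n_replicates,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# Prediction- and variability-corrected VPC
# ---------------------------------------------------------------------------


@dataclass
class VPCResult:
    """Binned observed percentiles with simulation confidence intervals.

    ``table`` has one row per (bin, percentile) with the corrected observed
    percentile and the 95% interval of the same percentile across simulated
    replicates.
    """

    table: pd.DataFrame
    bin_edges: np.ndarray
    n_sim: int

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed value lies
        inside the simulated 95% interval."""
        t = self.table
        ok = (t["observed"] >= t["ci_lower"]) & (t["observed"] <= t["ci_upper"])
        return float(ok.mean())


def _quantile_bins(tad: np.ndarray, n_bins: int, min_per_bin: int = 5):
    """Quantile bin edges on TAD; bins under ``min_per_bin`` get merged."""
    edges = np.quantile(tad, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    while len(edges) > 2:
        counts, _ = np.histogram(tad, edges)
        if counts.min() >= min_per_bin:
            break
        i = int(np.argmin(counts))
        # merge the thin bin with its smaller neighbour
        drop = i + 1 if i == 0 else i
        edges = np.delete(edges, drop)
    return edges


def pvc_vpc(
    fit_or_model,
    spec: ModelSpec | None = None,
    n_sim: int = 1000,
    bins: int = 6,
    seed: int = 0,
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
) -> VPCResult:
    """Prediction- and variability-corrected visual predictive check.

    Observations are binned by time after the last dose.  Within each bin
    every observed and simulated value is location/scale standardised to
    the bin's typical subject: ``y* = PRED_bin + (y - PRED_ij) *
    sd_bin / sd_ij`` where ``PRED`` is the population prediction and ``sd``
    the model-simulated SD of that observation; bin values are medians.
    Observed 5th/50th/95th percentiles per bin are then compared with the
    95% interval of the same percentile across simulated replicates.
    """
    if isinstance(fit_or_model, PopPKResults):
        model = fit_or_model.model
        spec = spec or fit_or_model.spec
    else:
        model = fit_or_model
        if spec is None:
            raise ValueError("spec is required when passing a bare model")
    des = model.design
    rng = np.random.default_rng(seed)

    mask = des.mask
    tad = _time_after_last_dose(model)[mask]
    obs = des.obs_y[mask]
    pred = model._conc(spec, None)[mask]

    sims = _simulate_matrix(model, spec, n_sim, rng)[:, mask]  # (n_sim, n_obs)
    sd_obs = sims.std(axis=0, ddof=1)
    sd_obs = np.maximum(sd_obs, 1e-12)

    edges = _quantile_bins(tad, bins)
    bin_idx = np.clip(np.digitize(tad, edges) - 1, 0, len(edges) - 2)

    rows = []
    for b in range(len(edges) - 1):
        sel = bin_idx == b
        pred_bin = np.median(pred[sel])
        sd_bin = np.median(sd_obs[sel])
        corr_obs = pred_bin + (obs[sel] - pred[sel]) * (sd_bin / sd_obs[sel])
        corr_sim = pred_bin + (sims[:, sel] - pred[sel]) * (sd_bin / sd_obs[sel])
        for p in percentiles:
            obs_p = np.percentile(corr_obs, p)
            sim_p = np.percentile(corr_sim, p, axis=1)
            lo, hi = np.percentile(sim_p, [2.5, 97.5])
            rows.append(
                {
                    "bin": b,
                    "tad_lower": edges[b],
                    "tad_upper": edges[b + 1],
                    "tad_mid": float(np.median(tad[sel])),
                    "n_obs": int(sel.sum()),
                    "percentile": p,
                    "observed": obs_p,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "sim_median": float(np.median(sim_p)),
                }
            )
    return VPCResult(table=pd.DataFrame(rows), bin_edges=edges, n_sim=n_sim)


# ---------------------------------------------------------------------------
# NPDE
# ---------------------------------------------------------------------------


@dataclass
class NPDEResult:
    """Normalised prediction distribution errors and the three tests."""

    npde: np.ndarray
    p_mean: float       # t-test of mean 0
    p_variance: float   # chi-square test of unit variance
    p_normality: float  # Shapiro-Wilk

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "n": len(self.npde),
                "mean": float(np.mean(self.npde)),
                "variance": float(np.var(self.npde, ddof=1)),
                "p_mean": self.p_mean,
                "p_variance": self.p_variance,
                "p_normality": self.p_normality,
            }
        )


def _variance_chi2_test(x: np.ndarray) -> float:
    """Two-sided chi-square test that Var(x) = 1."""
    n = len(x)
    stat = (n - 1) * np.var(x, ddof=1)
    cdf = stats.chi2.cdf(stat, df=n - 1)
    return float(2.0 * min(cdf, 1.0 - cdf))


def npde(
    fit_or_model,
    spec: ModelSpec | None = None,
    n_sim: int = 1000,
    seed: int = 0,
) -> NPDEResult:
    """Normalised prediction distribution errors with decorrelation.

    For each subject the observation vector is simulated ``n_sim`` times
    under the model; observed and simulated vectors are decorrelated with
    the Cholesky factor of the empirical simulation covariance; the
    prediction discrepancy of each decorrelated observation is its rank
    among its decorrelated simulations (ties smoothed with seeded uniform
    jitter), and NPDE is the standard-normal quantile of that rank.  Under
    the true model the NPDE are iid N(0, 1); a t-test (mean 0), a
    chi-square variance test (variance 1) and Shapiro-Wilk (normality)
    are reported.
    """
    if isinstance(fit_or_model, PopPKResults):
        model = fit_or_model.model
        spec = spec or fit_or_model.spec
    else:
        model = fit_or_model
        if spec is None:
            raise ValueError("spec is required when passing a bare model")
    des = model.design
    rng = np.random.default_rng(seed)
    sims = _simulate_matrix(model, spec, n_sim, rng)  # (K, n, m)
    K = n_sim

    values = []
    for i in range(des.n):
        sel = des.mask[i]
        m_i = int(sel.sum())
        y = des.obs_y[i, sel]
        s = sims[:, i, sel]  # (K, m_i)
        mu = s.mean(axis=0)
        if m_i == 1:
            sd = max(s.std(ddof=1), 1e-12)
            y_dec = (y - mu) / sd
            s_dec = (s - mu) / sd
        else:
            cov = np.cov(s, rowvar=False)
            ridge = 1e-10 * max(np.trace(cov) / m_i, 1.0)
            for _ in range(12):
                try:
                    L = np.linalg.cholesky(cov + ridge * np.eye(m_i))
                    break
                except np.linalg.LinAlgError:
                    ridge *= 10.0
            else:
                raise np.linalg.LinAlgError("simulation covariance is singular")
            y_dec = np.linalg.solve(L, y - mu)
            s_dec = np.linalg.solve(L, (s - mu).T).T
        less = (s_dec < y_dec).sum(axis=0)
        ties = (s_dec == y_dec).sum(axis=0)
        u = rng.uniform(size=m_i)
        pde = (less + u * (ties + 1.0)) / (K + 1.0)
        pde = np.clip(pde, 1.0 / (2 * K), 1.0 - 1.0 / (2 * K))
        values.append(stats.norm.ppf(pde))
    all_npde = np.concatenate(values)

    p_mean = float(stats.ttest_1samp(all_npde, 0.0).pvalue)
    p_var = _variance_chi2_test(all_npde)
    p_norm = float(stats.shapiro(all_npde[:5000]).pvalue)
    return NPDEResult(all_npde, p_mean, p_var, p_norm)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


def gof_table(fit_result: PopPKResults) -> pd.DataFrame:
    """Per-observation DV/PRED/IPRED/CWRES table with time after last dose."""
    frame = fit_result.predictions()
    tad = _time_after_last_dose(fit_result.model)[fit_result.model.design.mask]
    frame["TAD"] = tad
    return frame
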