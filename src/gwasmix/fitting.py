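"""Parameter estimation by weighted least squares on binned replication curves.

The four mixture parameters are found by Nelder-Mead minimization of

    c = sum_ijk w_ijk [(zbar_ijk - delta_ijk)^2 + (z2bar_ijk - eta_ijk)^2]

over all (fraction i, repetition j, bin k) cells, where zbar/z2bar are the
empirical per-bin replication mean and second moment, delta_ijk = E(z_r|z_d)
and eta_ijk = E(z_r^2|z_d) are the model predictions at the bin center, and
w_ijk is the bin count.  Internally the variances are optimized on log scale
and pi1 on logit scale so the search is unconstrained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .empirical import BinnedCurves, SplitRealization
from .model import ModelParams
from .prediction import replication_posterior

__all__ = [
    "CurveData",
    "FitResult",
    "flatten_curves",
    "model_curves",
    "cost",
    "fit",
    "confidence_intervals",
]

DEFAULT_START = ModelParams(pi1=0.01, sigma0_sq=1.0, sigma_a_sq=1e-5, sigma_b_sq=1e-4)
PARAM_NAMES = ("pi1", "sigma0_sq", "sigma_a_sq", "sigma_b_sq")


@dataclass
class CurveData:
    """Flattened (i, j, k) cells with nonzero weight."""

    z_center: np.ndarray
    weight: np.ndarray
    zbar: np.ndarray
    z2bar: np.ndarray
    het: np.ndarray
    n_d: np.ndarray
    n_r: np.ndarray


@dataclass
class FitResult:
    params: ModelParams
    cost: float
    n_evals: int
    converged: bool
    start: ModelParams
    fixed: dict[str, float]
    delta_model: np.ndarray
    eta_model: np.ndarray
    data: CurveData
    ci95: dict[str, tuple[float, float]] | None = None
    ci_method: str | None = None


def flatten_curves(
    realizations: list[tuple[SplitRealization, BinnedCurves]],
) -> CurveData:
    """Stack per-realization binned curves into flat arrays (zero-weight bins dropped)."""
    zs, ws, m1, m2, hs, nds, nrs = [], [], [], [], [], [], []
    for split, curves in realizations:
        keep = curves.count > 0
        centers = curves.centers[keep]
        zs.append(centers)
        ws.append(curves.count[keep])
        m1.append(curves.mean_zr[keep])
        m2.append(curves.mean_zr_sq[keep])
        h = curves.mean_het[keep]
        hs.append(h)
        nds.append(np.full(keep.sum(), split.n_d))
        nrs.append(np.full(keep.sum(), split.n_r))
    het = np.concatenate(hs)
    if np.any(~np.isfinite(het)):
        raise ValueError("binned curves lack per-bin mean heterozygosity")
    return CurveData(
        z_center=np.concatenate(zs),
        weight=np.concatenate(ws),
        zbar=np.concatenate(m1),
        z2bar=np.concatenate(m2),
        het=het,
        n_d=np.concatenate(nds),
        n_r=np.concatenate(nrs),
    )


def _curves_flat(params: ModelParams, data: CurveData):
    rp = replication_posterior(data.z_center, data.n_d, data.n_r, params, data.het)
    return rp.e_delta_r, rp.e_z_r_sq


def model_curves(params: ModelParams, split: SplitRealization, curves: BinnedCurves):
    """Model (delta, eta) over the bins of one realization (NaN at empty bins)."""
    keep = curves.count > 0
    delta = np.full(curves.n_bins, np.nan)
    eta = np.full(curves.n_bins, np.nan)
    rp = replication_posterior(
        curves.centers[keep], split.n_d, split.n_r, params, curves.mean_het[keep]
    )
    delta[keep] = rp.e_delta_r
    eta[keep] = rp.e_z_r_sq
    return delta, eta


def cost(params: ModelParams, data: CurveData) -> float:
    """Weighted squared discrepancy between empirical and model curves."""
    delta, eta = _curves_flat(params, data)
    return float(
        np.sum(data.weight * ((data.zbar - delta) ** 2 + (data.z2bar - eta) ** 2))
    )


# --- internal transform: (logit pi1, log s0, log sa, log sb) ----------------

_VAR_FLOOR = 1e-30  # natural-scale floor so log() is defined for tiny starts


def _to_internal(params: ModelParams, free: list[str]) -> np.ndarray:
    full = {
        "pi1": logit(min(max(params.pi1, 1e-12), 1 - 1e-12)),
        "sigma0_sq": np.log(params.sigma0_sq),
        "sigma_a_sq": np.log(max(params.sigma_a_sq, _VAR_FLOOR)),
        "sigma_b_sq": np.log(max(params.sigma_b_sq, _VAR_FLOOR)),
    }
    return np.array([full[name] for name in free])


def _from_internal(theta: np.ndarray, free: list[str], fixed: dict[str, float]) -> ModelParams:
    vals = dict(fixed)
    for name, t in zip(free, theta):
        vals[name] = float(expit(t)) if name == "pi1" else float(np.exp(t))
    return ModelParams(**vals)


def fit(
    realizations_or_data,
    start: ModelParams | None = None,
    n_starts: int = 5,
    seed: int = 0,
    fixed: dict[str, float] | None = None,
    maxfev: int = 2000,
    rel_ftol: float = 1e-6,
) -> FitResult:
    """Nelder-Mead fit of the mixture parameters to binned empirical curves.

    ``fixed`` pins parameters at given natural-scale values (e.g.
    ``{"sigma_b_sq": 0.0}`` for the degenerate no-sparse-effects variant).
    Multi-start: the first start is ``start`` (default order-of-magnitude
    neutral), the rest are jittered on the internal scale; the best final
    cost wins.  Deterministic given ``seed``.
    """
    if isinstance(realizations_or_data, CurveData):
        data = realizations_or_data
    else:
        data = flatten_curves(realizations_or_data)
    fixed = dict(fixed or {})
    free = [p for p in PARAM_NAMES if p not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")
    start = start or DEFAULT_START
    theta0 = _to_internal(start, free)

    def objective(theta):
        return cost(_from_internal(theta, free, fixed), data)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    best = None
    n_evals = 0
    converged = False
    c0 = objective(theta0)
    fatol = rel_ftol * max(c0, 1.0)
    for s in range(max(1, n_starts)):
        theta_s = theta0 if s == 0 else theta0 + rng.normal(0.0, 0.5, size=len(free))
        res = minimize(
            objective,
            theta_s,
            method="Nelder-Mead",
            options={"maxfev": maxfev, "fatol": fatol, "xatol": 1e-6},
        )
        n_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
            converged = converged or bool(res.success)
    if not converged:
        warnings.warn("Nelder-Mead did not converge; returning best point found")
    params_hat = _from_internal(best.x, free, fixed)
    delta, eta = _curves_flat(params_hat, data)
    return FitResult(
        params=params_hat,
        cost=float(best.fun),
        n_evals=n_evals,
        converged=converged,
        start=start,
        fixed=fixed,
        delta_model=delta,
        eta_model=eta,
        data=data,
    )


def confidence_intervals(
    fit_result: FitResult,
    generator_config: dict,
    n_boot: int = 50,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Parametric-bootstrap 95% intervals for the fitted parameters.

    Regenerates ``n_boot`` synthetic cohorts from the fitted parameters at
    the scale given by ``generator_config`` (keys: studies, m_snps and
    optionally maf_range, fractions, n_reps, p_threshold, n_bins), refits
    each, and takes 2.5/97.5 percentiles on the internal (log/logit) scale,
    giving asymmetric natural-scale intervals.  This is a declared
    substitute for a closed-form error propagation.
    """
    from .simulate import generate_cohort
    from .empirical import realized_curves

    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if n_boot < 20:
        warnings.warn(
            f"n_boot={n_boot} < 20: interval percentiles are noisy; widening by 1.5x"
        )
    cfg = dict(generator_config)
    studies = cfg["studies"]
    free = [p for p in PARAM_NAMES if p not in fit_result.fixed]
    ss = np.random.SeedSequence([seed, 11])
    draws = []
    for b, child in enumerate(ss.spawn(n_boot)):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        cohort = generate_cohort(
            fit_result.params,
            studies,
            m_snps=cfg["m_snps"],
            maf_range=cfg.get("maf_range", (0.005, 0.5)),
            seed=child_seed,
        )
        realizations = realized_curves(
            cohort.table,
            studies,
            ld=None,
            fractions=cfg.get("fractions", tuple(np.round(np.arange(1, 10) * 0.1, 1))),
            n_reps=cfg.get("n_reps", 10),
            p_threshold=cfg.get("p_threshold", 0.05),
            n_bins=cfg.get("n_bins", 200),
            seed=child_seed,
        )
        refit = fit(
            realizations,
            start=fit_result.params,
            n_starts=1,
            seed=child_seed,
            fixed=fit_result.fixed,
        )
        draws.append(_to_internal(refit.params, free))
    draws = np.array(draws)
    center = _to_internal(fit_result.params, free)
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    if n_boot < 20:
        lo = center - 1.5 * np.abs(center - lo)
        hi = center + 1.5 * np.abs(hi - center)
    # the interval contract includes the point estimate
    lo = np.minimum(lo, center)
    hi = np.maximum(hi, center)
    ci: dict[str, tuple[float, float]] = {}
    for k, name in enumerate(free):
        inv = (lambda t: float(expit(t))) if name == "pi1" else (lambda t: float(np.exp(t)))
        ci[name] = (inv(lo[k]), inv(hi[k]))
    fit_result.ci95 = ci
    fit_result.ci_method = f"parametric bootstrap (B={n_boot}, internal scale)"
    return ci
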