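"""Replication-sample and combined (multistage) predictions.

Given a discovery z-score z_d observed at effective sample size N_d, the
model predicts the distribution of the z-score the same SNP would obtain
in an independent replication sample of size N_r: effect sizes scale as
sqrt(N*H), so the posterior arms of delta given z_d are rescaled by
sqrt(N_r/N_d) and re-noised with sigma0_sq.  Multistage predictions
meta-combine the discovery score with the predicted replication score
using sample-size weights w = sqrt(N/(N_d+N_r)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .model import ModelParams, SnpContext, posterior_moments

__all__ = [
    "ReplicationPrediction",
    "CombinedPrediction",
    "p_to_z_one_tailed",
    "effective_sample_size",
    "total_n_from_eff",
    "replication_posterior",
    "expected_replication_z",
    "var_replication_z",
    "replication_rate",
    "combined_expectation",
    "combined_replication_rate",
]


@dataclass(frozen=True)
class ReplicationPrediction:
    """Posterior of z_r given z_d: two-arm mixture moments and summaries."""

    tdr: float | np.ndarray
    m_u: float | np.ndarray
    m_s: float | np.ndarray
    s_u_sq: float | np.ndarray
    s_s_sq: float | np.ndarray
    e_delta_r: float | np.ndarray
    var_delta_r: float | np.ndarray
    var_z_r: float | np.ndarray
    e_z_r_sq: float | np.ndarray


@dataclass(frozen=True)
class CombinedPrediction:
    """Posterior of the combined-dataset z_dr given z_d."""

    w_d: float
    w_r: float
    e_z_dr: float | np.ndarray
    var_z_dr: float | np.ndarray


def p_to_z_one_tailed(p_threshold: float) -> float:
    """Negative standard-normal quantile for a one-tailed p threshold."""
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie strictly between 0 and 1")
    return float(ndtri(p_threshold))


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """N_eff = 2 / (1/N_cases + 1/N_controls); equals N/2 when balanced."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 2.0 / (1.0 / n_cases + 1.0 / n_controls)


def total_n_from_eff(n_eff: float) -> float:
    """Total subjects in a balanced case-control study with the given N_eff."""
    if n_eff <= 0:
        raise ValueError("n_eff must be positive")
    return 2.0 * n_eff


def _check_sizes(n_d, n_r) -> None:
    if np.any(np.asarray(n_d) <= 0) or np.any(np.asarray(n_r) <= 0):
        raise ValueError("sample sizes must be positive")


def replication_posterior(z_d, n_d: float, n_r: float, params: ModelParams, het) -> ReplicationPrediction:
    """Two-arm posterior of z_r given z_d.

    m = sqrt(N_r/N_d) * mu,  s^2 = sigma0_sq + (N_r/N_d) * sigma^2,
    with mu, sigma^2 the posterior arms of delta at (z_d, N_d, het).
    """
    _check_sizes(n_d, n_r)
    ratio = n_r / n_d
    root = np.sqrt(ratio)
    pm = posterior_moments(z_d, params, SnpContext(n_eff=n_d, het=het))
    t = pm.tdr
    m_u = root * pm.mu_u
    m_s = root * pm.mu_s
    e_delta_r = (1.0 - t) * m_u + t * m_s
    var_delta_r = ratio * (
        (1.0 - t) * pm.var_u
        + t * pm.var_s
        + t * (1.0 - t) * np.square(pm.mu_s - pm.mu_u)
    )
    var_z_r = var_delta_r + params.sigma0_sq
    return ReplicationPrediction(
        tdr=t,
        m_u=m_u,
        m_s=m_s,
        s_u_sq=params.sigma0_sq + ratio * pm.var_u,
        s_s_sq=params.sigma0_sq + ratio * pm.var_s,
        e_delta_r=e_delta_r,
        var_delta_r=var_delta_r,
        var_z_r=var_z_r,
        e_z_r_sq=var_z_r + np.square(e_delta_r),
    )


def expected_replication_z(z_d, n_d: float, n_r: float, params: ModelParams, het):
    """E(z_r | z_d) = E(delta_r | z_d) = sqrt(N_r/N_d) [(1-tdr) mu_u + tdr mu_s]."""
    return replication_posterior(z_d, n_d, n_r, params, het).e_delta_r


def var_replication_z(z_d, n_d: float, n_r: float, params: ModelParams, het):
    """(var(delta_r|z_d), var(z_r|z_d)); the latter adds sigma0_sq."""
    rp = replication_posterior(z_d, n_d, n_r, params, het)
    return rp.var_delta_r, rp.var_z_r


def _folded_rate(rp: ReplicationPrediction, z_threshold):
    return (1.0 - rp.tdr) * ndtr(
        (z_threshold + np.abs(rp.m_u)) / np.sqrt(rp.s_u_sq)
    ) + rp.tdr * ndtr((z_threshold + np.abs(rp.m_s)) / np.sqrt(rp.s_s_sq))


def replication_rate(z_d, n_d: float, n_r: float, params: ModelParams, het, z_threshold: float):
    """Pr(replication z same-signed as z_d and one-tailed p_r < p_t)."""
    if z_threshold > 0:
        raise ValueError("z_threshold must be <= 0 (one-tailed convention)")
    rp = replication_posterior(z_d, n_d, n_r, params, het)
    out = _folded_rate(rp, z_threshold)
    return out if np.ndim(out) else float(out)


def combined_expectation(z_d, n_d: float, n_r: float, params: ModelParams, het) -> CombinedPrediction:
    """Posterior mean/variance of the combined-dataset z_dr given z_d."""
    if n_d <= 0 or n_r < 0:
        raise ValueError("need n_d > 0 and n_r >= 0")
    n_dr = n_d + n_r
    w_d = float(np.sqrt(n_d / n_dr))
    w_r = float(np.sqrt(n_r / n_dr))
    if n_r == 0:
        z_d = np.asarray(z_d, dtype=float)
        e = w_d * z_d
        return CombinedPrediction(w_d, w_r, e if e.ndim else float(e), 0.0)
    rp = replication_posterior(z_d, n_d, n_r, params, het)
    e = w_d * np.asarray(z_d, dtype=float) + w_r * rp.e_delta_r
    v = w_r**2 * rp.var_z_r
    return CombinedPrediction(
        w_d, w_r, e if np.ndim(e) else float(e), v if np.ndim(v) else float(v)
    )


def combined_replication_rate(z_d, n_d: float, n_r: float, params: ModelParams, het, z_threshold: float):
    """Pr(p_dr < p_t | z_d) for the combined discovery+replication dataset.

    Evaluates the replication-rate mixture at the transformed threshold
    z_t' = (z_t + w_d |z_d|) / w_r.  With no replication sample the combined
    score is z_d itself and the rate degenerates to the indicator.
    """
    if z_threshold > 0:
        raise ValueError("z_threshold must be <= 0 (one-tailed convention)")
    if n_d <= 0 or n_r < 0:
        raise ValueError("need n_d > 0 and n_r >= 0")
    z_d = np.asarray(z_d, dtype=float)
    if n_r == 0:
        out = (-np.abs(z_d) < z_threshold).astype(float)
        return out if out.ndim else float(out)
    n_dr = n_d + n_r
    w_d = np.sqrt(n_d / n_dr)
    w_r = np.sqrt(n_r / n_dr)
    z_t_prime = (z_threshold + w_d * np.abs(z_d)) / w_r
    rp = replication_posterior(z_d, n_d, n_r, params, het)
    out = _folded_rate(rp, z_t_prime)
    return out if np.ndim(out) else float(out)
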