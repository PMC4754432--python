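"""Two-component Gaussian mixture model for GWAS summary statistics.

The marginal distribution of a SNP z-score is modelled as

    f(z) = pi0 * phi(z; 0, s0 + s1) + pi1 * phi(z; 0, s0 + s1 + s2)

where s0 = sigma0_sq is the non-replicating (noise) variance, s1 =
sigma_a_sq * N * H is the variance of ubiquitous (small, replicating)
effects, and s2 = sigma_b_sq * N * H the additional variance of sparse
(large) effects carried by a fraction pi1 of SNPs.  N is the effective
sample size and H = 2p(1-p) the SNP heterozygosity.  All posterior
quantities of the true effect size delta (z = delta + eps) given z follow
in closed form from this mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr

__all__ = [
    "ModelParams",
    "SnpContext",
    "ScaledVariances",
    "PosteriorMoments",
    "heterozygosity",
    "scaled_variances",
    "mixture_pdf",
    "mixture_cdf",
    "tdr",
    "posterior_moments",
    "posterior_pdf",
    "expected_components",
    "expected_delta_sq",
    "overestimation_factor",
    "power_given_delta",
]

_LOG_2PI = np.log(2.0 * np.pi)

# heterozygosity below this is treated as degenerate (monomorphic SNPs are
# expected to be removed by QC upstream)
H_FLOOR = 1e-12
H_CEIL = 0.5


@dataclass(frozen=True)
class ModelParams:
    """The four mixture parameters, on natural scale.

    pi1          prior probability of the sparse (large-effect) class
    sigma0_sq    variance of the non-replicating noise component eps
    sigma_a_sq   per-allele variance of ubiquitous effects
    sigma_b_sq   per-allele additional variance of sparse effects
    """

    pi1: float
    sigma0_sq: float
    sigma_a_sq: float
    sigma_b_sq: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi1 <= 1.0:
            raise ValueError(f"pi1 must be in [0, 1], got {self.pi1}")
        if not self.sigma0_sq > 0.0:
            raise ValueError(f"sigma0_sq must be positive, got {self.sigma0_sq}")
        if self.sigma_a_sq < 0.0 or self.sigma_b_sq < 0.0:
            raise ValueError("per-allele variances must be nonnegative")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1

    def as_sigma_tuple(self) -> tuple[float, float, float, float]:
        """(pi1, sigma0, sigma_a, sigma_b) — square-root (sd) convention."""
        return (
            self.pi1,
            float(np.sqrt(self.sigma0_sq)),
            float(np.sqrt(self.sigma_a_sq)),
            float(np.sqrt(self.sigma_b_sq)),
        )

    @classmethod
    def from_sigmas(cls, pi1: float, sigma0: float, sigma_a: float, sigma_b: float) -> "ModelParams":
        return cls(pi1, sigma0**2, sigma_a**2, sigma_b**2)


@dataclass(frozen=True)
class SnpContext:
    """Per-SNP scale context: effective sample size and heterozygosity.

    Both fields broadcast against z, so arrays are accepted.
    """

    n_eff: float | np.ndarray
    het: float | np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n_eff, dtype=float)
        h = np.asarray(self.het, dtype=float)
        if np.any(n <= 0):
            raise ValueError("n_eff must be positive")
        if np.any(h < 0) or np.any(h > H_CEIL):
            raise ValueError("het must lie in [0, 0.5]")


@dataclass(frozen=True)
class ScaledVariances:
    """z-scale variances sigma1_sq = sigma_a_sq*N*H, sigma2_sq = sigma_b_sq*N*H."""

    sigma1_sq: float | np.ndarray
    sigma2_sq: float | np.ndarray


@dataclass(frozen=True)
class PosteriorMoments:
    """Arm-wise posterior moments of delta given z (Gaussian mixture posterior)."""

    tdr: float | np.ndarray
    mu_u: float | np.ndarray
    mu_s: float | np.ndarray
    var_u: float | np.ndarray
    var_s: float | np.ndarray


def heterozygosity(allele_freq):
    """H = 2 p (1 - p); symmetric in p <-> 1-p."""
    p = np.asarray(allele_freq, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("allele frequency must lie in [0, 1]")
    out = 2.0 * p * (1.0 - p)
    return out if out.ndim else float(out)


def scaled_variances(params: ModelParams, ctx: SnpContext) -> ScaledVariances:
    nh = np.asarray(ctx.n_eff, dtype=float) * np.clip(
        np.asarray(ctx.het, dtype=float), H_FLOOR, H_CEIL
    )
    return ScaledVariances(params.sigma_a_sq * nh, params.sigma_b_sq * nh)


def _arm_variances(params: ModelParams, ctx: SnpContext):
    """Total z variances of the two arms: (v_u, v_s) = (s0+s1, s0+s1+s2)."""
    sv = scaled_variances(params, ctx)
    v_u = params.sigma0_sq + sv.sigma1_sq
    return v_u, v_u + sv.sigma2_sq


def _log_normal_pdf(z, var):
    return -0.5 * (_LOG_2PI + np.log(var) + np.square(z) / var)


def mixture_pdf(z, params: ModelParams, ctx: SnpContext):
    """Marginal density of z under the two-component mixture."""
    z = np.asarray(z, dtype=float)
    v_u, v_s = _arm_variances(params, ctx)
    out = params.pi0 * np.exp(_log_normal_pdf(z, v_u)) + params.pi1 * np.exp(
        _log_normal_pdf(z, v_s)
    )
    return out if out.ndim else float(out)


def mixture_cdf(z, params: ModelParams, ctx: SnpContext):
    """Mixture CDF (the model's QQ curve uses this in place of the PDF)."""
    z = np.asarray(z, dtype=float)
    v_u, v_s = _arm_variances(params, ctx)
    out = params.pi0 * ndtr(z / np.sqrt(v_u)) + params.pi1 * ndtr(z / np.sqrt(v_s))
    return out if out.ndim else float(out)


def tdr(z, params: ModelParams, ctx: SnpContext):
    """Local true discovery rate: Pr(sparse class | z).

    Computed in log space so that extreme |z| does not underflow the
    mixture density.
    """
    z = np.asarray(z, dtype=float)
    if params.pi1 == 0.0:
        out = np.zeros_like(z)
        return out if out.ndim else float(out)
    if params.pi1 == 1.0:
        out = np.ones_like(z)
        return out if out.ndim else float(out)
    v_u, v_s = _arm_variances(params, ctx)
    log_sparse = np.log(params.pi1) + _log_normal_pdf(z, v_s)
    log_ubiq = np.log(params.pi0) + _log_normal_pdf(z, v_u)
    out = expit(log_sparse - log_ubiq)
    return out if out.ndim else float(out)


def posterior_moments(z, params: ModelParams, ctx: SnpContext) -> PosteriorMoments:
    """Arm means and variances of the posterior of delta given z.

    mu_u = z s1/(s0+s1),  mu_s = z (s1+s2)/(s0+s1+s2)
    var_u = s0 s1/(s0+s1),  var_s = s0 (s1+s2)/(s0+s1+s2)
    """
    z = np.asarray(z, dtype=float)
    s0 = params.sigma0_sq
    sv = scaled_variances(params, ctx)
    s1, s12 = sv.sigma1_sq, sv.sigma1_sq + sv.sigma2_sq
    shrink_u = s1 / (s0 + s1)
    shrink_s = s12 / (s0 + s12)
    t = tdr(z, params, ctx)
    return PosteriorMoments(
        tdr=t,
        mu_u=z * shrink_u,
        mu_s=z * shrink_s,
        var_u=s0 * shrink_u,
        var_s=s0 * shrink_s,
    )


def posterior_pdf(delta, z, params: ModelParams, ctx: SnpContext):
    """Density of the true effect size delta given an observed z."""
    delta = np.asarray(delta, dtype=float)
    pm = posterior_moments(z, params, ctx)
    d_u = np.exp(_log_normal_pdf(delta - pm.mu_u, pm.var_u))
    d_s = np.exp(_log_normal_pdf(delta - pm.mu_s, pm.var_s))
    out = (1.0 - pm.tdr) * d_u + pm.tdr * d_s
    return out if out.ndim else float(out)


def expected_components(z, params: ModelParams, ctx: SnpContext):
    """Posterior means of the four effect decompositions given z.

    Returns (E[delta_a|z], E[delta_b|z], E[delta_u|z], E[delta_s|z]); the
    two decompositions sum to the same total posterior mean E[delta|z].
    """
    z = np.asarray(z, dtype=float)
    s0 = params.sigma0_sq
    sv = scaled_variances(params, ctx)
    s1, s12 = sv.sigma1_sq, sv.sigma1_sq + sv.sigma2_sq
    t = tdr(z, params, ctx)
    e_a = z * (t * s1 / (s0 + s12) + (1.0 - t) * s1 / (s0 + s1))
    e_b = z * t * (s12 - s1) / (s0 + s12)
    pm = posterior_moments(z, params, ctx)
    e_u = (1.0 - t) * pm.mu_u
    e_s = t * pm.mu_s
    return e_a, e_b, e_u, e_s


def expected_delta_sq(z, params: ModelParams, ctx: SnpContext):
    """Posterior second moment E(delta^2 | z)."""
    pm = posterior_moments(z, params, ctx)
    t = pm.tdr
    mean = (1.0 - t) * pm.mu_u + t * pm.mu_s
    out = (
        (1.0 - t) * pm.var_u
        + t * pm.var_s
        + t * (1.0 - t) * np.square(pm.mu_s - pm.mu_u)
        + np.square(mean)
    )
    return out if np.ndim(out) else float(out)


def overestimation_factor(z, params: ModelParams, ctx: SnpContext):
    """z^2 / E(delta^2|z): inflation of the naive per-SNP variance estimate."""
    z = np.asarray(z, dtype=float)
    if np.any(z == 0.0):
        raise ValueError("overestimation factor is undefined at z = 0")
    out = np.square(z) / expected_delta_sq(z, params, ctx)
    return out if out.ndim else float(out)


def power_given_delta(delta, z_threshold: float, params: ModelParams):
    """Pr(one-tailed p < p_t | delta) = Phi(z_t; -|delta|, sigma0_sq)."""
    if z_threshold > 0:
        raise ValueError("z_threshold must be <= 0 (one-tailed convention)")
    delta = np.asarray(delta, dtype=float)
    s0 = np.sqrt(params.sigma0_sq)
    out = ndtr((z_threshold + np.abs(delta)) / s0)
    return out if out.ndim else float(out)
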