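"""Proportion of chip heritability explained by genome-wide-significant SNPs.

S(N; z_t) is the expected fraction of the additive tagged variance carried
by sparse-class SNPs whose z-scores reach the significance threshold z_t at
effective sample size N.  It is estimated by direct simulation of the
generative model: sparse SNPs receive a combined true effect
delta_c ~ N(0, (sigma_a_sq + sigma_b_sq) * N * Hbar) plus noise
eps ~ N(0, sigma0_sq), and S is the ratio of summed delta_c^2 over
significant SNPs to the total, with numerator and denominator averaged over
repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParams, SnpContext, expected_delta_sq

__all__ = [
    "ProjectionCurve",
    "simulate_S",
    "expected_S",
    "projection_curve",
    "n_for_target_S",
    "BracketError",
]


class BracketError(ValueError):
    """The requested target S is not spanned by the sample-size bracket."""


@dataclass
class ProjectionCurve:
    n_grid: np.ndarray
    s_values: np.ndarray
    s_se: np.ndarray
    z_threshold: float
    mean_het: float
    m_snps: int
    reps: int


def simulate_S(
    params: ModelParams,
    n_eff: float,
    z_threshold: float,
    mean_het: float,
    m_snps: int = 100_000,
    reps: int = 20,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of S(N; z_t) and its standard error.

    Draw order per repetition (relied on by exact-stream cross-checks):
    number of sparse SNPs ~ Binomial(m_snps, pi1), then their delta_c
    vector, then their eps vector.  S is the ratio of repetition-averaged
    numerator to repetition-averaged denominator.
    """
    if z_threshold > 0:
        raise ValueError("z_threshold must be <= 0 (one-tailed convention)")
    rng = np.random.default_rng(rng)
    sd_delta = np.sqrt((params.sigma_a_sq + params.sigma_b_sq) * n_eff * mean_het)
    sd_eps = np.sqrt(params.sigma0_sq)
    nums, dens = [], []
    for _ in range(reps):
        k = rng.binomial(m_snps, params.pi1)
        if k == 0:
            nums.append(0.0)
            dens.append(0.0)
            continue
        delta_c = rng.normal(0.0, sd_delta, size=k)
        eps = rng.normal(0.0, sd_eps, size=k)
        z = delta_c + eps
        sig = -np.abs(z) < z_threshold
        d2 = delta_c**2
        nums.append(float(d2[sig].sum()))
        dens.append(float(d2.sum()))
    nums = np.array(nums)
    dens = np.array(dens)
    if dens.sum() == 0:
        return float("nan"), float("nan")
    s = nums.sum() / dens.sum()
    ratios = np.divide(nums, dens, out=np.full(reps, np.nan), where=dens > 0)
    ratios = ratios[np.isfinite(ratios)]
    se = float(ratios.std(ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else float("nan")
    return float(s), se


def expected_S(z_scores, params: ModelParams, n_eff: float, z_threshold: float, het=0.25) -> float:
    """Posterior-expectation variant: replace delta^2 with E(delta^2 | z)."""
    if z_threshold > 0:
        raise ValueError("z_threshold must be <= 0 (one-tailed convention)")
    z = np.asarray(z_scores, dtype=float)
    e2 = np.asarray(expected_delta_sq(z, params, SnpContext(n_eff=n_eff, het=het)))
    total = e2.sum()
    if total == 0:
        return float("nan")
    sig = -np.abs(z) < z_threshold
    return float(e2[sig].sum() / total)


def projection_curve(
    params: ModelParams,
    z_threshold: float,
    mean_het: float,
    n_grid,
    m_snps: int = 100_000,
    reps: int = 20,
    seed: int = 0,
) -> ProjectionCurve:
    """S(N; z_t) over a sample-size grid, one seeded stream per grid point."""
    n_grid = np.asarray(n_grid, dtype=float)
    ss = np.random.SeedSequence([seed, 3])
    s_vals = np.empty(len(n_grid))
    s_ses = np.empty(len(n_grid))
    for i, (n, child) in enumerate(zip(n_grid, ss.spawn(len(n_grid)))):
        s_vals[i], s_ses[i] = simulate_S(
            params, float(n), z_threshold, mean_het, m_snps, reps,
            rng=np.random.default_rng(child),
        )
    return ProjectionCurve(
        n_grid=n_grid,
        s_values=s_vals,
        s_se=s_ses,
        z_threshold=z_threshold,
        mean_het=mean_het,
        m_snps=m_snps,
        reps=reps,
    )


def log_grid(n_lo: float, n_hi: float, points_per_decade: int = 20) -> np.ndarray:
    n_pts = max(2, int(np.ceil(np.log10(n_hi / n_lo) * points_per_decade)) + 1)
    return np.logspace(np.log10(n_lo), np.log10(n_hi), n_pts)


def n_for_target_S(
    params: ModelParams,
    z_threshold: float,
    mean_het: float,
    target_S: float,
    n_bracket: tuple[float, float] = (1e3, 1e7),
    points_per_decade: int = 20,
    m_snps: int = 100_000,
    reps: int = 20,
    seed: int = 0,
) -> float:
    """Smallest grid sample size whose (monotone-smoothed) S reaches target_S."""
    if not 0.0 < target_S < 1.0:
        raise ValueError("target_S must lie strictly in (0, 1)")
    grid = log_grid(n_bracket[0], n_bracket[1], points_per_decade)
    curve = projection_curve(params, z_threshold, mean_het, grid, m_snps, reps, seed)
    s = np.maximum.accumulate(curve.s_values)  # enforce monotone non-decrease
    if s[0] >= target_S or s[-1] < target_S:
        raise BracketError(
            f"target S={target_S} not spanned: S({grid[0]:.3g})={s[0]:.3f}, "
            f"S({grid[-1]:.3g})={s[-1]:.3f}"
        )
    return float(grid[np.argmax(s >= target_S)])
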