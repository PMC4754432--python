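"""Brute-force Monte-Carlo oracle for the conditional closed forms.

Simulates the generative model directly — shared per-SNP genetic effects
(class, a, b), independent per-stage noise — and estimates conditional
quantities by binning on the discovery z-score.  Never calls the package's
closed-form functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BinEstimate:
    """Empirical conditional estimates within one z_d bin."""

    n: int
    mean_z_d: float
    z_d_values: np.ndarray  # the binned discovery scores, for bin-averaged model evaluation
    tdr: float
    tdr_se: float
    e_delta_d: float          # E(delta | z_d), discovery scale
    e_delta_d_se: float
    e_delta_r: float          # E(delta_r | z_d), replication scale
    e_delta_r_se: float
    var_delta_r: float
    var_delta_r_se: float
    e_zr_sq: float            # E(z_r^2 | z_d)
    e_zr_sq_se: float
    e_delta_d_sq: float       # E(delta^2 | z_d), discovery scale
    e_delta_d_sq_se: float
    repl_rate: float
    repl_rate_se: float
    combined_rate: float
    combined_rate_se: float


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))


def simulate_conditionals(
    pi1: float,
    sigma0_sq: float,
    sigma_a_sq: float,
    sigma_b_sq: float,
    n_d: float,
    n_r: float,
    het: float,
    z_targets,
    z_threshold: float,
    n_draws: int = 1_000_000,
    half_width: float = 0.1,
    seed: int = 0,
) -> dict[float, BinEstimate]:
    """Draw SNPs from the generative model and bin on z_d around each target."""
    rng = np.random.default_rng(seed)
    cls = rng.uniform(size=n_draws) < pi1
    a = rng.normal(0.0, np.sqrt(sigma_a_sq), size=n_draws)
    b = np.where(cls, rng.normal(0.0, np.sqrt(sigma_b_sq), size=n_draws), 0.0)
    per_allele = a + b
    delta_d = np.sqrt(n_d * het) * per_allele
    delta_r = np.sqrt(n_r * het) * per_allele
    z_d = delta_d + rng.normal(0.0, np.sqrt(sigma0_sq), size=n_draws)
    z_r = delta_r + rng.normal(0.0, np.sqrt(sigma0_sq), size=n_draws)

    n_dr = n_d + n_r
    w_d, w_r = np.sqrt(n_d / n_dr), np.sqrt(n_r / n_dr)
    z_dr = w_d * z_d + w_r * z_r

    out: dict[float, BinEstimate] = {}
    for z_star in z_targets:
        in_bin = np.abs(z_d - z_star) <= half_width
        n = int(in_bin.sum())
        if n < 10:
            continue
        sgn = np.sign(z_d[in_bin])
        sgn[sgn == 0] = 1.0
        dd = delta_d[in_bin]
        dr = delta_r[in_bin]
        zr = z_r[in_bin]
        # replication: same sign as z_d, one-tailed |z_r| beyond threshold
        success = (sgn * zr > -z_threshold).astype(float)
        success_dr = (sgn * z_dr[in_bin] > -z_threshold).astype(float)
        v = dr.var(ddof=1)
        centered = dr - dr.mean()
        v_se = float(
            np.sqrt(max((centered**4).mean() - v**2, 0.0) / n)
        )
        t, t_se = _mean_se(cls[in_bin].astype(float))
        m_dd, se_dd = _mean_se(dd)
        m_dr, se_dr = _mean_se(dr)
        m_zr2, se_zr2 = _mean_se(zr**2)
        m_dd2, se_dd2 = _mean_se(dd**2)
        r, r_se = _mean_se(success)
        rc, rc_se = _mean_se(success_dr)
        out[z_star] = BinEstimate(
            n=n,
            mean_z_d=float(z_d[in_bin].mean()),
            z_d_values=z_d[in_bin].copy(),
            tdr=t,
            tdr_se=t_se,
            e_delta_d=m_dd,
            e_delta_d_se=se_dd,
            e_delta_r=m_dr,
            e_delta_r_se=se_dr,
            var_delta_r=float(v),
            var_delta_r_se=v_se,
            e_zr_sq=m_zr2,
            e_zr_sq_se=se_zr2,
            e_delta_d_sq=m_dd2,
            e_delta_d_sq_se=se_dd2,
            repl_rate=r,
            repl_rate_se=r_se,
            combined_rate=rc,
            combined_rate_se=rc_se,
        )
    return out
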