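"""Non-parametric estimation machinery for split/replication experiments.

A meta-analyzed GWAS is repeatedly divided into complementary discovery and
replication sets at the substudy level.  Within each realization, SNPs are
randomly LD-pruned, discovery z-scores are binned, and per-bin replication
means, second moments, and replication fractions are recorded.  Averaged
over repetitions these provide unbiased empirical estimates of the
conditional quantities E(z_r|z_d), E(z_r^2|z_d), and R(z_d; z_t) that the
mixture model predicts in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .model import heterozygosity

__all__ = [
    "StudyInfo",
    "SummaryStatsTable",
    "LdTable",
    "SplitRealization",
    "BinnedCurves",
    "EmptyTableError",
    "qc_filter",
    "random_prune",
    "tld_filter",
    "plan_splits",
    "meta_z",
    "bin_conditional",
    "aggregate_curves",
    "empirical_qq",
    "model_qq",
    "realized_curves",
]


class EmptyTableError(ValueError):
    """Raised when a filter removes every SNP."""


@dataclass(frozen=True)
class StudyInfo:
    """One substudy: id plus sample-size bookkeeping.

    Case-control studies supply (n_cases, n_controls) and get
    N_eff = 2/(1/n_cases + 1/n_controls); quantitative studies supply
    n_quant and get N_eff = n_quant.
    """

    study_id: str
    n_cases: float | None = None
    n_controls: float | None = None
    n_quant: float | None = None

    @property
    def n_eff(self) -> float:
        if self.n_quant is not None:
            if self.n_quant <= 0:
                raise ValueError("n_quant must be positive")
            return float(self.n_quant)
        if self.n_cases is None or self.n_controls is None:
            raise ValueError(f"study {self.study_id}: no sample size given")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case/control counts must be positive")
        return 2.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)


def total_n_eff(studies: list[StudyInfo]) -> float:
    return float(sum(s.n_eff for s in studies))


class SummaryStatsTable:
    """Per-SNP metadata plus a (n_snps, n_studies) matrix of z-scores.

    ``snps`` holds at least columns ``snp``, ``allele_freq``, ``het``;
    optional annotation columns (chrom, pos, a1, a2) are carried through
    untouched.  Missing per-study z-scores are NaN.
    """

    def __init__(self, snps: pd.DataFrame, z: np.ndarray, study_ids: list[str]):
        z = np.asarray(z, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if len(snps) != z.shape[0]:
            raise ValueError("snps and z have inconsistent lengths")
        if z.shape[1] != len(study_ids):
            raise ValueError("z columns and study_ids have inconsistent lengths")
        for col in ("snp", "allele_freq"):
            if col not in snps.columns:
                raise ValueError(f"snps frame is missing column {col!r}")
        snps = snps.reset_index(drop=True)
        if "het" not in snps.columns:
            snps = snps.assign(het=heterozygosity(snps["allele_freq"].to_numpy()))
        self.snps = snps
        self.z = z
        self.study_ids = list(study_ids)
        self.meta: dict = {}

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_studies(self) -> int:
        return self.z.shape[1]

    @property
    def het(self) -> np.ndarray:
        return self.snps["het"].to_numpy()

    def study_index(self, study_id: str) -> int:
        return self.study_ids.index(study_id)

    def subset(self, mask_or_idx) -> "SummaryStatsTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        sub = SummaryStatsTable(
            self.snps.iloc[idx].reset_index(drop=True), self.z[idx], self.study_ids
        )
        sub.meta = dict(self.meta)
        return sub


class LdTable:
    """Pairwise LD (snp_a, snp_b, r_sq) with symmetric access.

    Duplicate pairs are deduplicated keeping the maximum r²; self-pairs are
    dropped.
    """

    def __init__(self, pairs: pd.DataFrame | None = None):
        if pairs is None or len(pairs) == 0:
            pairs = pd.DataFrame({"snp_a": [], "snp_b": [], "r_sq": []})
        pairs = pairs[["snp_a", "snp_b", "r_sq"]].copy()
        r = pairs["r_sq"].to_numpy(dtype=float)
        if np.any((r < 0) | (r > 1)):
            raise ValueError("r_sq must lie in [0, 1]")
        pairs = pairs[pairs["snp_a"] != pairs["snp_b"]]
        # canonical orientation so duplicates collapse regardless of order
        a = pairs["snp_a"].astype(str)
        b = pairs["snp_b"].astype(str)
        lo = a.where(a < b, b)
        hi = b.where(a < b, a)
        pairs = pd.DataFrame({"snp_a": lo, "snp_b": hi, "r_sq": pairs["r_sq"]})
        pairs = (
            pairs.groupby(["snp_a", "snp_b"], as_index=False)["r_sq"].max()
        )
        self.pairs = pairs.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def tld(self) -> pd.Series:
        """Total LD per SNP: sum of r² over all recorded pairs containing it."""
        stacked = pd.concat(
            [
                self.pairs[["snp_a", "r_sq"]].rename(columns={"snp_a": "snp"}),
                self.pairs[["snp_b", "r_sq"]].rename(columns={"snp_b": "snp"}),
            ]
        )
        return stacked.groupby("snp")["r_sq"].sum()

    def adjacency(self, r_sq_min: float) -> dict[str, list[str]]:
        """Neighbour lists restricted to pairs with r² >= r_sq_min."""
        strong = self.pairs[self.pairs["r_sq"].to_numpy() >= r_sq_min]
        adj: dict[str, list[str]] = {}
        for a, b in zip(strong["snp_a"], strong["snp_b"]):
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        return adj


@dataclass(frozen=True)
class SplitRealization:
    """One random discovery/replication division of the substudies."""

    fraction_index: int
    repetition_index: int
    fraction_target: float
    discovery_studies: tuple[str, ...]
    replication_studies: tuple[str, ...]
    achieved_fraction: float
    n_d: float
    n_r: float
    seed: int
    kept_snps: np.ndarray | None = None


@dataclass
class BinnedCurves:
    """Per-bin empirical conditional estimates over a z_d grid.

    Bins are half-open [lo, hi) with the last bin closed; mean fields are
    NaN where the count is zero.
    """

    z_min: float
    z_max: float
    n_bins: int
    p_threshold: float
    count: np.ndarray
    mean_zr: np.ndarray
    mean_zr_sq: np.ndarray
    repl_frac: np.ndarray
    mean_het: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        edges = np.linspace(self.z_min, self.z_max, self.n_bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def width(self) -> float:
        return (self.z_max - self.z_min) / self.n_bins


def qc_filter(table: SummaryStatsTable, maf_min: float = 0.005) -> SummaryStatsTable:
    """Keep SNPs with min(p, 1-p) > maf_min and finite z in every study."""
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    p = table.snps["allele_freq"].to_numpy(dtype=float)
    maf = np.minimum(p, 1.0 - p)
    ok = (maf > maf_min) & np.all(np.isfinite(table.z), axis=1)
    if not ok.any():
        raise EmptyTableError("QC removed every SNP")
    out = table.subset(ok)
    out.meta["qc"] = {"input": int(len(ok)), "kept": int(ok.sum()), "removed": int((~ok).sum())}
    return out


def random_prune(
    snp_ids,
    ld: LdTable,
    r_sq_max: float = 0.8,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Random-representative LD pruning.

    Greedy maximal independent set on the graph of pairs with r² >= r_sq_max,
    visiting SNPs in a random order so the retained representative of each LD
    block is random (independent of z — explicitly avoiding winner's curse).
    Returns the kept ids in input order.
    """
    rng = np.random.default_rng(rng)
    snp_ids = np.asarray(snp_ids)
    if len(ld) == 0:
        return snp_ids.copy()
    adj = ld.adjacency(r_sq_max)
    order = rng.permutation(len(snp_ids))
    in_table = set(map(str, snp_ids))
    kept: set[str] = set()
    for i in order:
        sid = str(snp_ids[i])
        neighbors = adj.get(sid, ())
        if all(nb not in kept for nb in neighbors):
            kept.add(sid)
    # pairs referencing SNPs absent from the table never block anything
    del in_table
    keep_mask = np.fromiter((str(s) in kept for s in snp_ids), dtype=bool, count=len(snp_ids))
    return snp_ids[keep_mask]


def tld_filter(snp_ids, ld: LdTable, tld_max: float) -> np.ndarray:
    """Keep SNPs whose total LD (sum of recorded pairwise r²) is < tld_max."""
    if tld_max <= 0:
        raise ValueError("tld_max must be positive")
    snp_ids = np.asarray(snp_ids)
    tld = ld.tld()
    values = tld.reindex(pd.Index(map(str, snp_ids)), fill_value=0.0).to_numpy()
    return snp_ids[values < tld_max]


def plan_splits(
    studies: list[StudyInfo],
    fractions=tuple(np.round(np.arange(1, 10) * 0.1, 1)),
    n_reps: int = 100,
    seed: int = 0,
    rel_tol: float = 0.25,
    max_tries: int = 500,
) -> list[SplitRealization]:
    """Random discovery/replication substudy splits at each target fraction.

    Randomized greedy: shuffle the studies and add them to the discovery set
    until its N_eff share first meets or exceeds the target; accept when the
    achieved share is within ``rel_tol`` (relative) of the target and both
    sides are nonempty, otherwise redraw.  Deterministic given ``seed``.
    """
    if len(studies) < 2:
        raise ValueError("need at least two substudies to split")
    n_eff = np.array([s.n_eff for s in studies])
    total = n_eff.sum()
    ids = np.array([s.study_id for s in studies])
    out: list[SplitRealization] = []
    for i, frac in enumerate(fractions, start=1):
        if not 0.0 < frac < 1.0:
            raise ValueError("fractions must lie strictly in (0, 1)")
        for j in range(n_reps):
            stream_seed = int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(stream_seed)
            best = None
            best_err = np.inf
            for _ in range(max_tries):
                order = rng.permutation(len(ids))
                cum = np.cumsum(n_eff[order])
                stop = int(np.searchsorted(cum, frac * total, side="left"))
                take = order[: stop + 1]
                if len(take) >= len(ids):  # replication side must be nonempty
                    continue
                share = n_eff[take].sum() / total
                err = abs(share - frac) / frac
                if err < best_err:
                    best, best_err = take, err
                if err <= rel_tol:
                    break
            if best is None:
                raise RuntimeError(
                    f"could not split {len(ids)} studies at fraction {frac}"
                )
            disc = np.zeros(len(ids), dtype=bool)
            disc[best] = True
            out.append(
                SplitRealization(
                    fraction_index=i,
                    repetition_index=j,
                    fraction_target=float(frac),
                    discovery_studies=tuple(ids[disc]),
                    replication_studies=tuple(ids[~disc]),
                    achieved_fraction=float(n_eff[disc].sum() / total),
                    n_d=float(n_eff[disc].sum()),
                    n_r=float(n_eff[~disc].sum()),
                    seed=stream_seed,
                )
            )
    return out


def meta_z(z_by_study: np.ndarray, n_eff_by_study) -> np.ndarray:
    """Sample-size-weighted meta-analysis of per-study z-scores.

    z = sum_i sqrt(N_i) z_i / sqrt(sum_i N_i), summing over studies with a
    finite z for the SNP.  This preserves the model's sqrt(N) scaling of the
    genetic effect, so meta-analyzed scores follow the mixture at N = sum N_i.
    """
    z = np.atleast_2d(np.asarray(z_by_study, dtype=float))
    n = np.asarray(n_eff_by_study, dtype=float)
    if np.any(n <= 0):
        raise ValueError("n_eff must be positive")
    finite = np.isfinite(z)
    w = np.sqrt(n)
    num = np.where(finite, z, 0.0) @ w
    den = np.sqrt(finite @ n)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def _bin_index(z_d: np.ndarray, z_min: float, z_max: float, n_bins: int):
    """Half-open bins [lo, hi), last bin closed; out-of-range -> -1."""
    width = (z_max - z_min) / n_bins
    idx = np.floor((z_d - z_min) / width).astype(int)
    idx[z_d == z_max] = n_bins - 1
    idx[(z_d < z_min) | (z_d > z_max)] = -1
    return idx


def bin_conditional(
    z_d,
    z_r,
    p_threshold: float = 0.05,
    n_bins: int = 200,
    z_min: float = -6.0,
    z_max: float = 6.0,
    het=None,
) -> BinnedCurves:
    """Bin discovery z-scores and summarize replication scores per bin.

    Per bin: SNP count, mean z_r, mean z_r², fraction replicating (z_r has
    the sign of the bin center and one-tailed p_r < p_threshold), and the
    mean heterozygosity of the binned SNPs.  SNPs with |z_d| beyond the
    range are excluded.
    """
    z_d = np.asarray(z_d, dtype=float)
    z_r = np.asarray(z_r, dtype=float)
    ok = np.isfinite(z_d) & np.isfinite(z_r)
    idx = _bin_index(z_d[ok], z_min, z_max, n_bins)
    z_r = z_r[ok]
    h = None if het is None else np.asarray(het, dtype=float)[ok]
    inside = idx >= 0
    idx, z_r = idx[inside], z_r[inside]
    if h is not None:
        h = h[inside]

    count = np.bincount(idx, minlength=n_bins).astype(float)
    sum_zr = np.bincount(idx, weights=z_r, minlength=n_bins)
    sum_zr2 = np.bincount(idx, weights=z_r**2, minlength=n_bins)
    # replication: sign(z_r) matches the bin side and |z_r| exceeds the
    # one-tailed threshold
    z_t = ndtri(p_threshold)
    sign = np.where(idx < n_bins // 2, -1.0, 1.0)
    success = (sign * z_r > -z_t).astype(float)
    sum_succ = np.bincount(idx, weights=success, minlength=n_bins)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_zr = np.where(count > 0, sum_zr / count, np.nan)
        mean_zr2 = np.where(count > 0, sum_zr2 / count, np.nan)
        repl = np.where(count > 0, sum_succ / count, np.nan)
        if h is not None:
            sum_h = np.bincount(idx, weights=h, minlength=n_bins)
            mean_h = np.where(count > 0, sum_h / count, np.nan)
        else:
            mean_h = np.full(n_bins, np.nan)
    return BinnedCurves(
        z_min=z_min,
        z_max=z_max,
        n_bins=n_bins,
        p_threshold=p_threshold,
        count=count,
        mean_zr=mean_zr,
        mean_zr_sq=mean_zr2,
        repl_frac=repl,
        mean_het=mean_h,
    )


def aggregate_curves(curves: list[BinnedCurves]) -> BinnedCurves:
    """Count-weighted per-bin average of curves across repetitions."""
    if not curves:
        raise ValueError("need at least one repetition")
    first = curves[0]
    for c in curves[1:]:
        if (c.n_bins, c.z_min, c.z_max) != (first.n_bins, first.z_min, first.z_max):
            raise ValueError("curves have inconsistent binning")
    w = np.stack([c.count for c in curves])
    total = w.sum(axis=0)

    def wavg(attr):
        vals = np.stack([np.nan_to_num(getattr(c, attr)) for c in curves])
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, (w * vals).sum(axis=0) / np.where(total > 0, total, 1.0), np.nan)

    return BinnedCurves(
        z_min=first.z_min,
        z_max=first.z_max,
        n_bins=first.n_bins,
        p_threshold=first.p_threshold,
        count=total,
        mean_zr=wavg("mean_zr"),
        mean_zr_sq=wavg("mean_zr_sq"),
        repl_frac=wavg("repl_frac"),
        mean_het=wavg("mean_het"),
    )


def empirical_qq(z, p_grid=None):
    """Proportion of SNPs at least as significant as each two-tailed p threshold."""
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("need a nonempty z vector")
    if p_grid is None:
        p_grid = np.logspace(0, -8, 81)
    p_grid = np.asarray(p_grid, dtype=float)
    p = 2.0 * ndtr(-np.abs(z))
    p_sorted = np.sort(p)
    prop = np.searchsorted(p_sorted, p_grid, side="right") / z.size
    return p_grid, prop


def model_qq(params, n_eff: float, het, p_grid=None, n_windows: int = 5):
    """Model QQ curve: mixture tail probability averaged over het windows.

    SNP heterozygosities are split into equal-count windows; within each the
    mixture CDF is evaluated at the window-mean H and the tail proportions
    are count-weighted.
    """
    from .model import ModelParams, SnpContext, mixture_cdf

    if p_grid is None:
        p_grid = np.logspace(0, -8, 81)
    p_grid = np.asarray(p_grid, dtype=float)
    het = np.asarray(het, dtype=float)
    qs = np.quantile(het, np.linspace(0, 1, n_windows + 1))
    qs[-1] = np.nextafter(qs[-1], np.inf)
    window = np.clip(np.searchsorted(qs, het, side="right") - 1, 0, n_windows - 1)
    z_thresh = -ndtri(p_grid / 2.0)  # two-tailed
    prop = np.zeros_like(p_grid)
    for wdx in range(n_windows):
        mask = window == wdx
        if not mask.any():
            continue
        ctx = SnpContext(n_eff=n_eff, het=float(het[mask].mean()))
        tail = 2.0 * mixture_cdf(-z_thresh, params, ctx)
        prop += mask.mean() * np.asarray(tail)
    return p_grid, prop


def realized_curves(
    table: SummaryStatsTable,
    studies: list[StudyInfo],
    ld: LdTable | None = None,
    fractions=tuple(np.round(np.arange(1, 10) * 0.1, 1)),
    n_reps: int = 100,
    p_threshold: float = 0.05,
    seed: int = 0,
    n_bins: int = 200,
    z_min: float = -6.0,
    z_max: float = 6.0,
    r_sq_max: float = 0.8,
) -> list[tuple[SplitRealization, BinnedCurves]]:
    """Full split -> prune -> meta-analyze -> bin pipeline.

    For every (fraction, repetition) realization the substudies are divided,
    SNPs are randomly re-pruned, the per-side z-scores are meta-analyzed,
    and the conditional curves are binned.
    """
    splits = plan_splits(studies, fractions, n_reps, seed=seed)
    order = {s.study_id: k for k, s in enumerate(studies)}
    n_eff = np.array([s.n_eff for s in studies])
    snp_ids = table.snps["snp"].to_numpy()
    id_to_row = pd.Series(np.arange(len(snp_ids)), index=pd.Index(map(str, snp_ids)))
    het = table.het
    out = []
    for split in splits:
        if ld is not None and len(ld):
            prune_rng = np.random.default_rng(
                np.random.SeedSequence([split.seed, 1])
            )
            kept_ids = random_prune(snp_ids, ld, r_sq_max=r_sq_max, rng=prune_rng)
            rows = id_to_row.loc[list(map(str, kept_ids))].to_numpy()
        else:
            rows = np.arange(len(snp_ids))
        d_cols = [order[s] for s in split.discovery_studies]
        r_cols = [order[s] for s in split.replication_studies]
        z_d = meta_z(table.z[np.ix_(rows, d_cols)], n_eff[d_cols])
        z_r = meta_z(table.z[np.ix_(rows, r_cols)], n_eff[r_cols])
        curves = bin_conditional(
            z_d,
            z_r,
            p_threshold=p_threshold,
            n_bins=n_bins,
            z_min=z_min,
            z_max=z_max,
            het=het[rows],
        )
        out.append((replace(split, kept_snps=rows), curves))
    return out
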