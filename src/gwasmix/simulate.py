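"""Synthetic GWAS summary statistics from the generative mixture model.

Each SNP draws an allele frequency (MAF in a configurable range), a class
indicator (sparse with probability pi1), a per-allele ubiquitous effect
a ~ N(0, sigma_a_sq) and, for sparse SNPs, an additional per-allele effect
b ~ N(0, sigma_b_sq).  The genetic effect in a substudy of effective size
N_i is delta = sqrt(N_i * H) * (a + b), shared across substudies, and each
substudy adds independent noise eps ~ N(0, sigma0_sq): z = delta + eps.

Optional LD blocks attach tag SNPs to a causal member: a tag with signed
attenuation r carries delta multiplied by r and noise correlated with the
causal member's at correlation r, and the emitted LD table lists the
implied pairwise r-squared values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .empirical import LdTable, StudyInfo, SummaryStatsTable
from .model import ModelParams, heterozygosity

__all__ = [
    "LdBlockConfig",
    "Cohort",
    "make_studies",
    "generate_cohort",
    "generate_from_fitted",
]


@dataclass(frozen=True)
class LdBlockConfig:
    """LD-block layout: n_blocks blocks of block_size SNPs each.

    The first member of each block is the causal representative (r = 1);
    the others draw |r| uniformly from r_range with random sign.  Blocks
    occupy the first n_blocks * block_size SNPs of the cohort.
    """

    n_blocks: int
    block_size: int
    r_range: tuple[float, float] = (0.3, 0.95)

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValueError("block_size must be at least 2")
        lo, hi = self.r_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("r_range must satisfy 0 < lo <= hi <= 1")


@dataclass
class Cohort:
    """A generated cohort: summary stats, ground truth, and optional LD."""

    table: SummaryStatsTable
    truth: pd.DataFrame
    studies: list[StudyInfo]
    ld: LdTable | None = None


def make_studies(
    n_studies: int,
    total_n_eff: float,
    seed: int = 0,
    unevenness: float = 0.6,
    prefix: str = "study",
) -> list[StudyInfo]:
    """Substudy layout with lognormally uneven effective sample sizes.

    Sizes are lognormal weights (sigma = ``unevenness`` on the log scale)
    normalized and rounded to sum exactly to ``total_n_eff``.
    """
    if n_studies < 1:
        raise ValueError("need at least one study")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    w = np.exp(rng.normal(0.0, unevenness, size=n_studies))
    sizes = np.floor(total_n_eff * w / w.sum()).astype(int)
    sizes = np.maximum(sizes, 1)
    sizes[-1] += int(total_n_eff) - int(sizes.sum())
    if sizes[-1] < 1:
        raise ValueError("total_n_eff too small for the requested study count")
    return [
        StudyInfo(study_id=f"{prefix}{k + 1:02d}", n_quant=float(s))
        for k, s in enumerate(sizes)
    ]


def generate_cohort(
    params: ModelParams,
    studies: list[StudyInfo],
    m_snps: int,
    maf_range: tuple[float, float] = (0.005, 0.5),
    seed: int | np.random.Generator = 0,
    ld_config: LdBlockConfig | None = None,
) -> Cohort:
    """Draw a full per-substudy summary-statistics cohort plus ground truth."""
    if m_snps < 1:
        raise ValueError("m_snps must be at least 1")
    lo, hi = maf_range
    if not 0.0 < lo < hi <= 0.5:
        raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    )
    n_eff = np.array([s.n_eff for s in studies])
    n_studies = len(studies)

    maf = rng.uniform(lo, hi, size=m_snps)
    het = heterozygosity(maf)
    cls = (rng.uniform(size=m_snps) < params.pi1).astype(int)
    a = rng.normal(0.0, np.sqrt(params.sigma_a_sq), size=m_snps)
    b = rng.normal(0.0, np.sqrt(params.sigma_b_sq), size=m_snps) * cls
    eps = rng.normal(0.0, np.sqrt(params.sigma0_sq), size=(m_snps, n_studies))

    atten = np.ones(m_snps)
    block_id = np.full(m_snps, -1)
    ld = None
    if ld_config is not None:
        n_tagged = ld_config.n_blocks * ld_config.block_size
        if n_tagged > m_snps:
            raise ValueError("LD blocks require more SNPs than the cohort has")
        pairs_a, pairs_b, pairs_r2 = [], [], []
        for blk in range(ld_config.n_blocks):
            members = np.arange(blk * ld_config.block_size, (blk + 1) * ld_config.block_size)
            causal = members[0]
            r = np.empty(len(members))
            r[0] = 1.0
            mag = rng.uniform(*ld_config.r_range, size=len(members) - 1)
            sign = rng.choice([-1.0, 1.0], size=len(members) - 1)
            r[1:] = mag * sign
            block_id[members] = blk
            atten[members] = r
            # tags inherit the causal member's genetic and error draws
            a[members] = a[causal]
            b[members] = b[causal]
            cls[members] = cls[causal]
            maf[members] = maf[causal]
            het[members] = het[causal]
            shared = eps[causal].copy()
            own = eps[members[1:]]
            eps[members[1:]] = r[1:, None] * shared[None, :] + np.sqrt(
                1.0 - r[1:, None] ** 2
            ) * own
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    pairs_a.append(members[x])
                    pairs_b.append(members[y])
                    pairs_r2.append((r[x] * r[y]) ** 2)
        snp_names_pairs = (
            np.array([f"snp{i + 1:07d}" for i in pairs_a]),
            np.array([f"snp{i + 1:07d}" for i in pairs_b]),
        )
        ld = LdTable(
            pd.DataFrame(
                {
                    "snp_a": snp_names_pairs[0],
                    "snp_b": snp_names_pairs[1],
                    "r_sq": np.array(pairs_r2),
                }
            )
        )

    delta_base = np.sqrt(het) * (a + b) * atten  # per sqrt(N) unit
    z = delta_base[:, None] * np.sqrt(n_eff)[None, :] + eps

    snp_ids = np.array([f"snp{i + 1:07d}" for i in range(m_snps)])
    snps = pd.DataFrame({"snp": snp_ids, "allele_freq": maf, "het": het})
    table = SummaryStatsTable(snps, z, [s.study_id for s in studies])
    truth = pd.DataFrame(
        {
            "snp": snp_ids,
            "sparse": cls,
            "a": a,
            "b": b,
            "allele_freq": maf,
            "het": het,
            "attenuation": atten,
            "block_id": block_id,
        }
    )
    return Cohort(table=table, truth=truth, studies=list(studies), ld=ld)


def generate_from_fitted(fit_result, template: dict, seed: int = 0) -> Cohort:
    """Regenerate a cohort from fitted parameters (bootstrap engine).

    ``template`` carries the study layout: keys ``studies``, ``m_snps`` and
    optionally ``maf_range`` and ``ld_config``.
    """
    return generate_cohort(
        fit_result.params,
        template["studies"],
        m_snps=template["m_snps"],
        maf_range=template.get("maf_range", (0.005, 0.5)),
        seed=seed,
        ld_config=template.get("ld_config"),
    )
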