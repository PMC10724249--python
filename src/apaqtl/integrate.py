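"""GWAS integration: Bayesian colocalization and SMR/HEIDI prioritization.

Colocalization follows the standard single-causal-variant Bayesian
framework: per SNP and trait a Wakefield approximate Bayes factor is
computed from (beta, se) and a prior effect scale, and posterior
probabilities over the five causal configurations are obtained by summing
prior-weighted ABFs over configurations —

    H0 no causal variant, H1/H2 causal for one trait only,
    H3 two distinct causal variants, H4 one shared causal variant.

Priors: p1 = p2 = 1e-4 (causal for one trait), p12 = 1e-5 (causal for
both).  A region colocalizes when PP4 >= 0.75 and PP4/(PP3+PP4) >= 0.9.

Summary-data Mendelian randomization (SMR) uses the lead cis 3'aQTL as the
instrument: b_xy = b_GWAS / b_aQTL estimates the effect of distal polyA
usage on the trait, tested with T_SMR = z_aQTL^2 z_GWAS^2 /
(z_aQTL^2 + z_GWAS^2) ~ chi2(1); significance at p < 3.5e-9.  The HEIDI
heterogeneity test distinguishes a single shared causal variant
(homogeneous b_xy across SNPs linked to the lead) from linkage
(heterogeneous b_xy); genes with p_HEIDI > 0.05 are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "ColocPriors",
    "ColocResult",
    "SmrResult",
    "select_regions",
    "wakefield_abf",
    "coloc_pp",
    "smr_test",
    "heidi_test",
    "ld_tag_overlap",
]

GWAS_P_THRESHOLD = 5e-8
REGION_EXCLUSION = 1_000_000
REGION_FLANK = 100_000
PP4_THRESHOLD = 0.75
PP4_RATIO_THRESHOLD = 0.9
SMR_P_THRESHOLD = 3.5e-9
HEIDI_P_THRESHOLD = 0.05
INSTRUMENT_P_MAX = 5e-8


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of causal configurations."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")


@dataclass
class ColocResult:
    pp: np.ndarray                 # PP0..PP4
    n_snps: int
    region: str = ""

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def colocalized(self) -> bool:
        pp3, pp4 = float(self.pp[3]), float(self.pp[4])
        if pp3 + pp4 <= 0:
            return False
        return pp4 >= PP4_THRESHOLD and pp4 / (pp3 + pp4) >= PP4_RATIO_THRESHOLD


@dataclass
class SmrResult:
    b_xy: float
    se_xy: float
    t_smr: float
    p_smr: float
    p_heidi: float = np.nan
    n_heidi_snps: int = 0

    @property
    def significant(self) -> bool:
        return self.p_smr < SMR_P_THRESHOLD

    @property
    def passes_heidi(self) -> bool:
        return np.isnan(self.p_heidi) or self.p_heidi > HEIDI_P_THRESHOLD


def select_regions(gwas: pd.DataFrame, p_threshold: float = GWAS_P_THRESHOLD,
                   exclusion: int = REGION_EXCLUSION,
                   flank: int = REGION_FLANK) -> list[dict]:
    """Greedy GWAS peak selection with distance exclusion.

    Index SNPs are picked in ascending p-value order among SNPs below
    ``p_threshold``; any candidate within ``exclusion`` of an already picked
    index on the same chromosome is skipped.  Each region spans the index
    position +- ``flank``.
    """
    hits = gwas[gwas["p"] < p_threshold].sort_values("p", kind="stable")
    picked: list[dict] = []
    for _, row in hits.iterrows():
        if any(r["chrom"] == row["chrom"] and abs(r["pos"] - row["pos"]) < exclusion
               for r in picked):
            continue
        picked.append({"chrom": row["chrom"], "snp": row["snp"],
                       "pos": int(row["pos"]), "p": float(row["p"]),
                       "start": max(0, int(row["pos"]) - flank),
                       "end": int(row["pos"]) + flank})
    return picked


def wakefield_abf(beta, se, prior_sd: float = 0.15) -> np.ndarray:
    """Log approximate Bayes factor for association at one SNP.

    log ABF = 0.5 log(se^2/(se^2+W^2)) + (z^2/2) W^2/(se^2+W^2), z = beta/se,
    W the prior standard deviation of the true effect (0.15 for quantitative
    traits, 0.2 on the log-odds scale for case-control).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    z2 = (beta / se) ** 2
    r = prior_sd**2 / (se**2 + prior_sd**2)
    return 0.5 * np.log1p(-r) + 0.5 * z2 * r


def _logdiffexp(a: float, b: float) -> float:
    """log(e^a - e^b) for a >= b, -inf when the difference underflows."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_pp(trait1: pd.DataFrame, trait2: pd.DataFrame,
             priors: ColocPriors = ColocPriors(),
             prior_sd1: float = 0.15, prior_sd2: float = 0.15,
             region: str = "") -> ColocResult:
    """Posterior probabilities PP0-PP4 of the five colocalization hypotheses.

    Both traits' summary statistics are intersected on the ``snp`` column;
    per-hypothesis evidence is accumulated in log space (log-sum-exp) so no
    intermediate overflows, exactly reproducing exhaustive enumeration over
    all (causal-for-1 x causal-for-2) configurations.
    """
    merged = trait1.merge(trait2, on="snp", suffixes=("_1", "_2"))
    if len(merged) < 2:
        raise ValueError("need at least 2 overlapping SNPs")
    l1 = wakefield_abf(merged["beta_1"], merged["se_1"], prior_sd1)
    l2 = wakefield_abf(merged["beta_2"], merged["se_2"], prior_sd2)

    lse1 = logsumexp(l1)
    lse2 = logsumexp(l2)
    lse12 = logsumexp(l1 + l2)

    lp = np.empty(5)
    lp[0] = 0.0
    lp[1] = np.log(priors.p1) + lse1
    lp[2] = np.log(priors.p2) + lse2
    # sum over i != j pairs = (sum_i)(sum_j) - sum_i (i=j)
    lp[3] = np.log(priors.p1) + np.log(priors.p2) + _logdiffexp(lse1 + lse2, lse12)
    lp[4] = np.log(priors.p12) + lse12
    pp = np.exp(lp - logsumexp(lp))
    return ColocResult(pp / pp.sum(), len(merged), region)


def smr_test(b_aqtl: float, se_aqtl: float, b_gwas: float, se_gwas: float,
             check_instrument: bool = True) -> SmrResult:
    """Summary-data MR of the trait on distal polyA usage at the lead 3'aQTL.

    b_xy = b_GWAS/b_aQTL; T_SMR = z_a^2 z_g^2 / (z_a^2 + z_g^2) tested
    against chi2(1).  With ``check_instrument`` the lead must reach genome-
    wide aQTL significance (p < 5e-8), guarding against weak instruments.
    """
    if se_aqtl <= 0 or se_gwas <= 0:
        raise ValueError("standard errors must be positive")
    if b_aqtl == 0:
        raise ValueError("b_aqtl = 0: ratio estimate undefined")
    z_a = b_aqtl / se_aqtl
    if check_instrument:
        p_inst = 2.0 * stats.norm.sf(abs(z_a))
        if p_inst >= INSTRUMENT_P_MAX:
            raise ValueError(f"weak instrument: aQTL p = {p_inst:.3g} >= 5e-8")
    z_g = b_gwas / se_gwas
    if z_g == 0:
        t = 0.0
    else:
        t = z_a**2 * z_g**2 / (z_a**2 + z_g**2)
    p = float(stats.chi2.sf(t, 1))
    b_xy = b_gwas / b_aqtl
    se_xy = abs(b_xy) * np.sqrt((se_gwas / b_gwas) ** 2 + (se_aqtl / b_aqtl) ** 2) \
        if b_gwas != 0 else abs(se_gwas / b_aqtl)
    return SmrResult(b_xy, float(se_xy), float(t), max(p, np.finfo(float).tiny))


def _bxy_covariance(b_a, se_a, b_g, se_g, R) -> np.ndarray:
    """Delta-method covariance of the per-SNP Wald ratios b_xy = b_g/b_a.

    The two studies are independent, so cov splits into a GWAS term and an
    aQTL term, each propagated through the LD correlation r_ij:
    cov(bxy_i, bxy_j) = r_ij se_g_i se_g_j/(b_a_i b_a_j)
                      + r_ij b_g_i b_g_j se_a_i se_a_j/(b_a_i^2 b_a_j^2).
    """
    inv_a = 1.0 / b_a
    gwas_term = np.outer(se_g * inv_a, se_g * inv_a)
    aqtl_term = np.outer(b_g * se_a * inv_a**2, b_g * se_a * inv_a**2)
    return R * (gwas_term + aqtl_term)


def heidi_test(aqtl: pd.DataFrame, gwas: pd.DataFrame, ld: np.ndarray,
               lead: int, r2_min: float = 0.05, r2_max: float = 0.9,
               max_snps: int = 20, min_snps: int = 3) -> tuple[float, int]:
    """Heterogeneity-in-dependent-instruments test at one gene/trait pair.

    ``aqtl`` and ``gwas`` are row-aligned summary stats (columns beta, se)
    over the same cis SNPs; ``ld`` the SNP correlation matrix (r, signed);
    ``lead`` the row index of the instrument.  Eligible SNPs have
    r^2 to the lead in [``r2_min``, ``r2_max``] (capped at ``max_snps`` by
    descending r^2).  The statistic sums squared standardized differences
    d_i = b_xy(i) - b_xy(lead); its null distribution (a correlated
    chi-square sum) is approximated by a Satterthwaite-scaled chi-square
    matched to the mean and variance implied by the correlation of the d_i.
    Returns (p_heidi, n_snps_used); p is NaN when too few SNPs are eligible.
    """
    b_a = aqtl["beta"].to_numpy(dtype=float)
    se_a = aqtl["se"].to_numpy(dtype=float)
    b_g = gwas["beta"].to_numpy(dtype=float)
    se_g = gwas["se"].to_numpy(dtype=float)
    m = b_a.size
    if not (ld.shape == (m, m)):
        raise ValueError("LD matrix does not match the SNP set")

    r_to_lead = ld[lead]
    r2 = r_to_lead**2
    elig = np.flatnonzero((r2 >= r2_min) & (r2 <= r2_max) & (b_a != 0))
    elig = elig[elig != lead]
    if elig.size > max_snps:
        elig = elig[np.argsort(r2[elig])[::-1][:max_snps]]
    if elig.size < min_snps:
        return np.nan, int(elig.size)

    sel = np.concatenate(([lead], elig))
    b_a, se_a, b_g, se_g = b_a[sel], se_a[sel], b_g[sel], se_g[sel]
    R = ld[np.ix_(sel, sel)]

    bxy = b_g / b_a
    V = _bxy_covariance(b_a, se_a, b_g, se_g, R)
    # d_i = bxy_i - bxy_lead for i = 1..m-1
    k = bxy.size - 1
    d = bxy[1:] - bxy[0]
    Vd = V[1:, 1:] - V[1:, [0]] - V[[0], 1:] + V[0, 0]
    var_d = np.clip(np.diag(Vd), 1e-300, None)
    z_d = d / np.sqrt(var_d)
    T = float(np.sum(z_d**2))

    # Satterthwaite: T ~ c * chi2(nu) with c*nu = k, 2c^2 nu = var(T)
    C = Vd / np.sqrt(np.outer(var_d, var_d))
    varT = 2.0 * float(np.sum(C**2))
    c = varT / (2.0 * k)
    nu = 2.0 * k**2 / varT
    p = float(stats.chi2.sf(T / c, nu))
    return p, int(k)


def ld_tag_overlap(lead_a: str, lead_b: str, ld_r2: pd.DataFrame,
                   r2_thresh: float = 0.8) -> bool | None:
    """Do two lead SNPs tag each other (same SNP or r^2 >= 0.8)?

    Returns None (undetermined) when either SNP is absent from the matrix.
    """
    if lead_a == lead_b:
        return True
    if lead_a not in ld_r2.index or lead_b not in ld_r2.columns:
        return None
    return bool(ld_r2.loc[lead_a, lead_b] >= r2_thresh)
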