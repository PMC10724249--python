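"""cis-3'aQTL mapping with a permutation-calibrated gene-level null.

Per condition, each transcript's PDUI vector is regressed on every SNP
within the cis window under a standard additive linear model with known
covariates (ancestry indicators, genotype PCs) and hidden factors (top PCs
of the PDUI matrix, a surrogate for PEER-style latent confounders).  The
gene-level null is calibrated by permuting individual labels of the
phenotype: the minimum cis p-value is recorded for each permutation and the
empirical p-value is (1 + #{perm min-p <= observed}) / (n_perm + 1).
Empirical p-values are converted to Storey q-values across genes; genes
with q < 0.05 are significant 3'aGenes, and their cis SNPs are then called
at Benjamini-Hochberg FDR 5% on nominal p-values.  The genomic inflation
factor lambda (median association chi-square over its null median) is the
calibration diagnostic; when lambda exceeds 1.05 the caller escalates the
known genotype PCs from 3 to 10 and re-maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CovariateSet",
    "GenePermutationResult",
    "compute_hidden_factors",
    "filter_snps",
    "map_cis",
    "permutation_calibrate",
    "call_snp_level",
    "genomic_inflation",
    "storey_qvalues",
    "scan_condition",
]

MAF_MIN = 0.01
MIN_ALLELE_COUNT = 10
MIN_SAMPLES = 20
CIS_WINDOW = 1_000_000
NULL_CHI2_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.45494


@dataclass
class CovariateSet:
    """Known covariates plus hidden factors, aligned with samples."""

    known: np.ndarray | None = None    # (n, k_known): group indicators, genotype PCs
    hidden: np.ndarray | None = None   # (n, k_hidden): PDUI PCs

    def design(self, n: int) -> np.ndarray:
        """Intercept + known + hidden; must be full column rank."""
        parts = [np.ones((n, 1))]
        for block in (self.known, self.hidden):
            if block is not None and block.size:
                if block.shape[0] != n:
                    raise ValueError("covariate rows do not align with samples")
                parts.append(np.atleast_2d(block.astype(float)))
        X = np.hstack(parts)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate design is rank-deficient")
        return X


@dataclass
class GenePermutationResult:
    gene: str
    min_p: float
    empirical_p: float
    lead_snp: str
    n_perm: int
    qvalue: float = np.nan


def compute_hidden_factors(values: pd.DataFrame, k: int) -> np.ndarray:
    """Top-k sample-space principal factors of the PDUI matrix.

    Missing entries are imputed to the transcript mean for the decomposition
    only; transcripts are standardized, and the top-k left singular vectors
    of the resulting samples x transcripts matrix are returned (orthonormal
    columns).  These play the role of PEER-style hidden confounders.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = values.to_numpy(dtype=float).T  # samples x transcripts
    n, m = X.shape
    if k >= min(n, m):
        raise ValueError("k must be smaller than min(samples, transcripts)")
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(X, axis=0)
    col_mean[~np.isfinite(col_mean)] = 0.0  # transcripts missing everywhere
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    U, _, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :k]


def filter_snps(dosages: np.ndarray, snps: pd.DataFrame,
                maf_min: float = MAF_MIN,
                min_allele_count: int = MIN_ALLELE_COUNT) -> tuple[np.ndarray, pd.DataFrame]:
    """Variant QC: drop SNPs with MAF < maf_min or minor-allele count < 10.

    Both thresholds are inclusive on the keep side: MAF exactly ``maf_min``
    and a minor-dosage sum of exactly ``min_allele_count`` survive.
    """
    f = dosages.mean(axis=0) / 2.0
    maf = np.minimum(f, 1 - f)
    minor_count = np.minimum(dosages.sum(axis=0),
                             2 * dosages.shape[0] - dosages.sum(axis=0))
    keep = (maf >= maf_min) & (minor_count >= min_allele_count)
    return dosages[:, keep], snps.loc[keep].reset_index(drop=True)


def _residualizer(X: np.ndarray) -> np.ndarray:
    """Projection onto the orthogonal complement of the design's column space."""
    Q, _ = np.linalg.qr(X)
    return np.eye(X.shape[0]) - Q @ Q.T


def map_cis(pdui_row: np.ndarray, dosages: np.ndarray, snps: pd.DataFrame,
            covariates: CovariateSet | None = None, gene: str = "",
            min_samples: int = MIN_SAMPLES) -> pd.DataFrame:
    """Additive linear scan of one transcript against its cis SNPs.

    OLS of PDUI on dosage plus covariates via Frisch-Waugh partialling:
    phenotype and dosages are residualized against the covariate design once
    and the per-SNP slope, its standard error and the two-sided t-test
    p-value follow from the residual cross-products.  Samples with missing
    PDUI are dropped for the whole gene.  Monomorphic-after-subsetting SNPs
    are skipped.  Returns records sorted by p.
    """
    y = np.asarray(pdui_row, dtype=float)
    ok = ~np.isnan(y)
    if ok.sum() < min_samples:
        raise ValueError(f"fewer than {min_samples} non-missing samples")
    y = y[ok]
    G = dosages[ok].astype(float)
    n = y.size
    cov = covariates or CovariateSet()
    X = cov.design(len(pdui_row))[ok]
    q = X.shape[1]
    df = n - q - 1
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")

    M = _residualizer(X)
    ry = M @ y
    RG = M @ G
    ss_g = np.einsum("ij,ij->j", RG, RG)
    valid = ss_g > 1e-12
    num = ry @ RG
    ss_y = float(ry @ ry)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = num / ss_g
        sigma2 = np.clip(ss_y - num**2 / ss_g, 0.0, None) / df
        se = np.sqrt(sigma2 / ss_g)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame({
        "gene": gene,
        "snp": snps["snp"].to_numpy(),
        "beta": beta,
        "se": se,
        "t": t,
        "p": p,
        "n_used": n,
    })[valid]
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def permutation_calibrate(pdui_row: np.ndarray, dosages: np.ndarray,
                          snps: pd.DataFrame, covariates: CovariateSet | None = None,
                          n_perm: int = 1000, seed: int = 0, gene: str = "",
                          min_samples: int = MIN_SAMPLES) -> GenePermutationResult:
    """Gene-level empirical p-value from phenotype-label permutations.

    Individual labels of the phenotype vector are shuffled jointly for all
    cis SNPs (covariates stay aligned with genotypes, preserving LD and the
    covariate structure under the null); the cis scan is rerun per
    permutation and the minimum p recorded.  The empirical p-value carries
    the +1 pseudocount so it is never zero:
    (1 + #{perm min-p <= observed min-p}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable tail")
    rng = np.random.default_rng(seed)
    y = np.asarray(pdui_row, dtype=float)
    ok = ~np.isnan(y)
    if ok.sum() < min_samples:
        raise ValueError(f"fewer than {min_samples} non-missing samples")
    y = y[ok]
    G = dosages[ok].astype(float)
    n = y.size
    cov = covariates or CovariateSet()
    X = cov.design(len(pdui_row))[ok]
    df = n - X.shape[1] - 1

    M = _residualizer(X)
    RG = M @ G
    ss_g = np.einsum("ij,ij->j", RG, RG)
    valid = ss_g > 1e-12
    RG = RG[:, valid]
    ss_g = ss_g[valid]
    snp_ids = snps["snp"].to_numpy()[valid]

    def max_t2(Y: np.ndarray) -> np.ndarray:
        # Y: (b, n) raw phenotype rows -> max squared t over SNPs per row
        RY = Y @ M
        num = RY @ RG                       # (b, m)
        ss_y = np.einsum("ij,ij->i", RY, RY)[:, None]
        denom = np.clip(ss_g[None, :] * ss_y - num**2, 1e-300, None)
        return (df * num**2 / denom).max(axis=1), num

    (obs_t2,), num_obs = max_t2(y[None, :])
    lead = snp_ids[int(np.argmax(df * num_obs[0] ** 2 /
                                 np.clip(ss_g * float((M @ y) @ (M @ y)) - num_obs[0] ** 2,
                                         1e-300, None)))]
    min_p = float(2.0 * stats.t.sf(np.sqrt(obs_t2), df))

    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = y[rng.permutation(n)]
    perm_t2, _ = max_t2(perms)
    # larger max t^2 <=> smaller min p, so count perm_t2 >= observed
    emp_p = (1.0 + int(np.sum(perm_t2 >= obs_t2 - 1e-12))) / (n_perm + 1.0)
    return GenePermutationResult(gene, min_p, emp_p, lead, n_perm)


def storey_qvalues(pvalues: np.ndarray, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with the smoother pi0 estimate.

    pi0 is estimated on a lambda grid as #{p > lambda} / (m (1 - lambda)),
    smoothed with a cubic polynomial and evaluated at the largest lambda
    (the q value R package's default behaviour), then q_i = min over j>=i of
    pi0 * m * p_(j) / j.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if m < 20:
        pi0 = 1.0
    else:
        pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
        coef = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.clip(np.polyval(coef, lambdas.max()), 1.0 / m, 1.0))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def call_snp_level(records: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg at ``fdr`` over all cis SNPs of significant genes."""
    if records.empty:
        return records.assign(p_adj=np.array([], dtype=float))
    p_adj = stats.false_discovery_control(records["p"].to_numpy(), method="bh")
    out = records.assign(p_adj=p_adj)
    return out[out["p_adj"] <= fdr].reset_index(drop=True)


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median 1-df chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / NULL_CHI2_MEDIAN)


# ---------------------------------------------------------------------------
# whole-condition scan


@dataclass
class ScanResult:
    """One condition's full cis scan."""

    nominal: pd.DataFrame                 # all gene-SNP association records
    genes: pd.DataFrame                   # per-gene permutation results + q-values
    significant_pairs: pd.DataFrame       # BH-passing SNPs of significant genes
    lambda_gc: float
    n_known_pcs: int


def scan_condition(pdui: pd.DataFrame, dosages: np.ndarray, snps: pd.DataFrame,
                   gene_positions: pd.DataFrame, covariates: CovariateSet | None = None,
                   cis_window: int = CIS_WINDOW, n_perm: int = 1000, seed: int = 0,
                   q_threshold: float = 0.05, snp_fdr: float = 0.05,
                   lambda_escalate: float = 1.05,
                   genotype_pcs: np.ndarray | None = None) -> ScanResult:
    """Map one condition end to end: QC, per-gene scan + permutations, calls.

    ``gene_positions`` needs columns gene, chrom, utr_start, utr_end; the cis
    window is +- ``cis_window`` around the 3'UTR midpoint.  When the genomic
    inflation factor of the nominal p-values exceeds ``lambda_escalate`` and
    ``genotype_pcs`` (>= 10 columns) is supplied, the known genotype PCs are
    escalated from 3 to 10 and the condition is re-mapped once.
    """
    dosages, snps = filter_snps(dosages, snps)
    pos = snps["pos"].to_numpy()
    chrom = snps["chrom"].to_numpy()
    gene_positions = gene_positions.set_index("gene") \
        if "gene" in gene_positions.columns else gene_positions

    ss = np.random.SeedSequence(seed)
    gene_seeds = ss.generate_state(len(pdui.index)) >> 1  # keep below 2^31

    nominal_parts, gene_rows = [], []
    for gi, gene in enumerate(pdui.index):
        row = gene_positions.loc[gene]
        mid = (int(row["utr_start"]) + int(row["utr_end"])) // 2
        in_cis = (chrom == row["chrom"]) & (np.abs(pos - mid) <= cis_window)
        if not in_cis.any():
            continue
        G = dosages[:, in_cis]
        meta = snps[in_cis].reset_index(drop=True)
        y = pdui.loc[gene].to_numpy(dtype=float)
        try:
            recs = map_cis(y, G, meta, covariates, gene=gene)
            perm = permutation_calibrate(y, G, meta, covariates, n_perm=n_perm,
                                         seed=int(gene_seeds[gi]), gene=gene)
        except ValueError:
            continue
        nominal_parts.append(recs)
        gene_rows.append(perm)

    nominal = (pd.concat(nominal_parts, ignore_index=True)
               if nominal_parts else pd.DataFrame(
                   columns=["gene", "snp", "beta", "se", "t", "p", "n_used"]))
    lam = genomic_inflation(nominal["p"].to_numpy()) if len(nominal) >= 100 else np.nan

    if (np.isfinite(lam) and lam > lambda_escalate and genotype_pcs is not None
            and genotype_pcs.shape[1] >= 10):
        esc = CovariateSet(known=genotype_pcs[:, :10],
                           hidden=covariates.hidden if covariates else None)
        return scan_condition(pdui, dosages, snps.reset_index(drop=True),
                              gene_positions.reset_index(), esc, cis_window,
                              n_perm, seed, q_threshold, snp_fdr,
                              lambda_escalate=np.inf)

    emp = np.array([g.empirical_p for g in gene_rows])
    qvals = storey_qvalues(emp) if emp.size else emp
    for g, qv in zip(gene_rows, qvals):
        g.qvalue = float(qv)
    genes = pd.DataFrame([{
        "gene": g.gene, "min_p": g.min_p, "empirical_p": g.empirical_p,
        "qvalue": g.qvalue, "lead_snp": g.lead_snp, "n_perm": g.n_perm,
        "significant": g.qvalue < q_threshold,
    } for g in gene_rows])

    if len(genes) and genes["significant"].any():
        sig_genes = set(genes.loc[genes["significant"], "gene"])
        sub = nominal[nominal["gene"].isin(sig_genes)].reset_index(drop=True)
        pairs = call_snp_level(sub, fdr=snp_fdr)
    else:
        pairs = nominal.iloc[0:0].assign(p_adj=np.array([], dtype=float))
    return ScanResult(nominal, genes, pairs, lam,
                      0 if covariates is None or covariates.known is None
                      else covariates.known.shape[1])
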