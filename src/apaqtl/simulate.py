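"""Synthetic cohort generator for the 3'aQTL pipeline.

Every downstream stage of the pipeline (PDUI quantification, cis-QTL
mapping, cross-condition shrinkage, colocalization, SMR) assumes a
particular statistical structure in its input.  This module generates
cohorts with exactly that structure and a known ground truth, so the whole
pipeline can be exercised and validated without controlled-access data:

* biallelic genotypes with block LD and optional two-population
  allele-frequency divergence (Balding-Nichols model around a shared
  ancestral frequency), emulating a merged African/European-ancestry panel;
* two-isoform 3'UTR read coverage whose long/short mixture (the true PDUI)
  depends additively on the genotype at a causal SNP and on the stimulation
  condition;
* a multi-condition effect structure with shared, response (stimulation
  -only) and null genes;
* GWAS summary statistics with a shared, distinct or absent causal variant,
  generated analytically from the realized LD of the genotype panel.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_truth",
    "simulate_utr_coverage",
    "simulate_gwas_sumstats",
    "hudson_fst",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a desk-scale immune cohort: a few hundred donors
    measured at baseline and under one stimulation, ~50x mean 3'UTR
    coverage, and a 0.15 PDUI shift per alternative allele at causal SNPs
    (a clearly detectable but not overwhelming molecular effect).
    """

    n_samples: int = 200
    n_snps: int = 400
    n_genes: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    fst: float = 0.0
    depth: float = 50.0
    utr_length: int = 1000
    effect_size: float = 0.15
    conditions: tuple[str, ...] = ("baseline", "stimulated")
    response_fraction: float = 0.3
    aqtl_fraction: float = 0.1
    stim_shift: float = -0.2
    stim_shift_fraction: float = 0.2
    pdui_noise_sd: float = 0.1
    causal_maf_min: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        for name in ("fst", "response_fraction", "aqtl_fraction", "stim_shift_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.utr_length < 200:
            raise ValueError("utr_length must be >= 200 nt")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_samples < 2 or self.n_snps < 1:
            raise ValueError("need n_samples >= 2 and n_snps >= 1")
        if self.fst > 0 and self.n_samples % 2 != 0:
            raise ValueError("two-population mode needs an even n_samples")
        if len(self.conditions) < 1:
            raise ValueError("at least one condition required")


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x SNPs, values in {0,1,2}) plus SNP metadata.

    ``snps`` columns: snp, chrom, pos (1-based), ref, alt, maf (empirical).
    ``population`` labels each sample (all "POP1" when fst = 0).
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: list[str]
    population: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Empirical minor allele frequency per SNP."""
        f = self.dosages.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)


@dataclass
class GroundTruth:
    """Planted truth of a simulated cohort.

    ``genes`` columns: gene, chrom, utr_start, utr_end (0-based half-open),
    strand, proximal_offset (nt from the 5' end of the 3'UTR), base_pdui,
    causal_snp (index into the genotype matrix, -1 for non-aQTL genes),
    is_aqtl, is_response, stim_shifted.
    ``effects``: genes x conditions true PDUI shift per alt allele.
    ``true_pdui``: dict condition -> (n_genes, n_samples) array.
    """

    genes: pd.DataFrame
    effects: pd.DataFrame
    true_pdui: dict[str, np.ndarray]
    config: SimConfig


# ---------------------------------------------------------------------------
# genotypes


def _haplotypes(rng: np.random.Generator, n_hap: int, freqs: np.ndarray,
                block_size: int, rho: float = 0.9) -> np.ndarray:
    """Haplotypes from a thresholded latent AR(1) Gaussian within LD blocks.

    Correlation in the latent field induces positive haplotype correlation
    between adjacent SNPs of a block; blocks are independent.
    """
    m = freqs.size
    z = np.empty((n_hap, m))
    eps = rng.standard_normal((n_hap, m))
    for start in range(0, m, block_size):
        end = min(start + block_size, m)
        z[:, start] = eps[:, start]
        for j in range(start + 1, end):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * eps[:, j]
    thresh = stats.norm.ppf(freqs)
    return (z < thresh).astype(np.int8)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate biallelic dosages with block LD and optional population structure.

    Ancestral allele frequencies are uniform on ``maf_range``.  With
    ``fst > 0`` the cohort splits into two equal populations whose
    frequencies are Beta-distributed around the ancestral value with
    Balding-Nichols parameterization a = f(1-F)/F, b = (1-f)(1-F)/F.
    """
    rng = np.random.default_rng(config.seed)
    anc = rng.uniform(*config.maf_range, size=config.n_snps)

    if config.fst > 0:
        F = config.fst
        a = anc * (1 - F) / F
        b = (1 - anc) * (1 - F) / F
        half = config.n_samples // 2
        pops, labels = [], []
        for p in range(2):
            fp = np.clip(rng.beta(a, b), 0.005, 0.995)
            hap = _haplotypes(rng, 2 * half, fp, config.ld_block_size)
            pops.append(hap[:half] + hap[half:])
            labels += [f"POP{p + 1}"] * half
        dos = np.vstack(pops).astype(np.int8)
        population = np.array(labels)
    else:
        hap = _haplotypes(rng, 2 * config.n_samples, anc, config.ld_block_size)
        dos = (hap[: config.n_samples] + hap[config.n_samples:]).astype(np.int8)
        population = np.array(["POP1"] * config.n_samples)

    pos = np.sort(rng.choice(np.arange(1, config.n_snps * 1000 + 1), size=config.n_snps,
                             replace=False))
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=config.n_snps)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    f = dos.mean(axis=0) / 2.0
    snps = pd.DataFrame({
        "snp": [f"rs{i:06d}" for i in range(config.n_snps)],
        "chrom": "chr1",
        "pos": pos.astype(np.int64),
        "ref": ref,
        "alt": alt,
        "maf": np.minimum(f, 1 - f),
    })
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    return GenotypeMatrix(dos, snps, samples, population)


def hudson_fst(dos_a: np.ndarray, dos_b: np.ndarray) -> float:
    """Hudson FST estimator (ratio of averages) from two dosage matrices."""
    p1 = dos_a.mean(axis=0) / 2.0
    p2 = dos_b.mean(axis=0) / 2.0
    n1 = dos_a.shape[0] * 2
    n2 = dos_b.shape[0] * 2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


# ---------------------------------------------------------------------------
# ground truth and coverage


def simulate_truth(genotypes: GenotypeMatrix, config: SimConfig) -> GroundTruth:
    """Plant per-gene truth: proximal site, baseline PDUI, causal SNP, effects.

    A fraction ``aqtl_fraction`` of genes carry a causal cis SNP (drawn among
    SNPs with empirical MAF >= ``causal_maf_min`` near the gene); of those, a
    fraction ``response_fraction`` have their effect only in non-baseline
    conditions (response 3'aQTLs), the rest share the effect across all
    conditions.  A fraction ``stim_shift_fraction`` of all genes additionally
    shift their baseline PDUI by ``stim_shift`` upon stimulation, emulating
    global 3'UTR shortening on immune activation.  Independent Gaussian
    donor-level variation (sd ``pdui_noise_sd``) on top of the genetic and
    condition terms emulates the biological inter-individual dispersion of
    APA usage that read-counting noise alone would understate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ng = config.n_genes
    L = config.utr_length

    # genes laid out along the chromosome so each has cis SNPs nearby
    snp_pos = genotypes.snps["pos"].to_numpy()
    span = int(snp_pos.max())
    utr_start = np.linspace(0, max(span - L, 1), ng).astype(np.int64)
    proximal = rng.integers(int(0.2 * L), int(0.8 * L), size=ng)
    base = rng.uniform(0.25, 0.75, size=ng)
    strand = rng.choice(["+", "-"], size=ng)

    n_aqtl = int(round(config.aqtl_fraction * ng))
    aqtl_idx = rng.choice(ng, size=n_aqtl, replace=False)
    is_aqtl = np.zeros(ng, bool)
    is_aqtl[aqtl_idx] = True
    n_resp = int(round(config.response_fraction * n_aqtl))
    resp_idx = rng.choice(aqtl_idx, size=n_resp, replace=False) if n_aqtl else np.array([], int)
    is_resp = np.zeros(ng, bool)
    is_resp[resp_idx] = True

    maf = genotypes.maf()
    causal = np.full(ng, -1, dtype=np.int64)
    for g in aqtl_idx:
        center = utr_start[g] + L // 2
        dist = np.abs(snp_pos - center)
        ok = maf >= config.causal_maf_min
        if not ok.any():
            ok = maf >= maf.max() * 0.9  # fall back to the most common SNPs
        cand = np.flatnonzero(ok)
        causal[g] = cand[np.argmin(dist[cand])]

    sign = rng.choice([-1.0, 1.0], size=ng)
    effects = pd.DataFrame(0.0, index=[f"G{i:04d}" for i in range(ng)],
                           columns=list(config.conditions))
    for g in range(ng):
        if not is_aqtl[g]:
            continue
        for c, cond in enumerate(config.conditions):
            baseline_cond = c == 0
            if is_resp[g] and baseline_cond:
                continue
            effects.iloc[g, c] = sign[g] * config.effect_size

    stim_shifted = rng.random(ng) < config.stim_shift_fraction
    true_pdui: dict[str, np.ndarray] = {}
    for c, cond in enumerate(config.conditions):
        p = np.tile(base[:, None], (1, config.n_samples))
        if c > 0:
            p[stim_shifted] += config.stim_shift
        for g in range(ng):
            if causal[g] >= 0:
                dose = genotypes.dosages[:, causal[g]].astype(float)
                p[g] += effects.iloc[g, c] * dose
        if config.pdui_noise_sd > 0:
            p += rng.normal(0.0, config.pdui_noise_sd, size=p.shape)
        true_pdui[cond] = np.clip(p, 0.02, 0.98)

    genes = pd.DataFrame({
        "gene": effects.index,
        "chrom": "chr1",
        "utr_start": utr_start,
        "utr_end": utr_start + L,
        "strand": strand,
        "proximal_offset": proximal,
        "base_pdui": base,
        "causal_snp": causal,
        "is_aqtl": is_aqtl,
        "is_response": is_resp,
        "stim_shifted": stim_shifted,
    })
    return GroundTruth(genes, effects, true_pdui, config)


def expected_coverage(true_pdui: float, proximal: int, length: int,
                      depth: float) -> np.ndarray:
    """Noise-free expected per-base coverage of the two-isoform mixture.

    The long isoform covers the full 3'UTR, the short isoform only the part
    upstream of the proximal site; with total expression fixed at ``depth``
    the expectation is ``depth`` upstream and ``depth * PDUI`` downstream.
    """
    cov = np.full(length, depth * true_pdui)
    cov[:proximal] = depth
    return cov


def simulate_utr_coverage(truth: GroundTruth, config: SimConfig | None = None,
                          noise: bool = True) -> dict[str, np.ndarray]:
    """Poisson per-base 3'UTR coverage for every gene, sample and condition.

    Returns a dict condition -> int32 array (n_genes, n_samples, utr_length)
    in genomic (plus-strand) orientation: tracks of minus-strand genes run
    3'->5' left to right, exactly as a bedgraph would store them.
    ``noise=False`` returns the exact expectation (useful for
    model-faithfulness checks).
    """
    config = config or truth.config
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    L = config.utr_length
    prox = truth.genes["proximal_offset"].to_numpy()
    if np.any((prox <= 0) | (prox >= L)):
        raise ValueError("proximal site must lie strictly inside the 3'UTR")
    out: dict[str, np.ndarray] = {}
    for cond, pdui in truth.true_pdui.items():
        ng, ns = pdui.shape
        lam = np.empty((ng, ns, L))
        base_idx = np.arange(L)
        minus = truth.genes["strand"].to_numpy() == "-"
        for g in range(ng):
            downstream = base_idx >= prox[g]
            lam[g] = config.depth * np.where(downstream, pdui[g][:, None], 1.0)
            if minus[g]:
                lam[g] = lam[g][:, ::-1]
        if noise:
            out[cond] = rng.poisson(lam).astype(np.int32)
        else:
            out[cond] = lam
    return out


# ---------------------------------------------------------------------------
# GWAS summary statistics


def simulate_gwas_sumstats(genotypes: GenotypeMatrix, mode: str, n_gwas: int,
                           h2_snp: float = 0.001, seed: int = 0,
                           causal_snp: int | None = None,
                           z_causal: float | None = None,
                           snp_subset: np.ndarray | None = None) -> pd.DataFrame:
    """Analytic GWAS summary statistics with a single causal variant.

    Instead of simulating a phenotype cohort, z-scores are drawn from the
    multivariate normal implied by the realized LD of the panel: under a
    single causal SNP c with noncentrality z_c, E[z_i] = r_ic * z_c and
    Cov(z) = R (the LD correlation matrix).  This is exact under the standard
    GWAS asymptotics and gives the colocalization and SMR stages inputs with
    precisely controlled truth.

    mode: "shared" (requires ``causal_snp``, typically the aQTL causal SNP),
    "distinct" (causal drawn among SNPs with r^2 < 0.05 to ``causal_snp``),
    or "null" (no causal variant; z ~ N(0, R)).
    """
    if mode not in ("shared", "distinct", "null"):
        raise ValueError(f"unknown mode {mode!r}")
    if not (0.0 <= h2_snp <= 0.1):
        raise ValueError("h2_snp must be in [0, 0.1]")
    rng = np.random.default_rng(seed)

    idx = np.arange(genotypes.n_snps) if snp_subset is None else np.asarray(snp_subset)
    X = genotypes.dosages[:, idx].astype(float)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep]
    idx = idx[keep]
    R = np.corrcoef(X, rowvar=False)
    if R.ndim == 0:
        R = R.reshape(1, 1)

    mu = np.zeros(idx.size)
    causal_local = -1
    if mode in ("shared", "distinct"):
        if z_causal is None:
            z_causal = float(np.sqrt(n_gwas * h2_snp / (1 - h2_snp)))
        if mode == "shared":
            if causal_snp is None:
                raise ValueError("mode='shared' requires causal_snp")
            hits = np.flatnonzero(idx == causal_snp)
            if hits.size == 0:
                raise ValueError("causal_snp not in snp_subset")
            causal_local = int(hits[0])
        else:
            if causal_snp is not None and causal_snp in set(idx.tolist()):
                r_to = R[np.flatnonzero(idx == causal_snp)[0]]
                cand = np.flatnonzero(r_to**2 < 0.05)
                if cand.size == 0:
                    cand = np.array([int(np.argmin(r_to**2))])
            else:
                cand = np.arange(idx.size)
            causal_local = int(rng.choice(cand))
        mu = R[causal_local] * z_causal

    # draw correlated z-scores; eigenvalue floor keeps R usable when singular
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 1e-9, None)
    z = mu + (V * np.sqrt(w)) @ rng.standard_normal(idx.size)

    f = genotypes.maf()[idx]
    se = 1.0 / np.sqrt(2.0 * f * (1 - f) * n_gwas)
    meta = genotypes.snps.iloc[idx]
    out = pd.DataFrame({
        "snp": meta["snp"].to_numpy(),
        "chrom": meta["chrom"].to_numpy(),
        "pos": meta["pos"].to_numpy(),
        "a1": meta["alt"].to_numpy(),
        "a2": meta["ref"].to_numpy(),
        "beta": z * se,
        "se": se,
        "p": 2.0 * stats.norm.sf(np.abs(z)),
        "n": n_gwas,
    })
    out.attrs["causal_snp"] = int(idx[causal_local]) if causal_local >= 0 else -1
    out.attrs["mode"] = mode
    return out
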