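"""Cross-condition APA statistics: differential usage, empirical-Bayes
multivariate shrinkage of per-condition QTL effects, pairwise sharing and
response-3'aQTL calling.

Differential APA between two conditions uses the two-sided Wilcoxon test
(signed-rank when donors are shared, rank-sum otherwise) with
Benjamini-Hochberg correction; an event is significant when additionally
|delta PDUI| > 0.1.

The shrinkage model is a multivariate adaptive-shrinkage (mash-style)
empirical Bayes mixture.  Observed effects bhat_j (one row per gene, one
column per condition) are modelled as

    bhat_j | b_j ~ N(b_j, S_j),     b_j ~ sum_{k,l} pi_{k,l} N(0, w_l^2 U_k)

with S_j the diagonal of squared standard errors, canonical covariance
patterns U_k (null, identity = condition-independent effects, one singleton
per condition = condition-specific effects, all-ones = equal effects
everywhere) plus data-driven patterns from the principal components of the
strong-signal z-score matrix, and a geometric grid of scales w_l.  Mixture
weights pi are fitted by EM on a large random-SNP panel (so the prior
reflects the genome-wide effect distribution, not just the selected strong
signals); posteriors are then computed on the strong panel.  Per gene and
condition the local false sign rate

    lfsr = min{ P(b >= 0 | data), P(b <= 0 | data) }

is the significance measure: it is the posterior probability that even the
sign of the reported effect is wrong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectPanel",
    "MashFit",
    "diff_apa",
    "fit_shrinkage",
    "pairwise_sharing",
    "call_response",
]


@dataclass
class EffectPanel:
    """Genes x conditions effect estimates and standard errors."""

    beta: pd.DataFrame
    se: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.shape != self.se.shape:
            raise ValueError("beta and se shapes differ")
        if (self.se.to_numpy() <= 0).any() or not np.isfinite(self.se.to_numpy()).all():
            raise ValueError("standard errors must be positive and finite")

    @property
    def conditions(self) -> list[str]:
        return list(self.beta.columns)


@dataclass
class MashFit:
    """Fitted shrinkage model and strong-panel posteriors."""

    weights: pd.Series                 # mixture weight per (component, scale)
    posterior_mean: pd.DataFrame       # genes x conditions
    posterior_sd: pd.DataFrame
    lfsr: pd.DataFrame
    loglik_trace: np.ndarray           # random-panel log-likelihood per EM step


# ---------------------------------------------------------------------------
# differential APA


def diff_apa(pdui_a: pd.DataFrame, pdui_b: pd.DataFrame, paired: bool = True,
             delta_threshold: float = 0.1, fdr_threshold: float = 0.05,
             min_n: int = 5) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon test of PDUI between two conditions.

    ``delta_pdui`` is mean(a) - mean(b).  BH correction is applied across all
    genes of the call (concatenate results before recomputing ``fdr`` to
    correct jointly across several condition pairs); significance requires
    |delta_pdui| > ``delta_threshold`` and fdr < ``fdr_threshold``.
    """
    genes = pdui_a.index.intersection(pdui_b.index)
    rows = []
    for gene in genes:
        a = pdui_a.loc[gene].to_numpy(dtype=float)
        b = pdui_b.loc[gene].to_numpy(dtype=float)
        if paired:
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < min_n:
                continue
            a, b = a[ok], b[ok]
            d = a - b
            if np.all(d == 0):
                p = 1.0  # all ties carry no rank information
            else:
                p = float(stats.wilcoxon(a, b, zero_method="wilcox",
                                         alternative="two-sided").pvalue)
        else:
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if min(a.size, b.size) < min_n:
                continue
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"gene": gene, "delta_pdui": float(np.mean(a) - np.mean(b)),
                     "p": p, "n_a": a.size, "n_b": b.size})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(fdr=np.array([], dtype=float), significant=np.array([], bool))
    out["fdr"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    out["significant"] = (out["fdr"] < fdr_threshold) & \
        (out["delta_pdui"].abs() > delta_threshold)
    return out


# ---------------------------------------------------------------------------
# mash-style shrinkage


def _canonical_covs(r: int) -> dict[str, np.ndarray]:
    covs = {"identity": np.eye(r), "equal_effects": np.ones((r, r))}
    for c in range(r):
        U = np.zeros((r, r))
        U[c, c] = 1.0
        covs[f"singleton_{c}"] = U
    return covs


def _datadriven_covs(z: np.ndarray, n_pcs: int = 3) -> dict[str, np.ndarray]:
    """Covariance patterns from the top PCs of the strong-signal z matrix."""
    r = z.shape[1]
    n_pcs = min(n_pcs, r, max(z.shape[0] - 1, 1))
    zc = z - z.mean(axis=0)
    _, s, Vt = np.linalg.svd(zc, full_matrices=False)
    covs: dict[str, np.ndarray] = {}
    for i in range(n_pcs):
        covs[f"pca_{i + 1}"] = np.outer(Vt[i], Vt[i])
    if n_pcs > 1:
        low = (Vt[:n_pcs].T * (s[:n_pcs] ** 2 / z.shape[0])) @ Vt[:n_pcs]
        covs["pca_rank3"] = low
    return covs


def _normalize_cov(U: np.ndarray) -> np.ndarray:
    d = np.max(np.diag(U))
    return U / d if d > 0 else U


def _scale_grid(se: np.ndarray, beta: np.ndarray) -> np.ndarray:
    lo = 0.1 * float(np.median(se))
    hi = 2.0 * float(np.max(np.abs(beta)))
    hi = max(hi, lo * 2)
    n = int(np.ceil(np.log(hi / lo) / np.log(np.sqrt(2.0)))) + 1
    return lo * np.sqrt(2.0) ** np.arange(n)


def _component_logliks(beta: np.ndarray, se: np.ndarray,
                       covs: list[np.ndarray]) -> np.ndarray:
    """Marginal log-likelihood of each gene under each prior component.

    For component covariance V, bhat_j ~ N(0, V + S_j); evaluated with a
    batched Cholesky over genes (S_j varies by gene).
    """
    n, r = beta.shape
    out = np.empty((n, len(covs)))
    S = np.zeros((n, r, r))
    ii = np.arange(r)
    S[:, ii, ii] = se**2
    for c, V in enumerate(covs):
        Sig = S + V[None]
        L = np.linalg.cholesky(Sig)
        sol = np.linalg.solve(L, beta[:, :, None])[:, :, 0]
        quad = np.einsum("ij,ij->i", sol, sol)
        logdet = 2.0 * np.sum(np.log(L[:, ii, ii]), axis=1)
        out[:, c] = -0.5 * (r * np.log(2 * np.pi) + logdet + quad)
    return out


def fit_shrinkage(panel: EffectPanel, random_panel: EffectPanel,
                  n_pcs: int = 3, max_iter: int = 1000, tol: float = 1e-6,
                  null_weight_init: float = 10.0,
                  components: dict[str, np.ndarray] | None = None,
                  scales: np.ndarray | None = None,
                  include_null: bool = True) -> MashFit:
    """Fit the mixture prior by EM on the random panel; posteriors on the strong panel.

    Components: the null (point mass at zero) plus every (covariance pattern
    x scale) pair, patterns = canonical set + PCs of the strong z matrix,
    scales a sqrt(2)-geometric grid spanning [0.1 median se, 2 max |bhat|].
    EM updates only the mixture weights (component parameters are fixed), so
    the random-panel log-likelihood is non-decreasing; a decrease beyond
    numerical tolerance aborts with a diagnostic.

    ``components``/``scales``/``include_null`` override the default mixture
    (e.g. a single prior covariance for closed-form checks).
    """
    conds = panel.conditions
    r = len(conds)
    if r < 2 and components is None:
        raise ValueError("need at least 2 conditions (or explicit components)")
    B = panel.beta.to_numpy(dtype=float)
    SE = panel.se.to_numpy(dtype=float)
    RB = random_panel.beta.to_numpy(dtype=float)
    RSE = random_panel.se.to_numpy(dtype=float)
    for arr in (B, SE, RB, RSE):
        if not np.isfinite(arr).all():
            raise ValueError("non-finite effect or se")

    Z = B / SE
    if components is None:
        patterns = _canonical_covs(r) | _datadriven_covs(Z, n_pcs)
    else:
        patterns = components
    if scales is None:
        scales = _scale_grid(RSE, B)
    names: list[str] = []
    covs: list[np.ndarray] = []
    if include_null:
        names.append("null")
        covs.append(np.zeros((r, r)))
    for pname, U in patterns.items():
        Un = _normalize_cov(U) if components is None else U
        for w in scales:
            names.append(f"{pname}@{w:.4g}")
            covs.append(w**2 * Un)

    K = len(covs)
    L_rand = _component_logliks(RB, RSE, covs)

    if include_null:
        log_pi = np.log(np.full(K, 1.0 / (K - 1 + null_weight_init)))
        log_pi[0] = np.log(null_weight_init / (K - 1 + null_weight_init))
    else:
        log_pi = np.log(np.full(K, 1.0 / K))
    trace = []
    for it in range(max_iter):
        A = L_rand + log_pi[None, :]
        mx = A.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(A - mx).sum(axis=1))
        ll = float(lse.sum())
        if trace and ll < trace[-1] - 1e-8 * abs(trace[-1]):
            raise RuntimeError(f"EM log-likelihood decreased at iter {it}: "
                               f"{trace[-1]} -> {ll}")
        resp = np.exp(A - lse[:, None])
        new_pi = resp.mean(axis=0)
        log_pi = np.log(np.clip(new_pi, 1e-300, None))
        if trace and abs(ll - trace[-1]) < tol * abs(trace[-1]):
            trace.append(ll)
            break
        trace.append(ll)
    pi = np.exp(log_pi)
    pi /= pi.sum()

    # posteriors on the strong panel
    n = B.shape[0]
    L_strong = _component_logliks(B, SE, covs)
    A = L_strong + np.log(np.clip(pi, 1e-300, None))[None, :]
    mx = A.max(axis=1, keepdims=True)
    resp = np.exp(A - mx)
    resp /= resp.sum(axis=1, keepdims=True)

    post_mean = np.zeros((n, r))
    post_m2 = np.zeros((n, r))
    p_neg = np.zeros((n, r))
    p_pos = np.zeros((n, r))
    p_zero = np.zeros((n, r))
    ii = np.arange(r)
    S = np.zeros((n, r, r))
    S[:, ii, ii] = SE**2
    for k, V in enumerate(covs):
        wk = resp[:, k]
        if V.max() == 0.0 and V.min() == 0.0:
            p_zero += wk[:, None]
            continue
        Sig = S + V[None]
        mu = np.einsum("ab,nbc,nc->na", V, np.linalg.inv(Sig), B)
        # posterior covariance diagonal: V - V Sig^-1 V
        Sinv = np.linalg.inv(Sig)
        var = np.diag(V)[None, :] - np.einsum("ab,nbc,ca->na", V, Sinv, V)
        var = np.clip(var, 0.0, None)
        sd = np.sqrt(var)
        post_mean += wk[:, None] * mu
        post_m2 += wk[:, None] * (var + mu**2)
        point = sd < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            cdf0 = np.where(point, (mu < 0).astype(float), stats.norm.cdf(-mu / np.where(point, 1.0, sd)))
        p_neg += wk[:, None] * np.where(point & (np.abs(mu) < 1e-12), 0.0, cdf0)
        p_pos += wk[:, None] * np.where(point, (mu > 1e-12).astype(float), 1.0 - cdf0)
        p_zero += wk[:, None] * np.where(point & (np.abs(mu) < 1e-12), 1.0, 0.0)

    post_sd = np.sqrt(np.clip(post_m2 - post_mean**2, 0.0, None))
    lfsr = np.minimum(p_neg + p_zero, p_pos + p_zero)

    idx = panel.beta.index
    return MashFit(
        weights=pd.Series(pi, index=names, name="pi"),
        posterior_mean=pd.DataFrame(post_mean, index=idx, columns=conds),
        posterior_sd=pd.DataFrame(post_sd, index=idx, columns=conds),
        lfsr=pd.DataFrame(lfsr, index=idx, columns=conds),
        loglik_trace=np.asarray(trace),
    )


def null_weight(fit: MashFit) -> float:
    """Total mixture weight on the point-null component."""
    return float(fit.weights.get("null", 0.0))


# ---------------------------------------------------------------------------
# sharing and response calls


def _shared_by_magnitude(m1: np.ndarray, m2: np.ndarray, factor: float) -> np.ndarray:
    same_sign = np.sign(m1) == np.sign(m2)
    a1, a2 = np.abs(m1), np.abs(m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.maximum(a1, a2) / np.minimum(a1, a2)
    nonzero = (a1 > 0) & (a2 > 0)
    return same_sign & nonzero & (ratio <= factor)


def pairwise_sharing(fit: MashFit, lfsr_thresh: float = 0.05,
                     magnitude_factor: float = 2.0) -> pd.DataFrame:
    """Sharing-by-magnitude matrix across condition pairs.

    For each pair, among genes significant (lfsr < threshold) in at least
    one of the two conditions, the shared fraction = same posterior sign and
    magnitudes within ``magnitude_factor`` of each other.  Symmetric with
    unit diagonal; NaN where no gene is eligible.
    """
    conds = list(fit.lfsr.columns)
    M = fit.posterior_mean.to_numpy()
    L = fit.lfsr.to_numpy()
    out = pd.DataFrame(np.eye(len(conds)), index=conds, columns=conds)
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            elig = (L[:, i] < lfsr_thresh) | (L[:, j] < lfsr_thresh)
            if not elig.any():
                out.iloc[i, j] = out.iloc[j, i] = np.nan
                continue
            shared = _shared_by_magnitude(M[elig, i], M[elig, j], magnitude_factor)
            out.iloc[i, j] = out.iloc[j, i] = float(shared.mean())
    return out


def call_response(fit: MashFit, baseline: str,
                  stimulated: list[str] | None = None,
                  lfsr_thresh: float = 0.05,
                  magnitude_factor: float = 2.0) -> pd.DataFrame:
    """Classify genes as shared vs response (induced/lost) 3'aQTLs.

    Per stimulus s: "induced" when significant in s but not at baseline,
    "lost" when significant at baseline but not in s.  A gene is "shared"
    when significant at baseline and in every stimulus with all magnitudes
    within ``magnitude_factor`` of the baseline effect.
    """
    conds = list(fit.lfsr.columns)
    if baseline not in conds:
        raise ValueError(f"baseline {baseline!r} not in panel conditions")
    stimulated = stimulated or [c for c in conds if c != baseline]
    sig = fit.lfsr < lfsr_thresh
    M = fit.posterior_mean
    rows = []
    for gene in fit.lfsr.index:
        base_sig = bool(sig.loc[gene, baseline])
        induced = [s for s in stimulated if sig.loc[gene, s] and not base_sig]
        lost = [s for s in stimulated if base_sig and not sig.loc[gene, s]]
        all_sig = base_sig and all(sig.loc[gene, s] for s in stimulated)
        shared = False
        if all_sig:
            mb = M.loc[gene, baseline]
            shared = all(_shared_by_magnitude(np.array([mb]),
                                              np.array([M.loc[gene, s]]),
                                              magnitude_factor)[0]
                         for s in stimulated)
        rows.append({
            "gene": gene,
            "is_response": bool(induced or lost),
            "induced_in": ",".join(induced),
            "lost_in": ",".join(lost),
            "shared": shared,
        })
    return pd.DataFrame(rows).set_index("gene")
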