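import numpy as np
import pytest

from apaqtl import quantify, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort shared by read-only tests: 100 donors, 30 genes."""
    cfg = simulate.SimConfig(n_samples=100, n_snps=300, n_genes=30,
                             aqtl_fraction=0.2, utr_length=600, seed=11)
    geno = simulate.simulate_genotypes(cfg)
    truth = simulate.simulate_truth(geno, cfg)
    coverage = simulate.simulate_utr_coverage(truth, cfg)
    return cfg, geno, truth, coverage


@pytest.fixture(scope="session")
def small_pdui(small_cohort):
    cfg, geno, truth, coverage = small_cohort
    pdui = quantify.quantify_cohort(coverage, list(truth.genes["gene"]),
                                    geno.samples,
                                    strands=list(truth.genes["strand"]))
    return pdui


def naive_two_site_fit(tracks: np.ndarray, margin: int = 50):
    """Independent brute-force oracle for the two-site change-point fit.

    Plain Python loop over every candidate breakpoint; per sample the
    constrained least-squares segment fit is computed from scratch with
    np.mean.  Ties resolved to the most distal breakpoint, matching the
    documented contract.
    """
    tracks = np.atleast_2d(np.asarray(tracks, float))
    n, L = tracks.shape
    step = 1 if L <= 2000 else 5
    best = None
    for p in range(margin, L - margin + 1, step):
        rss = 0.0
        for s in range(n):
            up, down = tracks[s, :p], tracks[s, p:]
            m1, m2 = up.mean(), down.mean()
            if m2 > m1:  # ordering violated -> pooled single mean
                m = tracks[s].mean()
                rss += ((tracks[s] - m) ** 2).sum()
            else:
                rss += ((up - m1) ** 2).sum() + ((down - m2) ** 2).sum()
        if best is None or rss < best[0] - 1e-9 or (abs(rss - best[0]) <= 1e-9 and p > best[1]):
            best = (rss, p)
    p = best[1]
    w_long, w_short, pdui = [], [], []
    for s in range(n):
        m1, m2 = tracks[s, :p].mean(), tracks[s, p:].mean()
        if m2 > m1:
            m = tracks[s].mean()
            m1 = m2 = m
        wl = max(m2, 0.0)
        ws = max(m1 - wl, 0.0)
        w_long.append(wl)
        w_short.append(ws)
        pdui.append(wl / (wl + ws) if wl + ws > 0 else np.nan)
    return p, np.array(w_long), np.array(w_short), np.array(pdui), best[0]
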