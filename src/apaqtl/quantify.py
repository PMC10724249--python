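"""PDUI quantification from per-base 3'UTR coverage.

The model: each 3'UTR expresses two isoforms sharing a transcription start
but cleaved at two polyA sites.  The long (distal) isoform covers the whole
annotated 3'UTR; the short (proximal) isoform covers only the part upstream
of a latent proximal site.  Expected per-base coverage is therefore a step
function: ``w_short + w_long`` upstream of the proximal site and ``w_long``
downstream of it.  The proximal site is identified jointly across all
samples of a transcript by minimizing the total residual sum of squares
over candidate breakpoints; per sample the distal usage index is

    PDUI = w_long / (w_long + w_short),

the fraction of transcripts using the distal site.  Entries with mean
normalized coverage <= 20 are treated as missing, and transcripts missing
in more than half the samples are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UtrAnnotation",
    "TwoSiteFit",
    "PduiMatrix",
    "normalize_coverage",
    "fit_two_site_model",
    "apply_filters",
    "quantify_cohort",
]

MIN_MEAN_COVERAGE = 20.0     # "average normalized reads ... > 20"
MAX_MISSING_FRACTION = 0.5   # "missing values in > 50% of individuals"
DEFAULT_MARGIN = 50          # nt kept clear of both UTR ends in the search
FINE_STEP_MAX_LENGTH = 2000  # 1-nt breakpoint grid up to this UTR length


@dataclass(frozen=True)
class UtrAnnotation:
    """A transcript's 3'UTR: 0-based half-open genomic interval plus strand.

    ``distal_site`` is the annotated distal polyA position: the interval end
    on '+' transcripts and the interval start on '-'.
    """

    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start < 2 * DEFAULT_MARGIN:
            raise ValueError("3'UTR shorter than twice the search margin")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def distal_site(self) -> int:
        return self.end if self.strand == "+" else self.start

    def offset_to_genomic(self, offset: int) -> int:
        """Map a strand-oriented offset (nt from the UTR 5' end) to genomic."""
        return self.start + offset if self.strand == "+" else self.end - offset


@dataclass
class TwoSiteFit:
    """Joint two-polyA-site fit for one transcript across samples."""

    proximal_offset: int          # strand-oriented nt from the UTR 5' end
    w_long: np.ndarray            # per-sample distal-isoform abundance (depth units)
    w_short: np.ndarray           # per-sample proximal-only abundance
    rss: float                    # total residual sum of squares at the optimum
    pdui: np.ndarray              # per-sample w_long/(w_long+w_short); NaN if both 0


@dataclass
class PduiMatrix:
    """Transcripts x samples distal-usage fractions with a missingness mask.

    ``values`` holds NaN where masked; ``mean_coverage`` is the per-entry
    mean normalized 3'UTR coverage used by the filters.
    """

    values: pd.DataFrame
    mean_coverage: pd.DataFrame
    proximal_offsets: pd.Series

    @property
    def mask(self) -> pd.DataFrame:
        """True where the entry is missing."""
        return self.values.isna()


def normalize_coverage(track: np.ndarray, library_size: float,
                       target_depth: float) -> np.ndarray:
    """Library-size scaling: track * target_depth / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return np.asarray(track, dtype=float) * (target_depth / library_size)


def _candidate_grid(length: int, margin: int) -> np.ndarray:
    step = 1 if length <= FINE_STEP_MAX_LENGTH else 5
    return np.arange(margin, length - margin + 1, step)


def fit_two_site_model(tracks: np.ndarray, margin: int = DEFAULT_MARGIN) -> TwoSiteFit:
    """Fit the two-isoform step model jointly over all samples of a transcript.

    ``tracks``: (n_samples, utr_length) normalized coverage, oriented 5'->3'
    along the transcript.  For each candidate breakpoint the per-sample
    least-squares segment means are computed in closed form (upstream mean
    m1 = w_short + w_long, downstream mean m2 = w_long, constrained to
    m1 >= m2 >= 0 — when the unconstrained solution violates the ordering
    the optimum collapses to the pooled mean with w_short = 0).  The
    breakpoint minimizing the total RSS is returned; ties go to the most
    distal candidate.
    """
    tracks = np.atleast_2d(np.asarray(tracks, dtype=float))
    n, L = tracks.shape
    if n < 1:
        raise ValueError("need at least one sample")
    if L <= 2 * margin:
        raise ValueError("UTR shorter than twice the search margin")
    if not np.any(tracks > 0):
        raise ValueError("all-zero coverage in every sample; fit rejected")

    cand = _candidate_grid(L, margin)
    cs = np.cumsum(tracks, axis=1)
    css = np.cumsum(tracks**2, axis=1)
    total = cs[:, -1]
    total_sq = css[:, -1]

    S1 = cs[:, cand - 1]                       # (n, P) upstream sums
    n1 = cand.astype(float)
    n2 = float(L) - n1
    S2 = total[:, None] - S1
    m1 = S1 / n1
    m2 = S2 / n2

    rss_split = total_sq[:, None] - S1**2 / n1 - S2**2 / n2
    rss_pooled = total_sq[:, None] - (total[:, None] ** 2) / L
    violates = m2 > m1
    rss = np.where(violates, rss_pooled, rss_split)
    total_rss = rss.sum(axis=0)

    # argmin on the reversed array -> most distal candidate among ties
    j = len(cand) - 1 - int(np.argmin(total_rss[::-1]))
    p = int(cand[j])

    m1j, m2j = m1[:, j].copy(), m2[:, j].copy()
    pooled = m2j > m1j
    pool_mean = total / L
    w_long = np.where(pooled, pool_mean, np.clip(m2j, 0.0, None))
    upstream = np.where(pooled, pool_mean, np.clip(m1j, 0.0, None))
    w_short = np.clip(upstream - w_long, 0.0, None)

    denom = w_long + w_short
    with np.errstate(invalid="ignore", divide="ignore"):
        pdui = np.where(denom > 0, w_long / denom, np.nan)
    return TwoSiteFit(p, w_long, w_short, float(total_rss[j]), pdui)


def apply_filters(pdui: PduiMatrix, min_coverage: float = MIN_MEAN_COVERAGE,
                  max_missing: float = MAX_MISSING_FRACTION) -> PduiMatrix:
    """Coverage and missingness filters.

    Entries with mean normalized coverage <= ``min_coverage`` become missing;
    transcripts whose missing fraction strictly exceeds ``max_missing`` are
    dropped (a transcript missing in exactly half the samples survives).
    """
    values = pdui.values.where(pdui.mean_coverage > min_coverage)
    missing_frac = values.isna().mean(axis=1)
    keep = missing_frac <= max_missing
    return PduiMatrix(values.loc[keep],
                      pdui.mean_coverage.loc[keep],
                      pdui.proximal_offsets.loc[keep])


def quantify_cohort(coverage: dict[str, np.ndarray], gene_ids: list[str],
                    sample_ids: list[str], strands: list[str] | None = None,
                    margin: int = DEFAULT_MARGIN,
                    filter_output: bool = True) -> PduiMatrix:
    """Joint PDUI quantification of a simulated or loaded coverage cohort.

    ``coverage``: dict condition -> (n_genes, n_samples, L) arrays, plus
    strand orientation per gene (tracks on '-' transcripts are reversed to
    transcript orientation before fitting).  The proximal site is fitted
    jointly across samples of *all* conditions; PDUI columns are
    "{condition}:{sample}".
    """
    conditions = list(coverage)
    ng = coverage[conditions[0]].shape[0]
    cols = [f"{c}:{s}" for c in conditions for s in sample_ids]
    values = np.full((ng, len(cols)), np.nan)
    meancov = np.zeros((ng, len(cols)))
    offsets = np.zeros(ng, dtype=int)

    for g in range(ng):
        tracks = np.concatenate([coverage[c][g] for c in conditions], axis=0)
        if strands is not None and strands[g] == "-":
            tracks = tracks[:, ::-1]
        if not np.any(tracks > 0):
            continue
        fit = fit_two_site_model(tracks.astype(float), margin=margin)
        values[g] = fit.pdui
        meancov[g] = tracks.mean(axis=1)
        offsets[g] = fit.proximal_offset

    out = PduiMatrix(pd.DataFrame(values, index=gene_ids, columns=cols),
                     pd.DataFrame(meancov, index=gene_ids, columns=cols),
                     pd.Series(offsets, index=gene_ids, name="proximal_offset"))
    return apply_filters(out) if filter_output else out


def split_condition(pdui: PduiMatrix, condition: str) -> pd.DataFrame:
    """Extract one condition's transcripts x samples PDUI sub-matrix."""
    prefix = f"{condition}:"
    cols = [c for c in pdui.values.columns if c.startswith(prefix)]
    if not cols:
        raise KeyError(f"no columns for condition {condition!r}")
    sub = pdui.values[cols].copy()
    sub.columns = [c[len(prefix):] for c in cols]
    return sub
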