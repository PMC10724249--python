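"""Sequence- and interval-level interpretation of 3'aQTLs.

Three analyses: (1) does a variant create or destroy a polyadenylation
signal hexamer (canonically AAUAAA) in the transcript-strand sequence;
(2) are 3'aQTLs enriched within 50 nt of proximal/distal polyA sites
relative to matched shuffled controls; (3) are 3'aQTLs enriched inside
RBP binding peaks.  Enrichment uses the two-sided Fisher exact test with
controls drawn uniformly from gene bodies on the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PAS_MOTIFS",
    "MotifAlterationCall",
    "EnrichmentResult",
    "scan_motif_alteration",
    "au_rich_fraction",
    "proximity_enrichment",
    "shuffle_controls",
    "interval_enrichment",
    "fisher_enrichment",
]

# The canonical polyA signal, its strongest variant, and the ten common
# single-substitution variants of the standard 12-hexamer catalogue.
PAS_MOTIFS = (
    "AAUAAA", "AUUAAA", "UAUAAA", "AGUAAA", "AAGAAA", "AAUAUA",
    "AAUACA", "CAUAAA", "GAUAAA", "AAUGAA", "UUUAAA", "ACUAAA",
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifAlterationCall:
    snp: str
    ref: str
    alt: str
    motif: str                    # matched motif ("" when action == "none")
    action: str                   # "created" | "destroyed" | "none"
    distance_to_polya: float      # signed nt to the nearest polyA site; NaN if none in range


@dataclass
class EnrichmentResult:
    feature: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    table: tuple[int, int, int, int]   # (query in, query out, bg in, bg out)
    corrected: bool = False            # Haldane 0.5 applied to a zero margin
    fdr: float = np.nan


def scan_motif_alteration(snp: str, ref: str, alt: str, flank: str,
                          snp_offset: int, strand: str = "+",
                          motifs: tuple[str, ...] = PAS_MOTIFS,
                          polya_sites: np.ndarray | None = None,
                          snp_pos: int | None = None,
                          window: int = 50) -> MotifAlterationCall:
    """Classify a SNP as creating/destroying a polyA signal hexamer.

    ``flank`` is the plus-strand DNA sequence around the SNP with the
    variant base at ``snp_offset``; it must extend at least motif length - 1
    on both sides.  Sequences are converted to the RNA alphabet on the
    transcript strand before matching.  Every motif-length window
    overlapping the SNP is tested under both alleles: a motif matching
    under ref only is "destroyed", under alt only "created".
    """
    k = max(len(m) for m in motifs)
    if snp_offset < k - 1 or len(flank) - snp_offset < k:
        raise ValueError("flanking sequence too short for the motif scan")
    if flank[snp_offset].upper() != ref.upper():
        raise ValueError("flank does not carry the ref allele at snp_offset")

    ref_seq, alt_seq = flank, flank[:snp_offset] + alt + flank[snp_offset + 1:]
    if strand == "-":
        ref_seq = reverse_complement(ref_seq)
        alt_seq = reverse_complement(alt_seq)
        snp_offset = len(flank) - 1 - snp_offset
    ref_rna, alt_rna = _to_rna(ref_seq), _to_rna(alt_seq)

    created, destroyed = [], []
    for motif in motifs:
        L = len(motif)
        for start in range(snp_offset - L + 1, snp_offset + 1):
            if start < 0 or start + L > len(ref_rna):
                continue
            in_ref = ref_rna[start:start + L] == motif
            in_alt = alt_rna[start:start + L] == motif
            if in_ref and not in_alt:
                destroyed.append(motif)
            elif in_alt and not in_ref:
                created.append(motif)

    if destroyed:
        action, motif = "destroyed", destroyed[0]
    elif created:
        action, motif = "created", created[0]
    else:
        action, motif = "none", ""

    dist = np.nan
    if polya_sites is not None and len(polya_sites) and snp_pos is not None:
        sites = np.asarray(polya_sites)
        deltas = snp_pos - sites
        j = int(np.argmin(np.abs(deltas)))
        if abs(deltas[j]) <= window:
            dist = float(deltas[j])
    return MotifAlterationCall(snp, ref, alt, motif, action, dist)


def au_rich_fraction(flank: str, center: int, window: int = 20) -> float:
    """A/U composition in a window centred on a position (AU-rich score)."""
    half = window // 2
    seq = _to_rna(flank[max(0, center - half):center + half])
    if not seq:
        return np.nan
    return sum(c in "AU" for c in seq) / len(seq)


def fisher_enrichment(q_in: int, q_out: int, b_in: int, b_out: int,
                      feature: str = "") -> EnrichmentResult:
    """Two-sided Fisher exact test with log-OR normal-approximation CI.

    A zero margin makes the odds ratio undefined; the Haldane 0.5 correction
    is applied to all four cells and the result flagged.
    """
    table = (q_in, q_out, b_in, b_out)
    p = float(stats.fisher_exact([[q_in, q_out], [b_in, b_out]],
                                 alternative="two-sided")[1])
    cells = np.array(table, dtype=float)
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se_log = np.sqrt((1 / cells).sum())
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se_log)
    return EnrichmentResult(feature, float(or_), float(lo), float(hi), p,
                            table, corrected)


def _near_any(pos: np.ndarray, sites: np.ndarray, distance: int) -> np.ndarray:
    """Boolean: is each position within ``distance`` of any site?"""
    if sites.size == 0:
        return np.zeros(pos.size, dtype=bool)
    sites = np.sort(sites)
    j = np.searchsorted(sites, pos)
    left = np.abs(pos - sites[np.clip(j - 1, 0, sites.size - 1)])
    right = np.abs(pos - sites[np.clip(j, 0, sites.size - 1)])
    return np.minimum(left, right) <= distance


def proximity_enrichment(query: pd.DataFrame, background: pd.DataFrame,
                         polya_sites: pd.DataFrame,
                         distance: int = 50) -> EnrichmentResult:
    """Enrichment of query SNPs within ``distance`` nt of a polyA site.

    Inputs carry (chrom, pos); ``polya_sites`` lists proximal and distal
    site positions per chromosome.  Builds the 2x2 (query vs background) x
    (near vs far) table and runs the two-sided Fisher exact test.
    """
    if query.empty or background.empty:
        raise ValueError("query and background must be non-empty")

    def near_count(df: pd.DataFrame) -> int:
        total = 0
        for chrom, grp in df.groupby("chrom"):
            sites = polya_sites.loc[polya_sites["chrom"] == chrom, "pos"].to_numpy()
            total += int(_near_any(grp["pos"].to_numpy(), sites, distance).sum())
        return total

    q_in = near_count(query)
    b_in = near_count(background)
    return fisher_enrichment(q_in, len(query) - q_in, b_in,
                             len(background) - b_in, feature="polya_proximity")


def shuffle_controls(query: pd.DataFrame, gene_bodies: pd.DataFrame,
                     seed: int = 0, k: int = 1) -> pd.DataFrame:
    """Matched shuffled controls: uniform positions in same-chromosome gene bodies.

    For each query SNP, ``k`` control positions are sampled uniformly from
    the union of gene-body intervals (0-based half-open) on the SNP's
    chromosome.  Chromosomes without gene bodies are skipped with their
    queries.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, grp in query.groupby("chrom"):
        bodies = gene_bodies[gene_bodies["chrom"] == chrom]
        if bodies.empty:
            continue
        starts = bodies["start"].to_numpy(np.int64)
        lengths = (bodies["end"] - bodies["start"]).to_numpy(np.int64)
        cum = np.concatenate([[0], np.cumsum(lengths)])
        n = len(grp) * k
        offs = rng.integers(0, cum[-1], size=n)
        iv = np.searchsorted(cum, offs, side="right") - 1
        pos = starts[iv] + (offs - cum[iv])
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    if not rows:
        raise ValueError("no chromosome of the query has gene bodies")
    return pd.concat(rows, ignore_index=True)


def _in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership of positions in a set of disjoint sorted half-open intervals."""
    if starts.size == 0:
        return np.zeros(pos.size, dtype=bool)
    j = np.searchsorted(starts, pos, side="right") - 1
    j = np.clip(j, 0, starts.size - 1)
    return (pos >= starts[j]) & (pos < ends[j])


def interval_enrichment(query: pd.DataFrame, background: pd.DataFrame,
                        peak_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-factor Fisher enrichment of query SNPs in peak intervals, with BH.

    ``peak_sets`` maps a factor name (e.g. an RBP) to a BED-like frame
    (chrom, start, end, half-open).  Empty peak sets are skipped.  Returns a
    tidy frame with odds ratio, CI, p and BH-adjusted fdr per factor.
    """
    results = []
    for factor, peaks in peak_sets.items():
        if peaks.empty:
            continue

        def overlap_count(df: pd.DataFrame) -> int:
            total = 0
            for chrom, grp in df.groupby("chrom"):
                sub = peaks[peaks["chrom"] == chrom].sort_values("start")
                total += int(_in_intervals(grp["pos"].to_numpy(),
                                           sub["start"].to_numpy(),
                                           sub["end"].to_numpy()).sum())
            return total

        q_in = overlap_count(query)
        b_in = overlap_count(background)
        results.append(fisher_enrichment(q_in, len(query) - q_in, b_in,
                                         len(background) - b_in, feature=factor))
    if not results:
        return pd.DataFrame(columns=["feature", "odds_ratio", "ci_low", "ci_high",
                                     "p", "fdr", "corrected"])
    out = pd.DataFrame([{
        "feature": r.feature, "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
        "ci_high": r.ci_high, "p": r.p, "corrected": r.corrected,
    } for r in results])
    out["fdr"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out
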