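import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apaqtl.annotate import (PAS_MOTIFS, fisher_enrichment, interval_enrichment,
                             proximity_enrichment, reverse_complement,
                             scan_motif_alteration, shuffle_controls,
                             au_rich_fraction)


def bruteforce_motif_scan(ref_seq, alt_seq, motifs=PAS_MOTIFS):
    """Regex oracle over the two alleles' full RNA sequences."""
    ref_rna = ref_seq.upper().replace("T", "U")
    alt_rna = alt_seq.upper().replace("T", "U")
    destroyed = {m for m in motifs if re.search(m, ref_rna) and not re.search(m, alt_rna)}
    created = {m for m in motifs if re.search(m, alt_rna) and not re.search(m, ref_rna)}
    return created, destroyed


class TestMotifScan:
    def test_substitution_destroying_canonical_signal(self):
        flank = "GGGGG" + "AATAAA" + "GGGGG"  # SNP at the A in position 9
        call = scan_motif_alteration("rs1", "A", "C", flank, snp_offset=9)
        assert call.action == "destroyed"
        assert call.motif == "AAUAAA"

    def test_substitution_creating_canonical_signal(self):
        # scanned against the canonical signals only: AAUGAA -> AAUAAA
        flank = "GGGGG" + "AATGAA" + "GGGGG"
        call = scan_motif_alteration("rs1", "G", "A", flank, snp_offset=8,
                                     motifs=("AAUAAA", "AUUAAA"))
        assert call.action == "created"
        assert call.motif == "AAUAAA"

    def test_variant_hexamer_destruction_ranks_before_creation(self):
        # against the full catalogue the same SNP destroys AAUGAA
        flank = "GGGGG" + "AATGAA" + "GGGGG"
        call = scan_motif_alteration("rs1", "G", "A", flank, snp_offset=8)
        assert call.action == "destroyed"
        assert call.motif == "AAUGAA"

    def test_snp_outside_any_motif_window(self):
        flank = "GGGGGG" + "C" + "GGGGGG"
        call = scan_motif_alteration("rs1", "C", "T", flank, snp_offset=6)
        assert call.action == "none"
        assert call.motif == ""

    def test_minus_strand_call_equals_reverse_complement(self):
        # plus-strand TTTATT -> revcomp AATAAA; destroying it on '-'
        flank = "CCCCC" + "TTTATT" + "CCCCC"
        call = scan_motif_alteration("rs1", "T", "G", flank, snp_offset=7,
                                     strand="-")
        rc = reverse_complement(flank)
        off = len(flank) - 1 - 7
        fwd = scan_motif_alteration("rs1", "A", "C", rc, snp_offset=off)
        assert call.action == fwd.action == "destroyed"
        assert call.motif == fwd.motif == "AAUAAA"

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_regex_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        flank = "".join(rng.choice(bases, 21))
        # bias towards polyA-like context half the time
        if seed % 2:
            flank = flank[:7] + "AATAA" + flank[12:]
        ref = flank[10]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        call = scan_motif_alteration("rs", ref, alt, flank, snp_offset=10)
        alt_seq = flank[:10] + alt + flank[11:]
        created, destroyed = bruteforce_motif_scan(flank, alt_seq)
        if call.action == "destroyed":
            assert call.motif in destroyed
        elif call.action == "created":
            assert call.motif in created
        else:
            # windows overlap the SNP only; oracle may match elsewhere,
            # but a motif through the SNP must not change state
            span = flank[5:16]
            alt_span = alt_seq[5:16]
            c2, d2 = bruteforce_motif_scan(span, alt_span)
            assert not c2 and not d2

    def test_distance_to_nearest_polya_site(self):
        flank = "GGGGG" + "AATAAA" + "GGGGG"
        call = scan_motif_alteration("rs1", "A", "C", flank, snp_offset=9,
                                     polya_sites=np.array([1000, 2000]),
                                     snp_pos=1030, window=50)
        assert call.distance_to_polya == 30.0

    def test_short_flank_rejected(self):
        with pytest.raises(ValueError):
            scan_motif_alteration("rs1", "A", "C", "AATAA", snp_offset=2)

    def test_au_rich_score(self):
        assert au_rich_fraction("A" * 20 + "G" * 20, 10) == 1.0
        assert au_rich_fraction("G" * 40, 20) == 0.0


class TestFisherEnrichment:
    def test_hand_computed_odds_ratio(self):
        res = fisher_enrichment(90, 10, 50, 50)
        assert res.odds_ratio == pytest.approx(9.0)
        assert res.ci_low < 9.0 < res.ci_high
        assert res.p < 1e-6
        assert not res.corrected

    def test_identical_sets_give_unit_odds_ratio(self):
        res = fisher_enrichment(30, 70, 30, 70)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_margin_haldane_corrected_and_flagged(self):
        res = fisher_enrichment(50, 0, 0, 50)
        assert res.corrected
        assert np.isfinite(res.odds_ratio)


class TestProximity:
    def test_query_near_sites_enriched(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": np.arange(0, 100000, 10000)})
        q = pd.DataFrame({"chrom": "chr1", "pos": np.arange(0, 100000, 10000) + 20})
        bg = pd.DataFrame({"chrom": "chr1", "pos": np.arange(0, 100000, 10000) + 5000})
        res = proximity_enrichment(q, bg, sites, distance=50)
        assert res.odds_ratio > 1
        assert res.corrected  # background has zero near-hits

    def test_empty_input_rejected(self):
        sites = pd.DataFrame({"chrom": [], "pos": []})
        with pytest.raises(ValueError):
            proximity_enrichment(pd.DataFrame({"chrom": [], "pos": []}),
                                 pd.DataFrame({"chrom": ["chr1"], "pos": [1]}),
                                 sites)


class TestShuffleControls:
    def _bodies(self):
        return pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"],
                             "start": [100, 5000, 0],
                             "end": [1100, 6000, 500]})

    def test_controls_fall_inside_gene_bodies_on_same_chromosome(self):
        q = pd.DataFrame({"chrom": ["chr1"] * 50 + ["chr2"] * 20,
                          "pos": np.arange(70)})
        ctrl = shuffle_controls(q, self._bodies(), seed=1)
        assert len(ctrl) == 70
        for chrom, grp in ctrl.groupby("chrom"):
            bodies = self._bodies()[self._bodies()["chrom"] == chrom]
            inside = np.zeros(len(grp), bool)
            for _, b in bodies.iterrows():
                inside |= (grp["pos"].to_numpy() >= b["start"]) & \
                    (grp["pos"].to_numpy() < b["end"])
            assert inside.all()
        assert (ctrl["chrom"].value_counts()["chr1"] == 50)

    def test_different_seeds_different_controls_same_size(self):
        q = pd.DataFrame({"chrom": ["chr1"] * 30, "pos": np.arange(30)})
        a = shuffle_controls(q, self._bodies(), seed=1)
        b = shuffle_controls(q, self._bodies(), seed=2)
        assert len(a) == len(b) == 30
        assert not a["pos"].equals(b["pos"])


class TestIntervalEnrichment:
    def test_peaks_covering_only_query_maximally_enriched(self):
        q = pd.DataFrame({"chrom": "chr1", "pos": np.arange(100, 200)})
        bg = pd.DataFrame({"chrom": "chr1", "pos": np.arange(10000, 10100)})
        peaks = {"RBP1": pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                       "end": [500]})}
        res = interval_enrichment(q, bg, peaks)
        assert res["odds_ratio"].iloc[0] > 100
        assert res["p"].iloc[0] < 1e-10

    def test_nondiscriminating_peaks_give_unit_odds_ratio(self):
        rng = np.random.default_rng(3)
        ors = []
        for s in range(20):
            pos_q = rng.integers(0, 100000, 200)
            pos_b = rng.integers(0, 100000, 200)
            peaks = {"R": pd.DataFrame({"chrom": "chr1",
                                        "start": np.arange(0, 100000, 10000),
                                        "end": np.arange(0, 100000, 10000) + 1000})}
            res = interval_enrichment(pd.DataFrame({"chrom": "chr1", "pos": pos_q}),
                                      pd.DataFrame({"chrom": "chr1", "pos": pos_b}),
                                      peaks)
            ors.append(res["odds_ratio"].iloc[0])
        assert abs(np.log(ors).mean()) < 0.3

    def test_null_enrichment_pvalues_are_calibrated(self):
        """Query and background from one distribution: p-values ~ uniform."""
        rng = np.random.default_rng(4)
        ps = []
        peaks = {"R": pd.DataFrame({"chrom": "chr1",
                                    "start": np.arange(0, 100000, 5000),
                                    "end": np.arange(0, 100000, 5000) + 500})}
        for _ in range(200):
            q = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 100000, 100)})
            b = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 100000, 100)})
            ps.append(interval_enrichment(q, b, peaks)["p"].iloc[0])
        # Fisher p-values are discrete and conservative; check no excess of
        # small p rather than exact uniformity
        assert np.mean(np.array(ps) < 0.05) <= 0.08

    def test_empty_peak_sets_skipped(self):
        q = pd.DataFrame({"chrom": "chr1", "pos": [1]})
        out = interval_enrichment(q, q, {"R": pd.DataFrame(columns=["chrom", "start", "end"])})
        assert out.empty
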