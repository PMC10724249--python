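"""Map cis-3'aQTLs in one condition with permutation calibration.

Simulates an 80-donor cohort in which 20% of genes carry a causal cis SNP
shifting PDUI by 0.15 per alternative allele, maps each transcript against
its cis window, and reports the significant 3'aGenes (Storey q < 0.05 on
1,000-permutation empirical p-values) and the genomic inflation factor.
"""

from apaqtl import qtl, quantify, simulate

cfg = simulate.SimConfig(n_samples=80, n_genes=50, n_snps=300,
                         aqtl_fraction=0.2, effect_size=0.15,
                         utr_length=600, seed=3)
geno = simulate.simulate_genotypes(cfg)
truth = simulate.simulate_truth(geno, cfg)
coverage = simulate.simulate_utr_coverage(truth, cfg)
pdui = quantify.quantify_cohort(coverage, list(truth.genes["gene"]),
                                geno.samples,
                                strands=list(truth.genes["strand"]))
stim = quantify.split_condition(pdui, "stimulated")

covariates = qtl.CovariateSet(hidden=qtl.compute_hidden_factors(stim, 10))
res = qtl.scan_condition(stim, geno.dosages, geno.snps,
                         truth.genes[["gene", "chrom", "utr_start", "utr_end"]],
                         covariates, n_perm=1000, seed=0)

sig = res.genes[res.genes["significant"]]
truth_map = truth.genes.set_index("gene")["is_aqtl"]
print(f"lambda_gc = {res.lambda_gc:.3f}  (≈1 means well-calibrated p-values)")
print(f"significant 3'aGenes at q<0.05: {len(sig)} "
      f"({truth_map.loc[sig['gene']].sum()} carry a planted effect)")
print(sig[["gene", "min_p", "empirical_p", "qvalue", "lead_snp"]]
      .to_string(index=False))
# The lead SNP per called gene is the causal SNP itself or a tight LD tag.
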