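# Demo pipeline configuration: a 1-Mb toy genome with all five barrier
# classes at the package's default study conditions.
outdir = "nucbarrier_demo"
bandwidth = 15.0
fdr = 0.05

[simulation]
n_genes = 40

[simulation.chrom_sizes]
chr1 = 1000000
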