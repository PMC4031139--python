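# nucbarrier

Nucleosome phasing around DNase I hypersensitive sites (DHSs), built on the
barrier model of chromatin organisation.

Regulatory regions bound by proteins — promoters, enhancers, insulators —
are hypersensitive to DNase I and act as *barriers* against which
neighbouring nucleosomes pack: a nucleosome core (147 bp of DNA around a
histone octamer) abuts each barrier edge and successive cores follow at a
regular repeat, so MNase-seq read density oscillates on both sides of a DHS
with period equal to the nucleosome repeat length

&nbsp;&nbsp;&nbsp;&nbsp;*spacing = core + linker = 147 bp + linker*,

and the regularity decays with distance from the barrier. `nucbarrier`
implements the full genome-wide analysis of this phenomenon as a tested,
reusable pipeline for anyone studying nucleosome organisation from
MNase-seq and DNase-seq tag data:

* **synthetic data** (`nucbarrier.simulate`) — a toy genome with genes and
  barrier elements, ground-truth phased dyad maps obeying the barrier
  model, MNase fragments and DNase cut tags, so every stage is verifiable
  without any download;
* **DHS detection** (`nucbarrier.detect`) — Gaussian kernel density of
  DNase cut 5′ ends with an empirical false-discovery threshold calibrated
  on randomised datasets;
* **classification** (`nucbarrier.classify`) — five mutually exclusive
  genomic categories per DHS (proximal promoter ≤200 bp upstream of a TSS,
  distal promoter 200–1000 bp upstream, genic, ≤200 bp downstream,
  intergenic) plus five DHS length groups;
* **phasing profiles** (`nucbarrier.profiles`) — normalised strand-specific
  5′-end profiles around DHSs or TSSs (reads per bp per million mapped),
  per-gene TSS heatmaps sorted by promoter-DHS length, and an
  autocorrelation-based estimate of the oscillation period;
* **nucleosome calling** (`nucbarrier.nucleosomes`) — paired-end fragments
  ≤200 bp trimmed to the middle 40 bp around their midpoint (the dyad
  proxy), Fourier low-pass smoothing, and phased-nucleosome peak calling;
* **linker & spacing estimation** (`nucbarrier.linkers`) — Method A:
  distances from reverse-strand to next forward-strand profile peaks
  (direct linker estimate); Method B: consecutive called-dyad spacings,
  with implied linker = spacing − 147; Kolmogorov–Smirnov class
  comparisons;
* **binding-site statistics** (`nucbarrier.sites`) — DHS overlap fractions,
  the ±50-bp phased-nucleosome flanking criterion, matched random
  backgrounds, and an exact one-sided binomial enrichment test.

## Worked example

Run the whole pipeline — simulate, detect, classify, profile, call,
linkers, sites — on a 1-Mb toy genome:

```bash
nucbarrier run-all --config examples/demo.toml --seed 7 --outdir demo
```

The JSON report printed at the end contains (excerpt from this exact
command):

```
detect:   n_dhs 43, jaccard_vs_true_barriers 0.847
classify: {proximal: 8, distal: 6, genic: 8, downstream: 6, intergenic: 15}
linkers (intergenic): strand_peak_mean 37.8   spacing_mean 180.0  (n=98)
sites:    flanked_percent 100.0, background_percent 11.9, binomial_p 1.5e-39
```

Reading: 43 DHSs were called at the FDR<0.05 threshold and overlap the
planted barrier elements with base-level Jaccard 0.85; their genomic
categories match the generator's labels; around intergenic DHSs the
reverse-to-forward peak distance (Method A) averages ~38 bp and the
dyad-to-dyad spacing (Method B) ~180 bp — the generator planted 35-bp
linkers, i.e. a 182-bp repeat — and every barrier-derived binding site is
flanked by a phased nucleosome call within ±50 bp versus 11.9% of matched
random regions (binomial p ≈ 10⁻³⁹).

Each stage is also available as its own subcommand on plain text files
(BED/bedGraph/TSV): `nucbarrier simulate | detect-dhs | classify | profile
| call-nucs | linkers | sites`.

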