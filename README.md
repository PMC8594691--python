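# epiewas

Epigenome-wide association scans for plant DNA methylation.

Bisulfite sequencing gives base-resolution methylation calls for the three
plant cytosine contexts (CpG, CHG, CHH). Given per-sample call files, a
sample sheet with one environment value and optional covariates, and
(optionally) a genotype VCF and differential-methylation intervals,
`epiewas` builds the positions × samples methylation matrix, handles
missing data, and runs three mass-univariate linear-model scans:

- **Emodel** — `M ~ E + cvrt`: methylation on the environment value,
  per position. Output: potential environmentally associated markers.
- **Gmodel** — `M ~ G + cvrt`: methylation on genotype dosage for every
  cis (position, SNP) pair within a window (default 2000 bp). Output: a
  methQTL map of marker–SNP pairs.
- **GxE** — `M ~ G + E + G:E + cvrt`: the genotype-by-environment
  interaction coefficient per cis pair.

Genotypes are encoded 1/2/3 for major homozygote / heterozygote / minor
homozygote and treated as an additive dosage. Each scan reports, per row,
the coefficient of the tested term (`beta`), its two-sided *t* statistic
(`stats`), the p-value and a Benjamini–Hochberg q-value (`FDR`) computed
globally over the whole scan. Rows with non-finite statistics (exact fits,
degenerate regressors) are discarded before FDR correction.

Two design points matter for correctness at scale:

- **Missing-data imputation is local.** After row-wise NA filtering
  (`--filter-na`, default 0: complete rows only), each remaining missing
  cell is drawn from a beta distribution moment-fitted to the observed
  values at the same position, with a random stream keyed by
  (chromosome, position, sample, seed). A cell's imputed value therefore
  never depends on which other rows are present — p-values cannot drift
  when the data are split by chromosome or scaffold, which is a failure
  mode of global-mean filling.
- **FDR is chunk-safe.** Scans can run in chunks; merging concatenates
  the per-row statistics and recomputes BH q-values globally, and the
  result is bitwise identical to an unchunked run.

Four input granularities are supported: all methylated positions (MPs),
MPs restricted to differentially methylated positions (DMPs), MPs inside
differentially methylated regions (DMRs), and per-region averages over
union DMRs (uDMRs) built from several pairwise comparisons with a minimum
supporting fraction.

## Worked example

The package ships a deterministic toy bundle (4 samples, 10 CpGs at
coverage 10, 3 SNPs, 2 DMR comparisons) whose every number can be checked
by hand:

```sh
epiewas simulate --worked-example --out example
epiewas run --samples example/samples.tsv --methylation-dir example/bedGraph \
    --snps example/snps.vcf --out example_out --nochg --nochh \
    --filter-na 0.5 --seed 7
```

`example_out/positions/Emodel/CpG_Emodel.txt` then contains (among others):

```
ID	beta	stats	pvalue	FDR
chr1:30-31	0.102761	1.8304	0.208675	0.365182
chr1:60-61	0.23	3.50747	0.0725505	0.169284
chr1:70-71	-0.102076	-18.5884	0.0028816	0.0201712
```

The row `chr1:60-61` has methylation (0.1, 0.1, 0.6, 0.7) against
environment values (1, 2, 3, 4); its slope is the textbook least-squares
value Sxy/Sxx = 1.15/5 = **0.23**. The two rows that follow the
environment exactly (`chr1:10-11`, `chr1:40-41`) produce infinite *t*
statistics and are dropped, and the constant row `chr1:20-21` drops the
same way. `chr1:70-71` is significant at q < 0.1: its values
(0.9, 0.8, ·, 0.6) track the environment almost perfectly downhill (the
missing cell was imputed). The Gmodel output gains an `snp` column; for
the SNP at position 55 the encoded dosages are (1, 1, 2, 3) — two major
homozygotes, one heterozygote, one minor homozygote.

A full synthetic cohort with planted effects (for power studies or just
to try the tool) comes from the simulator:

```sh
epiewas simulate --out sim --seed 1 --n-samples 50 --positions 100 \
    --effect contig1:210:E:1.0 --effect contig1:610:GxE:1.0
epiewas run --samples sim/samples.tsv --methylation-dir sim/bedGraph \
    --snps sim/snps.vcf --out sim_out --nochg --nochh --filter-na 0.2 --seed 1
```

`sim/truth.tsv` lists the planted effects and their carrier SNPs.

## Output layout

```
outdir/
  input/                 env.txt, cov.txt, gxe.txt, snps.txt
    bed/                 unfiltered/, filtered/, imputed/ union tables per context
  positions/             per-position input types
    Emodel/ Gmodel/ GxE/ {context}_{model}.txt, *.filtered_{q}.txt, plots
  regions/               averaged-uDMR input type, same structure
```

Plots per model: p-value Q–Q plots and histograms for every scan,
Manhattan plots for the Emodel, cytosine-vs-SNP significance dot plots
for the Gmodel, and per-genotype-class interaction plots (AA/AB/BB trend
lines of methylation against environment) for the GxE scan.
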