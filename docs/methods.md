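# Methods

## Study design emulated

The pipeline targets a single-accession plant methylome/transcriptome
design: one control sample (CT 12 h) and three methyl-jasmonate treatment
time points (MJ 12 h, 24 h, 48 h) for WGBS, and eight tissues (root, leaf,
stem, seed, petal, pistil, sepal, stamen) plus the same four treatment
samples for RNA-seq. There are no biological replicates per time point —
every statistical choice below is made for that regime.

## Simulator

### Genome and gene models

Chromosomes are i.i.d. base draws with P(C) = P(G) = gc/2 (default gc
0.36, a typical plant euchromatin value). Genes are single-exon stranded
intervals (the statistics under test bin by start/stop positions; introns
would add nothing), placed non-overlapping with ≥ 2 kb clearance to
chromosome ends, lengths uniform on `gene_length_range` (default 1–3 kb),
and slack distributed multinomially so placement is exchangeable along the
chromosome. Family labels follow `family_spec` (the packaged scenario uses
CYP716 35, bAS 24, GGPS 32, plus CYP76/72/71 at 30/28/26); unlabelled genes
are `other`.

`min_intergenic_gap_bp` (default 1) optionally enforces a minimum body-to-
body gap. The packaged scenario sets it to 2 × flank (4 kb) so that no
gene's 2-kb regulatory span overlaps another gene's: with dense placement,
methylation effects injected into one family bleed into neighbouring genes'
flank annotations and bias family-level ratios (a real phenomenon in gene-
dense genomes, but one that would confound the recovery checks). Dense
placement remains supported and multi-gene flank assignment is tested.

### Methylome noise model

Every cytosine on both strands with two valid 3' bases is simulated
independently (no CpG-pair merging, matching per-strand cytosine-report
semantics). The model, per site i and sample s:

* true level: `p_i ~ Beta(mu_c * d, (1 - mu_c) * d)` with `mu_c` the context
  mean (defaults CG 0.891, CHG 0.724, CHH 0.189) and `d = site_dispersion`
  (default 50; `inf` collapses to a point mass). The draw is shared across
  samples, then shifted additively by any injected effect
  (`delta_pp / 100`, clipped to [0, 1]) for the affected family ×
  sample × region. Sharing the base draw means between-sample differences
  contain only injected effects plus read sampling — which makes the DMC
  null exactly exchangeable (hyper/hypo symmetric), a property the
  calibration tests exploit.
* coverage: `n_is ~ NegBin(mean = coverage_mean, size = coverage_dispersion)`
  (defaults 15 and 10; WGBS coverage is overdispersed relative to Poisson).
* methylated reads: `m_is ~ Binom(n_is, p + (1 - p) * eps)` with
  `eps = non_conversion_rate` (default 0.005). Non-conversion appears only
  as false methylation of unmethylated molecules; miscalls of methylated
  molecules are not modelled (error of the opposite sign is zero). This
  matches the one-sided binomial null used by the caller.

Consequence worth stating once: the calling pipeline does not subtract
non-conversion, so level estimates converge to the apparent level
`mu + (1 - mu) * eps` — a bias of +0.05 pp at CG 89.1% and +0.41 pp at CHH
18.9% under the defaults. The calibration tests therefore compare
estimates against the apparent-level expectation (with a ratio-estimator
Monte-Carlo SE) and additionally bound the distance to the configured truth
at 0.5 pp.

### Expression model

Fragment counts are `NegBin(mean, size = expression_nb_size)` around
per-gene lognormal baselines (median 200, ln-sd 0.8). Injected effects add
log2 shifts per family × sample/tissue. A signed `coupling` converts each
injected methylation shift into an expression shift of
`coupling * delta_pp / 10` log2 units for the same genes (so coupling −0.5
turns −20 pp into +1 log2 — de-repression).

`expression_nb_size = 100` models library-level technical noise (CV ≈ 10%
on top of Poisson). With no replicates this is the only dispersion in the
design. Two consequences, both visible in the tests: (1) the exact-test
screen is slightly anti-conservative on overdispersed counts, so its
false-positive rate is interpretable against the nominal p only at
near-Poisson settings; (2) FPKM normalisation is total-count, so strongly
induced genes depress every other gene's fold change — the induced mass
must stay a small fraction of the library for null genes to be null, which
is why recovery tests use transcriptome-like gene counts. Both are
properties of the screen being modelled, not artifacts to be removed.

### What the generator does not emulate

Read-level artifacts (alignment error, PCR duplicates, M-bias, SNPs under
bisulfite), context-specific coverage bias, chromosomal methylation
gradients (TE-rich heterochromatin), replicate-level biological variance,
and isoform structure. Passing tests therefore demonstrate correctness of
the analysis logic and its calibration under the stated noise model — not
robustness to upstream artifacts a real WGBS run would add.

## Calling

* Context is re-derived from the genome (two bases 3' of the C on its own
  strand; H = A/C/T; `undefined` at chromosome ends or ambiguity codes);
  a disagreeing input context loses, with a logged count.
* Level = mC/(mC + umC), undefined at zero coverage.
* One-sided upper-tail exact binomial p against `error_rate` (default
  0.005, explicitly configurable because a study's non-conversion rate must
  be measured, not assumed).
* BH is applied per sample across **all** depth-passing cytosines jointly,
  contexts pooled — one FDR threshold, no stratification. Depth-failing
  sites never enter the pool.
* Global means are reported both coverage-weighted (Σm/Σ(m+u); the
  headline) and unweighted per-site; the two differ when level correlates
  with coverage.

## Metagene profiles

Regions are 2-kb upstream, body, 2-kb downstream, split 10/50/10, ordered
5'→3' (70 bins). A position's bin is `floor(offset_fraction * n_bins)`
clamped into the region's last bin; genes shorter than 50 bp still map
(some body bins then receive no base — fractional binning, no per-gene
length normalisation). Bin means are unweighted over per-site levels across
all (gene, site) assignments; a site in two genes' spans contributes to
both. Depth-passing sites are used regardless of the methylated/FDR flag —
the flag marks significance of being methylated, not usability of the
level estimate.

## DMCs and family statistics

The DMC rule is a pure threshold — |Δ level| ≥ 10 pp between samples, both
covered ≥ 5× — with no further test on the difference; this is faithful to
the modelled procedure and is documented as such (at 15× coverage the rule
fires freely on sampling noise, which is why all family statistics are
built to be direction-symmetric under the null). Direction: hyper iff the
treatment level is higher. Annotation assigns each DMC to the upstream /
coding / downstream span of every gene it hits; unannotated DMCs stay in
genome-wide counts only.

Family shares are percentages of (DMC, gene)-deduplicated annotations over
a configurable gene universe (default: all family-labelled genes — the
reference denominator is genuinely ambiguous, so it is a parameter, not a
constant). "Top 30%" ranks genes by CG-DMC count, ties broken
lexicographically, keeping ⌈0.3 N⌉. The hyper/hypo ratio is
log2((n_hyper + c)/(n_hypo + c)) with pseudocount c = 0.5 (configurable,
recorded in the report manifest) to keep empty cells finite.

## Expression

FPKM = counts / ((length/10³)(total/10⁶)). The tissue test is a two-sided
Fisher's exact test on [gene in tissue, others in tissue; gene elsewhere,
others elsewhere] — exact tests need counts, so it runs on fragments, not
FPKM. The MJ screen replaces an isoform-resolved differential test with the
same 2×2 construction per gene (control vs treatment), keeping the
published thresholds (p < 0.01, |FC| ≥ 1.5, FC on FPKM + 1). Raw p and BH q
are both emitted.

## Integration

"Inverse correlation" with four samples cannot be a stable correlation
coefficient, so it is operationalised as sign opposition: a gene is flagged
at a time point when its mean CG level change (upstream+coding, vs CT) and
its expression log2FC have strictly opposite signs, it carries ≥ 1 CG-DMC
at that time point, and its expression change passes the MJ screen. The
screen prerequisite is what separates signal from noise — without it,
~half of all null genes show some sign opposition and nearly all carry a
threshold-rule DMC. A Pearson r over the CT + three-MJ time course is
reported alongside for transparency, never used for flagging.
`both_regions` marks genes where the upstream and coding changes each
oppose the expression change.

## Packaged scenario and problem sizes

`mj_hypomethylation_scenario(seed)`: 4.5 Mb, 600 genes (six labelled
families), CYP716 −20 pp CG over upstream+body at all three time points,
bAS the same at 48 h only, coupling −0.5, 4-kb minimum gaps. This yields
strongly negative CG hyper/hypo ratios exactly where effects were injected
(≈ −2.9), near-zero ratios elsewhere, CYP716/bAS dominance of the top-30%
DMC gene set, and ≈ 85–90% recall of coupled genes by the inverse flag at
≈ 1–2% false positives. Calibration checks use 0.6–2 Mb genomes; the
oracle-equivalence tests run at enumeration-friendly sizes (n ≤ 50 binomial,
m ≤ 1000 BH, margins ≤ 200 Fisher, ≤ 10⁴ sites DMC). These sizes give every
stochastic assertion a comfortable Monte-Carlo margin while keeping the full
suite in the low minutes on one core.

## Numerical and degenerate-input choices

Beta draws with mean exactly 0 or 1 collapse to point masses; negative-
binomial mean 0 yields all-zero counts; zero-coverage sites keep NaN levels
and never enter testing; empty DMC sets produce valid (empty/NaN) report
tables; chromosome name matching is exact string equality everywhere — no
"chr" aliasing, since silent aliasing corrupts interval joins. Coordinates
are 0-based half-open internally; GFF3 is written/read 1-based closed, BED
0-based half-open, cytosine reports 1-based. Gzip is transparent by file
extension for tabular formats.
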