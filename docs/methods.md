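# Methods

## The measurement model

After death, cytosines at the single-stranded overhangs of ancient DNA
fragments deaminate: unmethylated C → U, methylated C (5mC) → T.  Treating a
library with uracil-DNA glycosylase (UDG) removes the uracils, so in
sequenced UDG-treated reads only the *methylated* deamination events survive,
as C→T mismatches at CpG sites near fragment termini (G→A when the molecule
derives from the reverse strand).  The per-site methylation score is

    MS = n1 / (n0 + n1)

where `n1` counts deaminated and `n0` non-deaminated informative reads.  MS
is a *relative* methylation measure: its expectation is approximately
`m · d`, the product of the true methylation probability `m` and the
terminal deamination probability `d` of the library.  Because `d` differs
between laboratories and protocols by several fold, raw mean MS values
spread over roughly 1%–6% across genomes and must be normalized before any
between-genome comparison.

### Which reads are informative

A read inspects a CpG only where the damage signal lives: when the site's C
(forward orientation) or G (reverse orientation) lies within
`damage_window` bases of an eligible read end — the 5' end for
double-stranded libraries, both ends for single-stranded chemistry.  The
window default is 2 bp, the region where terminal overhang deamination is
concentrated; it is a declared approximation of the positional rule used by
damage-based methylation callers, and it is a config knob for users who
want to match a particular tool's footprint.  A read contributes at most
once per site; if both ends are eligible the 5' end wins, which prevents
double counting on short single-stranded fragments.

Read filters follow common aDNA practice: length ≥ 35 bp, MAPQ ≥ 30,
mismatch fraction ≤ 10%, with unmapped/secondary/duplicate reads dropped.
Base qualities are not consulted.  Sites need ≥ 4 informative reads
(`standard` preset; a `strict` ≥ 10 preset is provided) before any MS is
used.

## Monte Carlo normalization

To equalize the technical spread in mean MS, reads are randomly subsampled
so that every genome attains pooled mean MS `t = 0.02` (read-weighted,
Σn1/Σ(n0+n1); 0.02 sits at the low end of the observed range so every
genome can reach it by discarding reads):

* below target: keep all deaminated reads, draw `round(((1-t)/t)·N1)`
  non-deaminated reads — the 49× rule at t = 0.02;
* above target: keep all non-deaminated reads, subsample the deaminated
  ones to `round(N0/((1-t)/t))`.

Drawing uniformly without replacement from the genome-wide read pool
allocates retained reads across sites as a multivariate hypergeometric
draw; rounding is to the nearest integer, which minimizes the residual
|achieved − t| (always ≤ one read over the retained total).  The depth
filter is applied *before* normalization; sites whose retained total drops
to zero simply vanish from that replicate, so replicate gene sets differ
slightly.  Twenty independent replicates are the default.

The chrX dataset can be normalized the same way, but the sex analysis uses
the ratio normalization instead: per-genome chrX gene MS divided by that
genome's raw autosomal pooled mean MS.  Target-normalizing chrX would by
construction equalize the chrX pooled mean across genomes and therefore
erase exactly the female–male level difference the analysis is looking
for; the ratio preserves it (female X-inactivation hypermethylation raises
the numerator only).

## Gene-level statistics

Two datasets are built from the replicates, with CpGs assigned to a gene
when they fall in its exon-bounding span (an exon-only mode exists):

1. **Full data** — every (replicate, gene, genome, CpG) with subsampled
   counts; the read-level binary response for the multistratum models.
2. **Gene-averaged matrix** — per gene × genome, the mean of CpG MS values,
   averaged over the replicates where the cell exists.  One observation per
   genome: no pseudoreplication.

The multistratum models are

    deamination ~ subsistence + tissue + sex + Error(individual)   (Model 1)
    deamination ~ subsistence + tissue + sex + Error(laboratory)   (Model 2)

implemented as the between-stratum-unit analysis: the binary response is
aggregated to unit means weighted by read counts, and the fixed factors are
tested with sequential (Type I) sums of squares in the formula order
against the between-unit residual mean square.  For Error(individual) the
factors are constant within individuals, so this is exactly the stratum in
which a classical multistratum ANOVA estimates them; the implementation
reproduces R's `aov` p-values to ten decimals on the frozen test designs.
For Error(laboratory) the between-laboratory stratum has few residual
degrees of freedom (n_labs − 1 − 3), so many genes are inestimable — the
expected behaviour of that model, reported as missing rather than raised.
Factors aliased under the sequential fit, constant responses, or
non-positive residual df also yield missing p-values.

The gene-averaged screens are one-factor-at-a-time one-way ANOVA or
Kruskal–Wallis over genes observed in ≥ 20 genomes (presets 20/25/30),
which is the honest, pseudoreplication-free counterpart.  All corrections
are Benjamini–Hochberg across genes, per factor, per model, per replicate.

Cohort structure is summarized by classical (Torgerson) MDS of pairwise
Euclidean distances over complete-case genes, with a configurable outlier
exclusion list.  Co-directionality against an external
differential-methylation table is Spearman's rank correlation between
per-gene δMS(F−HG) — mean NF cell minus mean HG cell — and the external
logFC over the gene intersection, including an all-pairs matrix layout
(r upper triangle, p lower) for laboratory sub-datasets.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
sequence biology in detail.

* **Reference**: uniform-ACGT background (a CpG every ~16 bp), evenly
  spaced two-exon genes; the first `n_islands` genes carry a CpG island at
  their start (promoter CGIs, the common vertebrate arrangement) with a CG
  planted every 8 bp.  A SNP mask removes a configurable 1% of CpGs.
* **Truth methylome**: island CpGs ~ Beta with mean 0.1 (hypomethylated),
  all other CpGs ~ Beta with mean 0.8 (the 60–80% genome-wide methylation
  typical of tissues).  A `dmg_fraction` of genes receives an additive
  shift of `effect_size` (default 0.45) on the farmer group's CpGs,
  clamped to [0,1].  By default all planted effects are negative (farmer
  hypomethylation): shifts away from the high open-sea baseline keep their
  full magnitude instead of saturating at m = 1, making the planted effect
  size actually mean what it says; an alternating-sign mode exists.
* **Reads**: fragments placed uniformly (lognormal lengths, mean 60 bp,
  floored at 35 bp; Poisson-targeted coverage; males get half coverage on
  chrX).  At each eligible terminal CpG inspection the base becomes T (A on
  reverse strands) with probability `m·d`.  Every inspection is recorded in
  a truth ledger, so a faithful scorer must reproduce the ledger recount
  *exactly* — the central oracle of the test suite.  UDG excision of
  unmethylated deaminated cytosines is modeled as "no event", which has
  the same likelihood for the scorer.  No sequencing error, indels,
  contamination or alignment error are simulated; reads are emitted
  pre-aligned at their true positions.
* **Laboratories**: six default profiles spanning damage rates 0.012–0.065
  (reproducing the c.1%–6% mean-MS spread), two library chemistries, and a
  protocol-specific *CGI coverage factor* (0.6–1.4) that biases fragment
  recovery over island regions.  This factor is what lets laboratory batch
  structure survive the normalization, as it does in real joint datasets:
  labs that under- or over-recover CpG-rich DNA push island CpGs across
  the ≥ 4-read threshold differently, so gene scores are computed over
  systematically different site compositions.  Mean-level differences in
  `d` alone are removed by the normalization — verifiably so — and do not
  produce batch clustering.
* **Cohort**: the default metadata sheet has 34 genomes — 13 HG / 21 NF,
  23 bone / 11 tooth, 12 XX / 22 XY, six laboratories, four single-stranded
  libraries — with three laboratories containing both subsistence types.
  A scaled-down two-lab preset serves the tests.
* **External table**: `shared` mode draws logFC co-directional with the
  simulated NF−HG effects plus Gaussian noise (default sd 0.5);
  `independent` mode draws logFC unrelated to the truth.

### Coverage scaling on the miniature genome

The default lab coverages (150–300×) look high next to real shotgun data,
deliberately.  What the statistics see is the *informative depth* per CpG —
reads with an eligible terminal window over the site, roughly
`coverage × window / fragment_length` — and the miniature reference trades
genome length against nominal coverage so that informative depth sits in
the same regime (≈ 5–10 reads per site passing the ≥ 4 filter) that real
median-coverage genomes reach with a wider damage-assessment footprint over
a gigabase genome.  Simulations therefore exercise the same filtering and
estimation regime at desk scale.

### Problem sizes used by the test suite

The acceptance-style suites run, per check, cohorts of 6–34 genomes on
120 kb–1.3 Mb references (up to 2000 genes for the type-I suite), with 3–10
normalization replicates; these sizes give each check comfortable
statistical resolution while keeping the whole suite in the tens of
minutes on one CPU.

## What passing tests do and do not show

The generator shares the scorer's terminal-window geometry (the geometry
helper is common code; the BAM path re-derives everything from written
sequence, which keeps the round-trip check meaningful).  Passing the suite
shows the pipeline is internally correct and recovers planted structure
under the generator's assumptions: no mapping error, no reference bias, no
contamination, damage confined to a sharp terminal window, island/non-island
methylation drawn independently per CpG.  Real data violate all of these to
some degree; in particular, real laboratory effects have many more channels
(fragmentation chemistry, size selection, sequencing platform) than the
single CGI-recovery factor modeled here, so the batch-dominance results
should be read as a demonstration that such effects *can* dominate, not as
a calibration of their real-world size.

## Numerical choices

* Rounding in the normalization: nearest integer, half away from zero.
* Sequential ANOVA aliasing tolerance: a term is inestimable when its
  orthogonalized squared norm falls below 1e-10 of its raw squared norm;
  residual sums of squares are floored at zero.
* MDS eigenvalues below 1e-12 of the leading eigenvalue are treated as
  zero; negative eigenvalues are clipped when embedding.
* Ties in context classification (a site equidistant from two islands) go
  to the downstream flank of the nearer island; both flanks share a tier,
  so the choice only affects the 5'/3' suffix.
* Kruskal–Wallis on identical values is reported as statistic 0, p 1
  rather than an error.

## Known limitations

* The read simulator emits pre-aligned reads; alignment artefacts that
  correlate with damage (a real phenomenon) are out of scope.
* The Error(laboratory) model is tested in the between-laboratory stratum
  only; with six laboratories it has two residual degrees of freedom and
  low power by design, matching the behaviour of the corresponding
  multistratum analysis.
* Co-directionality against a table with only a small fraction of signal
  genes has a hard ceiling: with 10% true effects and independent noise on
  the null genes, Spearman's r across all genes cannot exceed ≈ 0.28
  regardless of measurement precision, because 90% of rank pairs are pure
  noise.  Strong observed correlations therefore require signal (or shared
  structure) across most genes, not just the designated effect genes.
* Promoter methylation scores are derived (4 kb windows, strand-mirrored)
  but no headline statistic consumes them.
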