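# Methods

## Discovery model

The unit of analysis is a reference site with read evidence from two
pooled libraries, *fast* and *slow*. Detection in a pool applies three
thresholds to the top non-reference base (ties broken alphabetically):
supporting reads ≥ `min_variant_reads` (default 4), supporting fraction
of total depth strictly > `min_variant_fraction` (default 0.20), and
aggregated Phred base quality strictly > `min_quality` (default 20).
The wording of the thresholds ("at least 4", ">20%", ">20") fixes which
inequalities are strict, and boundary tests pin that: 4 reads pass, a
fraction of exactly 0.20 fails, a mean quality of exactly 20 fails.

The quality aggregation is the mean Phred quality of the
variant-supporting reads. Whether the upstream caller that motivated
the rule used per-base, per-read or site-level quality is not knowable,
so the aggregator is a config knob (`quality_agg ∈ {mean, min}`); site
evidence stores per-base means, which is what the pileup parser can
compute exactly.

Pooled allele frequency is the plug-in estimator count/Σcounts over
A/C/G/T reads. The imbalance score is the ratio of the variant allele's
fast-pool frequency to its slow-pool frequency, oriented fast/slow on
the non-reference allele. `f_slow = 0` with a detected variant in the
fast pool yields +inf → amplification (and symmetrically score 0 →
LOH): these are the strongest imbalances and are retained, with "inf"
serialised in the VCF AIS field. Classification boundaries are strict
and excluded (score 5.0 and 0.2 are balanced). A site where both pools
pass detection on *different* alleles is excluded and flagged
`discordant_allele`; only the top non-reference allele per pool is ever
scored. By default a putative SNP needs detection in one pool
(`require_both_pools` exposes the stricter reading).

Paralog removal has two prongs: (a) membership in the doubled-haploid
self-variant list — the reference individual is fully homozygous, so
apparent heterozygosity in its own reads marks collapsed paralogs — and
(b) a heuristic for collapse signatures: variant fraction within
[0.3, 0.7] in *both* pools combined with site depth above 3× the median
site depth. The window and multiplier are config keys; no operational
rule is published, so (b) is deliberately conservative — a fixed
difference between two collapsed, comparably expressed loci shows ~50%
variant fraction in every library regardless of phenotype, with roughly
doubled coverage. Flagged records are removed from the funnel but kept
for a side file.

## Simulator

The generator emulates the discovery design: `n_fish_per_pool = 10`
diploid fish per pool, `coverage_per_fish = 0.97` (pool depth ~
Poisson(9.7)), one pooled library per phenotype with equal-mass pooling
(each read samples a uniformly chosen fish chromosome). Site classes
are drawn at `prop_true_snp = 0.05` and `prop_paralog = 0.02`; the
remainder is monomorphic. True-SNP population frequencies are
independent Beta(0.7, 0.7) draws per pool — a U-shaped site-frequency
spectrum that yields many divergent sites, which is what a screen of
divergent selection lines feeds on; fish genotypes are Hardy–Weinberg
binomial draws at the pool frequency. Sequencing error flips a read to
a uniformly chosen other base at `error_rate = 0.005`, typical of the
short-read chemistry emulated; qualities are Normal(32, 4) clipped to
[2, 41]. Paralog sites emit the alternate base at fraction 0.5 in both
pools with 2× depth (two collapsed loci), and appear in the
doubled-haploid self-variant list with probability `dh_detect_rate =
0.6` — the reference fish cannot expose collapses in genes it does not
express.

What the simulator does *not* model: read sequences and mapping (it is
site-level; 36-bp read structure never reaches per-site counts),
expression variation between fish (an equal-share assumption; a
Dirichlet weight would be the extension), RNA editing, library
artifacts, and the full-sib structure of the real pools (genotypes are
HWE draws at the pool frequency, not two-parent Mendelian families).
Consequently a passing simulation validates the *computational* funnel
— thresholds, frequency estimation, scoring, filtering, bookkeeping —
not the empirical error processes of any real library. The simulated
panel validation rate under the default noise settings lands in the
high-70s-to-mid-80s percent range; the ~70% reported for real data
reflects false-variant processes (mapping error, unmodelled artifacts)
that no desk-scale simulation can claim to reproduce, so the tests
treat the band only as a qualitative sanity check.

A second generator, `simulate_family_panel`, produces the association
panel: 40 full-sib families × 17 offspring plus parents, 30 biallelic
nuclear markers (MAF ~ U(0.1, 0.5), parents HWE, offspring Mendelian),
and 24 mitochondrial markers forming exactly three haplotypes at
frequencies 0.49/0.26/0.25, two of which differ only at marker
positions 8 and 21 — the structure a maternally inherited,
non-recombining genome produces. Growth is exponential between the four
weighing ages (170/218/282/372 days), with the first nuclear marker and
the third haplotype carrying small additive effects on the per-day
log-growth rate, so weights stay positive and the association scan has
a known signal to recover. Two QC stressors are built in (one
monomorphic marker, one with ~50% missingness).

## Statistics

**Exact Hardy–Weinberg.** Biallelic conditional exact test: all
heterozygote counts sharing the observed allele totals are enumerated,
table probabilities computed in log space via `lgamma`, and the P-value
sums tables as or less probable than the observed one (tolerance 1e-12
on ties). The Monte Carlo mode permutes the allele vector K = 20,000
times and reports the add-one empirical P. All retained markers are
biallelic SNPs, so the multi-allelic generalisation is out of scope.
Markers failing HWE are reported, never auto-dropped — deviation in a
selected line may itself be a selection signal.

**Association.** OLS of phenotype on allele dosage (0/1/2 copies of
A2; 0/1 carriage for haplotypes), optional covariates in the observed
statistic only. The empirical P is add-one: (1 + hits)/(K + 1), hits
counting permutations with |t*| ≥ |t|. Two permutation schemes:
`pooled` (exchange over all samples) and `within_family` (exchange only
among siblings, preserving family structure under the null). Without
covariates the permutation loop compares |correlations|, which is a
monotone transform of |t| and vectorises; with covariates each
permutation refits. Degenerate designs: constant dosage raises;
constant phenotype returns b = 0, t = 0, P = 1; exact collinearity
(SSE ≤ SST·1e-12) returns R² = 1 with a `degenerate_se` flag rather
than dividing by ~0.

**BH-FDR** is the standard step-up adjustment with enforced
monotonicity, capped at 1. Note that re-adjusting already-adjusted
values changes them — the adjustment is not an idempotent map, and the
tests assert the properties that do hold (hand-checked fixtures, bounds,
monotonicity in the order statistics, all-equal inputs as fixed points).

**Haplotypes.** Mitochondrial calls are haploid (dosage 0/2; het calls
flagged at parse time and treated as missing). Complete allele strings
define the haplotype set; samples with ≤ 2 missing calls are assigned
when exactly one haplotype is consistent, otherwise left unassigned.
Frequencies are over assigned samples.

**Unrelated sets.** One genotyped offspring sampled uniformly per
family, repeated independently for each of the (default 3) sets — the
population-based complement to the family-based analysis.

## Numerical and design choices

- Coordinates are 1-based (pileup/VCF convention); strand is ignored
  (transcriptome reference).
- One seeded `numpy` Generator per run; evidence uses stream seed+1 so
  truth and reads are independent but reproducible. Everything
  downstream of a fixed seed is byte-deterministic, which the test
  suite checks end to end through the CLI.
- Validation classes: "polymorphic" means at least two distinct called
  genotypes (two alternate homozygotes without a het still count);
  validation rate = polymorphic/(polymorphic + monomorphic) over
  successful assays. Whether the published imbalance re-screening of
  validated SNPs used genotype-derived or pooled frequencies is not
  documented; both paths exist (`require_imbalance` uses
  genotype-derived scores with the same 5.0/0.2 thresholds).
- Problem sizes in the tests and the acceptance script (10,000
  simulated sites; 3,000 sites per depth for frequency recovery;
  exhaustive HWE to n = 20; 500 null datasets at K = 199 for the
  uniformity check; K = 20,000 where a permutation count is itself part
  of the procedure) are chosen to make each property measurable at
  desk scale while keeping a full run in minutes.

## Known limitations

- The mpileup dialect expects exactly two sample blocks (fast, slow);
  arbitrary multi-sample pileups are out of scope.
- Indels are consumed and ignored; the screen is SNP-only.
- The simulator's validation-rate band is a property of its own noise
  model, not a calibration against any real library.
- The within-family permutation scheme treats family labels as the
  exchangeability blocks; half-sib structure within a family is not
  modelled.
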