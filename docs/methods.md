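# Methods

This note documents the models implemented in `imputebench`, the
parameters that matter, the synthetic study design, and the numerical and
design choices that were genuinely open.

## Population simulator (`synthpop`)

A forward-in-time Wright–Fisher model with discrete generations:

1. **Founder pool.** `founder_pool_haps` (default 96) haplotypes are drawn
   site-wise from Bernoulli(fⱼ) with fⱼ ~ Beta(0.2, 0.2).  The U-shaped
   Beta spectrum guarantees both common and rare founder alleles.  Drawn
   site-wise, founders carry no LD; LD arises in the next step.
2. **Ancestral mixing.** An ancestral population of the largest configured
   Nₑ is seeded from the pool and evolved for `mixing_generations`
   (default 60; 120 in the standard scenario).  The small founder pool
   plus recombination produces realistic haplotype-block structure: long
   shared segments that decay with genetic distance.
3. **Split and drift.** Each study population is founded from the
   ancestral generation and drifts independently for `split_generations`
   with symmetric per-site mutation `mu` (default 1e-5 per allele per
   generation), which continually injects rare variants.

Recombination: sites are placed uniformly at random on a `seq_length_cM`
map at 1 cM/Mb; each meiosis draws an independent crossover per
inter-site interval with probability `recomb_per_cM · d_cM / 100`.
Divergence (e.g. Hudson Fst over common sites) is non-decreasing in
`split_generations` in expectation; determinism is guaranteed by spawning
one child RNG stream per population from the configured seed.

**What the generator emulates:** multiple cohorts with tunable divergence,
block LD with distance decay, a site-frequency spectrum containing rare
and cohort-private variants, and ascertainable array content.  **What it
does not:** demographic growth, migration/admixture, gene conversion,
mutation-rate or recombination-rate heterogeneity, genotyping error and
phasing error (an explicit switch-error injector is provided instead),
multi-allelic sites, and genome-scale physical lengths.  Passing tests
therefore demonstrate correct behaviour of the *methods* under controlled
population-genetic structure, not calibrated performance on any real
cohort.

### Array design

Real array manifests are proprietary, so arrays are designed
algorithmically: candidate sites need design-population MAF ≥ `maf_floor`
(default 0.05); greedy tag selection repeatedly picks the candidate
covering the most uncovered candidates at r² ≥ `ld_r2_tag` (default 0.8),
a site covering itself, ties broken toward the lower position, stopping at
`target_density` or complete coverage.  This mirrors how genome-wide
coverage arrays are built and reproduces their ascertainment bias: the
matched array's sites are systematically more polymorphic in the design
population.

## Reference-panel QC (`panelqc`)

Filters run in a fixed order so audit counts are reproducible
(missingness → HWE → region mask → indel → multi-allelic → singleton →
monomorphic → external presence); each removed site is attributed to the
first filter that triggers, and counts plus survivors always equal the
input.  Defaults: exclude HWE exact p < 1e-6, per-site genotype missing
rate > 5 %, sites inside the (0-based half-open) mask intervals, indels,
records with more than 10 ALT alleles, singletons (AC = 1), monomorphic
sites (AC = 0 or 2N — a reference panel carries segregating variants
only), and sites present in fewer than `min_external_datasets` (default 2)
of the supplied external site lists; with no lists supplied the presence
filter is vacuous at threshold 0.  The HWE test is the exact conditional
test (two-sided, summing all heterozygote configurations no more probable
than the observed one) rather than chi-squared, because decisions at
p < 1e-6 on modest sample sizes are tail-sensitive; the implementation
uses the standard outward recurrence from the modal heterozygote count,
with a 1e-12 relative guard on the "no more probable" comparison against
floating-point ties.

## Haplotype-copying imputation (`lsimpute`)

Hidden state: which reference haplotype is being copied.  Transition over
an interval of d Morgans: switch probability ρ = 1 − exp(−4·n_eff·d/H),
floored at `min_recomb` (1e-8) and spread uniformly over the H reference
haplotypes; emission: match with probability 1 − ε, mismatch ε (default
1e-3); `n_eff` defaults to 1e4.  These defaults are this package's own
parameterization of the standard model, not a claim of numerical parity
with any specific tool.  The forward–backward pass is scaled per site (no
log-space needed at these panel sizes) and vectorized over target
haplotypes; posterior rows are normalized to 1 within 1e-9.

Dosages: at typed sites the output HDS is the posterior-weighted
reference allele (emission-dominated, so it honors the observed allele up
to ε); at untyped sites the flanking typed-site posteriors are dotted
with the reference alleles and interpolated linearly in genetic position
(nearest posterior beyond the outermost typed sites).  Leave-one-out
dosages at typed sites use the identity that the pre-emission forward
vector times the backward vector is the state posterior with the site's
own emission removed — one pass, no re-runs.  Estimated r² is
`Var(HDS)/(p̂(1−p̂))` with the population (divisor-n) variance over
haplotype dosages, 0 when p̂ ∈ {0, 1}, clamped to [0, 1].

With a panel of distinct haplotypes, a target drawn from the panel is
recovered essentially exactly (the perfect-panel check).  Under
Wright–Fisher structure panels contain locally identical haplotypes, so
posterior mass spreads over them and rare untyped alleles private to one
copy are diluted — expected model behaviour, which is why the recovery
check uses the site-wise founder panel.

## Meta-imputation (`metaimpute`)

Per target haplotype, a K-state HMM over panels: stay probability
1 − `switch_prob` (default 0.01 per typed interval), otherwise uniform
over the other panels; emission of panel k at a typed site is its
leave-one-out dosage if the observed allele is ALT, else its complement,
floored at `weight_floor` (1e-6).  Posterior weights at typed sites are
interpolated linearly in position to all other sites (held constant
beyond the outermost typed sites), zeroed and renormalized over the
panels that actually carry a site, and the meta HDS is the weighted sum;
estimated r² is recomputed from the meta dosages.  The combiner
re-derives the published idea (panel selection on leave-one-out accuracy)
rather than wrapping any external tool; its output is not expected to be
numerically identical to MetaMinimac2.  Mixing a good panel with a poor
one at small residual weight shrinks dosage variance and hence estimated
r² slightly; the effect fades as the typed backbone grows, which informs
the study design below.

## Evaluation (`evalmetrics`)

Per-site R² is the squared Pearson correlation of imputed diploid dosages
with truth dosages across samples; typed sites are excluded by default
(`include_typed=False`); sites monomorphic in truth or with constant
dosage are excluded and counted, not scored 0, because the correlation is
undefined there.  Bins on non-reference AF default to
{<0.2 %, 0.2–0.5 %, 0.5–5 %, ≥5 %}; the binning AF is the truth AF of the
evaluation samples (`af_source="truth"`), switchable to the
reference-panel AF, which resolves rarer bins than a small truth cohort
can (n samples bound the smallest observable truth frequency at 1/2n).
Both the per-bin mean of per-site R² (the headline) and a pooled R² over
all (site, sample) pairs are reported, since either averaging convention
appears in the literature.  % well-imputed is exact integer counting:
100 · #(est r² ≥ 0.8)/#imputed per bin, NaN (flagged) for empty bins.

## varLD (`varld`)

LD matrices are signed Pearson correlations of diploid genotype dosages
(the original method's practical variant; haplotype D′ is not used).
Windows are site-count based (default 50 shared sites with MAF ≥ 0.05 in
both cohorts, step half a window) so spectra are comparable across AF
regimes; spans are reported in bp.  Zero-variance sites are dropped
pairwise; a window with fewer than two variable sites is skipped.  Raw
score: L1 distance between descending-sorted eigenvalue spectra
(eigenvalues of a k-site correlation matrix sum to k, so equal-size
windows are on a common scale).  Standardization is (raw − mean)/SD over
all windows; the call threshold is the nearest-rank (100 − top_pct)
percentile, exceeded strictly, and overlapping or adjacent hit windows
merge into half-open bp regions.  Strict exceedance of the nearest-rank
cutoff caps the null call rate at top_pct by construction; the planted
experiment (LD destroyed by independent per-site permutation of one
cohort's haplotypes in a 30-site span) verifies sensitivity.

## Standard study conditions (`scenarios`)

Two cohorts, Wright–Fisher size 500, 150 samples each (100 reference +
50 target after the held-out split), 800 candidate sites on 4 cM, 120
mixing generations, 200 split generations.  These sizes keep a full
ten-seed experiment within minutes on one CPU while preserving the
paper-scale phenomena: matched-panel aggregated R² lands around 0.7–0.9
in the common bin with the mismatched panel far below.

Two experiments use different array densities deliberately:

* the **panel/array contrast** types 30 sites — sparse relative to the
  ~250 segregating common sites, as real arrays are sparse relative to a
  sequencing panel's variants — because ascertainment effects dominate
  only when tags are scarce.  The four panel × array combinations are
  ranked on sites typed on *neither* array, removing the asymmetry that a
  combination never scores its own typed sites;
* the **meta-imputation experiment** types 80 sites, a per-Mb density
  closer to a real array, giving the panel-selection HMM enough typed
  evidence that residual weight on the poorer panel stays small.
  Accuracy is compared on the site set shared by both panels
  (like-for-like), variant yield on the full outputs, where the union of
  panel sites is the point.

The recovery check uses a site-wise founder panel (distinct haplotypes,
2 Mb, typed every third site) as described above; the varLD experiments
use a single 1500-site, 3 cM cohort split into two 50-sample halves.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; VCF and manifest TSV are
  1-based on disk, BED 0-based half-open.  Dosages are serialized at 3
  decimals; internal computation is double precision.
* All randomness flows through `numpy.random.Generator` objects derived
  from explicit seeds (`SeedSequence.spawn` for per-population streams);
  identical configuration ⇒ byte-identical artifacts, which the pipeline
  records via a seed + config-hash provenance header in every output.
* Degenerate inputs raise rather than guess: empty panels, zero reference
  haplotypes, no typed/reference overlap, empty manifest∩truth, fewer
  than two meta panels, zero window-score variance.
* Ties in greedy array design break toward the lower position; percentile
  calls use the nearest-rank method.

## Known limitations

The simulator's single-contig, single-map, two-allele world understates
real LD heterogeneity; estimated r² inherits Minimac-style optimism at
rare sites; the meta combiner's linear weight interpolation is cruder
than per-variant weight estimation; truth-AF binning cannot populate bins
below 1/(2·n_target); and none of the measured accuracies transfer
quantitatively to real cohorts — the framework measures *orderings and
mechanisms* (matched vs mismatched, single vs meta, null vs planted), not
absolute real-data performance.
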