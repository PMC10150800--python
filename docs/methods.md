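# Methods

## Scope and data model

The pipeline analyses a two-way admixed cohort alongside its two source
populations ("east" and "west"). Internal coordinates are 0-based
half-open everywhere; the 1-based VCF convention is converted at the I/O
boundary only. Phased haplotypes are stored as a (2N × S) 0/1 matrix with
base-pair and genetic-map (Morgan) positions; expression is a genes ×
samples matrix of normalized abundances used as provided (an
inverse-normal transform is deliberately not applied by default);
local-ancestry tracks are BED-like per-haplotype segment lists.

## Synthetic cohorts

The generator defines the study conditions for every test.

- **Source populations: Balding–Nichols.** Each site has a shared base
  frequency p ~ Uniform(0.05, 0.95); each population draws its frequency
  from Beta(p(1−F)/F, (1−p)(1−F)/F). One parameter F controls
  differentiation symmetrically; F = 0 degenerates to identical
  populations. Sites fixed in both populations are written but flagged
  monomorphic, and downstream stages must skip them explicitly.
- **Admixture: Markov mosaic in genetic distance.** Each admixed
  haplotype receives ancestry switch points from a Poisson process of
  rate g (the admixture age in generations) per Morgan; at the origin
  and at every switch the ancestry is drawn from the stationary law
  (α_w west, 1−α_w east), and adjacent same-ancestry segments merge.
  Within a segment, alleles are copied from one random haplotype of the
  labelled panel. This reproduces the expected exponential decay of
  segment lengths with admixture age without a pedigree simulation; it
  does not model recombination hotspots, drift after admixture, or
  continuous migration.
- **Expression.** expression(g, i) = Σ over planted effects of
  β_east·(allele-1 copies on eastern haplotypes) + β_west·(copies on
  western haplotypes) + γ_g·(eastern-ancestry dosage at the gene locus)
  + N(0, σ²). Per-ancestry βs act on the ancestry of the haplotype
  carrying each copy, which is what makes ancestry-dependent regulation
  representable.
- **ASE counts.** Per heterozygous (sample, site): depth ~ Poisson(λ)
  truncated at ≥ 1, reference count ~ Binomial(depth, 0.5 + AI) with
  AI ∈ [0, 0.5] applied toward the reference allele. No reference/
  mapping bias is simulated, so passing recovery tests say nothing about
  bias correction on real read counts.
- **Determinism.** One master seed; each component draws from a named
  substream (`SeedSequence(master, spawn_key=(k,))` with a fixed
  component table), so any module's inputs can be regenerated
  independently and identical configurations produce byte-identical
  files.

Default conditions (panels of 500 diploids for calibration, 90 admixed
individuals, 2000 sites, F = 0.2, α_w = 0.5, ~30 generations over 1
Morgan, σ = 1, depth 50, AI = 0.2, down-sampling to 40 per cohort) mirror
the cohort scale the method targets: a ~90-sample admixed
transcriptome study with reference panels of a few hundred.

## Differentiation

Weir–Cockerham (1984) two-allele variance components a (among
population), b (among individual within population), c (within
individual), computed from per-population genotype counts with missing
genotypes dropped per site. θ̂ = a/(a+b+c); monomorphic sites carry an
explicit undefined marker, never a silent zero, and negative estimates
are retained but never classified as differentiated. HDS requires
θ̂ strictly > 0.2; HDG requires both the mean of per-site estimates and
the ratio-of-sums Σa/Σ(a+b+c) over the gene's sites strictly > 0.2. Gene
membership is position-in-interval with no flank (flank size is a
configuration knob).

A distributional fact worth stating: under Balding–Nichols at parameter
F, the per-site θ̂ is a ratio of skewed quantities — (p₁−p₂)² is
χ²₁-like — so its median sits near 0.45·F and its mean near 0.76·F even
with 500 diploids per population, while the genome-wide ratio-of-sums
estimator is consistent for F (0.204 at F = 0.2 in the calibration run).
Calibration is therefore asserted on the ratio-of-sums estimator; a
per-site median would test the wrong summary. The same skew is why 562
of 2000 simulated sites exceed the 0.2 threshold at a genome-wide F of
0.2.

## Admixture-frequency deviation

f_exp = α_w·f_west + (1−α_w)·f_east. The linear mixture is the only form
consistent with the worked lactase-persistence example (deviation 0.30
from sources 0 and 0.72 with observed 0.06), which it reproduces at
α_w = 0.5. α_w defaults to 0.5 — an inference, not a published value —
and should be overridden with the cohort's mean local-ancestry fraction
when tracks are available. Derived/ancestral polarity comes from an
ancestral-allele annotation; unpolarizable sites are dropped and
counted. Origin assignment (east/west/unassigned) uses a strict 0.20
contrast between source DAFs; the "high deviation" tier (> 0.1) is a
report-level filter.

## cis-QTL mapping

OLS with intercept and caller-supplied covariates; t-based two-sided
p-values with n − n_cov − 2 degrees of freedom; p floored at 1e-300 for
numerically perfect fits. Constant-dosage pairs are skipped as
untestable rather than reported at p = 1. The cis window defaults to
±1 Mb (half-open on both ends). FDR is one pooled Benjamini–Hochberg
pass across all tested pairs per run, matching summary-statistic-style
output; per-gene permutation p-values are out of scope. "High effect"
means |β| strictly > 5 on the supplied expression scale — the threshold
is configurable because the scale of a normalized expression matrix is
study-specific. Lead variants minimize p with ties broken by position
then variant id, making reruns reproducible.

## Allele-specific expression

AI = |ref/(ref+alt) − 0.5|; the signed variant is the derived-allele
fraction minus 0.5 and needs the ancestral allele. Sites-samples below
20 reads are excluded (the depth floor is configurable; 20 keeps the
exact binomial test's discreteness manageable). Significance is BH
q < 0.05 across all tested site-samples. The exact two-sided binomial
p sums outcome probabilities ≤ the observed outcome's probability
("minimum-likelihood" convention); its empirical size at α = 0.05 and
depth 30 is ~0.043 — conservative, as expected for a discrete exact
test. The aseQTL scan is a two-sided Wilcoxon rank-sum of AI by
candidate heterozygosity among ASE-site heterozygotes within ±100 kb;
with complete separation of 20 vs 20 samples the statistic attains its
maximum (U = 400). Driver attribution gives cis regulation precedence
over NMD (a site with both an aseQTL hit and a protein-truncating
annotation is called cis-regulated); missing annotation means no
consequence. Reference-bias correction is explicitly out of scope.

## Selection scan

EHH at offset x is the pair-counting estimate Σ_h C(n_h,2)/C(n,2) over
distinct extended haplotypes among carriers of the core allele — the
probability that two random distinct carriers are identical over
[core, x]. Missing alleles break a haplotype's extension (conservative).
iHH integrates each direction's curve by trapezoid to the first 0.05
crossing with linear interpolation; curves that never reach the cutoff
are integrated to the chromosome end and flagged truncated. Raw
iHS = ln(iHH_ancestral/iHH_derived) is standardized within 50
equal-width DAF bins (DAF outside [0.05, 0.95] excluded; bins with < 2
sites merged rightward); sweeps are flagged at |z| strictly > 2. On a
neutral exchangeable panel the tail beyond |z| = 2 is ~4.8% against the
Gaussian 4.55% — the within-bin distribution is approximately but not
exactly normal. Genetic distances come from the supplied map; the
fallback is 1 cM/Mb and is logged.

## Ancestry–expression association

Eastern dosage at a point is the count of haplotypes whose segment
covers it, with point queries right-closed — a breakpoint exactly at the
queried position belongs to the segment ending there (the first segment
also covers its own start). Gene-level dosage is taken at the gene
midpoint (averaging over the span is an option). Ancestral-like genes
use Pearson correlation (dosage is additive 0/1/2; Spearman is an
option), BH across genes, direction by sign. The eQTAS scan regresses a
gene's expression on each candidate segment's dosage within ±1 Mb,
candidates being the distinct segment midpoints observed in the cohort;
a segment whose dosage equals the gene-locus dosage reproduces the
gene-level statistics exactly.

## Expression state model

Effects are re-estimated per cohort on equal random subsets (default 40,
the size that makes three cohorts comparable when the smallest has ~40
members); heterogeneity between cohorts is z = (b₁−b₂)/√(se₁²+se₂²)
against the standard normal — the minimal test consistent with
"not ideal when P < 0.05" semantics. A pair is *ideal* when the admixed
beta lies in the **closed** ancestral interval (boundary = ideal) or
when neither heterogeneity test rejects; otherwise *enhanced*/*relaxed*
by magnitude relative to both ancestral magnitudes, with the residual
sign-flip-without-extremum case assigned by |b_adm| against the mean
ancestral magnitude (each such assignment is deterministic and logged).
The classification is invariant to a global sign flip (allele
relabeling), and the three states partition classified pairs. Under the
null (shared true effect) the non-ideal rate stays at the two-test alpha
level (≤ ~10%). With ancestral effects ±1, admixed effects at the
interval midpoint / at 3× the ancestral maximum / at zero, and noise
calibrated to se ≈ 0.15 (σ = 0.67 at n = 40), per-state recovery
accuracy is ≥ 99%.

## Numerical and reporting conventions

Report percentages use decimal half-up rounding at the configured
precision (so 4.3232% prints as 4.32 and 11.97% as 12). Result files
carry `#` header comments with version, seed and thresholds; floats are
written with `repr` and re-read with round-trip parsing so write→read is
bitwise lossless. All randomness flows from one seed through named
substreams; pipeline reruns are byte-identical.

## Problem sizes used by the checked experiments

F_ST calibration: 10 000 sites × 500 diploids/population. Null
calibrations: 1000 permuted association pairs at n = 90; 10 000 binomial
draws at depth 30. Recovery: 500 replicates at n = 90 (betas); 1000
sites at depth 50 (AI); 300 triples per state at 40 per cohort (states).
Neutral iHS: 100 haplotypes × 1500 exchangeable sites on a 1-Morgan map.
These sizes make Monte-Carlo error small relative to each assertion band
while the whole suite stays fast on a laptop.

## Known limitations

- No coalescent realism: no hotspots, no post-admixture drift,
  no mechanistic selection (sweep behaviour is exercised with a
  hand-constructed shared-haplotype fixture).
- ASE ignores reference/mapping bias and haplotype-level aggregation.
- Local-ancestry tracks are inputs or simulated truth; inference is out
  of scope, so track errors propagate unmodeled.
- The eQTL "ES > 5" threshold is scale-dependent and must be
  reinterpreted for any new expression normalization.
- Splicing phenotypes are handled as generic quantitative traits by the
  same association engine; no splicing-ratio construction.
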