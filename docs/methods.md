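# Methods

## The experimental design being modelled

A biparental F8 RIL population (Bay-0 × Shahdara-like): ~210 near-homozygous
lines genotyped at dense markers on five chromosomes, phenotyped for
transcript abundance under two treatments (control and salicylic acid),
with the whole experiment replicated twice. Three expression phenotypes are
derived per transcript per genotype — the control mean, the SA mean, and a
plasticity index delta — and each is mapped genome-wide.

## Genetic coordinates and the genotype model

Positions are centimorgans, 0-based per chromosome; chromosomes are
independent linkage groups. RIL genotypes are modelled as two-state Markov
chains along each chromosome: the allele at the first marker is A or B with
probability 1/2, and between adjacent markers at distance *d* cM the allele
switches with the Haldane–Waddington selfed-RIL recombination fraction

    R(d) = 2r/(1 + 2r),   r = (1 − e^(−2d/100)) / 2.

This stationary F∞ law is used directly instead of simulating seven selfing
generations; it is exact in the limit and a close approximation at F8. It is
an approximation in a second sense: composing per-interval transitions does
not reproduce R(d₁+d₂) exactly (the selfed-RIL genotype process is not
strictly Markov), so long-range co-segregation approaches but does not equal
independence — e.g. two markers 100 cM apart recombine with probability
2R(50)(1−R(50)) ≈ 0.475 under the chain. Residual F8 heterozygosity
(~0.8%) is ignored: genotypes are strictly homozygous, matching how the
mapping model treats lines.

Missing genotype calls are imputed as conditional expectations under the
same chain: a missing site between flanks at distances d_L, d_R gets

    g = T(d_L)[L,B] · T(d_R)[B,R] / Σ_s T(d_L)[L,s] · T(d_R)[s,R],

with T(d) the two-state transition with off-diagonal R(d); terminal gaps use
the single available flank, a fully missing chromosome gives 0.5. Complete
data pass through as exact 0/1 dosages, so imputation never perturbs
complete-data results.

## The synthetic transcriptome generator

Expression is generated as

    abundance = baseline + Σ_effects g·(b + 1{SA}·γ) + replicate shift + ε,

with allele coding g ∈ {−1/2, +1/2} so a baseline effect *b* equals the
parental mean difference, γ the SA-specific (plasticity) interaction, the
replicate shift one shared draw per (replicate, transcript) mirroring an
experimental-replicate random effect, and ε Gaussian, homoscedastic per
transcript. Defaults emulate the study conditions at desk scale: 210 lines,
chromosomes ending at 100/70/80/80/100 cM, two treatments × two replicates,
baseline mean 8 (log2-like microarray scale), noise SD 0.25, replicate SD
0.1, and marker spacing 2 cM (the study's 0.17 cM average spacing scaled
down ~12× purely for run time; at either density a single-QTL scan is
marker-limited, not grid-limited). Effect magnitudes are half-normal
(SD 1.0) plus a floor of 0.4–0.5 so every planted locus is in-principle
detectable; the field lacks a canonical effect-size law, so this
exponential-tailed choice is a simulation decision exposed in
`ArchitectureConfig`.

Architectural ingredients: cis effects at the transcript's own position;
dispersed trans effects at loci unlinked to their transcript; pleiotropic
hotspots loading many transcripts on one locus; and opposing-sign pairs —
two loci on one transcript with effects of equal magnitude and opposite
sign, so the parental sums cancel. Opposing pairs are the transgression
mechanism: parents respond identically while recombinants decouple the pair.

What the generator does **not** emulate: genotyping error, segregation
distortion, epistasis, heteroscedastic or heavy-tailed noise (a log-normal
switch exists but is off), probe cross-hybridisation, and annotation decay.
Tests passing on these simulations therefore validate the statistical
machinery under the stated generative model, not robustness to real
microarray pathologies.

## Variance partitioning

Per transcript, the fixed-effect model
`abundance ~ replicate + genotype + treatment + genotype:treatment` is fit
under sum-to-zero contrasts and type III sums of squares are computed as the
RSS increase from dropping each term's columns from the otherwise full
design (QR projection, vectorised over transcripts). Replicate is a fixed
blocking factor: for a two-level replicate this captures what a
random-effect replicate would absorb while keeping an SS decomposition
well defined; whether the original analysis used a true mixed model is not
determinable, and this choice is recorded rather than asserted. Proportions
are SS over total corrected SS, so balanced complete designs satisfy
Σ proportions = 1 (checked to 1e-8). Zero-variance transcripts are flagged
degenerate, report proportions of 0, and are excluded from clustering and
summaries. k-means (k = 10 by default, 10 seeded restarts, best inertia)
runs on the five-component proportion vectors; an independent statsmodels
type III ANOVA serves as the test oracle.

## Phenotypes, PCA, transgression

Genotype means are arithmetic means over replicate samples per treatment.
delta = (SA − control)/((SA + control)/2); cells whose cross-treatment mean
falls below ε = 1e-8 (on the data's scale) become missing — the ratio is
unstable there and the source analysis never addresses the case. The
expression scale (log2 vs linear) of the input estimates is likewise not
fixed by the method; a `log_transform` switch records the choice without
resolving it.

PCA is column-centred only (no variance scaling), fit on genotype ×
transcript mean tables with parents included; an exclusion set supports the
rerun without cis-eQTL transcripts. Transgression is the fraction of RIL
values strictly outside [min(parents), max(parents)] per transcript and
phenotype; ties count as inside (conservative). Note the null baseline is
high with only two parents — for i.i.d. values a new line falls outside the
range of two draws with probability 2/3 — so the informative signal is the
zero-noise mechanism (identical parents, non-degenerate RIL spread) and
comparisons across phenotypes, not the raw fraction.

## Genome scans and peak calling

Haley–Knott: at each marker, phenotype regressed on expected dosage;
LOD = (n/2)·log10(RSS₀/RSS₁). Scans run at observed markers only — no
pseudomarker grid, which adds nothing at these densities. The LOD is capped
(default 50) **only** when RSS₁ underflows to zero; large finite LODs keep
their ordering, which matters because clipping finite values flattens strong
peaks into plateaus and displaces the called peak. Scaling the phenotype by
any nonzero constant leaves the curve unchanged; zero-variance phenotypes
yield a flagged all-zero curve.

Peaks are local maxima at or above the 2-LOD threshold, accepted greedily by
descending LOD (ties → smaller cM) with two suppression rules: a candidate
within 11 cM of an accepted peak is dropped, and a candidate not separated
from every accepted peak by a valley at least 1.5 LOD below it is dropped as
a shoulder of the same QTL. The valley rule mirrors the peak-drop criterion
of standard QTL software; without it, noise wiggles on the flanks of strong
peaks are called as separate loci. Both constants are configurable
(`min_peak_separation_cM`, `peak_drop_lod`).

The 2-LOD threshold is applied per scan, genome-wide, with no cross-
transcript correction — exactly the published procedure. It is permissive:
under the null the genome-wide false-positive rate per scan is well above
5% (the suite measures ~20% on the five-chromosome map at n = 210), so
detected-record totals always include a material false-positive component.
Parameter-recovery statements are therefore made on records matched to
planted loci (same transcript, within 5 cM, matching phenotype); unmatched
proportions are dominated by the ~95%-trans geometry of false peaks and do
not measure classifier correctness.

## Classification, merging, effect size

Gene bp positions are interpolated to cM piecewise-linearly between marker
anchors, clamping beyond the anchored span. cis means same chromosome and
|peak − gene| ≤ 10 cM, boundary inclusive; transcripts without positions
are "unplaced" and excluded from proportions but kept in tables. Merging is
single-linkage over same-chromosome records with gap ≤ 5.5 cM; chaining is
allowed (0/5/10 cM becomes one cluster at 5.5) — the simplest deterministic
closure of "within 5.5 cM", since the source procedure does not specify
chaining. If one phenotype contributes two records to a cluster the higher-
LOD one stays and the spare re-clusters among the remaining spares; records
are canonically sorted first, making the merge order-invariant. Effect size
is computed once per merged locus at the marker nearest the consensus
position (one locus, one genotype vector), per member phenotype, with the
mean stored; on complete data R² = 1 − 10^(−2·LOD/n) holds to 1e-9.

Annotation: a trans locus is paralog-flagged when any paralog of its
transcript (precomputed table; synteny inference is out of scope) lies
within 10 cM of the consensus on that chromosome; hotspot membership is
distance ≤ 5 cM to a named region, with interior points at distance 0.

## Hotspots

Windows are half-open [s, s+10) stepped by 1 cM, plus a final window ending
exactly at the chromosome end when the grid falls short; a position exactly
at the terminus falls in no window (a measure-zero convention). Only
trans-labelled consensus positions are profiled for thresholding; cis
profiles are produced but never thresholded. The null redraws the observed
number of eQTLs uniformly over the map (chromosome chosen ∝ length;
a marker-frequency-weighted alternative is available) and the global
threshold is the 95th percentile of the pooled window counts over all
permutations — a global, not family-wise, criterion (a per-permutation-
maximum option exists, off by default). Called hotspots are maximal runs of
windows with count strictly above threshold, merged to [first start,
last end).

Calibration is checked on the disjoint window cover (step = window):
overlapping 1-cM-step windows share most of their positions, so their
counts are strongly correlated and a binomial error bar on the full grid
understates the sampling spread several-fold; the disjoint cover gives
independent counts at the correct resolution. Because counts are integers,
the exceedance probability at an integer threshold is P(X > q95) ≤ 5%
(ties), so the measured fraction sits slightly below the nominal 5%.

## Problem sizes and determinism

Default verification sizes: 100 random instances (50 lines × 20 markers)
for the identities; 2,000 lines for the recombination law; 210 lines × 500
transcripts with 50 planted effects for recovery; 200 permutations for
hotspot recovery and 1,000 for calibration (50 replicate null datasets);
10⁶ pairs for the delta properties. These complete in seconds to a few
minutes on one core and were chosen as the smallest sizes at which the
binomial/closed-form tolerances are meaningful. Every stochastic component
takes an explicit seed; the pipeline derives per-stage seeds by hashing the
stage name with the global seed, so stages can be re-run in isolation
without perturbing each other, and identical seeds give byte-identical
outputs (single-threaded; floats written at 6 significant digits).

## Known limitations

Single-QTL scans only: no multi-QTL models, covariates, kinship, or
epistasis. The merge's chaining behaviour and the peak-extraction constants
are documented conventions, not reproductions of unpublished choices. The
permutation null redraws eQTL positions rather than re-scanning permuted
phenotypes (the latter is prohibitive at scale and tests a different
hypothesis). Real-data curation steps — retired-annotation removal,
fragment exclusion — are left to the user, so headline counts from real
inputs will differ from published totals without equivalent curation.
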