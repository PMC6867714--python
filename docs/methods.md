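# Methods

## The oligomer model

The package models archaeal-histone protection as a tetramer footprint
of `f0 = 60` bp extended in dimer steps of `s = 30` bp:
`L(r) = f0 + s·(r − 1)` for oligomer rank `r = 1 … 4` (60, 90, 120,
150 bp).  Fragments are binned into size classes `L(r) ± 5` bp; the
four classes are disjoint and each admits 11 lengths.  Everything
downstream — peak widths, rank assignment, size-resolved coverage — is
anchored to this arithmetic.

## Normalization

Raw coverage confounds protein protection with the nuclease's strong
preference for cutting AT-rich DNA.  Occupancy is therefore defined
per base as

    O(x) = c_strain(x) / (c_EV(x) + 1)

with the empty-vector (EV) control pooled across all fragment sizes
and a +1 pseudocount so zero-coverage regions stay defined.  Library
scaling (fragments-per-million on both tracks before the ratio) is
exposed and defaults to on for cross-library comparisons; within a
matched strain/EV pair the ratio itself already cancels depth to first
order.  All rank-based statistics downstream are invariant to monotone
rescaling of the tracks.

## What the simulator emulates

`simulate` generates the full study conditions at desk scale
(defaults in `SimConfig`):

- **Genome** (200 kb, circular): background GC 0.5; 100 genes, each a
  1,000 bp CDS preceded by a 60 bp 5′ UTR and a 100 bp promoter at
  GC 0.3.  The TSS sits at the promoter's 3′ edge; the start codon is
  therefore 60 bp downstream of the TSS, which is what makes the
  51 bp start-codon control window a genuine control rather than a
  relabeling of the TSS window.  Real bacterial 5′ UTRs are tens of
  bp, so this is the realistic geometry, not a convenience.
- **Particle placement**: nucleation sites are drawn with probability
  ∝ exp(β_GC · GC61) (GC61 = GC fraction of the 61 bp window at the
  site), rejecting overlaps, to a density of 8 particles/kb.  Each
  particle grows *as it assembles*: up to three dimer extensions, side
  chosen uniformly, each succeeding with probability
  p0 · (1 − α · AT_flank) and failing permanently on the first
  Bernoulli failure or collision.  Interleaving nucleation and growth
  matters: if all tetramers are placed before any extension, crowding
  freezes ~80% of particles at rank 1 and the simulated digest never
  shows the hexamer-and-larger-dominated profile seen in real
  stationary-phase chromatin.  With p0 = 0.9 and α = 0.8 the realized
  per-step extension probability at background composition is ~0.5,
  giving rank fractions ≈ {0.59, 0.22, 0.10, 0.08} and a ladder with
  strong 90/120/150 rungs.
- **β_GC = 16** plants the sequence preference.  Packing at 8
  particles/kb saturates ~60% of the genome, which strongly flattens
  any nucleation preference (rejection sampling pushes particles into
  disfavoured sequence); β_GC was set from a generator-side
  measurement — the smallest value at which the planted 60 bp-window
  occupancy–GC Spearman correlation clears 0.3 with margin
  (ρ ≈ 0.41) — matching the strong GC–occupancy coupling the method
  is designed to detect.
- **Digestion**: each particle emits Poisson(μ = 20) fragments
  spanning its protected interval; both ends get rounded N(0, 2)
  jitter and are snapped, with probability w_AT = 0.7, to the nearest
  cut position flanked by A/T (the nuclease bias).  Lengths are
  clipped to ≥ 20 bp.  The EV control draws smooth 20 + Γ(3, 20)
  lengths (resampled, not clipped, above 159 bp, so no artifactual
  boundary peak) with the same AT cut bias and no footprint structure.
- **Libraries are population averages.**  A sequencing library pools
  chromatin from many cells, each with its own particle configuration.
  `simulate_library` therefore pools `simulate_digest` over
  `n_cells = 300` independent placement configurations at a default
  depth of 400,000 fragments (the study's library depth scaled to a
  200 kb genome).  This matters quantitatively: under a single quenched
  configuration the per-base occupancy of one size class is almost
  pure packing noise (the best possible sequence predictor of the
  120 bp class reaches Spearman ρ ≈ 0.03), whereas the ensemble
  average is a smooth sequence-determined field.  Single-configuration
  digests (`simulate_digest`) remain the right input where a planted
  ground-truth configuration is the point, i.e. footprint-recovery
  benchmarking.
- **Expression**: the binding strain's true log2 fold change is
  −γ·standardized(O_TSS) (γ = 1, repression sign convention) plus, for
  a random 10% of genes, a systemic shift shared with the non-binding
  (DNA-binding-deficient) strain — exercising the exclusion rule —
  plus N(0, 0.3) noise.  Replicate counts are negative-binomial
  (5 replicates, dispersion 0.2); DE estimates are log2 ratios of
  replicate means with BH-adjusted two-sample t p-values on log
  counts.  A deliberately simple estimator: the pipeline consumes DE
  tables agnostically, so the estimator brand is irrelevant here.
- **Compendium**: 50 N(0, sd(d)) comparison vectors plus one
  (`comp_planted`) constructed with correlation ≈ 0.5 to the
  binding-strain estimate.

What passing tests on these conditions do **not** show: performance on
real libraries with mappability artifacts, copy-number gradients,
replication-associated skews, or nucleases other than MNase; nor that
the LASSO's absolute ρ on real data would match the synthetic value.
They show the machinery is correct and that each planted effect is
recovered through the full chain.

## Peak calling

Tracks are low-pass filtered by discrete Fourier transform, keeping
the lowest ⌈κN⌉ frequencies (conjugate pairs together, DC always —
the filter is linear and mean-preserving).  Local maxima above the
q-quantile of the smoothed track become candidate calls; width is the
extent above half height; rank is assigned when the width is within
±5 bp of some L(r); score = relative height × closeness of width to
the nearest L(r).  Overlaps are resolved greedily by descending score
(leftmost center on ties), testing overlap on the central half of each
call's extent so directly adjacent footprints both survive.  Two
numerical guards: maxima below 5% of the track maximum are dropped
(the sharp spectral cutoff rings around isolated peaks with sidelobes
≤ ~4% of the peak) and widths below 20 bp are ignored (ringing
wavelength at the default κ).  Defaults κ = 0.02, q = 0.75 follow
common practice for this family of callers and are configurable, never
hard-coded; the right values are data-dependent.

**Footprint recovery** (the benchmark on planted placements) calls
peaks per size-class coverage track with κ = 0.05 and q = 0.5 — dense
class tracks carry many directly adjacent footprints, and the gentler
filter resolves neighbours that the heavier default would merge.  A
placement counts as recovered when a call's center lies within ±5 bp
of the true footprint center; its predicted rank is the rank of the
class track producing the nearest matching call.  On default
conditions this recovers ≥ 94% of tetramer placements with a rank
confusion diagonal ≥ 0.88.

## Sequence model

Features are exact forward-strand counts of all k-mers (k = 1–4; 340
features) in an odd window centered on each position — 121 bp for the
120 bp class (window pairs with class: 60→61, 90→91, 120→121).
Windows containing N are excluded.  No reverse-complement collapsing
by default (no principled collapsing rule for an asymmetric particle;
option exposed).  The response is raw normalized occupancy (log2
exposed as an option; both behave equivalently here).  Training uses
the contiguous genome prefix [0, ⌊L/6⌋) — for the 4,641,652 bp
E. coli K-12 chromosome that boundary is 773,608 — with positions
strided every 10 bp to keep the problem desk-scale; the penalty is
chosen by 10-fold cross-validation over contiguous blocks *within the
prefix* (contiguous, to limit spatial leakage).  Features are
standardized to unit variance for fitting; coefficients are reported
on the count scale.  Evaluation is on the held-out five-sixths
(strided every 10 bp in the shipped analyses), via Spearman ρ of
predicted vs observed, alongside univariate per-k-mer Spearman
correlations ("individually most informative k-mers", top/bottom 20).

Read-internal profiles use only fragments of one exact length,
oriented on the forward strand; enrichment is positional base
frequency over genome-wide composition, and the dyad-symmetry score is
the mean |E(p, b) − E(len+1−p, complement(b))| (0 = perfectly
symmetric).  Being internal to protected fragments, these are immune
to cut bias.

## Transcription linkage

Genes significant (BH-adjusted p < 0.05) in the same direction in both
the binding and non-binding comparisons are excluded (systemic
response, not occupancy); the rest are grouped by the binding
comparison.  Group occupancy is compared with a two-sided
Mann–Whitney U test (a rank test; occupancy distributions are far from
normal) per window type — TSS base, TSS ± 25 bp, annotated promoter,
gene body (whole CDS), and the 51 bp start-codon control — and per
size class, including a pooled "90 + bp" large-fragment class.
Compendium similarity is the raw dot product over shared genes (not
cosine — raw products preserve magnitude information; cosine and a
Spearman ρ of the paired vectors are also reported), with missing
genes dropped per comparison and the shared-gene count reported.
Up/down sub-vector similarities (zeros elsewhere) decompose the total
additively.

## Other numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere; 1-based inputs convert
  at the file boundary.  Chromosomes default to circular; coverage,
  windows and TSS profiles wrap across the origin (mass conserved).
- TSS selection within a broad region: argmax of read support, ties to
  the smallest coordinate; all-zero support keeps the leftmost
  position with a warning.
- "Downstream" for NAP Δ-occupancy means increasing genome coordinate;
  the last bound region on a linear contig is skipped and counted.
  All-zero Δ sets return p = 1 with a warning rather than an error.
- Zero-variance tracks/responses: correlations are flagged NaN, never
  silently 0; constant LASSO responses are rejected.
- Regional-transcription windows are non-overlapping 200-gene blocks
  per codirectionality stratum (codirectional ⇔ gene strand matches
  the replichore direction implied by configurable origin/terminus);
  overlap is configurable.  The moving GC–occupancy profile uses a
  500-gene span advanced 20 genes at a time, shrinking with a warning
  below 500 genes.
- The per-stage RNG seeds derive from one global seed by hashing the
  stage name, so any stage is independently reproducible and changing
  one stage's seed perturbs only that stage.

## Problem sizes in the shipped analyses

Defaults were chosen once as desk-scale study conditions: 200 kb
genome, 1,600 particles, clonal digests of ~32k fragments (μ = 20),
ladder analyses at 200,000 fragments, population libraries of 400,000
fragments over 300 cells, LASSO training on ~3,300 strided positions
and evaluation on ~16,600.  The ~30 bp sub-tetramer fragment
population sometimes seen in exponential-phase digests is deliberately
not simulated — it appears in EV controls too and is plausibly a
digestion artifact, so the generator does not plant it.

## Known limitations

- The placement sampler is sequential rejection sampling, not an
  equilibrium thermodynamic model; it plants a sequence preference but
  its saturation behaviour is mechanism-specific.
- The MNase bias model (end-snapping to A/T within ±4 bp, weight 0.7)
  is stylized; no quantitative bias model is available to calibrate
  against.
- Rank assignment from width at half height degrades for heavily
  overlapping footprints of different ranks; the size-resolved caller
  sidesteps this but assumes the class tracks are informative.
- The exact Fourier/threshold parameters of any particular real
  dataset must be tuned to that dataset; the defaults here are
  procedural, not universal.
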