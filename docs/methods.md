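# Methods

`lm2r` infers how often individual helices occur in an RNA's secondary-
structure ensemble — and whether pairs of helices co-occur or exclude each
other — from compensatory-rescue chemical mapping. This note records the
models, the numerical choices, and what the synthetic test bed does and does
not establish.

## The rescue factor

A candidate base pair (i, j) is interrogated by a *quartet* of per-nucleotide
reactivity profiles: wild type (WT), each single mutant (A: flip i to its
Watson-Crick complement; B: flip j), and the compensatory double mutant (AB),
which restores a Watson-Crick pair with the strands swapped. G-U wobbles are
resolved by flipping the G to C and the U to G so the double mutant is C-G.
The quartet is summarized by

    rescue = 1 − RMSD(WT, AB) / max(RMSD(WT, A), RMSD(WT, B)),

with RMSD the root-mean-square difference over the probed nucleotides.
Full rescue (≈1) indicates the pair is present in essentially every member of
the ensemble; no rescue (≈0) indicates it is absent; intermediate "partial
rescue" is the signature of a pair present in part of the ensemble: the
double mutant restores the structures that carried the pair but rearranges
the competing structures that used the same nucleotides elsewhere.

Choices that matter:

* **Comparison window.** By default the RMSD runs over every probed
  nucleotide, including the mutated positions; an optional flag excludes a
  ±w window around the substitutions (both behaviors are tested). The
  flanking reference hairpins are never part of the probed region — they are
  normalization anchors.
* **Negative factors are kept.** A double mutant more disrupted than either
  single gives rescue < 0; clipping would hide that anti-rescue signal.
  During calibration matching such observations fall into the lowest
  populated bin.
* **Uninformative quartets.** If neither single mutant perturbs the profile
  the denominator vanishes; the quartet is flagged and skipped (with a
  warning) when averaging over a helix, rather than contributing a
  meaningless value.
* The no/partial/full category thresholds (0.2, 0.7) are reporting
  conveniences and are configurable; nothing quantitative depends on them.

## Profile cleaning

RDAT-level operations mirror a standard capillary-electrophoresis pipeline:

* **Normalization** divides by the mean reactivity over the GAGUA reference
  loops (optionally a per-modifier subset of loop positions), making the
  loop mean 1.0; the operation is a single common scale factor and is
  idempotent.
* **Attenuation correction** models reverse-transcription drop-off as a
  geometric (exponential-in-position) factor anchored at the two reference
  loops. Anchors use the *geometric* mean of the loop intensities at the
  loop-center positions; because the exponent is linear in position, the
  corrected 3′ loop geometric mean then equals the 5′ one exactly, and the
  per-position factor is closed-form. This is a deliberate simplification of
  full trace-level attenuation estimators, which are out of scope.
* **Background subtraction** is elementwise with a floor at zero
  (reactivities are physically non-negative); errors combine in quadrature.

## In-silico calibration: rescue factor → helix frequency

The quantitative meaning of an intermediate rescue factor is established by
simulation. For each calibration sequence:

1. Fold to a base-pair probability (BPP) matrix.
2. Screen candidate helices: maximal stacked runs of Watson-Crick/G-U cells
   with BPP ≥ 1% (default) and length ≥ 3 bp. (Lowering the cutoff to 0.1%
   is a tested robustness regression.)
3. For every base pair of every screened helix, design the compensatory
   quartet, fold all four variants, and compute the rescue factor from
   simulated profiles.
4. Record one calibration sample per helix: base-pair count, mean simulated
   rescue factor over its pairs, and mean BPP over its pairs (the simulated
   helix frequency). Helix frequency in mutants is measured over the same
   (i, j) positions — position-defined, not base-defined.

**Simulated reactivity is the probability of being unpaired** (1 minus the
BPP row sum). Chemical probes read out backbone flexibility, and the
probability-unpaired profile is the simplest deterministic observable with
that property; simulated profiles are noise-free by default (optional
Gaussian noise is available for sensitivity analyses).

Two fold backends sit behind one interface:

* `ViennaBackend` — ViennaRNA's equilibrium partition function (Turner
  energies, 37 °C default): the production backend.
* `ReferenceBackend` — a self-contained McCaskill inside/outside dynamic
  program over an additive pair-energy model (G-C −3, A-U −2, G-U
  −1 kcal/mol; minimum hairpin loop 3; uniform per-nucleotide rescaling for
  numerical range). Its purpose is exact verifiability: for every fixture
  sequence ≤ 18 nt it matches brute-force Boltzmann enumeration of all
  structures to < 1e-9 in every BPP entry. The energy constants are round
  numbers chosen once for a well-conditioned toy ensemble; they are not
  fitted parameters.

Calibration tables are serialized as TSV with a JSON provenance sidecar
(backend, temperature, cutoffs, seed, table hash) and are bit-reproducible
given (sequence set, backend, seed).

Since a curated family database cannot be bundled, calibration inputs for
tests and the acceptance run are seeded uniform-random RNA sequences
(100–250 nt, matching the length window used for family screens); any FASTA
can be supplied in production. Random sequences lack the conserved structure
of real families, but the calibration relation only requires a diverse
population of helices across the frequency range, which they provide.

## Posteriors over frequency and correlation

Given an observed mean rescue factor for an n-bp helix, the frequency
posterior is the empirical set of calibration frequencies among samples with
the same base-pair count whose simulated factor falls in the same bin
(binwidth 0.05). The median is the point estimate; a Gaussian KDE
(Silverman bandwidth, boundary-reflected at 0 and 1) is attached for
plotting and combination. Bin starvation is handled by progressive widening
— ±1 bin, then ±1 bp, then ±2 of each — stopping as soon as 20 samples are
found; every relaxation is logged and recorded on the posterior.
Observations outside the populated bin range clamp to the nearest populated
bin with a warning. Credible intervals are reported from the samples (the
KDE-based alternative is available through the density itself).

The correlation value for helices h1, h2 is g = F(h1|h2)/F(h1), with
F(h1|h2) measured by probing h1 in a background that locks h2 (two
consecutive base pairs of h2 swapped to the alternative Watson-Crick pairs).
Its posterior is the set of pairwise ratios of conditional over
unconditional frequency samples; the cross-product is capped at 10⁶ ratios
by seeded subsampling. Zero wild-type samples are excluded (logged); g ≪ 1
indicates mutual exclusion — the signature of conformational selection
(MWC) — and g ≈ 1 independence.

A locked-probe experiment and its "flipped" partner (lock h1, probe h2)
estimate the same g. They are combined, under a flat prior on g, by
multiplying boundary-reflected KDEs of the two ratio posteriors on a shared
grid of 2048 points spanning [0, max(4, 99.5th percentile of pooled
samples)], renormalizing by the trapezoid rule, and drawing representative
samples by inverse-CDF with a seeded generator. The combination is
commutative by construction. A vanishing product (disjoint supports) raises
an error flagging mutually inconsistent experiments. *Posterior support*
above a threshold (default g > 1) integrates the combined density, or counts
samples when no density is attached; it is stable to within a factor of ~1.3
under halving/doubling of the KDE bandwidth in the tested regime.

## Two-state validation of lock mutants

A lock mutant is trusted when the wild-type profile decomposes as a
two-state mixture of locked-endpoint profiles: f minimizing
RMSD(target, f·A + (1−f)·B), solved in closed form and clamped to [0, 1],
with the raw optimum and the residual also reported. Multi-modifier fits
concatenate per-modifier (pre-normalized) profiles under a single shared f.
Endpoint scale freedom is deliberately fixed by prior normalization; the
mixture fraction is invariant under common affine transforms of all three
profiles, while the residual scales with the common gain.

## Synthetic ground truth

The toy ensembles are explicit mixtures of dot-bracket structures with
known weights — no folding involved — so every downstream inference can be
checked against exact truth:

* **Mutant response is structure-aware.** A mutation breaks any structure
  in which a mutated nucleotide is paired to a now-incompatible partner;
  broken weight rearranges to the most populated surviving structure
  (preferring structures without the probed pair), or spreads uniformly
  under the alternative response model. This one rule generates full,
  partial and no rescue in the right regimes.
* **Calibration family.** A three-state motif — target helix X:Y, decoy
  register Y:Z sharing the Y strand, and an open state — swept over true
  frequencies 0.05–0.95, base-pair counts 3–6, a seeded decoy share in
  [0.5, 0.9], and additive Gaussian noise (sd 0.1, a typical error scale
  for normalized reactivities). The noise-free rescue factor of this family
  increases smoothly from 0 to 1 with the true frequency.
* **Correlation families.** Mutual exclusion is modeled by two helices
  sharing a strand (true g = 0); graded correlation by a two-module
  ensemble whose 3×3 joint state distribution is a rank-one tilt of the
  product distribution, hitting any feasible target g while preserving both
  marginals (g = 1 is the independent case). Locking is emulated by
  conditioning the ensemble on the helix (renormalizing weight onto the
  structures that carry it; other structures stay listed at weight zero so
  they remain probeable).

What the fixtures do *not* emulate: sequence-dependent thermodynamics
(structures and weights are posited, not folded), correlated or
heteroscedastic measurement error, attenuation/saturation artifacts of real
electrophoresis data, and ensembles with more than a handful of discrete
states. Passing the recovery tests therefore demonstrates that the
inference chain is correct and well-calibrated *given* its generative
assumptions, not that those assumptions exhaust real chemical-mapping data.

The bundled 198-nt probed construct (5′ GAGUA reference hairpin, adenine
riboswitch, 3′ GAGUA reference hairpin, primer tail) ships with its
biological numbering (offset −14), reference-loop annotations, and the
helix registries implied by the published lock-mutant designs; the
strand-swap lock designer reproduces those printed mutant labels exactly.
Full helix endpoint registries are user input, as they are not fully
enumerable from the published designs.

## Problem sizes and determinism

Simulation-heavy checks run at desk scale by choice: the calibration-trend
check uses ~12 random 100–250-nt sequences (≥ 100 screened helices) with the
ViennaRNA backend; oracle-equivalence checks enumerate all structures for
~18 sequences ≤ 18 nt; recovery checks use the 150-helix toy calibration.
Every stochastic component takes an explicit seed (fixtures, subsampling,
inverse-CDF draws), and all tables and fixtures are bit-reproducible for a
fixed seed.

## Known limitations

* The additive energy model of the reference backend ignores stacking,
  loop-length and dangle contributions; it is for verification, not for
  quantitative thermodynamics.
* The attenuation correction is anchor-based; strongly position-dependent
  drop-off between anchors is not modeled.
* Frequency posteriors inherit the calibration population's prior: helices
  rare in the calibration set produce wide or clamped posteriors.
* Pseudoknots are out of scope throughout (screening, toy structures,
  backends).
* Error propagation from per-position reactivity uncertainties into rescue
  factors is limited to reporting per-pair spread.
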