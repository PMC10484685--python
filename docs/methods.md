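# Methods

This note documents the models, parameter choices and numerical
conventions behind `fourbase`, and states what the synthetic-data tests
do and do not establish about real probing data.

## The measurement model

DMS probing with mutational-profiling readout is treated as a
per-position Bernoulli process on each molecule. Unpaired Watson-Crick
faces acquire methyl adducts at base-specific rates; reverse
transcription converts each detected adduct into a mutation whose type
depends on the adduct class:

* A, C, U and N1-methyl-G adducts are decoded as mismatches; N1-G
  specifically as G→C or G→T.
* N7-methyl-G forms at every G at high rate (~0.2–0.8 per molecule)
  regardless of pairing, but is read through rarely (~1–3%) and almost
  exclusively as G→A.
* The reverse transcriptase additionally produces background
  substitutions and indels unrelated to any adduct.

The mutation-signature filter follows from this model: G→A mismatches,
multi-nucleotide mismatches whose reference span contains a G, and all
indels are reclassified as **no data** — not as "unmutated" — because
they carry N7-G or enzyme noise, not pairing information. Clearing the
validity mask over the event span (rather than counting the read as
unmutated there) keeps mutation rates unbiased; the filter removes both
the numerator event and the denominator coverage.

## Reactivity normalization

The background-subtracted modification rate r = rate(treated) −
rate(untreated) (or the treated rate alone) is normalized per nucleotide
type n by

    N_n = max{ mean of r in the [P90, P95] band,  P75 of {r > 0.001} }

Numerical conventions, fixed for reproducibility where the defining
description is silent:

* percentiles are linearly interpolated between closest ranks;
* the "[P90, P95] band" is the set of values v with P90 ≤ v ≤ P95; with
  heavy ties this set can be empty, in which case the interpolated
  92.5th percentile is used;
* the {r > 0.001} subset is taken on the same (background-subtracted)
  scale as the value being normalized; if empty, N_n falls back to the
  first term;
* negative background-subtracted rates are retained, not clamped — they
  carry information about background noise and are naturally excluded
  from the >0.001 subset.

QC masking defaults: effective depth < 1000 or untreated rate > 0.05
masks a position (both configurable). Normalization is per RNA; factors
are never pooled across transcripts unless the caller pools profiles
explicitly.

## Structural information

Each position is two-state (paired b / unpaired u) with a uniform prior.
Given class likelihoods p̂(r|b) and p̂(r|u), the posterior is the
equal-prior form p(b|r) = p̂(r|b) / (p̂(r|b) + p̂(r|u)) and the
per-position structural information is SI(r) = 1 − H(s|r) bits, with
H the binary Shannon entropy of the posterior. ESI is the mean of SI
over all unmasked positions; in two-base (A/C-only) mode, G and U
positions contribute SI = 0 but remain in the denominator so that the
two-base and four-base numbers are directly comparable.

Class likelihoods are double-gamma mixtures over r > 0 plus a point mass
at r ≤ 0 (normalized profiles contain exact zeros and negatives; the
point mass makes the likelihood well-defined on the whole line). SI is
evaluated with the raw likelihood ratio — posteriors of exactly 0 or 1
are representable, so perfectly separating models give SI = 1 exactly —
and a 1e-12 floor guards only the 0/0 case, where SI is 0 by convention
(no evidence leaves the prior standing).

### Mixture fitting

EM on the positive values, two gamma components, with:

* initialization by a quantile split (median by default, jittered
  uniformly in [0.25, 0.75] across 5 seeded restarts);
* weighted gamma M-steps solved by Newton iteration on the
  log-mean/mean-log equation;
* convergence at mean log-likelihood change < 1e-6, cap 2000 iterations;
  non-convergence across all restarts raises an error carrying the best
  parameters seen;
* a parsimony safeguard: the single-gamma MLE is also computed, and if
  BIC prefers it the fit is returned with all continuous weight on one
  component. The two-component family nests the single gamma with an
  unidentifiable weight split; without this safeguard, EM represents
  single-gamma data as two arbitrary similar components. The family
  remains capped at two components — this is a degeneracy tie-break, not
  a search over component counts.

Fitting a class requires ≥50 values of which ≥20 positive. On a ~150-nt
RNA this is rarely met per base and class; likelihood models are meant
to be trained once on a large molecule (the natural choice is a
ribosomal RNA, thousands of positions per class) and reused, which is
why the `esi` command accepts pre-fitted model files.

## PAIR analysis

Reads are reduced to boolean per-window indicators: a 3-nt window is
covered in a read iff all three positions are valid after signature
filtering, and modified iff it contains ≥1 retained mutation. For every
window pair the exact 2×2 contingency table is accumulated (vectorized
as three boolean matrix products, so 300k reads × ~10k window pairs run
in seconds).

Classification pipeline, in order:

1. windows must be separated by at least a 3-nt loop (j ≥ i + 6 for
   3-nt windows): two windows closer than a minimal hairpin loop cannot
   form a duplex, and in melting ensembles such neighbours are strongly
   co-modified for reasons that have nothing to do with pairing;
2. co-modification count n11 ≥ 10;
3. positive association: observed n11 must exceed its independence
   expectation (co-modification is a one-sided phenomenon; the G-test
   alone would also flag mutual exclusion);
4. G-test of independence (2×2 likelihood ratio, df = 1, no Williams
   correction), Bonferroni-corrected over all pairs reaching this stage,
   significant at alpha = 0.05;
5. full antiparallel complementarity: all 3 opposed positions must be
   Watson-Crick or GU pairable. A reported PAIR asserts a 3-bp duplex;
   requiring only partial complementarity lets through out-of-register
   echoes of real helices, which dominate false calls in ensembles where
   a helix melts as a block;
6. reactivity gates on the window means of the normalized profile
   (windows overlapping masked positions are dropped entirely): ≥ 0.2
   for a minor PAIR; a principal PAIR additionally needs ≥ 0.4 and must
   be mutually strongest — each window's highest-G significant partner
   is the other window.

The 0.2/0.4 gates reflect that a duplex detectable by correlated
modification must be open in an appreciable fraction of molecules, which
lifts its ensemble-average reactivity off the paired baseline.

PAIR ppv/sens against an accepted structure: a PAIR is correct if any of
its three window base pairs matches a structure pair exactly or shifted
by one position; sens is the fraction of accepted helices (≥3 bp, fully
inside data-covered regions when a mask is supplied) hit by ≥1 correct
PAIR. With no reported PAIRs, ppv is NaN rather than 0.

## Structure comparison

ppv/sens of predicted vs accepted structures counts canonical (WC + GU)
pairs only, drops singleton pairs (no stacked neighbour) from both
structures, and allows one-position register shifts. Matching is
one-to-one: each accepted pair can be claimed by at most one predicted
pair, resolved by maximum bipartite matching with a 5'-first tie-break
(pure greedy claiming can strand a predicted pair whose only partner was
taken by a shifted neighbour). ppv with an empty prediction is NaN, not
0, so empty predictions are distinguishable from wrong ones.

## The synthetic-data generator

The generator emulates the measurement model above, per molecule: draw
an ensemble state, draw adducts conditioned on pairing in that state,
draw detection and mutation type per adduct, superimpose background
errors, emit a full-length read. Defaults are the regime the method
addresses:

| parameter | default | meaning |
| --- | --- | --- |
| unpaired adduct rate | A, C 0.02; U 0.006; G (N1) 0.001 | detected WC-face events per molecule |
| paired adduct rate | 10× lower than unpaired | paired-class rates are not separately measurable in bulk data; the ratio is a configurable assumption |
| N7-G rate | per position, uniform in [0.2, 0.8] | N7 methylation is high-rate, pairing-independent, and heterogeneous across sites; the positional spread (not the mean) is what buries the unfiltered G signal |
| N7-G detection | 0.02 | read-through of N7-G as G→A (1–3% band) |
| N1-G signature | G→C : G→T = 1 : 1 | informative G mutations |
| background substitution / indel | 0.001 / 0.002 per position | enzyme noise floor |

N1-G detection is folded into its adduct rate (0.001 is the *detected*
rate); N7-G keeps rate and detection separate because both numbers are
independently meaningful. At most one event is emitted per position per
read, with adduct signatures taking precedence over background errors,
so every event traces to exactly one cause in the ground truth — this
is what lets the tests verify the filter class-by-class rather than only
in aggregate.

Two-state ensembles (`planted_helix_ensemble`) melt a helix in a
fraction f of molecules. Both strands become unpaired together, which
produces correlated co-modification across the helix — the signal PAIR
analysis detects — and ensemble-average reactivities of ≈ f on the
normalized scale at the helix positions.

What the generator does **not** model: sequencing quality, PCR
duplicates, alignment artifacts, read fragmentation (full-length
molecules by default), local breathing (helices melt as a block),
adduct-induced reverse-transcription drop-off, and sequence-context
biases in modification or detection. Passing tests therefore establish
the correctness and calibration of the algorithms under the stated
generative model, not the field performance of the chemistry.

## Problem sizes used by the test suite

Chosen to make the statistical assertions sharp at desk scale: rate
convergence and filter discrimination use 100k full-length reads over a
149-nt toy RNA (binomial SE small enough for 3-SE checks); the PAIR null
calibration uses 50k reads; planted-helix recovery uses 300k reads per
seed across five seeds, the coverage at which single-molecule duplex
detection becomes reliable; mixture-recovery fits use 5000 draws.

## Known limitations

* The PAIR variant is pinned and testable but is a re-derivation; the
  released single-molecule correlation tools differ in unpublished
  details (phased counting, correction factors, window stepping).
* The dists output uses this package's documented grammar; it is not
  byte-compatible with any folding engine's internal tables, and no
  folding engine is invoked.
* Gamma-mixture fits assume unimodal-per-class reactivity distributions;
  multimodal ensembles (beyond the two-state generator) are not modelled.
* ESI compares experiments only when the likelihood models are trained
  consistently; models fitted on different molecules embed those
  molecules' reactivity scales.
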