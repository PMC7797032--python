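# Methods

## Microhomology model

A DSB at 0-based cut index *c* (counting bases 5′ of the break) is
repaired by MMEJ when two exact repeats flanking the break anneal; the
repair deletes one repeat copy plus everything between the copies.  The
enumerator reports every arm pair with λ ≥ 3 (configurable down to 2)
whose left copy lies entirely 5′ of the break and right copy entirely 3′
(copies may abut the break), so the implied deletion straddles it.  Arm
pairs producing an identical deletion product — nested sub-arms and
placements shifted within a repeat run — are collapsed, keeping the
maximal-λ representative (leftmost on ties).  Coordinates are 0-based,
half-open throughout.

The pattern score is π = 100 · round(e^(−Δ/20), 3) · (λ + GC).  The
3-decimal rounding of the exponential factor *before* multiplication is
deliberate: it reproduces the arithmetic of the original published score,
whose hand-checkable values (444.6, 258.3, 516.6 for the documented
fixtures) are frozen in the tests.  The site-level score is the ratio of
the two largest π.  Conventions where the published description is
silent, fixed here once:

* a single candidate pattern has no competitor; its score ratio is +∞
  (maximal confidence) and classification then depends on ∂ only;
* ties in π rank by smaller ∂, then leftmost arm — output order is
  deterministic;
* no upper bound is imposed on ∂ or Δ beyond the context window;
* both PreMA comparisons are inclusive (score ≥ 1.50, ∂ ≤ 5), and the
  distance presets @3/@4/@5/@6 reuse the same score threshold.

## Nuclease geometry

SpCas9: NGG PAM, blunt cut 3 bp 5′ of the PAM; on the minus strand a
plus-strand `CCN` at *q* implies a plus-strand cut index *q* + 6.
Cas12a: TTTV PAM (V ∈ {A,C,G}); its staggered cut is represented by one
nominal blunt break 18 nt 3′ of the 4-nt PAM — the midpoint of the 18/23
stagger — configurable via `cas12a_offset`.  A reported site needs only
its PAM and cut inside the sequence, not a full protospacer; context
windows (52 bp for microhomology scanning, 60 bp for insertion
predictors, break at the midpoint) are extracted separately and a site
without a full window is skipped and counted.

## Ground-truth labeling

Read pools are consolidated by sequence and ranked by count (ties
lexicographic).  The top read is accepted only when it differs from the
wild type by exactly one contiguous indel with zero mismatches — the
class selected by a global alignment with match +1 / mismatch −50 and gap
penalties 10 (opening) + 4/nt (extension), the defaults of the alignment
routine the original analysis used.  Because that acceptance class has a
closed form (the longest common prefix and suffix must cover the shorter
sequence), the implementation detects it directly and canonicalizes
ambiguous placements leftmost; the scoring-based aligner is retained as
an independent oracle in the test suite.  Junction microhomology of a
deletion is the maximal exact overlap between the deleted segment and
either retained flank, maximized over all placements of the same product
(placement-invariant); ≥ 3 nt defines an MMEJ deletion.  Majority calls
(`is_prema`, `is_sm_insertion`) use the top read's fraction of the whole
consolidated pool with an inclusive 0.50 threshold; wild-type-identical
reads do not occur in processed profiles by construction, so the mutant
pool and the whole pool coincide.  A boolean `genomic` column supports
curating away guides that target artificial constructs; it is input
metadata, not sequence computation.

## MENdel combination

Probability predictors are consumed through an adapter contract
(60 nt window → outcome distribution; probabilities renormalized when
they deviate from 1 by more than 1e−6, sorted descending with a
deterministic tie-break).  The PreMA rule for a distribution: top outcome
probability ≥ 0.50 and the outcome is a deletion with junction
microhomology ≥ 3.  The single-majority insertion rule: top outcome is a
1 bp insertion at probability ≥ 0.50 — any 1 bp insertion is out of
frame, so the inserted base is irrelevant to the frameshift call.
MENdel's frameshift call is (out-of-frame PreMA) OR (majority 1 bp
insertion); with a null adapter it reduces exactly to the
deletion-only caller.  Published external insertion predictors are not
re-implemented or re-trained; tests use a deterministic mock adapter.

## Evaluation

Confusion ratios are exact on integer counts, with 0/0 reported as
undefined (None), never 0.  ROC sweeps place one point per distinct
score plus the limit points; in score-ratio mode the spacing gate (∂ ≤ 5
by default) is held fixed, so the curve is truncated at
`max_sensitivity` — the fraction of positives passing the gate — and the
trapezoidal AUC is computed over the attainable range only and flagged
as truncated.  Stratified splitting rounds the training count per class
(`round(frac · n_class)`), which reproduces a 70–30 split of 5,885
events with 614 positives as exactly 4,120/1,765; the 70–30 ratio is the
default with the fraction configurable.

Moon Rover (logistic regression) and Moon Walker (gradient boosting,
hyperparameters selected by 10-fold cross-validated ROC AUC over a grid
spanning trees {50,150,300,450,600} × depth {2,4,6} × min-node {5,10,20}
× shrinkage {0.01,0.1}; CV ties resolve to the first grid point) consume
two features per site: the competition score and the top-pattern ∂.
Infinite scores are capped at 1e6 and the capped score is then
log-transformed: the score is a ratio on [1, ∞), and without the
transform the capped outliers dominate the linear model's fit; the
transform is monotone, so tree-based results are unchanged.  Desk-scale
runs (tests, the acceptance script) use a single-point grid for Moon
Walker; the full default grid is exposed for larger studies.

The analytic dual-allele bound: with heterogeneous end joining each
allele is out of frame with probability ≈ 2/3 by length randomness, so
unselected dual-allele knockouts occur at (2/3)² = 4/9 < 1/2 under
independent repair of the two alleles — the ceiling that homogeneous
(single-majority) targeting is meant to beat.

## Gene screening

Cut positions within the first 30% of a CDS are screened, with a floor
of 182 bp (150 bp screened + 32 bp upstream context) for short genes;
"30% of the coding sequence" is measured from the start codon, and
context windows may extend past the screened span.  Sites within 30 nt
of either sequence end are skipped and counted as context-deficient.
Frameshift status of a deletion uses the top-ranked pattern only,
consistent with single-majority logic.  A CDS shorter than 182 bp is
reported unscreenable rather than raising.  Splice-site targeting and
combined-allele frameshift estimation are out of scope.

## Synthetic data generator

`plant_mh_sequence` must produce windows where the planted arm pair is
*provably* the only cut-spanning microhomology family.  A uniformly
random 60-mer contains on the order of ten accidental cross-break 3-mer
repeats, so uniform backgrounds would essentially never satisfy
uniqueness.  Backgrounds are therefore drawn from complementary
two-letter alphabets — {A,C} 5′ of the break, {G,T} 3′ of it — which
suppresses cross-break repeats by construction; the enumerator is still
run inside a bounded rejection loop (10,000 attempts) and only windows
where it finds exactly the planted pattern are accepted.  The break sits
at the window midpoint so planted windows serve directly as centered
prediction contexts.

`simulate_repair_pool` distributes multinomial read counts over the
planted MMEJ product, sampled non-MMEJ deletions (junction homology < 3
enforced by rejection, products distinct), and cut-site insertions; the
truth label is derived from the realized counts and the known category
of each product, independently of the alignment pipeline, so
generator/pipeline agreement is a meaningful end-to-end check.
`write_corpus` defaults: 1,000 reads per event; top-read category mix
~54% non-MMEJ deletion / ~31% MMEJ deletion / ~14% 1 bp insertion /
~0.2% longer insertion, emulating the composition of large Cas9 editing
datasets; PreMA prevalence 10.4% of events, the reported rate for
conventional (non-optimized) guide selection; majority events draw their
top-read fraction from U(0.55, 0.80) and sub-majority MMEJ events from
U(0.30, 0.45); 22.5% of 1 bp-insertion-topped events reach the majority
bar.

What the generator does **not** emulate: sequencing error, chimeric
reads, replicate structure, substitution-containing or multi-indel
reads, and — by design — microhomology *competition* (each planted
window contains a single strong family, so a scan of the corpus calls
most planted sites PreMA).  Passing tests therefore demonstrate
correctness of enumeration, scoring, labeling, and plumbing, not
real-data predictive performance, which requires real repair profiles.

## Problem sizes and determinism

Default verification sizes: 200 windows for oracle equivalence, a
1,000-event corpus for label recovery, n = 2,000 for ROC calibration and
baseline rule-recovery, 30 random 700 bp CDSs for the screen — sizes at
which every stochastic check is stable across seeds.  All randomness
flows through `numpy.random.default_rng` seeds; identical seeds give
byte-identical corpora.  Known limitations: the Cas12a cut offset is a
nominal midpoint rather than a validated rule; the canonical events TSV
is the only supported input layout; insertion predictions depend
entirely on the supplied adapter.
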