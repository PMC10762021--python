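# Methods

## Model

The unit of prediction is the capture target (exon).  Exon *i* carries a
chromosome index (1–22, X=23, Y=24), half-open coordinates, and a per-base
read-depth vector standardized by the global mean and standard deviation of
the training corpus (all per-base values over covered targets, zeros
included — the convention is declared, since either choice is defensible)
and left-padded with a −1 sentinel to `max_len`.  The sentinel is applied
after standardization; it is a mask marker, not a depth value, and a boolean
mask keeps it out of attention entirely, so padding content can never
influence a call (asserted to 1e-6 in the tests, and exactly true for the
gradients).

The classifier is a pre-norm transformer encoder with three deliberate
departures from the stock recipe:

- a **chromosome-specific classification token**: one learned H-vector per
  chromosome, the one matching the exon prepended at sequence position 0.
  The head always reads position 0; chromosome identity enters through
  *which* token was placed there.  This gives the model a per-chromosome
  prior (depth distributions differ by chromosome, most obviously for X/Y).
- an **absolute-coordinate positional encoding**: interleaved rows
  sin(loc/10^{9·2j/H}), cos(loc/10^{9·2j/H}), j = 0..H/2−1.  Depth columns
  carry absolute genomic positions spaced linearly from the exon start to
  its end across the unpadded suffix (step 1 when the exon fits whole);
  padded columns continue the same line and are masked; the token column
  carries loc = 0.  The 10⁹ base keeps the lowest frequency non-repeating
  over the ~290 Mb coordinate range, so absolute position is uniquely
  encoded.
- **masked exact softmax attention**: padded key columns receive −∞ logits.
  At ≤1001 tokens exact attention is affordable, better defined than kernel
  approximations, and makes the relevance propagation exact.

Head: two affine layers with a GELU between, hidden width `mlp_hidden`
(default H — the hidden widths are not architecturally constrained and are
simply declared), then softmax over {DEL, DUP, NOCALL}.

The network, its backward pass, Adam, and the cosine learning-rate schedule
are implemented directly in numpy.  Backward passes are hand-derived and
checked against central finite differences in the unit tests (the only
"disagreements" are parameters whose true gradient is exactly zero, e.g.
the key-projection bias, which softmax normalization cancels).

## Training and fine-tuning

Cross-entropy over the three classes (optionally class-weighted — NOCALL
dominates real label distributions), Adam, Xavier-uniform initialization,
cosine annealing from the initial learning rate over the configured epoch
budget with no restarts.  Quoted convergence epoch counts are treated as
fixed budgets for reproducibility.  All shuffling and initialization flow
from one seed; with BLAS pinned to one thread (the test suite and the
reproduction script pin it) runs are bit-reproducible.

Per-exon truth labels come from interval truth sets by the majority-base
rule: the class covering most of the exon's bases wins; no overlap or an
exact tie gives NOCALL.  The same rule projects segment calls onto exons
and assigns consensus truth labels to merged segments, so the three
operations are mutually consistent (a property the tests exercise by
round-tripping exon-resolution call sets through merge → consensus →
intersection).

Fine-tuning is continued training of a trained state on a small labeled
set, recording the base parameters' hash.  Desk-scale defaults: learning
rate 5e-4, batch 16, 5 epochs.  The full-scale regime's published learning
rate (5e-5) presumes corpora of ~10⁶ labeled exons; at the ~10³ exons of
the desk-scale study it leaves training far from convergence inside any
reasonable epoch budget, so the desk configuration uses 1e-3 (base
training) and 5e-4 (fine-tuning).  These are package defaults for the study
sizes shipped here, not recommendations for full corpora.

## No-depth exons and segments

Roughly 20% of targets lack depth in a typical exome.  Each such exon takes
the majority vote of the 3 nearest model-called exons on its chromosome
(interval-midpoint distance; distance ties toward the lower start
coordinate; NOCALL votes count; a 1/1/1 split and any exhausted-candidate
tie resolve to NOCALL; with fewer than 3 candidates the vote runs over
those available).  Imputed records carry a flag and no probabilities, and
imputation never alters existing records.  Segments are maximal runs of
consecutive same-call exons in sorted target order — adjacency in the
target list, not a genomic distance criterion, matching exon-resolution
callers; an optional gap cap is exposed.

## The simulator

`simulation` generates the three files the pipeline consumes.  What it
emulates, per design choice:

- **Capture design**: per chromosome, log-normal exon lengths (median
  ~150 bp, clipped) separated by log-normal gaps; coordinates start at
  20 kb, inside the encodable coordinate range.
- **Depth**: per-base counts with a gamma-Poisson (negative-binomial)
  hierarchy — NB dispersion `r` (default 10) captures the overdispersion of
  real WES coverage; Poisson is the r→∞ limit.  The latent gamma rate is
  smoothed with a short moving average (window 5; 1 disables) so depth has
  the short-range autocorrelation of real coverage and event boundaries
  appear as sharp steps rather than isolated noise.
- **Events**: DEL/DUP initiate per exon (defaults 0.05 each) and span a
  geometric number of consecutive exons (mean 2).  Heterozygous multipliers
  0.5/1.5; a configurable fraction (default 0.1) is homozygous (0.0/2.0).
  Each event breakpoint falls uniformly *inside* its boundary exon with
  probability `partial_boundary_fraction` (default 0.5) — real breakpoints
  do not respect probe boundaries, and the resulting intra-exon steps both
  exercise the majority-base labeling rule and give the model a reason to
  attend to depth shifts.
- **Missingness**: a fraction of exons (default 0.2) is emitted with no
  depth rows.
- **Cohorts**: samples share the capture design; a configurable fraction of
  the event rate is shared across samples, the rest private.
- Truth labels are derived from the event intervals by the same
  majority-base rule used for real truth sets, so label/interval
  consistency holds by construction.

What it does **not** emulate: GC and mappability bias, capture-efficiency
variation between probes and batches, reference artefacts, read-level error
profiles, allele-specific signals, tumor purity/subclonality.  Passing the
desk-scale study therefore shows that the architecture, optimization and
evaluation machinery work end to end on an idealized but overdispersed,
gapped, partially-missing depth signal — not that the model reaches any
particular accuracy on real exomes.

## The desk-scale study

The package's principal end-to-end check trains the scaled-down model
(H=32, L=2, 4 heads, max_len=200) on one simulated exome of a two-sample
cohort (2 chromosomes × 1000 exons, coverage 50×, dispersion 10, DEL/DUP
rates 0.05, multipliers 0.5/1.5, exon lengths 60–200 bp so every exon fits
the scaled max_len; cohort seed 7) and scores DEL/DUP macro-F1 on the
held-out exome's encodable exons: **0.948** (the imputation-inclusive
pipeline number over all 2000 targets is also reported by the reproduction
script).  Problem sizes were chosen so the whole study runs in minutes on
one CPU.

Two fine-tuning experiments probe transfer:

- **Somatic analogue** (duplications at 3.0×, initiation 0.15): the base
  model *already transfers essentially perfectly* — a 3.0× duplication is a
  strictly stronger signal than anything harder in training, and held-out
  macro-F1 on this regime matches the base regime.  Its residual errors are
  majority-base label ambiguities at intra-exon breakpoints, which no
  100-exon fine-tune can resolve; measured fine-tuning deltas are therefore
  ≈0 to slightly negative (recall rises, precision pays).  The reproduction
  script reports the measured delta rather than asserting an improvement
  that the study conditions cannot produce.
- **Weak deletions** (0.7×, never seen in training): here a genuine
  transfer gap exists — base DEL recall drops to ~0.76 — and fine-tuning on
  50 regime exons reliably shifts the decision distribution toward the new
  regime: held-out DEL recall rises by +0.02 to +0.16 across fine-tune-set
  draws (the precision-for-recall trade the somatic fine-tune of the
  full-scale system also exhibits).  The *net* macro-F1 delta at this
  fine-tune size is draw-dependent noise around zero, because the recall
  gain spends precision on the same ambiguous boundary exons.  The test
  suite therefore asserts the recall shift (robust across draws); the
  reproduction script reports both the recall gain and the macro-F1 delta.

## Explainability

`explain.relevance_map` implements gradient-weighted attention relevance
for the exact-softmax backend: per block, the attention map is weighted
elementwise by its gradient with respect to the target-class logit,
negative parts are clipped, heads are averaged *after* weighting (plain
head averages are noisy), and block maps accumulate through
R ← R + Ā·R from the identity.  The token row over depth columns, pads
zeroed and max-normalized, is the per-base relevance.  The method is
class-targeted; the target defaults to the predicted call.

On step-change exons the maps correctly emphasize the event side of the
breakpoint (2–3× the mean relevance of the normal side for duplications),
but the arg-maximum sits near the center of the event's evidence mass, not
at the edge: the desk-scale model solves majority-base classification by
estimating how many bases are affected, so nothing pushes its attention to
sharpen at the breakpoint itself.  Breakpoint localization by relevance
argmax is accordingly weak (~30% of cases within ±25 bp over seeded step
fixtures) and is reported, not asserted.  Treat the maps as evidence
highlighting, not as a breakpoint caller.

## Numerical and degenerate-input choices

- float32 parameters and activations; positional encodings computed in
  float64 before casting (coordinates up to 2.9e8 need the mantissa).
- Masked attention uses −∞ additive logits; the token column is never
  masked, so no softmax row is empty.
- Zero-denominator metrics report 0 with a warning, never NaN, so reports
  stay comparable; the negative universe for NPA/NPV is the evaluated
  sample's target list (one-vs-rest per class, macro-averaged).
- Exons longer than `max_len` keep their nonzero-depth positions in
  genomic order when those number < `max_len`; otherwise they join the
  no-depth exons and are imputed.  All-zero vectors are never encoded.
- Argmax ties in prediction resolve toward DEL (first class); vote and
  coverage ties resolve to NOCALL (conservative).
- Copy number 2 discretizes to NOCALL and is dropped from truth interval
  sets.
- Unknown contigs (chrM, alts) are skipped with a log count, not fatal.

## Known limitations

- The simulator's idealizations listed above; in particular there is no
  between-sample normalization machinery because the simulated cohort has
  no batch structure.
- Single-sample training at desk scale: standardization statistics come
  from one simulated sample, not a corpus.
- The 3-NN vote imputes isolated single-exon events poorly by construction
  (their neighbours are NOCALL); this bounds pipeline-level recall below
  classifier-level recall at the default 20% missingness.
- Kernel/low-rank attention is not implemented; sequences are capped at
  `max_len` ≤ ~1000 in practice.
- Relevance maps localize events, not breakpoints (see above).
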