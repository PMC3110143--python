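# Methods

## Model

A candidate mature miRNA is a placement on one arm of a folded stem-loop.
The classifier sees each candidate as a (ppri-miRNA, pre-miRNA, miRNA)
triple: the ppri-miRNA is the whole folded fragment (precursor plus
whatever flanking sequence the record or window carries), the pre-miRNA is
derived geometrically from the placement, and the miRNA is the placement
itself. Relative to the placement the hairpin decomposes into Basal
Segment, Lower Stem, Upper Stem, Top Stem and Terminal Loop; only the
Upper Stem and Terminal Loop are guaranteed to exist.

Assumptions: a pre-miRNA lives in a *single* stem-loop (multibranched
"budding" structures are excluded, both in training and scanning); folding
is deterministic MFE folding (no suboptimal ensemble, no pseudoknots); the
sense strand is scanned unless `--both-strands` is given.

### Coordinates and hairpin geometry

Everything internal is 0-based half-open; GFF3/TSV output is 1-based
inclusive. A hairpin's `arm5`/`arm3` are everything 5′/3′ of the terminal
loop within its span, so `arm5 ∪ loop ∪ arm3 = span` holds exactly and the
basal segment (the unpaired run flanking the outermost stem pair) is part
of the span. Unpaired runs between sibling stems in a multiloop or the
exterior loop are split at their midpoint, so sibling hairpin spans tile
without overlap.

The stem cap is 60 **pair levels**: a deeper stem is trimmed by discarding
pairs at the base (the trimmed region leaves the span). This stops genome
context from growing arbitrary basal duplexes under a real precursor. The
alternative reading of the cap (60 nt per strand) would trim real
precursors and was rejected.

The pre-miRNA of a placement runs from the loop-distal end of the mature,
across the terminal loop, to the partner of that end on the opposite arm,
extended by 2 nt on the 3′ side (the Drosha 3′ overhang), clipped to the
span. A base whose partner lies outside the pre-miRNA counts as
single-stranded for the overhang, since it would be single-stranded in the
excised product.

## Feature catalog

70 parameter specs in five categories; 53 are SVM-eligible. Ineligible
are (a) descriptive/text parameters and (b) every ppri-miRNA-scope
parameter, because random-start decoys share the positive's ppri-miRNA
byte-for-byte, so those values carry no label signal. The categorical
first base is one-hot encoded into four individually selectable binary
columns.

Conventions that needed a decision:

* **Component length** is the total nucleotide count over both sides of
  the component. Empty components yield the *undefined marker*, not 0;
  the scaler maps undefined to the component-absent code −1.
* **miRNA-scope structure statistics** run along the mature's own strand
  (unpaired counts are per-strand); G·U wobbles count each pair once.
* **pre/ppri duplex statistics** (unpaired counts/rate, wobbles, internal
  loops) exclude the terminal loop: they describe the duplex, and a loop
  contributes unpaired bases that say nothing about duplex quality.
* **pre_mfe** is the free energy of the fragment structure restricted to
  the pre-miRNA interval, evaluated thermodynamically (RNAeval-equivalent)
  rather than refolding the subsequence: deterministic, consistent with
  the context fold, and far cheaper per candidate.

The catalog is config-serializable, so alternative reconstructions are
drop-in; models record the catalog version they were trained with.

## Folding backends

Feature values depend on the folder, so each model bundle pins a backend
id (name + version). Three backends share one contract (same sequence +
same backend → same dot-bracket): in-process ViennaRNA bindings (default),
an `RNAfold`/`RNAeval` subprocess pair, and a generic external backend for
CT-format folders. Temperature/ionic settings are the folder's defaults.

## Training

* **Range filter**: per-parameter closed windows at the 0.1/99.9 empirical
  percentiles (linear interpolation between order statistics — recorded in
  the bundle) of the *positive* training values, plus the hard override
  MFE(ppri) < −20 kcal/mol. With linear interpolation the window excludes
  at most the smallest and largest of n values, so the per-parameter
  self-pass rate is ≥ (n−2)/n. Windows are fitted by default only on
  candidate-scope parameters (miRNA, pre-miRNA, upper/top stem, overhang):
  context-scope sizes (lower stem, basal segment, ppri statistics) measure
  how the *surroundings* folded and differ systematically between
  standalone precursor records and genome fragments — windows on them veto
  genuine hits in genome scans. Undefined values always pass (absence is
  legal).
* **Scaling**: per-parameter min–max to [−1, 1] on the training data;
  test-time values are clipped; undefined maps to −1. The inverse
  transform round-trips within 1e-9.
* **SVM**: RBF kernel, grid search over C ∈ {2⁻⁵…2¹⁵}, γ ∈ {2⁻¹⁵…2³}
  (step 2²) by stratified k-fold CV accuracy, ties toward smaller C then
  smaller γ, refit on all data. No class weights — the level mechanism
  (1:k positives:decoys, k = 1…20) is the imbalance treatment. Bundles
  store support vectors/coefficients in JSON and evaluate their own
  decision function, so prediction needs no training state.
* **Greedy chain selection**: stage 1 scores every parameter alone
  (averaged over three positive/negative subset pairings); the best `beam`
  (default 10) seed chains grow by one parameter per stage until the pool
  is exhausted, emitting the accuracy-versus-length curve. Scoring uses a
  default SVM (C = 1, γ = scale) with unshuffled stratified folds so the
  search is deterministic; ties keep the lexicographically smallest chain,
  and chains that are permutations of one set are recognized as exact
  ties. The curve is reported, never assumed monotone. `max_len` can stop
  the search early when only chain prefixes are needed.

## Synthetic data

`HairpinRecipe` emulates a miRBase-like record: a GC-biased 5′ arm
(30–45 nt), a reverse-complement 3′ arm perturbed by per-position
mismatches (0.08) and small bulges (0.03), an AU-rich terminal loop
(4–10 nt), flanks of 10–30 nt, and a 20–24-nt mature planted ending 2 nt
below the loop on a random arm. Each record is verified to fold into a
single stem-loop hosting its mature (bounded retries). Decoys inherit
none of the planted geometry, which is what makes the corpus separable —
the separation handle is the placement geometry, exactly as in real
Microprocessor processing.

Genomes embed such precursors at uniform non-overlapping positions in
background sampled from a second-order Markov model of a *shuffled*
precursor concatenation: composition is preserved while long-range
self-complementarity (accidental strong hairpins) is suppressed, keeping
the false-positive baseline measurable.

What the generator does **not** emulate: conserved sequence motifs,
family structure, multi-mature precursors in one corpus record (supported
by the corpus module but not generated), genome-scale isochore/GC
variation, and the full structural diversity of real miRBase clades.
Passing tests therefore demonstrate that the pipeline recovers planted
Microprocessor-like geometry against matched decoys and background — not
real-data accuracy, which additionally depends on annotation quality and
folding-backend agreement with the original study.

## Problem sizes and numerical choices

The reference study corpus is 200 positives at level 1; the test suite
also uses a 60-positive corpus for fast checks and 1000 positives where
percentile guarantees need n ≥ 1000. Genome scans in tests/acceptance use
12–20 kb with 5–8 plants. Selection recovery uses 3 × (50+50) synthetic
tabular sets with a pool of 40 features. These sizes keep a full run on
one CPU within a few minutes while leaving every measured property far
from its threshold.

Degenerate inputs: homopolymers fold to nothing and yield no hairpins;
placements without a paired base are rejected as unplaceable; constant
parameters give degenerate windows [v, v] and scale to 0; single-class
datasets and k larger than a class are errors, not silent misbehavior.
Duplicate placements from overlapping windows merge keeping the higher
score; region consolidation is single-linkage on strict interval overlap
and is order-invariant.

## Known limitations

* Absolute feature values are backend-dependent; a bundle must be used
  with the backend it was trained with (the predictor warns otherwise).
* The range filter assumes the training corpus spans the deployment
  distribution; narrow corpora give narrow windows and lower recall.
* Reverse-strand scanning folds the full reverse complement rather than
  per-window reverse complements, which doubles fold time when enabled.
* The geometric pre-miRNA is an approximation of Microprocessor cleavage;
  no attempt is made to model Drosha/DGCR8 sequence determinants beyond
  the catalog features.
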