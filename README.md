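# mirsweep

**mirsweep** scans DNA/RNA sequences of any length — up to whole genomes —
for the *most probable mature-miRNA coding regions*, using a support vector
machine trained on structural, sequence and stability properties of
precursor hairpins. It is aimed at small-RNA researchers who want a
screening step before (or alongside) high-throughput sequencing: given a
genome fragment, it reports where a mature miRNA is most likely to be
excised, not just whether a hairpin exists.

## How it works

A pri-miRNA is modelled as a single stem-loop with five components: Basal
Segment, Lower Stem, Upper Stem (the duplex spanned by the mature), Top
Stem and Terminal Loop. For a query sequence the pipeline is:

1. **Window** sequences longer than 500 nt into 500-nt fragments
   overlapping by 200 nt (pre-miRNAs are almost always < 200 nt, so each
   appears intact in at least one fragment).
2. **Fold** each fragment to its minimum-free-energy structure (ViennaRNA
   by default; the folding backend is pluggable and pinned per model) and
   collect every single stem-loop, capping stems at 60 base-pair levels by
   trimming unstable basal pairing.
3. **Enumerate** every mature placement of length 18–26 nt on either arm,
   sliding by 1 nt, and derive each placement's pre-miRNA geometrically
   (across the loop to the partner of the loop-distal end, plus the 2-nt
   Drosha 3′ overhang).
4. **Featurize** each (ppri-miRNA, pre-miRNA, miRNA) triple: lengths,
   paired-base counts, MFE, A/C/G/U and GC contents, first base, unpaired
   counts and rates, G·U wobbles, internal loops and the 3′ overhang, per
   scope and per component.
5. **Filter and classify**: a candidate must fall inside per-parameter
   windows taken at the 0.1/99.9 percentiles of the positive training
   values (with the hard constraint MFE(ppri) < −20 kcal/mol) and then
   score positive with an RBF-kernel SVM
   `f(x) = Σᵢ αᵢ yᵢ exp(−γ‖x − xᵢ‖²) + b`, trained on annotated precursors
   (positives) versus *random-start* decoys — the same precursor with the
   mature start shifted ≥ 5 nt (negatives), at a 1:k ("level") ratio.
6. **Consolidate** overlapping positive placements into coding regions,
   reported as GFF3 with support counts and best scores.

Training utilities include stratified cross-validation, the
LIBSVM-recommended (C, γ) grid search, and a beam-searched greedy
feature-chain selection that reproduces the accuracy-versus-chain-length
analysis used to pick a compact parameter subset.

Because retraining against real annotation requires a miRBase download,
the package ships a synthetic-precursor generator (`mirsweep.simulate`)
that emulates miRBase-like records and planted genomes, so every component
is trainable and testable offline.

## Worked example

```bash
python examples/scan_genome.py
```

trains a model on a synthetic corpus, plants five precursors in a 12-kb
synthetic genome and scans it:

```
310 placements passed the range filter -> 10 coding regions

planted mature   1229-1251   -> [1226-1256] 5p n=31 score=1.75
planted mature   6001-6021   -> [5996-6025] 3p n=33 score=2.02
planted mature   6729-6749   -> [6725-6755] 3p n=29 score=2.30
planted mature   7727-7751   -> [7722-7752] 3p n=32 score=2.28
planted mature   8161-8184   -> [8161-8188] 5p n=29 score=1.94

5 regions fall outside the planted truth (background hairpins the model
finds miRNA-like).
```

Each planted mature is recovered by a coding region only a few nucleotides
wider than the truth; `n` counts the overlapping positive placements
supporting the region and `score` is the best SVM decision value among
them. The other examples (`fold_and_segment.py`, `train_and_classify.py`,
`select_parameters.py`) walk through segmentation, training and feature
selection the same way.

The same workflows are available from the shell:

```bash
mirsweep simulate --seed 5 --n-plants 3 --genome-length 6000 --out-prefix sim
mirsweep train --n-pos 100 --seed 5 --out-prefix model
mirsweep predict --model model.model.json --query sim.fasta --out-prefix hits
mirsweep evaluate --model model.model.json --query sim.fasta \
    --truth sim.truth.gff3 --out-prefix eval
```

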