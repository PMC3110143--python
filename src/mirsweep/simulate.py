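"""Synthetic precursor corpora and genomes with planted miRNA signal.

The generator emulates miRBase-like records at realistic scale: a GC-biased
5' arm, a reverse-complement 3' arm perturbed by mismatches and small
bulges, a short terminal loop, and flanking sequence, with the mature
annotation planted a fixed distance below the loop.  Every record is
verified to fold into a single stem-loop hosting its mature under the
pinned backend (bounded retries), so downstream modules can train and test
without any download.  Genomes embed such precursors in low-structure
background sequence sampled from a second-order Markov model of the
shuffled precursor composition.

All randomness flows from one :class:`numpy.random.Generator`; a (recipe,
seed) pair regenerates corpora bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Optional, Sequence as Seq

import numpy as np

from .corpus import (
    AnnotatedPositive,
    LabeledExample,
    LevelDataset,
    NegativePlacement,
    PrecursorRecord,
    assemble_level,
    featurize_negative,
    featurize_positive,
    locate_mature,
    make_random_start_negatives,
)
from .features import default_catalog
from .structure import (
    COMPLEMENT,
    FoldingBackend,
    InputError,
    Interval,
    NucleotideSequence,
    fold,
    get_backend,
)

BASES = "ACGU"


@dataclass(frozen=True)
class HairpinRecipe:
    """Parameter-controlled description of a synthetic precursor family.

    Lengths are uniform-inclusive ranges in nucleotides; rates are per
    position.  ``mature_loop_distance`` is how many stem nucleotides sit
    between the mature's loop-proximal end and the terminal loop, the main
    handle on positive/decoy separability.
    """

    arm_len: tuple[int, int] = (30, 45)
    loop_len: tuple[int, int] = (4, 10)
    flank_len: tuple[int, int] = (10, 30)
    gc_bias: float = 0.5
    mismatch_rate: float = 0.08
    bulge_rate: float = 0.03
    mature_len: tuple[int, int] = (20, 24)
    mature_loop_distance: int = 2
    group: str = "other"
    max_retries: int = 50

    def __post_init__(self) -> None:
        for r in (self.gc_bias, self.mismatch_rate, self.bulge_rate):
            if not 0.0 <= r <= 1.0:
                raise InputError(f"rate {r} outside [0, 1]")
        for lo, hi in (self.arm_len, self.loop_len, self.flank_len, self.mature_len):
            if lo <= 0 or hi < lo:
                raise InputError("length ranges must be positive and ordered")

    def to_manifest(self) -> dict:
        return asdict(self)


def _rand_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U
    return "".join(rng.choice(list(BASES), size=n, p=p))


def _mutate_arm3(arm5: str, recipe: HairpinRecipe, rng: np.random.Generator,
                 protect5: tuple[int, int]) -> str:
    """Reverse complement of the 5' arm with mismatches/bulges injected.

    Positions pairing with the protected 5'-arm window (the mature, when it
    is on the 5' arm) are perturbed at the same rates -- imperfection inside
    the duplex is realistic -- but insertions there are suppressed so the
    planted geometry survives folding more often.
    """
    out = []
    n = len(arm5)
    for k, b in enumerate(reversed(arm5)):
        i5 = n - 1 - k  # 5'-arm position this base pairs with
        comp = COMPLEMENT[b]
        if rng.random() < recipe.mismatch_rate:
            comp = rng.choice([x for x in BASES if x != comp])
        out.append(comp)
        in_protected = protect5[0] <= i5 < protect5[1]
        if not in_protected and rng.random() < recipe.bulge_rate:
            out.append(rng.choice(list(BASES)))
    return "".join(out)


def make_hairpin(
    recipe: HairpinRecipe,
    rng: np.random.Generator,
    backend: Optional[FoldingBackend] = None,
    accession: str = "synt-hp",
) -> AnnotatedPositive:
    """One synthetic precursor record, guaranteed (bounded retries) to fold
    into a single stem-loop hosting its planted mature annotation."""
    if backend is None:
        backend = get_backend("vienna")
    for _ in range(recipe.max_retries):
        arm_n = int(rng.integers(recipe.arm_len[0], recipe.arm_len[1] + 1))
        loop_n = int(rng.integers(recipe.loop_len[0], recipe.loop_len[1] + 1))
        f5 = int(rng.integers(recipe.flank_len[0], recipe.flank_len[1] + 1))
        f3 = int(rng.integers(recipe.flank_len[0], recipe.flank_len[1] + 1))
        m = int(rng.integers(recipe.mature_len[0], recipe.mature_len[1] + 1))
        d = recipe.mature_loop_distance
        if m + d > arm_n:
            continue
        arm = "5p" if rng.random() < 0.5 else "3p"

        arm5 = _rand_seq(arm_n, recipe.gc_bias, rng)
        if arm == "5p":
            protect = (arm_n - d - m, arm_n - d)
        else:
            # mature pairs opposite [d, d+m) of the 3' arm = [arm_n-d-m, arm_n-d) of 5' arm
            protect = (arm_n - d - m, arm_n - d)
        loop = _rand_seq(loop_n, 0.2, rng)  # AU-rich loop folds reliably
        arm3 = _mutate_arm3(arm5, recipe, rng, protect)
        flank5 = _rand_seq(f5, recipe.gc_bias, rng)
        flank3 = _rand_seq(f3, recipe.gc_bias, rng)
        residues = flank5 + arm5 + loop + arm3 + flank3

        if arm == "5p":
            mature = (f5 + arm_n - d - m, f5 + arm_n - d)
        else:
            start3 = f5 + arm_n + loop_n
            mature = (start3 + d, start3 + d + m)

        seq = NucleotideSequence(id=accession, residues=residues)
        record = PrecursorRecord(accession=accession, sequence=seq,
                                 matures=(mature,), group=recipe.group)
        structure = fold(seq, backend, min_length=0)
        ap, reason = locate_mature(structure, seq, mature)
        if ap is None:
            continue
        return AnnotatedPositive(record=record, structure=structure,
                                 hairpin=ap.hairpin, mature=mature, arm=ap.arm)
    raise InputError(
        f"could not generate a clean hairpin in {recipe.max_retries} tries; "
        "recipe too noisy"
    )


def make_labeled_corpus(
    recipe: HairpinRecipe,
    n_pos: int,
    level: int = 1,
    rng: Optional[np.random.Generator] = None,
    backend: Optional[FoldingBackend] = None,
    catalog=None,
    min_shift: int = 5,
) -> tuple[LevelDataset, list[AnnotatedPositive]]:
    """A level-k dataset of featurized synthetic positives and random-start
    decoys drawn from the same records."""
    if n_pos < 20:
        raise InputError("n_pos must be >= 20 for a trainable corpus")
    if rng is None:
        rng = np.random.default_rng()
    if backend is None:
        backend = get_backend("vienna")
    if catalog is None:
        catalog = default_catalog()

    positives: list[LabeledExample] = []
    annotated: list[AnnotatedPositive] = []
    negatives: list[LabeledExample] = []
    for k in range(n_pos):
        ap = make_hairpin(recipe, rng, backend, accession=f"synt-hp-{k:04d}")
        annotated.append(ap)
        positives.append(featurize_positive(ap, catalog=catalog, backend=backend))
        # request a small surplus so assemble_level can sample without shortfall
        decoys = make_random_start_negatives(ap, level + 2, min_shift=min_shift, rng=rng)
        negatives.extend(featurize_negative(d, catalog=catalog, backend=backend)
                         for d in decoys)
    dataset = assemble_level(positives, negatives, level, rng=rng, group=recipe.group)
    return dataset, annotated


def _markov2_background(source: str, n: int, rng: np.random.Generator) -> str:
    """Sample ``n`` nt from a second-order Markov model fitted to a shuffled
    copy of ``source``: preserves composition, suppresses long-range
    self-complementarity and hence accidental strong hairpins."""
    shuffled = "".join(rng.permutation(list(source)))
    idx = {b: i for i, b in enumerate(BASES)}
    counts = np.ones((4, 4, 4))  # +1 smoothing
    for a, b, c in zip(shuffled, shuffled[1:], shuffled[2:]):
        counts[idx[a], idx[b], idx[c]] += 1
    trans = counts / counts.sum(axis=2, keepdims=True)
    out = list(shuffled[:2]) if len(shuffled) >= 2 else ["A", "A"]
    for _ in range(n - 2):
        a, b = idx[out[-2]], idx[out[-1]]
        out.append(BASES[rng.choice(4, p=trans[a, b])])
    return "".join(out[:n])


def make_genome(
    recipe: HairpinRecipe,
    n_plants: int,
    genome_length: int,
    rng: Optional[np.random.Generator] = None,
    backend: Optional[FoldingBackend] = None,
    genome_id: str = "synt-genome",
    min_gap: int = 150,
) -> tuple[NucleotideSequence, list[tuple[str, Interval]], list[AnnotatedPositive]]:
    """Background sequence with planted precursors at recorded positions.

    Returns (genome, truth, planted records) where ``truth`` lists the
    genome-coordinate mature intervals for evaluation.
    """
    if rng is None:
        rng = np.random.default_rng()
    if backend is None:
        backend = get_backend("vienna")

    plants = [
        make_hairpin(recipe, rng, backend, accession=f"{genome_id}-plant-{k}")
        for k in range(n_plants)
    ]
    occupied = sum(len(p.record.sequence) for p in plants)
    if occupied + n_plants * min_gap > genome_length:
        raise InputError(
            f"{n_plants} plants (+gaps) do not fit in {genome_length} nt"
        )

    seed_material = "".join(p.record.sequence.residues for p in plants) if plants else \
        _rand_seq(2000, recipe.gc_bias, rng)
    background = _markov2_background(seed_material, genome_length, rng)

    # draw non-overlapping insertion points uniformly, keeping min_gap spacing
    slots: list[int] = []
    lengths = [len(p.record.sequence) for p in plants]
    for _ in range(200):
        starts = sorted(int(s) for s in rng.integers(0, genome_length - max(lengths, default=1), size=n_plants)) if n_plants else []
        ok = all(b - a >= lengths[i] + min_gap for i, (a, b) in enumerate(zip(starts, starts[1:])))
        if ok and (not starts or starts[-1] + lengths[-1] <= genome_length):
            slots = starts
            break
    else:
        raise InputError("could not place plants without overlap (overcrowded)")

    residues = background
    truth: list[tuple[str, Interval]] = []
    for p, start in zip(plants, slots):
        rec = p.record.sequence.residues
        residues = residues[:start] + rec + residues[start + len(rec):]
        ms, me = p.mature
        truth.append((genome_id, (start + ms, start + me)))
    genome = NucleotideSequence(id=genome_id, residues=residues[:genome_length])
    return genome, truth, plants


def manifest(recipe: HairpinRecipe, seed: int, extra: Optional[dict] = None) -> str:
    doc = {"recipe": recipe.to_manifest(), "seed": seed}
    if extra:
        doc.update(extra)
    return json.dumps(doc, indent=1, sort_keys=True)
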