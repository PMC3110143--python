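"""Genome-scale scanning pipeline.

Long query sequences are cut into overlapping windows (500 nt stepping
300 nt by default) so that every pre-miRNA-sized hairpin appears intact in
at least one fragment.  Each fragment is folded, its single stem-loops are
collected, every plausible mature placement on every arm is enumerated,
featurized, passed through the range filter and scored by the SVM.  Because
the cleavage register cannot be pinned exactly, overlapping positive
placements are consolidated into *most probable miRNA coding regions*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence as Seq

import numpy as np
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve

from .corpus import GROUPS
from .features import FeatureVector, ParameterSpec, compute_features, default_catalog
from .structure import (
    FoldingBackend,
    Hairpin,
    InputError,
    Interval,
    NucleotideSequence,
    PlacementError,
    fold,
    get_backend,
    reverse_complement,
)
from .structure import extract_hairpins
from .training import Metrics, ModelBundle, apply_range_filter, compute_metrics, vectors_to_frame

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 500
DEFAULT_OVERLAP = 200
DEFAULT_LENGTH_RANGE = (18, 26)
MIN_QUERY_LEN = 40


@dataclass(frozen=True)
class CandidatePlacement:
    """One scored mature placement, in parent-sequence coordinates."""

    parent_id: str
    strand: str  # "+" | "-"
    arm: str  # "5p" | "3p"
    mirna: Interval
    premirna: Interval
    features: FeatureVector
    svm_score: float
    passed_filter: bool
    violations: tuple[str, ...] = ()

    @property
    def verdict(self) -> bool:
        return self.passed_filter and self.svm_score > 0


@dataclass(frozen=True)
class CodingRegion:
    """Union of overlapping positive placements on one parent/strand/arm."""

    parent_id: str
    strand: str
    arm: str
    interval: Interval
    n_support: int
    best_score: float
    representative: CandidatePlacement
    members: tuple[CandidatePlacement, ...] = ()


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def split_sequence(
    seq: NucleotideSequence,
    window: int = DEFAULT_WINDOW,
    overlap: int = DEFAULT_OVERLAP,
) -> list[NucleotideSequence]:
    """Overlapping fragments covering the whole sequence.

    Sequences no longer than ``window`` are returned whole; otherwise
    fragments start every ``window - overlap`` nt and the final fragment is
    clipped at the sequence end.
    """
    if not (window > overlap > 0):
        raise InputError("need window > overlap > 0")
    n = len(seq)
    if n <= window:
        return [seq]
    step = window - overlap
    frags = []
    for start in range(0, n, step):
        end = min(start + window, n)
        frags.append(
            NucleotideSequence(id=seq.id, residues=seq.residues[start:end],
                               offset=seq.offset + start)
        )
        if end == n:
            break
    return frags


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(
    h: Hairpin,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    loop_overlap_max: int = 3,
) -> list[tuple[Interval, str]]:
    """Every mature placement on either arm: all lengths in ``length_range``
    sliding by 1 nt, dipping at most ``loop_overlap_max`` nt into the
    terminal loop, never entering the basally-trimmed region, and holding at
    least one paired base."""
    lmin, lmax = length_range
    l0, l1 = h.loop
    sp0, sp1 = h.span
    table = h.structure.pairs
    out: list[tuple[Interval, str]] = []
    for m in range(lmin, lmax + 1):
        # 5' arm: candidate [s, s+m), end may dip <= loop_overlap_max into loop
        for s in range(sp0, min(l0 + loop_overlap_max, l1) - m + 1):
            e = s + m
            if e <= l0 + loop_overlap_max and e <= l1:
                duplex_hi = min(e, l0)
                if any(table[i] is not None for i in range(s, duplex_hi)):
                    out.append(((s, e), "5p"))
        # 3' arm
        for s in range(max(l1 - loop_overlap_max, l0), sp1 - m + 1):
            e = s + m
            if s >= l1 - loop_overlap_max and s >= l0:
                duplex_lo = max(s, l1)
                if any(table[i] is not None for i in range(duplex_lo, e)):
                    out.append(((s, e), "3p"))
    return out


# ---------------------------------------------------------------------------
# Prediction pipeline
# ---------------------------------------------------------------------------

def _scan_fragment(
    frag: NucleotideSequence,
    bundle: ModelBundle,
    backend: FoldingBackend,
    catalog: Seq[ParameterSpec],
    length_range: tuple[int, int],
    loop_overlap_max: int,
    strand: str,
    parent_len: int,
) -> list[CandidatePlacement]:
    structure = fold(frag, backend, min_length=0)
    placements: list[CandidatePlacement] = []
    vectors: list[FeatureVector] = []
    meta: list[tuple[Interval, Interval, str, bool, tuple[str, ...]]] = []
    frag_cache: dict = {}
    for h in extract_hairpins(structure, frag):
        for mirna, arm in enumerate_candidates(h, length_range, loop_overlap_max):
            try:
                fv = compute_features(frag, structure, h, mirna,
                                      catalog=catalog, backend=backend,
                                      cache=frag_cache)
            except PlacementError:
                continue
            ok, violated = apply_range_filter(bundle.range_filter, fv)
            vectors.append(fv)
            meta.append((mirna, fv.premirna, arm, ok, tuple(violated)))
    if not vectors:
        return placements
    scores = bundle.score_vectors(vectors)
    for fv, (mirna, pre, arm, ok, violated), score in zip(vectors, meta, scores):
        s, e = mirna
        ps, pe = pre
        if strand == "+":
            par_mi = (frag.offset + s, frag.offset + e)
            par_pre = (frag.offset + ps, frag.offset + pe)
        else:
            # fragment coordinates are on the reverse complement; map back
            par_mi = (parent_len - (frag.offset + e), parent_len - (frag.offset + s))
            par_pre = (parent_len - (frag.offset + pe), parent_len - (frag.offset + ps))
        placements.append(
            CandidatePlacement(
                parent_id=frag.id,
                strand=strand,
                arm=arm,
                mirna=par_mi,
                premirna=par_pre,
                features=fv,
                svm_score=float(score),
                passed_filter=ok,
                violations=violated,
            )
        )
    return placements


def predict(
    seqs: NucleotideSequence | Seq[NucleotideSequence],
    bundle: ModelBundle,
    backend: Optional[FoldingBackend | str] = None,
    window: int = DEFAULT_WINDOW,
    overlap: int = DEFAULT_OVERLAP,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    loop_overlap_max: int = 3,
    both_strands: bool = False,
    catalog: Optional[Seq[ParameterSpec]] = None,
    keep_all: bool = False,
) -> tuple[list[CandidatePlacement], list[CodingRegion]]:
    """Run the full pipeline on one or more query sequences.

    Returns (placements, coding regions).  Placements are every enumerated
    candidate when ``keep_all`` else only range-filter survivors; regions
    consolidate the positive-verdict placements.  Duplicate placements from
    overlapping fragments keep the higher score.  Deterministic for a fixed
    bundle and backend.
    """
    if isinstance(seqs, NucleotideSequence):
        seqs = [seqs]
    if backend is None:
        backend = get_backend("vienna")
    elif isinstance(backend, str):
        backend = get_backend(backend)
    if backend.id != bundle.backend_id:
        logger.warning("bundle was trained with backend %s but predicting with %s",
                       bundle.backend_id, backend.id)
    if catalog is None:
        catalog = default_catalog()

    all_placements: list[CandidatePlacement] = []
    for seq in seqs:
        if len(seq) < MIN_QUERY_LEN:
            logger.warning("%s: shorter than %d nt, skipped", seq.id, MIN_QUERY_LEN)
            continue
        strands = [("+", seq)]
        if both_strands:
            strands.append(
                ("-", NucleotideSequence(id=seq.id,
                                         residues=reverse_complement(seq.residues)))
            )
        dedup: dict[tuple, CandidatePlacement] = {}
        for strand, sseq in strands:
            for frag in split_sequence(sseq, window, overlap):
                for p in _scan_fragment(frag, bundle, backend, catalog,
                                        length_range, loop_overlap_max,
                                        strand, len(seq)):
                    key = (p.strand, p.arm, p.mirna)
                    old = dedup.get(key)
                    if old is None or p.svm_score > old.svm_score:
                        dedup[key] = p
        placements = sorted(dedup.values(),
                            key=lambda p: (p.strand, p.mirna, p.arm))
        if not keep_all:
            placements = [p for p in placements if p.passed_filter]
        all_placements.extend(placements)

    regions = consolidate_regions([p for p in all_placements if p.verdict])
    return all_placements, regions


def consolidate_regions(placements: Seq[CandidatePlacement]) -> list[CodingRegion]:
    """Single-linkage merge of overlapping positive placements per
    (parent, strand, arm).  Each region's interval is the exact union of its
    members; the result is invariant to input order."""
    by_key: dict[tuple, list[CandidatePlacement]] = {}
    for p in placements:
        by_key.setdefault((p.parent_id, p.strand, p.arm), []).append(p)
    regions: list[CodingRegion] = []
    for (parent, strand, arm), group in sorted(by_key.items()):
        group = sorted(group, key=lambda p: p.mirna)
        cluster: list[CandidatePlacement] = []
        hi = None
        for p in group + [None]:
            if p is not None and (hi is None or p.mirna[0] < hi):
                cluster.append(p)
                hi = p.mirna[1] if hi is None else max(hi, p.mirna[1])
                continue
            if cluster:
                best = max(cluster, key=lambda q: (q.svm_score, -q.mirna[0]))
                regions.append(
                    CodingRegion(
                        parent_id=parent,
                        strand=strand,
                        arm=arm,
                        interval=(min(q.mirna[0] for q in cluster), hi),
                        n_support=len(cluster),
                        best_score=best.svm_score,
                        representative=best,
                        members=tuple(cluster),
                    )
                )
            if p is not None:
                cluster = [p]
                hi = p.mirna[1]
    return regions


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def match_positive(predicted: Interval, truth: Interval, tol: int = 3) -> bool:
    """A prediction matches the truth when each end deviates by <= tol nt."""
    return abs(predicted[0] - truth[0]) <= tol and abs(predicted[1] - truth[1]) <= tol


@dataclass(frozen=True)
class EvaluationResult:
    metrics: Metrics
    roc_fpr: tuple[float, ...]
    roc_tpr: tuple[float, ...]
    auc: Optional[float]
    n_truth: int


def evaluate(
    placements: Seq[CandidatePlacement],
    truths: Seq[tuple[str, Interval]],
    tol: int = 3,
) -> EvaluationResult:
    """Score placements against truth annotations (parent id, interval).

    A placement is a hit when it matches a truth interval within ``tol`` at
    both ends.  Metrics count positive-verdict placements as predictions and
    unmatched truths as false negatives; the ROC sweeps the SVM decision
    threshold over all placements.  With no truths sensitivity is undefined
    (None) and no AUC is reported unless both classes exist.
    """
    truth_by_parent: dict[str, list[Interval]] = {}
    for parent, iv in truths:
        truth_by_parent.setdefault(parent, []).append(tuple(iv))

    hit_flags = []
    matched_truths: set[tuple[str, Interval]] = set()
    for p in placements:
        hit = False
        for iv in truth_by_parent.get(p.parent_id, []):
            if match_positive(p.mirna, iv, tol):
                hit = True
                if p.verdict:
                    matched_truths.add((p.parent_id, iv))
        hit_flags.append(hit)

    tp = sum(1 for p, h in zip(placements, hit_flags) if p.verdict and h)
    fp = sum(1 for p, h in zip(placements, hit_flags) if p.verdict and not h)
    tn = sum(1 for p, h in zip(placements, hit_flags) if not p.verdict and not h)
    fn = sum(1 for parent, iv in truths if (parent, tuple(iv)) not in matched_truths)
    metrics = compute_metrics(tp, tn, fp, fn) if (tp + tn + fp + fn) else None

    y = np.array(hit_flags, dtype=int)
    scores = np.array([p.svm_score for p in placements])
    if len(y) and 0 < y.sum() < len(y):
        fpr, tpr, _ = roc_curve(y, scores)
        roc_auc = float(sk_auc(fpr, tpr))
    else:
        fpr, tpr, roc_auc = np.array([]), np.array([]), None
    return EvaluationResult(
        metrics=metrics,
        roc_fpr=tuple(float(x) for x in fpr),
        roc_tpr=tuple(float(x) for x in tpr),
        auc=roc_auc,
        n_truth=len(truths),
    )
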