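"""Training corpora: precursor records, positive-set filters, decoy negatives.

Positives are experimentally annotated precursor records (miRBase-style):
a partial-pri-miRNA sequence plus mature coordinates and a taxonomy group.
Negatives are *random-start* decoys: the very same precursor sequence with
the putative mature start shifted by at least ``min_shift`` nucleotides on
the same arm, which makes them maximally confusable with the positives.
A level-k dataset pairs every positive with k sampled negatives.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence as Seq

import numpy as np

from .features import FeatureVector, ParameterSpec, compute_features, default_catalog
from .structure import (
    FoldingBackend,
    Hairpin,
    InputError,
    Interval,
    NucleotideSequence,
    PlacementError,
    SecondaryStructure,
    extract_hairpins,
    fold,
    get_backend,
    infer_arm,
    normalize_residues,
)

logger = logging.getLogger(__name__)

GROUPS = ("animal", "plant", "virus", "other")

# configurable kingdom -> group table (miRBase taxonomy heads)
DEFAULT_KINGDOM_TABLE = {
    "Metazoa": "animal",
    "Viridiplantae": "plant",
    "Viruses": "virus",
}


@dataclass(frozen=True)
class PrecursorRecord:
    accession: str
    sequence: NucleotideSequence
    matures: tuple[Interval, ...]
    group: str = "other"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InputError(f"{self.accession}: unknown group {self.group}")
        for s, e in self.matures:
            if not (0 <= s < e <= len(self.sequence)):
                raise InputError(f"{self.accession}: mature {s}-{e} out of bounds")


@dataclass(frozen=True)
class AnnotatedPositive:
    """A kept positive: record + its pinned folding + the hairpin and arm
    hosting one mature annotation."""

    record: PrecursorRecord
    structure: SecondaryStructure
    hairpin: Hairpin
    mature: Interval
    arm: str


@dataclass(frozen=True)
class LabeledExample:
    features: FeatureVector
    label: int  # +1 positive, -1 negative
    accession: str
    shift: int = 0  # decoy start offset from the true start; 0 for positives

    def __post_init__(self) -> None:
        if self.label == -1 and abs(self.shift) < 5:
            raise InputError("negative example with |shift| < 5")


@dataclass(frozen=True)
class LevelDataset:
    level: int
    group: str
    positives: tuple[LabeledExample, ...]
    negatives: tuple[LabeledExample, ...]

    def __post_init__(self) -> None:
        if not (1 <= self.level <= 20):
            raise InputError(f"level {self.level} outside 1..20")
        if len(self.negatives) != self.level * len(self.positives):
            raise InputError(
                f"level {self.level}: {len(self.negatives)} negatives for "
                f"{len(self.positives)} positives"
            )

    @property
    def examples(self) -> tuple[LabeledExample, ...]:
        return self.positives + self.negatives


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def map_kingdom(taxonomy: str, table: Optional[dict] = None) -> str:
    table = table or DEFAULT_KINGDOM_TABLE
    for kingdom, group in table.items():
        if kingdom.lower() in taxonomy.lower():
            return group
    return "other"


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


_MATURE_RE = re.compile(r"mature=(\d+)-(\d+)")
_GROUP_RE = re.compile(r"group=(\w+)")


def load_records(path, format: str = "annotated-fasta",
                 kingdom_table: Optional[dict] = None) -> list[PrecursorRecord]:
    """Load precursor records with mature annotations.

    Formats: ``annotated-fasta`` (mature coordinates 1-based inclusive in the
    description: ``>acc group=animal mature=17-38 mature=50-71``),
    ``tsv`` (columns accession, sequence, mature_start, mature_end, group;
    one row per mature), and ``mirbase-dat`` (EMBL-style flat file with
    ``FT   miRNA   s..e`` features and ``OC`` taxonomy lines).
    Records with out-of-bounds coordinates are rejected and logged.
    """
    if format == "annotated-fasta":
        raw = _load_annotated_fasta(path)
    elif format == "tsv":
        raw = _load_tsv(path)
    elif format == "mirbase-dat":
        raw = _load_mirbase_dat(path, kingdom_table)
    else:
        raise InputError(f"unknown corpus format {format!r}")

    records = []
    for acc, seq_raw, matures, group in raw:
        try:
            seq = NucleotideSequence.from_raw(acc, seq_raw)
            records.append(
                PrecursorRecord(accession=acc, sequence=seq,
                                matures=tuple(matures), group=group)
            )
        except InputError as exc:
            logger.warning("rejected record %s: %s", acc, exc)
    return records


def _load_annotated_fasta(path):
    out = []
    acc = None
    desc = ""
    chunks: list[str] = []

    def flush():
        if acc is None:
            return
        matures = [(int(a) - 1, int(b)) for a, b in _MATURE_RE.findall(desc)]
        m = _GROUP_RE.search(desc)
        out.append((acc, "".join(chunks), matures, m.group(1) if m else "other"))

    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                acc = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line)
        flush()
    return out


def _load_tsv(path):
    grouped: dict[str, list] = {}
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: k for k, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                continue
            acc = f[idx["accession"]]
            entry = grouped.setdefault(acc, [f[idx["sequence"]], [], f[idx.get("group", -1)] if "group" in idx else "other"])
            entry[1].append((int(f[idx["mature_start"]]) - 1, int(f[idx["mature_end"]])))
    return [(acc, seq, matures, group) for acc, (seq, matures, group) in grouped.items()]


def _load_mirbase_dat(path, kingdom_table):
    out = []
    with _open_text(path) as fh:
        acc = None
        taxonomy = ""
        matures: list[Interval] = []
        seq_chunks: list[str] = []
        in_seq = False
        for line in fh:
            if line.startswith("ID"):
                acc = line.split()[1]
                taxonomy, matures, seq_chunks, in_seq = "", [], [], False
            elif line.startswith("OC"):
                taxonomy += line[2:].strip()
            elif line.startswith("FT"):
                m = re.search(r"miRNA\s+(\d+)\.\.(\d+)", line)
                if m:
                    matures.append((int(m.group(1)) - 1, int(m.group(2))))
            elif line.startswith("SQ"):
                in_seq = True
            elif line.startswith("//"):
                if acc:
                    seq = re.sub(r"[\d\s/]", "", "".join(seq_chunks))
                    out.append((acc, seq, matures, map_kingdom(taxonomy, kingdom_table)))
                acc, in_seq = None, False
            elif in_seq:
                seq_chunks.append(line)
    return out


# ---------------------------------------------------------------------------
# Positive filtering
# ---------------------------------------------------------------------------

def locate_mature(
    structure: SecondaryStructure,
    sequence: NucleotideSequence,
    mature: Interval,
    loop_overlap_max: int = 3,
    max_stem: int = 60,
) -> tuple[Optional[AnnotatedPositive], Optional[str]]:
    """Find the single stem-loop hosting a mature annotation, or a rejection
    reason ('budding_stems', 'mature_in_terminal_loop', 'mature_unpaired')."""
    s, e = mature
    hairpins = extract_hairpins(structure, sequence, max_stem=max_stem)
    reason = "budding_stems"
    for h in hairpins:
        if not (h.span[0] <= s and e <= h.span[1]):
            continue
        l0, l1 = h.loop
        overlap = max(0, min(e, l1) - max(s, l0))
        if overlap > loop_overlap_max:
            return None, "mature_in_terminal_loop"
        try:
            arm = infer_arm(h, mature)
        except PlacementError:
            return None, "mature_in_terminal_loop"
        duplex = (s, min(e, l0)) if arm == "5p" else (max(s, l1), e)
        if not any(structure.pairs[i] is not None for i in range(*duplex)):
            return None, "mature_unpaired"
        return AnnotatedPositive(record=None, structure=structure, hairpin=h,
                                 mature=mature, arm=arm), None
    return None, reason


def filter_positives(
    records: Seq[PrecursorRecord],
    backend: FoldingBackend | str = "vienna",
    loop_overlap_max: int = 3,
    max_stem: int = 60,
) -> tuple[list[AnnotatedPositive], list[tuple[PrecursorRecord, Interval, str]]]:
    """Refold every record with the pinned backend and keep matures that sit
    on a single stem-loop outside the terminal loop.

    Each mature annotation yields an independent positive.  Returns
    (kept, rejected-with-reasons); idempotent on the kept set.
    """
    if isinstance(backend, str):
        backend = get_backend(backend)
    kept: list[AnnotatedPositive] = []
    rejected: list[tuple[PrecursorRecord, Interval, str]] = []
    for rec in records:
        try:
            structure = fold(rec.sequence, backend, min_length=0)
        except Exception as exc:  # folding failure: reject, keep going
            logger.warning("fold failed for %s: %s", rec.accession, exc)
            for mat in rec.matures:
                rejected.append((rec, mat, "fold_failed"))
            continue
        for mat in rec.matures:
            ap, reason = locate_mature(structure, rec.sequence, mat,
                                       loop_overlap_max, max_stem)
            if ap is None:
                rejected.append((rec, mat, reason))
            else:
                kept.append(
                    AnnotatedPositive(record=rec, structure=structure,
                                      hairpin=ap.hairpin, mature=mat, arm=ap.arm)
                )
    return kept, rejected


# ---------------------------------------------------------------------------
# Random-start negatives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NegativePlacement:
    positive: AnnotatedPositive
    mirna: Interval
    shift: int


def admissible_negative_starts(pos: AnnotatedPositive, min_shift: int = 5,
                               loop_overlap_max: int = 3) -> list[int]:
    """Every start position for a same-length decoy mature on the same arm:
    at least ``min_shift`` from the true start, inside the hairpin span, with
    a legal arm placement and at least one paired base."""
    s, e = pos.mature
    m = e - s
    h = pos.hairpin
    l0, l1 = h.loop
    table = pos.structure.pairs
    starts = []
    if pos.arm == "5p":
        lo, hi = h.span[0], l0 + loop_overlap_max - m  # end may dip <=3 nt into loop
        hi = min(hi, l1 - m)
    else:
        lo, hi = max(l1 - loop_overlap_max, l0), h.span[1] - m
    for sprime in range(lo, hi + 1):
        if abs(sprime - s) < min_shift:
            continue
        eprime = sprime + m
        if sprime < h.span[0] or eprime > h.span[1]:
            continue
        duplex = (sprime, min(eprime, l0)) if pos.arm == "5p" else (max(sprime, l1), eprime)
        if duplex[0] >= duplex[1]:
            continue
        if not any(table[i] is not None for i in range(*duplex)):
            continue
        starts.append(sprime)
    return starts


def make_random_start_negatives(
    pos: AnnotatedPositive,
    n: int,
    min_shift: int = 5,
    rng: Optional[np.random.Generator] = None,
    loop_overlap_max: int = 3,
) -> list[NegativePlacement]:
    """Draw up to ``n`` distinct decoy placements uniformly from the
    admissible starts.  Fewer than ``n`` are returned (and logged) when the
    precursor is too short to host enough decoys."""
    if min_shift < 1:
        raise InputError("min_shift must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    starts = admissible_negative_starts(pos, min_shift, loop_overlap_max)
    if not starts:
        logger.warning("%s: no admissible decoy start", pos.record.accession)
        return []
    k = min(n, len(starts))
    if k < n:
        logger.warning("%s: only %d of %d decoys possible", pos.record.accession, k, n)
    chosen = rng.choice(len(starts), size=k, replace=False)
    m = pos.mature[1] - pos.mature[0]
    out = []
    for idx in sorted(int(i) for i in chosen):
        sprime = starts[idx]
        out.append(NegativePlacement(positive=pos, mirna=(sprime, sprime + m),
                                     shift=sprime - pos.mature[0]))
    return out


# ---------------------------------------------------------------------------
# Featurization and level assembly
# ---------------------------------------------------------------------------

def featurize_positive(pos: AnnotatedPositive, catalog=None, backend=None) -> LabeledExample:
    fv = compute_features(pos.record.sequence, pos.structure, pos.hairpin,
                          pos.mature, catalog=catalog, backend=backend)
    return LabeledExample(features=fv, label=1, accession=pos.record.accession, shift=0)


def featurize_negative(neg: NegativePlacement, catalog=None, backend=None) -> LabeledExample:
    pos = neg.positive
    fv = compute_features(pos.record.sequence, pos.structure, pos.hairpin,
                          neg.mirna, catalog=catalog, backend=backend)
    return LabeledExample(features=fv, label=-1, accession=pos.record.accession,
                          shift=neg.shift)


def assemble_level(
    positives: Seq[LabeledExample],
    negatives: Seq[LabeledExample],
    level: int,
    rng: Optional[np.random.Generator] = None,
    group: str = "other",
) -> LevelDataset:
    """Sample level x |positives| negatives without replacement and shuffle
    deterministically under ``rng``."""
    if rng is None:
        rng = np.random.default_rng()
    need = level * len(positives)
    if len(negatives) < need:
        raise InputError(
            f"insufficient negatives: need {need}, have {len(negatives)} "
            f"(shortfall {need - len(negatives)})"
        )
    idx = rng.choice(len(negatives), size=need, replace=False)
    chosen = tuple(negatives[int(i)] for i in idx)
    pos_order = rng.permutation(len(positives))
    return LevelDataset(
        level=level,
        group=group,
        positives=tuple(positives[int(i)] for i in pos_order),
        negatives=chosen,
    )
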