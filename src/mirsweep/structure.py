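"""RNA secondary structure: folding backends, hairpin detection and segmentation.

A candidate pre-miRNA lives inside a *hairpin*: a single stem-loop with no
multibranching ("budding stems").  Relative to a mature-miRNA placement the
hairpin decomposes into five components -- Basal Segment, Lower Stem, Upper
Stem, Top Stem and Terminal Loop -- which drive the feature catalog.

Coordinates are 0-based half-open throughout; 1-based inclusive coordinates
appear only in user-facing writers (GFF3/TSV).
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from abc import ABC, abstractmethod
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

Interval = tuple[int, int]

RNA_ALPHABET = frozenset("ACGU")
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
# canonical pairs accepted by thermodynamic folders (Watson-Crick + wobble)
CANONICAL_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


class InputError(ValueError):
    """Malformed user input (bad residues, inconsistent lengths...)."""


class ConfigurationError(ValueError):
    """Unknown backend or invalid configuration."""


class PlacementError(ValueError):
    """A mature-miRNA interval that does not sit on a hairpin arm."""


def normalize_residues(raw: str) -> str:
    """Uppercase and map DNA T to RNA U; reject anything outside {A,C,G,U}."""
    res = raw.upper().replace("T", "U")
    bad = set(res) - RNA_ALPHABET
    if bad:
        raise InputError(f"residues outside A/C/G/U(T) alphabet: {sorted(bad)}")
    if not res:
        raise InputError("empty sequence")
    return res


def reverse_complement(residues: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(residues))


@dataclass(frozen=True)
class NucleotideSequence:
    """A (fragment of a) query or precursor sequence, normalized to RNA.

    ``offset`` is the 0-based position of this fragment within its parent
    sequence so fragment-local coordinates can be mapped back.
    ``original`` keeps the as-ingested residues for output echo.
    """

    id: str
    residues: str
    offset: int = 0
    original: Optional[str] = None

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise InputError("offset must be >= 0")
        if set(self.residues) - RNA_ALPHABET or not self.residues:
            raise InputError(f"{self.id}: residues must be non-empty A/C/G/U")

    @classmethod
    def from_raw(cls, id: str, raw: str, offset: int = 0) -> "NucleotideSequence":
        return cls(id=id, residues=normalize_residues(raw), offset=offset, original=raw)

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# Secondary structure and pair tables
# ---------------------------------------------------------------------------

def pair_table(dotbracket: str) -> tuple[Optional[int], ...]:
    """Pair table for a nested (pseudoknot-free) dot-bracket string.

    table[i] is the partner of i, or None if unpaired.
    """
    stack: list[int] = []
    table: list[Optional[int]] = [None] * len(dotbracket)
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise InputError(f"unbalanced bracket at {i}")
            j = stack.pop()
            table[j], table[i] = i, j
        elif c != ".":
            raise InputError(f"illegal structure character {c!r} at {i}")
    if stack:
        raise InputError("unbalanced dot-bracket: unclosed '('")
    return tuple(table)


@dataclass(frozen=True)
class SecondaryStructure:
    """MFE nested structure of one sequence: dot-bracket, pair table, energy."""

    dotbracket: str
    pairs: tuple[Optional[int], ...]
    mfe: float

    @classmethod
    def from_dotbracket(cls, dotbracket: str, mfe: float = 0.0) -> "SecondaryStructure":
        return cls(dotbracket=dotbracket, pairs=pair_table(dotbracket), mfe=mfe)

    def __post_init__(self) -> None:
        if len(self.dotbracket) != len(self.pairs):
            raise InputError("dot-bracket and pair table length mismatch")

    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pairs) if j is not None and j > i)


# ---------------------------------------------------------------------------
# Folding backends
# ---------------------------------------------------------------------------

class FoldingBackend(ABC):
    """One MFE folder behind one contract: identical sequence + backend id
    (name + version) must give an identical dot-bracket.  Feature values
    depend on the folder, so a trained model pins the backend id."""

    name: str = "abstract"

    @property
    def id(self) -> str:
        return f"{self.name}-{self.version()}"

    @abstractmethod
    def version(self) -> str: ...

    @abstractmethod
    def fold_residues(self, residues: str) -> tuple[str, float]:
        """Return (dot-bracket, MFE in kcal/mol)."""

    def energy(self, residues: str, dotbracket: str) -> float:
        """Free energy of a given structure on a given sequence."""
        raise NotImplementedError(f"{self.name} backend cannot evaluate energies")


class ViennaBackend(FoldingBackend):
    """In-process thermodynamic folder (ViennaRNA python bindings)."""

    name = "vienna"

    def __init__(self) -> None:
        import RNA  # deferred so other backends work without the bindings

        self._rna = RNA

    def version(self) -> str:
        return self._rna.__version__

    def fold_residues(self, residues: str) -> tuple[str, float]:
        db, mfe = self._rna.fold(residues)
        return db, float(mfe)

    def energy(self, residues: str, dotbracket: str) -> float:
        fc = self._rna.fold_compound(residues)
        return float(fc.eval_structure(dotbracket))


class RNAfoldCLIBackend(FoldingBackend):
    """External folder via the RNAfold/RNAeval executables."""

    name = "rnafold-cli"

    def __init__(self, executable: str = "RNAfold", eval_executable: str = "RNAeval") -> None:
        self.executable = executable
        self.eval_executable = eval_executable

    def version(self) -> str:
        out = subprocess.run(
            [self.executable, "--version"], capture_output=True, text=True, check=True
        )
        return out.stdout.strip().split()[-1]

    def fold_residues(self, residues: str) -> tuple[str, float]:
        out = subprocess.run(
            [self.executable, "--noPS"],
            input=residues + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        lines = out.stdout.strip().splitlines()
        db, energy = lines[1].rsplit(None, 1)
        return db.strip(), float(energy.strip("()"))

    def energy(self, residues: str, dotbracket: str) -> float:
        out = subprocess.run(
            [self.eval_executable],
            input=f"{residues}\n{dotbracket}\n",
            capture_output=True,
            text=True,
            check=True,
        )
        line = out.stdout.strip().splitlines()[1]
        return float(line.rsplit(None, 1)[1].strip("()"))


def parse_ct(text: str) -> tuple[str, tuple[Optional[int], ...], float]:
    """Parse CT-format folder output (UNAFold family) into
    (residues, pair table, energy).  Only the first structure is read."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise InputError("empty CT text")
    header = lines[0].split()
    n = int(header[0])
    energy = 0.0
    for tok_i, tok in enumerate(header):
        if tok.lower() in {"dg", "dg=", "energy"} and tok_i + 2 < len(header) + 1:
            try:
                energy = float(header[tok_i + 2] if header[tok_i + 1] == "=" else header[tok_i + 1])
            except (ValueError, IndexError):
                pass
    residues = []
    table: list[Optional[int]] = [None] * n
    for ln in lines[1 : n + 1]:
        f = ln.split()
        idx = int(f[0]) - 1
        residues.append(f[1].upper().replace("T", "U"))
        partner = int(f[4])
        table[idx] = partner - 1 if partner > 0 else None
    return "".join(residues), tuple(table), energy


def dotbracket_from_pairs(table: tuple[Optional[int], ...]) -> str:
    out = []
    for i, j in enumerate(table):
        out.append("." if j is None else ("(" if j > i else ")"))
    return "".join(out)


class ExternalCTBackend(FoldingBackend):
    """Generic wrapper over an UNAFold-compatible executable that writes CT
    output.  ``command`` is a template with a ``{infile}`` placeholder; the
    CT text is read from stdout."""

    name = "external-ct"

    def __init__(self, command: str, version: str = "unknown") -> None:
        self.command = command
        self._version = version

    def version(self) -> str:
        return self._version

    def fold_residues(self, residues: str) -> tuple[str, float]:
        with tempfile.NamedTemporaryFile("w", suffix=".seq", delete=False) as fh:
            fh.write(residues + "\n")
            infile = fh.name
        try:
            cmd = shlex.split(self.command.format(infile=infile))
            out = subprocess.run(cmd, capture_output=True, text=True, check=True)
            _, table, energy = parse_ct(out.stdout)
            return dotbracket_from_pairs(table), energy
        finally:
            Path(infile).unlink(missing_ok=True)


_BACKENDS = {
    "vienna": ViennaBackend,
    "rnafold-cli": RNAfoldCLIBackend,
    "external-ct": ExternalCTBackend,
}


def get_backend(name: str = "vienna", **kwargs) -> FoldingBackend:
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown folding backend {name!r}; known: {sorted(_BACKENDS)}"
        ) from None
    return cls(**kwargs)


def fold(
    seq: NucleotideSequence,
    backend: FoldingBackend | str = "vienna",
    min_length: int = 40,
) -> SecondaryStructure:
    """Predict the MFE nested structure of ``seq``.

    ``min_length`` guards against fragments too short to host a pre-miRNA
    (default 40 nt); pass 0 to fold anything.
    """
    if isinstance(backend, str):
        backend = get_backend(backend)
    if len(seq) < min_length:
        raise InputError(f"{seq.id}: length {len(seq)} < minimum foldable {min_length}")
    db, mfe = backend.fold_residues(seq.residues)
    return SecondaryStructure(dotbracket=db, pairs=pair_table(db), mfe=mfe)


# ---------------------------------------------------------------------------
# Hairpin extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hairpin:
    """A single stem-loop.  ``span`` covers the retained stem plus any
    unpaired flanking run assigned to it; ``arm5``/``arm3`` are everything
    5'/3' of the terminal loop within the span, so arm5+loop+arm3 tile the
    span exactly.  ``stem_pairs`` lists retained base pairs outermost-first;
    ``trimmed`` counts basal pairs discarded by the stem-length cap."""

    sequence: NucleotideSequence
    structure: SecondaryStructure
    span: Interval
    arm5: Interval
    arm3: Interval
    loop: Interval
    stem_pairs: tuple[Interval, ...]
    trimmed: int = 0

    @property
    def outer_pair(self) -> Interval:
        return self.stem_pairs[0]

    @property
    def inner_pair(self) -> Interval:
        return self.stem_pairs[-1]

    @property
    def n_stem_pairs(self) -> int:
        return len(self.stem_pairs)


def _pair_forest(table: tuple[Optional[int], ...]):
    """Children map of the pair-nesting forest.  Key None is the exterior
    loop; every key otherwise is a pair (i, j), i < j."""
    ROOT = None
    children: dict[Optional[Interval], list[Interval]] = {ROOT: []}
    parent: dict[Interval, Optional[Interval]] = {}
    stack: list[Optional[Interval]] = [ROOT]
    i = 0
    n = len(table)
    while i < n:
        j = table[i]
        if j is not None and j > i:
            p = (i, j)
            children[stack[-1]].append(p)
            parent[p] = stack[-1]
            children[p] = []
            stack.append(p)
        elif j is not None and j < i:
            stack.pop()
        i += 1
    return children, parent


def extract_hairpins(
    structure: SecondaryStructure,
    sequence: Optional[NucleotideSequence] = None,
    max_stem: int = 60,
) -> list[Hairpin]:
    """Every maximal single stem-loop in ``structure``.

    A stem-loop is the chain of pairs from a hairpin loop outwards until a
    multibranch loop or the exterior loop is met; multibranched regions
    themselves are never hairpins.  Stems longer than ``max_stem`` pair
    levels are trimmed by discarding pairs at the base (the discarded region
    leaves the span).  Unpaired runs in the parent loop flanking the stem are
    assigned to its span; a run between two sibling stems is split at its
    midpoint.
    """
    table = structure.pairs
    n = len(table)
    if sequence is None:
        sequence = NucleotideSequence(id="anonymous", residues="A" * n)
    if len(sequence) != n:
        raise InputError("sequence/structure length mismatch")

    children, parent = _pair_forest(table)
    hairpin_closing = [p for p in parent if not children[p]]

    # flank assignment: for every loop (exterior or multiloop-with->=2 or any
    # parent loop), compute the left/right unpaired run belonging to each branch
    flank: dict[Interval, tuple[int, int]] = {}  # branch outer pair -> (left_start, right_end)
    for loop_key, branches in children.items():
        if not branches:
            continue
        if loop_key is None:
            lo, hi = 0, n
        else:
            lo, hi = loop_key[0] + 1, loop_key[1]
        bounds = []
        prev_end = lo
        for k, (bi, bj) in enumerate(branches):
            left = prev_end if k == 0 else (prev_end + bi + 1) // 2
            bounds.append(left)
            prev_end = bj + 1
        for k, (bi, bj) in enumerate(branches):
            right = hi if k == len(branches) - 1 else bounds[k + 1]
            flank[(bi, bj)] = (bounds[k], right)

    hairpins: list[Hairpin] = []
    for hp in sorted(hairpin_closing):
        chain = [hp]
        par = parent[hp]
        while par is not None and len(children[par]) == 1:
            chain.append(par)
            par = parent[par]
        chain.reverse()  # outermost first
        trimmed = 0
        if len(chain) > max_stem:
            trimmed = len(chain) - max_stem
            chain = chain[trimmed:]
        outer = chain[0]
        inner = chain[-1]
        if trimmed:
            span = (outer[0], outer[1] + 1)
        else:
            left, right = flank[chain[0] if trimmed == 0 else outer]
            span = (left, right)
        loop = (inner[0] + 1, inner[1])
        hairpins.append(
            Hairpin(
                sequence=sequence,
                structure=structure,
                span=span,
                arm5=(span[0], loop[0]),
                arm3=(loop[1], span[1]),
                loop=loop,
                stem_pairs=tuple(chain),
                trimmed=trimmed,
            )
        )
    return hairpins


# ---------------------------------------------------------------------------
# Component segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinComponents:
    """The five structural components relative to one mature placement.

    Duplex components carry a (5'-side, 3'-side) interval pair; the terminal
    loop is a single interval.  Zero-length intervals mean the component is
    absent; the upper stem and terminal loop are never absent.  All intervals
    together tile the hairpin span.
    """

    basal_segment: tuple[Interval, Interval]
    lower_stem: tuple[Interval, Interval]
    upper_stem: tuple[Interval, Interval]
    top_stem: tuple[Interval, Interval]
    terminal_loop: Interval
    arm: str  # "5p" | "3p"
    mirna: Interval

    def duplex_components(self) -> dict[str, tuple[Interval, Interval]]:
        return {
            "basal_segment": self.basal_segment,
            "lower_stem": self.lower_stem,
            "upper_stem": self.upper_stem,
            "top_stem": self.top_stem,
        }

    def all_intervals(self) -> list[Interval]:
        ivs = []
        for five, three in self.duplex_components().values():
            ivs.extend([five, three])
        ivs.append(self.terminal_loop)
        return ivs


def _iv_len(iv: Interval) -> int:
    return max(0, iv[1] - iv[0])


def infer_arm(h: Hairpin, mirna: Interval) -> str:
    """Which arm a placement sits on; loop-straddling placements belong to
    the arm holding their duplex part."""
    s, e = mirna
    l0, l1 = h.loop
    if e <= l0:
        return "5p"
    if s >= l1:
        return "3p"
    if s < l0 and e <= l1:
        return "5p"
    if s >= l0 and e > l1:
        return "3p"
    raise PlacementError(f"placement {mirna} spans the terminal loop or lies inside it")


def _paired_positions(table, lo: int, hi: int) -> list[int]:
    return [i for i in range(lo, hi) if table[i] is not None]


def segment_components(h: Hairpin, mirna: Interval) -> HairpinComponents:
    """Partition the hairpin span into the five components relative to a
    mature placement on one arm.  Raises PlacementError if the placement is
    off-span, entirely unpaired, or crosses the loop onto the other arm."""
    s, e = mirna
    sp0, sp1 = h.span
    if not (sp0 <= s < e <= sp1):
        raise PlacementError(f"placement {mirna} outside hairpin span {h.span}")
    table = h.structure.pairs
    l0, l1 = h.loop
    a1, b1 = h.outer_pair
    an, bn = h.inner_pair
    arm = infer_arm(h, mirna)

    if arm == "5p":
        e_eff = min(e, l0)
        paired = _paired_positions(table, s, e_eff)
        if not paired:
            raise PlacementError(f"placement {mirna} has no paired base on the 5' arm")
        q_out = table[paired[0]]
        q_in = table[paired[-1]]
        basal5 = (sp0, min(a1, s))
        lower5 = (min(a1, s), s)
        upper5 = (s, e_eff)
        top5 = (e_eff, l0)
        top3 = (l1, q_in)
        upper3 = (q_in, q_out + 1)
        lower3 = (q_out + 1, b1 + 1)
        basal3 = (b1 + 1, sp1)
    else:
        s_eff = max(s, l1)
        paired = _paired_positions(table, s_eff, e)
        if not paired:
            raise PlacementError(f"placement {mirna} has no paired base on the 3' arm")
        u_in = table[paired[0]]
        u_out = table[paired[-1]]
        basal5 = (sp0, a1)
        lower5 = (a1, u_out)
        upper5 = (u_out, u_in + 1)
        top5 = (u_in + 1, l0)
        top3 = (l1, s_eff)
        upper3 = (s_eff, e)
        lower3 = (e, max(b1 + 1, e))
        basal3 = (max(b1 + 1, e), sp1)

    return HairpinComponents(
        basal_segment=(basal5, basal3),
        lower_stem=(lower5, lower3),
        upper_stem=(upper5, upper3),
        top_stem=(top5, top3),
        terminal_loop=(l0, l1),
        arm=arm,
        mirna=mirna,
    )


def derive_premirna(h: Hairpin, mirna: Interval, overhang: int = 2) -> Interval:
    """Geometric pre-miRNA: from the loop-distal end of the mature, across
    the terminal loop, to the partner of that end on the opposite arm, plus
    ``overhang`` nucleotides modelling the Drosha 3' overhang; clipped to the
    hairpin span."""
    s, e = mirna
    table = h.structure.pairs
    l0, l1 = h.loop
    sp0, sp1 = h.span
    arm = infer_arm(h, mirna)
    if arm == "5p":
        paired = _paired_positions(table, s, min(e, l0))
        if not paired:
            raise PlacementError(f"placement {mirna} has no paired base")
        q = table[paired[0]]
        return (s, min(q + 1 + overhang, sp1))
    paired = _paired_positions(table, max(s, l1), e)
    if not paired:
        raise PlacementError(f"placement {mirna} has no paired base")
    q = table[paired[-1]]
    return (q, min(e + overhang, sp1))
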