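"""Feature catalog and feature-vector computation for candidate miRNA placements.

Every candidate is a (ppri-miRNA, pre-miRNA, miRNA) triple on one folded
fragment: the ppri-miRNA is the whole fragment, the pre-miRNA the geometric
hairpin product, the miRNA the mature placement on one arm.  The catalog
reconstructs the published parameter families: Descriptive identifiers;
Size (lengths and paired-base counts); Stability (free energies); Sequence
(nucleotide/GC contents, first base); Structure (unpaired counts and rates,
GU wobbles, internal loops, 3' overhang), computed per scope (miRNA,
pre-miRNA, ppri-miRNA and the duplex components).

Parameters that describe the ppri-miRNA alone are flagged ineligible for SVM
training: decoy negatives share the positive's ppri-miRNA byte-for-byte, so
those values cannot separate the classes.  Descriptive/text parameters are
likewise ineligible.  Absent components yield the undefined marker (``None``),
which the scaler maps to the component-absent code -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence as Seq

from .structure import (
    Hairpin,
    HairpinComponents,
    Interval,
    NucleotideSequence,
    SecondaryStructure,
    FoldingBackend,
    InputError,
    WOBBLE,
    derive_premirna,
    get_backend,
    segment_components,
)

UNDEFINED = None  # component-absent marker; scaled representation is -1

CATALOG_VERSION = "default-1"

CATEGORIES = ("descriptive", "size", "stability", "sequence", "structure")
SCOPES = (
    "mirna",
    "premirna",
    "pprimirna",
    "basal_segment",
    "lower_stem",
    "upper_stem",
    "top_stem",
    "terminal_loop",
)


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    category: str
    scope: str
    value_kind: str  # real | integer | categorical | text
    svm_eligible: bool

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InputError(f"unknown category {self.category}")
        if self.scope not in SCOPES:
            raise InputError(f"unknown scope {self.scope}")
        if self.svm_eligible and (
            self.category == "descriptive"
            or self.value_kind in ("categorical", "text")
            or self.scope == "pprimirna"
        ):
            raise InputError(f"{self.name}: violates svm-eligibility invariants")


_SCOPE_PREFIX = {
    "mirna": "mi",
    "premirna": "pre",
    "pprimirna": "ppri",
    "basal_segment": "basalsegment",
    "lower_stem": "lowerstem",
    "upper_stem": "upperstem",
    "top_stem": "topstem",
    "terminal_loop": "terminalloop",
}

_DUPLEX_SCOPES = ("mirna", "premirna", "pprimirna", "lower_stem", "upper_stem", "top_stem")


def default_catalog() -> list[ParameterSpec]:
    """The reconstructed default parameter catalog.

    The catalog is data, not code: alternative reconstructions round-trip
    through the YAML config unchanged (see :func:`catalog_to_config`).
    """
    specs: list[ParameterSpec] = []

    def add(name, category, scope, kind, eligible=None):
        if eligible is None:
            eligible = not (
                category == "descriptive" or kind in ("categorical", "text") or scope == "pprimirna"
            )
        specs.append(ParameterSpec(name, category, scope, kind, eligible))

    # Descriptive: identifiers echoed in reports, never SVM input
    add("entry_id", "descriptive", "mirna", "text")
    add("mi_sequence", "descriptive", "mirna", "text")
    add("mi_structure", "descriptive", "mirna", "text")

    # Size: lengths ...
    for scope in ("mirna", "premirna", "pprimirna", "basal_segment",
                  "lower_stem", "upper_stem", "top_stem", "terminal_loop"):
        add(f"{_SCOPE_PREFIX[scope]}_length", "size", scope, "integer")
    # ... and paired-base counts for the duplex scopes
    for scope in ("mirna", "premirna", "pprimirna", "lower_stem", "upper_stem", "top_stem"):
        add(f"{_SCOPE_PREFIX[scope]}_npairs", "size", scope, "integer")

    # Stability
    add("pre_mfe", "stability", "premirna", "real")
    add("ppri_mfe", "stability", "pprimirna", "real")

    # Sequence: contents + first base (one-hot expansion is SVM input)
    for scope in ("mirna", "premirna", "pprimirna"):
        p = _SCOPE_PREFIX[scope]
        for base in "acgu":
            add(f"{p}_{base}_content", "sequence", scope, "real")
        add(f"{p}_gc_content", "sequence", scope, "real")
    add("mi_firstbase", "sequence", "mirna", "categorical")
    for base in "acgu":
        add(f"mi_firstbase_{base}", "sequence", "mirna", "integer")

    # Structure: duplex statistics per scope, plus the 3' overhang
    for scope in _DUPLEX_SCOPES:
        p = _SCOPE_PREFIX[scope]
        add(f"{p}_n_unpaired", "structure", scope, "integer")
        add(f"{p}_unpaired_rate", "structure", scope, "real")
        add(f"{p}_gu_wobbles", "structure", scope, "integer")
        add(f"{p}_biggest_internal_loop", "structure", scope, "integer")
        add(f"{p}_n_internal_loops", "structure", scope, "integer")
    add("overhang_3p", "structure", "lower_stem", "integer")

    return specs


def eligible_names(catalog: Seq[ParameterSpec]) -> list[str]:
    return [p.name for p in catalog if p.svm_eligible]


def numeric_names(catalog: Seq[ParameterSpec]) -> list[str]:
    return [p.name for p in catalog if p.value_kind in ("real", "integer")]


def range_filter_names(catalog: Seq[ParameterSpec]) -> list[str]:
    """Parameters of the pre-miRNA/miRNA pair itself -- the default set the
    prediction-time range filter windows.  Context-dependent sizes (basal
    segment, lower stem, whole-fragment ppri statistics) are excluded: they
    measure how a candidate's surroundings folded, not the candidate, and
    their ranges differ between standalone precursor records and genome
    fragments."""
    scopes = {"mirna", "premirna", "upper_stem", "top_stem", "terminal_loop"}
    return [
        p.name
        for p in catalog
        if p.value_kind in ("real", "integer")
        and (p.scope in scopes or p.name == "overhang_3p")
    ]


def catalog_to_config(catalog: Seq[ParameterSpec]) -> dict:
    return {
        "version": CATALOG_VERSION,
        "parameters": [
            {
                "name": p.name,
                "category": p.category,
                "scope": p.scope,
                "value_kind": p.value_kind,
                "svm_eligible": p.svm_eligible,
            }
            for p in catalog
        ],
    }


def catalog_from_config(cfg: dict) -> list[ParameterSpec]:
    return [
        ParameterSpec(
            name=d["name"],
            category=d["category"],
            scope=d["scope"],
            value_kind=d["value_kind"],
            svm_eligible=d["svm_eligible"],
        )
        for d in cfg["parameters"]
    ]


# ---------------------------------------------------------------------------
# Feature primitives
# ---------------------------------------------------------------------------

def nucleotide_content(residues: str, base: str):
    """Fraction of ``base`` in ``residues``; undefined for an empty string."""
    if not residues:
        return UNDEFINED
    return residues.count(base) / len(residues)


def gc_content(residues: str):
    if not residues:
        return UNDEFINED
    return (residues.count("G") + residues.count("C")) / len(residues)


def count_unpaired(intervals: Seq[Interval], table) -> int:
    return sum(
        1 for lo, hi in intervals for i in range(lo, hi) if table[i] is None
    )


def feature_length(intervals: Seq[Interval]) -> int:
    return sum(max(0, hi - lo) for lo, hi in intervals)


def unpaired_rate(intervals: Seq[Interval], table):
    """Proportion of unpaired bases within a feature's nucleotides."""
    n = feature_length(intervals)
    if n == 0:
        return UNDEFINED
    return count_unpaired(intervals, table) / n


def internal_loop_stats(intervals: Seq[Interval], table) -> tuple[int, int]:
    """(largest run, run count) of consecutive unpaired positions per strand.

    An internal loop is the largest bulge on either strand of a duplex
    feature; runs never span the boundary between the 5'- and 3'-side
    intervals.  A perfect duplex gives (0, 0).
    """
    largest = 0
    n_runs = 0
    for lo, hi in intervals:
        run = 0
        for i in range(lo, hi):
            if table[i] is None:
                run += 1
            else:
                if run:
                    n_runs += 1
                    largest = max(largest, run)
                run = 0
        if run:
            n_runs += 1
            largest = max(largest, run)
    return largest, n_runs


def gu_wobbles(intervals: Seq[Interval], table, residues: str) -> int:
    """G-U pairs with their 5'-most partner inside the feature, each counted once."""
    seen = set()
    count = 0
    for lo, hi in intervals:
        for i in range(lo, hi):
            j = table[i]
            if j is None:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            if (residues[i], residues[j]) in WOBBLE:
                count += 1
    return count


def count_pairs_within(intervals: Seq[Interval], table) -> int:
    """Base pairs with both partners inside the feature, counted once."""
    positions = {i for lo, hi in intervals for i in range(lo, hi)}
    return sum(1 for i in positions if table[i] is not None and table[i] in positions and table[i] > i)


def overhang_3p(premirna: Interval, table) -> int:
    """Unpaired 3'-side nucleotides protruding at the pre-miRNA base (0 if flush).

    A base whose partner lies outside the pre-miRNA is single-stranded in
    the excised product, so it counts toward the overhang.
    """
    lo, hi = premirna
    t = 0
    i = hi - 1
    while i >= lo and (table[i] is None or not (lo <= table[i] < hi)):
        t += 1
        i -= 1
    return t


# ---------------------------------------------------------------------------
# Feature vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """Named parameter values for one (ppri, pre, miRNA) triple."""

    values: dict
    ppri_id: str
    mirna: Interval
    premirna: Interval
    arm: str

    def __getitem__(self, name: str):
        return self.values[name]

    def as_numeric(self, names: Seq[str]) -> list:
        """Values for the named parameters, undefined marker passed through as None."""
        return [self.values.get(n, UNDEFINED) for n in names]


def _nonempty(intervals: Seq[Interval]) -> list[Interval]:
    return [iv for iv in intervals if iv[1] > iv[0]]


def compute_features(
    ppri: NucleotideSequence,
    structure: SecondaryStructure,
    hairpin: Hairpin,
    mirna: Interval,
    catalog: Optional[Seq[ParameterSpec]] = None,
    backend: Optional[FoldingBackend] = None,
    premirna_overhang: int = 2,
    cache: Optional[dict] = None,
) -> FeatureVector:
    """One value per catalog entry for a mature placement on a hairpin arm.

    ``ppri`` and ``structure`` must describe the same folding the hairpin was
    extracted from.  ``backend`` supplies thermodynamic evaluation for the
    pre-miRNA free energy (default: in-process ViennaRNA).
    Deterministic: identical triples give identical vectors.

    ``cache`` (one dict per folded fragment) memoizes whole-fragment
    statistics that are shared by every candidate on the same hairpin.
    """
    if len(ppri) != len(structure.dotbracket):
        raise InputError("sequence and structure lengths differ")
    if catalog is None:
        catalog = default_catalog()
    if backend is None:
        backend = get_backend("vienna")

    res = ppri.residues
    table = structure.pairs
    comps = segment_components(hairpin, mirna)
    pre = derive_premirna(hairpin, mirna, overhang=premirna_overhang)
    l0, l1 = hairpin.loop
    s, e = mirna
    ps, pe = pre

    # per-scope residue intervals (for contents/length) and duplex intervals
    # (for structure statistics; terminal loop excluded from pre/ppri duplexes)
    scope_res: dict[str, list[Interval]] = {
        "mirna": [(s, e)],
        "premirna": [(ps, pe)],
        "pprimirna": [(0, len(res))],
        "basal_segment": _nonempty(comps.basal_segment),
        "lower_stem": _nonempty(comps.lower_stem),
        "upper_stem": _nonempty(comps.upper_stem),
        "top_stem": _nonempty(comps.top_stem),
        "terminal_loop": _nonempty([comps.terminal_loop]),
    }
    scope_duplex: dict[str, list[Interval]] = dict(scope_res)
    scope_duplex["premirna"] = _nonempty([(ps, min(pe, l0)), (max(ps, l1), pe)])
    scope_duplex["pprimirna"] = _nonempty([(0, l0), (l1, len(res))])

    v: dict = {}
    v["entry_id"] = f"{ppri.id}:{s + 1}-{e}:{comps.arm}"
    v["mi_sequence"] = res[s:e]
    v["mi_structure"] = structure.dotbracket[s:e]

    for scope, prefix in _SCOPE_PREFIX.items():
        ivs = scope_res[scope]
        n = feature_length(ivs)
        v[f"{prefix}_length"] = n if n > 0 else UNDEFINED

    ppri_key = ("ppri_stats", l0, l1)
    for scope in _DUPLEX_SCOPES:
        prefix = _SCOPE_PREFIX[scope]
        ivs = scope_duplex[scope]
        if scope == "pprimirna" and cache is not None and ppri_key in cache:
            v.update(cache[ppri_key])
            continue
        if feature_length(ivs) == 0:
            for suffix in ("npairs", "n_unpaired", "unpaired_rate", "gu_wobbles",
                           "biggest_internal_loop", "n_internal_loops"):
                v[f"{prefix}_{suffix}"] = UNDEFINED
            continue
        if scope == "mirna":
            # mature-scope statistics run along the mature's own strand
            v["mi_npairs"] = sum(1 for i in range(s, e) if table[i] is not None)
        else:
            v[f"{prefix}_npairs"] = count_pairs_within(ivs, table)
        v[f"{prefix}_n_unpaired"] = count_unpaired(ivs, table)
        v[f"{prefix}_unpaired_rate"] = unpaired_rate(ivs, table)
        v[f"{prefix}_gu_wobbles"] = gu_wobbles(ivs, table, res)
        big, nloops = internal_loop_stats(ivs, table)
        v[f"{prefix}_biggest_internal_loop"] = big
        v[f"{prefix}_n_internal_loops"] = nloops

    if cache is not None and ppri_key not in cache:
        cache[ppri_key] = {
            k: v[k]
            for k in ("ppri_npairs", "ppri_n_unpaired", "ppri_unpaired_rate",
                      "ppri_gu_wobbles", "ppri_biggest_internal_loop",
                      "ppri_n_internal_loops")
            if k in v
        }

    v["pre_mfe"] = _premirna_energy(res, structure, pre, backend)
    v["ppri_mfe"] = structure.mfe

    for scope in ("mirna", "premirna", "pprimirna"):
        prefix = _SCOPE_PREFIX[scope]
        seq = "".join(res[lo:hi] for lo, hi in scope_res[scope])
        for base in "ACGU":
            v[f"{prefix}_{base.lower()}_content"] = nucleotide_content(seq, base)
        v[f"{prefix}_gc_content"] = gc_content(seq)

    first = res[s]
    v["mi_firstbase"] = first
    for base in "ACGU":
        v[f"mi_firstbase_{base.lower()}"] = int(first == base)

    v["overhang_3p"] = overhang_3p(pre, table)

    # restrict/validate against the catalog
    values = {p.name: v.get(p.name, UNDEFINED) for p in catalog}
    return FeatureVector(values=values, ppri_id=ppri.id, mirna=mirna, premirna=pre, arm=comps.arm)


def _premirna_energy(res: str, structure: SecondaryStructure, pre: Interval,
                     backend: FoldingBackend) -> float:
    """Free energy of the fragment structure restricted to the pre-miRNA
    interval (pairs leaving the interval are opened)."""
    lo, hi = pre
    sub = []
    for i in range(lo, hi):
        j = structure.pairs[i]
        if j is None or not (lo <= j < hi):
            sub.append(".")
        else:
            sub.append("(" if j > i else ")")
    db = "".join(sub)
    if "(" not in db:
        return 0.0
    return backend.energy(res[lo:hi], db)
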