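"""Readers and writers for the standard formats the tool speaks.

FASTA in/out goes through Biopython; GFF3 and TSV are written directly with
fixed float formatting so identical runs produce byte-identical files.
User-facing coordinates are 1-based inclusive (GFF3 convention); everything
internal stays 0-based half-open.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Optional, Sequence as Seq

import yaml
from Bio import SeqIO

from .features import default_catalog, numeric_names
from .predictor import CandidatePlacement, CodingRegion
from .structure import Interval, NucleotideSequence


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> list[NucleotideSequence]:
    """Multi-record, gzip-aware FASTA reader; residues normalized to RNA."""
    with _open_maybe_gzip(path) as fh:
        return [
            NucleotideSequence.from_raw(rec.id, str(rec.seq))
            for rec in SeqIO.parse(fh, "fasta")
        ]


def write_fasta(path, seqs: Seq[NucleotideSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def write_truth_gff3(path, truths: Seq[tuple[str, Interval]], source: str = "mirsweep") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, (parent, (s, e)) in enumerate(truths, 1):
            fh.write(
                f"{parent}\t{source}\tmiRNA\t{s + 1}\t{e}\t.\t+\t.\t"
                f"ID=true_mirna_{k}\n"
            )


def read_truth_gff3(path) -> list[tuple[str, Interval]]:
    out = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], (int(f[3]) - 1, int(f[4]))))
    return out


def write_regions_gff3(path, regions: Seq[CodingRegion], source: str = "mirsweep") -> None:
    """Most-probable miRNA coding regions as GFF3 features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, r in enumerate(regions, 1):
            s, e = r.interval
            attrs = (
                f"ID=coding_region_{k};arm={r.arm};n_support={r.n_support};"
                f"best_score={r.best_score:.6g}"
            )
            fh.write(
                f"{r.parent_id}\t{source}\tmiRNA_coding_region\t{s + 1}\t{e}\t"
                f"{r.best_score:.6g}\t{r.strand}\t.\t{attrs}\n"
            )


def write_placements_tsv(path, placements: Seq[CandidatePlacement],
                         catalog=None) -> None:
    """One row per placement: coordinates, score, verdict and every numeric
    feature value (undefined features print as NA)."""
    if catalog is None:
        catalog = default_catalog()
    names = numeric_names(catalog)
    with open(path, "w") as fh:
        head = ["id", "strand", "arm", "mirna_start", "mirna_end",
                "premirna_start", "premirna_end", "svm_score",
                "passed_filter", "verdict"] + names
        fh.write("\t".join(head) + "\n")
        for p in placements:
            vals = []
            for n in names:
                v = p.features.values.get(n)
                vals.append("NA" if v is None else f"{v:.6g}")
            row = [p.parent_id, p.strand, p.arm,
                   str(p.mirna[0] + 1), str(p.mirna[1]),
                   str(p.premirna[0] + 1), str(p.premirna[1]),
                   f"{p.svm_score:.6g}", str(int(p.passed_filter)),
                   str(int(p.verdict))] + vals
            fh.write("\t".join(row) + "\n")


def write_run_log(path, config: dict) -> None:
    Path(path).write_text(json.dumps(config, indent=1, sort_keys=True, default=str))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
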