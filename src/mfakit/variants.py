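"""Parse and summarise the transcribed KOD1-vs-TS559 genome difference table.

The packaged fixture transcribes the published table of differences between
the *T. kodakarensis* KOD1 reference and the TS559 laboratory strain:
35 records, each a substitution (``X → Y``), a single-base deletion
(``ΔΔX``) or a single-base insertion (``↑X``), with the affected gene (or an
intergenic flag), operon, predicted protein change and annotation.  Positions
are 1-based as printed; :meth:`VariantRecord.position_0based` converts to the
pipeline's 0-based convention.

Unicode change glyphs are normalised to ASCII classes at parse time; the
fixture carries both representations (``dna_change`` / ``dna_change_ascii``).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

FIXTURE_NAME = "table1_kod1_ts559.tsv"

CLASS_SUBSTITUTION = "substitution"
CLASS_DELETION = "deletion"
CLASS_INSERTION = "insertion"


class VariantParseError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    position: int               # 1-based, as printed
    gene: str                   # TK gene number or intergenic flag
    operon: str
    dna_change: str             # as printed (unicode glyphs)
    change_class: str           # substitution | deletion | insertion
    protein_change: str
    consequence: str            # missense | frameshift | no_change | intergenic
    annotation: str

    @property
    def intergenic(self) -> bool:
        return self.consequence == "intergenic"

    def position_0based(self) -> int:
        return self.position - 1


def _classify_dna_change(raw: str, ascii_token: str, rowname: str) -> str:
    token = (ascii_token or "").strip().upper()
    text = raw.strip()
    if token.startswith("SUB") or "→" in text or ">" in text:
        return CLASS_SUBSTITUTION
    if token.startswith("DEL") or "Δ" in text:
        return CLASS_DELETION
    if token.startswith("INS") or "↑" in text:
        return CLASS_INSERTION
    raise VariantParseError(f"{rowname}: unparseable DNA change {raw!r}")


def _consequence(gene: str, protein_change: str) -> str:
    if gene.strip().lower().startswith("inter"):
        return "intergenic"
    pc = protein_change.strip()
    if pc in ("N.C.", "NC", "N.C"):
        return "no_change"
    if pc.endswith("fs"):
        return "frameshift"
    return "missense"


def fixture_path() -> Path:
    """Path of the packaged difference-table transcription."""
    return Path(resources.files("mfakit").joinpath("data", FIXTURE_NAME))


def read_variant_table(path=None) -> list:
    """Parse the difference table; defaults to the packaged fixture."""
    path = fixture_path() if path is None else Path(path)
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[0] != "position":
            raise VariantParseError(f"{path}: missing or unexpected header")
        ncol = len(header)
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(f.strip() for f in row):
                continue
            row = (row + [""] * ncol)[:ncol]
            rowname = f"{path.name}:{lineno}"
            try:
                position = int(row[0])
            except ValueError as exc:
                raise VariantParseError(f"{rowname}: bad position {row[0]!r}") from exc
            if position < 1:
                raise VariantParseError(f"{rowname}: position must be >= 1")
            gene, operon, dna_change, ascii_token, protein, annot = row[1:7]
            records.append(VariantRecord(
                position=position,
                gene=gene.strip(),
                operon=operon.strip(),
                dna_change=dna_change.strip(),
                change_class=_classify_dna_change(dna_change, ascii_token, rowname),
                protein_change=protein.strip(),
                consequence=_consequence(gene, protein),
                annotation=annot.strip(),
            ))
    return records


def summarize_variants(records) -> dict:
    """Counts by DNA-change class and predicted consequence.

    Class counts and consequence counts each partition the record total.
    """
    counts = {
        "total": len(records),
        "substitutions": 0, "deletions": 0, "insertions": 0,
        "coding": 0, "intergenic": 0,
        "missense": 0, "frameshift": 0, "no_change": 0,
    }
    key = {CLASS_SUBSTITUTION: "substitutions", CLASS_DELETION: "deletions",
           CLASS_INSERTION: "insertions"}
    for rec in records:
        counts[key[rec.change_class]] += 1
        if rec.intergenic:
            counts["intergenic"] += 1
        else:
            counts["coding"] += 1
            counts[rec.consequence] += 1
    return counts


def write_summary_json(records, path) -> dict:
    summary = summarize_variants(records)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def write_variant_table(records, path) -> None:
    """Round-trip writer for the table dialect read by :func:`read_variant_table`."""
    ascii_of = {
        CLASS_SUBSTITUTION: lambda d: "SUB:" + d.replace(" → ", ">").replace("→", ">"),
        CLASS_DELETION: lambda d: "DEL:" + d.lstrip("Δ"),
        CLASS_INSERTION: lambda d: "INS:" + d.lstrip("↑"),
    }
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["position", "gene", "operon", "dna_change",
                         "dna_change_ascii", "protein_change", "annotation"])
        for r in records:
            writer.writerow([r.position, r.gene, r.operon, r.dna_change,
                             ascii_of[r.change_class](r.dna_change),
                             r.protein_change, r.annotation])
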