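"""Annotated-reference helpers: CDS extraction from GenBank records.

Used to pull individual coding sequences (for example the Cdc6-encoding
TK1901 gene of the *T. kodakarensis* KOD1 reference, accession NC_006624.1)
out of a GenBank flat file, either fetched from NCBI when a network is
available or read from a local copy.
"""

from __future__ import annotations

from typing import Optional

from Bio import Entrez, SeqIO


class FeatureNotFoundError(KeyError):
    pass


def fetch_genbank(accession: str, email: str = "mfakit@example.org",
                  timeout: Optional[float] = 30.0):
    """Fetch a GenBank record from NCBI nuccore (requires network access)."""
    import socket

    Entrez.email = email
    old = socket.getdefaulttimeout()
    socket.setdefaulttimeout(timeout)
    try:
        with Entrez.efetch(db="nuccore", id=accession, rettype="gbwithparts",
                           retmode="text") as handle:
            return SeqIO.read(handle, "genbank")
    finally:
        socket.setdefaulttimeout(old)


def load_genbank(path):
    """Read a local GenBank flat file (first record)."""
    return SeqIO.read(str(path), "genbank")


def find_cds(record, locus_tag: str):
    """The CDS feature whose locus_tag (or old_locus_tag/gene) matches."""
    want = locus_tag.lower()
    for feat in record.features:
        if feat.type != "CDS":
            continue
        tags = []
        for key in ("locus_tag", "old_locus_tag", "gene"):
            tags.extend(t.lower() for t in feat.qualifiers.get(key, []))
        if want in tags:
            return feat
    raise FeatureNotFoundError(
        f"no CDS with locus tag {locus_tag!r} in record {record.id}"
    )


def cds_length(record, locus_tag: str) -> int:
    """Genomic span of a CDS in bp (start codon through stop codon)."""
    feat = find_cds(record, locus_tag)
    return sum(int(part.end) - int(part.start) for part in feat.location.parts)


def cds_sequence(record, locus_tag: str) -> str:
    feat = find_cds(record, locus_tag)
    return str(feat.extract(record.seq))
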