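"""Read and write annotated plastomes and alignments in standard formats.

GenBank flat files are parsed and emitted through Biopython; the boundary
converts between GenBank's 1-based inclusive coordinates and the package's
0-based half-open convention.  Multi-exon features arrive as ``join(...)``
(or ``complement(join(...))``) locations and are resolved into ordered exon
lists; a ``join(x..L,1..y)`` on a circular record becomes a single
origin-wrapping feature.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignmentMatrix,
    EmptyInputError,
    GeneFeature,
    PlastomeRecord,
    PlastcompError,
    normalize_gene_name,
)

_FEATURE_TYPES = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}
_TYPE_FOR_CATEGORY = {v: k for k, v in _FEATURE_TYPES.items()}


class ParseError(PlastcompError):
    pass


def _exons_from_location(loc, n: int, strand: str) -> tuple[list[tuple[int, int]], bool]:
    """Resolve a Biopython location into strand-ordered exons.

    Returns (exons, wraps_origin).  Adjacent parts ``(x, n) + (0, y)`` in
    genomic order indicate an origin-wrapping feature, not an intron.
    """
    parts = sorted(
        ((int(p.start), int(p.end)) for p in loc.parts), key=lambda iv: iv[0]
    )
    wraps = len(parts) >= 2 and parts[-1][1] == n and parts[0][0] == 0
    exons = parts
    if strand == "-":
        exons = sorted(parts, key=lambda iv: -iv[0])
    return exons, wraps


def read_genbank(path: str | os.PathLike) -> PlastomeRecord:
    """Read one annotated plastome from a GenBank flat file.

    CDS/tRNA/rRNA features are kept (plain ``gene`` features duplicated by a
    CDS/tRNA/rRNA child are skipped); a ``/pseudo`` or ``/pseudogene``
    qualifier sets the pseudogene flag.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    n = len(rec.seq)
    circular = rec.annotations.get("topology", "circular") == "circular"
    features: list[GeneFeature] = []
    for f in rec.features:
        category = _FEATURE_TYPES.get(f.type)
        if category is None:
            continue
        quals = f.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
        strand = "-" if f.location.strand == -1 else "+"
        exons, wraps = _exons_from_location(f.location, n, strand)
        features.append(
            GeneFeature(
                name=normalize_gene_name(name),
                category=category,
                strand=strand,
                exons=exons,
                functional_group=(quals.get("function") or ["unknown"])[0],
                pseudogene="pseudo" in quals or "pseudogene" in quals,
                copy_of=(quals.get("copy_of") or [None])[0],
                wraps_origin=wraps and circular,
            )
        )
    return PlastomeRecord(rec.id or rec.name, str(rec.seq), circular, features)


def _location_for(feat: GeneFeature) -> SimpleLocation | CompoundLocation:
    strand = -1 if feat.strand == "-" else 1
    genomic = sorted(feat.exons)
    if feat.wraps_origin:
        # keep the (x..L, 1..y) part order of the wrap convention
        genomic = sorted(feat.exons, key=lambda iv: (iv[0] == 0, iv[0]))
    parts = [SimpleLocation(s, e, strand) for s, e in genomic]
    if len(parts) == 1:
        return parts[0]
    if strand == -1:
        parts = parts[::-1]
    return CompoundLocation(parts)


def write_genbank(rec: PlastomeRecord, path: str | os.PathLike) -> None:
    """Write a PlastomeRecord as a GenBank flat file (round-trip safe)."""
    sr = SeqRecord(
        Seq(rec.sequence),
        id=rec.id,
        name=rec.id.replace(" ", "_")[:16] or "plastome",
        description="plastome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if rec.circular else "linear",
        },
    )
    for f in rec.features:
        quals = {"gene": [f.name]}
        if f.functional_group != "unknown":
            quals["function"] = [f.functional_group]
        if f.pseudogene:
            quals["pseudo"] = [""]
        if f.copy_of:
            quals["copy_of"] = [f.copy_of]
        sr.features.append(
            SeqFeature(_location_for(f), type=_TYPE_FOR_CATEGORY[f.category], qualifiers=quals)
        )
    SeqIO.write([sr], str(path), "genbank")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file as (id, sequence) pairs."""
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(pairs: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in pairs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_alignment(path: str | os.PathLike) -> AlignmentMatrix:
    """Read an aligned FASTA (equal-length rows, '-' gaps)."""
    pairs = read_fasta(path)
    if not pairs:
        raise EmptyInputError(f"{path}: no sequences")
    return AlignmentMatrix.from_rows(pairs)


def write_alignment(aln: AlignmentMatrix, path: str | os.PathLike) -> None:
    write_fasta(((t, aln.row(t)) for t in aln.taxa), path)
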