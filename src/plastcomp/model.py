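"""Core data model for annotated plastomes and alignments.

A plastome is a circular DNA molecule, typically 120-170 kb in land plants,
with the canonical quadripartite layout: a large single-copy region (LSC), a
small single-copy region (SSC), and two inverted repeats (IRa, IRb) that are
exact or near-exact reverse complements of one another.

All internal coordinates are 0-based half-open; GenBank I/O converts to the
format's 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional

import numpy as np

VALID_BASES = frozenset("ACGTN")
GAP = "-"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class PlastcompError(Exception):
    """Base class for all package errors."""


class ValidationError(PlastcompError):
    pass


class CoordinateError(ValidationError):
    pass


class AlignmentShapeError(PlastcompError):
    pass


class EmptyInputError(PlastcompError):
    pass


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (report-table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def normalize_gene_name(name: str) -> str:
    """Canonical gene symbol: anticodon suffix joined by underscore.

    ``trnA-UGC`` and ``trna_ugc`` both normalize to ``trnA_UGC``; case of the
    locus stem is preserved as given apart from anticodon normalization.
    """
    if not name:
        raise ValueError("empty gene name")
    name = name.strip().replace("-", "_")
    if name.lower().startswith("trn") and "_" in name:
        stem, _, anticodon = name.partition("_")
        return f"{stem}_{anticodon.upper()}"
    return name


CATEGORIES = ("protein_coding", "tRNA", "rRNA")


@dataclass
class GeneFeature:
    """An annotated gene: one or more exons on one strand.

    ``exons`` are 0-based half-open intervals ordered along the strand (for a
    minus-strand gene the first exon is the one with the largest genomic
    coordinate).  ``copy_of`` links the second IR copy of a duplicated gene to
    its partner's name.  ``wraps_origin`` marks a feature that crosses the
    linearization origin of a circular record; its exons are stored split at
    the origin.
    """

    name: str
    category: str
    strand: str
    exons: list[tuple[int, int]]
    functional_group: str = "unknown"
    pseudogene: bool = False
    copy_of: Optional[str] = None
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r} for {self.name}")
        if self.strand not in "+-":
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"feature {self.name} has no exons")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise CoordinateError(f"bad exon interval [{s},{e}) in {self.name}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise CoordinateError(f"overlapping exons in {self.name}")

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate."""
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate (exclusive)."""
        return max(e for _, e in self.exons)

    @property
    def length(self) -> int:
        """Total exonic length in bp."""
        return sum(e - s for s, e in self.exons)

    def spliced(self, sequence: str) -> str:
        """Spliced, strand-resolved sequence of this feature."""
        parts = [sequence[s:e] for s, e in sorted(self.exons)]
        joined = "".join(parts)
        return revcomp(joined) if self.strand == "-" else joined


@dataclass
class PlastomeRecord:
    """A (possibly circular) annotated genome."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"record {self.id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValidationError(
                f"record {self.id}: invalid characters {sorted(bad)} (alphabet is ACGTN)"
            )
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise CoordinateError(
                    f"feature {f.name} extends to {f.end} beyond sequence length {n}"
                )
            if f.wraps_origin and not self.circular:
                raise CoordinateError(
                    f"feature {f.name} wraps the origin of a linear record"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, name: str) -> Optional[GeneFeature]:
        name = normalize_gene_name(name)
        for f in self.features:
            if normalize_gene_name(f.name) == name:
                return f
        return None

    def rotated(self, offset: int) -> "PlastomeRecord":
        """Rotate a circular record so position ``offset`` becomes position 0.

        Features are shifted accordingly; a feature whose span crosses the new
        origin has its exons split there and is flagged ``wraps_origin``.
        """
        n = len(self.sequence)
        offset %= n
        if offset == 0:
            return self
        if not self.circular:
            raise ValidationError("cannot rotate a linear record")
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats: list[GeneFeature] = []
        for f in self.features:
            fragments: list[tuple[int, int]] = []
            wraps = False
            for s, e in f.exons:
                s2, e2 = (s - offset) % n, (e - offset) % n
                if e2 == 0:
                    e2 = n
                if s2 < e2:
                    fragments.append((s2, e2))
                else:  # exon crosses the new origin: split
                    wraps = True
                    fragments.extend([(s2, n), (0, e2)])
            # re-join fragments of an exon previously split at the old origin
            fragments.sort()
            exons: list[tuple[int, int]] = []
            for s2, e2 in fragments:
                if exons and exons[-1][1] == s2:
                    exons[-1] = (exons[-1][0], e2)
                else:
                    exons.append((s2, e2))
            wraps = (
                len(exons) > 1
                and any(e2 == n for _, e2 in exons)
                and any(s2 == 0 for s2, _ in exons)
            )
            if f.strand == "-":
                exons.sort(key=lambda iv: -iv[0])
            feats.append(replace(f, exons=exons, wraps_origin=wraps))
        return PlastomeRecord(self.id, seq, self.circular, feats)

    def reverse_complemented(self) -> "PlastomeRecord":
        n = len(self.sequence)
        feats = []
        for f in self.features:
            exons = [(n - e, n - s) for s, e in f.exons]
            if f.strand == "+":
                exons.sort(key=lambda iv: -iv[0])
            else:
                exons.sort()
            feats.append(
                replace(f, exons=exons, strand="+" if f.strand == "-" else "-")
            )
        return PlastomeRecord(self.id, revcomp(self.sequence), self.circular, feats)


class AlignmentMatrix:
    """A multiple sequence alignment with optional per-column partition labels.

    Columns hold characters over {A,C,G,T,N,-}.  After
    :func:`plastcomp.divergence.project_annotation` each column additionally
    carries a region tag (LSC/SSC/IR), a coding tag, and a feature name
    projected from a designated reference taxon.
    """

    def __init__(self, taxa: list[str], rows: list[str]):
        if len(taxa) != len(rows):
            raise AlignmentShapeError("taxa/row count mismatch")
        if not rows:
            raise EmptyInputError("empty alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"ragged rows: lengths {sorted(lengths)}")
        if len(set(taxa)) != len(taxa):
            raise ValidationError("duplicate taxon labels")
        self.taxa = list(taxa)
        self.matrix = np.array(
            [np.frombuffer(r.upper().encode(), dtype="S1") for r in rows]
        )
        self.region: Optional[np.ndarray] = None  # per-column: LSC/SSC/IR
        self.coding: Optional[np.ndarray] = None  # per-column: coding/noncoding
        self.feature: Optional[np.ndarray] = None  # per-column feature label

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> str:
        try:
            i = self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None
        return self.matrix[i].tobytes().decode()

    def has_labels(self) -> bool:
        return self.region is not None and self.coding is not None

    @classmethod
    def from_rows(cls, pairs: Iterable[tuple[str, str]]) -> "AlignmentMatrix":
        taxa, rows = zip(*pairs)
        return cls(list(taxa), list(rows))
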