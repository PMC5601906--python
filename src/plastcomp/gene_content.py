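"""Gene inventory summaries: categories, IR duplication, introns, pseudogenes.

The package ships a reference inventory of the 115 unique genes found in
Nyssaceae-type plastomes (81 protein-coding, 30 tRNA, 4 rRNA), used both as
the classification dictionary and as a worked example.  Counting conventions
follow the standard plastome tabulation: a gene present in both inverted
repeats counts once among unique genes but is flagged IR-duplicated, the
trans-spliced rps12 is listed as two entries ("rps12" and "rps12*"), and
pseudogenes remain in all totals.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd

from .model import PlastomeRecord, PlastcompError, normalize_gene_name
from .structure import QuadripartiteStructure

ENTRY_COLUMNS = ["name", "category", "functional_group", "ir_duplicated", "introns", "pseudogene"]


class ClassificationError(PlastcompError):
    pass


@dataclass
class GeneInventory:
    """Per-gene entries plus the summary totals."""

    entries: pd.DataFrame  # columns ENTRY_COLUMNS
    unique_genes: int
    protein_coding: int
    trna: int
    rrna: int
    ir_duplicated_count: int
    intron_gene_count: int
    two_intron_count: int


def _totals(entries: pd.DataFrame) -> GeneInventory:
    cat = entries["category"].value_counts()
    inv = GeneInventory(
        entries=entries,
        unique_genes=len(entries),
        protein_coding=int(cat.get("protein_coding", 0)),
        trna=int(cat.get("tRNA", 0)),
        rrna=int(cat.get("rRNA", 0)),
        ir_duplicated_count=int(entries["ir_duplicated"].sum()),
        intron_gene_count=int((entries["introns"] > 0).sum()),
        two_intron_count=int((entries["introns"] == 2).sum()),
    )
    assert inv.unique_genes == inv.protein_coding + inv.trna + inv.rrna
    return inv


@lru_cache(maxsize=1)
def _reference_table() -> pd.DataFrame:
    path = importlib.resources.files("plastcomp.data") / "table2_genes.tsv"
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype={"pseudogene_in": "string"})
    df["pseudogene_in"] = df["pseudogene_in"].fillna("")
    return df


def load_reference_inventory(taxon: str | None = None) -> GeneInventory:
    """The packaged 115-gene reference inventory.

    ``taxon`` resolves the per-taxon pseudogene flags (ycf15 is pseudogenized
    only in *Davidia involucrata*); without it no entry is marked pseudogene
    except those flagged for every taxon.
    """
    df = _reference_table().copy()
    df["pseudogene"] = df["pseudogene_in"].map(
        lambda taxa: bool(taxa) and (taxon is not None and taxon in taxa.split(";"))
    )
    df["ir_duplicated"] = df["ir_duplicated"].astype(bool)
    return _totals(df[ENTRY_COLUMNS])


def classify_gene(name: str) -> tuple[str, str]:
    """(category, functional group) for a gene symbol.

    Known symbols come from the packaged reference inventory; unknown ones
    fall back to a prefix heuristic (trn->tRNA, rrn->rRNA, else
    protein-coding) with functional group "unknown".
    """
    norm = normalize_gene_name(name)
    table = _reference_table()
    hit = table[table["name"].str.lower() == norm.lower()]
    if len(hit):
        return hit.iloc[0]["category"], hit.iloc[0]["functional_group"]
    low = norm.lower()
    if low.startswith("trn"):
        return "tRNA", "unknown"
    if low.startswith("rrn"):
        return "rRNA", "unknown"
    return "protein_coding", "unknown"


def summarize_gene_content(
    rec: PlastomeRecord, qs: QuadripartiteStructure | None = None
) -> GeneInventory:
    """Summarize a record's annotation into a gene inventory.

    Features sharing a normalized name are one unique gene; a gene is
    IR-duplicated when it has two copies (linked by ``copy_of`` or by name)
    whose exons both lie within the IR intervals when a structure is given,
    or simply when two copies exist otherwise.  Intron count per entry is
    exons-1 of one copy; a gene is a pseudogene if any copy is flagged.
    """
    groups: dict[str, list] = {}
    for f in rec.features:
        if f.category not in ("protein_coding", "tRNA", "rRNA"):
            raise ClassificationError(f"feature {f.name}: unknown category")
        key = normalize_gene_name(f.copy_of or f.name)
        groups.setdefault(key, []).append(f)

    def _in_ir(f) -> bool:
        if qs is None:
            return True
        return all(
            (qs.irb[0] <= s and e <= qs.irb[1]) or (qs.ira[0] <= s and e <= qs.ira[1])
            for s, e in f.exons
        )

    rows = []
    for name in sorted(groups):
        copies = groups[name]
        primary = copies[0]
        dup = len(copies) >= 2 and all(_in_ir(c) for c in copies)
        rows.append(
            {
                "name": name,
                "category": primary.category,
                "functional_group": primary.functional_group,
                "ir_duplicated": dup,
                "introns": max(c.intron_count for c in copies),
                "pseudogene": any(c.pseudogene for c in copies),
            }
        )
    entries = pd.DataFrame(rows, columns=ENTRY_COLUMNS)
    if not len(entries):
        entries = pd.DataFrame(columns=ENTRY_COLUMNS)
    return _totals(entries)


def inventory_table(inv: GeneInventory) -> pd.DataFrame:
    """Entry table plus a one-row totals summary, for TSV export."""
    return inv.entries.copy()
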