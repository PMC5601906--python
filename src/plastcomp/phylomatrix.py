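"""Shared-gene supermatrix, partition schemes, and a neighbor-joining tree.

Protein-coding genes present (and not pseudogenized) in every input genome
are spliced, aligned per gene, and concatenated in lexicographic name order.
Four partition schemes are emitted for downstream model selection and
inference: S1 all columns in one subset; S2 three subsets by codon position;
S3 one subset per gene (k subsets); S4 one subset per gene x codon position
(3k subsets).  Tree inference proper (ML/Bayesian) is out of scope here — the
module writes the inputs those tools consume (relaxed PHYLIP, NEXUS with
charsets, RAxML-style partition files) and offers a distance-based
neighbor-joining tree as lightweight plumbing.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .model import (
    AlignmentMatrix,
    GeneFeature,
    PlastomeRecord,
    PlastcompError,
    normalize_gene_name,
)


class TaxonSetMismatchError(PlastcompError):
    pass


class DistanceUndefinedError(PlastcompError):
    pass


class SchemeError(PlastcompError):
    pass


@dataclass
class PartitionedSupermatrix:
    alignment: AlignmentMatrix
    gene_blocks: list[tuple[str, int, int]]  # (gene, start, end), tiling
    out_of_frame: set[str] = field(default_factory=set)

    @property
    def taxa(self) -> list[str]:
        return self.alignment.taxa

    @property
    def n_columns(self) -> int:
        return self.alignment.n_columns


def extract_shared_cds(
    records: list[PlastomeRecord],
) -> tuple[dict[str, dict[str, str]], list[str]]:
    """Spliced CDS of every gene shared by all records.

    A gene qualifies when a non-pseudogene protein-coding annotation exists
    in every record; IR-duplicated genes contribute one copy.  Returns
    (gene -> taxon -> sequence, frame warnings); genes whose CDS length is
    not a multiple of 3 are retained but flagged.
    """
    if len(records) < 2:
        raise PlastcompError("need at least two records")
    per_rec: list[dict[str, GeneFeature]] = []
    for rec in records:
        genes: dict[str, GeneFeature] = {}
        for f in rec.features:
            if f.category != "protein_coding" or f.pseudogene:
                continue
            key = normalize_gene_name(f.copy_of or f.name)
            genes.setdefault(key, f)  # first copy wins for IR duplicates
        per_rec.append(genes)
    shared = set(per_rec[0])
    for genes in per_rec[1:]:
        shared &= set(genes)
    out: dict[str, dict[str, str]] = {}
    warnings: list[str] = []
    for gene in sorted(shared):
        seqs = {
            rec.id: genes[gene].spliced(rec.sequence)
            for rec, genes in zip(records, per_rec)
        }
        for taxon, seq in seqs.items():
            if len(seq) % 3:
                warnings.append(f"{gene}/{taxon}: CDS length {len(seq)} not a multiple of 3")
        out[gene] = seqs
    return out, warnings


def concatenate(gene_alignments: dict[str, AlignmentMatrix]) -> PartitionedSupermatrix:
    """Concatenate per-gene alignments in lexicographic gene-name order."""
    if not gene_alignments:
        raise PlastcompError("no gene alignments to concatenate")
    names = sorted(gene_alignments)
    taxon_sets = {name: frozenset(gene_alignments[name].taxa) for name in names}
    reference = taxon_sets[names[0]]
    offenders = [n for n in names if taxon_sets[n] != reference]
    if offenders:
        raise TaxonSetMismatchError(f"taxon sets differ for genes: {offenders}")
    taxa = sorted(reference)
    blocks: list[tuple[str, int, int]] = []
    out_of_frame: set[str] = set()
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 0
    for name in names:
        aln = gene_alignments[name]
        width = aln.n_columns
        blocks.append((name, pos, pos + width))
        if width % 3:
            out_of_frame.add(name)
        for t in taxa:
            pieces[t].append(aln.row(t))
        pos += width
    sm = AlignmentMatrix(taxa, ["".join(pieces[t]) for t in taxa])
    return PartitionedSupermatrix(sm, blocks, out_of_frame)


def build_partition_schemes(sm: PartitionedSupermatrix) -> dict[str, dict[str, list[int]]]:
    """The four standard schemes as scheme -> subset name -> column indices.

    S1: one subset; S2: by codon position (3); S3: by gene (k); S4: by gene x
    codon position (3k).  Codon position is (column - block start) mod 3 + 1,
    assuming each annotated CDS begins in frame; out-of-frame genes are
    excluded from S2/S4.
    """
    ncol = sm.n_columns
    schemes: dict[str, dict[str, list[int]]] = {
        "S1": {"all": list(range(ncol))},
        "S2": {f"pos{i}": [] for i in (1, 2, 3)},
        "S3": {},
        "S4": {},
    }
    for gene, start, end in sm.gene_blocks:
        schemes["S3"][gene] = list(range(start, end))
        if gene in sm.out_of_frame:
            continue
        for c in range(start, end):
            p = (c - start) % 3 + 1
            schemes["S2"][f"pos{p}"].append(c)
            schemes["S4"].setdefault(f"{gene}_pos{p}", []).append(c)
    for gene in sm.out_of_frame:
        if gene not in {g for g, _, _ in sm.gene_blocks}:
            raise SchemeError(f"unknown out-of-frame gene {gene}")
    return schemes


def scheme_sizes(schemes: dict[str, dict[str, list[int]]]) -> dict[str, int]:
    return {name: len(subsets) for name, subsets in schemes.items()}


# ---------------------------------------------------------------------------
# distances and neighbor joining


def pairwise_distances(aln: AlignmentMatrix, model: str = "JC69") -> np.ndarray:
    """Pairwise distances ignoring gap/N sites.

    ``p`` is the raw proportion of differing comparable sites; ``JC69``
    applies the Jukes-Cantor correction d = -3/4 ln(1 - 4p/3).
    """
    if model not in ("p", "JC69"):
        raise ValueError(f"unknown distance model {model!r}")
    m = aln.matrix
    valid = (m != b"-") & (m != b"N")
    k = aln.n_taxa
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = valid[i] & valid[j]
            n_comp = int(both.sum())
            if n_comp == 0:
                raise DistanceUndefinedError(
                    f"no comparable columns between {aln.taxa[i]} and {aln.taxa[j]}"
                )
            p = float((m[i][both] != m[j][both]).sum()) / n_comp
            if model == "JC69":
                if p >= 0.75:
                    raise DistanceUndefinedError(
                        f"JC69 undefined at p={p:.3f} for {aln.taxa[i]}/{aln.taxa[j]}"
                    )
                dist = -0.75 * math.log1p(-4.0 * p / 3.0)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return d


def nj_tree(
    sm: PartitionedSupermatrix | AlignmentMatrix, distance: str = "JC69"
) -> dendropy.Tree:
    """Unrooted neighbor-joining tree from the supermatrix.

    Taxa are sorted by label before distances are computed, so the result is
    invariant under input order; ties resolve deterministically.
    """
    aln = sm.alignment if isinstance(sm, PartitionedSupermatrix) else sm
    if aln.n_taxa < 3:
        raise PlastcompError("need at least three taxa for a neighbor-joining tree")
    order = sorted(range(aln.n_taxa), key=lambda i: aln.taxa[i])
    sorted_aln = AlignmentMatrix(
        [aln.taxa[i] for i in order], [aln.row(aln.taxa[i]) for i in order]
    )
    d = pairwise_distances(sorted_aln, distance)
    buf = io.StringIO()
    buf.write("," + ",".join(sorted_aln.taxa) + "\n")
    for i, t in enumerate(sorted_aln.taxa):
        buf.write(t + "," + ",".join(f"{x:.10f}" for x in d[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        buf, taxon_namespace=dendropy.TaxonNamespace(sorted_aln.taxa)
    )
    tree = pdm.nj_tree()
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# writers


def tree_to_newick(tree: dendropy.Tree, precision: int = 8) -> str:
    """Canonical newick for an unrooted tree: rerooted at the vertex next to
    the alphabetically first taxon, children ordered by smallest descendant
    label, branch lengths at fixed precision — byte-stable across runs."""
    tree = tree.clone(depth=1)
    first = min(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    if first.parent_node is not tree.seed_node:
        tree.reroot_at_node(first.parent_node, suppress_unifurcations=True)

    def fmt(node) -> str:
        length = node.edge.length or 0.0
        suffix = f":{length:.{precision}f}"
        if node.is_leaf():
            return node.taxon.label.replace(" ", "_") + suffix
        parts = sorted(
            (min(lf.taxon.label for lf in ch.leaf_iter()), fmt(ch))
            for ch in node.child_nodes()
        )
        return "(" + ",".join(p for _, p in parts) + ")" + suffix

    root = tree.seed_node
    parts = sorted(
        (min(lf.taxon.label for lf in ch.leaf_iter()), fmt(ch))
        for ch in root.child_nodes()
    )
    return "(" + ",".join(p for _, p in parts) + ");"


def to_phylip(sm: PartitionedSupermatrix) -> str:
    """Relaxed PHYLIP (full taxon names, space-separated)."""
    aln = sm.alignment
    lines = [f" {aln.n_taxa} {aln.n_columns}"]
    width = max(len(t) for t in aln.taxa) + 2
    for t in aln.taxa:
        lines.append(t.ljust(width) + aln.row(t))
    return "\n".join(lines) + "\n"


def _ranges(cols: list[int]) -> list[tuple[int, int, int]]:
    """Compress sorted columns into (start, end, stride) runs, 0-based."""
    if not cols:
        return []
    runs = []
    start = prev = cols[0]
    stride = None
    for c in cols[1:]:
        step = c - prev
        if stride is None:
            stride = step
            prev = c
        elif step == stride:
            prev = c
        else:
            runs.append((start, prev, stride or 1))
            start = prev = c
            stride = None
    runs.append((start, prev, stride or 1))
    return runs


def _charset_expr(cols: list[int]) -> str:
    parts = []
    for s, e, stride in _ranges(cols):
        if s == e:
            parts.append(f"{s + 1}")
        elif stride == 1:
            parts.append(f"{s + 1}-{e + 1}")
        else:
            parts.append(f"{s + 1}-{e + 1}\\{stride}")
    return " ".join(parts)


def to_raxml_partitions(sm: PartitionedSupermatrix, scheme: dict[str, list[int]]) -> str:
    """RAxML-style partition file (``DNA, name = ranges``)."""
    return "".join(
        f"DNA, {name} = {_charset_expr(sorted(cols))}\n"
        for name, cols in scheme.items()
        if cols
    )


def to_nexus(sm: PartitionedSupermatrix, scheme: dict[str, list[int]] | None = None) -> str:
    """NEXUS data block with optional charsets for a partition scheme."""
    aln = sm.alignment
    out = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={aln.n_taxa} NCHAR={aln.n_columns};",
        "  FORMAT DATATYPE=DNA MISSING=N GAP=-;",
        "  MATRIX",
    ]
    width = max(len(t) for t in aln.taxa) + 2
    for t in aln.taxa:
        out.append("    " + t.ljust(width) + aln.row(t))
    out += ["  ;", "END;"]
    if scheme:
        out.append("BEGIN SETS;")
        for name, cols in scheme.items():
            if cols:
                out.append(f"  CHARSET {name} = {_charset_expr(sorted(cols))};")
        out.append("END;")
    return "\n".join(out) + "\n"
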