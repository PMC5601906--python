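"""Synthetic quadripartite plastomes with known structure, SNPs and tree.

The generator builds a random ancestor genome with an exactly planted
inverted-repeat pair (IRa = reverse complement of IRb), annotates it from a
gene template, and evolves it along a newick tree: per branch, each site
mutates independently with probability branch_length x site rate multiplier,
the mutated base drawn uniformly from the three alternatives (a Jukes-Cantor
-like scheme).  Mutations are drawn only in LSC, SSC and IRb; IRa is rewritten
as the reverse complement of IRb after every branch, emulating the copy
correction that keeps plastid IRs near-identical and their observed
divergence low.  No indels are introduced, so the leaf sequences are a
positionally exact alignment and the planted SNP columns are unambiguous.

Site rate multipliers compose region x coding-class x per-gene factors; the
defaults produce the divergence gradient characteristic of plastomes
(IR lowest, coding below non-coding, SSC highest).  A few genes carry an
elevated per-gene factor ("hot" marker candidates); one hot gene is longer
than the usable marker range so the length filter of the hotspot screen is
exercised.

Randomness comes from one seeded generator consumed in a fixed order:
ancestor bases first, then branches in newick preorder (sites ascending
within each branch), so identical config + seed reproduce byte-identical
output.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np

from .model import AlignmentMatrix, GeneFeature, PlastomeRecord, PlastcompError
from .plastome_io import write_fasta, write_genbank
from .structure import QuadripartiteStructure
from .divergence import reference_labels

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class LayoutError(PlastcompError):
    pass


class RateConfigError(PlastcompError):
    pass


@dataclass
class GeneSpec:
    """A gene to plant: absolute exon coordinates in the ancestor frame."""

    name: str
    category: str
    strand: str
    exons: list[tuple[int, int]]
    functional_group: str = "unknown"
    pseudogene: bool = False
    copy_of: str | None = None
    rate_mult: float = 1.0

    @property
    def hot(self) -> bool:
        return self.rate_mult > 1.0


#: six-taxon tree emulating a small Cornales-like clade (two nested sisters,
#: then two successively deeper branches and two outgroups); branch lengths
#: in expected substitutions/site at multiplier 1
DEFAULT_TREE = (
    "((((Nyssa:0.0020,Camptotheca:0.0022):0.0016,Davidia:0.0042):0.0018,"
    "Diplopanax:0.0060):0.0025,Hydrangea:0.0080,Swida:0.0085);"
)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated clade (scaled-down plastomes)."""

    lsc: int = 11000
    ssc: int = 4600
    ir: int = 2600
    tree: str = DEFAULT_TREE
    r_lsc: float = 1.0
    r_ssc: float = 2.4
    r_ir: float = 0.4
    r_coding: float = 0.5
    r_noncoding: float = 1.05
    hot_mult: float = 4.0
    seed: int = 0
    # base composition approximating plastome AT richness (A, C, G, T)
    base_probs: tuple[float, float, float, float] = (0.315, 0.185, 0.185, 0.315)
    genes: list[GeneSpec] | None = None  # None -> default template

    @property
    def total(self) -> int:
        return self.lsc + self.ssc + 2 * self.ir

    def __post_init__(self) -> None:
        if min(self.lsc, self.ssc, self.ir) <= 0:
            raise LayoutError("region lengths must be positive")
        if self.lsc == self.ssc:
            raise LayoutError("LSC and SSC must differ in length")
        for r in (self.r_lsc, self.r_ssc, self.r_ir, self.r_coding, self.r_noncoding):
            if r < 0:
                raise RateConfigError("rate multipliers must be >= 0")


def default_gene_map(cfg: SimulationConfig) -> list[GeneSpec]:
    """The default template: ~17 genes with the diagnostic border layout.

    Requires the default region sizes (or larger).  Plants rps19 spanning the
    LSC/IRb junction, a truncated ycf1 pseudogene spanning IRb/SSC that
    overlaps ndhF by 25 bp, ycf1 spanning SSC/IRa, rpl2 ending near IRa/LSC
    with trnH just inside the LSC, and mirrored IR copies of rpl2 and rrn16.

    Hot marker candidates mimic the usual pattern of SSC-enriched hotspots:
    rps15, ccsA and ndhG sit in the SSC, rpl22 and the junction gene rps19 in
    the LSC.  Two hot genes fall outside the usable marker length range —
    accD (too long) and psbI (too short) — to exercise the screen's length
    filter.  Strongly conserved SSC genes (ndhF, ycf1 and its pseudogene)
    carry a reduced factor, as is typical of these genes relative to the SSC
    background.
    """
    L, S, R = cfg.lsc, cfg.ssc, cfg.ir
    if L < 11000 or S < 4600 or R < 2600:
        raise LayoutError(
            f"default gene template needs lsc>=11000, ssc>=4600, ir>=2600; "
            f"got {L}/{S}/{R}"
        )
    N = cfg.total
    jlb, jsb, jsa = L, L + R, L + R + S
    hot = cfg.hot_mult

    def mirror(a: int, b: int) -> tuple[int, int]:
        # IRb interval [a,b) -> its reverse-complement image in IRa
        return (N + L) - b, (N + L) - a

    genes = [
        GeneSpec("trnH_GUG", "tRNA", "+", [(10, 85)], "Transfer RNA genes"),
        GeneSpec("psbA", "protein_coding", "-", [(300, 1362)]),
        GeneSpec("matK", "protein_coding", "+", [(1900, 3400)]),
        GeneSpec("rpl22", "protein_coding", "+", [(3800, 4250)], rate_mult=hot),
        GeneSpec("atpF", "protein_coding", "+", [(4600, 5011), (5200, 5410)]),
        GeneSpec("accD", "protein_coding", "+", [(5800, 7501)], rate_mult=2.0),
        GeneSpec("rpoB", "protein_coding", "+", [(8000, 8900)]),
        GeneSpec("psbI", "protein_coding", "+", [(9200, 9449)], rate_mult=hot),
        # spans JLB: 200 bp in the LSC, 79 bp into IRb
        GeneSpec("rps19", "protein_coding", "+", [(jlb - 200, jlb + 79)], rate_mult=6.0),
        GeneSpec("rpl2", "protein_coding", "+", [(jlb + 200, jlb + 1700)]),
        GeneSpec("rrn16", "rRNA", "+", [(jlb + 1740, jlb + 2140)], "Ribosomal RNA genes"),
        # truncated ycf1 copy spanning JSB: 400 bp in IRb, 300 bp into SSC
        GeneSpec(
            "ycf1_psi", "protein_coding", "+", [(jsb - 400, jsb + 300)],
            pseudogene=True, rate_mult=0.3,
        ),
        # overlaps the ycf1 pseudogene by 25 bp
        GeneSpec("ndhF", "protein_coding", "-", [(jsb + 275, jsb + 1775)], rate_mult=0.3),
        GeneSpec("rps15", "protein_coding", "+", [(jsb + 2000, jsb + 2300)], rate_mult=2.5),
        GeneSpec("ccsA", "protein_coding", "+", [(jsb + 2500, jsb + 2899)], rate_mult=2.5),
        GeneSpec("ndhG", "protein_coding", "+", [(jsb + 3100, jsb + 3631)], rate_mult=2.5),
        # spans JSA: 300 bp in SSC, 300 bp into IRa
        GeneSpec("ycf1", "protein_coding", "-", [(jsa - 300, jsa + 300)], rate_mult=0.3),
        GeneSpec("rrn16", "rRNA", "+", [mirror(jlb + 1740, jlb + 2140)],
                 "Ribosomal RNA genes", copy_of="rrn16"),
        GeneSpec("rpl2", "protein_coding", "-", [mirror(jlb + 200, jlb + 1700)],
                 copy_of="rpl2"),
    ]
    return genes


def _features(genes: list[GeneSpec]) -> list[GeneFeature]:
    feats = []
    for g in genes:
        exons = sorted(g.exons, reverse=(g.strand == "-"))
        feats.append(
            GeneFeature(
                name=g.name,
                category=g.category,
                strand=g.strand,
                exons=exons,
                functional_group=g.functional_group,
                pseudogene=g.pseudogene,
                copy_of=g.copy_of,
            )
        )
    return feats


def _planted_structure(cfg: SimulationConfig) -> QuadripartiteStructure:
    L, S, R, N = cfg.lsc, cfg.ssc, cfg.ir, cfg.total
    return QuadripartiteStructure(
        lsc=(0, L), irb=(L, L + R), ssc=(L + R, L + R + S), ira=(L + R + S, N),
        total_length=N,
    )


def _enforce_boundary_guards(arr: np.ndarray, cfg: SimulationConfig) -> None:
    """Keep the planted IR maximal: break chance complementarity just outside
    each repeat end so the detected boundaries equal the planted ones."""
    L, R, S = cfg.lsc, cfg.ir, cfg.ssc
    # outer flank: last LSC base vs (circularly) first LSC base
    if arr[L - 1] == 3 - arr[0]:
        arr[L - 1] = (arr[L - 1] + 1) % 4
    # inner flank: first SSC base vs last SSC base
    if arr[L + R] == 3 - arr[L + R + S - 1]:
        arr[L + R] = (arr[L + R] + 1) % 4


def _mirror_ir(arr: np.ndarray, cfg: SimulationConfig) -> None:
    L, R, S, N = cfg.lsc, cfg.ir, cfg.ssc, cfg.total
    arr[L + R + S : N] = (3 - arr[L : L + R])[::-1]


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def build_ancestor(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[PlastomeRecord, QuadripartiteStructure]:
    """Random ancestor with the planted IR pair and template annotation."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genes = default_gene_map(cfg) if cfg.genes is None else cfg.genes
    N = cfg.total
    core = rng.choice(4, size=cfg.lsc + cfg.ir + cfg.ssc, p=cfg.base_probs)
    arr = np.empty(N, dtype=np.int64)
    arr[: cfg.lsc + cfg.ir + cfg.ssc] = core
    _mirror_ir(arr, cfg)
    _enforce_boundary_guards(arr, cfg)
    _mirror_ir(arr, cfg)  # guards touch single-copy bases only; keep IRs exact
    for g in genes:
        for s, e in g.exons:
            if not (0 <= s < e <= N):
                raise LayoutError(f"gene {g.name} exon [{s},{e}) outside genome of {N} bp")
    rec = PlastomeRecord("ancestor", _to_str(arr), circular=True, features=_features(genes))
    return rec, _planted_structure(cfg)


def site_rates(cfg: SimulationConfig, rec: PlastomeRecord) -> np.ndarray:
    """Per-site rate multipliers; IRa sites are 0 (they mirror IRb)."""
    qs = _planted_structure(cfg)
    N = cfg.total
    region_mult = np.empty(N)
    region_mult[qs.lsc[0] : qs.lsc[1]] = cfg.r_lsc
    region_mult[qs.irb[0] : qs.irb[1]] = cfg.r_ir
    region_mult[qs.ssc[0] : qs.ssc[1]] = cfg.r_ssc
    region_mult[qs.ira[0] : qs.ira[1]] = 0.0
    class_mult = np.full(N, cfg.r_noncoding)
    for f in rec.features:
        for s, e in f.exons:
            class_mult[s:e] = cfg.r_coding
    gene_mult = np.ones(N)
    genes = cfg.genes if cfg.genes is not None else default_gene_map(cfg)
    for g in genes:  # where hot and cold genes overlap, the hot factor wins
        for s, e in g.exons:
            if g.rate_mult >= 1:
                gene_mult[s:e] = np.maximum(gene_mult[s:e], g.rate_mult)
            else:
                gene_mult[s:e] = np.minimum(gene_mult[s:e], g.rate_mult)
    return region_mult * class_mult * gene_mult


@dataclass
class SimulationTruth:
    """Everything the generator knows: the oracle for downstream modules."""

    config: SimulationConfig
    ancestor: PlastomeRecord
    structure: QuadripartiteStructure
    records: dict[str, PlastomeRecord]
    alignment: AlignmentMatrix
    snp_columns: np.ndarray
    region: np.ndarray
    coding: np.ndarray
    feature: np.ndarray
    site_rate: np.ndarray
    branch_substitutions: dict[str, np.ndarray]
    tree: str
    hot_genes: list[str] = field(default_factory=list)

    @property
    def guard_sites(self) -> tuple[int, int]:
        """The two single-copy sites adjusted by the IR-maximality guard."""
        cfg = self.config
        return (cfg.lsc - 1, cfg.lsc + cfg.ir)


def evolve(
    ancestor: PlastomeRecord,
    cfg: SimulationConfig,
    structure: QuadripartiteStructure | None = None,
) -> SimulationTruth:
    """Evolve the ancestor along the configured tree; return the full truth."""
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise RateConfigError("tree must have at least two leaves")
    rng = np.random.default_rng(cfg.seed)
    rng.choice(4, size=cfg.lsc + cfg.ir + cfg.ssc, p=cfg.base_probs)  # ancestor draw slot
    anc_arr = np.frombuffer(ancestor.sequence.encode(), dtype="S1")
    anc_idx = np.searchsorted(_BASES, anc_arr).astype(np.int64)
    rates = site_rates(cfg, ancestor)

    states: dict[int, np.ndarray] = {id(tree.seed_node): anc_idx}
    branch_subs: dict[str, np.ndarray] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        p = t * rates
        if np.any(p > 1.0):
            raise RateConfigError(
                f"branch length {t} with max multiplier {rates.max():.3g} "
                "yields per-site probability > 1"
            )
        parent = states[id(node.parent_node)]
        child = parent.copy()
        if t > 0:
            u = rng.random(len(child))
            sites = np.flatnonzero(u < p)
            if len(sites):
                off = rng.integers(1, 4, size=len(sites))
                child[sites] = (child[sites] + off) % 4
        _mirror_ir(child, cfg)
        _enforce_boundary_guards(child, cfg)
        states[id(node)] = child
        counter += 1
        label = node.taxon.label if node.taxon else f"node{counter}"
        branch_subs[label] = np.flatnonzero(child != parent)

    records = {}
    rows = []
    for lf in tree.leaf_node_iter():
        name = lf.taxon.label
        seq = _to_str(states[id(lf)])
        records[name] = PlastomeRecord(
            name, seq, circular=True,
            features=[replace(f) for f in ancestor.features],
        )
        rows.append((name, seq))
    aln = AlignmentMatrix.from_rows(rows)
    snp_columns = np.flatnonzero((aln.matrix != aln.matrix[0]).any(axis=0))
    qs = structure or _planted_structure(cfg)
    region, coding, feature = reference_labels(ancestor, qs)
    genes = cfg.genes if cfg.genes is not None else default_gene_map(cfg)
    hot = sorted({g.name for g in genes if g.hot})
    return SimulationTruth(
        config=cfg,
        ancestor=ancestor,
        structure=qs,
        records=records,
        alignment=aln,
        snp_columns=snp_columns,
        region=region,
        coding=coding,
        feature=feature,
        site_rate=rates,
        branch_substitutions=branch_subs,
        tree=cfg.tree,
        hot_genes=hot,
    )


def simulate(cfg: SimulationConfig) -> SimulationTruth:
    """build_ancestor + evolve under one seed."""
    anc, qs = build_ancestor(cfg)
    return evolve(anc, cfg, qs)


def emit(truth: SimulationTruth, outdir: str | os.PathLike) -> list[Path]:
    """Write the simulated clade and its truth tables to ``outdir``.

    Per taxon: GenBank + FASTA.  Clade-wide: the whole-genome alignment, one
    aligned FASTA per shared gene, the true tree, a per-column truth table
    (region/coding/feature labels and SNP flags), and a JSON summary with the
    planted boundaries and hot genes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "genes").mkdir(exist_ok=True)
    written = []
    for name, rec in truth.records.items():
        gb, fa = outdir / f"{name}.gb", outdir / f"{name}.fasta"
        write_genbank(rec, gb)
        write_fasta([(name, rec.sequence)], fa)
        written += [gb, fa]
    aln_path = outdir / "whole_genome.aln.fasta"
    write_fasta([(t, truth.alignment.row(t)) for t in truth.alignment.taxa], aln_path)
    written.append(aln_path)
    seen = set()
    for f in truth.ancestor.features:
        if f.category != "protein_coding" or f.pseudogene:
            continue
        gene = f.copy_of or f.name
        if gene in seen:
            continue
        seen.add(gene)
        path = outdir / "genes" / f"{gene}.aln.fasta"
        write_fasta(
            [(t, truth.records[t].feature_by_name(f.name).spliced(truth.records[t].sequence))
             for t in truth.alignment.taxa],
            path,
        )
        written.append(path)
    tree_path = outdir / "true_tree.nwk"
    tree_path.write_text(truth.tree + "\n")
    written.append(tree_path)
    snp_mask = np.zeros(truth.config.total, dtype=bool)
    snp_mask[truth.snp_columns] = True
    cols_path = outdir / "truth_columns.tsv"
    with open(cols_path, "w") as fh:
        fh.write("column\tregion\tcoding\tfeature\tis_snp\n")
        for i in range(truth.config.total):
            fh.write(
                f"{i}\t{truth.region[i]}\t{truth.coding[i]}\t{truth.feature[i]}"
                f"\t{int(snp_mask[i])}\n"
            )
    written.append(cols_path)
    qs = truth.structure
    summary = {
        "seed": truth.config.seed,
        "total_length": truth.config.total,
        "regions": {"LSC": qs.lsc, "IRb": qs.irb, "SSC": qs.ssc, "IRa": qs.ira},
        "n_taxa": len(truth.records),
        "n_snp_columns": int(len(truth.snp_columns)),
        "hot_genes": truth.hot_genes,
    }
    summary_path = outdir / "truth.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    written.append(summary_path)
    return written
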