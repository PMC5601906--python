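"""End-to-end comparative analysis: structure, genes, junctions, divergence,
hotspots, supermatrix — each stage a thin call into the library modules,
emitting diff-able TSVs plus a hashed MANIFEST.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import divergence as dv
from . import gene_content as gc
from . import junctions as jx
from . import phylomatrix as pm
from . import structure as st
from .model import AlignmentMatrix, PlastomeRecord, PlastcompError
from .plastome_io import read_alignment, read_genbank
from .simulate import SimulationConfig, emit, simulate


class StageError(PlastcompError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: Path
    genome_paths: list[Path] = field(default_factory=list)
    alignment_path: Path | None = None
    gene_aln_dir: Path | None = None
    reference: str | None = None  # default: first genome
    min_ir_len: int = 1000
    ir_max_mismatches: int = 0
    hotspot_min_len: int = 250
    hotspot_max_len: int = 1500
    hotspot_min_div: float = 3.5
    simulate: bool = False
    seed: int = 0
    sim_config: SimulationConfig | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return path


def structure_stage(
    records: list[PlastomeRecord], cfg: PipelineConfig
) -> tuple[list[PlastomeRecord], dict[str, st.QuadripartiteStructure], pd.DataFrame]:
    """Detect IRs, partition and measure every genome; Table-1-style rows."""
    rotated, structures, rows = [], {}, []
    for rec in records:
        pair = st.detect_inverted_repeats(
            rec, min_len=cfg.min_ir_len, max_mismatches=cfg.ir_max_mismatches
        )
        rot, qs = st.partition_genome(rec, pair, max_mismatches=cfg.ir_max_mismatches)
        qs = st.region_metrics(rot, qs)
        rotated.append(rot)
        structures[rec.id] = qs
        rows.append(
            {
                "species": rec.id,
                "total_bp": qs.total_length,
                "total_gc": qs.region_gc["total"],
                "lsc_bp": qs.lsc_length,
                "lsc_gc": qs.region_gc["LSC"],
                "ssc_bp": qs.ssc_length,
                "ssc_gc": qs.region_gc["SSC"],
                "ir_bp": qs.ir_length,
                "ir_gc": qs.region_gc["IR"],
                "coding_bp": qs.coding_length,
                "coding_gc": qs.coding_gc,
                "noncoding_bp": qs.noncoding_length,
                "noncoding_gc": qs.noncoding_gc,
            }
        )
    return rotated, structures, pd.DataFrame(rows)


def inventory_stage(
    records: list[PlastomeRecord], structures: dict[str, st.QuadripartiteStructure]
) -> pd.DataFrame:
    rows = []
    for rec in records:
        inv = gc.summarize_gene_content(rec, structures.get(rec.id))
        rows.append(
            {
                "genome": rec.id,
                "unique_genes": inv.unique_genes,
                "protein_coding": inv.protein_coding,
                "trna": inv.trna,
                "rrna": inv.rrna,
                "ir_duplicated": inv.ir_duplicated_count,
                "intron_genes": inv.intron_gene_count,
                "two_intron_genes": inv.two_intron_count,
            }
        )
    return pd.DataFrame(rows)


def junction_stage(
    records: list[PlastomeRecord], structures: dict[str, st.QuadripartiteStructure]
) -> pd.DataFrame:
    reports = [jx.analyze_junctions(rec, structures[rec.id]) for rec in records]
    if len(reports) == 1:
        reports = reports * 2  # comparison table of a single genome
    return jx.compare_junctions(reports)


def divergence_stage(
    aln: AlignmentMatrix,
    reference_rec: PlastomeRecord,
    reference_qs: st.QuadripartiteStructure,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    dv.project_annotation(aln, reference_rec, reference_qs)
    snps = dv.call_snps(aln)
    table = dv.divergence_table(aln, snps)
    features = dv.per_feature_divergence(aln, snps)
    hotspots = dv.screen_hotspots(
        features,
        min_len=cfg.hotspot_min_len,
        max_len=cfg.hotspot_max_len,
        min_div=cfg.hotspot_min_div,
    )
    return table, features, hotspots


def supermatrix_stage(
    records: list[PlastomeRecord], cfg: PipelineConfig, outdir: Path
) -> list[Path]:
    shared, warnings = pm.extract_shared_cds(records)
    gene_alns: dict[str, AlignmentMatrix] = {}
    for gene, seqs in shared.items():
        if cfg.gene_aln_dir is not None:
            path = Path(cfg.gene_aln_dir) / f"{gene}.aln.fasta"
            if path.exists():
                gene_alns[gene] = read_alignment(path)
                continue
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise PlastcompError(
                f"gene {gene}: unaligned CDS of unequal lengths {sorted(lengths)}; "
                "provide a per-gene alignment directory"
            )
        gene_alns[gene] = AlignmentMatrix.from_rows(sorted(seqs.items()))
    sm = pm.concatenate(gene_alns)
    schemes = pm.build_partition_schemes(sm)
    written = []
    phy = outdir / "supermatrix.phy"
    phy.write_text(pm.to_phylip(sm))
    written.append(phy)
    nex = outdir / "supermatrix.nex"
    nex.write_text(pm.to_nexus(sm, schemes["S4"]))
    written.append(nex)
    for name, scheme in schemes.items():
        p = outdir / f"partitions_{name}.txt"
        p.write_text(pm.to_raxml_partitions(sm, scheme))
        written.append(p)
    tree = pm.nj_tree(sm)
    nwk = outdir / "nj_tree.nwk"
    nwk.write_text(pm.tree_to_newick(tree) + "\n")
    written.append(nwk)
    if warnings:
        w = outdir / "frame_warnings.txt"
        w.write_text("\n".join(warnings) + "\n")
        written.append(w)
    return written


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; emit TSVs, supermatrix files, MANIFEST and log."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    status = "complete"
    stage = "setup"
    try:
        if cfg.simulate:
            stage = "simulate"
            sim_cfg = cfg.sim_config or SimulationConfig(seed=cfg.seed)
            truth = simulate(sim_cfg)
            simdir = outdir / "sim"
            written += emit(truth, simdir)
            genome_paths = sorted(simdir.glob("*.gb"))
            alignment_path = simdir / "whole_genome.aln.fasta"
            gene_aln_dir = simdir / "genes"
        else:
            genome_paths = [Path(p) for p in cfg.genome_paths]
            alignment_path = cfg.alignment_path
            gene_aln_dir = cfg.gene_aln_dir
        if len(genome_paths) < 2:
            raise PlastcompError("need at least two genomes (or --simulate)")

        stage = "read"
        records = [read_genbank(p) for p in genome_paths]

        stage = "structure"
        rotated, structures, structure_df = structure_stage(records, cfg)
        written.append(_write_tsv(structure_df, outdir / "structure.tsv"))

        stage = "genes"
        written.append(
            _write_tsv(inventory_stage(rotated, structures), outdir / "inventory.tsv")
        )

        stage = "junctions"
        written.append(
            _write_tsv(junction_stage(rotated, structures), outdir / "junctions.tsv")
        )

        stage = "divergence"
        if alignment_path is not None:
            aln = read_alignment(alignment_path)
            ref_id = cfg.reference or aln.taxa[0]
            ref_rec = next(r for r in rotated if r.id == ref_id)
            table, features, hotspots = divergence_stage(
                aln, ref_rec, structures[ref_id],
                PipelineConfig(
                    outdir=outdir,
                    hotspot_min_len=cfg.hotspot_min_len,
                    hotspot_max_len=cfg.hotspot_max_len,
                    hotspot_min_div=cfg.hotspot_min_div,
                ),
            )
            written.append(_write_tsv(table, outdir / "divergence.tsv"))
            written.append(_write_tsv(features, outdir / "features.tsv"))
            written.append(_write_tsv(hotspots, outdir / "hotspots.tsv"))

        stage = "supermatrix"
        sm_cfg = PipelineConfig(outdir=outdir, gene_aln_dir=gene_aln_dir)
        written += supermatrix_stage(rotated, sm_cfg, outdir)
    except Exception as exc:
        status = "incomplete"
        _write_manifest(outdir, written, status, stage)
        raise StageError(stage, exc) from exc

    log = outdir / "run.log"
    log.write_text(
        json.dumps(
            {
                "seed": cfg.seed,
                "simulate": cfg.simulate,
                "min_ir_len": cfg.min_ir_len,
                "ir_max_mismatches": cfg.ir_max_mismatches,
                "hotspot_min_len": cfg.hotspot_min_len,
                "hotspot_max_len": cfg.hotspot_max_len,
                "hotspot_min_div": cfg.hotspot_min_div,
                "reference": cfg.reference,
                "n_genomes": len(genome_paths),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    written.append(log)
    manifest = _write_manifest(outdir, written, status, None)
    return {"status": status, "files": [str(p) for p in written], "manifest": str(manifest)}


def _write_manifest(
    outdir: Path, written: list[Path], status: str, failed_stage: str | None
) -> Path:
    manifest = {
        "status": status,
        "failed_stage": failed_stage,
        "files": {
            str(p.relative_to(outdir)): _sha256(p) for p in written if p.exists()
        },
    }
    path = outdir / "MANIFEST.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
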