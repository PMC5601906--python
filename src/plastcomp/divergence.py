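"""SNP divergence across a whole-genome multiple alignment.

A column is a SNP iff, ignoring gaps and N, it carries at least two distinct
bases — substitution-only counting; indel polymorphisms are not SNPs.
Columns are assigned to partitions (LSC/SSC/IR region, coding/non-coding,
per-feature) by projecting a reference taxon's annotation across the
alignment; character counts are alignment-column counts per partition, so
region and coding splits are always additive to the genome total.

Divergence proportion = 100 * SNPs / characters, reported half-up to two
decimals.  Hotspot screening retains protein-coding features in a usable
marker length range whose divergence strictly exceeds a threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gene_content import classify_gene
from .model import (
    AlignmentMatrix,
    EmptyInputError,
    PlastomeRecord,
    PlastcompError,
    round2,
)
from .structure import QuadripartiteStructure

_MISSING = (b"-", b"N")


class ProjectionError(PlastcompError):
    pass


class UndefinedProportionError(PlastcompError):
    pass


def call_snps(aln: AlignmentMatrix) -> np.ndarray:
    """Indices of SNP columns (>=2 distinct bases among non-missing chars)."""
    if aln.n_taxa < 2:
        raise EmptyInputError("need at least two taxa to call SNPs")
    m = aln.matrix.view(np.uint8)
    missing = (m == ord("-")) | (m == ord("N"))
    n_obs = (~missing).sum(axis=0)
    # a column is polymorphic iff its non-missing chars are not all equal
    anchor = np.where(missing, 0, m).max(axis=0)  # one non-missing char per column
    mismatch = ((m != anchor) & ~missing).any(axis=0)
    return np.flatnonzero(mismatch & (n_obs >= 2))


def reference_labels(
    rec: PlastomeRecord, qs: QuadripartiteStructure
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position (region, coding, feature) labels of an annotated genome.

    Non-coding positions get an intergenic-spacer label named after the
    flanking genes.  IRa and IRb both map to region "IR".
    """
    n = len(rec)
    region = np.empty(n, dtype=object)
    for name, (s, e) in (("LSC", qs.lsc), ("IR", qs.irb), ("SSC", qs.ssc), ("IR", qs.ira)):
        region[s:e] = name
    coding = np.full(n, "noncoding", dtype=object)
    feature = np.empty(n, dtype=object)
    spans = []
    for f in rec.features:
        for s, e in f.exons:
            coding[s:e] = "coding"
            feature[s:e] = f.name
        spans.append((f.start, f.name))
    for f in rec.features:  # intron positions: inside the span, outside exons
        for i in range(f.start, f.end):
            if feature[i] is None:
                feature[i] = f"{f.name}_intron"
    spans.sort()
    names = [nm for _, nm in spans]
    starts = [s for s, _ in spans]
    for i in range(n):
        if feature[i] is None:
            if spans:
                j = int(np.searchsorted(starts, i, side="right"))
                left = names[j - 1] if j > 0 else names[-1]
                right = names[j % len(names)]
                feature[i] = f"{left}-{right}"
            else:
                feature[i] = "intergenic"
    return region, coding, feature


def project_annotation(
    aln: AlignmentMatrix, rec: PlastomeRecord, qs: QuadripartiteStructure, reference: str | None = None
) -> AlignmentMatrix:
    """Label alignment columns from a reference taxon's annotation.

    Each column inherits the region/coding/feature label of the reference
    base aligned to it; columns where the reference has a gap inherit the
    labels of the preceding labeled reference position.
    """
    reference = reference or rec.id
    ref_row = aln.row(reference)
    ungapped = ref_row.replace("-", "")
    if ungapped != rec.sequence:
        raise ProjectionError(
            f"reference row {reference!r} does not match the annotated sequence"
        )
    region_pos, coding_pos, feature_pos = reference_labels(rec, qs)
    ncol = aln.n_columns
    region = np.empty(ncol, dtype=object)
    coding = np.empty(ncol, dtype=object)
    feature = np.empty(ncol, dtype=object)
    ref_arr = np.frombuffer(ref_row.encode(), dtype="S1")
    # per-column index of the governing reference base: the base at the
    # column, or the nearest preceding base for reference-gap columns
    is_base = ref_arr != b"-"
    idx = np.cumsum(is_base) - 1
    idx = np.clip(idx, 0, None)  # leading gap columns borrow the first base
    region[:] = region_pos[idx]
    coding[:] = coding_pos[idx]
    feature[:] = feature_pos[idx]
    aln.region, aln.coding, aln.feature = region, coding, feature
    return aln


def divergence_percent(snp_count: int, character_count: int) -> float:
    """Divergence proportion in %, half-up to 2 decimals."""
    if character_count == 0:
        raise UndefinedProportionError("zero characters in partition")
    return round2(100.0 * snp_count / character_count)


def divergence_table(aln: AlignmentMatrix, snps: np.ndarray) -> pd.DataFrame:
    """Per-partition SNP counts, character counts and divergence proportions.

    Rows: complete genome, coding, non-coding, LSC, SSC, IR.  Character
    counts are alignment column counts, so LSC+SSC+IR and coding+noncoding
    each sum to the total.
    """
    if not aln.has_labels():
        raise ProjectionError("column labels missing; run project_annotation first")
    snp_mask = np.zeros(aln.n_columns, dtype=bool)
    snp_mask[snps] = True
    rows = []

    def _row(name: str, mask: np.ndarray) -> None:
        chars = int(mask.sum())
        count = int((snp_mask & mask).sum())
        rows.append(
            {
                "partition": name,
                "snp_count": count,
                "character_count": chars,
                "divergence_pct": divergence_percent(count, chars),
            }
        )

    all_mask = np.ones(aln.n_columns, dtype=bool)
    _row("complete", all_mask)
    _row("coding", aln.coding == "coding")
    _row("noncoding", aln.coding == "noncoding")
    _row("LSC", aln.region == "LSC")
    _row("SSC", aln.region == "SSC")
    _row("IR", aln.region == "IR")
    return pd.DataFrame(rows)


def per_feature_divergence(aln: AlignmentMatrix, snps: np.ndarray) -> pd.DataFrame:
    """One row per gene and per intergenic spacer, in reference coordinates."""
    if aln.feature is None:
        raise ProjectionError("feature labels missing; run project_annotation first")
    snp_mask = np.zeros(aln.n_columns, dtype=bool)
    snp_mask[snps] = True
    df = pd.DataFrame(
        {"feature": aln.feature, "coding": aln.coding, "snp": snp_mask}
    )
    grouped = (
        df.groupby(["feature", "coding"], sort=True)
        .agg(length_bp=("snp", "size"), snp_count=("snp", "sum"))
        .reset_index()
    )
    grouped["divergence_pct"] = [
        divergence_percent(int(s), int(c))
        for s, c in zip(grouped["snp_count"], grouped["length_bp"])
    ]
    grouped["kind"] = [
        classify_gene(name)[0] if coding == "coding" else "intergenic"
        for name, coding in zip(grouped["feature"], grouped["coding"])
    ]
    return grouped[["feature", "kind", "coding", "length_bp", "snp_count", "divergence_pct"]]


def screen_hotspots(
    feature_table: pd.DataFrame,
    min_len: int = 250,
    max_len: int = 1500,
    min_div: float = 3.5,
) -> pd.DataFrame:
    """Rank candidate marker genes: protein-coding, usable length, divergent.

    Retains protein-coding features with min_len <= length <= max_len
    (inclusive) and divergence strictly above ``min_div`` %; sorted by
    divergence descending, ties by length descending then name.
    """
    if not len(feature_table):
        return feature_table.copy()
    keep = (
        (feature_table["kind"] == "protein_coding")
        & (feature_table["length_bp"] >= min_len)
        & (feature_table["length_bp"] <= max_len)
        & (feature_table["divergence_pct"] > min_div)
    )
    out = feature_table[keep].sort_values(
        ["divergence_pct", "length_bp", "feature"], ascending=[False, False, True]
    )
    return out.reset_index(drop=True)
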