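"""Region-boundary (junction) neighborhoods: border genes, IR extensions, overlaps.

The four junctions of a quadripartite plastome are JLB (LSC/IRb), JSB
(IRb/SSC), JSA (SSC/IRa) and JLA (IRa/LSC, at the canonical origin).  Gene
positions relative to them are diagnostic of IR expansion and contraction:
e.g. rps19 spanning JLB marks IRb expansion into the LSC, and the truncated
ycf1 pseudogene at JSB marks IRb expansion into the SSC.  In Cornales the
IRa/LSC boundary falls between rpl2 and trnH, a configuration flagged here as
a candidate diagnostic character.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import PlastomeRecord, PlastcompError, normalize_gene_name
from .structure import QuadripartiteStructure

#: left/right region flanking each junction in the canonical rotation
JUNCTION_SIDES = {
    "JLB": ("LSC", "IRb"),
    "JSB": ("IRb", "SSC"),
    "JSA": ("SSC", "IRa"),
    "JLA": ("IRa", "LSC"),
}

JUNCTION_ORDER = ("JLB", "JSB", "JSA", "JLA")


class JunctionsUndefinedError(PlastcompError):
    pass


@dataclass
class JunctionEntry:
    junction: str
    gene: str
    pseudogene: bool
    spanning: bool
    # spanning gene: bp on each side of the junction; else signed distance
    # (positive bp into the named side's region, 0 if abutting)
    left_bp: int = 0
    right_bp: int = 0
    side: str = ""  # for non-spanning genes: region the gene lies in
    distance_bp: int = 0


@dataclass
class JunctionReport:
    genome: str
    entries: list[JunctionEntry] = field(default_factory=list)
    overlaps: list[tuple[str, str, int]] = field(default_factory=list)
    rpl2_trnh_at_jla: bool = False


def _spans(rec: PlastomeRecord) -> list[tuple[str, bool, int, int]]:
    """(name, pseudogene, start, end) spans; wrap features unrolled past n."""
    n = len(rec)
    out = []
    for f in rec.features:
        if f.wraps_origin:
            high = [iv for iv in f.exons if iv[1] > n // 2]
            low = [iv for iv in f.exons if iv[1] <= n // 2]
            s = min(iv[0] for iv in high)
            e = max(iv[1] for iv in low) + n
        else:
            s, e = f.start, f.end
        out.append((f.name, f.pseudogene, s, e))
    return out


def analyze_junctions(
    rec: PlastomeRecord, qs: QuadripartiteStructure | None, window: int = 5000
) -> JunctionReport:
    """Report the genes at each of the four region boundaries.

    Genes spanning a junction report the bp on each side (their extension
    across the boundary); genes strictly inside a region report their
    distance to the junction (0 if abutting).  Genes farther than ``window``
    bp are omitted.  Gene pairs sharing bases near a junction are reported as
    overlaps (e.g. ndhF against the ycf1 pseudogene at JSB).
    """
    if qs is None:
        raise JunctionsUndefinedError(f"{rec.id}: no quadripartite structure")
    n = qs.total_length
    report = JunctionReport(genome=rec.id)
    spans = _spans(rec)
    near: dict[str, list[tuple[str, bool, int, int]]] = {j: [] for j in JUNCTION_ORDER}

    for jname, c in qs.junctions.items():
        left_region, right_region = JUNCTION_SIDES[jname]
        for name, pseudo, s0, e0 in spans:
            # choose the circular image of the gene closest to the junction
            best = None
            for shift in (-n, 0, n):
                s, e = s0 + shift, e0 + shift
                gap = 0 if s < c < e else min(abs(s - c), abs(c - e))
                if best is None or gap < best[0]:
                    best = (gap, s, e)
            gap, s, e = best
            if s < c < e:
                near[jname].append((name, pseudo, s, e))
                report.entries.append(
                    JunctionEntry(
                        junction=jname,
                        gene=name,
                        pseudogene=pseudo,
                        spanning=True,
                        left_bp=c - s,
                        right_bp=e - c,
                    )
                )
            elif gap <= window:
                near[jname].append((name, pseudo, s, e))
                side = left_region if e <= c else right_region
                report.entries.append(
                    JunctionEntry(
                        junction=jname,
                        gene=name,
                        pseudogene=pseudo,
                        spanning=False,
                        side=side,
                        distance_bp=gap,
                    )
                )

    seen = set()
    for jname in JUNCTION_ORDER:
        genes = near[jname]
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                (na, _, sa, ea), (nb, _, sb, eb) = genes[i], genes[j]
                ov = min(ea, eb) - max(sa, sb)
                if ov > 0 and na != nb:
                    key = tuple(sorted((na, nb)))
                    if key not in seen:
                        seen.add(key)
                        report.overlaps.append((key[0], key[1], ov))

    jla = [e for e in report.entries if e.junction == "JLA"]
    has_trnh = any(
        normalize_gene_name(e.gene).startswith("trnH")
        and (e.side == "LSC" or (e.spanning and e.right_bp > 0))
        for e in jla
    )
    has_rpl2 = any(
        normalize_gene_name(e.gene).startswith("rpl2")
        and not normalize_gene_name(e.gene).startswith("rpl20")
        and (e.side == "IRa" or e.spanning)
        for e in jla
    )
    report.rpl2_trnh_at_jla = has_trnh and has_rpl2
    return report


def compare_junctions(reports: list[JunctionReport]) -> pd.DataFrame:
    """Long-format comparison table across genomes.

    One row per (genome, junction, gene, side): spanning genes contribute a
    row per side with the bp of the gene on that side; interior genes one row
    with their distance to the junction.
    """
    if len(reports) < 2:
        raise ValueError("need at least two junction reports to compare")
    labelsets = {frozenset(e.junction for e in r.entries) for r in reports}
    if len(labelsets) > 1:
        raise PlastcompError("junction reports carry inconsistent junction labels")
    rows = []
    for r in reports:
        for e in r.entries:
            left_region, right_region = JUNCTION_SIDES[e.junction]
            if e.spanning:
                rows.append((r.genome, e.junction, e.gene, e.pseudogene, left_region, e.left_bp, True, r.rpl2_trnh_at_jla))
                rows.append((r.genome, e.junction, e.gene, e.pseudogene, right_region, e.right_bp, True, r.rpl2_trnh_at_jla))
            else:
                rows.append((r.genome, e.junction, e.gene, e.pseudogene, e.side, e.distance_bp, False, r.rpl2_trnh_at_jla))
    return pd.DataFrame(
        rows,
        columns=["genome", "junction", "gene", "pseudogene", "side", "bp", "spanning", "rpl2_trnH_at_JLA"],
    )
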