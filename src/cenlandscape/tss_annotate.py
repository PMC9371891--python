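"""Categorize (peri)cenRNA transcription start sites into four origin classes.

For each centromere and entry side, the main TSS (the modal 5'-end position
of the periCEN read set) is placed relative to neighboring genes and to
nucleosome-depleted regions, and assigned one of:

1. READTHROUGH_NEIGHBOR_GENE — the TSS sits at or upstream of a
   same-direction neighbor gene's promoter and the transcript reads through
   that gene's 3' end on its way to the centromere;
2. ADJACENT_NDR — the TSS falls inside an NDR overlapping a neighbor
   gene's promoter or transcription-termination anchor;
3. ANTISENSE_NEIGHBOR_GENE — the TSS falls inside a neighbor gene body on
   the strand opposite that gene;
4. INTERGENIC — none of the above.

Precedence is 1 > 2 > 3 > 4: readthrough is the most geometrically
specific call, the residual class the least.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .annotations import CentromereModel, GeneModel, GenomicInterval
from .classify import ClassifiedTranscript, PERICEN_SET


class TSSError(ValueError):
    pass


class TSSCategory(str, enum.Enum):
    READTHROUGH_NEIGHBOR_GENE = "READTHROUGH_NEIGHBOR_GENE"
    ADJACENT_NDR = "ADJACENT_NDR"
    INTERGENIC = "INTERGENIC"
    ANTISENSE_NEIGHBOR_GENE = "ANTISENSE_NEIGHBOR_GENE"


@dataclass(frozen=True)
class TSSCall:
    centromere_id: str
    entry_side: str
    main_tss: int
    category: TSSCategory
    supporting_reads: int
    most_abundant: bool = False


def _border_position(cen: CentromereModel, entry_side: str) -> int:
    return cen.outer_edge(entry_side)


def main_tss(
    classified: Sequence[ClassifiedTranscript],
    cen: CentromereModel,
    entry_side: str,
) -> Optional[Tuple[int, int]]:
    """Modal 5'-end position of the periCEN reads in one (centromere, side)
    cell, with ties broken toward the position closest to the CEN border.

    Returns (position, supporting read count at that position), or None for
    an empty cell.
    """
    border = _border_position(cen, entry_side)
    tally: Dict[int, int] = {}
    for c in classified:
        if (c.centromere_id == cen.cen_id and c.entry_side == entry_side
                and c.label in PERICEN_SET):
            pos = c.alignment.tss
            tally[pos] = tally.get(pos, 0) + 1
    if not tally:
        return None
    best = min(tally, key=lambda p: (-tally[p], abs(p - border), p))
    return best, tally[best]


def _neighbor_genes(
    pos: int,
    side_sign: int,
    cen: CentromereModel,
    genes: Sequence[GeneModel],
    horizon: int,
) -> List[GeneModel]:
    """Genes on the TSS's side of the centromere within ``horizon`` bp of it."""
    span = cen.span
    out = []
    for g in genes:
        if g.body.chrom != cen.chrom:
            continue
        if side_sign < 0 and g.body.start >= span.start:
            continue
        if side_sign > 0 and g.body.end <= span.end:
            continue
        if g.body.contains(pos):
            dist = 0
        else:
            dist = min(abs(pos - g.body.start), abs(pos - (g.body.end - 1)))
        if dist <= horizon:
            out.append(g)
    return out


def categorize_tss(
    pos: int,
    strand: str,
    genes: Sequence[GeneModel],
    ndrs: Sequence[GenomicInterval],
    cen: CentromereModel,
    horizon: int = 2000,
) -> TSSCategory:
    """Assign one TSS position (for a read of ``strand`` converging on
    ``cen``) to its origin class; see the module docstring for the rules."""
    span = cen.span
    if pos < span.start:
        side_sign = -1
    elif pos >= span.end:
        side_sign = 1
    else:
        return TSSCategory.INTERGENIC  # TSS inside the CEN span: no neighbors
    neighbors = _neighbor_genes(pos, side_sign, cen, genes, horizon)

    # 1. readthrough of a same-direction neighbor gene
    for g in neighbors:
        if g.strand != strand:
            continue
        if strand == "+":
            at_or_upstream = pos <= g.body.start
            traverses = g.tts_anchor < span.start and g.tts_anchor >= pos
        else:
            at_or_upstream = pos >= g.body.end - 1
            traverses = g.tts_anchor >= span.end and g.tts_anchor <= pos
        if at_or_upstream and traverses:
            return TSSCategory.READTHROUGH_NEIGHBOR_GENE

    # 2. inside an NDR tied to a neighbor gene's promoter or TTS anchor
    for ndr in ndrs:
        if ndr.chrom != cen.chrom or not ndr.contains(pos):
            continue
        for g in neighbors:
            if ndr.contains(g.promoter_anchor) or ndr.contains(g.tts_anchor):
                return TSSCategory.ADJACENT_NDR

    # 3. antisense within a neighbor gene body
    for g in neighbors:
        if g.body.contains(pos) and g.strand != strand:
            return TSSCategory.ANTISENSE_NEIGHBOR_GENE

    return TSSCategory.INTERGENIC


def tss_calls(
    classified: Sequence[ClassifiedTranscript],
    cens: Sequence[CentromereModel],
    genes: Sequence[GeneModel],
    ndrs: Sequence[GenomicInterval],
    horizon: int = 2000,
) -> List[TSSCall]:
    """Main-TSS call per (centromere, entry side) cell; empty cells are
    skipped. The most abundant call per centromere (by supporting reads,
    ties toward the border-closest TSS) is flagged."""
    strand_of = {}
    for c in classified:
        if c.entry_side is not None:
            strand_of[(c.centromere_id, c.entry_side)] = c.alignment.strand
    calls: List[TSSCall] = []
    for cen in cens:
        cen_calls: List[TSSCall] = []
        for side in ("CDEI", "CDEIII"):
            mt = main_tss(classified, cen, side)
            if mt is None:
                continue
            pos, support = mt
            strand = strand_of.get((cen.cen_id, side))
            if strand is None:
                continue
            cat = categorize_tss(pos, strand, genes, ndrs, cen, horizon)
            cen_calls.append(TSSCall(cen.cen_id, side, pos, cat, support))
        if cen_calls:
            border = {s: _border_position(cen, s) for s in ("CDEI", "CDEIII")}
            top = min(cen_calls,
                      key=lambda c: (-c.supporting_reads,
                                     abs(c.main_tss - border[c.entry_side])))
            cen_calls = [
                TSSCall(c.centromere_id, c.entry_side, c.main_tss, c.category,
                        c.supporting_reads, most_abundant=(c is top))
                for c in cen_calls
            ]
        calls.extend(cen_calls)
    return calls


_SIDE_LABEL = {"CDEI": "CDEI-Ent", "CDEIII": "CDEIII-Ent"}


def table_one(calls: Sequence[TSSCall]) -> pd.DataFrame:
    """Per-centromere x category table of entry-side labels; the most
    abundant isoform per centromere is marked with '*'."""
    cats = [c.value for c in TSSCategory]
    rows: Dict[str, Dict[str, List[str]]] = {}
    for call in calls:
        cell = rows.setdefault(call.centromere_id,
                               {c: [] for c in cats})
        label = _SIDE_LABEL[call.entry_side]
        if call.most_abundant:
            label += "*"
        cell[call.category.value].append(label)
    table = pd.DataFrame(
        [{"centromere": cen, **{c: "; ".join(v) for c, v in cells.items()}}
         for cen, cells in sorted(rows.items())],
        columns=["centromere"] + cats,
    )
    return table
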