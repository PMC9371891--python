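"""Classify full-length transcripts relative to a point centromere.

Nomenclature follows the field's usage for yeast point centromeres:

* a transcript *converges* on the centromere when its 5' end lies outside
  the CEN span and its direction of transcription points toward it;
* *pericenRNAs* (CONVERGING_PERICEN) are converging transcripts whose 3'
  end terminates within a window (default 50 bp, inclusive) upstream of the
  approached centromere border without entering it;
* *cenRNAs* (CEN_ENTERING) enter the centromere by at least 1 bp;
  CEN_SPANNING transcripts cover all three CDEs. Both are counted as part
  of the pericentromeric (periCEN) read set for entry-proportion
  denominators;
* DIVERGENT transcripts start inside the centromere span, or within the
  window of a border, and point away from it; everything else is
  UNRELATED.

The entry side is expressed in CDE space (CDEI vs CDEIII) via the
centromere orientation, so a read approaching from high coordinates on a
minus-orientation centromere enters via CDEI.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

from .annotations import CentromereModel, GenomicInterval
from .ingest import Library, TranscriptAlignment


class ClassifyError(ValueError):
    pass


class ClassLabel(str, enum.Enum):
    CONVERGING_PERICEN = "CONVERGING_PERICEN"
    CEN_ENTERING = "CEN_ENTERING"
    CEN_SPANNING = "CEN_SPANNING"
    DIVERGENT = "DIVERGENT"
    UNRELATED = "UNRELATED"


#: labels counted in the periCEN set (entry-proportion denominator): cenRNAs
#: are the readthrough subset of pericenRNAs.
PERICEN_SET = frozenset({ClassLabel.CONVERGING_PERICEN, ClassLabel.CEN_ENTERING,
                         ClassLabel.CEN_SPANNING})
ENTERING_SET = frozenset({ClassLabel.CEN_ENTERING, ClassLabel.CEN_SPANNING})


@dataclass(frozen=True)
class ClassifiedTranscript:
    """Per-read classification result.

    ``entry_depth`` is the total base overlap of the aligned blocks with the
    CEN span for converging reads (0 otherwise). ``termination_offset`` is
    the signed distance from the approached border to the 3' end (negative
    upstream of the border, 0 at the last pericentromeric base, positive =
    bases inside the CEN); it is None for non-converging reads, which
    approach no border.
    """

    read_id: str
    centromere_id: Optional[str]
    label: ClassLabel
    entry_side: Optional[str]  # "CDEI" / "CDEIII" / None
    entry_depth: int
    termination_offset: Optional[int]
    alignment: TranscriptAlignment = field(repr=False, compare=False)


def _span_overlap(t: TranscriptAlignment, span: GenomicInterval) -> int:
    total = 0
    for s, e in t.blocks:
        total += max(0, min(e, span.end) - max(s, span.start))
    return total


def classify_transcript(
    t: TranscriptAlignment,
    c: CentromereModel,
    window: int = 50,
) -> ClassifiedTranscript:
    """Assign one transcript a class relative to one centromere.

    Boundary conventions (inclusive window): a 3' end exactly at the border
    (0 bp inside) is pericentromeric with termination offset 0; a 3' end
    ``window`` bp upstream still counts; one base further is UNRELATED.
    Entry depth uses block-level overlap, so a spliced alignment whose
    intron covers part of the CEN is CEN_ENTERING, not CEN_SPANNING.
    """
    if t.chrom != c.chrom:
        raise ClassifyError(
            f"read {t.read_id} on {t.chrom} vs centromere {c.cen_id} on {c.chrom}"
        )
    span = c.span
    p5, p3 = t.tss, t.tes
    converging = (t.strand == "+" and p5 < span.start) or \
                 (t.strand == "-" and p5 >= span.end)
    if converging:
        if t.strand == "+":
            offset = p3 - span.start + 1
            side = c.border_side("left")
        else:
            offset = span.end - p3
            side = c.border_side("right")
        depth = _span_overlap(t, span)
        if depth == len(span):
            label = ClassLabel.CEN_SPANNING
        elif depth >= 1:
            label = ClassLabel.CEN_ENTERING
        elif -window <= offset <= 0:
            label = ClassLabel.CONVERGING_PERICEN
        else:
            label = ClassLabel.UNRELATED
        return ClassifiedTranscript(t.read_id, c.cen_id, label, side, depth,
                                    offset, t)
    # non-converging: divergent if it starts in the span or just outside a
    # border while pointing away
    if span.contains(p5):
        label = ClassLabel.DIVERGENT
    elif t.strand == "+" and p5 >= span.end and p5 - span.end <= window:
        label = ClassLabel.DIVERGENT
    elif t.strand == "-" and p5 < span.start and span.start - 1 - p5 <= window:
        label = ClassLabel.DIVERGENT
    else:
        label = ClassLabel.UNRELATED
    return ClassifiedTranscript(t.read_id, c.cen_id, label, None, 0, None, t)


def classify_library(
    lib: Union[Library, Sequence[TranscriptAlignment]],
    cens: Sequence[CentromereModel],
    window: int = 50,
) -> List[ClassifiedTranscript]:
    """Classify every read against the centromere on its chromosome.

    Reads on chromosomes without an annotated centromere are UNRELATED.
    """
    reads = lib.reads if isinstance(lib, Library) else lib
    by_chrom: Dict[str, CentromereModel] = {}
    for c in cens:
        if c.chrom in by_chrom:
            raise ClassifyError(f"two centromeres on {c.chrom}")
        by_chrom[c.chrom] = c
    out: List[ClassifiedTranscript] = []
    for r in reads:
        c = by_chrom.get(r.chrom)
        if c is None:
            out.append(ClassifiedTranscript(r.read_id, None,
                                            ClassLabel.UNRELATED, None, 0,
                                            None, r))
        else:
            out.append(classify_transcript(r, c, window))
    return out


def classifications_to_frame(classified: Iterable[ClassifiedTranscript]):
    """Tidy per-read classification table (TSV-ready)."""
    import pandas as pd

    rows = [{
        "read_id": c.read_id,
        "centromere": c.centromere_id if c.centromere_id is not None else ".",
        "label": c.label.value,
        "entry_side": c.entry_side if c.entry_side is not None else ".",
        "entry_depth": c.entry_depth,
        "termination_offset": c.termination_offset,
    } for c in classified]
    return pd.DataFrame(rows, columns=["read_id", "centromere", "label",
                                       "entry_side", "entry_depth",
                                       "termination_offset"])


def write_class_beds(
    classified: Sequence[ClassifiedTranscript], out_dir: str | Path
) -> None:
    """One BED12 per class label, for genome-browser inspection."""
    from .ingest import write_bed12

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for label in ClassLabel:
        reads = [c.alignment for c in classified if c.label == label]
        write_bed12(reads, out_dir / f"reads_{label.value.lower()}.bed")
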