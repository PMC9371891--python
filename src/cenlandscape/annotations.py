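"""Genomic data model: centromere DNA elements, genes, and nucleosome maps.

A budding-yeast point centromere is a ~111-125 bp locus made of three
adjacent Centromere DNA Elements: CDEI (~8 bp, the Cbf1 binding site), the
AT-rich CDEII, and CDEIII (~25 bp, the CBF3 binding site). The element
order along the chromosome may run either way; :class:`CentromereModel`
records that as ``cen_orientation``.

All coordinates throughout the package are 0-based half-open (BED
convention). GFF3 input (1-based closed) is converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd


class AnnotationError(ValueError):
    """Raised when an annotation file violates a structural invariant."""


_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Base pairs of overlap with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class CentromereModel:
    """One point centromere: its three CDEs and their orientation.

    ``cen_orientation`` is '+' when CDEI -> CDEIII runs with increasing
    genomic coordinates, '-' when mirrored. It is inferred from element
    order, never from a strand column.
    """

    cen_id: str
    chrom: str
    cdeI: GenomicInterval
    cdeII: GenomicInterval
    cdeIII: GenomicInterval
    cen_orientation: str

    def __post_init__(self) -> None:
        for el in (self.cdeI, self.cdeII, self.cdeIII):
            if el.chrom != self.chrom:
                raise AnnotationError(
                    f"{self.cen_id}: CDE on {el.chrom}, expected {self.chrom}"
                )
        if self.cen_orientation == "+":
            ok = (self.cdeI.end == self.cdeII.start
                  and self.cdeII.end == self.cdeIII.start)
        elif self.cen_orientation == "-":
            ok = (self.cdeIII.end == self.cdeII.start
                  and self.cdeII.end == self.cdeI.start)
        else:
            raise AnnotationError(f"{self.cen_id}: bad orientation")
        if not ok:
            raise AnnotationError(
                f"{self.cen_id}: CDEs are not adjacent in "
                f"{self.cen_orientation} orientation"
            )

    @property
    def span(self) -> GenomicInterval:
        return cen_span(self)

    def border_side(self, which: str) -> str:
        """CDE element name ('CDEI'/'CDEIII') at the 'left' or 'right' border."""
        if which not in ("left", "right"):
            raise ValueError(which)
        if self.cen_orientation == "+":
            return "CDEI" if which == "left" else "CDEIII"
        return "CDEIII" if which == "left" else "CDEI"

    def outer_edge(self, side: str) -> int:
        """Genomic position of the outermost base of the CDEI or CDEIII element.

        This is the first centromeric base met by a transcript entering via
        that side.
        """
        el = {"CDEI": self.cdeI, "CDEIII": self.cdeIII}[side]
        sp = self.span
        if el.start == sp.start:
            return el.start
        return el.end - 1


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand; promoter anchor = 5' end, TTS anchor = 3' end."""

    gene_id: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: strand must be +/-")

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def promoter_anchor(self) -> int:
        """Genomic position of the 5'-most base of the gene body."""
        return self.body.start if self.strand == "+" else self.body.end - 1

    @property
    def tts_anchor(self) -> int:
        """Genomic position of the 3'-most base of the gene body."""
        return self.body.end - 1 if self.strand == "+" else self.body.start


@dataclass
class NucleosomeMap:
    """Per-chromosome sorted, non-overlapping nucleosome intervals."""

    intervals: Dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, ivs: Iterable[GenomicInterval]) -> "NucleosomeMap":
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        out: Dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            arr = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise AnnotationError(f"overlapping nucleosomes on {chrom}")
            out[chrom] = arr
        return cls(out)

    def chromosomes(self) -> List[str]:
        return sorted(self.intervals)


# ---------------------------------------------------------------------------
# operations

_CDE_NAME = re.compile(r"^(?P<cen>.+)_CDE(?P<el>III|II|I)$")


def cen_span(c: CentromereModel) -> GenomicInterval:
    """The full centromere span: union of the three adjacent CDE intervals."""
    start = min(c.cdeI.start, c.cdeII.start, c.cdeIII.start)
    end = max(c.cdeI.end, c.cdeII.end, c.cdeIII.end)
    return GenomicInterval(c.chrom, start, end)


def load_centromeres(path: str | Path) -> List[CentromereModel]:
    """Read centromere CDEs from a BED-like file (name = ``CEN<k>_CDE<I|II|III>``).

    Groups the three elements per centromere, infers orientation from element
    order, and validates adjacency. The BED strand column, if present, is
    ignored. Raises :class:`AnnotationError` naming the offending centromere
    on a missing element, overlap, unknown element tag, or two centromeres on
    one chromosome.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str, "name": str})
    groups: Dict[str, Dict[str, GenomicInterval]] = {}
    order: List[str] = []
    for row in df.itertuples(index=False):
        m = _CDE_NAME.match(row.name)
        if not m:
            raise AnnotationError(f"unknown CDE record name {row.name!r}")
        cen, el = m.group("cen"), "CDE" + m.group("el")
        if cen not in groups:
            groups[cen] = {}
            order.append(cen)
        if el in groups[cen]:
            raise AnnotationError(f"{cen}: duplicate {el} record")
        groups[cen][el] = GenomicInterval(row.chrom, int(row.start), int(row.end))
    cens: List[CentromereModel] = []
    for cen in order:
        els = groups[cen]
        missing = {"CDEI", "CDEII", "CDEIII"} - set(els)
        if missing:
            raise AnnotationError(f"{cen}: missing element(s) {sorted(missing)}")
        orientation = "+" if els["CDEI"].start < els["CDEIII"].start else "-"
        try:
            cens.append(CentromereModel(cen, els["CDEI"].chrom, els["CDEI"],
                                        els["CDEII"], els["CDEIII"], orientation))
        except AnnotationError as exc:
            raise AnnotationError(f"{cen}: {exc}") from None
    seen: Dict[str, str] = {}
    for c in cens:
        if c.chrom in seen:
            raise AnnotationError(
                f"two centromeres ({seen[c.chrom]}, {c.cen_id}) on {c.chrom}"
            )
        seen[c.chrom] = c.cen_id
    return cens


def write_centromeres(cens: Sequence[CentromereModel], path: str | Path) -> None:
    """Write centromere CDEs as BED6 (round-trips with :func:`load_centromeres`)."""
    with open(path, "w") as fh:
        for c in cens:
            for el_name, el in (("CDEI", c.cdeI), ("CDEII", c.cdeII),
                                ("CDEIII", c.cdeIII)):
                fh.write(f"{c.chrom}\t{el.start}\t{el.end}\t"
                         f"{c.cen_id}_{el_name}\t0\t.\n")


def load_genes(path: str | Path) -> List[GeneModel]:
    """Read feature-type ``gene`` records from GFF3 (converted to 0-based)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True)
    genes: List[GeneModel] = []
    for feat in db.features_of_type("gene", order_by="start"):
        body = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        genes.append(GeneModel(feat.id, body))
    return genes


def write_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.body.chrom}\tcenlandscape\tgene\t{g.body.start + 1}\t"
                     f"{g.body.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")


def load_nucleosomes(path: str | Path) -> NucleosomeMap:
    """Read a nucleosome position map from BED3/BED6."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    return NucleosomeMap.from_intervals(
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    )


def write_nucleosomes(nmap: NucleosomeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in nmap.chromosomes():
            for start, end in nmap.intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def find_ndrs(nmap: NucleosomeMap, min_gap: int = 80) -> List[GenomicInterval]:
    """Nucleosome-depleted regions: inter-nucleosome gaps strictly > ``min_gap`` bp.

    The NDR is the gap interval itself (edge-to-edge). Chromosome ends are
    not gaps; a chromosome with fewer than two nucleosomes yields no NDR.
    """
    ndrs: List[GenomicInterval] = []
    for chrom in nmap.chromosomes():
        arr = nmap.intervals[chrom]
        for i in range(len(arr) - 1):
            gap_start, gap_end = int(arr[i, 1]), int(arr[i + 1, 0])
            if gap_end - gap_start > min_gap:
                ndrs.append(GenomicInterval(chrom, gap_start, gap_end))
    return ndrs
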