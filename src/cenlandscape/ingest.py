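"""Read full-length transcript alignments, filter, and deduplicate by UMI.

Input is either a BAM of mapped full-length non-chimeric molecules with the
UMI in a tag (default ``RX``), or BED12 with the UMI appended to the name
field as ``readID:UMI``. Records that are unmapped, secondary, or
supplementary (the components of SAM flag 2308) are dropped, so each
molecule is represented by exactly one primary alignment.

Deduplication collapses PCR duplicates by exact key: identical UMI plus
identical 5' and 3' genomic ends on the same strand (zero UMI mismatches,
zero coordinate shift). The post-dedup mapped read count is the library
size used as the counts-per-thousand denominator downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

FLAG_EXCLUDE = 2308  # unmapped (4) | secondary (256) | supplementary (2048)


class IngestError(ValueError):
    """Raised on malformed alignment input."""


@dataclass(frozen=True)
class TranscriptAlignment:
    """One full-length, UMI-tagged molecule as an aligned record.

    ``blocks`` are sorted, non-overlapping aligned segments. The 5' end
    (``tss``) and 3' end (``tes``) are genomic positions of the terminal
    aligned bases, resolved by strand.
    """

    read_id: str
    umi: str
    chrom: str
    strand: str
    blocks: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise IngestError(f"{self.read_id}: strand must be +/-")
        if not self.blocks:
            raise IngestError(f"{self.read_id}: no aligned blocks")
        prev_end = -1
        for s, e in self.blocks:
            if not (0 <= s < e) or s < prev_end:
                raise IngestError(
                    f"{self.read_id}: blocks must be sorted and non-overlapping"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def tss(self) -> int:
        """Genomic position of the 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Genomic position of the 3' end (strand-aware)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class Library:
    """A deduplicated sequencing library; ``library_size`` is the CPT denominator."""

    library_id: str
    reads: List[TranscriptAlignment]
    duplicate_group_sizes: List[int] = field(default_factory=list)

    @property
    def library_size(self) -> int:
        return len(self.reads)


def _dedup_key(r: TranscriptAlignment) -> Tuple[str, str, str, int, int]:
    return (r.umi, r.chrom, r.strand, r.tss, r.tes)


def dedup_umi(
    reads: Sequence[TranscriptAlignment],
) -> Tuple[List[TranscriptAlignment], List[int]]:
    """Collapse exact duplicates: same UMI, chromosome, strand, 5' and 3' ends.

    Keeps the lexicographically lowest read id of each group (deterministic)
    and returns the surviving reads with per-group sizes (sizes sum to the
    input count). Mixed UMI lengths are rejected: the zero-mismatch contract
    is only meaningful for equal-length tags.
    """
    if reads:
        lens = {len(r.umi) for r in reads}
        if len(lens) > 1:
            raise IngestError(f"mixed UMI lengths in input: {sorted(lens)}")
    groups: Dict[Tuple, List[TranscriptAlignment]] = {}
    order: List[Tuple] = []
    for r in reads:
        k = _dedup_key(r)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(r)
    kept: List[TranscriptAlignment] = []
    sizes: List[int] = []
    for k in order:
        grp = groups[k]
        kept.append(min(grp, key=lambda r: r.read_id))
        sizes.append(len(grp))
    return kept, sizes


def make_library(
    library_id: str, reads: Sequence[TranscriptAlignment]
) -> Library:
    """Deduplicate ``reads`` and wrap them as a :class:`Library`."""
    kept, sizes = dedup_umi(reads)
    return Library(library_id, kept, sizes)


# ---------------------------------------------------------------------------
# readers / writers

def read_alignments(
    path: str | Path,
    umi_source: str = "name",
    umi_tag: str = "RX",
) -> List[TranscriptAlignment]:
    """Read alignments from BAM/SAM (UMI in a tag) or BED12 (UMI in the name).

    ``umi_source`` is ``"name"`` (BED12 ``readID:UMI``) or ``"tag"`` (BAM tag
    ``umi_tag``); BAM/SAM inputs always use the tag. Unmapped, secondary, and
    supplementary records are excluded.
    """
    path = Path(path)
    if path.suffix.lower() in (".bam", ".sam", ".cram"):
        return _read_bam(path, umi_tag)
    return _read_bed12(path)


def _read_bam(path: Path, umi_tag: str) -> List[TranscriptAlignment]:
    import pysam

    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    out: List[TranscriptAlignment] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.flag & FLAG_EXCLUDE:
                continue
            if not aln.has_tag(umi_tag):
                raise IngestError(
                    f"read {aln.query_name!r} has no UMI tag {umi_tag}"
                )
            blocks = tuple((int(s), int(e)) for s, e in aln.get_blocks())
            out.append(TranscriptAlignment(
                read_id=aln.query_name,
                umi=str(aln.get_tag(umi_tag)),
                chrom=aln.reference_name,
                strand="-" if aln.is_reverse else "+",
                blocks=blocks,
            ))
    return out


_BED12_COLS = ["chrom", "start", "end", "name", "score", "strand",
               "thick_start", "thick_end", "rgb", "block_count",
               "block_sizes", "block_starts"]


def _read_bed12(path: Path) -> List[TranscriptAlignment]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=_BED12_COLS,
                         dtype={"chrom": str, "name": str, "strand": str,
                                "block_sizes": str, "block_starts": str})
    except pd.errors.EmptyDataError:
        return []
    out: List[TranscriptAlignment] = []
    for row in df.itertuples(index=False):
        name = row.name
        if ":" not in name:
            raise IngestError(f"BED12 name {name!r} lacks ':UMI' suffix")
        read_id, umi = name.rsplit(":", 1)
        try:
            sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
            starts = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
            count = int(row.block_count)
        except (ValueError, TypeError) as exc:
            raise IngestError(f"{read_id}: malformed BED12 blocks: {exc}") from None
        if len(sizes) != count or len(starts) != count:
            raise IngestError(
                f"{read_id}: blockCount {count} does not match block lists"
            )
        chrom_start = int(row.start)
        blocks = tuple((chrom_start + st, chrom_start + st + sz)
                       for st, sz in zip(starts, sizes))
        if blocks[-1][1] != int(row.end):
            raise IngestError(f"{read_id}: blocks do not end at chromEnd")
        out.append(TranscriptAlignment(read_id, umi, row.chrom,
                                       row.strand, blocks))
    return out


def write_bed12(reads: Iterable[TranscriptAlignment], path: str | Path) -> None:
    """Write reads as BED12 with the UMI in the name field (``readID:UMI``)."""
    with open(path, "w") as fh:
        for r in reads:
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            starts = ",".join(str(s - r.start) for s, _ in r.blocks)
            fh.write("\t".join(map(str, [
                r.chrom, r.start, r.end, f"{r.read_id}:{r.umi}", 0, r.strand,
                r.start, r.end, 0, len(r.blocks), sizes, starts,
            ])) + "\n")


def write_bam(
    reads: Sequence[TranscriptAlignment],
    path: str | Path,
    chrom_sizes: Dict[str, int],
    umi_tag: str = "RX",
) -> None:
    """Write reads as an unsorted BAM with the UMI in ``umi_tag`` (no sequence)."""
    import pysam

    names = sorted(chrom_sizes)
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": n, "LN": int(chrom_sizes[n])} for n in names]}
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wb", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.read_id
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = 60
            a.flag = 16 if r.strand == "-" else 0
            cigar = []
            prev_end: Optional[int] = None
            for s, e in r.blocks:
                if prev_end is not None and s > prev_end:
                    cigar.append((3, s - prev_end))  # N gap between blocks
                cigar.append((0, e - s))
                prev_end = e
            a.cigartuples = cigar
            a.set_tag(umi_tag, r.umi)
            fh.write(a)
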