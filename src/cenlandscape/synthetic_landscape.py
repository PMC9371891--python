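"""Synthetic 16-centromere genome and full-length transcript library generator.

The generator emulates the statistical structure of a targeted long-read
(Iso-Seq-style) capture experiment at yeast point centromeres:

* each chromosome carries one ~111-125 bp centromere (CDEI 8 bp, AT-rich
  CDEII, CDEIII 25 bp) embedded in AT-rich pericentromeric flanks, with
  neighbor genes and a canonical-nucleosome map that yields promoter- and
  terminator-side nucleosome-depleted regions (NDRs);
* pericentromeric transcription converges on the centromere from both
  sides, initiating from four start classes (readthrough of a neighbor
  gene's promoter, an NDR adjacent to a neighbor gene, an intergenic
  nucleosome-covered position, or antisense within a neighbor gene body);
* a converging molecule crosses the centromere border with probability
  ``p_enter`` (the roadblock leak rate); non-entering molecules terminate
  within the 50 bp upstream window with probability ``p_window``, else
  uniformly 51-300 bp upstream; entering molecules either traverse the
  whole centromere (``p_fullspan``) or terminate with a constant per-bp
  hazard along CDEII;
* PCR duplicates share UMI and coordinates; background reads sit on genes;
  an in-silico hybridization capture retains probe-overlapping reads with
  one probability and everything else with another.

Named profiles calibrate (p_enter, p_window) to the three study-like
conditions: wild-type G1 (strong roadblock), wild-type S phase (accessible
centromere), and a roadblock-deficient G1 mutant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotations import (CentromereModel, GeneModel, GenomicInterval,
                          NucleosomeMap, write_centromeres, write_genes,
                          write_nucleosomes)
from .ingest import TranscriptAlignment, write_bed12


class ConfigurationError(ValueError):
    pass


#: (p_enter, p_window) calibrations for the three study-like conditions.
PROFILES: Dict[str, Dict[str, float]] = {
    "wt_g1": {"p_enter": 0.010, "p_window": 0.622},
    "wt_s": {"p_enter": 0.536, "p_window": 0.569},
    "cbf1d_g1": {"p_enter": 0.450, "p_window": 0.545},
}

_BASES = np.array(list("ACGT"))

# CDEI consensus (Cbf1 E-box site) and a CDEIII-like 25-mer scaffold; 'N'
# positions are filled randomly per centromere.
_CDEI_CONSENSUS = "GTCACGTG"
_CDEIII_TEMPLATE = "TGTTTNTGNTTTCCGAANNNAAAAN"

# Pericentromeric layout, as distances upstream of the centromere border.
# The right flank is the mirror image. Gene 1 transcribes toward the
# centromere (readthrough donor); gene 2 transcribes away (antisense host).
_GENE1 = (2600, 1700)
_GENE2 = (1000, 400)
_NDRS = [(2650, 2550),  # straddles gene-1 promoter anchor
         (1750, 1650),  # straddles gene-1 TTS anchor
         (1040, 950),   # straddles gene-2 TTS anchor
         (460, 360)]    # straddles gene-2 promoter anchor (border-proximal)
_COVERED_SEGMENTS = [(2550, 1750), (1650, 1040), (950, 460), (360, 0)]
# 5'-end regions per initiation class (distances; readthrough is a point)
_INIT_REGIONS = {
    "readthrough": (2600, 2600),
    "antisense": (900, 501),
    "intergenic": (1400, 1151),
    "adjacent_ndr": (460, 361),
}
_MIN_FLANK = 3000
_NUC_LEN = 147
_MAX_LINKER = 80

INITIATION_CLASSES = ("readthrough", "adjacent_ndr", "intergenic", "antisense")


@dataclass
class SimulationConfig:
    """Generative parameters for the synthetic landscape.

    Defaults are the wild-type G1-like condition: pervasive pericentromeric
    transcription that almost never crosses the centromere border
    (``p_enter`` = 0.010) and mostly terminates within the 50 bp window
    (``p_window`` = 0.622).
    """

    n_chromosomes: int = 16
    flank: int = 3000
    cdeI_len: int = 8
    cdeII_len_range: Tuple[int, int] = (78, 86)
    cdeIII_len: int = 25
    cdeII_at_fraction: float = 0.90
    flank_gc: float = 0.25
    n_converging_reads: int = 100  # per centromere-strand
    initiation_weights: Dict[str, float] = field(default_factory=lambda: {
        "readthrough": 0.25, "adjacent_ndr": 0.40,
        "intergenic": 0.20, "antisense": 0.15,
    })
    p_enter: float = 0.010
    p_window: float = 0.622
    window: int = 50
    upstream_max: int = 300
    p_fullspan: float = 0.05
    cdeii_stop_hazard: float = 0.08
    strand_bias: float = 0.5  # fraction of converging molecules from the right
    duplicate_rate: float = 0.3
    umi_length: int = 6
    n_background_reads: int = 1000
    divergent_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {"p_enter": self.p_enter, "p_window": self.p_window,
                 "p_fullspan": self.p_fullspan,
                 "cdeii_stop_hazard": self.cdeii_stop_hazard,
                 "strand_bias": self.strand_bias,
                 "cdeII_at_fraction": self.cdeII_at_fraction,
                 "flank_gc": self.flank_gc,
                 "divergent_fraction": self.divergent_fraction}
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if set(self.initiation_weights) != set(INITIATION_CLASSES):
            raise ConfigurationError("initiation_weights must cover exactly "
                                     f"{INITIATION_CLASSES}")
        if abs(sum(self.initiation_weights.values()) - 1.0) > 1e-9:
            raise ConfigurationError("initiation weights must sum to 1")
        if self.umi_length < 1:
            raise ConfigurationError("umi_length must be >= 1")
        if self.flank < _MIN_FLANK:
            raise ConfigurationError(
                f"flank {self.flank} too short to place neighbor genes "
                f"(need >= {_MIN_FLANK})"
            )
        if self.duplicate_rate < 0:
            raise ConfigurationError("duplicate_rate must be >= 0")

    @classmethod
    def from_profile(cls, name: str, **overrides) -> "SimulationConfig":
        """Config for a named study-like condition (see :data:`PROFILES`)."""
        if name not in PROFILES:
            raise ConfigurationError(f"unknown profile {name!r}; "
                                     f"choose from {sorted(PROFILES)}")
        params = dict(PROFILES[name])
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class CaptureModel:
    """In-silico hybridization capture retention probabilities."""

    on_target_retention: float
    off_target_retention: float

    def __post_init__(self) -> None:
        for p in (self.on_target_retention, self.off_target_retention):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("retention probabilities in [0,1]")


@dataclass
class SyntheticGenome:
    """A built synthetic genome with its annotations and initiation layout."""

    config: SimulationConfig
    sequences: Dict[str, str]
    centromeres: List[CentromereModel]
    genes: List[GeneModel]
    nucleosomes: NucleosomeMap
    # per (cen_id, side): strand, genomic border base, and 5'-start regions
    initiation_layout: Dict[Tuple[str, str], Dict] = field(default_factory=dict)

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def write(self, out_dir: str | Path) -> Dict[str, Path]:
        """Write FASTA + BED/GFF3 annotation files; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out_dir / "genome.fa",
            "cdes": out_dir / "cdes.bed",
            "genes": out_dir / "genes.gff3",
            "nucleosomes": out_dir / "nucleosomes.bed",
        }
        with open(paths["genome"], "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        write_centromeres(self.centromeres, paths["cdes"])
        write_genes(self.genes, paths["genes"])
        write_nucleosomes(self.nucleosomes, paths["nucleosomes"])
        return paths


# ---------------------------------------------------------------------------
# genome construction

def _tile_segment(start: int, end: int) -> List[Tuple[int, int]]:
    """Place 147 bp nucleosomes pinned to both segment ends, linkers <= 80 bp."""
    length = end - start
    if length < _NUC_LEN:
        return []
    n = max(1, -(-(length + _MAX_LINKER) // (_NUC_LEN + _MAX_LINKER)))
    while n * _NUC_LEN > length:
        n -= 1
    if n <= 0:
        return []
    if n == 1:
        return [(start, start + _NUC_LEN)]
    rem = length - n * _NUC_LEN
    base, extra = divmod(rem, n - 1)
    out = []
    pos = start
    for i in range(n):
        out.append((pos, pos + _NUC_LEN))
        pos += _NUC_LEN
        if i < n - 1:
            pos += base + (1 if i < extra else 0)
    return out


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _cdeii_seq(rng: np.random.Generator, n: int, at_fraction: float) -> str:
    p_at = min(1.0, at_fraction + 0.05)
    seq = list(_random_seq(rng, n, 1.0 - p_at))
    # enforce the AT floor deterministically
    max_gc = int(n * (1.0 - at_fraction))
    gc_pos = [i for i, b in enumerate(seq) if b in "GC"]
    if len(gc_pos) > max_gc:
        flip = rng.permutation(gc_pos)[: len(gc_pos) - max_gc]
        for i in flip:
            seq[i] = "AT"[rng.integers(2)]
    return "".join(seq)


def _fill_template(rng: np.random.Generator, template: str) -> str:
    return "".join(b if b != "N" else _BASES[rng.integers(4)]
                   for b in template)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def build_genome(
    cfg: SimulationConfig,
    out_dir: Optional[str | Path] = None,
) -> SyntheticGenome:
    """Build the synthetic genome, centromeres, genes, and nucleosome map.

    Deterministic under (cfg, cfg.seed); with ``out_dir`` the FASTA/BED/GFF3
    files are also written (byte-identical across runs).
    """
    rng = np.random.default_rng(cfg.seed)
    sequences: Dict[str, str] = {}
    cens: List[CentromereModel] = []
    genes: List[GeneModel] = []
    nuc_ivs: List[GenomicInterval] = []
    layout: Dict[Tuple[str, str], Dict] = {}

    for k in range(1, cfg.n_chromosomes + 1):
        chrom = f"chr{k:02d}"
        cen_id = f"CEN{k}"
        cdeII_len = int(rng.integers(cfg.cdeII_len_range[0],
                                     cfg.cdeII_len_range[1] + 1))
        cen_len = cfg.cdeI_len + cdeII_len + cfg.cdeIII_len
        B = cfg.flank            # span start
        E = B + cen_len          # span end
        chrom_len = 2 * cfg.flank + cen_len
        orientation = "+" if rng.random() < 0.5 else "-"

        # sequence: AT-rich flanks, consensus-like CDEI/CDEIII, AT-rich CDEII
        left = _random_seq(rng, cfg.flank, cfg.flank_gc)
        right = _random_seq(rng, cfg.flank, cfg.flank_gc)
        cdeI_seq = _CDEI_CONSENSUS[: cfg.cdeI_len].ljust(cfg.cdeI_len, "A")
        cdeIII_seq = _fill_template(
            rng, (_CDEIII_TEMPLATE * 3)[: cfg.cdeIII_len])
        cdeII_seq = _cdeii_seq(rng, cdeII_len, cfg.cdeII_at_fraction)
        cassette = cdeI_seq + cdeII_seq + cdeIII_seq
        if orientation == "-":
            cassette = _revcomp(cassette)
        sequences[chrom] = left + cassette + right

        if orientation == "+":
            cdeI = GenomicInterval(chrom, B, B + cfg.cdeI_len)
            cdeII = GenomicInterval(chrom, cdeI.end, cdeI.end + cdeII_len)
            cdeIII = GenomicInterval(chrom, cdeII.end, E)
        else:
            cdeIII = GenomicInterval(chrom, B, B + cfg.cdeIII_len)
            cdeII = GenomicInterval(chrom, cdeIII.end, cdeIII.end + cdeII_len)
            cdeI = GenomicInterval(chrom, cdeII.end, E)
        cen = CentromereModel(cen_id, chrom, cdeI, cdeII, cdeIII, orientation)
        cens.append(cen)

        mirror = B + E  # interval [a,b) reflects to [mirror-b, mirror-a)

        def refl(a: int, b: int) -> Tuple[int, int]:
            return mirror - b, mirror - a

        # genes (left frame, then mirrored with flipped strand)
        g1l = GenomicInterval(chrom, B - _GENE1[0], B - _GENE1[1], "+")
        g2l = GenomicInterval(chrom, B - _GENE2[0], B - _GENE2[1], "-")
        g1r = GenomicInterval(chrom, *refl(g1l.start, g1l.end), "-")
        g2r = GenomicInterval(chrom, *refl(g2l.start, g2l.end), "+")
        genes += [GeneModel(f"{cen_id}_gene_L1", g1l),
                  GeneModel(f"{cen_id}_gene_L2", g2l),
                  GeneModel(f"{cen_id}_gene_R1", g1r),
                  GeneModel(f"{cen_id}_gene_R2", g2r)]

        # nucleosomes: covered segments with pinned NDR gaps, both flanks
        segs = [(B - cfg.flank, B - _NDRS[0][0])]
        segs += [(B - hi, B - lo) for hi, lo in _COVERED_SEGMENTS]
        for s, e in segs:
            for a, b in _tile_segment(s, e):
                nuc_ivs.append(GenomicInterval(chrom, a, b))
            ra, rb = refl(s, e)
            for a, b in _tile_segment(ra, rb):
                nuc_ivs.append(GenomicInterval(chrom, a, b))

        for side, strand in (("left", "+"), ("right", "-")):
            regions = {}
            for cls_name, (hi, lo) in _INIT_REGIONS.items():
                a, b = B - hi, B - lo + 1  # half-open genomic start interval
                if side == "right":
                    a, b = refl(a, b)
                regions[cls_name] = (a, b)
            layout[(cen_id, side)] = {
                "strand": strand, "regions": regions, "chrom": chrom,
                "span": (B, E),
            }

    syn = SyntheticGenome(cfg, sequences, cens, genes,
                          NucleosomeMap.from_intervals(nuc_ivs), layout)
    if out_dir is not None:
        syn.write(out_dir)
    return syn


# ---------------------------------------------------------------------------
# library simulation

def _umi_strings(rng: np.random.Generator, n: int, length: int) -> List[str]:
    mat = rng.integers(0, 4, size=(n, length))
    return ["".join(_BASES[row]) for row in mat]


def _truncated_geometric(
    rng: np.random.Generator, hazard: float, upper: int, n: int
) -> np.ndarray:
    """Per-bp stop positions 1..upper under a constant hazard, conditioned on
    stopping within ``upper`` bases (inverse-CDF sampling)."""
    if hazard >= 1.0:
        return np.ones(n, dtype=np.int64)
    u = rng.random(n)
    tail = (1.0 - hazard) ** upper
    k = np.ceil(np.log1p(-u * (1.0 - tail)) / np.log1p(-hazard))
    return np.clip(k.astype(np.int64), 1, upper)


def simulate_library(
    cfg: SimulationConfig,
    syn: SyntheticGenome,
    n_per_cell: Optional[int] = None,
    cell_counts: Optional[Dict[Tuple[str, str], int]] = None,
    seed: Optional[int] = None,
) -> List[TranscriptAlignment]:
    """Simulate one UMI-tagged full-length read library on ``syn``.

    For every centromere and approach side, ``n_per_cell`` converging
    molecules are drawn (5' end per initiation-class weights, 3' end per the
    roadblock model), then PCR duplicates, background genic reads, and
    optional divergent reads are appended. ``cell_counts`` overrides the
    per-(centromere, side) molecule count. Deterministic under (cfg, seed).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    base_n = cfg.n_converging_reads if n_per_cell is None else n_per_cell
    weights = np.array([cfg.initiation_weights[c] for c in INITIATION_CLASSES])
    reads: List[TranscriptAlignment] = []
    counter = 0

    def new_ids(n: int) -> List[str]:
        nonlocal counter
        ids = [f"r{counter + i:08d}" for i in range(n)]
        counter += n
        return ids

    total_converging = 0
    for cen in syn.centromeres:
        span_len = len(cen.span)
        for side in ("left", "right"):
            cell = syn.initiation_layout[(cen.cen_id, side)]
            strand = cell["strand"]
            B, E = cell["span"]
            if cell_counts is not None:
                n = cell_counts.get((cen.cen_id, side), 0)
            else:
                frac = cfg.strand_bias if side == "right" else 1 - cfg.strand_bias
                n = int(round(2 * base_n * frac))
            if n <= 0:
                continue
            total_converging += n
            # 5' ends
            cls_idx = rng.choice(len(INITIATION_CLASSES), size=n, p=weights)
            p5 = np.empty(n, dtype=np.int64)
            for ci, cls_name in enumerate(INITIATION_CLASSES):
                mask = cls_idx == ci
                a, b = cell["regions"][cls_name]
                if b - a <= 1:
                    p5[mask] = a
                else:
                    p5[mask] = rng.integers(a, b, size=int(mask.sum()))
            # 3' ends: signed offset from the approached border
            # (0 = last base before the span, d >= 1 = d-th base inside)
            outer_len = {"CDEI": cfg.cdeI_len, "CDEIII": cfg.cdeIII_len}[
                cen.border_side(side)]
            cdeII_len = len(cen.cdeII)
            enter = rng.random(n) < cfg.p_enter
            offset = np.empty(n, dtype=np.int64)
            n_in = int(enter.sum())
            if n_in:
                full = rng.random(n_in) < cfg.p_fullspan
                depth = np.empty(n_in, dtype=np.int64)
                n_stop = int((~full).sum())
                if n_stop:
                    depth[~full] = outer_len + _truncated_geometric(
                        rng, cfg.cdeii_stop_hazard, cdeII_len, n_stop)
                if int(full.sum()):
                    depth[full] = span_len + rng.integers(
                        0, 51, size=int(full.sum()))
                offset[enter] = depth
            n_out = n - n_in
            if n_out:
                in_window = rng.random(n_out) < cfg.p_window
                off_out = np.empty(n_out, dtype=np.int64)
                nw = int(in_window.sum())
                if nw:
                    off_out[in_window] = -rng.integers(0, cfg.window + 1,
                                                       size=nw)
                if n_out - nw:
                    off_out[~in_window] = -rng.integers(
                        cfg.window + 1, cfg.upstream_max + 1,
                        size=n_out - nw)
                offset[~enter] = off_out
            if strand == "+":
                p3 = B - 1 + offset
                blocks = np.stack([p5, p3 + 1], axis=1)
            else:
                p3 = E - offset
                blocks = np.stack([p3, p5 + 1], axis=1)
            ids = new_ids(n)
            umis = _umi_strings(rng, n, cfg.umi_length)
            for i in range(n):
                reads.append(TranscriptAlignment(
                    ids[i], umis[i], cell["chrom"], strand,
                    ((int(blocks[i, 0]), int(blocks[i, 1])),)))

    # divergent reads (off by default)
    n_div = int(round(cfg.divergent_fraction * total_converging))
    if n_div:
        for _ in range(n_div):
            cen = syn.centromeres[rng.integers(len(syn.centromeres))]
            sp = cen.span
            p5 = int(rng.integers(sp.start, sp.end))
            strand = "+" if rng.random() < 0.5 else "-"
            ext = int(rng.integers(20, 201))
            if strand == "+":
                block = (p5, p5 + ext)
            else:
                block = (max(0, p5 - ext), p5 + 1)
            rid = new_ids(1)[0]
            reads.append(TranscriptAlignment(
                rid, _umi_strings(rng, 1, cfg.umi_length)[0], cen.chrom,
                strand, (block,)))

    # background genic reads
    if cfg.n_background_reads and syn.genes:
        gi = rng.integers(0, len(syn.genes), size=cfg.n_background_reads)
        ids = new_ids(cfg.n_background_reads)
        umis = _umi_strings(rng, cfg.n_background_reads, cfg.umi_length)
        for j in range(cfg.n_background_reads):
            g = syn.genes[int(gi[j])]
            body = g.body
            cut = int(rng.integers(body.start + 1, body.end))
            if g.strand == "+":
                block = (body.start, cut)
            else:
                block = (cut - 1, body.end)
            reads.append(TranscriptAlignment(ids[j], umis[j], body.chrom,
                                             g.strand, (block,)))

    # PCR duplicates sharing UMI and coordinates
    if cfg.duplicate_rate > 0:
        n_dups = rng.poisson(cfg.duplicate_rate, size=len(reads))
        dups: List[TranscriptAlignment] = []
        for r, nd in zip(reads, n_dups):
            for j in range(int(nd)):
                dups.append(dataclasses.replace(r,
                                                read_id=f"{r.read_id}_d{j:02d}"))
        reads += dups
    return reads


# ---------------------------------------------------------------------------
# in-silico capture

def _merge_intervals(pairs: Sequence[Tuple[int, int]]) -> np.ndarray:
    arr = sorted(pairs)
    merged: List[List[int]] = []
    for s, e in arr:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64).reshape(-1, 2)


def overlap_mask_arrays(
    starts: np.ndarray, ends: np.ndarray,
    probe_starts: np.ndarray, probe_ends: np.ndarray,
) -> np.ndarray:
    """Vectorized >= 1 bp overlap test of intervals against merged probes."""
    order = np.argsort(probe_starts, kind="stable")
    merged = _merge_intervals(list(zip(probe_starts[order], probe_ends[order])))
    idx = np.searchsorted(merged[:, 0], ends, side="left") - 1
    ok = idx >= 0
    hit = np.zeros(len(starts), dtype=bool)
    hit[ok] = merged[idx[ok], 1] > starts[ok]
    return hit


def simulate_capture(
    reads: Sequence[TranscriptAlignment],
    probes: Sequence[GenomicInterval],
    cm: CaptureModel,
    seed: int,
) -> List[TranscriptAlignment]:
    """Retain each read independently: probe-overlapping (>= 1 bp, block
    level) with ``on_target_retention``, all others with
    ``off_target_retention``."""
    if not probes:
        raise ConfigurationError("probe list must be non-empty")
    rng = np.random.default_rng(seed)
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for p in probes:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged = {c: _merge_intervals(v) for c, v in by_chrom.items()}
    retained: List[TranscriptAlignment] = []
    for r in reads:
        m = merged.get(r.chrom)
        on = False
        if m is not None:
            for s, e in r.blocks:
                i = int(np.searchsorted(m[:, 0], e, side="left")) - 1
                if i >= 0 and m[i, 1] > s:
                    on = True
                    break
        p = cm.on_target_retention if on else cm.off_target_retention
        if rng.random() < p:
            retained.append(r)
    return retained


def simulate_capture_arrays(
    starts: np.ndarray,
    ends: np.ndarray,
    probe_starts: np.ndarray,
    probe_ends: np.ndarray,
    cm: CaptureModel,
    seed: int,
) -> np.ndarray:
    """Array form of :func:`simulate_capture` for lightweight single-block
    records on one chromosome; returns the boolean retention mask."""
    if len(probe_starts) == 0:
        raise ConfigurationError("probe list must be non-empty")
    rng = np.random.default_rng(seed)
    on = overlap_mask_arrays(np.asarray(starts), np.asarray(ends),
                             np.asarray(probe_starts), np.asarray(probe_ends))
    p = np.where(on, cm.on_target_retention, cm.off_target_retention)
    return rng.random(len(p)) < p
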