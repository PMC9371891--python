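"""Hybridization-capture probe design over point centromeres.

Per centromere the panel carries three probes: one core probe covering the
centromere (anchored on the CDEII midpoint) and one flanking probe on each
pericentromeric side, all 103-120 nt with a nearest-neighbor duplex
melting temperature inside a common band (default 66.9-70.8 C, targeting
67.6 C). Among feasible windows for a slot the longest wins; ties go to
the Tm closest to the target, then to the leftmost start, which makes the
design deterministic and biases the panel toward the maximal length.

Tm uses the unified nearest-neighbor parameter set (Allawi & SantaLucia)
with a monovalent-salt entropy correction; the ionic conditions are
explicit configuration, defaulting to 0.1 M monovalent and 0.25 uM probe
strand, calibrated so AT-rich pericentromeric 120-mers land inside the
default Tm band.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .annotations import CentromereModel, GenomicInterval


class ProbeDesignError(ValueError):
    pass


@dataclass(frozen=True)
class ThermoConditions:
    """Duplex formation conditions: monovalent cation and probe strand
    concentrations, both molar."""

    monovalent_M: float = 0.10
    probe_conc_M: float = 0.25e-6

    def __post_init__(self) -> None:
        if self.monovalent_M <= 0 or self.probe_conc_M <= 0:
            raise ProbeDesignError("thermodynamic concentrations must be > 0")


@dataclass(frozen=True)
class ProbeConstraints:
    min_length: int = 103
    max_length: int = 120
    tm_min: float = 66.9
    tm_max: float = 70.8
    tm_target: float = 67.6
    flank_zone: int = 500
    thermo: ThermoConditions = field(default_factory=ThermoConditions)


@dataclass(frozen=True)
class ProbeCandidate:
    name: str
    sequence: str
    source: GenomicInterval
    strand: str
    gc: float
    tm: float

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProbePanel:
    probes: List[ProbeCandidate]

    def summary(self) -> Dict[str, float]:
        lengths = [p.length for p in self.probes]
        gcs = [p.gc for p in self.probes]
        tms = [p.tm for p in self.probes]
        return {
            "n_probes": len(self.probes),
            "length_mode": statistics.mode(lengths),
            "gc_min": min(gcs), "gc_max": max(gcs),
            "tm_min": min(tms), "tm_max": max(tms),
        }


class ProbePanelError(ProbeDesignError):
    """Raised when some centromeres are infeasible; carries the partial panel."""

    def __init__(self, failures: Sequence[str], partial: ProbePanel):
        self.failures = list(failures)
        self.partial = partial
        super().__init__("infeasible probe slots: " + "; ".join(self.failures))


_VALID = set("ACGT")


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length of an A/C/G/T string."""
    if not seq:
        raise ProbeDesignError("empty sequence")
    bad = set(seq) - _VALID
    if bad:
        raise ProbeDesignError(f"non-ACGT character(s) {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str, tc: ThermoConditions = ThermoConditions()) -> float:
    """Two-state nearest-neighbor Tm (C) with monovalent-salt correction."""
    if len(seq) < 8:
        raise ProbeDesignError("sequence too short for a NN duplex Tm")
    bad = set(seq) - _VALID
    if bad:
        raise ProbeDesignError(f"ambiguity codes not supported: {sorted(bad)}")
    return float(_mt.Tm_NN(
        seq, nn_table=_mt.DNA_NN3,
        Na=tc.monovalent_M * 1000.0,  # mM
        K=0, Tris=0, Mg=0, dNTPs=0,
        dnac1=tc.probe_conc_M * 1e9,  # nM
        dnac2=0, selfcomp=False, saltcorr=5,
    ))


GenomeLike = Union[Mapping[str, str], "object"]


def _get_seq(genome: GenomeLike, chrom: str, start: int, end: int) -> str:
    if isinstance(genome, Mapping):
        return str(genome[chrom][start:end]).upper()
    # pyfaidx.Fasta or similar
    return str(genome[chrom][start:end]).upper()


def _best_window(
    genome: GenomeLike,
    chrom: str,
    zone: Tuple[int, int],
    must_cover: Optional[int],
    constraints: ProbeConstraints,
    forbid: Sequence[Tuple[int, int]] = (),
) -> Optional[Tuple[int, int, str, float]]:
    """Longest feasible window in ``zone``; ties by |Tm - target| then
    leftmost start. ``must_cover`` pins a base the window must contain."""
    lo, hi = zone
    for length in range(constraints.max_length, constraints.min_length - 1, -1):
        best = None
        start_min, start_max = lo, hi - length
        if must_cover is not None:
            start_min = max(start_min, must_cover - length + 1)
            start_max = min(start_max, must_cover)
        for s in range(start_min, start_max + 1):
            e = s + length
            if any(s < fe and e > fs for fs, fe in forbid):
                continue
            seq = _get_seq(genome, chrom, s, e)
            if set(seq) - _VALID:
                continue
            tm = melting_temperature(seq, constraints.thermo)
            if not (constraints.tm_min <= tm <= constraints.tm_max):
                continue
            key = (abs(tm - constraints.tm_target), s)
            if best is None or key < best[0]:
                best = (key, s, e, seq, tm)
        if best is not None:
            _, s, e, seq, tm = best
            return s, e, seq, tm
    return None


def design_probes_for_cen(
    genome: GenomeLike,
    c: CentromereModel,
    constraints: ProbeConstraints = ProbeConstraints(),
) -> List[ProbeCandidate]:
    """Design the three probes for one centromere.

    The core probe must cover the CDEII midpoint (so it always overlaps the
    centromere span); the two flanking probes sit within ``flank_zone`` bp
    of the span on either side without entering it or overlapping the core.
    Raises :class:`ProbeDesignError` naming the centromere and slot when a
    slot has no window satisfying the length and Tm constraints.
    """
    span = c.span
    mid = (c.cdeII.start + c.cdeII.end - 1) // 2
    zone_core = (span.start - constraints.flank_zone,
                 span.end + constraints.flank_zone)
    core = _best_window(genome, c.chrom, zone_core, mid, constraints)
    if core is None:
        raise ProbeDesignError(f"{c.cen_id}: no feasible core probe window")
    taken = [(core[0], core[1])]
    out = [ProbeCandidate(f"{c.cen_id}_core", core[2],
                          GenomicInterval(c.chrom, core[0], core[1]), "+",
                          gc_fraction(core[2]), core[3])]
    for slot, zone in (("left_flank", (span.start - constraints.flank_zone,
                                       span.start)),
                       ("right_flank", (span.end,
                                        span.end + constraints.flank_zone))):
        w = _best_window(genome, c.chrom, zone, None, constraints,
                         forbid=taken)
        if w is None:
            raise ProbeDesignError(f"{c.cen_id}: no feasible {slot} probe window")
        taken.append((w[0], w[1]))
        out.append(ProbeCandidate(f"{c.cen_id}_{slot}", w[2],
                                  GenomicInterval(c.chrom, w[0], w[1]), "+",
                                  gc_fraction(w[2]), w[3]))
    return out


def design_panel(
    genome: GenomeLike,
    cens: Sequence[CentromereModel],
    constraints: ProbeConstraints = ProbeConstraints(),
) -> ProbePanel:
    """Design the full panel (3 probes per centromere).

    If any centromere is infeasible, raises :class:`ProbePanelError`
    carrying the partial panel and the per-slot failure messages.
    """
    probes: List[ProbeCandidate] = []
    failures: List[str] = []
    for c in cens:
        try:
            probes.extend(design_probes_for_cen(genome, c, constraints))
        except ProbeDesignError as exc:
            failures.append(str(exc))
    panel = ProbePanel(probes)
    if failures:
        raise ProbePanelError(failures, panel)
    return panel


def panel_to_frame(panel: ProbePanel) -> pd.DataFrame:
    return pd.DataFrame([{
        "name": p.name, "chrom": p.source.chrom, "start": p.source.start,
        "end": p.source.end, "strand": p.strand, "length": p.length,
        "gc_percent": round(100 * p.gc, 1), "tm_C": round(p.tm, 1),
    } for p in panel.probes])


def write_panel(panel: ProbePanel, out_dir: str | Path) -> Dict[str, Path]:
    """Write probe FASTA (5'-biotin noted in headers), BED6 footprints, and
    a summary TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": out_dir / "probes.fa", "bed": out_dir / "probes.bed",
             "tsv": out_dir / "probes.tsv"}
    with open(paths["fasta"], "w") as fh:
        for p in panel.probes:
            fh.write(f">{p.name} 5'-biotin len={p.length} "
                     f"gc={100 * p.gc:.1f}% tm={p.tm:.1f}C\n{p.sequence}\n")
    with open(paths["bed"], "w") as fh:
        for p in panel.probes:
            fh.write(f"{p.source.chrom}\t{p.source.start}\t{p.source.end}\t"
                     f"{p.name}\t0\t{p.strand}\n")
    panel_to_frame(panel).to_csv(paths["tsv"], sep="\t", index=False)
    return paths
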