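"""Library-level statistics for centromeric transcription.

Counts are depth-normalized to counts per thousand (CPT = count /
library_size x 1000), the natural scale for targeted-capture libraries
where the enrichment step precludes dispersion-based differential testing.
Entry proportions (the fraction of periCEN reads that read through into
the centromere) are the central roadblock statistic; they are compared
between conditions with an exact paired Wilcoxon signed-rank test over the
16 centromeres x 2 approach directions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import CentromereModel
from .classify import (ClassLabel, ClassifiedTranscript, ENTERING_SET,
                       PERICEN_SET)


class QuantifyError(ValueError):
    pass


def compute_cpt(count: float, library_size: int) -> float:
    """Counts per thousand: ``count / library_size * 1000``."""
    if library_size <= 0:
        raise QuantifyError("library_size must be > 0 for CPT")
    if count < 0:
        raise QuantifyError("count must be >= 0")
    return count / library_size * 1000.0


def count_table(
    classified: Sequence[ClassifiedTranscript],
    library_id: str,
    library_size: int,
) -> pd.DataFrame:
    """Raw and CPT counts per (library, centromere, entry side, class)."""
    rows: Dict[Tuple[str, str, str], int] = {}
    for c in classified:
        key = (c.centromere_id or ".", c.entry_side or ".", c.label.value)
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [{"library": library_id, "centromere": cen, "entry_side": side,
          "label": lab, "count": n,
          "cpt": compute_cpt(n, library_size)}
         for (cen, side, lab), n in sorted(rows.items())]
    )
    return df


def entry_proportions(
    classified: Sequence[ClassifiedTranscript],
    cens: Optional[Sequence[CentromereModel]] = None,
) -> pd.DataFrame:
    """Per (centromere, entry_side) periCEN counts and CEN-entry proportions.

    The denominator is the full periCEN set (pericenRNAs plus the entering
    and spanning subset); the numerator is reads entering by >= 1 bp. Cells
    with a zero denominator are flagged with a NaN proportion. If ``cens``
    is given, all 2 x len(cens) cells appear even when empty.
    """
    counts: Dict[Tuple[str, str], List[int]] = {}
    if cens is not None:
        for c in cens:
            for side in ("CDEI", "CDEIII"):
                counts[(c.cen_id, side)] = [0, 0]
    for c in classified:
        if c.label not in PERICEN_SET:
            continue
        key = (c.centromere_id, c.entry_side)
        cell = counts.setdefault(key, [0, 0])
        cell[0] += 1
        if c.label in ENTERING_SET:
            cell[1] += 1
    rows = []
    for (cen, side), (n_tot, n_ent) in sorted(counts.items()):
        rows.append({
            "centromere": cen, "entry_side": side,
            "n_pericen_total": n_tot, "n_entering": n_ent,
            "proportion": (n_ent / n_tot) if n_tot > 0 else float("nan"),
        })
    return pd.DataFrame(rows, columns=["centromere", "entry_side",
                                       "n_pericen_total", "n_entering",
                                       "proportion"])


def pooled_entry_proportion(table: pd.DataFrame) -> float:
    """Entering / periCEN pooled over all cells (count-weighted)."""
    tot = int(table["n_pericen_total"].sum())
    if tot == 0:
        return float("nan")
    return float(table["n_entering"].sum()) / tot


def median_entry_proportion(table: pd.DataFrame) -> float:
    """Median of per-cell proportions; empty (NaN) cells are excluded."""
    vals = table["proportion"].dropna()
    if vals.empty:
        return float("nan")
    return float(vals.median())


@dataclass
class AggregateProfile:
    """Median per-base coverage across centromeres on a border-anchored axis.

    Position 0 is the outermost base of the anchoring element (CDEI or
    CDEIII); positive positions run into the centromere, negative into the
    pericentromere, regardless of each centromere's genomic orientation.
    """

    anchor: str
    positions: np.ndarray
    values: np.ndarray
    per_centromere: Dict[str, np.ndarray]


_ANCHOR_SIDE = {"CDEI_start": "CDEI", "CDEIII_start": "CDEIII"}


def aggregate_profile(
    classified: Sequence[ClassifiedTranscript],
    cens: Sequence[CentromereModel],
    anchor: str = "CDEI_start",
    flank: int = 500,
    library_size: Optional[int] = None,
) -> AggregateProfile:
    """Median coverage track anchored at a centromere border.

    For each centromere, per-base coverage of reads converging toward the
    anchored border is accumulated on an axis oriented pericentromere ->
    centromere (mirrored for minus-orientation centromeres); the profile is
    the per-position median over the per-centromere tracks. With
    ``library_size`` the tracks are CPT-scaled.
    """
    if flank <= 0:
        raise QuantifyError("flank must be > 0")
    if anchor not in _ANCHOR_SIDE:
        raise QuantifyError(f"unknown anchor {anchor!r}")
    side = _ANCHOR_SIDE[anchor]
    npos = 2 * flank + 1
    tracks: Dict[str, np.ndarray] = {c.cen_id: np.zeros(npos) for c in cens}
    geom = {}
    for c in cens:
        b0 = c.outer_edge(side)
        direction = 1 if b0 == c.span.start else -1
        geom[c.cen_id] = (b0, direction)
    by_id = {c.cen_id: c for c in cens}
    for cl in classified:
        if cl.termination_offset is None or cl.entry_side != side:
            continue
        if cl.centromere_id not in by_id:
            continue
        b0, direction = geom[cl.centromere_id]
        track = tracks[cl.centromere_id]
        for s, e in cl.alignment.blocks:
            if direction == 1:
                a0, a1 = s - b0, e - b0
            else:
                a0, a1 = b0 - e + 1, b0 - s + 1
            a0 = max(a0, -flank)
            a1 = min(a1, flank + 1)
            if a0 < a1:
                track[a0 + flank:a1 + flank] += 1
    if library_size is not None:
        for t in tracks.values():
            t *= 1000.0 / library_size
    stacked = np.vstack([tracks[c.cen_id] for c in cens]) if cens else \
        np.zeros((0, npos))
    values = np.median(stacked, axis=0) if len(stacked) else np.zeros(npos)
    return AggregateProfile(anchor, np.arange(-flank, flank + 1), values,
                            tracks)


def orientation_preference(
    classified: Sequence[ClassifiedTranscript],
    cens: Optional[Sequence[CentromereModel]] = None,
) -> pd.DataFrame:
    """Per centromere, the fraction of CEN-entering reads per entry side.

    Centromeres with zero entering reads are flagged with NaN fractions.
    """
    counts: Dict[str, Dict[str, int]] = {}
    if cens is not None:
        counts = {c.cen_id: {"CDEI": 0, "CDEIII": 0} for c in cens}
    for c in classified:
        if c.label not in ENTERING_SET:
            continue
        cell = counts.setdefault(c.centromere_id, {"CDEI": 0, "CDEIII": 0})
        cell[c.entry_side] += 1
    rows = []
    for cen in sorted(counts):
        n1, n3 = counts[cen]["CDEI"], counts[cen]["CDEIII"]
        tot = n1 + n3
        rows.append({
            "centromere": cen, "n_entering": tot,
            "frac_cdeI": n1 / tot if tot else float("nan"),
            "frac_cdeIII": n3 / tot if tot else float("nan"),
        })
    return pd.DataFrame(rows, columns=["centromere", "n_entering",
                                       "frac_cdeI", "frac_cdeIII"])


def fold_change(cpt_a: float, cpt_b: float) -> float:
    """``cpt_a / cpt_b``; a zero denominator is flagged as infinite."""
    if cpt_b == 0:
        warnings.warn("fold change with zero denominator; reporting inf")
        return math.inf
    return cpt_a / cpt_b


def replicate_mean(cpt_values: Iterable[float]) -> float:
    """Arithmetic mean of per-replicate CPT values."""
    vals = list(cpt_values)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# exact paired Wilcoxon signed-rank test

def _exact_signed_rank_sf(ranks2: np.ndarray) -> np.ndarray:
    """Null distribution of twice the positive-rank sum by sign enumeration.

    ``ranks2`` are doubled mid-ranks (integers). Returns counts of each value
    of 2*W+ over all 2^n sign assignments, conditional on the observed tied
    ranks; counts stay below 2^53 for any practical n, so float64 is exact.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts += shifted
    return counts


def paired_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    exact_max_n: int = 64,
) -> float:
    """Two-sided p-value of the paired Wilcoxon signed-rank test.

    Zero differences are dropped (all-zero input warns and returns p = 1).
    Ties among |differences| take mid-ranks. For n <= ``exact_max_n`` the
    null distribution of the positive-rank sum is enumerated exactly by
    dynamic programming (so figure-legend significance thresholds are
    reproducible without approximation error); beyond that a normal
    approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise QuantifyError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())
    if method == "exact" or (method == "auto" and n <= exact_max_n):
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        counts = _exact_signed_rank_sf(ranks2)
        probs = counts / counts.sum()
        w2 = int(round(2 * w_plus))
        p_le = float(probs[:w2 + 1].sum())
        p_ge = float(probs[w2:].sum())
        return min(1.0, 2.0 * min(p_le, p_ge))
    # normal approximation with continuity correction (variance from the
    # observed mid-ranks, which also absorbs the tie correction)
    mean = float(ranks.sum()) / 2.0
    sd = math.sqrt(float((ranks ** 2).sum()) / 4.0)
    if sd == 0:
        return 1.0
    z = (w_plus - mean - math.copysign(0.5, w_plus - mean)) / sd
    return min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
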