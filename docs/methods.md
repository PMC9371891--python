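# Methods

## Coordinate and data conventions

All internal coordinates are 0-based half-open (BED convention); GFF3
input is converted on read. A point centromere is modeled as three
adjacent CDE intervals whose orientation (`cen_orientation`) is inferred
purely from element order on the chromosome — CDEI→CDEIII with increasing
coordinates is "+" — never from a strand column. One centromere per
chromosome is enforced at annotation load.

A transcript alignment is a set of sorted, non-overlapping blocks with a
strand; its 5′ end (TSS) and 3′ end (TES) are the terminal aligned bases
resolved by strand. Records that are unmapped, secondary, or supplementary
(SAM flag mask 2308) are dropped on ingest so each molecule has exactly
one primary alignment.

## Classification model

A transcript *converges* on the centromere when its 5′ end lies outside
the CEN span and its transcription direction points toward it; convergence
is purely geometric (strand × position), with no expression threshold.
Among converging reads:

* `CEN_SPANNING` — the blocks cover every base of the span;
* `CEN_ENTERING` — block-level overlap with the span ≥ 1 bp (a spliced
  read whose intron covers part of the span is entering, not spanning);
* `CONVERGING_PERICEN` — no overlap, 3′ end within the window upstream of
  the approached border. The window is **inclusive**: termination offsets
  −50 … 0 count, −51 does not. "Within 50 bp" admits either reading; the
  inclusive one is fixed here and the window is a parameter (`window`,
  default 50 bp).
* otherwise `UNRELATED`.

Non-converging reads are `DIVERGENT` when the 5′ end lies inside the span
(including reads fully inside it) or within the window of a border while
pointing away; otherwise `UNRELATED`. Every read receives exactly one
label. The entry side (CDEI vs CDEIII) is the border the read approaches,
translated through `cen_orientation`.

Entry-proportion denominators use the full periCEN set — pericenRNAs
*plus* the entering and spanning subset — because cenRNAs are by
definition the readthrough subset of the pericentromeric repertoire. This
subset semantics controls the entry-proportion statistic and is asserted
in tests.

## Quantification

* **CPT** = count / deduplicated library size × 1000. The denominator is
  the post-dedup mapped read count; fold changes compare CPT, not raw
  counts. Replicate averaging is the arithmetic mean of per-replicate CPT.
* **Entry proportions** are computed per (centromere × entry side) cell;
  cells with a zero denominator are flagged NaN and excluded from medians
  (never imputed). The pooled proportion is the count-weighted mean of
  cells, which the tests assert explicitly.
* **Aggregate profiles** anchor each centromere at the outermost base of
  CDEI (or CDEIII), orient the axis pericentromere → centromere (mirrored
  for "−"-orientation centromeres), accumulate per-base block coverage of
  reads converging toward that border, and take the per-position median
  over the 16 per-centromere tracks. The median over an even number of
  tracks is the mean of the middle pair (numpy convention). Using 16
  per-centromere tracks split by approach direction — rather than 32
  centromere-strand tracks — matches the two-arrow, per-border
  presentation of such plots; the anchor and flank are parameters.
* **Paired signed-rank test.** Zero differences are dropped; |d| ties take
  mid-ranks; the null distribution of the positive-rank sum is enumerated
  exactly by dynamic programming over doubled ranks (counts < 2⁵³, so
  float64 arithmetic is exact), conditional on the observed ranks. The
  exact path is used up to n = 64 — deliberately covering the 16- and
  32-cell designs this analysis produces, so significance thresholds don't
  inherit approximation error — with a continuity-corrected normal
  approximation beyond. For tie-free inputs the exact p matches
  `scipy.stats.wilcoxon(mode="exact")` to machine precision; for n ≤ 12 it
  matches full 2ⁿ enumeration.

## UMI deduplication

Duplicates are collapsed by the exact key (UMI, chromosome, strand, 5′
end, 3′ end): zero UMI mismatches and zero coordinate shift. This is a
deliberate simplification of clustering-based dedup, justified when the
upstream tool is run with zero-mismatch/zero-shift settings. The group
representative is the lexicographically lowest read id (deterministic);
group sizes are recorded and sum to the input count. Mixed UMI lengths are
rejected. Note that UMI length is configurable (default 6 nt) because RT
oligo designs and tag-step configurations in this assay family disagree
between 6 and 7 nt.

## NDRs and TSS origin classes

A nucleosome-depleted region is an inter-nucleosome gap strictly greater
than `min_gap` (default 80 bp), measured edge-to-edge on the canonical
nucleosome map (dyad-to-dyad is the other defensible reading; edge-to-edge
is fixed here). Chromosome ends are not gaps.

The main TSS of a (centromere × entry side) cell is the modal 5′-end
position of its periCEN reads; ties break toward the border, then to the
smaller coordinate. A modal rule is a stated choice: start sites can
spread over hundreds of bases, and no standard "main TSS" definition
exists for such pervasive transcription.

Origin categories are assigned with precedence readthrough > adjacent-NDR
> antisense > intergenic (most to least geometrically specific).
"Neighboring gene" means any gene on the TSS's side of the centromere
within a 2 kb horizon (distance 0 if the TSS is inside the body).
Readthrough requires the TSS at or 5′ of a same-strand neighbor's
promoter *and* that gene's 3′ end between the TSS and the border;
adjacent-NDR requires the TSS inside an NDR containing a neighbor's
promoter or TTS anchor base.

## Probe design

Three probes per centromere: a core probe whose window must contain the
CDEII midpoint base (hence always overlapping the span) and one probe per
flank inside a 500 bp search zone outside the span, non-overlapping with
the core. Constraints: length 103–120 nt and nearest-neighbor Tm within
66.9–70.8 °C (target 67.6 °C). Selection scans lengths from 120 down,
keeps the first length with any feasible window, and breaks ties by
|Tm − target| then leftmost start — deterministic, and verified against
brute-force enumeration of all windows. Every emitted probe is re-checked
against every active constraint.

Tm is the unified Allawi–SantaLucia nearest-neighbor model
(`Bio.SeqUtils.MeltingTemp.Tm_NN`, table DNA_NN3) with the entropic
monovalent-salt correction. The ionic conditions are explicit
configuration — 0.1 M monovalent, 0.25 µM probe strand by default —
calibrated once so that 120-mers from AT-rich pericentromeric sequence
(flank GC ≈ 25%, CDEII ≥ 90% AT) land inside the default Tm band; at
typical hybridization-buffer ionic strengths the same windows would sit
~5 °C higher, so the band and the conditions should be changed together.
GC content is reported but not constrained: in AT-rich pericentromeric
windows the Tm band already pins the GC range (~14–25%).

## Synthetic landscape generator

The generator emulates the statistical structure the analysis assumes,
per chromosome: one centromere (CDEI 8 bp with the Cbf1 E-box consensus;
CDEII 78–86 bp with an enforced AT floor, default ≥ 0.90; CDEIII 25 bp on
a consensus-like scaffold; orientation random per chromosome), flanked by
3 kb pericentromeric arms at GC 0.25 carrying, per side: a gene
transcribing toward the centromere (readthrough donor), a gene
transcribing away (antisense host), and a 147 bp-nucleosome map with
designed > 80 bp NDRs pinned exactly over the four gene anchors (all other
linkers ≤ 80 bp, so NDR detection recovers exactly the designed gaps plus
the nucleosome-free centromere itself).

Converging molecules per (centromere × side) draw their 5′ end from four
disjoint initiation regions — neighbor promoter (readthrough), the
border-proximal anchor NDR, a nucleosome-covered intergenic stretch, and
the interior of the away-gene body (antisense) — with weights defaulting
to 0.25/0.40/0.20/0.15 (the NDR class the most abundant, as observed for
this class of non-coding RNA). Because the regions are disjoint, the TSS
categorizer recovers the generating class exactly, which the tests assert
as a diagonal confusion matrix.

The 3′ end follows the roadblock model: with probability `p_enter` the
molecule crosses the approached border, then either traverses the whole
span (`p_fullspan`, default 0.05, exiting 0–50 bp beyond) or terminates
with a constant per-bp hazard along CDEII (default 0.08, giving a median
entry depth of ~10–20 bp from the CDEI side; entry via CDEIII adds that
element's 25 bp first). Non-entering molecules stop inside the 50 bp
window with probability `p_window` (uniform over offsets 0…−50) or else
uniformly 51–300 bp upstream; the uniform upstream tail is the
least-assumptive testable choice in the absence of a known termination
distribution. The classifier's conditional entry estimate therefore
converges to p_enter / (p_enter + (1 − p_enter)·p_window), which is how
the three named profiles were calibrated:

| profile | p_enter | p_window | conditional entry |
| --- | --- | --- | --- |
| `wt_g1` (default) | 0.010 | 0.622 | 1.6% |
| `wt_s` | 0.536 | 0.569 | 67.0% |
| `cbf1d_g1` | 0.450 | 0.545 | 60.0% |

PCR duplicates are appended per molecule (Poisson, rate 0.3 by default)
sharing UMI and coordinates exactly; UMIs are uniform random 6-mers.
Background reads sit on gene bodies away from borders. An optional
divergent-read fraction defaults to 0: divergent transcription is labeled
by the classifier but not modeled generatively. In-silico capture retains
each read independently — probe-overlapping (≥ 1 bp, block level) with one
probability, everything else with another; there is no thermodynamic or
coverage-bias model. One seeded generator per `build_genome` /
`simulate_*` call; no global RNG state; identical (config, seed) gives
byte-identical files.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing and alignment error, chimeras,
splice structure (simulated molecules are single-block), length-dependent
RT/PCR/capture efficiency, probe-specific pull-down variation,
centromere-to-centromere initiation heterogeneity beyond the strand-bias
parameter, and any correlation between duplicates and molecule abundance.
Parameter-recovery results show the pipeline is correct under its own
model, not that the model is complete.

## Problem sizes in the recompute script

`scripts/acceptance.py` uses 500 molecules per (centromere × direction)
cell for median/paired-test statistics, 50 000 converging molecules for
pooled proportions, two 100 000-read libraries for the fold change, and
5 × 10⁶ lightweight records for the capture enrichment — sizes chosen so
each Monte-Carlo standard error is small relative to the quantity
estimated while the whole script stays desk-scale on one CPU. Tolerances
in the test suite are three Monte-Carlo standard errors from the binomial
closed forms.

## Known limitations

* Divergent transcripts are labeled but not further analyzed or simulated.
* No isoform collapsing or splice-aware model building; entry depth uses
  block overlap only.
* Dispersion-based differential expression is deliberately out of scope:
  capture enrichment biases read composition, so CPT comparisons and the
  paired rank test are the supported statistics.
* The probe designer does no cross-hybridization screening.
* Exact dedup treats any UMI mismatch as a distinct molecule; sequencing
  errors in UMIs would inflate library size on real data.
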