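# Methods

## The problem

In budding yeast the genome must replicate once per cell cycle. Licensed
origins fire in a characteristic temporal order (summarised by each
origin's median replication time, `T_rep`), and the checkpoint kinase Rad53
restrains initiation when DNA is damaged: at the G1/S transition through
the G1/S transcription programme (Swi6/SBF) and through direct inhibition
of the firing factors Sld3 and Dbf4, and in G2/M by limiting re-initiation
when licensing control is compromised. Re-initiation produces local
copy-number gains above the 2n baseline and, via fork breakage and strand
annealing across a split marker, re-replication-induced gene amplification
(RRIGA) that can be scored as Leu⁺ colonies.

This package quantifies both phenomena from binned sequencing coverage, and
ships a forward simulator so every estimator can be validated against a
known ground truth.

## Simulator

### S-phase entry (G1 release)

Per cell and origin *i*, the firing time is
`T_i = max(N(trep_i + δ, σ_i), 0)`, with `δ` the checkpoint transcription
delay (0 when the uninhibitable Swi4 truncation is expressed) and `σ_i` the
origin's per-cell firing spread. Independently, with probability `p`
(optionally restricted to the early or late half of the `T_rep`
distribution) the origin is held until a release time — the Rad53→Sld3/Dbf4
arm; `p = 0` models the checkpoint-refractory `sld3-A dbf4-A` background.
Position *x* is replicated at time *t* if
`min_i (T_i + |x − pos_i| / v) ≤ t` (forks at speed *v*; passive
replication included). The population profile per bin is
`1 + fraction of cells replicated at the bin midpoint`, averaged over
`n_cells` Monte-Carlo cells.

Forks do not stall or terminate except implicitly at meeting points (the
`min` over origins) and chromosome ends. All random draws are made once per
(seed, configuration) before thresholding on *t*, so profiles from the same
seed are non-decreasing in *t*, increasing the block probability can only
lower values, and a transcription delay is an exact time shift — all three
are tested as properties.

### G2/M re-replication

Per cell, origin *k* re-initiates `Poisson(λ_k · s)` times, where `λ_k` is
the origin's re-initiation rate and `s` a global scale modelling relief of
the checkpoint brake. Each event adds one copy over `[pos − L₁, pos + L₂]`
with `L₁, L₂ ~ Exp(mean extent)` — an "onion-skin" model: events are
independent and additive, with no fork-collision modelling. Closed forms
used as test oracles: expected copy at the origin is `2 + λ`; at distance
*d* it is `2 + λ·exp(−d/extent)`; total excess mass per cell is
`Σ_k λ_k · 2 · extent`. With licensing disabled the profile is exactly 2.

### Read sampling and RRIGA counts

Counts per bin are `Poisson(depth × copy)`; non-replicating references are
sampled from a flat profile at the scenario baseline. RRIGA plating
emulates the standard serial-dilution plan — per replicate, one rich plate
(0.1 ml of a 10⁴-fold dilution) and two selective plates (0.1 and 0.01 ml
undiluted) — with Poisson colony counts at rate `n_viable × volume /
dilution`, scaled by `p_amp` on selective medium.

## Copy-number pipeline

1. **Binning.** BedGraph intervals are re-accumulated onto a fixed-width
   grid (default 1 kb) with overlap-proportional allocation, kept as
   floats.
2. **Ratio.** Per bin, `(s_i/S)/(r_i/R)` with `S, R` the unmasked totals.
   Bins whose reference count falls below `min_ref_count` (default 10) are
   masked. Masks only grow downstream.
3. **Baseline calibration.** The profile is scaled so its unreplicated mode
   sits at the known ploidy (1 or 2). The mode is located on a 0.01-width
   histogram of a 15-bin-smoothed copy of the profile, taking the
   *lowest-value* prominent peak (prominence ≥ 25% of the tallest): in a
   partially replicated profile the replicated bins form a second, possibly
   larger peak. The estimate is then refined on the raw values by a
   twice-iterated local median (±0.10 band). The two-stage rule matters
   numerically: the raw ratio of two Poisson counts is right-skewed, so its
   raw histogram argmax sits ~1% below the unreplicated centre at depth
   100, while smoothed values centre on the mean (inflated ~0.5% by the
   E[1/r] bias); the iterated local median of raw values is immune to both
   and calibrates a flat 2n control to a median within ~0.5% of 2.0.
   Calibration requires ≥50 unmasked bins.
4. **Smoothing.** Centred moving average (default 15 bins = 15 kb), masked
   bins excluded from numerator and denominator, truncated windows at
   edges. The default width preserves single-origin peaks of the default
   simulator geometry.

End-to-end on simulated data at depth 100 the calibrated, smoothed profile
tracks the simulator truth with mean absolute error below 0.1 copy units
(tested).

## Analyses

* **Per-origin replication** (baseline-1 profiles): mean copy over unmasked
  bins whose midpoints lie within ±5 kb of the origin, minus 1, clipped to
  [0, 1]. Fully masked windows are dropped and logged; windows at
  chromosome ends truncate.
* **Quintiles.** Origins ranked by `trep` (ties broken by (chrom, pos));
  the rank range is split into five contiguous groups differing in size by
  ≤1, earlier quintiles taking the extra member. Summaries use
  linear-interpolated quantiles; comparisons use the unpaired two-sided
  Student t-test (pooled variance), Welch by flag. Two zero-variance groups
  with equal means return t = 0, p = 1, flagged.
* **Re-replication** (baseline-2 profiles): gained segments are maximal
  runs of unmasked bins at copy ≥ 2.2 (threshold 0.2) of length ≥ 5 bins,
  no gap-merging; the per-chromosome index is `mean(copy) − 2`; peak height
  is the window maximum at a marker origin.
* **RRIGA.** Cells/ml per plate is `colonies × dilution / volume`. Per
  replicate, plates of the same medium are averaged before the ratio
  `%Leu⁺ = selective / rich × 100` (pairing across media is by replicate
  id). Replicates aggregate with mean and sample SD (n − 1); Poisson
  counting error is deliberately not propagated — reported spread is
  replicate spread only. Zero viable counts flag the replicate as
  undefined rather than raising.

## The stated world (synthetic defaults)

The simulator's defaults are a fixed description of the system, chosen once
at desk scale and not revisited:

| parameter | default | rationale |
|---|---|---|
| genome | 4 chromosomes, 230/810/315/1090 kb | yeast-scale chromosomes incl. a chrIII-like 315 kb |
| origins | 121, frozen registry | ≥100 origins, realistic ~20 kb spacing |
| `trep` | uniform 15–45 min | an S phase spanning ~30 min |
| fork speed | 1.5 kb/min | typical yeast fork rate |
| firing spread σ | 5 min | cell-to-cell initiation variability |
| `n_cells` | 500 | population average stable to ~2% |
| read depth | 100 /bin/copy | desk-scale sequencing depth |
| re-initiation rate λ | 0.02 (baseline), 0.3 (chrIII), 1.0 (ARS317) | chrIII susceptibility is configuration, not code |
| bubble extent | 10 kb | sub-chromosomal re-replication bubbles |
| checkpoint-relief scale | 3 | relieved strains re-fire several-fold more |
| RRIGA `p_amp` | 10⁻⁶ pre-induction; 10⁻³ induced, ×2 relieved | per-mil amplification frequencies, doubled without the brake |

What the generator does **not** emulate: mappability/GC bias, repetitive
regions, fork stalling or collision, breakage/repair mechanics behind
RRIGA (collapsed into the single `p_amp`), chromatin context, or origin
licensing efficiency differences. A green test therefore establishes that
the estimators are correct for Poisson-sampled data from this model — not
that real libraries are free of coverage artefacts (no GC or mappability
correction is applied; that is a documented extension point).

## Numerical choices and degenerate inputs

* 0-based half-open coordinates throughout; origin positions are points;
  the last bin of a chromosome truncates at its end.
* Quintile ties, quantile interpolation and the mode refinement are exact,
  deterministic rules (above) so seeded runs are byte-reproducible.
* Chromosomes without origins stay at copy 1 in the S-phase simulator (not
  an error); empty quintiles yield flagged n = 0 rows; fully masked
  chromosomes/windows are dropped with a log line.
* Seeds: scenario runs derive sub-stream seeds as `[seed, tag…]` entropy
  lists, so sample and reference tracks are independent but reproducible.
* The packaged scenario timepoints (10/20/30 min) span early-to-mid S for
  this registry. By ~40 min replication is nearly complete and a 1n
  baseline no longer exists in the data; mode calibration of such profiles
  is meaningless and is the main known limitation of baseline-by-mode.

## Known limitations

* Ordinal, not absolute, reproduction of re-replication biology: the model
  has no printed kinetic parameters to match, so conclusions are rankings
  and monotone responses (chrIII top-ranked; relief increases gains;
  doubled `p_amp` doubles %Leu⁺).
* The per-origin window mean (±5 kb, unsmoothed-peak scale) is this
  package's definition of "replication amount"; other window statistics
  (max, smoothed mean) would shift absolute values but not orderings.
* Student's t on 3 replicates has limited power; the Welch option exists
  but small-n normality is assumed, as is conventional for plating assays.
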