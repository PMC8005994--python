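# Methods

## The mass-based formulation model

Capsule filling by hand compacts powder only partially: a capsule ends up
holding more than its volume times the poured (bulk) density ρ_b but less
than its volume times the fully compacted (compressed) density ρ_c. The
required bulking-agent mass for a batch is therefore taken as a weighted
mean biased toward the bulk state,

    m_b = (3·ρ_b + ρ_c) / 4 · V_C · n_C,

with V_C the capsule volume (0.5 mL for size #1) and n_C the batch size.
The formula is empirical; the package treats it as given and enforces only
ρ_b ≤ ρ_c, which also bounds m_b between the two density extremes.

Densities come from replicate measuring-cylinder readings (9–11 g powder;
volume read before and after a defined compaction procedure). Aggregation
follows the per-replicate convention: ρ_b, ρ_c and the density increase
(ρ_c − ρ_b)/ρ_c · 100 % are computed per replicate first, then averaged
(mean ± sample SD, n−1). Averaging per-replicate increases rather than
taking the increase of the mean densities matters at the third decimal and
is the convention that reproduces tabulated aggregates exactly. Cylinder
volumes (0.1 mL resolution) are taken at face value; no measurement
uncertainty is propagated.

The blend adds the API with a deliberate overage (default 10 %) on top of
the nominal label claim — the overage compensates for powder lost to the
equipment during blending and encapsulation, while the label claim, and
hence every content-uniformity calculation, stays at the nominal dose. The
glidant fraction (default 0.5 % m/m) is interpreted as a mass fraction of
the *bulking agent* (filler + glidant), the reading that reproduces
published blend tables cell for cell. Reported masses are rounded to
0.1 mg; internal arithmetic is unrounded.

## Quality metrics

**Content uniformity.** The acceptance value on individual contents
expressed as percent of label claim, for the T ≤ 101.5 % case:
AV = |M − X̄| + k·s with M = X̄ clipped to [98.5, 101.5] and s the sample
SD. A batch passes at AV ≤ 15 (L1), evaluated after rounding to 2 dp so a
printed 15.00 passes. The acceptability constant k defaults to the
compendial n-based value — 2.4 for n ≤ 10, 2.0 otherwise — because the
n = 30 evaluations this package targets are only consistent with k = 2.0;
an explicit override is available everywhere. A two-stage mode implements
the full compendial procedure (stage 1 on 10 units with k = 2.4; stage 2 on
30 units with k = 2.0 plus the individual-unit limit of ±25 % around M).
The summary form of the AV converts a relative content SD (percent of the
mean) to percent of label before applying the M-rule, making it exactly
consistent with the raw-sample form.

**Powder loss.** (m_t − (m_a − n·m_c))/m_t · 100 %, where m_t is the
weighed blend mass, m_a the summed gross capsule masses and m_c the mean
empty-shell mass (per-capsule tares are used when weighed). Negative losses
(weighing noise) are reported, not clamped. Guideline limit 3 %.

**Mass uniformity.** Relative sample SD of gross filled-capsule masses
(what a pharmacy weighs); a flag switches to net fill masses. Limit 5 %.

**Blend homogeneity.** Relative sample SD of the per-capsule quotients
content / net mass; a perfectly homogeneous blend gives a constant quotient
regardless of fill-mass variation.

Sample SDs (n−1) are used throughout, per dosage-unit-statistics
convention.

## Mass balance

The API ledger closes by construction: unaccounted = weighed API − API in
capsules − Σ residues. Equipment residues are normalized by the weighed API
(which includes the overage); shell retention — relevant because pediatric
capsules are opened and sprinkled onto food — by the nominal dose.
Over-recovery (> 100 %) warns rather than errors, since swab assays carry
noise.

## The batch simulator

The simulator emulates what a batch *measures like*, not powder physics.
One seeded generator drives six stages: blend formation (from the
formulation module), biased mass loss, fill-mass draws, per-capsule
concentration draws, outlier injection, and tare draws.

Parameters, defaults, and what they emulate:

| parameter | default | meaning |
|---|---|---|
| `cv_fill` | 0.02 | relative SD of per-capsule fill mass (hand filling; observed mass SDs 0.7–4 %) |
| `cv_mix` | 0.02 | relative SD of the per-capsule API mass fraction (blend inhomogeneity; observed content SDs 1–7 %) |
| `loss_fraction` | 0.035 | fraction of blend mass lost to equipment (observed 1–11 %) |
| `segregation` | 1.0 | API concentration of lost powder relative to the blend; 1 = unbiased |
| `device_weights` | bowl 0.35, machine 0.35, spreader 0.12, pestle 0.08, spatula 0.05, boat 0.05 | allocation of lost mass; bowl and filling machine dominate (largest contact surfaces) — qualitative only |
| `shell_tare_mean/sd` | 74 / 2 mg | empty size-#1 shell masses |
| `outlier_rate`, `outlier_depletion` | 0.02 / 0.20 | probability and relative content deficit of a gross mixing failure (emulating occasional −15 to −22 % capsules) |

Distributions: truncated normals (at zero) for fill masses and tares; a
log-normal option for content fractions avoids negative draws at high CV.
Draws are renormalized so the fills sum exactly to the remaining blend mass
and the contents exactly to the remaining API; conservation is therefore
exact to machine precision, at the cost of a weak negative correlation
between capsules within a batch. Under this model the expected content per
capsule is (1 + overage) · dose · (1 − segregation · loss_fraction): an
unbiased loss of 1/11 exactly cancels a 10 % overage, and the zero-noise,
zero-loss limit pins the AV at 8.5 (mean 110 % of label against the 101.5 %
reference bound). The segregation factor is the single knob that decouples
API loss from powder loss, reproducing the empirical observation that
content and powder loss need not be related.

What the simulator does **not** capture: position-dependent filling effects
on the machine plate, time trends during filling, correlated loss between
replicate batches prepared in sequence, assay (HPLC) error as a separate
noise source, and particle-size-driven mixing mechanisms (interactive
mixtures). Passing parameter-recovery tests therefore show the QC metrics
are unbiased estimators under idealized noise, not that real batches meet
the defaults.

Seeding: one integer seed; replicate batches derive child seeds via a seed
sequence, so any batch series is reproducible bit for bit.

## Numerical and design choices

- Rounding: AVs report at 2 dp, loss/SD percents at 2 dp, mean contents at
  3 dp (0.001 mg); pass/fail flags evaluate on the rounded values.
- Degenerate inputs: single density replicates report zero SDs with a flag;
  QC requires ≥ 2 capsules; a tare exceeding the gross mass is an error
  (swapped inputs), as is a bulk density exceeding the compressed density.
- The published 54-batch summary table and the density table ship as
  package data; the summary re-evaluation recomputes each AV from the
  printed mean and relative SD and counts powder-loss exceedances from the
  data rather than trusting any prose total. With the printed (rounded)
  summaries, the recomputed AV at k = 2.0 lands within 0.3 of the printed
  column for 43 of 54 batches — and for 0 of 54 at k = 2.4, which is what
  fixes the default constant at the n = 30 compendial value. The residual
  disagreements concentrate in the 0.5 mg tables, where several printed AVs
  are not consistent with their own printed mean/SD pair under any
  constant.
- Analysis problem sizes: the drivers simulate 54 batches of 30 capsules
  (the study layout); property tests use 200–1000 seeded batches, enough to
  put Monte Carlo CIs well inside the asserted bands.

## Known limitations

- The blend-mass formula is empirical and validated only for the density
  range of the three characterized bulking agents (ρ_b ≈ 0.39–0.56 g/mL).
- Only the T ≤ 101.5 % case of the acceptance-value rule is implemented
  (label claims are taken at 100 %); dosage forms with elevated targets are
  out of scope.
- Device-level residue allocation is qualitative; no swab-recovery
  efficiency correction is applied.
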