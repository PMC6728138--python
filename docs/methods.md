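# Methods

## Binding model and the two-step global fit

Per-bead bound-protein fluorescence is modeled with the single-site Langmuir
isotherm

    I_i(c) = Imax · c / (Kd_i + c)

where `c` is the total protein concentration (nM), `Kd_i` the dissociation
constant of peptide `i`, and `Imax` the fluorescence at bead saturation,
shared by all peptides in one assay (constant binding stoichiometry and
comparable peptide surface density). Free protein is approximated by total
protein: in a pooled assay the accessible peptide is roughly 20 nM divided by
the number of species probed (`estimate_peptide_concentration`, logged as a
diagnostic), far below the Kd range of interest, so ligand depletion is
negligible.

Fitting proceeds in two steps:

1. **Global Imax.** Series are ranked by their maximum median intensity and
   the top 80% (configurable `top_fraction`) are fit jointly — one shared
   `Imax`, one `Kd` per series — because the series closest to saturation are
   the ones that constrain the plateau. The joint fit runs in log-parameter
   space with `scipy.optimize.least_squares` (unweighted least squares on
   intensities; tight tolerances so noiseless data are recovered to ~1e-6
   relative).
2. **Per-peptide Kd.** With `Imax` fixed, each series is a one-parameter
   least-squares problem. A 256-point log-spaced scan over the Kd bounds
   `[1e-2, 1e6]` nM brackets the global minimum and a bounded scalar
   minimization polishes it; this is deterministic and matches a 10⁴-point
   brute-force log-grid oracle to within one grid step.

Medians (not means) are fit at each concentration: they are robust to the
multiplicative bead-to-bead noise and to occasional outlier beads. A constant
per-assay background — the overall median of the antibody-only control, else
0 — is subtracted before fitting so that the `c → 0` limit of the model is
consistent with zero specific signal.

**Uncertainty.** Kd intervals come from a bead-level percentile bootstrap
(default 500 resamples, seeded): beads are resampled with replacement within
each concentration, medians recomputed, Kd refit. No distributional assumption
is needed; a resample over a single bead at some concentration triggers a
warning because the interval can then be degenerate.

**QC flags.**

- `NONSPECIFIC`: either single-concentration control (a binding-deficient
  protein mutant, or labeled antibody alone, both at 250 nM) has a
  background-subtracted median above `0.2 × Imax` (configurable). Flagged
  peptides are excluded from energetics by default; with no control data the
  result is `UNTESTED`, never silently clean.
- `NON_SATURATING`: fitted fraction bound at the top concentration,
  `c_max/(Kd + c_max)`, is strictly below 0.5; the Kd then has lower-bound
  semantics only (a series that never approaches the plateau cannot pin both
  a point Kd and its distance to saturation).
- `LOW_SIGNAL`: all background-subtracted medians ≤ 0, or fewer than
  `min_beads` (default 5) beads at some concentration; the reported Kd is a
  lower bound at the maximum assayed concentration.

## Energetics

Relative binding energies use `ΔΔG = RT·ln(Kd_i/Kd_ref)` with
R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ and T defaulting to 298.15 K. The temperature is
configurable; it only scales the energy axis and cancels from all relative
comparisons, so the default is the conventional standard temperature rather
than the (colder) incubation temperature of a typical bead assay.

Absolute affinities are recovered by anchoring to a reference peptide of known
affinity (default 980 nM, the high-affinity PVIVIT reference):
`Kd_cal,i = Kd_ref,lit · (Kd_fit,i / Kd_fit,ref)`. This is a pure rescaling —
ΔΔG values and rank order are identical before and after — and is refused when
the reference itself is flagged. Bootstrap Kd intervals propagate to ΔΔG by
transforming the endpoints (the log transform is monotone).

Double-mutant-cycle interaction energies are
`ε = ΔΔG_ab − ΔΔG_a − ΔΔG_b` with all corners on a common reference; the
choice of reference cancels. Replicate concordance is the squared Pearson
correlation of matched ΔΔG vectors, reported with the regression slope and
intercept so anti-correlation is visible in the slope's sign.

## Code calling

Ratios are coding-channel medians divided by the internal-standard channel
median, making decoding invariant to overall illumination scale; beads with a
near-zero standard signal are rejected. Assignment uses a Gaussian mixture
with means fixed at the code map's target ratio vectors, equal priors, and a
shared diagonal covariance re-estimated from residuals over three hard-EM
rounds (a variance floor keeps noiseless data well-posed, where the procedure
reduces to nearest-centroid). A bead is `UNASSIGNED` when its posterior falls
below 0.95 or its Mahalanobis distance to the assigned centroid exceeds 3.

Decoding **accuracy is defined over assigned beads**: with truly Gaussian
ratio noise in three channels, ~3% of beads legitimately fall beyond
Mahalanobis 3 of their own centroid and are dropped by the conservative
distance cut. Dropping beads costs statistical power; miscalling them would
corrupt another peptide's series, so rejection is the intended behavior and
the ≥99%-accuracy guarantee applies to the beads that survive it.

## What the simulator emulates — and what it does not

The generator reproduces the study conditions as its defaults: a 48-plex code
library drawn from a 4-level grid in 3 coding channels, 100 beads per sequence,
the six-point dilution series (2000, 1000, 500, 250, 125, 62.5 nM), control
assays at a single 250 nM concentration, a shared true Imax (1000 a.u.), and
true Kds spanning 30–3000 nM so the series brackets them.

Unstated noise magnitudes were chosen once, as plausible for bead assays, and
are not tuned: per-bead intensity noise is multiplicative lognormal with
σ = 0.15 (coating variation is proportional; medians are robust to it) plus a
constant additive background (default 10 a.u.); ratio noise is isotropic
Gaussian with σ = 0.03 per channel, well separated from the 4-level grid
spacing (~0.27). Nonspecific control binding is a per-peptide fraction of
Imax, zero for most peptides and elevated for designated "sticky" ones.

Not modeled: spectral bleed-through between lanthanide channels, flat-field
and illumination gradients, bead-size variation, binding kinetics (slow on/off
rates are the mechanism that lets washed beads approximate equilibrium, not
part of the analysis), ligand depletion, and inter-assay Imax drift beyond
what calibration absorbs. Passing tests therefore demonstrate correctness of
the estimators under the stated generative model, not robustness to every
real-world artifact; the QC flags and controls are the hooks by which real
artifacts are caught.

Rendered images place beads as non-overlapping uniform discs with channel
means equal to the tabulated bead values; they exercise segmentation and
median extraction, while the tabular path is primary.

## Numerical and design choices

- Kd bounds `[1e-2, 1e6]` nM; fits are deterministic (no random starts).
- The "top 80%" selection for the Imax step ranks per-peptide series by
  maximum median intensity; at least two series are always kept.
- Scaled-logo weights at a position are `max(0, −ΔΔG + offset)` normalized to
  sum 1, with the offset equal to the largest measured destabilization there —
  a shift-invariant convention that makes stabilizing residues tall; a
  position where all residues are equivalent gets uniform heights.
- Heat maps clip the color scale at ±2.5 kcal/mol (configurable) and render
  flagged/missing cells in grey, never as 0; every figure has a CSV twin and
  recomputes nothing.
- Variant ids are canonical (`SCAFFOLD_2K_9Z`, sorted by position) and round-
  trip to the substitution list; scaffold names may not contain `_`.
- The end-to-end pipeline writes a manifest (config hash, seed, version) and
  is bit-identical on tabular outputs for a fixed config.

## Problem sizes used in the test suite

The suite exercises the full study-scale recovery experiment (48 × 100 × 6 =
28,800 beads) once; the bootstrap-coverage calibration uses 40 simulation
replicates of 50 beads per concentration with 150 resamples each, enough to
bound the empirical coverage of the nominal 95% interval from below at 85%
with comfortable binomial margin. The demo pipeline in the tests scans one
position at 30 beads per code. These sizes are the package's choices for a
fast, deterministic suite; all estimators accept the full-scale inputs.

## Known limitations

- The fixed-means mixture assumes the code map's target ratios are accurate;
  systematic ratio drift (e.g. from chemistry exposure) would need re-centered
  targets.
- NON_SATURATING series yield qualitative affinity ordering only; no attempt
  is made to fit a second parameter to them.
- The nonspecific flag is a threshold rule on control medians, not a model of
  the cross-reactive binding itself.
- FASTA output uses `X`/`Z` as nonstandard letters; downstream tools that
  enforce the 20-letter alphabet will reject them.
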