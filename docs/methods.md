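# Methods

## Model overview

`reefsim` models the *attraction* process only: a fixed stock of fish
biomass is redistributed when an artificial reef (AR) is added near
natural reef (NR). No production (growth, survival), temporal dynamics,
density dependence or movement trajectories are modelled; the total
biomass in the system is identical before and after deployment, which is
the premise the harvest comparison rests on.

The arena is a square lattice, by default 211 × 211 cells of 10 m — a
2.11 km square chosen so that the exponential and logistic kernels decay
to negligible values well inside the boundary for every documented
parameter combination. There is no toroidal wrap; kernels are truncated
at the edge, and with the default arena the truncated mass is far below
the 1e-9 conservation tolerance used in tests.

### Biomass placement

Relative biomass around a reef follows `B_i = exp(-k D_i)`, `k = ln2/D_h`,
with `D_i` the Euclidean distance between cell centres to the *nearest*
reef cell. Using the nearest-cell distance implements the non-additive
"maximum" rule for cells within reach of several reef cells: because the
kernel is monotone decreasing, the max over per-reef-cell exponentials
equals the exponential of the minimum distance (verified against a
brute-force oracle in the test suite). Reef cells carry `B = 1`; all
totals are relative and reported as fractions, never absolute mass.

### Attraction

A cell at distance `D_i` from the AR gives up the fraction

    f(D_i) = Q0 / (1 + exp((ln 99² / D_99)(D_i − D_50))),  Q0 = Q/(Q+1).

The slope constant `ln 99² = 2 ln 99` makes `f(0) = 0.99·Q0`,
`f(D_50) = Q0/2` and `f(D_99) = 0.01·Q0` when `D_99 = 2·D_50` (enforced;
this keeps the curve symmetric about `D_50`). We keep the literal
logistic rather than rescaling it to attain `Q0` exactly at zero
distance: `Q0` is the *limiting* attracted proportion as distance goes to
zero. Consequently the realized AR:adjacent-NR density split at one
cell's separation is slightly below `Q` (≈1.93 for `Q = 2`); the exact
identity `Q = Q0/(1−Q0)` holds in the zero-distance limit and is exposed
as `density_ratio_at_zero`.

### Redistribution and the overlap rule

The attracted total is distributed over the whole grid proportionally to
the exponential kernel around the AR. Two rules govern cells influenced
by both reefs after deployment:

- `additive` (default): `B_ai = B_ri + attracted_total · w_i`. Conserves
  total biomass to machine precision and is the rule used everywhere in
  the shipped analyses.
- `max`: element-wise maximum of the remaining field and the incoming
  redistribution. This is the literal reading of the non-additive rule
  across reefs, but it destroys conservation (the premise of the model),
  so it is offered only as a switch and its use is logged.

### Functional groups

*Reef residents* start with the NR exponential field. *Reef-associated
pelagics* start uniform at 1 per cell, are first attracted to the NR with
quality `Q_nr = 1` and redistributed around it (that state is the
pre-deployment baseline for CPUE), then attracted to the AR with quality
`Q`. No cell is exempt from the second round: NR cells lose biomass to
the AR like any other cell, since the habitat-choice rule applies to all
fish within reach.

### Harvest

CPUE is the summed biomass of the `p` richest cells, with cells
re-selected before and after deployment (effort follows the fish). Ties —
ubiquitous under the threshold model — break by row-major cell order, so
every result is bit-reproducible. The threshold variant caps per-cell
catch at `0.70 × max(before field)`; the cap derives from the
*pre-deployment* maximum and is reused after deployment, and the capped
catch (not raw biomass) is the ranking key, which is what lets maximum
CPUE occur over a wider area.

## Parameters

| Parameter | Meaning | Units | Default / levels |
|---|---|---|---|
| `D_h` | fidelity: distance at which density halves | m | 10–40 in 7 levels |
| `Q` | AR quality (AR:NR density ratio at zero distance) | – | 1–10 |
| `D_50` | mobility: distance at which half a cell's biomass relocates | m | 300 (residents), 200 (pelagics); 100–300 in the sensitivity analysis |
| `D_99` | span of ~99% of the attraction decline | m | fixed at `2·D_50` |
| `D_r` | reef separation | m | 12 diagonal steps: 42.43–509.12 |
| `S_r` | NR side length | cells | 1, 2, 3 (AR fixed at 1×1) |
| `p` | cells fished simultaneously | cells | 2–100 in 9 levels |
| `Q_nr` | NR quality for the pelagic first stage | – | 1 |

Reef placement: the NR block is anchored at the grid centre and the AR
sits on the main diagonal, `3·step` cells away in each axis from the
nearest NR cell, so each step adds `3·10·√2 ≈ 42.43` m. This reproduces
the standard separation ladder (42, 85, …, 509 m) exactly and makes
separation independent of NR size. `D_r` is recorded as the realized
centre-to-nearest-centre distance; for multi-cell reefs an edge-to-edge
convention would differ, which output metadata makes explicit by storing
the realized value rather than a nominal label.

## Sensitivity analysis

`Q, D_h, D_50, S_r, p` are sampled independently and uniformly from their
discrete levels, 2000 iterations per reef-separation stratum, and the
CPUE ratio recorded. Separation is *fixed* within each stratum (steps 1,
6, 12 → 42.43, 254.56, 509.12 m) rather than sampled and binned: the
response is strongly nonlinear in separation, and stratifying keeps each
fit a main-effects local model. A separate OLS fit per stratum regresses
the z-scored ratio on z-scored predictors.

One scaling choice matters: predictors are standardized within each
stratum, but the response is z-scored on the **pooled** (all-strata) mean
and standard deviation. Comparing coefficient magnitudes *across* strata
— the headline claim that resident parameter influence collapses with
distance — is only meaningful on a common response scale; per-stratum
response scaling renormalizes every stratum to unit variance and inflates
coefficients precisely where the ratio barely responds at all. The
per-stratum option (`response_scaling="per-stratum"`) and a coded
[−1, 1] predictor option are available for within-stratum rankings.

The far-stratum resident fidelity coefficient deserves a note: exact
enumeration of the full 9450-scenario factorial at the far stratum puts
it at −2×10⁻⁶ — negative, but three orders of magnitude below the
Monte-Carlo standard error at 2000 iterations, so its estimated sign in
any finite sample is noise. Tests therefore assert negativity only where
the coefficient is statistically resolvable.

## What the simulator does and does not emulate

The model is a demonstration model: it generates its own study
conditions (parameter grids, reef layouts) rather than ingesting field
data, and is meant to reveal generalities, not predict a specific
system. Passing tests show that the redistribution arithmetic, harvest
accounting and parameter rankings are correct *under the model's
assumptions* — exponential halos, a single deterministic habitat-choice
rule, effort that tracks biomass perfectly, no production, no
density-dependent quality, no effort entering from outside the system.
None of those assumptions should be read as validated against real reefs.

## Numerical choices and problem sizes

- Conservation checks use 1e-9 relative tolerance; in practice the
  additive rule conserves to ~1e-16.
- Distance fields are exact (vectorized minimum over ≤9 reef cells) and
  cached per layout; a 211×211 scenario evaluates in a few milliseconds.
- The logistic is evaluated with overflow suppressed: distant cells
  underflow to an attracted fraction of exactly 0.
- Degenerate inputs fail loudly: zero redistribution weights, zero
  pre-deployment CPUE, even grid sides, out-of-range parameters.
- Default test problem sizes: full 211×211 arena everywhere; 200 random
  scenarios for the conservation suite; full 120- and 63-cell panels for
  pattern checks; 2000 Monte-Carlo iterations per stratum per group for
  the sensitivity acceptance test (≈40 s); property tests use grids up
  to 50×50 against brute-force oracles.

## Known limitations

- Single AR, rectangular reefs, flat bathymetry, no multiple-NR layouts
  (the two-NR illustration in the literature is out of scope).
- The `max` overlap rule is provided for completeness but breaks
  conservation; analyses shipped here all use `additive`.
- Reef separations are constrained to the diagonal ladder; arbitrary
  separations would require sub-cell placement.
- `D_50` ranges (100–300 m) are small relative to documented fish
  mobility; results are generalities about attraction, not siting advice
  for a particular reef.
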