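# Methods

This note documents the models implemented in `larvaconnect`, their
assumptions, the defaults and why, and what the synthetic study system
does and does not emulate.

## The biological model

Blue mussels spawn into the water column over a roughly three-month
season. The release scheduler encodes that season as inclusive date
windows with fixed fractions — forward (spawning) releases May 15 –
Jul 14 (75%) and Jul 15 – Aug 14 (25%); backward (settlement-period)
releases use the same windows shifted +30 days — with 3000 larvae per
site and at least one release in every hour slot. Window and hour
counts use deterministic largest-remainder apportionment rather than
multinomial sampling, so the 75/25 split and the 40/40/20 drift-depth
and 70/10/10/10 bed-depth quotas are realized *exactly* (2250/750,
1200/1200/600, 2100/300/300/300 of 3000); only the within-band uniform
depth draw and the depth-to-event shuffle consume the seed. The egg
stage (1–2 d) is not modelled separately: a particle exists from spawn
time and its 27–33 d competency window is measured from release, which
the drift duration subsumes.

Days to settlement relate to temperature through the fitted logarithmic
curve *y* = −28.06 ln(*x*) + 101.32 (*R*² = 0.7545, metadata only),
valid for *x* > 0 °C; `site_mean_development_time` averages the model
over hourly site temperatures. The fixed 27–33 d window is the default
competency rule; a site-specific window (model mean ± 3 d) can be
configured through `SettlementGridSpec.competency_window_days` because
how the two rules interact is genuinely open — the fixed window is the
declared default.

## Transport

The tracker is a minimal passive Lagrangian integrator: bilinear
horizontal interpolation among water cells (land cells are removed from
the stencil and the remaining weights renormalized), nearest depth
level, linear interpolation in time, and RK4 (default) or Euler
stepping at 30-minute internal steps with hourly output. Horizontal
diffusion adds independent Gaussian displacements with standard
deviation sqrt(2·K_h·Δt) per axis; K_h defaults to 1 m²/s, an ordinary
coastal value. Geodesy is equirectangular (metres per degree of
longitude scaled by cos φ): over a ~2° domain the error is negligible
relative to the other idealizations. Each particle keeps one fixed
drift depth for its whole drift — larvae are treated as non-swimming
and non-migrating. Backward tracing integrates the negated velocity
field along reversed field time, the exact adjoint of the deterministic
step, which is what makes the forward/backward closure test meaningful.

Coastline handling defaults to specular reflection off the crossed cell
face (falling back to the pre-step position if the mirrored point is
also land); a `halt` mode freezes particles at the coast for
sensitivity tests. Particles crossing the open boundary are flagged
`lost_domain`, frozen, and score zero settlement everywhere — an
all-or-nothing rule that follows the scoring contract (a lost larva has
no settlement probability), at the cost of discarding dwell the larva
accumulated before it was lost.

## Settlement scoring and connectivity

Settlement probability is time-fraction scoring: per larva,
`w(cell) = dwell(cell, depth < 10 m, days 27–33) / (144 h)`. Stored
hourly samples represent the half-open interval `[t, t+1 h)`. Row sums
are ≤ 1 by construction; mass is conserved under summation (checked by
brute-force recount in the tests). Site catchments are the shallow
cells whose centres lie within 0.03° of the site (about two cells at
the 0.015° settlement resolution); the radius is configurable and
recorded in output metadata, since the mapping from settled cells to
named sites is a modelling choice, not a measurement. Transfers are
normalized by larvae *released* (the alternative, normalizing by larvae
successfully settling, is available via the returned released counts).
Donor/recipient degree counts apply a two-decimal display threshold so
they can be reproduced from a printed matrix.

Backward runs are scored with the mirrored window: positions during
backward-time days 27–33 over source-site catchments. This requires
33 d of back-tracing; `advect`'s bare backward default remains 27 d
(the minimum to reach spawn time from a settlement event), and the
pipeline extends it when scoring.

Kriging uses an exponential semivariogram γ(h) = nugget + sill·(1 −
exp(−h/range)) fitted to the binned empirical semivariogram by weighted
least squares (weights √pair-count), then solves the ordinary-kriging
system per grid node at 0.01°. With nugget 0 the interpolator is exact
at the sites (diagonal γ(0) = 0). A singular system (e.g. duplicated
site coordinates) triggers an inverse-distance-weighting fallback with
a logged warning; constant observations short-circuit to a constant
surface.

## Inner/outer comparisons

`summarize_sites` derives the five per-site responses (sites donated
to, sites received from, larvae donated, larvae received, retained vs
failed). Contrasts are fitted as GLMs with log (counts) or logit
(retained/failed two-vector) links; the dispersion is estimated as
Pearson χ²/df and inflates the standard errors — the quasi-Poisson /
quasi-binomial device for overdispersed ecological counts. Point
estimates equal the plain Poisson/binomial fits; p-values are two-sided
on t with residual df (n_sites − 2), the standard quasi-GLM choice. A
numerically perfect fit (dispersion ~0) is reported as a null contrast
rather than a 0/0 artefact.

## The synthetic study system

`make_coastal_bathymetry` builds a 2°×2° domain at 0.015° with a
mainland along the east, a shallow (<10 m) fringe of mussel habitat, a
shelf sloping to 80 m, optional islands, and fjord basins (8 m deep)
carved into the mainland behind ~3-cell straits. `make_flow_field`
evaluates a streamfunction on cell centres — a counterclockwise basin
gyre plus a northward along-coast jet decaying offshore (e-folding
0.1°) — and differentiates it with centred differences, so the matching
discrete divergence vanishes identically; the streamfunction is
constant east of the coastline, leaving fjord basins quiescent.
Velocity decays with depth as exp(−z/e-folding). Because storing hourly
frames of a 0.015° field over a four-month season would be multi-GB,
fields are stored as daily frames (or two frames when steady) with
linear interpolation in time; the time axis stays uniform.

The connectivity study scenario (`scenarios.archipelago_domain`) uses a
straight coastline, one fjord whose mouth falls between site latitudes,
27 open-coast sites evenly spaced along the fringe plus the fjord site,
jet speed 0.15 m/s, gyre 0.05 m/s, and depth levels every 1.5 m with an
8 m velocity e-folding. The level spacing is chosen so that
nearest-level sampling of the sheared jet produces a near-continuous
spectrum of drift speeds across the drift-depth quota: the ratio of
speeds at adjacent levels (e^{0.1875} ≈ 1.21) is below the 33/27 ratio
of the competency window, so window-time travel distances tile the
along-coast separations without gaps — deep slow drifters supply
neighbouring sites, shallow fast ones distant sites. The scenario runs
28 sites × 500 larvae at 60-minute steps in under a minute on one core;
these sizes are the package's default desk-scale configuration.

What the generator does *not* emulate: tides, wind and wave forcing,
river plumes, stratification, vertical mixing or larval behaviour, and
any interannual variability — so passing tests demonstrate that the
*operators* recover directional transport and fjord isolation when the
physics contains them, not that a real hindcast would.

## Synthetic genotypes

`simulate_genotypes` draws ancestral allele frequencies Uniform(0.05,
0.95), population frequencies from the Beta F-model (default K = 4,
F = 0.3 — strongly diverged lineages, as for *M. edulis* /
*M. trossulus* / *M. galloprovincialis*), and genotypes as two Bernoulli
gametes at the ancestry-weighted frequency. Admixed individuals carry
recorded true ancestry rows; technical replicates copy genotypes
exactly; close relatives share one gamete. Coverage (the fraction of
loci at read depth ≥ 5) is Beta-distributed with mean 0.814 and SD
0.0851 — the coverage profile reported for real 2b-RAD mussel libraries
— and an individual's missing-call rate is 1 − coverage, applied
independently per sequencing copy.

The expected-mode IBS distance is the deterministic expectation of
single-allele sampling, `p_i(1−p_j) + p_j(1−p_i)` with p = dosage/2
averaged over co-called loci (two heterozygotes contribute 0.5); a
seeded sampled mode reproduces the single-read behaviour of
likelihood-based pipelines. Consequences worth knowing: an exact
duplicate's distance is half its heterozygosity, ≈ 0.13 for drifted
populations under this spectrum but ≈ 0.155 for a 50/50 admixed genome
— *above* the 0.15 pruning threshold. The simulator therefore plants
replicate and relative pairs on source-population individuals, where
the planted structure (replicates ≈ 0.13, half-sib-like relatives
≈ 0.19, unrelated ≳ 0.23) brackets the threshold the way the filtering
rule assumes; with real skewed site-frequency spectra all these
distances are lower. Close relatives are deliberately *not* pruned at
0.15 under these defaults — they sit just above it — which the tests
assert as a property of the threshold, not a failure.

Pruning is single-linkage clustering cut strictly below the threshold
(connected components of the "distance < 0.15" graph), keeping the
highest-coverage member per cluster with lexicographic ID tie-breaks.
Admixture-cluster assignment takes coefficients from file or from the
simulator truth; estimating admixture itself is out of scope.

## Numerical choices and degenerate inputs

- Cells are half-open `[edge_i, edge_{i+1})`; a point exactly on an
  upper edge belongs to the next cell.
- Depth is positive-down; land lives in the mask, never as NaN or a
  depth sentinel.
- Quota ties in largest-remainder apportionment break by band order;
  scheduler remainders go to the first window.
- A pair of individuals with no co-called locus is an error naming the
  pair; an SD of exactly zero in the coverage filter discards nobody;
  an all-zero GLM response and single-category contrasts are errors.
- Trajectories shorter than the window start score zero ("immature");
  zero-length scoring windows are empty, not errors.

## Known limitations

Fixed drift depth ignores that a 25 m drifter cannot occupy a 8 m water
column; the scoring grid inherits the bathymetry's nearest-cell depth
when resolutions differ; the all-or-nothing treatment of lost particles
truncates transfers near the open boundary; and the equirectangular
metric and divergence-free construction are only as good as the ~2°
domain assumption. The GLM example shows a boundary case (a category
exporting to zero sites) where log-link estimates diverge — the
quasi-likelihood standard errors flag rather than mask it.
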