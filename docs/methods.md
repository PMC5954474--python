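# Methods

## The budget model

The package treats the giant-iceberg blue-carbon budget as explicit
Fermi arithmetic on a small registry of constants.  Generation for a
newly calved iceberg of area A is

    base = G0 * A / 5000 km2,    G0 = 7e4 t C yr-1,

the production of the newly opened shelf water left behind by the
calving, multiplied by a post-collapse benthic growth factor g
(point 2.5, range 2–3, from observed two- to threefold increases in
sponge density after ice-shelf collapses) and an ocean-fertilization
factor f (point 5, range 5–10).  The annual cost of grounded giants is
q * A_g * rho with q = 0.25 (maximum fraction of a grounded footprint
that scours), A_g = 10 000 km2 of grounded giants, and rho = 16 t C
km-2 (the top of the 8–16 t C km-2 standing-stock range — deliberately
the climax value, making the cost an upper bound).

**Reporting convention.**  The published chain prints
7e4 × 2.5 = 2e5 and 2e5 × 5 = 1e6, which is *sequential* rounding to
one significant figure: each reported value feeds the next
multiplication.  A single rounding of the exact product 8.75e5 would
print 9e5 instead, so the convention matters and is made explicit in
`report_round`.  The net figure truncates to two significant figures
(1.96e6 → 1.9e6), consistent with its "at least" reading.  Every
operation returns both branches — raw (exact) and reported — and a step
ledger that replays to the reported value; uncertainty propagation
always consumes the raw branch, so quantization never leaks into the
envelopes.  A scenario with more cost than generation would have a
negative net; the reporting rounding is defined on magnitudes, so the
sign is factored out and restored.

The per-iceberg point values are the low ends of their ranges where the
chain uses the low end (f = 5), the chain's own value where it states
one (g = 2.5), and the range midpoint where only a range is given
(T_rec = 5 from 4–6 yr).  Parameters with no published range carry a
degenerate range and stay fixed under sampling.

## The scaling ladder

The circumpolar total is a second chain: mean organic zoobenthic
production 3 g C m-2 yr-1 (the published mean over the 13 / 5 / 1.5
g C m-2 yr-1 depth bands; the averaging weights are not published, so
the mean is consumed directly and the bands are carried in the registry
for reporting only), times (1 + 0.12) because benthos produce roughly
as much carbonate as organic matter of which 12% is carbon, times 2 for
the under-sampled shallows, times the 4.4e6 km2 shelf area, then × 2
(sea-ice losses), + 10 Mt × 2 (ice-shelf-loss areas, growth-corrected),
× 2 (sub-Antarctic shelves).  Units: 1 g C m-2 yr-1 = 1 t C km-2 yr-1
exactly, so the "scale-up" is an identity applied silently.  The
reported branch rounds each rung to two significant figures before the
next rung (3.4 → 6.8 → 30 → 60 → 80 → 160); a raw branch (ending at
158.3 Mt) is kept alongside, and the two never differ by more than one
unit in the second significant figure at any rung.  The ladder stores
each rung's inputs and can replay itself, which the tests use to detect
any drift between stored and recomputed values.

## Monte-Carlo propagation

Ranges are propagated by independent sampling — uniform by default
(only ranges are published, no shapes), triangular (peaked at the point
value) as an option — through the raw arithmetic.  No correlation
between parameters is imposed because none is published; the registry
deliberately stores the sea-ice (×2) and fertilization (×5–10)
multipliers independently.  Summaries are median, central 95% interval,
and sampled min/max.  Because every model output is monotone in each
parameter separately, the exact extrema over the parameter box lie at
corners; `propagate` enumerates the corners of the non-degenerate
parameters (at most a few, so 2^k is tiny) and reports these exact
bounds next to the sampled envelope.  With the default registry the
cost envelope spans exactly [2e4, 4e4] t C yr-1, driven solely by
rho ∈ [8, 16].

## The scour–recovery simulator

The static cost q·A_g·rho assumes climax benthos is destroyed over the
full scoured area every year.  The simulator quantifies the
overstatement.  The seabed is a grid of equal-area cells (default 400 ×
25 km2 = 10 000 km2, matching A_g) with depths spanning 50–500 m, each
holding a standing stock that regrows *linearly* from 0 to its climax
(16 t C km-2) over T_rec = 5 years after a scour.  The linear ramp was
chosen over a logistic because only the recovery duration is known, and
the ramp gives closed forms the tests can pin down exactly: a cell
re-scoured every year yields climax/T_rec = 3.2 t C km-2 per event.

Each year, a fixed number of giants ground (default 8; a Poisson option
exists, but a fixed count matches the accounting style of the budget
and lets paired hotspot/uniform comparisons hold grounding counts
identical).  Each grounding scours a whole-cell footprint of
round(iceberg area × q / cell area) cells, at least one (default
1250 km2 × 0.25 / 25 km2 → 13 cells).  Scoured cells are drawn i.i.d.
with probability proportional to exp(−depth / 150 m) — scour frequency
falls rapidly with depth because few keels reach deep; the exponential
form and its 150 m scale are this package's modelling choice, isolated
in `ArrivalModel` — either across the whole grid ("uniform") or
restricted to a fixed subset ("hotspot", standing in for rises and
sills that are hit repeatedly).  An optional fast-ice modulation scales
the arrival rate linearly with open-water days, reflecting that fast
ice obstructs wind-driven iceberg travel.

Carbon is conserved exactly: cumulative recycled + standing stock −
initial stock = cumulative regrowth every year, and the event ledger
sums to the annual series exactly.  At the default settings the
simulator recycles roughly half the static cost under uniform placement
and under a tenth of it under hotspot placement — the two mechanisms
(recovering seabed re-scoured early; hotspots re-hit) the static
formula deliberately ignores.  Whether the q = 0.25 scoured fraction
applies per grounding event or per iceberg lifetime is not published;
it is applied per event, with the parameter exposed.

## Zone analysis

Benthic samples are stratified by depth into zones A [0, 10) m,
B [10, 40) m, a zone of ignorance [40, 200) m (too deep for divers, too
shallow/close inshore for safe ship work — never analysed), C
[200, 500) m and D [500, 1000] m; bounds are half-open with inclusive
lower edges, the deepest cap inclusive, and all are overridable since
they are read off a narrative description rather than published as
numbers.  Within each analysable zone, Pearson's product-moment
correlation (two-sided p from the exact t transform, via
`scipy.stats.pearsonr`) relates blue-carbon stock to annual sea-ice
duration; correlation is computed on raw values (no transform is
published) and is scale-invariant, so the unit of the stock column does
not matter.  Sign classes are positive/negative when p < α (default
0.05), else none; constant inputs are flagged insufficient rather than
raising.  No multiple-testing correction is applied across the four
zones — the analysis this mirrors applied none — and the output
metadata says so.  The fast-ice fit correlates annual fast-ice duration
with the scoured proportion of monitored shallow seabed and adds a
least-squares slope.

## Synthetic data

The monitoring and survey data behind the field relationships are not
deposited, so generators emulate their structure; all are deterministic
under a seed and their census constraints are hard.

* **Monitoring series** (default 14 years, the length of a 2003-onward
  annual record): scoured proportion = clip(0.9 − (0.85/300)·ice-days +
  N(0, 0.08), 0, 1), with ice-days uniform on [50, 300] — the noiseless
  line passes 0.05 at 300 ice-days.  The noise level follows from a
  Fisher-z power calculation: the linear signal has sd ≈ 0.23, so
  σ = 0.08 puts the population correlation near −0.94 and P(r ≤ −0.7)
  at n = 14 above 99%, comfortably meeting the ≥ 95-of-100-seeds
  calibration the tests enforce.  The observed field correlation
  (≈ −0.86) is a qualitative reference only; raw data are unpublished.
* **Benthic samples** (default 50 per zone): stock = 25·exp(−depth/300)
  + 5 + slope_zone·ice-days + N(0, 0.5), clipped at zero, ice-days
  uniform on [50, 300], slopes (+0.02, 0, −0.02, 0) t C km-2 per
  ice-day for zones A, B, C, D.  The slope magnitudes are synthetic
  calibration choices (the real effect sizes are unknowable); ±0.02
  gives essentially full power at n = 50 while the depth-varying
  baseline keeps zone C's correlation realistic rather than perfect.
  The baseline floor keeps stocks positive under the negative zone-C
  slope.
* **Iceberg registry**: exactly the census counts (47 total, 6 over
  1000 km2, 4 grounded), with at least half of all areas in the
  dominant 100–500 km2 band, areas log-uniform within bands (iceberg
  sizes are heavy-tailed), statuses and regions drawn at random.

**What passing these tests shows — and does not.**  The generators
produce Gaussian noise around linear rules; real monitoring data are
autocorrelated in time, zero-inflated in scour proportions, and the
real stock–depth relationship is not a smooth exponential.  Parameter
recovery on these generators demonstrates that the analysis chain is
correct and adequately powered at the stated n, not that the field
relationships themselves are reproduced — they cannot be, without the
original data.  Note also that with two truly null zones and no
multiplicity correction, the joint probability of recovering all four
zone signs in one dataset is about 0.95² ≈ 0.90, so occasional misses
over random seeds are expected behaviour, not a defect.

## Numerical choices and degenerate inputs

Significant-figure rounding is computed through floor/half-up on the
scaled mantissa with a 1e-9 guard against float noise in the truncating
mode; zero is a fixed point of every mode and negatives are rejected.
Zero-variance inputs to correlations return NaN flags.  Empty grids,
zero draws, inconsistent censuses, out-of-range config overrides
(strict mode) and malformed CSV rows raise with messages naming the
offending key or line.  A cell scoured twice in one year recycles
nothing the second time.  All randomness flows through
`numpy.random.default_rng` seeds; the acceptance script splits its one
user seed into per-stage streams with `SeedSequence`.

## Problem sizes

The shipped tests and the acceptance script run the simulator at 400
cells for 40–80 years (200 paired replicates for the hotspot
comparison), Monte-Carlo at 2e4 draws, and the calibration analyses at
100 (monitoring) and 20 (zone-recovery) seeds — sizes at which the
stochastic checks are stable to well within the tolerances asserted,
while the whole suite stays fast enough to run on every change.

## Known limitations

No geographic realism (no coastline, bathymetry map, currents or
iceberg tracks); no sediment-berm burial or resuspension side effects
of scour; no regional disaggregation of the circumpolar total (the
Amundsen-Sea halving is exposed only as a user-settable multiplier); no
modelling of how the 13/5/1.5 depth-band rates average to 3 (weights
unpublished); the interaction between the sea-ice and fertilization
multipliers is unknown and they are treated as independent.
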