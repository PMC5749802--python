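# Methods

This note documents the model implemented in `planktivore`, the choices made
where the method was genuinely open, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Energy budget and units

The daily balance is C = R + F + E + S + G per fish. The internal currency
is the Joule throughout: respiration is converted from specific oxygen
consumption (g O₂ g⁻¹ d⁻¹) with the oxycalorific coefficient 13 560 J g⁻¹
O₂, and growth is the day-over-day change in total body energy. Formulations
that divide the respiration intercept by the predator energy density and
later multiply consumption back by energy-density ratios are algebraically
equivalent to this energy formulation; computing in energy avoids the double
conversion. Specific rates in g prey g fish⁻¹ d⁻¹ are produced at output
time by dividing consumed energy by the diet-weighted mean prey energy
density and by body mass.

With egestion F = θC, excretion E = ε(C − F) and SDA S = ω(C − F), the
budget solves in closed form: C = (R + G)/D with
D = 1 − θ − (ε + ω)(1 − θ). Well-posedness (D > 0) is validated on
construction of every parameter set; the packaged values give D = 0.61152
(mackerel), 0.609 (herring), 0.6142 (blue whiting). The closed form is
cross-checked in the tests against an independent fixed-point iteration of
the balance.

**Energy-drawdown days.** Late in the season the body-energy trajectory can
decline faster than respiration (herring after its mid-July energy-density
peak). Since a fish cannot consume negative mass, G is floored at −R so that
C ≥ 0; the number of floored days is logged and counted in the run manifest.
This is the minimal intervention; it makes late-season consumption near zero
rather than negative.

## Respiration

Mackerel and herring use the exponential form
R = RA·W^β·e^(ρ·aT)·e^(Topt·SW)·W·13560, where the per-species constant
labelled "Topt" acts as a slope on swimming speed SW (body lengths s⁻¹,
default 1). Blue whiting uses a temperature dome
R = RA·W^β·V^x·e^(x(1−V))·act·W·13560 with V = (Tmax − aT)/(Tmax − Topt),
Tmax = 24 °C, Topt = 21 °C, and shape exponent
x = Z²(1 + √(1 + 40/Y))²/400, Z = ln ρ(Tmax − Topt), Y = ln ρ(Tmax − Topt + 2).
Ambient temperatures at or above Tmax are an error (V ≤ 0).

**Swimming speed for the dome form.** The dome form has no explicit
swimming-speed term; activity costs enter through the Winberg multiplier
act = 1.25. We scale the activity multiplier linearly with relative swimming
speed (act·SW), so that faster cruising raises metabolic cost for all three
species and the swimming-speed sensitivity is defined (and small) for blue
whiting, consistent with its reported weak positive effect.

## Ambient temperature

aT = Σ T·SA / Σ SA over matched (1° cell, 10 m depth-bin) pairs; multiple
CTD profiles in a cell are first averaged per depth. Pairs present in only
one field are dropped with a logged count (the alternative — imputation —
would invent data). Mackerel, unreliable acoustically because it shoals
near the surface, uses surface-trawl CPUE per cell as the weight, paired
with the temperature of the bin nearest a fixed 10 m depth (ties resolve to
the shallower bin, i.e. the 5 m midpoint of the 0–10 m layer). Daily values
are plateau–linear–plateau between the May estimate (before 1 June, day
152) and the July estimate (after 1 July, day 182). The non-leap calendar
is used for all years; the ≤1-day distortion in 2008 is negligible.

## Population structure

Assessment numbers-at-age are spread over 0.1 cm length bins with a
Gaussian kernel centred at the age's mean length — obtained by inverting
W = aL^b on the assessment weight-at-age — with the SD of winter commercial
length samples within (year, age). Kernel mass falling outside the species
length range (25–45, 28–38, 15–40 cm) is renormalized within range per age,
so truncation loses no fish and the biomass rescaling below is the only
abundance adjustment. The distribution is then scaled by one common factor
so that Σ W(L, t=91)·ABD(L) over 1 cm groups equals the assessment biomass
exactly (total-stock biomass for mackerel and blue whiting, spawning-stock
biomass for herring). The reference day 91 (1 April) applies to all species,
including mackerel whose feeding starts at day 136 — as in the source
method; a config switch (`biomass_ref: feeding_start`) uses the species
feeding start instead.

## Growth

Weight-at-day is an OLS quadratic per 1 cm group, pooled across years
(raw samples, not group means — the source is silent; raw least squares is
the natural choice). The annual length increment is dL = k(Lmax − Ls) with
per-year k from winter length-at-age increments
k_age = (L[x+1, a+1] − L[x, a])/(Lmax − L[x, a]), averaged unweighted over
age groups; ages at or above Lmax are skipped with a warning, and dL is
floored at zero for length groups above Lmax (no shrinkage). Years without
an estimate use the cross-year mean.

A fractional dL is split between the bracketing integer increments with the
unique convex weights whose expectation is dL (e.g. dL = 1.3 → 70% at
+1 cm, 30% at +2 cm); each branch gets a quadratic daily weight trajectory
through three anchors: the origin group's curve at the window start, the
destination group's curve at the window end, and the window midpoint at the
average of the two curves (day 175 for herring's 91–258 window; the
midpoint generalizes per species, half-days rounding up). The whole annual
increment is realized within the feeding window, consistent with near-zero
winter growth. A 15-day-bin mean-weight diagnostic for the modal length
groups (34/32/26 cm) is provided for eyeballing the feeding window, but the
windows themselves are fixed constants: mackerel 136–243, herring 91–258,
blue whiting 91–273.

## Energy density and the liver submodel

Mackerel and herring energy densities are seasonal polynomials in day of
year, parameterised in kJ g⁻¹ (magnitudes ~8–32 match whole-fish energy
densities on that scale) and converted to J g⁻¹ on output. Herring is
piecewise with a breakpoint at day 195/196; valid windows are 121–243
(mackerel) and 74–259 (herring), slightly wider than or offset from the
feeding windows; evaluation outside a window clamps to the nearest endpoint
with a logged warning. The mackerel cubic reaches ~32 kJ g⁻¹ at the end of
its window — implausibly high for wet tissue, but it is implemented as
printed in its source; this materially raises mackerel consumption
estimates (see Limitations).

Blue whiting, a gadoid, stores energy in the liver: ED is a constant muscle
density of 4500 J g⁻¹ plus the total liver energy spread per gram of body
mass (adding a total energy to a per-gram density directly would be
dimensionally inconsistent). The liver index grows linearly,
L_ind = 4 + t/30.33 percent of body mass with t in days since 1 April —
the only time convention that reproduces the documented 4% → 9% rise from
April to September. Liver energy density combines a dry-matter fraction
1.085 − 0.824/L_ind − 0.276·ln(L_ind) and an oil fraction
0.276·ln(L_ind) − 0.2 (oil at 39.55 kJ g⁻¹). The logarithms are natural:
base-10 gives a negative oil fraction at L_ind = 4, which is impossible,
and the implementation raises a validity error if a coefficient
misconfiguration ever produces fractions outside their physical ranges.

## Diet

Seven prey groups with energy densities 3600 J g⁻¹ (copepods, other
crustaceans, appendicularians, other), 4000 (euphausiids, amphipods) and a
conservative 8500 for fish prey. Sub-percent table entries ("<1") are read
as 0.5% and rows renormalized — the only way to use such rows as fractions.
Proportions are interpreted as wet-weight (stomach-content mass) shares.
Missing survey cells are filled with the per-group cross-year mean for the
same species and season; mackerel, never sampled in May, uses its July
composition all season. Daily compositions interpolate linearly between May
and July with the same day-152/182 breakpoints as temperature, each group
independently, renormalized. Allocation of consumed energy to prey grams
inverts the diet-weighted mean energy density, so the energy-weighted sum
of allocated grams reconstructs consumed energy exactly.

## Aggregation and reporting

Stock daily consumption is Σ over cohorts of abundance × (branch mix by the
split fractions); months are calendar months on the non-leap day-of-year
grid; all views (day→month→year, group→total) are exact partitions. The
mean daily specific rate weights by abundance × weight (gram-days), the
interpretation under which a per-gram rate aggregates consistently across
fish sizes; an unweighted per-fish alternative is available by flag.
Mortality is zero within the season (constant cohort abundance). C/B is
annual consumed tonnes over the assessment biomass used in the rescaling;
extrapolation multiplies mean C/B by a biomass series. The sensitivity
sweep multiplies one of {ambient temperature, swimming speed, annual length
increment dL, SDA coefficient ω} by a factor and reports the percent change
in total energy consumption per species; factor 0 on growth reproduces the
no-length-growth comparison. Reported rates are accompanied by the
stock-level series rather than significance tests.

## Synthetic scenario

The generator emulates the study conditions with known ground truth:

- **Temperature fields**: per-species May/July levels (mackerel 8.5/10.3,
  herring 8.3/10.0, blue whiting 4.5/7.5 °C) on a 9-cell grid with five
  10 m bins, cell anomalies (SD 0.3 °C), a 0.15 °C-per-bin vertical
  gradient, and lognormal fish densities that concentrate in warm-anomaly
  cells (association 0.5), so the weighted aT sits ~0.3–0.5 °C above the
  level — inside the 8–11 °C (surface feeders) and 4–8 °C (blue whiting)
  bands the scenario targets.
- **Weight curves**: true weight per 1 cm group is the allometric winter
  weight at the group midpoint times a quadratic seasonal condition factor
  1 + g(u + u²)/2, u the position in the feeding window; end-of-season
  condition gains are +10% (mackerel — modest, because the steep mackerel
  energy-density cubic already carries most of the energetic densification),
  +25% (herring) and +10% (blue whiting, which stores energy in the liver).
  Seasonal samples add 4% multiplicative noise, 200 per group.
- **Winter cohorts**: mean length-at-age follows a saturating curve whose
  asymptote sits 1 cm below Lmax (every age keeps a well-conditioned
  increment denominator), advanced between winters with the packaged
  per-year k values; 200 samples per age with 0.5 cm SD.
- **Assessment**: numbers-at-age decline exponentially with age
  (rate 0.35); weight-at-age matches the winter length means through the
  length–weight regression; biomass is computed from the implied day-91
  population, so the rescaling factor is ~1 unless deliberately perturbed.
- Diet tables and k values ship as packaged fixtures transcribed from the
  source surveys; the generator never fabricates alternatives to them.

The default scenario is one year (runs in ~2 s); `six_year_default` covers all
six years (~10 s). What passing tests on synthetic data show: the pipeline
propagates known growth, temperature and diet signals into consumption
correctly, conserves mass/energy/abundance where it should, and recovers
generating parameters at realistic noise. What they do not show: agreement
with real survey data, whose spatial structure, measurement error and
sampling gaps the generator does not emulate.

## Numerical choices

Quadratic fits via `numpy.polyfit` (≥3 points on ≥3 distinct days required);
Gaussian length spreading via exact normal CDF differences on bin edges;
bit-exact `repr`-based round-trip of parameter configs; independent seeded
substreams per generator product (CRC-based stream labels, stable across
processes); day grids are integer day-of-year, non-leap. Trajectory weights
must be positive over the window (error otherwise); non-monotone
trajectories are tolerated with a log message since late-season weight loss
is real.

## Known limitations

- The mackerel energy-density cubic, as printed in its source, implies a
  ~3× rise in whole-body energy density over the feeding window. Carried
  through the budget it makes the mackerel mean daily specific rate land
  around 0.12 g g⁻¹ d⁻¹ on the default scenario — above the ~0.08
  reported from the original survey-driven inputs. We keep the curve as
  printed rather than re-deriving it; users fitting their own energy
  densities can substitute coefficients.
- Absolute stock-level totals depend on the assessment series and survey
  fields; the synthetic scenario reproduces patterns and ratios, not the
  historical tonnages.
- Diet gaps are filled by cross-year means, which flattens genuine
  inter-annual diet variation in the filled cells.
- No within-season mortality, movement or prey-availability feedback; the
  model integrates energetics over a fixed population.
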