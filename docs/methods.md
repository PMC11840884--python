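# Methods

## Model

The package models the transfer phase of active dispersal as straight-line
travel at a constant, mass-dependent sustained speed, fuelled entirely by
the fat store. Four allometries, parameterized separately for flying birds,
running mammals and swimming fishes, carry the whole model:

* **Energy storage** E₀ = a·M^b [J] — the convertible fat reserve
  (birds a = 2.5×10⁶, b = 0.98; mammals 2.00×10⁶, 1.00; fish 4.78×10⁶,
  1.02).
* **Basal metabolic rate** BMR = a·M^b [J/s] (birds 3.63, 0.65; mammals
  2.89, 0.74; fish 0.29, 0.95).
* **Sustained travel speed** v = v₀·M^c / (1 + v₀·k·M^(c+d)) [m/s], with
  mode-specific v₀ (30.54 flying, 0.28 running, 0.39 swimming) and shared
  c = 0.27, k = 0.03, d = 0.24. The numerator is the metabolic power-law
  speed capacity; the denominator is a heat-dissipation cap that bends the
  curve over at large masses (the speed maximum for runners falls around
  10⁴ kg). Equivalently v = (1/k)·M^c / (M^(c+d) + 1/(k·v₀)), a harmonic
  combination of an energy-supply-limited and a heat-loss-limited speed.
* **Locomotion cost** LCOT(v) [J/s]: flying
  32.00·M^0.66·v⁻¹ + 0.0033·M^0.66·v^2.5 + 0.0058·M^0.49·v^2.5 (induced
  power falling with speed plus profile/parasite power rising with it —
  U-shaped); running 11.30·M^0.72·v (linear); swimming
  0.12·M·exp(1.88·M^−0.36·v) — a mass-specific exponential cost of
  swimming scaled by body mass, with M^−0.36·v acting as a
  length-normalized speed (fish length scales roughly as M^1/3).

Dispersal power is FMRdis = p·BMR + LCOT(v), with a postural surcharge
p on maintenance for flying (1.10) and running (1.20); neutrally buoyant
swimmers pay none. Cost over distance D is E_c = FMRdis·D/v, exactly
linear in D; remaining storage is E_r = E₀ − E_c.

A fraction λ of E₀ (default 0.1) must remain on arrival for post-arrival
survival, so Eα = (1−λ)·E₀ is spendable and

    Dmax = v·Eα/FMRdis,        Dmax(λ) = (1−λ)·Dmax(0).

With a resting-time fraction β, depletion takes
t₃ = Eα/((1−β)·FMRdis + β·BMR) and Dmax_β = (1−β)·v·t₃; β = 0 recovers
Dmax exactly, β = 1 gives zero, and Dmax_β decreases strictly in β.

**Assumptions.** Straight-line travel at the optimal sustained speed; no
feeding en route (energy gain is out of scope — the resting extension is
the only time-budget refinement); fat is the sole fuel; temperature
effects ignored. These make Dmax an upper bound on realized dispersal:
recorded maxima should, and in compilations overwhelmingly do, fall below
it.

## Equation-parse resolution

Two table equations in the model's source are typographically corrupted
(the travel-speed formula and the swimming-cost formula). The package
treats the algebraic reading as an explicit configuration
(`ParseOptions`) and ships the reading selected by a small harness
(`dispersalenergy.reference.resolve_parse`): candidates are the
denominator exponent δ ∈ {d, c+d}, v₀ present or absent in the heat term,
and a swimming mass-prefactor exponent ∈ {0, 1, 1.02}; the selected parse
minimizes the summed squared relative discrepancy over the nine published
worked results (two costs per metre, one rounded percentage, six Dmax
endpoints). The shipped default — δ = c+d, v₀ in the heat term, swimming
prefactor M¹ — beats every alternative and reproduces seven of the nine
numbers within 1% (most within 0.3%).

The two exceptions are the smallest-mass Dmax endpoints (0.0076 kg
running mammal, printed 8.47 km, model 8.62 km, +1.7%; 0.22 kg swimming
fish, printed 1860.75 km, model 1824.5 km, −1.9%). At such small masses
the heat-dissipation denominator is ≈1, so every candidate parse
coincides there: no reading can close the gap. The residuals are
consistent with the two-significant-figure rounding of the empirical
mass-range endpoints at which those values were computed (e.g. a true
minimum fish mass of 0.2233 kg, printing as 0.22, reproduces 1860.75 km
exactly). The corresponding two golden-number tests are left failing
rather than widening the 1% gate; the `reproduce` CLI likewise exits
non-zero under its strict gate. A companion published figure (68% of
available energy for the 4.5 kg mammal over 100 km) is internally
inconsistent with the published 58.82 J/m and the mammal storage
coefficients under any λ convention (58.82·10⁵/(0.9·9×10⁶) = 72.6%) and
is excluded from machine checks; the model's value prints as 72.8%.

**Conventions fixed here** (genuinely open in the source): relative
depletion is normalized by Eα, not E₀ (the "7%" figure matches either way
after rounding); reported percentages round to nearest integer; the
postural multiplier applies to BMR only, not to LCOT (validated by the
cost-per-metre figures); exact SI units internally.

## Tunable parameters

| Parameter | Meaning | Default | Unit |
|---|---|---|---|
| λ | residual energy fraction required on arrival | 0.1 | – |
| β | fraction of time budget spent resting | 0 | – |
| a1–a14, b1–b12, c, d, k, v₀ | allometric coefficients/exponents | table values above | SI |

All coefficients are overridable (`ModelParameters.replace`, the
`--param` CLI flag, or a flat `name = value` config file) for sensitivity
analysis; λ has no strong empirical anchor, so `lambda_sweep` exposes the
(exactly linear) dependence of Dmax on it. Masses outside
[10⁻⁶, 10⁶] kg evaluate with a warning — the allometries are fits over a
much narrower range and anything beyond is extrapolation.

## Spatial networks

Patch landscapes are point sets in a Cartesian plane (metres); distances
are Euclidean. Link weight between patches i, j is
w_ij = max(0, 1 − E_c(d_ij)/Eα), which by linearity of E_c equals
max(0, 1 − d_ij/Dmax) — the implementation uses the latter form so that
d = Dmax lands exactly on w = 0. Networks are undirected (the model is
symmetric), self-links are excluded, and "within Dmax" is read strictly:
a pair exactly at Dmax has no link. Connectance is the fraction of the
n(n−1)/2 patch pairs with w > 0; weighted connectance is Σw over the same
all-pairs denominator (the "proportion of possible links" reading), so
weighted ≤ unweighted ≤ 1 always, and both metrics are invariant to
jointly rescaling coordinates and Dmax.

Two seeded generators provide fixtures: uniform-random patches, and
Gaussian clusters (sd = `spread`) around uniform centres with strays
reflected back into the extent. They emulate patch geometry only — no
habitat quality, no barriers, no correlation between patch size and
position — so network tests demonstrate the weighting and metrics, not
realism of any particular landscape.

## Empirical comparison

`fraction_above_below` scores a record table (species, mass, recorded
maximum distance, mode) against the predicted Dmax at the record's mass:
strictly greater counts as above, ties as below, so the two fractions sum
to 1 exactly, and raising λ can only raise the above-fraction. The
synthetic fixture generator draws masses log-uniformly within the
empirical ranges per mode (birds 0.0031–8.44 kg, mammals 0.0076–3940 kg,
fish 0.22–550 kg) and distances as a ratio of Dmax drawn lognormally
(median 10^−1.5, sd 0.75 decades) — recorded maxima typically sitting one
to two orders of magnitude under the physiological limit with a thin tail
above, the shape real compilations show. It stands in for such
compilations in tests; it does not emulate taxonomic clustering,
measurement error structure, or riverine constraints on fish, so passing
tests validate the statistic, not any empirical claim. Real tables load
via `read_records_csv` with the same column contract.

## Numerical choices

Golden-number comparisons use 10⁻² relative tolerance (published values
are rounded to 2 decimals and the equations were reconstructed from
them); algebraic identities and property tests use 10⁻⁹–10⁻¹² relative.
Costs beyond Dmax do not raise — `energy_cost` reports negative remaining
energy with a feasibility flag, and the network layer does the zero
clamping — so the raw budget is available where needed. λ = 1 is valid
for Dmax (zero) but rejected where it would divide by Eα = 0
(relative depletion, network construction). Stochastic tests are seeded;
the spatial generators take explicit seeds and are reproducible
bit-for-bit.

Problem sizes in the test suite (landscapes of ~30–40 patches, fixture
tables of ≤2000 records per mode, 4000-point spatial-statistics checks)
were chosen as the smallest at which the statistical oracles
(Clark–Evans nearest-neighbour spacing, Gaussian pairwise distance,
binomial bands) have comfortably narrow error bands; everything runs in
seconds.

## Known limitations

* Straight-line dispersal overestimates reach in structured landscapes
  (rivers, corridors, barriers); the network layer uses Euclidean, not
  least-cost, distances by design.
* The three pairings are fixed; swimming mammals, running birds, or any
  taxon outside the three groups are rejected rather than approximated.
* Energy gain en route (foraging, stop-over refuelling) is not modelled;
  predictions are hard ceilings under fasting.
* The λ threshold is a free parameter with little empirical support; all
  headline numbers use λ = 0.1 and the sweep utility exposes the
  sensitivity.
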