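# Methods

## Dose model

Each preset family maps its discrete tube-current list to CTDIvol by
the standard helical scaling

    CTDIvol = k · mA · T_rot / pitch            [mGy]

with a per-family coefficient `k` (mGy per mA·s at pitch 1) absorbing
everything this package deliberately does not model: kV-pair spectra,
focal-spot output differences, bowtie filtration, and scanner dose
calibration.  Published preset tables print only each family's range
endpoints at one-decimal mGy, so a family may be defined bounds-only;
`ctdi_grid` then substitutes a uniform grid of `n_grid` points
(default 20, endpoints exact) for the unpublished current list.  When
both representations are supplied they must agree to 0.05 mGy — half a
unit in the last printed decimal.  All internal arithmetic is full
precision; one-decimal mGy and whole-HU rounding happen only at the
presentation layer.

Which physical current (low-kV, high-kV, or an effective value) the
grid represents is left abstract: a single current axis suffices for
every dose-side statement the package makes.

## Profile construction

Candidates are canonically ordered by ascending minimum CTDIvol (ties:
ascending maximum, then input order; the sort is stable), the same
layout as published candidate tables, and filtered by the clinical
constraints (exact SFOV and collimation match, pitch and rotation-time
intervals, XLarge focal spot only when allowed).  The greedy selection
is then:

* **small** — the first candidate;
* **medium** — the *last* large-focal-spot candidate whose minimum is
  strictly below the small family's maximum;
* **large** — likewise relative to the medium family's maximum;
* **extra-large** — the candidate (any allowed focal spot) with the
  highest maximum; ties break toward the lower minimum, then canonical
  order.

"Strictly below" is taken literally: equality excludes a candidate.
The strict inequalities guarantee that whenever the medium and large
searches return distinct families, consecutive ranges overlap; the
extra-large step carries no such guarantee, and `validate_profile`
flags any gap (plus a total-overlap-fraction summary — the design goal
is overlap, but as little as possible).  When a search fails or
returns the family already selected for the previous role, the roles
collapse and the profile simply has fewer members; a requested primary
role that collapsed resolves to the surviving role.  The primary role
(default medium; large for bariatric-heavy and small for pediatric
populations) is metadata only — it controls serialization order, not
the selection.

The builder is the greedy published-style procedure by construction;
no exhaustive search is offered outside the test oracle.

## Dose-matching precision

For a dose ladder (the union of a profile's per-family grids) and a
target `t`, the nearest achievable value `a` minimises `|v − t|`; an
exact midpoint tie resolves to the *lower* value, a recorded package
choice (the scanner's tie behaviour is unpublished) that favours the
lower dose.  The signed mismatch is `f = (t − a)/t`; coverage
statements use `|f| ≤ τ` with τ = 0.05 by default, a two-sided band.
The report's default target grid is 200 log-spaced points from 0.5×
the union floor to 1.5× its ceiling, deliberately extending beyond the
ladder so the clamped tails are visible.  A 25% dose change
(`CLINICALLY_INSIGNIFICANT_DOSE_CHANGE`) is the annotation threshold
below which a dose error produces no noticeable noise change.

Noise propagates as dose^(−1/2), so a relative noise-index error δ
corresponds to a dose error of `1 − (1+δ)^(−2) ≈ 2δ`; the first-order
form is used (the error of the linearisation is below 3δ², verified
numerically in the tests).  At a prescribed noise index of 18 HU, the
2 HU switching threshold is an 11% noise and 22% dose mismatch —
within the 25% band.

## Scan-time simulation

A patient is a water-equivalent thickness profile `d(z)` (cm) at
strictly increasing table positions.  The dose required to reach noise
index `ni` at thickness `d` is

    required(d, ni) = ctdi_ref · (ni_ref/ni)² · 2^((d − d_ref)/d_double)

The exponential thickness law and its calibration are model choices,
not vendor fact: `d_double = 5 cm` encodes the observation that
abdominal transmission changes by about a factor of two over 5 cm of
patient, and the anchor (`ctdi_ref = 12 mGy` at `d_ref = 30 cm`,
`ni_ref = 18 HU`) places a mid-sized adult at the centre of a typical
medium-family range at a routine abdominal noise index.  All four are
per-patient parameters; the simulator's accuracy claims are
self-consistency properties that hold for any calibration, not scanner
replication.

The single per-scan target dose is the unweighted mean of the
per-slice requirements over the sampled positions (default 20 samples
per patient).  The vendor's aggregation rule and the averaging weights
of the displayed mean projected noise are both unpublished; the mean
is the assumption, with `max` and quantile aggregation available
behind a keyword.  Since the 70 keV monochromatic image of a
dose-matched dual-energy acquisition carries the same noise as the
single-energy image, a single noise channel is used throughout — no
spectral modeling.

For a delivered dose `A` the projected noise index is
`PNI(z) = ni·sqrt(required(d(z), ni)/A)`, its mean is the AvgPNI shown
to the operator (flagged "above" when it exceeds the prescribed NI),
and the switching rule is strict: switch to the small (large) family
only when the primary's AvgPNI is *more than* `threshold` HU (default
2) below (above) the prescribed NI; a deviation of exactly the
threshold keeps the primary.  When the recommended role is absent from
the profile the recommendation stands but the selection stays with the
primary.  For constant-thickness patients the whole pipeline collapses
to `AvgPNI = ni·sqrt(target/actual)` exactly, which the tests verify
to 1e-9 relative.

## Synthetic data

`generate_family_table` draws pitches and rotation times from the
scanner's actual discrete options ({0.508, 0.992, 1.375, 1.531} and
{0.5, 0.6, 0.8, 1.0} s), gives each family 10–40 evenly spaced
currents, and calibrates `k` so range floors land in the realistic
2–20 mGy regime.  `generate_patient` builds a linear taper (abdominal
thickness can change by ~5 cm over one exam) plus lightly smoothed
Gaussian noise clipped at ±3 σ; `generate_cohort` spaces mean
thicknesses evenly so recommendations can be checked for monotonicity
in habitus.  All generators are reproducible from an explicit seed.

What the generators do *not* emulate: real mA lists are neither
uniform nor equally long across families; real thickness profiles have
anatomy (shoulders, lungs) rather than a taper; and the dose
coefficients of real families are correlated with focal spot and kV
pair.  Passing tests therefore demonstrate the correctness of the
selection, matching and propagation logic under realistic magnitudes —
not agreement with any particular scanner's calibration, and not the
vendor profiles' ~1% noise-matching figure, which depends entirely on
the unpublished current lists.

## Numerical and degenerate-input choices

* Nearest-value search is `searchsorted` plus a single comparison;
  exact midpoints resolve low (see above).
* A bounds-only family with `ctdi_min == ctdi_max`, or `n_grid = 1`,
  yields a one-value grid.
* A single-member profile is legal everywhere; the builder emits it
  for degenerate tables via role collapse.
* Family tables serialize to CSV/JSON with `dose_coeff` written at
  full `repr` precision and read back with round-trip float parsing,
  so tables survive serialization bit-exactly; published one-decimal
  values are stored as the exact printed numbers.
* Targets, currents, noise indices and thicknesses must be strictly
  positive; violations raise `ValueError` before any computation.

## Limitations

Tube-heat current caps, angular/organ-based modulation, reconstruction
(kernel/ASIR) settings, scout-image segmentation and DICOM handling
are all out of scope; thickness profiles are inputs, not derived from
images.  The coverage figures for bounds-only families depend on the
synthetic `n_grid` and should be read as structural, not
point-for-point reproductions of any scanner's charts.
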