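# gsiprofile

Tools for designing and analysing automatic-exposure-control (AEC)
profiles for fast kV-switching dual-energy CT.

## The problem

In dual-energy mode on fast kV-switching scanners the tube currents are
fixed for the whole helical acquisition — no longitudinal or angular
modulation.  The AEC can therefore only pick, from a small set of
**preset families** (fixed combinations of scan field of view, focal
spot, collimation, rotation time and helical pitch, each with a
discrete tube-current list), the current whose dose output comes
closest to a single target CTDIvol derived from the prescribed noise
index and the patient's thickness.  A **profile** is an ordered set of
such families; the first is the *primary* and is used unless the
operator overrides it.

A profile with too few or badly placed families either cannot reach low
enough doses for small patients (excess dose) or high enough doses for
large ones (excess noise).  This package is for medical physicists
setting up such profiles: it

* models preset families and their achievable CTDIvol values
  (`CTDIvol = k · mA · T_rot / pitch` per family);
* builds small/medium/large/extra-large profiles by a greedy procedure
  that picks families with overlapping but minimally redundant ranges;
* quantifies how precisely a profile can match any target dose via the
  signed fractional mismatch `f(t) = (t − a)/t`, where `a` is the
  nearest achievable dose, with coverage at a tolerance (default ±5%);
* simulates the scan-time workflow: target dose from the noise index
  `NI` and thickness profile `d(z)` (noise ∝ dose^(−1/2), dose doubling
  per 5 cm of tissue), the projected noise index
  `PNI(z) = NI·sqrt(required(z)/actual)`, and the operator's rule —
  keep the primary family unless the average PNI deviates from the
  prescribed NI by more than 2 HU.

Published preset tables give only each family's CTDIvol range
endpoints, never the mA lists, so bounds-only families are first-class
and get a configurable uniform synthetic grid.  The package embeds six
published profile tables (a three-family liver profile and five
large-body 80 mm design variants) plus seeded random generators for
full candidate tables and synthetic patients.

## Worked example

Build an abdomen profile from the embedded candidate table (13
families), restricted to the Large Body SFOV, 80 mm collimation,
pitch ≤ 1.375, extra-large focal spot allowed:

```sh
gsiprofile fixtures --export table -o families.csv
gsiprofile build --families families.csv --sfov "Large Body" \
    --collimation-mm 80 --pitch-max 1.375 --allow-xlarge -o abdomen.json
```

```
profile 'profile' (primary: medium)
 * medium  Large Body/80 mm/L/0.8 s/0.992:1         7.1 –  18.9 mGy
   small   Large Body/80 mm/L/0.5 s/1.375:1         3.4 –   8.8 mGy
   large   Large Body/80 mm/L/1 s/0.508:1          17.2 –  45.5 mGy
   xlarge  Large Body/80 mm/XL/1 s/0.508:1         49.7 –  53.7 mGy
```

The greedy selection picked four families: the small family's ladder
starts at 3.4 mGy, each subsequent range overlaps the previous one
(7.1 < 8.8, 17.2 < 18.9), and the extra-large family extends the reach
to 53.7 mGy (with a flagged 45.5 → 49.7 mGy gap — no family covers
that band).  The primary (medium) family is listed first, which is how
the scanner identifies it.

How precisely can this profile match an arbitrary target dose, and
what happens at scan time for a large patient (mean water-equivalent
thickness 36 cm, prescribed noise index 18 HU)?

```sh
gsiprofile coverage --profile abdomen.json -o report.csv
# union 3.4-53.7 mGy; covered fraction at |f|<=0.05: 0.735

gsiprofile simulate --profile abdomen.json --patient patient.csv --ni 18 -o result.json
# target CTDIvol 27.7 mGy; primary AvgPNI 21.7 HU; recommendation: switch_large (use large)
```

The coverage report evaluates 200 log-spaced targets from 0.5× the
union floor to 1.5× its ceiling; 73.5% fall within ±5% of an
achievable dose (the remainder lie below, above, or in the flagged
gap).  For the 36 cm patient the required dose (27.7 mGy) exceeds the
primary family's 18.9 mGy ceiling, so the projected noise (21.7 HU)
runs more than 2 HU above the prescribed 18 HU and the simulated
operator is told to switch to the large-patient family.

The same operations are available as a library (`build_profile`,
`coverage_report`, `simulate_exam`, …); see `docs/methods.md` for the
model details.

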