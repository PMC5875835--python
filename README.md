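# vmatadapt

Adapt VMAT plans optimized for a Varian **HD120** high-definition MLC so
they can be delivered on a linac with a standard-definition **Millennium
120** MLC.

When the high-definition machine in a department goes down, keeping a
patient's fractionation schedule means transferring the treatment to
another linac. Going from coarse to fine leaves is routine; the reverse
requires reshaping every aperture. `vmatadapt` implements the geometric
transfer: it extracts the per-control-point leaf apertures and meterset
weights from the DICOM RT Plan, converts them to the coarser bank, and
validates the result, so a physicist can import the adapted plan into the
TPS for dose calculation and verification. Dose calculation itself (and
phantom measurement) is deliberately out of scope.

## Method

Both MLCs have 60 leaf pairs. The HD120 bank follows a 14–32–14 pattern of
0.5 / 0.25 / 0.5 cm leaf widths at isocenter (22 cm span); the Millennium
bank a 10–40–10 pattern of 1.0 / 0.5 / 1.0 cm (40 cm span). Aligning the
two banks on the beam axis yields a unique leaf correspondence per bank:

* **18 averaged targets** — where two adjacent HD leaves tile one SD leaf
  exactly (the 32 central 0.25 cm leaves, plus the outermost 0.5 cm pair
  on each side), the SD position is the unweighted mean
  `x̄ = (x₁ + x₂)/2`;
* **24 direct targets** — HD and SD leaves of equal width and identical
  interval, mapped one-to-one (bit-exact);
* **18 closed targets** — SD leaves outside the 22 cm HD extent, parked
  closed behind the jaw.

Because the mean of two travels obeys
`|Δx̄| = |Δx₁ + Δx₂|/2 ≤ (|Δx₁| + |Δx₂|)/2 < C` whenever each source leaf
obeys the per-interval speed limit `C`, the adapted plan automatically
satisfies the same leaf-speed constraint as the original — a property the
validation module checks rather than assumes. Likewise the adapted gap is
the mean of the two source gaps and never falls below their minimum.

For clinical review of the adapted dose distribution the package computes

* `%diff = 100 · (D_SDL − D_HDL) / D_HDL` for mean/max dose per structure,
  with a configurable review band (±10 % by default, strict inequality);
* the homogeneity index `HI = (D_max − D_min) / D_mean` for targets,

from per-structure dose statistics exported as CSV
(`structure,stat,value,plan_label`).

## Worked example

No clinical data is needed — the synthetic-plan module writes valid RT
Plan files for every aperture family:

```sh
vmatadapt make-fixtures plans --seed 42
vmatadapt adapt plans/hd_random.dcm adapted.dcm --machine SDL-2 --provenance prov.json
vmatadapt validate adapted.dcm -c 0.51 --against plans/hd_random.dcm
```

prints

```
adapted 1 arc(s), 100 control points -> adapted.dcm
HD_RANDOM: max travel 0.5 cm/interval vs limit 0.51 -> PASS
HD_RANDOM: max |area diff| central 2.132e-14 cm2, peripheral 0 cm2
```

i.e. the adapted arc keeps all 100 control points, its worst per-interval
leaf travel (0.5 cm) is no larger than the original's and passes the
configured limit, the peripheral (directly mapped) field is identical to
machine precision, and the central region — where averaging reshapes the
aperture — differs only at float round-off for this equal-gap arc.
A dose-change report from two summary CSVs:

```sh
vmatadapt report hdl.csv sdl.csv
```

```
structure stat  original  adapted  percent_diff  outside_band
      PTV mean    60.000   61.800         3.000         False
      PTV  max    63.000   70.000        11.111          True

homogeneity index:
structure  hi_original  hi_adapted
      PTV        0.100       0.227

review REQUIRED (±10% band, strict)
```

The max-dose increase of 11.1 % exceeds the ±10 % band, so the adapted
plan is flagged for additional review before treatment.

The same operations are available as a library
(`vmatadapt.read_plan`, `adapt_plan`, `check_leaf_travel`,
`compare_apertures`, `build_comparison`, ...); see `docs/methods.md` for
the numerical conventions.

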