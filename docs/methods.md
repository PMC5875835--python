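# Methods

## Problem and model

A VMAT arc is an ordered sequence of control points, each carrying the
positions of 60 opposing leaf pairs (two banks), a gantry angle, and a
cumulative meterset weight — the monotone fraction of the beam's monitor
units delivered so far. Adapting a plan from the HD120 MLC to the
Millennium 120 MLC replaces each high-definition aperture with a
standard-definition one on the *same* control-point grid: weights, gantry
angles, jaws and control-point count are never touched; only the leaf
geometry changes.

The transformation is defined entirely by the two bank geometries. With
both banks centered on the beam axis, every SD leaf interval either (a)
coincides with one HD leaf (copied bit-exactly), (b) is tiled exactly by
two adjacent HD leaves (positions averaged with equal weight), or (c) lies
outside the 22 cm HD extent (closed). The resulting 24/18/18 partition per
bank is derived at run time from the interval structure, not hard-coded,
and is validated by an independent interval-enumeration oracle in the test
suite.

Assumptions inherited from the problem: both machines share the same
leaf-speed constraint; the plan is normalized downstream by the TPS, so no
meterset rescaling is needed; leaf-end curvature, tongue-and-groove and
transmission differences are dosimetric effects outside the geometric
transfer and are not modeled.

### Why the averaged plan stays deliverable

If each source leaf travels at most `C` between adjacent control points,
the averaged leaf travels `|Δx̄| = |Δx₁ + Δx₂|/2 ≤ max(|Δx₁|, |Δx₂|) ≤ C`
(triangle inequality), under any time model shared by the two machines.
Similarly the adapted gap equals the mean of the two source gaps, hence is
at least their minimum: a minimum-gap constraint satisfied by the source
plan is preserved. Both bounds are exact in real arithmetic; in floats the
subtractions forming gaps and travels can carry one ulp of noise, so the
property tests and validators use an absolute slack of 1e-12 cm
(~10 orders of magnitude below mechanical tolerance).

## Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| travel limit `C` | cm/interval or cm/s | none (required) | machine-specific; no universal value exists, so reports always print the configured limit. Travel ≥ `C` is flagged (the constraint is strict `< C`). |
| gantry speed (time model) | deg/s | off | optional; converts travel/interval to cm/s. The speed theorem holds under any shared time model. |
| park position | cm | bank-A X-jaw edge, else 0 | closed SD leaves outside the HD extent are parked with zero gap behind the jaw, where they are shielded; configurable. |
| `min_gap` | cm | 0 (off) | deliverable minimum for open pairs. Averaging staggered nearly-closed pairs can yield a small open gap; default is to fail loudly, `repair` mode opens the pair symmetrically to the minimum and records it in provenance. Exactly-closed pairs (gap 0) are legitimate and exempt. |
| review band | % | ±10, strict | structures whose mean or max dose changes by strictly more than the band trigger additional review. |
| central/peripheral split | cm | 4 / 10 | region accounting: \|y\| ≤ 4 cm is the 0.25 cm-leaf span where averaging changes the aperture; 4–10 cm is the directly mapped band (bit-identical by construction); beyond 10 cm only the SD bank has leaves. |
| fluence grid | cm | 0.1 | rasterization pixel at isocenter; fractional pixel coverage, uniform intensity. |

## Numerical conventions

* **Units.** All in-memory lengths are cm at isocenter; the DICOM wire
  format carries mm. Conversion lives only in `rtplan_io` and is bit-exact
  both ways: values are written as `str(Decimal(repr(cm)) * 10)` (trailing
  zeros stripped) and read as `float(Decimal(s) / 10)`. Since `repr` gives
  the shortest decimal that parses back to the double, and scaling by ten
  is exact in decimal arithmetic, the read is a single correctly-rounded
  conversion back to the identical double. Naive float scaling fails this
  for ~7 % of doubles due to double rounding.
* **Averaging.** `x̄` is computed as the decimal mean of the operands'
  shortest-decimal forms. Positions exported by planning systems are short
  decimals (0.1 mm grid), so their means are too (0.05 mm grid), stay
  within the 16-character DICOM DS limit, and survive file round trips
  bit-exactly. For arbitrary non-decimal doubles the writer falls back to
  the best ≤ 16-character representation.
* **Sign convention.** In the 120-value MLC position list, the first 60
  entries are bank A (retracts negative), the last 60 bank B; `A ≤ B` per
  pair, gap = `B − A`. Asserted on read and before every write, naming the
  offending beam/control point/leaf.
* **Leaf indexing.** 1..60 per bank from the most negative transverse
  boundary; each leaf owns the half-open interval `[bᵢ, bᵢ₊₁)` so every
  in-bank position maps to exactly one leaf. The absolute transverse
  origin is not part of the wire format; the center-symmetric placement is
  an implementation convention recorded in provenance output.
* **Degenerate inputs.** A single-control-point arc has no travel
  intervals and passes the speed check trivially; an all-closed aperture
  adapts to an all-closed aperture; plans whose boundary pattern matches
  neither supported model are rejected rather than guessed.

## Synthetic plans

The generator emulates the delivery data of clinical VMAT arcs without
any dose realism: conformal-ellipse apertures (static, like a conformal
arc), a constant-gap sliding window (the canonical dynamic stress
pattern), and seeded random leaf walks with a generator-enforced maximum
travel per interval and minimum gap — the adversarial input for the speed
and gap theorems. Positions are drawn on a 0.01 cm grid (the precision of
clinical exports; the random family works on an integer grid so its
constraints hold exactly). Meterset schedules are uniform or random
monotone with endpoints 0 and 1; gantry angles interpolate linearly
between start and stop without 0°/360° wrap-around. Fixture arcs stay at
or below 178 control points (a typical arc resolution) so the whole suite
generates in seconds; all randomness is seeded and recorded in the fixture
manifest.

What passing tests on these plans does **not** show: dosimetric
acceptability of adapted clinical plans. The generator produces valid
delivery sequences, not optimized treatment plans; the dose-change
metrics therefore operate on user-supplied dose summaries, and the
clinical decision (the ±10 % review policy) remains with the physicist.

## Design choices where the design was open

* The two outermost HD 0.5 cm leaves on each side overlap one SD 1.0 cm
  leaf exactly; they are averaged pairwise like the central leaves — the
  natural extension of the equal-coverage averaging rule — rather than
  truncated. Recorded in provenance.
* The correspondence is derived generically from interval overlap, so a
  malformed geometry pair fails construction instead of producing a silent
  partial mapping.
* `prepare_template` generates fresh SOP/series UIDs deterministically
  from the source UID and target machine, so re-preparing the same plan is
  reproducible.
* Carriage/leaf-span limits after adaptation are not checked by default
  (no universal value); the gap and travel checks are the load-bearing
  constraints.

## Problem sizes

The test suite checks the averaging oracle on 1 000 random apertures, the
speed and gap theorems on 1 000 (respectively 200) seeded adversarial arcs
of 4–5 control points, and round trips on the full fixture suite
(349 control points across five plans); the acceptance script uses 300
adversarial arcs. These sizes make every run complete in well under a
minute on one CPU while exercising every branch of the correspondence.

## Known limitations

* Only the HD120 → Millennium 120 direction is implemented; upsampling to
  a finer MLC is a different (under-determined) problem.
* RT Dose / RT Struct objects are not read; dose summaries arrive as CSV.
* The fluence model is uniform-intensity with square leaf ends — adequate
  for aperture-fidelity accounting, not for dose prediction.
* Gantry angles in synthetic arcs do not cross 0°/360°.
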