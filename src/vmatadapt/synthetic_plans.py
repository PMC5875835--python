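"""Parametric synthetic VMAT arcs written as valid RT Plan files.

No clinical data ships with the package; every consumer (tests, examples,
acceptance runs) generates its inputs here.  Three aperture families cover
the delivery patterns the adaptation must handle:

* ``ellipse`` — a conformal elliptical aperture: each leaf pair opens to
  the ellipse's half-width at its leaf center, leaves outside the ellipse
  closed.  Static across control points, like a conformal arc.
* ``sliding_window`` — a fixed-gap window translating across the field at
  constant speed, the canonical dynamic-MLC stress pattern.
* ``random`` — seeded random leaf walks with a generator-enforced maximum
  travel per interval and minimum gap; adversarial input for the travel
  and gap theorems.

Positions are drawn on a 0.01 cm (0.1 mm) grid — the precision clinical
RT Plan exports use — so every generated value is a short decimal that
round-trips bit-exactly through the DICOM wire format.  Generation is
deterministic given the recipe seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import RecipeError
from .mlc_geometry import HD_MODEL, LeafBankGeometry, build_geometry
from .rtplan_io import ControlPoint, RTPlanDocument, VMATArc, new_plan_document, write_plan

_Q = 100  # integer position grid: hundredths of a cm


@dataclass(frozen=True)
class ArcRecipe:
    """Parameters of one synthetic arc.

    Lengths in cm at isocenter.  ``max_travel`` bounds each leaf's motion
    between adjacent control points (generator-enforced for the random
    family; the other families move slower by construction unless the
    recipe itself is too fast, which is rejected).
    """

    family: str = "ellipse"  # ellipse | sliding_window | random | all_closed
    n_control_points: int = 60
    gantry_start: float = 200.0
    gantry_stop: float = 160.0
    meterset: str = "uniform"  # uniform | random
    seed: int = 0
    semi_axis_x: float = 3.0
    semi_axis_y: float = 3.0
    window_width: float = 2.0
    window_start: float = -4.0
    window_stop: float = 4.0
    field_halfwidth: float = 4.0  # transverse half-extent for window/random
    max_travel: float = 0.5
    min_gap: float = 0.0
    max_gap: float = 4.0
    beam_id: str = "ARC1"
    beam_number: int = 1


def _quantize(x: float) -> float:
    return round(x * _Q) / _Q


def _meterset_weights(recipe: ArcRecipe, rng: np.random.Generator) -> np.ndarray:
    n = recipe.n_control_points
    if n == 1:
        return np.array([0.0])
    if recipe.meterset == "uniform":
        w = np.linspace(0.0, 1.0, n)
    elif recipe.meterset == "random":
        inner = np.sort(rng.uniform(0.0, 1.0, n - 2))
        w = np.concatenate([[0.0], inner, [1.0]])
    else:
        raise RecipeError(f"unknown meterset schedule {recipe.meterset!r}")
    w = np.round(w, 6)
    w[0], w[-1] = 0.0, 1.0
    return np.maximum.accumulate(w)


def _ellipse_banks(recipe: ArcRecipe, geometry: LeafBankGeometry):
    a, b = recipe.semi_axis_x, recipe.semi_axis_y
    if a <= 0 or b <= 0:
        raise RecipeError("ellipse semi-axes must be positive")
    if b > geometry.span / 2:
        raise RecipeError(
            f"ellipse semi-axis {b} cm exceeds the {geometry.model_name} "
            f"bank half-extent {geometry.span / 2} cm"
        )
    bank_a = np.zeros(geometry.n_leaves)
    bank_b = np.zeros(geometry.n_leaves)
    for i, yc in enumerate(geometry.leaf_centers):
        if abs(yc) < b:
            half = a * np.sqrt(1.0 - (yc / b) ** 2)
            bank_a[i] = _quantize(-half)
            bank_b[i] = _quantize(half)
    return bank_a, bank_b


def _window_mask(recipe: ArcRecipe, geometry: LeafBankGeometry) -> np.ndarray:
    return np.array(
        [abs(yc) <= recipe.field_halfwidth for yc in geometry.leaf_centers]
    )


def generate_arc(recipe: ArcRecipe, geometry: LeafBankGeometry) -> VMATArc:
    """Generate one VMAT arc; deterministic given ``recipe.seed``."""
    n = recipe.n_control_points
    if n < 1:
        raise RecipeError("need at least one control point")
    rng = np.random.default_rng(recipe.seed)
    weights = _meterset_weights(recipe, rng)
    gantry = np.round(np.linspace(recipe.gantry_start, recipe.gantry_stop, n), 4)
    half_span = geometry.span / 2
    jaw_x = (-half_span / 2, half_span / 2)
    jaw_y = (-half_span, half_span)

    cps: list[ControlPoint] = []
    if recipe.family == "ellipse":
        bank_a, bank_b = _ellipse_banks(recipe, geometry)
        for k in range(n):
            cps.append(ControlPoint(k, bank_a.copy(), bank_b.copy(),
                                    float(weights[k]), float(gantry[k]),
                                    jaw_x, jaw_y))
    elif recipe.family == "all_closed":
        zero = np.zeros(geometry.n_leaves)
        for k in range(n):
            cps.append(ControlPoint(k, zero.copy(), zero.copy(),
                                    float(weights[k]), float(gantry[k]),
                                    jaw_x, jaw_y))
    elif recipe.family == "sliding_window":
        w = recipe.window_width
        if w <= 0:
            raise RecipeError("window width must be positive")
        if recipe.window_stop + w > half_span or recipe.window_start < -half_span:
            raise RecipeError("sliding window leaves the bank extent")
        if n > 1:
            step = abs(recipe.window_stop - recipe.window_start) / (n - 1)
            if step > recipe.max_travel:
                raise RecipeError(
                    f"window speed {step:g} cm/interval exceeds max_travel "
                    f"{recipe.max_travel:g}"
                )
        mask = _window_mask(recipe, geometry)
        starts = np.linspace(recipe.window_start, recipe.window_stop, n)
        for k in range(n):
            s = _quantize(float(starts[k]))
            bank_a = np.zeros(geometry.n_leaves)
            bank_b = np.zeros(geometry.n_leaves)
            bank_a[mask] = s
            bank_b[mask] = _quantize(s + w)  # constant gap: s and w both on grid
            cps.append(ControlPoint(k, bank_a, bank_b, float(weights[k]),
                                    float(gantry[k]), jaw_x, jaw_y))
    elif recipe.family == "random":
        cps = _random_walk_cps(recipe, geometry, rng, weights, gantry,
                               jaw_x, jaw_y)
    else:
        raise RecipeError(f"unknown aperture family {recipe.family!r}")

    arc = VMATArc(
        beam_id=recipe.beam_id,
        beam_number=recipe.beam_number,
        control_points=cps,
        mlc_model=geometry.model_name,
        beam_meterset=200.0,
        final_cumulative_weight=float(weights[-1]),
    )
    return arc


def _random_walk_cps(recipe, geometry, rng, weights, gantry, jaw_x, jaw_y):
    """Adversarial random apertures on an integer 0.01 cm grid.

    All arithmetic is integer, so the travel bound and minimum gap hold
    exactly after conversion to cm.  Clamping is contractive (|clip(x+d) −
    clip(x)| ≤ |d|) and the bank-A repair only ever pulls A down to
    ``B − min_gap``, which stays within the step bound because the
    previous control point already satisfied the gap.
    """
    n_leaves = geometry.n_leaves
    mask = _window_mask(recipe, geometry)
    lim = int(round(geometry.span / 2 * _Q))  # leaf-travel range, ± half span
    mt = int(round(recipe.max_travel * _Q))
    if mt < 1:
        raise RecipeError("max_travel below the 0.01 cm position grid")
    mg = int(round(recipe.min_gap * _Q))
    gmax = int(round(recipe.max_gap * _Q))
    if gmax < mg:
        raise RecipeError("max_gap below min_gap")

    mid0 = rng.integers(-lim // 4, lim // 4 + 1, n_leaves)
    gap0 = rng.integers(mg, gmax + 1, n_leaves)
    a = mid0 - gap0 // 2
    b = a + gap0
    a[~mask] = 0
    b[~mask] = 0

    cps = []
    for k in range(recipe.n_control_points):
        if k > 0:
            da = rng.integers(-mt, mt + 1, n_leaves)
            db = rng.integers(-mt, mt + 1, n_leaves)
            da[~mask] = 0
            db[~mask] = 0
            a2 = np.clip(a + da, -lim, lim)
            b2 = np.clip(b + db, -lim, lim)
            a = np.minimum(a2, b2 - np.where(mask, mg, 0))
            b = b2
        cps.append(
            ControlPoint(k, a / _Q, b / _Q, float(weights[k]),
                         float(gantry[k]), jaw_x, jaw_y)
        )
    return cps


# ---------------------------------------------------------------------------
# fixture suite

DEFAULT_SUITE_SEED = 20170720

_SUITE: tuple[tuple[str, dict], ...] = (
    ("hd_ellipse", {"family": "ellipse", "n_control_points": 60,
                    "semi_axis_x": 4.0, "semi_axis_y": 3.0}),
    ("hd_sliding_window", {"family": "sliding_window", "n_control_points": 178,
                           "window_width": 2.0, "window_start": -4.0,
                           "window_stop": 4.0, "max_travel": 0.5}),
    ("hd_random", {"family": "random", "n_control_points": 100,
                   "meterset": "random", "max_travel": 0.5, "min_gap": 0.05}),
    ("hd_single_cp", {"family": "ellipse", "n_control_points": 1,
                      "semi_axis_x": 2.0, "semi_axis_y": 2.0}),
    ("hd_all_closed", {"family": "all_closed", "n_control_points": 10}),
)


def write_fixture_suite(directory: str | Path,
                        seed: int = DEFAULT_SUITE_SEED) -> dict[str, Path]:
    """Write the documented RT Plan fixture set used by the test suite.

    All fixtures use the HD model (the adaptation's source device), stay
    at or below 178 control points, and round-trip bit-exactly.  A
    ``fixtures.json`` manifest records every recipe including seeds so the
    set can be regenerated identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geometry = build_geometry(HD_MODEL)
    paths: dict[str, Path] = {}
    manifest = {}
    for idx, (name, params) in enumerate(_SUITE):
        recipe = ArcRecipe(beam_id=name.upper(), seed=seed + idx, **params)
        arc = generate_arc(recipe, geometry)
        doc = new_plan_document([arc], machine_name="HDL-1", plan_label=name[:16],
                                uid_entropy=f"{name}:{seed + idx}")
        path = directory / f"{name}.dcm"
        write_plan(doc, path)
        paths[name] = path
        manifest[name] = asdict(recipe)
    (directory / "fixtures.json").write_text(json.dumps(manifest, indent=2))
    return paths
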