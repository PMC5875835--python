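"""Delivery-constraint and aperture-fidelity checks.

Two families of checks:

* **Leaf travel** — VMAT optimizers impose a maximum leaf speed; between
  adjacent control points each leaf may travel at most ``C`` (cm per
  interval, or cm/s under a time model).  Because the adaptation averages
  pairs of positions, the adapted travel per interval is bounded by the
  mean of the two source travels and hence by the larger of them, so an
  adapted plan can never violate a limit the original satisfied.
  :func:`check_leaf_travel` measures and flags travel per interval.
* **Aperture fidelity** — per-control-point open area (gap × leaf width,
  square leaf ends) resolved into a central region (the HD 0.25 cm leaf
  span, |y| ≤ 4 cm, where averaging changes the aperture), a peripheral
  region (4 < |y| ≤ 10 cm, where leaves are mapped one-to-one and must be
  bit-identical) and an outer region (|y| > 10 cm).  Optionally, uniform-
  intensity fluence maps (aperture indicator × meterset increment summed
  over control points) and their difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mlc_geometry import LeafBankGeometry, build_geometry
from .rtplan_io import VMATArc

_FLOAT_SLACK = 1e-12  # one-ulp noise from gap/travel subtraction


@dataclass(frozen=True)
class GantrySpeedTimeModel:
    """Constant gantry speed: interval time = |Δ gantry| / speed."""

    speed_deg_per_s: float

    def interval_times(self, gantry_angles: np.ndarray) -> np.ndarray:
        return np.abs(np.diff(gantry_angles)) / self.speed_deg_per_s


@dataclass
class TravelViolation:
    interval: int  # between control points interval and interval+1
    bank: str  # "A" or "B"
    leaf: int  # 1-based
    value: float  # cm (or cm/s under a time model)


@dataclass
class ConstraintReport:
    """Leaf-travel and gap check results for one arc."""

    arc_id: str
    limit: float
    unit: str  # "cm/interval" or "cm/s"
    per_interval_max: np.ndarray = field(repr=False)
    max_travel: float = 0.0
    violations: list[TravelViolation] = field(default_factory=list)
    gap_violations: list[dict] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations and not self.gap_violations

    def travel_ratio(self, other: "ConstraintReport") -> float:
        """Max-travel ratio self/other (adapted vs original comparison)."""
        if other.max_travel == 0.0:
            return 0.0 if self.max_travel == 0.0 else float("inf")
        return self.max_travel / other.max_travel


def check_leaf_travel(
    arc: VMATArc,
    limit: float,
    time_model: GantrySpeedTimeModel | None = None,
    min_gap: float = 0.0,
) -> ConstraintReport:
    """Measure per-leaf travel between adjacent control points and flag ≥ limit.

    With ``time_model`` the travel is divided by the interval time and the
    limit is interpreted in cm/s; otherwise it is pure cm per interval.
    A single-control-point arc has no intervals and passes trivially.
    Gap violations (bank overlap, or an open gap below ``min_gap``) are
    reported alongside.
    """
    pos = arc.positions()  # (n_cp, 2, 60)
    n_cp = pos.shape[0]
    unit = "cm/s" if time_model else "cm/interval"
    if n_cp < 2:
        rates = np.zeros((0, 2, pos.shape[2]))
    else:
        rates = np.abs(np.diff(pos, axis=0))
        if time_model is not None:
            dt = time_model.interval_times(arc.gantry_angles())
            if np.any(dt <= 0):
                raise ValueError(
                    "time model yields a non-positive interval time (static "
                    "gantry between control points)"
                )
            rates = rates / dt[:, None, None]
    per_interval_max = rates.max(axis=(1, 2)) if rates.size else np.zeros(0)
    violations = [
        TravelViolation(int(k), "AB"[int(b)], int(leaf) + 1, float(rates[k, b, leaf]))
        for k, b, leaf in zip(*np.nonzero(rates >= limit))
    ]
    gap_violations = []
    for cp in arc.control_points:
        gaps = cp.gaps
        bad = np.nonzero(gaps < -_FLOAT_SLACK)[0]
        for leaf in bad:
            gap_violations.append(
                {"control_point": cp.index, "leaf": int(leaf) + 1,
                 "gap": float(gaps[leaf]), "kind": "overlap"}
            )
        if min_gap > 0:
            small = np.nonzero((gaps > _FLOAT_SLACK) & (gaps < min_gap - _FLOAT_SLACK))[0]
            for leaf in small:
                gap_violations.append(
                    {"control_point": cp.index, "leaf": int(leaf) + 1,
                     "gap": float(gaps[leaf]), "kind": "min_gap"}
                )
    return ConstraintReport(
        arc_id=arc.beam_id,
        limit=float(limit),
        unit=unit,
        per_interval_max=per_interval_max,
        max_travel=float(per_interval_max.max()) if per_interval_max.size else 0.0,
        violations=violations,
        gap_violations=gap_violations,
    )


# ---------------------------------------------------------------------------
# aperture comparison


def _region_of(center: float, central_halfwidth: float, peripheral_halfwidth: float) -> str:
    if abs(center) <= central_halfwidth:
        return "central"
    if abs(center) <= peripheral_halfwidth:
        return "peripheral"
    return "outer"


def aperture_area(cp, geometry: LeafBankGeometry) -> float:
    """Open aperture area in cm²: Σ gap × leaf width (square leaf ends)."""
    widths = np.asarray(geometry.leaf_widths)
    return float(np.sum(np.maximum(cp.gaps, 0.0) * widths))


def region_areas(
    cp,
    geometry: LeafBankGeometry,
    central_halfwidth: float = 4.0,
    peripheral_halfwidth: float = 10.0,
) -> dict[str, float]:
    """Aperture area split by transverse region of each leaf's center."""
    widths = np.asarray(geometry.leaf_widths)
    contrib = np.maximum(cp.gaps, 0.0) * widths
    out = {"central": 0.0, "peripheral": 0.0, "outer": 0.0}
    for i, center in enumerate(geometry.leaf_centers):
        out[_region_of(center, central_halfwidth, peripheral_halfwidth)] += contrib[i]
    return out


def fluence_map(
    arc: VMATArc,
    grid: float = 0.1,
    x_extent: tuple[float, float] = (-15.0, 15.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform-intensity fluence grid summed over control-point increments.

    Each interval contributes (meterset increment) × (open-aperture
    indicator of its end control point), rasterized with fractional pixel
    coverage.  Returns ``(grid2d, x_edges, y_edges)``; rows are transverse
    (leaf) bands, columns the leaf-motion axis.  Arbitrary units.
    """
    geometry = build_geometry(arc.mlc_model)
    y_edges = np.arange(geometry.leaf_boundaries[0],
                        geometry.leaf_boundaries[-1] + grid / 2, grid)
    x_edges = np.arange(x_extent[0], x_extent[1] + grid / 2, grid)
    fl = np.zeros((len(y_edges) - 1, len(x_edges) - 1))
    weights = arc.weights()
    increments = np.diff(np.concatenate([[0.0], weights]))
    bounds = np.asarray(geometry.leaf_boundaries)
    # fractional row coverage of each leaf band
    lo = np.maximum(bounds[:-1, None], y_edges[None, :-1])
    hi = np.minimum(bounds[1:, None], y_edges[None, 1:])
    row_cover = np.clip(hi - lo, 0.0, None) / grid  # (60, n_rows)
    for cp, dw in zip(arc.control_points, increments):
        if dw == 0.0:
            continue
        a = cp.bank_a[:, None]
        b = cp.bank_b[:, None]
        col_cover = (
            np.clip(np.minimum(b, x_edges[None, 1:]) -
                    np.maximum(a, x_edges[None, :-1]), 0.0, None) / grid
        )  # (60, n_cols)
        fl += dw * (row_cover.T @ col_cover)
    return fl, x_edges, y_edges


@dataclass
class ApertureComparison:
    """Per-control-point aperture areas of two aligned arcs, by region."""

    area_original: np.ndarray
    area_adapted: np.ndarray
    regions_original: dict[str, np.ndarray]
    regions_adapted: dict[str, np.ndarray]
    fluence_original: np.ndarray | None = None
    fluence_adapted: np.ndarray | None = None
    fluence_diff: np.ndarray | None = None
    x_edges: np.ndarray | None = None
    y_edges: np.ndarray | None = None

    @property
    def peripheral_area_diff(self) -> np.ndarray:
        return self.regions_adapted["peripheral"] - self.regions_original["peripheral"]

    @property
    def central_area_diff(self) -> np.ndarray:
        return self.regions_adapted["central"] - self.regions_original["central"]


def compare_apertures(
    original: VMATArc,
    adapted: VMATArc,
    grid: float | None = None,
    central_halfwidth: float = 4.0,
    peripheral_halfwidth: float = 10.0,
) -> ApertureComparison:
    """Region-resolved aperture comparison of two aligned arcs.

    Requires equal control-point counts and aligned meterset weights.
    Passing ``grid`` additionally rasterizes both arcs into summed
    uniform-fluence maps and their difference.
    """
    if original.n_control_points != adapted.n_control_points:
        raise ValueError(
            f"control-point counts differ: {original.n_control_points} vs "
            f"{adapted.n_control_points}"
        )
    if not np.array_equal(original.weights(), adapted.weights()):
        raise ValueError("cumulative meterset weights are not aligned")
    geo_o = build_geometry(original.mlc_model)
    geo_a = build_geometry(adapted.mlc_model)

    def _collect(arc, geo):
        areas = np.array([aperture_area(cp, geo) for cp in arc.control_points])
        regs = {k: np.zeros(arc.n_control_points)
                for k in ("central", "peripheral", "outer")}
        for idx, cp in enumerate(arc.control_points):
            for k, v in region_areas(cp, geo, central_halfwidth,
                                     peripheral_halfwidth).items():
                regs[k][idx] = v
        return areas, regs

    area_o, regs_o = _collect(original, geo_o)
    area_a, regs_a = _collect(adapted, geo_a)
    comp = ApertureComparison(area_o, area_a, regs_o, regs_a)
    if grid is not None:
        fo, x_edges, y_edges_o = fluence_map(original, grid)
        fa, _, y_edges_a = fluence_map(adapted, grid)
        # banks differ in extent: embed both on the wider (adapted) row grid
        if fo.shape != fa.shape:
            rows = max(fo.shape[0], fa.shape[0])
            def _embed(f):
                pad = (rows - f.shape[0]) // 2
                out = np.zeros((rows, f.shape[1]))
                out[pad:pad + f.shape[0]] = f
                return out
            fo, fa = _embed(fo), _embed(fa)
            y_edges = y_edges_o if len(y_edges_o) - 1 == rows else y_edges_a
        else:
            y_edges = y_edges_o
        comp.fluence_original = fo
        comp.fluence_adapted = fa
        comp.fluence_diff = fa - fo
        comp.x_edges = x_edges
        comp.y_edges = y_edges
    return comp
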