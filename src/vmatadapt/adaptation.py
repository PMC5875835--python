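"""HD120 → Millennium-120 aperture adaptation by pairwise leaf averaging.

The adaptation is purely geometric.  Each standard-definition (SD) target
leaf is driven by one of three recipes derived from the two bank
geometries:

* **AVERAGE** — two transversely adjacent HD leaves whose union covers the
  SD leaf exactly; the SD position is the unweighted arithmetic mean of the
  two HD positions, ``x̄ = (x1 + x2) / 2``.  This applies to the 32 central
  0.25 cm HD leaves (16 SD targets) and to the two outermost 0.5 cm HD
  leaves on each side, which together cover one 1.0 cm SD leaf (2 SD
  targets), 18 targets per bank in all.
* **DIRECT** — an HD leaf of identical width and transverse interval; the
  position is copied bit-exactly (24 targets per bank).
* **CLOSED** — SD leaves outside the 22 cm HD bank extent (9 on each end,
  18 per bank); both banks are parked at a common position with zero gap.

Averaging two positions can only reduce the per-interval leaf travel
(triangle inequality), so an adapted plan inherits the original plan's
leaf-speed compliance; likewise the adapted gap is the mean of the two
source gaps and can never fall below their minimum.

The mean is evaluated in decimal arithmetic on the shortest-decimal
representation of the operands, so positions that arrived as short
decimals from a DICOM file stay short decimals and survive file round
trips bit-exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from decimal import Decimal

import numpy as np

from .errors import CorrespondenceError, GapViolationError, PlanIntegrityError
from .mlc_geometry import (
    HD_MODEL,
    SD_MODEL,
    LeafBankGeometry,
    build_geometry,
)
from .rtplan_io import ControlPoint, RTPlanDocument, VMATArc, prepare_template

_TOL = 1e-9


class MapKind(enum.Enum):
    DIRECT = "direct"
    AVERAGE = "average"
    CLOSED = "closed"


@dataclass(frozen=True)
class CorrespondenceEntry:
    """Recipe for one SD target leaf: combination rule + 1-based HD sources."""

    kind: MapKind
    sources: tuple[int, ...] = ()


@dataclass(frozen=True)
class LeafCorrespondence:
    """Per-target-leaf adaptation recipe for one bank (applies to both banks)."""

    entries: tuple[CorrespondenceEntry, ...]
    hd: LeafBankGeometry = field(repr=False)
    sd: LeafBankGeometry = field(repr=False)

    def count(self, kind: MapKind) -> int:
        return sum(1 for e in self.entries if e.kind is kind)

    @property
    def direct_targets(self) -> tuple[int, ...]:
        """1-based SD leaf indices that are mapped one-to-one."""
        return tuple(
            i + 1 for i, e in enumerate(self.entries) if e.kind is MapKind.DIRECT
        )

    def summary(self) -> dict:
        return {
            "direct": self.count(MapKind.DIRECT),
            "average": self.count(MapKind.AVERAGE),
            "closed": self.count(MapKind.CLOSED),
            "entries": [
                {"target": i + 1, "rule": e.kind.value, "sources": list(e.sources)}
                for i, e in enumerate(self.entries)
            ],
        }


def build_correspondence(
    hd: LeafBankGeometry, sd: LeafBankGeometry
) -> LeafCorrespondence:
    """Derive the unique geometry-driven HD→SD leaf correspondence.

    For each SD target interval the overlapping HD leaves are collected:
    an exactly coincident single HD leaf is mapped directly, a set of HD
    leaves tiling the target exactly is averaged (the supported pair of
    models always yields two), and targets with no HD coverage are closed.

    Raises
    ------
    CorrespondenceError
        If the geometries are not the supported HD/SD pair or a target is
        only partially covered.
    """
    if hd.model_name != HD_MODEL or sd.model_name != SD_MODEL:
        raise CorrespondenceError(
            f"correspondence is defined for {HD_MODEL} -> {SD_MODEL}, got "
            f"{hd.model_name} -> {sd.model_name}"
        )
    entries: list[CorrespondenceEntry] = []
    used: list[int] = []
    for j in range(1, sd.n_leaves + 1):
        lo, hi = sd.leaf_interval(j)
        sources = [
            i
            for i in range(1, hd.n_leaves + 1)
            if min(hi, hd.leaf_interval(i)[1]) - max(lo, hd.leaf_interval(i)[0]) > _TOL
        ]
        if not sources:
            entries.append(CorrespondenceEntry(MapKind.CLOSED))
            continue
        s_lo = hd.leaf_interval(sources[0])[0]
        s_hi = hd.leaf_interval(sources[-1])[1]
        if abs(s_lo - lo) > _TOL or abs(s_hi - hi) > _TOL:
            raise CorrespondenceError(
                f"SD leaf {j} [{lo}, {hi}) is only partially covered by the HD "
                f"bank ([{s_lo}, {s_hi}))"
            )
        if len(sources) == 1:
            entries.append(CorrespondenceEntry(MapKind.DIRECT, (sources[0],)))
        elif len(sources) == 2:
            entries.append(CorrespondenceEntry(MapKind.AVERAGE, tuple(sources)))
        else:
            raise CorrespondenceError(
                f"SD leaf {j} overlaps {len(sources)} HD leaves; only direct "
                f"mapping and pairwise averaging are defined"
            )
        used.extend(sources)
    if sorted(used) != list(range(1, hd.n_leaves + 1)):
        raise CorrespondenceError("every HD leaf must be consumed exactly once")
    return LeafCorrespondence(tuple(entries), hd, sd)


def average_positions(x1: float, x2: float) -> float:
    """Unweighted mean of two leaf positions, exact in decimal arithmetic."""
    return float((Decimal(repr(float(x1))) + Decimal(repr(float(x2)))) / 2)


@dataclass(frozen=True)
class AdaptationConfig:
    """Policies for the geometric adaptation.

    park_position:
        Common position (cm) for both banks of CLOSED SD leaves.  ``None``
        parks at the bank-A X-jaw edge when the control point carries jaws,
        else at 0 — either way the pair is closed (zero gap) and shielded.
    min_gap:
        Deliverable minimum gap (cm) demanded of every open adapted pair;
        0 disables the check.
    gap_policy:
        ``"error"`` fails loudly when averaging staggered nearly-closed
        source pairs yields a gap below ``min_gap``; ``"repair"`` opens the
        pair symmetrically to ``min_gap`` and records the repair.
    """

    park_position: float | None = None
    min_gap: float = 0.0
    gap_policy: str = "error"

    def __post_init__(self) -> None:
        if self.gap_policy not in ("error", "repair"):
            raise ValueError(f"gap_policy must be 'error' or 'repair', got "
                             f"{self.gap_policy!r}")
        if self.min_gap < 0:
            raise ValueError("min_gap must be non-negative")


def adapt_control_point(
    cp: ControlPoint,
    corr: LeafCorrespondence,
    config: AdaptationConfig = AdaptationConfig(),
    repairs: list | None = None,
) -> ControlPoint:
    """Transform one HD control point into its SD counterpart.

    Meterset weight, gantry angle and jaws are copied unchanged; only the
    leaf positions are adapted per the correspondence.
    """
    n_hd = corr.hd.n_leaves
    if len(cp.bank_a) != n_hd or len(cp.bank_b) != n_hd:
        raise PlanIntegrityError(
            f"control point {cp.index} has {len(cp.bank_a)} leaf pairs; the "
            f"correspondence expects the {corr.hd.model_name} structure ({n_hd})"
        )
    if config.park_position is not None:
        park = float(config.park_position)
    elif cp.jaws_x is not None:
        park = float(cp.jaws_x[0])
    else:
        park = 0.0

    a_out = np.empty(corr.sd.n_leaves)
    b_out = np.empty(corr.sd.n_leaves)
    for j, entry in enumerate(corr.entries):
        if entry.kind is MapKind.CLOSED:
            a_out[j] = b_out[j] = park
            continue
        if entry.kind is MapKind.DIRECT:
            (i,) = entry.sources
            a_out[j] = cp.bank_a[i - 1]
            b_out[j] = cp.bank_b[i - 1]
        else:
            i1, i2 = entry.sources
            a_out[j] = average_positions(cp.bank_a[i1 - 1], cp.bank_a[i2 - 1])
            b_out[j] = average_positions(cp.bank_b[i1 - 1], cp.bank_b[i2 - 1])
        gap = b_out[j] - a_out[j]
        if gap < -_TOL:
            raise GapViolationError(
                f"control point {cp.index}, SD leaf {j + 1}: adapted bank A "
                f"exceeds bank B by {-gap:g} cm"
            )
        # exactly-closed pairs (gap 0) are legitimate; the deliverable
        # minimum applies to pairs the averaging left slightly open
        if config.min_gap > 0 and 0 < gap < config.min_gap - 1e-12:
            if config.gap_policy == "error":
                raise GapViolationError(
                    f"control point {cp.index}, SD leaf {j + 1}: adapted gap "
                    f"{gap:g} cm below deliverable minimum {config.min_gap:g} cm"
                )
            mid = average_positions(a_out[j], b_out[j])
            half = Decimal(repr(config.min_gap)) / 2
            a_out[j] = float(Decimal(repr(mid)) - half)
            b_out[j] = float(Decimal(repr(mid)) + half)
            if repairs is not None:
                repairs.append(
                    {"control_point": cp.index, "leaf": j + 1, "gap_before": gap}
                )
    return ControlPoint(
        cp.index,
        a_out,
        b_out,
        cp.cumulative_weight,
        cp.gantry_angle,
        cp.jaws_x,
        cp.jaws_y,
    )


def adapt_plan(
    original: RTPlanDocument,
    target_machine: str,
    config: AdaptationConfig = AdaptationConfig(),
) -> tuple[RTPlanDocument, dict]:
    """Adapt a full HD plan for delivery on a standard-definition machine.

    Returns the adapted plan (a populated :func:`prepare_template` copy)
    and a provenance record describing the correspondence, the policies
    applied, and a per-arc change summary.

    Raises
    ------
    PlanIntegrityError
        If any beam does not use the HD model (e.g. re-running the
        adaptation on an already-adapted plan).
    """
    for arc in original.arcs:
        if arc.mlc_model != HD_MODEL:
            raise PlanIntegrityError(
                f"beam {arc.beam_id} uses {arc.mlc_model}; adaptation requires "
                f"an {HD_MODEL} source plan"
            )
    corr = build_correspondence(build_geometry(HD_MODEL), build_geometry(SD_MODEL))
    template = prepare_template(original, target_machine)

    arc_records = []
    adapted_arcs: list[VMATArc] = []
    for src_arc, tpl_arc in zip(original.arcs, template.arcs):
        repairs: list = []
        cps = [
            adapt_control_point(cp, corr, config, repairs)
            for cp in src_arc.control_points
        ]
        adapted_arcs.append(replace(tpl_arc, control_points=cps))
        # position shift introduced by averaging = half the source stagger
        max_shift = 0.0
        for cp in src_arc.control_points:
            for entry in corr.entries:
                if entry.kind is MapKind.AVERAGE:
                    i1, i2 = entry.sources
                    max_shift = max(
                        max_shift,
                        abs(cp.bank_a[i1 - 1] - cp.bank_a[i2 - 1]) / 2,
                        abs(cp.bank_b[i1 - 1] - cp.bank_b[i2 - 1]) / 2,
                    )
        arc_records.append(
            {
                "beam_id": src_arc.beam_id,
                "n_control_points": src_arc.n_control_points,
                "n_repaired_gaps": len(repairs),
                "repairs": repairs,
                "max_position_shift_cm": max_shift,
            }
        )
    adapted = RTPlanDocument(
        arcs=adapted_arcs,
        machine_name=template.machine_name,
        dataset=template.dataset,
    )
    adapted.validate()
    provenance = {
        "source_model": HD_MODEL,
        "target_model": SD_MODEL,
        "target_machine": str(target_machine),
        "config": {
            "park_position": config.park_position,
            "min_gap": config.min_gap,
            "gap_policy": config.gap_policy,
        },
        "correspondence": corr.summary(),
        "arcs": arc_records,
    }
    return adapted, provenance
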