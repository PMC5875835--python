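"""DICOM RT Plan I/O for VMAT arcs.

Reads the delivery data of a VMAT plan — per-control-point MLC leaf
positions, jaw positions, gantry angles and cumulative meterset weights —
into plain dataclasses, and writes (possibly adapted) plans back out as
standards-valid RT Plan files.

Units and conventions
---------------------
* All in-memory lengths are **cm at isocenter**; the RT Plan wire format
  carries **mm**.  Conversion is confined to this module and is bit-exact
  on round trip: a value is written as ``str(Decimal(repr(cm)) * 10)`` and
  read back as ``float(Decimal(s) / 10)``, which recovers the identical
  IEEE double (the shortest-repr decimal of the double is scaled exactly in
  decimal arithmetic, so the read is a single correctly-rounded conversion
  back to the original double).
* Leaf sign convention: the first 60 values of the DICOM ``MLCX`` position
  list are bank A (retracts toward negative x), the last 60 are bank B
  (retracts toward positive x).  Bank A ≤ bank B per leaf pair defines a
  non-overlapping aperture; the gap is ``B − A``.  Asserted on read.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import (
    ApertureGuardError,
    PlanFormatError,
    PlanIntegrityError,
    UnsupportedDeviceError,
)
from .mlc_geometry import SD_MODEL, build_geometry, infer_model

RTPLAN_SOP_CLASS_UID = "1.2.840.10008.5.1.4.1.1.481.5"

#: Deterministic UID root for synthetic/derived plans (pydicom test root).
_UID_PREFIX = "1.2.826.0.1.3680043.8.498."

_MLC_TYPES = ("MLCX", "MLCY")
_X_JAW_TYPES = ("X", "ASYMX")
_Y_JAW_TYPES = ("Y", "ASYMY")


# ---------------------------------------------------------------------------
# exact cm <-> mm DS conversion


def format_ds(value: float) -> str:
    """Shortest DICOM DS string for a double, exact when it fits 16 chars."""
    s = repr(float(value))
    if len(s) <= 16:
        return s
    for prec in range(15, 0, -1):
        cand = f"{value:.{prec}g}"
        if float(cand) == value and len(cand) <= 16:
            return cand
    return f"{value:.10g}"


def cm_to_mm_string(cm: float) -> str:
    """Exact mm DS string for a cm double (see module docstring)."""
    s = str(Decimal(repr(float(cm))) * 10)
    if "." in s and "E" not in s and "e" not in s:
        s = s.rstrip("0").rstrip(".") or "0"
    if len(s) <= 16:
        return s
    # Cannot represent exactly within the DS limit; best 16-char effort.
    mm = float(cm) * 10.0
    for prec in range(15, 0, -1):
        cand = f"{mm:.{prec}g}"
        if len(cand) <= 16 and float(Decimal(cand) / 10) == cm:
            return cand
    return f"{mm:.10g}"


def mm_string_to_cm(s: str) -> float:
    return float(Decimal(str(s).strip()) / 10)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ControlPoint:
    """One VMAT snapshot: leaf/jaw positions, gantry angle, meterset weight.

    Leaf positions are cm at isocenter along the leaf-motion axis, 60 per
    bank; ``bank_a[i] <= bank_b[i]`` for every pair.  ``cumulative_weight``
    is the monotone fraction of the beam meterset delivered by this control
    point.  Jaw pairs are optional (carried when the file provides them).
    """

    index: int
    bank_a: np.ndarray
    bank_b: np.ndarray
    cumulative_weight: float
    gantry_angle: float
    jaws_x: tuple[float, float] | None = None
    jaws_y: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.bank_a = np.asarray(self.bank_a, dtype=float)
        self.bank_b = np.asarray(self.bank_b, dtype=float)

    @property
    def gaps(self) -> np.ndarray:
        """Per-pair aperture gap ``B − A`` in cm (non-negative when valid)."""
        return self.bank_b - self.bank_a

    def copy(self) -> "ControlPoint":
        return ControlPoint(
            self.index,
            self.bank_a.copy(),
            self.bank_b.copy(),
            self.cumulative_weight,
            self.gantry_angle,
            self.jaws_x,
            self.jaws_y,
        )


@dataclass
class VMATArc:
    """An ordered control-point sequence for one beam plus its metadata."""

    beam_id: str
    beam_number: int
    control_points: list[ControlPoint]
    mlc_model: str
    beam_meterset: float | None = None
    final_cumulative_weight: float = 1.0

    @property
    def n_control_points(self) -> int:
        return len(self.control_points)

    def positions(self) -> np.ndarray:
        """Stacked ``(n_cp, 2, 60)`` array: axis 1 is (bank A, bank B)."""
        return np.stack(
            [np.stack([cp.bank_a, cp.bank_b]) for cp in self.control_points]
        )

    def weights(self) -> np.ndarray:
        return np.array([cp.cumulative_weight for cp in self.control_points])

    def gantry_angles(self) -> np.ndarray:
        return np.array([cp.gantry_angle for cp in self.control_points])


@dataclass
class RTPlanDocument:
    """Parsed VMAT arcs plus the opaque plan-level DICOM dataset.

    The pydicom dataset carries identifiers, prescription references and
    any other plan metadata unchanged; the arcs are the authoritative
    delivery data and are written back into a copy of the dataset by
    :func:`write_plan`.
    """

    arcs: list[VMATArc]
    machine_name: str
    dataset: Dataset = field(repr=False)

    def validate(self) -> None:
        """Check structural invariants, naming the offending beam/CP/leaf."""
        for arc in self.arcs:
            n_pairs = build_geometry(arc.mlc_model).n_leaves
            prev_w = None
            for cp in arc.control_points:
                if len(cp.bank_a) != n_pairs or len(cp.bank_b) != n_pairs:
                    raise PlanIntegrityError(
                        f"beam {arc.beam_id}, control point {cp.index}: expected "
                        f"{n_pairs} leaf pairs, got {len(cp.bank_a)}/{len(cp.bank_b)}"
                    )
                overlap = np.nonzero(cp.bank_a > cp.bank_b)[0]
                if overlap.size:
                    leaf = int(overlap[0]) + 1
                    raise ApertureGuardError(
                        f"beam {arc.beam_id}, control point {cp.index}, leaf pair "
                        f"{leaf}: bank A ({cp.bank_a[leaf - 1]:g} cm) exceeds bank B "
                        f"({cp.bank_b[leaf - 1]:g} cm)"
                    )
                if prev_w is not None and cp.cumulative_weight < prev_w:
                    raise PlanIntegrityError(
                        f"beam {arc.beam_id}, control point {cp.index}: cumulative "
                        f"meterset weight decreases ({prev_w:g} -> "
                        f"{cp.cumulative_weight:g})"
                    )
                prev_w = cp.cumulative_weight
            if arc.control_points and arc.control_points[0].cumulative_weight != 0.0:
                raise PlanIntegrityError(
                    f"beam {arc.beam_id}: first cumulative meterset weight is "
                    f"{arc.control_points[0].cumulative_weight:g}, expected 0"
                )


# ---------------------------------------------------------------------------
# reading


def _find_bld(sequence: Iterable[Dataset], types: Sequence[str]) -> Dataset | None:
    for item in sequence:
        if item.RTBeamLimitingDeviceType in types:
            return item
    return None


def read_plan(path: str | Path) -> RTPlanDocument:
    """Read a DICOM RT Plan and extract every MLC-carrying beam as a VMAT arc.

    Control points are returned in file order.  Positions omitted on a
    control point (DICOM allows writing only changes) are carried forward
    from the previous one.  The MLC model is inferred from the
    leaf-position-boundary pattern declared by the beam.

    Raises
    ------
    PlanFormatError
        Not a DICOM RT Plan, or no beam carries an MLC.
    UnsupportedDeviceError
        A beam's MLC has other than 60 leaf pairs or its boundary pattern
        matches neither supported model.
    PlanIntegrityError
        Non-monotone cumulative weights or overlapping opposing leaves.
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pydicom raises several types on bad input
        raise PlanFormatError(f"{path}: not a readable DICOM file ({exc})") from exc
    sop = str(getattr(ds, "SOPClassUID", ""))
    modality = str(getattr(ds, "Modality", ""))
    if sop != RTPLAN_SOP_CLASS_UID and modality != "RTPLAN":
        raise PlanFormatError(
            f"{path}: not an RT Plan (SOP class {sop or 'missing'}, "
            f"modality {modality or 'missing'})"
        )
    if not hasattr(ds, "BeamSequence"):
        raise PlanFormatError(f"{path}: RT Plan carries no BeamSequence")

    metersets: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(rb, "BeamMeterset"):
                metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    arcs: list[VMATArc] = []
    machine_name = ""
    for beam in ds.BeamSequence:
        mlc = _find_bld(getattr(beam, "BeamLimitingDeviceSequence", []), _MLC_TYPES)
        if mlc is None:
            continue  # static or setup field without an MLC
        n_pairs = int(mlc.NumberOfLeafJawPairs)
        if n_pairs != 60:
            raise UnsupportedDeviceError(
                f"beam {beam.BeamNumber}: MLC with {2 * n_pairs} leaves is not "
                f"supported (expected 120, 60 per bank)"
            )
        boundaries = [mm_string_to_cm(str(v)) for v in mlc.LeafPositionBoundaries]
        model = infer_model(boundaries)
        machine_name = str(getattr(beam, "TreatmentMachineName", machine_name))

        control_points: list[ControlPoint] = []
        bank_a = bank_b = None
        jaws_x = jaws_y = None
        gantry = 0.0
        for k, cp in enumerate(beam.ControlPointSequence):
            for bld in cp.get("BeamLimitingDevicePositionSequence", []):
                kind = bld.RTBeamLimitingDeviceType
                vals = [mm_string_to_cm(str(v)) for v in bld.LeafJawPositions]
                if kind in _MLC_TYPES:
                    bank_a = np.array(vals[:n_pairs])
                    bank_b = np.array(vals[n_pairs:])
                elif kind in _X_JAW_TYPES:
                    jaws_x = (vals[0], vals[1])
                elif kind in _Y_JAW_TYPES:
                    jaws_y = (vals[0], vals[1])
            if "GantryAngle" in cp:
                gantry = float(cp.GantryAngle)
            if bank_a is None or bank_b is None:
                raise PlanIntegrityError(
                    f"beam {beam.BeamNumber}: no MLC positions at or before "
                    f"control point {k}"
                )
            weight = float(cp.CumulativeMetersetWeight)
            point = ControlPoint(k, bank_a.copy(), bank_b.copy(), weight, gantry,
                                 jaws_x, jaws_y)
            control_points.append(point)

        beam_number = int(beam.BeamNumber)
        arc = VMATArc(
            beam_id=str(getattr(beam, "BeamName", beam_number)),
            beam_number=beam_number,
            control_points=control_points,
            mlc_model=model,
            beam_meterset=metersets.get(beam_number),
            final_cumulative_weight=float(
                getattr(beam, "FinalCumulativeMetersetWeight", 1.0)
            ),
        )
        arcs.append(arc)

    if not arcs:
        raise PlanFormatError(f"{path}: no beam carries an MLC device")
    doc = RTPlanDocument(arcs=arcs, machine_name=machine_name, dataset=ds)
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# template preparation


def prepare_template(original: RTPlanDocument, target_machine: str) -> RTPlanDocument:
    """Copy a plan onto the transfer linac with a fresh SD MLC declaration.

    Mirrors the clinical template workflow: the machine name is replaced,
    the MLC device is re-declared with the standard-definition boundary
    list, fresh plan identifiers are generated, and every control point
    keeps its meterset weight, gantry angle and jaws while the leaf
    positions are closed (zeroed) pending adaptation.  The control-point
    count per beam always matches the original.
    """
    ds = copy.deepcopy(original.dataset)
    old_uid = str(getattr(ds, "SOPInstanceUID", "0"))
    ds.SOPInstanceUID = generate_uid(
        prefix=_UID_PREFIX, entropy_srcs=[old_uid, target_machine, "template-sop"]
    )
    if hasattr(ds, "SeriesInstanceUID"):
        ds.SeriesInstanceUID = generate_uid(
            prefix=_UID_PREFIX, entropy_srcs=[old_uid, target_machine, "template-series"]
        )
    if hasattr(ds, "file_meta"):
        ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    label = str(getattr(ds, "RTPlanLabel", "PLAN"))
    ds.RTPlanLabel = label[:12] + "_SDL"  # SH VR caps the label at 16 chars

    sd_geom = build_geometry(SD_MODEL)
    arcs: list[VMATArc] = []
    for arc in original.arcs:
        n = sd_geom.n_leaves
        closed = np.zeros(n)
        cps = [
            ControlPoint(
                cp.index,
                closed.copy(),
                closed.copy(),
                cp.cumulative_weight,
                cp.gantry_angle,
                cp.jaws_x,
                cp.jaws_y,
            )
            for cp in arc.control_points
        ]
        arcs.append(
            replace(
                arc,
                control_points=cps,
                mlc_model=SD_MODEL,
            )
        )
    template = RTPlanDocument(arcs=arcs, machine_name=str(target_machine), dataset=ds)
    _sync_dataset(template)
    return template


# ---------------------------------------------------------------------------
# writing


def _set_bld_positions(cp_item: Dataset, kind: str, values_cm: Sequence[float]) -> None:
    seq = cp_item.get("BeamLimitingDevicePositionSequence")
    if seq is None:
        cp_item.BeamLimitingDevicePositionSequence = []
        seq = cp_item.BeamLimitingDevicePositionSequence
    for item in seq:
        if item.RTBeamLimitingDeviceType == kind or (
            kind in _MLC_TYPES and item.RTBeamLimitingDeviceType in _MLC_TYPES
        ):
            item.LeafJawPositions = [cm_to_mm_string(v) for v in values_cm]
            return
    item = Dataset()
    item.RTBeamLimitingDeviceType = kind
    item.LeafJawPositions = [cm_to_mm_string(v) for v in values_cm]
    seq.append(item)


def _sync_dataset(doc: RTPlanDocument) -> None:
    """Write the arcs' delivery data into the document's dataset in place."""
    ds = doc.dataset
    arcs_by_number = {arc.beam_number: arc for arc in doc.arcs}
    for beam in ds.BeamSequence:
        arc = arcs_by_number.get(int(beam.BeamNumber))
        if arc is None:
            continue
        geom = build_geometry(arc.mlc_model)
        beam.TreatmentMachineName = doc.machine_name
        mlc = _find_bld(beam.BeamLimitingDeviceSequence, _MLC_TYPES)
        mlc.NumberOfLeafJawPairs = geom.n_leaves
        mlc.LeafPositionBoundaries = [
            cm_to_mm_string(b) for b in geom.leaf_boundaries
        ]
        cp_seq = beam.ControlPointSequence
        if len(cp_seq) != arc.n_control_points:
            raise PlanIntegrityError(
                f"beam {arc.beam_id}: dataset has {len(cp_seq)} control points "
                f"but the arc carries {arc.n_control_points}"
            )
        for item, cp in zip(cp_seq, arc.control_points):
            item.ControlPointIndex = cp.index
            item.CumulativeMetersetWeight = format_ds(cp.cumulative_weight)
            item.GantryAngle = format_ds(cp.gantry_angle)
            _set_bld_positions(
                item, "MLCX", list(cp.bank_a) + list(cp.bank_b)
            )
            if cp.jaws_x is not None:
                _set_bld_positions(item, "ASYMX", cp.jaws_x)
            if cp.jaws_y is not None:
                _set_bld_positions(item, "ASYMY", cp.jaws_y)
        beam.NumberOfControlPoints = arc.n_control_points
        beam.FinalCumulativeMetersetWeight = format_ds(
            arc.control_points[-1].cumulative_weight
            if arc.control_points
            else arc.final_cumulative_weight
        )
        if arc.beam_meterset is not None:
            for fg in getattr(ds, "FractionGroupSequence", []):
                for rb in getattr(fg, "ReferencedBeamSequence", []):
                    if int(rb.ReferencedBeamNumber) == arc.beam_number:
                        rb.BeamMeterset = format_ds(arc.beam_meterset)


def write_plan(doc: RTPlanDocument, path: str | Path) -> Path:
    """Write a plan document to a standards-valid RT Plan file.

    The document is validated first: overlapping opposing leaves or
    non-monotone cumulative weights refuse the write, naming the offending
    beam, control point and leaf.  Leaf positions and meterset weights are
    bit-exact on re-read.
    """
    doc.validate()
    out = RTPlanDocument(
        arcs=doc.arcs, machine_name=doc.machine_name, dataset=copy.deepcopy(doc.dataset)
    )
    _sync_dataset(out)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.dataset.save_as(str(path), enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# plan construction (used by the synthetic generator)


def new_plan_document(
    arcs: Sequence[VMATArc],
    machine_name: str,
    plan_label: str = "SYNTH",
    patient_id: str = "SYN0001",
    uid_entropy: str | None = None,
) -> RTPlanDocument:
    """Build a minimal, standards-valid RT Plan dataset around ``arcs``.

    UIDs are generated deterministically from ``uid_entropy`` (plus the
    label) so identical inputs produce identical files.
    """
    entropy = uid_entropy if uid_entropy is not None else plan_label
    uid = lambda tag: generate_uid(  # noqa: E731
        prefix=_UID_PREFIX, entropy_srcs=[entropy, plan_label, tag]
    )

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTPLAN_SOP_CLASS_UID
    meta.MediaStorageSOPInstanceUID = uid("sop")
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTPLAN_SOP_CLASS_UID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = uid("study")
    ds.SeriesInstanceUID = uid("series")
    ds.Modality = "RTPLAN"
    ds.Manufacturer = "vmatadapt synthetic"
    ds.PatientName = "Synthetic^Phantom"
    ds.PatientID = patient_id
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"
    ds.StudyID = "1"
    ds.SeriesNumber = 1
    ds.StudyDate = "20170101"
    ds.StudyTime = "000000"
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.OperatorsName = ""
    ds.RTPlanLabel = plan_label[:16]
    ds.RTPlanDate = "20170101"
    ds.RTPlanTime = "000000"
    ds.RTPlanGeometry = "TREATMENT_DEVICE"
    ds.ApprovalStatus = "UNAPPROVED"

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.NumberOfBeams = len(arcs)
    fg.NumberOfBrachyApplicationSetups = 0
    fg.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fg]

    ds.BeamSequence = []
    for arc in arcs:
        geom = build_geometry(arc.mlc_model)
        rb = Dataset()
        rb.ReferencedBeamNumber = arc.beam_number
        rb.BeamMeterset = format_ds(
            arc.beam_meterset if arc.beam_meterset is not None else 100.0
        )
        fg.ReferencedBeamSequence.append(rb)

        beam = Dataset()
        beam.BeamNumber = arc.beam_number
        beam.BeamName = arc.beam_id
        beam.BeamType = "DYNAMIC"
        beam.RadiationType = "PHOTON"
        beam.TreatmentMachineName = machine_name
        beam.PrimaryDosimeterUnit = "MU"
        beam.SourceAxisDistance = "1000.0"
        beam.TreatmentDeliveryType = "TREATMENT"
        beam.NumberOfWedges = 0
        beam.NumberOfCompensators = 0
        beam.NumberOfBoli = 0
        beam.NumberOfBlocks = 0
        beam.NumberOfControlPoints = arc.n_control_points
        beam.FinalCumulativeMetersetWeight = format_ds(
            arc.control_points[-1].cumulative_weight if arc.control_points else 1.0
        )

        bld_x = Dataset()
        bld_x.RTBeamLimitingDeviceType = "ASYMX"
        bld_x.NumberOfLeafJawPairs = 1
        bld_y = Dataset()
        bld_y.RTBeamLimitingDeviceType = "ASYMY"
        bld_y.NumberOfLeafJawPairs = 1
        bld_mlc = Dataset()
        bld_mlc.RTBeamLimitingDeviceType = "MLCX"
        bld_mlc.NumberOfLeafJawPairs = geom.n_leaves
        bld_mlc.LeafPositionBoundaries = [
            cm_to_mm_string(b) for b in geom.leaf_boundaries
        ]
        beam.BeamLimitingDeviceSequence = [bld_x, bld_y, bld_mlc]

        beam.ControlPointSequence = []
        for cp in arc.control_points:
            item = Dataset()
            item.ControlPointIndex = cp.index
            item.CumulativeMetersetWeight = format_ds(cp.cumulative_weight)
            item.GantryAngle = format_ds(cp.gantry_angle)
            item.GantryRotationDirection = "NONE"
            if cp.index == 0:
                item.NominalBeamEnergy = "6"
                item.DoseRateSet = "600"
                item.BeamLimitingDeviceAngle = "0.0"
                item.PatientSupportAngle = "0.0"
                item.IsocenterPosition = ["0.0", "0.0", "0.0"]
            item.BeamLimitingDevicePositionSequence = []
            _set_bld_positions(item, "MLCX", list(cp.bank_a) + list(cp.bank_b))
            if cp.jaws_x is not None:
                _set_bld_positions(item, "ASYMX", cp.jaws_x)
            if cp.jaws_y is not None:
                _set_bld_positions(item, "ASYMY", cp.jaws_y)
            beam.ControlPointSequence.append(item)
        ds.BeamSequence.append(beam)

    doc = RTPlanDocument(arcs=list(arcs), machine_name=machine_name, dataset=ds)
    doc.validate()
    return doc


def control_point_table(doc: RTPlanDocument) -> "pd.DataFrame":
    """Long-format table of every leaf position for CSV inspection dumps."""
    import pandas as pd

    rows = []
    for arc in doc.arcs:
        for cp in arc.control_points:
            for leaf in range(len(cp.bank_a)):
                rows.append(
                    {
                        "beam": arc.beam_id,
                        "control_point": cp.index,
                        "cumulative_weight": cp.cumulative_weight,
                        "gantry_angle": cp.gantry_angle,
                        "leaf_pair": leaf + 1,
                        "bank_a_cm": cp.bank_a[leaf],
                        "bank_b_cm": cp.bank_b[leaf],
                    }
                )
    return pd.DataFrame(rows)
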