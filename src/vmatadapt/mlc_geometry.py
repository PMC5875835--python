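"""Leaf-bank geometries of the two supported Varian MLC models.

Both the HD120 (high-definition) and Millennium 120 (standard-definition)
multileaf collimators carry 120 leaves, 60 per opposing bank.  They differ
in the transverse leaf-width pattern projected to isocenter:

* **HD120** — 14 outer leaves of 0.5 cm, 32 central leaves of 0.25 cm,
  14 outer leaves of 0.5 cm (bank span 22 cm).
* **Millennium 120** — 10 outer leaves of 1.0 cm, 40 central leaves of
  0.5 cm, 10 outer leaves of 1.0 cm (bank span 40 cm).

The transverse coordinate is measured in cm at isocenter, origin on the
beam axis, increasing with leaf index; each bank is centered on the axis so
the boundary list is symmetric about zero.  Leaves are indexed 1..60 from
the most negative boundary, and each leaf owns the half-open interval
``[boundary[i], boundary[i+1])`` so that every in-bank transverse position
maps to exactly one leaf.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from functools import lru_cache

from .errors import UnknownModelError

HD_MODEL = "HD120"
SD_MODEL = "Millennium120"

#: (count, width-cm) runs from the most negative boundary upward.
_WIDTH_PATTERNS: dict[str, tuple[tuple[int, float], ...]] = {
    HD_MODEL: ((14, 0.5), (32, 0.25), (14, 0.5)),
    SD_MODEL: ((10, 1.0), (40, 0.5), (10, 1.0)),
}

_ALIASES = {
    "hd120": HD_MODEL,
    "hd": HD_MODEL,
    "highdefinition": HD_MODEL,
    "millennium120": SD_MODEL,
    "millennium": SD_MODEL,
    "m120": SD_MODEL,
    "sd": SD_MODEL,
    "standarddefinition": SD_MODEL,
}

SUPPORTED_MODELS = (HD_MODEL, SD_MODEL)


def normalize_model(name: str) -> str:
    """Resolve a model name or common alias to its canonical label."""
    key = str(name).replace("-", "").replace("_", "").replace(" ", "").lower()
    try:
        return _ALIASES[key]
    except KeyError:
        raise UnknownModelError(
            f"unknown MLC model {name!r}; supported models: {', '.join(SUPPORTED_MODELS)}"
        ) from None


@dataclass(frozen=True)
class LeafBankGeometry:
    """Ordered leaf widths and boundaries for one bank of one MLC model.

    Attributes
    ----------
    model_name:
        Canonical model label (``"HD120"`` or ``"Millennium120"``).
    leaf_widths:
        One width per leaf, cm at isocenter, ordered by leaf index.
    leaf_boundaries:
        ``n_leaves + 1`` strictly increasing transverse positions (cm at
        isocenter) centered on the beam axis.
    """

    model_name: str
    leaf_widths: tuple[float, ...]
    leaf_boundaries: tuple[float, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_widths)

    @property
    def span(self) -> float:
        """Total transverse extent of the bank in cm."""
        return self.leaf_boundaries[-1] - self.leaf_boundaries[0]

    def leaf_interval(self, index: int) -> tuple[float, float]:
        """Half-open transverse interval ``[low, high)`` of a 1-based leaf index."""
        if not 1 <= index <= self.n_leaves:
            raise IndexError(f"leaf index {index} outside 1..{self.n_leaves}")
        return self.leaf_boundaries[index - 1], self.leaf_boundaries[index]

    def leaf_center(self, index: int) -> float:
        low, high = self.leaf_interval(index)
        return (low + high) / 2.0

    @property
    def leaf_centers(self) -> tuple[float, ...]:
        return tuple(self.leaf_center(i) for i in range(1, self.n_leaves + 1))


@lru_cache(maxsize=None)
def build_geometry(model_name: str) -> LeafBankGeometry:
    """Construct the leaf-bank geometry for a supported MLC model.

    The bank is placed symmetrically about the beam axis.  Widths are exact
    binary fractions (0.25/0.5/1.0 cm) so boundaries are computed without
    rounding error and the symmetry invariant holds exactly.
    """
    canonical = normalize_model(model_name)
    pattern = _WIDTH_PATTERNS[canonical]
    widths: list[float] = []
    for count, width in pattern:
        widths.extend([width] * count)
    half_span = sum(widths) / 2.0
    boundaries = [-half_span]
    for w in widths:
        boundaries.append(boundaries[-1] + w)
    return LeafBankGeometry(canonical, tuple(widths), tuple(boundaries))


def leaf_index_at(geometry: LeafBankGeometry, y: float) -> int:
    """1-based index of the leaf whose interval ``[b[i], b[i+1])`` contains ``y``.

    Raises
    ------
    ValueError
        If ``y`` lies outside ``[first boundary, last boundary)``.
    """
    b = geometry.leaf_boundaries
    if not b[0] <= y < b[-1]:
        raise ValueError(
            f"transverse position {y} cm outside the {geometry.model_name} "
            f"bank extent [{b[0]}, {b[-1]}) cm"
        )
    return bisect_right(b, y)  # interval index (0-based) + 1


def infer_model(boundaries_cm, tol: float = 1e-6) -> str:
    """Identify the MLC model whose boundary list matches ``boundaries_cm``.

    Used when reading RT Plan files: the wire format carries the boundary
    list, not the model name.  Raises :class:`UnsupportedDeviceError` when
    neither supported pattern matches within ``tol`` cm.
    """
    from .errors import UnsupportedDeviceError

    values = tuple(float(v) for v in boundaries_cm)
    for model in SUPPORTED_MODELS:
        ref = build_geometry(model).leaf_boundaries
        if len(ref) == len(values) and all(
            abs(a - b) <= tol for a, b in zip(values, ref)
        ):
            return model
    raise UnsupportedDeviceError(
        f"leaf-position boundaries ({len(values)} values) match neither "
        f"supported MLC model ({', '.join(SUPPORTED_MODELS)})"
    )
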