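"""Dose-summary comparison metrics and the clinical review-flag policy.

Dose calculation itself requires a treatment planning system and is out of
scope; this module consumes per-structure dose statistics (mean/max/min,
in Gy or %Rx — any unit consistent within a file) exported as CSV with the
schema ``structure,stat,value,plan_label`` where ``stat`` is one of
``mean``/``max``/``min``.

Metrics:

* percent difference between adapted (SDL) and original (HDL) dose,
  ``%diff = 100 × (D_SDL − D_HDL) / D_HDL`` — note the asymmetry: the
  original plan is always the baseline;
* homogeneity index of a target structure,
  ``HI = (D_max − D_min) / D_mean`` (lower is more homogeneous; HI is
  invariant under rescaling all three doses);
* the review policy: any structure whose mean or max dose changes by
  strictly more than the threshold (±10% by clinical default) is flagged
  for additional review of the adapted plan.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import MetricsError

REVIEW_THRESHOLD_PERCENT = 10.0

_STATS = ("mean", "max", "min")
_SCHEMA = ("structure", "stat", "value", "plan_label")


def percent_diff(d_sdl: float, d_hdl: float) -> float:
    """Percent difference of an adapted dose against the original baseline.

    Returns ``100 × (d_sdl − d_hdl) / d_hdl``; the baseline must be
    positive.
    """
    if not d_hdl > 0:
        raise MetricsError(
            f"baseline (original-plan) dose must be positive, got {d_hdl}"
        )
    return 100.0 * (d_sdl - d_hdl) / d_hdl


def homogeneity_index(d_max: float, d_min: float, d_mean: float) -> float:
    """Homogeneity index ``(d_max − d_min) / d_mean`` of a dose distribution."""
    if not d_mean > 0:
        raise MetricsError(f"mean dose must be positive, got {d_mean}")
    if d_max < d_min:
        raise MetricsError(f"max dose {d_max} below min dose {d_min}")
    return (d_max - d_min) / d_mean


@dataclass(frozen=True)
class StructureDoseSummary:
    """Mean/max/min dose to one structure in one plan."""

    structure: str
    d_mean: float
    d_max: float
    d_min: float
    plan_label: str = ""

    def __post_init__(self) -> None:
        if min(self.d_mean, self.d_max, self.d_min) < 0:
            raise MetricsError(f"{self.structure}: doses must be non-negative")
        if not self.d_min <= self.d_mean <= self.d_max:
            raise MetricsError(
                f"{self.structure}: require D_min <= D_mean <= D_max, got "
                f"{self.d_min}/{self.d_mean}/{self.d_max}"
            )


def _to_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        missing = set(_SCHEMA[:3]) - set(summaries.columns)
        if missing:
            raise MetricsError(f"dose-summary table lacks columns {sorted(missing)}")
        return summaries
    rows = []
    for s in summaries:
        for stat in _STATS:
            rows.append(
                {"structure": s.structure, "stat": stat,
                 "value": getattr(s, f"d_{stat}"), "plan_label": s.plan_label}
            )
    return pd.DataFrame(rows)


def read_dose_summaries(path: str | Path) -> pd.DataFrame:
    """Read a ``structure,stat,value,plan_label`` CSV of dose statistics."""
    df = pd.read_csv(path)
    missing = set(_SCHEMA[:3]) - set(df.columns)
    if missing:
        raise MetricsError(f"{path}: dose-summary CSV lacks columns {sorted(missing)}")
    bad = set(df["stat"].unique()) - set(_STATS)
    if bad:
        raise MetricsError(f"{path}: unknown stat values {sorted(bad)}")
    if (df["value"] < 0).any():
        raise MetricsError(f"{path}: doses must be non-negative")
    return df


@dataclass
class ComparisonTable:
    """Per-structure dose changes with review flags.

    ``table`` has one row per (structure, stat) present in both plans:
    original and adapted values, percent difference, and ``outside_band``
    (strictly greater than ``threshold`` in magnitude triggers review).
    ``hi_table`` lists HI per structure where all three statistics exist.
    ``unpaired`` names structures present in only one plan (excluded from
    flags).
    """

    table: pd.DataFrame
    hi_table: pd.DataFrame
    unpaired: list[str]
    threshold: float

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["outside_band"]]

    @property
    def review_required(self) -> bool:
        return bool(self.table["outside_band"].any())


def build_comparison(
    original: "pd.DataFrame | Iterable[StructureDoseSummary]",
    adapted: "pd.DataFrame | Iterable[StructureDoseSummary]",
    threshold: float = REVIEW_THRESHOLD_PERCENT,
    stats: Sequence[str] = ("mean", "max"),
) -> ComparisonTable:
    """Compare dose summaries of an original and an adapted plan.

    Percent differences are computed for ``stats`` (clinically mean and
    max), flags applied with strict inequality against ``threshold``, and
    the homogeneity index computed per structure and plan wherever all
    three statistics are available.
    """
    df_o = _to_frame(original)
    df_a = _to_frame(adapted)
    piv_o = df_o.pivot_table(index="structure", columns="stat", values="value")
    piv_a = df_a.pivot_table(index="structure", columns="stat", values="value")
    common = sorted(set(piv_o.index) & set(piv_a.index))
    unpaired = sorted(set(piv_o.index) ^ set(piv_a.index))

    rows = []
    for structure in common:
        for stat in stats:
            if stat not in piv_o.columns or stat not in piv_a.columns:
                continue
            v_o = piv_o.loc[structure, stat]
            v_a = piv_a.loc[structure, stat]
            if pd.isna(v_o) or pd.isna(v_a):
                continue
            pd_val = percent_diff(float(v_a), float(v_o))
            rows.append(
                {"structure": structure, "stat": stat, "original": float(v_o),
                 "adapted": float(v_a), "percent_diff": pd_val,
                 "outside_band": abs(pd_val) > threshold}
            )
    table = pd.DataFrame(
        rows, columns=["structure", "stat", "original", "adapted",
                       "percent_diff", "outside_band"]
    )

    hi_rows = []
    for structure in common:
        row = {"structure": structure}
        for label, piv in (("original", piv_o), ("adapted", piv_a)):
            if all(s in piv.columns and not pd.isna(piv.loc[structure, s])
                   for s in _STATS):
                row[f"hi_{label}"] = homogeneity_index(
                    float(piv.loc[structure, "max"]),
                    float(piv.loc[structure, "min"]),
                    float(piv.loc[structure, "mean"]),
                )
        if len(row) == 3:
            hi_rows.append(row)
    hi_table = pd.DataFrame(hi_rows, columns=["structure", "hi_original", "hi_adapted"])
    return ComparisonTable(table, hi_table, unpaired, float(threshold))


def cohort_summary(tables: Iterable[ComparisonTable]) -> pd.DataFrame:
    """Mean ± SD of percent differences across a set of plan pairs."""
    frames = [t.table for t in tables]
    if not frames:
        return pd.DataFrame(columns=["structure", "stat", "mean", "sd", "n"])
    allrows = pd.concat(frames, ignore_index=True)
    g = allrows.groupby(["structure", "stat"])["percent_diff"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    return out
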