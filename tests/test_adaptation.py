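"""Correspondence construction and control-point adaptation.

The brute-force oracle here re-derives the per-leaf recipe independently:
for each SD target interval it scans a fine transverse sampling, collects
the HD leaves covering those samples, and averages their positions with
equal weight in exact decimal arithmetic.  It shares no code path with
``build_correspondence``/``adapt_control_point`` beyond the geometry
tables themselves.
"""

from decimal import Decimal

import numpy as np
import pytest

from vmatadapt.adaptation import (
    AdaptationConfig,
    MapKind,
    adapt_control_point,
    adapt_plan,
    average_positions,
    build_correspondence,
)
from vmatadapt.errors import (
    CorrespondenceError,
    GapViolationError,
    PlanIntegrityError,
)
from vmatadapt.mlc_geometry import build_geometry, leaf_index_at
from vmatadapt.rtplan_io import ControlPoint
from vmatadapt.synthetic_plans import ArcRecipe, generate_arc


def oracle_adapt(cp, hd, sd, park=0.0):
    """Independent per-leaf re-derivation of the adapted banks."""
    n = sd.n_leaves
    a_out, b_out = np.empty(n), np.empty(n)
    for j in range(1, n + 1):
        lo, hi = sd.leaf_interval(j)
        samples = np.linspace(lo + 1e-6, hi - 1e-6, 25)
        src = sorted(
            {leaf_index_at(hd, y) for y in samples
             if hd.leaf_boundaries[0] <= y < hd.leaf_boundaries[-1]}
        )
        if not src:
            a_out[j - 1] = b_out[j - 1] = park
            continue
        a_out[j - 1] = float(
            sum(Decimal(repr(float(cp.bank_a[i - 1]))) for i in src) / len(src)
        )
        b_out[j - 1] = float(
            sum(Decimal(repr(float(cp.bank_b[i - 1]))) for i in src) / len(src)
        )
    return a_out, b_out


@pytest.fixture
def hd_cp(hd_geom):
    rng = np.random.default_rng(7)
    mid = np.round(rng.uniform(-4, 4, 60), 2)
    gap = np.round(rng.uniform(0.1, 3, 60), 2)
    return ControlPoint(0, mid - gap, mid + gap, 0.0, 180.0, (-5.0, 5.0), (-10.0, 10.0))


class TestCorrespondence:
    def test_partition_counts(self, correspondence):
        assert correspondence.count(MapKind.AVERAGE) == 18
        assert correspondence.count(MapKind.DIRECT) == 24
        assert correspondence.count(MapKind.CLOSED) == 18

    def test_every_hd_leaf_used_once(self, correspondence):
        used = [i for e in correspondence.entries for i in e.sources]
        assert sorted(used) == list(range(1, 61))

    def test_symmetric_about_bank_center(self, correspondence):
        entries = correspondence.entries
        for j, entry in enumerate(entries):
            mirror = entries[len(entries) - 1 - j]
            assert entry.kind is mirror.kind
            assert tuple(61 - i for i in reversed(mirror.sources)) == entry.sources

    def test_direct_entries_coincide(self, correspondence, hd_geom, sd_geom):
        for j, entry in enumerate(correspondence.entries, start=1):
            if entry.kind is MapKind.DIRECT:
                (i,) = entry.sources
                assert hd_geom.leaf_interval(i) == sd_geom.leaf_interval(j)

    def test_average_entries_tile_target(self, correspondence, hd_geom, sd_geom):
        for j, entry in enumerate(correspondence.entries, start=1):
            if entry.kind is MapKind.AVERAGE:
                i1, i2 = entry.sources
                assert i2 == i1 + 1  # transversely adjacent
                lo, hi = sd_geom.leaf_interval(j)
                assert hd_geom.leaf_interval(i1)[0] == pytest.approx(lo, abs=1e-9)
                assert hd_geom.leaf_interval(i2)[1] == pytest.approx(hi, abs=1e-9)

    def test_closed_targets_outside_hd_extent(self, correspondence):
        closed = [j + 1 for j, e in enumerate(correspondence.entries)
                  if e.kind is MapKind.CLOSED]
        assert closed == list(range(1, 10)) + list(range(52, 61))

    def test_rejects_wrong_pair(self, hd_geom, sd_geom):
        with pytest.raises(CorrespondenceError):
            build_correspondence(sd_geom, hd_geom)
        with pytest.raises(CorrespondenceError):
            build_correspondence(hd_geom, hd_geom)


class TestAdaptControlPoint:
    def test_average_is_arithmetic_mean(self, correspondence, hd_cp):
        # central pair (HD 15, 16) set to 2.0 and 3.0 on bank B
        hd_cp.bank_b[14], hd_cp.bank_b[15] = 2.0, 3.0
        hd_cp.bank_a[14] = hd_cp.bank_a[15] = -4.0
        out = adapt_control_point(hd_cp, correspondence)
        assert out.bank_b[22] == 2.5  # SD leaf 23 <- HD 15+16
        assert out.bank_a[22] == -4.0  # identity under averaging equals

    def test_direct_leaves_copied_bit_exact(self, correspondence, hd_cp):
        hd_cp.bank_b[2] = 4.7  # HD leaf 3 -> SD leaf 11, peripheral field
        hd_cp.bank_a[2] = -1.1
        out = adapt_control_point(hd_cp, correspondence)
        assert out.bank_b[10] == 4.7
        assert out.bank_a[10] == -1.1

    def test_all_closed_stays_closed(self, correspondence):
        zero = np.zeros(60)
        cp = ControlPoint(0, zero.copy(), zero.copy(), 0.0, 0.0)
        out = adapt_control_point(cp, correspondence)
        assert np.all(out.gaps == 0.0)

    def test_metadata_copied(self, correspondence, hd_cp):
        out = adapt_control_point(hd_cp, correspondence)
        assert out.cumulative_weight == hd_cp.cumulative_weight
        assert out.gantry_angle == hd_cp.gantry_angle
        assert out.jaws_x == hd_cp.jaws_x and out.jaws_y == hd_cp.jaws_y

    def test_closed_targets_park_behind_jaw(self, correspondence, hd_cp):
        out = adapt_control_point(hd_cp, correspondence)
        assert np.all(out.bank_a[:9] == hd_cp.jaws_x[0])
        assert np.all(out.gaps[:9] == 0.0)
        out2 = adapt_control_point(
            hd_cp, correspondence, AdaptationConfig(park_position=-14.0)
        )
        assert np.all(out2.bank_b[51:] == -14.0)

    def test_wrong_structure_rejected(self, correspondence):
        cp = ControlPoint(0, np.zeros(40), np.zeros(40), 0.0, 0.0)
        with pytest.raises(PlanIntegrityError, match="40 leaf pairs"):
            adapt_control_point(cp, correspondence)

    def test_min_gap_fails_loudly(self, correspondence):
        a = np.zeros(60)
        b = np.zeros(60)
        # staggered nearly-closed central pair: gaps 0.02 at offset positions
        a[14], b[14] = 0.0, 0.02
        a[15], b[15] = 1.0, 1.02
        cp = ControlPoint(0, a, b, 0.0, 0.0)
        cfg = AdaptationConfig(min_gap=0.05)
        with pytest.raises(GapViolationError, match="SD leaf 23"):
            adapt_control_point(cp, correspondence, cfg)

    def test_min_gap_repair_opens_symmetrically(self, correspondence):
        a = np.zeros(60)
        b = np.zeros(60)
        a[14], b[14] = 0.0, 0.02
        a[15], b[15] = 1.0, 1.02
        cp = ControlPoint(0, a, b, 0.0, 0.0)
        repairs = []
        out = adapt_control_point(
            cp, correspondence,
            AdaptationConfig(min_gap=0.05, gap_policy="repair"), repairs
        )
        assert out.gaps[22] == pytest.approx(0.05, abs=1e-12)
        assert (out.bank_a[22] + out.bank_b[22]) / 2 == pytest.approx(0.51, abs=1e-12)
        assert repairs and repairs[0]["leaf"] == 23

    def test_exactly_closed_pairs_exempt_from_min_gap(self, correspondence):
        zero = np.zeros(60)
        cp = ControlPoint(0, zero.copy(), zero.copy(), 0.0, 0.0)
        out = adapt_control_point(cp, correspondence, AdaptationConfig(min_gap=0.05))
        assert np.all(out.gaps == 0.0)


class TestOracleEquivalence:
    def test_random_apertures_match_bruteforce(self, correspondence, hd_geom, sd_geom):
        rng = np.random.default_rng(42)
        for _ in range(50):
            mid = np.round(rng.uniform(-5, 5, 60), 2)
            gap = np.round(rng.uniform(0.0, 4, 60), 2)
            cp = ControlPoint(0, mid - gap, mid + gap, 0.0, 0.0)
            out = adapt_control_point(
                cp, correspondence, AdaptationConfig(park_position=0.0)
            )
            oa, ob = oracle_adapt(cp, hd_geom, sd_geom, park=0.0)
            np.testing.assert_array_equal(out.bank_a, oa)
            np.testing.assert_array_equal(out.bank_b, ob)


class TestAdaptPlan:
    def test_structure_preserved(self, fixture_docs):
        doc = fixture_docs["hd_random"]
        adapted, prov = adapt_plan(doc, "SDL-2")
        assert len(adapted.arcs) == len(doc.arcs)
        for src, out in zip(doc.arcs, adapted.arcs):
            assert out.n_control_points == src.n_control_points
            assert out.mlc_model == "Millennium120"
            np.testing.assert_array_equal(out.weights(), src.weights())
            np.testing.assert_array_equal(out.gantry_angles(), src.gantry_angles())
        assert prov["correspondence"]["direct"] == 24
        assert prov["arcs"][0]["n_control_points"] == doc.arcs[0].n_control_points

    def test_rejects_already_adapted_plan(self, fixture_docs):
        adapted, _ = adapt_plan(fixture_docs["hd_ellipse"], "SDL-2")
        with pytest.raises(PlanIntegrityError, match="Millennium120"):
            adapt_plan(adapted, "SDL-3")

    def test_provenance_records_policies(self, fixture_docs):
        cfg = AdaptationConfig(park_position=-10.0, min_gap=0.05,
                               gap_policy="repair")
        _, prov = adapt_plan(fixture_docs["hd_ellipse"], "SDL-2", cfg)
        assert prov["config"] == {"park_position": -10.0, "min_gap": 0.05,
                                  "gap_policy": "repair"}


def test_average_positions_decimal_exact():
    assert average_positions(2.0, 3.0) == 2.5
    assert average_positions(0.1, 0.2) == 0.15
    assert average_positions(-1.83, -0.57) == -1.2
    x = 3.17
    assert average_positions(x, x) == x
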