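"""Unit and property tests for the MLC transmission / fluence model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mlcsim import (Aperture, Beam, GridSpec, Jaws, LeafGeometry,
                    MLCParameters, OffsetModel, Plan, Segment,
                    compute_plan_fluence, compute_segment_fluence,
                    evaluate_tip_position, fit_offset_model,
                    point_transmission)
from mlcsim.errors import AnalysisError, DataError
from mlcsim.fluence import compute_composite_fluence
from mlcsim.synth import make_offset_table


class TestOffsetModel:
    def test_quadratic_vanishes_at_origin(self, offset_model):
        assert evaluate_tip_position(offset_model, 0.0) == 0.0

    def test_printed_curve_at_full_travel(self, offset_model):
        # 20 + 0.0008 * 400
        assert evaluate_tip_position(offset_model, 20.0) == pytest.approx(20.32)

    def test_offset_magnitude_bounded_over_travel(self, offset_model):
        x = np.linspace(-20, 20, 401)
        off = np.abs(evaluate_tip_position(offset_model, x) - x)
        assert np.all(off <= 0.35)
        assert off.max() == pytest.approx(0.32)

    def test_out_of_range_position_rejected(self, offset_model):
        with pytest.raises(DataError):
            evaluate_tip_position(offset_model, 25.0)

    def test_noiseless_fit_recovers_exactly(self, offset_model):
        table = make_offset_table(offset_model, noise_sigma=0.0)
        fit = fit_offset_model(table)
        assert fit.model.curvature == pytest.approx(0.0008, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_table(self):
        fit = fit_offset_model([(x, 0.1) for x in range(-20, 21)])
        assert fit.model.offset == pytest.approx(0.1, abs=1e-9)
        assert fit.model.gain == pytest.approx(0.0, abs=1e-12)
        assert fit.model.curvature == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c0=st.floats(-0.1, 0.1), c1=st.floats(-0.005, 0.005),
           c2=st.floats(0.0, 0.001))
    def test_fit_recovers_any_quadratic(self, c0, c1, c2):
        model = OffsetModel(c0, c1, c2)
        fit = fit_offset_model(make_offset_table(model, noise_sigma=0.0))
        assert fit.model.offset == pytest.approx(c0, abs=1e-9)
        assert fit.model.gain == pytest.approx(c1, abs=1e-9)
        assert fit.model.curvature == pytest.approx(c2, abs=1e-10)

    def test_rank_deficient_table_rejected(self):
        with pytest.raises(DataError):
            fit_offset_model([(0.0, 0.0), (0.0, 0.1), (1.0, 0.2)])


class TestPointTransmission:
    def test_open_tip_band_and_leaf_body(self, params, zero_offset):
        pair = (-5.0, 5.0)
        assert point_transmission(pair, params, zero_offset, 0.0) == 1.0
        assert point_transmission(pair, params, zero_offset, -5.15) == \
            pytest.approx(np.sqrt(0.025))
        assert point_transmission(pair, params, zero_offset, -10.0) == \
            pytest.approx(0.025)

    def test_half_open_boundaries(self, params, zero_offset):
        pair = (-5.0, 5.0)
        # the tip position itself belongs to the band, not the open field
        assert point_transmission(pair, params, zero_offset, -5.0) == \
            pytest.approx(params.tip_transmission)
        assert point_transmission(pair, params, zero_offset, 5.0) == \
            pytest.approx(params.tip_transmission)

    def test_abutted_pair_has_no_open_point(self, params, zero_offset):
        x = np.linspace(-1, 1, 101)
        vals = point_transmission((0.0, 0.0), params, zero_offset, x)
        assert np.all(vals < 1.0)
        assert np.all(vals >= params.transmission)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(-15, 5), width=st.floats(0, 15), x=st.floats(-20, 20),
           w=st.floats(0, 1), t=st.floats(0.005, 0.1))
    def test_bounded_between_t_and_one(self, a, width, x, w, t):
        p = MLCParameters(leaf_tip_width=w, transmission=t, tng_width=0.05)
        v = point_transmission((a, a + width), p, OffsetModel(), x)
        assert t - 1e-12 <= v <= 1.0 + 1e-12


class TestSegmentFluence:
    def test_open_field_interior_is_unity(self, params, zero_offset, geometry,
                                          small_grid):
        p = MLCParameters(leaf_tip_width=params.leaf_tip_width,
                          transmission=params.transmission, tng_width=0.0)
        ap = Aperture.rectangle(5.0, 5.0, geometry, jaws=Jaws(5, 5, 5, 5))
        f = compute_segment_fluence(ap, p, zero_offset, geometry, small_grid)
        xx, yy = np.meshgrid(small_grid.x, small_grid.y)
        interior = (np.abs(xx) < 4.0) & (np.abs(yy) < 4.0)
        assert np.allclose(f.values[interior], 1.0)

    def test_asymmetric_field_edges_at_tip_positions(self, params, offset_model,
                                                     geometry):
        # (X1=18, X2=0): leaf ends at -18 and 0; tips via the offset quadratic
        grid = GridSpec.centered(44.0, 12.0, 0.2)
        ap = Aperture.rectangle(18.0, 0.0, geometry, jaws=Jaws(20, 20, 20, 20))
        f = compute_segment_fluence(ap, params, offset_model, geometry, grid)
        row = f.values[grid.ny // 2]
        half = 0.5 * row.max()
        x = grid.x
        tip_left = -18.0 + 0.0008 * (-18.0) ** 2
        tip_right = 0.0
        win = (x > tip_left - 1) & (x < tip_left + 1)
        left_cross = np.interp(half, row[win], x[win])
        win_r = (x > tip_right - 1) & (x < tip_right + 1)
        right_cross = np.interp(half, row[win_r][::-1], x[win_r][::-1])
        assert left_cross == pytest.approx(tip_left, abs=0.5 * grid.spacing)
        assert right_cross == pytest.approx(tip_right, abs=0.5 * grid.spacing)

    def test_bounds_and_floor_inside_jaws(self, params, offset_model, geometry,
                                          small_grid):
        ap = Aperture.rectangle(8.0, 3.0, geometry, jaws=Jaws(20, 20, 20, 20))
        f = compute_segment_fluence(ap, params, offset_model, geometry,
                                    small_grid)
        assert np.all(f.values >= 0.0) and np.all(f.values <= 1.0)
        assert np.all(f.values >= params.transmission - 1e-12)

    def test_mirror_symmetry(self, params, offset_model, geometry, small_grid):
        rng = np.random.default_rng(7)
        a = rng.uniform(-6, 0, geometry.n_pairs)
        b = a + rng.uniform(0.5, 5, geometry.n_pairs)
        ap = Aperture(a, b, jaws=Jaws(8, 8, 8, 8))
        f = compute_segment_fluence(ap, params, offset_model, geometry,
                                    small_grid)
        fm = compute_segment_fluence(ap.mirrored(), params, offset_model,
                                     geometry, small_grid)
        assert np.allclose(f.values, fm.values[:, ::-1], atol=1e-12)

    def test_tip_width_monotonicity(self, offset_model, geometry, small_grid):
        ap = Aperture.rectangle(5.0, 5.0, geometry, jaws=Jaws(10, 10, 10, 10))
        prev = None
        for w in (0.1, 0.2, 0.3, 0.4):
            p = MLCParameters(leaf_tip_width=w, transmission=0.025,
                              tng_width=0.0)
            f = compute_segment_fluence(ap, p, offset_model, geometry,
                                        small_grid).values
            if prev is not None:
                assert np.all(f >= prev - 1e-12)
            prev = f

    def test_tng_band_only_at_aperture_periphery(self, zero_offset, geometry):
        # pair boundaries at 0.5 cm multiples; 1 mm grid resolves a 0.1 cm band
        grid = GridSpec.centered(16.0, 8.0, 0.1)
        p = MLCParameters(leaf_tip_width=0.0, transmission=0.04, tng_width=0.1)
        n = geometry.n_pairs
        a = np.full(n, -5.0)
        b = np.full(n, 5.0)
        # central pair opens wider than its neighbors -> its leaf edges at the
        # periphery acquire sqrt(T) bands where neighbors cover x
        mid = n // 2
        a[mid], b[mid] = -7.0, 7.0
        f = compute_segment_fluence(Aperture(a, b, Jaws(10, 10, 10, 10)), p,
                                    zero_offset, geometry, grid)
        # the wide pair spans y in [0, 0.5); its T&G bands hug those edges
        row_band = f.values[np.argmin(np.abs(grid.y - 0.05))]
        row_center = f.values[np.argmin(np.abs(grid.y - 0.25))]
        x = grid.x
        flank = (x > -6.8) & (x < -5.2)  # open for mid pair, covered by neighbor
        assert np.all(row_band[flank] < 1.0)
        assert np.all(row_center[flank] == pytest.approx(1.0))

    def test_no_tng_where_neighbors_share_the_opening(self, zero_offset,
                                                      geometry):
        grid = GridSpec.centered(16.0, 8.0, 0.1)
        p = MLCParameters(leaf_tip_width=0.0, transmission=0.04, tng_width=0.1)
        ap = Aperture.rectangle(5.0, 5.0, geometry, Jaws(10, 10, 10, 10))
        f = compute_segment_fluence(ap, p, zero_offset, geometry, grid)
        xx, yy = np.meshgrid(grid.x, grid.y)
        interior = (np.abs(xx) < 4.5) & (np.abs(yy) < 3.5)
        assert np.allclose(f.values[interior], 1.0)

    def test_no_tng_against_closed_neighbor(self, zero_offset, geometry):
        grid = GridSpec.centered(16.0, 8.0, 0.1)
        p = MLCParameters(leaf_tip_width=0.0, transmission=0.04, tng_width=0.1)
        n = geometry.n_pairs
        a = np.full(n, 2.0)   # all pairs closed (abutted at x=2)
        b = np.full(n, 2.0)
        mid = n // 2
        a[mid], b[mid] = -5.0, 5.0
        f = compute_segment_fluence(Aperture(a, b, Jaws(10, 10, 10, 10)), p,
                                    zero_offset, geometry, grid)
        row = f.values[np.argmin(np.abs(grid.y - 0.05))]
        open_x = (grid.x > -4.5) & (grid.x < 1.5)
        assert np.allclose(row[open_x], 1.0)

    def test_aperture_geometry_mismatch(self, params, zero_offset, geometry,
                                        small_grid):
        ap = Aperture(np.full(10, -3.0), np.full(10, 3.0))
        with pytest.raises(DataError):
            compute_segment_fluence(ap, params, zero_offset, geometry,
                                    small_grid)


class TestPlanFluence:
    def _plan(self, geometry, weights):
        ap = Aperture.rectangle(4.0, 4.0, geometry, Jaws(5, 5, 5, 5))
        segs = tuple(Segment(aperture=ap, mu=w) for w in weights)
        return Plan(beams=(Beam(segments=segs),))

    def test_single_segment_matches_segment_fluence(self, params, zero_offset,
                                                    geometry, small_grid):
        plan = self._plan(geometry, [3.0])
        f_plan = compute_plan_fluence(plan, params, zero_offset, geometry,
                                      small_grid)[0]
        ap = plan.beams[0].segments[0].aperture
        f_seg = compute_segment_fluence(ap, params, zero_offset, geometry,
                                        small_grid)
        assert np.allclose(f_plan.values, f_seg.values)

    def test_mu_linearity(self, params, zero_offset, geometry, small_grid):
        two = self._plan(geometry, [1.0, 1.0])
        one = self._plan(geometry, [2.0])
        fa = compute_plan_fluence(two, params, zero_offset, geometry,
                                  small_grid)[0]
        fb = compute_plan_fluence(one, params, zero_offset, geometry,
                                  small_grid)[0]
        assert np.allclose(fa.values, fb.values)

    def test_mu_scale_invariance(self, params, offset_model, geometry,
                                 small_grid):
        from mlcsim.synth import make_random_plan
        plan = make_random_plan(n_beams=2, n_segments=10, seed=11,
                                geometry=geometry)
        scaled = Plan(beams=tuple(
            Beam(segments=tuple(Segment(s.aperture, 2.0 * s.mu)
                                for s in beam.segments), name=beam.name)
            for beam in plan.beams))
        f1 = compute_composite_fluence(plan, params, offset_model, geometry,
                                       small_grid)
        f2 = compute_composite_fluence(scaled, params, offset_model, geometry,
                                       small_grid)
        assert np.allclose(f1.values, f2.values, atol=1e-12)

    def test_zero_mu_plan_rejected(self, params, zero_offset, geometry,
                                   small_grid):
        plan = self._plan(geometry, [0.0])
        with pytest.raises(AnalysisError):
            compute_plan_fluence(plan, params, zero_offset, geometry,
                                 small_grid)


class TestValidation:
    def test_crossed_banks_rejected(self):
        with pytest.raises(DataError):
            Aperture(np.array([1.0]), np.array([0.0]))

    def test_transmission_fraction_validated(self):
        with pytest.raises(DataError):
            MLCParameters(transmission=1.5)
        with pytest.raises(DataError):
            MLCParameters(leaf_tip_width=-0.1)

    def test_tip_transmission_exceeds_body(self, params):
        assert params.tip_transmission > params.transmission
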