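"""Fluence rendering: closed forms, brute-force oracle, invariances."""

import numpy as np
import pytest

from dynaqa import (
    compute_fluence,
    expand_opening,
    fluence_difference,
    make_sliding_window_plan,
)
from dynaqa.fluence import (
    FluenceMap,
    _pair_row_weights,
    read_fluence_csv,
    write_fluence_csv,
)

from conftest import static_beam


def brute_force_fluence(beam, spacing_mm=2.0, n_sub=1000):
    """Independent renderer: midpoint time-subsampling of the aperture
    coverage (x area-weighted per substep), same pair-row weighting."""
    g = beam.geometry
    x = np.arange(-200.0, 200.0 + spacing_mm / 2, spacing_mm)
    y = np.arange(-g.total_width_mm / 2, g.total_width_mm / 2 + spacing_mm / 2, spacing_mm)
    h = spacing_mm
    xl, xr = x - h / 2, x + h / 2
    tips = beam.tip_array()
    idx = beam.indices
    dmu = np.diff(idx) * beam.total_mu
    s = (np.arange(n_sub) + 0.5) / n_sub
    row = np.zeros((g.n_pairs, len(x)))
    for j in range(len(dmu)):
        if dmu[j] <= 0:
            continue
        a = tips[j, 0][None, :] + s[:, None] * (tips[j + 1, 0] - tips[j, 0])[None, :]
        b = tips[j, 1][None, :] + s[:, None] * (tips[j + 1, 1] - tips[j, 1])[None, :]
        for k in range(g.n_pairs):
            cov = np.clip(
                (np.minimum(b[:, k][:, None], xr) - np.maximum(a[:, k][:, None], xl)) / h,
                0.0,
                1.0,
            )
            row[k] += dmu[j] * cov.mean(axis=0)
    return _pair_row_weights(g, y).T @ row


def test_static_rectangle_closed_form(open_square_beam):
    """Static aperture: MU inside, 0 outside, area-weighted at the edges."""
    f = compute_fluence(open_square_beam, spacing_mm=1.0)
    X, Y = np.meshgrid(f.x_mm, f.y_mm)
    inside = (np.abs(X) <= 49.0) & (np.abs(Y) <= 49.0)
    outside = (np.abs(X) >= 51.0) | (np.abs(Y) >= 51.0)
    np.testing.assert_allclose(f.values[inside], 100.0, atol=1e-9)
    np.testing.assert_allclose(f.values[outside], 0.0, atol=1e-9)
    # the +-50 mm edge bisects its 1 mm pixel
    iy = np.argmin(np.abs(f.y_mm))
    ix = np.argmin(np.abs(f.x_mm - 50.0))
    assert f.values[iy, ix] == pytest.approx(50.0, abs=1e-9)


def test_sliding_window_interior_matches_analytic(ramp_beam):
    """Constant gap g sweeping a length L at constant speed gives interior
    fluence MU x g / L (here 100 x 12 / 120 = 10 MU)."""
    f = compute_fluence(ramp_beam, spacing_mm=1.0)
    X, Y = np.meshgrid(f.x_mm, f.y_mm)
    interior = (np.abs(X) <= 50.0) & (np.abs(Y) <= 45.0)
    np.testing.assert_allclose(f.values[interior], 10.0, atol=1e-9)


def test_exact_integration_matches_brute_force_oracle():
    """Analytic crossing-time integration vs 1000-substep rendering."""
    for seed in (3, 4):
        beam = make_sliding_window_plan(1, "random", seed=seed).beams[0]
        f = compute_fluence(beam, spacing_mm=2.0)
        brute = brute_force_fluence(beam, spacing_mm=2.0, n_sub=1000)
        err = np.max(np.abs(f.values - brute)) / f.values.max()
        assert err <= 1e-3


def test_integral_invariant_under_control_point_refinement(random_beam):
    from dynaqa import ControlPoint

    cps = list(random_beam.control_points)
    refined = [cps[0]]
    for a, b in zip(cps, cps[1:]):
        refined.append(
            ControlPoint(
                index=0.5 * (a.index + b.index),
                bank_a=0.5 * (a.bank_a + b.bank_a),
                bank_b=0.5 * (a.bank_b + b.bank_b),
            )
        )
        refined.append(b)
    doubled = random_beam.with_control_points(refined)
    f1 = compute_fluence(random_beam, spacing_mm=1.0)
    f2 = compute_fluence(doubled, spacing_mm=1.0)
    assert f1.integral() == pytest.approx(f2.integral(), rel=1e-12)
    np.testing.assert_allclose(f1.values, f2.values, atol=1e-9)


def test_integral_fluence_increases_with_opening_expansion(random_beam):
    integrals = [
        compute_fluence(expand_opening(random_beam, mm), spacing_mm=2.0).integral()
        for mm in (0.0, 1.0, 2.0, 4.0)
    ]
    assert integrals == sorted(integrals)
    assert all(b > a for a, b in zip(integrals, integrals[1:]))


def test_transmission_floor(open_square_beam):
    f = compute_fluence(open_square_beam, spacing_mm=2.0, transmission=0.02)
    # rows fully covered by leaves see at least the transmitted fraction
    # (the outermost rows straddle the end of the leaf span)
    covered = np.abs(f.y_mm) <= 195.0
    assert f.values[covered, :].min() >= 0.02 * 100.0 - 1e-9
    assert f.values.max() <= 100.0 + 1e-9


def test_fluence_values_bounded_by_total_mu(random_beam):
    f = compute_fluence(random_beam, spacing_mm=1.0)
    assert f.values.min() >= 0.0
    assert f.values.max() <= random_beam.total_mu + 1e-9


def test_difference_map_and_summary(ramp_beam):
    f = compute_fluence(ramp_beam, spacing_mm=2.0)
    diff, summary = fluence_difference(f, f)
    np.testing.assert_allclose(diff, 0.0)
    assert summary["max_abs"] == 0.0
    a = FluenceMap(values=np.full((4, 4), 10.0), x_mm=np.arange(4.0), y_mm=np.arange(4.0))
    b = FluenceMap(values=np.full((4, 4), 7.0), x_mm=np.arange(4.0), y_mm=np.arange(4.0))
    diff, summary = fluence_difference(a, b)
    np.testing.assert_allclose(diff, 3.0)
    assert summary["mean_abs"] == pytest.approx(3.0)
    c = FluenceMap(values=np.zeros((3, 3)), x_mm=np.arange(3.0), y_mm=np.arange(3.0))
    with pytest.raises(ValueError, match="grid"):
        fluence_difference(a, c)


def test_bank_shift_difference_confined_to_moving_edges(ramp_beam):
    """A 0.5 mm bank-A shift changes fluence only near positions swept by
    the A leaf edge; verified against the brute-force renderer."""
    from dynaqa import shift_bank

    shifted = shift_bank(ramp_beam, "A", 0.5)
    f0 = compute_fluence(ramp_beam, spacing_mm=2.0)
    f1 = compute_fluence(shifted, spacing_mm=2.0)
    diff, summary = fluence_difference(f1, f0)
    assert summary["max_abs"] > 0
    brute = brute_force_fluence(shifted, spacing_mm=2.0, n_sub=1000)
    assert np.max(np.abs(f1.values - brute)) / f1.values.max() <= 1e-3
    # far from the sweep range and the parked-pair slivers nothing changes
    far = np.abs(f0.x_mm) > 75.0
    np.testing.assert_allclose(diff[:, far], 0.0, atol=1e-12)


def test_spacing_validation(random_beam):
    with pytest.raises(ValueError, match="spacing"):
        compute_fluence(random_beam, spacing_mm=0.01)


def test_csv_round_trip(tmp_path, ramp_beam):
    f = compute_fluence(ramp_beam, spacing_mm=2.0)
    path = tmp_path / "f.csv"
    write_fluence_csv(f, path)
    back = read_fluence_csv(path)
    assert back.same_grid(f)
    np.testing.assert_allclose(back.values, f.values, rtol=1e-6)
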