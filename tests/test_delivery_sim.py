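"""Delivery simulator and fixture generators."""

import numpy as np
import pytest

from dynaqa import (
    ErrorModel,
    compare_sequences,
    make_phantom,
    make_sliding_window_plan,
    reconstruct_beam,
    simulate_delivery,
)

from conftest import static_beam


def test_snapshot_count_from_dose_rate():
    """100 MU at 600 MU/min lasts 10 s: about 182 55-ms samples."""
    beam = static_beam(-20.0, 20.0, pairs=slice(25, 35), total_mu=100.0)
    res = simulate_delivery(beam, 600.0, seed=0)
    n = len(res.record.bank_a_log.snapshots)
    assert abs(n - 10.0 / 0.055) <= 2
    assert res.record.complete


def test_same_seed_reproduces_delivery(random_beam):
    model = ErrorModel(jitter_sd_mm=0.2)
    r1 = simulate_delivery(random_beam, 300.0, model, seed=42)
    r2 = simulate_delivery(random_beam, 300.0, model, seed=42)
    np.testing.assert_array_equal(
        r1.record.positions("recorded"), r2.record.positions("recorded")
    )
    np.testing.assert_array_equal(r1.record.dose_indices(), r2.record.dose_indices())


def test_zero_error_recorded_equals_planned(random_beam):
    res = simulate_delivery(random_beam, 300.0, ErrorModel(), seed=1, quantize=False)
    planned = res.record.positions("planned")
    recorded = res.record.positions("recorded")
    # planned is written at 0.01 mm resolution; recorded kept exact here
    assert np.max(np.abs(planned - recorded)) <= 0.005 + 1e-12


def test_recorded_quantization_bound(random_beam):
    res = simulate_delivery(random_beam, 300.0, ErrorModel(jitter_sd_mm=0.17), seed=2)
    recorded = res.record.positions("recorded")
    lattice = np.round(recorded / 0.1) * 0.1
    np.testing.assert_allclose(recorded, lattice, atol=1e-9)


def test_segment_stream_matches_control_point_intervals(random_beam):
    res = simulate_delivery(random_beam, 300.0, seed=3)
    seg = res.record.segments()
    frac = res.record.dose_indices() / 25000
    idx = random_beam.indices
    expect = np.clip(np.searchsorted(idx, frac, side="right") - 1, 0, len(idx) - 2)
    np.testing.assert_array_equal(seg, expect)


def test_error_free_round_trip_through_simulator(random_beam):
    res = simulate_delivery(random_beam, 300.0, ErrorModel(), seed=4)
    recon = reconstruct_beam(res.record, mode="planned", total_mu=random_beam.total_mu)
    assert compare_sequences(random_beam, recon).max() <= 0.01


def test_beam_holds_pause_dose_accumulation(random_beam):
    """Jitter beyond the hold tolerance produces held samples whose dose
    index repeats; the delivery still completes."""
    model = ErrorModel(jitter_sd_mm=0.4)
    res = simulate_delivery(
        random_beam, 300.0, model, seed=5, hold_tolerance_mm=1.0
    )
    on = res.record.beam_on()
    assert (~on).sum() > 0
    di = res.record.dose_indices()
    held_next = np.flatnonzero(~on[:-1]) + 1
    np.testing.assert_array_equal(di[held_next], di[held_next - 1])
    assert res.record.complete


def test_persistent_hold_raises(random_beam):
    with pytest.raises(RuntimeError, match="stalled"):
        simulate_delivery(
            random_beam, 300.0, ErrorModel(offset_a_mm=-5.0), seed=6,
            hold_tolerance_mm=2.0,
        )


def test_closed_pairs_stay_closed_under_jitter():
    """Abutting pairs get common-mode jitter: no interpenetration and no
    phantom aperture from noise."""
    beam = static_beam(-30.0, 30.0, pairs=slice(25, 35))  # others closed at 0
    res = simulate_delivery(
        beam, 600.0, ErrorModel(jitter_sd_mm=0.3), seed=7, quantize=False
    )
    rec = res.record.positions("recorded")
    closed = np.ones(60, dtype=bool)
    closed[25:35] = False
    gaps = rec[:, 1, closed] - rec[:, 0, closed]
    np.testing.assert_allclose(gaps, 0.0, atol=1e-12)


def test_error_model_validation(random_beam):
    with pytest.raises(ValueError, match="finite"):
        simulate_delivery(random_beam, 300.0, ErrorModel(offset_a_mm=np.nan))
    with pytest.raises(ValueError, match="dose_rate"):
        simulate_delivery(random_beam, 0.0)


def test_plan_generator_presets_and_determinism():
    p1 = make_sliding_window_plan(5, "random", seed=9)
    p2 = make_sliding_window_plan(5, "random", seed=9)
    assert len(p1.beams) == 5
    assert [b.gantry_angle for b in p1.beams] == [0.0, 72.0, 144.0, 216.0, 288.0]
    np.testing.assert_array_equal(p1.beams[2].tip_array(), p2.beams[2].tip_array())
    with pytest.raises(ValueError, match="preset"):
        make_sliding_window_plan(1, "bogus")


def test_generated_plans_are_leaf_speed_feasible():
    """Tip travel per unit meterset fraction stays below 300 mm, i.e.
    under 25 mm/s for 100 MU delivered at 300 MU/min."""
    for preset in ("ramp", "pyramid", "random"):
        beam = make_sliding_window_plan(1, preset, seed=13).beams[0]
        tips = beam.tip_array()
        df = np.diff(beam.indices)[:, None, None]
        speed = np.abs(np.diff(tips, axis=0)) / df
        assert speed.max() <= 300.0


def test_phantom_masks():
    phantom, masks = make_phantom()
    assert phantom.density.shape == (100, 100, 100)
    vox = [m.voxels for m in masks.values()]
    for v in vox:
        assert v.any()
    # pairwise disjoint
    assert not np.any(vox[0] & vox[1])
    assert not np.any(vox[0] & vox[2])
    assert not np.any(vox[1] & vox[2])
    iso = tuple(s // 2 for s in phantom.shape)
    assert masks["target"].voxels[iso]
    with pytest.raises(ValueError, match="preset"):
        make_phantom("bogus")
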