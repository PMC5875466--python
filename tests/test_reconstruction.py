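"""Log-to-sequence reconstruction: interpolation, round trips, recovery."""

import numpy as np
import pytest

from dynaqa import (
    ControlPoint,
    DynamicBeam,
    ErrorModel,
    compare_sequences,
    make_sliding_window_plan,
    millennium120,
    reconstruct_beam,
    shift_bank,
    simulate_delivery,
)
from dynaqa.dynalog import SAMPLE_INTERVAL_MS, DeliveryLog, DeliveryRecord, LogSnapshot
from dynaqa.reconstruct import IncompleteDeliveryError


def _record_from_streams(fractions, segments, leaf0_positions):
    """Minimal record: leaf 1 follows the given positions, others at 0."""
    n = 60
    logs = []
    for bank in ("A", "B"):
        snaps = []
        for i, (f, s, p) in enumerate(zip(fractions, segments, leaf0_positions)):
            pos = np.zeros(n)
            pos[0] = p if bank == "B" else 0.0  # keep tipA <= tipB
            snaps.append(
                LogSnapshot(
                    time_ms=i * SAMPLE_INTERVAL_MS,
                    dose_index=int(round(f * 25000)),
                    segment=s,
                    beam_on=True,
                    planned_positions=pos,
                    recorded_positions=pos.copy(),
                )
            )
        logs.append(DeliveryLog(field_id="f", bank=bank, snapshots=snaps))
    return DeliveryRecord(bank_a_log=logs[0], bank_b_log=logs[1])


def test_boundary_interpolation_hand_example():
    """Snapshots at fractions 0.4/0.6 with a leaf at 10/12 mm around a
    segment boundary at 0.5 interpolate to 11.0 mm (motion at 5 mm per
    unit fraction on both sides)."""
    record = _record_from_streams(
        fractions=[0.0, 0.4, 0.6, 1.0],
        segments=[0, 0, 1, 1],
        leaf0_positions=[8.0, 10.0, 12.0, 14.0],
    )
    beam = reconstruct_beam(record, mode="actual", total_mu=100.0)
    mid = [cp for cp in beam.control_points if 0 < cp.index < 1]
    assert len(mid) == 1
    assert mid[0].index == pytest.approx(0.5)
    assert mid[0].bank_b[0] == pytest.approx(11.0, abs=1e-9)


def test_static_field_reconstructs_identical_apertures():
    record = _record_from_streams(
        fractions=[0.0, 0.3, 0.5, 0.8, 1.0],
        segments=[0, 0, 1, 1, 1],
        leaf0_positions=[25.0] * 5,
    )
    beam = reconstruct_beam(record, mode="planned", total_mu=50.0)
    for cp in beam.control_points:
        assert cp.bank_b[0] == pytest.approx(25.0, abs=1e-9)
        assert cp.bank_a[1:] == pytest.approx(0.0)


@pytest.mark.parametrize("preset", ["ramp", "random"])
def test_planned_mode_round_trip_within_file_quantum(preset):
    """Error-free delivery + planned-mode reconstruction reproduces the
    planned sequence to within the 0.01 mm position resolution."""
    beam = make_sliding_window_plan(1, preset, seed=21).beams[0]
    res = simulate_delivery(beam, 300.0, ErrorModel(), seed=3)
    recon = reconstruct_beam(res.record, mode="planned", total_mu=beam.total_mu)
    assert compare_sequences(beam, recon).max() <= 0.01


def test_actual_mode_recovers_systematic_bank_offset():
    """A delivery whose bank-A leaves sat 0.5 mm outward reconstructs to
    the bank-shifted sequence within the recording precision.

    The bound is the 0.05 mm quantization half-step (attained exactly by
    a leaf whose true position falls on a rounding boundary, where the
    log simply carries no finer information) plus the ~0.005 mm
    least-squares fit noise of the spline reconstruction.
    """
    beam = make_sliding_window_plan(1, "random", seed=23).beams[0]
    res = simulate_delivery(beam, 300.0, ErrorModel(offset_a_mm=-0.5), seed=4)
    recon = reconstruct_beam(res.record, mode="actual", total_mu=beam.total_mu)
    assert compare_sequences(shift_bank(beam, "A", 0.5), recon).max() <= 0.055


def test_compare_sequences_self_is_zero(random_beam):
    np.testing.assert_allclose(compare_sequences(random_beam, random_beam), 0.0)


def test_compare_sequences_detects_constant_shift(random_beam):
    shifted = shift_bank(random_beam, "A", 0.5)
    deltas = compare_sequences(random_beam, shifted)
    np.testing.assert_allclose(deltas, 0.5, atol=1e-12)


def test_compare_sequences_refined_encoding_agrees(random_beam):
    """Inserting midpoint control points encodes the same motion: the
    resampled comparison sees only floating-point noise."""
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
    assert compare_sequences(random_beam, doubled).max() <= 1e-9


def test_incompatible_geometries_rejected(random_beam):
    from dynaqa.geometry import LeafBankGeometry

    small = DynamicBeam(
        beam_id="s",
        control_points=[
            ControlPoint(index=0.0, bank_a=np.zeros(4), bank_b=np.zeros(4)),
            ControlPoint(index=1.0, bank_a=np.zeros(4), bank_b=np.zeros(4)),
        ],
        total_mu=10.0,
        geometry=LeafBankGeometry((5.0, 5.0, 5.0, 5.0)),
    )
    with pytest.raises(ValueError, match="geometries"):
        compare_sequences(random_beam, small)


def test_incomplete_delivery_reports_achieved_fraction():
    record = _record_from_streams(
        fractions=[0.0, 0.4, 0.8],
        segments=[0, 0, 0],
        leaf0_positions=[10.0, 10.0, 10.0],
    )
    with pytest.raises(IncompleteDeliveryError, match="0.8000"):
        reconstruct_beam(record, mode="actual", total_mu=100.0)


def test_invalid_mode_and_mu_rejected():
    record = _record_from_streams([0.0, 1.0], [0, 0], [5.0, 5.0])
    with pytest.raises(ValueError, match="mode"):
        reconstruct_beam(record, mode="bogus", total_mu=1.0)
    with pytest.raises(ValueError, match="total_mu"):
        reconstruct_beam(record, mode="actual", total_mu=0.0)


def test_beam_hold_snapshots_use_resumed_state():
    """During a hold the fraction repeats; the reconstruction must follow
    the delivery-resumed (later) samples, not the held ones."""
    record = _record_from_streams(
        fractions=[0.0, 0.4, 0.4, 0.4, 0.6, 1.0],
        segments=[0, 0, 0, 0, 1, 1],
        leaf0_positions=[8.0, 10.0, 55.0, 10.0, 12.0, 14.0],
    )
    beam = reconstruct_beam(record, mode="actual", total_mu=100.0)
    mid = [cp for cp in beam.control_points if 0 < cp.index < 1][0]
    assert mid.bank_b[0] == pytest.approx(11.0, abs=1e-9)
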