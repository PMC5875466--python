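"""Rebuild a control-point MLC sequence from a delivery log pair.

The log samples the delivery every 55 ms, so each control-point interval
("segment") of the planned sequence produces many snapshots.  The
reconstruction places one control point at every segment boundary seen in
the segment-number stream and evaluates each leaf's tip there.

Within a segment the leaf trajectory is linear in fractional MU, so the
full trajectory is a linear spline with knots at the segment boundaries.
Tip positions are estimated by least-squares fitting that spline (knots
fixed, one shared design matrix for every leaf) to the snapshot stream.
Compared with interpolating straight across a boundary between the two
bracketing snapshots, the spline fit does not cut the trajectory corner
and averages recording quantization and jitter down by the root of the
per-segment sample count; it reduces to exact interpolation when each
segment contributes a single snapshot.

Modes
-----
``planned``
    Uses the planned positions of the log.  For an error-free delivery
    this reproduces the planned sequence to well under the 0.01 mm file
    resolution.
``actual``
    Uses the recorded positions.

In both modes the boundary *fraction* is estimated from the planned
-position stream — the intersection of the adjacent per-leaf planned
motion lines (weighted by slope change, clipped to the bracketing
snapshot fractions, midpoint when no leaf changes slope).  The planned
stream carries no recording noise, so the knot estimate is sharp, and
the controller switches segments at the same meterset fraction for both
streams.

Snapshots taken during a beam hold (equal dose fraction) are collapsed to
the latest one, the delivery-resumed state.
"""

from __future__ import annotations

import warnings

import numpy as np

from .dynalog import DeliveryRecord, fractional_mu
from .plan import ControlPoint, DynamicBeam

__all__ = ["reconstruct_beam", "compare_sequences", "IncompleteDeliveryError"]


class IncompleteDeliveryError(ValueError):
    """The log does not reach full meterset (final fractional MU < 1)."""

    def __init__(self, achieved: float):
        self.achieved = achieved
        super().__init__(
            f"incomplete delivery: final fractional MU {achieved:.4f} < 1.0"
        )


def _segment_lines(
    frac: np.ndarray, pos: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """LSQ line per leaf through one segment's samples.

    ``pos`` has shape (n_samples, n_leaves); returns (intercept, slope)
    arrays plus the first/last sample fractions.  Duplicate fractions
    (beam holds) keep the last sample.
    """
    _, last_idx = np.unique(frac[::-1], return_index=True)
    keep = len(frac) - 1 - last_idx  # last occurrence of each fraction
    f = frac[keep]
    p = pos[keep]
    if len(f) == 1:
        return p[0].copy(), np.zeros(p.shape[1]), float(f[0]), float(f[0])
    fm = f - f.mean()
    var = float(np.dot(fm, fm))
    slope = fm @ p / var
    intercept = p.mean(axis=0) - slope * f.mean()
    return intercept, slope, float(f[0]), float(f[-1])


def reconstruct_beam(
    record: DeliveryRecord,
    mode: str = "actual",
    total_mu: float = 1.0,
    gantry_angle: float = 0.0,
) -> DynamicBeam:
    """Convert a delivery log pair into a control-point sequence.

    ``total_mu`` is carried over from the reference plan (the log holds
    only fractional MU).  Raises :class:`IncompleteDeliveryError` when the
    final dose index is short of full meterset.
    """
    if mode not in ("actual", "planned"):
        raise ValueError(f"mode must be 'actual' or 'planned', got {mode!r}")
    if not total_mu > 0:
        raise ValueError("total_mu must be positive")
    record.validate()
    frac = fractional_mu(record)
    if frac[-1] < 1.0 - 1e-12:
        raise IncompleteDeliveryError(float(frac[-1]))
    seg = record.segments()
    if len(seg) == 0:
        raise ValueError("empty segment stream")
    planned_flat = record.positions("planned")
    n_snap, _, n_pairs = planned_flat.shape
    planned_flat = planned_flat.reshape(n_snap, 2 * n_pairs)
    if mode == "planned":
        flat = planned_flat
    else:
        flat = record.positions("recorded").reshape(n_snap, 2 * n_pairs)

    # collapse beam-hold duplicates (equal fraction) to the resumed state
    _, last_idx = np.unique(frac[::-1], return_index=True)
    keep = np.sort(len(frac) - 1 - last_idx)
    frac, seg = frac[keep], seg[keep]
    flat, planned_flat = flat[keep], planned_flat[keep]
    n_snap = len(frac)

    # group snapshots by segment (stream is non-decreasing)
    change = np.flatnonzero(np.diff(seg) != 0)
    starts = np.concatenate([[0], change + 1])
    stops = np.concatenate([change + 1, [n_snap]])
    planned_lines = [
        _segment_lines(frac[a:b], planned_flat[a:b]) for a, b in zip(starts, stops)
    ]

    # boundary meterset fractions from the noise-free planned stream
    knots = [0.0]
    for s in range(len(planned_lines) - 1):
        f_lo = frac[stops[s] - 1]  # last snapshot of the old segment
        f_hi = frac[starts[s + 1]]  # first snapshot of the new segment
        f_star = _knot_from_lines(planned_lines[s], planned_lines[s + 1], f_lo, f_hi)
        if f_star > knots[-1] + 1e-9:
            knots.append(float(f_star))
    if knots[-1] < 1.0 - 1e-9:
        knots.append(1.0)
    else:
        knots[-1] = 1.0
    knots = np.asarray(knots)

    # linear-spline LSQ: hat-function design matrix shared by all leaves
    j = np.clip(np.searchsorted(knots, frac, side="right") - 1, 0, len(knots) - 2)
    t = (frac - knots[j]) / (knots[j + 1] - knots[j])
    design = np.zeros((n_snap, len(knots)))
    rows = np.arange(n_snap)
    np.add.at(design, (rows, j), 1.0 - t)
    np.add.at(design, (rows, j + 1), t)
    positions, *_ = np.linalg.lstsq(design, flat, rcond=None)

    control_points = []
    for f_star, p in zip(knots, positions):
        a = p[:n_pairs].copy()
        b = p[n_pairs:].copy()
        bad = b < a
        if np.any(bad):
            warnings.warn(
                f"pinched {int(bad.sum())} colliding pair(s) at index {f_star:.4f}",
                stacklevel=2,
            )
            mid = 0.5 * (a[bad] + b[bad])
            a[bad] = mid
            b[bad] = mid
        control_points.append(ControlPoint(index=f_star, bank_a=a, bank_b=b))

    beam = DynamicBeam(
        beam_id=record.field_id,
        control_points=control_points,
        total_mu=total_mu,
        gantry_angle=gantry_angle,
        geometry=record.geometry,
    )
    beam.validate()
    return beam


def _knot_from_lines(line_old, line_new, f_lo: float, f_hi: float) -> float:
    """Boundary fraction estimated from per-leaf motion-line intersections.

    Leaves whose slope changes across the boundary all intersect at the
    true knot; the estimate is their slope-change-weighted mean, clipped
    to the bracketing snapshot fractions.  Falls back to the midpoint when
    no leaf changes slope (the boundary is then geometrically redundant).
    """
    i0, s0, _, _ = line_old
    i1, s1, _, _ = line_new
    dslope = s1 - s0
    use = np.abs(dslope) > 1e-6
    if not np.any(use):
        return 0.5 * (f_lo + f_hi)
    cand = (i0[use] - i1[use]) / dslope[use]
    w = np.abs(dslope[use])
    f_star = float(np.sum(w * np.clip(cand, f_lo, f_hi)) / np.sum(w))
    return min(max(f_star, f_lo), f_hi)


def compare_sequences(a: DynamicBeam, b: DynamicBeam) -> np.ndarray:
    """Per-control-point maximum |position difference| in mm.

    The two sequences are resampled onto the union of their meterset
    indices (linear interpolation), so encodings with different
    control-point counts are comparable.  Returns one value per common
    index; all zeros iff the sequences describe the same motion.
    """
    if a.geometry.n_pairs != b.geometry.n_pairs:
        raise ValueError("incompatible geometries")
    grid = np.union1d(a.indices, b.indices)
    tips_a = a.interpolate(grid)
    tips_b = b.interpolate(grid)
    return np.max(np.abs(tips_a - tips_b), axis=(1, 2))
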