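"""Systematic MLC error injection.

Ten realistic delivery-error classes are built from three primitives:
symmetric expansion of the MLC opening (1, 2, 4 mm total), a whole-bank
outward shift (0.5, 1, 2 mm on bank A or bank B), and removal of
control points from the sequence (emulating a transfer/network failure).

Closed-pair handling differs deliberately between the primitives: an
*opening expansion* leaves closed pairs closed (expanding a zero gap
would create apertures the error class does not imply), while a *bank
shift* moves every leaf of the bank, closed pairs included.  Each
injector reports how many closed pairs it skipped or moved via the
returned beam's control points themselves (and a module logger).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .plan import ControlPoint, DynamicBeam

__all__ = ["expand_opening", "shift_bank", "drop_segments"]

logger = logging.getLogger(__name__)

#: gap below which a pair counts as closed
_CLOSED_GAP_MM = 1e-9


def expand_opening(beam: DynamicBeam, total_mm: float) -> DynamicBeam:
    """Expand every open pair's gap by ``total_mm``, split equally per bank.

    Bank-A tips move by ``-total_mm/2`` and bank-B tips by ``+total_mm/2``
    at every control point; closed pairs are left untouched.  A negative
    ``total_mm`` contracts the opening and raises if any pair would
    collide.
    """
    beam.validate()
    half = total_mm / 2.0
    skipped = 0
    cps = []
    for cp in beam.control_points:
        gap = cp.bank_b - cp.bank_a
        open_pair = gap > _CLOSED_GAP_MM
        skipped += int(np.sum(~open_pair))
        a = np.where(open_pair, cp.bank_a - half, cp.bank_a)
        b = np.where(open_pair, cp.bank_b + half, cp.bank_b)
        if np.any(b < a - 1e-9):
            raise ValueError(
                f"contraction of {-total_mm} mm collides leaves at index {cp.index:.4f}"
            )
        cps.append(ControlPoint(index=cp.index, bank_a=a, bank_b=b))
    if skipped:
        logger.info("expand_opening(%.2f mm): left %d closed pair states unchanged",
                    total_mm, skipped)
    out = beam.with_control_points(cps)
    out.validate()
    return out


def shift_bank(beam: DynamicBeam, bank: str, mm: float) -> DynamicBeam:
    """Shift every leaf of one bank outward by ``mm`` (opening increases).

    Bank A moves toward -x, bank B toward +x; closed pairs move too (the
    error affects all leaves of the bank), so a shifted closed pair
    acquires a gap of ``mm``.
    """
    beam.validate()
    if bank not in ("A", "B"):
        raise ValueError(f"bank must be 'A' or 'B', got {bank!r}")
    if mm < 0:
        raise ValueError("shift must be non-negative (outward)")
    cps = []
    for cp in beam.control_points:
        a = cp.bank_a - mm if bank == "A" else cp.bank_a
        b = cp.bank_b + mm if bank == "B" else cp.bank_b
        cps.append(ControlPoint(index=cp.index, bank_a=a, bank_b=b))
    out = beam.with_control_points(cps)
    out.validate()
    return out


def drop_segments(beam: DynamicBeam, segment_indices) -> DynamicBeam:
    """Remove interior control points by index (simulated transfer failure).

    Indices refer to the sequence's control points (0-based); the first
    and last control point must survive, and the meterset indices of the
    survivors are *not* renormalized — the aperture simply moves directly
    between them, as a controller skipping data would.
    """
    beam.validate()
    drop = set(int(i) for i in segment_indices)
    n = len(beam.control_points)
    if not drop:
        return beam.with_control_points(list(beam.control_points))
    bad = [i for i in drop if not 0 <= i < n]
    if bad:
        raise ValueError(f"control-point indices out of range: {sorted(bad)}")
    if 0 in drop or n - 1 in drop:
        raise ValueError("first and last control points must be retained")
    survivors = [cp for i, cp in enumerate(beam.control_points) if i not in drop]
    if len(survivors) < 2:
        raise ValueError("cannot drop all interior control points")
    out = beam.with_control_points(survivors)
    out.validate()
    return out
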