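"""Dynamic-delivery simulation and synthetic fixtures.

This module is the package's test bed: it emulates the controller that
writes the per-bank delivery logs (55 ms sampling, integer dose index,
beam holds, finite recording precision), and generates sliding-window
plans and a simple phantom so every pipeline stage can be exercised
without machine data.

The simulated controller is kinematic: leaves track the planned
trajectory exactly in meterset-fraction space, and the *recorded*
positions are the planned ones perturbed by a systematic per-bank offset,
zero-mean Gaussian jitter, and 0.01 cm recording quantization.  Beam
holds follow a simple rule: whenever any leaf's recorded-minus-planned
deviation exceeds a tolerance (default 2 mm), the beam is held for that
sample and the dose index does not advance.  Servo dynamics, gravity
effects and dose-rate modulation are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynalog import (
    DOSE_INDEX_SCALE,
    RECORD_QUANTUM_MM,
    SAMPLE_INTERVAL_MS,
    DeliveryLog,
    DeliveryRecord,
    LogSnapshot,
)
from .geometry import LeafBankGeometry, millennium120
from .plan import ControlPoint, DynamicBeam, Plan

__all__ = [
    "ErrorModel",
    "SimulationResult",
    "simulate_delivery",
    "make_sliding_window_plan",
    "make_phantom",
    "Phantom",
    "StructureMask",
]

_STORE_QUANTUM_MM = 0.01


@dataclass(frozen=True)
class ErrorModel:
    """Recorded-position error model of the simulated controller.

    ``offset_a_mm``/``offset_b_mm`` are signed displacements added to the
    tip coordinate of every leaf of the bank (negative on bank A / positive
    on bank B opens the aperture).  ``jitter_sd_mm`` is the SD of
    independent zero-mean Gaussian noise per leaf per sample.
    """

    offset_a_mm: float = 0.0
    offset_b_mm: float = 0.0
    jitter_sd_mm: float = 0.0

    def validate(self) -> None:
        for name in ("offset_a_mm", "offset_b_mm", "jitter_sd_mm"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.jitter_sd_mm < 0:
            raise ValueError("jitter_sd_mm must be >= 0")


@dataclass
class SimulationResult:
    """A simulated delivery: the log pair plus the true delivered motion.

    ``delivered_beam`` encodes the actual (pre-quantization) leaf
    trajectory as one control point per distinct meterset fraction; it is
    the ground truth against which log-based reconstructions are judged.
    """

    record: DeliveryRecord
    delivered_beam: DynamicBeam


def simulate_delivery(
    beam: DynamicBeam,
    dose_rate_mu_min: float = 300.0,
    error_model: ErrorModel | None = None,
    seed: int | None = None,
    hold_tolerance_mm: float = 2.0,
    quantize: bool = True,
    contact_gap_mm: float = 0.5,
) -> SimulationResult:
    """Simulate delivering ``beam`` and return the synthetic log pair.

    The dose index advances linearly at ``dose_rate_mu_min`` in 55 ms
    steps (integer 0..25000), the segment number is the control-point
    interval containing the current fraction, and recorded positions
    follow ``error_model``.  Pairs whose planned gap is below
    ``contact_gap_mm`` are treated as mechanically abutting: their two
    tips receive common-mode jitter (the contact point wanders, the pair
    stays closed) since opposed leaves cannot interpenetrate.
    Reproducible for a fixed ``seed``.
    """
    beam.validate()
    if not dose_rate_mu_min > 0:
        raise ValueError("dose_rate_mu_min must be positive")
    error_model = error_model or ErrorModel()
    error_model.validate()
    rng = np.random.default_rng(seed)
    n = beam.geometry.n_pairs

    duration_s = beam.total_mu / dose_rate_mu_min * 60.0
    df_per_step = (SAMPLE_INTERVAL_MS / 1000.0) / duration_s
    n_advance = int(np.ceil(1.0 / df_per_step))  # dose-advancing samples needed

    indices = beam.indices
    offsets = np.array([[error_model.offset_a_mm], [error_model.offset_b_mm]])

    # the hold decision depends only on the error draws (recorded - planned
    # = offset + jitter in this kinematic model), so the sample count can be
    # settled before interpolating the trajectory.
    def draw_jitter(n_rows: int) -> np.ndarray:
        if error_model.jitter_sd_mm > 0:
            return rng.normal(0.0, error_model.jitter_sd_mm, size=(n_rows, 2, n))
        return np.zeros((n_rows, 2, n))

    jitter = draw_jitter(n_advance + 1)
    while True:
        deviation = np.max(np.abs(offsets[None, :, :] + jitter), axis=(1, 2))
        held = deviation > hold_tolerance_mm
        advanced = np.cumsum(~held)
        done = np.flatnonzero(advanced >= n_advance)
        if len(done) and int(done[0]) + 2 <= len(jitter):
            n_snap = int(done[0]) + 2  # + final snapshot at full meterset
            jitter = jitter[:n_snap]
            held = held[:n_snap]
            break
        if len(jitter) > 20 * (n_advance + 1):
            raise RuntimeError("simulated delivery stalled (persistent beam hold)")
        jitter = np.concatenate([jitter, draw_jitter(n_advance)])

    # fraction stream: advances by one step per non-held preceding sample
    steps = np.concatenate([[0], np.cumsum(~held[:-1])])
    frac = np.minimum(steps * df_per_step, 1.0)
    frac[-1] = 1.0
    held[-1] = False
    beam_on = ~held

    planned = beam.interpolate(frac)  # (n_snap, 2, n_pairs)
    # common-mode jitter for abutting pairs: gap stays exactly closed
    contact = (planned[:, 1, :] - planned[:, 0, :]) < contact_gap_mm
    common = 0.5 * (jitter[:, 0, :] + jitter[:, 1, :])
    for bi in (0, 1):
        jitter[:, bi, :] = np.where(contact, common, jitter[:, bi, :])
    true_recorded = planned + offsets[None, :, :] + jitter

    dose_idx = np.round(frac * DOSE_INDEX_SCALE).astype(int)
    dose_idx = np.maximum.accumulate(dose_idx)
    dose_idx[-1] = DOSE_INDEX_SCALE
    seg = np.clip(np.searchsorted(indices, frac, side="right") - 1, 0, len(indices) - 2)

    planned_q = np.round(planned / _STORE_QUANTUM_MM) * _STORE_QUANTUM_MM
    recorded_q = (
        np.round(true_recorded / RECORD_QUANTUM_MM) * RECORD_QUANTUM_MM
        if quantize
        else true_recorded
    )

    logs = []
    for bi, bank in enumerate(("A", "B")):
        snapshots = [
            LogSnapshot(
                time_ms=k * SAMPLE_INTERVAL_MS,
                dose_index=int(dose_idx[k]),
                segment=int(seg[k]),
                beam_on=bool(beam_on[k]),
                planned_positions=planned_q[k, bi],
                recorded_positions=recorded_q[k, bi],
            )
            for k in range(n_snap)
        ]
        logs.append(
            DeliveryLog(
                field_id=beam.beam_id,
                bank=bank,
                snapshots=snapshots,
                geometry=beam.geometry,
                tolerance_mm=hold_tolerance_mm,
                seed=seed,
            )
        )
    record = DeliveryRecord(bank_a_log=logs[0], bank_b_log=logs[1])
    record.validate()

    # ground-truth delivered motion: one control point per distinct fraction
    keep = np.concatenate([[True], np.diff(frac) > 0])
    cps = [
        ControlPoint(index=float(frac[k]), bank_a=true_recorded[k, 0], bank_b=true_recorded[k, 1])
        for k in np.flatnonzero(keep)
    ]
    delivered = DynamicBeam(
        beam_id=beam.beam_id,
        control_points=cps,
        total_mu=beam.total_mu,
        gantry_angle=beam.gantry_angle,
        geometry=beam.geometry,
        plan_id=beam.plan_id,
    )
    # systematic offsets may nominally cross closed pairs; pinch collisions
    _pinch_collisions(delivered)
    delivered.validate()
    return SimulationResult(record=record, delivered_beam=delivered)


def _pinch_collisions(beam: DynamicBeam) -> None:
    for cp in beam.control_points:
        gap = cp.bank_b - cp.bank_a
        bad = gap < 0
        if np.any(bad):
            mid = 0.5 * (cp.bank_a[bad] + cp.bank_b[bad])
            cp.bank_a[bad] = mid
            cp.bank_b[bad] = mid


# ---------------------------------------------------------------------------
# fixture plans
# ---------------------------------------------------------------------------

#: pairs driven by the sliding window (central 100 mm of the field)
_ACTIVE_PAIRS = slice(20, 40)
_SWEEP_START = -60.0
_SWEEP_LENGTH = 120.0


def _smooth_random(rng: np.random.Generator, f: np.ndarray, n_terms: int = 3) -> np.ndarray:
    """Smooth random function of the meterset fraction, amplitude ~1."""
    out = np.zeros_like(f)
    for k in range(1, n_terms + 1):
        out += rng.normal() * np.sin(np.pi * k * f) / k
        out += rng.normal() * np.cos(np.pi * k * f) / k
    return out / n_terms


def make_sliding_window_plan(
    n_beams: int = 5,
    modulation_preset: str = "random",
    seed: int | None = None,
    n_control_points: int = 25,
    total_mu: float = 100.0,
    plan_id: str = "fixture",
) -> Plan:
    """Generate a leaf-speed-feasible sliding-window plan.

    Presets: ``"ramp"`` (constant 12 mm gap sweeping at constant speed;
    interior fluence has the closed form MU x gap / sweep length),
    ``"pyramid"`` (gap varying across pairs), ``"random"`` (seeded smooth
    modulation of window centre and gap per pair).  Beams are spaced
    evenly in gantry angle (72 deg apart for the default five beams).
    """
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    if modulation_preset not in ("ramp", "pyramid", "random"):
        raise ValueError(f"unknown preset {modulation_preset!r}")
    rng = np.random.default_rng(seed)
    geometry = millennium120()
    n = geometry.n_pairs
    f_grid = np.linspace(0.0, 1.0, n_control_points)

    beams = []
    for b in range(n_beams):
        centers = _SWEEP_START + _SWEEP_LENGTH * f_grid  # (n_cp,)
        bank_a = np.zeros((n_control_points, n))
        bank_b = np.zeros((n_control_points, n))
        active = np.zeros(n, dtype=bool)
        active[_ACTIVE_PAIRS] = True
        pair_ids = np.flatnonzero(active)
        for k in pair_ids:
            if modulation_preset == "ramp":
                gap = np.full_like(f_grid, 12.0)
                c = centers
            elif modulation_preset == "pyramid":
                peak = 1.0 - abs(k - (n - 1) / 2.0) / len(pair_ids)
                gap = np.full_like(f_grid, 6.0 + 12.0 * peak)
                c = centers
            else:
                gap = 8.0 + 5.0 * _smooth_random(rng, f_grid)
                gap = np.clip(gap, 2.0, 20.0)
                c = centers + 4.0 * _smooth_random(rng, f_grid)
            bank_a[:, k] = c - gap / 2.0
            bank_b[:, k] = c + gap / 2.0
        # parked (closed) pairs sit at x = 0
        bank_a = np.clip(bank_a, -70.0, 70.0)
        bank_b = np.clip(bank_b, -70.0, 70.0)
        bank_b = np.maximum(bank_b, bank_a)
        cps = [
            ControlPoint(index=float(f_grid[j]), bank_a=bank_a[j], bank_b=bank_b[j])
            for j in range(n_control_points)
        ]
        beams.append(
            DynamicBeam(
                beam_id=f"beam{b + 1}",
                control_points=cps,
                total_mu=total_mu,
                gantry_angle=(360.0 / n_beams) * b,
                geometry=geometry,
                plan_id=plan_id,
            )
        )
    plan = Plan(plan_id=plan_id, beams=beams, prescription_dose=2.0)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------


@dataclass
class StructureMask:
    """Boolean voxel mask congruent with a dose grid."""

    name: str
    voxels: np.ndarray

    def validate(self) -> None:
        if self.voxels.dtype != bool:
            raise ValueError("mask voxels must be boolean")
        if not self.voxels.any():
            raise ValueError(f"structure {self.name!r} has no voxels")


@dataclass
class Phantom:
    """Homogeneous cubic phantom centred on the isocenter.

    ``density`` is relative electron density (ones for the water-like
    default); axes are (x, y, z) in the fixed room frame with the beam
    rotating about y.
    """

    size_mm: float
    voxel_mm: float
    density: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates along each axis, isocenter at 0."""
        nv = self.density.shape[0]
        half = self.size_mm / 2.0
        c = (np.arange(nv) + 0.5) * self.voxel_mm - half
        return c, c.copy(), c.copy()


def make_phantom(
    preset: str = "cube_target_oars",
    size_mm: float = 200.0,
    voxel_mm: float = 2.0,
) -> tuple[Phantom, dict[str, StructureMask]]:
    """Cubic phantom with a cylindrical target and two lateral OARs.

    The target is a 25 mm-radius cylinder (axis along y, 60 mm long)
    centred on the isocenter; the OARs are 12 mm-radius cylinders offset
    +-45 mm along x.  Deterministic.
    """
    if preset != "cube_target_oars":
        raise ValueError(f"unknown phantom preset {preset!r}")
    nv = int(round(size_mm / voxel_mm))
    density = np.ones((nv, nv, nv))
    phantom = Phantom(size_mm=size_mm, voxel_mm=voxel_mm, density=density)
    cx, cy, cz = phantom.coords()
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")

    def cylinder(x0: float, radius: float, half_len: float) -> np.ndarray:
        return ((X - x0) ** 2 + Z**2 <= radius**2) & (np.abs(Y) <= half_len)

    masks = {
        "target": StructureMask("target", cylinder(0.0, 25.0, 30.0)),
        "oar_right": StructureMask("oar_right", cylinder(45.0, 12.0, 30.0)),
        "oar_left": StructureMask("oar_left", cylinder(-45.0, 12.0, 30.0)),
    }
    for m in masks.values():
        m.validate()
    return phantom, masks
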