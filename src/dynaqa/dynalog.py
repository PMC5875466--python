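"""Per-bank dynamic-delivery log files ("DynaLog"-style) and their dialect.

During a dynamic delivery the MLC controller samples the machine state
every 55 ms and writes one log file per bank.  Each snapshot carries the
dose index (cumulative fractional MU scaled to an integer 0..25000), the
current segment number, a beam-on flag, and the planned and recorded tip
position of every leaf of that bank.

Log dialect (line-oriented text, one file per bank)::

    DynaQA DynaLog v1
    Field = <field id>
    Bank = A|B
    Tolerance = <mm>
    Seed = <int or ->
    time_ms,dose_index,segment,beam_on,P001,...,P060,R001,...,R060
    0,0,0,1,-60000,...,...

``P``/``R`` columns are planned/recorded positions as signed integers in
0.01 mm units.  Planned positions are stored at full 0.01 mm resolution;
recorded positions are quantized to 0.01 cm (0.1 mm), the finite
recording precision of the modelled controller, so a written-then-read
recorded position is within 0.05 mm of the in-memory value.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .geometry import LeafBankGeometry, millennium120

__all__ = [
    "LogSnapshot",
    "DeliveryLog",
    "DeliveryRecord",
    "DynalogError",
    "DynalogMismatchError",
    "read_dynalog",
    "read_dynalog_pair",
    "write_dynalog_pair",
    "fractional_mu",
    "DOSE_INDEX_SCALE",
    "SAMPLE_INTERVAL_MS",
]

DOSE_INDEX_SCALE = 25000
SAMPLE_INTERVAL_MS = 55.0
_MAGIC = "DynaQA DynaLog v1"
#: storage resolution of log positions (integer units)
_STORE_QUANTUM_MM = 0.01
#: recording precision of recorded positions
RECORD_QUANTUM_MM = 0.1


class DynalogError(ValueError):
    """A single log file is corrupt or violates the log invariants."""


class DynalogMismatchError(ValueError):
    """Two per-bank log files do not describe the same delivery."""


@dataclass(frozen=True)
class LogSnapshot:
    """Machine state at one 55 ms sampling instant (one bank)."""

    time_ms: float
    dose_index: int
    segment: int
    beam_on: bool
    planned_positions: np.ndarray  # mm, signed, one entry per pair
    recorded_positions: np.ndarray

    @property
    def fraction(self) -> float:
        return self.dose_index / DOSE_INDEX_SCALE


@dataclass
class DeliveryLog:
    """Ordered snapshot stream for one bank of one delivered field."""

    field_id: str
    bank: str
    snapshots: list[LogSnapshot]
    geometry: LeafBankGeometry = field(default_factory=millennium120)
    tolerance_mm: float = 2.0
    seed: int | None = None

    def validate(self) -> None:
        if self.bank not in ("A", "B"):
            raise DynalogError(f"bank must be 'A' or 'B', got {self.bank!r}")
        if not self.snapshots:
            raise DynalogError("log has no snapshots")
        n = self.geometry.n_pairs
        prev_di = -1
        for i, s in enumerate(self.snapshots):
            if s.planned_positions.shape != (n,) or s.recorded_positions.shape != (n,):
                raise DynalogError(f"snapshot {i}: expected {n} positions per array")
            if not (
                np.isfinite(s.planned_positions).all()
                and np.isfinite(s.recorded_positions).all()
            ):
                raise DynalogError(f"snapshot {i}: non-finite position")
            if s.dose_index < prev_di:
                raise DynalogError(
                    f"snapshot {i}: dose index decreases ({prev_di} -> {s.dose_index})"
                )
            if not 0 <= s.dose_index <= DOSE_INDEX_SCALE:
                raise DynalogError(f"snapshot {i}: dose index {s.dose_index} out of range")
            expected_t = i * SAMPLE_INTERVAL_MS
            if abs(s.time_ms - expected_t) > 1e-6:
                raise DynalogError(
                    f"snapshot {i}: time {s.time_ms} ms not on the 55 ms grid"
                )
            prev_di = s.dose_index

    @property
    def complete(self) -> bool:
        return bool(self.snapshots) and self.snapshots[-1].dose_index == DOSE_INDEX_SCALE

    def planned_array(self) -> np.ndarray:
        return np.array([s.planned_positions for s in self.snapshots])

    def recorded_array(self) -> np.ndarray:
        return np.array([s.recorded_positions for s in self.snapshots])


@dataclass
class DeliveryRecord:
    """The paired bank-A / bank-B logs of one delivered field."""

    bank_a_log: DeliveryLog
    bank_b_log: DeliveryLog

    def validate(self) -> None:
        a, b = self.bank_a_log, self.bank_b_log
        a.validate()
        b.validate()
        if (a.bank, b.bank) != ("A", "B"):
            raise DynalogMismatchError(
                f"expected banks (A, B), got ({a.bank!r}, {b.bank!r})"
            )
        if a.field_id != b.field_id:
            raise DynalogMismatchError(
                f"field id mismatch: {a.field_id!r} vs {b.field_id!r}"
            )
        if len(a.snapshots) != len(b.snapshots):
            raise DynalogMismatchError(
                f"unequal snapshot count: bank A has {len(a.snapshots)}, "
                f"bank B has {len(b.snapshots)}"
            )
        for i, (sa, sb) in enumerate(zip(a.snapshots, b.snapshots)):
            if sa.dose_index != sb.dose_index or sa.segment != sb.segment:
                raise DynalogMismatchError(
                    f"snapshot {i}: dose-index/segment streams differ between banks"
                )

    @property
    def field_id(self) -> str:
        return self.bank_a_log.field_id

    @property
    def geometry(self) -> LeafBankGeometry:
        return self.bank_a_log.geometry

    @property
    def complete(self) -> bool:
        return self.bank_a_log.complete

    def dose_indices(self) -> np.ndarray:
        return np.array([s.dose_index for s in self.bank_a_log.snapshots])

    def segments(self) -> np.ndarray:
        return np.array([s.segment for s in self.bank_a_log.snapshots])

    def beam_on(self) -> np.ndarray:
        return np.array([s.beam_on for s in self.bank_a_log.snapshots], dtype=bool)

    def positions(self, which: str) -> np.ndarray:
        """Stack per-bank positions: shape (n_snapshots, 2, n_pairs), axis 1 = (A, B).

        ``which`` is ``"planned"`` or ``"recorded"``.
        """
        if which not in ("planned", "recorded"):
            raise ValueError("which must be 'planned' or 'recorded'")
        getter = DeliveryLog.planned_array if which == "planned" else DeliveryLog.recorded_array
        return np.stack([getter(self.bank_a_log), getter(self.bank_b_log)], axis=1)


def fractional_mu(record: DeliveryRecord) -> np.ndarray:
    """Cumulative fractional MU per snapshot (dose_index / 25000)."""
    return record.dose_indices() / DOSE_INDEX_SCALE


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _quantize(values: np.ndarray, quantum_mm: float) -> np.ndarray:
    return np.round(values / quantum_mm) * quantum_mm


def write_dynalog(log: DeliveryLog, path) -> None:
    log.validate()
    n = log.geometry.n_pairs
    lines = [
        _MAGIC,
        f"Field = {log.field_id}",
        f"Bank = {log.bank}",
        f"Tolerance = {log.tolerance_mm:.2f}",
        f"Seed = {'-' if log.seed is None else log.seed}",
        "time_ms,dose_index,segment,beam_on,"
        + ",".join(f"P{k + 1:03d}" for k in range(n))
        + ","
        + ",".join(f"R{k + 1:03d}" for k in range(n)),
    ]
    for s in log.snapshots:
        planned = np.round(s.planned_positions / _STORE_QUANTUM_MM).astype(int)
        recorded = np.round(
            _quantize(s.recorded_positions, RECORD_QUANTUM_MM) / _STORE_QUANTUM_MM
        ).astype(int)
        row = [f"{s.time_ms:.0f}", str(s.dose_index), str(s.segment), str(int(s.beam_on))]
        row += [str(v) for v in planned]
        row += [str(v) for v in recorded]
        lines.append(",".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_dynalog_pair(record: DeliveryRecord, directory) -> tuple[str, str]:
    """Write the two per-bank files ``<field>_A.dlg`` / ``<field>_B.dlg``."""
    record.validate()
    os.makedirs(directory, exist_ok=True)
    paths = []
    for log in (record.bank_a_log, record.bank_b_log):
        path = os.path.join(str(directory), f"{log.field_id}_{log.bank}.dlg")
        write_dynalog(log, path)
        paths.append(path)
    return tuple(paths)


def read_dynalog(path, geometry: LeafBankGeometry | None = None) -> DeliveryLog:
    geometry = geometry or millennium120()
    n = geometry.n_pairs
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _MAGIC:
        raise DynalogError(f"{path}: not a '{_MAGIC}' file")
    header: dict[str, str] = {}
    for i in (1, 2, 3, 4):
        if i >= len(lines) or "=" not in lines[i]:
            raise DynalogError(f"{path}: truncated header")
        key, _, value = lines[i].partition("=")
        header[key.strip()] = value.strip()
    for key in ("Field", "Bank", "Tolerance"):
        if key not in header:
            raise DynalogError(f"{path}: missing header key {key!r}")
    seed = None if header.get("Seed", "-") == "-" else int(header["Seed"])

    snapshots: list[LogSnapshot] = []
    for ln, raw in enumerate(lines[6:], start=7):
        if not raw.strip():
            continue
        parts = raw.split(",")
        if len(parts) != 4 + 2 * n:
            raise DynalogError(
                f"{path}: line {ln}: expected {4 + 2 * n} fields, got {len(parts)}"
            )
        try:
            time_ms = float(parts[0])
            dose_index = int(parts[1])
            segment = int(parts[2])
            beam_on = bool(int(parts[3]))
            values = np.array(parts[4:], dtype=float) * _STORE_QUANTUM_MM
        except ValueError as exc:
            raise DynalogError(f"{path}: line {ln}: {exc}") from None
        snapshots.append(
            LogSnapshot(
                time_ms=time_ms,
                dose_index=dose_index,
                segment=segment,
                beam_on=beam_on,
                planned_positions=values[:n],
                recorded_positions=values[n:],
            )
        )
    log = DeliveryLog(
        field_id=header["Field"],
        bank=header["Bank"],
        snapshots=snapshots,
        geometry=geometry,
        tolerance_mm=float(header["Tolerance"]),
        seed=seed,
    )
    log.validate()
    return log


def read_dynalog_pair(
    path_a, path_b, geometry: LeafBankGeometry | None = None
) -> DeliveryRecord:
    """Read and cross-validate the two per-bank log files of one field."""
    record = DeliveryRecord(
        bank_a_log=read_dynalog(path_a, geometry),
        bank_b_log=read_dynalog(path_b, geometry),
    )
    record.validate()
    return record
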