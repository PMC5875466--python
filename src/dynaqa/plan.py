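"""Control-point MLC sequences and the ``dva`` text file dialect.

A dynamic (sliding-window) beam is described by an ordered list of control
points.  Each control point carries a cumulative meterset fraction
("index", 0 at beam-on, 1 at beam-off) and the tip position of every leaf
in both banks, in mm at the isocenter plane (see :mod:`dynaqa.geometry`
for the sign convention).

``dva`` dialect
---------------
Line-oriented ``key = value`` text.  Header keys::

    File Rev = G
    Plan ID = <text>
    Beam ID = <text>
    Total MU = <float>
    Gantry = <float degrees>
    Number of Fields = <int, number of control points>

followed by one block per control point::

    Index = <float in [0, 1]>
    Leaf 1A = <cm, 3 decimals>
    ...
    Leaf 60A = <cm>
    Leaf 1B = <cm>
    ...
    Leaf 60B = <cm>

Positions are serialized in cm with three decimals (0.01 mm resolution,
the coarsest layer of the modelled hardware); the writer is canonical, so
write -> read -> write is byte-identical.  This schema is a self-contained
stand-in for vendor MLC-sequence files and is documented here rather than
inferred from any proprietary format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import LeafBankGeometry, millennium120

__all__ = [
    "ControlPoint",
    "DynamicBeam",
    "Plan",
    "MLCFileError",
    "read_mlc_file",
    "write_mlc_file",
]

#: resolution of serialized leaf positions (3 decimals in cm)
POSITION_QUANTUM_MM = 0.01


class MLCFileError(ValueError):
    """Malformed MLC sequence file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class ControlPoint:
    """One control point: meterset fraction plus per-pair tip positions (mm)."""

    index: float
    bank_a: np.ndarray
    bank_b: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "bank_a", np.asarray(self.bank_a, dtype=float))
        object.__setattr__(self, "bank_b", np.asarray(self.bank_b, dtype=float))

    def validate(self, n_pairs: int, atol_mm: float = 1e-6) -> None:
        if not 0.0 <= self.index <= 1.0:
            raise ValueError(f"control-point index {self.index} outside [0, 1]")
        if self.bank_a.shape != (n_pairs,) or self.bank_b.shape != (n_pairs,):
            raise ValueError(
                f"expected {n_pairs} leaf positions per bank, got "
                f"{self.bank_a.shape} / {self.bank_b.shape}"
            )
        if not (np.isfinite(self.bank_a).all() and np.isfinite(self.bank_b).all()):
            raise ValueError("leaf positions must be finite")
        gap = self.bank_b - self.bank_a
        if np.any(gap < -atol_mm):
            k = int(np.argmin(gap))
            raise ValueError(
                f"leaf collision at pair {k + 1}: tip A {self.bank_a[k]:.3f} mm > "
                f"tip B {self.bank_b[k]:.3f} mm"
            )


@dataclass
class DynamicBeam:
    """A dynamic-MLC beam: ordered control points, total MU and geometry."""

    beam_id: str
    control_points: list[ControlPoint]
    total_mu: float
    gantry_angle: float = 0.0
    geometry: LeafBankGeometry = field(default_factory=millennium120)
    plan_id: str = ""

    def validate(self) -> None:
        if len(self.control_points) < 2:
            raise ValueError("a dynamic beam needs at least 2 control points")
        if not self.total_mu > 0:
            raise ValueError("total_mu must be positive")
        n = self.geometry.n_pairs
        indices = [cp.index for cp in self.control_points]
        if abs(indices[0]) > 1e-12:
            raise ValueError(f"first control-point index must be 0, got {indices[0]}")
        if abs(indices[-1] - 1.0) > 1e-12:
            raise ValueError(f"last control-point index must be 1, got {indices[-1]}")
        for i, cp in enumerate(self.control_points):
            cp.validate(n)
            if i and cp.index < self.control_points[i - 1].index - 1e-12:
                raise ValueError(
                    f"control-point indices must be non-decreasing "
                    f"(index {cp.index:.6f} at control point {i + 1} after "
                    f"{self.control_points[i - 1].index:.6f})"
                )

    @property
    def indices(self) -> np.ndarray:
        return np.array([cp.index for cp in self.control_points])

    def tip_array(self) -> np.ndarray:
        """Positions as an array of shape (n_cp, 2, n_pairs); axis 1 = (A, B)."""
        return np.array(
            [[cp.bank_a, cp.bank_b] for cp in self.control_points]
        )

    def interpolate(self, fraction: float | np.ndarray) -> np.ndarray:
        """Leaf tips at arbitrary meterset fraction(s), linear between control points.

        Returns shape (2, n_pairs) for a scalar fraction, else
        (len(fraction), 2, n_pairs).
        """
        f = np.clip(np.asarray(fraction, dtype=float), 0.0, 1.0)
        idx = self.indices
        tips = self.tip_array()  # (n_cp, 2, n_pairs)
        flat = tips.reshape(len(idx), -1)
        out = np.empty(f.shape + (flat.shape[1],))
        for j in range(flat.shape[1]):
            out[..., j] = np.interp(f, idx, flat[:, j])
        return out.reshape(f.shape + (2, self.geometry.n_pairs))

    def with_control_points(self, control_points: list[ControlPoint]) -> "DynamicBeam":
        return replace(self, control_points=list(control_points))


@dataclass
class Plan:
    """A set of dynamic beams sharing a prescription dose."""

    plan_id: str
    beams: list[DynamicBeam]
    prescription_dose: float = 1.0

    def validate(self) -> None:
        if not self.beams:
            raise ValueError("a plan needs at least one beam")
        if not self.prescription_dose > 0:
            raise ValueError("prescription_dose must be positive")
        for beam in self.beams:
            beam.validate()


# ---------------------------------------------------------------------------
# dva dialect I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("File Rev", "Plan ID", "Beam ID", "Total MU", "Gantry", "Number of Fields")


def _fmt_cm(position_mm: float) -> str:
    v = position_mm / 10.0
    # avoid "-0.000"
    if abs(v) < 5e-4:
        v = 0.0
    return f"{v:.3f}"


def write_mlc_file(beam: DynamicBeam, path) -> None:
    """Serialize a beam in the canonical ``dva`` dialect (validates first)."""
    beam.validate()
    n = beam.geometry.n_pairs
    buf = io.StringIO()
    buf.write("File Rev = G\n")
    buf.write(f"Plan ID = {beam.plan_id}\n")
    buf.write(f"Beam ID = {beam.beam_id}\n")
    buf.write(f"Total MU = {beam.total_mu:.2f}\n")
    buf.write(f"Gantry = {beam.gantry_angle:.1f}\n")
    buf.write(f"Number of Fields = {len(beam.control_points)}\n")
    for cp in beam.control_points:
        buf.write(f"Index = {cp.index:.6f}\n")
        for k in range(n):
            buf.write(f"Leaf {k + 1}A = {_fmt_cm(cp.bank_a[k])}\n")
        for k in range(n):
            buf.write(f"Leaf {k + 1}B = {_fmt_cm(cp.bank_b[k])}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_mlc_file(path, geometry: LeafBankGeometry | None = None) -> DynamicBeam:
    """Parse a ``dva``-dialect file into a validated :class:`DynamicBeam`."""
    geometry = geometry or millennium120()
    n = geometry.n_pairs
    with open(path) as fh:
        lines = fh.read().splitlines()

    header: dict[str, str] = {}
    pos = 0
    for pos, raw in enumerate(lines):
        if not raw.strip():
            continue
        if raw.startswith("Index"):
            break
        if "=" not in raw:
            raise MLCFileError(f"expected 'key = value', got {raw!r}", pos + 1)
        key, _, value = raw.partition("=")
        header[key.strip()] = value.strip()
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise MLCFileError(f"missing header key(s): {', '.join(missing)}", pos + 1)
    try:
        total_mu = float(header["Total MU"])
        gantry = float(header["Gantry"])
        n_fields = int(header["Number of Fields"])
    except ValueError as exc:
        raise MLCFileError(f"malformed header value: {exc}", pos + 1) from None

    control_points: list[ControlPoint] = []
    i = pos
    while i < len(lines):
        raw = lines[i]
        if not raw.strip():
            i += 1
            continue
        key, _, value = raw.partition("=")
        if key.strip() != "Index":
            raise MLCFileError(f"expected 'Index = ...', got {raw!r}", i + 1)
        try:
            index = float(value)
        except ValueError:
            raise MLCFileError(f"malformed index {value.strip()!r}", i + 1) from None
        if not 0.0 <= index <= 1.0:
            raise MLCFileError(f"index {index} outside [0, 1]", i + 1)
        if control_points and index < control_points[-1].index:
            raise MLCFileError(
                f"non-monotone index {index:.6f} after "
                f"{control_points[-1].index:.6f} (control point "
                f"{len(control_points) + 1})",
                i + 1,
            )
        banks = {"A": np.empty(n), "B": np.empty(n)}
        i += 1
        for bank in ("A", "B"):
            for k in range(n):
                if i >= len(lines):
                    raise MLCFileError("unexpected end of file in leaf block", i)
                key, _, value = lines[i].partition("=")
                expect = f"Leaf {k + 1}{bank}"
                if key.strip() != expect:
                    raise MLCFileError(
                        f"expected {expect!r}, got {key.strip()!r}", i + 1
                    )
                try:
                    banks[bank][k] = float(value) * 10.0  # cm -> mm
                except ValueError:
                    raise MLCFileError(
                        f"malformed position {value.strip()!r}", i + 1
                    ) from None
                i += 1
        cp = ControlPoint(index=index, bank_a=banks["A"], bank_b=banks["B"])
        try:
            cp.validate(n, atol_mm=1e-6)
        except ValueError as exc:
            raise MLCFileError(str(exc), i) from None
        control_points.append(cp)

    if len(control_points) != n_fields:
        raise MLCFileError(
            f"header declares {n_fields} control points, file has "
            f"{len(control_points)}"
        )
    beam = DynamicBeam(
        beam_id=header["Beam ID"],
        control_points=control_points,
        total_mu=total_mu,
        gantry_angle=gantry,
        geometry=geometry,
        plan_id=header["Plan ID"],
    )
    beam.validate()
    return beam
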