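"""MU-weighted fluence maps in the isocenter plane.

For each control-point interval the leaf tips move linearly in meterset
fraction.  A point x' in the row of pair k is inside the aperture while
``A(s) <= x' <= B(s)`` (s the normalized position within the interval).
Because tip motion is linear, the time a uniformly-sweeping tip spends
below x' is the uniform-distribution CDF of its sweep range, so the open
-time fraction has the closed form::

    T(x') = clip((x' - loA)/(hiA - loA), 0, 1) - clip((x' - loB)/(hiB - loB), 0, 1)

with ``lo``/``hi`` the per-interval sweep ranges of the A and B tips.
(The difference form holds because A <= B at all times, which makes
"behind A" and "behind B" nested events.)  Pixel values are the exact
average of T over the pixel footprint — the antiderivative of a clipped
ramp is piecewise quadratic — so no time subsampling is involved; the
per-pixel crossing times are integrated analytically.  Rows are mapped to
leaf pairs through the geometry's widths with area weighting where a
pixel straddles two pairs.

Leaf transmission is modelled as a uniform fraction of the interval MU
reaching covered pixels; tongue-and-groove, rounded leaf ends and head
scatter are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plan import DynamicBeam

__all__ = [
    "FluenceMap",
    "compute_fluence",
    "fluence_difference",
    "write_fluence_csv",
    "read_fluence_csv",
]


@dataclass
class FluenceMap:
    """MU-weighted open-time map on a regular grid (x = leaf travel)."""

    values: np.ndarray  # (ny, nx), MU
    x_mm: np.ndarray
    y_mm: np.ndarray
    beam_id: str = ""
    normalization: str = "none"

    @property
    def spacing_mm(self) -> float:
        return float(self.x_mm[1] - self.x_mm[0])

    def same_grid(self, other: "FluenceMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.x_mm, other.x_mm)
            and np.allclose(self.y_mm, other.y_mm)
        )

    def integral(self) -> float:
        """Integral of the map over the plane, MU * mm^2."""
        return float(self.values.sum()) * self.spacing_mm**2


def _ramp_antiderivative(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Antiderivative of clip((x - lo)/(hi - lo), 0, 1); step when hi == lo."""
    span = hi - lo
    degenerate = span <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        mid = (x - lo) ** 2 / (2.0 * np.where(degenerate, 1.0, span))
    out = np.where(
        x <= lo, 0.0, np.where(x >= hi, x - 0.5 * (lo + hi), mid)
    )
    step = np.maximum(x - lo, 0.0)
    return np.where(degenerate, step, out)


def _pair_row_weights(geometry, y_mm: np.ndarray) -> np.ndarray:
    """(n_pairs, ny) fraction of each pixel row covered by each pair."""
    h = y_mm[1] - y_mm[0] if len(y_mm) > 1 else 1.0
    lo_pix = y_mm - h / 2.0
    hi_pix = y_mm + h / 2.0
    edges = geometry.pair_edges_mm()
    lo_pair = edges[:-1][:, None]
    hi_pair = edges[1:][:, None]
    overlap = np.minimum(hi_pair, hi_pix[None, :]) - np.maximum(lo_pair, lo_pix[None, :])
    return np.clip(overlap, 0.0, None) / h


def compute_fluence(
    beam: DynamicBeam,
    spacing_mm: float = 1.0,
    transmission: float = 0.0,
    x_range_mm: tuple[float, float] = (-200.0, 200.0),
    y_range_mm: tuple[float, float] | None = None,
) -> FluenceMap:
    """Render the MU-weighted fluence of a dynamic beam.

    ``transmission`` is the fractional MU reaching pixels under a leaf
    (default 0: ideal aperture).  Grid spacing must lie in [0.1, 5] mm.
    """
    if not 0.1 <= spacing_mm <= 5.0:
        raise ValueError(f"spacing_mm must be in [0.1, 5], got {spacing_mm}")
    if not 0.0 <= transmission < 1.0:
        raise ValueError("transmission must be in [0, 1)")
    beam.validate()
    geometry = beam.geometry
    x = np.arange(x_range_mm[0], x_range_mm[1] + spacing_mm / 2.0, spacing_mm)
    if y_range_mm is None:
        half = geometry.total_width_mm / 2.0
        y_range_mm = (-half, half)
    y = np.arange(y_range_mm[0], y_range_mm[1] + spacing_mm / 2.0, spacing_mm)
    h = spacing_mm
    xl = x - h / 2.0
    xr = x + h / 2.0

    tips = beam.tip_array()  # (n_cp, 2, n_pairs)
    indices = beam.indices
    dmu = np.diff(indices) * beam.total_mu

    row_open = np.zeros((geometry.n_pairs, len(x)))  # open-time MU per pair row
    for j in range(len(dmu)):
        if dmu[j] <= 0:
            continue
        a0, a1 = tips[j, 0], tips[j + 1, 0]
        b0, b1 = tips[j, 1], tips[j + 1, 1]
        alo = np.minimum(a0, a1)[:, None]
        ahi = np.maximum(a0, a1)[:, None]
        blo = np.minimum(b0, b1)[:, None]
        bhi = np.maximum(b0, b1)[:, None]
        ia = _ramp_antiderivative(xr[None, :], alo, ahi) - _ramp_antiderivative(
            xl[None, :], alo, ahi
        )
        ib = _ramp_antiderivative(xr[None, :], blo, bhi) - _ramp_antiderivative(
            xl[None, :], blo, bhi
        )
        coverage = np.clip((ia - ib) / h, 0.0, 1.0)
        row_open += dmu[j] * coverage

    total = float(np.sum(dmu))
    if transmission > 0:
        row_open = row_open + transmission * (total - row_open)
    weights = _pair_row_weights(geometry, y)
    values = weights.T @ row_open
    return FluenceMap(values=values, x_mm=x, y_mm=y, beam_id=beam.beam_id)


def fluence_difference(a: FluenceMap, b: FluenceMap) -> tuple[np.ndarray, dict]:
    """Signed difference map ``a - b`` and a summary (max/mean |delta|)."""
    if not a.same_grid(b):
        raise ValueError("fluence maps are on different grids")
    diff = a.values - b.values
    summary = {
        "max_abs": float(np.max(np.abs(diff))),
        "mean_abs": float(np.mean(np.abs(diff))),
        "max": float(diff.max()),
        "min": float(diff.min()),
    }
    return diff, summary


def write_fluence_csv(fmap: FluenceMap, path) -> None:
    """Portable text format: '#' header (grid metadata) + CSV of values."""
    header = (
        f"beam_id = {fmap.beam_id}\n"
        f"spacing_mm = {fmap.spacing_mm:.6g}\n"
        f"x0_mm = {fmap.x_mm[0]:.6g}\n"
        f"y0_mm = {fmap.y_mm[0]:.6g}\n"
        f"nx = {len(fmap.x_mm)}\n"
        f"ny = {len(fmap.y_mm)}"
    )
    np.savetxt(path, fmap.values, delimiter=",", header=header, fmt="%.8g")


def read_fluence_csv(path) -> FluenceMap:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
    values = np.loadtxt(path, delimiter=",", comments="#")
    spacing = float(meta["spacing_mm"])
    nx, ny = int(meta["nx"]), int(meta["ny"])
    values = values.reshape(ny, nx)
    x = float(meta["x0_mm"]) + spacing * np.arange(nx)
    y = float(meta["y0_mm"]) + spacing * np.arange(ny)
    return FluenceMap(values=values, x_mm=x, y_mm=y, beam_id=meta.get("beam_id", ""))
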