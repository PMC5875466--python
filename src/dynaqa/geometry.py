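"""Leaf-bank geometry of the multileaf collimator.

The toolkit models a Millennium-120-style MLC: two opposed banks (A and B)
of 60 leaf pairs each.  Leaf widths are projected to the isocenter plane:
the central 40 pairs are 5.0 mm wide, the 10 outermost pairs on each side
are 10.0 mm wide, for a total cross-pair extent of 400 mm.

Coordinate convention (used everywhere in the package):

* ``x`` is the leaf-travel axis in mm at the isocenter plane.  Bank-A
  leaves approach from -x, bank-B leaves from +x; the aperture of pair
  ``k`` is the open interval ``(tip_a[k], tip_b[k])``.
* ``y`` runs across the leaf pairs; pair 0 occupies the most negative
  ``y`` interval.

A closed pair is represented by ``tip_a == tip_b`` (zero gap), not by a
sentinel value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LeafBankGeometry", "millennium120"]

BANKS = ("A", "B")


@dataclass(frozen=True)
class LeafBankGeometry:
    """Per-pair leaf widths of a two-bank MLC, projected to isocenter."""

    leaf_widths_mm: tuple[float, ...]
    banks: tuple[str, str] = BANKS

    def __post_init__(self) -> None:
        widths = np.asarray(self.leaf_widths_mm, dtype=float)
        if widths.ndim != 1 or widths.size == 0:
            raise ValueError("leaf_widths_mm must be a non-empty 1-D sequence")
        if np.any(widths <= 0):
            raise ValueError("leaf widths must be positive")
        if len(self.banks) != 2:
            raise ValueError("exactly two banks are required")

    @property
    def n_pairs(self) -> int:
        return len(self.leaf_widths_mm)

    @property
    def total_width_mm(self) -> float:
        return float(np.sum(self.leaf_widths_mm))

    def pair_edges_mm(self) -> np.ndarray:
        """y coordinates of the n_pairs+1 leaf-side boundaries, centered on 0."""
        widths = np.asarray(self.leaf_widths_mm, dtype=float)
        edges = np.concatenate([[0.0], np.cumsum(widths)])
        return edges - edges[-1] / 2.0

    def pair_centers_mm(self) -> np.ndarray:
        edges = self.pair_edges_mm()
        return 0.5 * (edges[:-1] + edges[1:])


def millennium120() -> LeafBankGeometry:
    """Standard 60-pair geometry: 10x10 mm + 40x5 mm + 10x10 mm (400 mm total)."""
    widths = (10.0,) * 10 + (5.0,) * 40 + (10.0,) * 10
    return LeafBankGeometry(leaf_widths_mm=widths)
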