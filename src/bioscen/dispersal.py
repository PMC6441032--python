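"""Dispersal assumptions as cell masks.

Two assumptions bracket a species' reachable area over the scenario horizon:
'no dispersal' keeps the species inside its current range, 'limited dispersal'
lets it reach every cell within a taxon-specific maximal distance of that
range.  Distances are planar Euclidean between cell centres, boundary
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .world import Grid

# Taxon -> buffer distance (km), used for both pseudo-absence sampling and the
# limited-dispersal domain.
DEFAULT_BUFFER_KM = {"amphibian": 2000.0, "mammal": 3000.0, "bird": 4000.0}

NO_DISPERSAL = "no_dispersal"
LIMITED_DISPERSAL = "limited_dispersal"


class DispersalError(ValueError):
    pass


@dataclass
class DispersalMask:
    species_id: str
    assumption: str
    mask: np.ndarray  # boolean, grid shape
    distance_km: float | None = None


def limited_dispersal_mask(
    range_mask: np.ndarray, grid: Grid, distance_km: float, species_id: str = ""
) -> DispersalMask:
    """Cells whose centre lies within ``distance_km`` of any range-cell centre."""
    if distance_km < 0:
        raise DispersalError("distance_km must be >= 0")
    if not range_mask.any():
        raise DispersalError(f"{species_id or 'species'}: empty range")
    centers = grid.cell_centers_km()
    src = centers[range_mask.ravel()]
    tree = cKDTree(src)
    dist, _ = tree.query(centers, k=1)
    # inclusive boundary, robust to float rounding of exact lattice distances
    tol = 1e-9 * max(distance_km, grid.cell_size_km)
    mask = (dist <= distance_km + tol).reshape(grid.shape)
    return DispersalMask(species_id, LIMITED_DISPERSAL, mask, float(distance_km))


def no_dispersal_mask(range_mask: np.ndarray, species_id: str = "") -> DispersalMask:
    """The current range, exactly."""
    if not range_mask.any():
        raise DispersalError(f"{species_id or 'species'}: empty range")
    return DispersalMask(species_id, NO_DISPERSAL, range_mask.copy(), None)
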