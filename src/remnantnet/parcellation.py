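"""Region-level parcellation metadata.

A parcellation is the common coordinate frame of every network in the
package: an ordered list of cortical regions, each with a hemisphere
label, a centroid in millimetres and a volume in cubic millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["Parcellation", "read_parcellation", "write_parcellation"]

_HEMIS = frozenset({"L", "R"})


@dataclass(frozen=True)
class Parcellation:
    """Ordered region metadata: ids, hemispheres, centroids (mm), volumes (mm^3)."""

    region_id: tuple
    hemisphere: tuple
    centroid: np.ndarray
    volume: np.ndarray

    def __post_init__(self):
        ids = tuple(self.region_id)
        hemi = tuple(self.hemisphere)
        cent = np.asarray(self.centroid, dtype=float)
        vol = np.asarray(self.volume, dtype=float)
        n = len(ids)
        if len(set(ids)) != n:
            raise ValueError("region ids must be unique")
        if len(hemi) != n or cent.shape != (n, 3) or vol.shape != (n,):
            raise ValueError("parcellation field lengths disagree")
        if not set(hemi) <= _HEMIS:
            raise ValueError(f"hemisphere labels must be in {{L, R}}, got {set(hemi) - _HEMIS}")
        if not np.all(np.isfinite(cent)):
            raise ValueError("centroids must be finite")
        if not np.all(vol > 0):
            raise ValueError("volumes must be strictly positive")
        object.__setattr__(self, "region_id", ids)
        object.__setattr__(self, "hemisphere", hemi)
        object.__setattr__(self, "centroid", cent)
        object.__setattr__(self, "volume", vol)

    @property
    def n_regions(self) -> int:
        return len(self.region_id)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean inter-centroid distances (mm), zero diagonal."""
        return squareform(pdist(self.centroid))

    def hemisphere_index(self) -> np.ndarray:
        """Boolean vector, True where the region is in the left hemisphere."""
        return np.asarray([h == "L" for h in self.hemisphere])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_id,
                "hemisphere": self.hemisphere,
                "x": self.centroid[:, 0],
                "y": self.centroid[:, 1],
                "z": self.centroid[:, 2],
                "volume": self.volume,
            }
        )


def read_parcellation(path) -> Parcellation:
    """Read a six-column delimited table (id, hemisphere, x, y, z, volume)."""
    df = pd.read_csv(path, sep=None, engine="python")
    return Parcellation(
        region_id=tuple(df.iloc[:, 0]),
        hemisphere=tuple(df.iloc[:, 1]),
        centroid=df.iloc[:, 2:5].to_numpy(dtype=float),
        volume=df.iloc[:, 5].to_numpy(dtype=float),
    )


def write_parcellation(parcels: Parcellation, path) -> None:
    parcels.to_frame().to_csv(path, index=False)
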