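"""Cell geometry: the 3-D lattice of Ca release units (CRUs).

The default cell is 65 x 27 x 11 CRUs (19,305 total, ~1.93 million RyRs),
with 1.84 um longitudinal and 0.9 um transverse spacing.  Each CRU carries a
cluster of 1-25 LTCCs whose size is drawn from a rounded Gaussian with mean
10 and standard deviation 3, clamped to [1, 25].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as K

__all__ = ["CellGeometry", "draw_cluster_sizes", "resting_concentrations"]


@dataclass(frozen=True)
class CellGeometry:
    nx: int = K.GRID_NX
    ny: int = K.GRID_NY
    nz: int = K.GRID_NZ
    dx_long: float = K.DX_LONG
    dx_trans: float = K.DX_TRANS
    cluster_mean: float = K.CLUSTER_MEAN
    cluster_sd: float = K.CLUSTER_SD
    cluster_min: int = K.CLUSTER_MIN
    cluster_max: int = K.CLUSTER_MAX
    n_ryr: int = K.N_RYR_PER_CRU

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.cluster_sd < 0:
            raise ValueError("cluster_sd must be >= 0")

    @property
    def n_cru(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def n_ryr_total(self) -> int:
        return self.n_cru * self.n_ryr

    @classmethod
    def reduced(cls, nx: int = 16, ny: int = 8, nz: int = 4, **kw) -> "CellGeometry":
        """Desk-scale lattice used by tests and scaled-down protocols."""
        return cls(nx=nx, ny=ny, nz=nz, **kw)


def draw_cluster_sizes(geometry: CellGeometry, seed: int) -> np.ndarray:
    """LTCC cluster size per CRU: rounded N(mean, sd^2), clamped to bounds."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(geometry.cluster_mean, geometry.cluster_sd, geometry.n_cru)
    sizes = np.clip(np.rint(raw), geometry.cluster_min, geometry.cluster_max)
    return sizes.astype(np.int64)


def resting_concentrations() -> dict[str, float]:
    """Documented resting values (uM) used to initialise every CRU."""
    return {"ci": 0.1, "cs": 0.1, "cp": 0.1, "cnsr": 800.0, "cjsr": 800.0}
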