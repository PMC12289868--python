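"""Windowed porosity maps: the four response variables on a 0.9 mm grid.

Each cubic window of the label volume yields four percentages of the colony
(non-mask) volume it contains: microporosity (MiP), macroporosity (MaP),
total porosity (TP = MiP + MaP) and solid volume fraction (SVF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import AIR, MASK, MICROPORE, SOLID, PhaseLabelVolume

VARIABLES = ("MiP", "MaP", "TP", "SVF")


@dataclass
class PorosityMap:
    """Full 3D grid of windows, one DataFrame row per window.

    Columns: window indices ``i, j, k``; window-center coordinates in voxels
    and in physical mm; raw phase counts; the four variables; the colony
    fraction (non-mask voxels relative to the nominal window volume); and a
    validity flag.  Windows with
    too little colony volume are flagged invalid and excluded from all
    downstream statistics but kept in the grid so the map replicates the
    fragment's shape.
    """

    windows: pd.DataFrame
    window_size_mm: float
    voxel_size_um: float
    fragment_id: str = ""

    def __post_init__(self) -> None:
        if not self.window_size_mm > 0:
            raise ValueError("window_size_mm must be > 0")

    @property
    def valid(self) -> pd.DataFrame:
        return self.windows[self.windows["valid"]]


def compute_porosity_map(
    phases: PhaseLabelVolume,
    window_size_mm: float = 0.9,
    min_colony_fraction: float = 0.05,
    stride_mm: float | None = None,
) -> PorosityMap:
    """Tile the label volume into cubic windows and compute MiP/MaP/TP/SVF.

    The window edge is rounded to the nearest whole voxel count and the grid
    is anchored at the colony's bounding box.  Windows are non-overlapping by
    default (stride = size); edge windows shorter than the full edge are kept
    when they reach ``min_colony_fraction``, otherwise flagged invalid.

    Per window, with colony count ``c = solid + micro + air``:
    ``MiP = 100·micro/c``, ``MaP = 100·air/c``, ``SVF = 100·solid/c`` and
    ``TP = MiP + MaP`` exactly by construction.
    """
    labels = phases.labels
    vox_mm = phases.voxel_size_um / 1000.0
    w = int(round(window_size_mm / vox_mm))
    if w < 1:
        raise ValueError(
            f"window of {window_size_mm} mm is smaller than one voxel ({vox_mm} mm)"
        )
    s = w if stride_mm is None else max(1, int(round(stride_mm / vox_mm)))

    colony = labels != MASK
    if not colony.any():
        raise ValueError("label volume contains no colony voxels")
    idx = [np.where(colony.any(axis=tuple(a for a in range(3) if a != ax)))[0]
           for ax in range(3)]
    starts = [int(ix[0]) for ix in idx]
    stops = [int(ix[-1]) + 1 for ix in idx]

    rows = []
    for i, xlo in enumerate(range(starts[0], stops[0], s)):
        xhi = min(xlo + w, stops[0])
        for j, ylo in enumerate(range(starts[1], stops[1], s)):
            yhi = min(ylo + w, stops[1])
            for k, zlo in enumerate(range(starts[2], stops[2], s)):
                zhi = min(zlo + w, stops[2])
                block = labels[xlo:xhi, ylo:yhi, zlo:zhi]
                n_solid = int(np.count_nonzero(block == SOLID))
                n_micro = int(np.count_nonzero(block == MICROPORE))
                n_air = int(np.count_nonzero(block == AIR))
                n_mask = block.size - n_solid - n_micro - n_air
                n_col = n_solid + n_micro + n_air
                # fraction of the *nominal* window volume, so windows clipped
                # at the grid edge are judged by the same yardstick as full
                # ones and thin slivers fall below the validity threshold
                colony_fraction = n_col / float(w * w * w)
                valid = colony_fraction >= min_colony_fraction
                if n_col > 0:
                    mip = 100.0 * n_micro / n_col
                    map_ = 100.0 * n_air / n_col
                    svf = 100.0 * n_solid / n_col
                else:
                    mip = map_ = svf = np.nan
                    valid = False
                cx, cy, cz = 0.5 * (xlo + xhi), 0.5 * (ylo + yhi), 0.5 * (zlo + zhi)
                rows.append((
                    i, j, k, cx, cy, cz,
                    cx * vox_mm, cy * vox_mm, cz * vox_mm,
                    n_solid, n_micro, n_air, n_mask,
                    mip, map_, mip + map_, svf, colony_fraction, valid,
                ))
    df = pd.DataFrame(rows, columns=[
        "i", "j", "k", "cx_vox", "cy_vox", "cz_vox", "cx_mm", "cy_mm", "cz_mm",
        "n_solid", "n_micro", "n_air", "n_mask",
        "MiP", "MaP", "TP", "SVF", "colony_fraction", "valid",
    ])
    if not df["valid"].any():
        raise ValueError("all windows invalid (colony fraction below threshold everywhere)")
    return PorosityMap(
        windows=df,
        window_size_mm=window_size_mm,
        voxel_size_um=phases.voxel_size_um,
        fragment_id=phases.fragment_id,
    )


def fragment_mean(pmap: PorosityMap) -> pd.DataFrame:
    """Per-variable mean and standard error over the map's valid windows.

    Windows are equally weighted regardless of how much colony volume they
    hold, so mean TP + mean SVF need not equal 100% — the summaries are
    deliberately not renormalized.  The s.e.m. is sd/sqrt(n) with ddof=1; a
    single-window map reports s.e.m. 0 with its n recorded.
    """
    valid = pmap.valid
    if valid.empty:
        raise ValueError("porosity map has no valid windows")
    n = len(valid)
    out = []
    for var in VARIABLES:
        vals = valid[var].to_numpy(dtype=float)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append((var, float(vals.mean()), sem, n))
    return pd.DataFrame(out, columns=["variable", "mean", "sem", "n"])
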