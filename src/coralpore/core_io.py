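"""Volume and tabular I/O, fragment metadata, run configuration and logging.

Tomographic volumes travel as NetCDF (read and written through xarray's
scipy backend); porosity maps, profiles and statistics tables are plain CSV
so that every numeric artifact of a run can be diffed and re-read exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import xarray as xr
import yaml

logger = logging.getLogger("coralpore")

#: canonical axis order for all volumes in this package
AXES = ("x", "y", "z")


def configure_logging(level: str = "INFO") -> None:
    """Install a plain stderr handler with stage/fragment context in messages."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass
class Tomogram:
    """A 3D X-ray attenuation volume with its physical voxel size.

    The third array axis is the vertical (Z) axis, oriented apical (living
    tissue, index 0) to basal.  Volumes scanned the other way are flipped on
    read via the ``flip_z`` config flag.
    """

    intensities: np.ndarray
    voxel_size_um: float
    fragment_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"Tomogram needs a 3D volume, got {self.intensities.ndim}D"
            )
        if min(self.intensities.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities must be finite")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths (x, y, z) in millimeters."""
        return tuple(n * self.voxel_size_mm for n in self.shape)  # type: ignore[return-value]


@dataclass
class FragmentMeta:
    """Per-fragment metadata consumed from config (not computed).

    ``green_band_range_mm`` is the stereoscope-measured extent of the
    pigmented endolithic band on the vertical mm scale.
    """

    fragment_id: str
    species: str
    location: str
    depth_m: float
    green_band_range_mm: tuple[float, float]
    selected_for_intracolonial: bool = False
    annotations: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        low, high = self.green_band_range_mm
        if not (0 <= low < high):
            raise ValueError(
                f"fragment {self.fragment_id}: green band interval must satisfy "
                f"0 <= low < high, got [{low}, {high}]"
            )
        if self.depth_m < 0:
            raise ValueError(f"fragment {self.fragment_id}: depth_m must be >= 0")

    @property
    def band_midpoint_mm(self) -> float:
        low, high = self.green_band_range_mm
        return 0.5 * (low + high)


@dataclass
class RunConfig:
    """Pipeline configuration with the study's default scale constants.

    window_size_mm
        Edge of the cubic porosity-analysis window (0.9 mm).
    conversion_factor_mm / correction_factor_mm
        Vertical-scale constants: the normalized coordinate is stretched by
        the length of the largest porosity map (8 mm) and shifted by half a
        window (0.45 mm) so each profile point sits at its window center.
    threshold_mode
        "auto" (multi-level histogram criterion) or "fixed" (t_low/t_high).
    """

    window_size_mm: float = 0.9
    threshold_mode: str = "auto"
    t_low: float | None = None
    t_high: float | None = None
    loess_span: float = 0.3
    conversion_factor_mm: float = 8.0
    correction_factor_mm: float = 0.45
    vertical_scale_max_mm: float = 10.0
    min_colony_fraction: float = 0.05
    flip_z: bool = False
    nc_variable: str | None = None
    voxel_size_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.window_size_mm > 0:
            raise ValueError("window_size_mm must be > 0")
        if not (0 < self.loess_span <= 1):
            raise ValueError(f"LOESS span must be in (0, 1], got {self.loess_span}")
        if not (self.conversion_factor_mm > 0 and self.correction_factor_mm > 0):
            raise ValueError("conversion and correction factors must be > 0")
        if self.threshold_mode not in ("auto", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed":
            if self.t_low is None or self.t_high is None:
                raise ValueError("fixed threshold mode requires t_low and t_high")
            if not self.t_low < self.t_high:
                raise ValueError("t_low must be < t_high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


# ---------------------------------------------------------------------------
# Tomogram NetCDF I/O

VOXEL_ATTR = "voxel_size_um"


def write_tomogram(tomogram: Tomogram, path: str | Path, variable: str = "intensity") -> None:
    """Write a tomogram to NetCDF with its voxel size as a global attribute."""
    ds = xr.Dataset(
        {variable: (AXES, tomogram.intensities)},
        attrs={VOXEL_ATTR: float(tomogram.voxel_size_um),
               "fragment_id": tomogram.fragment_id},
    )
    ds.to_netcdf(path, engine="scipy")


def read_tomogram(
    path: str | Path,
    fragment_id: str = "",
    variable: str | None = None,
    voxel_size_um: float | None = None,
    flip_z: bool = False,
) -> Tomogram:
    """Read a 3D volume from a NetCDF file.

    Parameters
    ----------
    variable
        NetCDF variable holding the volume.  By default the first 3D variable
        in the file is used, since deposited scans do not share a schema.
    voxel_size_um
        Override for files lacking a ``voxel_size_um`` attribute.  If the file
        carries neither, reading fails: every millimeter-scale output depends
        on the voxel size and it is never silently defaulted.
    flip_z
        Reverse the vertical axis so that index 0 is apical.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tomogram file not found: {path}")
    ds = xr.open_dataset(path, engine="scipy")
    try:
        if variable is not None:
            if variable not in ds:
                raise KeyError(f"variable {variable!r} not in {path}")
            da = ds[variable]
            if da.ndim != 3:
                raise ValueError(
                    f"variable {variable!r} in {path} is {da.ndim}D, expected 3D"
                )
        else:
            candidates = [name for name in ds.data_vars if ds[name].ndim == 3]
            if not candidates:
                raise ValueError(f"no 3D volume found in {path}")
            da = ds[candidates[0]]
        vox = voxel_size_um
        if vox is None:
            vox = ds.attrs.get(VOXEL_ATTR, da.attrs.get(VOXEL_ATTR))
        if vox is None:
            raise ValueError(
                f"{path}: no {VOXEL_ATTR!r} attribute on file or variable "
                f"{da.name!r}; supply voxel_size_um explicitly"
            )
        if not fragment_id:
            fragment_id = str(ds.attrs.get("fragment_id", path.stem))
        data = np.asarray(da.values, dtype=np.float64)
    finally:
        ds.close()
    if flip_z:
        data = data[:, :, ::-1]
    logger.info("read_tomogram fragment=%s shape=%s voxel_um=%s", fragment_id, data.shape, vox)
    return Tomogram(intensities=data, voxel_size_um=float(vox), fragment_id=fragment_id)


def write_labels(labels: np.ndarray, path: str | Path, provenance: dict[str, Any] | None = None) -> None:
    """Write an integer phase-label volume (codes 0=MASK,1=AIR,2=MICROPORE,3=SOLID)."""
    attrs: dict[str, Any] = {"codes": "0=MASK,1=AIR,2=MICROPORE,3=SOLID"}
    for k, v in (provenance or {}).items():
        if v is not None:
            attrs[k] = v
    ds = xr.Dataset({"labels": (AXES, labels.astype(np.int16))}, attrs=attrs)
    ds.to_netcdf(path, engine="scipy")


def read_labels(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    ds = xr.open_dataset(path, engine="scipy")
    try:
        labels = np.asarray(ds["labels"].values, dtype=np.int16)
        attrs = dict(ds.attrs)
    finally:
        ds.close()
    return labels, attrs


# ---------------------------------------------------------------------------
# Porosity map CSV I/O

PMAP_COLUMNS = [
    "i", "j", "k",
    "cx_vox", "cy_vox", "cz_vox",
    "cx_mm", "cy_mm", "cz_mm",
    "n_solid", "n_micro", "n_air", "n_mask",
    "MiP", "MaP", "TP", "SVF",
    "colony_fraction", "valid",
]


def write_porosity_map(pmap: "PorosityMapLike", path: str | Path) -> None:
    """Write a porosity map as CSV, one row per window, full float precision.

    The numeric columns round-trip bit exactly through
    :func:`read_porosity_map` (floats are serialized with repr precision).
    """
    df = pmap.windows
    if df.empty:
        raise ValueError("refusing to write an empty porosity map")
    header = {
        "fragment_id": pmap.fragment_id,
        "window_size_mm": repr(pmap.window_size_mm),
        "voxel_size_um": repr(pmap.voxel_size_um),
    }
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        # shortest-repr floats + round_trip parsing give bit-exact recovery
        df.to_csv(fh, index=False)


def read_porosity_map(path: str | Path) -> "PorosityMapLike":
    from .porosity_mapping import PorosityMap

    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    df["valid"] = df["valid"].astype(bool)
    return PorosityMap(
        windows=df,
        window_size_mm=float(meta["window_size_mm"]),
        voxel_size_um=float(meta["voxel_size_um"]),
        fragment_id=meta.get("fragment_id", ""),
    )


# forward-declared protocol: anything with .windows/.window_size_mm/...
PorosityMapLike = Any


# ---------------------------------------------------------------------------
# Fragment metadata

_REQUIRED_META = ("fragment_id", "species", "location", "depth_m", "green_band_range_mm")


def load_fragment_metadata(path: str | Path) -> list[FragmentMeta]:
    """Load fragment metadata from a YAML file.

    The file holds a list (or a ``fragments:`` list) of mappings with keys
    ``fragment_id, species, location, depth_m, green_band_range_mm`` and
    optionally ``selected_for_intracolonial``.  Unknown keys are preserved on
    ``FragmentMeta.annotations``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = data.get("fragments", data)
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a list of fragment entries")
    out = []
    for entry in data:
        missing = [k for k in _REQUIRED_META if k not in entry]
        if missing:
            raise ValueError(
                f"{path}: fragment entry {entry.get('fragment_id', '<unnamed>')!r} "
                f"missing required field(s): {', '.join(missing)}"
            )
        known = set(_REQUIRED_META) | {"selected_for_intracolonial"}
        gb = entry["green_band_range_mm"]
        out.append(
            FragmentMeta(
                fragment_id=str(entry["fragment_id"]),
                species=str(entry["species"]),
                location=str(entry["location"]),
                depth_m=float(entry["depth_m"]),
                green_band_range_mm=(float(gb[0]), float(gb[1])),
                selected_for_intracolonial=bool(entry.get("selected_for_intracolonial", False)),
                annotations={k: v for k, v in entry.items() if k not in known},
            )
        )
    return out
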