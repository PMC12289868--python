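"""Masking filter and four-phase segmentation of attenuation volumes.

Every voxel ends up in exactly one of four categories: SOLID (dense
carbonate skeleton), AIR (resolvable voids, i.e. macropores), MICROPORE
(intermediate attenuation from sub-resolution pores, the partial-volume
signature of boring channels), or MASK (container, separators, and air
connected to the exterior of the colony — large voids open to the outside
are not pores).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .core_io import Tomogram

MASK, AIR, MICROPORE, SOLID = 0, 1, 2, 3
LABEL_NAMES = {MASK: "MASK", AIR: "AIR", MICROPORE: "MICROPORE", SOLID: "SOLID"}


@dataclass
class PhaseLabelVolume:
    """Per-voxel phase labels over the same lattice as the source tomogram."""

    labels: np.ndarray
    voxel_size_um: float
    fragment_id: str = ""
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        bad = ~np.isin(self.labels, (MASK, AIR, MICROPORE, SOLID))
        if bad.any():
            raise ValueError("labels contain values outside {MASK, AIR, MICROPORE, SOLID}")

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == code))
            for code, name in LABEL_NAMES.items()
        }


def _boundary_components(mask: np.ndarray, structure: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` whose connected component touches the volume boundary."""
    lab, _ = ndimage.label(mask, structure=structure)
    boundary_labels = np.unique(
        np.concatenate([
            lab[0, :, :].ravel(), lab[-1, :, :].ravel(),
            lab[:, 0, :].ravel(), lab[:, -1, :].ravel(),
            lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
        ])
    )
    boundary_labels = boundary_labels[boundary_labels != 0]
    return np.isin(lab, boundary_labels)


def apply_mask_filter(
    tomogram: Tomogram,
    air_threshold: float,
    container_threshold: float | None = None,
    keep_largest_component: bool = True,
    connectivity: int = 1,
) -> np.ndarray:
    """Return a boolean colony mask (True = colony voxel).

    Air-intensity voxels connected to the volume boundary by face adjacency
    are flagged as exterior (MASK-eligible) — enclosed voids inside the
    colony stay colony voxels and remain candidate macropores.  Container and
    separator artifacts are removed by two complementary policies:

    * ``container_threshold`` — voxels at or above this intensity are masked
      (the tube material occupies its own intensity band);
    * ``keep_largest_component`` (default) — among the non-exterior voxels,
      only the largest connected component is kept as the colony.  The tube
      wall and fragment separators are bathed in exterior air and therefore
      form their own, much smaller components, so this removes them without
      needing to know their attenuation.

    Parameters
    ----------
    connectivity
        1 for 6-connectivity (face adjacency, default; conservative against
        diagonal leaks through thin walls) or 3 for 26-connectivity.
    """
    vol = tomogram.intensities
    air_like = vol < air_threshold
    structure = ndimage.generate_binary_structure(3, connectivity)
    exterior = _boundary_components(air_like, structure=structure)

    masked = exterior
    if container_threshold is not None:
        masked = masked | (vol >= container_threshold)

    colony = ~masked
    if keep_largest_component and colony.any():
        lab, n = ndimage.label(colony, structure=structure)
        if n > 1:
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            colony = lab == int(np.argmax(sizes))

    if not colony.any():
        raise ValueError(f"no colony found: mask covers the entire volume of {tomogram.fragment_id or 'tomogram'}")
    return colony


def select_thresholds(
    tomogram: Tomogram,
    mode: str = "auto",
    t_low: float | None = None,
    t_high: float | None = None,
    colony_mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Choose the two intensity cut points separating air / micropore / solid.

    ``auto`` applies a three-class multi-level Otsu criterion to the
    intensity histogram of colony (non-mask) voxels; ``fixed`` returns the
    supplied thresholds unchanged.
    """
    if mode == "fixed":
        if t_low is None or t_high is None:
            raise ValueError("fixed mode requires t_low and t_high")
        if not t_low < t_high:
            raise ValueError(f"need t_low < t_high, got {t_low} >= {t_high}")
        return float(t_low), float(t_high)
    if mode != "auto":
        raise ValueError(f"unknown threshold mode {mode!r}")

    values = tomogram.intensities if colony_mask is None else tomogram.intensities[colony_mask]
    if np.unique(values).size < 3:
        raise ValueError(
            "automatic threshold selection needs >= 3 distinct intensity values"
        )
    lo, hi = threshold_multiotsu(values.ravel(), classes=3)
    return float(lo), float(hi)


def segment_phases(
    tomogram: Tomogram,
    colony_mask: np.ndarray,
    t_low: float,
    t_high: float,
) -> PhaseLabelVolume:
    """Label every voxel: AIR < t_low <= MICROPORE < t_high <= SOLID; mask voxels MASK.

    Deterministic whole-voxel classification; no morphological cleanup is
    applied by default.
    """
    if not t_low < t_high:
        raise ValueError(f"need t_low < t_high, got {t_low} >= {t_high}")
    if colony_mask.shape != tomogram.shape:
        raise ValueError("colony mask shape does not match tomogram")
    vol = tomogram.intensities
    labels = np.full(vol.shape, MASK, dtype=np.int16)
    labels[colony_mask & (vol < t_low)] = AIR
    labels[colony_mask & (vol >= t_low) & (vol < t_high)] = MICROPORE
    labels[colony_mask & (vol >= t_high)] = SOLID
    return PhaseLabelVolume(
        labels=labels,
        voxel_size_um=tomogram.voxel_size_um,
        fragment_id=tomogram.fragment_id,
        provenance={"t_low": float(t_low), "t_high": float(t_high)},
    )


def segment_tomogram(
    tomogram: Tomogram,
    air_threshold: float | None = None,
    container_threshold: float | None = None,
    mode: str = "auto",
    t_low: float | None = None,
    t_high: float | None = None,
    connectivity: int = 1,
) -> PhaseLabelVolume:
    """Convenience wrapper: mask, select thresholds, segment.

    When ``air_threshold`` is not given it is bootstrapped from a first
    multi-level Otsu pass over the whole volume (the lower cut separates the
    air mode).  Container artifacts are removed by the largest-component
    policy of :func:`apply_mask_filter`; an explicit ``container_threshold``
    may be supplied in addition.
    """
    if air_threshold is None:
        lo, _hi = select_thresholds(tomogram, mode="auto")
        air_threshold = lo
    colony = apply_mask_filter(
        tomogram,
        air_threshold=air_threshold,
        container_threshold=container_threshold,
        connectivity=connectivity,
    )
    lo, hi = select_thresholds(tomogram, mode=mode, t_low=t_low, t_high=t_high, colony_mask=colony)
    out = segment_phases(tomogram, colony, lo, hi)
    out.provenance.update(
        air_threshold=float(air_threshold),
        container_threshold=None if container_threshold is None else float(container_threshold),
    )
    return out
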