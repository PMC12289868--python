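"""Synthetic coral-skeleton phantoms with known phase ground truth.

A phantom emulates the features of a scanned skeletal fragment that the
pipeline must handle: a solid carbonate matrix, resolvable voids
(macropores), a sub-resolution micropore phase expressed as intermediate
attenuation, a depth-localized "green band" with elevated microporosity and
depressed macroporosity, an exterior air field plus a container wall to give
the masking filter realistic work, and additive Gaussian intensity noise.

Macropores are Boolean-model spheres: centers follow an inhomogeneous
Poisson process along Z with intensity chosen so the expected void volume
fraction matches the requested profile (for a Poisson Boolean model the
covered fraction is ``1 - exp(-lambda * mean_sphere_volume)``).  Micropores
are single voxels of intermediate intensity — a partial-volume proxy for
boring channels below the scan resolution — drawn per voxel at a
Z-dependent rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .core_io import Tomogram
from .segmentation import AIR, MASK, MICROPORE, SOLID


@dataclass
class SyntheticTruth:
    """Generator parameters: the ground truth a phantom is built from.

    Band profile: a Gaussian bump (optionally skewed toward the apical end)
    centered on ``band_center_mm`` with full width at half maximum
    ``band_width_mm``.  The bump raises the micropore fraction by
    ``mip_amplitude_pct`` and lowers the macropore fraction by
    ``map_decrement_pct`` at its center.  All fractions are percentages of
    colony volume.
    """

    band_center_mm: float = 2.5
    band_width_mm: float = 1.2
    mip_baseline_pct: float = 5.0
    mip_amplitude_pct: float = 5.0
    map_baseline_pct: float = 35.0
    map_decrement_pct: float = 10.0
    macropore_radius_mm: tuple[float, float] = (0.1, 0.5)
    #: skew < 0 leans the band toward the apical (low-Z) side
    band_skew: float = 0.0
    air_level: float = 0.0
    micropore_level: float = 100.0
    solid_level: float = 200.0
    container_level: float = 250.0
    noise_sd: float = 10.0  # 5% of the solid-air gap at default levels
    air_margin_vox: int = 4
    container_thickness_vox: int = 2
    #: solid crust kept free of macropores so the colony surface stays closed
    #: (radial; the axial crust is thinner to keep edge windows representative)
    crust_vox: int = 2
    crust_axial_vox: int = 1
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.air_level < self.micropore_level < self.solid_level):
            raise ValueError("phase intensity levels must satisfy air < micropore < solid")
        for name in ("mip_baseline_pct", "map_baseline_pct"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.mip_baseline_pct + self.mip_amplitude_pct > 100 or self.mip_baseline_pct + self.mip_amplitude_pct < 0:
            raise ValueError("micropore baseline + amplitude must stay within [0, 100]")
        if not (0 <= self.map_baseline_pct - self.map_decrement_pct <= 100):
            raise ValueError("macropore baseline - decrement must stay within [0, 100]")
        if self.macropore_radius_mm[0] > self.macropore_radius_mm[1]:
            raise ValueError("macropore radius range inverted")

    def band_profile(self, z_mm: np.ndarray) -> np.ndarray:
        """Unit-peak band shape evaluated at vertical positions (mm)."""
        sigma = self.band_width_mm / 2.3548200450309493  # FWHM -> sigma
        u = (np.asarray(z_mm, dtype=float) - self.band_center_mm) / sigma
        g = np.exp(-0.5 * u * u)
        if self.band_skew:
            g = g * (1.0 + erf(self.band_skew * u / np.sqrt(2.0)))
            peak = g.max()
            if peak > 0:
                g = g / peak
        return g

    def mip_target_pct(self, z_mm: np.ndarray) -> np.ndarray:
        return self.mip_baseline_pct + self.mip_amplitude_pct * self.band_profile(z_mm)

    def map_target_pct(self, z_mm: np.ndarray) -> np.ndarray:
        return self.map_baseline_pct - self.map_decrement_pct * self.band_profile(z_mm)


def _mean_sphere_volume(r_min: float, r_max: float) -> float:
    # E[(4/3) pi R^3] for R ~ U(r_min, r_max)
    if r_max == r_min:
        return 4.0 / 3.0 * np.pi * r_min**3
    return np.pi / 3.0 * (r_max**4 - r_min**4) / (r_max - r_min)


def generate_phantom(
    truth: SyntheticTruth,
    dims: tuple[int, int, int],
    voxel_size_um: float = 24.3,
    fragment_id: str = "phantom",
) -> tuple[Tomogram, np.ndarray]:
    """Build a noisy intensity volume and its exact ground-truth labels.

    The colony is a rectangular block inside an open-ended cylindrical
    container wall; everything outside the colony (exterior air, the gap
    inside the tube, and the wall itself) is ground-truth MASK.  Identical
    ``truth.seed`` gives bit-identical output.

    Raises if the requested phase fractions exceed 100% anywhere along Z, or
    if fewer than three 0.9 mm windows fit along the colony's Z extent.
    """
    nx, ny, nz = dims
    vox_mm = voxel_size_um / 1000.0
    rng = np.random.default_rng(truth.seed)

    margin = truth.air_margin_vox
    wall = truth.container_thickness_vox
    # geometry: a cylindrical colony nested inside an open-ended cylindrical
    # container wall, with an air gap between colony and wall and an air
    # margin out to the volume boundary
    cxc, cyc = (nx - 1) / 2.0, (ny - 1) / 2.0
    r_outer = min(nx, ny) / 2.0 - margin
    r_colony = r_outer - wall - 2.5
    z0, z1 = margin, nz - margin
    if r_colony < 3 or z1 - z0 < 2:
        raise ValueError(f"dims {dims} too small for margins/container")
    colony_z_mm = (z1 - z0) * vox_mm
    if colony_z_mm < 3 * 0.9:
        raise ValueError(
            f"colony Z extent {colony_z_mm:.2f} mm cannot hold three 0.9 mm windows"
        )
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rad = np.sqrt((ii - cxc) ** 2 + (jj - cyc) ** 2)

    z_mm = (np.arange(nz) + 0.5) * vox_mm
    mip_t = truth.mip_target_pct(z_mm) / 100.0
    map_t = truth.map_target_pct(z_mm) / 100.0
    if np.any(mip_t + map_t > 1.0):
        raise ValueError("target micropore + macropore fraction exceeds 100% along Z")

    labels = np.full(dims, MASK, dtype=np.int16)
    colony = np.zeros(dims, dtype=bool)
    colony[:, :, z0:z1] = (rad <= r_colony)[:, :, None]
    labels[colony] = SOLID
    colony_z = slice(z0, z1)

    # --- macropores: Boolean sphere model, Z-inhomogeneous Poisson centers.
    # Voids are carved only inside a "core" (colony eroded by crust_vox) so
    # that the colony surface stays closed and enclosed voids are genuine
    # macropores rather than exterior-connected cavities.  The Poisson rate is
    # scaled by colony/core cross-section so the expected void fraction of the
    # *colony* slab still tracks the target profile.
    r_min, r_max = truth.macropore_radius_mm
    vbar = _mean_sphere_volume(r_min, r_max)
    crust = truth.crust_vox
    r_core = r_colony - crust
    cz0, cz1 = z0 + truth.crust_axial_vox, z1 - truth.crust_axial_vox
    if r_core < 2 or cz1 - cz0 < 2:
        raise ValueError("colony too small for the macropore-free crust")
    core = np.zeros(dims, dtype=bool)
    core[:, :, cz0:cz1] = (rad <= r_core)[:, :, None]
    area_ratio = r_colony**2 / r_core**2
    # Edge correction: sphere centers are sampled from the core padded by
    # r_max on every side (carving still clipped to the core), so the covered
    # fraction inside the core matches the stationary Boolean-model value
    # 1 - exp(-lambda * vbar) right up to the core boundaries.
    r_pad = int(np.ceil(r_max / vox_mm))
    pz0, pz1 = cz0 - r_pad, cz1 + r_pad
    r_ext = r_core + r_pad
    layers = np.arange(pz0, pz1)
    z_layer_mm = (layers + 0.5) * vox_mm
    frac_core = np.clip(truth.map_target_pct(z_layer_mm) / 100.0 * area_ratio, 0.0, 0.97)
    lam_z = -np.log1p(-frac_core) / vbar  # sphere centers per mm^3 per Z layer
    layer_vol_mm3 = np.pi * (r_ext * vox_mm) ** 2 * vox_mm
    expected = lam_z * layer_vol_mm3
    n_spheres = rng.poisson(expected.sum()) if expected.sum() > 0 else 0
    if n_spheres > 0:
        pz = expected / expected.sum()
        layer_idx = rng.choice(len(pz), size=n_spheres, p=pz)
        cz = (pz0 + layer_idx + rng.random(n_spheres)) * vox_mm
        # centers uniform over the padded disc
        rr = r_ext * np.sqrt(rng.random(n_spheres))
        th = rng.uniform(0, 2 * np.pi, n_spheres)
        cx = (cxc + rr * np.cos(th) + 0.5) * vox_mm
        cy = (cyc + rr * np.sin(th) + 0.5) * vox_mm
        radii = rng.uniform(r_min, r_max, n_spheres)
        xs = (np.arange(nx) + 0.5) * vox_mm
        ys = (np.arange(ny) + 0.5) * vox_mm
        zs = z_mm
        for k in range(n_spheres):
            r = radii[k]
            ix = np.searchsorted(xs, [cx[k] - r, cx[k] + r])
            iy = np.searchsorted(ys, [cy[k] - r, cy[k] + r])
            iz = np.searchsorted(zs, [cz[k] - r, cz[k] + r])
            sub = np.ix_(
                np.arange(max(ix[0] - 1, 0), min(ix[1] + 1, nx)),
                np.arange(max(iy[0] - 1, 0), min(iy[1] + 1, ny)),
                np.arange(max(iz[0] - 1, 0), min(iz[1] + 1, nz)),
            )
            dx = xs[sub[0][:, 0, 0]] - cx[k]
            dy = ys[sub[1][0, :, 0]] - cy[k]
            dz = zs[sub[2][0, 0, :]] - cz[k]
            inside = (
                dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
                <= r * r
            )
            block = labels[sub]
            block[inside & core[sub]] = AIR
            labels[sub] = block

    # --- micropores: per-voxel draws on remaining solid, rate adjusted so the
    # expected fraction of *colony* volume matches the target profile
    solid_mask = labels == SOLID
    realized_air = (labels == AIR) & colony
    n_col_layer = colony[:, :, colony_z].sum(axis=(0, 1)).astype(float)
    n_air_layer = realized_air[:, :, colony_z].sum(axis=(0, 1)).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        solid_frac = np.where(n_col_layer > 0, 1.0 - n_air_layer / n_col_layer, 1.0)
        q_z = np.where(solid_frac > 0, mip_t[colony_z] / solid_frac, 0.0)
    q_z = np.clip(q_z, 0.0, 1.0)
    q_vol = np.zeros(nz)
    q_vol[colony_z] = q_z
    draws = rng.random(dims)
    labels[solid_mask & (draws < q_vol[None, None, :])] = MICROPORE

    # --- intensity volume
    level = np.empty(dims, dtype=np.float64)
    level.fill(truth.air_level)
    level[labels == SOLID] = truth.solid_level
    level[labels == MICROPORE] = truth.micropore_level
    level[labels == AIR] = truth.air_level
    # container wall: cylinder shell around the colony, open at both ends
    shell = (rad <= r_outer) & (rad > r_outer - wall)
    level[shell, :] = truth.container_level
    labels[shell, :] = MASK

    if truth.noise_sd > 0:
        level = level + rng.normal(0.0, truth.noise_sd, dims)

    tomo = Tomogram(intensities=level, voxel_size_um=voxel_size_um, fragment_id=fragment_id)
    return tomo, labels


def truth_profile(
    truth: SyntheticTruth,
    labels: np.ndarray,
    window_size_mm: float = 0.9,
    voxel_size_um: float = 24.3,
):
    """Ground-truth vertical profile by direct label counting, no segmentation.

    The colony's Z range is tiled into slabs of ``window_size_mm``; within
    each slab the true labels are counted and MiP/MaP/TP/SVF computed as
    percentages of colony (non-mask) voxels.  This is the oracle the
    pipeline's segmentation-based estimates are judged against.
    """
    from .profile_analysis import VerticalProfile

    vox_mm = voxel_size_um / 1000.0
    w = max(1, round(window_size_mm / vox_mm))
    colony = labels != MASK
    if not colony.any():
        raise ValueError("label volume contains no colony voxels")
    z_any = np.where(colony.any(axis=(0, 1)))[0]
    z_start, z_stop = z_any[0], z_any[-1] + 1
    if w > labels.shape[2]:
        raise ValueError("window larger than volume Z extent")

    rows = []
    for k, zlo in enumerate(range(z_start, z_stop, w)):
        zhi = min(zlo + w, z_stop)
        slab = labels[:, :, zlo:zhi]
        n_solid = int(np.count_nonzero(slab == SOLID))
        n_micro = int(np.count_nonzero(slab == MICROPORE))
        n_air = int(np.count_nonzero(slab == AIR))
        n_col = n_solid + n_micro + n_air
        if n_col == 0:
            continue
        mip = 100.0 * n_micro / n_col
        map_ = 100.0 * n_air / n_col
        svf = 100.0 * n_solid / n_col
        rows.append(
            dict(
                z_index=k,
                z_center_vox=0.5 * (zlo + zhi),
                z_mm_phys=0.5 * (zlo + zhi) * vox_mm,
                n_windows=1,
                MiP_mean=mip, MiP_sem=0.0,
                MaP_mean=map_, MaP_sem=0.0,
                TP_mean=mip + map_, TP_sem=0.0,
                SVF_mean=svf, SVF_sem=0.0,
                n_solid=n_solid, n_micro=n_micro, n_air=n_air,
            )
        )
    import pandas as pd

    return VerticalProfile(data=pd.DataFrame(rows), fragment_id="truth")
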