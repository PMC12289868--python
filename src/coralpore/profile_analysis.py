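"""Vertical profiles, coordinate/variable normalization, LOESS and zones.

A vertical profile is the Z-axis sequence of per-level means of the porosity
variables, from the apical end (living tissue) down to the basal skeleton.
Two normalizations make fragments comparable before pooling:

* coordinates — each fragment's window index is scaled against the Z range
  of the *largest* fragment and mapped to millimeters with a conversion
  factor (default 8 mm, the length of the largest porosity map) plus a
  correction factor (default 0.45 mm, half a window, so each point sits at
  the middle of its 0.9 mm sampling interval);
* variables — each profile is shifted to its own minimum and scaled by its
  own range (delta normalization), preserving intra-colonial fluctuation
  that raw values would flatten when pooled.

LOESS here is local quadratic regression with tricube weights over the
span-nearest neighbors, evaluated on a uniform grid inside the data range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FragmentMeta
from .porosity_mapping import VARIABLES, PorosityMap

ZONES = ("coral_tissue", "green_band", "skeleton")


@dataclass
class VerticalProfile:
    """Per-Z-level means ± s.e.m. of the porosity variables.

    ``data`` columns: ``z_index`` (window index along Z), ``z_center_vox``,
    ``z_mm_phys`` (physical mm from the volume origin), ``n_windows``, and
    ``<var>_mean`` / ``<var>_sem`` for each variable.  After
    :func:`normalize_coordinates` it also carries ``z_norm`` and ``z_mm``
    (the standardized mm scale).
    """

    data: pd.DataFrame
    fragment_id: str = ""

    def __post_init__(self) -> None:
        z = self.data["z_index"].to_numpy()
        if len(z) and not (np.diff(z) > 0).all():
            raise ValueError("z_index must be strictly increasing")


@dataclass
class TransformedProfile:
    """Delta-normalized variable values over a profile (per fragment)."""

    z_mm: np.ndarray
    values: np.ndarray
    delta: np.ndarray
    delta_max: float
    v_min: float
    v_max: float
    normalized: np.ndarray
    variable: str
    fragment_id: str = ""


@dataclass
class LoessCurve:
    grid: np.ndarray
    fitted: np.ndarray
    span: float
    variable: str = ""
    tag: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.fitted).all():
            raise ValueError("LOESS fit produced non-finite values")


@dataclass
class ExtremumResult:
    kind: str
    location_mm: float
    value: float
    variable: str = ""
    fragment_id: str = ""
    at_boundary: bool = False


@dataclass
class ZoneAssignment:
    """Three-way split of a profile by the stereoscope green-band interval.

    ``z < low`` is coral tissue, ``low <= z <= high`` the green band, and
    ``z > high`` basal skeleton (half-open at the tissue edge, closed at the
    band edges).
    """

    labels: np.ndarray
    z_mm: np.ndarray
    band_range_mm: tuple[float, float]
    counts: dict[str, int] = field(default_factory=dict)


def extract_vertical_profile(pmap: PorosityMap) -> VerticalProfile:
    """Collapse a porosity map to per-Z means ± s.e.m. over valid XY windows.

    Z levels with no valid window are dropped; at least two usable levels are
    required to form a profile.
    """
    valid = pmap.valid
    rows = []
    for k, grp in valid.groupby("k"):
        row: dict = {
            "z_index": int(k),
            "z_center_vox": float(grp["cz_vox"].iloc[0]),
            "z_mm_phys": float(grp["cz_mm"].iloc[0]),
            "n_windows": len(grp),
        }
        for var in VARIABLES:
            vals = grp[var].to_numpy(dtype=float)
            row[f"{var}_mean"] = float(vals.mean())
            row[f"{var}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            )
        rows.append(row)
    if len(rows) < 2:
        raise ValueError(f"need >= 2 usable Z levels, found {len(rows)}")
    df = pd.DataFrame(rows).sort_values("z_index").reset_index(drop=True)
    return VerticalProfile(data=df, fragment_id=pmap.fragment_id)


def normalize_coordinates(
    profile: VerticalProfile,
    reference: tuple[float, float],
    conversion_mm: float = 8.0,
    correction_mm: float = 0.45,
) -> VerticalProfile:
    """Standardize the profile's Z coordinate and map it to millimeters.

    ``z_norm = (z - z_min_own) / (ref_max - ref_min)`` where the denominator
    comes from the largest selected fragment, so fragment sizes stay
    comparable; then ``z_mm = z_norm * conversion + correction``.  For the
    largest fragment itself the endpoints land on ``correction`` and
    ``conversion + correction`` (0.45 and 8.45 mm at the defaults).
    """
    ref_min, ref_max = reference
    if not ref_max > ref_min:
        raise ValueError(f"reference range is empty: ({ref_min}, {ref_max})")
    if not (conversion_mm > 0 and correction_mm > 0):
        raise ValueError("conversion and correction factors must be > 0")
    df = profile.data.copy()
    z = df["z_index"].to_numpy(dtype=float)
    z_norm = (z - z.min()) / (ref_max - ref_min)
    df["z_norm"] = z_norm
    df["z_mm"] = z_norm * conversion_mm + correction_mm
    return VerticalProfile(data=df, fragment_id=profile.fragment_id)


def transform_variable(
    profile: VerticalProfile | None = None,
    variable: str = "MiP",
    values: np.ndarray | None = None,
    z_mm: np.ndarray | None = None,
    fragment_id: str = "",
) -> TransformedProfile:
    """Delta-normalize one variable within a fragment.

    ``delta = v - v_min``, ``delta_max = v_max - v_min`` and
    ``v_norm = delta / delta_max``, all relative to this fragment's own
    profile.  A constant profile has no range and raises rather than divide
    by zero.
    """
    if values is None:
        if profile is None:
            raise ValueError("provide either a profile or raw values")
        values = profile.data[f"{variable}_mean"].to_numpy(dtype=float)
        zcol = "z_mm" if "z_mm" in profile.data else "z_mm_phys"
        z_mm = profile.data[zcol].to_numpy(dtype=float)
        fragment_id = fragment_id or profile.fragment_id
    values = np.asarray(values, dtype=float)
    if z_mm is None:
        z_mm = np.arange(len(values), dtype=float)
    if len(values) < 2:
        raise ValueError("need >= 2 values to normalize")
    v_min, v_max = float(values.min()), float(values.max())
    delta_max = v_max - v_min
    if delta_max == 0:
        raise ValueError(f"zero range: profile of {variable!r} is constant at {v_min}")
    delta = values - v_min
    return TransformedProfile(
        z_mm=np.asarray(z_mm, dtype=float),
        values=values,
        delta=delta,
        delta_max=delta_max,
        v_min=v_min,
        v_max=v_max,
        normalized=delta / delta_max,
        variable=variable,
        fragment_id=fragment_id,
    )


def fit_loess(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.3,
    degree: int = 2,
    n_grid: int = 101,
    weights: np.ndarray | None = None,
    variable: str = "",
    tag: str = "",
) -> LoessCurve:
    """Locally weighted polynomial regression on a uniform grid.

    At each grid point the ``ceil(span * n)`` nearest observations get
    tricube weights and a degree-``degree`` polynomial is fitted by weighted
    least squares; the grid never extends beyond the data range.  Optional
    case ``weights`` multiply the tricube kernel — used to weight porosity
    windows by their colony volume, whose sampling variance scales inversely
    with it.  The fit is fully deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (0 < span <= 1):
        raise ValueError(f"span must be in (0, 1], got {span}")
    n = len(x)
    q = max(int(np.ceil(span * n)), degree + 1)
    if n < max(5, q):
        raise ValueError(
            f"too few points (n={n}) for span {span} and degree {degree}"
        )
    cw = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if cw.shape != x.shape or (cw < 0).any() or not cw.any():
        raise ValueError("weights must be non-negative, not all zero, aligned with x")
    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y[order], cw[order]
    grid = np.linspace(xs[0], xs[-1], n_grid)
    fitted = np.empty(n_grid)
    for gi, x0 in enumerate(grid):
        d = np.abs(xs - x0)
        cut = np.partition(d, q - 1)[q - 1]
        sel = d <= cut
        xd, yd, dd, wd = xs[sel], ys[sel], d[sel], ws[sel]
        dmax = dd.max()
        if dmax == 0:
            fitted[gi] = np.average(yd, weights=wd) if wd.any() else yd.mean()
            continue
        w = (1 - (dd / dmax) ** 3) ** 3 * wd
        w = np.maximum(w, 1e-12)
        deg = min(degree, len(np.unique(xd)) - 1)
        coeffs = np.polynomial.polynomial.polyfit(xd - x0, yd, deg, w=np.sqrt(w))
        fitted[gi] = coeffs[0]
    return LoessCurve(grid=grid, fitted=fitted, span=span, variable=variable, tag=tag)


def fit_map_loess(
    pmap: PorosityMap,
    variable: str = "MiP",
    span: float = 0.3,
    n_grid: int = 101,
    tag: str = "",
) -> LoessCurve:
    """LOESS over all valid windows of a porosity map along the vertical axis.

    Fits the raw window values (not per-level means) against the physical
    window-center Z in mm, weighting each window by its colony voxel count so
    that low-volume edge slivers do not dominate the local fits.
    """
    valid = pmap.valid
    w = (valid["n_solid"] + valid["n_micro"] + valid["n_air"]).to_numpy(dtype=float)
    return fit_loess(
        valid["cz_mm"].to_numpy(dtype=float),
        valid[variable].to_numpy(dtype=float),
        span=span,
        n_grid=n_grid,
        weights=w,
        variable=variable,
        tag=tag or pmap.fragment_id,
    )


def locate_extremum(curve: LoessCurve, kind: str = "peak") -> ExtremumResult:
    """Locate the curve's maximum (peak) or minimum (valley) on its grid.

    Ties break toward the smallest Z (the apical end); an extremum on the
    first or last grid point is flagged ``at_boundary`` so monotone profiles
    can be excluded by callers.
    """
    if kind not in ("peak", "valley"):
        raise ValueError(f"kind must be 'peak' or 'valley', got {kind!r}")
    if len(curve.grid) < 3:
        raise ValueError("curve needs >= 3 grid points")
    idx = int(np.argmax(curve.fitted) if kind == "peak" else np.argmin(curve.fitted))
    return ExtremumResult(
        kind=kind,
        location_mm=float(curve.grid[idx]),
        value=float(curve.fitted[idx]),
        variable=curve.variable,
        at_boundary=idx in (0, len(curve.grid) - 1),
    )


def assign_zones(profile: VerticalProfile, meta: FragmentMeta) -> ZoneAssignment:
    """Label each profile level coral_tissue / green_band / skeleton.

    Uses the stereoscope-measured band interval from the fragment metadata on
    the profile's mm scale.  Fails loudly when the band interval lies wholly
    outside the profile's Z range.
    """
    zcol = "z_mm" if "z_mm" in profile.data else "z_mm_phys"
    z = profile.data[zcol].to_numpy(dtype=float)
    low, high = meta.green_band_range_mm
    if high < z.min() or low > z.max():
        raise ValueError(
            f"green band [{low}, {high}] mm does not overlap profile range "
            f"[{z.min():.3g}, {z.max():.3g}] mm"
        )
    labels = np.where(z < low, "coral_tissue", np.where(z <= high, "green_band", "skeleton"))
    counts = {zone: int((labels == zone).sum()) for zone in ZONES}
    return ZoneAssignment(labels=labels, z_mm=z, band_range_mm=(low, high), counts=counts)
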