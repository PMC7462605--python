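"""Kernel utilization distributions and range-use scores.

A group's space use is summarised by a utilization distribution (UD): a
probability density over the plane estimated by Gaussian kernel density
from relocation fixes. Percent-volume isopleths of the UD give the
conventional home range (95%) and core area (50%); the overlap of two
groups' isopleths measures range sharing, and the "usage" of a point is
100 minus the smallest percent-volume isopleth containing it, so the
density mode scores near 100 and points outside the range score 0.

The per-hunt "usage difference" is the non-hunting group's usage at the
hunt location minus the hunting group's: positive values mean the hunt
fell in an area used relatively more by the group that did *not* hunt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator

__all__ = [
    "KernelUD",
    "UsageScore",
    "fit_kde",
    "gaussian_ud",
    "overlap_fraction",
    "usage_difference",
    "region_to_geojson",
]

MIN_RELOCATIONS = 30
# points beyond this isopleth are treated as outside the range entirely
OUTSIDE_ISOPLETH = 99.9


class KernelUD(BaseEstimator):
    """Gaussian-kernel utilization distribution on a regular grid.

    Parameters
    ----------
    bandwidth : "href" or float or (float, float)
        Per-coordinate kernel sd in km. The default "href" is the Gaussian
        reference rule ``h_j = sd_j * n**(-1/6)``, the conventional default
        for kernel home ranges.
    cell_size : float
        Grid cell edge in km.
    pad_bandwidths : float
        Grid padding beyond the data extent, in bandwidths (>= 3 keeps
        essentially all kernel mass on the grid).
    grid_bounds : None or (xmin, xmax, ymin, ymax)
        Fix the grid explicitly, e.g. to place two groups' UDs on a common
        grid. Data outside the bounds still contribute via their kernels'
        on-grid mass.

    Attributes (after ``fit``)
    --------------------------
    density_ : (ny, nx) array, normalised so sum(density_) * cell area = 1.
    isopleth_ : (ny, nx) array in (0, 100]; the smallest percent-volume
        isopleth containing each cell (low = core, 100 = fringe/empty).
    x_, y_ : cell-centre coordinates; grid_origin_ : (x0, y0) of the first
        cell centre; bandwidth_ : realised (hx, hy).
    """

    def __init__(self, bandwidth="href", cell_size=0.1, pad_bandwidths=3.0,
                 grid_bounds=None, group_id=None):
        self.bandwidth = bandwidth
        self.cell_size = cell_size
        self.pad_bandwidths = pad_bandwidths
        self.grid_bounds = grid_bounds
        self.group_id = group_id

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of planar km coordinates")
        n = len(X)
        if n < MIN_RELOCATIONS:
            raise ValueError(
                f"insufficient relocations: {n} < {MIN_RELOCATIONS} required"
            )
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        sd = X.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ValueError("zero variance in a coordinate; UD undefined")

        if self.bandwidth == "href":
            h = sd * n ** (-1.0 / 6.0)
        else:
            h = np.broadcast_to(np.asarray(self.bandwidth, dtype=float), (2,)).copy()
            if np.any(h <= 0):
                raise ValueError("bandwidth must be positive")
        self.bandwidth_ = h

        pad = self.pad_bandwidths * h
        if self.grid_bounds is not None:
            xmin, xmax, ymin, ymax = self.grid_bounds
        else:
            xmin, ymin = X.min(axis=0) - pad
            xmax, ymax = X.max(axis=0) + pad
        cs = float(self.cell_size)
        nx = max(int(np.ceil((xmax - xmin) / cs)), 1)
        ny = max(int(np.ceil((ymax - ymin) / cs)), 1)
        self.x_ = xmin + (np.arange(nx) + 0.5) * cs
        self.y_ = ymin + (np.arange(ny) + 0.5) * cs
        self.grid_origin_ = (float(self.x_[0]), float(self.y_[0]))

        # binned KDE: histogram counts convolved with the Gaussian kernel;
        # exact up to the binning, which is fine for cell_size << bandwidth
        counts, _, _ = np.histogram2d(
            X[:, 1], X[:, 0],
            bins=[ny, nx],
            range=[[ymin, ymin + ny * cs], [xmin, xmin + nx * cs]],
        )
        dens = gaussian_filter(counts, sigma=(h[1] / cs, h[0] / cs),
                               mode="constant", truncate=6.0)
        total = dens.sum() * cs * cs
        self.density_ = dens / total
        self.isopleth_ = _isopleth_surface(self.density_, cs)
        return self

    # -- queries ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "density_"):
            raise AttributeError("KernelUD is not fitted")

    def percent_volume_region(self, p):
        """Boolean mask of the p%-volume region and its area in km².

        Returns ``(mask, area_km2)``; the region is the set of grid cells
        whose containing isopleth is <= p.
        """
        self._check_fitted()
        if not 0 < p <= 100:
            raise ValueError("p must be in (0, 100]")
        if p == 100:
            mask = self.density_ > 0
        else:
            mask = self.isopleth_ <= p
        return mask, float(mask.sum()) * self.cell_size ** 2

    def area(self, p=95):
        return self.percent_volume_region(p)[1]

    def usage_at(self, points):
        """Kernel usage (0–100) at planar points; off-grid points score 0."""
        self._check_fitted()
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        cs = self.cell_size
        ix = np.floor((pts[:, 0] - (self.x_[0] - cs / 2)) / cs).astype(int)
        iy = np.floor((pts[:, 1] - (self.y_[0] - cs / 2)) / cs).astype(int)
        ok = (ix >= 0) & (ix < len(self.x_)) & (iy >= 0) & (iy < len(self.y_))
        usage = np.zeros(len(pts))
        iso = self.isopleth_[iy[ok], ix[ok]]
        u = 100.0 - iso
        u[iso > OUTSIDE_ISOPLETH] = 0.0
        usage[ok] = u
        return float(usage[0]) if single else usage

    def to_frame(self):
        """Long-format (x, y, density, isopleth) table of the grid."""
        self._check_fitted()
        xx, yy = np.meshgrid(self.x_, self.y_)
        return pd.DataFrame({
            "x_km": xx.ravel(), "y_km": yy.ravel(),
            "density": self.density_.ravel(),
            "isopleth": self.isopleth_.ravel(),
        })


def _isopleth_surface(density, cell_size):
    """Percent-volume surface: sort cells by density (desc), accumulate mass;
    a cell's value is the cumulative percent including itself, so the modal
    cell gets the smallest value and empty cells get 100."""
    flat = density.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order]) * cell_size ** 2 * 100.0
    surface = np.empty_like(flat)
    surface[order] = np.minimum(cum, 100.0)
    surface[flat <= 0] = 100.0
    return surface.reshape(density.shape)


def fit_kde(relocations, bandwidth_rule="href", cell_size=0.1, group_id=None,
            grid_bounds=None):
    """Fit a :class:`KernelUD` from a relocation table or (n, 2) array.

    Accepts a DataFrame with ``x_km``/``y_km`` columns or a plain array.
    """
    if isinstance(relocations, pd.DataFrame):
        X = relocations[["x_km", "y_km"]].to_numpy()
    else:
        X = np.asarray(relocations, dtype=float)
    return KernelUD(bandwidth=bandwidth_rule, cell_size=cell_size,
                    group_id=group_id, grid_bounds=grid_bounds).fit(X)


def gaussian_ud(center=(0.0, 0.0), sigma=1.0, cell_size=0.05, n_sigma=6.0):
    """Analytic isotropic-Gaussian UD on a grid (no data, no smoothing).

    Useful as a closed-form reference: its p% isopleth is the disk of
    squared Mahalanobis radius chi²₂(p), area −2 ln(1−p/100)·π·σ².
    """
    cx, cy = center
    half = n_sigma * sigma
    ud = KernelUD.__new__(KernelUD)
    ud.bandwidth = None
    ud.cell_size = cell_size
    ud.pad_bandwidths = 0.0
    ud.grid_bounds = (cx - half, cx + half, cy - half, cy + half)
    ud.group_id = None
    nx = int(np.ceil(2 * half / cell_size))
    ud.x_ = cx - half + (np.arange(nx) + 0.5) * cell_size
    ud.y_ = cy - half + (np.arange(nx) + 0.5) * cell_size
    ud.grid_origin_ = (float(ud.x_[0]), float(ud.y_[0]))
    xx, yy = np.meshgrid(ud.x_, ud.y_)
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    dens = np.exp(-r2 / (2 * sigma ** 2))
    dens /= dens.sum() * cell_size ** 2
    ud.density_ = dens
    ud.isopleth_ = _isopleth_surface(dens, cell_size)
    ud.bandwidth_ = np.array([sigma, sigma])
    return ud


def _common_grid_masks(ud_a, ud_b, p):
    mask_a, _ = ud_a.percent_volume_region(p)
    mask_b, _ = ud_b.percent_volume_region(p)
    same = (len(ud_a.x_) == len(ud_b.x_) and len(ud_a.y_) == len(ud_b.y_)
            and np.allclose(ud_a.x_, ud_b.x_) and np.allclose(ud_a.y_, ud_b.y_))
    if same:
        return mask_a, mask_b, ud_a.cell_size
    # resample B's isopleth surface onto A's grid (nearest cell)
    from scipy.interpolate import RegularGridInterpolator
    interp = RegularGridInterpolator(
        (ud_b.y_, ud_b.x_), ud_b.isopleth_, method="nearest",
        bounds_error=False, fill_value=100.0)
    xx, yy = np.meshgrid(ud_a.x_, ud_a.y_)
    iso_b = interp(np.column_stack([yy.ravel(), xx.ravel()])).reshape(xx.shape)
    return mask_a, iso_b <= p, ud_a.cell_size


def overlap_fraction(ud_a, ud_b, p=95):
    """Fractions of each group's p%-range lying in the other's, and the
    shared area in km².

    Returns ``(fraction_a_in_b, fraction_b_in_a, shared_area_km2)``.
    """
    mask_a, mask_b, cs = _common_grid_masks(ud_a, ud_b, p)
    shared = float((mask_a & mask_b).sum()) * cs ** 2
    area_a = float(mask_a.sum()) * cs ** 2
    area_b = float(mask_b.sum()) * cs ** 2
    fa = shared / area_a if area_a > 0 else 0.0
    fb = shared / area_b if area_b > 0 else 0.0
    return fa, fb, shared


@dataclass
class UsageScore:
    hunt_id: object
    usage_hunt_group: float
    usage_other_group: float

    @property
    def usage_difference(self) -> float:
        return self.usage_other_group - self.usage_hunt_group


def usage_difference(hunts, ud_by_group):
    """Per-hunt usage scores: other group's usage minus the hunting group's.

    ``hunts`` needs ``hunt_id``, ``x_km``, ``y_km``, ``catcher_group``;
    ``ud_by_group`` maps the two group ids to fitted UDs.
    """
    groups = list(ud_by_group)
    if len(groups) != 2:
        raise ValueError("exactly two groups' UDs are required")
    missing = set(hunts["catcher_group"]) - set(groups)
    if missing:
        raise ValueError(f"missing UD for group(s): {sorted(missing)}")
    pts = hunts[["x_km", "y_km"]].to_numpy()
    usage = {g: np.atleast_1d(ud_by_group[g].usage_at(pts)) for g in groups}
    hunt_is_first = (hunts["catcher_group"] == groups[0]).to_numpy()
    u_hunt = np.where(hunt_is_first, usage[groups[0]], usage[groups[1]])
    u_other = np.where(hunt_is_first, usage[groups[1]], usage[groups[0]])
    return pd.DataFrame({
        "hunt_id": hunts["hunt_id"].to_numpy(),
        "usage_hunt_group": u_hunt,
        "usage_other_group": u_other,
        "usage_difference": u_other - u_hunt,
    })


def region_to_geojson(ud, levels=(50, 95)):
    """GeoJSON FeatureCollection of isopleth outlines (cells as squares)."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    features = []
    cs = ud.cell_size
    for level in levels:
        mask, area = ud.percent_volume_region(level)
        ys, xs = np.nonzero(mask)
        boxes = [box(ud.x_[j] - cs / 2, ud.y_[i] - cs / 2,
                     ud.x_[j] + cs / 2, ud.y_[i] + cs / 2)
                 for i, j in zip(ys, xs)]
        geom = unary_union(boxes) if boxes else None
        features.append({
            "type": "Feature",
            "geometry": mapping(geom) if geom is not None else None,
            "properties": {"group": ud.group_id, "level": level,
                           "area_km2": area},
        })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh)
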