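"""Level-set model of signal-driven cell shape change and migration.

The cell boundary is the zero level set of a potential ``psi`` on a 2-D
Cartesian grid (negative inside).  The cortex is a Voigt element (spring
``kc`` parallel to dashpot ``tau_c``) in series with a viscous cytoplasm
``tau_a``; its elongation state ``l`` lives on the grid near the boundary.
Membrane pressures are slaved to the receptor-phosphorylation kymograph:
bins with above-mean activity protrude, below-mean bins retract, a global
area-restoring pressure keeps the flat cell's 2-D area near its initial
value, and cortical tension penalizes curvature in excess of the resting
``1/R``.  The normal boundary velocity

    v = -(kc/tau_c) * l + (1/tau_c + 1/tau_a) * P_total

advects both ``psi`` (Hamilton-Jacobi, Godunov upwinding with a
second-order ENO option) and ``l`` (first-order upwind transport plus local
Voigt relaxation).  ``psi`` is periodically re-distanced; the grid window
recenters itself when the migrating cell approaches a border.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .motility import Track
from .signaling import Kymograph

__all__ = [
    "MechParams",
    "LevelSetField",
    "BoundaryPressure",
    "CellShapeSeries",
    "init_signed_distance",
    "contour_geometry",
    "boundary_pressures",
    "mechanics_step",
    "simulate_cell",
]


@dataclass
class MechParams:
    """Mechanical parameters (nN, um, min)."""

    kc: float = 0.1          # cortex spring, nN/um^3
    tau_c: float = 0.08      # cortex dashpot, nN*min/um^3
    tau_a: float = 0.1       # cytoplasm viscosity, nN*min/um^3
    Kprot: float = 0.08      # protrusion gain, nN/um^2
    Kretr: float = 0.05      # retraction gain, nN/um^2
    Karea: float = 0.02      # area restoring gain, nN/um^4
    Kten: float = 0.1        # cortical tension, nN/um
    R: float = 2.0           # rest radius, um
    pts_per_um: float = 5.0
    dt: float = 0.01         # min
    reinit_every: int = 50   # steps between re-distancing
    band_cells: int = 6      # half-width of the narrow band, grid cells
    scheme: str = "eno2"     # 'eno2' | 'upwind1'

    def __post_init__(self) -> None:
        if min(self.kc, self.tau_c, self.tau_a, self.Kprot, self.Kretr,
               self.Karea, self.Kten, self.R, self.pts_per_um, self.dt) <= 0:
            raise ValueError("all mechanical parameters must be positive")
        if self.scheme not in ("eno2", "upwind1"):
            raise ValueError("scheme must be 'eno2' or 'upwind1'")

    @property
    def h(self) -> float:
        return 1.0 / self.pts_per_um


@dataclass
class LevelSetField:
    """Signed-distance-like potential on a uniform grid (negative inside)."""

    psi: np.ndarray          # (ny, nx)
    origin: tuple[float, float]   # physical (x, y) of grid point [0, 0]
    h: float

    def xy_mesh(self):
        ny, nx = self.psi.shape
        x = self.origin[0] + np.arange(nx) * self.h
        y = self.origin[1] + np.arange(ny) * self.h
        return np.meshgrid(x, y)

    def mask(self) -> np.ndarray:
        return self.psi < 0

    def area(self, eps_cells: float = 1.5) -> float:
        """Sub-cell area of the interior via a smoothed Heaviside."""
        eps = eps_cells * self.h
        p = np.clip(self.psi, -eps, eps)
        H = 0.5 * (1.0 - p / eps - np.sin(np.pi * p / eps) / np.pi)
        return float(H.sum() * self.h ** 2)

    def centroid(self) -> np.ndarray:
        eps = 1.5 * self.h
        p = np.clip(self.psi, -eps, eps)
        H = 0.5 * (1.0 - p / eps - np.sin(np.pi * p / eps) / np.pi)
        X, Y = self.xy_mesh()
        w = H.sum()
        return np.array([float((X * H).sum() / w), float((Y * H).sum() / w)])

    def copy(self) -> "LevelSetField":
        return LevelSetField(self.psi.copy(), self.origin, self.h)


def init_signed_distance(center: tuple[float, float], R: float,
                         extent: tuple[float, float] = (12.0, 12.0),
                         pts_per_um: float = 5.0,
                         origin: tuple[float, float] | None = None
                         ) -> LevelSetField:
    """Signed distance to a circle of radius ``R`` (negative inside).

    The circle must fit in the grid with at least a 5-cell margin.
    """
    h = 1.0 / pts_per_um
    if origin is None:
        origin = (center[0] - extent[0] / 2, center[1] - extent[1] / 2)
    nx = int(round(extent[0] / h)) + 1
    ny = int(round(extent[1] / h)) + 1
    x = origin[0] + np.arange(nx) * h
    y = origin[1] + np.arange(ny) * h
    X, Y = np.meshgrid(x, y)
    psi = np.hypot(X - center[0], Y - center[1]) - R
    margin = 5 * h
    if (center[0] - R < x[0] + margin or center[0] + R > x[-1] - margin or
            center[1] - R < y[0] + margin or center[1] + R > y[-1] - margin):
        raise ValueError("circle does not fit in the grid with a 5-cell margin")
    return LevelSetField(psi, origin, h)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _grad(psi: np.ndarray, h: float):
    gy, gx = np.gradient(psi, h)
    return gx, gy


def _curvature(psi: np.ndarray, h: float) -> np.ndarray:
    """kappa = div(grad psi / |grad psi|) on the grid."""
    gx, gy = _grad(psi, h)
    norm = np.sqrt(gx ** 2 + gy ** 2) + 1e-12
    nxx = np.gradient(gx / norm, h, axis=1)
    nyy = np.gradient(gy / norm, h, axis=0)
    return nxx + nyy


def _find_single_contour(field: LevelSetField) -> np.ndarray:
    """Closed zero contour in physical (x, y) coordinates, (n, 2)."""
    contours = measure.find_contours(field.psi, 0.0)
    closed = [c for c in contours if np.allclose(c[0], c[-1])]
    if len(closed) == 0:
        raise ValueError("no closed zero level set found")
    if len(closed) > 1:
        # keep the largest; more than one sizeable component is an error
        lens = sorted(len(c) for c in closed)
        if lens[-2] > 8:
            raise ValueError("multiple zero level-set components")
    c = max(closed, key=len)
    xy = np.empty_like(c)
    xy[:, 0] = field.origin[0] + c[:, 1] * field.h
    xy[:, 1] = field.origin[1] + c[:, 0] * field.h
    return xy


def _sample(grid_field: np.ndarray, field: LevelSetField, pts: np.ndarray,
            order: int = 1) -> np.ndarray:
    rows = (pts[:, 1] - field.origin[1]) / field.h
    cols = (pts[:, 0] - field.origin[0]) / field.h
    return ndimage.map_coordinates(grid_field, [rows, cols], order=order,
                                   mode="nearest")


def contour_geometry(field: LevelSetField):
    """Contour samples with outward normals, curvature and enclosed area.

    Returns ``(points, normals, kappa, area)``; the polygon is traversed once
    (duplicate endpoint dropped), normals are ``grad psi/|grad psi|`` sampled
    on the contour, curvature is the divergence of the normal field, and the
    area is the shoelace area of the polygon.
    """
    xy = _find_single_contour(field)
    pts = xy[:-1]
    gx, gy = _grad(field.psi, field.h)
    nx = _sample(gx, field, pts)
    ny = _sample(gy, field, pts)
    norm = np.hypot(nx, ny) + 1e-12
    normals = np.column_stack([nx / norm, ny / norm])
    kappa = _sample(_curvature(field.psi, field.h), field, pts)
    x, y = xy[:, 0], xy[:, 1]
    area = 0.5 * abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1]))
    return pts, normals, kappa, float(area)


# ---------------------------------------------------------------------------
# pressures
# ---------------------------------------------------------------------------

@dataclass
class BoundaryPressure:
    """Per-sample pressure magnitudes along the outward normal (nN/um^2)."""

    Pprot: np.ndarray
    Pretr: np.ndarray
    Parea: float
    Pten: np.ndarray

    @property
    def Ptotal(self) -> np.ndarray:
        return self.Pprot + self.Pretr + self.Parea - self.Pten


def boundary_pressures(ep_on_contour: np.ndarray, kappa: np.ndarray,
                       area: float, A0: float, mech: MechParams,
                       eps_den: float = 1e-9) -> BoundaryPressure:
    """Protrusion/retraction/area/tension pressures from membrane signaling.

    Boundary samples with ``Ep`` above the membrane mean protrude, samples
    below it retract; both strengths are normalized by the excursion of the
    activity maximum above the mean, ``(max - mean)``, so the deepest
    retraction matches the scale of the leading protrusion rather than
    being pinned at full strength by an arbitrarily shallow minimum.  A
    degenerate normalizer (uniform ``Ep``) switches both pressures off.
    The area term is uniform along the boundary; tension penalizes
    curvature in excess of the resting ``1/R``.
    """
    ep = np.asarray(ep_on_contour, dtype=float)
    m, hi = ep.mean(), ep.max()
    prot = np.zeros_like(ep)
    retr = np.zeros_like(ep)
    if hi - m > eps_den:
        prot = np.where(ep > m, mech.Kprot * (ep - m) / (hi - m), 0.0)
        retr = np.where(ep < m, -mech.Kretr * (m - ep) / (hi - m), 0.0)
    parea = mech.Karea * (A0 - area)
    pten = mech.Kten * (np.asarray(kappa, dtype=float) - 1.0 / mech.R)
    return BoundaryPressure(prot, retr, float(parea), pten)


# ---------------------------------------------------------------------------
# advection
# ---------------------------------------------------------------------------

def _minmod(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.where(a * b > 0, np.where(np.abs(a) < np.abs(b), a, b), 0.0)


def _one_sided(psi: np.ndarray, h: float, axis: int, scheme: str):
    """Backward/forward one-sided derivatives (ENO2 or first order)."""
    dm = (psi - np.roll(psi, 1, axis=axis)) / h
    dp = (np.roll(psi, -1, axis=axis) - psi) / h
    if scheme == "eno2":
        d2 = (np.roll(psi, -1, axis=axis) - 2 * psi
              + np.roll(psi, 1, axis=axis)) / h ** 2
        d2m = np.roll(d2, 1, axis=axis)
        d2p = np.roll(d2, -1, axis=axis)
        dm = dm + 0.5 * h * _minmod(d2m, d2)
        dp = dp - 0.5 * h * _minmod(d2, d2p)
    return dm, dp


def _godunov_gradnorm(psi: np.ndarray, h: float, v: np.ndarray,
                      scheme: str) -> np.ndarray:
    """Godunov |grad psi| for H-J advection with normal speed ``v``."""
    xm, xp = _one_sided(psi, h, axis=1, scheme=scheme)
    ym, yp = _one_sided(psi, h, axis=0, scheme=scheme)
    pos = (np.maximum(np.maximum(xm, 0) ** 2, np.minimum(xp, 0) ** 2)
           + np.maximum(np.maximum(ym, 0) ** 2, np.minimum(yp, 0) ** 2))
    neg = (np.maximum(np.minimum(xm, 0) ** 2, np.maximum(xp, 0) ** 2)
           + np.maximum(np.minimum(ym, 0) ** 2, np.maximum(yp, 0) ** 2))
    return np.where(v > 0, np.sqrt(pos), np.sqrt(neg))


def _reinit(field: LevelSetField, iters: int = 12) -> LevelSetField:
    """Re-distance psi toward |grad psi| = 1 without moving the zero set.

    Iterates the reinitialization equation psi_t = S(psi0) (1 - |grad psi|)
    with the smoothed sign S = psi0 / sqrt(psi0^2 + h^2) and Godunov
    upwinding, which preserves the sub-cell position of the interface.
    """
    h = field.h
    psi0 = field.psi
    S = psi0 / np.sqrt(psi0 ** 2 + h ** 2)
    psi = psi0.copy()
    dtau = 0.5 * h
    for _ in range(iters):
        gn = _godunov_gradnorm(psi, h, S, "upwind1")
        psi = psi - dtau * S * (gn - 1.0)
    return LevelSetField(psi, field.origin, field.h)


def _extend_closest_point(grid_field: np.ndarray, field: LevelSetField,
                          band: np.ndarray) -> np.ndarray:
    """Closest-point extension f(x) <- f(x - psi*n) within the band."""
    gx, gy = _grad(field.psi, field.h)
    norm = np.sqrt(gx ** 2 + gy ** 2) + 1e-12
    X, Y = field.xy_mesh()
    cx = X - field.psi * gx / norm
    cy = Y - field.psi * gy / norm
    out = grid_field.copy()
    rows = (cy[band] - field.origin[1]) / field.h
    cols = (cx[band] - field.origin[0]) / field.h
    out[band] = ndimage.map_coordinates(grid_field, [rows, cols], order=1,
                                        mode="nearest")
    return out


def mechanics_step(field: LevelSetField, l: np.ndarray,
                   ptotal: np.ndarray, mech: MechParams,
                   dt: float | None = None):
    """One explicit step of the coupled psi / viscoelastic-state advection.

    ``ptotal`` is the total pressure as a grid field (already extended off
    the interface).  The normal velocity is ``v = -(kc/tau_c) l +
    (1/tau_c + 1/tau_a) ptotal``, evaluated inside the narrow band around
    the interface and zero outside it (the far field is maintained by
    reinitialization); ``psi`` moves by Godunov upwinding of the
    Hamilton-Jacobi equation and ``l`` by upwind transport along the normal
    plus Voigt relaxation.  When the CFL bound ``max|v| dt < h`` fails, the
    step is internally split in halves (up to 4 times) before failing.
    Returns ``(field', l', v)``.
    """
    dt = mech.dt if dt is None else dt
    h = field.h
    band = np.abs(field.psi) < mech.band_cells * h
    v = -(mech.kc / mech.tau_c) * l + (1.0 / mech.tau_c
                                       + 1.0 / mech.tau_a) * ptotal
    v = np.where(band, v, 0.0)
    vmax = float(np.max(np.abs(v)))
    n_sub, trial = 1, 0
    while vmax * dt / n_sub >= h:
        n_sub *= 2
        trial += 1
        if trial > 4:
            raise RuntimeError(
                f"CFL violation persists after 4 halvings (max|v|={vmax:.3g})")
    sub = dt / n_sub
    psi = field.psi
    for _ in range(n_sub):
        gn = _godunov_gradnorm(psi, h, v, mech.scheme)
        psi = psi - sub * v * gn
        # l transport: upwind along the velocity v*n
        gx, gy = _grad(psi, h)
        norm = np.sqrt(gx ** 2 + gy ** 2) + 1e-12
        ux = v * gx / norm
        uy = v * gy / norm
        lxm, lxp = _one_sided(l, h, axis=1, scheme="upwind1")
        lym, lyp = _one_sided(l, h, axis=0, scheme="upwind1")
        adv = (np.where(ux > 0, ux * lxm, ux * lxp)
               + np.where(uy > 0, uy * lym, uy * lyp))
        l = l + sub * (-adv - (mech.kc / mech.tau_c) * l
                       + ptotal / mech.tau_c)
        l = np.where(band, l, 0.0)
    return LevelSetField(psi, field.origin, field.h), l, v


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

@dataclass
class CellShapeSeries:
    """Per-frame masks, geometry and signaling of a simulated cell."""

    times: np.ndarray
    masks: list                    # boolean (ny, nx) arrays
    origins: list                  # grid origin per frame (moving window)
    h: float
    centroids: np.ndarray          # (n, 2) um
    areas: np.ndarray
    solidity: np.ndarray
    contours: list                 # (k, 2) physical xy per frame
    ep_bins: np.ndarray            # (n, n_bins) Ep per sector per frame
    meta: dict = field(default_factory=dict)

    def centroid_track(self, cell_id: int = 0) -> Track:
        return Track(cell_id, self.times, self.centroids)

    def save_masks_tiff(self, path) -> None:
        import tifffile
        tifffile.imwrite(path, np.stack(self.masks).astype(np.uint8))


def _ep_field(field: LevelSetField, centroid: np.ndarray,
              ep_bins: np.ndarray) -> np.ndarray:
    """Map per-sector Ep onto the grid by angle from the centroid.

    Values are interpolated periodically between sector centers so pressures
    vary smoothly along the boundary.
    """
    n = len(ep_bins)
    X, Y = field.xy_mesh()
    theta = np.mod(np.arctan2(Y - centroid[1], X - centroid[0]), 2 * np.pi)
    pos = theta / (2 * np.pi / n) - 0.5        # sector-center coordinates
    i0 = np.floor(pos).astype(int) % n
    frac = pos - np.floor(pos)
    return ep_bins[i0] * (1 - frac) + ep_bins[(i0 + 1) % n] * frac


def _solidity(contour_xy: np.ndarray) -> float:
    """Contour-polygon solidity (sub-pixel, avoids rasterization bias)."""
    if len(contour_xy) < 4:
        return float("nan")
    from scipy.spatial import ConvexHull
    x, y = contour_xy[:, 0], contour_xy[:, 1]
    area = 0.5 * abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1]))
    hull_area = ConvexHull(contour_xy[:-1]).volume
    return float(area / hull_area)


def _recenter(field: LevelSetField, l: np.ndarray, margin_cells: int = 10):
    """Shift the window by whole cells so the cell regains its margin."""
    inside = field.psi < 0
    rows = np.any(inside, axis=1)
    cols = np.any(inside, axis=0)
    ny, nx = field.psi.shape
    r0, r1 = np.argmax(rows), ny - 1 - np.argmax(rows[::-1])
    c0, c1 = np.argmax(cols), nx - 1 - np.argmax(cols[::-1])
    shift_r = shift_c = 0
    if r0 < margin_cells or ny - 1 - r1 < margin_cells:
        shift_r = (ny - 1 - r1 - r0) // 2
    if c0 < margin_cells or nx - 1 - c1 < margin_cells:
        shift_c = (nx - 1 - c1 - c0) // 2
    if shift_r == 0 and shift_c == 0:
        return field, l
    big = float(np.max(field.psi))
    psi = np.roll(field.psi, (shift_r, shift_c), axis=(0, 1))
    lsh = np.roll(l, (shift_r, shift_c), axis=(0, 1))
    # rolled-in borders hold stale values: overwrite with 'far outside'
    if shift_r > 0:
        psi[:shift_r] = big
        lsh[:shift_r] = 0.0
    elif shift_r < 0:
        psi[shift_r:] = big
        lsh[shift_r:] = 0.0
    if shift_c > 0:
        psi[:, :shift_c] = big
        lsh[:, :shift_c] = 0.0
    elif shift_c < 0:
        psi[:, shift_c:] = big
        lsh[:, shift_c:] = 0.0
    origin = (field.origin[0] - shift_c * field.h,
              field.origin[1] - shift_r * field.h)
    return LevelSetField(psi, origin, field.h), lsh


def simulate_cell(kymo: Kymograph, mech: MechParams | None = None,
                  t_end: float | None = None, frame_dt: float = 1.0,
                  extent: tuple[float, float] = (12.0, 12.0),
                  keep_masks: bool = True,
                  ep_smooth_bins: int = 3) -> CellShapeSeries:
    """Drive the level-set cell with a signaling kymograph.

    The kymograph's per-bin ``Ep`` (20 sectors, lab frame, sector 0 starting
    at angle 0) is mapped onto the boundary by angle from the current
    centroid and linearly interpolated in time.  ``ep_smooth_bins`` applies
    a circular rolling mean over that many sectors before the pressures are
    evaluated: cortical force generation is spatially coherent over more
    than one 18-degree sector, and unsmoothed per-bin noise couples into
    large area fluctuations through the protrusion/retraction
    normalization.  Shape, centroid, area and solidity are recorded every
    ``frame_dt``; the run is deterministic given the kymograph.  Raises on
    pinch-off (boundary splits into several components).
    """
    mech = mech or MechParams()
    if t_end is None:
        t_end = float(kymo.times[-1])
    if kymo.times[0] > 1e-9 or kymo.times[-1] < t_end - 1e-9:
        raise ValueError("kymograph must cover [0, t_end]")
    field = init_signed_distance((0.0, 0.0), mech.R, extent, mech.pts_per_um)
    l = np.zeros_like(field.psi)
    A0 = field.area()
    n_steps = int(round(t_end / mech.dt))
    stride = max(1, int(round(frame_dt / mech.dt)))
    inv_R = 1.0 / mech.R

    times, masks, origins, cents, areas, solids, conts, eps = \
        [], [], [], [], [], [], [], []

    t_idx = 0
    ep_now = kymo.values[:, 0]

    def record(t):
        mask = field.mask()
        lab, n_comp = ndimage.label(mask)
        if n_comp != 1:
            raise RuntimeError(
                f"cell mask split into {n_comp} components at t={t:.2f}")
        times.append(t)
        if keep_masks:
            masks.append(mask.copy())
            origins.append(field.origin)
        cents.append(field.centroid())
        areas.append(field.area())
        try:
            c = _find_single_contour(field)
        except ValueError:
            c = np.empty((0, 2))
        conts.append(c)
        solids.append(_solidity(c))
        eps.append(np.asarray(ep_now).copy())

    record(0.0)
    for step in range(1, n_steps + 1):
        t = (step - 1) * mech.dt
        # linear interpolation of the kymograph in time
        while t_idx + 1 < len(kymo.times) - 1 and kymo.times[t_idx + 1] <= t:
            t_idx += 1
        t0, t1 = kymo.times[t_idx], kymo.times[t_idx + 1]
        w = float(np.clip((t - t0) / (t1 - t0), 0.0, 1.0))
        ep_now = (1 - w) * kymo.values[:, t_idx] + w * kymo.values[:, t_idx + 1]
        if ep_smooth_bins > 1:
            ep_now = ndimage.uniform_filter1d(ep_now, ep_smooth_bins,
                                              mode="wrap")

        centroid = field.centroid()
        band = np.abs(field.psi) < mech.band_cells * field.h
        kap_raw = np.clip(_curvature(field.psi, field.h),
                          -2.0 / field.h, 2.0 / field.h)
        ep_grid = _ep_field(field, centroid, ep_now)
        kappa = _extend_closest_point(kap_raw, field, band)
        m, hi = ep_now.mean(), ep_now.max()
        prot = np.zeros_like(ep_grid)
        retr = np.zeros_like(ep_grid)
        if hi - m > 1e-9:
            prot = np.where(ep_grid > m,
                            mech.Kprot * (ep_grid - m) / (hi - m), 0.0)
            retr = np.where(ep_grid < m,
                            -mech.Kretr * (m - ep_grid) / (hi - m), 0.0)
        parea = mech.Karea * (A0 - field.area())
        ptotal = prot + retr + parea - mech.Kten * (kappa - inv_R)

        field, l, _ = mechanics_step(field, l, ptotal, mech)

        if step % mech.reinit_every == 0:
            field = _reinit(field)
            band = np.abs(field.psi) < mech.band_cells * field.h
            l = _extend_closest_point(l, field, band)
            field, l = _recenter(field, l)

        if step % stride == 0:
            record(step * mech.dt)

    return CellShapeSeries(
        np.array(times), masks, origins, field.h, np.array(cents),
        np.array(areas), np.array(solids), conts, np.array(eps),
        meta={"mech": mech.__dict__.copy(), "A0": A0,
              "kymo_species": kymo.meta.get("species"),
              "kymo_hash": kymo.meta.get("params_hash")})
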