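"""Single-cell quantification of signaling, morphological and migratory memory.

Implements the analysis procedures applied to ratiometric membrane
fluorescence records (PTB-domain translocation reporting EGFR
phosphorylation), binary cell-mask series and migration tracks:

* per-bin EGFRp kymograph construction with endosomal correction and
  baseline/max normalization, plus the whole-membrane temporal profile;
* GMM-based classification into non-activated / activated / pre-activated;
* memory-duration estimators in three modalities: polarized-membrane-area
  persistence (signaling), solidity recovery (morphology) and
  gradient-aligned displacement statistics (migration, both ensemble
  KS-test based and per-cell threshold based);
* inverse-sigmoid (Hill-type) decay fits of the phosphorylation fall-off;
* Takens delay embedding for state-space reconstruction;
* local-gradient quantification around the cell perimeter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq, curve_fit
from scipy.signal import savgol_filter
from scipy.stats import ks_2samp
from sklearn.mixture import GaussianMixture

from .motility import Track, TrackEnsemble, cos_theta_series
from .signaling import Kymograph

__all__ = [
    "CellFluorescenceRecord",
    "MemoryEstimate",
    "SigmoidFit",
    "EmbeddingResult",
    "egfrp_kymograph",
    "egfrp_timecourse",
    "classify_activation",
    "polarization_memory",
    "shape_metrics",
    "morphology_memory",
    "fit_inverse_sigmoid",
    "takens_embedding",
    "migration_memory",
    "single_cell_cos_memory",
    "gradient_alignment",
    "kalman_smooth",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CellFluorescenceRecord:
    """Ratiometric membrane fluorescence of one cell (20 bins x time).

    ``ptb_pm``/``egfr_pm`` are per-bin plasma-membrane intensities of the
    translocation reporter and the receptor; ``ptb_t``/``egfr_t`` whole-cell
    totals; ``ptb_endo`` the endosome-bound reporter fraction subtracted in
    the ratio.  ``egf_pm`` optionally carries the local ligand around the
    perimeter.
    """

    t: np.ndarray
    ptb_pm: np.ndarray           # (n_bins, n_times)
    egfr_pm: np.ndarray
    ptb_t: np.ndarray            # (n_times,)
    egfr_t: np.ndarray
    ptb_endo: np.ndarray
    egf_pm: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("ptb_pm", "egfr_pm", "ptb_t", "egfr_t", "ptb_endo"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.ptb_pm < 0) or np.any(self.egfr_pm < 0):
            raise ValueError("fluorescence must be non-negative")
        if np.any(self.ptb_endo > self.ptb_t + 1e-9):
            raise ValueError("endosomal PTB cannot exceed total PTB")

    @property
    def n_bins(self) -> int:
        return self.ptb_pm.shape[0]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class MemoryEstimate:
    """A detected memory interval in one modality.

    ``duration`` is ``t_memory_end - t_stimulus_end``; ``inf`` encodes
    "at least as long as the observation window", ``nan`` "none detected /
    undefined".
    """

    modality: str                    # signaling | morphology | migration
    t_stimulus_end: float
    t_memory_end: float
    duration: float
    rule: str
    per_cell: bool = True

    @classmethod
    def none(cls, modality: str, t_stim_end: float, rule: str,
             per_cell: bool = True) -> "MemoryEstimate":
        return cls(modality, t_stim_end, float("nan"), float("nan"), rule,
                   per_cell)

    @classmethod
    def at_least_window(cls, modality: str, t_stim_end: float, t_last: float,
                        rule: str, per_cell: bool = True) -> "MemoryEstimate":
        return cls(modality, t_stim_end, float(t_last), float("inf"), rule,
                   per_cell)


# ---------------------------------------------------------------------------
# kymographs and temporal profiles
# ---------------------------------------------------------------------------

def egfrp_kymograph(rec: CellFluorescenceRecord, t_pre: float = 5.0,
                    normalize: bool = True) -> Kymograph:
    """Per-bin fraction of phosphorylated receptor, as a kymograph.

    The raw per-bin ratio is ``(PTB_i/(PTB_T - PTB_endo)) /
    (EGFR_i/EGFR_T)`` (endosome-corrected reporter translocation over
    relative receptor density).  With ``normalize`` the pre-stimulus mean is
    subtracted and the result scaled by its global maximum, mapping the
    kymograph to about [0, 1].  Bins with a vanishing receptor denominator
    are flagged as NaN.
    """
    denom_cell = rec.ptb_t - rec.ptb_endo
    if np.any(denom_cell <= 0):
        raise ValueError("PTB_T - PTB_endo must stay positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (rec.ptb_pm / denom_cell) / (rec.egfr_pm / rec.egfr_t)
    ratio[~np.isfinite(ratio)] = np.nan
    values = ratio
    if normalize:
        pre = rec.t <= t_pre
        base = np.nanmean(ratio[:, pre])
        peak = np.nanmax(ratio)
        scale = peak - base
        if abs(scale) < 1e-12:
            values = np.zeros_like(ratio)
        else:
            values = (ratio - base) / scale
    angles = (np.arange(rec.n_bins) + 0.5) * 2 * np.pi / rec.n_bins
    return Kymograph(values, rec.t, angles,
                     {"species": "EGFRp", "normalized": normalize,
                      "t_pre": t_pre})


def egfrp_timecourse(rec: CellFluorescenceRecord, t_pre: float = 5.0):
    """Whole-membrane phosphorylation profile and liganded-receptor fraction.

    Returns ``(egfrp_norm, egf_bound)``: the summed membrane ratio
    normalized to its pre-stimulus baseline (0) and overall maximum (1),
    and the bound-ligand fraction ``sum(EGF_PM)/sum(EGFR_PM)`` (empty array
    when the record carries no ligand channel).
    """
    if rec.t[0] > t_pre - 1e-9 or not np.any(rec.t <= t_pre):
        raise ValueError("record must include a pre-stimulus baseline")
    denom_cell = rec.ptb_t - rec.ptb_endo
    num = rec.ptb_pm.sum(axis=0) / denom_cell
    den = rec.egfr_pm.sum(axis=0) / rec.egfr_t
    prof = num / den
    pre = rec.t <= t_pre
    base = prof[pre].mean()
    scale = prof.max() - base
    norm = np.zeros_like(prof) if abs(scale) < 1e-12 else (prof - base) / scale
    if rec.egf_pm is not None:
        egf_bound = rec.egf_pm.sum(axis=0) / rec.egfr_pm.sum(axis=0)
    else:
        egf_bound = np.array([])
    return norm, egf_bound


# ---------------------------------------------------------------------------
# activation classification
# ---------------------------------------------------------------------------

def _gmm_intersection(gmm: GaussianMixture) -> tuple[float, bool]:
    """Crossing point of the two weighted component densities.

    Returns (threshold, ok); when no crossing exists between the means the
    midpoint of the means is returned with ok=False.
    """
    mus = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    ws = gmm.weights_.ravel()
    order = np.argsort(mus)
    m1, m2 = mus[order]
    s1, s2 = sds[order]
    w1, w2 = ws[order]

    def diff(x):
        p1 = w1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) / s1
        p2 = w2 * np.exp(-0.5 * ((x - m2) / s2) ** 2) / s2
        return p1 - p2

    if m2 - m1 < 1e-12 or diff(m1) * diff(m2) > 0:
        return 0.5 * (m1 + m2), False
    return float(brentq(diff, m1, m2)), True


def classify_activation(records: list[CellFluorescenceRecord],
                        t_pre: float = 5.0, t_resp: float = 65.0,
                        pre_activated_frac: float = 0.30,
                        random_state: int = 0):
    """Label cells as non-activated, activated or pre-activated.

    A two-component GMM is fitted to the pooled pre-stimulus per-bin
    phosphorylation values of all cells and its component-density crossing
    used as a threshold: cells with more than ``pre_activated_frac`` of
    their pre-stimulus bins above it are pre-activated.  The remaining
    cells are split by a second GMM on their mean phosphorylation over
    ``[0, t_resp]``.  Returns ``(labels, info)``; ``info`` carries both
    thresholds and fallback flags.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 cells")
    # raw (unnormalized) ratios: per-cell baseline normalization would erase
    # exactly the between-cell baseline differences the GMM separates
    kymos = [egfrp_kymograph(r, t_pre=t_pre, normalize=False)
             for r in records]
    pre_vals = [k.values[:, k.times <= t_pre].ravel() for k in kymos]
    pooled = np.concatenate(pre_vals)
    pooled = pooled[np.isfinite(pooled)]
    info: dict = {}
    degenerate = np.ptp(pooled) < 1e-12
    if degenerate:
        info["degenerate"] = True
        thr1, ok1 = float(pooled[0]) + 1.0, False
    else:
        g1 = GaussianMixture(2, random_state=random_state).fit(
            pooled.reshape(-1, 1))
        thr1, ok1 = _gmm_intersection(g1)
        if not (pooled.min() <= thr1 <= pooled.max()):
            thr1 = float(np.mean(g1.means_))
            ok1 = False
    info["pre_threshold"], info["pre_threshold_ok"] = thr1, ok1

    labels = np.empty(len(records), dtype=object)
    rest = []
    for i, vals in enumerate(pre_vals):
        frac = np.mean(vals > thr1)
        if frac > pre_activated_frac:
            labels[i] = "pre-activated"
        else:
            rest.append(i)

    if rest:
        means = []
        for i in rest:
            k = kymos[i]
            sel = k.times <= t_resp
            means.append(np.nanmean(k.values[:, sel]))
        means = np.array(means)
        if np.ptp(means) < 1e-12 or len(rest) < 2:
            info["response_degenerate"] = True
            for i in rest:
                labels[i] = "non-activated"
        else:
            g2 = GaussianMixture(2, random_state=random_state).fit(
                means.reshape(-1, 1))
            thr2, ok2 = _gmm_intersection(g2)
            if not (means.min() <= thr2 <= means.max()):
                thr2 = float(np.mean(g2.means_))
                ok2 = False
            info["resp_threshold"], info["resp_threshold_ok"] = thr2, ok2
            for i, m in zip(rest, means):
                labels[i] = "activated" if m > thr2 else "non-activated"
    return labels, info


# ---------------------------------------------------------------------------
# memory estimators
# ---------------------------------------------------------------------------

def polarization_memory(kymo: Kymograph, t_stim_end: float,
                        consecutive: int = 3) -> MemoryEstimate:
    """Signaling memory from the fraction of polarized membrane area (FPA).

    Bins above (mean + s.d.) of the normalized kymograph over the whole
    record constitute polarized area; FPA(t) is their fraction.  Memory
    ends at the first post-stimulus time where FPA stays below its own
    time-average minus one s.d. for ``consecutive`` samples.
    """
    v = kymo.values
    thr = np.nanmean(v) + np.nanstd(v)
    fpa = np.mean(v > thr, axis=0)
    # FPA is non-negative, so the crossing threshold is clamped at zero;
    # <= lets a record with no polarized area at all (FPA at its floor)
    # carry zero memory rather than an undetermined one
    fthr = max(fpa.mean() - fpa.std(), 0.0)
    below = fpa <= fthr
    start = int(np.searchsorted(kymo.times, t_stim_end - 1e-9))
    run = 0
    for i in range(start, len(fpa)):
        run = run + 1 if below[i] else 0
        if run >= consecutive:
            t_end = float(kymo.times[i - consecutive + 1])
            return MemoryEstimate("signaling", t_stim_end, t_end,
                                  max(0.0, t_end - t_stim_end), "FPA<mean-sd")
    return MemoryEstimate.at_least_window("signaling", t_stim_end,
                                          float(kymo.times[-1]),
                                          "FPA<mean-sd")


def _mask_solidity(mask: np.ndarray) -> float:
    """Sub-pixel solidity from the mask's half-level contour polygon.

    Pixel-count solidity of a rasterized disc is biased low (~0.95 at a
    20-px radius) because the pixelated hull exceeds the pixelated region
    by about half the perimeter; the contour polygon removes that bias.
    Falls back to pixel counting when no closed contour is found.
    """
    from scipy.spatial import ConvexHull
    from skimage.measure import find_contours, regionprops
    smooth = ndimage.gaussian_filter(mask.astype(float), 1.0)
    conts = [c for c in find_contours(smooth, 0.5)
             if np.allclose(c[0], c[-1]) and len(c) > 8]
    if not conts:
        return float(regionprops(mask.astype(np.uint8))[0].solidity)
    c = max(conts, key=len)
    x, y = c[:, 1], c[:, 0]
    area = 0.5 * abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1]))
    hull = ConvexHull(c[:-1]).volume
    return float(area / hull)


def shape_metrics(masks: np.ndarray, pixel_size: float,
                  gradient_direction: tuple[float, float] = (-1.0, 0.0),
                  area_threshold_um2: float | None = 1.2,
                  smooth_sigma_px: float = 1.0,
                  smooth_sigma_t: float = 1.0):
    """Solidity and directed protrusion area from a binary mask series.

    ``masks`` is (n_times, ny, nx); the gradient direction is given in
    physical (x, y).  Solidity is cell area over convex-hull area.  The
    directed protrusion area compares consecutive (Gaussian pre-smoothed)
    masks: new pixels are split into front/back by the axis through the
    first frame's centroid perpendicular to the gradient, combined as
    ``A_prot_front/A_front - A_prot_back/A_back`` and Gaussian-smoothed in
    time.  An area threshold (in um^2, per the live-imaging procedure) can
    be disabled with ``None`` for simulation masks.
    """
    masks = np.asarray(masks).astype(bool)
    n = masks.shape[0]
    solidity = np.empty(n)
    for i in range(n):
        if not masks[i].any():
            raise ValueError(f"empty mask at frame {i}")
        solidity[i] = _mask_solidity(masks[i])

    d = np.asarray(gradient_direction, dtype=float)
    d /= np.linalg.norm(d)
    cy0, cx0 = ndimage.center_of_mass(masks[0])
    Y, X = np.indices(masks[0].shape)
    # front = half-plane toward the gradient source from the initial centroid
    proj = (X - cx0) * d[0] + (Y - cy0) * d[1]
    front = proj > 0

    min_px = None
    if area_threshold_um2 is not None:
        min_px = max(10, int(np.ceil(area_threshold_um2 / pixel_size ** 2)))

    dpa = np.zeros(n)
    for i in range(1, n):
        m0 = ndimage.gaussian_filter(masks[i - 1].astype(float),
                                     smooth_sigma_px) > 0.5
        m1 = ndimage.gaussian_filter(masks[i].astype(float),
                                     smooth_sigma_px) > 0.5
        new = m1 & ~m0
        if min_px is not None and int(new.sum()) <= min_px:
            new = np.zeros_like(new)
        a_front = int((m1 & front).sum())
        a_back = int((m1 & ~front).sum())
        pf = int((new & front).sum()) / a_front if a_front else 0.0
        pb = int((new & ~front).sum()) / a_back if a_back else 0.0
        dpa[i] = pf - pb
    if smooth_sigma_t > 0:
        dpa = ndimage.gaussian_filter1d(dpa, smooth_sigma_t)
    return solidity, dpa


def morphology_memory(solidity: np.ndarray, times: np.ndarray,
                      t_stim_start: float, t_stim_end: float
                      ) -> MemoryEstimate:
    """Morphological memory from solidity recovery after washout.

    The threshold is (mean - s.d.) of solidity during gradient presence;
    memory ends at the last post-washout time at which solidity is still
    below it (the cell has recovered its rounded shape afterwards).
    Sentinel "none" when solidity never drops below the threshold during
    the gradient (no morphological response to lose).
    """
    times = np.asarray(times, dtype=float)
    sol = np.asarray(solidity, dtype=float)
    grad = (times >= t_stim_start) & (times <= t_stim_end)
    thr = sol[grad].mean() - sol[grad].std()
    if not np.any(sol[grad] < thr):
        return MemoryEstimate.none("morphology", t_stim_end, "sol<mean-sd")
    post = times > t_stim_end
    below = post & (sol < thr)
    if not below.any():
        return MemoryEstimate("morphology", t_stim_end, t_stim_end, 0.0,
                              "sol<mean-sd")
    t_end = float(times[np.where(below)[0][-1]])
    if t_end >= times[-1] - 1e-9:
        return MemoryEstimate.at_least_window("morphology", t_stim_end,
                                              float(times[-1]), "sol<mean-sd")
    return MemoryEstimate("morphology", t_stim_end, t_end,
                          t_end - t_stim_end, "sol<mean-sd")


# ---------------------------------------------------------------------------
# sigmoid decay fits
# ---------------------------------------------------------------------------

@dataclass
class SigmoidFit:
    """Inverse-sigmoid fit f(t) = a0 / (a^n + t^n) of a decaying profile.

    ``half_life`` is the closed-form half-decay time: f(t) = f(0)/2 exactly
    at t = a, independent of a0 and n.
    """

    a0: float
    a: float
    n: float
    r2: float
    converged: bool = True

    @property
    def half_life(self) -> float:
        return self.a

    def __call__(self, t):
        return self.a0 / (self.a ** self.n + np.asarray(t) ** self.n)


def fit_inverse_sigmoid(t: np.ndarray, y: np.ndarray,
                        fix_a: float | None = None,
                        p0: tuple | None = None) -> SigmoidFit:
    """Nonlinear least-squares fit of the inverse sigmoid decay.

    With ``fix_a`` the scale parameter is held fixed and only (a0, n) are
    free.  Non-convergence is reported via ``converged=False`` with the
    best-effort parameters.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 8:
        raise ValueError("need at least 8 samples for a stable fit")
    tmed = max(float(np.median(t)), 1e-6)
    ok = True
    try:
        if fix_a is None:
            def f(tt, a0, a, n):
                return a0 / (a ** n + tt ** n)
            if p0 is None:
                p0 = (y[0] * tmed, tmed, 2.0)
            popt, _ = curve_fit(f, t, y, p0=p0, maxfev=40000,
                                bounds=([0, 1e-6, 1e-3],
                                        [np.inf, np.inf, 50]))
            a0, a, n = popt
        else:
            def f(tt, a0, n):
                return a0 / (fix_a ** n + tt ** n)
            if p0 is None:
                p0 = (y[0] * fix_a, 2.0)
            popt, _ = curve_fit(f, t, y, p0=p0, maxfev=40000,
                                bounds=([0, 1e-3], [np.inf, 50]))
            a0, n = popt
            a = fix_a
    except RuntimeError:
        ok = False
        a0, a, n = (y[0] * tmed, tmed if fix_a is None else fix_a, 1.0)
    resid = y - a0 / (a ** n + t ** n)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 \
        else float("nan")
    return SigmoidFit(float(a0), float(a), float(n), float(r2), ok)


# ---------------------------------------------------------------------------
# delay embedding
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingResult:
    delay: int
    dim: int
    embedded: np.ndarray          # (N - (m-1) d, m)
    smoothed: np.ndarray
    fnn_fraction: float
    capped: bool = False


def _autocorr_delay(x: np.ndarray, max_lag: int) -> int:
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 1
    for lag in range(1, max_lag):
        c = float(np.dot(x[:-lag], x[lag:])) / denom
        if c < 1.0 / np.e:
            return lag
    return max_lag


def _fnn_fraction(x: np.ndarray, d: int, m: int, rtol: float = 15.0,
                  atol: float = 2.0) -> float:
    """False-nearest-neighbour fraction going from dimension m to m+1.

    A neighbour is false when the extra coordinate stretches it by more
    than ``rtol`` relative to its distance, or beyond ``atol`` times the
    series spread (the loneliness criterion that keeps stochastic series
    from being declared deterministic).
    """
    n = len(x) - m * d
    if n < 10:
        return 1.0
    sd = x.std() + 1e-12
    emb = np.column_stack([x[i * d: i * d + n] for i in range(m)])
    nxt = x[m * d: m * d + n]
    bad = 0
    for i in range(n):
        dist = np.linalg.norm(emb - emb[i], axis=1)
        dist[i] = np.inf
        j = int(np.argmin(dist))
        dm = dist[j]
        if dm == 0:
            continue
        dm1 = np.hypot(dm, nxt[i] - nxt[j])
        if (dm1 - dm) / dm > rtol or dm1 / sd > atol:
            bad += 1
    return bad / n


def takens_embedding(series: np.ndarray, delay: int | None = None,
                     dim: int | None = None, max_dim: int = 5,
                     fnn_threshold: float = 0.05,
                     smooth_window: int = 11, smooth_order: int = 3
                     ) -> EmbeddingResult:
    """Time-delay state-space reconstruction of a scalar series.

    The series is Savitzky-Golay smoothed, the delay taken as the first
    autocorrelation drop below 1/e, and the dimension as the smallest m
    with a false-nearest-neighbour fraction below ``fnn_threshold``
    (capped at ``max_dim`` and flagged when the cap binds).  Explicit
    ``delay``/``dim`` override the automatic choices.
    """
    x = np.asarray(series, dtype=float)
    if smooth_window and len(x) > smooth_window:
        x = savgol_filter(x, smooth_window, smooth_order)
    if delay is None:
        delay = _autocorr_delay(x, max_lag=max(2, len(x) // 3))
    capped = False
    fnn = float("nan")
    if dim is None:
        dim = max_dim
        capped = True
        for m in range(2, max_dim + 1):
            fnn = _fnn_fraction(x, delay, m)
            if fnn < fnn_threshold:
                dim = m
                capped = False
                break
    rows = len(x) - (dim - 1) * delay
    if rows < 10:
        raise ValueError("series too short for the requested embedding")
    emb = np.column_stack([x[i * delay: i * delay + rows]
                           for i in range(dim)])
    return EmbeddingResult(int(delay), int(dim), emb, x, float(fnn), capped)


# ---------------------------------------------------------------------------
# migration memory
# ---------------------------------------------------------------------------

def _pooled_costheta(tracks: list[Track], source_direction, idx0, idx1
                     ) -> np.ndarray:
    vals = []
    for tr in tracks:
        ct = cos_theta_series(tr, source_direction)
        vals.append(ct[max(idx0, 0): idx1])
    out = np.concatenate(vals) if vals else np.array([])
    return out[np.isfinite(out)]


def migration_memory(ensemble: TrackEnsemble,
                     source_direction: tuple[float, float],
                     reference: np.ndarray,
                     t_washout: float,
                     window: int = 5, alpha: float = 0.05,
                     consecutive: int = 2,
                     min_samples: int = 20) -> MemoryEstimate:
    """Ensemble migration memory via sliding-window KS tests on cos(theta).

    Each window of ``window`` time points pools the per-step displacement
    alignments of all tracks and compares them against the no-stimulus
    ``reference`` distribution with a two-sided Kolmogorov-Smirnov test.
    Memory ends at the first post-washout window where the test fails to
    reject (p >= alpha) in ``consecutive`` consecutive windows.  Windows
    with fewer than ``min_samples`` alignments are widened symmetrically
    (flagged in the rule string).
    """
    reference = np.asarray(reference, dtype=float)
    reference = reference[np.isfinite(reference)]
    tr0 = ensemble.tracks[0]
    n_steps = ensemble.min_length() - 1
    i_wash = int(np.searchsorted(tr0.t, t_washout - 1e-9))
    hits = 0
    widened = False
    for i0 in range(i_wash, n_steps - window + 1):
        i1 = i0 + window
        vals = _pooled_costheta(ensemble.tracks, source_direction, i0, i1)
        grow = 0
        while len(vals) < min_samples and grow < 5:
            grow += 1
            widened = True
            vals = _pooled_costheta(ensemble.tracks, source_direction,
                                    i0 - grow, i1 + grow)
        if len(vals) < 3:
            continue
        p = ks_2samp(vals, reference).pvalue
        hits = hits + 1 if p >= alpha else 0
        if hits >= consecutive:
            t_end = float(tr0.t[i0 - (consecutive - 1)])
            rule = f"KS p>={alpha} x{consecutive}" + \
                (" (widened)" if widened else "")
            return MemoryEstimate("migration", t_washout, t_end,
                                  max(0.0, t_end - t_washout), rule,
                                  per_cell=False)
    return MemoryEstimate.at_least_window(
        "migration", t_washout, float(tr0.t[n_steps]),
        f"KS p>={alpha} x{consecutive}", per_cell=False)


def kalman_smooth(track: Track, process_std: float = 0.1,
                  measurement_std: float = 0.5) -> Track:
    """Constant-velocity Kalman (RTS) smoothing of a 2-D track.

    State is (x, y, vx, vy) with white-acceleration process noise of
    standard deviation ``process_std`` (um/min^2) and isotropic position
    measurement noise ``measurement_std`` (um).
    """
    dt = track.dt
    z = track.xy
    n = len(z)
    F = np.eye(4)
    F[0, 2] = F[1, 3] = dt
    q = process_std ** 2
    Q = np.zeros((4, 4))
    for (a, b) in ((0, 2), (1, 3)):
        Q[a, a] = q * dt ** 4 / 4
        Q[a, b] = Q[b, a] = q * dt ** 3 / 2
        Q[b, b] = q * dt ** 2
    H = np.zeros((2, 4))
    H[0, 0] = H[1, 1] = 1.0
    R = measurement_std ** 2 * np.eye(2)

    xs = np.zeros((n, 4))
    Ps = np.zeros((n, 4, 4))
    xp = np.zeros((n, 4))
    Pp = np.zeros((n, 4, 4))
    x = np.array([z[0, 0], z[0, 1], 0.0, 0.0])
    P = np.diag([measurement_std ** 2] * 2 + [1.0] * 2)
    for k in range(n):
        if k > 0:
            x = F @ x
            P = F @ P @ F.T + Q
        xp[k], Pp[k] = x, P
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (z[k] - H @ x)
        P = (np.eye(4) - K @ H) @ P
        xs[k], Ps[k] = x, P
    for k in range(n - 2, -1, -1):       # RTS backward pass
        C = Ps[k] @ F.T @ np.linalg.inv(Pp[k + 1])
        xs[k] = xs[k] + C @ (xs[k + 1] - xp[k + 1])
        Ps[k] = Ps[k] + C @ (Ps[k + 1] - Pp[k + 1]) @ C.T
    return Track(track.cell_id, track.t, xs[:, :2], track.phase)


def single_cell_cos_memory(track: Track,
                           source_direction: tuple[float, float],
                           t_washout: float,
                           threshold: float = 0.75,
                           consecutive: int = 3,
                           process_std: float = 0.1,
                           measurement_std: float = 0.5) -> MemoryEstimate:
    """Per-cell migration memory from Kalman-smoothed alignment.

    The track is smoothed with a constant-velocity Kalman filter, per-step
    alignments cos(theta) with the source direction computed, and memory
    ends at the first post-washout time where ``consecutive`` consecutive
    alignments fall below ``threshold``.
    """
    sm = kalman_smooth(track, process_std, measurement_std)
    ct = cos_theta_series(sm, source_direction)
    i_wash = int(np.searchsorted(track.t, t_washout - 1e-9))
    run = 0
    for i in range(i_wash, len(ct)):
        below = bool(np.isfinite(ct[i]) and ct[i] < threshold)
        run = run + 1 if below else 0
        if run >= consecutive:
            t_end = float(track.t[i - consecutive + 2])
            return MemoryEstimate("migration", t_washout, t_end,
                                  max(0.0, t_end - t_washout),
                                  f"cos<{threshold} x{consecutive}")
    return MemoryEstimate.at_least_window(
        "migration", t_washout, float(track.t[-1]),
        f"cos<{threshold} x{consecutive}")


# ---------------------------------------------------------------------------
# gradient alignment
# ---------------------------------------------------------------------------

def _wrapped_gaussian(theta, amp, mu, sigma, base):
    d = np.angle(np.exp(1j * (theta - mu)))
    return base + amp * np.exp(-0.5 * (d / sigma) ** 2)


def gradient_alignment(rec: CellFluorescenceRecord, kymo: Kymograph,
                       t_window: tuple[float, float] | None = None):
    """Angle between the local EGF maximum and the phosphorylation maximum.

    The time-averaged 20-bin EGF projection around the perimeter is fitted
    with a wrapped Gaussian; the angle is the circular bin distance between
    the EGF and EGFRp spatial maxima times the bin width (2*pi/20,
    circular perimeter assumption).  Returns ``(fit_params, angle)`` with
    ``fit_params = (amp, mu, sigma, base)``; the angle is NaN for a flat
    EGF profile.
    """
    if rec.egf_pm is None:
        raise ValueError("record carries no local EGF channel")
    sel = np.ones(len(rec.t), dtype=bool)
    if t_window is not None:
        sel = (rec.t >= t_window[0]) & (rec.t <= t_window[1])
    egf = rec.egf_pm[:, sel].mean(axis=1)
    n = len(egf)
    angles = (np.arange(n) + 0.5) * 2 * np.pi / n
    if np.ptp(egf) < 1e-12:
        return None, float("nan")
    p0 = (float(np.ptp(egf)), float(angles[int(np.argmax(egf))]), 1.0,
          float(egf.min()))
    try:
        popt, _ = curve_fit(_wrapped_gaussian, angles, egf, p0=p0,
                            maxfev=20000)
    except RuntimeError:
        popt = p0
    ep_mean = np.nanmean(kymo.values[:, sel], axis=1)
    i_egf = int(np.argmax(egf))
    i_ep = int(np.argmax(ep_mean))
    d_bins = abs(i_egf - i_ep)
    d_bins = min(d_bins, n - d_bins)
    return tuple(float(v) for v in popt), float(d_bins * 2 * np.pi / n)
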