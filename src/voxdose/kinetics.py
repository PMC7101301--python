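"""Time-activity curves, mono-exponential washout fits, time-integrated activity.

The washout model is a single exponential anchored at injection time,

    a(t) = a0 * exp(-t / tau),

fit by unweighted least squares in linear space.  For fixed tau the
amplitude has the closed form a0(tau) = sum(y w) / sum(w^2) with
w = exp(-t/tau), so the fit reduces to a 1-D profile minimization over
tau, which we solve deterministically: log-linear closed-form start,
safeguarded Newton on the profile-SSE gradient, dense-grid fallback.

The time-integrated activity (TIA) is the analytic integral from 0 to
infinity, A = a0 * tau (kBq h), converted to decays with 3.6e6 decays
per kBq h.  Activity before the first scan is extrapolated by the same
exponential; there is no uptake phase in the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ActivitySeries, RoiMask, VoxelGrid, check_same_grid

KBQ_H_TO_DECAYS = 3.6e6

LU177_PHYSICAL_HALF_LIFE_H = 160.8

# tau search window (hours): generous on both sides of anything a 4-point
# TAC over 4-72 h can resolve.
_TAU_LO, _TAU_HI = 1e-2, 1e5

STATUS_OK = "ok"
STATUS_FALLBACK = "fallback"
STATUS_FAILED = "failed"


@dataclass
class Tac:
    """Measured activity as a function of time for one source region."""

    times_h: np.ndarray
    activities: np.ndarray  # kBq for ROI-summed, kBq/mL for a single voxel
    label: str = ""

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=np.float64)
        self.activities = np.asarray(self.activities, dtype=np.float64)
        if self.times_h.shape != self.activities.shape or self.times_h.size < 2:
            raise ValueError("TAC needs matching times/activities with >= 2 samples")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("TAC times must be strictly increasing")


@dataclass
class MonoExpFit:
    """Result of fitting a0 * exp(-t/tau) to a TAC."""

    a0: float
    tau_h: float
    sse: float
    status: str = STATUS_OK

    @property
    def effective_half_life_h(self) -> float:
        return self.tau_h * np.log(2.0)


@dataclass
class TiaMap:
    """Voxel-wise time-integrated activity for one or more ROIs.

    ``voxel_decays`` holds absolute per-voxel decays; ``fractions`` the
    per-ROI normalized source fraction (summing to 1 within each ROI);
    ``roi_decays`` the ROI-level totals the fractions are scaled by.
    """

    grid: VoxelGrid
    voxel_decays: np.ndarray
    fractions: np.ndarray
    roi_decays: dict[int, float]
    roi_fits: dict[int, MonoExpFit]
    fallback_voxels: dict[int, int]


def roi_tac(series: ActivitySeries, mask: RoiMask, label: int) -> Tac:
    """Sum concentration over the ROI at each time point -> kBq.

    Activity per frame is sum(concentration) * voxel volume, i.e. the
    total activity contained in the source region.
    """
    check_same_grid(series, mask)
    idx = mask.voxel_indices(label)
    vol_ml = series.grid.voxel_volume_ml
    stack = series.stack().reshape(len(series.volumes), -1)
    activities = stack[:, idx].sum(axis=1) * vol_ml
    return Tac(times_h=series.times_h, activities=activities, label=mask.names[label][0])


def _profile_sse(t: np.ndarray, y: np.ndarray, tau: np.ndarray):
    """SSE minimized over a0 for each tau; returns (sse, a0)."""
    tau = np.atleast_1d(np.asarray(tau, dtype=np.float64))
    w = np.exp(-t[None, :] / tau[:, None])
    sw2 = (w * w).sum(axis=1)
    a0 = (y[None, :] * w).sum(axis=1) / sw2
    resid = y[None, :] - a0[:, None] * w
    return (resid * resid).sum(axis=1), a0


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0
_BRACKET_GRID = np.exp(np.linspace(np.log(_TAU_LO), np.log(_TAU_HI), 240))


def _profile_minimize(t: np.ndarray, ys: np.ndarray):
    """Vectorized profile minimization of the mono-exponential SSE.

    ys: (n_rows, n_times).  For each row the SSE (profiled over a0) is
    bracketed on a fixed log-tau grid and refined by golden-section
    search -- fully deterministic.  Returns (a0, tau, sse, interior)
    where ``interior`` is False when the minimum sits on the tau search
    boundary (non-decaying or unresolvably fast decay).
    """
    n = ys.shape[0]
    grid = _BRACKET_GRID
    # SSE for every row on every grid point: (n_rows, n_grid); guard
    # against exp underflow at tau << min(t)
    w = np.exp(-t[None, :] / grid[:, None])          # (G, T)
    sw2 = (w * w).sum(axis=1)                        # (G,)
    ok_g = sw2 > 0
    num = ys @ w.T                                   # (n, G)
    a0g = num / np.where(ok_g, sw2, 1.0)[None, :]
    sy2 = (ys * ys).sum(axis=1)[:, None]
    sseg = np.where(ok_g[None, :], sy2 - a0g * num, np.inf)
    k = np.argmin(sseg, axis=1)
    interior = (k > 0) & (k < grid.size - 1)
    lo = np.log(grid[np.maximum(k - 1, 0)])
    hi = np.log(grid[np.minimum(k + 1, grid.size - 1)])

    def sse_at(ltau):
        wv = np.exp(-t[None, :] / np.exp(ltau)[:, None])
        sw2v = (wv * wv).sum(axis=1)
        good = sw2v > 0
        a0v = (ys * wv).sum(axis=1) / np.where(good, sw2v, 1.0)
        a0v = np.where(good, a0v, 0.0)
        resid = ys - a0v[:, None] * wv
        return np.where(good, (resid * resid).sum(axis=1), np.inf), a0v

    for _ in range(95):
        x1 = hi - _GOLDEN * (hi - lo)
        x2 = lo + _GOLDEN * (hi - lo)
        f1, _ = sse_at(x1)
        f2, _ = sse_at(x2)
        left = f1 < f2
        hi = np.where(left, x2, hi)
        lo = np.where(left, lo, x1)
        if np.max(hi - lo) < 1e-13:
            break
    ltau = 0.5 * (lo + hi)
    sse, a0 = sse_at(ltau)
    return a0, np.exp(ltau), sse, interior


def fit_monoexp(tac: Tac) -> MonoExpFit:
    """Least-squares mono-exponential fit in linear space.

    The profiled SSE is minimized over tau by a bracketed deterministic
    search (log-linear theory guarantees the bracket grid spans any
    resolvable decay).  Degenerate inputs: all samples <= 0 -> status
    'failed'; non-decaying data (minimum at the tau boundary) -> status
    'fallback' with a0 = mean of the samples.
    """
    t, y = tac.times_h, tac.activities
    if np.all(y <= 0):
        return MonoExpFit(a0=0.0, tau_h=np.nan, sse=float(np.sum(y * y)),
                          status=STATUS_FAILED)
    a0, tau, sse, interior = _profile_minimize(t, y[None, :])
    a0, tau, sse = float(a0[0]), float(tau[0]), float(sse[0])
    if not interior[0] or a0 <= 0:
        a0_fb = float(np.mean(y))
        return MonoExpFit(a0=a0_fb, tau_h=np.nan,
                          sse=float(np.sum((y - a0_fb) ** 2)),
                          status=STATUS_FALLBACK)
    return MonoExpFit(a0=a0, tau_h=tau, sse=sse, status=STATUS_OK)


def tia_from_fit(fit: MonoExpFit) -> float:
    """Time-integrated activity in decays: a0 * tau kBq h * 3.6e6."""
    if fit.status != STATUS_OK:
        raise ValueError(f"cannot integrate a fit with status {fit.status!r}")
    return fit.a0 * fit.tau_h * KBQ_H_TO_DECAYS


def effective_half_life(fit: MonoExpFit,
                        physical_half_life_h: float = LU177_PHYSICAL_HALF_LIFE_H) -> float:
    """tau * ln 2; warns (does not clamp) when exceeding physical decay.

    Apparent half-lives above the physical one occur in measured data
    (e.g. ongoing uptake between scans) and are reported as fitted.
    """
    if fit.status != STATUS_OK:
        raise ValueError(f"no half-life for fit with status {fit.status!r}")
    t_half = fit.tau_h * np.log(2.0)
    if t_half > physical_half_life_h:
        warnings.warn(
            f"effective half-life {t_half:.1f} h exceeds the physical "
            f"half-life {physical_half_life_h:.1f} h", stacklevel=2)
    return float(t_half)


def _fit_voxels(t: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-voxel mono-exponential fits.

    ys: (n_voxels, n_times).  Returns (a0, tau, ok_mask); voxels without
    a valid decaying fit (fewer than 2 positive samples, boundary
    minimum, or non-positive amplitude) get ok=False.
    """
    n = ys.shape[0]
    a0 = np.zeros(n)
    tau = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)

    enough = (ys > 0).sum(axis=1) >= 2
    if not enough.any():
        return a0, tau, ok
    idx = np.flatnonzero(enough)
    a0c, tauc, _, interior = _profile_minimize(t, ys[idx])
    valid = interior & (a0c > 0) & np.isfinite(tauc)
    a0[idx[valid]] = a0c[valid]
    tau[idx[valid]] = tauc[valid]
    ok[idx[valid]] = True
    return a0, tau, ok


def voxelwise_tia(series: ActivitySeries, mask: RoiMask, label: int,
                  roi_fit: MonoExpFit,
                  absolute_scale: str = "roi_fit") -> TiaMap:
    """Per-voxel TIA fractions for one ROI, scaled to the ROI total.

    Each voxel's TAC (concentration * voxel volume) is fit independently;
    voxel TIAs are normalized to fractions summing to 1, then multiplied
    by the ROI-level TIA from ``roi_fit``.  Voxels whose own fit fails
    (too few positive samples, or a non-decaying TAC) keep the ROI tau
    and refit only their amplitude, so the source map stays consistent;
    their count is reported.

    ``absolute_scale``: 'roi_fit' (default) scales fractions by the
    ROI-level fit integral; 'voxel_sum' keeps the sum of the voxel
    integrals instead.
    """
    if roi_fit.status != STATUS_OK:
        raise ValueError("ROI-level fit must have status 'ok'")
    check_same_grid(series, mask)
    idx = mask.voxel_indices(label)
    t = series.times_h
    vol_ml = series.grid.voxel_volume_ml
    ys = series.stack().reshape(len(series.volumes), -1)[:, idx].T * vol_ml  # kBq

    a0, tau, ok = _fit_voxels(t, ys)
    n_fallback = int((~ok).sum())
    if n_fallback:
        # amplitude-only refit at the ROI tau
        w = np.exp(-t / roi_fit.tau_h)
        a0_fb = (ys[~ok] * w).sum(axis=1) / (w * w).sum()
        a0[~ok] = np.maximum(a0_fb, 0.0)
        tau[~ok] = roi_fit.tau_h

    voxel_tia = a0 * tau * KBQ_H_TO_DECAYS
    total = voxel_tia.sum()
    if total <= 0:
        raise ValueError("ROI has zero total voxel TIA")
    fractions_roi = voxel_tia / total
    if absolute_scale == "roi_fit":
        roi_total = tia_from_fit(roi_fit)
    elif absolute_scale == "voxel_sum":
        roi_total = float(total)
    else:
        raise ValueError(f"unknown absolute_scale {absolute_scale!r}")

    frac = np.zeros(np.prod(series.grid.dims))
    dec = np.zeros_like(frac)
    frac[idx] = fractions_roi
    dec[idx] = fractions_roi * roi_total
    shape = tuple(series.grid.dims)
    return TiaMap(
        grid=series.grid,
        voxel_decays=dec.reshape(shape),
        fractions=frac.reshape(shape),
        roi_decays={label: roi_total},
        roi_fits={label: roi_fit},
        fallback_voxels={label: n_fallback},
    )


def merge_tia_maps(maps: list[TiaMap]) -> TiaMap:
    """Combine single-ROI TIA maps (disjoint ROIs) into one."""
    if not maps:
        raise ValueError("no TIA maps to merge")
    base = maps[0]
    out = TiaMap(
        grid=base.grid,
        voxel_decays=base.voxel_decays.copy(),
        fractions=base.fractions.copy(),
        roi_decays=dict(base.roi_decays),
        roi_fits=dict(base.roi_fits),
        fallback_voxels=dict(base.fallback_voxels),
    )
    for m in maps[1:]:
        check_same_grid(base, m)
        out.voxel_decays += m.voxel_decays
        out.fractions += m.fractions
        out.roi_decays.update(m.roi_decays)
        out.roi_fits.update(m.roi_fits)
        out.fallback_voxels.update(m.fallback_voxels)
    return out
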