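"""Pixel-wise relaxometry: R2*/T2*, T1 and T2 parameter mapping.

The central operation is the offline T2* computation used for iron-sensitive
imaging: an ordinary least-squares line through (TE, ln S) per pixel, with
R2* = -slope (converted to 1/s).  Inversion-recovery T1 and T2-prepared T2
fits stand in for scanner-side vendor maps so that the whole quantification
chain can be run on phantom data.

All fits return a :class:`ParameterMap` carrying per-pixel values, an R^2
fit-quality map and a validity mask; pixels that cannot be fit (too few
usable samples, non-physical estimates, non-convergence) are marked invalid
rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import AcquisitionSchedule, EchoSeries

__all__ = ["ParameterMap", "fit_t2star", "fit_t1_ir", "fit_t2prep", "invert_map",
           "estimate_background_sigma"]

_KINDS = ("R2star", "T2star", "T1", "T2")
_UNITS = {"R2star": "1/s", "T2star": "ms", "T1": "ms", "T2": "ms"}


@dataclass
class ParameterMap:
    """A fitted per-pixel parameter map with fit quality and validity.

    ``values`` are in 1/s for kind "R2star" and ms otherwise.  ``quality``
    is the coefficient of determination (R^2) of the per-pixel fit, clipped
    to [0, 1].  Entries outside ``valid_mask`` are NaN.
    """

    values: np.ndarray
    quality: np.ndarray
    valid_mask: np.ndarray
    kind: str
    schedule_used: AcquisitionSchedule | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if not (self.values.shape == self.quality.shape == self.valid_mask.shape):
            raise ValueError("values, quality and valid_mask must share shape")

    @property
    def units(self) -> str:
        return _UNITS[self.kind]


def _finalize(values: np.ndarray, quality: np.ndarray, valid: np.ndarray,
              kind: str, schedule: AcquisitionSchedule,
              extras: dict | None = None) -> ParameterMap:
    values = np.where(valid, values, np.nan)
    quality = np.where(valid, np.clip(quality, 0.0, 1.0), np.nan)
    return ParameterMap(values=values, quality=quality, valid_mask=valid,
                        kind=kind, schedule_used=schedule, extras=extras or {})


def estimate_background_sigma(series: EchoSeries, patch: int = 8) -> float:
    """Estimate the noise sigma from the four in-plane corner patches.

    Corner pixels of a cardiac short-axis frame contain only noise; their
    magnitude follows a Rayleigh distribution with mean sigma*sqrt(pi/2),
    so sigma = corner mean / sqrt(pi/2).  Returns 0 for noiseless data.
    """
    imgs = series.images
    ny, nx = imgs.shape[1], imgs.shape[2]
    p = min(patch, ny // 4, nx // 4)
    if p < 1:
        return 0.0
    corners = [
        imgs[:, :p, :p], imgs[:, :p, -p:], imgs[:, -p:, :p], imgs[:, -p:, -p:]
    ]
    mean = float(np.mean([c.mean() for c in corners]))
    return mean / np.sqrt(np.pi / 2.0)


def _ols_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted per-pixel OLS of y against x with indicator/soft weights.

    x has shape (nt, 1, ...); y, w have shape (nt, *grid).  Returns
    (slope, intercept, r2, n_used) arrays over the grid.  Pixels with
    sum(w) == 0 or zero x-variance get slope 0 and r2 0.
    """
    sw = w.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = (w * x).sum(axis=0) / sw
        my = (w * y).sum(axis=0) / sw
        sxx = (w * (x - mx) ** 2).sum(axis=0)
        sxy = (w * (x - mx) * (y - my)).sum(axis=0)
        syy = (w * (y - my) ** 2).sum(axis=0)
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        intercept = my - slope * mx
        ss_res = syy - slope * sxy
        r2 = np.where(syy > 0, 1.0 - ss_res / np.where(syy > 0, syy, 1.0), 0.0)
    n_used = (w > 0).sum(axis=0)
    # R^2 of a line through <3 points has no residual dof; report 0, not 1
    r2 = np.where(n_used >= 3, r2, 0.0)
    return (np.nan_to_num(slope), np.nan_to_num(intercept),
            np.nan_to_num(r2), n_used)


def fit_t2star(
    series: EchoSeries,
    mask: np.ndarray | None = None,
    min_signal: float | None = None,
    *,
    weighted: bool = False,
) -> ParameterMap:
    """Pixel-wise log-linear R2* fit of a multi-echo magnitude series.

    For every pixel, echoes with signal strictly above ``min_signal`` (and
    above zero) enter an ordinary least-squares line of ln S against TE;
    R2* = -slope * 1000 (1/s), ln S0 = intercept.  Pixels with fewer than
    two usable echoes, or a non-positive R2* estimate, are marked invalid.
    The fit is unweighted by default; ``weighted=True`` applies S^2 weights
    (first-order variance stabilization of the log transform).

    ``min_signal=None`` uses 3x the background noise sigma estimated from
    corner patches, excluding Rician-floor echoes from the line.
    """
    if series.schedule.kind != "multi_echo":
        raise ValueError("fit_t2star requires a multi_echo series")
    imgs = series.images
    grid = imgs.shape[1:]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    if mask.shape != grid:
        raise ValueError("mask shape does not match series")
    if not mask.any():
        raise ValueError("empty mask")
    if min_signal is None:
        min_signal = 3.0 * estimate_background_sigma(series)
    if not np.any(imgs[:, mask] > min_signal):
        raise ValueError("no signal above min_signal anywhere in the mask")

    te = series.schedule.times_ms[(...,) + (None,) * len(grid)]
    usable = (imgs > min_signal) & (imgs > 0)
    w = usable.astype(float)
    if weighted:
        w = w * imgs**2
    with np.errstate(divide="ignore", invalid="ignore"):
        lns = np.where(usable, np.log(np.where(usable, imgs, 1.0)), 0.0)

    slope, intercept, r2, n_used = _ols_line(te, lns, w)
    r2star = -slope * 1000.0  # 1/ms -> 1/s
    valid = mask & (n_used >= 2) & (r2star > 0)
    with np.errstate(over="ignore"):
        s0 = np.where(valid, np.exp(intercept), np.nan)
    return _finalize(r2star, r2, valid, "R2star", series.schedule,
                     extras={"s0": s0, "min_signal": float(min_signal),
                             "weighted": weighted})


def _golden_t1(y_signed: np.ndarray, times: np.ndarray, lo: np.ndarray,
               hi: np.ndarray, n_iter: int = 70):
    """Vectorized golden-section minimization of the IR SSE over T1.

    For fixed T1 the amplitude A of A*(1 - 2*exp(-TI/T1)) is linear and
    solved in closed form, so the search is one-dimensional per pixel.
    ``y_signed`` has shape (nt, n_pix); lo/hi bracket T1 per pixel (ms).
    Returns (t1, a, sse).
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0

    def sse_at(t1: np.ndarray):
        f = 1.0 - 2.0 * np.exp(-times[:, None] / t1[None, :])
        denom = (f * f).sum(axis=0)
        a = np.where(denom > 0, (f * y_signed).sum(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
        r = a[None, :] * f - y_signed
        return (r * r).sum(axis=0), a

    a_lo, b_hi = lo.copy(), hi.copy()
    for _ in range(n_iter):
        c = b_hi - invphi * (b_hi - a_lo)
        d = a_lo + invphi * (b_hi - a_lo)
        fc, _ = sse_at(c)
        fd, _ = sse_at(d)
        take_left = fc < fd
        b_hi = np.where(take_left, d, b_hi)
        a_lo = np.where(take_left, a_lo, c)
    t1 = 0.5 * (a_lo + b_hi)
    sse, a = sse_at(t1)
    return t1, a, sse


def _golden_t1_3p(y_signed: np.ndarray, times: np.ndarray, lo: np.ndarray,
                  hi: np.ndarray, n_iter: int = 70):
    """Golden-section search for the apparent-T1 model A - B*exp(-TI/T1star).

    (A, B) are solved per candidate T1star by 2x2 normal equations.
    Returns (t1star, a, b, sse).
    """
    nt = times.shape[0]

    def sse_at(t1s: np.ndarray):
        e = np.exp(-times[:, None] / t1s[None, :])  # (nt, n_pix)
        s_e = e.sum(axis=0)
        s_ee = (e * e).sum(axis=0)
        s_y = y_signed.sum(axis=0)
        s_ey = (e * y_signed).sum(axis=0)
        det = nt * s_ee - s_e * s_e
        safe = np.abs(det) > 1e-12
        det_s = np.where(safe, det, 1.0)
        # model y = A - B e  =>  normal equations in (A, B)
        a = (s_ee * s_y - s_e * s_ey) / det_s
        b = (s_e * s_y - nt * s_ey) / det_s
        a = np.where(safe, a, 0.0)
        b = np.where(safe, b, 0.0)
        r = a[None, :] - b[None, :] * e - y_signed
        return (r * r).sum(axis=0), a, b

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a_lo, b_hi = lo.copy(), hi.copy()
    for _ in range(n_iter):
        c = b_hi - invphi * (b_hi - a_lo)
        d = a_lo + invphi * (b_hi - a_lo)
        fc, _, _ = sse_at(c)
        fd, _, _ = sse_at(d)
        left = fc < fd
        b_hi = np.where(left, d, b_hi)
        a_lo = np.where(left, a_lo, c)
    t1s = 0.5 * (a_lo + b_hi)
    sse, a, b = sse_at(t1s)
    return t1s, a, b, sse


_T1_GRID = np.geomspace(20.0, 8000.0, 96)


def fit_t1_ir(
    series: EchoSeries,
    mask: np.ndarray | None = None,
    *,
    three_param: bool = False,
) -> ParameterMap:
    """Pixel-wise T1 fit of a magnitude inversion-recovery series.

    The magnitude data |S| lose the sign of the recovery curve, so polarity
    is restored by flipping the sign of the earliest TIs up to either side
    of the minimum-signal TI and keeping the candidate with the lower
    residual.  Per candidate, nonlinear least squares of the signed data
    against A*(1 - 2*exp(-TI/T1)) is solved by a dense T1 grid followed by
    a bracketed golden-section refinement (amplitude eliminated in closed
    form at every step).

    With ``three_param=True`` the apparent-T1 model A - B*exp(-TI/T1*) is
    fitted instead and the Look-Locker-style correction
    T1 = T1* (B/A - 1) is applied.

    Pixels that are all-zero, hit the search bounds, or yield non-physical
    amplitudes are marked invalid.
    """
    if series.schedule.kind != "inversion_recovery":
        raise ValueError("fit_t1_ir requires an inversion_recovery series")
    imgs = series.images
    grid = imgs.shape[1:]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    if mask.shape != grid:
        raise ValueError("mask shape does not match series")
    times = series.schedule.times_ms
    nt = times.shape[0]

    flat = imgs.reshape(nt, -1)
    sel = mask.ravel() & (flat.max(axis=0) > 0)
    idx = np.flatnonzero(sel)
    values = np.full(grid, np.nan).ravel()
    quality = np.zeros(grid).ravel()
    valid = np.zeros(grid, dtype=bool).ravel()

    if idx.size:
        y = flat[:, idx]  # (nt, n_pix)
        jmin = np.argmin(y, axis=0)
        best_sse = np.full(idx.size, np.inf)
        best_t1 = np.zeros(idx.size)
        best_a = np.zeros(idx.size)
        best_b = np.zeros(idx.size)

        for shift in (0, 1):
            k = np.clip(jmin + shift, 0, nt)
            signs = np.where(np.arange(nt)[:, None] < k[None, :], -1.0, 1.0)
            ys = signs * y
            # coarse grid to bracket the 1-D minimum per pixel
            if three_param:
                sse_grid = np.stack(
                    [_golden_t1_3p(ys, times, np.full(idx.size, g),
                                   np.full(idx.size, g), n_iter=0)[3]
                     for g in _T1_GRID]
                )
            else:
                sse_grid = np.empty((_T1_GRID.size, idx.size))
                for gi, g in enumerate(_T1_GRID):
                    f = 1.0 - 2.0 * np.exp(-times[:, None] / g)
                    denom = float((f * f).sum())
                    a = (f * ys).sum(axis=0) / denom
                    r = a[None, :] * f - ys
                    sse_grid[gi] = (r * r).sum(axis=0)
            gbest = np.argmin(sse_grid, axis=0)
            lo = _T1_GRID[np.maximum(gbest - 1, 0)]
            hi = _T1_GRID[np.minimum(gbest + 1, _T1_GRID.size - 1)]
            if three_param:
                t1s, a, b, sse = _golden_t1_3p(ys, times, lo, hi)
                with np.errstate(divide="ignore", invalid="ignore"):
                    t1 = np.where(a > 0, t1s * (b / np.where(a != 0, a, 1.0) - 1.0), np.nan)
                ok = (a > 0) & (b > a) & np.isfinite(t1)
            else:
                t1, a, sse = _golden_t1(ys, times, lo, hi)
                b = 2.0 * a
                ok = a > 0
            better = ok & (sse < best_sse)
            best_sse = np.where(better, sse, best_sse)
            best_t1 = np.where(better, t1, best_t1)
            best_a = np.where(better, a, best_a)
            best_b = np.where(better, b, best_b)

        found = np.isfinite(best_sse) & (best_t1 > 0)
        # reject solutions pinned at the search bounds
        found &= (best_t1 > _T1_GRID[0] * 1.01) & (best_t1 < _T1_GRID[-1] * 0.99)
        sst = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(sst > 0, 1.0 - best_sse / np.where(sst > 0, sst, 1.0), 0.0)
        values[idx] = np.where(found, best_t1, np.nan)
        quality[idx] = np.nan_to_num(r2)
        valid[idx] = found

    return _finalize(values.reshape(grid), quality.reshape(grid),
                     valid.reshape(grid), "T1", series.schedule,
                     extras={"three_param": three_param})


def fit_t2prep(series: EchoSeries, mask: np.ndarray | None = None) -> ParameterMap:
    """Pixel-wise T2 fit of a T2-prepared series by a log-linear fit.

    ln S is regressed against the preparation time tau over the samples with
    strictly positive signal; T2 = -1/slope in ms.  Pixels with fewer than
    two positive samples or a non-negative slope are invalid.
    """
    if series.schedule.kind != "t2_prep":
        raise ValueError("fit_t2prep requires a t2_prep series")
    imgs = series.images
    grid = imgs.shape[1:]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    if mask.shape != grid:
        raise ValueError("mask shape does not match series")
    tau = series.schedule.times_ms[(...,) + (None,) * len(grid)]
    usable = imgs > 0
    w = usable.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lns = np.where(usable, np.log(np.where(usable, imgs, 1.0)), 0.0)
    slope, _, r2, n_used = _ols_line(tau, lns, w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(slope < 0, -1.0 / np.where(slope < 0, slope, 1.0), np.nan)
    valid = mask & (n_used >= 2) & (slope < 0)
    return _finalize(np.nan_to_num(t2, nan=0.0), r2, valid, "T2", series.schedule)


def invert_map(pmap: ParameterMap) -> ParameterMap:
    """Convert between R2* (1/s) and T2* (ms): value' = 1000 / value.

    Invalid pixels propagate; valid pixels with non-positive values become
    invalid (the reciprocal would be non-physical).
    """
    if pmap.kind not in ("R2star", "T2star"):
        raise ValueError("invert_map applies to R2star/T2star maps only")
    new_kind = "T2star" if pmap.kind == "R2star" else "R2star"
    valid = pmap.valid_mask & (np.nan_to_num(pmap.values) > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(valid, 1000.0 / pmap.values, np.nan)
    quality = np.where(valid, pmap.quality, np.nan)
    return ParameterMap(values=values, quality=quality, valid_mask=valid,
                        kind=new_kind, schedule_used=pmap.schedule_used,
                        extras=dict(pmap.extras))
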