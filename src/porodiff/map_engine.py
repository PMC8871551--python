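"""Voxelwise model fitting: anomalous-exponent (Mα) and mean-diffusivity maps.

The anomalous exponent α of each voxel is obtained by fitting the
stretched-exponential ratio model ``R(Δ) = exp(-K_α q² Δ^α)`` to the
g>0 / g=0 signal ratio across the diffusion-time series, separately for the
x, y and z gradient directions; Mα is the voxelwise mean of the three
directional α maps.  The mean diffusivity MD is one third of the trace of a
diffusion tensor fitted log-linearly to a b0 + six-direction acquisition.

The α fitter is a Levenberg-Marquardt minimiser vectorised across voxels,
with bounds enforced by the smooth reparametrisation
``α = 0.1 + 1.4·logistic(u)``, ``K = exp(v)`` and a two-start strategy
(log-log linearisation and a Brownian α=1 start); the lower-cost solution is
kept.
"""

from __future__ import annotations

import numpy as np

from .containers import Acquisition, DWISeries, ParameterMap, ROIDistribution
from .signal_models import PGSTEProtocol, SubdiffusionParams, q_value

ALPHA_LO, ALPHA_SPAN = 0.1, 1.4      # fitter bounds alpha in [0.1, 1.5]
MAX_ITER = 200
COST_TOL = 1e-10
NO_DECAY_LEVEL = 0.99                # ratios all above this -> unfittable voxel


def _sigmoid(u):
    return 1.0 / (1.0 + np.exp(-u))


def _to_internal(alpha, K):
    a = np.clip((np.asarray(alpha) - ALPHA_LO) / ALPHA_SPAN, 1e-6, 1 - 1e-6)
    return np.log(a / (1 - a)), np.log(np.asarray(K))


def _from_internal(u, v):
    return ALPHA_LO + ALPHA_SPAN * _sigmoid(u), np.exp(v)


def _model_and_jac(u, v, q2, logD, D_pow):
    """Model ratios and Jacobian wrt (u, v) for all voxels at once.

    Parameters are (N,) vectors; D_pow is a scratch (N, M) array of Δ^α.
    """
    s = _sigmoid(u)
    alpha = ALPHA_LO + ALPHA_SPAN * s
    K = np.exp(v)
    np.exp(alpha[:, None] * logD[None, :], out=D_pow)
    expo = K[:, None] * q2 * D_pow
    m = np.exp(-expo)
    dm_dv = -expo * m                                   # dK/dv = K
    dm_du = dm_dv * logD[None, :] * (ALPHA_SPAN * s * (1 - s))[:, None]
    return m, dm_du, dm_dv


def fit_alpha_stack(ratios: np.ndarray, Deltas: np.ndarray, q: float):
    """Fit (α, K_α) per voxel to stacks of attenuation ratios.

    Parameters
    ----------
    ratios : (N, M) array
        g>0 / g=0 signal ratios of N voxels at M diffusion times.
    Deltas : (M,) array
        Diffusion times, s, strictly increasing.
    q : float
        Wavevector magnitude, m^-1 (> 0).

    Returns
    -------
    alpha, K : (N,) arrays
    mask : (N,) bool — False where the voxel could not be fitted
    diagnostics : dict with per-voxel ``residual_norm``, ``n_iter``,
        ``reason`` (int code: 0 ok, 1 insufficient attenuation,
        2 no convergence)
    """
    if q <= 0:
        raise ValueError("q must be > 0 for the anomalous fit")
    ratios = np.atleast_2d(np.asarray(ratios, dtype=float))
    Deltas = np.asarray(Deltas, dtype=float)
    N, M = ratios.shape
    if M < 3 or M != Deltas.size:
        raise ValueError("need >= 3 ratio points matching the Delta grid")

    q2 = q * q
    logD = np.log(Deltas)
    reason = np.zeros(N, dtype=int)

    # voxels with no measurable decay cannot constrain (alpha, K)
    no_decay = np.all(ratios >= NO_DECAY_LEVEL, axis=1)
    bad_vals = np.any(~np.isfinite(ratios), axis=1) | np.all(ratios <= 0, axis=1)
    reason[no_decay] = 1
    reason[bad_vals] = 1
    fit_idx = np.flatnonzero(~(no_decay | bad_vals))

    alpha_out = np.full(N, np.nan)
    K_out = np.full(N, np.nan)
    rnorm = np.full(N, np.nan)
    n_iter = np.zeros(N, dtype=int)

    if fit_idx.size:
        y = np.clip(ratios[fit_idx], 1e-12, 1.05)
        a_f, K_f, r_f, it_f, conv = _fit_alpha_core(y, q2, logD)
        alpha_out[fit_idx] = a_f
        K_out[fit_idx] = K_f
        rnorm[fit_idx] = r_f
        n_iter[fit_idx] = it_f
        reason[fit_idx[~conv]] = 2

    mask = reason == 0
    return alpha_out, K_out, mask, {
        "residual_norm": rnorm,
        "n_iter": n_iter,
        "reason": reason,
    }


def _loglog_init(y, q2, logD):
    """Initial (α, K) from ln(-ln R) = ln(K q²) + α ln Δ on decaying points."""
    N, M = y.shape
    neg_log = -np.log(np.clip(y, 1e-12, None))
    use = y < NO_DECAY_LEVEL
    # weighted linear regression per voxel on the usable points
    w = use.astype(float)
    z = np.where(use, np.log(np.clip(neg_log, 1e-300, None)), 0.0)
    sw = w.sum(axis=1)
    sx = (w * logD).sum(axis=1)
    sz = (w * z).sum(axis=1)
    sxx = (w * logD**2).sum(axis=1)
    sxz = (w * logD * z).sum(axis=1)
    det = sw * sxx - sx * sx
    ok = (sw >= 2) & (det > 1e-12)
    alpha = np.where(ok, (sw * sxz - sx * sz) / np.where(det > 0, det, 1.0), 1.0)
    logKq2 = np.where(ok, (sxx * sz - sx * sxz) / np.where(det > 0, det, 1.0),
                      np.log(np.clip(neg_log.mean(axis=1), 1e-12, None)))
    K = np.exp(logKq2) / q2
    return np.clip(alpha, 0.11, 1.49), np.clip(K, 1e-300, None)


def _brownian_init(y, q2, logD):
    """α = 1 start; K from the slope of -ln R against q²Δ through the origin."""
    D = np.exp(logD)
    neg_log = -np.log(np.clip(y, 1e-12, None))
    x = q2 * D
    K = np.clip((neg_log * x).sum(axis=1) / (x * x).sum(), 1e-300, None)
    return np.full(y.shape[0], 1.0), K


def _lm_run(y, q2, logD, alpha0, K0):
    """Vectorised Levenberg-Marquardt from one start; returns params + cost."""
    N, M = y.shape
    u, v = _to_internal(alpha0, K0)
    D_pow = np.empty((N, M))
    m, Ju, Jv = _model_and_jac(u, v, q2, logD, D_pow)
    r = m - y
    cost = 0.5 * (r * r).sum(axis=1)
    lam = np.full(N, 1e-3)
    active = np.ones(N, dtype=bool)
    iters = np.zeros(N, dtype=int)

    for _ in range(MAX_ITER):
        if not active.any():
            break
        # normal equations (2x2 per voxel) with LM damping
        A11 = (Ju * Ju).sum(axis=1) * (1 + lam)
        A22 = (Jv * Jv).sum(axis=1) * (1 + lam)
        A12 = (Ju * Jv).sum(axis=1)
        g1 = (Ju * r).sum(axis=1)
        g2 = (Jv * r).sum(axis=1)
        det = A11 * A22 - A12 * A12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        du = -(A22 * g1 - A12 * g2) / det
        dv = -(A11 * g2 - A12 * g1) / det

        u_new = np.where(active, u + du, u)
        v_new = np.where(active, np.clip(v + dv, -800, 700), v)
        m_new, Ju_new, Jv_new = _model_and_jac(u_new, v_new, q2, logD, D_pow)
        r_new = m_new - y
        cost_new = 0.5 * (r_new * r_new).sum(axis=1)

        improved = active & (cost_new < cost)
        stalled = active & ~improved
        converged = improved & (cost - cost_new < COST_TOL)

        u = np.where(improved, u_new, u)
        v = np.where(improved, v_new, v)
        m = np.where(improved[:, None], m_new, m)
        Ju = np.where(improved[:, None], Ju_new, Ju)
        Jv = np.where(improved[:, None], Jv_new, Jv)
        r = np.where(improved[:, None], r_new, r)
        cost = np.where(improved, cost_new, cost)
        lam = np.where(improved, lam * 0.3, np.where(stalled, lam * 4.0, lam))
        iters += active
        active = active & ~converged & (lam < 1e12)

    alpha, K = _from_internal(u, v)
    return alpha, K, cost, iters, ~active


def _fit_alpha_core(y, q2, logD):
    a1, K1 = _loglog_init(y, q2, logD)
    a2, K2 = _brownian_init(y, q2, logD)
    res1 = _lm_run(y, q2, logD, a1, K1)
    res2 = _lm_run(y, q2, logD, a2, K2)
    take2 = res2[2] < res1[2]
    alpha = np.where(take2, res2[0], res1[0])
    K = np.where(take2, res2[1], res1[1])
    cost = np.where(take2, res2[2], res1[2])
    iters = np.where(take2, res2[3], res1[3])
    conv = np.where(take2, res2[4], res1[4])
    return alpha, K, np.sqrt(2 * cost), iters, conv


def fit_voxel_alpha(ratios, Deltas, q: float):
    """Fit one voxel's ratio decay; returns (SubdiffusionParams | None, diag)."""
    alpha, K, mask, diag = fit_alpha_stack(
        np.asarray(ratios, float)[None, :], Deltas, q
    )
    d = {k: v[0] for k, v in diag.items()}
    reasons = {0: "ok", 1: "insufficient attenuation", 2: "no convergence"}
    d["reason"] = reasons[int(d["reason"])]
    if not mask[0]:
        return None, d
    return SubdiffusionParams(alpha=float(alpha[0]), K_alpha=float(K[0])), d


# ---------------------------------------------------------------------------
# series-level map construction
# ---------------------------------------------------------------------------

def estimate_background_noise(image: np.ndarray, patch: int = 8) -> float:
    """Mean magnitude over the four corner patches (pure-noise background)."""
    p = patch
    corners = np.concatenate([
        image[:p, :p].ravel(), image[:p, -p:].ravel(),
        image[-p:, :p].ravel(), image[-p:, -p:].ravel(),
    ])
    return float(corners.mean())


def _ratio_stack(series: DWISeries, direction, noise_guard: float = 5.0):
    """Ratio images across the Δ grid for one direction, plus validity mask."""
    deltas = sorted({a.Delta for a in series.acquisitions if a.g > 0})
    ny, nx = series.data.shape[1:]
    ratios = np.empty((len(deltas), ny, nx))
    valid = np.ones((ny, nx), dtype=bool)
    b0_ref = None
    for i, D in enumerate(deltas):
        idx_g = series.select(g=None, Delta=D, direction=direction)
        idx_g = [k for k in idx_g if series.acquisitions[k].g > 0]
        if not idx_g:
            raise ValueError(f"missing direction {direction} at Delta={D}")
        idx_0 = [k for k in series.select(Delta=D) if series.acquisitions[k].g == 0]
        s0 = series.data[idx_0[0]]
        sg = series.data[idx_g[0]]
        if b0_ref is None:
            b0_ref = s0
        noise = estimate_background_noise(s0)
        ok = s0 > noise_guard * noise if noise > 0 else s0 > 0
        valid &= ok
        ratios[i] = np.divide(sg, s0, out=np.zeros_like(sg), where=s0 > 0)
    return np.array(deltas), ratios, valid


def alpha_maps_by_direction(series: DWISeries, protocol: PGSTEProtocol) -> dict:
    """One α ParameterMap per gradient direction of the series."""
    q = q_value(protocol)
    maps = {}
    for direction in protocol.directions:
        deltas, ratios, valid = _ratio_stack(series, direction)
        ny, nx = valid.shape
        flat_idx = np.flatnonzero(valid.ravel())
        stack = ratios.reshape(len(deltas), -1).T[flat_idx]
        alpha, K, fmask, diag = fit_alpha_stack(stack, deltas, q)

        values = np.full(ny * nx, np.nan)
        mask = np.zeros(ny * nx, dtype=bool)
        values[flat_idx] = alpha
        mask[flat_idx] = fmask
        rn = np.full(ny * nx, np.nan)
        rn[flat_idx] = diag["residual_norm"]
        ni = np.zeros(ny * nx, dtype=int)
        ni[flat_idx] = diag["n_iter"]
        kmap = np.full(ny * nx, np.nan)
        kmap[flat_idx] = K

        key = "xyz"[int(np.argmax(np.abs(direction)))]
        maps[key] = ParameterMap(
            values=values.reshape(ny, nx),
            mask=mask.reshape(ny, nx),
            diagnostics={
                "residual_norm": rn.reshape(ny, nx),
                "n_iter": ni.reshape(ny, nx),
                "K_alpha": kmap.reshape(ny, nx),
            },
            units="dimensionless",
        )
    return maps


def mean_alpha_map(maps_xyz: dict) -> ParameterMap:
    """Mα map: voxelwise mean of the directional α maps where all are valid."""
    maps = list(maps_xyz.values())
    if len(maps) != 3:
        raise ValueError("need exactly three directional maps")
    shape = maps[0].values.shape
    for m in maps:
        if m.values.shape != shape:
            raise ValueError("directional maps have mismatched grids")
    mask = maps[0].mask & maps[1].mask & maps[2].mask
    stack = np.stack([np.where(m.mask, m.values, 0.0) for m in maps])
    values = np.where(mask, stack.sum(axis=0) / 3.0, np.nan)
    return ParameterMap(values=values, mask=mask,
                        diagnostics={}, units="dimensionless")


def fit_voxel_adc(signals, bvals):
    """ADC from a weighted log-linear fit of S against b.

    Weights are the squared signals, the standard correction for
    log-transformed exponential noise.  Returns (D, ok_flag).
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(bvals, dtype=float)
    if s.size != b.size or s.size < 2 or np.unique(b).size < 2:
        raise ValueError("need >= 2 distinct b-values")
    if np.any(s <= 0):
        return np.nan, False
    w = s * s
    ln_s = np.log(s)
    sw = w.sum()
    sb = (w * b).sum()
    sl = (w * ln_s).sum()
    sbb = (w * b * b).sum()
    sbl = (w * b * ln_s).sum()
    det = sw * sbb - sb * sb
    slope = (sw * sbl - sb * sl) / det
    D = -slope
    if D <= 0:
        return 0.0, False
    return float(D), True


def _tensor_design(bvals, directions):
    """Design matrix for ln S = ln S0 - b (n ⊗ n) : D, one row per acquisition."""
    rows = []
    for b, n in zip(bvals, directions):
        nx, ny, nz = n
        rows.append([
            1.0,
            -b * nx * nx, -b * ny * ny, -b * nz * nz,
            -2 * b * nx * ny, -2 * b * nx * nz, -2 * b * ny * nz,
        ])
    return np.asarray(rows)


def fit_tensor_md(signals, bvals, directions):
    """Mean diffusivity (trace/3) from a log-linear diffusion tensor fit.

    ``signals`` may be (n_acq,) for a single voxel or (n_acq, N) for a stack.
    Returns (MD, tensor_elements, ok) with the tensor in the order
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
    """
    A = _tensor_design(bvals, directions)
    if np.linalg.matrix_rank(A) < 7:
        raise ValueError("gradient direction set is rank-deficient; "
                         "need six non-coplanar directions plus b0")
    s = np.asarray(signals, dtype=float)
    single = s.ndim == 1
    s2 = s[:, None] if single else s
    ok = np.all(s2 > 0, axis=0)
    ln_s = np.log(np.clip(s2, 1e-300, None))
    coef, *_ = np.linalg.lstsq(A, ln_s, rcond=None)
    md = coef[1:4].sum(axis=0) / 3.0
    tensor = coef[1:7]
    ok = ok & (md > 0)
    if single:
        return float(md[0]), tensor[:, 0], bool(ok[0])
    return md, tensor, ok


def md_map(series: DWISeries, protocol: PGSTEProtocol) -> ParameterMap:
    """MD ParameterMap from a b0 + six-direction acquisition series."""
    acqs = series.acquisitions
    bvals, dirs, idx = [], [], []
    for k, a in enumerate(acqs):
        if a.g > 0:
            gd = protocol.gamma * a.g * protocol.delta
            bvals.append(gd * gd * (a.Delta - protocol.delta / 3.0))
            dirs.append(a.direction)
        else:
            bvals.append(0.0)
            dirs.append((1.0, 0.0, 0.0))
        idx.append(k)
    ny, nx = series.data.shape[1:]
    s0_idx = [k for k, a in enumerate(acqs) if a.g == 0][0]
    noise = estimate_background_noise(series.data[s0_idx])
    guard = series.data[s0_idx] > 5.0 * noise if noise > 0 else series.data[s0_idx] > 0

    signals = series.data[idx].reshape(len(idx), -1)
    md, _, ok = fit_tensor_md(signals, bvals, dirs)
    mask = ok.reshape(ny, nx) & guard
    return ParameterMap(values=md.reshape(ny, nx), mask=mask,
                        diagnostics={}, units="m^2/s")


def roi_distribution(pmap: ParameterMap, center, radius: float,
                     voxel_size: float = 1.0) -> ROIDistribution:
    """Distribution of unmasked map values inside a circular ROI.

    ``center`` is (row, col) in world units (same units as ``radius``,
    which default to voxel units when ``voxel_size`` is 1).  Membership is
    decided by the voxel-center position.
    """
    ny, nx = pmap.values.shape
    rows = (np.arange(ny) + 0.5) * voxel_size
    cols = (np.arange(nx) + 0.5) * voxel_size
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    sel = inside & pmap.mask
    vals = pmap.values[sel]
    if vals.size == 0:
        raise ValueError("ROI contains no valid voxels")
    return ROIDistribution(values=vals)


def discrimination_stat(a: ROIDistribution, b: ROIDistribution) -> float:
    """Cliff's delta P(x > y) - P(x < y) between two ROI distributions.

    Computed exactly in O(n log n) by rank counting over all cross pairs.
    +1 means every value of ``a`` exceeds every value of ``b``.
    """
    x = np.sort(a.values)
    y = np.sort(b.values)
    n_gt = np.searchsorted(y, x, side="left").sum()       # pairs with x > y
    n_le = np.searchsorted(y, x, side="right").sum()
    n_eq = n_le - n_gt
    n_lt = x.size * y.size - n_le
    return float((n_gt - n_lt) / (x.size * y.size))
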