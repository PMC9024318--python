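"""Voxel-wise regularized inversion of the two-compartment DW-ASL model.

Each voxel's (k_W, CBF, ATT) is estimated by minimising

    cost(p) = sum_i gamma_i^2 (I_i - f_i(p))^2 + mu * ||p / scales||^2

where f is the forward model, gamma_i weights each encode by its noise
precision (gamma_i = sqrt(NEX_i) by default, since averaging NEX excitations
shrinks the noise SD by sqrt(NEX)), and the ridge penalty acts on
nondimensionalized parameters so a single mu is meaningful across the three
maps. The solver is a projected Levenberg-Marquardt iteration (damped
Gauss-Newton, which reduces to scaled gradient descent as the damping grows):
steps are accepted only under an Armijo decrease condition, so descent is
monotone; bounds are enforced by projection; and every voxel carries its own
damping and convergence state, so fitting a volume is bit-identical to
fitting each voxel in isolation. Initialization follows the usual practice -
k_W starts at zero, CBF from the single-compartment quantification of the
PLD = 1.5 s encode, ATT from the signal-weighted mean PLD of the crushed
multi-delay encodes - and, because the joint landscape has local minima for
long-transit voxels, a deterministic coarse (k_W, ATT) grid presearch with
closed-form CBF provides a second start; the lower-cost solution wins.

The regularization weight mu can be fixed, or selected by the L-curve method:
fits are repeated over a grid of mu on a voxel subsample, and the corner of
maximal curvature of the (log residual norm, log solution norm) curve is
chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .model import (
    AcquisitionSpec,
    VoxelParams,
    _signal_and_jac_batch,
    default_protocol,
    forward_series_batch,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "PermeabilityFitter",
    "cost",
    "gradient",
    "init_cbf",
    "init_att",
    "fit_voxel",
    "fit_volume",
    "select_mu_lcurve",
]

_DEFAULT_BOUNDS = ((0.0, 500.0), (0.0, 200.0), (0.3, 3.0))
_DEFAULT_SCALES = (100.0, 50.0, 1.5)
_DEFAULT_MU_GRID = tuple(float(m) for m in np.logspace(-4, 2, 13))


@dataclass(frozen=True)
class FitConfig:
    """Solver settings.

    mu : float or "auto"
        Ridge weight on the nondimensionalized parameters; "auto" selects it
        with the L-curve method over ``mu_grid``.
    max_iter, rel_tol
        Iteration cap (100) and relative-change stopping tolerance (0.01):
        a voxel stops when every nondimensionalized parameter changes by less
        than rel_tol relative to max(|value|, 0.01) in one accepted step.
    bounds, param_scales
        Box constraints and nominal scales for (k_W [1/min],
        CBF [mL/100 g/min], ATT [s]).
    gamma
        "sqrt_nex" (default, inverse-noise-SD weighting) or "nex".
    """

    mu: float | str = 0.0
    mu_grid: tuple[float, ...] = _DEFAULT_MU_GRID
    max_iter: int = 100
    rel_tol: float = 0.01
    armijo_c: float = 1e-4
    backtrack_factor: float = 0.5
    max_backtracks: int = 40
    bounds: tuple[tuple[float, float], ...] = _DEFAULT_BOUNDS
    param_scales: tuple[float, float, float] = _DEFAULT_SCALES
    gamma: str = "sqrt_nex"
    init_encode: int | None = None
    init_pld: float = 1.5
    lcurve_subsample: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.rel_tol > 0:
            raise ValueError("rel_tol must be positive")
        if isinstance(self.mu, str):
            if self.mu != "auto":
                raise ValueError(f"mu must be a nonnegative number or 'auto', got {self.mu!r}")
        elif self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if self.gamma not in ("sqrt_nex", "nex"):
            raise ValueError("gamma must be 'sqrt_nex' or 'nex'")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"bounds must satisfy lo < hi, got ({lo}, {hi})")

    def gamma2(self, spec: AcquisitionSpec) -> np.ndarray:
        """Squared residual weights per encode."""
        nex = spec.nex
        return nex if self.gamma == "sqrt_nex" else nex**2


@dataclass
class FitResult:
    """Fitted parameter maps plus per-voxel diagnostics (shared grid)."""

    kw_map: np.ndarray
    cbf_map: np.ndarray
    att_map: np.ndarray
    iterations: np.ndarray
    final_cost: np.ndarray
    converged: np.ndarray
    mu_used: float


# ---------------------------------------------------------------------------
# cost / gradient on flattened (n_voxels, n_encodes) data


def _scaled_bounds(cfg: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(cfg.bounds, dtype=float)
    s = np.asarray(cfg.param_scales, dtype=float)
    return b[:, 0] / s, b[:, 1] / s


def _cost_batch(x, data, gam2, r1b, m0, spec, mu, scales):
    kw, cbf, att = (x[:, j] * scales[j] for j in range(3))
    f = forward_series_batch(kw, cbf, att, r1b, m0, spec)
    r = f - data
    return np.einsum("ij,ij,j->i", r, r, gam2) + mu * np.einsum("ij,ij->i", x, x)


def _cost_grad_batch(x, data, gam2, r1b, m0, spec, mu, scales):
    kw, cbf, att = (x[:, j] * scales[j] for j in range(3))
    f, dkw, dcbf, datt = _signal_and_jac_batch(kw, cbf, att, r1b, m0, spec)
    r = f - data
    c = np.einsum("ij,ij,j->i", r, r, gam2) + mu * np.einsum("ij,ij->i", x, x)
    w = 2.0 * r * gam2[None, :]
    g = np.stack(
        [(w * dkw).sum(axis=1), (w * dcbf).sum(axis=1), (w * datt).sum(axis=1)],
        axis=1,
    )
    g *= scales[None, :]
    g += 2.0 * mu * x
    return c, g


def cost(p: VoxelParams, data, spec: AcquisitionSpec, cfg: FitConfig) -> float:
    """Regularized cost of one voxel's parameters against its data vector."""
    data = np.asarray(data, dtype=float)
    if data.shape != (len(spec),):
        raise ValueError(f"data has {data.size} values but the protocol has {len(spec)} encodes")
    scales = np.asarray(cfg.param_scales, dtype=float)
    mu = 0.0 if cfg.mu == "auto" else float(cfg.mu)
    x = np.array([[p.kw, p.cbf, p.att]]) / scales
    return float(
        _cost_batch(x, data[None, :], cfg.gamma2(spec), np.array([p.r1b]),
                    np.array([p.m0]), spec, mu, scales)[0]
    )


def gradient(p: VoxelParams, data, spec: AcquisitionSpec, cfg: FitConfig) -> np.ndarray:
    """Analytic (d cost / d kw, d cost / d cbf, d cost / d att) in native units."""
    data = np.asarray(data, dtype=float)
    if data.shape != (len(spec),):
        raise ValueError(f"data has {data.size} values but the protocol has {len(spec)} encodes")
    scales = np.asarray(cfg.param_scales, dtype=float)
    mu = 0.0 if cfg.mu == "auto" else float(cfg.mu)
    x = np.array([[p.kw, p.cbf, p.att]]) / scales
    _, g = _cost_grad_batch(x, data[None, :], cfg.gamma2(spec), np.array([p.r1b]),
                            np.array([p.m0]), spec, mu, scales)
    return g[0] / scales  # back to native parameter units


# ---------------------------------------------------------------------------
# initialization


def _init_encode_index(spec: AcquisitionSpec, cfg: FitConfig) -> int:
    if cfg.init_encode is not None:
        if not 0 <= cfg.init_encode < len(spec):
            raise ValueError(f"init_encode {cfg.init_encode} out of range for {len(spec)} encodes")
        return cfg.init_encode
    return int(np.argmin(np.abs(spec.plds - cfg.init_pld)))


def _init_cbf_batch(data, m0, spec, cfg):
    j = _init_encode_index(spec, cfg)
    e = spec.encodes[j]
    c = spec.constants
    dm = data[:, j]
    t1a = 1.0 / c.r1a
    denom = 2.0 * c.epsilon * t1a * np.asarray(m0, float) * (1.0 - np.exp(-c.delta * c.r1a))
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf0 = 6000.0 * c.lam * dm * np.exp(e.pld * c.r1a) / denom
    cbf0 = np.where((dm <= 0) | (np.asarray(m0) <= 0), 0.0, cbf0)
    lo, hi = cfg.bounds[1]
    return np.clip(cbf0, lo, hi)


def _init_att_batch(data, spec, cfg):
    crushed = spec.crushed
    plds = spec.plds[crushed]
    uniq, inv = np.unique(plds, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("ATT initialization needs crushed encodes at >= 2 distinct PLDs")
    dm = data[:, crushed]
    # average duplicate-PLD encodes before weighting
    sums = np.zeros((dm.shape[0], uniq.size))
    counts = np.bincount(inv, minlength=uniq.size).astype(float)
    np.add.at(sums, (slice(None), inv), dm)
    dm_mean = sums / counts[None, :]
    w = np.maximum(dm_mean, 0.0)
    sw = w.sum(axis=1)
    mid = 0.5 * (uniq[0] + uniq[-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        att0 = np.where(sw > 0, (w * uniq[None, :]).sum(axis=1) / np.where(sw > 0, sw, 1.0), mid)
    att0 = np.clip(att0, uniq[0], uniq[-1])
    lo, hi = cfg.bounds[2]
    return np.clip(att0, lo, hi)


def init_cbf(data, M0: float, spec: AcquisitionSpec, cfg: FitConfig | None = None) -> float:
    """Single-compartment CBF estimate from the designated (PLD = 1.5 s) encode.

    Uses the consensus single-delay pCASL quantification
    ``CBF = 6000 lam dM exp(PLD R1a) / (2 eps T1a M0 (1 - exp(-delta R1a)))``
    clamped to the fit bounds; returns 0 when dM <= 0 or M0 = 0.
    """
    cfg = cfg or FitConfig()
    data = np.asarray(data, dtype=float)[None, :]
    return float(_init_cbf_batch(data, np.array([M0]), spec, cfg)[0])


def init_att(data, spec: AcquisitionSpec, cfg: FitConfig | None = None) -> float:
    """Signal-weighted-PLD ATT estimate over the crushed multi-delay encodes."""
    cfg = cfg or FitConfig()
    data = np.asarray(data, dtype=float)[None, :]
    return float(_init_att_batch(data, spec, cfg)[0])


# ---------------------------------------------------------------------------
# solver


_LAM_INIT = 1e-3
_LAM_UP = 10.0
_LAM_DOWN = 0.3
_PRESEARCH_KW = (0.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0)
_PRESEARCH_ATT = (0.4, 0.7, 1.0, 1.3, 1.6, 1.9, 2.2, 2.5, 2.8)


def _cost_grad_hess_batch(x, data, gam2, r1b, m0, spec, mu, scales):
    """Cost, gradient and Gauss-Newton Hessian in nondimensional coordinates."""
    kw, cbf, att = (x[:, j] * scales[j] for j in range(3))
    f, dkw, dcbf, datt = _signal_and_jac_batch(kw, cbf, att, r1b, m0, spec)
    r = f - data
    c = np.einsum("ij,ij,j->i", r, r, gam2) + mu * np.einsum("ij,ij->i", x, x)
    J = np.stack([dkw, dcbf, datt], axis=2) * scales[None, None, :]
    g = 2.0 * np.einsum("ij,ijk,j->ik", r, J, gam2) + 2.0 * mu * x
    H = 2.0 * np.einsum("ijk,ijl,j->ikl", J, J, gam2) + 2.0 * mu * np.eye(3)[None]
    return c, g, H


def _lm_batch(x0, data, gam2, r1b, m0, spec, cfg, mu, scales, lo, hi):
    """Projected Levenberg-Marquardt from ``x0``; all solver state per-voxel.

    A trial step solves (H + lam diag(H)) d = -g and is clipped to the box;
    it is accepted under the Armijo condition on the projected step, else the
    voxel's damping is inflated and the step retried. Acceptance guarantees
    monotone descent. A voxel stops when the relative parameter change of an
    accepted step falls below rel_tol, or when no acceptable step exists.
    """
    n = x0.shape[0]
    x = np.clip(x0, lo, hi)
    cst, g, H = _cost_grad_hess_batch(x, data, gam2, r1b, m0, spec, mu, scales)
    lam = np.full(n, _LAM_INIT)
    iters = np.zeros(n, dtype=np.int32)
    conv = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    eye = np.arange(3)

    for _ in range(cfg.max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        sub = idx
        ntries = 0
        x_new = x.copy()
        c_new = cst.copy()
        accepted = np.zeros(n, dtype=bool)
        while sub.size:
            Hd = H[sub].copy()
            diag = np.maximum(Hd[:, eye, eye], 1e-300)
            Hd[:, eye, eye] = diag * (1.0 + lam[sub, None])
            try:
                d = -np.linalg.solve(Hd, g[sub][..., None])[..., 0]
            except np.linalg.LinAlgError:  # pragma: no cover - singular fallback
                d = -g[sub] / np.maximum(diag, 1e-12)
            xt = np.clip(x[sub] + d, lo, hi)
            dd = xt - x[sub]
            gd = np.einsum("ij,ij->i", g[sub], dd)
            ct = _cost_batch(xt, data[sub], gam2, r1b[sub], m0[sub], spec, mu, scales)
            ok = (gd <= 0) & (ct <= cst[sub] + cfg.armijo_c * gd)
            acc = sub[ok]
            x_new[acc] = xt[ok]
            c_new[acc] = ct[ok]
            accepted[acc] = True
            lam[acc] = np.maximum(lam[acc] * _LAM_DOWN, 1e-12)
            rej = sub[~ok]
            lam[rej] *= _LAM_UP
            ntries += 1
            if ntries > cfg.max_backtracks:
                # no descent step found: numerically stationary (KKT) point
                conv[rej] = True
                active[rej] = False
                rej = rej[:0]
            sub = rej
        acc = np.flatnonzero(accepted)
        if acc.size == 0:
            continue
        s = x_new[acc] - x[acc]
        rel = (np.abs(s) / np.maximum(np.abs(x_new[acc]), 0.01)).max(axis=1)
        x[acc] = x_new[acc]
        cst[acc] = c_new[acc]
        c2, g2, H2 = _cost_grad_hess_batch(x[acc], data[acc], gam2, r1b[acc],
                                           m0[acc], spec, mu, scales)
        g[acc] = g2
        H[acc] = H2
        iters[acc] += 1
        done = rel < cfg.rel_tol
        conv[acc[done]] = True
        active[acc[done]] = False

    return x, iters, cst, conv


def _presearch(data, gam2, r1b, m0, spec, cfg, mu, scales, lo, hi):
    """Best (k_W, ATT) node of a coarse grid, with closed-form ridge CBF.

    The model is linear in CBF, so for each grid node the optimal CBF is
    ``sum(gam2 I f_u) / (sum(gam2 f_u^2) + mu / s_cbf^2)`` with f_u the
    unit-CBF signal; the least-cost node seeds the second solver start.
    """
    n = data.shape[0]
    s_cbf2 = scales[1] ** 2
    cbf_lo, cbf_hi = cfg.bounds[1]
    best_cost = np.full(n, np.inf)
    best = np.zeros((n, 3))
    for kw in _PRESEARCH_KW:
        for att in _PRESEARCH_ATT:
            f_u = forward_series_batch(
                np.full(n, kw), np.ones(n), np.full(n, att), r1b, m0, spec)
            num = np.einsum("ij,ij,j->i", data, f_u, gam2)
            den = np.einsum("ij,ij,j->i", f_u, f_u, gam2) + mu / s_cbf2
            with np.errstate(divide="ignore", invalid="ignore"):
                cbf = np.where(den > 0, num / den, 0.0)
            cbf = np.clip(cbf, cbf_lo, cbf_hi)
            r = cbf[:, None] * f_u - data
            c = (np.einsum("ij,ij,j->i", r, r, gam2)
                 + mu * ((kw / scales[0]) ** 2 + (cbf / scales[1]) ** 2
                         + (att / scales[2]) ** 2))
            better = c < best_cost
            best_cost[better] = c[better]
            best[better, 0] = kw
            best[better, 1] = cbf[better]
            best[better, 2] = att
    return np.clip(best / scales[None, :], lo, hi)


def _fit_batch(data, m0, r1b, spec, cfg, mu):
    """Fit every row of ``data``: LM from the standard initialization and
    from the grid presearch, keeping the lower-cost solution per voxel
    (ties go to the standard initialization)."""
    n = data.shape[0]
    scales = np.asarray(cfg.param_scales, dtype=float)
    gam2 = cfg.gamma2(spec)
    lo, hi = _scaled_bounds(cfg)

    x0 = np.zeros((n, 3))
    x0[:, 0] = cfg.bounds[0][0] / scales[0]  # k_W starts at its lower bound (0)
    x0[:, 1] = _init_cbf_batch(data, m0, spec, cfg) / scales[1]
    x0[:, 2] = _init_att_batch(data, spec, cfg) / scales[2]
    xa, ita, ca, cva = _lm_batch(x0, data, gam2, r1b, m0, spec, cfg, mu, scales, lo, hi)

    xg = _presearch(data, gam2, r1b, m0, spec, cfg, mu, scales, lo, hi)
    xb, itb, cb, cvb = _lm_batch(xg, data, gam2, r1b, m0, spec, cfg, mu, scales, lo, hi)

    use_b = cb < ca
    x = np.where(use_b[:, None], xb, xa)
    iters = np.where(use_b, itb, ita)
    cst = np.where(use_b, cb, ca)
    conv = np.where(use_b, cvb, cva)
    return x * scales[None, :], iters, cst, conv


def fit_voxel(data, M0: float, R1b: float, spec: AcquisitionSpec,
              cfg: FitConfig | None = None):
    """Fit one voxel; returns (VoxelParams, diagnostics dict).

    Non-finite data or a nonpositive M0 flags the voxel: parameters are set
    to zero (ATT to its lower bound) with converged=False.
    """
    cfg = cfg or FitConfig()
    data = np.asarray(data, dtype=float)
    if data.shape != (len(spec),):
        raise ValueError(f"data has {data.size} values but the protocol has {len(spec)} encodes")
    if not np.all(np.isfinite(data)) or not M0 > 0:
        p = VoxelParams(kw=0.0, cbf=0.0, att=cfg.bounds[2][0], r1b=R1b, m0=max(M0, 0.0))
        return p, {"iterations": 0, "final_cost": np.nan, "converged": False}
    mu = 0.0 if cfg.mu == "auto" else float(cfg.mu)
    params, iters, cst, conv = _fit_batch(
        data[None, :], np.array([float(M0)]), np.array([float(R1b)]), spec, cfg, mu
    )
    p = VoxelParams(kw=float(params[0, 0]), cbf=float(params[0, 1]),
                    att=float(params[0, 2]), r1b=float(R1b), m0=float(M0))
    return p, {"iterations": int(iters[0]), "final_cost": float(cst[0]),
               "converged": bool(conv[0])}


def fit_volume(series, m0, r1b, mask, spec: AcquisitionSpec,
               cfg: FitConfig | None = None) -> FitResult:
    """Fit every masked voxel of a 4-D series; deterministic, voxel-independent.

    ``series`` has shape ``spatial + (n_encodes,)``; ``m0``, ``r1b`` and the
    boolean ``mask`` share the spatial grid. Voxels outside the mask are 0;
    masked voxels with non-finite data or M0 <= 0 are flagged unconverged.
    """
    cfg = cfg or FitConfig()
    series = np.asarray(series, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    r1b = np.asarray(r1b, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    spatial = series.shape[:-1]
    if series.shape[-1] != len(spec):
        raise ValueError(
            f"series has {series.shape[-1]} frames but the protocol has {len(spec)} encodes"
        )
    for name, vol in (("m0", m0), ("r1b", r1b), ("mask", mask)):
        if vol.shape != spatial:
            raise ValueError(f"{name} shape {vol.shape} does not match series grid {spatial}")

    flat = series.reshape(-1, len(spec))
    m0f, r1bf, maskf = m0.ravel(), r1b.ravel(), mask.ravel()
    good = maskf & np.all(np.isfinite(flat), axis=1) & (m0f > 0) & (r1bf > 0)
    idx = np.flatnonzero(good)

    mu = float(cfg.mu) if cfg.mu != "auto" else select_mu_lcurve(
        series, m0, r1b, mask, spec, cfg)[0]

    nvox = flat.shape[0]
    kw = np.zeros(nvox)
    cbf = np.zeros(nvox)
    att = np.zeros(nvox)
    iters = np.zeros(nvox, dtype=np.int32)
    cst = np.zeros(nvox)
    conv = np.zeros(nvox, dtype=bool)
    if idx.size:
        params, it, c, cv = _fit_batch(flat[idx], m0f[idx], r1bf[idx], spec, cfg, mu)
        kw[idx], cbf[idx], att[idx] = params[:, 0], params[:, 1], params[:, 2]
        iters[idx], cst[idx], conv[idx] = it, c, cv
    bad = maskf & ~good
    cst[bad] = np.nan

    return FitResult(
        kw_map=kw.reshape(spatial), cbf_map=cbf.reshape(spatial),
        att_map=att.reshape(spatial), iterations=iters.reshape(spatial),
        final_cost=cst.reshape(spatial), converged=conv.reshape(spatial),
        mu_used=mu,
    )


def select_mu_lcurve(series, m0, r1b, mask, spec: AcquisitionSpec,
                     cfg: FitConfig | None = None):
    """L-curve choice of the ridge weight mu.

    Fits a seeded subsample of masked voxels at every mu in ``cfg.mu_grid``,
    records (log residual norm, log solution norm), and returns the mu of
    maximal Menger curvature on that log-log curve (ties toward smaller mu),
    together with the curve table.
    """
    cfg = cfg or FitConfig()
    grid = np.asarray(cfg.mu_grid, dtype=float)
    if grid.size < 4 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("mu_grid must hold >= 4 strictly increasing positive values")
    series = np.asarray(series, dtype=float)
    flat = series.reshape(-1, len(spec))
    m0f = np.asarray(m0, float).ravel()
    r1bf = np.asarray(r1b, float).ravel()
    maskf = np.asarray(mask, bool).ravel()
    good = maskf & np.all(np.isfinite(flat), axis=1) & (m0f > 0) & (r1bf > 0)
    idx = np.flatnonzero(good)
    if idx.size == 0:
        raise ValueError("no usable voxels in mask")
    if idx.size > cfg.lcurve_subsample:
        rng = np.random.default_rng(cfg.seed)
        idx = np.sort(rng.choice(idx, size=cfg.lcurve_subsample, replace=False))

    gam2 = cfg.gamma2(spec)
    scales = np.asarray(cfg.param_scales, dtype=float)
    res_norm = np.empty(grid.size)
    sol_norm = np.empty(grid.size)
    for i, mu in enumerate(grid):
        params, _, _, _ = _fit_batch(flat[idx], m0f[idx], r1bf[idx], spec, cfg, mu)
        x = params / scales[None, :]
        f = forward_series_batch(params[:, 0], params[:, 1], params[:, 2],
                                 r1bf[idx], m0f[idx], spec)
        r = f - flat[idx]
        res_norm[i] = np.sqrt(np.einsum("ij,ij,j->", r, r, gam2))
        sol_norm[i] = np.sqrt(np.einsum("ij,ij->", x, x))

    with np.errstate(divide="ignore"):
        lx = np.log10(np.maximum(res_norm, 1e-300))
        ly = np.log10(np.maximum(sol_norm, 1e-300))
    pts = np.column_stack([lx, ly])
    if np.allclose(pts, pts[0], atol=1e-12):
        raise ValueError("degenerate L-curve: all points identical")
    curv = np.zeros(grid.size)
    for i in range(1, grid.size - 1):
        a, b_, c_ = pts[i - 1], pts[i], pts[i + 1]
        area2 = abs((b_[0] - a[0]) * (c_[1] - a[1]) - (c_[0] - a[0]) * (b_[1] - a[1]))
        la, lb, lc = np.linalg.norm(b_ - a), np.linalg.norm(c_ - b_), np.linalg.norm(c_ - a)
        if min(la, lb, lc) < 1e-12:
            continue
        curv[i] = 2.0 * area2 / (la * lb * lc)
    mu_star = float(grid[int(np.argmax(curv))])
    table = pd.DataFrame({"mu": grid, "resid_norm": res_norm,
                          "sol_norm": sol_norm, "curvature": curv})
    return mu_star, table


# ---------------------------------------------------------------------------
# estimator interface


class PermeabilityFitter(BaseEstimator):
    """Scikit-learn-style estimator for voxel-wise k_W / CBF / ATT mapping.

    Rows of ``X`` are voxels, columns the encodes of ``spec`` in storage
    order. ``fit`` requires per-voxel (or scalar) ``m0`` and ``r1b`` side
    inputs and exposes the fitted maps as flat arrays.

    Parameters mirror :class:`FitConfig`; see there for meanings.

    Attributes
    ----------
    kw_, cbf_, att_ : ndarray of shape (n_voxels,)
        Fitted water exchange rate (1/min), perfusion (mL/100 g/min) and
        arterial transit time (s).
    n_iter_, cost_, converged_ : per-voxel solver diagnostics.
    mu_ : float
        Regularization weight actually used ("auto" resolves via L-curve).

    Examples
    --------
    >>> from qpmap.model import default_protocol
    >>> est = PermeabilityFitter(spec=default_protocol())
    >>> est.fit(signals, m0=1000.0, r1b=0.77)   # doctest: +SKIP
    """

    def __init__(self, spec: AcquisitionSpec | None = None, mu: float | str = 0.0,
                 mu_grid=_DEFAULT_MU_GRID, max_iter: int = 100, rel_tol: float = 0.01,
                 bounds=_DEFAULT_BOUNDS, param_scales=_DEFAULT_SCALES,
                 gamma: str = "sqrt_nex", init_encode: int | None = None,
                 init_pld: float = 1.5, lcurve_subsample: int = 500, seed: int = 0):
        self.spec = spec
        self.mu = mu
        self.mu_grid = mu_grid
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.bounds = bounds
        self.param_scales = param_scales
        self.gamma = gamma
        self.init_encode = init_encode
        self.init_pld = init_pld
        self.lcurve_subsample = lcurve_subsample
        self.seed = seed

    def _config(self) -> FitConfig:
        return FitConfig(
            mu=self.mu, mu_grid=tuple(self.mu_grid), max_iter=self.max_iter,
            rel_tol=self.rel_tol, bounds=tuple(tuple(b) for b in self.bounds),
            param_scales=tuple(self.param_scales), gamma=self.gamma,
            init_encode=self.init_encode, init_pld=self.init_pld,
            lcurve_subsample=self.lcurve_subsample, seed=self.seed,
        )

    def fit(self, X, y=None, *, m0, r1b):
        spec = self.spec if self.spec is not None else default_protocol()
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_voxels, n_encodes)")
        if X.shape[1] != len(spec):
            raise ValueError(
                f"X has {X.shape[1]} columns but the protocol has {len(spec)} encodes"
            )
        n = X.shape[0]
        m0 = np.broadcast_to(np.asarray(m0, dtype=float), (n,)).copy()
        r1b = np.broadcast_to(np.asarray(r1b, dtype=float), (n,)).copy()
        res = fit_volume(X.reshape(n, 1, 1, -1),
                         m0.reshape(n, 1, 1), r1b.reshape(n, 1, 1),
                         np.ones((n, 1, 1), dtype=bool), spec, cfg)
        self.spec_ = spec
        self._m0_ = m0
        self._r1b_ = r1b
        self.n_features_in_ = X.shape[1]
        self.kw_ = res.kw_map.ravel()
        self.cbf_ = res.cbf_map.ravel()
        self.att_ = res.att_map.ravel()
        self.n_iter_ = res.iterations.ravel()
        self.cost_ = res.final_cost.ravel()
        self.converged_ = res.converged.ravel()
        self.mu_ = res.mu_used
        return self

    def predict(self, X=None) -> np.ndarray:
        """Model-predicted signal matrix at the fitted parameters."""
        if not hasattr(self, "kw_"):
            raise AttributeError("estimator is not fitted")
        return forward_series_batch(self.kw_, self.cbf_, self.att_,
                                    self._r1b_, self._m0_, self.spec_)

    def fit_predict(self, X, y=None, *, m0, r1b):
        self.fit(X, m0=m0, r1b=r1b)
        return self.predict()
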