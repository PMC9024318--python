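"""Independent oracles for the test suite.

These are deliberately separate transcriptions of the closed-form signal
equations and a brute-force grid minimiser; they share no code with the
package implementation so they can serve as cross-checks.
"""

from __future__ import annotations

import numpy as np


def oracle_delta_mb(kw, cbf, att, r1b, m0, pld, delta=1.5, eps=0.6, lam=0.9, r1a=0.6):
    """Literal transcription of the tissue-compartment difference signal."""
    k = kw / 60.0
    alpha = k + r1a
    beta = k / (k + r1a - r1b) if k != 0 else 0.0
    t = delta + pld
    flow = cbf / 6000.0
    return (2.0 * flow * eps * m0 * beta / lam
            * (np.exp(-(r1a - r1b) * att) / r1b
               * (np.exp(-r1b * (t - delta)) - np.exp(-r1b * t))
               - np.exp(-(r1a - alpha) * att) / alpha
               * (np.exp(-alpha * (t - delta)) - np.exp(-alpha * t))))


def oracle_delta_mc(kw, cbf, att, r1b, m0, pld, delta=1.5, eps=0.6, lam=0.9, r1a=0.6):
    """Literal transcription of the capillary-compartment difference signal."""
    k = kw / 60.0
    alpha = k + r1a
    t = delta + pld
    flow = cbf / 6000.0
    return (2.0 * flow * eps * m0 * np.exp(-(r1a - r1b) * att) / (lam * alpha)
            * (np.exp(-alpha * (t - delta)) - np.exp(-alpha * t)))


def oracle_series(kw, cbf, att, r1b, m0, plds, crushed, **consts):
    """Encode-by-encode signal: tissue plus capillary on uncrushed encodes."""
    out = []
    for pld, cr in zip(plds, crushed):
        s = oracle_delta_mb(kw, cbf, att, r1b, m0, pld, **consts)
        if not cr:
            s += oracle_delta_mc(kw, cbf, att, r1b, m0, pld, **consts)
        out.append(s)
    return np.array(out)


def grid_search_fit(data, r1b, m0, plds, crushed, gam2,
                    kw_grid=None, cbf_grid=None, att_grid=None):
    """Exhaustive grid minimiser of the (unregularized) weighted SSE.

    Default grids: k_W 0..200 step 1, CBF 0..100 step 0.5, ATT 0.5..2.5 step
    0.01. The SSE is evaluated at every grid node; linearity of the signal in
    CBF lets the CBF axis be evaluated through the exact quadratic expansion
    SSE(c) = A - 2cB + c^2 C, which is identical to direct evaluation.
    """
    if kw_grid is None:
        kw_grid = np.arange(0.0, 200.0 + 1e-9, 1.0)
    if cbf_grid is None:
        cbf_grid = np.arange(0.0, 100.0 + 1e-9, 0.5)
    if att_grid is None:
        att_grid = np.arange(0.5, 2.5 + 1e-9, 0.01)

    data = np.asarray(data, dtype=float)
    gam2 = np.asarray(gam2, dtype=float)
    A = float(np.sum(gam2 * data**2))
    best = (np.inf, 0.0, 0.0, 0.0)
    plds = np.asarray(plds, dtype=float)
    crushed = np.asarray(crushed, dtype=bool)
    for kw in kw_grid:
        # unit-CBF signals for every (att, encode) pair at this kw
        f_u = np.empty((att_grid.size, plds.size))
        for ia, att in enumerate(att_grid):
            f_u[ia] = oracle_series(kw, 1.0, att, r1b, m0, plds, crushed)
        B = (gam2[None, :] * data[None, :] * f_u).sum(axis=1)
        C = (gam2[None, :] * f_u * f_u).sum(axis=1)
        sse = A - 2.0 * np.outer(B, cbf_grid) + np.outer(C, cbf_grid**2)
        ia, ic = np.unravel_index(np.argmin(sse), sse.shape)
        if sse[ia, ic] < best[0]:
            best = (float(sse[ia, ic]), float(kw), float(cbf_grid[ic]), float(att_grid[ia]))
    return {"cost": best[0], "kw": best[1], "cbf": best[2], "att": best[3]}
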