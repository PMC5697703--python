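"""Shared minimax phase optimizer.

Minimizes ``max_t |C(t,:) @ exp(i*phi)|`` over phase vectors, optionally
restricted to the antisymmetric (AM) subspace.  The nonsmooth max is
approached through a staged sequence of p-norm surrogates (p = 8 .. 2048,
renormalized per stage to avoid overflow) solved with L-BFGS from random
restarts; the final peak is measured on a dense grid with local refinement.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = ["am_expand", "am_reduce_grad", "minimize_peak_phases"]

_STAGES = (8, 32, 128, 512, 2048)


def am_expand(x: np.ndarray, mb: int) -> np.ndarray:
    """Antisymmetric phase vector from its ``mb // 2`` free components
    (central phase pinned to zero for odd mb)."""
    x = np.asarray(x, float)
    if mb % 2:
        return np.concatenate([x, [0.0], -x[::-1]])
    return np.concatenate([x, -x[::-1]])


def am_reduce_grad(g: np.ndarray, mb: int) -> np.ndarray:
    """Chain rule of :func:`am_expand`: gradient wrt the free components."""
    h = mb // 2
    return g[:h] - g[-h:][::-1]


def _peak(C: np.ndarray, phi: np.ndarray) -> float:
    return float(np.abs(C @ np.exp(1j * phi)).max())


def minimize_peak_phases(C: np.ndarray, mb: int, am: bool,
                         n_starts: int = 100, seed: int = 1234,
                         stages: tuple[int, ...] = _STAGES,
                         x0_list=None):
    """Best-of-restarts minimax phase search.

    Parameters
    ----------
    C:
        Complex matrix (n_t, mb); column n carries the fixed factor
        multiplying ``exp(i*phi_n)`` at each evaluation point.
    am:
        Restrict to the antisymmetric subspace (conjugate-symmetric
        modulation, real waveform).
    x0_list:
        Optional explicit start points (free-variable dimension); random
        uniform starts are appended up to ``n_starts``.

    Returns
    -------
    (phases, peak): the full phase vector (length mb) and achieved peak.
    """
    rng = np.random.default_rng(seed)
    nfree = mb // 2 if am else mb
    if nfree == 0:  # mb == 1, nothing to optimize
        return np.zeros(mb), _peak(C, np.zeros(mb))

    def expand(x):
        return am_expand(x, mb) if am else np.asarray(x, float)

    def obj_grad(x, p, K):
        phi = expand(x)
        ph = C * np.exp(1j * phi)
        f = ph.sum(axis=1)
        af = np.abs(f) / K
        with np.errstate(over="ignore", invalid="ignore"):
            J = (af ** p).mean()
            w = (af ** (p - 2))[:, None]
            g = p * (w * np.real(np.conj(f / K)[:, None] * 1j * ph / K)).mean(axis=0)
        if not np.isfinite(J):
            return 1e300, np.zeros(nfree)
        if am:
            g = am_reduce_grad(g, mb)
        return J, g

    starts = list(x0_list) if x0_list else []
    while len(starts) < n_starts:
        starts.append(rng.uniform(-np.pi, np.pi, nfree))

    best_pk, best_phi = np.inf, None
    for x0 in starts:
        x = np.asarray(x0, float)
        for p in stages:
            K = max(_peak(C, expand(x)), 1e-12)
            res = minimize(obj_grad, x, args=(p, K), jac=True,
                           method="L-BFGS-B", options={"maxiter": 200})
            x = res.x
        pk = _peak(C, expand(x))
        if pk < best_pk:
            best_pk, best_phi = pk, expand(x)
    return best_phi, best_pk
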