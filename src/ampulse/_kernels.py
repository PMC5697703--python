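"""Optional numba-accelerated inner recursions; pure-numpy fallbacks live in
:mod:`ampulse.slr`.  The inverse SLR recursion dominates the root-flip
genetic search, so the jitted path matters there."""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    @njit(cache=True)
    def inverse_slr_kernel(a, b):          # pragma: no cover - jitted
        n = a.shape[0]
        rf = np.zeros(n, dtype=np.complex128)
        m = n
        for j in range(n - 1, -1, -1):
            t = b[0] / a[0]
            at = abs(t)
            phi = 2.0 * np.arctan(at)
            if at > 0.0:
                e = t / at
            else:
                e = 1.0 + 0.0j
            rf[j] = phi * e
            C = np.cos(phi / 2.0)
            S = e * np.sin(phi / 2.0)
            Sc = np.conj(S)
            for k in range(m):
                ak = a[k]
                bk = b[k]
                a[k] = C * ak + Sc * bk
                b[k] = -S * ak + C * bk
            for k in range(m - 1):
                b[k] = b[k + 1]
            if m > 1:
                b[m - 1] = 0.0
                m -= 1
        return rf

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    inverse_slr_kernel = None
    HAVE_NUMBA = False
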