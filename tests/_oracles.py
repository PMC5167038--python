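"""Naive reference implementations used to cross-check the vectorized code.

Everything here is written as plain loops over animals, occasions and
mask points, building on nothing but `occasion_capture_probs`, so it is
independent of the array algebra in `mastsecr.likelihood`.
"""

import numpy as np
from scipy.special import gammaln

from mastsecr import occasion_capture_probs


def loop_neg_loglik(session, traps, mask, D, params):
    """Triple-loop multi-catch SECR negative log-likelihood."""
    animals = sorted({r[0] for r in session.records})
    hist = {a: {} for a in animals}
    for a, occ, t in session.records:
        hist[a][occ] = t
    K = session.n_occasions
    c = mask.cell_area
    a_theta = 0.0
    for x in mask.points:
        _, p_none = occasion_capture_probs(x, traps, params.lambda0,
                                           params.sigma)
        a_theta += c * (1.0 - p_none ** K)
    ll = -D * a_theta + len(animals) * np.log(D) - gammaln(len(animals) + 1)
    for a in animals:
        ll += np.log(animal_integral(hist[a], traps, mask, params, K))
    return -ll


def animal_integral(history, traps, mask, params, K):
    """c * sum_m Pr(omega | x_m) for one animal's {occasion: trap} history."""
    first = min(history)
    total = 0.0
    for x in mask.points:
        pr = 1.0
        for occ in range(1, K + 1):
            lam = params.lambda0 * (params.b_mult if occ > first else 1.0)
            p, p_none = occasion_capture_probs(x, traps, lam, params.sigma)
            if occ in history:
                pr *= p[traps.index_of(history[occ])]
            else:
                pr *= p_none
        total += mask.cell_area * pr
    return total


def brute_force_mask_points(traps, buffer, spacing):
    """Enumerate-and-filter reference for build_mask."""
    lo = traps.xy.min(axis=0)
    hi = traps.xy.max(axis=0)
    n = int(np.ceil(buffer / spacing))
    pts = []
    for i in range(-n, int(round((hi[0] - lo[0]) / spacing)) + n + 1):
        for j in range(-n, int(round((hi[1] - lo[1]) / spacing)) + n + 1):
            p = np.array([lo[0] + i * spacing, lo[1] + j * spacing])
            dmin = min(np.hypot(*(p - t)) for t in traps.xy)
            if dmin <= buffer * (1 + 1e-12):
                pts.append(p)
    return np.array(pts)
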