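"""Independent brute-force re-implementations used as test oracles.

Deliberately written with plain ``math`` loops (no clutchkit internals) so
that agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_distance(blunt, center):
    return math.hypot(blunt[0] - center[0], blunt[1] - center[1])


def oracle_angle(blunt, center, y_down=False):
    dy = blunt[1] - center[1]
    if y_down:
        dy = -dy
    return math.degrees(math.atan2(dy, blunt[0] - center[0])) % 360.0


def oracle_orientation(blunt, sharp, y_down=False):
    dy = blunt[1] - sharp[1]
    if y_down:
        dy = -dy
    return math.degrees(math.atan2(dy, blunt[0] - sharp[0])) % 180.0


def oracle_adjacent(blunts, sharps, center, y_down=False):
    """Adjacent axial angles with eggs sorted clockwise (descending math
    polar angle) around the center."""
    idx = sorted(
        range(len(blunts)),
        key=lambda i: (-oracle_angle(blunts[i], center, y_down),
                       oracle_distance(blunts[i], center)),
    )
    orients = [oracle_orientation(blunts[i], sharps[i], y_down) for i in idx]
    n = len(orients)
    return [(orients[(k + 1) % n] - orients[k]) % 180.0 for k in range(n)]


def oracle_circular_sd_two(a, b, period=360.0):
    """Mardia circular SD of two angles via explicit unit-vector averaging."""
    f = 2.0 * math.pi / period
    z = (complex(math.cos(a * f), math.sin(a * f)) + complex(math.cos(b * f), math.sin(b * f))) / 2.0
    r = max(abs(z), 1e-12)
    return math.sqrt(-2.0 * math.log(r)) / f


def irls_glm(y, X, family, alpha_nb=None, tol=1e-10, maxiter=200):
    """Iteratively reweighted least squares for canonical-ish GLMs.

    family: "binomial" (logit) or "nb" (log link, known NB2 dispersion
    ``alpha_nb``).  Returns the coefficient vector.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        if family == "binomial":
            mu = 1.0 / (1.0 + np.exp(-eta))
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
            var = mu * (1 - mu)
            dmu = var  # d mu / d eta for logit
        elif family == "nb":
            mu = np.exp(np.clip(eta, -30, 30))
            var = mu + alpha_nb * mu**2
            dmu = mu
        else:
            raise ValueError(family)
        w = dmu**2 / var
        z = eta + (y - mu) / dmu
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta
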