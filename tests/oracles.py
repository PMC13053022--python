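"""Independent oracles used by the test suite.

These are deliberately written against the *generative definitions* of the
quantities being tested (numerical integration, brute-force enumeration,
recounting), not against the package's own formulas, so that agreement is
evidence and not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm


def posterior_quadrature(
    F: np.ndarray, J: np.ndarray, f_target: np.ndarray, phantom_mask: np.ndarray
) -> np.ndarray:
    """Target posterior by numerical integration.

    Treats the belief (F, J) per cell as the Gaussian data summary: the
    likelihood of the accumulated evidence given a true feature value ``a``
    is proportional to N(a; F, 1/J). The posterior that object ``o`` is the
    target is then

        p_o  proportional to  prod_f  N(f_target_f; F_of, 1/J_of)
                               / integral N(a; F_of, 1/J_of) N(a; 0, 1) da,

    with the evidence integral evaluated by adaptive quadrature.
    """
    F = np.asarray(F, dtype=float)
    J = np.asarray(J, dtype=float)
    n_o, n_f = F.shape
    log_scores = np.zeros(n_o)
    for o in range(n_o):
        for f in range(n_f):
            sd = 1.0 / np.sqrt(J[o, f])
            num = norm.logpdf(f_target[f], loc=F[o, f], scale=sd)

            def integrand(a, loc=F[o, f], s=sd):
                return norm.pdf(a, loc=loc, scale=s) * norm.pdf(a)

            den, _ = quad(integrand, -40.0, 40.0, limit=200)
            log_scores[o] += num - np.log(den)
    log_scores = log_scores - log_scores[~phantom_mask].max()
    p = np.where(phantom_mask, 0.0, np.exp(log_scores))
    return p / p.sum()


def merge_measurements(measurements) -> tuple[np.ndarray, np.ndarray]:
    """Precision-weighted combination of a list of (X, J_meas) pairs."""
    J_total = sum(m.J_meas for m in measurements)
    num = sum(m.X * m.J_meas for m in measurements)
    with np.errstate(invalid="ignore"):
        X = np.where(J_total > 0, num / np.maximum(J_total, 1e-300), 0.0)
    return X, J_total


def enumerate_open_loop_sequences(n_objects: int, max_len: int):
    """All fixation sequences of length 0..max_len over ``n_objects`` objects.

    An open-loop policy executes its sequence verbatim, then terminates and
    reports the MAP object; the empty sequence reports from the prior.
    """
    for length in range(max_len + 1):
        yield from itertools.product(range(n_objects), repeat=length)


def sphere_chord_density_histogram(n_bins: int) -> np.ndarray:
    """Expected D2 histogram mass for uniform points on the unit sphere.

    The chord length between two uniform points on the unit sphere has
    density f(d) = d/2 on [0, 2]; the expected mass of bin [a, b] is
    (b^2 - a^2)/4.
    """
    edges = np.linspace(0.0, 2.0, n_bins + 1)
    return (edges[1:] ** 2 - edges[:-1] ** 2) / 4.0
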