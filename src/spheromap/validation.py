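"""Brute-force references for validating the per-gene optimizer.

The grid search below evaluates the exact same log posterior the MAP fit
maximizes, over a dense box of (a, b, c, theta) values. It is deliberately
naive — no gradients, no staging — so it serves as an independent check
that the optimizer does not stop at an inferior point on small instances.
"""

from __future__ import annotations

import numpy as np

from .model import RegulationPriors, _safe_abundance, nb_logpmf


def grid_max_log_posterior(
    counts,
    radial,
    depth,
    priors: RegulationPriors,
    n_points: int = 15,
    a_box: tuple[float, float] = (0.2, 5.0),
    trend_box: float = 3.0,
    theta_box: tuple[float, float] = (0.1, 100.0),
) -> float:
    """Maximum log posterior over an (n_points)^4 grid.

    The box is scaled by the pooled abundance a0 = sum(n)/sum(N):
    a in [a_box] * a0, b and c in +/- trend_box * a0, theta log-spaced
    over ``theta_box``.
    """
    counts = np.asarray(counts, dtype=float)
    radial = np.asarray(radial, dtype=float)
    depth = np.asarray(depth, dtype=float)
    a0 = counts.sum() / depth.sum()

    a_grid = np.linspace(a_box[0] * a0, a_box[1] * a0, n_points)
    bc_grid = np.linspace(-trend_box * a0, trend_box * a0, n_points)
    theta_grid = np.geomspace(theta_box[0], theta_box[1], n_points)

    A, B, C = (g.ravel() for g in np.meshgrid(a_grid, bc_grid, bc_grid,
                                              indexing="ij"))
    f = A[:, None] + B[:, None] * radial + C[:, None] * radial**2
    g, _ = _safe_abundance(f, priors.floor)
    mu = g * depth  # (combos, cells)

    # priors, vectorized over combos (same formulas as RegulationPriors)
    grid_r = np.linspace(0.0, 1.0, 21)
    f_grid = A[:, None] + B[:, None] * grid_r + C[:, None] * grid_r**2
    w = 0.5 * priors.floor
    barrier = -np.logaddexp(0.0, (priors.floor - f_grid) / w).sum(axis=1)
    gauss = -(B**2 + C**2) / (2.0 * priors.trend_sigma**2)
    lp = barrier + gauss

    best = -np.inf
    counts_b = np.broadcast_to(counts, mu.shape)
    for theta in theta_grid:
        ll = nb_logpmf(counts_b, mu, theta).sum(axis=1)
        best = max(best, float((ll + lp).max()))
    return best
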