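"""Built-in validation benchmarks with known ground truth.

Each function generates a seeded synthetic dataset at the package's
standard benchmark scale (1,500 cells, median depth 20,000 UMIs), runs the
relevant part of the inference stack, and returns summary metrics. They
back both the test suite and the reproducibility script, so the numbers
reported there are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kstest, poisson

from .calling import bh_fdr, call_spatial_genes, downsampling_curve
from .io import filter_expressed_genes
from .model import GeneRegulationModel, RegulationFunction, nb_logpmf
from .pathways import xi_correlation
from .simulate import (
    GeneBlock,
    SimulationConfig,
    make_benchmark,
    sample_radial_positions,
)
from .validation import grid_max_log_posterior


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, n)]


def _mixed_benchmark(seed: int, n_spatial_mono: int = 80,
                     n_spatial_interior: int = 20, n_null: int = 200,
                     n_cells: int = 1500):
    cfg = SimulationConfig(
        n_cells=n_cells,
        median_depth=20_000,
        gene_blocks=[
            GeneBlock("core", n_spatial_mono),
            GeneBlock("periphery", n_spatial_mono),
            GeneBlock("intermediate", n_spatial_interior),
            GeneBlock("extrema", n_spatial_interior),
            GeneBlock("flat", n_null),
        ],
        seed=seed,
    )
    cells, counts, truth = make_benchmark(cfg)
    truth = truth.copy()
    truth["mean_umis"] = counts.counts.sum(axis=1) / counts.n_cells
    return cells, counts, truth


def parameter_recovery(seed: int) -> dict:
    """Fit 200 spatial + 200 null genes; measure recovery and CI coverage.

    Returns per-gene relative error of the fitted f at r in {0, 0.5, 1}
    summarized over "strong" genes (true magnitude >= 0.5, mean >= 1
    UMI/cell), and the fraction of 95% Wald intervals for b covering the
    true value across all converged fits.
    """
    cells, counts, truth = _mixed_benchmark(seed)
    r = np.array([c.radial_position for c in cells])
    N = np.array([c.depth for c in cells], dtype=float)
    max_rel_err, within = [], []
    covered = n_conv = 0
    for i, row in enumerate(truth.itertuples(index=False)):
        res = GeneRegulationModel(counts.counts[i], (r, N)).fit()
        if not (res.converged and res.has_se):
            continue
        n_conv += 1
        covered += abs(res.params.b - row.b) <= 1.96 * res.se_b
        strong = (
            row.pattern != "flat" and row.magnitude >= 0.5
            and row.mean_umis >= 1.0
        )
        if strong:
            fn = RegulationFunction(row.a, row.b, row.c)
            errs = [
                abs(res.predict(x) - fn(x)) / fn(x) for x in (0.0, 0.5, 1.0)
            ]
            max_rel_err.append(max(errs))
            within.append(max(errs) <= 0.30)
    return {
        "n_genes": len(truth),
        "n_converged": n_conv,
        "n_strong": len(max_rel_err),
        "median_max_rel_err": float(np.median(max_rel_err)),
        "frac_within_30pct": float(np.mean(within)),
        "wald_coverage_b": covered / n_conv,
    }


def null_calibration(seed: int, n_genes: int = 500) -> dict:
    """All-null benchmark: fraction of genes called spatial at q < 0.1."""
    cfg = SimulationConfig(
        n_cells=1500, median_depth=20_000,
        gene_blocks=[GeneBlock("flat", n_genes)], seed=seed,
    )
    cells, counts, _ = make_benchmark(cfg)
    filtered = filter_expressed_genes(counts)
    table = call_spatial_genes(filtered, cells)
    frac = float(table["spatial"].mean())
    return {
        "n_genes_tested": len(table),
        "frac_called": frac,
        "bound": 0.10 + 3 * np.sqrt(0.10 * 0.90 / len(table)),
    }


def pattern_classification(seed: int) -> dict:
    """Accuracy of pattern labels on planted strong (magnitude >= 0.5) genes.

    A planted gene counts as correct only when it is both called spatial and
    assigned its true label; genes below the expression filter are outside
    the analysis universe and excluded.
    """
    cfg = SimulationConfig(
        n_cells=1500, median_depth=20_000,
        gene_blocks=[
            GeneBlock("core", 40, magnitude_range=(0.5, 0.9)),
            GeneBlock("periphery", 40, magnitude_range=(0.5, 0.9)),
            GeneBlock("intermediate", 30, magnitude_range=(0.5, 0.9)),
            GeneBlock("extrema", 30, magnitude_range=(0.5, 0.9)),
            GeneBlock("flat", 100),
        ],
        seed=seed,
    )
    cells, counts, truth = make_benchmark(cfg)
    filtered = filter_expressed_genes(counts)
    table = call_spatial_genes(filtered, cells)
    m = table.merge(truth, on="gene_id", suffixes=("", "_true"))
    planted = m[(m["pattern_true"] != "flat") & (m["magnitude_true"] >= 0.5)]
    acc = float((planted["pattern"] == planted["pattern_true"]).mean())
    return {"n_planted": len(planted), "pattern_accuracy": acc}


def optimizer_vs_grid(seed: int, n_instances: int = 20, n_cells: int = 50
                      ) -> dict:
    """MAP optimizer vs exhaustive 15^4 grid search on small instances."""
    rng = np.random.default_rng(seed)
    r = sample_radial_positions(n_cells, seed=_child_seeds(seed, 2)[0])
    N = np.full(n_cells, 5000.0)
    n_ok = 0
    margins = []
    for _ in range(n_instances):
        a = float(np.exp(rng.uniform(np.log(1e-4), np.log(1e-3))))
        b = float(rng.uniform(-0.5 * a, 2.0 * a))
        theta = float(np.exp(rng.uniform(np.log(0.5), np.log(10.0))))
        mu = (a + b * r) * N
        counts = rng.poisson(rng.gamma(theta, mu / theta))
        if counts.sum() == 0:
            counts[0] = 1
        model = GeneRegulationModel(counts, (r, N))
        res = model.fit()
        grid_best = grid_max_log_posterior(counts, r, N, model.priors)
        margins.append(res.logpost - grid_best)
        n_ok += res.logpost >= grid_best - 1e-9
    return {
        "n_instances": n_instances,
        "n_optimizer_at_least_grid": int(n_ok),
        "min_margin": float(min(margins)),
    }


def closed_form_checks(seed: int) -> dict:
    """Deviations of core statistics from their closed forms."""
    nb_zero_err = abs(nb_logpmf(0, 1.0, 1.0) - 1.0 * np.log(1.0 / (1.0 + 1.0)))
    pois_err = abs(nb_logpmf(3, 2.0, 1e8) - poisson.logpmf(3, 2.0))
    bh = bh_fdr([0.01, 0.02, 0.03, 0.04])
    bh_err = float(np.abs(bh - 0.04).max())
    x = np.arange(5.0)
    xi5, _ = xi_correlation(x, x, method="asymptotic", seed=0)
    rng = np.random.default_rng(seed)
    stats = [
        xi_correlation(rng.normal(size=1000), rng.normal(size=1000),
                       method="asymptotic")[0]
        for _ in range(500)
    ]
    var_ratio = float(np.var(stats) / (2.0 / (5.0 * 1000)))
    return {
        "nb_logpmf_zero_abs_err": float(nb_zero_err),
        "nb_poisson_limit_abs_err": float(pois_err),
        "bh_staircase_abs_err": bh_err,
        "xi_identity_n5": float(xi5),
        "xi_null_var_ratio": var_ratio,
    }


def radial_geometry(seed: int, n: int = 5000) -> dict:
    """KS test that r^3 of sampled positions is uniform (r^2 density)."""
    r = sample_radial_positions(n, seed=seed)
    return {"ks_pvalue_r_cubed_uniform": float(kstest(r**3, "uniform").pvalue)}


def downsampling_behavior(seed: int) -> dict:
    """Spatial-gene counts along the binomial downsampling ladder."""
    s1, s2 = _child_seeds(seed, 2)
    cells, counts, _ = make_benchmark(SimulationConfig(seed=s1))
    ps = [0.003, 0.01, 0.03, 0.1, 0.3, 1.0]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = downsampling_curve(counts, cells, ps, seed=s2)
    n = curve["n_spatial_genes"].to_numpy()
    diffs = np.diff(n)
    inversions = int((diffs < 0).sum())
    worst_dip = float(
        min((n[i + 1] - n[i]) / max(n[i], 1) for i in range(len(n) - 1))
    )
    return {
        "curve": dict(zip(map(str, ps), (int(v) for v in n))),
        "n_inversions": inversions,
        "worst_relative_dip": worst_dip,
        "n_spatial_full_depth": int(n[-1]),
    }


def thinning_closure(seed: int, mu: float = 50.0, theta: float = 4.0,
                     p: float = 0.3, n_draws: int = 100_000) -> dict:
    """Binomial thinning of NB draws keeps the NB size (Gamma-Poisson)."""
    rng = np.random.default_rng(seed)
    draws = rng.poisson(rng.gamma(theta, mu / theta, size=n_draws))
    thinned = rng.binomial(draws, p)
    m, v = thinned.mean(), thinned.var()
    return {
        "mean_ratio": float(m / (p * mu)),
        "theta_ratio": float((m**2 / (v - m)) / theta),
    }
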