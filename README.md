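# spheromap

Inference of spatial gene regulation along the core–periphery axis of tumor
spheroids from dye-positioned single-cell UMI counts.

## The problem

Spheroids — 3D in-vitro aggregates of tumor cells — develop a radial
gradient: peripheral cells see oxygen and nutrients and proliferate, core
cells starve. Incubating spheroids with a partially diffusing dye
(Calcein-AM) labels each cell by its depth from the surface, so after
dissociation, sorting and deep single-cell RNA sequencing, every cell
carries both its transcriptome (UMI counts) and a fluorescence readout of
its radial position. The analysis question is: **which genes and pathways
are regulated by a cell's position on the core–periphery axis, and how?**
Single-cell counts are noisy — transcriptional bursting plus sampling —
so position-dependence has to be separated from that noise statistically.
This package is for computational biologists analyzing such dye-diffusion
spheroid (or organoid) experiments.

## The model

Each cell gets a radial coordinate r ∈ [0, 1] (0 = core, 1 = periphery)
by min–max scaling its log dye intensity. For gene g, cell c with position
r_c and sequencing depth N_c (total UMIs):

    n_gc ~ NB( mean = f_g(r_c) · N_c ,  size = θ_g )
    f_g(r) = a + b·r + c·r²,   f_g > 0 on [0, 1]

f_g(r) is the gene's *fractional abundance* — its share of the
transcriptome at position r; a is core expression, b and c the linear and
quadratic trends, θ_g a gene-specific negative-binomial size (variance
μ + μ²/θ). Parameters are fitted by MAP under weak priors (a positivity
floor tied to sequencing depth and near-flat "no trend" priors on b and
c), with Laplace standard errors from the Hessian at the optimum. A gene
is called **spatial** when its trend test survives Benjamini–Hochberg FDR
(q < 0.1) and its regulation magnitude 1 − min f/max f exceeds 0.3; called
genes are classified as *core*, *periphery*, *intermediate* (interior
maximum) or *extrema* (interior minimum). Pathways are tested without the
polynomial assumption: per-cell pathway UMI fractions against r with
Chatterjee's Xi correlation, plus an abundance-weighted mean position
(avgR) over 10 radial bins. A seeded synthetic-data generator (r² cell
density, lognormal depths, Gamma–Poisson counts with planted regulation
functions) makes the whole stack verifiable against ground truth. See
`docs/methods.md` for assumptions and limitations.

## Worked example

```python
import numpy as np
import spheromap as sp

# synthetic spheroid: 1,500 cells, planted periphery/core/null genes
cfg = sp.SimulationConfig(
    n_cells=1500,
    gene_blocks=[
        sp.GeneBlock("periphery", 30, magnitude_range=(0.5, 0.9)),
        sp.GeneBlock("core", 30, magnitude_range=(0.5, 0.9)),
        sp.GeneBlock("flat", 60),
    ],
    seed=42,
)
cells, counts, truth = sp.make_benchmark(cfg)
matrix = sp.filter_expressed_genes(counts)   # analysis universe: >= 1 UMI/cell

# fit one gene, statsmodels-style
r = np.array([c.radial_position for c in cells])
N = np.array([c.depth for c in cells], dtype=float)
i = matrix.gene_index("g0015_periphery")
res = sp.GeneRegulationModel(matrix.counts[i], (r, N),
                             gene_id="g0015_periphery").fit()
print(res.summary())
```

```
Spatial regulation fit: g0015_periphery
==============================================
cells used                                1500
converged                                 True
log likelihood                        -5489.75
----------------------------------------------
                estimate    std err          p
a (core)       0.0001395   7.65e-05
b (linear)     0.0008407   0.000281    0.00278
c (quad.)     -8.447e-07   0.000235      0.997
theta (NB size)                          1.989
magnitude                                0.858
==============================================
```

The fitted core abundance a ≈ 1.4×10⁻⁴ and linear trend b ≈ 8.4×10⁻⁴
recover the planted truth (a = 1.5×10⁻⁴, b = 8.4×10⁻⁴): this gene's share
of the transcriptome rises ~7-fold from core to periphery (magnitude
0.86), with moderate overdispersion (θ ≈ 2). The genome-wide screen calls
and classifies every gene at once:

```python
screen = sp.SpatialScreen(matrix, cells).fit()
print(screen.summary())
```

```
Spatial gene screen
==========================================
genes tested                           111
fits retained                          111
spatial genes called                    55
------------------------------------------
pattern core                            24
pattern periphery                       28
pattern intermediate                     1
pattern extrema                          0
pattern other                            2
==========================================
```

51 of the 60 planted spatial genes pass the 1-UMI/cell expression filter,
and all 51 are called at q < 0.1 and magnitude > 0.3, nearly all with
their true label; 4 of the 60 null genes are called (7% of calls — within
the 10% FDR being controlled). `screen.table` holds per-gene estimates,
standard errors, p- and q-values, magnitudes and pattern labels;
`sp.pathway_spatial_scan` adds the gene-set level (Xi, q, avgR).

The same workflow is available from the shell:

```bash
spheromap simulate --seed 42 --out-dir sim/
spheromap fit --counts sim/counts.mtx --cells sim/cells_metadata.tsv --out calls.tsv
spheromap pathways --counts sim/counts.mtx --cells sim/cells_metadata.tsv \
    --gmt sets.gmt --out pathways.tsv
spheromap downsample --counts sim/counts.mtx --cells sim/cells_metadata.tsv \
    --ps 0.003,0.01,0.03,0.1,0.3 --seed 1 --out curve.tsv
```

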