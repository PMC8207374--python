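# zoicomp

Zone-of-influence (ZOI) neighborhood competition models for stem-mapped
forest censuses.

Classical tree neighborhood models treat every tree as a mathematical point
and sum the basal area of larger neighbors within a radius of each focal
stem. `zoicomp` implements a spatially extended alternative in which each
tree's crown — a disc of radius `cr = a + b·√gbh` from a pooled crown
allometry — is filled with random points that jointly carry the tree's basal
area, either at constant density (`equal`, 10 points·m⁻²) or with as many
points as the tree's basal area in cm² (`larsm`, so larger trees are
disproportionally denser). Crown plasticity is mimicked by flagging any
point lying within a tolerance Δd of a strictly larger tree's point as
*shaded* (Δd may differ for conspecific and heterospecific neighbors) and
then either deleting the shaded points (*removal*) or moving them into the
unshaded crown contour estimated by a 2-D kernel density (*relocation*),
hierarchically from the largest tree down.

On top of the canopy machinery the package fits, for each focal species and
census period, the neighborhood regressions

```
ln(agr)    = β₀ + α·ln(ba_t1) + β·ln(1 + Σba_CON/d) + γ·ln(1 + Σba_HET/d) + ε
logit(surv) = β₀ + α·ln(ba_t1) + β·ln(1 + Σba_CON/d) + γ·ln(1 + Σba_HET/d)
```

over every cell of a (r_CON, r_HET, Δd_CON, Δd_HET) grid — 20 × 20 radii
(1–20 m) times 7 × 7 tolerances (0–1.2 m in 0.2-m steps) = 19,600 spatial
cells — ranks them by AICc, and reports the unweighted mean of the raw CON
and HET coefficients over all cells within 2 AICc units of the best one.
Community-level syntheses (effects vs. plot abundance, growth-change vs.
survival-effect correlations, Procrustes comparison of community
ordinations) and a location-randomization null model (±3 SE envelopes,
slope-sign counts) complete the pipeline. A synthetic-forest generator
produces clustered multi-species stands whose growth and survival are drawn
from these same equations at known true parameters, so the whole chain can
be validated by parameter recovery.

The package is for spatial ecologists studying conspecific negative density
dependence and asymmetric (light) competition in permanent forest plots, and
for methodologists who want a reproducible reference implementation of
crown-overlap neighborhood predictors.

## Worked example

```python
import numpy as np
import zoicomp as z

# a 100 x 400 m stand of five clustered species whose dynamics follow the
# growth/survival equations at true r = 10 m, Δd = 0
spec = z.SyntheticSpec(true_dd=0.0, counts=(900,)*5,
                       plot=z.PlotSpec(100, 400, 20, (0.0, 10.0)))
census = z.generate_census(spec, seed=1)
period = census.plot.period(1)
print(z.select_focal_species(census, period))

cfg = z.ScanConfig(spatial=True, position_mode="stem",
                   radii=(6, 8, 10, 12, 14), dd_levels=(0.0,))
growth, survival = z.scan_pair(census, "sp01", 1, cfg, seed=1)
print(growth.summary())
print(survival.summary())
b = survival.average_band("con")
print("CON odds change per ln-unit: %.1f%%" % ((np.exp(b.coefficient)-1)*100))
```

prints

```
['sp01', 'sp02', 'sp03', 'sp04', 'sp05']
Neighborhood scan: sp01, period 1, growth (larsm/reloc/stem, decay=linear)
  observations: 508
  grid cells: 25 (25 retained)
  best cell: r_con=10, r_het=10, dd_con=0.0, dd_het=0.0, AICc=-188.37
  CON: mean coef -0.1915 over 1 models, mean r 10.0 m
  HET: mean coef -0.0953 over 1 models, mean r 10.0 m
Neighborhood scan: sp01, period 1, survival (larsm/reloc/stem, decay=linear)
  observations: 620
  grid cells: 25 (25 retained)
  best cell: r_con=6, r_het=12, dd_con=0.0, dd_het=0.0, AICc=560.16
  CON: mean coef -0.3925 over 22 models, mean r 9.5 m
  HET: mean coef -0.1489 over 22 models, mean r 10.5 m
CON odds change per ln-unit of neighborhood: -32.5%
```

The scan finds the generative radius (10 m) as the best growth cell and
recovers the true coefficients (growth CON −0.2, HET −0.1; survival CON
−0.5, HET −0.25, here attenuated by a single seed's sampling noise): a
focal tree's growth declines with the distance-decayed basal area of larger
conspecific neighbors about twice as steeply as with heterospecific ones,
and each ln-unit of conspecific neighborhood multiplies its survival odds
by exp(β) ≈ 0.68.

A `zoicomp` command-line pipeline (`simulate`, `predictors`, `fit`,
`average`, `community`, `randomize`, `report`) drives the same steps from a
YAML configuration with per-stage caching and manifests; see
`zoicomp --help`.

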