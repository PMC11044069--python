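# phylanchor

Landmark-based geometric morphometrics of monogenoid haptoral anchors in a
phylogenetic comparative framework.

Monogenoids (Platyhelminthes) attach to their fish hosts with a posterior
organ, the haptor, whose paired sclerotized anchors are classic material
for asking whether attachment-organ form tracks shared evolutionary
history or host-driven convergence. This package implements the full
analysis chain used to answer that question for 2-D anchor outlines, one
specimen per species:

1. **Input** — landmark/semilandmark configurations in TPS format
   (tpsDig dialect), slider-definition files, and a rooted Newick
   phylogeny whose tip labels match the specimen identifiers.
2. **Superimposition** — generalized Procrustes analysis (GPA) removes
   position, scale and orientation; semilandmarks may slide along their
   outline tangents minimising thin-plate-spline bending energy (or
   squared Procrustes distance). Centroid size
   CS = √Σᵢ‖xᵢ − x̄‖² is the size variable; log CS the allometric
   predictor.
3. **Shape space** — PCA of the covariance matrix of Procrustes
   coordinates; multivariate regression of shape on log CS ("through the
   origin" after mean-centring) with a permutation test, both ordinary
   and on Felsenstein's phylogenetic independent contrasts (PIC);
   size-corrected shapes are the regression residuals.
4. **Phylogenetic signal** — squared-change parsimony maps tip
   configurations onto the tree (weighted reconstruction = Brownian
   maximum-likelihood ancestral states); the mapped **tree length**
   (total summed squared change) is tested by permuting rows across tips
   (lower tail: signal shortens the tree). The **multivariate K**
   statistic

   K = [tr(YᶜᵀYᶜ) / tr(Yᶜᵀ C⁻¹ Yᶜ)] / [(tr C − n/(1ᵀC⁻¹1)) / (n − 1)],

   with C the Brownian tip covariance of the tree and Yᶜ the data centred
   on the phylogenetic (GLS) mean, equals 1 when trait covariance matches
   Brownian motion on the tree; its significance comes from an
   upper-tailed randomization.
5. **Visualization** — thin-plate-spline deformation grids from the
   consensus to each species with analytically computed Jacobian
   expansion factors (red > 1 expansion, blue < 1 contraction), and
   phylomorphospace plots (tips + ancestral nodes + branches in PC
   space), all with CSV companions.

A synthetic-data module generates anchor-like datasets (83 points: 5
fixed landmarks + 5 arcs of 29/20/12/11/6 semilandmarks, 10 species on a
simulated ultrametric tree) with controlled phylogenetic signal,
allometric fraction and non-phylogenetic noise, so the whole chain is
testable without downloads.

## Worked example

```python
from pathlib import Path
from phylanchor import SyntheticSpec, simulate_anchor_dataset
from phylanchor.pipeline import AnalysisConfig, run_analysis

man = simulate_anchor_dataset(
    SyntheticSpec(seed=42, allometry_fraction=0.3), "demo/data"
)
report = run_analysis(AnalysisConfig(
    tps=man["tps"], tree=man["tree"], sliders=man["sliders"],
    output_dir="demo/out", seed=1, write_figures=False,
))
print(sum(report.pca_percent_variance[:2]))          # 63.6
print(report.allometry["percent_predicted"])         # 21.6 (p = 0.0497)
print(report.tree_length_tests["shape_pcs"])         # 0.0596, p = 0.0033
print(report.k_mult_tests["shape"])                  # K = 0.232, p = 0.002
print(report.k_mult_tests["log_cs"])                 # K = 0.092, p = 0.68
```

Reading these numbers: the first two shape PCs carry 63.6 % of the
variation; the regression of shape on log CS explains 21.6 % of shape
variation (the generator injected a 30 % allometric share, part of which
sliding and superimposition reapportion); the mapped tree is
significantly shorter than random permutations (p = 0.0033) and K is
significantly larger than its permutation null (p = 0.002), i.e. anchor
*shape* carries phylogenetic signal — while log CS, drawn independently
of the tree, does not (p = 0.68). This mirrors the qualitative outcome of
the study system: phylogeny structures anchor shape but not anchor size.

The same run from the shell:

```sh
phylanchor simulate --out demo/data --seed 42
phylanchor run --config demo/config.yaml
phylanchor version
```

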