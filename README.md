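# hepaclone

Stochastic simulation of hepatoblast fate choice and quantitative
clonal-lineage-tracing statistics for multispectral 3D labelled livers.

During embryonic liver development a pool of progenitors (hepatoblasts)
differentiates into hepatocytes and biliary epithelial cells (BECs),
settling at roughly nine hepatocytes per BEC. `hepaclone` implements the
computational machinery for asking how that proportion arises and how
clonal lineage-tracing data should be read:

* **`fate_sim`** — an exact-Gillespie, agent-based model of hepatoblast
  expansion, division-linked differentiation (fate table over H+C, C+C,
  H+H daughter pairs) and fate-maintaining proliferation, run from 100
  hepatoblasts to a 3000-cell liver, with six preset parameterisations
  spanning fully bipotent pools, mixed uni-/bipotent pools and slowed
  BEC division. Optional relaxed-3D mode with soft-sphere mechanics.
* **`mean_field`** — the deterministic ODE limit used as an oracle:
  closed form `(p_hc + 2p_hh)/(p_hc + 2p_cc)` for equal
  differentiated-cell rates, numerical integration otherwise.
* **`clone_call`** — distance-based clone reconstruction from labelled
  nucleus coordinates (single-linkage components at a 45 or 70 μm
  radius), fate classification, and the size-to-division rule
  `floor(log2 k)`.
* **`clonality_stats`** — the statistical framework for assessing
  clonality: P_same(r)/P_diff(r) colour-neighbour curves, the
  exponential clone-size scaling law `P(k) = e^(−k/⟨k⟩)`, the Poisson
  division-number law, liver subsets by labelling density, and the x/3
  colour-blind misassignment estimate.
* **`spatial_stats`** — cell-type ratios, distance-to-organ-surface
  comparisons (t test / rank-sum) and nearest-neighbour distributions.
* **`synthetic_data`** — a ground-truth generator of multispectral
  labelled-liver cohorts (heavy-tailed induction, four colours, Yule
  clone growth, bounded dispersal, organ expansion) against which every
  pipeline stage is validated.

Audience: developmental and systems biologists analysing multicolour
lineage-tracing point clouds, and anyone needing a tested reference
implementation of clone-size / division-number scaling-law analyses.

## Worked example

Which progenitor composition produces the in-vivo ~1:9 BEC:hepatocyte
proportion? Compare a fully bipotent pool with slowed BEC division
(model 2) to a 20% bipotent / 80% hepatocyte-unipotent pool (model 6):

```
$ hepaclone oracle --model 2
model2: expected H per BEC = 2.3049 (stop at t = 30.40 a.u.)

$ hepaclone oracle --model 6
model6: expected H per BEC = 9.0000 (stop at t = 27.08 a.u.)
closed form (equal rates): 9.0000
```

Slower BEC cycling alone (24 h → 36 h) only reaches ≈ 1:2.3; progenitor
heterogeneity reaches 1:9. The stochastic simulation agrees within
replicate noise:

```python
from hepaclone import run_model

ens = run_model(6, n_reps=10, seed=0)
print(f"mean H per BEC = {ens.mean_ratio:.2f} (SD {ens.sd_ratio:.2f}, 10 replicates)")
# mean H per BEC = 9.95 (SD 3.28, 10 replicates)
```

(The per-replicate ratio is right-skewed — BEC founder numbers at the
differentiation threshold are binomial — so the ensemble mean of ratios
sits slightly above the deterministic 9.0.)

On the data side, generate a small synthetic cohort and push it through
clone reconstruction and the clonality statistics:

```
$ hepaclone synth --livers 10 --seed 0 --out out/synth
10 livers, 272 labelled cells (median 22/liver, 0% livers > 100 cells)

$ hepaclone clonality out/synth/cells.csv --out out/clonality
{
  "n_clones": 30,
  "mean_clone_size": 4.1,
  "clone_size_max_cdf_deviation": 0.11397266089940694,
  "poisson_lambda": 1.3666666666666667,
  "poisson_chi2": 0.03665624436835451,
  "poisson_pvalue": 0.848166622143334,
  "colour_mixing_fraction_x": 0.2608695652173913,
  "same_colour_merge_estimate": 0.08695652173913043
}
```

Reading the numbers: 30 clones survive the quantitative ruleset (45 μm
grouping, livers under 40 labelled cells) with mean size 4.1; the
division counts are consistent with the Poisson null (p = 0.85); the
clone-size tail deviates from a single exponential by at most 0.114 —
large for this tiny cohort, shrinking towards ≈ 0.05 at 1000 clones;
and colour-blind grouping mixes colours in 26% of groups, implying
roughly a 9% same-colour merge rate at this labelling density.

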