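# Methods

## The fate model

Embryonic liver development is modelled as a continuous-time branching
process over three cell types: hepatoblasts (P), hepatocytes (H) and
biliary epithelial cells (BECs, C). The simulation has three phases:

1. **Expansion.** `n_init = 100` hepatoblasts divide symmetrically
   (P → P + P) at rate `rate_p`.
2. **Differentiation.** From the first instant the hepatoblast pool
   reaches `n_diff_threshold = 200`, every hepatoblast division becomes a
   differentiation event: the mother is replaced by a daughter pair drawn
   from the fate table (H+C with probability `p_hc`, C+C with `p_cc`,
   H+H with `p_hh`; the three probabilities sum to 1). The pool is
   therefore depleted by differentiation — each fate row lists exactly
   two products per division, so no hepatoblast survives its own
   differentiating division.
3. **Lineage growth.** Hepatocytes and BECs divide at `rate_h` and
   `rate_c`, maintaining their fate. The run stops at the first division
   that brings the population to `n_final = 3000` cells.

Division timing is an exact Gillespie draw: waiting times are exponential
with rate equal to the summed per-cell rates, and the divider is chosen
proportionally to its rate. Because all cells of a type share one rate,
the engine draws the type first (probability ∝ count × rate) and then a
uniform cell of that type — identical in law, O(1) per event. Rates are
per arbitrary time unit with 10 a.u. = 24 h; the default `1/10`
corresponds to a 24-hour cycle, and the slowed BEC rate `1/15` to a
36-hour cycle. There is no cell death in the model.

Six presets span the hypotheses of interest: fully bipotent pools
(models 1–2), a 50/50 bipotent/unipotent mix (model 3), and mixes
dominated by hepatocyte-producing unipotent hepatoblasts with (models
4–5) or without (model 6) a small BEC-restricted class; models 2 and 5
additionally slow BEC division to 1/15.

**Ensemble statistic.** A model's reported ratio is the mean over
replicates (default 10) of the per-replicate final H/C. The number of
BEC founders produced at the differentiation threshold is binomial
(e.g. Binomial(200, 0.2) for model 6), so per-replicate ratios are
right-skewed and their mean sits a few percent above the mean-field
prediction — e.g. ≈ 9.5–10 against the deterministic 9.0 for model 6.
This convexity is a property of the ratio statistic, not a bias of the
engine; the mean-field oracle and the 3-standard-error agreement check
in the test suite pin the engine itself to the analytic expectation.
When a parameter set produces no BECs the ratio is reported as
undefined (NaN), never raised as an error.

## Mean-field oracle

In the deterministic limit the expected counts obey

    dP/dt = −rate_p·P
    dH/dt = rate_p·P·(p_hc + 2·p_hh) + rate_h·H
    dC/dt = rate_p·P·(p_hc + 2·p_cc) + rate_c·C

Phase 1 multiplies all counts equally and cannot move the final ratio,
so integration starts at the differentiation onset
(P = `n_diff_threshold`, H = C = 0) and stops when P + H + C first
reaches `n_final`, located by the integrator's event root-finding
(tolerances rtol 1e-10 / atol 1e-8, well below one cell). With equal
differentiated-cell rates the ratio is time-invariant once the pool is
exhausted and reduces to the closed form
`(p_hc + 2·p_hh) / (p_hc + 2·p_cc)`.

## Spatial modes

Fates never depend on position in this model, so the default
`well-mixed` mode tracks no coordinates. The `relaxed-3d` mode places
each daughter uniformly within `placement_radius` of its mother and
relaxes overlaps with an overdamped soft-sphere scheme: overlapping
pairs are pushed apart along the pair axis, near-contact pairs (up to
1.5× the minimum separation) feel a weak adhesion that keeps the
aggregate cohesive. Adhesion acts only during the first half of each
relaxation budget so the converged packing satisfies the hard-core
constraint; interim relaxations run every 25 events on a short budget
and a final full relaxation (tolerance 1% of the cell diameter)
finishes the packing. A full 3000-cell replicate takes well under a
minute on one core. The test suite verifies that final cell-type counts
are statistically indistinguishable between the two modes.

## Clone reconstruction

A clone is recovered per colour as a connected component of the graph
linking cells at pairwise distance ≤ radius (single-linkage transitive
closure; ties at exactly the radius are linked). Single linkage was
chosen because it is order-independent and deterministic; complete
linkage is available as an option for sensitivity analysis. Two preset
rulesets: 70 μm emulating manual assignment (maximum observed cell
movement of ~20 μm compounded with ~3.2-fold organ volume growth
between labelling and fixation), and 45 μm restricted to livers with
fewer than 40 labelled cells for the quantitative ruleset. A
colour-blind variant groups irrespective of colour and feeds the
misassignment estimate.

Fate classification: pure-hepatocyte / pure-BEC require all member
fates known and uniform; any proven co-occurrence of both fates is
mixed; otherwise the clone is unknown. Fate must be supplied in the
input — no morphological inference is attempted.

**Divisions from size.** Clone size k maps to `floor(log2 k)`
divisions: sizes between exact doublings are rounded down, so a 5-cell
clone counts 2 divisions. Note that under this rule a 33-cell clone
counts 5 divisions, although such a clone is sometimes described as six
doublings (2^5 = 32 < 33 ≤ 2^6); the round-down rule is applied
uniformly because it is the one the worked 5-cell example defines, and
rounding direction does not change the shape of the division
distribution.

## Clonality statistics

* **Colour-neighbour curves.** Every unordered within-liver pair is
  binned by 3D distance (default 5 μm bins; the bin width is not
  canonical and is configurable) and tallied as same- or
  different-colour. In each occupied bin P_same + P_diff = 1; empty
  bins are flagged NaN. Under sparse clonal labelling P_same ≈ 1 below
  the typical clone extent and falls to the colour-marginal Σ f_c²
  (0.25 for four equal colours) at large r; the crossover distance is
  reported as a clonality scale.
* **Clone-size scaling law.** The null model is the one-parameter
  exponential `P(k) = exp(−k/⟨k⟩)` with ⟨k⟩ the sample mean. The
  empirical curve is the strict tail P(K > k) evaluated on the integer
  support: for a discrete size law the strict tail is the quantity
  whose logarithm is exactly linear in k (the inclusive tail is pinned
  to 1 at k = 1 and cannot follow a pure exponential), so it is the
  faithful finite-size analogue of the continuum scaling law. The
  goodness-of-fit output is the maximum absolute deviation between the
  two curves plus a plot-ready semi-log table; no binary verdict is
  issued.
* **Division-number law.** The null model is Poisson with λ = kT equal
  to the mean number of divisions. The fit reports a chi-square
  statistic on the observed support with sparse tail categories pooled
  to a minimum expected count of 5 and one degree of freedom spent on
  the estimated λ.
* **Misassignment.** If colour-blind grouping mixes colours in a
  fraction x of groups, then with four equiprobable colours a merge
  between two clones goes unseen (same colour) one time in three for
  every two visible times, so the same-colour merge rate is estimated
  as x/3.
* **Liver subsets.** Nested cohort subsets keep livers with fewer than
  10 / 40 / 50 / 100 labelled cells (configurable); clonality
  diagnostics sharpen as labelling density falls.

## Synthetic labelled-liver generator

The generator produces cohorts with the statistical structure the
analysis assumes, with full ground truth, so every pipeline stage is
testable without imaging data.

* **Induction.** Labelled founders per liver follow a two-component
  mixture: 1 + Poisson(4) with probability 0.89 and 1 + Poisson(30)
  with probability 0.11. Only two calibration quantiles are treated as
  constraints — about half the livers below 30 labelled cells and
  about 10% above 100 — and this mixture meets both (median ≈ 23,
  9.9% above 100 over twenty 97-liver cohorts); the mixture form
  itself is a convenience, not a claim about induction biology.
* **Clone growth.** Each founder grows by a pure-birth (Yule) process
  at rate ln⟨k⟩ over a unit window, so sizes are geometric with mean
  ⟨k⟩ (default 4.5) — the discrete distribution with an exactly
  exponential tail — and the division count along the founder's own
  lineage is exactly Poisson(ln⟨k⟩). Ground truth records both this
  lineage count (the quantity the Poisson null concerns: divisions of
  one cell line in a fixed window) and the clone's total realised
  divisions (k − 1).
* **Fates.** Each clone is pure-hepatocyte / mixed / pure-BEC with
  probabilities (0.888, 0.107, 0.005). A mixed clone must contain both
  fates, so its size is resampled until k ≥ 2 (acceptance ≈ 0.78;
  this nudges the overall mean size up by ~2%); its BEC count is
  uniform on {1, …, k−1}, reflecting the observed variability of mixed
  compositions without asserting a law.
* **Space.** The organ is an axis-aligned ellipsoid, default semi-axes
  (110, 80, 60) μm — a realistic embryonic-liver envelope consistent
  with ~3000 cells at nuclear packing density. Founders are uniform in
  the pre-expansion ellipsoid; each daughter lands uniformly within
  the dispersal radius (default 10 μm, adjacent placement) of its
  mother; a jitter term (default 5 μm) emulates residual nuclear
  movement; all positions are scaled by the linear expansion factor
  3.2^(1/3) (3.2-fold volume growth over the tracing window) and
  clamped just inside the surface, so spatial-statistics preconditions
  hold by construction. An optional minimum founder separation (with
  rejection sampling and an explicit error when the geometry cannot
  host the density) builds separation-guaranteed cohorts for exact
  ground-truth recovery tests.

**What the generator does not emulate:** spectral bleed-through,
segmentation and localisation error beyond the jitter knob, anisotropic
z-resolution, directed tissue flows, and any specific clone-merging law
at dense labelling (founder density is the control knob instead).
Passing tests therefore validate the statistical machinery and its
self-consistency, not the imaging pipeline upstream of real data.

## Spatial statistics

Point-to-ellipsoid distance solves the projection equation for the
Lagrange parameter by bracketed root finding (xtol 1e-10), with closed
forms for the centre and the on-axis degenerate cases; mesh surfaces
use exact point-to-triangle minimisation. The marked-vs-rest surface
comparison retains the two-tailed two-sample t test for fidelity with
common practice, with a rank-sum alternative offered because distance
distributions are typically skewed; Cohen's d is reported as effect
size. Nearest-neighbour queries use a KD-tree and exclude self-matches
when the query and reference sets coincide.

## Problem sizes and reproducibility

All stochastic outputs derive from a single master seed via spawned
substreams, so every table is byte-reproducible. Default analysis
sizes — 10 replicates per fate model, 1000-clone cohorts for the
scaling-law checks, twenty 97-liver cohorts for induction calibration —
are the package's reference conditions and run in seconds to a few
minutes on one core.

## Known limitations

* The relaxed-3D mechanics are a generic soft-sphere scheme; no
  attempt is made to calibrate forces to real tissue rheology, and the
  spatial mode exists to demonstrate fate/position independence, not to
  predict morphology.
* The exponential-law fit with ⟨k⟩ = sample mean leaves a small
  systematic gap (≈ 0.045 in tail deviation at ⟨k⟩ = 4.5) between a
  geometric size law and the continuum exponential; at a few hundred
  clones sampling noise is of the same order, so the deviation
  statistic should be read quantitatively, not as a sharp test.
* The misassignment estimate x/3 assumes four equifrequent colours and
  pairwise merges; it degrades at high labelling density where groups
  span more than two true clones.
* Fate classification requires supplied fates; clones containing
  unknowns are never counted as pure.
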