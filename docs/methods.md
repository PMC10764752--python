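# Methods

`fconn` implements a whole-brain resting-state functional-connectome group
analysis of the kind used to compare early Parkinson's disease subgroups
(patients with and without probable REM-sleep-behaviour disorder, plus
healthy controls): subject-level weighted graph topology over a density
sweep, covariate-adjusted group inference with FDR, the network-based
statistic (NBS), and large-scale within/between-network functional
connectivity. Because such clinical datasets are not redistributable, the
package ships a synthetic cohort generator that reproduces the statistical
structure the analyses assume, so every stage is tested end to end on data
generated at run time.

## Connectivity and graphs

Functional connectivity between two ROIs is the Pearson correlation of
their preprocessed BOLD time series, Fisher r-to-z transformed
(z = atanh r). r is clipped to |r| ≤ 1 − 1e−7 first so duplicated signals
give a large finite z rather than infinity; the diagonal is zero. The
package consumes ROI-level time series; voxel-level preprocessing (motion
correction, nuisance regression, normalisation, filtering) is upstream and
out of scope.

Graphs are built by proportional (density) thresholding: at density d the
round(d · n(n−1)/2) strongest positive edges are kept **with their
weights** (half-even rounding; ties at the cutoff broken lexicographically
by (i, j) so results are bit-reproducible). Negative z values are discarded
before thresholding — shortest-path lengths are undefined for negative
weights and this matches common connectome practice; `negative_edges:
absolute` folds them in by magnitude instead. The default sweep is
10%–34% in 1% steps (25 graphs), generated by integer stepping to avoid
floating-point drift; edge sets are nested across the sweep.

## Topological measures

All measures are weighted. Conventions:

* **Weight → length.** Shortest paths use l_ij = 1/w_ij.
* **Normalisation.** By default all weights are divided by the graph
  maximum before metric computation (`normalize_weights: max`), which
  bounds efficiency and clustering in [0, 1] even though Fisher-z weights
  can exceed 1. `none` disables this. Assortativity, modularity and
  betweenness are scale-invariant either way.
* **Degree vs strength.** Denominators of the form k(k−1) use the binary
  neighbour count (the formulas are not otherwise well defined); the
  reported nodal "degree" is the weighted strength Σ_j w_ij. Both are
  computed and labelled distinctly.

Global measures at each density: global efficiency E_glob (mean inverse
shortest distance, 1/∞ := 0), local efficiency E_loc (mean over nodes of
the neighbourhood-subgraph efficiency with cube-root weighting
(w_ij w_ih / d_jh(N_i))^{1/3} / k_i(k_i−1); defined as the mean over nodes —
a leading constant of 1/2 would make the quantity grow with n), weighted
assortativity r^w (weight-weighted Pearson correlation of end-point
strengths over links; a zero-variance denominator, e.g. regular graphs,
raises an explicit undefined-value error), modularity Q (Newman weighted
modularity of the best partition found by seeded Louvain with 20 restarts;
Q itself is evaluated by the package's own formula, and the restart count is
a tunable — small graphs may need more restarts to reach the global
optimum), characteristic path length L_p (mean shortest distance over
**reachable** ordered pairs, with the unreachable count reported alongside)
and clustering C_p (mean of C_i = 2t_i/k_i(k_i−1) with triangle intensity
t_i = ½ Σ (w_ij w_ih w_jh)^{1/3}).

Nodal measures: strength, betweenness (Brandes accumulation on 1/w lengths,
normalised by (n−1)(n−2) over ordered pairs, so b_i ∈ [0,1]), nodal
efficiency and nodal clustering.

Each metric's curve over the sweep is aggregated by its **AUC** with the
rectangle rule (Σ value · step — the convention of the common neuroimaging
toolboxes; trapezoid available behind a flag). A single-point curve uses
the default 0.01 step.

Note that E_glob and 1/L_p are closely related but not identical statistics
(harmonic versus inverse-arithmetic mean of distances): they rank subjects
almost, not exactly, identically.

## Group inference

AUC values are compared between groups with an ordinary-least-squares GLM:
intercept, a 0/1 group contrast (the second-named group of
`GROUPA-vs-GROUPB` is the reference) and nuisance covariates age, sex,
education and mean frame-wise displacement. Nodal families are corrected by
Benjamini–Hochberg FDR (Benjamini–Yekutieli behind a flag). Three effect
sizes are always reported, because values labelled "Cohen's d" in this
literature frequently track t²/df rather than the classical definition:
classical d = t·√(1/n₁+1/n₂), partial η² = t²/(t²+df), and Cohen's
f² = t²/df (for correlations, f² = r²/(1−r²)). Identical groups (zero
residual variance) give t = 0 by convention.

Clinical correlations are partial Pearson correlations of the
covariate-residualised metric and score (df = n − n_cov − 2), computed
pairwise-complete with the n used reported, FDR across the whole screen.

## Network-based statistic

Every ROI pair gets the same GLM; edges with two-tailed p below the primary
threshold (default 0.001) and the tested sign form a graph whose connected
components (union-find) are the candidate effects. Significance comes from
permutation: the null distribution of the **maximum component edge count**
over `n_perm` (default 5000) Freedman–Lane permutations — residuals of the
nuisance-only model are row-permuted, the nuisance fit added back, and the
full model re-fit — with component p = (1 + #{null max ≥ observed})/(n_perm
+ 1), so p is never exactly zero. Naive row permutation is available
(`permutation: labels`); with zero-effect covariates the two schemes agree.
Decreases and increases are tested as separate one-sided families at the
two-tailed primary threshold. The component-size statistic is edge count
("extent"); intensity is deliberately not the default.

A note on calibration at reduced scale: the max-component statistic is
integer-valued, and its discreteness depends on the expected number of
suprathreshold edges (≈ p_primary × n_edges). At the full 160-node scale
this is ≈ 12.7; on a 60-node test family the same p_primary leaves ≈ 1.8
expected edges and the permutation test, while still valid, becomes
strongly conservative (achievable p-values jump past 0.05). Calibration
simulations therefore scale the primary threshold to hold the expected
suprathreshold edge count (p ≈ 0.0072 at 60 nodes) so that the null
family-wise error rate is interpretable against the nominal 0.05.

## Large-scale network FC

The eight-network parcellation (VN, SMN, DAN, VAN, SCN, FPN, DMN, CBN)
defines 8 within-network and 28 between-network blocks. Block means are
taken on the **unthresholded** Fisher-z matrix (they are independent of the
density sweep), giving 36 values per subject, contrasted with the same GLM
and BH-FDR across the family at q = 0.05. A single-node network has no
within pair; its value is NaN and is excluded from the family with a
warning, never silently zeroed. The printed corrected threshold of .005
seen in some reports is treated as an alternative fixed-threshold flag, not
the default.

## Synthetic cohort generator

Each subject's T×N time series is a zero-mean multivariate normal draw
(Cholesky) from a group-specific correlation matrix with two-level block
structure: `rho_within` (default 0.35) inside network blocks, `rho_between`
(default 0.10) across, unit diagonal, positive definite (diagonal loading
applied and logged if a configuration requires it). Group effects are
additive correlation reductions on whole network-block pairs
(`effect_map`), mirroring block-level rather than edge-level findings. The
defaults encode the study layout the generator emulates: group sizes
(36, 57, 71), T = 166 at TR = 2 s, posterior-network reductions
(SMN/VN/DMN within-blocks −0.08, their between-blocks −0.05) in patients
with probable RBD and frontoparietal/ventral-attention reductions
(−0.06/−0.04) in patients without. No effect-size estimates on the
correlation scale exist for the real contrasts, so these deltas are chosen
for testability, not biological fidelity: large enough that planted-effect
recovery tests have power at reduced scale, small enough that global
topology contrasts remain weak — consistent with the small published
effect sizes (f² ≈ 0.05–0.11). At the reduced demo scale the global
E_glob contrast is genuinely underpowered and its t statistic is noise;
the planted block-FC contrasts are strongly detected.

Covariates and clinical scores are drawn per group from truncated normals
whose moments follow the emulated study's demographics table (age ≈ 58–61
± 7–9 years, ≈ 45–53% male, education ≈ 9–12 years, mean FD ≤ 0.2 mm
post-QC, MoCA medians ordered PD+pRBD < PD−pRBD ≈ HC). RBDQ-HK totals and
subscales are truncated to the questionnaire's classification regions
(total ≥ 19 and subscale ≥ 8 for pRBD-positive; both strictly below
otherwise), so the classification rule recovers the generated labels
exactly.

Seeding: one master seed spawns per-subject generators via
`SeedSequence(entropy=seed, spawn_key=(group_index, subject_index))`, so
enlarging a cohort never changes existing subjects and everything is
bit-reproducible.

What the generator does **not** model: hemodynamics, temporal
autocorrelation (an optional AR(1) coefficient exists, default off — the
analyses under test operate on sample correlations, where serial
correlation mainly widens subject-level sampling variance), scanner drift,
motion artefacts at the image level, atrophy, and spatially structured
noise. Passing tests therefore demonstrate correctness of the analysis
chain under its own statistical assumptions, not robustness to real
acquisition artefacts.

## QC and group assignment

Subjects are excluded when maximum translation exceeds 2 mm, maximum
rotation exceeds 2°, mean frame-wise displacement exceeds 0.2 mm, or brain
coverage falls below 90% of the group mask — strict inequalities, so
boundary values are retained. FD is consumed as a precomputed column
(re-deriving it from realignment parameters is preprocessing territory).
The probable-RBD rule: positive iff RBDQ-HK total ≥ 19 **and** subscale
≥ 8; negative iff both strictly below; mixed quadrants are excluded.

## Numerical choices and degenerate inputs

* Correlation clip 1 − 1e−7 before atanh (z ≈ 8.4 ceiling).
* Density grid by integer stepping; AUC requires a uniform grid and errors
  on unequal spacing.
* Fewer positive edges than a density requests: all are kept, a warning
  logs the achieved density.
* Disconnected graphs: E_glob uses 1/∞ := 0; L_p averages reachable pairs.
* Zero residual variance in the GLM: t = 0 when the contrast estimate is
  also zero (identical groups), ±∞ otherwise.
* All stochastic steps (cohort draws, Louvain restarts, permutations) are
  seeded; pipeline outputs carry no timestamps, and a provenance file
  (config hash, seed, package versions) makes `all` runs byte-identical
  under a fixed seed.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at reduced scale, chosen as the smallest sizes
at which each property is informative: metric-oracle batteries on graphs of
n ≤ 12 (exhaustive modularity search on n ≤ 7); NBS calibration on 200 null
cohorts of 60 nodes and 20 subjects/group with 500 permutations; planted
30-edge block recovery at the same size with 1000 permutations; parameter
recovery with 60 subjects, T = 166, 40 nodes; end-to-end determinism on a
20-node, 13-subject cohort. The full-scale configuration (160 nodes,
164 subjects, 5000 permutations) is the package default for real use.

## Known limitations

* Louvain is a heuristic; Q is a lower bound on the optimal modularity and
  restart-dependent on hard instances.
* Betweenness path counting relies on floating-point equality of path
  lengths; exact ties between distinct paths (measure-zero for continuous
  weights) could split counts differently across implementations.
* The generator's block-constant effects are idealised; real FC differences
  are spatially heterogeneous within blocks.
* Partial-correlation p-values assume bivariate normality of the
  residualised variables.
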