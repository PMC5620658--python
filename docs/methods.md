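# Methods

This note records the model as implemented, the parameterizations that
matter, the numerical choices, what the synthetic generators do and do not
emulate, and the known limitations.

## Model

All geometry lives in the reproducing kernel Hilbert space of a Gaussian
kernel k(x,y) = exp(−‖x−y‖²/2σ²), in which every point has unit norm
(k(x,x) = 1) and squared distances are bounded by 2. Both classes are
described by enclosing hyperspheres expressed entirely through kernel
evaluations.

**Weighted patient sphere.** The dual

min β′Kβ − β′diag(K), 0 ≤ β_i ≤ C_i, Σβ_i = 1

is a box-constrained minimum-enclosing-ball problem. The per-sample caps
C_i = (C1_i + C2_i)/2 encode two anomaly signals computed before the fit:

- C1_i = exp(2 k(x_i, x_inear) − 2) ∈ (e⁻², 1], where x_inear is the
  nearest same-class neighbor in kernel (equivalently Euclidean) distance —
  isolated records get small caps;
- C2_i = exp(−|OTHER_i| / max(|OWN_i|, 1)) ∈ (0, 1] over the k_nn = 5
  nearest neighbors among all other training points of both classes —
  records living among the other class get small caps. The max(·,1) guard
  covers neighborhoods with no own-class member, preserving the
  "more other-class neighbors → smaller cap" ordering.

A point whose multiplier reaches its cap with positive slack lies outside
the sphere; those points form OsetP, the model's outlier/overlap set. Its
mean squared distance to the center is P². The radius R² is the mean
squared distance of the *free* support vectors (0 < β_i < C_i); if no free
support vector exists, the maximum over β_i > 0 is used. When the caps sum
to less than 1 the simplex constraint is infeasible and the caps are
rescaled by (1+10⁻⁶)/ΣC with a warning — a minimal perturbation that
preserves their ratios.

**Shifted kernel.** The health model works in coordinates translated so
the patient center a = Σβ_iφ(x_i) is the origin:
k′(x,y) = k(x,y) − Σβ_ik(x_i,x) − Σβ_ik(x_i,y) + Σβ_iβ_jk(x_i,x_j).
Because the translation cancels in differences,
k′(x,x) + k′(y,y) − 2k′(x,y) = 2 − 2k(x,y) exactly; this identity is the
main correctness oracle for the implementation. k′(x,x) = ‖φ(x)−a‖² is
clamped at 0 before use under square roots (floating-point cancellation
near the center).

**Furthest health sphere.** The dual

min γ′K′γ/(1−η) − γ′diag(K′), 0 ≤ γ_i ≤ C, Σγ_i = 1

encloses the health class while rewarding distance of its center
b = Σγ_iφ′(x_i)/(1−η) from the mapped patient center. From stationarity,
‖b‖² = γ′K′γ/(1−η)² and the squared distance of point j to b is
K′_jj − 2(K′γ)_j/(1−η) + ‖b‖²; Z², OsetH and H² follow exactly as for the
patient sphere.

**Balance coefficient η = 1/(1+s).** s measures the health class's
feature-space scatter. Two computations are provided:

- `pairwise` (default): s = mean over i≠j of ‖φ′(x_i)−φ′(x_j)‖²
  = 2 − 2k(x_i,x_j) ≥ 0. This matches the quantity's meaning — an average
  intra-class distance — and keeps η ∈ (0,1).
- `literal`: s = mean over all ordered pairs, including i=j, of
  2 − 2k′(x_i,x_j). Because the shifted diagonal k′(x,x) exceeds 1
  whenever the health class sits far from the patient center, this form
  can go negative, driving η into its clamp at 1−10⁻⁶ and inflating
  ‖b‖² ∝ 1/(1−η)² by many orders of magnitude, at which point the health
  membership saturates to a constant for every query. It is retained
  behind the `eta_mode` flag for comparison but is not the default.

η is clamped to [10⁻⁶, 1−10⁻⁶] in both modes.

**Health cap C.** A fixed cap interacts badly with class size: with
Σγ = 1, only about 1/C points can carry weight, so for large classes the
dual concentrates on the handful of points farthest from the patient
center and the geometry degenerates. The default is therefore the
ν-style rule C = 1/(0.3·N_h) — support spread over roughly 30% of the
class regardless of its size — with an explicit float accepted wherever a
tuned value is wanted. The cross-validation grid tunes explicit caps
(0.1, 0.2, 0.5), suited to the small training subsets it operates on.

**Labeling.** G_p(Q) = exp(−d²_a(Q)/(R²+P²)) and
G_h(Q) = exp(−d²_b(Q)/(Z²+H²)); empty outlier sets give P² = 0 (resp.
H² = 0), so the memberships degrade gracefully to plain radius scaling.
With ε_Q = 0.10·max(G_p, G_h) (configurable fraction), a query whose
memberships differ by more than ε_Q takes the larger one; otherwise the
most analogous member of OsetP ∪ OsetH donates its label. Similarity is
the feature-space cosine: for OsetP members the raw kernel k(Q,x) (unit
diagonals make it a cosine already); for OsetH members
k′(Q,x)/√(k′(Q,Q)k′(x,x)), with candidates at the mapped origin
(k′(x,x) ≈ 0) skipped since they subtend no angle. A `raw` mode
ranks raw k/k′ values instead. Ties prefer the patient class — the
conservative choice in a diagnosis setting — then the lowest training
index. If both outlier sets are empty the decision falls back to the
larger membership, still flagged as a tie-break.

## QP solver

Both duals share one deterministic most-violating-pair SMO solver: each
iteration moves mass between the coordinate with the smallest gradient
that can still grow and the largest that can still shrink, with the exact
line-search step clipped to the box. Convergence is declared at a gradient
gap of 10⁻⁹; the gradient is refreshed from scratch every 2000 iterations
to bound float drift. Correctness is judged by the KKT residual (≤ 10⁻⁶
on every fitted model, typically ~10⁻¹⁰) and, on problems with up to four
points, by dense enumeration of the feasible simplex at step 10⁻³.
Support-vector classification uses the absolute tolerance
τ = 10⁻⁷·max(1, max C).

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| σ (width) | median pairwise distance of the pooled training data | Gaussian kernel scale |
| health C | 1/(0.3·N_h) | slack cap of the health dual |
| k_nn | 5 | neighborhood size of the overlap penalty C2 |
| ε fraction | 0.10 | rejection band as a fraction of the larger membership |
| tie-break | cosine_normalized | similarity ranking of outlier-set members |
| η mode | pairwise | scatter formula behind the balance coefficient |

The method is markedly width-sensitive: the balance coefficient, both
radii and the membership contrast all depend on how the kernel resolves
the two classes' scales, and no single width serves every dataset size and
geometry. The evaluation protocol therefore selects σ and the health cap
by stratified 10-fold cross-validation inside each training subset
(`grid_search_cv`, grid σ ∈ {0.25, 0.5, 1, 2}, C ∈ {0.1, 0.2, 0.5}).
Accuracy ties in the grid — the norm on easily separable data — resolve
toward the configuration with the largest mean membership gap |G_p − G_h|
on the held-out folds, i.e. the most decisive model, then toward the
smallest width and cap. Analyses of within-class outlier structure
(planted-outlier recovery) instead fix σ = 1.0, the patient-class
standard deviation, because that structure lives at the within-class
scale; the median-distance default on a well-separated two-class scene is
dominated by the between-class gap and smooths it away.

## Synthetic data

All generators are pure functions of their parameters and a seed.

- **XOR** (`make_xor`): four unit-covariance·0.3² Gaussian clusters at
  (±1, ±1); the patient class occupies the (+,+) and (−,−) quadrants. A
  multimodal, non-linearly-separable planar benchmark.
- **Crossing lines** (`make_crossing_lines`): two segments through the
  origin at ±45°, positions uniform on [−1, 1], Gaussian perpendicular
  noise 0.03, 150 points per line. Near the crossing the classes overlap
  irreducibly; the defaults were calibrated so that a 3-nearest-neighbor
  reference attains ≈ 0.95 under the 20%-train holdout, the difficulty
  band typical of published results on this layout.
- **Anomalous blobs** (`make_blobs_with_outliers`): a unit-sd patient
  blob at the origin (optionally a mixture of lobes at radius 2.5 for a
  genuinely diverse patient class), an sd-0.5 health blob at distance 6,
  plus two kinds of planted patient-label anomalies: *overlap* points
  drawn from the health blob itself, and *far outliers* — rare
  (2.5% of the class), mutually dispersed points placed 6–8 health-sd
  around the health cloud on the arc facing away from the patient blob,
  at least 5 patient-sd from the patient center. This placement reflects
  the clinical premise the method targets: non-classical patient records
  resemble healthy subjects rather than drifting into empty feature
  space. It is also what makes the weighting mechanism identifiable: a
  far point's cap is at least C1/2, and its dual weight cannot exceed
  its share of the simplex, so only isolated points with other-class
  neighborhoods (small C1 *and* small C2) can be driven to their bound —
  an intrinsic property of the cap formulas, not of this implementation.
- **Synthetic beats** (`make_synthetic_beats`): per beat, Gaussian bumps
  for P/QRS/T on a unit-time grid with ~10% per-beat parameter jitter and
  additive noise; the patient class has a taller, broader P bump
  (amplitude 0.30 / width 0.05 vs. 0.15 / 0.03) — the P-wave morphology
  change characteristic of atrial hypertrophy — and an `atypical_frac` of
  beats swap class morphology to emulate records without classical
  symptoms. The class signal occupies only the few P-wave dimensions of
  the 50-dim vector, so classification accuracy on this fixture sits well
  below the planar benchmarks — as it does on real multi-beat recordings.

What the generators do *not* emulate: correlated beat-to-beat dynamics,
baseline wander and electrode artifacts, inter-patient variability
structure, label noise, and the unquantified outlier/overlap rates of
clinical archives. Passing the suite shows the machinery behaves as
designed under the stated statistical structure; it does not certify
clinical performance.

## Evaluation protocol

Accuracy is (TP+TN)/(TP+TN+FP+FN). The holdout protocol draws a
stratified random 20% of each class for training (at least 2 per class)
and tests the remainder, over 10 runs; mean and sample standard deviation
are reported, with per-run CV tuning as above. The imbalance designs
T1–T8 train on fixed per-class counts (5/20 … 5/35 patient-starved;
30/5 … 75/5 health-starved) and test the remainder. Classifier comparison
uses the Iman–Davenport form of the Friedman rank test,
F_F = (N−1)χ²_F/(N(k−1)−χ²_F) against F(α; k−1, (k−1)(N−1)) — for k = 6
classifiers over N = 10 runs at α = 0.05 the critical value is 2.422 —
and an exact two-sided Wilcoxon signed-rank test whose null distribution
is built by convolution over integer-doubled ranks (equivalent to full
2ⁿ enumeration; zeros dropped, mean ranks for ties, n ≤ 25).

Problem sizes in the shipped analyses — 80–160-point planar fixtures, a
150/100 blob scene for the imbalance designs, 10 holdout runs — were
chosen as the smallest at which the studied effects are stable across
seeds.

## Known limitations

- The membership contrast degrades when the kernel width is large
  relative to the health class's scatter (η → 1 inflates ‖b‖² and
  flattens G_h) or small relative to the patient class's extent (RBF
  distances saturate and G_p loses resolution). Cross-validated width
  selection is part of the method, not an optional refinement.
- The outlier set OsetP is only populated when the cap formulas can bind,
  which requires anomalies to be both isolated within their class and
  embedded near the other class; a lone far cluster of same-class points
  will be enclosed instead.
- The exact Wilcoxon test is limited to 25 non-zero differences; beyond
  that a large-sample approximation (not shipped) is the standard tool.
- Binary labels only; multi-class extension and probability calibration
  are out of scope.
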