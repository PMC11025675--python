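# Methods

## Connectivity model

Each subject contributes a T×P matrix of regional mean BOLD-like time
series (default T = 239 retained volumes at TR = 2 s, P = 90 regions).
Low-order functional connectivity (LOFC) is the P×P Pearson correlation
matrix of those columns. Before the second correlation round all LOFC
values are Fisher-transformed, z = arctanh(r), so the profile entries are
variance-stabilised and approximately normal; values with |r| above
0.999999 are clipped first and the clip count logged. High-order
functional connectivity (HOFC) correlates the z-profiles of region pairs:
entry (i, j) is the Pearson correlation of rows z_i· and z_j· with
entries i and j removed from both rows. Dropping both indices avoids the
mechanical inflation that the z_ii/z_jj and z_ij entries would introduce;
keeping the full rows is available via `exclude_pair="none"`. A variant
that dropped only each row's own diagonal entry would leave the two
profiles indexed over different region sets and is therefore not offered.
The exclusion is evaluated in closed form (row sums and the full Gram
matrix corrected for the two excluded terms), which is exactly equivalent
to the loop-wise definition and what the test oracle checks it against.
Diagonals are stored as 0 for every matrix kind — arctanh(1) is infinite,
and the graph stages ignore self-loops anyway. Negative correlations are
kept (the transform preserves sign); the alternative of zeroing negative
LOFC values before the second round changes HOFC only slightly at these
connectivity levels and is not implemented.

## Temporal preprocessing

The ROI-level pipeline is drop → detrend → band-pass → nuisance
regression: the first 5 volumes are discarded, a least-squares line is
removed per region, a zero-phase band-pass keeps 0.01–0.08 Hz, and each
region is residualised on [1, nuisance] by ordinary least squares
(rank-deficient nuisance sets — common with 24-parameter motion
expansions — fall back to the pseudo-inverse with a logged warning).
Nuisance regression can be moved before filtering with a switch. Two
band-pass realisations are provided: the default 4th-order Butterworth
applied forward–backward (`sosfiltfilt`; zero phase, so correlations are
not lag-distorted) and an ideal FFT ("brick-wall") passband. The
Butterworth response is only maximally flat, so refiltering attenuates
band-edge energy again: strict idempotence (re-filtering changes nothing)
holds exactly for the FFT realisation and only near the geometric band
centre for the Butterworth one; the tests check each realisation for the
property it can honour (≥ 20 dB stopband attenuation for both, exact
idempotence for FFT, centre-frequency near-idempotence for Butterworth).

## Graph construction and metrics

A connectivity matrix is binarised by keeping the floor(S·P(P−1)/2)
strongest edges at sparsity S; by default only positive values are
eligible (standard for correlation networks; `edge_sign="absolute"` ranks
by magnitude instead). Ties at the cutoff are broken by value then
lexicographic edge index, so edge sets are reproducible. The grid is
S = 0.06–0.40 in steps of 0.01 (35 levels).

All group-level topology metrics use binary-graph definitions: C_p is the
mean local clustering coefficient (nodes of degree < 2 contribute 0), L_p
is the mean shortest-path length over connected ordered pairs (the
disconnected fraction is logged; E_glob, the mean of 1/d over all ordered
pairs with disconnected pairs contributing 0, captures fragmentation),
E_loc is the mean over nodes of the global efficiency of the subgraph
induced on each node's neighbours, B_c is unnormalised shortest-path
betweenness with fractional credit for tied geodesics, D_c is binary
degree, and N_e(i) is the mean of 1/d(i, j) over j ≠ i. The weighted
(Onnela) clustering coefficient is used only as the classification
feature. Small-world normalisation divides C_p and L_p by the means of a
degree-preserving null ensemble generated by double-edge swaps (10·E
attempted swaps per null, 100 nulls by default, seeded); γ = C_p/C_rand,
λ = L_p/L_rand, σ = γ/λ, with σ·λ = γ holding to machine precision by
construction. Each metric's profile over the sparsity grid is summarised
by its trapezoidal AUC, and group comparisons default to the AUC values
(per-sparsity comparisons remain available from the long-format table).

## Mesoscale structure

The shipped partition groups the 90 regions into five modules — SMN (20),
DMN (22), FPN (16), VN (14), SN (18), contiguous index blocks. It is a
deliberate approximation: published region-to-module tables for this
parcellation differ between sources, so the assignment is user-replaceable
(`partition.csv`). Modular strengths are means of the weighted,
unthresholded matrix over all region pairs of a block; single-region
modules report a missing intra strength. Rich-club nodes are the 10
top-ranked regions (10 of 90 is the conventional "top 12 %" count, kept
at exactly 10) by binary degree of the entrywise group-mean network
averaged across the sparsity grid, ties broken by region index and
logged; ranking by weighted strength of the unthresholded mean matrix is
available by flag. Rich sets are derived per group. Edges are classed
rich/feeder/local by endpoint membership, and group comparisons of class
strengths run on per-subject class means with each subject classified
against their group's rich set.

## Network-based statistic

Per edge, value ~ intercept + group + covariates is fitted by least
squares; the group coefficient's t (df = n − rank of design) and
two-sided p form the edgewise maps. Edges with p below the primary
threshold (default 0.001) and the requested sign form a graph whose
connected components are scored by edge count. The null distribution of
the maximal component size comes from permuting group labels (covariates
stay attached to their subjects — valid under exchangeability and the
simplest correct scheme) and re-running the identical pipeline; corrected
p values use +1 smoothing, (1 + #{null ≥ size})/(1 + n_perm), so the
smallest attainable value is 1/(n_perm + 1). Defaults are 1000
permutations and a corrected threshold of 0.01; both are configuration
values since reported practice also includes 0.05.

## Classification

Features are Onnela weighted local clustering coefficients of the
unthresholded positive-weight matrix, normalised by the matrix maximum:
c_i = Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i(k_i−1)). Evaluation is nested
leave-one-out: per fold, features are standardised on the training set,
the LASSO penalty is chosen by an inner shuffled 5-fold CV over a
50-point logarithmic alpha path spanning two decades below the null-model
alpha (a narrower span than the sklearn default, which wastes most of the
path on near-unregularised fits), nonzero-coefficient features feed a
linear SVM with C = 1 (the hyperparameter is deliberately not tuned), and
the held-out decision value is recorded. A fold where the LASSO selects
nothing falls back to all features, logged. Patient is the positive
class; ROC-AUC is the normalised Mann–Whitney rank statistic over the
pooled leave-one-out decision values with ties at half credit.

## Group statistics

Scalar measures are compared by the same covariate-adjusted least-squares
contrast (age, gender, education by default); nodal families are
Bonferroni-corrected with family size 90 per metric × network kind;
modular and rich-club strength comparisons are reported uncorrected, as
is conventional for those secondary contrasts. A Shapiro–Wilk screen can
route non-normal measures to a two-sided label-permutation test
(p = (1 + #{|t*| ≥ |t|})/(1 + n_perm)).

## Synthetic cohorts

The generator plants group structure at the level of stationary
cross-sectional correlation: within-module pairs get r_within (0.4),
between-module pairs r_between (0.1), and listed effects add a delta to
named blocks for one group — by default patients gain +0.12 on SMN–DMN
and DMN–VN and lose 0.12 within DMN, giving the modular and NBS stages a
known direction of effect. Deltas that push any entry out of (−1, 1) are
rejected naming the block. The target is projected to the nearest
positive-definite matrix by eigenvalue clamping at 1e-6 followed by
rescaling to unit diagonal, iterated because the rescaling can nudge the
spectrum back below the floor; the repair distance is logged. Time series
are stationary Gaussian AR(1) processes (lag-1 coefficient 0.3, a typical
BOLD-like smoothness at TR = 2 s) whose innovation covariance is scaled
by 1 − φ² so the marginal covariance equals the target exactly; the first
sample is drawn from the stationary law, so no burn-in is needed.
Covariates are drawn from group-specific normals (age 62.75 ± 7.15 vs
61.08 ± 3.93 years; education 10.93 ± 2.02 vs 10.78 ± 1.79 years;
per-ear hearing thresholds 33.10 ± 4.40 / 33.34 ± 5.96 vs 17.93 ± 5.84 /
17.40 ± 5.19 dB HL) and Bernoulli gender (26/60 vs 24/50 male),
independent of the planted connectivity effect by default; a
`confound_by_age` switch instead scales each patient's planted effect
with their age z-score, so the group difference is mediated by age and
should vanish under covariate adjustment — the probe for the adjustment
machinery. What the generator does **not** emulate: non-stationarity,
scanner drift and motion artifacts, spatial autocorrelation beyond the
module blocks, non-Gaussian BOLD amplitude distributions, and
heterogeneous per-subject connectivity in the unconfounded branch.
Passing calibration on these cohorts therefore demonstrates correctness
of the statistical machinery under its own assumptions, not robustness to
real-data artifacts.

## Calibration experiments and problem sizes

`hofcnet.evaluation` fixes the desk-scale experiment sizes: small-world
calibration uses 90-node Erdős–Rényi (S = 0.2) and Watts–Strogatz
(k = 10, rewiring 0.1) graphs with 20 nulls; NBS error control uses 40
global-null runs × 200 permutations at n = 30/30 (T = 120) and power uses
a planted 10-edge connected subnetwork at δ = 0.25 over 20 seeds;
classifier checks use separable clusters and 20 permuted-label repeats at
the full 60/50 size; modular sign recovery regenerates 20 full cohorts at
δ = 0.12. These sizes keep each experiment to minutes on a single core
while leaving the binomial noise on the measured rates well inside the
asserted margins.

## Numerical choices and degenerate inputs

Zero-variance time series are rejected naming the region (detected at
relative tolerance 1e-12). Constant HOFC profiles after exclusion yield 0
with a warning. Thresholding a matrix with fewer positive entries than
requested keeps what exists and logs the achieved sparsity. Edges with
zero residual variance in the NBS get p ∈ {0, 1} by effect sign, logged.
γ is reported missing when the null ensemble has zero mean clustering.
Metric AUCs require a complete, strictly increasing grid and name the
offending sparsity otherwise. All randomness flows through explicit
seeds: the pipeline fans a single run seed into per-stage child seeds via
`SeedSequence.spawn`, so stages can be re-run independently yet
reproducibly.

## Known limitations

Static connectivity only (no sliding-window dynamics); binary-graph
metric definitions except where the classification feature demands
weights; no community detection (the five-module partition is a fixed
template); no voxel-level preprocessing, motion exclusion or image I/O —
the pipeline begins at extracted ROI time series, and nuisance regressors
are supplied as columns, not derived from images.
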