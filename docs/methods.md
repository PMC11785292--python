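# Methods

## Problem and model

The package groups *sets* of functional observations by their
probability law. The motivating data are EEG epochs: each auditory
stimulus in a rhythmic sequence over the alphabet {0 = silent unit,
1 = weak beat, 2 = strong beat} triggers one epoch `Y_n`, a curve on
[-0.05, 0.4] s sampled at 500 Hz (226 points), and each epoch is keyed
by the three-symbol window `u = (X_{n-2}, X_{n-1}, X_n)` that ends at
its stimulus. Twelve windows have positive probability under the
stimulus chain; the scientific question is which windows produce epochs
with the same law `Q^u`, i.e. which partition of the 12 strings the
brain's response respects. The reference hypothesis is the strong-beat
partition `P*`, which groups strings by the position (or absence) of
the symbol 2:

    P* = {000,001,101,100}, {200,210}, {020,021,120,121}, {002,012}.

## Stimulus chain

Starting at `X_0 = 2`, the next symbol depends on the distance to the
most recent strong beat: one or three steps after it the symbol is 1
with probability 0.8 (else 0), two steps after it the symbol is 0, and
four steps after it the strong beat recurs. The strong beat is
therefore periodic with period 4 and is a renewal point. The simulator
exploits the resulting `2 a 0 b` block structure and draws the two
Bernoulli(0.8) slots per block with one PCG64 generator
(`numpy.random.default_rng`), consuming one variate per random slot in
index order; this is distributionally identical to the step-by-step
rule. Bit-level reproducibility is promised only within this
implementation; across implementations only equality in law holds.
The 12-string universe is enumerated deterministically from the phase
structure (positions mod 4), not by sampling; a simulation cross-check
lives in the tests.

## Projective dissimilarity

Two sets of curves `A`, `B` on the same grid are compared through `M`
independent Brownian bridges `B_1..B_M` on [t0, t1] (covariance
`(min(s,t)-t0)(t1-max(s,t))/(t1-t0)`, simulated by cumulative Gaussian
increments pinned by subtracting the linear interpolant of the endpoint
-- exact in distribution on the grid). Every curve is projected onto
every bridge by the left-Riemann inner product `sum_k Y(t_k) B(t_k) dt`
(the bridge vanishes at both ends, so left/right/trapezoid sums
coincide). For each bridge the two projection samples are compared
with the two-sample Kolmogorov-Smirnov statistic (right-continuous
ECDFs, ties counted with <=), and

    dhat(A, B) = (1/M) * #{ j : KS_j > delta(|A|, |B|) } ,

with the two-sided Smirnov critical value
`delta = sqrt(ln(2/alpha)/2 * (n+m)/(nm))` at level `alpha = 0.05`.
An alternative parse of this bound without the factor 1/2 is available
as `threshold_rule="loose"` for sensitivity analysis. When
`delta >= 1` (tiny samples) the test is powerless and a warning is
emitted. Within one projection the *same* bridge is applied to both
sets; by default every pair of sets receives a fresh, independent
bridge ensemble seeded deterministically from the root seed and the
pair indices (`shared_bridges=True` instead reuses one ensemble for all
pairs, which projects each set once and is markedly cheaper).

## Per-subject clustering and the gamma cut

The 12x12 matrix of `dhat` values is agglomerated with complete
linkage (maximum pairwise dissimilarity between clusters) and the tree
is cut by keeping every merge strictly below

    gamma = q / M,  q = min{ k : BinomialCDF(k; M, beta) >= nu } ,

with `beta = 0.05`, `nu = 0.95`; at `M = 5000` this gives
`gamma = 276/5000`. Under complete linkage this cut is the coarsest
partition in which every within-cluster pair has `dhat < gamma`.
Linkage is delegated to `scipy.cluster.hierarchy`; its deterministic
nearest-neighbour-chain tie-breaking is accepted as the tie rule (ties
have probability zero for the continuous dissimilarities used here).

## Consensus across subjects

With per-subject partitions `C_v`, `v = 1..|V|`, the consensus
co-clustering index of a string pair is
`eta(u, u') = S(S-1) / (|V|(|V|-1))` where `S` counts subjects
co-clustering the pair (the fraction of ordered pairs of distinct
subjects that agree on co-clustering). Although sometimes described as
a dissimilarity, `eta` is monotone in agreement, so the matrix fed to
the consensus Ward pass is `1 - eta`; this is the only
monotone-consistent reading. Ward linkage follows the Ward.D2
convention by default (the Lance-Williams recurrence on squared
entries, scipy's `ward`); the Ward.D variant (recurrence on raw
entries) is selectable and is implemented by feeding scipy the square
roots of the entries, which leaves the merge order -- and hence any
k-cluster cut -- identical to the classical recurrence. Both variants
were verified against R's `hclust` `ward.D`/`ward.D2` during
development. Cluster counts k = 2..5 are scored by a distance-based
Calinski-Harabasz pseudo-F (squared-dissimilarity decomposition:
`W = sum_c (1/n_c) sum_{i<j in c} d_ij^2`, `T = (1/n) sum_{i<j} d_ij^2`,
`CH = ((T-W)/(k-1)) / (W/(n-k))`), the mean silhouette width on the
dissimilarities, and the Dunn index; at most five clusters are
considered to avoid multiple singletons, and the criteria are reported,
not auto-selected.

## Significance

The null model draws a symmetric 12x12 matrix with i.i.d. Uniform(0,1)
upper-triangle entries (the diagonal is never read by linkage),
Ward-cuts it at `k` clusters and records the Hubert-Arabie adjusted
Rand index with the reference partition. The estimated p-value is the
fraction of replicates with `ARI(null, reference) >=
ARI(reference, observed)`; ties count as exceedances, and a `1e-12`
slack guards the comparison because the two ARIs come from different
code paths. For the degenerate contingency cases (both partitions all
singletons or both one block) the ARI is defined as 1, the
identical-partition value. The hot loop (10^5-10^6 Ward cuts) runs in
numba-compiled kernels implementing the Lance-Williams recurrence and
the ARI; the kernels are validated in the test suite against
`scipy.cluster.hierarchy` (identical partitions on random matrices) and
`sklearn.metrics.adjusted_rand_score`. The "expected classification"
count matches observed clusters to reference blocks one-to-one by
maximum-overlap Hungarian assignment.

A noteworthy arithmetic fact: the published right-prefrontal and
central-prefrontal consensus partitions have the *same* ARI with `P*`
(38/115 = 0.3304...), so their reported null probabilities (0.0174 and
0.018) estimate one and the same quantity. This package's estimates at
5x10^5 replicates are ~0.0170 (Ward.D2) and ~0.0175 (Ward.D), both
compatible with the published values at Monte-Carlo resolution.

## Synthetic cohort

The generator emulates the structural assumption the pipeline tests:
the law of an epoch depends only on the `P*` block of its string. Per
subject it simulates a chain, then emits per epoch

    Y_n = a_v * template_{P*(u_n)} + noise_n ,

with `a_v ~ Uniform(1 - 0.15, 1 + 0.15)` a subject amplitude factor,
four templates built from 2-3 Gaussian bumps with class-specific
latencies and amplitudes (2-6 units, an N1/P2-like morphology), and
stationary squared-exponential Gaussian noise with unit marginal
standard deviation and correlation length 0.015 s (bandwidth comparable
to 1-30 Hz band-passed EEG; sampled through a truncated
eigendecomposition of the kernel). With probability 0.02 an epoch is
replaced by a smooth drift of amplitude ~50 to exercise depth trimming.
Defaults: 19 subjects and 5000 chain steps per subject, at which the
rarest strings (chain frequency 0.01) contribute ~50 epochs -- the
smallest size at which the pairwise KS test retains any power.

What the generator does *not* emulate: electrode geometry and volume
conduction, non-stationary or subject-specific noise spectra,
latency jitter across trials, overlapping responses from the 450 ms
stimulus rate. Passing recovery tests therefore show that the pipeline
retrieves a class-conditional law structure when it exists; they do not
certify performance on real recordings.

## Preprocessing operations

Baseline correction subtracts from each curve its mean over a half-open
window (default the 50 ms before onset). Electrode-set averaging is
the row-wise pointwise mean of aligned channels. Outlier trimming
removes the `floor(0.10 * n)` curves with the lowest Fraiman-Muniz
depth, where the pointwise depth is the classical
`1 - |1/2 - F_t(y)|` with the right-continuous ECDF over the set at
each time; the floor rounding and the per-string-set (not pooled)
trimming are this package's choices, as is breaking depth ties by
keeping earlier rows.

## Numerical and design notes

- Binomial quantile: left-continuous inverse CDF (smallest k with
  CDF >= nu), which reproduces 276/5000 at the defaults.
- The batched KS statistic evaluates the ECDF gap only after all
  observations tied at a value are consumed; it agrees with
  `scipy.stats.ks_2samp` exactly, including tied data.
- Per-pair seeds derive from `SeedSequence([root, i, j])`; per-subject
  seeds from `SeedSequence([root, subject_index])`. One root seed makes
  every pipeline output reproducible byte for byte.
- The depth integration interval is the full epoch [-0.05, 0.4] s.

## Known limitations

The calibration of `gamma` as a Binomial(M, beta) quantile treats the
M per-bridge rejections as independent, but Brownian-bridge directions
are strongly mutually correlated (the bridge Karhunen-Loeve eigenvalues
decay like 1/k^2, giving mean squared cosine ~0.4 between two random
directions). Under equal laws `dhat` is therefore heavy-tailed: its
mean stays below `alpha` (the Smirnov bound is conservative), yet a
non-negligible fraction of equal-law set pairs -- roughly 15-25% at
n = m = 200, across noise smoothness choices -- exceeds `gamma`, and
per-subject partitions routinely split true classes. The consensus
stage absorbs this (splits are not systematic across subjects), which
is visible in the end-to-end tests: individual subjects rarely produce
`P*` exactly, while the 19-subject consensus recovers it almost always.
Interpreting a single subject's gamma-cut partition as a calibrated
simultaneous test would be unwarranted.

## Problem sizes used by the test suite

Unit tests run in seconds on small inputs. The statistical acceptance
checks use 10^5 null replicates per Ward variant for the significance
reproduction (the acceptance script uses 5x10^5), 100 equal-law
replicates at n = m = 200 with M = 2000 for the type-I study, and 100
full cohort replicates (19 subjects x 5000 steps, M = 64 shared
bridges) for end-to-end recovery.
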