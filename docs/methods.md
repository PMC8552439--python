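# Methods

This note defines the models implemented in `msmhdx`, their parameters and
defaults, the numerical choices behind them, and the limits of the synthetic
generator used for validation. Units are nanometres (distances), degrees
(angles), frames or picoseconds (times; `frame_interval` defaults to 10 ps).

## Featurization

`pairwise_ca_distances` computes all Cα–Cα Euclidean distances for the
selected residues, columns ordered lexicographically by (chain, resid) pair
(n(n−1)/2 features). No periodic minimum-image correction is applied; the
intended system is a single solvated monomer.

## Integrated VAC (IVAC)

Plain VAC/tICA solves C(τ) v = λ C(0) v at one lag τ. IVAC sums the
symmetrized lagged covariances over a lag range,

    C_int = Σ_{τ = lag_min}^{lag_max (step stride)}  ½ (C(τ) + C(τ)ᵀ),

and solves the generalized symmetric eigenproblem C_int v = λ C(0) v
(`scipy.linalg.eigh`). Eigenvalues are sorted descending; eigenvectors are
normalized to vᵀC(0)v = 1, so projected components are mutually
uncorrelated with unit variance. Lagged pairs never straddle trajectory
boundaries; a trajectory shorter than `lag_max` is rejected by name. For a
reversible two-state chain with indicator features the leading integrated
eigenvalue is exactly Σ λ₂^τ — this geometric-sum identity is used as a test
oracle.

Numerical choices: the mean is removed globally over all trajectories;
C(0) receives a ridge ε·tr(C0)/d with ε = 1e−10 only when its condition
number exceeds 1e12. A `stride` > 1 thins the lag schedule for long ranges
(cost grows linearly in the number of lags; accuracy is barely affected
because neighboring C(τ) are highly correlated).

`spectral_gap` returns the number of components before the largest
consecutive eigenvalue drop. `select_seeds` picks the lowest-density frames
in tIC space (Gaussian KDE, Scott's rule, deterministic subsampling above
`max_kde_samples` = 20 000 frames) with an optional minimum mutual
separation — the re-seeding step of the adaptive sampling loop
(`iterative_ivac_sampling`).

## Markov state model

Microstates come from k-means (k-means++ init, fixed seed, final labels
recomputed as nearest center so the nearest-center invariant holds exactly).
Transitions are counted with a sliding window at lag τ within each
trajectory. Two estimators:

* `symmetrized` (default): counts are replaced by (C + Cᵀ)/2 before row
  normalization. This enforces detailed balance, gives an exactly real
  spectrum (computed via the symmetric similarity transform
  D^{1/2} T D^{−1/2}), and makes the stationary vector available in closed
  form as row sums / total. PCCA requires this estimator.
* `naive`: raw row normalization; the stationary vector comes from the
  left eigenproblem. Useful for diagnosing irreversibility.

The model is restricted to the largest strongly connected component of the
count graph, chosen by total count weight (not state count); dropped states
are logged. Implied timescales are t_i = −τ / ln λ_{i+1}; eigenvalues ≥ 1
map to ∞ and ≤ 0 to NaN (no defined relaxation time).

Frame weights: frame in microstate s gets π_s / n_s (n_s = frames assigned
to s); frames outside the connected set get 0 (logged) and the weights are
renormalized to sum to 1. Averages over frames with these weights reproduce
equilibrium ("physically weighted") expectations.

Chapman–Kolmogorov: for each factor f the lag-τ model propagated f steps is
compared with a model re-estimated at lag fτ, after lumping microstates into
the macro sets; start states are weighted by the base model's π. The
standard error is a binomial estimate using the number of *non-overlapping*
windows at the long lag — conservative for the sliding-window estimator.

## PCCA

The m leading right eigenvectors map microstates into an (m−1)-simplex. The
inner-simplex algorithm selects m extreme rows as vertices, writes every
microstate as χ = Ψ · Ψ_vertices^{−1}, clips negative memberships and
renormalizes rows. Crisp labels are the argmax; clusters are relabeled by
descending population (ties by ascending original label). Equilibrium flux
F_AB = Σ_{i∈A, j∈B} π_i T_ij (zero diagonal, symmetric for reversible
models); fluxes ≥ 25 % of the maximum are flagged as highlighted edges.

## Hydrogen-bond counting

A backbone amide site is a protein residue with an N and exactly one amide
hydrogen (atom name `H` or `HN`; proline-like residues are simply not
sites). A bond is counted when the donor–acceptor distance
d(N, A) ≤ `distance_cutoff` **and** the angle at the donor N between N→H and
N→A is ≤ `angle_cutoff`; both comparisons are inclusive (the angle test uses
the cosine with 1e−12 slack), so cutoff-boundary behavior is deterministic.
Degenerate zero-length vectors count as aligned. Acceptors for HB_p are all
protein O and N atoms except the donor's own N and H; `include_self_residue`
(default true) controls whether the donor's own carbonyl/side-chain oxygens
are eligible. HB_w counts water oxygens under the same geometry. Defaults:
0.50 nm / 70°; the robustness grid is distances {0.35, 0.40, 0.50, 0.60} nm
× angles {40, 50, 70, 90}°. `angle_vertex="hydrogen"` switches to the
deviation-from-linearity convention at H (angle between N→H and H→A).

## Protection factors

With NH = min(HB_p, 1) and NW = min(HB_w, 1), the per-structure protection f
is

| model              | f                      | range                |
|--------------------|------------------------|----------------------|
| `park`             | b · NH                 | {0, b}               |
| `ratio`            | HB_p / max(HB_w, 1)    | ≥ 0, finite at HB_w=0|
| `difference`       | HB_p − HB_w            | integers             |
| `bound_difference` | NH − NW                | {−1, 0, 1}           |

All four are monotone: non-decreasing in HB_p, non-increasing in HB_w. The
Park base parameter b defaults to 500 (historically 1e4–1e6 has been used; b
only rescales the two-valued output).

Cluster values PF_ij are means of f over `n_sample` = 4000 frames resampled
from the cluster with probabilities proportional to the equilibrium frame
weights (with replacement when fewer positive-weight frames exist than
`n_sample`; logged). The sampling RNG is keyed by (seed, cluster label), so
results are deterministic and independent of which other clusters are
evaluated. The ensemble PF_i is the population-weighted average of PF_ij
over the included clusters — by default the five most populated — with the
included populations renormalized to 1.

`variable_sites` flags sites whose protection varies across clusters, by
either the variance-ratio criterion (population variance ≥ 10 × mean;
nonpositive-mean sites skipped and logged) or the coefficient of variation
(std/mean ≥ 0.10). Both criteria are provided because the variance-ratio is
scale-dependent (natural for the large-b Park model) while the CV is
scale-free.

`compare_experimental` matches sites by exact chain+residue label, requires
at least 3 shared sites, and reports the Pearson r, residuals, and unmatched
labels on both sides.

EX2 kinetics: in the two-state model (closed ↔ open, intrinsic exchange
k_int from the open state), PF = k_cl / k_op and k_obs = k_int / PF, valid
when k_cl ≥ 100 · k_int (`ex2_threshold`); violating the condition issues a
RuntimeWarning rather than an error.

## Structural annotation

Collective variables: backbone φ/ψ (IUPAC sign, (−180°, 180°], verified
against an independent implementation), per-frame α-helix content of a
residue range (residue i is helical when its carbonyl O accepts a bond from
the amide N–H of i+4 under 0.35 nm / 40° criteria; residues without an
evaluable i+4 partner are excluded from the denominator, which is therefore
constant across frames), minimum inter-selection distance, signed distance
from a three-anchor plane (sign fixed so a configured reference atom is
positive; near-collinear anchors are rejected), and presence of a specific
backbone hydrogen bond. Rules are data (YAML), composable with `all_of` /
`any_of` / `not`; a stand-in insulin rule set ships in
`msmhdx/data/insulin_rules.yaml`. Element percentages per cluster use the
equilibrium frame weights, with occupancy bands green (≥ 80 %), orange
(20–80 %) and low; the headline fraction is the weighted fraction of frames
showing at least one headline element.

## Synthetic generator: realism and limits

`generate_ensemble` draws a hidden discrete-state Markov chain (stationary
starts by default; per-trajectory pinned starts for adaptive-sampling
rounds) and emits frames as the current state's coordinate template plus iid
isotropic Gaussian noise. Templates place designed hydrogen-bond acceptors
0.30 nm from the donor at small angles (counted under *every* grid
criterion) and park unused acceptors several nm away; residues are spaced
1.5 nm apart so sites cannot contaminate each other under any grid cutoff;
per-state Cα displacements make states separable in feature space.

This generator is deliberately idealized: noise is iid per frame (no
intra-state dynamics, so the only slow modes are the hidden-chain ones),
geometry is not sterically realistic, and hydrogen-bond counts fluctuate
only through noise on a rigid designed geometry. That is exactly what makes
populations, timescales and per-site bond patterns analytically known — the
point is validation, not physical realism. Angle noise on the short
(0.1 nm) N–H lever arm means designed bonds are realized in a large
majority, not all, of noisy frames; statistical tests use modal or ranked
statistics accordingly.

Benchmarks: `benchmark_three_state` (three metastable states, analytic
populations ≈ 0.545/0.268/0.187, slowest analytic timescale ≈ 52 frames)
and `benchmark_protection` (two states with populations 0.7/0.3 enforced by
detailed balance, protected sites HB_p=2/HB_w=0 in the dominant state,
exposed sites HB_p=0/HB_w=2).

## Known limitations

* The symmetrized count estimator is a plain symmetrization, not a
  maximum-likelihood reversible estimator; for strongly non-equilibrium
  sampling its stationary vector is biased toward empirical occupancies.
* CK standard errors are conservative (non-overlapping-window counts).
* k-means and KDE seed selection are deterministic per seed but not
  invariant to frame ordering.
* The annotation rule set shipped as `insulin_rules.yaml` is a structural
  stand-in wired to the expected chain/residue labels; thresholds are
  placeholders to be calibrated against a real reference ensemble.
* `pf_ensemble` silently restricts to the five most populated clusters by
  default; pass `included_clusters` explicitly to override.
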