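# Methods

## The model

`ndfawm` works with weighted, undirected networks whose symmetric
adjacency matrix `A` is modelled by the degree-corrected
distribution-free model (DCDFM). Each node `i` carries a community label
`l_i ∈ {1..K}` and a positive heterogeneity factor `θ_i`; communities
interact through a symmetric K×K connectivity matrix `P` with entries in
[−1, 1], rank K, and max |P| = 1 (the overall scale lives in θ). Each
entry of `A` is an independent draw from some distribution family `F`
with mean

    E[A_ij] = Ω_ij = θ_i θ_j P[l_i, l_j].

Because `F` is arbitrary, edge weights may be binary (Bernoulli — the
DCSBM reduction), counts (Binomial, Poisson, Geometric), continuous
(Exponential, Normal, Laplace, Uniform) or signed (±1). Whether `P` may
carry negative entries depends on `F`: probability- and rate-based
families need `P ≥ 0` (or `> 0`), while Normal, Laplace and signed
networks admit negative blocks. `validate_spec` enforces these rules
entrywise on Ω.

## The estimator

Given `A` and a candidate bound `K0`, the estimator runs, for each
`k = 1..K0`:

1. **nDFA spectral clustering** — take the k eigenpairs of `A` with the
   largest |eigenvalue|, row-normalize the n×k eigenvector matrix, and
   k-means the rows into k clusters. Row normalization cancels θ, which
   is what makes the method degree-robust; magnitude (not algebraic)
   ordering is essential because signed, Normal and Laplace networks
   make `A` indefinite and informative eigenvalues can be negative.
2. **Weighted modularity** — split `A = A⁺ − A⁻` into positive and
   negative parts and compute

       Q(k) = (2m⁺ Q⁺ − 2m⁻ Q⁻) / (2m⁺ + 2m⁻),

   where `Q⁺`/`Q⁻` are Newman–Girvan sums over ordered within-community
   pairs of `A⁺`/`A⁻` (indicator-guarded when one part is empty). When
   all weights are nonnegative, Q is exactly the Newman–Girvan
   modularity; Q(1) = 0 identically and Q is invariant to positive
   rescaling of `A`.

The estimate is `K̂ = argmax_k Q(k)`, smallest k on ties (parsimony; the
tie-break matters on noiseless inputs where Q plateaus beyond the true
K). A greedy variant that stops at the first non-increase of Q is
available (`early_stop=True`) but the global argmax is the default and
the definition of record.

### Numerical choices

- The double sums include the `i = j` terms exactly as the definition is
  written. With the default zero diagonal this is immaterial for the
  argmax (the diagonal contribution is partition-independent), but
  self-loops are honoured literally when present.
- Q is computed from community-level aggregates (within-community weight
  and degree totals), algebraically identical to the O(n²) literal
  double sum and tested against it at 1e−12.
- `modularity_curve` computes one full symmetric eigendecomposition and
  re-slices (and re-normalizes) its leading columns for every candidate
  k; results are identical to per-k decompositions and the cost of a
  K0 = 20 scan drops by ~K0×.
- Eigen ties in |λ| (within 1e−12 relative) are ordered by algebraic
  value descending — an arbitrary but fixed choice.
- Zero rows of the eigenvector matrix (isolated nodes) are left as zero
  vectors, flagged, and still clustered, so no node is dropped.
- k-means uses 10 seeded restarts by default (scikit-learn `KMeans`,
  best inertia kept); the output is deterministic given
  `(A, k, restarts, seed)`. When the embedding has fewer distinct rows
  than k, the partition reports its effective cluster count.
- `k = 1` short-circuits to the all-ones partition without touching the
  spectrum.

## The simulator

`sample_adjacency` draws the strict upper triangle once per pair and
mirrors it, so symmetry is exact and `(spec, seed)` pairs are bit-wise
reproducible. Family laws:

| family      | law for A_ij                         | E[A_ij] |
|-------------|--------------------------------------|---------|
| bernoulli   | Bernoulli(Ω)                         | Ω       |
| binomial    | Binomial(m, Ω/m)                     | Ω       |
| poisson     | Poisson(Ω)                           | Ω       |
| geometric   | support {1,2,...}, success prob 1/Ω  | Ω       |
| exponential | rate 1/Ω                             | Ω       |
| normal      | Normal(Ω, σ²)                        | Ω       |
| laplace     | mean Ω, scale σ/√2 (variance σ²)     | Ω       |
| uniform     | Uniform(0, Ω)                        | **Ω/2** |
| signed      | ±1, P(+1) = (1+Ω)/2                  | Ω       |

Two deliberate readings of ambiguous conventions:

- **Uniform**: the sampling law `Uniform(0, Ω_ij)` is implemented
  verbatim even though its mean is Ω/2, not Ω; the uniform family is
  therefore excluded from the expectation checks. No silent ×2
  correction is applied.
- **Laplace**: parameterized by mean Ω and *variance* σ² (scale σ/√2),
  mirroring the Normal family.

Diagonal entries default to 0 (no self-loops; modularity degree sums are
insensitive to the choice in the argmax, see above). A flag samples the
diagonal from the same law for strict literalism.

Bernoulli/Binomial/signed success probabilities can stray above 1 when a
heterogeneity draw is large (e.g. Binomial with θ_i = U(0,1)·ρ and
ρ close to m); with `clip=True` (the simulation harness's setting) the
probabilities are clipped into [0, 1] and validation downgrades the
range finding to a warning. Validation rejects such specs otherwise.

## Simulation studies

36 built-in settings ("1a".."9d") pair each family with four grids:
varying sparsity ρ, varying K, varying ρ at K = 1, and varying the
off-diagonal connectivity β. Conventions: 50 nodes per community (100
for signed networks), labels assigned uniformly at random, K0 = 20,
`θ_i = U(0,1)·ρ` redrawn per repetition — except the geometric and
signed families, which use constant `θ_i = √ρ` so that `Ω = ρ·ZPZ′`
with ρ the network sparsity (the distribution-free-model convention;
this is the scaling under which the geometric validity constraint
`ρ·min P ≥ 1` holds with equality at the grid boundaries, and the
signed range ρ ∈ (0,1] maps to |Ω| ≤ ρ). Repetition r at grid point g
uses seed `seed_base + 10000·g + r`, making every grid point an
independent reproducible stream.

The accuracy rate at a grid point is the fraction of repetitions with
`K̂ = K`. Default repetitions are 20 per grid point — a desk-scale
choice that keeps a full four-setting family under a few minutes on one
CPU while the binomial standard error (≤ 0.11) still resolves the
qualitative trends; pass `reps=` to scale up.

### What the simulations do and do not show

The generator produces exactly the model the estimator assumes:
independent entries, exact block structure, no degree truncation,
transitivity or motif structure beyond what the block model implies.
Passing the simulation checks therefore demonstrates correctness of the
pipeline under the model, not robustness to real-network features such
as overlapping groups, hubs beyond the θ profile, or weight
distributions outside the nine families.

Known hard regimes, visible in the shipped results and deliberately not
papered over:

- **K = 1 at moderate n** (settings 1c/4c style, n = 50): k-means on a
  noise eigenvector occasionally yields a slightly positive Q(2), so
  `K̂ = 2` errors occur at a ~5–15% rate. This is the familiar spurious
  modularity of null networks at finite n.
- **Near-diagonal connectivity with multiplicative noise** (setting 4d,
  β ≥ 0.7): for geometric weights the entry standard deviation is ≈ Ω,
  so the community eigenvalue (n/2)(1−β)ρ sits at or below the random-
  matrix bulk edge ~2σ√n regardless of ρ — both signal and noise scale
  together — and no spectral method recovers the split. Accuracy
  collapses there by detectability, not by implementation.

## Real networks

`read_network` ingests TSV weighted edge lists, GML, Pajek `.net` and
dense CSV adjacencies (signed weights preserved; unweighted edges get
weight 1; conflicting duplicate pairs are an error, not averaged).
Zachary's Karate club — binary and weighted — is bundled via networkx
and analysed with `K0 = n`; both versions yield `K̂ = 2`, the accepted
faction count. Other published estimates of this estimator's family
(Gahuku-Gama subtribes, Slovene Parliamentary Party, Dolphins, College
football, Political books, Political blogs) require downloading the
datasets from their public sources; the loaders support their formats.

## Limitations

- Non-overlapping communities only; undirected networks only.
- Dense linear algebra throughout (one full eigendecomposition per
  network) — appropriate for n up to a few thousand, not beyond.
- No consistency theory is claimed for the estimator; the package is a
  computational tool plus a calibrated simulator.
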