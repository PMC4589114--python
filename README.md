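# orthospace

Subspace clustering of orthologous gene nucleotide sequences.

Genes descended from a common ancestral gene (orthologs, as grouped in
COG-style databases) accumulate mutations along the branches of their
phylogeny.  Encoding each aligned sequence over the ring Z4
(A→0, C→1, G→2, T→3) turns a gene family into a real matrix
`W ∈ R^{m×M}` (m sequences, M positions), and the working hypothesis is
that one family spans a *low-dimensional subspace* of R^M: the more
mutation and elapsed time, the higher the subspace dimension.  Distinct
families with independent ancestors occupy near-orthogonal subspaces,
which makes mixtures of families separable by subspace clustering.

The package is aimed at researchers in molecular evolution and
comparative genomics who want to classify or sanity-check orthologous
group membership with linear-algebraic tools rather than similarity
graphs.

## What it computes

- **Effective rank** of a family matrix by penalized model selection,

  `r_eff = argmin_r  σ²_{r+1} / Σ_{i≤r} σ²_i  +  κ·r`

  over the singular values σ of `W` (default κ = 0.0048, calibrated on
  the simulator — see `docs/methods.md`), and the 90%-energy rank:
  the smallest k with `Σ_{j≤k} σ²_j ≥ 0.9 · Σ σ²`.
- **Subspace bases** `S_k = V†` from the truncated SVD
  `U Σ V† = A_k`, and **principal angles** between family subspaces,
  `cos θ = max v_i∈S_i, v_j∈S_j  v_iᵀv_j / (‖v_i‖‖v_j‖)`,
  plus the cumulative angle-count table
  `f(i, α) = Σ_{j≠i} 1[θ_{i,j} ≤ α]` for α = 0…90°.
- **LSA segmentation** (Local Subspace Affinity): rows of a mixed stack
  are projected onto the top right-singular directions, local bases are
  fitted per point, affinities `exp(−Σ_m sin²θ_m)` are spectrally
  clustered into K groups.
- **Significance**: errors after optimal label matching are compared
  with random assignment, `P(n errors) = C(N,n) p_s^{N−n}(1−p_s)^n`
  with `p_s = 1/k`, reported as the lower tail `P(≤ n errors)`.
- A **mutation-tree simulator**: a balanced binary tree of depth d with
  `N_s = 2^{d+1}−1` species; every branch applies a per-site
  Bernoulli(p_b) × uniform-nucleotide mutation vector; species are
  `S = (V C) mod 4` with `C` the ancestor-path inheritance matrix.
  It ties subspace rank to depth and mutation rate and generates all
  test fixtures.

## Worked example

Thirty randomized trials, each mixing sequences sampled from two
independently rooted simulated families (depth 3, 400 bp, 5% branch
mutation probability), segmented blind with LSA (d = 7, K = 2):

```python
from orthospace import ExperimentConfig, run_experiment, simulate_cluster_pool

pool = simulate_cluster_pool(2, depth=3, length=400, p_b=0.05, seed=11)
result = run_experiment(ExperimentConfig(K=2, R=30, seed=17), pool)
print(result.to_frame().head())
print(result.mean_missrate, result.mean_p_value)
```

```
 trial   N  n_errors  missrate      p_value
     1  22         0       0.0 2.384186e-07
     2  20         0       0.0 9.536743e-07
     3  25         0       0.0 2.980232e-08
     4  26         0       0.0 1.490116e-08
     5  25         0       0.0 2.980232e-08
0.0 7.047938803831736e-07
```

Every trial is classified perfectly (missrate 0), and each p-value is
the probability that random guessing would do at least that well —
about 10⁻⁷ per trial, so the subspace structure, not chance, explains
the separation.

Rank versus mutation rate on the simulator (31 species × 64 bp):

```python
from orthospace import TreeParams, spectrum_experiment

df = spectrum_experiment([TreeParams(4, 64, 0.1, seed=1)], replicates=1000)
print(df["r_modal"].mode()[0], df["r_energy"].mean())   # -> 6  6.569
```

A height-4 tree at 10% branch mutation has modal effective rank 6 — far
below the ambient 31 — and the 90%-energy rank rises from ≈6.6 at
p_b = 0.1 to ≈17.7 at p_b = 0.5: more mutation, higher subspace
dimension.

The same functionality is available from the shell:

```sh
orthospace simulate-tree --depth 4 --length 64 --p-b 0.1 --seed 1 --out tree.fasta
orthospace rank tree.fasta --center model
orthospace experiment --trials 30 --k 2 --seed 17 --out-prefix exp
```

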