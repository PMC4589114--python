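"""Balanced binary random mutation-tree simulator.

A common ancestor sequence in Z4^M sits at the root of a perfect binary
tree of depth d.  Every branch applies an independent random mutation
vector whose entries are a Bernoulli(p_b) event times a uniformly drawn
nucleotide, and each of the N_s = 2^(d+1) - 1 species sequences is the
ancestor plus the sum of mutation vectors along its root path, reduced
mod 4.  Writing the mutation vectors as columns of V and the root-path
membership as a 0/1 inheritance matrix C gives the species matrix
S = (V C) mod 4 in one linear-algebra step.

The simulator links subspace geometry to phylogeny: the effective rank
of S grows with both tree depth and mutation probability, and species of
independently rooted trees are uncorrelated after centering, so separate
gene families occupy near-orthogonal subspaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import SequenceRecord, decode_row
from .subspace import DEFAULT_KAPPA, MODEL_MEAN, compute_spectrum, energy_rank, modal_rank

__all__ = [
    "TreeParams",
    "MutationTree",
    "CrossTreeSummary",
    "parent_index",
    "node_depth",
    "inheritance_matrix",
    "sample_mutation_vectors",
    "species_matrix",
    "simulate_tree",
    "branch_mutation_fraction",
    "spectrum_experiment",
    "cross_tree_correlation",
    "tree_to_records",
]

_ALPHABETS = ("z4_full", "nonzero")


@dataclass(frozen=True)
class TreeParams:
    """Parameters of one simulated tree.

    ``change_alphabet`` selects the support of the uniform nucleotide
    factor in a mutation entry: ``z4_full`` draws from {0,1,2,3} (the
    model's literal definition, under which a drawn "mutation" is a
    silent zero change with probability 1/4, so the realized per-branch
    change fraction is (3/4) p_b), while ``nonzero`` draws from {1,2,3}
    so every mutation event changes the site and the realized change
    fraction is exactly p_b.
    """

    depth: int
    length: int
    p_b: float
    change_alphabet: str = "z4_full"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.length < 1:
            raise ValueError("sequence length must be >= 1")
        if not 0 <= self.p_b <= 1:
            raise ValueError("p_b must lie in [0, 1]")
        if self.change_alphabet not in _ALPHABETS:
            raise ValueError(f"change_alphabet must be one of {_ALPHABETS}")

    @property
    def n_species(self) -> int:
        """Node count of a perfect binary tree: 2^(d+1) - 1."""
        return 2 ** (self.depth + 1) - 1


@dataclass
class MutationTree:
    """A realized tree: mutation matrix V, inheritance C, species S.

    Columns are heap-indexed (root = 1, parent(m) = floor(m/2)).  Column
    1 of V is the common ancestor; column m >= 2 is the mutation
    difference vector from parent(m) to m.  S = (V C) mod 4 column-wise.
    """

    V: np.ndarray
    C: np.ndarray
    S: np.ndarray
    params: TreeParams


def parent_index(m: int) -> int:
    """Heap parent of node m (1-indexed); the root has no parent."""
    if m < 2:
        raise ValueError("the root node has no parent")
    return m // 2


def node_depth(m: int) -> int:
    """Depth of heap node m, root at depth 0."""
    if m < 1:
        raise ValueError("node indices start at 1")
    return int(np.log2(m))


def inheritance_matrix(d: int) -> np.ndarray:
    """Ancestor-path indicator matrix C of a depth-d perfect binary tree.

    C[m-1, k-1] = 1 iff node m lies on the root path of node k
    (ancestor-or-self).  Upper triangular with unit diagonal; column k
    carries depth(k) + 1 ones.
    """
    if d < 0:
        raise ValueError("depth must be >= 0")
    n = 2 ** (d + 1) - 1
    C = np.zeros((n, n), dtype=int)
    for k in range(1, n + 1):
        m = k
        while m >= 1:
            C[m - 1, k - 1] = 1
            m //= 2
    return C


def sample_mutation_vectors(
    params: TreeParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the M x N_s mutation matrix V.

    Column 1 is the common ancestor, uniform over Z4^M.  Each entry of
    column m >= 2 is X * B with B ~ Bernoulli(p_b) and X uniform over the
    change alphabet.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    M, n = params.length, params.n_species
    V = np.zeros((M, n), dtype=float)
    V[:, 0] = rng.integers(0, 4, size=M)
    if n > 1:
        events = rng.random((M, n - 1)) < params.p_b
        low = 1 if params.change_alphabet == "nonzero" else 0
        nucleotides = rng.integers(low, 4, size=(M, n - 1))
        V[:, 1:] = nucleotides * events
    return V


def species_matrix(V: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Species matrix S = (V C) mod 4; columns are Z4 sequences."""
    V = np.asarray(V, dtype=float)
    C = np.asarray(C, dtype=float)
    if V.shape[1] != C.shape[0] or C.shape[0] != C.shape[1]:
        raise ValueError(
            f"shape mismatch: V is {V.shape}, C is {C.shape}; need V (M, N_s) "
            "and C (N_s, N_s)"
        )
    return (V @ C) % 4


def simulate_tree(
    params: TreeParams, rng: np.random.Generator | None = None
) -> MutationTree:
    """Simulate one tree; exactly reproducible for a fixed seed."""
    V = sample_mutation_vectors(params, rng)
    C = inheritance_matrix(params.depth)
    return MutationTree(V, C, species_matrix(V, C), params)


def branch_mutation_fraction(tree: MutationTree) -> float:
    """Mean per-branch fraction of changed sites.

    Averages the Hamming weight of (child - parent) mod 4, divided by M,
    over every branch.  Expectation: p_b under the ``nonzero`` alphabet
    and (3/4) p_b under ``z4_full``.
    """
    n = tree.params.n_species
    if n < 2:
        raise ValueError("a root-only tree has no branches")
    fracs = []
    for m in range(2, n + 1):
        diff = (tree.S[:, m - 1] - tree.S[:, parent_index(m) - 1]) % 4
        fracs.append(np.count_nonzero(diff) / tree.params.length)
    return float(np.mean(fracs))


def spectrum_experiment(
    params_grid: list[TreeParams],
    replicates: int,
    kappa: float = DEFAULT_KAPPA,
    fraction: float = 0.9,
    center: str = "model",
) -> pd.DataFrame:
    """Rank-vs-depth / rank-vs-mutation-rate simulation sweep.

    For each parameter set, simulates ``replicates`` independent trees
    (seed streams spawned from ``params.seed``), computes the singular
    spectrum of the model-centered species matrix, and records the modal
    effective rank and the 90%-energy rank.  Returns one row per
    replicate with columns p_b, depth, length, n_species, replicate,
    r_modal, r_energy.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rows = []
    for params in params_grid:
        streams = np.random.SeedSequence(
            params.seed if params.seed is not None else 0
        ).spawn(replicates)
        for i, stream in enumerate(streams):
            tree = simulate_tree(params, np.random.default_rng(stream))
            spec = compute_spectrum(tree.S, center=center)
            rows.append(
                {
                    "p_b": params.p_b,
                    "depth": params.depth,
                    "length": params.length,
                    "n_species": params.n_species,
                    "replicate": i,
                    "r_modal": modal_rank(spec, kappa).r_eff,
                    "r_energy": energy_rank(spec, fraction),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CrossTreeSummary:
    """Centered inner products between the species of two trees.

    ``products`` holds <s_j - 1.5, s_k - 1.5> / M for every species pair
    (1.5 is the exact entry mean of the model).  For independently rooted
    trees the mean is near zero at a scale of 1/sqrt(M): distinct gene
    families are uncorrelated.  Within one tree, shared root-path
    mutation components keep parent-child and sibling products positive.
    """

    products: np.ndarray
    mean: float


def cross_tree_correlation(
    treeA: MutationTree, treeB: MutationTree
) -> CrossTreeSummary:
    """Normalized centered inner products between all cross-tree pairs."""
    if treeA.params.length != treeB.params.length:
        raise ValueError("trees must share the sequence length M")
    M = treeA.params.length
    A = treeA.S - MODEL_MEAN
    B = treeB.S - MODEL_MEAN
    products = (A.T @ B) / M
    return CrossTreeSummary(products, float(products.mean()))


def tree_to_records(tree: MutationTree) -> list[SequenceRecord]:
    """Decode species columns into FASTA-ready records.

    Ids encode the heap node index and its depth, e.g. ``n5_d2``.
    """
    records = []
    for k in range(1, tree.params.n_species + 1):
        records.append(
            SequenceRecord(f"n{k}_d{node_depth(k)}", decode_row(tree.S[:, k - 1]))
        )
    return records
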