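"""Randomized K-cluster segmentation experiments, end to end.

A cluster source is simply a list of :class:`SequenceRecord` (one
orthologous group, read from a FASTA file or decoded from a simulated
tree).  Each trial draws K distinct clusters, samples a random number of
sequences from each, stacks and shuffles them, optionally aligns,
encodes, segments with LSA, and scores the result against the saved
truth labels with the optimal-matching missrate and its binomial lower
tail.  All random draws run off seed streams spawned from one master
seed, so a whole experiment is replayable bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lsa import LsaConfig, lsa_segment
from .seqio import SequenceRecord, align_external, encode_sequences
from .stats import TrialOutcome, missrate, pvalue_at_most
from .subspace import DEFAULT_KAPPA, angle_histogram, compute_spectrum, fit_basis, modal_rank
from .tree import TreeParams, simulate_tree, tree_to_records

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "simulate_cluster_pool",
    "run_experiment",
    "survey_ranks",
    "survey_angles",
]

logger = logging.getLogger("orthospace")

Cluster = list[SequenceRecord]


@dataclass
class ExperimentConfig:
    """Settings for a randomized clustering experiment.

    ``m_range`` bounds the per-trial, per-cluster sample size
    (inclusive); samples must stay comfortably above the LSA local
    neighborhood size, so the lower bound must be >= d + 2.  ``align``
    only applies to FASTA sources; simulated sequences are equal-length
    by construction and skip alignment.
    """

    K: int = 2
    R: int = 30
    m_range: tuple[int, int] = (8, 15)
    source: str = "simulator"
    lsa: LsaConfig | None = None
    align: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("need at least one trial")
        if self.K < 2:
            raise ValueError("need at least K = 2 clusters per trial")
        if self.source not in ("simulator", "fasta_dir"):
            raise ValueError("source must be 'simulator' or 'fasta_dir'")
        if self.lsa is None:
            self.lsa = LsaConfig(K=self.K)
        if self.m_range[0] > self.m_range[1] or self.m_range[0] < 2:
            raise ValueError("m_range must be nondecreasing with lower bound >= 2")
        # the LSA neighborhood must fit inside the smallest possible stack
        if self.K * self.m_range[0] <= self.lsa.n_neighbors:
            raise ValueError(
                f"K * m_min = {self.K * self.m_range[0]} must exceed "
                f"n_neighbors = {self.lsa.n_neighbors}"
            )


@dataclass
class ExperimentResult:
    """Per-trial outcomes plus their truth/predicted label vectors."""

    trials: list[TrialOutcome]
    truths: list[np.ndarray] = field(default_factory=list)
    predictions: list[np.ndarray] = field(default_factory=list)

    @property
    def mean_missrate(self) -> float:
        return float(np.mean([t.missrate for t in self.trials]))

    @property
    def mean_p_value(self) -> float:
        return float(np.mean([t.p_value for t in self.trials]))

    def to_frame(self) -> pd.DataFrame:
        """Trial table: trial, N, n_errors, missrate, p_value."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self.trials) + 1),
                "N": [t.N for t in self.trials],
                "n_errors": [t.n_errors for t in self.trials],
                "missrate": [t.missrate for t in self.trials],
                "p_value": [t.p_value for t in self.trials],
            }
        )

    def summary(self) -> dict:
        return {
            "trials": len(self.trials),
            "mean_missrate": self.mean_missrate,
            "mean_p_value": self.mean_p_value,
        }


def simulate_cluster_pool(
    n_clusters: int,
    depth: int = 3,
    length: int = 400,
    p_b: float = 0.05,
    change_alphabet: str = "z4_full",
    seed: int = 0,
) -> list[Cluster]:
    """Simulate independent trees (independent random ancestors) and
    return their species sets as cluster sources."""
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    streams = np.random.SeedSequence(seed).spawn(n_clusters)
    pool = []
    for stream in streams:
        params = TreeParams(depth=depth, length=length, p_b=p_b,
                            change_alphabet=change_alphabet)
        pool.append(tree_to_records(simulate_tree(params, np.random.default_rng(stream))))
    return pool


def _sample_trial(
    clusters: list[Cluster],
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> tuple[list[SequenceRecord], np.ndarray]:
    """Algorithm stages: cluster choice, per-cluster sampling, stacking,
    truth capture, then blind row randomization."""
    chosen = rng.choice(len(clusters), size=config.K, replace=False)
    records: list[SequenceRecord] = []
    truth: list[int] = []
    for label, ci in enumerate(chosen, start=1):
        cluster = clusters[ci]
        m = int(rng.integers(config.m_range[0], config.m_range[1] + 1))
        if m > len(cluster):
            raise ValueError(
                f"cluster {ci} has {len(cluster)} sequences, fewer than the "
                f"requested sample of {m}"
            )
        picks = rng.choice(len(cluster), size=m, replace=False)
        records.extend(cluster[p] for p in picks)
        truth.extend([label] * m)
    logger.info("trial sampling: clusters=%s sizes=%s",
                chosen.tolist(), np.bincount(truth)[1:].tolist())
    truth_arr = np.asarray(truth)
    perm = rng.permutation(len(records))
    return [records[p] for p in perm], truth_arr[perm]


def run_experiment(
    config: ExperimentConfig, clusters: list[Cluster]
) -> ExperimentResult:
    """Run R randomized trials of K-cluster segmentation.

    Identical configs (including seed) reproduce identical results.
    """
    if len(clusters) < config.K:
        raise ValueError(
            f"need at least K={config.K} cluster sources, got {len(clusters)}"
        )
    trial_streams = np.random.SeedSequence(config.seed).spawn(config.R)
    result = ExperimentResult(trials=[])
    for j, stream in enumerate(trial_streams, start=1):
        sample_stream, lsa_stream = stream.spawn(2)
        rng = np.random.default_rng(sample_stream)
        records, truth = _sample_trial(clusters, config, rng)
        if config.align and config.source == "fasta_dir":
            records = align_external(records)
        W = encode_sequences(records)
        lsa_cfg = LsaConfig(
            K=config.K,
            d=config.lsa.d,
            projection_rank=config.lsa.projection_rank,
            n_neighbors=config.lsa.n_neighbors,
            seed=int(lsa_stream.generate_state(1)[0] % (2**31)),
        )
        assignment = lsa_segment(W, lsa_cfg)
        n_err, rate = missrate(truth, assignment.labels, config.K)
        outcome = TrialOutcome(
            N=len(truth),
            n_errors=n_err,
            k=config.K,
            missrate=rate,
            p_value=pvalue_at_most(len(truth), n_err, config.K),
        )
        logger.info("trial %d: N=%d errors=%d missrate=%.3f p=%.3g",
                    j, outcome.N, n_err, rate, outcome.p_value)
        result.trials.append(outcome)
        result.truths.append(truth)
        result.predictions.append(assignment.labels)
    return result


def survey_ranks(
    clusters: list[Cluster],
    kappa: float = DEFAULT_KAPPA,
    center: str = "none",
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """Effective-rank survey: one row (cluster, m, M, r_eff) per cluster."""
    if not clusters:
        raise ValueError("no clusters to survey")
    ids = ids or [f"cluster{i}" for i in range(len(clusters))]
    rows = []
    for cid, cluster in zip(ids, clusters):
        W = encode_sequences(cluster)
        spec = compute_spectrum(W, center=center)
        rows.append(
            {
                "cluster": cid,
                "m": W.shape[0],
                "M": W.shape[1],
                "r_eff": modal_rank(spec, kappa).r_eff,
            }
        )
    return pd.DataFrame(rows)


def survey_angles(
    clusters: list[Cluster],
    r_per_cluster: int | str = "auto",
    kappa: float = DEFAULT_KAPPA,
    center: str = "mean",
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """Cumulative inter-subspace angle table.

    Fits one basis per cluster (rank from the modal estimate when
    "auto"), measures the smallest pairwise principal angles, and counts
    for each cluster i and integer threshold alpha in 0..90 how many
    other clusters lie within alpha degrees.  Bases are fitted on
    mean-centered data by default so the shared composition component
    does not mask inter-subspace geometry.  Returns a 91-row DataFrame
    indexed by alpha with one column per cluster.
    """
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    ids = ids or [f"cluster{i}" for i in range(len(clusters))]
    bases = []
    for cid, cluster in zip(ids, clusters):
        W = encode_sequences(cluster)
        if r_per_cluster == "auto":
            r = modal_rank(compute_spectrum(W, center=center), kappa).r_eff
            r = max(r, 1)
        else:
            r = int(r_per_cluster)
        if r > min(W.shape):
            raise ValueError(
                f"cluster {cid} has shape {W.shape}, smaller than rank {r}"
            )
        bases.append(fit_basis(W, r, center=(center == "mean"), source_cluster=cid))
    alphas = np.arange(91)
    counts = angle_histogram(bases, alphas)
    return pd.DataFrame(counts.T, index=pd.Index(alphas, name="alpha"), columns=ids)
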