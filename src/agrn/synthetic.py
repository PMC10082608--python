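"""Synthetic regulatory networks and multifactorial-style expression data.

The generator emulates steady-state expression measured after small
simultaneous perturbations of all genes: a sparse directed acyclic network
in which each regulated gene is a noisy linear function of its regulators.
Root genes (no incoming edge) receive independent standard-normal values,
so a regulated gene with a single unit-weight regulator and noise standard
deviation sigma has population correlation 1/sqrt(1 + sigma^2) with that
regulator — an analytically checkable signal.

All outputs are pure functions of the configuration, seed included.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import (
    ExpressionMatrix,
    GoldStandard,
    RegulatorSet,
    write_expression,
    write_gold_standard,
    write_tf_list,
)

__all__ = ["SyntheticConfig", "SyntheticNetwork", "generate_network",
           "simulate_expression", "write_fixture_set"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study conditions.

    Defaults describe a small recoverable network: 20 genes of which the
    first 5 are transcription factors, eligible TF->target edges present
    with probability 0.3, regulatory weights of unit magnitude, additive
    noise of s.d. 0.1, and 200 steady-state samples.
    """

    n_genes: int = 20
    n_tfs: int = 5
    edge_density: float = 0.3
    effect_scale: float = 1.0
    noise_sd: float = 0.1
    n_samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (1 <= self.n_tfs <= self.n_genes):
            raise ValueError("n_tfs must satisfy 1 <= n_tfs <= n_genes")
        if not (0.0 <= self.edge_density <= 1.0):
            raise ValueError("edge_density must lie in [0, 1]")
        if self.effect_scale <= 0:
            raise ValueError("effect_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not (0 <= int(self.seed) < 2**63):
            raise ValueError("seed must be a nonnegative integer")


@dataclass(frozen=True)
class SyntheticNetwork:
    """A sparse DAG of weighted TF->target edges.

    The first ``n_tfs`` entries of ``gene_ids`` are the transcription
    factors; every edge runs from a TF to a strictly later gene in index
    order, so the graph is acyclic by construction.
    """

    gene_ids: tuple[str, ...]
    n_tfs: int
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        index = {g: i for i, g in enumerate(self.gene_ids)}
        for reg, tgt in self.edges:
            if index[reg] >= self.n_tfs:
                raise ValueError(f"edge source {reg} is not a transcription factor")
            if index[reg] >= index[tgt]:
                raise ValueError(f"edge {reg}->{tgt} violates the acyclic index ordering")

    @property
    def tf_ids(self) -> tuple[str, ...]:
        return self.gene_ids[: self.n_tfs]

    def parents_of(self, gene_id: str) -> list[tuple[str, float]]:
        return [(reg, w) for (reg, tgt), w in self.edges.items() if tgt == gene_id]


def generate_network(config: SyntheticConfig) -> SyntheticNetwork:
    """Draw a random sparse DAG of TF->target edges.

    Each eligible pair (TF u, gene v) with index(u) < index(v) receives an
    edge independently with probability ``edge_density``; its weight has
    magnitude uniform on [0.5, 1.5] * effect_scale and a random sign.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    gene_ids = tuple(f"G{i + 1}" for i in range(config.n_genes))
    edges: dict[tuple[str, str], float] = {}
    for i in range(config.n_tfs):
        for j in range(i + 1, config.n_genes):
            present = rng.random() < config.edge_density
            magnitude = rng.uniform(0.5, 1.5) * config.effect_scale
            sign = 1.0 if rng.random() < 0.5 else -1.0
            if present:
                edges[(gene_ids[i], gene_ids[j])] = sign * magnitude
    return SyntheticNetwork(gene_ids=gene_ids, n_tfs=config.n_tfs, edges=edges)


def simulate_expression(network: SyntheticNetwork, config: SyntheticConfig) -> ExpressionMatrix:
    """Simulate steady-state expression by one topological pass.

    Genes are processed in index order: a gene with no incoming edge gets
    i.i.d. standard-normal values; a regulated gene gets the weighted sum
    of its regulators' values plus i.i.d. Gaussian noise of s.d.
    ``noise_sd``.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    n, g = config.n_samples, len(network.gene_ids)
    index = {gid: i for i, gid in enumerate(network.gene_ids)}
    values = np.empty((n, g), dtype=float)
    parents: list[list[tuple[int, float]]] = [[] for _ in range(g)]
    for (reg, tgt), w in network.edges.items():
        parents[index[tgt]].append((index[reg], w))
    for j in range(g):
        if not parents[j]:
            values[:, j] = rng.standard_normal(n)
        else:
            col = np.zeros(n)
            for pi, w in sorted(parents[j]):
                col += w * values[:, pi]
            col += config.noise_sd * rng.standard_normal(n)
            values[:, j] = col
    return ExpressionMatrix(gene_ids=network.gene_ids, values=values)


def write_fixture_set(
    network: SyntheticNetwork,
    expression: ExpressionMatrix,
    directory: str | os.PathLike,
) -> dict[str, Path]:
    """Write expression TSV, TF list and gold standard into ``directory``.

    The gold standard lists every generated edge with label 1; absent pairs
    are implied negatives, matching the evaluation convention.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "tf_list": directory / "tf_list.txt",
        "gold_standard": directory / "gold_standard.tsv",
    }
    write_expression(expression, paths["expression"])
    write_tf_list(RegulatorSet(tf_ids=network.tf_ids), paths["tf_list"])
    gold = GoldStandard(labeled_pairs={pair: 1 for pair in network.edges})
    write_gold_standard(gold, paths["gold_standard"])
    return paths
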