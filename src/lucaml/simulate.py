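"""Forward simulation of gene gain/loss histories down the species tree.

The generator implements exactly the generative reading of the likelihood:
the root state is drawn from the prior pi, and each child node's state is
drawn from its parent's row of P(branch length) = expm(Q t).  States are
simulated at the nodes directly (the likelihood only ever sees node states,
so event-level simulation of the chain within a branch would add nothing).
True internal states are retained so that recovery experiments can compare
against them.

Emitted count tables use copy number 2 as the canonical representative of
state m, and round-trip exactly through ``read_count_table`` and
``encode_counts``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import RootPrior, make_root_prior
from .models import RateParameters, build_rate_matrix, transition_matrices
from .tree import PhylogeneticTree

__all__ = ["SimulationConfig", "SimulatedGene", "SimulationResult",
           "simulate_gene", "simulate_dataset", "random_tree"]


@dataclass(frozen=True)
class SimulationConfig:
    """Inputs of a simulation run; a fixed seed makes output byte-identical."""

    tree: PhylogeneticTree
    params: RateParameters
    prior: RootPrior
    n_genes: int
    seed: int
    gene_prefix: str = "gene"

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.prior.n_states != self.params.n_states:
            raise ValueError("prior state space does not match the model")


@dataclass(frozen=True)
class SimulatedGene:
    """One simulated gene with its full true history."""

    gene_id: str
    root_state: int
    node_states: np.ndarray  # state per tree node index
    leaf_states: np.ndarray  # in tree.leaf_names order

    @property
    def counts(self) -> np.ndarray:
        """Copy counts per leaf: state m is emitted as 2 copies."""
        return self.leaf_states.copy()


@dataclass
class SimulationResult:
    """Count table plus the truth needed for recovery experiments."""

    config: SimulationConfig
    genes: list[SimulatedGene]
    counts: pd.DataFrame  # genes x species copy counts
    truth: pd.DataFrame  # gene_id, true root state, generating rates

    def write(self, outdir) -> None:
        """Write counts.tsv, truth.tsv and the resolved config.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        cfg = {
            "model": self.config.params.model_id,
            "rates": self.config.params.rates,
            "prior": self.config.prior.probs.tolist(),
            "n_genes": self.config.n_genes,
            "seed": self.config.seed,
            "tree": self.config.tree.to_newick(),
        }
        (outdir / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")


def _simulate_states(
    tree: PhylogeneticTree,
    params: RateParameters,
    prior: RootPrior,
    n_genes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Node states for n_genes genes, shape (n_genes, n_nodes)."""
    k = params.n_states
    Q = build_rate_matrix(params)
    P = transition_matrices(Q, tree.branch_length)  # (n_nodes, k, k)
    cum = np.cumsum(P, axis=-1)
    states = np.zeros((n_genes, tree.n_nodes), dtype=int)
    preorder = tree.postorder[::-1]  # parents before children
    states[:, tree.root] = rng.choice(k, size=n_genes, p=prior.probs)
    for node in preorder:
        if node == tree.root:
            continue
        parent_states = states[:, tree.parent[node]]
        u = rng.random(n_genes)
        states[:, node] = (u[:, None] > cum[node][parent_states]).sum(axis=1)
    return states


def simulate_gene(cfg: SimulationConfig, rng: np.random.Generator,
                  gene_id: str = "gene") -> SimulatedGene:
    """Simulate a single gene's history (root state ~ pi, children ~ P(t))."""
    states = _simulate_states(cfg.tree, cfg.params, cfg.prior, 1, rng)[0]
    return SimulatedGene(
        gene_id=gene_id,
        root_state=int(states[cfg.tree.root]),
        node_states=states,
        leaf_states=states[cfg.tree.leaf_nodes],
    )


def simulate_dataset(cfg: SimulationConfig) -> SimulationResult:
    """Simulate a cohort of genes and package it as a count table + truth.

    The count table is column-ordered by ``tree.leaf_names`` and contains
    the copy-count encoding of the simulated leaf states (0, 1, or 2 for
    state m); the truth table records each gene's true root state and the
    generating rates.
    """
    rng = np.random.default_rng(cfg.seed)
    all_states = _simulate_states(cfg.tree, cfg.params, cfg.prior, cfg.n_genes, rng)
    width = max(1, len(str(max(cfg.n_genes - 1, 0))))
    genes = []
    for i in range(cfg.n_genes):
        states = all_states[i]
        genes.append(
            SimulatedGene(
                gene_id=f"{cfg.gene_prefix}{i:0{width}d}",
                root_state=int(states[cfg.tree.root]),
                node_states=states,
                leaf_states=states[cfg.tree.leaf_nodes],
            )
        )
    counts = pd.DataFrame(
        [g.counts for g in genes] if genes else np.empty((0, cfg.tree.n_leaves), int),
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=cfg.tree.leaf_names,
        dtype=int,
    )
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "root_state": [g.root_state for g in genes],
        }
    )
    for name, value in cfg.params.rates.items():
        truth[f"true_{name}"] = value
    return SimulationResult(config=cfg, genes=genes, counts=counts, truth=truth)


def random_tree(
    n_leaves: int,
    rng: np.random.Generator,
    min_branch: float = 0.05,
    max_branch: float = 1.0,
    prefix: str = "sp",
) -> PhylogeneticTree:
    """A random rooted binary tree with uniform branch lengths.

    Built by successive random coalescence of the leaf set — a cheap
    topology generator for simulation studies, not a coalescent model.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    width = len(str(n_leaves - 1))

    def blen() -> float:
        return rng.uniform(min_branch, max_branch)

    nodes = [f"{prefix}{i:0{width}d}:{blen():.6f}" for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{blen():.6f}"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [merged]
    newick = f"({nodes[0]},{nodes[1]});"
    return PhylogeneticTree.from_newick(newick)
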