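"""Phyletic 0/1/m-vectors from gene copy-count tables.

Each gene (orthologous group, COG) is summarized per genome by one of three
states: ``0`` (absent), ``1`` (exactly one copy) or ``m`` (multiple
in-paralogs).  The ordered list of states across the analyzed genomes is the
gene's *phyletic vector* — the observed data of the likelihood.  Internally
states are coded as the integers 0, 1, 2 in the fixed order (0, 1, m).

This module also implements the two data-preparation rules used for the
prokaryotic COG analysis: dropping genes confined to a single domain of life
(a gene found only in Bacteria or only in Archaea is unlikely to predate the
bacterial/archaeal split at the root), and editing a vector when a
horizontal transfer into a clade is known (all presences in the recipient
clade are reset to absences before inference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import PhylogeneticTree, TreeError

__all__ = [
    "STATE_ABSENT",
    "STATE_SINGLE",
    "STATE_MULTI",
    "read_count_table",
    "read_domain_labels",
    "encode_counts",
    "binarize_vector",
    "filter_single_domain",
    "DomainFilterResult",
    "hgt_edit_vector",
    "hgt_edit_counts",
]

STATE_ABSENT, STATE_SINGLE, STATE_MULTI = 0, 1, 2


def read_count_table(path) -> pd.DataFrame:
    """Read a genes x genomes copy-count TSV.

    Expects a header row of species ids and a first column of gene ids;
    every cell must be a nonnegative integer.  Returns a DataFrame indexed
    by gene id with one integer column per species.

    Raises ``ValueError`` naming the offending row/column for non-integer
    cells, and for duplicated gene ids.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValueError(f"duplicate gene ids: {dupes}")
    if raw.columns.duplicated().any():
        dupes = sorted(set(raw.columns[raw.columns.duplicated()]))
        raise ValueError(f"duplicate species ids: {dupes}")
    out = pd.DataFrame(index=raw.index.astype(str), dtype=int)
    out.index.name = raw.index.name or "gene_id"
    for col in raw.columns:
        values = np.empty(len(raw), dtype=int)
        for i, cell in enumerate(raw[col]):
            try:
                v = int(str(cell).strip())
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {cell!r} at gene {raw.index[i]!r}, "
                    f"species {col!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"negative count {v} at gene {raw.index[i]!r}, species {col!r}"
                )
            values[i] = v
        out[col] = values
    return out


def read_domain_labels(path) -> pd.Series:
    """Read a two-column species_id -> domain TSV into a Series."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("domain label table must have two columns")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    if s.index.duplicated().any():
        raise ValueError("duplicate species ids in domain label table")
    return s


def encode_counts(counts) -> np.ndarray:
    """Encode per-species copy counts as three-state phyletic states.

    count 0 -> state 0 (absent); count 1 -> state 1 (single copy);
    count >= 2 -> state m (in-paralogs).  Works on a 1-d row or a 2-d
    genes x species array; raises on negative counts.
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.floor(counts)):
            raise ValueError("counts must be integers")
        counts = counts.astype(int)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    return np.minimum(counts, STATE_MULTI)


def binarize_vector(states) -> np.ndarray:
    """Collapse a three-state vector to presence/absence: 0->0, 1->1, m->1."""
    states = np.asarray(states, dtype=int)
    return np.minimum(states, 1)


@dataclass
class DomainFilterResult:
    """Outcome of :func:`filter_single_domain`.

    ``retained``, ``bacteria_only`` and ``archaea_only`` partition the input
    genes exactly; ``universal`` lists the retained genes present in every
    species.
    """

    retained: pd.DataFrame
    bacteria_only: list[str]
    archaea_only: list[str]
    universal: list[str]


def filter_single_domain(
    table: pd.DataFrame,
    labels: pd.Series,
    bacteria: str = "Bacteria",
    archaea: str = "Archaea",
) -> DomainFilterResult:
    """Drop genes found only in Bacteria or only in Archaea.

    With the root placed between the two prokaryotic domains, a gene
    confined to one domain cannot be reconstructed as ancestral with
    appreciable probability, so such genes are removed before fitting.
    Genes present (count >= 1) in at least one species of each domain are
    retained; retained genes present in *every* species are additionally
    flagged as universal.

    Raises ``ValueError`` if any species in the table lacks a domain label,
    or if a gene is absent from every species (an all-absent vector carries
    no signal and cannot be fit).
    """
    missing = [sp for sp in table.columns if sp not in labels.index]
    if missing:
        raise ValueError(f"unlabeled species: {missing}")
    lab = labels.loc[list(table.columns)]
    in_bact = (table.loc[:, (lab == bacteria).values] > 0).any(axis=1)
    in_arch = (table.loc[:, (lab == archaea).values] > 0).any(axis=1)
    nowhere = ~in_bact & ~in_arch
    if nowhere.any():
        raise ValueError(
            f"genes absent from every species: {sorted(table.index[nowhere])}"
        )
    keep = in_bact & in_arch
    retained = table.loc[keep]
    universal = retained.index[(retained > 0).all(axis=1)].tolist()
    return DomainFilterResult(
        retained=retained,
        bacteria_only=table.index[in_bact & ~in_arch].tolist(),
        archaea_only=table.index[in_arch & ~in_bact].tolist(),
        universal=universal,
    )


def hgt_edit_vector(
    states: np.ndarray,
    tree: PhylogeneticTree,
    recipient: int,
    leaf_order: list[str] | None = None,
) -> np.ndarray:
    """Reset all presences below a transfer recipient to absences.

    When a gene is known to have been horizontally transferred into the
    clade rooted at ``recipient``, its presences there say nothing about
    vertical descent from the root, so every leaf of that clade (inclusive
    if the recipient is itself a leaf) is set to state 0 before inference.

    ``leaf_order`` gives the species order of ``states``; defaults to
    ``tree.leaf_names``.  Idempotent for a fixed recipient.
    """
    if not 0 <= recipient < tree.n_nodes:
        raise TreeError(f"unknown node id {recipient}")
    names = leaf_order if leaf_order is not None else tree.leaf_names
    pos = {n: i for i, n in enumerate(names)}
    out = np.array(states, dtype=int, copy=True)
    for leaf in tree.leaves_under(recipient):
        name = tree.leaf_names[tree.leaf_nodes.index(leaf)]
        out[pos[name]] = STATE_ABSENT
    return out


def hgt_edit_counts(
    table: pd.DataFrame,
    tree: PhylogeneticTree,
    edits: list[tuple[str, list[str]]],
) -> pd.DataFrame:
    """Apply HGT edits to a count table.

    ``edits`` is a list of ``(gene_id, recipient_leaf_names)`` pairs; the
    recipient clade is the MRCA of the named leaves.  Counts of every
    species in the clade are set to 0 for that gene; untouched genes pass
    through unchanged.
    """
    out = table.copy()
    for gene_id, leaf_names in edits:
        if gene_id not in out.index:
            raise ValueError(f"unknown gene id {gene_id!r}")
        node = tree.mrca(leaf_names)
        for leaf in tree.leaves_under(node):
            name = tree.leaf_names[tree.leaf_nodes.index(leaf)]
            if name not in out.columns:
                raise ValueError(f"species {name!r} not in count table")
            out.loc[gene_id, name] = 0
    return out
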