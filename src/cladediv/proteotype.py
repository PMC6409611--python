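"""Consensus-signature proteotyping of protein alignments.

A *proteotype* is a shared amino-acid signature pattern within an alignment.
The workflow: compute the per-column consensus, express each sequence as its
deviations from the consensus (the signature matrix, the quantity behind the
white-consensus / black-gap / colored-residue alignment displays), and call
proteotypes by single-linkage clustering of pairwise signature divergence,
splitting clusters at 10% divergence by default.

Two divergence readings are computed: the pairwise between-sequence
divergence (drives the clustering) and each taxon's divergence from the
consensus (reported as a score). Clustering is the default because a blended
consensus between two groups that each sit ~10% from it would otherwise
merge the groups the display plainly separates.

Also here: inter-group percent-identity summaries, the genome-ordered
assortment table of per-region proteotypes, and breakpoint calls for taxon
pairs (used to localise recombination boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .seqio import ProteinAlignment

__all__ = [
    "ConsensusProfile",
    "ProteotypeAssignment",
    "consensus",
    "signature_matrix",
    "pairwise_divergence",
    "call_proteotypes",
    "intergroup_identity",
    "assortment",
    "breakpoints",
    "RESIDUE_COLORS",
]

CONSENSUS_TOKEN = "."
GAP_TOKEN = "-"

#: fixed residue -> display color (hex), stable across exports
RESIDUE_COLORS = {
    res: col
    for res, col in zip(
        "ACDEFGHIKLMNPQRSTVWYX*",
        [
            "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
            "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
            "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
            "#c49c94", "#f7b6d2", "#c7c7c7", "#dbdb8d", "#9edae5",
            "#393b79", "#000000",
        ],
    )
}


@dataclass
class ConsensusProfile:
    """Per-column consensus of a protein alignment.

    ``consensus`` holds the most frequent non-gap residue per column (ties
    broken alphabetically); an all-gap column is recorded as ``-`` with
    frequency 0. ``frequency`` is the consensus residue's fraction of the
    non-gap residues in the column.
    """

    consensus: str
    frequency: np.ndarray
    counts: list[dict[str, int]]

    def __len__(self) -> int:
        return len(self.consensus)


def consensus(alignment: ProteinAlignment) -> ConsensusProfile:
    mat = alignment.to_matrix()
    cons, freq, counts = [], [], []
    for col in mat.T:
        vals, cnt = np.unique(col[col != "-"], return_counts=True)
        col_counts = dict(zip(vals.tolist(), cnt.tolist()))
        counts.append(col_counts)
        if not col_counts:
            cons.append("-")
            freq.append(0.0)
            continue
        # alphabetical tie rule: among max-count residues take the smallest
        top = max(col_counts.values())
        best = min(r for r, c in col_counts.items() if c == top)
        cons.append(best)
        freq.append(col_counts[best] / sum(col_counts.values()))
    return ConsensusProfile("".join(cons), np.asarray(freq), counts)


def signature_matrix(
    alignment: ProteinAlignment,
    leaf_order: Sequence[str] | None = None,
    profile: ConsensusProfile | None = None,
) -> pd.DataFrame:
    """Token matrix of deviations from the consensus.

    Rows are emitted in ``leaf_order`` (typically the ladderized leaf order
    of the accompanying tree). Tokens: ``.`` where the residue equals the
    column consensus, ``-`` for gaps, otherwise the literal residue. The
    fixed :data:`RESIDUE_COLORS` table supplies one color per residue for
    display exports.
    """
    if leaf_order is None:
        leaf_order = alignment.taxa
    if sorted(leaf_order) != sorted(alignment.taxa):
        raise ValueError("leaf_order is not a permutation of alignment taxa")
    profile = profile or consensus(alignment)
    rows = {}
    for taxon in leaf_order:
        seq = alignment[taxon].seq
        rows[taxon] = [
            GAP_TOKEN if ch == "-" else (CONSENSUS_TOKEN if ch == c else ch)
            for ch, c in zip(seq, profile.consensus)
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(len(profile)))


def pairwise_divergence(alignment: ProteinAlignment) -> pd.DataFrame:
    """Fraction of columns, non-gap in both sequences, at which a pair
    differs. Pairs with no comparable columns get divergence 1.0."""
    mat = alignment.to_matrix()
    ok = mat != "-"
    n = alignment.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            d[i, j] = d[j, i] = (
                1.0 if m == 0 else float((mat[i][both] != mat[j][both]).sum()) / m
            )
    return pd.DataFrame(d, index=alignment.taxa, columns=alignment.taxa)


@dataclass
class ProteotypeAssignment:
    """Proteotype ids (contiguous from 1) with per-taxon consensus scores."""

    ids: dict[str, int]
    divergence_from_consensus: dict[str, float]
    threshold: float

    @property
    def n_proteotypes(self) -> int:
        return max(self.ids.values())

    def members(self, k: int) -> list[str]:
        return [t for t, v in self.ids.items() if v == k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "proteotype": pd.Series(self.ids),
                "divergence_from_consensus": pd.Series(
                    self.divergence_from_consensus
                ),
            }
        ).rename_axis("taxon")


def call_proteotypes(
    alignment: ProteinAlignment, threshold: float = 0.10
) -> ProteotypeAssignment:
    """Assign proteotypes at the given residue-divergence threshold.

    Single-linkage clustering on pairwise signature divergence: two taxa
    share a proteotype iff they are connected by a chain of pairs each
    diverging by less than ``threshold``. Ids are assigned by decreasing
    cluster size, then by first occurrence in alignment order, starting at 1.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    d = pairwise_divergence(alignment).to_numpy()
    adj = csr_matrix(d < threshold)
    _, comp = connected_components(adj, directed=False)
    taxa = alignment.taxa
    sizes = {c: int((comp == c).sum()) for c in set(comp)}
    first = {c: int(np.argmax(comp == c)) for c in set(comp)}
    ranked = sorted(sizes, key=lambda c: (-sizes[c], first[c]))
    relabel = {c: k + 1 for k, c in enumerate(ranked)}
    ids = {t: relabel[c] for t, c in zip(taxa, comp)}
    prof = consensus(alignment)
    cons = np.array(list(prof.consensus))
    mat = alignment.to_matrix()
    scores = {}
    for t, row in zip(taxa, mat):
        ok = (row != "-") & (cons != "-")
        scores[t] = (
            float((row[ok] != cons[ok]).sum()) / int(ok.sum()) if ok.any() else 0.0
        )
    return ProteotypeAssignment(ids, scores, threshold)


def intergroup_identity(
    alignment: ProteinAlignment,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> dict:
    """Mean/min/max percent identity over all cross-group sequence pairs.

    Identity is computed over columns non-gap in both members of a pair and
    reported to 0.1%.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    mat = alignment.to_matrix()
    idx = {t: i for i, t in enumerate(alignment.taxa)}
    ok = mat != "-"
    idents = []
    for a in group_a:
        for b in group_b:
            i, j = idx[a], idx[b]
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {a!r} and {b!r}")
            idents.append(100.0 * float((mat[i][both] == mat[j][both]).sum()) / m)
    arr = np.asarray(idents)
    return {
        "mean": round(float(arr.mean()), 1),
        "min": round(float(arr.min()), 1),
        "max": round(float(arr.max()), 1),
        "n_pairs": len(idents),
    }


def assortment(
    per_region: dict[str, ProteotypeAssignment],
    region_order: Sequence[str],
    anchor: str | None = None,
) -> pd.DataFrame:
    """Taxa x regions table of proteotype ids, in genomic region order.

    Ids are per-region and not comparable across regions. If ``anchor``
    names a region, rows are sorted by that region's id (then taxon name),
    mirroring sorting the display by the anchoring gene.
    """
    missing = [r for r in region_order if r not in per_region]
    if missing:
        raise ValueError(f"regions without assignments: {missing}")
    taxa = set(per_region[region_order[0]].ids)
    for r in region_order[1:]:
        if set(per_region[r].ids) != taxa:
            raise ValueError(f"taxon set mismatch in region {r!r}")
    table = pd.DataFrame(
        {r: pd.Series(per_region[r].ids) for r in region_order}
    ).rename_axis("taxon")
    if anchor is not None:
        if anchor not in region_order:
            raise ValueError(f"anchor region {anchor!r} not in region order")
        table = table.sort_index(kind="stable").sort_values(by=anchor, kind="stable")
    return table


def breakpoints(table: pd.DataFrame, taxon_pair: tuple[str, str]) -> list[tuple[str, str]]:
    """Region boundaries at which a taxon pair flips between sharing and not
    sharing a proteotype id, in genomic order."""
    a, b = taxon_pair
    for t in (a, b):
        if t not in table.index:
            raise KeyError(t)
    share = (table.loc[a] == table.loc[b]).to_numpy()
    regions = list(table.columns)
    return [
        (regions[i], regions[i + 1])
        for i in range(len(regions) - 1)
        if share[i] != share[i + 1]
    ]
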