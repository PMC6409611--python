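"""Relative synonymous codon usage (RSCU) and correspondence analysis.

RSCU for codon *c* of an amino acid with an *n*-codon synonymous family is

    RSCU(c) = n * count(c) / sum over the family of counts,

so 1 means no bias and the values over each family average to 1. Following
the usual convention, the single-codon families (ATG, TGG) and stop codons
are excluded, leaving 59 informative codons.

Correspondence analysis projects the taxa x 59 table into a low-dimensional
space: with P the table over its grand total, r and c its margins, the SVD
of the standardised residuals ``D_r^{-1/2} (P - r c') D_c^{-1/2}`` yields
principal coordinates whose inter-point distances approximate chi-square
distances between usage profiles. CA is run on RSCU values by default (an
option runs it on raw counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._codons import CODON_INDEX, FAMILIES, RSCU_CODONS
from .seqio import CodonAlignment

__all__ = [
    "RSCU_CODONS",
    "rscu",
    "rscu_matrix",
    "CAResult",
    "correspondence_analysis",
    "group_separation",
]


def _codon_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for k in range(len(seq) // 3):
        codon = seq[3 * k : 3 * k + 3]
        if codon in CODON_INDEX:
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def rscu(seq_or_counts) -> pd.Series:
    """RSCU values over the 59 informative codons for one coding sequence.

    Accepts an in-frame nucleotide string (gap and ambiguous codons are
    skipped) or a precomputed codon-count mapping. Codons of an amino acid
    absent from the sequence are reported as 0.
    """
    if isinstance(seq_or_counts, str):
        if len(seq_or_counts) % 3:
            raise ValueError("sequence length is not a multiple of 3")
        counts = _codon_counts(seq_or_counts)
    else:
        counts = dict(seq_or_counts)
    values = {}
    for aa, family in FAMILIES.items():
        n = len(family)
        if n == 1:
            continue
        total = sum(counts.get(c, 0) for c in family)
        for c in family:
            values[c] = n * counts.get(c, 0) / total if total else 0.0
    return pd.Series([values[c] for c in RSCU_CODONS], index=list(RSCU_CODONS))


def rscu_matrix(
    alignment: CodonAlignment, region: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Taxa x 59 RSCU matrix, optionally restricted to a column region
    (0-based, half-open, codon-aligned nucleotide coordinates)."""
    from .seqio import extract_region

    if region is not None:
        alignment = extract_region(alignment, region)
    rows = {rec.id: rscu(rec.seq) for rec in alignment.records}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class CAResult:
    """Correspondence-analysis embedding of a non-negative table."""

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    singular_values: np.ndarray
    inertia: np.ndarray  # per retained dimension, as fractions of total
    total_inertia: float
    dropped_rows: list
    dropped_cols: list


def correspondence_analysis(table: pd.DataFrame, n_components: int = 2) -> CAResult:
    """Standard correspondence analysis via SVD of standardised residuals.

    Rows and columns with zero sums are dropped (and recorded). Principal
    coordinates: rows ``D_r^{-1/2} U S``, columns ``D_c^{-1/2} V S``. Total
    inertia equals the table's chi-square statistic over its grand total.
    """
    x = table.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("correspondence analysis requires a non-negative table")
    row_ok = x.sum(axis=1) > 0
    col_ok = x.sum(axis=0) > 0
    dropped_rows = [i for i, ok in zip(table.index, row_ok) if not ok]
    dropped_cols = [c for c, ok in zip(table.columns, col_ok) if not ok]
    x = x[np.ix_(row_ok, col_ok)]
    if x.size == 0 or x.sum() == 0:
        raise ValueError("degenerate table: no positive mass")
    p = x / x.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    total_inertia = float((sv**2).sum())
    ncomp = min(n_components, len(sv))
    rows = (u[:, :ncomp] * sv[:ncomp]) / np.sqrt(r)[:, None]
    cols = (vt.T[:, :ncomp] * sv[:ncomp]) / np.sqrt(c)[:, None]
    dims = [f"dim{i + 1}" for i in range(ncomp)]
    inertia = (sv[:ncomp] ** 2) / total_inertia if total_inertia > 0 else np.zeros(ncomp)
    return CAResult(
        row_coords=pd.DataFrame(rows, index=table.index[row_ok], columns=dims),
        col_coords=pd.DataFrame(cols, index=table.columns[col_ok], columns=dims),
        singular_values=sv[:ncomp],
        inertia=inertia,
        total_inertia=total_inertia,
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
    )


def plot_ca(ca_result: CAResult, group_labels: dict | None = None, path=None):
    """Scatter the first two CA dimensions (taxa), optionally colored by
    group. Requires matplotlib; returns the figure, saving to ``path`` if
    given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = ca_result.row_coords
    fig, ax = plt.subplots(figsize=(5, 4))
    if group_labels is None:
        ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=25)
    else:
        for g in sorted({group_labels[t] for t in coords.index}):
            sel = [t for t in coords.index if group_labels[t] == g]
            sub = coords.loc[sel]
            ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=25, label=f"group {g}")
        ax.legend(frameon=False)
    pct = 100 * ca_result.inertia
    ax.set_xlabel(f"dim 1 ({pct[0]:.1f}% inertia)")
    if len(pct) > 1:
        ax.set_ylabel(f"dim 2 ({pct[1]:.1f}% inertia)")
    ax.axhline(0, lw=0.5, color="0.7")
    ax.axvline(0, lw=0.5, color="0.7")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def group_separation(ca_result: CAResult, group_labels: dict) -> dict:
    """Silhouette score of group labels in the 2-D embedding, with group
    centroids. A quantitative stand-in for visual group separation in the
    ordination plot; returns 0 (flagged) for a degenerate embedding."""
    from sklearn.metrics import silhouette_score

    coords = ca_result.row_coords
    labels = [group_labels[t] for t in coords.index]
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    counts = {g: labels.count(g) for g in uniq}
    empty = [g for g, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"empty group(s): {empty}")
    xy = coords.to_numpy()
    centroids = {
        g: xy[[l == g for l in labels]].mean(axis=0).tolist() for g in uniq
    }
    if np.allclose(xy.std(axis=0), 0):
        return {"silhouette": 0.0, "centroids": centroids, "degenerate": True}
    score = float(silhouette_score(xy, labels))
    return {"silhouette": score, "centroids": centroids, "degenerate": False}
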