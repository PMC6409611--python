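"""Standard genetic code tables shared across the package.

Everything here is derived once, at import time, from Biopython's standard
codon table (NCBI table 1): the 61 sense codons, the synonymous-family map,
and the single-nucleotide neighbour structure used by the codon rate matrix.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: stop codons of the standard code (TAA, TAG, TGA)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: the 61 sense codons, alphabetical, fixed package-wide ordering
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid (one-letter) encoded by each sense codon, same order
CODON_AA: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

#: amino acid -> list of synonymous sense codons
FAMILIES: dict[str, list[str]] = {}
for _c, _a in zip(SENSE_CODONS, CODON_AA):
    FAMILIES.setdefault(_a, []).append(_c)

#: the 59 codons informative for synonymous usage bias: 61 sense codons
#: minus the single-codon families ATG (Met) and TGG (Trp)
RSCU_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if len(FAMILIES[CODON_AA[CODON_INDEX[c]]]) > 1
)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES)


def _neighbour_structure():
    """Index arrays over ordered codon pairs differing at exactly one site."""
    src, dst, ts, syn, pos = [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            src.append(i)
            dst.append(j)
            pos.append(k)
            ts.append(_is_transition(ci[k], cj[k]))
            syn.append(CODON_AA[i] == CODON_AA[j])
    return (
        np.asarray(src, dtype=np.intp),
        np.asarray(dst, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(syn, dtype=bool),
        np.asarray(pos, dtype=np.intp),
    )


#: PAIR_I/PAIR_J index the single-nucleotide-difference codon pairs;
#: PAIR_TS marks transitions, PAIR_SYN synonymous changes, PAIR_POS the
#: codon position (0..2) at which the pair differs.
PAIR_I, PAIR_J, PAIR_TS, PAIR_SYN, PAIR_POS = _neighbour_structure()

NUC_ORDER = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUC_ORDER)}

#: 61 x 3 array of nucleotide indices of each sense codon at each position
CODON_NUC = np.array(
    [[NUC_INDEX[b] for b in codon] for codon in SENSE_CODONS], dtype=np.intp
)
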