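"""Independent oracles: slow, direct computations used to check the fast paths.

Kept deliberately naive — exhaustive enumeration and scipy expm — and
independent of the pruning/spectral code under test.
"""

import itertools

import numpy as np
from scipy.linalg import expm

from cladediv._codons import CODON_INDEX
from cladediv.clademodel import _rate_matrix_unscaled


def brute_force_loglik(alignment, tree, params, pi):
    """Clade-model ln-likelihood by enumerating all internal-node states.

    Missing leaves (gap/ambiguous codons) contribute a factor
    ``sum_j P[parent, j] = 1`` and are skipped, which marginalises them
    exactly. Only feasible for <= 4 taxa and a few sites.
    """
    p_weights = list(params.proportions)
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]

    def flow(w):
        q = _rate_matrix_unscaled(params.kappa, w, pi)
        return -(pi * np.diag(q)).sum()

    p0, p1, p2 = p_weights
    rate = p0 * flow(params.omega0) + p1 * flow(1.0) + p2 * flow(params.omega2[0])

    def pmat(node, w):
        q = _rate_matrix_unscaled(params.kappa, w, pi)
        return expm(q * node.length / rate)

    seqs = {r.id: r.seq for r in alignment.records}
    omega_of_class = [
        lambda k: params.omega0,
        lambda k: 1.0,
        lambda k: params.omega2[k],
    ]
    total = 0.0
    for s in range(alignment.n_codons):
        obs = {
            id(lf): CODON_INDEX.get(seqs[lf.name][3 * s : 3 * s + 3], -1)
            for lf in leaves
        }
        site_lik = 0.0
        for weight, w_of in zip(p_weights, omega_of_class):
            if weight == 0:
                continue
            mats = {
                id(n): pmat(n, w_of(n.partition))
                for n in nodes
                if n.parent is not None
            }
            lik = 0.0
            for assign in itertools.product(range(61), repeat=len(internals)):
                st = {id(n): a for n, a in zip(internals, assign)}
                pr = pi[st[id(nodes[-1])]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    target = st[id(n)] if not n.is_leaf else obs[id(n)]
                    if target == -1:
                        continue
                    pr *= mats[id(n)][st[id(n.parent)], target]
                lik += pr
            site_lik += weight * lik
        total += np.log(site_lik)
    return float(total)
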