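"""Clade model C: divergent selection between clade partitions of a tree.

The substrate is the Goldman–Yang codon substitution model on the 61 sense
codons: substitutions touch one codon position at a time, with rate
``pi_j * kappa^[transition] * omega^[nonsynonymous]``. Clade model C layers
three site classes on top:

* class 0 — purifying, ``0 < omega0 < 1``, shared by all branches;
* class 1 — neutral, ``omega = 1`` fixed;
* class 2 — *divergent*: its omega differs between clade partitions of the
  tree, ``omega2[k]`` on branches labeled ``k``.

A fit with the focal clade merged into one partition (K = 2: background +
focal) is the null; splitting the focal clade (K = 3) adds exactly one free
parameter, and twice the log-likelihood difference is referred to a χ²(1)
distribution — the likelihood-ratio test of divergent selection between the
subclades.

Usage follows the Model/Results convention::

    model = CladeModelC(codon_alignment, labeled_tree)
    res = model.fit(seed=0)
    print(res.summary())
    test = lrt(res_null, res_alt)

Free parameters (``k_params``): one per branch (unless branch lengths are
fixed), plus kappa, two site-class proportions, omega0, and K divergent
omegas — for an unrooted binary tree on n taxa with K partitions,
``(2n-3) + 4 + K``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import expit, logit
from scipy.stats import chi2

from ._codons import (
    CODON_INDEX,
    CODON_NUC,
    PAIR_I,
    PAIR_J,
    PAIR_SYN,
    PAIR_TS,
)
from .phylo import LabeledTree
from .seqio import CodonAlignment

__all__ = [
    "CodonModelParams",
    "CladeModelC",
    "CladeModelCResults",
    "LRTResult",
    "build_rate_matrix",
    "transition_probs",
    "codon_frequencies",
    "fit_nested_pair",
    "lrt",
    "lrt_from_loglik",
    "chi2_sf",
]

N_CODONS = 61


# ---------------------------------------------------------------------------
# rate matrix and transition probabilities


def _rate_matrix_unscaled(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    q = np.zeros((N_CODONS, N_CODONS))
    rates = pi[PAIR_J] * np.where(PAIR_TS, kappa, 1.0) * np.where(PAIR_SYN, 1.0, omega)
    q[PAIR_I, PAIR_J] = rates
    q[np.arange(N_CODONS), np.arange(N_CODONS)] = -q.sum(axis=1)
    return q


def _flow(q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time under ``q``."""
    return float(-(pi * np.diag(q)).sum())


def build_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, scale: bool = True
) -> np.ndarray:
    """61x61 codon substitution generator.

    Off-diagonal entries are nonzero only for codon pairs differing at a
    single position; the diagonal makes rows sum to zero. With ``scale``,
    the generator is normalised so the expected substitution rate
    ``-sum_i pi_i q_ii`` equals 1, i.e. branch lengths are expected
    substitutions per codon at this omega. (Inside :class:`CladeModelC` the
    normalisation instead uses the site-class mixture average of the
    background partition, so one scale is shared by all classes and
    partitions.)
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
        raise ValueError("pi must be 61 strictly positive frequencies summing to 1")
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    q = _rate_matrix_unscaled(kappa, omega, pi)
    if scale:
        q = q / _flow(q, pi)
    return q


def transition_probs(q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1, P(0) = I."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return scipy.linalg.expm(q * t)


class _SpectralQ:
    """Eigendecomposition of a reversible codon generator.

    The GY94 generator satisfies detailed balance with respect to ``pi``, so
    ``diag(sqrt(pi)) Q diag(1/sqrt(pi))`` is symmetric and P(t) follows from
    a single symmetric eigendecomposition per omega — much cheaper than one
    ``expm`` per branch.
    """

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        q = _rate_matrix_unscaled(kappa, omega, pi)
        self.rate = _flow(q, pi)
        sq = np.sqrt(pi)
        sym = q * (sq[:, None] / sq[None, :])
        w, v = np.linalg.eigh(0.5 * (sym + sym.T))
        self.w = w
        self.left = v / sq[:, None]
        self.right = (v * sq[:, None]).T

    def transition(self, t: float) -> np.ndarray:
        # generator eigenvalues are <= 0; clip numerical noise above 0
        p = (self.left * np.exp(np.minimum(self.w * t, 0.0))) @ self.right
        np.maximum(p, 0.0, out=p)
        return p


# ---------------------------------------------------------------------------
# codon frequencies


def codon_frequencies(alignment: CodonAlignment, kind: str = "F3x4") -> np.ndarray:
    """Equilibrium codon frequencies.

    ``F3x4``: products of empirical position-specific nucleotide frequencies,
    renormalised over sense codons (the usual empirical choice; not counted
    as free parameters). ``F61``: empirical codon frequencies with a small
    pseudocount. ``uniform``: 1/61.
    """
    if kind == "uniform":
        return np.full(N_CODONS, 1.0 / N_CODONS)
    counts3 = np.zeros((3, 4))
    counts61 = np.zeros(N_CODONS)
    for rec in alignment.records:
        for k in range(alignment.n_codons):
            codon = rec.seq[3 * k : 3 * k + 3]
            idx = CODON_INDEX.get(codon)
            if idx is None:
                continue
            counts61[idx] += 1
            counts3[np.arange(3), CODON_NUC[idx]] += 1
    if kind == "F61":
        pi = counts61 + 0.1
        return pi / pi.sum()
    if kind != "F3x4":
        raise ValueError(f"unknown frequency kind {kind!r}")
    counts3 += 0.1
    nucfreq = counts3 / counts3.sum(axis=1, keepdims=True)
    pi = (
        nucfreq[0, CODON_NUC[:, 0]]
        * nucfreq[1, CODON_NUC[:, 1]]
        * nucfreq[2, CODON_NUC[:, 2]]
    )
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# parameters


@dataclass
class CodonModelParams:
    """Clade model C parameter set.

    ``proportions`` are the three site-class weights (p0, p1, p2);
    ``omega2`` holds one divergent-class omega per clade partition
    (index 0 = background).
    """

    kappa: float
    proportions: tuple[float, float, float]
    omega0: float
    omega2: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not (0 < self.omega0 < 1):
            raise ValueError("omega0 must be in (0, 1)")
        if np.any(p < 0) or abs(p.sum() - 1) > 1e-8:
            raise ValueError("class proportions must be >= 0 and sum to 1")
        if any(w <= 0 for w in self.omega2):
            raise ValueError("divergent omegas must be > 0")

    @property
    def n_partitions(self) -> int:
        return len(self.omega2)


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested clade-model fits."""

    lr: float
    df: int
    pvalue: float
    flagged: bool = False

    def __str__(self) -> str:
        note = "  [flagged: LR <= 0, check convergence]" if self.flagged else ""
        return f"LR = {self.lr:.2f}, df = {self.df}, p = {self.pvalue:.3g}{note}"


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail χ² probability (accurate far into the tail)."""
    if x < 0:
        raise ValueError("x must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(chi2.sf(x, df))


def lrt_from_loglik(llf_null: float, llf_alt: float, np_null: int, np_alt: int) -> LRTResult:
    """LRT from ln-likelihoods and parameter counts of nested fits."""
    if np_alt <= np_null:
        raise ValueError("alternate model must have more parameters than the null")
    lr = 2.0 * (llf_alt - llf_null)
    df = np_alt - np_null
    return LRTResult(lr=lr, df=df, pvalue=chi2_sf(max(lr, 0.0), df), flagged=lr < 0)


def lrt(null_results, alt_results) -> LRTResult:
    """LRT between two fitted results (anything exposing llf and k_params)."""
    return lrt_from_loglik(
        null_results.llf, alt_results.llf, null_results.k_params, alt_results.k_params
    )


# ---------------------------------------------------------------------------
# the model


class CladeModelC:
    """Clade model C likelihood on a codon alignment and a labeled tree.

    Parameters
    ----------
    alignment
        In-frame codon alignment; gap and ambiguous codons are treated as
        missing data.
    tree
        :class:`~cladediv.phylo.LabeledTree` whose leaves match the
        alignment taxa and whose branches carry partition labels
        0..K-1 (0 = background).
    frequencies
        Codon equilibrium frequencies: ``"F3x4"`` (default), ``"F61"``,
        ``"uniform"``, or an explicit 61-vector.
    fix_branch_lengths
        Keep the input tree's branch lengths fixed instead of estimating
        them (faster; ``k_params`` drops the branch-length terms and fits
        are no longer comparable with branch-optimised ones).
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: LabeledTree,
        n_partitions: int | None = None,
        frequencies="F3x4",
        fix_branch_lengths: bool = False,
    ):
        if sorted(tree.leaf_names()) != sorted(alignment.taxa):
            raise ValueError("tree leaves do not match alignment taxa")
        self.alignment = alignment
        self.tree = tree.copy()
        self.fix_branch_lengths = fix_branch_lengths
        labels = sorted(self.tree.partitions)
        k_seen = max(labels) + 1
        self.n_partitions = n_partitions if n_partitions is not None else k_seen
        if self.n_partitions < k_seen:
            raise ValueError("tree uses more partitions than n_partitions")
        if isinstance(frequencies, str):
            self.pi = codon_frequencies(alignment, frequencies)
            self.frequencies = frequencies
        else:
            self.pi = np.asarray(frequencies, dtype=float)
            self.frequencies = "custom"
        self._index_tree()
        self._compress_patterns()

    # -- bookkeeping --------------------------------------------------------

    def _index_tree(self) -> None:
        post = self.tree.postorder()
        self._nodes = post  # root last
        self._node_id = {id(n): i for i, n in enumerate(post)}
        self._edge_nodes = [n for n in post if n.parent is not None]
        self._edge_index = {id(n): i for i, n in enumerate(self._edge_nodes)}
        for n in self._edge_nodes:
            if n.length is None or n.length < 0:
                raise ValueError("tree must have non-negative branch lengths")

    def _compress_patterns(self) -> None:
        n_codons = self.alignment.n_codons
        taxa_pos = {n.name: k for k, n in enumerate(self.tree.leaves())}
        states = np.full((len(taxa_pos), n_codons), -1, dtype=np.int64)
        for rec in self.alignment.records:
            row = taxa_pos[rec.id]
            for k in range(n_codons):
                codon = rec.seq[3 * k : 3 * k + 3]
                states[row, k] = CODON_INDEX.get(codon, -1)
        patterns, inverse, counts = np.unique(
            states, axis=1, return_inverse=True, return_counts=True
        )
        self._site_of_pattern = inverse
        self._patterns = patterns  # leaves x n_patterns
        self._weights = counts.astype(float)
        self._leaf_row = {name: r for name, r in taxa_pos.items()}
        # leaf partial likelihood matrices (61 x n_patterns)
        self._leaf_partials = {}
        for leaf in self.tree.leaves():
            codes = patterns[taxa_pos[leaf.name]]
            part = np.zeros((N_CODONS, len(codes)))
            obs = codes >= 0
            part[:, ~obs] = 1.0
            part[codes[obs], np.nonzero(obs)[0]] = 1.0
            self._leaf_partials[id(leaf)] = part

    @property
    def n_branches(self) -> int:
        return len(self._edge_nodes)

    @property
    def k_params(self) -> int:
        """Free-parameter count: branches (if estimated) + kappa + two
        class proportions + omega0 + one divergent omega per partition."""
        branch_terms = 0 if self.fix_branch_lengths else self.n_branches
        return branch_terms + 4 + self.n_partitions

    # -- likelihood ---------------------------------------------------------

    def loglike(
        self, params: CodonModelParams, branch_lengths: np.ndarray | None = None
    ) -> float:
        """ln-likelihood by Felsenstein pruning, vectorised over site
        patterns, with one spectral decomposition per distinct omega."""
        if params.n_partitions != self.n_partitions:
            raise ValueError("params.omega2 length does not match n_partitions")
        p0, p1, p2 = params.proportions
        if branch_lengths is None:
            blens = np.array([n.length for n in self._edge_nodes], dtype=float)
        else:
            blens = np.asarray(branch_lengths, dtype=float)
        omegas = {params.omega0, 1.0, *params.omega2}
        spectral = {w: _SpectralQ(params.kappa, w, self.pi) for w in omegas}
        # one global scale: the background-partition site-class mixture rate,
        # so branch lengths read as expected substitutions/codon on
        # background branches and the scale is identical across partitions
        rate = (
            p0 * spectral[params.omega0].rate
            + p1 * spectral[1.0].rate
            + p2 * spectral[params.omega2[0]].rate
        )
        rate_k = {k: rate for k in range(self.n_partitions)}
        class_omegas = [
            {k: params.omega0 for k in range(self.n_partitions)},
            {k: 1.0 for k in range(self.n_partitions)},
            {k: params.omega2[k] for k in range(self.n_partitions)},
        ]
        class_logs = []
        for omega_of in class_omegas:
            logl = self._class_site_loglik(omega_of, spectral, rate_k, blens)
            class_logs.append(logl)
        class_logs = np.vstack(class_logs)  # 3 x npat
        weights = np.array([p0, p1, p2])[:, None]
        mx = class_logs.max(axis=0)
        site_lik = (weights * np.exp(class_logs - mx)).sum(axis=0)
        if np.any(site_lik <= 0) or not np.all(np.isfinite(mx)):
            bad = np.nonzero((site_lik <= 0) | ~np.isfinite(mx))[0]
            sites = np.nonzero(np.isin(self._site_of_pattern, bad))[0]
            raise ValueError(f"zero site likelihood at site(s) {sites.tolist()}")
        return float((self._weights * (np.log(site_lik) + mx)).sum())

    def _class_site_loglik(self, omega_of, spectral, rate_k, blens) -> np.ndarray:
        npat = self._patterns.shape[1]
        partial = {}
        logscale = np.zeros(npat)
        for node in self._nodes:
            if node.is_leaf:
                partial[id(node)] = self._leaf_partials[id(node)]
                continue
            acc = np.ones((N_CODONS, npat))
            for ch in node.children:
                w = omega_of[ch.partition]
                t = blens[self._edge_index[id(ch)]] / rate_k[ch.partition]
                p = spectral[w].transition(t)
                acc *= p @ partial[id(ch)]
            if node.parent is not None:
                m = acc.max(axis=0)
                safe = np.where(m > 0, m, 1.0)
                acc = acc / safe
                logscale += np.where(m > 0, np.log(safe), -np.inf)
            partial[id(node)] = acc
        root = self._nodes[-1]
        lik = self.pi @ partial[id(root)]
        with np.errstate(divide="ignore"):
            return np.where(lik > 0, np.log(np.maximum(lik, 1e-320)), -np.inf) + logscale

    # -- fitting ------------------------------------------------------------

    def _pack(self, params: CodonModelParams, blens: np.ndarray | None) -> np.ndarray:
        p = np.asarray(params.proportions)
        z = [
            np.log(params.kappa),
            np.log(p[0] / p[2]),
            np.log(p[1] / p[2]),
            logit(params.omega0),
            *np.log(params.omega2),
        ]
        if not self.fix_branch_lengths:
            z.extend(np.log(np.maximum(blens, 1e-6)))
        return np.asarray(z, dtype=float)

    def _unpack(self, z: np.ndarray) -> tuple[CodonModelParams, np.ndarray | None]:
        z = np.clip(z, -40.0, 40.0)  # keep exp() finite on wild optimizer steps
        kappa = float(np.exp(z[0]))
        e0, e1 = np.exp(z[1]), np.exp(z[2])
        denom = 1.0 + e0 + e1
        props = (float(e0 / denom), float(e1 / denom), float(1.0 / denom))
        omega0 = float(np.clip(expit(z[3]), 1e-8, 1 - 1e-8))
        k = self.n_partitions
        omega2 = tuple(float(w) for w in np.exp(z[4 : 4 + k]))
        blens = None
        if not self.fix_branch_lengths:
            blens = np.exp(z[4 + k :])
        return CodonModelParams(kappa, props, omega0, omega2), blens

    def _default_starts(self, n_starts: int, seed: int) -> list[CodonModelParams]:
        k = self.n_partitions
        starts = [
            CodonModelParams(2.0, (0.5, 0.3, 0.2), 0.1, tuple([1.0] * k)),
            CodonModelParams(
                2.0, (0.4, 0.3, 0.3), 0.2, tuple(0.5 * 2.0**i for i in range(k))
            ),
        ]
        rng = np.random.default_rng(seed)
        while len(starts) < n_starts:
            p = rng.dirichlet([2.0, 2.0, 2.0])
            starts.append(
                CodonModelParams(
                    float(rng.lognormal(np.log(2.0), 0.3)),
                    tuple(p),
                    float(rng.uniform(0.02, 0.8)),
                    tuple(np.exp(rng.normal(0.0, 0.7, size=k))),
                )
            )
        return starts[:n_starts]

    def fit(
        self,
        start_params: CodonModelParams | None = None,
        n_starts: int = 3,
        seed: int = 0,
        maxiter: int = 500,
        ftol: float = 1e-9,
        warm_start_results: "CladeModelCResults | None" = None,
    ) -> "CladeModelCResults":
        """Maximise the likelihood over the transformed parameter space.

        Rates use log transforms, the class proportions a logistic simplex,
        omega0 a logit; the box-constrained problem becomes unconstrained
        and is solved with L-BFGS-B from ``n_starts`` starting points (the
        likelihood surface is multimodal), keeping the best ln-likelihood.
        ``warm_start_results`` seeds an extra start from a nested fit's
        solution, which also guarantees the nesting inequality numerically.
        """
        from scipy.optimize import minimize

        blens0 = np.array([n.length for n in self._edge_nodes], dtype=float)
        starts: list[tuple[CodonModelParams, np.ndarray]] = []
        if start_params is not None:
            starts.append((start_params, blens0))
        if warm_start_results is not None:
            wp = warm_start_results.params
            omega2 = list(wp.omega2)
            while len(omega2) < self.n_partitions:
                omega2.append(omega2[-1])
            starts.append(
                (
                    CodonModelParams(
                        wp.kappa, wp.proportions, wp.omega0,
                        tuple(omega2[: self.n_partitions]),
                    ),
                    warm_start_results.branch_lengths
                    if warm_start_results.branch_lengths is not None
                    else blens0,
                )
            )
        for sp in self._default_starts(max(n_starts - len(starts), 0), seed):
            starts.append((sp, blens0))

        def objective(z: np.ndarray) -> float:
            try:
                params, blens = self._unpack(z)
                return -self.loglike(params, blens)
            except (ValueError, FloatingPointError):
                return 1e12

        best = None
        for sp, bl in starts:
            z0 = self._pack(sp, bl)
            res = minimize(
                objective,
                z0,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": ftol, "maxcor": 20},
            )
            if best is None or res.fun < best.fun:
                best = res
        params, blens = self._unpack(best.x)
        llf = -float(best.fun)
        if blens is not None:
            for node, bl in zip(self._edge_nodes, blens):
                node.length = float(bl)
        converged = bool(best.success)
        if not converged:
            warnings.warn(
                f"clade model fit did not converge: {best.message}", RuntimeWarning
            )
        grad_norm = (
            float(np.linalg.norm(best.jac)) if getattr(best, "jac", None) is not None
            else float("nan")
        )
        return CladeModelCResults(
            model=self,
            params=params,
            branch_lengths=blens,
            llf=llf,
            converged=converged,
            n_iter=int(best.nit),
            grad_norm=grad_norm,
            message=str(best.message),
        )


def fit_nested_pair(
    alignment: CodonAlignment,
    alt_tree: LabeledTree,
    partition_collapse: dict[int, int] | None = None,
    seed: int = 0,
    n_starts: int = 3,
    ftol: float = 1e-9,
    fix_branch_lengths: bool = False,
) -> tuple["CladeModelCResults", "CladeModelCResults", LRTResult]:
    """Fit a nested pair of clade-model configurations and their LRT.

    The null configuration is derived from the alternate tree by *merging
    branch labels* per ``partition_collapse`` (default: 0 -> 0, every k > 0
    -> min(k, 1), i.e. the two focal subclades merge). Merging labels — as
    opposed to re-deriving the null labeling from leaf monophyly, which would
    absorb the merged clade's stem branch — keeps the null strictly nested in
    the alternate, so the LRT degrees of freedom equal the parameter-count
    difference.

    The alternate fit is warm-started from the null solution (guaranteeing
    the nesting inequality numerically); the null is then refit once more,
    warm-started from the alternate's solution with the divergent omegas of
    merged partitions collapsed to their geometric mean, and the better null
    ln-likelihood is kept. This cross warm-starting protects the LR statistic
    against one-sided optimisation error, which would otherwise inflate it.
    """
    from .phylo import merge_partitions

    alt_model = CladeModelC(
        alignment, alt_tree, fix_branch_lengths=fix_branch_lengths
    )
    if partition_collapse is None:
        partition_collapse = {
            k: min(k, 1) for k in range(alt_model.n_partitions)
        }
    null_tree = merge_partitions(alt_tree, partition_collapse)
    null_model = CladeModelC(
        alignment, null_tree, fix_branch_lengths=fix_branch_lengths
    )
    null_res = null_model.fit(n_starts=n_starts, seed=seed, ftol=ftol)
    alt_res = alt_model.fit(
        n_starts=n_starts, seed=seed, ftol=ftol, warm_start_results=null_res
    )
    # collapse the alternate solution onto the null parameter space
    w2 = np.zeros(null_model.n_partitions)
    cnt = np.zeros(null_model.n_partitions)
    for k_alt, k_null in partition_collapse.items():
        w2[k_null] += np.log(alt_res.params.omega2[k_alt])
        cnt[k_null] += 1
    collapsed = CodonModelParams(
        alt_res.params.kappa,
        alt_res.params.proportions,
        alt_res.params.omega0,
        tuple(np.exp(w2 / np.maximum(cnt, 1))),
    )
    null_re = null_model.fit(
        start_params=collapsed, n_starts=1, seed=seed, ftol=ftol
    )
    if null_re.llf > null_res.llf:
        null_res = null_re
    return null_res, alt_res, lrt(null_res, alt_res)


@dataclass
class CladeModelCResults:
    """Fitted clade model C: estimates, ln-likelihood and bookkeeping."""

    model: CladeModelC
    params: CodonModelParams
    branch_lengths: np.ndarray | None
    llf: float
    converged: bool
    n_iter: int
    grad_norm: float = float("nan")
    message: str = ""

    @property
    def k_params(self) -> int:
        return self.model.k_params

    @property
    def tree_length(self) -> float:
        if self.branch_lengths is not None:
            return float(np.sum(self.branch_lengths))
        return float(sum(n.length for n in self.model._edge_nodes))

    def summary(self) -> str:
        p = self.params
        k = self.model.n_partitions
        lines = [
            "Clade Model C Results",
            "=" * 54,
            f"No. taxa:            {self.model.alignment.n_taxa}",
            f"No. codons:          {self.model.alignment.n_codons}",
            f"Clade partitions:    {k}",
            f"Codon frequencies:   {self.model.frequencies}",
            f"Branch lengths:      "
            f"{'fixed' if self.model.fix_branch_lengths else 'estimated'}",
            f"ln L:                {self.llf:.2f}",
            f"Np:                  {self.k_params}",
            f"Converged:           {self.converged} ({self.n_iter} iterations)",
            "-" * 54,
            f"kappa (ts/tv):       {p.kappa:.3f}",
            f"p0, p1, p2:          {p.proportions[0]:.3f}, "
            f"{p.proportions[1]:.3f}, {p.proportions[2]:.3f}",
            f"omega0 (purifying):  {p.omega0:.3f}",
            f"omega1 (neutral):    1 (fixed)",
        ]
        for i, w in enumerate(p.omega2):
            tag = "background" if i == 0 else f"partition {i}"
            lines.append(f"omega2[{i}] ({tag}): {w:.3f}")
        lines.append(f"tree length:         {self.tree_length:.3f}")
        lines.append("=" * 54)
        return "\n".join(lines)
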