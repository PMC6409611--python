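"""Synthetic codon alignments with planted clade-divergence structure.

The generator is the generative twin of the clade-model-C likelihood: a
species-level tree carries two focal subclades on a background, sites fall
into purifying / neutral / divergent classes, and the divergent class's
omega differs between clade partitions — but only inside a designated
divergent window of the gene (emulating a conserved-region sub-domain such
as a 62-codon transactivation region inside a ~253-codon gene). Outside the
window the divergent omegas collapse to the background value, so excising
the window removes the planted signal.

Codon usage bias is planted separately (:func:`plant_codon_bias`): post-hoc
synonymous resampling toward group-preferred codons, which changes exactly
what RSCU measures while leaving the amino-acid sequence — and hence the
dN/dS structure — untouched.

All randomness flows from the config seed; outputs are bit-identical across
re-runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._codons import CODON_AA, CODON_INDEX, FAMILIES, SENSE_CODONS
from .clademodel import _SpectralQ
from .phylo import LabeledTree, Node, label_clades
from .seqio import CodonAlignment, SequenceRecord, write_fasta

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_tree",
    "simulate_partitioned_tree",
    "simulate_codon_alignment",
    "plant_codon_bias",
    "make_fixture_set",
]

N_CODONS61 = 61


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a 253-codon gene with a 62-codon divergent window and
    two focal subclades on a multi-species background: strong purifying
    pressure on half the sites, a neutral class, and a divergent class whose
    omega is mildly purifying in group 1 and positively selected in group 2
    inside the window only.
    """

    n_background: int = 4
    n_group1: int = 5
    n_group2: int = 5
    n_codons: int = 253
    window_start: int = 138  # codons, 0-based
    window_length: int = 62
    proportions: tuple[float, float, float] = (0.5, 0.2, 0.3)
    omega0: float = 0.1
    omega2: tuple[float, float, float] = (1.0, 0.15, 3.5)
    depth: float = 0.6  # expected root-to-tip substitutions/codon
    seed: int = 0
    tree_newick: str | None = None  # optional user topology (labeled)

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions)
        if abs(p.sum() - 1) > 1e-8 or np.any(p < 0):
            raise ValueError("proportions must be non-negative and sum to 1")
        if not (0 <= self.window_start
                and self.window_start + self.window_length <= self.n_codons):
            raise ValueError("divergent window outside the gene")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def n_taxa(self) -> int:
        return self.n_background + self.n_group1 + self.n_group2

    @property
    def n_partitions(self) -> int:
        return len(self.omega2)


@dataclass
class TruthRecord:
    """Generating truth emitted alongside a synthetic alignment."""

    site_classes: np.ndarray  # 0/1/2 per codon site
    window: tuple[int, int]  # codon interval [start, end)
    group_labels: dict[str, int]
    config: SimulationConfig
    tree: LabeledTree


def _yule_topology(n_taxa: int, rng: np.random.Generator) -> Node:
    """Pure-birth topology with exponential waiting times, unit birth rate."""
    root = Node()
    a, b = Node(), Node()
    root.add(a)
    root.add(b)
    tips = [a, b]
    t_of = {id(a): 0.0, id(b): 0.0}
    elapsed = 0.0
    while len(tips) < n_taxa:
        elapsed += rng.exponential(1.0 / len(tips))
        k = int(rng.integers(len(tips)))
        parent = tips.pop(k)
        parent.length = elapsed - t_of.pop(id(parent))
        c, d = Node(), Node()
        parent.add(c)
        parent.add(d)
        tips.extend([c, d])
        t_of[id(c)] = t_of[id(d)] = elapsed
    elapsed += rng.exponential(1.0 / len(tips))
    for tip in tips:
        tip.length = elapsed - t_of[id(tip)]
    return root


def simulate_tree(n_taxa: int, depth: float = 0.5, seed: int = 0) -> LabeledTree:
    """Random Yule tree with branch lengths rescaled so the root-to-tip
    expectation equals ``depth`` (substitutions/codon). Deterministic for a
    given seed; leaves are named t1..tN in tree order."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    root = _yule_topology(n_taxa, rng)
    tree = LabeledTree(root)
    for i, leaf in enumerate(tree.leaves()):
        leaf.name = f"t{i + 1}"
    depths = []
    for leaf in tree.leaves():
        d, n = 0.0, leaf
        while n.parent is not None:
            d += n.length
            n = n.parent
        depths.append(d)
    scale = depth / float(np.mean(depths))
    for node in tree.preorder():
        if node.length is not None:
            node.length *= scale
    return tree


def simulate_partitioned_tree(
    n_background: int,
    n_group1: int,
    n_group2: int,
    depth: float = 0.6,
    seed: int = 0,
) -> tuple[LabeledTree, dict[str, int]]:
    """Tree with two planted focal subclades joined onto a background clade.

    Returns the clade-labeled tree and the taxon -> partition map
    (0 background, 1 group 1, 2 group 2). Subclade crowns are half as deep
    as the full tree, leaving a long internal stem that separates the
    groups.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for prefix, n, part in (
        ("bg", n_background, 0),
        ("g1", n_group1, 1),
        ("g2", n_group2, 2),
    ):
        if n == 1:
            sub = Node(name=f"{prefix}_1", length=depth / 2)
        else:
            sub = _yule_topology(n, np.random.default_rng(rng.integers(2**31)))
            subtree = LabeledTree(sub)
            for i, leaf in enumerate(subtree.leaves()):
                leaf.name = f"{prefix}_{i + 1}"
            crown = depth / 2
            depths = []
            for leaf in subtree.leaves():
                d, m = 0.0, leaf
                while m.parent is not None:
                    d += m.length
                    m = m.parent
                depths.append(d)
            scale = crown / float(np.mean(depths))
            for node in subtree.preorder():
                if node.length is not None:
                    node.length *= scale
            sub.length = depth / 2
        parts.append((sub, part))
    root = Node()
    bg, g1, g2 = parts[0][0], parts[1][0], parts[2][0]
    # unrooted shape: background crown children at the root + focal stem
    if bg.children:
        for ch in list(bg.children):
            root.add(ch)
            ch.length = (ch.length or 0) + (bg.length or 0) / 2
    else:
        root.add(bg)
    focal = Node(length=depth / 2)
    focal.add(g1)
    focal.add(g2)
    root.add(focal)
    tree = LabeledTree(root)
    mapping = {
        name: 0 if name.startswith("bg") else (1 if name.startswith("g1") else 2)
        for name in tree.leaf_names()
    }
    return label_clades(tree, mapping), mapping


def simulate_codon_alignment(
    config: SimulationConfig,
) -> tuple[CodonAlignment, TruthRecord]:
    """Evolve a codon alignment under the clade-model-C generative process.

    The root sequence is drawn from the equilibrium frequencies; each site
    gets a class by the configured proportions; along each branch, sites
    evolve by the GY94 process with omega set by (site class, branch
    partition), the divergent omegas applying only inside the window
    (``omega2[0]`` everywhere outside). Transition probabilities are exact
    (matrix exponential per branch), so no stop codon can ever arise.
    """
    rng = np.random.default_rng(config.seed)
    if config.tree_newick is not None:
        tree = LabeledTree.from_newick(config.tree_newick)
    else:
        tree, _ = simulate_partitioned_tree(
            config.n_background,
            config.n_group1,
            config.n_group2,
            depth=config.depth,
            seed=int(rng.integers(2**31)),
        )
    pi = np.full(N_CODONS61, 1.0 / N_CODONS61)
    p0, p1, p2 = config.proportions
    site_classes = rng.choice(3, size=config.n_codons, p=[p0, p1, p2])
    w_start = config.window_start
    w_end = config.window_start + config.window_length
    in_window = np.zeros(config.n_codons, dtype=bool)
    in_window[w_start:w_end] = True

    kappa = 2.0
    omegas = sorted({config.omega0, 1.0, *config.omega2})
    spectral = {w: _SpectralQ(kappa, w, pi) for w in omegas}
    # global scale = background mixture rate (matches the fitted model), so
    # sites outside the window are exchangeable across partitions
    rate = (
        p0 * spectral[config.omega0].rate
        + p1 * spectral[1.0].rate
        + p2 * spectral[config.omega2[0]].rate
    )
    rate_of = {k: rate for k in range(config.n_partitions)}

    def omega_at(site: int, partition: int) -> float:
        cls = site_classes[site]
        if cls == 0:
            return config.omega0
        if cls == 1:
            return 1.0
        return config.omega2[partition] if in_window[site] else config.omega2[0]

    states = {id(tree.root): rng.choice(N_CODONS61, size=config.n_codons, p=pi)}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_state = states[id(node.parent)]
        child_state = parent_state.copy()
        t = node.length / rate_of[node.partition]
        site_omega = np.array(
            [omega_at(s, node.partition) for s in range(config.n_codons)]
        )
        for w in np.unique(site_omega):
            sel = site_omega == w
            pmat = spectral[float(w)].transition(t)
            pmat = pmat / pmat.sum(axis=1, keepdims=True)
            rows = pmat[parent_state[sel]]
            u = rng.random(int(sel.sum()))
            child_state[sel] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
        states[id(node)] = child_state

    records = [
        SequenceRecord(
            leaf.name, "".join(SENSE_CODONS[s] for s in states[id(leaf)])
        )
        for leaf in tree.leaves()
    ]
    alignment = CodonAlignment(records)
    group_labels = {
        leaf.name: leaf.partition for leaf in tree.leaves()
    }
    truth = TruthRecord(
        site_classes=site_classes,
        window=(w_start, w_end),
        group_labels=group_labels,
        config=config,
        tree=tree,
    )
    return alignment, truth


def default_preferences(n_groups: int) -> dict[int, dict[str, str]]:
    """Group -> amino acid -> preferred codon; groups prefer codons at
    opposite ends of each synonymous family."""
    prefs: dict[int, dict[str, str]] = {}
    for g in range(n_groups):
        prefs[g] = {}
        for aa, family in FAMILIES.items():
            if len(family) > 1:
                fam = sorted(family)
                prefs[g][aa] = fam[(g * (len(fam) - 1)) // max(n_groups - 1, 1)]
    return prefs


def plant_codon_bias(
    alignment: CodonAlignment,
    group_labels: dict[str, int],
    strength: float,
    seed: int = 0,
    preferences: dict[int, dict[str, str]] | None = None,
) -> CodonAlignment:
    """Resample synonymous codons toward group-preferred codons.

    With probability ``strength`` each codon is replaced by its group's
    preferred synonymous codon; the translated protein is unchanged for any
    strength. ``strength = 0`` returns the alignment unmodified.
    """
    if not (0.0 <= strength <= 1.0):
        raise ValueError("strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_groups = max(group_labels.values()) + 1
    prefs = preferences if preferences is not None else default_preferences(n_groups)
    out = []
    for rec in alignment.records:
        g = group_labels[rec.id]
        codons = [rec.seq[3 * k : 3 * k + 3] for k in range(alignment.n_codons)]
        flips = rng.random(len(codons)) < strength
        new = []
        for codon, flip in zip(codons, flips):
            idx = CODON_INDEX.get(codon)
            if flip and idx is not None:
                aa = CODON_AA[idx]
                new.append(prefs[g].get(aa, codon))
            else:
                new.append(codon)
        out.append(SequenceRecord(rec.id, "".join(new)))
    return CodonAlignment(out, permissive=alignment.permissive)


def make_fixture_set(out_dir, seed: int = 0, config: SimulationConfig | None = None) -> dict:
    """Write a canonical synthetic bundle: alignment FASTA, labeled Newick,
    partition map TSV, truth TSV and the config as JSON. Byte-identical for
    a given seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config if config is not None else SimulationConfig(seed=seed)
    if config is not None and config.seed != seed:
        cfg = SimulationConfig(**{**asdict(config), "seed": seed})
    alignment, truth = simulate_codon_alignment(cfg)
    paths = {
        "alignment": out / "alignment.fasta",
        "tree": out / "tree.nwk",
        "partitions": out / "partitions.tsv",
        "truth": out / "truth.tsv",
        "config": out / "config.json",
    }
    write_fasta(alignment.records, paths["alignment"])
    paths["tree"].write_text(truth.tree.to_newick() + "\n")
    with open(paths["partitions"], "w") as fh:
        for taxon in alignment.taxa:
            fh.write(f"{taxon}\t{truth.group_labels[taxon]}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("site\tclass\tin_window\n")
        for s, cls in enumerate(truth.site_classes):
            inw = truth.window[0] <= s < truth.window[1]
            fh.write(f"{s}\t{int(cls)}\t{int(inw)}\n")
    cfg_dict = asdict(cfg)
    paths["config"].write_text(json.dumps(cfg_dict, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
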