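import numpy as np
import pytest

from cladediv import (
    ProteinAlignment,
    SequenceRecord,
    SimulationConfig,
    simulate_codon_alignment,
)


@pytest.fixture(scope="session")
def sim_bundle():
    """Canonical synthetic dataset under the default study conditions."""
    cfg = SimulationConfig(seed=11)
    alignment, truth = simulate_codon_alignment(cfg)
    return alignment, truth


@pytest.fixture(scope="session")
def small_sim_bundle():
    """Small, fast dataset for likelihood fits in unit tests."""
    cfg = SimulationConfig(
        n_background=2,
        n_group1=2,
        n_group2=2,
        n_codons=40,
        window_start=0,
        window_length=40,
        depth=0.5,
        seed=23,
    )
    alignment, truth = simulate_codon_alignment(cfg)
    return alignment, truth


def planted_protein_alignment(
    n_per_group=5,
    n_cols=100,
    between_frac=0.2,
    within_frac=0.02,
    seed=0,
):
    """Two-group protein alignment: groups differ at ``between_frac`` of
    columns, members carry ``within_frac`` private noise."""
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    base = rng.choice(aas, size=n_cols)
    group2 = base.copy()
    flip = rng.choice(n_cols, size=int(between_frac * n_cols), replace=False)
    for c in flip:
        group2[c] = rng.choice(aas[aas != group2[c]])
    records = []
    for g, proto, prefix in ((1, base, "x"), (2, group2, "y")):
        for i in range(n_per_group):
            row = proto.copy()
            noise = rng.choice(
                n_cols, size=int(within_frac * n_cols), replace=False
            )
            for c in noise:
                row[c] = rng.choice(aas[aas != row[c]])
            records.append(SequenceRecord(f"{prefix}{i}", "".join(row)))
    truth = {r.id: 1 if r.id.startswith("x") else 2 for r in records}
    return ProteinAlignment(records), truth
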