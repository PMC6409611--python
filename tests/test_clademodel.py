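import numpy as np
import pytest

from cladediv import (
    CladeModelC,
    CodonAlignment,
    CodonModelParams,
    LabeledTree,
    SequenceRecord,
    SimulationConfig,
    chi2_sf,
    lrt_from_loglik,
    simulate_codon_alignment,
)
from cladediv._codons import PAIR_I, PAIR_J, PAIR_SYN, SENSE_CODONS
from cladediv.clademodel import build_rate_matrix, transition_probs
from cladediv.phylo import label_clades
from tests._oracles import brute_force_loglik

UNIFORM = np.full(61, 1 / 61.0)


def random_codon_alignment(taxa, n_codons, seed):
    rng = np.random.default_rng(seed)
    return CodonAlignment(
        [
            SequenceRecord(
                t, "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, n_codons))
            )
            for t in taxa
        ]
    )


class TestRateMatrix:
    def test_rows_sum_to_zero(self):
        q = build_rate_matrix(2.5, 0.4, UNIFORM, scale=False)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_detailed_balance_under_uniform_frequencies(self):
        q = build_rate_matrix(3.0, 0.7, UNIFORM)
        flux = UNIFORM[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        q = build_rate_matrix(2.0, 0.0, UNIFORM, scale=False)
        assert np.all(q[PAIR_I[~PAIR_SYN], PAIR_J[~PAIR_SYN]] == 0.0)
        assert np.any(q[PAIR_I[PAIR_SYN], PAIR_J[PAIR_SYN]] > 0.0)

    def test_scaling_normalises_flow(self):
        q = build_rate_matrix(2.0, 0.5, UNIFORM, scale=True)
        assert -(UNIFORM * np.diag(q)).sum() == pytest.approx(1.0)

    def test_multi_position_changes_forbidden(self):
        q = build_rate_matrix(2.0, 0.5, UNIFORM, scale=False)
        for i, ci in enumerate(SENSE_CODONS[:10]):
            for j, cj in enumerate(SENSE_CODONS):
                ndiff = sum(a != b for a, b in zip(ci, cj))
                if ndiff > 1:
                    assert q[i, j] == 0.0

    def test_invalid_frequencies(self):
        with pytest.raises(ValueError, match="pi"):
            build_rate_matrix(2.0, 0.5, np.ones(61))


class TestTransitionProbs:
    def test_identity_at_zero(self):
        q = build_rate_matrix(2.0, 0.5, UNIFORM)
        assert np.allclose(transition_probs(q, 0.0), np.eye(61))

    def test_rows_are_distributions(self):
        q = build_rate_matrix(2.0, 0.5, UNIFORM)
        p = transition_probs(q, 0.7)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(p >= -1e-15)

    def test_semigroup_property(self):
        q = build_rate_matrix(2.0, 0.5, UNIFORM)
        assert np.allclose(
            transition_probs(q, 0.5),
            transition_probs(q, 0.2) @ transition_probs(q, 0.3),
            atol=1e-8,
        )

    def test_negative_time_rejected(self):
        q = build_rate_matrix(2.0, 0.5, UNIFORM)
        with pytest.raises(ValueError):
            transition_probs(q, -0.1)


class TestPruningLikelihood:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(3, 5))
        n_sites = int(rng.integers(1, 4))
        taxa = [chr(ord("a") + i) for i in range(n_taxa)]
        if n_taxa == 3:
            nwk = f"({taxa[0]}:0.2,{taxa[1]}:0.3,{taxa[2]}$1:0.4);"
        else:
            nwk = (
                f"(({taxa[0]}:0.2,{taxa[1]}:0.3)$1:0.15,"
                f"({taxa[2]}:0.25,{taxa[3]}:0.1)$2:0.2);"
            )
        tree = LabeledTree.from_newick(nwk)
        aln = random_codon_alignment(taxa, n_sites, seed + 100)
        if seed % 2:  # plant a missing codon
            recs = aln.records
            recs[0] = SequenceRecord(recs[0].id, "---" + recs[0].seq[3:])
            aln = CodonAlignment(recs, permissive=True)
        k = max(n.partition for n in tree.preorder()) + 1
        params = CodonModelParams(
            float(rng.uniform(1.5, 4.0)),
            tuple(rng.dirichlet([3, 3, 3])),
            float(rng.uniform(0.05, 0.8)),
            tuple(np.exp(rng.normal(0, 0.6, size=k))),
        )
        model = CladeModelC(aln, tree, frequencies=UNIFORM, fix_branch_lengths=True)
        assert model.loglike(params) == pytest.approx(
            brute_force_loglik(aln, tree, params, UNIFORM), abs=1e-8
        )

    def test_two_taxon_short_branch_limit(self):
        # identical codons at t -> 0: site likelihood -> pi of the codon
        tree = LabeledTree.from_newick("(a:1e-9,b:1e-9);")
        aln = CodonAlignment(
            [SequenceRecord("a", "ATG"), SequenceRecord("b", "ATG")]
        )
        model = CladeModelC(aln, tree, frequencies=UNIFORM, fix_branch_lengths=True)
        params = CodonModelParams(2.0, (1 / 3, 1 / 3, 1 / 3), 0.5, (1.0,))
        assert model.loglike(params) == pytest.approx(np.log(1 / 61), abs=1e-5)

    def test_merged_partitions_match_single_partition_model(self):
        aln = random_codon_alignment(list("abcd"), 5, 0)
        t2 = LabeledTree.from_newick("((a:0.2,b:0.3)$1:0.15,(c:0.25,d:0.1)$1:0.2);")
        t1 = LabeledTree.from_newick("((a:0.2,b:0.3):0.15,(c:0.25,d:0.1):0.2);")
        m2 = CladeModelC(aln, t2, frequencies=UNIFORM, fix_branch_lengths=True)
        m1 = CladeModelC(aln, t1, frequencies=UNIFORM, fix_branch_lengths=True)
        p2 = CodonModelParams(2.3, (0.3, 0.3, 0.4), 0.2, (0.7, 0.7))
        p1 = CodonModelParams(2.3, (0.3, 0.3, 0.4), 0.2, (0.7,))
        assert m2.loglike(p2) == pytest.approx(m1.loglike(p1), abs=1e-9)

    def test_invariant_to_taxon_order_and_rerooting(self, small_sim_bundle):
        aln, truth = small_sim_bundle
        params = CodonModelParams(2.0, (0.4, 0.3, 0.3), 0.15, (1.0, 0.5, 2.0))
        base = CladeModelC(
            aln, truth.tree, frequencies=UNIFORM, fix_branch_lengths=True
        ).loglike(params)
        rev = aln.reorder(sorted(aln.taxa, reverse=True))
        assert CladeModelC(
            rev, truth.tree, frequencies=UNIFORM, fix_branch_lengths=True
        ).loglike(params) == pytest.approx(base, abs=1e-8)
        bg = [t for t, v in truth.group_labels.items() if v == 0][-1]
        rerooted = label_clades(
            truth.tree.rerooted_at_leaf(bg), truth.group_labels
        )
        assert CladeModelC(
            aln, rerooted, frequencies=UNIFORM, fix_branch_lengths=True
        ).loglike(params) == pytest.approx(base, abs=1e-8)

    def test_taxon_mismatch_rejected(self):
        aln = random_codon_alignment(list("ab"), 3, 1)
        tree = LabeledTree.from_newick("(a:1,x:1);")
        with pytest.raises(ValueError, match="match"):
            CladeModelC(aln, tree)


class TestParameterCounting:
    def test_unrooted_binary_tree_formula(self, small_sim_bundle):
        aln, truth = small_sim_bundle
        n = aln.n_taxa
        model = CladeModelC(aln, truth.tree)
        assert model.n_branches == 2 * n - 3
        assert model.k_params == (2 * n - 3) + 4 + 3

    def test_fixed_branch_lengths_drop_branch_terms(self, small_sim_bundle):
        aln, truth = small_sim_bundle
        model = CladeModelC(aln, truth.tree, fix_branch_lengths=True)
        assert model.k_params == 4 + 3


class TestChiSquare:
    def test_far_tail(self):
        assert chi2_sf(65.22, 1) == pytest.approx(6.71e-16, rel=5e-3)

    def test_moderate_tail(self):
        assert chi2_sf(2.58, 1) == pytest.approx(0.108, abs=5e-4)

    def test_zero_statistic(self):
        assert chi2_sf(0.0, 3) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            chi2_sf(-1.0, 1)
        with pytest.raises(ValueError):
            chi2_sf(1.0, 0)


class TestLRT:
    def test_from_loglikelihoods(self):
        res = lrt_from_loglik(-7622.25, -7589.64, 123, 124)
        assert res.lr == pytest.approx(65.22)
        assert res.df == 1

    def test_marginal_case(self):
        res = lrt_from_loglik(-5826.58, -5825.29, 123, 124)
        assert res.lr == pytest.approx(2.58)
        assert res.pvalue == pytest.approx(0.108, abs=5e-4)

    def test_equal_likelihoods(self):
        res = lrt_from_loglik(-100.0, -100.0, 5, 6)
        assert res.lr == 0.0 and res.pvalue == 1.0

    def test_negative_lr_is_flagged(self):
        assert lrt_from_loglik(-100.0, -101.0, 5, 6).flagged

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="more parameters"):
            lrt_from_loglik(-100.0, -99.0, 6, 6)


class TestFit:
    def test_fit_recovers_planted_divergent_omegas(self):
        hits = 0
        reps = 4
        for i in range(reps):
            cfg = SimulationConfig(
                n_background=3,
                n_group1=3,
                n_group2=3,
                n_codons=200,
                window_start=0,
                window_length=200,
                proportions=(0.4, 0.2, 0.4),
                omega0=0.1,
                omega2=(1.0, 0.5, 3.0),
                depth=0.7,
                seed=500 + i,
            )
            aln, truth = simulate_codon_alignment(cfg)
            model = CladeModelC(aln, truth.tree, fix_branch_lengths=True)
            res = model.fit(n_starts=2, seed=i, ftol=1e-7)
            ok = all(
                abs(res.params.omega2[k] - cfg.omega2[k]) <= 0.4 * cfg.omega2[k]
                for k in (1, 2)
            )
            hits += ok
        assert hits >= reps - 1

    def test_summary_reports_fit(self, small_sim_bundle):
        aln, truth = small_sim_bundle
        model = CladeModelC(aln, truth.tree, fix_branch_lengths=True)
        res = model.fit(n_starts=1, seed=0, ftol=1e-6)
        text = res.summary()
        assert "ln L" in text and "kappa" in text and f"Np:" in text
        assert res.k_params == 7
        assert np.isfinite(res.llf)
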