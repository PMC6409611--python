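import numpy as np
import pandas as pd
import pytest

from cladediv import (
    ProteinAlignment,
    SequenceRecord,
    assortment,
    breakpoints,
    call_proteotypes,
    consensus,
    intergroup_identity,
    signature_matrix,
)
from cladediv.proteotype import ProteotypeAssignment, pairwise_divergence
from tests.conftest import planted_protein_alignment


def aln_from(rows: dict[str, str]) -> ProteinAlignment:
    return ProteinAlignment([SequenceRecord(k, v) for k, v in rows.items()])


class TestConsensus:
    def test_majority_and_frequency(self):
        aln = aln_from({"1": "A", "2": "A", "3": "A", "4": "T"})
        prof = consensus(aln)
        assert prof.consensus == "A"
        assert prof.frequency[0] == pytest.approx(0.75)

    def test_alphabetical_tie_rule_exhaustive_pairs(self):
        # every 2-residue tie resolves to the alphabetically smaller residue
        for x in "ACDE":
            for y in "ACDE":
                if x == y:
                    continue
                prof = consensus(aln_from({"1": x, "2": y, "3": x, "4": y}))
                assert prof.consensus == min(x, y)

    def test_all_gap_column(self):
        prof = consensus(aln_from({"1": "-A", "2": "-A"}))
        assert prof.consensus[0] == "-"
        assert prof.frequency[0] == 0.0

    def test_identical_alignment(self):
        aln = aln_from({"1": "MKV", "2": "MKV"})
        prof = consensus(aln)
        assert prof.consensus == "MKV"
        assert np.all(prof.frequency == 1.0)


class TestSignatureMatrix:
    def test_identical_rows_all_consensus(self):
        aln = aln_from({"1": "MKV", "2": "MKV"})
        sig = signature_matrix(aln)
        assert (sig.to_numpy() == ".").all()

    def test_counts_non_consensus_tokens(self):
        base = "A" * 100
        variant = "T" * 3 + "A" * 97
        aln = aln_from({"1": base, "2": base, "3": variant})
        sig = signature_matrix(aln)
        row = sig.loc["3"].to_numpy()
        assert (row == "T").sum() == 3 and (row == ".").sum() == 97

    def test_gap_token_regardless_of_consensus(self):
        aln = aln_from({"1": "A-", "2": "AA", "3": "AA"})
        assert signature_matrix(aln).loc["1", 1] == "-"

    def test_rows_follow_leaf_order(self):
        aln = aln_from({"a": "MK", "b": "MK", "c": "MK"})
        sig = signature_matrix(aln, leaf_order=["c", "a", "b"])
        assert list(sig.index) == ["c", "a", "b"]

    def test_leaf_order_mismatch(self):
        aln = aln_from({"a": "MK", "b": "MK"})
        with pytest.raises(ValueError, match="permutation"):
            signature_matrix(aln, leaf_order=["a", "x"])


class TestCallProteotypes:
    def test_identical_alignment_single_proteotype(self):
        aln = aln_from({"1": "MKVA", "2": "MKVA", "3": "MKVA"})
        assert call_proteotypes(aln).n_proteotypes == 1

    def test_planted_groups_recovered(self):
        aln, truth = planted_protein_alignment(seed=1)
        calls = call_proteotypes(aln, threshold=0.10)
        assert calls.n_proteotypes == 2
        by_group = {
            g: {calls.ids[t] for t, tg in truth.items() if tg == g} for g in (1, 2)
        }
        assert len(by_group[1]) == 1 and len(by_group[2]) == 1
        assert by_group[1] != by_group[2]

    def test_brute_force_divergences_back_the_assignment(self):
        aln, truth = planted_protein_alignment(seed=2)
        d = pairwise_divergence(aln)
        mats = {r.id: np.array(list(r.seq)) for r in aln.records}
        for a in aln.taxa[:3]:
            for b in aln.taxa[-3:]:
                ok = (mats[a] != "-") & (mats[b] != "-")
                expect = (mats[a][ok] != mats[b][ok]).mean()
                assert d.loc[a, b] == pytest.approx(expect)

    def test_loose_threshold_merges_everything(self):
        aln, _ = planted_protein_alignment(seed=3)
        assert call_proteotypes(aln, threshold=1.0).n_proteotypes == 1

    def test_partition_invariant_to_row_and_column_order(self):
        # the grouping is order-invariant; id numbers may relabel on size ties
        aln, _ = planted_protein_alignment(seed=4)

        def clusters(assignment):
            groups = {}
            for t, k in assignment.ids.items():
                groups.setdefault(k, set()).add(t)
            return frozenset(frozenset(g) for g in groups.values())

        base = clusters(call_proteotypes(aln))
        rev = aln.reorder(sorted(aln.taxa, reverse=True))
        assert clusters(call_proteotypes(rev)) == base
        rng = np.random.default_rng(0)
        perm = rng.permutation(aln.length)
        shuffled = ProteinAlignment(
            [
                SequenceRecord(r.id, "".join(r.seq[i] for i in perm))
                for r in aln.records
            ]
        )
        assert clusters(call_proteotypes(shuffled)) == base

    def test_count_non_increasing_in_threshold(self):
        aln, _ = planted_protein_alignment(within_frac=0.06, seed=5)
        counts = [
            call_proteotypes(aln, threshold=t).n_proteotypes
            for t in (0.02, 0.05, 0.10, 0.25, 0.50)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_ids_ranked_by_cluster_size(self):
        aln, _ = planted_protein_alignment(n_per_group=4, seed=6)
        extra = ProteinAlignment(
            aln.records + [SequenceRecord("lone", "W" * aln.length)]
        )
        calls = call_proteotypes(extra)
        assert calls.ids["lone"] == calls.n_proteotypes  # smallest cluster last


class TestIntergroupIdentity:
    def test_identical_groups(self):
        aln = aln_from({"a": "MKVA", "b": "MKVA"})
        out = intergroup_identity(aln, ["a"], ["b"])
        assert (out["mean"], out["min"], out["max"]) == (100.0, 100.0, 100.0)

    def test_hand_counted_toy(self):
        # 10 columns, every cross pair shares exactly 6
        g1 = {"a1": "AAAAAAAAAA", "a2": "AAAAAAAAAA"}
        g2 = {"b1": "AAAAAACCCC", "b2": "AAAAAACCCC"}
        aln = aln_from({**g1, **g2})
        out = intergroup_identity(aln, list(g1), list(g2))
        assert out["mean"] == 60.0

    def test_disjoint_alphabets(self):
        aln = aln_from({"a": "AAAA", "b": "TTTT"})
        assert intergroup_identity(aln, ["a"], ["b"])["mean"] == 0.0

    def test_empty_group_rejected(self):
        aln = aln_from({"a": "AAAA", "b": "TTTT"})
        with pytest.raises(ValueError, match="non-empty"):
            intergroup_identity(aln, [], ["b"])


def assign(ids: dict[str, int]) -> ProteotypeAssignment:
    return ProteotypeAssignment(ids, {t: 0.0 for t in ids}, 0.10)


class TestAssortment:
    def test_single_region_equals_assignment(self):
        a = assign({"x": 1, "y": 2})
        table = assortment({"r1": a}, ["r1"])
        assert table["r1"].to_dict() == {"x": 1, "y": 2}

    def test_comembership_change_between_regions(self):
        # mirrors one taxon leaving a shared proteotype partway along the genome
        regions = ["e1a", "penton_hvl1", "penton_hvl2", "hexon"]
        per_region = {
            "e1a": assign({"d47": 1, "d56": 1, "d9": 1, "other": 2}),
            "penton_hvl1": assign({"d47": 1, "d56": 1, "d9": 1, "other": 2}),
            "penton_hvl2": assign({"d47": 3, "d56": 1, "d9": 1, "other": 2}),
            "hexon": assign({"d47": 3, "d56": 1, "d9": 1, "other": 2}),
        }
        table = assortment(per_region, regions, anchor="e1a")
        assert breakpoints(table, ("d47", "d56")) == [("penton_hvl1", "penton_hvl2")]
        assert breakpoints(table, ("d56", "d9")) == []

    def test_taxon_set_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            assortment(
                {"r1": assign({"x": 1}), "r2": assign({"y": 1})}, ["r1", "r2"]
            )

    def test_identical_regions_no_breakpoints(self):
        a = assign({"x": 1, "y": 1})
        table = assortment({"r1": a, "r2": a, "r3": a}, ["r1", "r2", "r3"])
        assert breakpoints(table, ("x", "y")) == []


class TestBreakpoints:
    def make_table(self, shares):
        # build a 2-taxon table from a share/differ pattern
        data = {"p": [], "q": []}
        for i, s in enumerate(shares):
            data["p"].append(1)
            data["q"].append(1 if s else 2)
        return pd.DataFrame(data, index=[f"r{i}" for i in range(len(shares))]).T

    def test_single_boundary(self):
        table = self.make_table([True, True, False, False])
        assert breakpoints(table, ("p", "q")) == [("r1", "r2")]

    def test_never_sharing_pair(self):
        table = self.make_table([False, False, False])
        assert breakpoints(table, ("p", "q")) == []

    def test_alternating_pattern(self):
        table = self.make_table([True, False, True, False])
        assert len(breakpoints(table, ("p", "q"))) == 3

    def test_unknown_taxon(self):
        table = self.make_table([True])
        with pytest.raises(KeyError):
            breakpoints(table, ("p", "zzz"))
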