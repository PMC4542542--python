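"""Clone processing, verification filtering, trimming and Hamming distances."""

import itertools

import numpy as np
import pytest

import sedlineage as sl
from sedlineage.errors import FormatError, InvalidArgumentError
from sedlineage.seqproc import MatchedPair

from conftest import random_lineage_set


class TestFastaIO:
    def test_round_trip_preserves_ids_order_and_sequences(self, tmp_path, rng):
        records = [
            sl.SequenceRecord(f"r{i}", "".join(rng.choice(list("ACGT"), size=30)))
            for i in range(100)
        ]
        path = tmp_path / "x.fasta"
        sl.write_fasta(records, path)
        back = sl.read_fasta(path)
        assert [r.id for r in back] == [r.id for r in records]
        assert [r.sequence for r in back] == [r.sequence for r in records]

    def test_lowercase_is_uppercased_on_read(self, tmp_path):
        (tmp_path / "x.fasta").write_text(">a\nacgt\n")
        assert sl.read_fasta(tmp_path / "x.fasta")[0].sequence == "ACGT"

    @pytest.mark.parametrize(
        "content", ["", ">a\nACGT\n>a\nACGT\n", ">a\nACXT\n"],
        ids=["empty", "duplicate-id", "non-iupac"],
    )
    def test_malformed_fasta_rejected(self, tmp_path, content):
        (tmp_path / "bad.fasta").write_text(content)
        with pytest.raises(FormatError):
            sl.read_fasta(tmp_path / "bad.fasta")


class TestDereplicate:
    def test_hand_tally(self):
        recs = [sl.SequenceRecord(f"c{i}", s, sample_id="s1")
                for i, s in enumerate(["AAA", "AAA", "AAA", "AAC", "AAC"])]
        types = sl.dereplicate([sl.CloneLibrary(recs, "s1")])
        assert [(t.sequence, t.clone_count) for t in types] == [("AAA", 3), ("AAC", 2)]

    def test_all_identical_collapses_to_one(self):
        recs = [sl.SequenceRecord(f"c{i}", "ACGT", sample_id="s") for i in range(7)]
        types = sl.dereplicate([sl.CloneLibrary(recs, "s")])
        assert len(types) == 1 and types[0].clone_count == 7

    def test_empty_input_gives_empty_list(self):
        assert sl.dereplicate([]) == []

    def test_unequal_lengths_rejected(self):
        recs = [sl.SequenceRecord("a", "AC", sample_id="s"),
                sl.SequenceRecord("b", "ACG", sample_id="s")]
        with pytest.raises(InvalidArgumentError):
            sl.dereplicate([sl.CloneLibrary(recs, "s")])

    def test_clone_counts_conserved(self, rng):
        libs = []
        n_clones = 0
        for s in range(4):
            recs = [
                sl.SequenceRecord(
                    f"s{s}c{i}",
                    "".join(rng.choice(list("ACGT"), size=10)),
                    sample_id=f"s{s}",
                    pcr_id=f"p{i % 2}",
                )
                for i in range(rng.integers(3, 12))
            ]
            n_clones += len(recs)
            libs.append(sl.CloneLibrary(recs, f"s{s}"))
        types = sl.dereplicate(libs)
        assert sum(t.clone_count for t in types) == n_clones


class TestVerification:
    def test_singleton_discarded_under_defaults(self):
        types = [
            sl.SequenceType("t1", "AAAA", clone_count=5, n_samples=2, n_pcrs=3),
            sl.SequenceType("t2", "AAAC", clone_count=1, n_samples=1, n_pcrs=1),
        ]
        kept, report = sl.verify_sequence_types(types)
        assert kept.sequences == ["AAAA"]
        assert list(report.type_id) == ["t2"]

    def test_disabled_filter_is_identity(self):
        types = [sl.SequenceType("t1", "AAAA", 1, 1, 1), sl.SequenceType("t2", "AAAC", 1, 1, 1)]
        kept, report = sl.verify_sequence_types(types, min_clones=1, min_pcrs=1)
        assert len(kept) == 2 and report.empty

    def test_retention_monotone_in_clone_count(self):
        base = dict(n_samples=1, n_pcrs=2)
        types = [sl.SequenceType(f"t{c}", "AAAA"[:3] + "ACGT"[c], clone_count=c, **base)
                 for c in range(1, 4)]
        kept, _ = sl.verify_sequence_types(types, min_clones=2, min_pcrs=2)
        kept_counts = {t for t in kept.sequences}
        assert all(("AAA" + "ACGT"[c] in kept_counts) == (c >= 2) for c in range(1, 4))

    def test_polymerase_error_variants_rejected_templates_kept(self):
        """Known templates survive verification; error-only variants are culled."""
        all_templates_kept = 0
        discarded = total = 0
        runs = 20
        for s in range(runs):
            base = sl.evolve_sequences(sl.simulate_tree(10, seed=s), 191, 0.05, seed=s)
            libs = [
                sl.simulate_clone_library(seq, 20, 0.002, seed=1000 * s + i,
                                          sample_id="s1", template_id=tid)
                for i, (tid, seq) in enumerate(zip(base.ids, base.sequences))
            ]
            types = sl.dereplicate(libs)
            kept, _ = sl.verify_sequence_types(types)
            tset, kset = set(base.sequences), set(kept.sequences)
            all_templates_kept += tset <= kset
            errs = [t.sequence for t in types if t.sequence not in tset]
            total += len(errs)
            discarded += sum(1 for e in errs if e not in kset)
        assert all_templates_kept == runs
        assert discarded / total >= 0.95


class TestTrimCollapse:
    def test_full_window_is_identity(self, tiny_lineages):
        out = sl.trim_to_subfragment(tiny_lineages, 0, tiny_lineages.length)
        assert out.sequences == tiny_lineages.sequences

    def test_direct_slice(self):
        ls = sl.LineageSet(["a"], ["ACGTACGT"])
        assert sl.trim_to_subfragment(ls, 2, 5).sequences == ["GTA"]

    def test_out_of_range_rejected(self, tiny_lineages):
        for start, end in [(-1, 4), (0, 99), (5, 3)]:
            with pytest.raises(InvalidArgumentError):
                sl.trim_to_subfragment(tiny_lineages, start, end)

    def test_hand_collapse_and_mapping(self):
        ls = sl.LineageSet(["s1", "s2", "s3"], ["AAA", "AAA", "AAC"])
        out, mapping = sl.collapse_identical(ls)
        assert out.sequences == ["AAA", "AAC"]
        assert mapping == {"s1": "s1", "s2": "s1", "s3": "s3"}

    def test_collapse_idempotent_and_no_dup_identity(self, rng):
        ls = random_lineage_set(rng, n=6, length=12)
        once, m1 = sl.collapse_identical(ls)
        assert once.sequences == ls.sequences  # distinct input: identity
        twice, m2 = sl.collapse_identical(once)
        assert twice.sequences == once.sequences

    def test_trim_then_collapse_never_increases_count(self, rng):
        for s in range(5):
            ls = random_lineage_set(np.random.default_rng(s), n=10, length=20)
            trimmed = sl.trim_to_subfragment(ls, 3, 8)
            collapsed, _ = sl.collapse_identical(trimmed)
            assert len(collapsed) <= len(ls)


class TestHamming:
    def test_simple_count(self):
        ls = sl.LineageSet(["a", "b"], ["ACGT", "ACGA"])
        assert sl.hamming_matrix(ls)["a", "b"] == 1

    def test_ambiguous_site_skipped_by_default(self):
        ls = sl.LineageSet(["a", "b"], ["ACGT", "ACNT"])
        assert sl.hamming_matrix(ls)["a", "b"] == 0
        assert sl.hamming_matrix(ls, site_policy="strict")["a", "b"] == 1

    def test_metric_axioms_on_random_sets(self):
        for s in range(5):
            ls = random_lineage_set(np.random.default_rng(s), n=7, length=15)
            d = sl.hamming_matrix(ls, site_policy="strict").data
            assert np.allclose(d, d.T)
            assert (np.diag(d) == 0).all()
            off = d[~np.eye(len(d), dtype=bool)]
            assert (off >= 1).all()  # distinct lineages differ somewhere
            n = len(d)
            for i, j, k in itertools.permutations(range(n), 3):
                assert d[i, j] <= d[i, k] + d[k, j]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sl.LineageSet(["a", "b"], ["ACG", "ACGT"])


class TestDistanceSummary:
    def test_single_pair(self):
        ls = sl.LineageSet(["a", "b"], ["A" * 67, "A" * 63 + "CCCC"])
        s = sl.distance_summary(sl.hamming_matrix(ls), 67)
        assert s == {"mean_count": 4.0, "max_count": 4.0, "mean_pct": 6.0, "max_pct": 6.0}

    def test_hand_mean_of_three(self):
        from skbio import DistanceMatrix
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float),
                           ids=list("abc"))
        assert sl.distance_summary(d, 67)["mean_count"] == 2.0

    def test_single_lineage_rejected(self):
        from skbio import DistanceMatrix
        with pytest.raises(InvalidArgumentError):
            sl.distance_summary(DistanceMatrix(np.zeros((1, 1)), ids=["a"]), 67)


class TestMatchLineageSets:
    def test_identical_sequence_flagged(self):
        a = sl.LineageSet(["a1"], ["ACGT"])
        b = sl.LineageSet(["b1", "b2"], ["ACGT", "TTTT"])
        pairs = sl.match_lineage_sets(a, b)
        assert pairs == [MatchedPair("a1", "b1", 0, True)]

    def test_zero_budget_is_sequence_intersection(self, rng):
        a = random_lineage_set(rng, n=6, length=10, prefix="a")
        b = sl.LineageSet(["b0", "b1"], [a.sequences[2], "T" * 10])
        pairs = sl.match_lineage_sets(a, b, max_mismatch=0)
        assert [(p.id_a, p.id_b) for p in pairs] == [("a_02", "b0")]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        a = random_lineage_set(rng, n=10, length=67, prefix="a")
        b = random_lineage_set(rng, n=10, length=67, prefix="b")
        got = sl.match_lineage_sets(a, b, max_mismatch=40)
        expected = sorted(
            (
                (sum(x != y for x, y in zip(sa, sb)), ia, ib)
                for ia, sa in zip(a.ids, a.sequences)
                for ib, sb in zip(b.ids, b.sequences)
            ),
        )
        expected = [(ia, ib, d) for d, ia, ib in expected if d <= 40]
        assert [(p.id_a, p.id_b, p.distance) for p in got] == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sl.match_lineage_sets(sl.LineageSet(["a"], ["ACG"]),
                                  sl.LineageSet(["b"], ["ACGT"]))
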