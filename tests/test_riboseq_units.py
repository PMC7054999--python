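"""Trimming, exact-match index, classification hierarchy, counting rules,
normalization factors, RD arithmetic, and category labeling."""

import numpy as np
import pandas as pd
import pytest

from transquant.riboseq import (ExactMatchIndex, ReadClassifier, CountTable,
                                categorize_and_shift, categorize_genes,
                                compute_rd, count_orf_reads, mean_rd,
                                median_ratio_size_factors, spike_normalize,
                                trim_read)
from transquant.riboseq.classify import ReadAssignment
from transquant.riboseq.normalize import SpikeInError

ADAPTER = "TGGAATTCTCGG"
RNG = np.random.default_rng(99)
BASES = np.array(list("ACGT"))


def rand_seq(n, rng=RNG):
    return "".join(BASES[rng.integers(0, 4, n)])


class TestTrim:
    def test_wrapped_insert_recovered(self):
        insert = rand_seq(29)
        raw = rand_seq(4) + insert + rand_seq(4) + ADAPTER[:8]
        out = trim_read(raw, ADAPTER)
        assert out.accepted and out.sequence == insert
        assert out.adapter_found

    def test_full_adapter_preferred_over_short_prefix(self):
        insert = rand_seq(30)
        # plant a 6-nt adapter prefix inside the insert; the longer, real
        # adapter match downstream must win
        insert = insert[:10] + ADAPTER[:6] + insert[16:]
        raw = rand_seq(4) + insert + rand_seq(4) + ADAPTER
        out = trim_read(raw, ADAPTER)
        assert out.sequence == insert

    def test_too_short_read_rejected(self):
        out = trim_read(rand_seq(2 * 4 + 14), ADAPTER)  # insert would be 14
        assert not out.accepted and out.reason == "too_short"

    def test_identity_without_randoms_or_adapter(self):
        seq = rand_seq(30)
        out = trim_read(seq, ADAPTER, n_random=0)
        assert out.sequence == seq and out.reason == "no_adapter"

    def test_overlong_insert_rejected(self):
        raw = rand_seq(4) + rand_seq(46) + rand_seq(4) + ADAPTER
        out = trim_read(raw, ADAPTER)
        assert not out.accepted and out.reason == "too_long"


class TestIndex:
    def test_substring_found_and_mismatch_missed(self):
        seq = rand_seq(200)
        idx = ExactMatchIndex({"t1": seq})
        read = seq[37:66]
        assert ("t1", 37) in idx.query(read)
        mutated = ("A" if read[10] != "A" else "C").join(
            [read[:10], read[11:]])
        assert idx.query(mutated) == []

    def test_short_query_falls_back_to_direct_scan(self):
        seq = rand_seq(80)
        idx = ExactMatchIndex({"a": seq}, k=20)
        assert ("a", 5) in idx.query(seq[5:15])  # below the seed length

    def test_all_occurrences_reported_vs_naive_scan(self):
        rng = np.random.default_rng(5)
        seqs = {f"t{i}": rand_seq(150, rng) for i in range(6)}
        idx = ExactMatchIndex(seqs)
        for _ in range(200):
            tid = f"t{rng.integers(0, 6)}"
            start = int(rng.integers(0, 120))
            read = seqs[tid][start:start + int(rng.integers(16, 31))]
            naive = []
            for t, s in seqs.items():
                p = s.find(read)
                while p >= 0:
                    naive.append((t, p))
                    p = s.find(read, p + 1)
            assert sorted(idx.query(read)) == sorted(naive)


class TestClassify:
    def test_rrna_outranks_mrna(self, toy_references):
        refs = toy_references
        read = refs.transcripts["TXA1"].sequence[65:95]  # also inside RR1
        a = ReadClassifier(refs).classify("r", read)
        assert a.category == "rRNA"

    def test_unmapped_read(self, toy_references):
        a = ReadClassifier(toy_references).classify("r", "N" * 29)
        assert a.category == "unmapped" and a.hits == ()

    def test_yeast_cds_read_flagged_within_orf(self, toy_references):
        refs = toy_references
        read = refs.transcripts["TXY"].sequence[40:70]
        a = ReadClassifier(refs).classify("r", read)
        assert a.category == "yeast"
        assert all(w for _, _, w in a.hits)

    def test_utr_read_not_within_orf(self, toy_references):
        refs = toy_references
        read = refs.transcripts["TXB"].sequence[0:25]  # 5'UTR starts CDS at 40
        a = ReadClassifier(refs).classify("r", read)
        assert a.category == "transcriptome"
        assert not any(w for _, _, w in a.hits)


class TestCounting:
    def _assign(self, refs, reads):
        clf = ReadClassifier(refs)
        return [clf.classify(f"r{i}", s) for i, s in enumerate(reads)]

    def test_orf_rule_and_discard_ledger(self, toy_references):
        refs = toy_references
        a_cds = refs.transcripts["TXA1"].sequence
        reads = [a_cds[100:128], a_cds[120:149], a_cds[130:158],  # in CDS
                 a_cds[265:295]]                                  # 3'UTR
        table = count_orf_reads(self._assign(refs, reads), refs)
        assert table.counts == {"geneA": 3}
        assert table.discards["outside_orf"] == 1

    def test_multi_gene_read_discarded(self):
        from transquant.riboseq import ReferenceSet, Transcript
        shared = rand_seq(60)
        t1 = Transcript("t1", rand_seq(50) + shared + rand_seq(50),
                        "human", "mRNA", "geneA", 10, 150)
        t2 = Transcript("t2", rand_seq(40) + shared + rand_seq(60),
                        "human", "mRNA", "geneB", 5, 150)
        refs = ReferenceSet({"t1": t1, "t2": t2})
        read = shared[10:40]
        table = count_orf_reads(self._assign(refs, [read]), refs)
        assert table.counts == {} and table.discards["multi_gene"] == 1

    def test_multi_isoform_same_gene_counted_once(self, toy_references):
        refs = toy_references
        read = refs.transcripts["TXA1"].sequence[60:90]  # shared CDS segment
        # remove the rRNA trap so the read reaches the transcriptome level
        transcripts = {k: v for k, v in refs.transcripts.items() if k != "RR1"}
        from transquant.riboseq import ReferenceSet
        refs2 = ReferenceSet(transcripts)
        table = count_orf_reads(self._assign(refs2, [read]), refs2)
        assert table.counts == {"geneA": 1}

    def test_empty_assignments_give_zero(self, toy_references):
        table = count_orf_reads([], toy_references)
        assert table.counts == {} and table.n_counted == 0


def _count_table(yeast, human):
    t = CountTable()
    t.counts = {"y": yeast, "h": human}
    t.species = {"y": "yeast", "h": "human"}
    return t


class TestSpikeNormalize:
    def test_equal_totals_give_unit_factors(self):
        f = spike_normalize({"a": _count_table(100, 5), "b": _count_table(100, 9)},
                            "a")
        assert f == {"a": 1.0, "b": 1.0}

    def test_halved_spike_doubles_factor(self):
        f = spike_normalize({"a": _count_table(1000, 1), "b": _count_table(500, 1)},
                            "a")
        assert f["a"] == 1.0 and f["b"] == 2.0

    def test_factors_ignore_human_counts(self):
        f1 = spike_normalize({"a": _count_table(300, 10), "b": _count_table(600, 99)},
                             "a")
        f2 = spike_normalize({"a": _count_table(300, 12345), "b": _count_table(600, 1)},
                             "a")
        assert f1 == f2

    def test_zero_spike_raises(self):
        with pytest.raises(SpikeInError):
            spike_normalize({"a": _count_table(0, 5)}, "a")


class TestRd:
    def _counts(self, fp_c, fp_t, in_c, in_t):
        def make(h):
            t = CountTable()
            t.counts = {"g": h, "y": 50}
            t.species = {"g": "human", "y": "yeast"}
            return t
        return ({"control": make(fp_c), "treated": make(fp_t)},
                {"control": make(in_c), "treated": make(in_t)})

    def test_rd_arithmetic(self):
        fp, inp = self._counts(100, 100, 50, 50)
        ones = {"control": 1.0, "treated": 1.0}
        table = compute_rd(fp, inp, ones, ones, "control", "treated")
        row = table.set_index("gene_symbol").loc["g"]
        assert row["rd_control"] == pytest.approx(2.0)
        assert row["delta_rd"] == pytest.approx(1.0)
        assert "y" not in table["gene_symbol"].values  # yeast excluded

    def test_min_input_filter(self):
        fp, inp = self._counts(100, 100, 5, 50)
        ones = {"control": 1.0, "treated": 1.0}
        with pytest.raises(ValueError):
            compute_rd(fp, inp, ones, ones, "control", "treated", min_input=10)

    def test_delta_rd_invariant_to_common_fp_scaling(self):
        fp, inp = self._counts(80, 40, 50, 50)
        ones = {"control": 1.0, "treated": 1.0}
        doubled = {"control": 2.0, "treated": 2.0}
        d1 = compute_rd(fp, inp, ones, ones, "control", "treated")
        d2 = compute_rd(fp, inp, doubled, ones, "control", "treated")
        assert d1.loc[0, "delta_rd"] == pytest.approx(d2.loc[0, "delta_rd"])

    def test_mean_rd_examples(self):
        table = pd.DataFrame({
            "gene_symbol": ["a", "b"], "fp_control": [10, 30],
            "fp_treated": [10, 30], "input_control": [10, 10],
            "input_treated": [10, 10], "passes_filter": [True, True],
            "rd_control": [1.0, 3.0], "rd_treated": [1.0, 3.0],
            "delta_rd": [1.0, 1.0]})
        res = mean_rd(table)
        assert res.mean_rd_control == pytest.approx(2.0)
        assert res.fold_change == pytest.approx(1.0)
        single = mean_rd(table.iloc[:1])
        assert single.mean_rd_control == pytest.approx(1.0)


class TestMedianRatio:
    def test_identical_samples_equal_factors(self):
        m = pd.DataFrame({"s1": [3, 8, 11], "s2": [3, 8, 11]})
        f = median_ratio_size_factors(m)
        assert f["s1"] == pytest.approx(f["s2"])

    def test_exact_doubling(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 200, 30)
        m = pd.DataFrame({"s1": base, "s2": 2 * base})
        f = median_ratio_size_factors(m)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_single_sample_factor_is_one(self):
        f = median_ratio_size_factors(pd.DataFrame({"s1": [4, 9, 2]}))
        assert f["s1"] == pytest.approx(1.0)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = pd.DataFrame(rng.integers(0, 50, size=(20, 4)),
                             columns=list("abcd"))
            try:
                f = median_ratio_size_factors(m)
            except ValueError:
                assert not (m.to_numpy() > 0).all(axis=1).any()
                continue
            keep = m[(m > 0).all(axis=1)]
            geo = np.exp(np.log(keep).mean(axis=1))
            for col in m.columns:
                assert f[col] == pytest.approx(np.median(keep[col] / geo))

    def test_all_zero_gene_matrix_rejected(self):
        with pytest.raises(ValueError):
            median_ratio_size_factors(pd.DataFrame({"a": [0, 1], "b": [1, 0]}))


class TestCategories:
    def test_precedence_top_over_ires(self, toy_references):
        labels = categorize_genes(["geneA", "geneB", "geneY"], toy_references)
        assert list(labels) == ["TOP", "IRES", "other"]

    def test_identical_distributions_have_zero_ks(self, toy_references):
        table = pd.DataFrame({
            "gene_symbol": ["geneA", "geneB", "gX", "gY"],
            "fp_control": 20, "fp_treated": 20,
            "input_control": 20, "input_treated": 20,
            "passes_filter": True,
            "rd_control": 1.0, "rd_treated": 1.0,
            "delta_rd": [0.5, 0.5, 0.5, 0.5]})
        out = categorize_and_shift(table, toy_references).set_index("category")
        assert out.loc["TOP", "ks_distance_vs_other"] == pytest.approx(0.0)
        assert out.loc["TOP", "median_log2_delta_rd"] == pytest.approx(-1.0)
        assert out.loc["mito_rp", "n_genes"] == 0
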