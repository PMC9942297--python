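"""Pairing, duplicate removal, negative sampling, and dataset splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genesieve.sequence_io import (
    NEGATIVE,
    POSITIVE,
    UNLABELED,
    GeneRecord,
    SequencePair,
    load_gene_set,
    make_split,
    sample_negatives,
    write_gene_set,
)


def _write_dataset(tmp_path, rows):
    """rows: list of (gene, cds_id, cds, prot_id, prot, chrom)."""
    cds = tmp_path / "c.fasta"
    prot = tmp_path / "p.fasta"
    mapping = tmp_path / "map.tsv"
    seen_c, seen_p = set(), set()
    with open(cds, "w") as cf, open(prot, "w") as pf, open(mapping, "w") as mf:
        mf.write("gene_id\tcds_id\tprotein_id\tchromosome\n")
        for g, cid, cseq, pid, pseq, chrom in rows:
            if cid not in seen_c:
                cf.write(f">{cid}\n{cseq}\n")
                seen_c.add(cid)
            if pid not in seen_p:
                pf.write(f">{pid}\n{pseq}\n")
                seen_p.add(pid)
            mf.write(f"{g}\t{cid}\t{pid}\t{chrom}\n")
    return cds, prot, mapping


class TestLoadGeneSet:
    def test_exact_duplicates_within_gene_are_removed(self, tmp_path):
        rows = [
            ("G1", "c1", "ATGGCTTAA", "p1", "MA", "chr1"),
            ("G1", "c2", "ATGGCTTAA", "p2", "MA", "chr1"),
        ]
        genes = load_gene_set(*_write_dataset(tmp_path, rows))
        assert len(genes) == 1 and genes[0].n_samples == 1

    def test_matching_translation_is_unflagged(self):
        pair = SequencePair("c", "ATGGCTTAA", "p", "MA")
        assert not pair.translation_mismatch

    def test_mismatched_translation_is_kept_but_flagged(self, tmp_path):
        rows = [("G1", "c1", "ATGGCTTAA", "p1", "MV", "chr1")]
        genes = load_gene_set(*_write_dataset(tmp_path, rows))
        assert genes[0].pairs[0].translation_mismatch

    def test_unpaired_id_is_hard_error(self, tmp_path):
        cds, prot, mapping = _write_dataset(tmp_path, [("G1", "c1", "ATGTAA", "p1", "M", "chr1")])
        with open(mapping, "a") as mf:
            mf.write("G2\tc_missing\tp1\tchr2\n")
        with pytest.raises(ValueError, match="c_missing"):
            load_gene_set(cds, prot, mapping)

    def test_empty_fasta_is_hard_error(self, tmp_path):
        cds, prot, mapping = _write_dataset(tmp_path, [("G1", "c1", "ATGTAA", "p1", "M", "chr1")])
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(ValueError):
            load_gene_set(empty, prot, mapping)

    def test_round_trip(self, tmp_path):
        rows = [
            ("G1", "c1", "ATGGCTTAA", "p1", "MA", "chr1"),
            ("G2", "c2", "ATGTGGTAA", "p2", "MW", "chr2"),
            ("G2", "c3", "ATGTGGGCTTAA", "p3", "MWA", "chr2"),
        ]
        genes = load_gene_set(*_write_dataset(tmp_path, rows))
        out = tmp_path / "out"
        out.mkdir()
        write_gene_set(genes, out / "c.fasta", out / "p.fasta", out / "m.tsv")
        reloaded = load_gene_set(out / "c.fasta", out / "p.fasta", out / "m.tsv")
        orig = {(g.gene_id, p.cds_id, p.cds, p.protein) for g in genes for p in g.pairs}
        new = {(g.gene_id, p.cds_id, p.cds, p.protein) for g in reloaded for p in g.pairs}
        assert orig == new


def _gene(gid, chrom, label=UNLABELED):
    return GeneRecord(gid, chrom, [SequencePair(f"{gid}.c", "ATGGCTTAA", f"{gid}.p", "MA")], label)


class TestSampleNegatives:
    def _pools(self, per_chrom_pos, per_chrom_unlab):
        positives = [_gene(f"P{c}_{i}", c, POSITIVE)
                     for c, n in per_chrom_pos.items() for i in range(n)]
        unlabeled = [_gene(f"U{c}_{i}", c) for c, n in per_chrom_unlab.items() for i in range(n)]
        return positives, unlabeled

    def test_counts_proportional_to_positive_chromosomes(self):
        pos, unlab = self._pools({"chr1": 10, "chr2": 10}, {"chr1": 50, "chr2": 50})
        negatives = sample_negatives(unlab, pos, multiplier=2, seed=1)
        counts = {c: sum(g.chromosome == c for g in negatives) for c in ("chr1", "chr2")}
        assert counts == {"chr1": 20, "chr2": 20}
        assert all(g.label == NEGATIVE for g in negatives)

    def test_multiplier_scales_total(self):
        pos, unlab = self._pools({"chr1": 5, "chr2": 3}, {"chr1": 100, "chr2": 100})
        assert len(sample_negatives(unlab, pos, multiplier=10, seed=0)) == 80

    def test_same_seed_reproduces_draw(self):
        pos, unlab = self._pools({"chr1": 4, "chr2": 4}, {"chr1": 30, "chr2": 30})
        a = [g.gene_id for g in sample_negatives(unlab, pos, multiplier=3, seed=9)]
        b = [g.gene_id for g in sample_negatives(unlab, pos, multiplier=3, seed=9)]
        assert a == b

    def test_positives_never_sampled(self):
        pos, unlab = self._pools({"chr1": 4}, {"chr1": 30})
        drawn = sample_negatives(unlab + pos, pos, multiplier=2, seed=2)
        assert {g.gene_id for g in drawn}.isdisjoint({g.gene_id for g in pos})

    def test_exhausted_chromosome_redistributes_with_warning(self):
        pos, unlab = self._pools({"chr1": 5, "chr2": 5}, {"chr1": 2, "chr2": 100})
        with pytest.warns(UserWarning, match="chr1"):
            drawn = sample_negatives(unlab, pos, multiplier=2, seed=0)
        assert len(drawn) == 20
        assert sum(g.chromosome == "chr1" for g in drawn) == 2

    @given(st.dictionaries(st.sampled_from(["c1", "c2", "c3", "c4"]),
                           st.integers(1, 12), min_size=2),
           st.integers(1, 3), st.integers(0, 5))
    @settings(max_examples=25, deadline=None)
    def test_largest_remainder_proportionality(self, pos_counts, multiplier, seed):
        pos, unlab = self._pools(pos_counts, {c: 100 for c in pos_counts})
        drawn = sample_negatives(unlab, pos, multiplier=multiplier, seed=seed)
        total = multiplier * sum(pos_counts.values())
        assert len(drawn) == total
        for c, n_pos in pos_counts.items():
            exact = n_pos / sum(pos_counts.values()) * total
            got = sum(g.chromosome == c for g in drawn)
            assert abs(got - exact) < 1.0


class TestMakeSplit:
    def _samples(self, n_pos, n_neg):
        return ([((f"P{i}", f"P{i}.c"), POSITIVE) for i in range(n_pos)]
                + [((f"N{i}", f"N{i}.c"), NEGATIVE) for i in range(n_neg)])

    def test_622_counts_at_scale(self):
        split = make_split(self._samples(570, 570), (0.6, 0.2, 0.2), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (684, 228, 228)

    def test_tiny_input_rounds_to_622(self):
        split = make_split(self._samples(5, 5), (0.6, 0.2, 0.2), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (6, 2, 2)

    def test_train_is_class_balanced(self):
        split = make_split(self._samples(60, 100), (0.6, 0.2, 0.2), seed=3)
        labels = [k[0][0] for k in split.train]
        assert labels.count("P") == labels.count("N")

    def test_same_seed_reproduces_partitions(self):
        s = self._samples(20, 20)
        a, b = make_split(s, seed=7), make_split(s, seed=7)
        assert (a.train, a.validation, a.test) == (b.train, b.validation, b.test)

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError):
            make_split(self._samples(1, 1), (0.6, 0.2, 0.2), seed=0)

    @given(st.integers(5, 60), st.integers(5, 60), st.integers(0, 10))
    @settings(max_examples=30, deadline=None)
    def test_partitions_disjoint_and_exhaustive(self, n_pos, n_neg, seed):
        samples = self._samples(n_pos, n_neg)
        split = make_split(samples, (0.6, 0.2, 0.2), seed=seed)
        parts = [set(split.train), set(split.validation), set(split.test)]
        union = parts[0] | parts[1] | parts[2]
        assert sum(map(len, parts)) == len(union)  # disjoint
        all_keys = {k for k, _ in samples}
        assert union <= all_keys
        if n_pos == n_neg:  # no train down-sampling needed: exhaustive
            assert union == all_keys
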