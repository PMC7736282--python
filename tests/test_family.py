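"""Sequence-similarity network construction and MSA position annotation."""

from io import StringIO

import numpy as np
import pytest
from Bio import AlignIO
from hypothesis import given, settings
from hypothesis import strategies as st

from mtasekit import family as fam
from mtasekit import synthetic as syn


def msa_from_text(text: str):
    return AlignIO.read(StringIO(text), "fasta")


class TestPairwiseSimilarity:
    def test_identity_with_self(self):
        recs, _ = syn.gen_sequence_family(root_length=300, clades=(), seed=0)
        hit = fam.pairwise_similarity(recs[0], recs[0])
        assert hit.percent_identity == 100.0
        assert hit.alignment_length >= 300
        assert hit.e_value < 1e-30

    def test_shuffled_sequence_above_threshold(self):
        recs, _ = syn.gen_sequence_family(root_length=300, clades=(), seed=1)
        rng = np.random.default_rng(1)
        shuffled = "".join(rng.permutation(list(recs[0].sequence))[::-1])
        hit = fam.pairwise_similarity(
            recs[0], fam.SequenceRecord("SHUF", shuffled)
        )
        assert hit.e_value > 1e-30

    def test_family_identity_near_target(self):
        recs, truth = syn.gen_sequence_family(
            root_length=300, clades=((3, 0.5),), seed=2
        )
        for rec in recs[1:]:
            hit = fam.pairwise_similarity(recs[0], rec)
            assert abs(hit.percent_identity - 50.0) <= 10.0

    def test_rejects_bad_characters(self):
        with pytest.raises(ValueError, match="[JZ]"):
            fam.SequenceRecord("BAD", "ACDEFGJZ")


class TestBlastTabular:
    def _write(self, tmp_path, rows):
        path = tmp_path / "hits.tsv"
        path.write_text("".join(rows))
        return path

    def row(self, q, s, e, pid=50.0, length=260):
        return (
            f"{q}\t{s}\t{pid}\t{length}\t0\t0\t1\t{length}\t1\t{length}\t{e}\t100\n"
        )

    def test_parses_rows(self, tmp_path):
        path = self._write(
            tmp_path,
            [self.row("A", "B", 1e-40), self.row("B", "C", 1e-10),
             self.row("A", "C", 1e-50)],
        )
        assert len(fam.parse_blast_tabular(path)) == 3

    def test_reciprocal_dedup_keeps_lower(self, tmp_path):
        path = self._write(
            tmp_path, [self.row("A", "B", 1e-40), self.row("B", "A", 1e-35)]
        )
        hits = fam.parse_blast_tabular(path)
        assert len(hits) == 1
        assert hits[0].e_value == 1e-40

    def test_empty_file(self, tmp_path):
        assert fam.parse_blast_tabular(self._write(tmp_path, [])) == []

    def test_wrong_column_count_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A\tB\t50\n")
        with pytest.raises(ValueError, match="line 1"):
            fam.parse_blast_tabular(path)


class TestBuildSSN:
    def test_threshold_rule(self):
        hits = [
            fam.PairwiseHit("A", "B", 50, 260, 1e-40),
            fam.PairwiseHit("B", "C", 30, 260, 1e-10),
        ]
        net = fam.build_ssn(hits, threshold=1e-30)
        assert set(net.edges) == {("A", "B")}
        comps = {frozenset({"A", "B"}), frozenset({"C"})}
        got = set()
        for n in net.nodes:
            got.add(
                frozenset(
                    m for m in net.nodes
                    if net.nodes[m]["component"] == net.nodes[n]["component"]
                )
            )
        assert got == comps

    def test_zero_threshold_no_edges(self):
        hits = [fam.PairwiseHit("A", "B", 50, 260, 1e-40)]
        assert fam.build_ssn(hits, threshold=0.0).number_of_edges() == 0

    def test_strict_inequality_at_boundary(self):
        at = [fam.PairwiseHit("A", "B", 50, 260, 1e-30)]
        below = [fam.PairwiseHit("A", "B", 50, 260, 0.999e-30)]
        assert fam.build_ssn(at, 1e-30).number_of_edges() == 0
        assert fam.build_ssn(below, 1e-30).number_of_edges() == 1

    @settings(max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        log_threshold=st.floats(min_value=-60, max_value=-5),
    )
    def test_equals_brute_force(self, seed, log_threshold):
        rng = np.random.default_rng(seed)
        names = [f"S{i}" for i in range(20)]
        hits = []
        for i in range(20):
            for j in range(i + 1, 20):
                if rng.random() < 0.4:
                    e = 10.0 ** rng.uniform(-80, 0)
                    hits.append(fam.PairwiseHit(names[i], names[j], 40, 260, e))
        threshold = 10.0**log_threshold
        net = fam.build_ssn(hits, threshold)
        expected = {
            tuple(sorted(h.pair)) for h in hits if h.e_value < threshold
        }
        assert {tuple(sorted(e)) for e in net.edges} == expected
        # node count is conserved regardless of threshold
        assert set(net.nodes) == {h.query_id for h in hits} | {
            h.subject_id for h in hits
        }

    def test_no_self_loops(self):
        hits = [fam.PairwiseHit("A", "A", 100, 300, 0.0),
                fam.PairwiseHit("A", "B", 60, 260, 1e-50)]
        net = fam.build_ssn(fam.dedupe_hits(hits))
        assert not any(u == v for u, v in net.edges)


class TestExtractSubnetwork:
    def _net(self):
        hits = [
            fam.PairwiseHit("A", "B", 60, 260, 1e-50),
            fam.PairwiseHit("B", "C", 55, 260, 1e-45),
            fam.PairwiseHit("A", "C", 50, 260, 1e-40),
        ]
        return fam.build_ssn(hits), hits

    def test_triangle_minus_node(self):
        net, _ = self._net()
        sub = fam.extract_subnetwork(net, node_set={"A", "B"})
        assert set(sub.edges) == {("A", "B")}

    def test_median_identity(self):
        net, hits = self._net()
        sub = fam.extract_subnetwork(net, node_set={"A", "B", "C"}, hits=hits)
        assert sub.graph["median_pairwise_identity"] == 55

    def test_unknown_node_errors(self):
        net, _ = self._net()
        with pytest.raises(KeyError):
            fam.extract_subnetwork(net, node_set={"A", "Z"})

    def test_empty_node_set(self):
        net, _ = self._net()
        sub = fam.extract_subnetwork(net, node_set=set())
        assert sub.number_of_nodes() == 0


class TestPositionMapping:
    def test_hand_countable(self):
        msa = msa_from_text(">R\nM-KT\n>H\nMDKA\n")
        assert fam.map_reference_position(msa, "R", 2) == 3
        assert fam.map_reference_position(msa, "R", 1) == 1

    def test_beyond_length_errors(self):
        msa = msa_from_text(">R\nM-KT\n>H\nMDKA\n")
        with pytest.raises(ValueError, match="beyond"):
            fam.map_reference_position(msa, "R", 4)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        residues = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 12)
        gapped = []
        for ch in residues:
            gapped.extend(["-"] * rng.integers(0, 3))
            gapped.append(ch)
        row = "".join(gapped)
        msa = msa_from_text(f">R\n{row}\n>H\n{'A' * len(row)}\n")
        pos = int(rng.integers(1, 13))
        col = fam.map_reference_position(msa, "R", pos)
        # naive scan oracle
        seen = 0
        for i, ch in enumerate(row, 1):
            if ch != "-":
                seen += 1
                if seen == pos:
                    assert col == i
                    break

    def test_gap_insertion_invariance(self):
        plain = ">R\nMKTA\n>H\nMDTA\n"
        gapped = ">R\n--MK-TA\n>H\n--MD-TA\n"
        for pos in (1, 2, 3, 4):
            c1 = fam.map_reference_position(msa_from_text(plain), "R", pos)
            c2 = fam.map_reference_position(msa_from_text(gapped), "R", pos)
            r1 = str(msa_from_text(plain)[0].seq)[c1 - 1]
            r2 = str(msa_from_text(gapped)[0].seq)[c2 - 1]
            assert r1 == r2


class TestAnnotation:
    def test_homolog_annotation(self):
        msa = msa_from_text(">VP39\nAKC\n>H1\nADC\n")
        net = fam.build_ssn(
            [fam.PairwiseHit("VP39", "H1", 60, 260, 1e-50)]
        )
        (ann,) = fam.annotate_nodes(net, msa, "VP39", [2])
        assert ann.per_node_residue == {"VP39": "K", "H1": "D"}
        assert ann.counts()["D"] == 1

    def test_planted_family_count(self):
        recs, truth = syn.gen_sequence_family(
            root_length=120, clades=((5, 0.95), (10, 0.85)), n_planted=5, seed=4
        )
        text = "".join(f">{r.id}\n{r.sequence}\n" for r in recs)
        msa = msa_from_text(text)
        net = fam.build_ssn([], nodes=[r.id for r in recs])
        (ann,) = fam.annotate_nodes(net, msa, "ROOT", [truth["planted_position"]])
        assert ann.counts()[truth["planted_residue"]] == 5
        assert {n for n, r in ann.per_node_residue.items() if r == "D"} == set(
            truth["planted_ids"]
        )

    def test_missing_node_warns(self):
        msa = msa_from_text(">VP39\nAKC\n")
        net = fam.build_ssn([], nodes=["VP39", "GHOST"])
        with pytest.warns(UserWarning, match="missing from MSA"):
            (ann,) = fam.annotate_nodes(net, msa, "VP39", [1])
        assert ann.per_node_residue["GHOST"] == "?"


class TestColumnProbabilities:
    def test_pure_column(self):
        msa = msa_from_text(">a\nA\n>b\nA\n>c\nA\n>d\nA\n")
        pm = fam.column_probabilities(msa, [1])
        assert pm.probabilities[0] == {"A": 1.0}

    def test_gap_handling(self):
        msa = msa_from_text(">a\nA\n>b\nA\n>c\nC\n>d\n-\n")
        pm = fam.column_probabilities(msa, [1])
        assert pm.probabilities[0] == pytest.approx({"A": 2 / 3, "C": 1 / 3})
        assert pm.gap_fraction[0] == pytest.approx(0.25)

    def test_all_gap_flagged(self):
        msa = msa_from_text(">a\n-A\n>b\n-C\n")
        pm = fam.column_probabilities(msa, [1, 2])
        assert pm.all_gap == [True, False]
        assert pm.probabilities[0] == {}

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            "".join(rng.choice(list("ACDE-"), 8)) for _ in range(6)
        ]
        msa = msa_from_text("".join(f">s{i}\n{r}\n" for i, r in enumerate(rows)))
        pm = fam.column_probabilities(msa, list(range(1, 9)))
        for prob, empty in zip(pm.probabilities, pm.all_gap):
            if not empty:
                assert sum(prob.values()) == pytest.approx(1.0, abs=1e-9)
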