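import dendropy
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxdup.formats import (
    Alignment,
    AnnotationRecord,
    FormatError,
    HitRecord,
    SequenceRecord,
    TreeNode,
    read_annotations,
    read_fasta,
    read_hit_table,
    read_peptides,
    write_annotations,
    write_fasta,
    write_hit_table,
    write_newick,
    write_peptides,
)


class TestFasta:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "t.fasta"
        p.write_text(">a\nACDE\n>b\nKR\n")
        records = read_fasta(p)
        assert [r.id for r in records] == ["a", "b"]
        assert [r.residues for r in records] == ["ACDE", "KR"]

    def test_duplicate_id_error(self, tmp_path):
        p = tmp_path / "t.fasta"
        p.write_text(">a\nAC\n>a\nGG\n")
        with pytest.raises(FormatError, match="'a'"):
            read_fasta(p)

    def test_empty_sequence_error_names_line(self, tmp_path):
        p = tmp_path / "t.fasta"
        p.write_text(">a\nAC\n>b\n>c\nGG\n")
        with pytest.raises(FormatError, match=":3"):
            read_fasta(p)

    def test_description_and_wrapping(self, tmp_path):
        p = tmp_path / "t.fasta"
        write_fasta([SequenceRecord(id="x", residues="A" * 130, description="desc here")], p)
        text = p.read_text()
        assert text.startswith(">x desc here\n")
        assert max(len(line) for line in text.splitlines()) == 60
        (rec,) = read_fasta(p)
        assert rec.residues == "A" * 130 and rec.description == "desc here"

    def test_dot_gap_normalised(self, tmp_path):
        p = tmp_path / "t.fasta"
        p.write_text(">a\nAC.E\n")
        assert read_fasta(p)[0].residues == "AC-E"

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 10**6),
                st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=150),
            ),
            min_size=1,
            max_size=100,
            unique_by=lambda t: t[0],
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_round_trip_identity(self, tmp_path_factory, items):
        records = [
            SequenceRecord(id=f"seq{i}", residues=res) for i, res in items
        ]
        p = tmp_path_factory.mktemp("fa") / "round.fasta"
        write_fasta(records, p)
        back = read_fasta(p)
        assert back == records
        # byte-identity of a second write (wrapped 60-col output)
        p2 = tmp_path_factory.mktemp("fa") / "round2.fasta"
        write_fasta(back, p2)
        assert p.read_bytes() == p2.read_bytes()


class TestAlignment:
    def test_ragged_rejected(self):
        with pytest.raises(FormatError, match="length"):
            Alignment.from_records(
                [SequenceRecord(id="a", residues="ACD"), SequenceRecord(id="b", residues="AC")]
            )

    def test_all_gap_row_rejected(self):
        with pytest.raises(FormatError, match="all gaps"):
            Alignment.from_records(
                [SequenceRecord(id="a", residues="ACD"), SequenceRecord(id="b", residues="---")]
            )


class TestHitTable:
    ROW = "q1\tt1\t98.0\t100\t2\t0\t1\t100\t1\t100\t1e-30\t200\t0.95"

    def test_parse_row(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.ROW + "\n")
        (hit,) = read_hit_table(p)
        assert hit.evalue == 1e-30
        assert hit.query_coverage == 0.95
        assert hit.rank == 1

    def test_rank_assignment(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(
            "q1\tt2\t90\t100\t2\t0\t1\t100\t1\t100\t1e-10\t150\t0.9\n"
            "q1\tt1\t98\t100\t2\t0\t1\t100\t1\t100\t1e-30\t200\t0.95\n"
        )
        hits = read_hit_table(p)
        by_subject = {h.subject_id: h.rank for h in hits}
        assert by_subject == {"t1": 1, "t2": 2}

    def test_non_numeric_evalue_names_line(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.ROW + "\n" + self.ROW.replace("1e-30", "oops") + "\n")
        with pytest.raises(FormatError, match=":2"):
            read_hit_table(p)

    def test_percent_coverage_unit(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.ROW.replace("\t0.95", "\t95.0") + "\n")
        (hit,) = read_hit_table(p, coverage_unit="percent")
        assert hit.query_coverage == pytest.approx(0.95)

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\tt1\t98.0\n")
        with pytest.raises(FormatError, match="13"):
            read_hit_table(p)

    def test_round_trip_rerank_stable(self, tmp_path, rng):
        hits = []
        for i in range(1000):
            hits.append(
                HitRecord(
                    query_id=f"q{rng.integers(0, 40)}",
                    subject_id=f"t{i}",
                    percent_identity=float(rng.uniform(30, 100)),
                    alignment_length=int(rng.integers(20, 500)),
                    mismatches=int(rng.integers(0, 50)),
                    gap_opens=int(rng.integers(0, 5)),
                    q_start=1,
                    q_end=100,
                    s_start=1,
                    s_end=100,
                    evalue=float(10.0 ** rng.uniform(-180, 0)),
                    bitscore=float(rng.uniform(20, 900)),
                    query_coverage=float(rng.uniform(0, 1)),
                )
            )
        p1 = tmp_path / "a.tsv"
        p2 = tmp_path / "b.tsv"
        write_hit_table(hits, p1)
        back = read_hit_table(p1)
        write_hit_table(back, p2)
        assert read_hit_table(p2) == back
        # record-level identity modulo the recomputed rank
        strip = lambda h: (h.query_id, h.subject_id, h.evalue, h.bitscore, h.query_coverage)  # noqa: E731
        assert sorted(map(strip, back)) == sorted(map(strip, hits))


class TestAnnotations:
    def test_round_trip(self, tmp_path):
        table = {
            "p1": AnnotationRecord(protein_id="p1", tm_count=2, domain_ok=False,
                                   go_excluded=True, is_toxin_subject=False),
            "p2": AnnotationRecord(protein_id="p2"),
        }
        p = tmp_path / "ann.tsv"
        write_annotations(table, p)
        assert read_annotations(p) == table

    def test_negative_tm_rejected(self):
        with pytest.raises(FormatError):
            AnnotationRecord(protein_id="p", tm_count=-1)

    def test_bad_header(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("who\tknows\n")
        with pytest.raises(FormatError, match=":1"):
            read_annotations(p)


class TestPeptides:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "p.txt"
        write_peptides(["ACDK", "MMMR"], p)
        assert read_peptides(p) == ["ACDK", "MMMR"]

    def test_invalid_line(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text("AC DK\n")
        with pytest.raises(FormatError, match=":1"):
            read_peptides(p)


class TestNewick:
    def test_single_leaf(self):
        assert write_newick(TreeNode(label="g1")) == "g1;"

    def test_cherry(self):
        tree = TreeNode(children=[
            TreeNode(label="g2", length=0.5), TreeNode(label="g1", length=0.5),
        ])
        assert write_newick(tree) == "(g1:0.5,g2:0.5);"

    def test_unlabelled_leaf(self):
        with pytest.raises(FormatError, match="unlabelled"):
            write_newick(TreeNode(children=[TreeNode(label="a", length=1), TreeNode(length=1)]))

    def test_round_trip_through_dendropy(self, rng):
        # random 10-leaf tree by sequential random joins
        nodes = [TreeNode(label=f"t{i}", length=float(rng.uniform(0, 2))) for i in range(10)]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            merged = TreeNode(children=[nodes[i], nodes[j]], length=float(rng.uniform(0, 2)))
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
        text = write_newick(nodes[0])
        tree = dendropy.Tree.get(data=text, schema="newick")
        assert sorted(leaf.taxon.label for leaf in tree.leaf_node_iter()) == sorted(
            f"t{i}" for i in range(10)
        )
        # serialisation is deterministic under child-order permutation
        def shuffle(node):
            if node.children:
                order = rng.permutation(len(node.children))
                node.children = [node.children[k] for k in order]
                for c in node.children:
                    shuffle(c)
        shuffle(nodes[0])
        assert write_newick(nodes[0]) == text
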