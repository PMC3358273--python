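"""Format readers/writers: parsing contracts and round-trips."""

from __future__ import annotations

import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcstalk.domain_extraction import DomainInstance
from tcstalk.sequence_io import (ClusterSet, DomainHit, GeneLocus, Model,
                                 ProteinRecord, assign_ordinals,
                                 read_cluster_table, read_domtblout,
                                 read_fasta, read_gene_table,
                                 read_probability_table, write_cluster_table,
                                 write_domtblout, write_fasta,
                                 write_gene_table, write_probability_table)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_text(path, text):
    path.write_text(textwrap.dedent(text))


class TestReadFasta:
    def test_parses_entries_in_order(self, tmp_path):
        f = tmp_path / "a.fasta"
        write_text(f, """\
            >p1|Escherichia coli|chr
            MKV
            >p2|Rhodobacter sphaeroides
            ACDEF
            """)
        records = read_fasta(f)
        assert [r.protein_id for r in records] == ["p1", "p2"]
        assert records[0].species == "Escherichia coli"
        assert records[0].replicon == "chr"
        assert records[1].replicon is None

    def test_uppercases_and_strips_terminator(self, tmp_path):
        f = tmp_path / "a.fasta"
        write_text(f, ">p1|sp\nmkv*\n")
        assert read_fasta(f)[0].sequence == "MKV"

    def test_duplicate_id_is_hard_error(self, tmp_path):
        f = tmp_path / "a.fasta"
        write_text(f, ">p1|sp\nMKV\n>p1|sp\nACD\n")
        with pytest.raises(ValueError, match="p1"):
            read_fasta(f)

    def test_empty_sequence_is_hard_error(self, tmp_path):
        f = tmp_path / "a.fasta"
        write_text(f, ">p1|sp\n*\n")
        with pytest.raises(ValueError, match="empty"):
            read_fasta(f)

    def test_unknown_residue_becomes_x_with_warning(self, tmp_path):
        f = tmp_path / "a.fasta"
        write_text(f, ">p1|sp\nMKJV\n")
        with pytest.warns(UserWarning, match="J"):
            records = read_fasta(f)
        assert records[0].sequence == "MKXV"

    def test_round_trip(self, tmp_path):
        records = [
            ProteinRecord("p1", "sp one", "MKVLA", "chr"),
            ProteinRecord("p2", "sp two", "ACDEFX"),
        ]
        f = tmp_path / "rt.fasta"
        write_fasta(records, f)
        assert read_fasta(f) == records


# ---------------------------------------------------------------------------
# domtblout
# ---------------------------------------------------------------------------

MODEL_MAP = {"HisKA": Model.DHP, "Response_reg": Model.REC}


class TestReadDomtblout:
    def test_field_mapping_and_filtering(self, tmp_path):
        hits = [
            DomainHit("p1", Model.DHP, 5, 120, 1e-30, 1),
            DomainHit("p2", Model.REC, 3, 115, 2e-9, 1),
            DomainHit("p2", Model.REC, 130, 240, 5e-4, 2),
        ]
        f = tmp_path / "hits.domtblout"
        write_domtblout(hits, f, {Model.DHP: "HisKA", Model.REC: "Response_reg"},
                        {"p1": 300, "p2": 260})
        parsed = read_domtblout(f, MODEL_MAP)
        assert parsed == hits

    def test_unmapped_model_skipped(self, tmp_path):
        f = tmp_path / "hits.domtblout"
        write_domtblout(
            [DomainHit("p1", Model.DHP, 1, 50, 1e-5)], f,
            {Model.DHP: "SomeOtherModel"})
        assert read_domtblout(f, MODEL_MAP) == []

    def test_truncated_line_names_line_number(self, tmp_path):
        f = tmp_path / "bad.domtblout"
        f.write_text("# comment\np1 - 300 HisKA -\n")
        with pytest.raises(ValueError, match=":2"):
            read_domtblout(f, MODEL_MAP)


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

class TestGeneTable:
    def test_ordinals_follow_start_order(self, tmp_path):
        loci = [
            GeneLocus("g3", "p3", "sp", "chr", 900, 1200, "+"),
            GeneLocus("g1", "p1", "sp", "chr", 10, 300, "+"),
            GeneLocus("g4", "p4", "sp", "chr", 2000, 2400, "-"),
            GeneLocus("g2", "p2", "sp", "chr", 500, 800, "+"),
        ]
        f = tmp_path / "genes.tsv"
        write_gene_table(loci, f)
        parsed = read_gene_table(f)
        assert [(g.gene_id, g.ordinal) for g in parsed] == [
            ("g1", 0), ("g2", 1), ("g3", 2), ("g4", 3)]

    def test_replicons_get_independent_ordinals(self, tmp_path):
        loci = [
            GeneLocus("a1", "p1", "sp", "chrA", 10, 100, "+"),
            GeneLocus("b1", "p2", "sp", "chrB", 5, 90, "+"),
            GeneLocus("b2", "p3", "sp", "chrB", 200, 400, "+"),
        ]
        f = tmp_path / "genes.tsv"
        write_gene_table(loci, f)
        ordinals = {g.gene_id: g.ordinal for g in read_gene_table(f)}
        assert ordinals == {"a1": 0, "b1": 0, "b2": 1}

    def test_missing_strand_is_hard_error(self, tmp_path):
        f = tmp_path / "genes.tsv"
        f.write_text("gene_id\tprotein_id\tspecies\treplicon\tstart\tend\tstrand\n"
                     "g1\tp1\tsp\tchr\t1\t90\t.\n")
        with pytest.raises(ValueError, match="strand"):
            read_gene_table(f)

    def test_gff3_subset(self, tmp_path):
        f = tmp_path / "genes.gff3"
        f.write_text(
            "##gff-version 3\n"
            "chr\tsrc\tgene\t10\t300\t.\t+\t.\tID=g1;protein_id=p1;species=sp\n"
            "chr\tsrc\tgene\t500\t800\t.\t-\t.\tID=g2;protein_id=p2;species=sp\n")
        parsed = read_gene_table(f)
        assert [(g.gene_id, g.protein_id, g.strand) for g in parsed] == [
            ("g1", "p1", "+"), ("g2", "p2", "-")]

    def test_gff3_missing_strand_is_hard_error(self, tmp_path):
        f = tmp_path / "genes.gff3"
        f.write_text("##gff-version 3\n"
                     "chr\tsrc\tgene\t10\t300\t.\t.\t.\tID=g1;protein_id=p1;species=sp\n")
        with pytest.raises(ValueError, match="strand"):
            read_gene_table(f)

    def test_identical_coordinates_warn_but_load(self, tmp_path):
        loci = [
            GeneLocus("g1", "p1", "sp", "chr", 10, 100, "+"),
            GeneLocus("g2", "p2", "sp", "chr", 10, 100, "+"),
        ]
        with pytest.warns(UserWarning, match="identical coordinates"):
            parsed = assign_ordinals(loci)
        assert len(parsed) == 2


# ---------------------------------------------------------------------------
# cluster / probability tables
# ---------------------------------------------------------------------------

def _instance(pid, model, cluster_seq="ACDEF"):
    return DomainInstance(f"{pid}/{model.value}/1", pid, "sp", model,
                          1, len(cluster_seq), 1e-20, cluster_seq)


class TestClusterTable:
    def test_round_trip_partition(self, tmp_path):
        instances = [_instance(f"p{i}", Model.DHP) for i in range(5)]
        clusters = ClusterSet(
            {i.instance_id: k % 2 for k, i in enumerate(instances)},
            model=Model.DHP)
        f = tmp_path / "clusters.tsv"
        write_cluster_table(clusters, instances, f, header_comment="prov")
        assert read_cluster_table(f) == clusters

    def test_empty_clusterset_gives_header_only_file(self, tmp_path):
        f = tmp_path / "clusters.tsv"
        write_cluster_table(ClusterSet({}, model=Model.REC), [], f)
        parsed = read_cluster_table(f)
        assert parsed.assignments == {}

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.dictionaries(
        st.text(alphabet="abcdef", min_size=1, max_size=4).map(lambda s: f"{s}/DHP/1"),
        st.integers(min_value=0, max_value=5), min_size=1, max_size=12))
    def test_round_trip_arbitrary_assignments(self, tmp_path_factory, assignments):
        clusters = ClusterSet(dict(assignments), model=Model.DHP)
        instances = [
            DomainInstance(iid, iid.rsplit("/", 2)[0], "sp", Model.DHP,
                           1, 5, 1e-9, "ACDEF")
            for iid in assignments
        ]
        f = tmp_path_factory.mktemp("rt") / "clusters.tsv"
        write_cluster_table(clusters, instances, f)
        assert read_cluster_table(f) == clusters


class TestProbabilityTable:
    def test_rows_sum_to_one(self, tmp_path):
        import pandas as pd
        probs = pd.DataFrame([[0.75, 0.25], [0.4, 0.6]],
                             index=[0, 1], columns=[0, 1])
        f = tmp_path / "prob.tsv"
        write_probability_table(probs, f)
        loaded = read_probability_table(f)
        assert (abs(loaded.sum(axis=1) - 1.0) < 1e-12).all()
        assert loaded.values == pytest.approx(probs.values)
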