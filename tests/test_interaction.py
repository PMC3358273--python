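"""Interaction table accumulation and partner / cross-talk queries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tcstalk.domain_extraction import DomainInstance
from tcstalk.genome_context import CognatePair
from tcstalk.interaction import (InteractionTable, build_table,
                                 predict_crosstalk, predict_partners)
from tcstalk.sequence_io import ClusterSet, Model


def pair(h, r, species="sp"):
    return CognatePair(h, r, species, 0, 0)


def cluster_set(mapping, model):
    return ClusterSet(dict(mapping), model=model)


def _instance(pid, model, species="sp", rank=1, seq="ACDEF"):
    return DomainInstance(f"{pid}/{model.value}/{rank}", pid, species, model,
                          1, len(seq), 1e-20, seq)


class TestBuildTable:
    def test_counts_normalize_to_row_probabilities(self):
        dhp = cluster_set({"h1/DHP/1": 0, "h2/DHP/1": 0, "h3/DHP/1": 0,
                           "h4/DHP/1": 0}, Model.DHP)
        rec = cluster_set({"r1/REC/1": 0, "r2/REC/1": 1}, Model.REC)
        pairs = [pair("h1", "r1"), pair("h2", "r1"), pair("h3", "r1"),
                 pair("h4", "r2")]
        table = build_table(pairs, dhp, rec)
        assert table.counts.loc[0].tolist() == [3, 1]
        assert table.probabilities.loc[0].tolist() == [0.75, 0.25]

    def test_empty_pairs_flag_every_row_no_prediction(self):
        dhp = cluster_set({"h1/DHP/1": 0, "h2/DHP/1": 1}, Model.DHP)
        rec = cluster_set({"r1/REC/1": 0}, Model.REC)
        table = build_table([], dhp, rec)
        assert table.total_count == 0
        assert table.no_prediction_rows == [0, 1]
        assert (table.probabilities.values == 0).all()

    def test_multi_domain_protein_counts_every_instance_combination(self):
        dhp = cluster_set({"h1/DHP/1": 0}, Model.DHP)
        rec = cluster_set({"r1/REC/1": 0, "r1/REC/2": 1}, Model.REC)
        table = build_table([pair("h1", "r1")], dhp, rec)
        assert table.counts.values.tolist() == [[1, 1]]
        per_protein = build_table([pair("h1", "r1")], dhp, rec,
                                  count_mode="per_protein_pair")
        assert per_protein.total_count == 1

    def test_unclustered_pair_member_is_hard_error(self):
        dhp = cluster_set({"h1/DHP/1": 0}, Model.DHP)
        rec = cluster_set({"r1/REC/1": 0}, Model.REC)
        with pytest.raises(KeyError, match="ghost"):
            build_table([pair("ghost", "r1")], dhp, rec)

    def test_total_counts_equal_pair_events(self):
        rng = np.random.default_rng(3)
        dhp = cluster_set({f"h{i}/DHP/1": int(rng.integers(0, 3))
                           for i in range(10)}, Model.DHP)
        rec = cluster_set({f"r{i}/REC/1": int(rng.integers(0, 4))
                           for i in range(10)}, Model.REC)
        pairs = [pair(f"h{int(rng.integers(0, 10))}",
                      f"r{int(rng.integers(0, 10))}") for _ in range(25)]
        table = build_table(pairs, dhp, rec)
        assert table.total_count == 25
        probs = table.probabilities
        supported = table.counts.sum(axis=1) > 0
        assert np.allclose(probs.loc[supported].sum(axis=1), 1.0, atol=1e-12)

    def test_planted_one_to_one_pairing_gives_permutation_matrix(self):
        # 4 families, 50 pairs each, bijective pairing: the probability
        # matrix is a permutation matrix (off-diagonal mass < 0.05)
        mapping = [2, 0, 3, 1]
        dhp_assign, rec_assign, pairs = {}, {}, []
        for fam in range(4):
            for k in range(50):
                h, r = f"h{fam}_{k}", f"r{fam}_{k}"
                dhp_assign[f"{h}/DHP/1"] = fam
                rec_assign[f"{r}/REC/1"] = mapping[fam]
                pairs.append(pair(h, r))
        table = build_table(pairs,
                            cluster_set(dhp_assign, Model.DHP),
                            cluster_set(rec_assign, Model.REC))
        probs = table.probabilities
        for fam in range(4):
            assert probs.loc[fam, mapping[fam]] > 0.95
            off = probs.loc[fam].drop(mapping[fam]).sum()
            assert off < 0.05


class TestPredictPartners:
    def _table(self, rows):
        counts = pd.DataFrame(rows, index=range(len(rows)),
                              columns=range(len(rows[0])))
        counts.index.name = "dhp_cluster"
        return InteractionTable(counts=counts)

    def test_argmax_cluster_wins(self):
        table = self._table([[1, 7, 2]])
        rec = cluster_set({}, Model.REC)
        prediction = predict_partners(0, table, rec, top_k=1)
        assert prediction.best_cluster == 1
        assert prediction.ranking[0][1] == pytest.approx(0.7)

    def test_zero_row_is_explicit_no_prediction(self):
        table = self._table([[0, 0], [3, 1]])
        prediction = predict_partners(0, table, cluster_set({}, Model.REC))
        assert prediction.no_prediction
        assert prediction.ranking == []

    def test_probability_tie_broken_by_count_then_cluster_id(self):
        table = self._table([[2, 2, 0]])
        prediction = predict_partners(0, table, cluster_set({}, Model.REC),
                                      top_k=2)
        assert [c for c, _ in prediction.ranking] == [0, 1]

    def test_unknown_cluster_is_error(self):
        table = self._table([[1, 0]])
        with pytest.raises(KeyError):
            predict_partners(99, table, cluster_set({}, Model.REC))

    def test_species_filter_lists_that_species_candidates(self):
        table = self._table([[0, 4]])
        rec_instances = [
            _instance("rA", Model.REC, species="host"),
            _instance("rB", Model.REC, species="other"),
        ]
        rec = cluster_set({"rA/REC/1": 1, "rB/REC/1": 1}, Model.REC)
        prediction = predict_partners(
            0, table, rec, species_filter="host", rec_instances=rec_instances)
        assert prediction.candidates == {1: ["rA"]}


class TestPredictCrosstalk:
    def _db(self):
        dhp_instances = [
            _instance("q", Model.DHP, species="donor"),
            _instance("hostK", Model.DHP, species="host"),
            _instance("otherK", Model.DHP, species="host"),
        ]
        rec_instances = [
            _instance("hostR", Model.REC, species="host"),
            _instance("farR", Model.REC, species="elsewhere"),
        ]
        dhp = cluster_set({"q/DHP/1": 0, "hostK/DHP/1": 0,
                           "otherK/DHP/1": 1}, Model.DHP)
        rec = cluster_set({"hostR/REC/1": 0, "farR/REC/1": 1}, Model.REC)
        counts = pd.DataFrame([[5, 0], [0, 2]], index=[0, 1], columns=[0, 1])
        return dhp_instances, rec_instances, dhp, rec, InteractionTable(counts)

    def test_reports_cluster_mates_and_partner_cluster_members(self):
        dhp_instances, rec_instances, dhp, rec, table = self._db()
        report = predict_crosstalk("q", "host", dhp, rec, table,
                                   dhp_instances, rec_instances)
        assert report.query_cluster == 0
        assert report.kinase_candidates == ["hostK"]
        assert report.substrate_candidates == ["hostR"]

    def test_query_never_lists_itself(self):
        dhp_instances, rec_instances, dhp, rec, table = self._db()
        report = predict_crosstalk("hostK", "host", dhp, rec, table,
                                   dhp_instances, rec_instances)
        assert "hostK" not in report.kinase_candidates

    def test_host_without_members_gives_empty_lists(self):
        dhp_instances, rec_instances, dhp, rec, table = self._db()
        report = predict_crosstalk("otherK", "elsewhere", dhp, rec, table,
                                   dhp_instances, rec_instances)
        assert report.kinase_candidates == []
        # cluster 1's top partner is REC cluster 1; farR is the only
        # elsewhere regulator and it sits there
        assert report.substrate_candidates == ["farR"]

    def test_unknown_host_species_is_error(self):
        dhp_instances, rec_instances, dhp, rec, table = self._db()
        with pytest.raises(KeyError, match="nowhere"):
            predict_crosstalk("q", "nowhere", dhp, rec, table,
                              dhp_instances, rec_instances)

    def test_unassignable_novel_sequence_is_flagged_not_raised(self):
        dhp_instances, rec_instances, dhp, rec, table = self._db()
        report = predict_crosstalk("WWWWPPPP", "host", dhp, rec, table,
                                   dhp_instances, rec_instances,
                                   evalue_cutoff=1e-6)
        assert report.unassignable
        assert report.kinase_candidates == []

    def test_consistent_with_predict_partners(self):
        dhp_instances, rec_instances, dhp, rec, table = self._db()
        report = predict_crosstalk("q", "host", dhp, rec, table,
                                   dhp_instances, rec_instances)
        prediction = predict_partners(report.query_cluster, table, rec,
                                      species_filter="host",
                                      rec_instances=rec_instances)
        expected = sorted(
            pid for c, _ in prediction.ranking
            for pid in prediction.candidates[c])
        assert report.substrate_candidates == expected
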