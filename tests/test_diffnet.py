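"""Condition consensus networks and the N-vs-C differential network."""

import json

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from apmsnet.diffnet import (
    ConditionNetwork,
    build_condition_network,
    build_differential_network,
    export_network,
    node_share_attributes,
)
from apmsnet.errors import ConfigurationError


def _aggregates(rows):
    return pd.DataFrame(
        rows, columns=["bait_id", "condition", "protein_id", "mean_dbnsaf", "sd_dbnsaf"]
    )


def _net(condition, weights):
    w = pd.Series(weights, name="weight")
    w.index.name = "protein_id"
    return ConditionNetwork(condition, w, pd.DataFrame())


class TestConditionNetwork:
    def test_consensus_mean_over_condition_baits(self):
        agg = _aggregates(
            [
                ("HDAC1", "N", "X", 0.4, 0.0),
                ("HDAC2", "N", "X", 0.2, 0.0),
            ]
        )
        sig = {("HDAC1", "N"): {"X"}, ("HDAC2", "N"): set()}
        net = build_condition_network(agg, sig, "N")
        assert net.weights["X"] == pytest.approx(0.3)

    def test_nonsignificant_prey_absent(self):
        agg = _aggregates([("HDAC1", "N", "X", 0.4, 0.0)])
        net = build_condition_network(agg, {("HDAC1", "N"): set()}, "N")
        assert "X" not in net.weights.index

    def test_single_bait_identity(self):
        agg = _aggregates([("HDAC1", "N", "X", 0.7, 0.0)])
        net = build_condition_network(agg, {("HDAC1", "N"): {"X"}}, "N")
        assert net.weights["X"] == pytest.approx(0.7)

    def test_no_baits_errors(self):
        agg = _aggregates([("HDAC1", "N", "X", 0.7, 0.0)])
        with pytest.raises(ConfigurationError):
            build_condition_network(agg, {}, "C")


class TestDifferentialNetwork:
    def test_direction_and_width(self):
        edges = build_differential_network(
            _net("N", {"X": 0.5}), _net("C", {"X": 0.1})
        )
        row = edges.iloc[0]
        assert row["delta"] == pytest.approx(-0.4)
        assert row["direction"] == "N-enriched"
        assert row["width_value"] == pytest.approx(0.4)

    def test_zero_change_no_edge(self):
        edges = build_differential_network(
            _net("N", {"X": 0.7}), _net("C", {"X": 0.7})
        )
        assert edges.empty

    def test_boundary_inclusive(self):
        edges = build_differential_network(_net("N", {}), _net("C", {"X": 0.2}))
        assert len(edges) == 1
        assert edges.iloc[0]["direction"] == "C-enriched"

    def test_planted_recovery_bands(self):
        deltas = {"big_up": 0.5, "big_dn": -0.35, "edge": 0.2, "small": 0.1, "tiny": -0.05}
        wc = {k: max(v, 0.0) for k, v in deltas.items()}
        wn = {k: max(-v, 0.0) for k, v in deltas.items()}
        edges = build_differential_network(_net("N", wn), _net("C", wc))
        got = set(edges["prey_id"])
        assert got == {"big_up", "big_dn", "edge"}
        by = edges.set_index("prey_id")
        assert (by.loc[by["delta"] > 0, "direction"] == "C-enriched").all()
        assert (by.loc[by["delta"] < 0, "direction"] == "N-enriched").all()

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        names = [f"P{i}" for i in range(30)]
        wn = dict(zip(names, rng.uniform(0, 1, 30)))
        wc = dict(zip(names, rng.uniform(0, 1, 30)))
        fwd = build_differential_network(_net("N", wn), _net("C", wc))
        rev = build_differential_network(_net("N", wc), _net("C", wn))
        merged = fwd.merge(rev, on="prey_id", suffixes=("_f", "_r"))
        assert len(merged) == len(fwd) == len(rev)
        assert np.allclose(merged["delta_f"], -merged["delta_r"], atol=1e-12)
        assert (merged["direction_f"] != merged["direction_r"]).all()

    def test_width_monotone_in_abs_delta(self):
        rng = np.random.default_rng(2)
        wc = {f"P{i}": float(v) for i, v in enumerate(rng.uniform(0, 2, 20))}
        edges = build_differential_network(_net("N", {}), _net("C", wc))
        srt = edges.sort_values("width_value")
        assert (np.diff(srt["delta"].abs()) > 0).all() or len(srt) < 2

    def test_negative_min_change_errors(self):
        with pytest.raises(ConfigurationError):
            build_differential_network(_net("N", {}), _net("C", {}), min_change=-0.1)


class TestNodeShares:
    def test_hand_normalization(self):
        mat = pd.DataFrame(
            [[2.0, 1.0, 1.0, 0.0]],
            index=["X"],
            columns=["a", "b", "c", "d"],
        )
        shares = node_share_attributes(mat)
        assert shares.loc["X", ["share_a", "share_b", "share_c", "share_d"]].tolist() == [
            0.5,
            0.25,
            0.25,
            0.0,
        ]
        assert not shares.loc["X", "undetected"]

    def test_single_nonzero_and_symmetry(self):
        mat = pd.DataFrame(
            [[0, 3.0, 0, 0], [1.0, 1.0, 1.0, 1.0]],
            index=["one", "eq"],
            columns=list("abcd"),
        )
        shares = node_share_attributes(mat)
        assert shares.loc["one", "share_b"] == 1.0
        assert np.allclose(shares.loc["eq", [f"share_{c}" for c in "abcd"]], 0.25)

    def test_all_zero_flagged(self):
        mat = pd.DataFrame([[0.0, 0.0]], index=["X"], columns=["a", "b"])
        shares = node_share_attributes(mat)
        assert shares.loc["X", "undetected"]
        assert shares.loc["X", ["share_a", "share_b"]].sum() == 0.0

    def test_negative_errors(self):
        mat = pd.DataFrame([[-0.1, 0.2]], index=["X"], columns=["a", "b"])
        with pytest.raises(ConfigurationError):
            node_share_attributes(mat)


class TestExport:
    @pytest.fixture()
    def edges(self):
        return build_differential_network(
            _net("N", {"A": 0.5, "B": 0.0}), _net("C", {"A": 0.0, "B": 0.9, "C": 0.3})
        )

    def test_sif_one_row_per_edge(self, edges, tmp_path):
        p = export_network(edges, tmp_path / "net.sif", "sif")
        lines = p.read_text().strip().splitlines()
        assert len(lines) == len(edges) == 3
        assert all(len(l.split("\t")) == 3 for l in lines)

    def test_graphml_round_trip_preserves_delta(self, edges, tmp_path):
        p = export_network(edges, tmp_path / "net.graphml", "graphml")
        g = nx.read_graphml(p)
        for row in edges.itertuples(index=False):
            attrs = g.edges["HDAC_baits", row.prey_id]
            assert attrs["delta"] == pytest.approx(row.delta, abs=1e-12)
            assert attrs["direction"] == row.direction

    def test_empty_network_valid_documents(self, tmp_path):
        empty = build_differential_network(_net("N", {}), _net("C", {}))
        sif = export_network(empty, tmp_path / "e.sif", "sif")
        assert sif.read_text() == ""
        gml = export_network(empty, tmp_path / "e.graphml", "graphml")
        assert nx.read_graphml(gml).number_of_edges() == 0
        js = export_network(empty, tmp_path / "e.json", "json")
        assert json.loads(js.read_text())["edges"] == []

    def test_unknown_format(self, edges, tmp_path):
        with pytest.raises(ConfigurationError):
            export_network(edges, tmp_path / "x.bin", "gexf")
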