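"""Distributed spectral counting and the dSAF/dNSAF/dBNSAF chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from apmsnet.errors import (
    BaitNotDetectedError,
    ConfigurationError,
    EmptyRunError,
    UnmappedPeptideError,
)
from apmsnet.quant import (
    aggregate_replicates,
    classify_peptides,
    compute_dbnsaf,
    compute_dnsaf,
    distribute_shared_counts,
    distribute_shared_counts_naive,
    quantify_run,
)

from conftest import make_evidence, random_instance


class TestClassify:
    def test_single_mapping_is_unique(self, toy_db):
        ev = make_evidence([("a", 2, ["P1"]), ("b", 3, ["P1", "P2"])])
        out = classify_peptides(ev, toy_db)
        assert list(out["unique"]) == [True, False]
        assert out.loc[1, "proteins"] == ("P1", "P2")

    def test_unknown_protein_raises_listing_offenders(self, toy_db):
        ev = make_evidence([("a", 2, ["P1"]), ("b", 1, ["NOPE"])])
        with pytest.raises(UnmappedPeptideError, match="NOPE"):
            classify_peptides(ev, toy_db)


class TestDistribute:
    def _run(self, rows, db):
        return distribute_shared_counts(classify_peptides(make_evidence(rows), db))

    def test_unique_weighted_apportionment(self, toy_db):
        # A has 4 unique, B has 1; shared 10 splits 8:2
        out = self._run(
            [("u1", 4, ["P1"]), ("u2", 1, ["P2"]), ("s", 10, ["P1", "P2"])], toy_db
        )
        assert out.loc["P1", "dSpC"] == pytest.approx(12.0)
        assert out.loc["P2", "dSpC"] == pytest.approx(3.0)

    def test_no_shared_identity(self, toy_db):
        out = self._run([("u1", 4, ["P1"]), ("u2", 7, ["P2"])], toy_db)
        assert out.loc["P1", "dSpC"] == 4
        assert out.loc["P2", "dSpC"] == 7
        assert (out["shared_attributed"] == 0).all()

    def test_symmetric_split(self, toy_db):
        out = self._run(
            [("u1", 3, ["P1"]), ("u2", 3, ["P2"]), ("s", 4, ["P1", "P2"])], toy_db
        )
        assert out.loc["P1", "dSpC"] == pytest.approx(5.0)
        assert out.loc["P2", "dSpC"] == pytest.approx(5.0)

    def test_zero_unique_equal_split(self, toy_db):
        out = self._run([("s", 6, ["P1", "P2"])], toy_db)
        assert out.loc["P1", "dSpC"] == pytest.approx(3.0)
        assert out.loc["P2", "dSpC"] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_random(self, seed):
        rng = np.random.default_rng(seed)
        ev, db = random_instance(rng)
        out = distribute_shared_counts(classify_peptides(ev, db))
        assert out["dSpC"].sum() == pytest.approx(ev["spectral_count"].sum(), abs=1e-9)

    def test_oracle_equivalence_many_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(300):
            ev, db = random_instance(rng)
            classified = classify_peptides(ev, db)
            fast = distribute_shared_counts(classified)
            slow = distribute_shared_counts_naive(classified)
            pd.testing.assert_frame_equal(fast, slow, atol=1e-12, rtol=0)

    @given(extra=st.integers(min_value=1, max_value=10))
    def test_unique_spectrum_monotonicity(self, extra, toy_db):
        base = [("u1", 2, ["P1"]), ("u2", 5, ["P2"]), ("s", 9, ["P1", "P2"])]
        before = self._run(base, toy_db)
        after = self._run(base + [("u3", extra, ["P1"])], toy_db)
        assert after.loc["P1", "dSpC"] >= before.loc["P1", "dSpC"]


class TestDnsaf:
    def test_hand_example(self):
        out = compute_dnsaf(
            pd.Series({"A": 10.0, "B": 10.0}), {"A": 100, "B": 200}
        )
        assert out["dSAF"].to_dict() == pytest.approx({"A": 0.1, "B": 0.05})
        assert out["dNSAF"].to_dict() == pytest.approx({"A": 2 / 3, "B": 1 / 3})

    def test_single_protein_normalizes_to_one(self):
        out = compute_dnsaf(pd.Series({"A": 5.0}), {"A": 123})
        assert out["dNSAF"].iloc[0] == pytest.approx(1.0)

    def test_symmetry_equal_counts_and_lengths(self):
        out = compute_dnsaf(pd.Series({c: 4.0 for c in "ABCD"}), {c: 50 for c in "ABCD"})
        assert np.allclose(out["dNSAF"], 0.25)

    def test_rescaling_invariance(self):
        dspc = pd.Series({"A": 3.0, "B": 9.0, "C": 1.0})
        lengths = {"A": 100, "B": 300, "C": 40}
        a = compute_dnsaf(dspc, lengths)["dNSAF"]
        b = compute_dnsaf(dspc * 7.5, lengths)["dNSAF"]
        assert np.allclose(a, b, atol=1e-12)

    def test_empty_run_errors(self):
        with pytest.raises(EmptyRunError):
            compute_dnsaf(pd.Series({"A": 0.0}), {"A": 100})


class TestDbnsaf:
    def test_bait_is_one_and_ratios(self):
        dsaf = pd.Series({"BAIT": 0.4, "X": 0.2, "Y": 0.1})
        out = compute_dbnsaf(dsaf, "BAIT")
        assert out["BAIT"] == pytest.approx(1.0)
        assert out["X"] == pytest.approx(0.5)

    def test_dsaf_and_dnsaf_inputs_agree(self):
        dsaf = pd.Series({"BAIT": 0.4, "X": 0.2, "Y": 0.13})
        dnsaf = dsaf / dsaf.sum()
        a, b = compute_dbnsaf(dsaf, "BAIT"), compute_dbnsaf(dnsaf, "BAIT")
        assert np.allclose(a, b, rtol=1e-12)

    def test_missing_bait_names_run(self):
        with pytest.raises(BaitNotDetectedError, match="run7"):
            compute_dbnsaf(pd.Series({"X": 0.2}), "BAIT", run_id="run7")


class TestAggregate:
    def _frames(self, dbnsafs, dspcs):
        return [
            pd.DataFrame(
                {"dBNSAF": v, "dSpC": c},
                index=pd.Index(list(v), name="protein_id") if False else v.index,
            )
            for v, c in zip(dbnsafs, dspcs)
        ]

    def test_mean_and_sample_sd(self):
        runs = [
            pd.DataFrame({"dBNSAF": [x], "dSpC": [5.0]}, index=pd.Index(["X"], name="protein_id"))
            for x in (1.0, 2.0, 3.0)
        ]
        agg = aggregate_replicates(runs)
        assert agg.loc["X", "mean_dbnsaf"] == pytest.approx(2.0)
        assert agg.loc["X", "sd_dbnsaf"] == pytest.approx(1.0)  # n-1 denominator

    def test_nondetection_counts_as_zero(self):
        r1 = pd.DataFrame({"dBNSAF": [0.6], "dSpC": [3.0]}, index=pd.Index(["X"], name="protein_id"))
        r2 = pd.DataFrame({"dBNSAF": [0.3], "dSpC": [2.0]}, index=pd.Index(["X"], name="protein_id"))
        r3 = pd.DataFrame({"dBNSAF": [1.0], "dSpC": [9.0]}, index=pd.Index(["Y"], name="protein_id"))
        agg = aggregate_replicates([r1, r2, r3])
        assert agg.loc["X", "mean_dbnsaf"] == pytest.approx(0.3)
        assert agg.loc["X", "detection_fraction"] == pytest.approx(2 / 3)

    def test_identical_replicates_zero_sd(self):
        runs = [
            pd.DataFrame({"dBNSAF": [0.5], "dSpC": [4.0]}, index=pd.Index(["X"], name="protein_id"))
            for _ in range(3)
        ]
        agg = aggregate_replicates(runs)
        assert agg.loc["X", "sd_dbnsaf"] == 0.0

    def test_empty_input_errors(self):
        with pytest.raises(ConfigurationError):
            aggregate_replicates([])


def test_quantify_run_invariants(toy_db):
    ev = make_evidence(
        [("u1", 8, ["BAIT"]), ("u2", 4, ["P1"]), ("s", 6, ["P1", "P2"]), ("u3", 2, ["P3"])]
    )
    q = quantify_run(ev, toy_db, bait_id="BAIT")
    assert q["dSpC"].sum() == pytest.approx(20.0)
    assert q["dNSAF"].sum() == pytest.approx(1.0, abs=1e-9)
    assert q.loc["BAIT", "dBNSAF"] == pytest.approx(1.0)
    assert (q["dSpC"] >= q["uSpC"]).all()
    assert np.isfinite(q[["dSAF", "dNSAF", "dBNSAF"]].to_numpy()).all()
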