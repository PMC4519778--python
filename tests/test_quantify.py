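"""TPM arithmetic, proportions, expression filters, event quantification."""

import numpy as np
import pandas as pd
import pytest

from ateseq.annotation import GeneModel
from ateseq.events import build_event_annotation, find_events
from ateseq.quantify import (
    counts_to_tpm,
    filter_expressed,
    quantify_event,
    top_transcript,
    transcript_proportions,
    validate_metadata,
)
from conftest import make_transcript


def frame(data, samples=None):
    df = pd.DataFrame(data).T if isinstance(data, dict) else pd.DataFrame(data)
    if samples is not None:
        df.columns = samples
    return df


class TestCountsToTpm:
    def test_length_normalisation_arithmetic(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        lengths = pd.Series({"a": 1000, "b": 2000})
        tpm = counts_to_tpm(counts, lengths)
        np.testing.assert_allclose(
            tpm["s1"].to_numpy(), [2e6 / 3, 1e6 / 3], rtol=1e-12
        )

    def test_all_zero_column_stays_zero(self):
        counts = pd.DataFrame({"s1": [5, 5], "s2": [0, 0]}, index=["a", "b"])
        tpm = counts_to_tpm(counts, pd.Series({"a": 100, "b": 100}))
        assert (tpm["s2"] == 0).all()
        assert tpm["s1"].sum() == pytest.approx(1e6)

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(30, 6)),
            index=[f"t{i}" for i in range(30)],
        )
        lengths = pd.Series(
            rng.integers(200, 3000, size=30), index=counts.index
        )
        tpm = counts_to_tpm(counts, lengths)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_length_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["a"])
        with pytest.raises(ValueError, match="> 0"):
            counts_to_tpm(counts, pd.Series({"a": 0}))


class TestProportions:
    def test_simple_division(self):
        tpm = pd.DataFrame({"s1": [6.0, 2.0, 2.0]}, index=list("abc"))
        gene_of = pd.Series({"a": "g", "b": "g", "c": "g"})
        props = transcript_proportions(tpm, gene_of)
        np.testing.assert_allclose(props["s1"], [0.6, 0.2, 0.2])

    def test_single_transcript_gene_is_one(self):
        tpm = pd.DataFrame({"s1": [3.0], "s2": [7.0]}, index=["a"])
        props = transcript_proportions(tpm, pd.Series({"a": "g"}))
        assert (props.loc["a"] == 1.0).all()

    def test_zero_gene_flagged_missing(self):
        tpm = pd.DataFrame({"s1": [0.0, 0.0]}, index=["a", "b"])
        props = transcript_proportions(tpm, pd.Series({"a": "g", "b": "g"}))
        assert props["s1"].isna().all()

    def test_unknown_gene_rejected(self):
        tpm = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="unknown gene"):
            transcript_proportions(tpm, pd.Series({"b": "g"}))

    def test_inversion_recovers_tpm(self, rng):
        tpm = pd.DataFrame(
            rng.uniform(0, 50, size=(9, 4)), index=[f"t{i}" for i in range(9)]
        )
        gene_of = pd.Series(
            {f"t{i}": f"g{i // 3}" for i in range(9)}
        )
        props = transcript_proportions(tpm, gene_of)
        gene_sums = tpm.groupby(gene_of).transform("sum")
        np.testing.assert_allclose(props * gene_sums, tpm, rtol=1e-9)


class TestTopTranscript:
    def _gene(self):
        t1 = make_transcript([(0, 100)], tid="g.t1", gid="g")
        t2 = make_transcript([(0, 200)], tid="g.t2", gid="g")
        return GeneModel("g", [t1, t2])

    def test_highest_mean_wins(self):
        tpm = pd.DataFrame(
            {"s1": [5.0, 3.0], "s2": [5.0, 3.0]}, index=["g.t1", "g.t2"]
        )
        assert top_transcript(tpm, self._gene()) == "g.t1"

    def test_tie_breaks_lexicographically(self, caplog):
        tpm = pd.DataFrame({"s1": [3.0, 3.0]}, index=["g.t1", "g.t2"])
        with caplog.at_level("WARNING"):
            assert top_transcript(tpm, self._gene()) == "g.t1"
        assert any("tie" in r.message for r in caplog.records)

    def test_unexpressed_gene_raises(self):
        tpm = pd.DataFrame({"s1": [0.0, 0.0]}, index=["g.t1", "g.t2"])
        with pytest.raises(KeyError, match="unexpressed"):
            top_transcript(tpm, self._gene())

    def test_argmax_property(self, rng):
        tpm = pd.DataFrame(
            rng.uniform(0.1, 20, size=(2, 8)), index=["g.t1", "g.t2"]
        )
        top = top_transcript(tpm, self._gene())
        assert tpm.loc[top].mean() == tpm.mean(axis=1).max()


class TestFilterExpressed:
    def _inputs(self, group_means):
        """One gene, one transcript; group means set exactly per condition."""
        rows = []
        samples, values = [], []
        for (mf, tr), mean in group_means.items():
            for i in range(2):
                samples.append(f"{mf}_{tr}_{i}")
                values.append(mean)
                rows.append(
                    {"sample_id": f"{mf}_{tr}_{i}", "mf_type": mf,
                     "treatment": tr, "donor": f"d{i}_{mf}"}
                )
        tpm = pd.DataFrame([values], index=["t1"], columns=samples)
        return tpm, pd.Series({"t1": "g1"}), pd.DataFrame(rows)

    def test_kept_when_all_groups_above(self):
        means = {(m, t): 3.0 for m in ("MDM", "IPSDM") for t in ("naive", "LPS")}
        tpm, gene_of, meta = self._inputs(means)
        assert filter_expressed(tpm, gene_of, meta, 2.0, "all_conditions") == ["g1"]

    def test_one_low_group_drops_in_all_mode_keeps_in_any(self):
        means = {
            ("MDM", "naive"): 3.0, ("MDM", "LPS"): 3.0,
            ("IPSDM", "naive"): 3.0, ("IPSDM", "LPS"): 1.9,
        }
        tpm, gene_of, meta = self._inputs(means)
        assert filter_expressed(tpm, gene_of, meta, 2.0, "all_conditions") == []
        assert filter_expressed(tpm, gene_of, meta, 2.0, "any_condition") == ["g1"]

    def test_strict_inequality_at_threshold(self):
        means = {(m, t): 2.0 for m in ("MDM", "IPSDM") for t in ("naive", "LPS")}
        tpm, gene_of, meta = self._inputs(means)
        assert filter_expressed(tpm, gene_of, meta, 2.0, "all_conditions") == []

    def test_unknown_mode_rejected(self):
        means = {(m, t): 3.0 for m in ("MDM", "IPSDM") for t in ("naive", "LPS")}
        tpm, gene_of, meta = self._inputs(means)
        with pytest.raises(ValueError, match="mode"):
            filter_expressed(tpm, gene_of, meta, 2.0, "sometimes")

    def test_manual_ten_gene_fixture(self, rng):
        """Threshold 2 reproduces a hand-filtered result on random group means."""
        genes = [f"g{i}" for i in range(10)]
        group_names = [
            (m, t) for m in ("MDM", "IPSDM") for t in ("naive", "LPS")
        ]
        means = {g: dict(zip(group_names, rng.uniform(0, 6, 4))) for g in genes}
        rows, cols = [], {}
        for mf, tr in group_names:
            for i in range(2):
                sid = f"{mf}_{tr}_{i}"
                rows.append({"sample_id": sid, "mf_type": mf, "treatment": tr,
                             "donor": f"d{i}{mf}"})
                cols[sid] = [means[g][(mf, tr)] for g in genes]
        tpm = pd.DataFrame(cols, index=genes)
        gene_of = pd.Series(dict(zip(genes, genes)))
        expected = sorted(
            g for g in genes if all(v > 2.0 for v in means[g].values())
        )
        meta = pd.DataFrame(rows)
        assert filter_expressed(tpm, gene_of, meta, 2.0, "all_conditions") == expected


class TestQuantifyEvent:
    def _cassette_gene(self):
        t1 = make_transcript(
            [(100, 200), (300, 400), (500, 600)], tid="g.t1", gid="g"
        )
        t2 = make_transcript([(100, 200), (500, 600)], tid="g.t2", gid="g")
        return GeneModel("g", [t1, t2]), t1, t2

    def test_two_transcript_cassette_proportion(self):
        gene, t1, t2 = self._cassette_gene()
        (ev,) = find_events(t1, t2)
        ann = build_event_annotation(ev, t1, t2)
        tpm = pd.DataFrame({"s1": [8.0, 2.0]}, index=["g.t1", "g.t2"])
        props = quantify_event(ann, gene, tpm)
        assert props.loc["ref", "s1"] == pytest.approx(0.8)
        assert props.loc["alt", "s1"] == pytest.approx(0.2)

    def test_unrelated_transcript_assigned_neither(self):
        gene, t1, t2 = self._cassette_gene()
        t3 = make_transcript([(900, 1000)], tid="g.t3", gid="g")
        gene3 = GeneModel("g", [t1, t2, t3])
        (ev,) = find_events(t1, t2)
        ann = build_event_annotation(ev, t1, t2)
        tpm = pd.DataFrame(
            {"s1": [8.0, 2.0, 100.0]}, index=["g.t1", "g.t2", "g.t3"]
        )
        props = quantify_event(ann, gene3, tpm)
        assert props.loc["ref", "s1"] == pytest.approx(0.8)

    def test_both_zero_sample_flagged_missing(self):
        gene, t1, t2 = self._cassette_gene()
        (ev,) = find_events(t1, t2)
        ann = build_event_annotation(ev, t1, t2)
        tpm = pd.DataFrame(
            {"s1": [8.0, 2.0], "s2": [0.0, 0.0]}, index=["g.t1", "g.t2"]
        )
        props = quantify_event(ann, gene, tpm)
        assert props["s2"].isna().all()
        assert props.loc["ref", "s1"] == pytest.approx(0.8)

    def test_invariant_to_sample_rescaling(self):
        gene, t1, t2 = self._cassette_gene()
        (ev,) = find_events(t1, t2)
        ann = build_event_annotation(ev, t1, t2)
        tpm = pd.DataFrame(
            {"s1": [8.0, 2.0], "s2": [4.0, 6.0]}, index=["g.t1", "g.t2"]
        )
        p1 = quantify_event(ann, gene, tpm)
        p2 = quantify_event(ann, gene, tpm * 37.0)
        pd.testing.assert_frame_equal(p1, p2)


class TestValidateMetadata:
    def test_accepts_default_design(self, metadata):
        validate_metadata(metadata)

    def test_rejects_missing_columns(self, metadata):
        with pytest.raises(ValueError, match="columns"):
            validate_metadata(metadata.drop(columns="donor"))

    def test_rejects_underreplicated_group(self, metadata):
        small = metadata[
            ~((metadata.mf_type == "IPSDM") & (metadata.treatment == "LPS"))
            | (metadata.donor == "d6")
        ]
        with pytest.raises(ValueError, match=">= 2"):
            validate_metadata(small)
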