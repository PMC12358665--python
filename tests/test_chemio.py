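"""Reading, validating and round-tripping compound tables and reports."""

import json

import pandas as pd
import pytest
from rdkit import Chem

from skinqsar import chemio
from skinqsar.records import MoleculeRecord, PredictionRecord


def _write_csv(path, rows, header="id,smiles,label"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadSmilesTable:
    def test_parses_valid_rows_with_labels(self, tmp_path):
        p = tmp_path / "in.csv"
        _write_csv(p, ["m1,CCO,0", "m2,c1ccccc1,1"])
        recs = chemio.read_smiles_table(p, label_col="label")
        assert [r.id for r in recs] == ["m1", "m2"]
        assert [r.label for r in recs] == [0, 1]
        assert recs[1].smiles == Chem.CanonSmiles("c1ccccc1")

    def test_unparseable_smiles_dropped_with_count(self, tmp_path):
        p = tmp_path / "in.csv"
        _write_csv(p, ["m1,CCO,0", "m2,c1ccccc1,1", "m3,not_a_smiles,1"])
        with pytest.warns(UserWarning, match="1 row"):
            recs = chemio.read_smiles_table(p, label_col="label")
        assert len(recs) == 2

    def test_duplicate_id_is_an_error(self, tmp_path):
        p = tmp_path / "in.csv"
        _write_csv(p, ["m1,CCO,0", "m1,CCN,1"])
        with pytest.raises(ValueError, match="duplicate id"):
            chemio.read_smiles_table(p, label_col="label")

    def test_duplicate_structure_first_occurrence_wins(self, tmp_path):
        p = tmp_path / "in.csv"
        _write_csv(p, ["m1,CCO,0", "m2,OCC,1"])   # same canonical structure
        with pytest.warns(UserWarning, match="duplicate structure"):
            recs = chemio.read_smiles_table(p, label_col="label")
        assert [r.id for r in recs] == ["m1"]

    def test_label_outside_01_is_hard_error(self, tmp_path):
        p = tmp_path / "in.csv"
        _write_csv(p, ["m1,CCO,2"])
        with pytest.raises(ValueError, match="not 0 or 1"):
            chemio.read_smiles_table(p, label_col="label")

    def test_missing_column_and_empty_input(self, tmp_path):
        p = tmp_path / "in.csv"
        _write_csv(p, ["m1,CCO,0"])
        with pytest.raises(KeyError):
            chemio.read_smiles_table(p, smiles_col="structure")
        q = tmp_path / "bad.csv"
        _write_csv(q, ["m1,xxxx,0"])
        with pytest.warns(UserWarning), pytest.raises(chemio.EmptyInputError):
            chemio.read_smiles_table(q, label_col="label")

    def test_mixture_rejected_unless_largest_fragment_kept(self, tmp_path):
        p = tmp_path / "in.csv"
        _write_csv(p, ["m1,CCO.[Na+],0", "m2,CCN,1"])
        with pytest.warns(UserWarning):
            recs = chemio.read_smiles_table(p, label_col="label")
        assert [r.id for r in recs] == ["m2"]
        recs = chemio.read_smiles_table(p, label_col="label",
                                        keep_largest_fragment=True)
        assert recs[0].smiles == Chem.CanonSmiles("CCO")


class TestSDF:
    def test_round_trip_preserves_canonical_smiles(self, tmp_path, small_records):
        sdf = tmp_path / "out.sdf"
        chemio.write_sdf(small_records, sdf)
        back = chemio.read_sdf(sdf)
        assert sorted(r.smiles for r in back) == \
            sorted(r.smiles for r in small_records)
        assert [r.id for r in back] == [r.id for r in small_records]

    def test_repeated_structure_records(self, tmp_path):
        recs = [MoleculeRecord(f"e{i}", "CCO") for i in range(3)]
        sdf = tmp_path / "eth.sdf"
        chemio.write_sdf(recs, sdf)
        with pytest.warns(UserWarning, match="duplicate structure"):
            back = chemio.read_sdf(sdf)
        assert len({r.smiles for r in back}) == 1

    def test_empty_sdf(self, tmp_path):
        p = tmp_path / "empty.sdf"
        p.write_text("")
        assert chemio.read_sdf(p) == []


class TestPredictions:
    PREDS = [
        PredictionRecord("m1", "irritation", 1, 0.93251, True),
        PredictionRecord("m2", "irritation", 0, 0.1, False),
    ]

    def test_round_trip_at_4_decimals(self, tmp_path):
        p = tmp_path / "preds.csv"
        chemio.write_predictions(self.PREDS, p)
        back = chemio.read_predictions(p)
        assert back[0].probability == pytest.approx(0.9325)
        assert back[0].reliable is True
        assert back[1] == self.PREDS[1]

    def test_empty_list_writes_header_only(self, tmp_path):
        p = tmp_path / "preds.csv"
        chemio.write_predictions([], p)
        assert p.read_text().strip() == ",".join(chemio.PREDICTION_HEADER)

    def test_single_record_two_lines(self, tmp_path):
        p = tmp_path / "preds.csv"
        chemio.write_predictions(self.PREDS[:1], p)
        assert len(p.read_text().strip().splitlines()) == 2


def test_model_card_schema(tmp_path):
    """Card carries algorithm, hyperparameters, metrics and AD thresholds."""
    import numpy as np
    from sklearn.ensemble import RandomForestClassifier

    from skinqsar import addomain, evaluate, train

    rng = np.random.default_rng(0)
    X = rng.random((20, 5))
    y = rng.integers(0, 2, 20)
    est = RandomForestClassifier(n_estimators=5, random_state=0).fit(X, y)
    model = train.TrainedModel("rf", "descriptors", est,
                               {"n_estimators": 5}, [f"d{i}" for i in range(5)])
    rep = evaluate.full_report(y, est.predict(X), est.predict_proba(X)[:, 1])
    ad = addomain.ADBundle(
        euclidean=addomain.EuclideanApplicabilityDomain().fit(X))
    card_path = tmp_path / "card.json"
    card = chemio.write_model_card(model, rep, ad, card_path)
    loaded = json.loads(card_path.read_text())
    assert set(loaded) >= {"algorithm", "hyperparameters", "metrics",
                           "applicability_domain"}
    assert loaded["metrics"] == {k: (v if not isinstance(v, float) else
                                     pytest.approx(v))
                                 for k, v in rep.to_dict().items()}
    assert loaded["applicability_domain"]["euclidean"]["dt"] == \
        pytest.approx(ad.euclidean.dt_)
    assert card == loaded
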