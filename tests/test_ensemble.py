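import numpy as np
import pytest

from planttf.ensemble import (
    UNKNOWN_LABEL,
    EnsembleModel,
    finalize,
    max_vote,
    predict,
    score_all,
    two_stage,
)
from planttf.features import FeatureMask, FeatureScaler
from planttf.kmers import build_vocabulary, encode_corpus, apply_mask
from planttf.models import ClassifierSpec, TrainConfig, train_binary, train_stacker
from planttf.pipeline import train_pipeline
from planttf.seqio import LabeledCorpus, ProteinRecord

FAST = TrainConfig(max_epochs=20, min_updates=200, patience_updates=60,
                   input_noise=0.5, seed=0)


@pytest.fixture(scope="module")
def tiny_ensemble(small_corpus):
    """A quickly-trained ensemble over the three-family fixture corpus."""
    corpus, _ = small_corpus
    ensemble, split = train_pipeline(
        corpus, k=2, n_features=50, seed=11, train_config=FAST
    )
    return corpus, ensemble, split


def test_max_vote_argmax_and_threshold():
    fams = ["F1", "F2", "F3"]
    assert max_vote(np.array([0.1, 0.9, 0.3]), 0.5, fams) == ("F2", 0.9)
    assert max_vote(np.array([0.4, 0.3]), 0.5, ["F1", "F2"]) == (UNKNOWN_LABEL, 0.4)
    # threshold 0 always yields a family
    assert max_vote(np.array([0.0, 0.0]), 0.0, ["F1", "F2"])[0] == "F1"


def test_max_vote_tie_breaks_to_lower_index():
    label, conf = max_vote(np.array([0.7, 0.7]), 0.5, ["F1", "F2"])
    assert label == "F1" and conf == 0.7


def test_max_vote_threshold_equality_accepts():
    label, _ = max_vote(np.array([0.5, 0.2]), 0.5, ["F1", "F2"])
    assert label == "F1"


def test_max_vote_empty_row_errors():
    with pytest.raises(ValueError):
        max_vote(np.array([]), 0.5)


def test_finalize_monotone_rejection(rng):
    scores = rng.random((50, 4))
    fams = ["A", "B", "C", "D"]
    assigned = []
    for t in (0.0, 0.5, 0.95, 0.98, 0.99):
        labels, _ = finalize(scores, fams, t)
        assigned.append({i for i, l in enumerate(labels) if l != UNKNOWN_LABEL})
    for looser, stricter in zip(assigned, assigned[1:]):
        assert stricter <= looser
    assert len(assigned[0]) == 50  # threshold 0: no rejection


def test_score_all_shape_range_and_determinism(tiny_ensemble):
    corpus, ensemble, _ = tiny_ensemble
    records = corpus.records[:10] + corpus.records[:2]  # duplicates at the end
    P = score_all(ensemble, records)
    assert P.shape == (12, len(ensemble.families))
    assert np.all((P >= 0) & (P <= 1))
    assert np.array_equal(P[0], P[10]) and np.array_equal(P[1], P[11])


def test_two_stage_row_api(tiny_ensemble):
    _, ensemble, _ = tiny_ensemble
    row = np.full(len(ensemble.families), 0.1)
    label, conf = two_stage(row, ensemble.stacker, 1.0, ensemble.families)
    assert label == UNKNOWN_LABEL and 0 <= conf <= 1
    label0, _ = two_stage(row, ensemble.stacker, 0.0, ensemble.families)
    assert label0 in ensemble.families


def test_predict_report_structure(tiny_ensemble):
    corpus, ensemble, split = tiny_ensemble
    test = corpus.labeled().subset(split.test_ids)
    report = predict(ensemble, test, method="two_stage", threshold=0.5)
    assert len(report.table) == len(test)
    assert set(report.table["final_label"]) <= set(ensemble.families) | {UNKNOWN_LABEL}
    for fam in ensemble.families:
        assert f"p_{fam}" in report.table.columns
        assert f"p2_{fam}" in report.table.columns  # stacker scores also emitted
    # confidence backs the final label
    row = report.table.iloc[0]
    if row["final_label"] != UNKNOWN_LABEL:
        assert row["confidence"] == row[f"p2_{row['final_label']}"]


def test_predict_threshold_zero_total(tiny_ensemble):
    corpus, ensemble, split = tiny_ensemble
    test = corpus.labeled().subset(split.test_ids)
    for method in ("max_vote", "two_stage"):
        report = predict(ensemble, test, method=method, threshold=0.0)
        assert UNKNOWN_LABEL not in report.final_labels


def test_predict_empty_corpus(tiny_ensemble):
    _, ensemble, _ = tiny_ensemble
    report = predict(ensemble, LabeledCorpus([]), method="max_vote", threshold=0.5)
    assert len(report.table) == 0


def test_predict_requires_stacker_for_two_stage(tiny_ensemble):
    corpus, ensemble, _ = tiny_ensemble
    bare = EnsembleModel(
        k=ensemble.k, mask=ensemble.mask, families=ensemble.families,
        binaries=ensemble.binaries, stacker=None, scaler=ensemble.scaler,
    )
    with pytest.raises(ValueError, match="stacker"):
        predict(bare, corpus.records[:2], method="two_stage")


def test_predict_validates_method_and_threshold(tiny_ensemble):
    corpus, ensemble, _ = tiny_ensemble
    with pytest.raises(ValueError, match="method"):
        predict(ensemble, corpus.records[:2], method="majority")
    with pytest.raises(ValueError, match="threshold"):
        predict(ensemble, corpus.records[:2], threshold=1.2)


def test_family_summary_counts(tiny_ensemble):
    corpus, ensemble, split = tiny_ensemble
    test = corpus.labeled().subset(split.test_ids)
    report = predict(ensemble, test, method="two_stage", threshold=0.5)
    summary = report.family_summary()
    assert set(summary["family"]) == set(ensemble.families)
    n_assigned = summary["assigned"].sum()
    n_unknown = sum(l == UNKNOWN_LABEL for l in report.final_labels)
    assert n_assigned + n_unknown == len(test)


def test_bundle_save_load_roundtrip(tmp_path, tiny_ensemble):
    corpus, ensemble, _ = tiny_ensemble
    ensemble.save(tmp_path / "bundle")
    back = EnsembleModel.load(tmp_path / "bundle")
    assert back.families == ensemble.families
    assert back.k == ensemble.k
    assert back.mask.indices == ensemble.mask.indices
    records = corpus.records[:5]
    assert np.array_equal(score_all(back, records), score_all(ensemble, records))
    r1 = predict(back, records, method="two_stage", threshold=0.5)
    r2 = predict(ensemble, records, method="two_stage", threshold=0.5)
    assert r1.table.equals(r2.table)


def test_column_permutation_consistency(tiny_ensemble):
    corpus, ensemble, _ = tiny_ensemble
    records = corpus.labeled().records[:30]
    perm = [2, 0, 1]
    permuted = EnsembleModel(
        k=ensemble.k, mask=ensemble.mask,
        families=[ensemble.families[i] for i in perm],
        binaries=[ensemble.binaries[i] for i in perm],
        stacker=None, scaler=ensemble.scaler,
    )
    base = predict(ensemble, records, method="max_vote", threshold=0.5)
    swapped = predict(permuted, records, method="max_vote", threshold=0.5)
    assert base.final_labels == swapped.final_labels


def test_threshold_sweep_reuses_scores(tiny_ensemble):
    from planttf.metrics import threshold_sweep

    corpus, ensemble, split = tiny_ensemble
    test = corpus.labeled().subset(split.test_ids)
    truth = [r.family for r in test]
    reports = threshold_sweep(ensemble, test, truth, method="two_stage",
                              thresholds=(0.0, 0.5, 0.95))
    assert [r.threshold for r in reports] == [0.0, 0.5, 0.95]
    accs = [r.micro["accuracy"] for r in reports]
    assert accs == sorted(accs, reverse=True)
    with pytest.raises(ValueError, match="sorted"):
        threshold_sweep(ensemble, test, truth, thresholds=(0.5, 0.0))
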