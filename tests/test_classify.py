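import numpy as np
import pytest
from sklearn.base import clone

from shapebias import classify as C
from shapebias.stimuli import render_silhouette, serrate, part_scramble


def _flat(cat):
    X, y = [], []
    for label in cat.vocabulary:
        for m in cat.train[label]:
            X.append(m)
            y.append(label)
    return X, y


def test_validate_probs():
    assert C.validate_probs([0.5, 0.5]).ok
    assert not C.validate_probs([0.5, 0.6]).ok
    assert not C.validate_probs([-0.1, 1.1]).ok
    assert not C.validate_probs([]).ok


def test_image_to_mask_from_rendered(disk_mask):
    stim = render_silhouette(disk_mask)
    mask = C.image_to_mask(stim.pixels)
    assert set(np.unique(mask)) <= {0, 1}
    # same figure up to the 224-canvas placement: area ratio of mask to
    # canvas matches the placed silhouette
    assert mask.sum() > 0


def test_image_to_mask_uniform_error():
    with pytest.raises(ValueError):
        C.image_to_mask(np.full((20, 20, 3), 255, dtype=np.uint8))


@pytest.mark.parametrize("kind", ["curvature", "efd"])
def test_toy_classifier_fit_predict(small_catalog, kind):
    X, y = _flat(small_catalog)
    clf = C.ToyShapeClassifier(feature_kind=kind).fit(X, y)
    Xte = [m for label in small_catalog.vocabulary
           for m in small_catalog.test[label]]
    yte = [label for label in small_catalog.vocabulary
           for _ in small_catalog.test[label]]
    P = clf.predict_proba(Xte)
    assert P.shape == (len(Xte), 4)
    for row in P:
        assert C.validate_probs(row).ok
    acc = float(np.mean(clf.predict(Xte) == np.array(yte)))
    assert acc >= 0.75  # small catalog, held-out split


def test_toy_classifier_deterministic(small_catalog):
    X, y = _flat(small_catalog)
    a = C.ToyShapeClassifier().fit(X, y)
    b = C.ToyShapeClassifier().fit(X, y)
    assert np.array_equal(a.centroids_, b.centroids_)


def test_toy_classifier_sklearn_contract(small_catalog):
    clf = C.ToyShapeClassifier(temperature=2.0)
    params = clf.get_params()
    assert params["temperature"] == 2.0
    cloned = clone(clf)
    assert cloned.get_params() == params
    clf.set_params(temperature=0.5)
    assert clf.get_params()["temperature"] == 0.5


def test_toy_classifier_errors(small_catalog):
    X, y = _flat(small_catalog)
    with pytest.raises(ValueError):
        C.ToyShapeClassifier(temperature=0.0).fit(X, y)
    with pytest.raises(ValueError):
        C.ToyShapeClassifier().fit([], [])
    with pytest.raises(ValueError):
        C.ToyShapeClassifier(feature_kind="resnet").fit(X, y)
    with pytest.raises(Exception):
        C.ToyShapeClassifier().predict(X)  # not fitted


def test_serialization_round_trip(small_catalog, tmp_path):
    X, y = _flat(small_catalog)
    clf = C.ToyShapeClassifier(feature_kind="efd").fit(X, y)
    clf.save(tmp_path / "m.json")
    back = C.ToyShapeClassifier.load(tmp_path / "m.json")
    Xte = [small_catalog.test[v][0] for v in small_catalog.vocabulary]
    assert np.allclose(clf.predict_proba(Xte), back.predict_proba(Xte))
    assert list(back.classes_) == list(clf.classes_)


def test_fit_predict_toy_wrappers(small_catalog):
    model = C.fit_toy(small_catalog.train, feature_kind="curvature")
    p = C.predict_toy(model, small_catalog.test[small_catalog.vocabulary[0]][0])
    assert C.validate_probs(p).ok
    with pytest.raises(ValueError):
        C.fit_toy({"empty": []})


def test_curvature_classifier_insensitive_to_scramble(small_catalog):
    """Directional property at small scale: scrambling hurts the local-
    feature classifier less than serration does."""
    X, y = _flat(small_catalog)
    clf = C.ToyShapeClassifier(feature_kind="curvature").fit(X, y)
    Xte = [m for v in small_catalog.vocabulary for m in small_catalog.test[v]]
    yte = np.array([v for v in small_catalog.vocabulary
                    for _ in small_catalog.test[v]])
    scr = [part_scramble(m, n_parts=3, seed=i)[0] for i, m in enumerate(Xte)]
    ser = [serrate(m)[0] for m in Xte]
    acc_scr = float(np.mean(clf.predict(scr) == yte))
    acc_ser = float(np.mean(clf.predict(ser) == yte))
    assert acc_scr > acc_ser


def test_mock_adapter_contract():
    adapter = C.MockAdapter(classes=["a", "b"], probs=[0.7, 0.3])
    out = adapter.predict_proba([None, None, None])
    assert out.shape == (3, 2)
    for row in out:
        assert C.validate_probs(row).ok
    with pytest.raises(ValueError):
        C.MockAdapter(classes=["a"], probs=[0.5, 0.5])


def test_external_adapter_contract_documented():
    contract = C.external_adapter_contract()
    assert "predict_proba(images) -> (n, K) array" in contract["methods"]
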