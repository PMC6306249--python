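import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from shapebias import metrics as M
from shapebias.stimuli import StimulusRecord

VOCAB = tuple(f"c{i}" for i in range(6))


def _outcome(shape="c0", texture=None, probs=None, manipulation="silhouette"):
    if probs is None:
        probs = np.full(len(VOCAB), 1 / len(VOCAB))
    rec = StimulusRecord(shape_label=shape, manipulation=manipulation,
                         texture_label=texture, item_id=f"{shape}/000")
    return M.ClassificationOutcome(record=rec, probs=tuple(probs),
                                   vocabulary=VOCAB)


# -- label_rank / in_topk ---------------------------------------------------


def test_label_rank_uniform_vector_vocab_first():
    p = np.full(6, 1 / 6)
    assert M.label_rank(p, VOCAB, "c0") == 1
    assert M.label_rank(p, VOCAB, "c5") == 6


def test_label_rank_unknown_label():
    with pytest.raises(KeyError):
        M.label_rank([1.0], ("a",), "b")


@settings(max_examples=100, deadline=None)
@given(st.integers(min_value=0, max_value=10 ** 9))
def test_label_rank_matches_sort_oracle(seed):
    rng = np.random.default_rng(seed)
    K = int(rng.integers(2, 20))
    p = rng.random(K)
    if rng.random() < 0.3:  # exercise ties
        p = np.round(p, 1)
    vocab = tuple(f"v{i}" for i in range(K))
    order = sorted(range(K), key=lambda j: (-p[j], j))
    for i in range(K):
        assert M.label_rank(p, vocab, vocab[i]) == order.index(i) + 1


def test_in_topk_matches_rank_and_is_monotone():
    rng = np.random.default_rng(1)
    p = rng.random(6)
    for k in range(1, 7):
        for label in VOCAB:
            assert M.in_topk(p, VOCAB, label, k) == \
                (M.label_rank(p, VOCAB, label) <= k)
    with pytest.raises(ValueError):
        M.in_topk(p, VOCAB, "c0", 0)
    with pytest.raises(ValueError):
        M.in_topk(p, VOCAB, "c0", 7)


def test_chance_level():
    assert M.chance_level(1000) == 0.001
    assert M.chance_level(1) == 1.0
    with pytest.raises(ValueError):
        M.chance_level(0)


# -- preference and vs-class-mean -------------------------------------------


def test_shape_texture_preference():
    assert M.shape_texture_preference([0.6, 0.4], ("s", "t"), "s", "t") == "shape"
    assert M.shape_texture_preference([0.4, 0.6], ("s", "t"), "s", "t") == "texture"
    assert M.shape_texture_preference([0.5, 0.5], ("s", "t"), "s", "t") == "tie"
    with pytest.raises(ValueError):
        M.shape_texture_preference([1.0], ("s",), "s", "s")


def test_vs_class_mean():
    above, p, mean = M.vs_class_mean([0.5, 0.3, 0.2], ("a", "b", "c"),
                                     "a", ["b", "c"])
    assert above and p == 0.5 and mean == pytest.approx(0.25)
    with pytest.raises(ValueError):
        M.vs_class_mean([0.5, 0.5], ("a", "b"), "a", ["a", "b"])
    with pytest.raises(ValueError):
        M.vs_class_mean([0.5, 0.5], ("a", "b"), "a", [])


def test_vs_class_mean_null_rate_is_half():
    """Under a uniform-random null the target beats the others' mean ~50%."""
    rng = np.random.default_rng(0)
    vocab = tuple(f"v{i}" for i in range(10))
    hits = 0
    n = 10_000
    for _ in range(n):
        p = rng.random(10)
        p /= p.sum()
        hits += M.vs_class_mean(p, vocab, "v0", list(vocab[1:]))[0]
    assert abs(hits / n - 0.5) < 0.02


# -- summarize ----------------------------------------------------------------


def test_summarize_counts_and_grouping():
    good = _outcome(probs=[0.9, 0.02, 0.02, 0.02, 0.02, 0.02])
    bad = _outcome(probs=[0.01, 0.02, 0.03, 0.04, 0.05, 0.85],
                   manipulation="serrate")
    tables = M.summarize([good, good, bad])
    assert set(tables) == {"silhouette", "serrate"}
    t = tables["silhouette"]
    assert t.n == 2 and t.n_top1_correct == 2 and t.n_below_chance == 0
    b = tables["serrate"]
    assert b.n == 1 and b.n_top1_correct == 0 and b.n_below_chance == 1
    assert b.mean_rank == 6.0
    # ratio of means: silhouette 0.9 vs serrate 0.01
    assert t.ratio_of_means == pytest.approx(90.0)
    assert b.ratio_of_means == pytest.approx(1 / 90.0)


def test_summarize_preference_counts():
    o = _outcome(shape="c0", texture="c1",
                 probs=[0.5, 0.3, 0.05, 0.05, 0.05, 0.05],
                 manipulation="chimera")
    t = M.summarize([o])["chimera"]
    assert t.preference_counts == {"shape": 1, "texture": 0, "tie": 0}
    assert t.mean_prob_texture == pytest.approx(0.3)


def test_summarize_empty_error():
    with pytest.raises(ValueError):
        M.summarize([])


def test_summary_table_invariants():
    with pytest.raises(ValueError):
        M.SummaryTable(group="g", n=1, n_top1_correct=2, n_top5_correct=0,
                       mean_rank=1.0, mean_prob_shape=0.5,
                       mean_prob_texture=None, n_below_chance=0)


def test_ratio_of_means():
    assert M.ratio_of_means([17.90], [1.75]) == pytest.approx(10.2285714286)
    with pytest.raises(ZeroDivisionError):
        M.ratio_of_means([1.0], [0.0])


# -- score_human --------------------------------------------------------------


def _table_responses():
    items = ["Camel", "Hammer", "Microphone", "Warplane", "Shirt", "Violin"]
    data = {
        ("scrambled", "1s"): [40, 10, 40, 20, 20, 40],
        ("scrambled", "unlimited"): [60, 0, 30, 20, 30, 80],
        ("unscrambled", "1s"): [100, 100, 90, 90, 100, 70],
        ("unscrambled", "unlimited"): [100, 100, 100, 90, 100, 90],
    }
    out = []
    for (cond, dt), pcts in data.items():
        for item, pct in zip(items, pcts):
            for s in range(10):
                out.append(M.HumanResponse(subject=f"s{s}_{dt}", item=item,
                                           condition=cond, display_time=dt,
                                           correct=s < pct // 10))
    return out


def test_score_human_reproduces_condition_means():
    per_item, per_cond = M.score_human(_table_responses())
    got = {(r.condition, r.display_time): r.accuracy
           for r in per_cond.itertuples()}
    assert got[("scrambled", "1s")] == pytest.approx(0.283333, abs=1e-6)
    assert got[("scrambled", "unlimited")] == pytest.approx(0.366667, abs=1e-6)
    assert got[("unscrambled", "1s")] == pytest.approx(0.916667, abs=1e-6)
    assert got[("unscrambled", "unlimited")] == pytest.approx(0.966667, abs=1e-6)
    camel = per_item[(per_item["item"] == "Camel")
                     & (per_item["condition"] == "scrambled")
                     & (per_item["display_time"] == "1s")]
    assert camel["accuracy"].iloc[0] == pytest.approx(0.4)


def test_score_human_duplicate_key_error():
    r = M.HumanResponse(subject="s", item="i", condition="scrambled",
                        display_time="1s", correct=True)
    with pytest.raises(ValueError):
        M.score_human([r, r])


def test_human_response_validation():
    with pytest.raises(ValueError):
        M.HumanResponse(subject="s", item="i", condition="upside-down",
                        display_time="1s", correct=True)
    with pytest.raises(ValueError):
        M.HumanResponse(subject="s", item="i", condition="scrambled",
                        display_time="2s", correct=True)


# -- t test -------------------------------------------------------------------


def test_two_sample_t_matches_scipy():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = rng.normal(0, 1, int(rng.integers(2, 30)))
        b = rng.normal(0.5, 2, int(rng.integers(2, 30)))
        r = M.two_sample_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert abs(r.t - ref.statistic) < 1e-10
        assert abs(r.p - ref.pvalue) < 1e-10
        assert r.df == len(a) + len(b) - 2


def test_two_sample_t_zero_variance_branches():
    r = M.two_sample_t([1.0, 1.0], [1.0, 1.0, 1.0])
    assert r.t == 0.0 and r.p == 1.0 and r.df == 3
    with pytest.raises(ValueError):
        M.two_sample_t([1.0, 1.0], [2.0, 2.0])
    with pytest.raises(ValueError):
        M.two_sample_t([1.0], [1.0, 2.0])


# -- report output ------------------------------------------------------------


def test_outcomes_table_and_write_report(tmp_path):
    o1 = _outcome(probs=[0.9, 0.02, 0.02, 0.02, 0.02, 0.02])
    o2 = _outcome(shape="c1", probs=[0.5, 0.3, 0.05, 0.05, 0.05, 0.05],
                  manipulation="serrate")
    df = M.outcomes_table([o1, o2])
    assert list(df["p_shape"]) == [0.9, 0.3]
    assert list(df["top1_correct"]) == [True, False]
    assert df["top1_label"].iloc[0] == "c0"
    paths = M.write_report([o1, o2], tmp_path, name="r")
    assert (tmp_path / "r.csv").exists() and (tmp_path / "r.json").exists()
    import json
    d = json.loads((tmp_path / "r.json").read_text())
    assert d["silhouette"]["n_top1_correct"] == 1


def test_outcome_validation():
    with pytest.raises(ValueError):
        _outcome(probs=[0.5, 0.5])  # wrong length
    rec = StimulusRecord(shape_label="nope", manipulation="silhouette")
    with pytest.raises(ValueError):
        M.ClassificationOutcome(record=rec, probs=tuple(np.full(6, 1 / 6)),
                                vocabulary=VOCAB)
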