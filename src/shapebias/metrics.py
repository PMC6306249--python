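"""Analysis statistics for classifier outputs and human responses.

Implements the study's report quantities: competition label ranks and
top-k correctness, chance level, shape-vs-texture preference on
cue-conflict stimuli, target-vs-class-mean comparisons, grouped summary
tables (top-1/top-5 counts, mean rank, mean probabilities, below-chance
counts, preference counts, ratio of group means), per-item / per-condition
human accuracy tables, and the pooled two-sample t test.

Conventions
-----------
* Ranking is *competition ranking*: rank = 1 + number of labels with
  strictly greater probability; ties are broken by vocabulary order so
  reports are deterministic.
* Preference and target-vs-mean comparisons use strict inequality; ties
  are reported explicitly, never split.
* The t test is the pooled (Student) form with df = n1 + n2 - 2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .stimuli import StimulusRecord

__all__ = [
    "ClassificationOutcome",
    "SummaryTable",
    "HumanResponse",
    "TTestResult",
    "label_rank",
    "in_topk",
    "chance_level",
    "shape_texture_preference",
    "vs_class_mean",
    "summarize",
    "ratio_of_means",
    "score_human",
    "two_sample_t",
    "outcomes_table",
    "write_report",
]

TOPK_DEFAULT = 5


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ClassificationOutcome:
    """One stimulus, one probability vector over a fixed vocabulary."""

    record: StimulusRecord
    probs: tuple
    vocabulary: tuple

    def __post_init__(self):
        if len(self.probs) != len(self.vocabulary):
            raise ValueError("probs and vocabulary must align")
        if self.record.shape_label not in self.vocabulary:
            raise ValueError(f"shape label {self.record.shape_label!r} not in vocabulary")
        if self.record.texture_label and self.record.texture_label not in self.vocabulary:
            raise ValueError(f"texture label {self.record.texture_label!r} not in vocabulary")


@dataclass(frozen=True)
class SummaryTable:
    """Aggregate report quantities for one group of outcomes.

    ``ratio_of_means`` is this group's mean shape-label probability divided
    by the pooled mean of all *other* groups in the same ``summarize``
    call; ``None`` when there is no other group.
    """

    group: str
    n: int
    n_top1_correct: int
    n_top5_correct: int
    mean_rank: float
    mean_prob_shape: float
    mean_prob_texture: float | None
    n_below_chance: int
    preference_counts: dict = field(default_factory=dict)
    ratio_of_means: float | None = None

    def __post_init__(self):
        if not (self.n_top1_correct <= self.n and self.n_top5_correct <= self.n
                and self.n_below_chance <= self.n):
            raise ValueError("counts cannot exceed group size")
        if not self.mean_rank >= 1:
            raise ValueError("mean_rank must be >= 1")


@dataclass(frozen=True)
class HumanResponse:
    """One subject's correctness on one item in one condition."""

    subject: str
    item: str
    condition: str
    display_time: str
    correct: bool

    def __post_init__(self):
        if self.condition not in ("scrambled", "serrated", "unscrambled"):
            raise ValueError("condition must be scrambled|serrated|unscrambled")
        if self.display_time not in ("1s", "unlimited"):
            raise ValueError("display_time must be '1s' or 'unlimited'")

    @property
    def key(self) -> tuple:
        return (self.subject, self.item, self.condition, self.display_time)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.df < 1:
            raise ValueError("df must be >= 1")


# ---------------------------------------------------------------------------
# per-vector statistics


def _index_of(vocabulary, label) -> int:
    try:
        return list(vocabulary).index(label)
    except ValueError:
        raise KeyError(f"label {label!r} not in vocabulary") from None


def label_rank(probs, vocabulary, label) -> int:
    """Competition rank of ``label``: 1 + #{strictly greater}.

    Ties are broken by vocabulary order (earlier labels rank better), so
    a uniform vector ranks the vocabulary-first label 1.
    """
    p = np.asarray(probs, dtype=float)
    i = _index_of(vocabulary, label)
    greater = int(np.sum(p > p[i]))
    earlier_ties = int(np.sum(p[:i] == p[i]))
    return 1 + greater + earlier_ties


def in_topk(probs, vocabulary, label, k: int = TOPK_DEFAULT) -> bool:
    """True iff the label's competition rank is <= k (monotone in k)."""
    if not 1 <= k <= len(vocabulary):
        raise ValueError("k must satisfy 1 <= k <= K")
    return label_rank(probs, vocabulary, label) <= k


def chance_level(K: int) -> float:
    """Uninformed per-label probability: exactly 1/K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return 1.0 / K


def shape_texture_preference(probs, vocabulary, shape_label, texture_label) -> str:
    """Which of the two cue labels got strictly more probability ("tie" if equal)."""
    if shape_label == texture_label:
        raise ValueError("shape and texture labels must be distinct")
    p = np.asarray(probs, dtype=float)
    ps = p[_index_of(vocabulary, shape_label)]
    pt = p[_index_of(vocabulary, texture_label)]
    if ps > pt:
        return "shape"
    if pt > ps:
        return "texture"
    return "tie"


def vs_class_mean(probs, vocabulary, target_label, other_labels):
    """Is the target label's probability strictly above the mean of the others?

    Returns ``(above, p_target, mean_others)``.
    """
    others = list(other_labels)
    if not others:
        raise ValueError("other_labels must be nonempty")
    if target_label in others:
        raise ValueError("target must not appear among other_labels")
    p = np.asarray(probs, dtype=float)
    p_target = float(p[_index_of(vocabulary, target_label)])
    mean_others = float(np.mean([p[_index_of(vocabulary, o)] for o in others]))
    return p_target > mean_others, p_target, mean_others


# ---------------------------------------------------------------------------
# aggregation


def _default_grouping(outcome: ClassificationOutcome) -> str:
    return outcome.record.manipulation


def summarize(outcomes, grouping=None, topk: int = TOPK_DEFAULT) -> dict:
    """Group outcomes and compute a :class:`SummaryTable` per group.

    ``grouping`` is a callable ``outcome -> group name`` (default: the
    stimulus record's manipulation).  Empty input is an error; groups that
    come out empty after grouping are simply absent.  Each table's
    ``ratio_of_means`` divides its mean shape probability by the pooled
    mean over all other groups (``None`` for a single group; ``inf`` when
    the other groups' mean is zero).
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    grouping = grouping or _default_grouping
    groups: dict[str, list] = {}
    for o in outcomes:
        groups.setdefault(str(grouping(o)), []).append(o)

    shape_probs = {
        g: [float(np.asarray(o.probs)[_index_of(o.vocabulary, o.record.shape_label)])
            for o in members]
        for g, members in groups.items()
    }
    tables = {}
    for g, members in sorted(groups.items()):
        ranks, ps_list, pt_list, prefs = [], [], [], {"shape": 0, "texture": 0, "tie": 0}
        n_top1 = n_topk = n_below = 0
        for o in members:
            r = label_rank(o.probs, o.vocabulary, o.record.shape_label)
            ranks.append(r)
            n_top1 += r == 1
            n_topk += r <= topk
            ps = float(np.asarray(o.probs)[_index_of(o.vocabulary, o.record.shape_label)])
            ps_list.append(ps)
            n_below += ps < chance_level(len(o.vocabulary))
            if o.record.texture_label:
                pt_list.append(float(np.asarray(o.probs)[
                    _index_of(o.vocabulary, o.record.texture_label)]))
                prefs[shape_texture_preference(o.probs, o.vocabulary,
                                               o.record.shape_label,
                                               o.record.texture_label)] += 1
        other = [v for g2, vals in shape_probs.items() if g2 != g for v in vals]
        if other:
            om = float(np.mean(other))
            ratio = float(np.mean(ps_list)) / om if om > 0 else float("inf")
        else:
            ratio = None
        tables[g] = SummaryTable(
            group=g, n=len(members), n_top1_correct=n_top1, n_top5_correct=n_topk,
            mean_rank=float(np.mean(ranks)), mean_prob_shape=float(np.mean(ps_list)),
            mean_prob_texture=float(np.mean(pt_list)) if pt_list else None,
            n_below_chance=n_below, preference_counts=prefs, ratio_of_means=ratio)
    return tables


def ratio_of_means(means_a, means_b) -> float:
    """Ratio of two group means (e.g. printed 17.90 / 1.75 -> ~10x)."""
    ma = float(np.mean(np.asarray(means_a, dtype=float)))
    mb = float(np.mean(np.asarray(means_b, dtype=float)))
    if mb == 0:
        raise ZeroDivisionError("denominator group mean is zero")
    return ma / mb


# ---------------------------------------------------------------------------
# human scoring


def score_human(responses) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-item and per-condition accuracy tables from human responses.

    Returns ``(per_item, per_condition)`` data frames.  Per-item rows are
    ``(item, condition, display_time, n, accuracy)``; per-condition
    accuracy is the *unweighted mean over items* (the study's condition
    means equal the item-column means).  Duplicate
    (subject, item, condition, display_time) keys are an error.
    """
    responses = list(responses)
    if not responses:
        raise ValueError("no responses")
    seen = set()
    for r in responses:
        if r.key in seen:
            raise ValueError(f"duplicate response key {r.key}")
        seen.add(r.key)
    df = pd.DataFrame([asdict(r) for r in responses])
    per_item = (df.groupby(["item", "condition", "display_time"], sort=True)["correct"]
                  .agg(n="count", accuracy="mean").reset_index())
    per_condition = (per_item.groupby(["condition", "display_time"], sort=True)["accuracy"]
                     .agg(n_items="count", accuracy="mean").reset_index())
    return per_item, per_condition


def two_sample_t(a, b) -> TTestResult:
    """Pooled-variance two-sample t test, df = n1 + n2 - 2, two-sided p.

    Zero pooled variance: equal means give ``t = 0, p = 1``; unequal means
    are an error (infinite t under the pooled model).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0)
        raise ValueError("zero pooled variance with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * float(_stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=int(df), p=min(p, 1.0))


# ---------------------------------------------------------------------------
# report output


def outcomes_table(outcomes, topk: int = TOPK_DEFAULT) -> pd.DataFrame:
    """Per-stimulus report rows mirroring the study's figure tables.

    Columns: stimulus id, shape label and its probability, texture label
    and its probability (when present), the top-k labels and probabilities,
    and correctness flags.
    """
    rows = []
    for i, o in enumerate(outcomes):
        p = np.asarray(o.probs, dtype=float)
        order = np.argsort(-p, kind="stable")[:topk]
        row = {
            "stimulus": f"{o.record.shape_label}/{o.record.manipulation}/{i:04d}",
            "shape_label": o.record.shape_label,
            "p_shape": float(p[_index_of(o.vocabulary, o.record.shape_label)]),
            "texture_label": o.record.texture_label or "",
            "p_texture": (float(p[_index_of(o.vocabulary, o.record.texture_label)])
                          if o.record.texture_label else np.nan),
            "rank_shape": label_rank(o.probs, o.vocabulary, o.record.shape_label),
        }
        row["top1_correct"] = row["rank_shape"] == 1
        row[f"top{topk}_correct"] = row["rank_shape"] <= topk
        for j, idx in enumerate(order, start=1):
            row[f"top{j}_label"] = o.vocabulary[idx]
            row[f"top{j}_prob"] = float(p[idx])
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(outcomes, out_dir, name: str = "report",
                 grouping=None, topk: int = TOPK_DEFAULT) -> dict:
    """Write per-stimulus CSV + summary JSON for a batch of outcomes.

    Returns ``{"csv": path, "json": path}``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = outcomes_table(outcomes, topk=topk)
    csv_path = out / f"{name}.csv"
    table.to_csv(csv_path, index=False)
    tables = summarize(outcomes, grouping=grouping, topk=topk)
    json_path = out / f"{name}.json"
    json_path.write_text(json.dumps({g: asdict(t) for g, t in tables.items()},
                                    indent=2, sort_keys=True))
    return {"csv": str(csv_path), "json": str(json_path)}
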