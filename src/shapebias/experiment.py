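"""End-to-end experiment runner: generate -> classify -> analyze -> report.

Each experiment presents a seeded synthetic catalog to one or two toy
classifiers (or an external adapter) under a family of stimulus
manipulations and reports per-stimulus outcomes plus grouped summary
tables:

* ``chimera`` — silhouettes vs texture chimeras (cue conflict).
* ``outline`` — silhouettes vs outline drawings.
* ``silhouette_colorways`` — the same silhouettes in three colorways.
* ``scramble`` — silhouettes vs part-scrambled figures.
* ``serrate`` — silhouettes vs serrated figures.

Runs are deterministic given the config (toy classifiers), written to
disk (PNG stimuli, manifest CSV, outcome CSV/JSON, run metadata JSON) and
resumable: per-stimulus probabilities are appended to ``outcomes.jsonl``
as they are computed, and a re-run over a partial directory skips the
finished ones.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

from pathlib import Path

import numpy as np

from . import stimuli as S
from . import synth
from .classify import ToyShapeClassifier, image_to_mask, validate_probs
from .metrics import ClassificationOutcome, summarize, write_report

__all__ = [
    "EXPERIMENTS",
    "ExperimentConfig",
    "RunReport",
    "run_experiment",
    "compare_runs",
    "load_report",
]

log = logging.getLogger("shapebias")

EXPERIMENTS = ("chimera", "outline", "silhouette_colorways", "scramble", "serrate")
CLASSIFIERS = ("curvature", "efd", "both")

# texture palettes avoid pure white so chimera foregrounds never merge
# with the white canvas background during mask recovery
_TEXTURE_CYCLE = (
    ("grating", (0, 0, 0), (128, 128, 128)),
    ("checkerboard", (200, 30, 30), (30, 30, 200)),
    ("dots", (60, 120, 60), (230, 230, 40)),
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a run bit-identically."""

    experiment: str
    seed: int
    out_dir: str
    classifier: str = "both"          # curvature | efd | both | adapter key
    n_classes: int = 10
    n_exemplars: int = 20
    blob_fraction: float = 1.0
    manipulation_params: dict = field(default_factory=dict)
    canvas: tuple = (224, 224)
    save_stimuli: bool = False

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_classes < 2 or self.n_exemplars < 2:
            raise ValueError("need >= 2 classes and >= 2 exemplars")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "canvas" in d:
            d["canvas"] = tuple(d["canvas"])
        return cls(**d)


@dataclass(frozen=True)
class RunReport:
    """Manifest, per-stimulus outcomes and summary tables for one run."""

    config: dict
    version: str
    manifest: tuple                   # StimulusRecord per stimulus
    outcomes: dict                    # classifier name -> tuple[ClassificationOutcome]
    tables: dict                      # classifier name -> {condition: SummaryTable}
    elapsed_s: float = 0.0

    def __post_init__(self):
        for name, outs in self.outcomes.items():
            if len(outs) != len(self.manifest):
                raise ValueError(
                    f"{name}: {len(outs)} outcomes for {len(self.manifest)} stimuli")


# ---------------------------------------------------------------------------
# stimulus construction per experiment


def _stimulus_id(record: S.StimulusRecord) -> str:
    return f"{record.item_id}|{record.manipulation}|{record.params.get('variant', '')}"


def _class_texture(vocabulary, label, seed: int) -> synth.TextureSpec:
    i = list(vocabulary).index(label)
    kind, ca, cb = _TEXTURE_CYCLE[i % len(_TEXTURE_CYCLE)]
    return synth.TextureSpec(kind=kind, period=12.0 + 4.0 * (i % 3),
                             angle=0.4 * i, color_a=ca, color_b=cb,
                             seed=seed + i)


def _build_stimuli(config: ExperimentConfig, catalog: synth.Catalog) -> list:
    """List of (record, StimulusImage) covering every test exemplar in every
    condition of the configured experiment."""
    mp = dict(config.manipulation_params)
    out = []

    def silhouette(label, idx, mask, colorway=S.BLACK_ON_WHITE, variant="base"):
        rec = S.StimulusRecord(
            shape_label=label, manipulation="silhouette", colorway=colorway,
            params={"variant": variant}, item_id=f"{label}/{idx:03d}")
        return rec, S.render_silhouette(mask, colorway=colorway,
                                        out_size=config.canvas, record=rec)

    for label in catalog.vocabulary:
        for idx, mask in enumerate(catalog.test[label]):
            if config.experiment != "silhouette_colorways":
                out.append(silhouette(label, idx, mask))
            if config.experiment == "silhouette_colorways":
                for cw, name in ((S.BLACK_ON_WHITE, "black_on_white"),
                                 (S.WHITE_ON_BLACK, "white_on_black"),
                                 (S.RED_ON_WHITE, "red_on_white")):
                    out.append(silhouette(label, idx, mask, colorway=cw,
                                          variant=name))
            elif config.experiment == "outline":
                rec = S.StimulusRecord(
                    shape_label=label, manipulation="outline",
                    params={"stroke_px": mp.get("stroke_px", 2)},
                    item_id=f"{label}/{idx:03d}")
                out.append((rec, S.render_outline(
                    mask, stroke_px=mp.get("stroke_px", 2),
                    out_size=config.canvas, record=rec)))
            elif config.experiment == "chimera":
                others = [c for c in catalog.vocabulary if c != label]
                li = list(catalog.vocabulary).index(label)
                tex_label = others[(idx + li) % len(others)]
                tex = synth.gen_texture(
                    _class_texture(catalog.vocabulary, tex_label, config.seed),
                    config.canvas)
                rec = S.StimulusRecord(
                    shape_label=label, manipulation="chimera",
                    texture_label=tex_label, item_id=f"{label}/{idx:03d}")
                out.append((rec, S.render_texture_chimera(
                    mask, tex, out_size=config.canvas, record=rec)))
            elif config.experiment == "scramble":
                seed = config.seed * 100_003 + idx
                scr, _report = S.part_scramble(
                    mask, n_parts=mp.get("n_parts", 3), seed=seed)
                rec = S.StimulusRecord(
                    shape_label=label, manipulation="part_scramble",
                    params={"n_parts": mp.get("n_parts", 3)}, seed=seed,
                    item_id=f"{label}/{idx:03d}")
                out.append((rec, S.render_silhouette(scr, out_size=config.canvas,
                                                     record=rec)))
            elif config.experiment == "serrate":
                ser, _report = S.serrate(
                    mask, amplitude_px=mp.get("amplitude_px"),
                    period_px=mp.get("period_px"))
                rec = S.StimulusRecord(
                    shape_label=label, manipulation="serrate",
                    params={k: mp[k] for k in ("amplitude_px", "period_px")
                            if k in mp},
                    item_id=f"{label}/{idx:03d}")
                out.append((rec, S.render_silhouette(ser, out_size=config.canvas,
                                                     record=rec)))
    return out


# ---------------------------------------------------------------------------
# classification with resumable cache


def _classifiers(config: ExperimentConfig, catalog: synth.Catalog,
                 adapters: dict | None) -> dict:
    if config.classifier in ("curvature", "efd", "both"):
        kinds = ("curvature", "efd") if config.classifier == "both" \
            else (config.classifier,)
        out = {}
        X = [m for label in catalog.vocabulary for m in catalog.train[label]]
        y = [label for label in catalog.vocabulary
             for _ in catalog.train[label]]
        for kind in kinds:
            out[kind] = ToyShapeClassifier(feature_kind=kind).fit(X, y)
        return out
    adapters = adapters or {}
    if config.classifier not in adapters:
        raise LookupError(
            f"adapter {config.classifier!r} unavailable; pass it via "
            f"run_experiment(..., adapters={{{config.classifier!r}: obj}}) "
            f"or use a toy classifier ({', '.join(CLASSIFIERS)})")
    return {config.classifier: adapters[config.classifier]}


def _load_cache(path: Path) -> dict:
    cache = {}
    if path.exists():
        for line in path.read_text().splitlines():
            if line.strip():
                d = json.loads(line)
                cache[(d["classifier"], d["stimulus"])] = d["probs"]
    return cache


def _classify_all(stimuli, models: dict, cache_path: Path) -> dict:
    cache = _load_cache(cache_path)
    if cache:
        log.info("resuming: %d cached outcomes found", len(cache))
    outcomes = {name: [] for name in models}
    with cache_path.open("a") as fh:
        for name, model in models.items():
            vocab = tuple(str(c) for c in model.classes_)
            for rec, stim in stimuli:
                key = (name, _stimulus_id(rec))
                if key in cache:
                    probs = cache[key]
                else:
                    probs = model.predict_proba([stim.pixels])[0].tolist()
                    diag = validate_probs(probs)
                    if not diag.ok:
                        raise ValueError(
                            f"{name} violated the probability contract on "
                            f"{key[1]}: {diag.message}")
                    fh.write(json.dumps({"classifier": name, "stimulus": key[1],
                                         "probs": probs}) + "\n")
                    fh.flush()
                outcomes[name].append(ClassificationOutcome(
                    record=rec, probs=tuple(probs), vocabulary=vocab))
    return outcomes


def _grouping(outcome: ClassificationOutcome) -> str:
    variant = outcome.record.params.get("variant")
    if outcome.record.manipulation == "silhouette" and variant not in (None, "base"):
        return f"silhouette:{variant}"
    return outcome.record.manipulation


# ---------------------------------------------------------------------------
# the operations


def run_experiment(config: ExperimentConfig, adapters: dict | None = None) -> RunReport:
    """Run one experiment end to end and write all outputs under
    ``config.out_dir``.  Deterministic given the config (toy classifiers);
    resumable from a partial output directory."""
    from . import __version__

    t0 = time.monotonic()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    try:
        log.info("experiment=%s seed=%d classifier=%s",
                 config.experiment, config.seed, config.classifier)
        catalog = synth.build_catalog(config.n_classes, config.n_exemplars,
                                      seed=config.seed,
                                      blob_fraction=config.blob_fraction,
                                      canvas=config.canvas)
        models = _classifiers(config, catalog, adapters)
        stimuli = _build_stimuli(config, catalog)
        log.info("generated %d stimuli over %d classes",
                 len(stimuli), len(catalog.vocabulary))
        if config.save_stimuli:
            png_dir = out_dir / "stimuli"
            png_dir.mkdir(exist_ok=True)
            for i, (rec, stim) in enumerate(stimuli):
                S.save_stimulus(stim, png_dir / f"{i:05d}.png")
        S.write_manifest([rec for rec, _ in stimuli], out_dir / "manifest.csv")
        outcomes = _classify_all(stimuli, models, out_dir / "outcomes.jsonl")
        tables = {}
        for name, outs in outcomes.items():
            tables[name] = summarize(outs, grouping=_grouping)
            write_report(outs, out_dir, name=f"report_{name}", grouping=_grouping)
        report = RunReport(
            config=asdict(config), version=__version__,
            manifest=tuple(rec for rec, _ in stimuli),
            outcomes={k: tuple(v) for k, v in outcomes.items()},
            tables=tables, elapsed_s=time.monotonic() - t0)
        (out_dir / "run.json").write_text(json.dumps({
            "config": report.config, "version": report.version,
            "n_stimuli": len(report.manifest),
            "elapsed_s": round(report.elapsed_s, 3),
            "tables": {name: {g: asdict(t) for g, t in tbl.items()}
                       for name, tbl in tables.items()},
        }, indent=2, sort_keys=True))
        log.info("done: %d stimuli, %.1f s", len(stimuli), report.elapsed_s)
        return report
    finally:
        log.removeHandler(fh)
        fh.close()


def _shape_probs_by_item(report: RunReport, classifier: str,
                         condition: str | None = None) -> dict:
    if classifier not in report.outcomes:
        raise KeyError(f"classifier {classifier!r} not in report "
                       f"({sorted(report.outcomes)})")
    probs = {}
    for o in report.outcomes[classifier]:
        if condition is not None and _grouping(o) != condition:
            continue
        key = _stimulus_id(o.record)
        i = list(o.vocabulary).index(o.record.shape_label)
        probs[key] = float(np.asarray(o.probs)[i])
    if condition is not None and not probs:
        raise ValueError(f"no outcomes in condition {condition!r}")
    return probs


def compare_runs(report_a: RunReport, report_b: RunReport,
                 classifier: str | None = None,
                 condition_a: str | None = None,
                 condition_b: str | None = None) -> dict:
    """Per-item and mean shape-probability ratios A / B.

    Items are matched by stimulus id; a mismatch in item sets or
    vocabulary is an error.  A report compared against itself yields all
    ratios exactly 1.  ``condition_a`` / ``condition_b`` restrict each
    report to one condition group first, so the same run can supply both
    sides (e.g. ``condition_a="silhouette", condition_b="part_scramble"``
    gives the unscrambled-over-scrambled per-item ratios).
    ``log10_ratios`` is provided for log-scale plots (items with a zero
    probability on either side are skipped there).
    """
    if classifier is None:
        shared = sorted(set(report_a.outcomes) & set(report_b.outcomes))
        if len(shared) != 1:
            raise ValueError(f"specify classifier explicitly (shared: {shared})")
        classifier = shared[0]
    va = report_a.outcomes[classifier][0].vocabulary
    vb = report_b.outcomes[classifier][0].vocabulary
    if va != vb:
        raise ValueError("vocabulary mismatch between runs")
    pa = _shape_probs_by_item(report_a, classifier, condition_a)
    pb = _shape_probs_by_item(report_b, classifier, condition_b)
    if set(pa) == set(pb):
        # identical stimulus keys (e.g. report vs itself): match exactly
        a_by_item, b_by_item = pa, pb
    else:
        # different conditions over the same items (e.g. unscrambled run vs
        # scrambled run): match on item id, which must be unique per report
        def by_item(p, which):
            out = {}
            for k, v in p.items():
                item = k.split("|")[0]
                if item in out:
                    raise ValueError(
                        f"report {which} has multiple conditions per item "
                        f"({item}); compare single-condition runs or "
                        f"identical stimulus sets")
                out[item] = v
            return out
        a_by_item = by_item(pa, "A")
        b_by_item = by_item(pb, "B")
        if set(a_by_item) != set(b_by_item):
            raise ValueError(
                "item mismatch: "
                f"{sorted(set(a_by_item) ^ set(b_by_item))[:5]} not shared")
    per_item = {}
    for item in sorted(a_by_item):
        num, den = a_by_item[item], b_by_item[item]
        per_item[item] = num / den if den > 0 else float("inf")
    finite = [r for r in per_item.values() if np.isfinite(r) and r > 0]
    return {
        "classifier": classifier,
        "per_item_ratio": per_item,
        "mean_ratio": float(np.mean(list(per_item.values())))
        if all(np.isfinite(list(per_item.values()))) else float("inf"),
        "log10_ratios": {k: float(np.log10(v)) for k, v in per_item.items()
                         if np.isfinite(v) and v > 0},
        "n_items": len(per_item),
        "n_finite": len(finite),
    }


def load_report(out_dir) -> dict:
    """Load the serialized summary of a finished run (run.json)."""
    return json.loads((Path(out_dir) / "run.json").read_text())
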