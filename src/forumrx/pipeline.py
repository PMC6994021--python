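"""Pipeline orchestration: stage functions, manifests, and configuration.

Stages (``simulate``, ``preprocess``, ``classify``, ``extract``, ``lines``,
``match``, ``compare``) are runnable independently against a shared output
directory, or end to end via :func:`run_all`. Each stage writes a manifest
recording its inputs' checksums, configuration and seed, so any output table
can be reproduced from its recorded provenance. Stage seeds are derived from
the master seed by stage name, so rerunning one stage never perturbs another.

The in-memory core (:func:`analyze_posts`, :func:`run_end_to_end`) is the
library surface tests and scripts use; the file-based stages wrap it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import classify as clf
from .compare import compare_sources, concordance_report, frequency_match
from .context import resolve_mentions, resolved_to_frame
from .ingest import (build_sentence_table, filter_treatment_users,
                     read_posts_jsonl, write_posts_jsonl)
from .lexicon import default_lexicon, find_mentions, load_lexicon
from .lines import DEFAULT_COMBO_WINDOW_DAYS, line_counts, lines_table
from .synthetic import (SimulationConfig, NoiseConfig, generate_truth,
                        render_comparators, render_posts, stage_rng,
                        truth_lines_table, write_comparators_csv,
                        write_labels_csv, write_truth_csv)

__all__ = [
    "PipelineError",
    "PipelineConfig",
    "STAGES",
    "analyze_posts",
    "run_end_to_end",
    "run_stage",
    "run_all",
]

log = logging.getLogger("forumrx")

STAGES = ("simulate", "preprocess", "classify", "extract", "lines", "match",
          "compare")

SM_NAME = "social_media"


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; serializable to YAML."""

    outdir: Path = Path("forumrx-out")
    seed: int = 0
    sim: SimulationConfig | None = field(default_factory=SimulationConfig)
    lexicon_path: Path | None = None  # None -> bundled default lexicon
    classifier: str = "auto"  # auto | svm_linear | naive_bayes | knn | none
    combo_window_days: int = DEFAULT_COMBO_WINDOW_DAYS
    match_ratio: int = 4
    top_k: int = 6
    log_level: str = "INFO"

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.sim is not None and self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def lexicon(self):
        if self.lexicon_path is None:
            return default_lexicon()
        return load_lexicon(self.lexicon_path)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["outdir"] = str(self.outdir)
        out["lexicon_path"] = (
            None if self.lexicon_path is None else str(self.lexicon_path))
        if self.sim is not None:
            out["sim"]["noise"] = dataclasses.asdict(self.sim.noise)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.get("sim")
        if sim is not None:
            sim = dict(sim)
            noise = sim.get("noise")
            if isinstance(noise, dict):
                sim["noise"] = NoiseConfig(**noise)
            if "year_counts" in sim:
                sim["year_counts"] = {
                    int(k): v for k, v in sim["year_counts"].items()}
            if "regimen_weights" in sim:
                sim["regimen_weights"] = {
                    int(k): dict(v) for k, v in sim["regimen_weights"].items()}
            if "comparator_pools" in sim:
                sim["comparator_pools"] = {
                    db: {int(y): c for y, c in pool.items()}
                    for db, pool in sim["comparator_pools"].items()}
            for key in ("line_gap_months", "post_lag_days", "forums",
                        "forum_weights"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            data["sim"] = SimulationConfig(**sim)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stage_seed(seed: int, stage: str) -> int:
    return int(stage_rng(seed, stage).integers(2**31))


# --------------------------------------------------------------------------
# in-memory core

def classify_sentences(sentences: pd.DataFrame, labels: pd.DataFrame,
                       classifier: str = "auto", seed: int = 0):
    """Train on the labeled subset; return verdicts for every sentence.

    Returns ``(verdicts, metrics, model_name)`` where verdicts maps
    (user_id, post_id, sentence_index) -> receipt/non_receipt. With
    ``classifier='none'`` — or when the labels contain a single class, as in
    a noise-free corpus — the classifier gate is disabled and every sentence
    is treated as receipt.
    """
    keys = ["user_id", "post_id", "sentence_index"]
    all_keys = [tuple(t) for t in sentences[keys].itertuples(index=False)]
    labeled = sentences.merge(labels, on=keys, how="inner")
    n_classes = labeled["label"].nunique()
    if classifier == "none" or n_classes < 2:
        if classifier != "none":
            log.info("single-class labels: classifier gate disabled")
        return {k: clf.RECEIPT for k in all_keys}, None, None

    if classifier == "auto":
        metrics, model_name = clf.compare_models(labeled, seed=seed)
    else:
        metrics, _ = clf.compare_models(labeled, seed=seed,
                                        models=(classifier,))
        model_name = classifier
    final = clf.train(clf.balance_classes(labeled, seed=seed), model_name,
                      seed=seed)
    predictions = final.predict(sentences["text"])
    verdicts = dict(zip(all_keys, predictions))
    return verdicts, metrics, model_name


def analyze_posts(posts, labels, lexicon=None, classifier="auto",
                  combo_window_days=DEFAULT_COMBO_WINDOW_DAYS, seed=0) -> dict:
    """Posts + sentence labels -> lines of therapy (full in-memory pipeline)."""
    lexicon = lexicon or default_lexicon()
    sentences = filter_treatment_users(build_sentence_table(posts), lexicon)
    verdicts, metrics, model_name = classify_sentences(
        sentences, labels, classifier, seed=_stage_seed(seed, "classify"))
    mentions = [
        m for row in sentences.itertuples()
        for m in find_mentions(row, lexicon)
    ]
    resolved = resolved_to_frame(resolve_mentions(mentions, sentences, verdicts))
    sm_lines = lines_table(resolved, combo_window_days)
    return {
        "sentences": sentences,
        "verdicts": verdicts,
        "classifier_metrics": metrics,
        "model_name": model_name,
        "resolved": resolved,
        "sm_lines": sm_lines,
    }


def run_end_to_end(config: PipelineConfig) -> dict:
    """Simulate, analyze, match, and compare — all in memory."""
    if config.sim is None:
        raise PipelineError("run_end_to_end requires a simulation config")
    lexicon = config.lexicon()
    journeys = generate_truth(config.sim)
    posts, labels = render_posts(journeys, config.sim, lexicon)
    comparators = render_comparators(config.sim)
    result = analyze_posts(posts, labels, lexicon, config.classifier,
                           config.combo_window_days, seed=config.seed)
    sm_lines = result["sm_lines"]

    sm_first = sm_lines[sm_lines["line_number"] == 1]
    sm_years = sm_first["start_date"].map(lambda d: d.year).value_counts().to_dict()
    matched = {}
    for db in sorted(set(comparators["database"])):
        matched[db] = frequency_match(
            sm_years, comparators, ratio=config.match_ratio,
            seed=_stage_seed(config.seed, f"match:{db}"), database=db)
    db_lines = {db: m.patients for db, m in matched.items()}

    rows = []
    for line_number in (1, 2, 3):
        try:
            rows.extend(compare_sources(sm_lines, db_lines, line_number,
                                        top_k=config.top_k, sm_name=SM_NAME))
        except ValueError:  # no patients at this line in some source
            log.warning("skipping line %d comparison", line_number)
    return {
        "journeys": journeys,
        "truth_lines": truth_lines_table(journeys),
        "posts": posts,
        "labels": labels,
        "comparators": comparators,
        **result,
        "matched": matched,
        "comparison_rows": rows,
        "concordance": concordance_report(rows),
        "line_counts": line_counts(sm_lines),
    }


# --------------------------------------------------------------------------
# file-based stages

_ARTIFACTS = {
    "posts.jsonl": "simulate",
    "labels.csv": "simulate",
    "truth_lines.csv": "simulate",
    "comparators.csv": "simulate",
    "sentences.csv": "preprocess",
    "verdicts.csv": "classify",
    "resolved_mentions.csv": "extract",
    "sm_lines.csv": "lines",
    "matched_comparators.csv": "match",
    "match_summary.json": "match",
}

_DATE_COLS = {"post_date", "event_date", "start_date"}


def _read_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    for col in _DATE_COLS & set(df.columns):
        df[col] = df[col].map(date.fromisoformat)
    return df


def _require(config: PipelineConfig, *names: str) -> list[Path]:
    paths = []
    for name in names:
        path = config.outdir / name
        if not path.exists():
            raise PipelineError(
                f"missing {name}: run the '{_ARTIFACTS[name]}' stage first")
        paths.append(path)
    return paths


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(config: PipelineConfig, stage: str,
                    inputs: list[Path], outputs: list[Path]) -> dict:
    from . import __version__

    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
        "version": __version__,
    }
    mdir = config.outdir / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    with open(mdir / f"{stage}.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_simulate(config: PipelineConfig):
    if config.sim is None:
        raise PipelineError("simulate stage needs a simulation config")
    journeys = generate_truth(config.sim)
    posts, labels = render_posts(journeys, config.sim, config.lexicon())
    out = config.outdir
    write_posts_jsonl(posts, out / "posts.jsonl")
    write_labels_csv(labels, out / "labels.csv")
    write_truth_csv(journeys, out / "truth_lines.csv")
    write_comparators_csv(render_comparators(config.sim), out / "comparators.csv")
    return [], [out / n for n in
               ("posts.jsonl", "labels.csv", "truth_lines.csv", "comparators.csv")]


def _stage_preprocess(config: PipelineConfig):
    (posts_path,) = _require(config, "posts.jsonl")
    posts = read_posts_jsonl(posts_path)
    sentences = filter_treatment_users(build_sentence_table(posts),
                                       config.lexicon())
    out = config.outdir / "sentences.csv"
    sentences.to_csv(out, index=False)
    return [posts_path], [out]


def _stage_classify(config: PipelineConfig):
    sent_path, labels_path = _require(config, "sentences.csv", "labels.csv")
    sentences = _read_csv(sent_path)
    labels = _read_csv(labels_path)
    verdicts, metrics, model_name = classify_sentences(
        sentences, labels, config.classifier,
        seed=_stage_seed(config.seed, "classify"))
    vdf = pd.DataFrame(
        [(u, p, i, v) for (u, p, i), v in sorted(verdicts.items())],
        columns=["user_id", "post_id", "sentence_index", "verdict"])
    out = config.outdir / "verdicts.csv"
    vdf.to_csv(out, index=False)
    metrics_out = config.outdir / "classifier_metrics.json"
    with open(metrics_out, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "selected_model": model_name,
                "metrics": {
                    name: {"precision": m.precision, "recall": m.recall}
                    for name, m in (metrics or {}).items()
                },
            },
            fh, indent=2, sort_keys=True)
    return [sent_path, labels_path], [out, metrics_out]


def _stage_extract(config: PipelineConfig):
    sent_path, verd_path = _require(config, "sentences.csv", "verdicts.csv")
    sentences = _read_csv(sent_path)
    vdf = _read_csv(verd_path)
    verdicts = {
        (r.user_id, r.post_id, int(r.sentence_index)): r.verdict
        for r in vdf.itertuples()
    }
    lexicon = config.lexicon()
    mentions = [m for row in sentences.itertuples()
                for m in find_mentions(row, lexicon)]
    resolved = resolved_to_frame(resolve_mentions(mentions, sentences, verdicts))
    out = config.outdir / "resolved_mentions.csv"
    resolved.to_csv(out, index=False)
    return [sent_path, verd_path], [out]


def _stage_lines(config: PipelineConfig):
    (resolved_path,) = _require(config, "resolved_mentions.csv")
    resolved = _read_csv(resolved_path)
    sm_lines = lines_table(resolved, config.combo_window_days)
    out = config.outdir / "sm_lines.csv"
    sm_lines.to_csv(out, index=False)
    counts_out = config.outdir / "line_counts.csv"
    line_counts(sm_lines).to_csv(counts_out, index=False)
    return [resolved_path], [out, counts_out]


def _stage_match(config: PipelineConfig):
    lines_path, comp_path = _require(config, "sm_lines.csv", "comparators.csv")
    sm_lines = _read_csv(lines_path)
    comparators = _read_csv(comp_path)
    sm_first = sm_lines[sm_lines["line_number"] == 1]
    sm_years = sm_first["start_date"].map(lambda d: d.year).value_counts().to_dict()
    frames, summary = [], {}
    for db in sorted(set(comparators["database"])):
        cohort = frequency_match(
            sm_years, comparators, ratio=config.match_ratio,
            seed=_stage_seed(config.seed, f"match:{db}"), database=db)
        frames.append(cohort.patients)
        summary[db] = {
            "matched_counts": {str(y): c for y, c in
                               sorted(cohort.matched_counts.items())},
            "total_matched": cohort.total_matched,
            "n_dropped_sm": len(cohort.dropped_sm),
        }
    out = config.outdir / "matched_comparators.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    summary_out = config.outdir / "match_summary.json"
    with open(summary_out, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return [lines_path, comp_path], [out, summary_out]


def _stage_compare(config: PipelineConfig):
    lines_path, matched_path = _require(config, "sm_lines.csv",
                                        "matched_comparators.csv")
    sm_lines = _read_csv(lines_path)
    matched = _read_csv(matched_path)
    db_lines = {db: g for db, g in matched.groupby("database")}
    rows = []
    for line_number in (1, 2, 3):
        try:
            rows.extend(compare_sources(sm_lines, db_lines, line_number,
                                        top_k=config.top_k, sm_name=SM_NAME))
        except ValueError:
            log.warning("skipping line %d comparison", line_number)
    report = concordance_report(rows)
    out = config.outdir / "concordance.json"
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    grid = pd.json_normalize(report["rows"]) if report["rows"] else pd.DataFrame()
    grid_out = config.outdir / "comparison_rows.csv"
    grid.to_csv(grid_out, index=False)
    return [lines_path, matched_path], [out, grid_out]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "classify": _stage_classify,
    "extract": _stage_extract,
    "lines": _stage_lines,
    "match": _stage_match,
    "compare": _stage_compare,
}


def run_stage(stage: str, config: PipelineConfig) -> dict:
    """Run one named stage; returns its manifest."""
    if stage not in _STAGE_FUNCS:
        raise PipelineError(f"unknown stage {stage!r}; stages: {STAGES}")
    config.outdir.mkdir(parents=True, exist_ok=True)
    log.info("stage %s: starting", stage)
    inputs, outputs = _STAGE_FUNCS[stage](config)
    manifest = _write_manifest(config, stage, inputs, outputs)
    log.info("stage %s: wrote %s", stage, ", ".join(p.name for p in outputs))
    return manifest


def run_all(config: PipelineConfig) -> list[dict]:
    return [run_stage(stage, config) for stage in STAGES]
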