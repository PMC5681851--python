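"""End-to-end orchestration: inputs -> annotations -> statistics -> report.

One run loads a taxonomy, a robotic seed list and a corpus, annotates the
content paragraphs (or ingests an external annotation TSV — both routes
share the same downstream analysis), and writes every statistics table
plus a machine-readable run report.  Outputs are deterministic: running
twice on identical inputs produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .corpus import load_corpus
from .coverage_analysis import (
    coverage_threshold_table,
    keyword_overlap,
    method_frequency_table,
    profile_corpus,
    summarize_corpus,
    unique_method_distribution,
)
from .lexicon_annotator import (
    annotate_corpus,
    build_lexicon,
    ingest_external_annotations,
    write_annotations_tsv,
)
from .method_classification import (
    MethodClass,
    expand_robotic_set,
    load_seed_ids,
    write_mapping_csv,
)
from .taxonomy import load_taxonomy

__all__ = ["PipelineConfig", "PipelineError", "RunReport", "run_pipeline"]


class PipelineError(RuntimeError):
    """An upstream failure, tagged with the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")


@dataclass
class PipelineConfig:
    taxonomy_path: Path
    seeds_path: Path
    corpus_path: Path
    out_dir: Path
    external_annotations_path: Path | None = None
    restrict_lexicon_to_methods: bool = False
    top_k: int = 10

    def __post_init__(self) -> None:
        self.taxonomy_path = Path(self.taxonomy_path)
        self.seeds_path = Path(self.seeds_path)
        self.corpus_path = Path(self.corpus_path)
        self.out_dir = Path(self.out_dir)
        if self.external_annotations_path is not None:
            self.external_annotations_path = Path(self.external_annotations_path)


@dataclass
class RunReport:
    """Provenance and results of one pipeline run (serialized as JSON)."""

    inputs: dict[str, dict] = field(default_factory=dict)
    taxonomy_size: int = 0
    lexicon_size: int = 0
    n_seeds: int = 0
    n_robotic_ids: int = 0
    n_method_ids: int = 0
    corpus_stats: dict = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(
            {
                "inputs": self.inputs,
                "taxonomy_size": self.taxonomy_size,
                "lexicon_size": self.lexicon_size,
                "mapping_sizes": {
                    "n_seeds": self.n_seeds,
                    "n_robotic_ids": self.n_robotic_ids,
                    "n_method_ids": self.n_method_ids,
                },
                "corpus_stats": self.corpus_stats,
                # names only: keeps the report byte-identical across run dirs
                "outputs": sorted(self.outputs),
                "warnings": self.warnings,
                "version": self.version,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _input_stamp(path: Path) -> dict:
    return {"path": str(path), "sha256": _sha256(path) if path.is_file() else "dir"}


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # surface the failing stage
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write all artifacts under ``config.out_dir``.

    Emits: ``annotations.tsv``, ``mapping.csv``, ``corpus_stats.json``,
    ``robotic_frequency.csv``, ``nonrobotic_frequency.csv``,
    ``coverage_thresholds.csv``, ``robotic_histogram.json``,
    ``nonrobotic_histogram.json``, ``keyword_overlap.json`` and
    ``run_report.json``.
    """
    report = RunReport()

    tax = _stage("load_taxonomy")(load_taxonomy)(config.taxonomy_path)
    seeds = _stage("load_seeds")(load_seed_ids)(config.seeds_path)
    documents = _stage("load_corpus")(load_corpus)(config.corpus_path)
    mapping = _stage("expand_robotic_set")(expand_robotic_set)(tax, seeds)
    report.warnings.extend(mapping.warnings)

    lexicon = _stage("build_lexicon")(build_lexicon)(
        tax, restrict_to_method_subtree=config.restrict_lexicon_to_methods
    )

    if config.external_annotations_path is not None:
        external = _stage("ingest_external_annotations")(ingest_external_annotations)(
            config.external_annotations_path, tax
        )
        mentions = external.mentions
        if external.n_warnings:
            report.warnings.append(
                f"{external.n_warnings} external concept ids unknown to the taxonomy"
            )
    else:
        mentions = _stage("annotate")(annotate_corpus)(lexicon, documents)

    profiles = _stage("profile")(profile_corpus)(documents, mentions, mapping)
    stats = _stage("summarize")(summarize_corpus)(profiles, len(documents))

    config.out_dir.mkdir(parents=True, exist_ok=True)
    out = config.out_dir
    labels = {cid: c.preferred_label for cid, c in tax.concepts.items()}

    def emit(name: str, write) -> None:
        path = out / name
        write(path)
        report.outputs[name] = str(path)

    emit("annotations.tsv", lambda p: write_annotations_tsv(mentions, p))
    emit("mapping.csv", lambda p: write_mapping_csv(mapping, tax, p))
    emit(
        "corpus_stats.json",
        lambda p: p.write_text(json.dumps(stats.to_dict(), indent=2, sort_keys=True), encoding="utf-8"),
    )
    emit(
        "robotic_frequency.csv",
        lambda p: method_frequency_table(profiles, mapping, labels, MethodClass.ROBOTIC, config.top_k).to_csv(p, index=False),
    )
    emit(
        "nonrobotic_frequency.csv",
        lambda p: method_frequency_table(profiles, mapping, labels, MethodClass.NON_ROBOTIC, config.top_k).to_csv(p, index=False),
    )
    emit(
        "coverage_thresholds.csv",
        lambda p: coverage_threshold_table(profiles).to_csv(p, index=False),
    )
    for name, cls in (("robotic_histogram.json", MethodClass.ROBOTIC), ("nonrobotic_histogram.json", MethodClass.NON_ROBOTIC)):
        hist = unique_method_distribution(profiles, cls)
        emit(
            name,
            lambda p, h=hist: p.write_text(
                json.dumps({str(k): v for k, v in h.items()}, indent=2, sort_keys=True),
                encoding="utf-8",
            ),
        )
    overlap = keyword_overlap(profiles, documents)
    emit(
        "keyword_overlap.json",
        lambda p: p.write_text(json.dumps(overlap.to_dict(), indent=2, sort_keys=True), encoding="utf-8"),
    )

    report.inputs = {
        "taxonomy": _input_stamp(config.taxonomy_path),
        "seeds": _input_stamp(config.seeds_path),
        "corpus": _input_stamp(config.corpus_path),
    }
    if config.external_annotations_path is not None:
        report.inputs["external_annotations"] = _input_stamp(config.external_annotations_path)
    report.taxonomy_size = len(tax)
    report.lexicon_size = len(lexicon)
    report.n_seeds = len(mapping.seed_ids)
    report.n_robotic_ids = len(mapping.robotic_ids)
    report.n_method_ids = len(mapping.method_ids)
    report.corpus_stats = stats.to_dict()

    (out / "run_report.json").write_text(report.to_json(), encoding="utf-8")
    report.outputs["run_report.json"] = str(out / "run_report.json")
    return report
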