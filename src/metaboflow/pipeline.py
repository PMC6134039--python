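"""End-to-end orchestration: simulate or ingest tables, normalize, run the
differential / flow / multivariate / growth stages, and emit machine-readable
summaries.

Every run writes: the (possibly simulated) input tables, per-compartment
differential TSVs, the flow assignment TSV, ``venn.json``, PCA scores and
Newick trees per compartment, an optional growth summary, and
``summary.json`` holding every count the downstream bookkeeping needs plus
the parameters of each stage (runs are self-describing). Runs are
deterministic for a fixed config and seed. A failing stage aborts the run
with the stage name and removes the partially written output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import differential, flow as flow_mod, growth as growth_mod, multivariate
from .core import StudyBundle, TableError
from .differential import Thresholds, classify_table, differential_table
from .flow import ConcordanceRule, category_counts, flow_table, group_counts, venn_counts
from .synthetic import (
    PlantedTruth,
    SyntheticStudyConfig,
    default_paper_config,
    generate,
    generate_growth_series,
)

log = logging.getLogger("metaboflow")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: ``simulate`` (requires a seed) draws a synthetic
    study; ``ingest`` reads abundance tables from ``input_dir``.
    """

    input_mode: str = "simulate"  # simulate | ingest
    input_dir: str | None = None
    out_dir: str = "metaboflow_run"
    seed: int | None = 42
    study: SyntheticStudyConfig | None = None
    thresholds: Thresholds | None = None  # None -> derive from data
    concordance_factor: float = 1.3
    fdr: bool = False
    distance: str = "euclidean"
    linkage: str = "ward"
    nd_policy: str = "half_min"
    pca_components: int = 2
    growth_series: str | None = None  # TSV path; "simulate" to synthesize
    ration_rate: float = 0.03

    def validate(self) -> None:
        if self.input_mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.input_mode == "simulate" and self.seed is None:
            raise ValueError("simulate mode requires a seed")
        if self.input_mode == "ingest" and not self.input_dir:
            raise ValueError("ingest mode requires input_dir")


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler)
               and h.stream is sys.stderr for h in log.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(stream)
    return handler


def summarize(
    flow: pd.DataFrame,
    diffs: dict[str, pd.DataFrame],
    venn: dict,
) -> dict:
    """Machine-readable count summary, recomputable from the emitted tables.

    Per-compartment class counts, Venn counts with serum-panel percentages
    at 1 decimal, pellet group sizes a-e, transport category sizes i-iii.
    """
    summary: dict = {"classes": {}, "venn": venn}
    for compartment, diff in diffs.items():
        summary["classes"][compartment] = differential.class_counts(diff)
    summary["pellet_groups"] = group_counts(flow)
    summary["transport_categories"] = category_counts(flow)
    return summary


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dict."""
    config.validate()
    out_dir = Path(config.out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out_dir)
    stage = "setup"
    try:
        truth = None
        stage = "input"
        if config.input_mode == "simulate":
            study = config.study or default_paper_config(seed=config.seed)
            if config.seed is not None and study.seed != config.seed:
                study = dataclasses.replace(study, seed=config.seed)
            log.info("simulate: seed=%d", study.seed)
            bundle, truth = generate(study)
            bundle.write(out_dir / "tables")
            truth.write(out_dir / "tables" / "truth.tsv")
        else:
            log.info("ingest: %s", config.input_dir)
            bundle = StudyBundle.read(config.input_dir)

        stage = "normalize"
        normalized = bundle.normalized()

        stage = "differential"
        diffs: dict[str, pd.DataFrame] = {}
        thresholds_used: dict[str, Thresholds] = {}
        for compartment in ("intestine", "serum"):
            if not any(c == compartment for c, _ in normalized.tables):
                continue
            diff = differential_table(normalized, compartment)
            diff, thr = classify_table(diff, config.thresholds, fdr=config.fdr)
            diffs[compartment] = diff
            thresholds_used[compartment] = thr
            diff.to_csv(out_dir / f"diff_{compartment}.tsv", sep="\t",
                        index_label="id")
            log.info(
                "differential %s: thresholds upper=%.4g lower=%.4g",
                compartment, thr.upper, thr.lower,
            )
        if "intestine" not in diffs or "serum" not in diffs:
            raise TableError("pipeline requires intestine and serum tables")

        stage = "pellet_shift"
        pellet_shift_p = None
        if any(c == "pellet" for c, _ in normalized.tables):
            frame = normalized.compartment_frame("pellet")
            pro = frame[[c for c in frame.columns[2:] if "_probiotic_" in c]]
            con = frame[[c for c in frame.columns[2:] if "_control_" in c]]
            pellet_shift_p = differential.distribution_shift_test(
                con.mean(axis=1).dropna(), pro.mean(axis=1).dropna(),
                alternative="two_sided",
            )
            log.info("pellet distribution-shift p=%.4g", pellet_shift_p)

        stage = "flow"
        rule = ConcordanceRule(config.concordance_factor)
        flow = flow_table(diffs["intestine"], diffs["serum"],
                          normalized.members("pellet"), rule)
        flow.to_csv(out_dir / "flow.tsv", sep="\t", index_label="id")
        venn = venn_counts(
            {c: normalized.members(c) for c in normalized.compartments()}
        )
        (out_dir / "venn.json").write_text(json.dumps(venn, indent=2))

        stage = "multivariate"
        for compartment in ("intestine", "serum"):
            matrix = multivariate.build_sample_matrix(
                normalized, compartment, config.nd_policy
            )
            scores, explained = multivariate.pca_scores(
                matrix, config.pca_components
            )
            scores["explained"] = list(explained) + [float("nan")] * (
                len(scores) - len(explained)
            )
            scores.to_csv(out_dir / f"pca_{compartment}.tsv", sep="\t",
                          index_label="sample")
            z, labels = multivariate.hca_tree(
                matrix, config.distance, config.linkage
            )
            (out_dir / f"tree_{compartment}.nwk").write_text(
                multivariate.to_newick(z, labels) + "\n"
            )

        stage = "growth"
        growth_summary = None
        if config.growth_series == "simulate":
            series = generate_growth_series(seed=config.seed or 0)
        elif config.growth_series:
            series = pd.read_csv(config.growth_series, sep="\t")
        else:
            series = None
        if series is not None:
            growth = growth_mod.group_summary(series, rate=config.ration_rate)
            growth.to_csv(out_dir / "growth_summary.tsv", sep="\t")
            growth_summary = growth.to_dict(orient="index")

        stage = "summarize"
        summary = summarize(flow, diffs, venn)
        summary["parameters"] = {
            "input_mode": config.input_mode,
            "seed": config.seed,
            "concordance_factor": config.concordance_factor,
            "fdr": config.fdr,
            "distance": config.distance,
            "linkage": config.linkage,
            "nd_policy": config.nd_policy,
            "ration_rate": config.ration_rate,
            "thresholds": {
                c: dataclasses.asdict(t) for c, t in thresholds_used.items()
            },
        }
        if pellet_shift_p is not None:
            summary["pellet_shift_p"] = pellet_shift_p
        if growth_summary is not None:
            summary["growth"] = growth_summary
        if truth is not None:
            summary["truth_counts"] = {
                "classes": {
                    c: truth.class_counts(c) for c in ("intestine", "serum")
                },
                "pellet_groups": truth.group_counts(),
                "transport_categories": truth.category_counts(),
            }
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        log.info("run complete: %s", out_dir / "summary.json")
        return summary
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        handler.close()
        log.removeHandler(handler)
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        else:
            for item in out_dir.iterdir():
                if item.is_dir():
                    shutil.rmtree(item, ignore_errors=True)
                else:
                    item.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    finally:
        if handler in log.handlers:
            handler.close()
            log.removeHandler(handler)
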