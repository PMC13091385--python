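"""End-to-end orchestration of the screening stages.

The SSP funnel runs: vascular-plant exclusion (label-based) -> exhaustive
motif screen with coverage/similarity filters -> secretion-evidence
annotation (tiers, never removal) -> profile rescoring against the
family's log-odds profile with a shuffle null -> annotation-blacklist
removal -> presence/absence matrix.  Every stage logs and reports input
and surviving counts so the funnel is auditable.

All randomness derives from the one root seed in RunConfig: stage k uses
``numpy.random.default_rng([rng_seed, k])``, so stages are independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ProteinRecord, RunConfig, log, log_stage, write_tsv
from .presence import PresenceMatrix, build_presence_matrix
from .receptors import ArchitectureCall, calls_to_frame, screen_rlk_collection
from .screen import (MotifQuery, ScreenHit, annotation_blacklist_filter,
                     competitive_family_assignment, hits_to_frame,
                     profile_rescore, screen_collection)
from .secretion import assess_hits
from .traceability import GroupedAlignment, table_to_frame, traceability_table

#: stage indices for seed derivation (documented, stable)
_STAGE_SEEDS = {"profile_rescore": 2, "traceability": 3, "tree": 4}


@dataclass
class PipelineReport:
    seed: int
    thresholds: dict
    stages: list[dict] = field(default_factory=list)
    survival: pd.DataFrame | None = None

    def add_stage(self, name: str, n_in: int, n_out: int, **extra) -> None:
        if self.stages and n_in > self.stages[-1]["n_out"] and name != "screen":
            log.warning("stage %s has more input than previous output", name)
        self.stages.append({"stage": name, "n_in": n_in, "n_out": n_out, **extra})

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "thresholds": self.thresholds,
            "stages": self.stages,
        }
        if self.survival is not None:
            payload["survival"] = self.survival.to_dict(orient="records")
        Path(path).write_text(json.dumps(payload, indent=2))


def stage_rng(config: RunConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, _STAGE_SEEDS.get(stage, 99)])


def run_ssp_pipeline(
    queries: Sequence[MotifQuery],
    collections: Mapping[str, Sequence[ProteinRecord]],
    config: RunConfig,
    annotations: Mapping[str, str] | None = None,
) -> tuple[list[ScreenHit], PresenceMatrix, PipelineReport]:
    """Run the full SSP identification funnel over per-lineage collections.

    Returns all hits (kept and dropped, for the audit trail), the presence
    matrix over kept hits, and the stage report.
    """
    if not queries:
        raise ValueError("no reference motif queries supplied")
    annotations = annotations or {}
    report = PipelineReport(
        seed=config.rng_seed,
        thresholds={
            "coverage_min": config.coverage_min,
            "similarity_min": config.similarity_min,
            "profile_p_max": config.profile_p_max,
            "cterm_min": config.cterm_min,
        },
    )
    proteins: list[ProteinRecord] = []
    n_all = 0
    for lineage, records in collections.items():
        n_all += len(records)
        if lineage in config.vascular_labels:
            log.info("excluding vascular-plant lineage %s (%d sequences)", lineage, len(records))
            continue
        proteins.extend(records)
    report.add_stage("vascular_exclusion", n_all, len(proteins),
                     excluded=list(config.vascular_labels))

    hits = screen_collection(queries, proteins, config)
    report.add_stage("screen", len(proteins), len(hits))

    by_id = {p.id: p for p in proteins}
    assess_hits(hits, by_id, config)
    report.add_stage("secretion_annotation", len(hits), len(hits))

    null_len = int(np.median([len(p.seq) for p in proteins])) if proteins else 150
    hits = profile_rescore(
        hits, queries, config, stage_rng(config, "profile_rescore"),
        n_database=len(proteins), null_subject_len=null_len,
        subjects={p.id: p.seq for p in proteins},
    )
    n_kept = sum(h.kept for h in hits)
    report.add_stage("profile_rescore", len(hits), n_kept)

    hits = competitive_family_assignment(hits)
    n_comp = sum(h.kept for h in hits)
    report.add_stage("family_competition", n_kept, n_comp)

    hits = annotation_blacklist_filter(hits, annotations, config.blacklist)
    n_final = sum(h.kept for h in hits)
    report.add_stage("annotation_blacklist", n_comp, n_final)

    lineages = [l for l in collections if l not in config.vascular_labels]
    families = sorted({q.family for q in queries})
    matrix = build_presence_matrix([h for h in hits if h.kept], lineages, families)
    report.survival = _survival_table(hits)
    return hits, matrix, report


def _survival_table(hits: Sequence[ScreenHit]) -> pd.DataFrame:
    rows = {}
    for h in hits:
        key = (h.family, h.lineage)
        d = rows.setdefault(key, {"family": h.family, "lineage": h.lineage,
                                  "screened": 0, "kept": 0})
        d["screened"] += 1
        d["kept"] += int(h.kept)
    return pd.DataFrame(list(rows.values()))


def run_rlk_pipeline(
    kinase_refs: Sequence[ProteinRecord],
    lrr_refs: Sequence[ProteinRecord],
    collections: Mapping[str, Sequence[ProteinRecord]],
    config: RunConfig,
) -> tuple[list[ArchitectureCall], PipelineReport]:
    """Receptor funnel: dual domain search, intersection, architecture
    validation, with vascular-plant exclusion and stage reporting."""
    report = PipelineReport(seed=config.rng_seed,
                            thresholds={"rlk_evalue_max": config.rlk_evalue_max})
    proteins: list[ProteinRecord] = []
    n_all = 0
    for lineage, records in collections.items():
        n_all += len(records)
        if lineage in config.vascular_labels:
            continue
        proteins.extend(records)
    report.add_stage("vascular_exclusion", n_all, len(proteins))
    calls = screen_rlk_collection(kinase_refs, lrr_refs, proteins, config)
    n_valid = sum(c.verdict for c in calls)
    report.add_stage("architecture_validation", len(calls), n_valid)
    return calls, report


def run_traceability(
    grouped: Mapping[str, GroupedAlignment | None],
    config: RunConfig,
    reps: int = 1000,
) -> dict[str, tuple[list, dict]]:
    """Per-family traceability tables.

    Families whose alignment has no protistan rows (``None`` entries, or
    blocks that could not be grouped) are skipped with a log line — the
    vascular-plant-specific families have nothing to trace.
    """
    rng = stage_rng(config, "traceability")
    out = {}
    for family, galn in grouped.items():
        if galn is None:
            log.info("traceability: family %s skipped (no protistan homologs)", family)
            continue
        rows, summary = traceability_table(galn, reps=reps, rng=rng)
        out[family] = (rows, summary)
    return out


def write_ssp_outputs(hits, matrix: PresenceMatrix, report: PipelineReport,
                      out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(hits_to_frame(hits), out / "hits.tsv")
    matrix.cells.to_csv(out / "presence.tsv", sep="\t")
    matrix.counts.to_csv(out / "presence_counts.tsv", sep="\t")
    report.to_json(out / "report.json")


def write_rlk_outputs(calls, report: PipelineReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(calls_to_frame(calls), out / "architecture_calls.tsv")
    report.to_json(out / "rlk_report.json")


def write_traceability_outputs(results: Mapping[str, tuple[list, dict]],
                               out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for family, (rows, summary) in results.items():
        safe = family.replace("/", "-")
        write_tsv(table_to_frame(rows), out / f"traceability_{safe}.tsv")
        summaries[family] = summary
    (out / "traceability_summary.json").write_text(json.dumps(summaries, indent=2, default=str))
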