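"""Scoring against planted truth, annotation joins, and the pipeline driver."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .errors import AnnotationError, ConfigError, EvaluationError
from .evidence_io import (
    EvidenceTable,
    StudyDesign,
    load_design,
    read_evidence_table,
    write_classification,
    write_evidence_table,
)
from .trap_classify import (
    Category,
    ClassificationRecord,
    ExclusionList,
    category_counts,
    classify,
    final_lists,
)
from .trap_filters import FilterParams, aggregate, apply_score_filter
from .synthetic_data import (
    EXPECTED_CATEGORY,
    DEFAULT_EXCLUSIONS,
    PlantedRole,
    SimParams,
    TruthTable,
    build_paper_fixture,
    simulate,
)

__all__ = [
    "EvaluationReport",
    "AnnotationTable",
    "read_annotations",
    "evaluate",
    "annotate",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("clptrap")


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion of planted roles against assigned categories.

    Precision and recall are None (absent) when their denominator is zero,
    never 0/0.  For the SUBSTRATE role a correct assignment additionally
    requires the substrate flag (trap-specific minus the exclusion list).
    """

    confusion: Dict[str, Dict[str, int]]
    precision: Dict[str, Optional[float]]
    recall: Dict[str, Optional[float]]
    n_proteins: int

    def perfect(self) -> bool:
        vals = list(self.precision.values()) + list(self.recall.values())
        return all(v == 1.0 for v in vals if v is not None)

    def to_dict(self) -> dict:
        return {
            "n_proteins": self.n_proteins,
            "confusion": self.confusion,
            "precision": self.precision,
            "recall": self.recall,
        }


def _assigned_as(record: ClassificationRecord, role: PlantedRole) -> bool:
    if role is PlantedRole.SUBSTRATE:
        return record.substrate
    return record.category is EXPECTED_CATEGORY[role]


def evaluate(
    results: Sequence[ClassificationRecord], truth: TruthTable
) -> EvaluationReport:
    """Score classification output against planted roles."""
    if len(truth) == 0:
        raise EvaluationError("empty truth table")
    by_id = {r.protein_id: r for r in results}
    missing = sorted(set(truth.roles) - set(by_id))
    if missing:
        raise EvaluationError(
            f"truth proteins missing from results: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )

    confusion: Dict[str, Dict[str, int]] = {
        role.value: {c.value: 0 for c in Category} for role in PlantedRole
    }
    for pid, role in truth.items():
        confusion[role.value][by_id[pid].category.value] += 1

    precision: Dict[str, Optional[float]] = {}
    recall: Dict[str, Optional[float]] = {}
    for role in PlantedRole:
        planted = [p for p, r in truth.items() if r is role]
        assigned = [r for r in results
                    if r.protein_id in truth.roles and _assigned_as(r, role)]
        correct = sum(1 for r in assigned if truth[r.protein_id] is role)
        precision[role.value] = correct / len(assigned) if assigned else None
        recall[role.value] = correct / len(planted) if planted else None

    return EvaluationReport(
        confusion=confusion,
        precision=precision,
        recall=recall,
        n_proteins=len(truth),
    )


@dataclass(frozen=True)
class AnnotationTable:
    """protein accession -> (homologue accession, gene, name, tags)."""

    entries: Dict[str, Tuple[str, str, str, str]]

    def get(self, protein_id: str) -> Tuple[str, str, str, str]:
        return self.entries.get(protein_id, ("", "", "", ""))


def read_annotations(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = ["protein_id", "homolog_accession", "gene_symbol"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    dupes = df.protein_id[df.protein_id.duplicated()].tolist()
    if dupes:
        raise AnnotationError(f"{path}: duplicate protein_id {dupes[:5]}")
    entries = {}
    for row in df.itertuples(index=False):
        entries[str(row.protein_id)] = (
            str(row.homolog_accession),
            str(row.gene_symbol),
            str(getattr(row, "protein_name", "")),
            str(getattr(row, "tags", "")),
        )
    return AnnotationTable(entries)


def annotate(
    results: Sequence[ClassificationRecord],
    annotations: AnnotationTable | Mapping[str, Tuple[str, str, str, str]],
) -> pd.DataFrame:
    """Left-join annotations onto classification rows (row count unchanged)."""
    if isinstance(annotations, Mapping):
        seen = list(annotations)
        if len(seen) != len(set(seen)):
            raise AnnotationError("duplicate protein_id in annotations")
        annotations = AnnotationTable(dict(annotations))
    rows = []
    for r in results:
        homolog, gene, name, tags = annotations.get(r.protein_id)
        rows.append({
            "protein_id": r.protein_id,
            "category": r.category.value,
            "substrate": r.substrate,
            "trap_enriched": r.trap_enriched,
            "trap_exclusive": r.trap_exclusive,
            "homolog_accession": homolog,
            "gene_symbol": gene,
            "protein_name": name,
            "tags": tags,
        })
    return pd.DataFrame(
        rows,
        columns=["protein_id", "category", "substrate", "trap_enriched",
                 "trap_exclusive", "homolog_accession", "gene_symbol",
                 "protein_name", "tags"],
    )


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration.

    Exactly one input source must be given: an evidence/design file pair, a
    simulation parameter block, or the deterministic table fixture.
    """

    evidence_path: Optional[str] = None
    design_path: Optional[str] = None
    sim_params: Optional[SimParams] = None
    fixture: Optional[Tuple[int, int]] = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    exclusions: ExclusionList = field(
        default_factory=lambda: ExclusionList(DEFAULT_EXCLUSIONS)
    )
    annotations: Optional[AnnotationTable] = None
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        fp = FilterParams(**doc.get("filters", {}))
        sim = SimParams(**doc["simulate"]) if "simulate" in doc else None
        fixture = None
        if "fixture" in doc:
            fx = doc["fixture"] or {}
            fixture = (int(fx.get("contaminants", 10)), int(fx.get("sporadic", 5)))
        exclusions = ExclusionList(frozenset(doc.get("exclude", DEFAULT_EXCLUSIONS)))
        return cls(
            evidence_path=doc.get("evidence"),
            design_path=doc.get("design"),
            sim_params=sim,
            fixture=fixture,
            filter_params=fp,
            exclusions=exclusions,
            out_dir=doc.get("out_dir", "results"),
        )


def run_pipeline(config: RunConfig) -> dict:
    """Read/generate -> score filter -> aggregate -> classify -> write.

    Emits classification.tsv, summary.json and (for generated inputs)
    truth.tsv plus evaluation.json under ``config.out_dir``.  Returns the
    summary dict.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth: Optional[TruthTable] = None
    try:
        if config.evidence_path is not None:
            if config.design_path is None:
                raise ConfigError("evidence input requires a design file")
            design = load_design(config.design_path)
            table = read_evidence_table(config.evidence_path, design)
            source = f"evidence:{config.evidence_path}"
        elif config.sim_params is not None:
            table, truth = simulate(config.sim_params)
            source = f"simulate:seed={config.sim_params.seed}"
        elif config.fixture is not None:
            table, truth = build_paper_fixture(*config.fixture)
            source = f"fixture:contaminants={config.fixture[0]},sporadic={config.fixture[1]}"
        else:
            raise ConfigError("no input source (evidence, simulate or fixture)")
    except ConfigError:
        raise
    except Exception as exc:
        raise type(exc)(f"[read] {exc}") from exc

    log.info("input %s: %d records, %d proteins", source, len(table),
             len(table.protein_ids))

    params = config.filter_params
    filtered = apply_score_filter(table, params.score_min)
    aggregates = aggregate(filtered, params)
    results = classify(aggregates, table.design, params, config.exclusions)

    # planted proteins that yielded no evidence at all are, by definition,
    # not reproducibly detected; give them an explicit record so the
    # evaluation covers the full truth table
    if truth is not None:
        observed = {r.protein_id for r in results}
        for pid in sorted(set(truth.roles) - observed):
            results.append(ClassificationRecord(
                protein_id=pid, category=Category.NOT_REPRODUCIBLE,
                trap_enriched=False, trap_exclusive=False, substrate=False,
                ef_trap_vs_ref=None, ef_ref_vs_control=None,
                ef_trap_vs_control=None, sample_means={},
                trap_sample_id=table.design.trap,
                audit=(("reproducibility", "no detection in any replicate"),),
            ))

    lists = final_lists(results)
    write_classification(out_dir / "classification.tsv", results)
    if config.annotations is not None:
        annotate(results, config.annotations).to_csv(
            out_dir / "classification_annotated.tsv", sep="\t", index=False
        )

    summary = {
        "source": source,
        "n_records": len(table),
        "n_proteins": len(results),
        "category_counts": category_counts(results),
        "n_interactors": len(lists.interactors),
        "n_substrates": len(lists.substrates),
        "n_trap_enriched": len(lists.enriched),
        "n_trap_exclusive": sum(
            1 for r in results
            if r.category is Category.TRAP_SPECIFIC and r.trap_exclusive
        ),
        "params": asdict(params),
        "exclusions": sorted(config.exclusions.protein_ids),
        "runtime_s": round(time.time() - t0, 3),
    }
    if truth is not None:
        truth.write(out_dir / "truth.tsv")
        report = evaluate(results, truth)
        summary["evaluation"] = report.to_dict()
        with open(out_dir / "evaluation.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("categories: %s", summary["category_counts"])
    return summary
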