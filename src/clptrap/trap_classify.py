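"""Decision cascade assigning every observed protein to exactly one category.

The cascade formalizes the selection logic of a three-arm substrate-trapping
AP-MS design (background control, active bait, catalytically dead trap
bait):

1.  Reproducibility — a protein must be detected in at least
    ``min_replicates`` replicates of a sample to count as present there;
    present nowhere means NOT_REPRODUCIBLE.
2.  Background subtraction — presence in the control taints a protein;
    it re-enters a bait's candidate set only if its bait-vs-control
    spectral-count enrichment exceeds the rescue factor.  Tainted and
    rescued in neither bait means BACKGROUND.
3.  Candidate comparison — candidates of both baits are SHARED_INTERACTOR
    unless the trap-vs-reference enrichment exceeds the trap-specific
    factor, in which case they join TRAP_SPECIFIC (non-exclusive branch);
    trap-only candidates are TRAP_SPECIFIC (exclusive branch);
    reference-only candidates are WT_PREFERENTIAL (reported, but excluded
    from the final interactor lists).
4.  Evidence floor — interactor and trap-specific calls additionally need a
    mean unique-peptide count above the floor in their supporting bait
    sample(s); failures are demoted to LOW_EVIDENCE.  WT_PREFERENTIAL
    records are reported as-is: they never feed the final lists, so the
    floor carries no downstream meaning for them and low-abundance
    reference-only proteins remain visible to the analyst.
5.  Substrate flag — trap-specific proteins not on the bait-machinery
    exclusion list (the chaperone partner of the protease) are potential
    substrates.

Every decision is appended to a per-protein audit trail.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, NamedTuple, Optional, Tuple

from .errors import EvidenceError
from .evidence_io import StudyDesign
from .trap_filters import AggregateTable, FilterParams, enrichment_factor

__all__ = [
    "Category",
    "ExclusionList",
    "ClassificationRecord",
    "classify",
    "final_lists",
    "category_counts",
    "FinalLists",
]


class Category(enum.Enum):
    """Mutually exclusive outcome of the cascade (declaration = report order)."""

    SHARED_INTERACTOR = "SHARED_INTERACTOR"
    TRAP_SPECIFIC = "TRAP_SPECIFIC"
    WT_PREFERENTIAL = "WT_PREFERENTIAL"
    BACKGROUND = "BACKGROUND"
    LOW_EVIDENCE = "LOW_EVIDENCE"
    NOT_REPRODUCIBLE = "NOT_REPRODUCIBLE"

    @property
    def order(self) -> int:
        return list(Category).index(self)


@dataclass(frozen=True)
class ExclusionList:
    """Accessions of bait machinery (e.g. the chaperone partner)."""

    protein_ids: FrozenSet[str] = frozenset()

    @classmethod
    def of(cls, *ids: str) -> "ExclusionList":
        return cls(frozenset(ids))

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.protein_ids


@dataclass(frozen=True)
class ClassificationRecord:
    protein_id: str
    category: Category
    trap_enriched: bool
    trap_exclusive: bool
    substrate: bool
    ef_trap_vs_ref: Optional[float]
    ef_ref_vs_control: Optional[float]
    ef_trap_vs_control: Optional[float]
    sample_means: Dict[str, float]
    trap_sample_id: str
    audit: Tuple[Tuple[str, str], ...]

    @property
    def trap_mean_unique(self) -> float:
        return self.sample_means.get(self.trap_sample_id, 0.0)


def _fmt(ef: Optional[float]) -> str:
    return "undefined" if ef is None else f"{ef:.3g}"


def classify(
    aggregates: AggregateTable,
    design: StudyDesign,
    params: FilterParams,
    exclusions: ExclusionList = ExclusionList(),
) -> List[ClassificationRecord]:
    """Assign every protein with any detection to exactly one category."""
    for protein_id, sample_id in aggregates.data:
        if sample_id not in design.sample_ids:
            raise EvidenceError(
                f"aggregate for {protein_id!r} references unknown sample "
                f"{sample_id!r}"
            )
    control, ref, trap = design.control, design.reference, design.trap
    results: List[ClassificationRecord] = []

    for pid in aggregates.protein_ids:
        audit: List[Tuple[str, str]] = []
        present = {s: aggregates.present(pid, s) for s in (control, ref, trap)}
        detections = {
            s: (aggregates.get(pid, s).n_detected if aggregates.get(pid, s) else 0)
            for s in (control, ref, trap)
        }
        audit.append((
            "reproducibility",
            ", ".join(
                f"{s}:{detections[s]}/{design.n_replicates(s)}"
                f"{'+' if present[s] else '-'}"
                for s in (control, ref, trap)
            ),
        ))

        ef_ref_ctrl = _safe_ef(aggregates, pid, ref, control)
        ef_trap_ctrl = _safe_ef(aggregates, pid, trap, control)
        ef_trap_ref = _safe_ef(aggregates, pid, trap, ref)

        means = {
            s: aggregates.mean_unique(pid, s) for s in (control, ref, trap)
        }

        def emit(category, trap_enriched=False, trap_exclusive=False):
            substrate = category is Category.TRAP_SPECIFIC and pid not in exclusions
            if category is Category.TRAP_SPECIFIC:
                audit.append((
                    "exclusion",
                    "bait machinery, not a substrate" if pid in exclusions
                    else "not excluded, potential substrate",
                ))
            results.append(ClassificationRecord(
                protein_id=pid,
                category=category,
                trap_enriched=trap_enriched,
                trap_exclusive=trap_exclusive,
                substrate=substrate,
                ef_trap_vs_ref=None if trap_exclusive else ef_trap_ref,
                ef_ref_vs_control=ef_ref_ctrl,
                ef_trap_vs_control=ef_trap_ctrl,
                sample_means=means,
                trap_sample_id=trap,
                audit=tuple(audit),
            ))

        # (1) reproducibility
        if not any(present.values()):
            audit.append(("category", "not reproducible in any sample"))
            emit(Category.NOT_REPRODUCIBLE)
            continue

        # (2) background subtraction with enrichment rescue
        tainted = present[control]
        candidate = {}
        for bait, ef in ((ref, ef_ref_ctrl), (trap, ef_trap_ctrl)):
            if not present[bait]:
                candidate[bait] = False
            elif not tainted:
                candidate[bait] = True
            else:
                rescued = ef is not None and ef > params.rescue_factor
                candidate[bait] = rescued
                audit.append((
                    f"background_rescue[{bait}]",
                    f"EF vs control {_fmt(ef)} "
                    f"{'>' if rescued else '<='} {params.rescue_factor:g}",
                ))
        if tainted and not (candidate[ref] or candidate[trap]):
            audit.append(("category", "background (present in control, not rescued)"))
            emit(Category.BACKGROUND)
            continue

        # (3) candidate comparison
        if candidate[ref] and candidate[trap]:
            if ef_trap_ref is not None and ef_trap_ref > params.specific_factor:
                audit.append((
                    "trap_vs_reference",
                    f"EF {_fmt(ef_trap_ref)} > {params.specific_factor:g}: "
                    "trap-specific by enrichment",
                ))
                category, kwargs = Category.TRAP_SPECIFIC, {"trap_exclusive": False}
            else:
                enriched = (
                    ef_trap_ref is not None
                    and ef_trap_ref > params.enriched_factor
                )
                audit.append((
                    "trap_vs_reference",
                    f"EF {_fmt(ef_trap_ref)} (spectral counts): shared"
                    + (", trap-enriched" if enriched else ""),
                ))
                category, kwargs = Category.SHARED_INTERACTOR, {"trap_enriched": enriched}
        elif candidate[trap]:
            audit.append((
                "trap_vs_reference",
                "no reproducible reference presence: trap-exclusive"
                + (f" (stray reference detections: {detections[ref]})"
                   if detections[ref] else ""),
            ))
            category, kwargs = Category.TRAP_SPECIFIC, {"trap_exclusive": True}
        else:
            audit.append((
                "reference_only",
                "preferential to active bait, excluded from final lists"
                + (f" (stray trap detections: {detections[trap]})"
                   if detections[trap] else ""),
            ))
            category, kwargs = Category.WT_PREFERENTIAL, {}

        # (4) unique-peptide evidence floor for list-feeding categories
        if category is Category.SHARED_INTERACTOR:
            floor_samples = [ref, trap]
        elif category is Category.TRAP_SPECIFIC:
            floor_samples = [trap]
        else:
            floor_samples = []
        failing = [
            s for s in floor_samples
            if not means[s] > params.min_avg_unique_peptides
        ]
        if failing:
            audit.append((
                "unique_peptide_floor",
                "mean unique peptides <= "
                f"{params.min_avg_unique_peptides:g} in {', '.join(failing)}",
            ))
            emit(Category.LOW_EVIDENCE)
            continue
        if floor_samples:
            audit.append((
                "unique_peptide_floor",
                "mean unique peptides > "
                f"{params.min_avg_unique_peptides:g} in "
                + ", ".join(f"{s} ({means[s]:.3g})" for s in floor_samples),
            ))
        emit(category, **kwargs)

    return results


def _safe_ef(aggregates, pid, num, den):
    num_total = aggregates.total_spectral(pid, num)
    den_total = aggregates.total_spectral(pid, den)
    if den_total == 0:
        return None
    return num_total / den_total


class FinalLists(NamedTuple):
    interactors: List[ClassificationRecord]
    substrates: List[ClassificationRecord]
    enriched: List[ClassificationRecord]


def final_lists(results: Iterable[ClassificationRecord]) -> FinalLists:
    """Interactor / substrate / trap-enriched report lists.

    Sorted by descending trap-sample mean unique peptides, ties broken by
    accession.
    """
    def _sort(records):
        return sorted(records, key=lambda r: (-r.trap_mean_unique, r.protein_id))

    results = list(results)
    shared = [r for r in results if r.category is Category.SHARED_INTERACTOR]
    return FinalLists(
        interactors=_sort(shared),
        substrates=_sort([r for r in results if r.substrate]),
        enriched=_sort([r for r in shared if r.trap_enriched]),
    )


def category_counts(results: Iterable[ClassificationRecord]) -> Dict[str, int]:
    counts = {c.value: 0 for c in Category}
    for r in results:
        counts[r.category.value] += 1
    return counts
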