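"""Evidence-quality filters and per-sample spectral-count aggregation.

The filters mirror a stringent presence/absence AP-MS workflow:

* a search-engine score threshold (default 40, retain if ``score >= 40``),
* a reproducibility rule (detected in at least ``min_replicates`` of the
  sample's biological replicates, default 2 of 3),
* spectral-count enrichment factors between samples, computed as the ratio
  of summed spectral counts across replicates (no pseudocount; a zero
  denominator yields "undefined", never infinity).

Mean unique-peptide counts are taken over ALL replicates of a sample,
zeros included, which reproduces the one-decimal display convention of
published per-sample averages (e.g. counts (2, 1, 1) over 3 replicates
give 4/3, displayed as 1.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

from .errors import EvidenceError, ParamError
from .evidence_io import EvidenceTable, StudyDesign

__all__ = [
    "FilterParams",
    "SampleAggregate",
    "AggregateTable",
    "apply_score_filter",
    "aggregate",
    "enrichment_factor",
]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the classification cascade.

    score_min
        search-engine score threshold; records with ``score < score_min``
        are discarded (a record at exactly the threshold is retained).
    min_replicates
        replicates with detection required for a reproducible presence call.
    rescue_factor
        background-rescue threshold: a protein present in the control is
        kept as a bait candidate only if its bait-vs-control spectral-count
        enrichment exceeds this factor (strict >).
    specific_factor
        trap-vs-reference enrichment above which a protein shared by both
        baits is reclassified as trap-specific (strict >).
    enriched_factor
        trap-vs-reference enrichment above which a shared protein is
        flagged trap-enriched (strict >).
    min_avg_unique_peptides
        evidence floor: mean unique peptides over all replicates of the
        supporting sample(s) must exceed this (strict >).
    """

    score_min: float = 40.0
    min_replicates: int = 2
    rescue_factor: float = 3.0
    specific_factor: float = 3.0
    enriched_factor: float = 1.5
    min_avg_unique_peptides: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rescue_factor", "specific_factor", "enriched_factor",
                     "min_avg_unique_peptides"):
            if getattr(self, name) <= 0:
                raise ParamError(f"{name} must be > 0")
        if self.score_min < 0:
            raise ParamError("score_min must be >= 0")
        if self.min_replicates < 1:
            raise ParamError("min_replicates must be >= 1")
        if self.enriched_factor > self.specific_factor:
            raise ParamError("enriched_factor must be <= specific_factor")


@dataclass(frozen=True)
class SampleAggregate:
    """Per-protein, per-sample summary of post-filter evidence."""

    protein_id: str
    sample_id: str
    n_detected: int
    n_replicates: int
    mean_unique_peptides: float
    total_spectral: int
    present: bool

    def __post_init__(self) -> None:
        if not (0 <= self.n_detected <= self.n_replicates):
            raise EvidenceError(
                f"{self.protein_id!r}: n_detected out of range"
            )
        if (self.total_spectral == 0) != (self.n_detected == 0):
            raise EvidenceError(
                f"{self.protein_id!r}: total_spectral zero iff no detection"
            )


@dataclass(frozen=True)
class AggregateTable:
    """All (protein, sample) aggregates of a table, with lookup helpers."""

    design: StudyDesign
    min_replicates: int
    data: Dict[Tuple[str, str], SampleAggregate] = field(default_factory=dict)

    @property
    def protein_ids(self) -> Tuple[str, ...]:
        return tuple(sorted({p for p, _ in self.data}))

    def get(self, protein_id: str, sample_id: str) -> Optional[SampleAggregate]:
        if sample_id not in self.design.sample_ids:
            raise EvidenceError(f"unknown sample {sample_id!r}")
        return self.data.get((protein_id, sample_id))

    def present(self, protein_id: str, sample_id: str) -> bool:
        agg = self.get(protein_id, sample_id)
        return agg is not None and agg.present

    def mean_unique(self, protein_id: str, sample_id: str) -> float:
        agg = self.get(protein_id, sample_id)
        return 0.0 if agg is None else agg.mean_unique_peptides

    def total_spectral(self, protein_id: str, sample_id: str) -> int:
        agg = self.get(protein_id, sample_id)
        return 0 if agg is None else agg.total_spectral


def apply_score_filter(table: EvidenceTable, score_min: float) -> EvidenceTable:
    """Drop records below the score threshold (inclusive retention)."""
    kept = tuple(r for r in table.records if r.score >= score_min)
    return EvidenceTable(table.design, kept)


def aggregate(table: EvidenceTable, params: FilterParams) -> AggregateTable:
    """Summarize post-filter evidence per (protein, sample).

    Only pairs with at least one detection get an aggregate.  The mean
    unique-peptide count divides by the design's replicate number for the
    sample, counting undetected replicates as zero.
    """
    acc: Dict[Tuple[str, str], list] = {}
    for r in table.records:
        key = (r.protein_id, r.sample_id)
        acc.setdefault(key, []).append(r)
    data = {}
    for (protein_id, sample_id), recs in acc.items():
        n_rep = table.design.n_replicates(sample_id)
        n_det = len(recs)
        total_unique = sum(r.unique_peptides for r in recs)
        data[(protein_id, sample_id)] = SampleAggregate(
            protein_id=protein_id,
            sample_id=sample_id,
            n_detected=n_det,
            n_replicates=n_rep,
            mean_unique_peptides=total_unique / n_rep,
            total_spectral=sum(r.spectral_count for r in recs),
            present=n_det >= params.min_replicates,
        )
    return AggregateTable(table.design, params.min_replicates, data)


def enrichment_factor(
    aggregates: AggregateTable,
    protein_id: str,
    numerator_sample: str,
    denominator_sample: str,
) -> Optional[float]:
    """Ratio of summed spectral counts between two samples.

    Returns None (undefined) when the denominator total is zero; the
    exclusivity branch of classification covers that case.
    """
    if protein_id not in set(aggregates.protein_ids):
        raise EvidenceError(f"unknown protein {protein_id!r}")
    num = aggregates.total_spectral(protein_id, numerator_sample)
    den = aggregates.total_spectral(protein_id, denominator_sample)
    if den == 0:
        return None
    return num / den
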