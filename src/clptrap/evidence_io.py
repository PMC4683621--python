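"""Reading, validation and writing of protein-evidence tables and study designs.

The canonical exchange format is a flat per-replicate TSV with one row per
(sample, replicate, protein) observation carrying the search-engine score,
the number of unique peptides and the spectral count.  Absence is encoded by
a missing row or an all-zero row; both normalize to "not detected".

A study design maps the three purification arms of a substrate-trapping
experiment to roles:

``control``
    background purification from the untagged strain,
``bait_reference``
    purification of the catalytically active (wild-type) tagged bait,
``bait_trap``
    purification of the catalytically dead "trap" bait.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Tuple

import pandas as pd
import yaml

from .errors import DesignError, EvidenceError, MzTabError

__all__ = [
    "Role",
    "StudyDesign",
    "EvidenceRecord",
    "EvidenceTable",
    "load_design",
    "read_evidence_table",
    "write_evidence_table",
    "read_mztab_proteins",
    "write_classification",
    "read_classification",
]

EVIDENCE_COLUMNS = [
    "sample_id",
    "replicate",
    "protein_id",
    "score",
    "unique_peptides",
    "spectral_count",
]


class Role(str, enum.Enum):
    CONTROL = "control"
    BAIT_REFERENCE = "bait_reference"
    BAIT_TRAP = "bait_trap"


@dataclass(frozen=True)
class StudyDesign:
    """Sample labels, their experimental roles and replicate counts."""

    entries: Tuple[Tuple[str, Role, int], ...]

    def __post_init__(self) -> None:
        seen_roles: dict[Role, str] = {}
        seen_samples: set[str] = set()
        for sample_id, role, n_rep in self.entries:
            if sample_id in seen_samples:
                raise DesignError(f"duplicate sample id {sample_id!r}")
            seen_samples.add(sample_id)
            if role in seen_roles:
                raise DesignError(
                    f"duplicate role {role.value!r} "
                    f"({seen_roles[role]!r} and {sample_id!r})"
                )
            seen_roles[role] = sample_id
            if n_rep < 1:
                raise DesignError(
                    f"sample {sample_id!r}: replicate count must be >= 1, got {n_rep}"
                )
        for role in Role:
            if role not in seen_roles:
                raise DesignError(f"missing role {role.value!r}")

    @classmethod
    def from_samples(cls, samples: Iterable[Tuple[str, str | Role, int]]) -> "StudyDesign":
        return cls(tuple((s, Role(r), int(n)) for s, r, n in samples))

    def sample_for_role(self, role: Role) -> str:
        for sample_id, r, _ in self.entries:
            if r == role:
                return sample_id
        raise DesignError(f"missing role {role.value!r}")  # pragma: no cover

    def n_replicates(self, sample_id: str) -> int:
        for sid, _, n in self.entries:
            if sid == sample_id:
                return n
        raise DesignError(f"unknown sample {sample_id!r}")

    @property
    def sample_ids(self) -> Tuple[str, ...]:
        return tuple(s for s, _, _ in self.entries)

    @property
    def control(self) -> str:
        return self.sample_for_role(Role.CONTROL)

    @property
    def reference(self) -> str:
        return self.sample_for_role(Role.BAIT_REFERENCE)

    @property
    def trap(self) -> str:
        return self.sample_for_role(Role.BAIT_TRAP)


@dataclass(frozen=True)
class EvidenceRecord:
    """One protein observation in one replicate of one sample.

    Invariants: a detected protein has at least one unique peptide and one
    spectrum, and each unique peptide contributes at least one spectrum,
    hence ``1 <= unique_peptides <= spectral_count`` whenever detected.
    """

    sample_id: str
    replicate_id: int
    protein_id: str
    score: float
    unique_peptides: int
    spectral_count: int

    def __post_init__(self) -> None:
        if self.replicate_id < 1:
            raise EvidenceError(
                f"{self.protein_id!r}: replicate index must be 1-based, "
                f"got {self.replicate_id}"
            )
        if self.score < 0:
            raise EvidenceError(f"{self.protein_id!r}: negative score {self.score}")
        if self.unique_peptides < 0 or self.spectral_count < 0:
            raise EvidenceError(f"{self.protein_id!r}: negative count")
        if (self.unique_peptides >= 1) != (self.spectral_count >= 1):
            raise EvidenceError(
                f"{self.protein_id!r}: unique_peptides >= 1 exactly when "
                f"spectral_count >= 1 (got {self.unique_peptides}, "
                f"{self.spectral_count})"
            )
        if self.spectral_count < self.unique_peptides:
            raise EvidenceError(
                f"{self.protein_id!r}: spectral_count ({self.spectral_count}) "
                f"< unique_peptides ({self.unique_peptides})"
            )

    @property
    def detected(self) -> bool:
        return self.spectral_count >= 1


@dataclass(frozen=True)
class EvidenceTable:
    """A validated collection of evidence records under a study design.

    All-zero records are normalized away at construction; the key
    (sample, replicate, protein) is unique.
    """

    design: StudyDesign
    records: Tuple[EvidenceRecord, ...]

    def __post_init__(self) -> None:
        kept = tuple(r for r in self.records if r.detected)
        object.__setattr__(self, "records", kept)
        seen: set[Tuple[str, int, str]] = set()
        for r in kept:
            if r.sample_id not in self.design.sample_ids:
                raise EvidenceError(f"unknown sample label {r.sample_id!r}")
            if r.replicate_id > self.design.n_replicates(r.sample_id):
                raise EvidenceError(
                    f"{r.protein_id!r}: replicate {r.replicate_id} out of range "
                    f"for sample {r.sample_id!r}"
                )
            key = (r.sample_id, r.replicate_id, r.protein_id)
            if key in seen:
                raise EvidenceError(f"duplicate key {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def protein_ids(self) -> Tuple[str, ...]:
        return tuple(sorted({r.protein_id for r in self.records}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.sample_id, r.replicate_id, r.protein_id, r.score,
             r.unique_peptides, r.spectral_count)
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)

    def sorted(self) -> "EvidenceTable":
        order = sorted(
            self.records, key=lambda r: (r.sample_id, r.replicate_id, r.protein_id)
        )
        return EvidenceTable(self.design, tuple(order))


def load_design(path: str | Path) -> StudyDesign:
    """Load a study design from a YAML config.

    Expected layout::

        samples:
          - id: ctrl
            role: control      # control | bait_reference | bait_trap
            replicates: 3
          ...
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "samples" not in doc:
        raise DesignError(f"{path}: design config must contain a 'samples' list")
    samples = []
    for entry in doc["samples"]:
        try:
            sid = str(entry["id"])
            role = Role(entry["role"])
            n = int(entry.get("replicates", 3))
        except (KeyError, TypeError) as exc:
            raise DesignError(f"{path}: malformed sample entry {entry!r}") from exc
        except ValueError as exc:
            raise DesignError(f"{path}: unknown role in entry {entry!r}") from exc
        samples.append((sid, role, n))
    return StudyDesign.from_samples(samples)


def write_design(path: str | Path, design: StudyDesign) -> None:
    doc = {
        "samples": [
            {"id": s, "role": r.value, "replicates": n}
            for s, r, n in design.entries
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_evidence_table(path: str | Path, design: StudyDesign) -> EvidenceTable:
    """Read a per-replicate evidence TSV and validate it against a design."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise EvidenceError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        try:
            rec = EvidenceRecord(
                sample_id=str(row.sample_id),
                replicate_id=int(row.replicate),
                protein_id=str(row.protein_id),
                score=float(row.score),
                unique_peptides=int(row.unique_peptides),
                spectral_count=int(row.spectral_count),
            )
        except (TypeError, ValueError) as exc:
            raise EvidenceError(f"{path}: malformed numeric field in row {row}") from exc
        records.append(rec)
    return EvidenceTable(design, tuple(records))


def write_evidence_table(path: str | Path, table: EvidenceTable) -> None:
    table.sorted().to_frame().to_csv(path, sep="\t", index=False)


_MSRUN_COL = re.compile(r"num_psms_ms_run\[(\d+)\]")


def read_mztab_proteins(
    path: str | Path,
    design: StudyDesign,
    assay_map: Mapping[int, Tuple[str, int]],
) -> EvidenceTable:
    """Read the protein section of an mzTab file into an evidence table.

    ``assay_map`` maps the mzTab ms_run/assay index to a (sample_id,
    replicate_id) pair of the study design.  Per-run spectral counts are
    taken from ``num_psms_ms_run[k]`` (or ``opt_ms_run[k]_spectral_count``),
    unique peptides from ``num_peptides_unique_ms_run[k]`` (or
    ``opt_ms_run[k]_unique_peptides``); the protein score from
    ``best_search_engine_score[1]``.
    """
    from pyteomics import mztab

    try:
        doc = mztab.MzTab(str(path))
        proteins = doc.protein_table
    except Exception as exc:
        raise MzTabError(f"{path}: cannot parse mzTab: {exc}") from exc
    if proteins is None or len(proteins) == 0:
        raise MzTabError(f"{path}: missing or empty protein section")

    run_indices = sorted(
        int(m.group(1))
        for c in proteins.columns
        for m in [_MSRUN_COL.fullmatch(str(c))]
        if m
    )
    if not run_indices:
        raise MzTabError(f"{path}: no per-run spectral count columns found")
    for k in run_indices:
        if k not in assay_map:
            raise MzTabError(f"{path}: assay/ms_run {k} absent from assay map")

    def _get(row, *names):
        for name in names:
            if name in proteins.columns:
                return row[name]
        return None

    records = []
    for _, row in proteins.iterrows():
        accession = str(row["accession"])
        score_val = _get(row, "best_search_engine_score[1]")
        score = 0.0 if score_val is None or pd.isna(score_val) else float(score_val)
        for k in run_indices:
            sample_id, replicate_id = assay_map[k]
            sc = _get(row, f"num_psms_ms_run[{k}]", f"opt_ms_run[{k}]_spectral_count")
            up = _get(
                row,
                f"num_peptides_unique_ms_run[{k}]",
                f"opt_ms_run[{k}]_unique_peptides",
            )
            if sc is None or pd.isna(sc):
                continue
            try:
                sc = int(sc)
                up = 0 if up is None or pd.isna(up) else int(up)
            except (TypeError, ValueError) as exc:
                raise MzTabError(
                    f"{path}: malformed numeric field for {accession!r}, run {k}"
                ) from exc
            if sc == 0:
                continue
            records.append(
                EvidenceRecord(
                    sample_id=sample_id,
                    replicate_id=replicate_id,
                    protein_id=accession,
                    score=score,
                    unique_peptides=up,
                    spectral_count=sc,
                )
            )
    return EvidenceTable(design, tuple(records))


def _fmt_ef(value) -> str:
    return "" if value is None else f"{value:.6g}"


def write_classification(path: str | Path, results: Sequence) -> None:
    """Write classification records to a TSV with a stable column layout.

    Rows are ordered by category (cascade order) then protein accession.
    Enrichment-factor fields are empty when undefined.
    """
    sample_ids: list[str] = []
    for rec in results:
        for sid in rec.sample_means:
            if sid not in sample_ids:
                sample_ids.append(sid)
    sample_ids = sorted(sample_ids)
    columns = (
        ["protein_id", "category", "substrate", "trap_enriched", "trap_exclusive",
         "ef_trap_vs_ref", "ef_ref_vs_control", "ef_trap_vs_control"]
        + [f"mean_unique_peptides.{s}" for s in sample_ids]
        + ["audit"]
    )
    order = sorted(results, key=lambda r: (r.category.order, r.protein_id))
    rows = []
    for rec in order:
        rows.append(
            [rec.protein_id, rec.category.value,
             str(bool(rec.substrate)), str(bool(rec.trap_enriched)),
             str(bool(rec.trap_exclusive)),
             _fmt_ef(rec.ef_trap_vs_ref), _fmt_ef(rec.ef_ref_vs_control),
             _fmt_ef(rec.ef_trap_vs_control)]
            + [f"{rec.sample_means.get(s, 0.0):.6g}" for s in sample_ids]
            + ["; ".join(f"{rule}={outcome}" for rule, outcome in rec.audit)]
        )
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_classification(path: str | Path) -> pd.DataFrame:
    """Read back a classification TSV (e.g. for summary/count checks)."""
    return pd.read_csv(path, sep="\t", keep_default_na=False)
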