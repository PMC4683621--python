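"""Synthetic evidence generation with planted ground truth.

Two generators are provided:

``simulate``
    a stochastic count model: per-protein baseline abundance lambda drawn
    log-normal, spectral counts Poisson around lambda times a role-and-
    sample multiplier, unique peptides binomially thinned from spectral
    counts, and a search-engine score increasing in the spectral count with
    Gaussian noise.  Planted roles mirror the populations a three-arm
    trapping experiment distinguishes: resin/matrix contaminants (all
    samples), interactors (both baits), substrates (trap bait, optionally
    leaking into the reference bait), reference-only partners, and sporadic
    one-replicate identifications.

``build_paper_fixture``
    a fully deterministic table that re-encodes published per-sample
    average unique-peptide counts from a CLPP substrate-trapping study in
    *Podospora anserina*: 47 proteins co-purifying with both bait variants,
    18 trap-exclusive proteins, two trap-enriched proteins with spectral
    enrichment factors of exactly 3.8 and 4.0, two low-abundance
    reference-preferential proteins, plus configurable synthetic
    contaminants and sporadic identifications.  Per-replicate unique
    peptide counts distribute round(3 x printed average) as evenly as
    possible across the three replicates (remainder to the lowest
    replicate indices); spectral counts are ten times the unique-peptide
    count except where a printed enrichment factor is honored exactly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import EvidenceError, ParamError
from .evidence_io import EvidenceRecord, EvidenceTable, Role, StudyDesign
from .trap_classify import Category

__all__ = [
    "PlantedRole",
    "SimParams",
    "TruthTable",
    "simulate",
    "build_paper_fixture",
    "default_design",
    "paper_annotations",
    "CLPX_ACCESSION",
    "DEFAULT_EXCLUSIONS",
]


class PlantedRole(str, enum.Enum):
    CONTAMINANT = "CONTAMINANT"
    INTERACTOR = "INTERACTOR"
    SUBSTRATE = "SUBSTRATE"
    WT_PARTNER = "WT_PARTNER"
    SPORADIC = "SPORADIC"


#: category each planted role should end up in under default thresholds
EXPECTED_CATEGORY: Dict[PlantedRole, Category] = {
    PlantedRole.CONTAMINANT: Category.BACKGROUND,
    PlantedRole.INTERACTOR: Category.SHARED_INTERACTOR,
    PlantedRole.SUBSTRATE: Category.TRAP_SPECIFIC,
    PlantedRole.WT_PARTNER: Category.WT_PREFERENTIAL,
    PlantedRole.SPORADIC: Category.NOT_REPRODUCIBLE,
}


@dataclass(frozen=True)
class TruthTable:
    """Planted role per generated protein."""

    roles: Dict[str, PlantedRole]

    def __len__(self) -> int:
        return len(self.roles)

    def __getitem__(self, protein_id: str) -> PlantedRole:
        return self.roles[protein_id]

    def items(self):
        return self.roles.items()

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted((p, r.value) for p, r in self.roles.items()),
            columns=["protein_id", "role"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        return cls({str(p): PlantedRole(r) for p, r in zip(df.protein_id, df.role)})


@dataclass(frozen=True)
class SimParams:
    """Count-model parameters of the stochastic generator.

    Counts are Poisson around a log-normal per-protein baseline: the
    minimal standard noise model for spectral counts.  Defaults plant 50
    contaminants, 20 interactors, 10 substrates, 2 reference-only partners
    and 5 sporadic proteins in a 3-sample x 3-replicate design with median
    baseline expected spectral count 20 (log-normal location ln 20,
    scale 0.8), no dropout, trap-exclusive substrates, and a score model
    ``30 + 15 log2(1 + SC) + N(0, 5)`` truncated at zero.
    """

    n_contaminants: int = 50
    n_interactors: int = 20
    n_substrates: int = 10
    n_wt_partners: int = 2
    n_sporadic: int = 5
    abundance_location: float = math.log(20.0)
    abundance_scale: float = 0.8
    substrate_ref_fraction: float = 0.0
    interactor_control_fraction: float = 0.0
    dropout: float = 0.0
    peptide_yield: float = 0.5
    score_intercept: float = 30.0
    score_slope: float = 15.0
    score_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_contaminants", "n_interactors", "n_substrates",
                     "n_wt_partners", "n_sporadic"):
            if getattr(self, name) < 0:
                raise ParamError(f"{name} must be >= 0")
        for name in ("substrate_ref_fraction", "interactor_control_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParamError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ParamError("dropout must be in [0, 1)")
        if self.abundance_scale <= 0:
            raise ParamError("abundance_scale must be > 0")
        if not 0.0 < self.peptide_yield <= 1.0:
            raise ParamError("peptide_yield must be in (0, 1]")
        if self.score_sd < 0:
            raise ParamError("score_sd must be >= 0")


def default_design() -> StudyDesign:
    return StudyDesign.from_samples([
        ("control", Role.CONTROL, 3),
        ("wt_tag", Role.BAIT_REFERENCE, 3),
        ("trap_tag", Role.BAIT_TRAP, 3),
    ])


_ROLE_COUNTS = (
    (PlantedRole.CONTAMINANT, "n_contaminants"),
    (PlantedRole.INTERACTOR, "n_interactors"),
    (PlantedRole.SUBSTRATE, "n_substrates"),
    (PlantedRole.WT_PARTNER, "n_wt_partners"),
    (PlantedRole.SPORADIC, "n_sporadic"),
)


def _multipliers(role: PlantedRole, params: SimParams) -> Dict[Role, float]:
    icf = params.interactor_control_fraction
    if role is PlantedRole.CONTAMINANT:
        return {Role.CONTROL: 1.0, Role.BAIT_REFERENCE: 1.0, Role.BAIT_TRAP: 1.0}
    if role is PlantedRole.INTERACTOR:
        return {Role.CONTROL: icf, Role.BAIT_REFERENCE: 1.0, Role.BAIT_TRAP: 1.0}
    if role is PlantedRole.SUBSTRATE:
        return {Role.CONTROL: icf,
                Role.BAIT_REFERENCE: params.substrate_ref_fraction,
                Role.BAIT_TRAP: 1.0}
    if role is PlantedRole.WT_PARTNER:
        return {Role.CONTROL: 0.0, Role.BAIT_REFERENCE: 1.0, Role.BAIT_TRAP: 0.0}
    return {}  # SPORADIC handled separately


def simulate(
    params: SimParams, design: Optional[StudyDesign] = None
) -> Tuple[EvidenceTable, TruthTable]:
    """Draw an evidence table with planted ground truth.

    Identical parameters (including the seed) give byte-identical output.
    """
    if design is None:
        design = default_design()
    rng = np.random.default_rng(params.seed)
    records: List[EvidenceRecord] = []
    truth: Dict[str, PlantedRole] = {}
    role_of_sample = {s: r for s, r, _ in design.entries}

    def draw_replicate(pid: str, sample_id: str, replicate: int, mu: float) -> None:
        if mu <= 0:
            return
        sc = int(rng.poisson(mu))
        if params.dropout > 0 and rng.random() < params.dropout:
            sc = 0
        if sc < 1:
            return
        up = max(1, int(rng.binomial(sc, params.peptide_yield)))
        up = min(up, sc)
        score = params.score_intercept + params.score_slope * math.log2(1 + sc)
        if params.score_sd > 0:
            score += rng.normal(0.0, params.score_sd)
        records.append(EvidenceRecord(
            sample_id=sample_id, replicate_id=replicate, protein_id=pid,
            score=max(0.0, float(score)), unique_peptides=up, spectral_count=sc,
        ))

    for role, attr in _ROLE_COUNTS:
        for i in range(getattr(params, attr)):
            pid = f"{role.value}_{i + 1:04d}"
            truth[pid] = role
            lam = float(rng.lognormal(params.abundance_location,
                                      params.abundance_scale))
            if role is PlantedRole.SPORADIC:
                s_idx = int(rng.integers(0, len(design.sample_ids)))
                sample_id = design.sample_ids[s_idx]
                rep = int(rng.integers(1, design.n_replicates(sample_id) + 1))
                draw_replicate(pid, sample_id, rep, lam)
                continue
            mult = _multipliers(role, params)
            for sample_id in design.sample_ids:
                mu = lam * mult.get(role_of_sample[sample_id], 0.0)
                for rep in range(1, design.n_replicates(sample_id) + 1):
                    draw_replicate(pid, sample_id, rep, mu)

    return EvidenceTable(design, tuple(records)), TruthTable(truth)


# ---------------------------------------------------------------------------
# Deterministic fixture re-encoding the published co-purification tables.
# Per-sample values are the printed average unique-peptide counts
# (P. anserina accession, active-bait avg, trap-bait avg, Swiss-Prot
# homologue, gene symbol); "" marks rows with no homologue determinable.

SHARED_TABLE: Tuple[Tuple[str, float, float, str, str], ...] = (
    ("Pa_6_2570", 27.0, 28.3, "P38646", "HSPA9"),
    ("Pa_6_5750", 16.7, 13.7, "P10809", "HSPD1"),
    ("Pa_2_9700", 14.3, 15.3, "O94826", "TOMM70A"),
    ("Pa_2_10580", 9.0, 9.3, "O96008", "TOMM40"),
    ("Pa_6_1920", 3.0, 2.7, "Q15388", "TOMM20"),
    ("Pa_2_12760", 1.7, 1.3, "P35232", "PHB"),
    ("Pa_1_22300", 12.0, 15.3, "P23378", "GLDC"),
    ("Pa_3_10790", 11.3, 13.0, "O95571", "ETHE1"),
    ("Pa_5_5970", 10.0, 9.0, "Q99798", "ACO2"),
    ("Pa_3_11290", 8.7, 9.3, "P00505", "GOT2"),
    ("Pa_6_1590", 8.0, 7.0, "P24752", "ACAT1"),
    ("Pa_3_6780", 7.3, 14.0, "O75390", "CS"),
    ("Pa_6_2730", 7.3, 6.3, "P50213", "IDH3A"),
    ("Pa_3_2310", 6.7, 12.0, "P10515", "DLAT"),
    ("Pa_5_11920", 5.7, 5.0, "Q13825", "AUH"),
    ("Pa_2_1050", 5.7, 4.3, "P78827", "ilv-2"),
    ("Pa_6_10000", 5.0, 3.7, "C7C436", "mcsA"),
    ("Pa_1_13140", 4.7, 6.3, "P31327", "CPS1"),
    ("Pa_3_7700", 4.3, 7.7, "Q9P2R7", "SUCLA2"),
    ("Pa_1_3450", 4.0, 6.0, "Q92506", "HSD17B8"),
    ("Pa_1_17280", 3.3, 5.0, "Q12428", "PDH1"),
    ("Pa_1_14630", 3.0, 6.3, "Q8N159", "NAGS"),
    ("Pa_4_7010", 3.0, 3.7, "Q16698", "DECR1"),
    ("Pa_3_10910", 3.0, 3.3, "P15937", "acu-8"),
    ("Pa_4_8600", 3.0, 3.0, "O15382", "BCAT2"),
    ("Pa_2_6200", 2.3, 5.0, "P23434", "GCSH"),
    ("Pa_6_8420", 2.3, 4.0, "P45954", "ACADSB"),
    ("Pa_2_430", 2.3, 3.3, "Q9Y697", "NFS1"),
    ("Pa_3_2600", 2.0, 5.3, "P40926", "MDH2"),
    ("Pa_1_15690", 2.0, 3.7, "Q10341", "cys2"),
    ("Pa_2_4980", 2.0, 3.3, "Q16836", "HADH"),
    ("Pa_3_1420", 2.0, 2.0, "Q9UHQ9", "CYB5R1"),
    ("Pa_3_9430", 1.7, 3.0, "P04181", "OAT"),
    ("Pa_4_3040", 1.7, 1.7, "P48735", "IDH2"),
    ("Pa_1_7660", 1.7, 1.3, "Q02252", "ALDH6A1"),
    ("Pa_7_10210", 1.3, 3.0, "P30084", "ECHS1"),
    ("Pa_1_1980", 1.3, 1.7, "P51649", "ALDH5A1"),
    ("Pa_4_660", 1.3, 1.3, "P34897", "SHMT2"),
    ("Pa_1_14370", 2.7, 2.3, "O75947", "ATP5H"),
    ("Pa_4_7160", 2.0, 4.7, "O75489", "NDUFS3"),
    ("Pa_1_8620", 2.0, 1.7, "O75306", "NDUFS2"),
    ("Pa_5_7500", 1.3, 1.7, "O14561", "NDUFAB1"),
    ("Pa_6_240", 1.3, 1.3, "P47985", "UQCRFS1"),
    ("Pa_2_12010", 8.7, 10.0, "P49411", "TUFM"),
    ("Pa_4_1130", 2.3, 2.3, "", ""),
    ("Pa_5_8240", 2.0, 2.7, "P30044", "PRDX5"),
    ("Pa_6_8740", 2.0, 2.3, "P10599", "TXN"),
)

TRAP_EXCLUSIVE_TABLE: Tuple[Tuple[str, float, str, str], ...] = (
    ("Pa_6_5510", 7.3, "Q8NBU5", "ATAD1"),
    ("Pa_6_5590", 3.7, "O76031", "CLPX"),
    ("Pa_6_5560", 15.7, "Q02218", "OGDH"),
    ("Pa_6_1640", 7.7, "P31327", "CPS1"),
    ("Pa_7_9520", 7.3, "O00330", "PDHX"),
    ("Pa_7_10050", 4.0, "P08559", "PDHA1"),
    ("Pa_1_13750", 2.7, "P48728", "AMT"),
    ("Pa_5_5810", 2.3, "P09622", "DLD"),
    ("Pa_1_15800", 2.0, "P11177", "PDHB"),
    ("Pa_1_20100", 1.3, "P26440", "IVD"),
    ("Pa_3_9520", 1.3, "P35914", "HMGCL"),
    ("Pa_3_4870", 21.0, "P28331", "NDUFS1"),
    ("Pa_4_7950", 3.7, "P49821", "NDUFV1"),
    ("Pa_5_9670", 3.3, "Q5T2R2", "PDSS1"),
    ("Pa_1_18430", 2.7, "P22626", "HNRNPA2B1"),
    ("Pa_2_10680", 2.0, "Q86SX6", "GLRX5"),
    ("Pa_1_6330", 1.7, "Q96RP9", "GFM1"),
    ("Pa_5_2590", 1.7, "G2TRP3", "ymr31"),
)

# (accession, trap avg unique peptides, per-replicate trap spectral count,
#  Swiss-Prot, gene); reference side is fixed at unique (1,1,1) and
# spectral (10,10,10) so the trap-vs-reference spectral enrichment is
# exactly 3 x 38 / 30 = 3.8 and 3 x 40 / 30 = 4.0.
TRAP_ENRICHED_TABLE: Tuple[Tuple[str, float, int, str, str], ...] = (
    ("Pa_5_5370", 5.0, 38, "P36957", "DLST"),
    ("Pa_3_11170", 10.7, 40, "O59778", "bio2"),
)

# Reference-preferential, low-abundance proteins (no P. anserina accession
# was published; the Swiss-Prot homologue IDs serve as accessions).
WT_PREFERENTIAL_TABLE: Tuple[Tuple[str, str], ...] = (
    ("Q9HCC0", "MCCC2"),
    ("Q7SDV9", "ccp-1"),
)

CLPX_ACCESSION = "Pa_6_5590"
DEFAULT_EXCLUSIONS = frozenset({CLPX_ACCESSION})

_FIXTURE_SCORE = 100.0
_SPECTRA_PER_PEPTIDE = 10


def _spread(total: int, n: int = 3) -> List[int]:
    """Distribute ``total`` over ``n`` replicates, remainder to the lowest."""
    base, rem = divmod(total, n)
    return [base + 1 if i < rem else base for i in range(n)]


def _counts_from_avg(avg: float) -> List[int]:
    return _spread(int(round(3 * avg)))


def build_paper_fixture(
    n_contaminants: int = 10, n_sporadic: int = 5
) -> Tuple[EvidenceTable, TruthTable]:
    """Deterministically encode the published co-purification tables."""
    if n_contaminants < 0 or n_sporadic < 0:
        raise ParamError("fixture counts must be >= 0")
    design = default_design()
    ref, trap = design.reference, design.trap
    records: List[EvidenceRecord] = []
    truth: Dict[str, PlantedRole] = {}

    def add(pid, sample, unique_by_rep, spectral_by_rep=None):
        if spectral_by_rep is None:
            spectral_by_rep = [u * _SPECTRA_PER_PEPTIDE for u in unique_by_rep]
        for rep, (up, sc) in enumerate(zip(unique_by_rep, spectral_by_rep), start=1):
            if sc == 0:
                continue
            records.append(EvidenceRecord(
                sample_id=sample, replicate_id=rep, protein_id=pid,
                score=_FIXTURE_SCORE, unique_peptides=up, spectral_count=sc,
            ))

    for pid, wt_avg, trap_avg, _, _ in SHARED_TABLE:
        truth[pid] = PlantedRole.INTERACTOR
        add(pid, ref, _counts_from_avg(wt_avg))
        add(pid, trap, _counts_from_avg(trap_avg))

    for pid, trap_avg, _, _ in TRAP_EXCLUSIVE_TABLE:
        truth[pid] = PlantedRole.SUBSTRATE
        add(pid, trap, _counts_from_avg(trap_avg))

    for pid, trap_avg, trap_sc, _, _ in TRAP_ENRICHED_TABLE:
        truth[pid] = PlantedRole.SUBSTRATE
        add(pid, ref, [1, 1, 1])
        add(pid, trap, _counts_from_avg(trap_avg), [trap_sc] * 3)

    for pid, _ in WT_PREFERENTIAL_TABLE:
        truth[pid] = PlantedRole.WT_PARTNER
        add(pid, ref, [1, 1, 0])
        add(pid, trap, [1, 0, 0])

    for i in range(n_contaminants):
        pid = f"SYN_CONTAMINANT_{i + 1:03d}"
        truth[pid] = PlantedRole.CONTAMINANT
        for sample in design.sample_ids:
            add(pid, sample, [5, 5, 5])

    for i in range(n_sporadic):
        pid = f"SYN_SPORADIC_{i + 1:03d}"
        truth[pid] = PlantedRole.SPORADIC
        sample = design.sample_ids[i % len(design.sample_ids)]
        rep = (i // len(design.sample_ids)) % 3
        unique = [0, 0, 0]
        unique[rep] = 2
        add(pid, sample, unique)

    return EvidenceTable(design, tuple(records)), TruthTable(truth)


def paper_annotations() -> Dict[str, Tuple[str, str, str, str]]:
    """Homologue annotations for the fixture accessions.

    Maps accession to (homologue accession, gene symbol, protein name,
    free-text tags); usable with the annotation join.
    """
    out: Dict[str, Tuple[str, str, str, str]] = {}
    for pid, _, _, sp, gene in SHARED_TABLE:
        out[pid] = (sp, gene, "", "shared")
    for pid, _, sp, gene in TRAP_EXCLUSIVE_TABLE:
        out[pid] = (sp, gene, "", "trap-exclusive")
    for pid, _, _, sp, gene in TRAP_ENRICHED_TABLE:
        out[pid] = (sp, gene, "", "trap-enriched")
    for pid, gene in WT_PREFERENTIAL_TABLE:
        out[pid] = (pid, gene, "", "wt-preferential")
    return out
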