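import itertools
import random

import pytest

from clptrap import (
    Category,
    ExclusionList,
    FilterParams,
    Role,
    StudyDesign,
    aggregate,
    final_lists,
)
from clptrap.trap_classify import category_counts

from conftest import make_table, run_cascade
from oracle import oracle_classify

DESIGN = StudyDesign.from_samples([
    ("ctrl", Role.CONTROL, 3),
    ("wt", Role.BAIT_REFERENCE, 3),
    ("trap", Role.BAIT_TRAP, 3),
])


def by_id(results):
    return {r.protein_id: r for r in results}


class TestPublishedExamples:
    """Rows of the encoded co-purification tables behave as printed."""

    def test_citrate_synthase_is_shared_and_trap_enriched(self, fixture_results):
        rec = by_id(fixture_results[0])["Pa_3_6780"]
        assert rec.category is Category.SHARED_INTERACTOR
        assert rec.trap_enriched
        assert rec.sample_means["wt_tag"] == pytest.approx(22 / 3)   # shows as 7.3
        assert rec.sample_means["trap_tag"] == pytest.approx(14.0)
        assert rec.ef_trap_vs_ref == pytest.approx(42 / 22)

    def test_ndufs1_is_trap_exclusive_substrate(self, fixture_results):
        rec = by_id(fixture_results[0])["Pa_3_4870"]
        assert rec.category is Category.TRAP_SPECIFIC
        assert rec.trap_exclusive
        assert rec.substrate
        assert rec.sample_means["trap_tag"] == pytest.approx(21.0)
        assert rec.ef_trap_vs_ref is None

    def test_chaperone_partner_is_excluded_from_substrates(self, fixture_results):
        rec = by_id(fixture_results[0])["Pa_6_5590"]
        assert rec.category is Category.TRAP_SPECIFIC
        assert rec.trap_exclusive
        assert not rec.substrate

    def test_dlst_reclassified_trap_specific_by_enrichment(self, fixture_results):
        rec = by_id(fixture_results[0])["Pa_5_5370"]
        assert rec.category is Category.TRAP_SPECIFIC
        assert not rec.trap_exclusive
        assert rec.substrate
        assert rec.ef_trap_vs_ref == pytest.approx(3.8)

    def test_wt_preferential_reported_not_listed(self, fixture_results):
        results, _ = fixture_results
        for pid in ("Q9HCC0", "Q7SDV9"):
            rec = by_id(results)[pid]
            assert rec.category is Category.WT_PREFERENTIAL
            # single stray trap detection is visible in the audit trail
            assert any("stray trap detections: 1" in outcome
                       for _, outcome in rec.audit)
        lists = final_lists(results)
        listed = {r.protein_id for r in
                  lists.interactors + lists.substrates + lists.enriched}
        assert {"Q9HCC0", "Q7SDV9"}.isdisjoint(listed)


class TestCascadeRules:
    def test_weak_enrichment_over_control_stays_background(self):
        # present in all three samples, each bait only 2x over control
        rows = [(s, rep, "P1", 90.0, 3, 10 if s == "ctrl" else 20)
                for s in ("ctrl", "wt", "trap") for rep in (1, 2, 3)]
        rec = by_id(run_cascade(make_table(DESIGN, rows)))["P1"]
        assert rec.category is Category.BACKGROUND
        assert rec.ef_trap_vs_control == pytest.approx(2.0)

    def test_strong_enrichment_over_control_is_rescued(self):
        rows = [(s, rep, "P1", 90.0, 3, 10 if s == "ctrl" else 40)
                for s in ("ctrl", "wt", "trap") for rep in (1, 2, 3)]
        rec = by_id(run_cascade(make_table(DESIGN, rows)))["P1"]
        assert rec.category is Category.SHARED_INTERACTOR

    def test_single_replicate_is_not_reproducible(self):
        rows = [("trap", 1, "P1", 90.0, 5, 20)]
        rec = by_id(run_cascade(make_table(DESIGN, rows)))["P1"]
        assert rec.category is Category.NOT_REPRODUCIBLE

    def test_unique_peptide_floor_demotes_to_low_evidence(self):
        # trap-exclusive but only one peptide per replicate (mean 1.0, not > 1)
        rows = [("trap", rep, "P1", 90.0, 1, 5) for rep in (1, 2, 3)]
        rec = by_id(run_cascade(make_table(DESIGN, rows)))["P1"]
        assert rec.category is Category.LOW_EVIDENCE
        assert not rec.substrate

    def test_audit_trail_names_every_stage(self, fixture_results):
        rec = by_id(fixture_results[0])["Pa_3_6780"]
        rules = [rule for rule, _ in rec.audit]
        assert rules[0] == "reproducibility"
        assert "trap_vs_reference" in rules
        assert "unique_peptide_floor" in rules


class TestFinalLists:
    def test_background_only_gives_empty_lists(self):
        rows = [(s, rep, "P1", 90.0, 3, 10)
                for s in ("ctrl", "wt", "trap") for rep in (1, 2, 3)]
        lists = final_lists(run_cascade(make_table(DESIGN, rows)))
        assert lists == ([], [], [])

    def test_sorted_by_trap_abundance_then_accession(self, fixture_results):
        lists = final_lists(fixture_results[0])
        keys = [(-r.trap_mean_unique, r.protein_id) for r in lists.substrates]
        assert keys == sorted(keys)
        assert lists.substrates[0].protein_id == "Pa_3_4870"  # trap mean 21.0
        assert len(lists.interactors) == 47
        assert len(lists.enriched) == 12


# -- structural properties ---------------------------------------------------

def random_rows(rng, n_proteins=3, score_choices=(30.0, 39.0, 40.0, 100.0)):
    rows = []
    for i in range(n_proteins):
        pid = f"P{i}"
        for s in ("ctrl", "wt", "trap"):
            for rep in (1, 2, 3):
                sc = rng.choice([0, 0, 1, 2, 5, 12, 40])
                if sc == 0:
                    continue
                up = rng.randint(1, min(sc, 6))
                rows.append((s, rep, pid, rng.choice(score_choices), up, sc))
    return rows


@pytest.mark.parametrize("seed", range(30))
def test_partition_every_observed_protein_once(seed):
    rng = random.Random(seed)
    table = make_table(DESIGN, random_rows(rng, n_proteins=4))
    params = FilterParams()
    results = run_cascade(table, params)
    from clptrap import apply_score_filter

    observed = set(aggregate(apply_score_filter(table, params.score_min),
                             params).protein_ids)
    assert {r.protein_id for r in results} == observed
    assert len(results) == len(observed)
    assert sum(category_counts(results).values()) == len(results)
    # substrates within trap-specific, enriched within shared
    for r in results:
        if r.substrate:
            assert r.category is Category.TRAP_SPECIFIC
        if r.trap_enriched:
            assert r.category is Category.SHARED_INTERACTOR
        if r.trap_exclusive:
            assert r.ef_trap_vs_ref is None


@pytest.mark.parametrize("seed", range(30))
def test_order_invariance(seed):
    rng = random.Random(seed)
    rows = random_rows(rng, n_proteins=4)
    results = run_cascade(make_table(DESIGN, rows))
    rng.shuffle(rows)
    shuffled = run_cascade(make_table(DESIGN, rows))
    assert sorted(results, key=lambda r: r.protein_id) == \
        sorted(shuffled, key=lambda r: r.protein_id)


@pytest.mark.parametrize("seed", range(30))
def test_threshold_monotonicity(seed):
    rng = random.Random(seed)
    table = make_table(DESIGN, random_rows(rng, n_proteins=4))
    n_specific, n_background = [], []
    for factor in (1.5, 3.0, 6.0, 12.0):
        counts = category_counts(
            run_cascade(table, FilterParams(specific_factor=factor,
                                            enriched_factor=1.5)))
        n_specific.append(counts["TRAP_SPECIFIC"])
    for factor in (1.0, 3.0, 6.0, 12.0):
        counts = category_counts(
            run_cascade(table, FilterParams(rescue_factor=factor)))
        n_background.append(counts["BACKGROUND"])
    assert n_specific == sorted(n_specific, reverse=True)
    assert n_background == sorted(n_background)


@pytest.mark.parametrize("seed", range(30))
def test_deleting_control_empties_background(seed):
    rng = random.Random(seed)
    rows = random_rows(rng, n_proteins=4)
    with_ctrl = by_id(run_cascade(make_table(DESIGN, rows)))
    no_ctrl_rows = [r for r in rows if r[0] != "ctrl"]
    without_ctrl = by_id(run_cascade(make_table(DESIGN, no_ctrl_rows)))
    assert all(r.category is not Category.BACKGROUND
               for r in without_ctrl.values())
    # trap-specific calls whose reference arm was not reproducibly present
    # are unaffected by the control arm
    for pid, rec in with_ctrl.items():
        if rec.category is Category.TRAP_SPECIFIC and rec.trap_exclusive:
            ref_reps = {r[1] for r in rows if r[0] == "wt" and r[2] == pid
                        and r[3] >= 40.0}
            if len(ref_reps) < 2:
                assert without_ctrl[pid].category is Category.TRAP_SPECIFIC


# -- equivalence with the brute-force oracle ---------------------------------

def _compare(rows, params=FilterParams(), exclusions=frozenset({"P0"})):
    results = run_cascade(make_table(DESIGN, rows), params,
                          ExclusionList(exclusions))
    got = {r.protein_id: (r.category, r.trap_enriched, r.trap_exclusive,
                          r.substrate) for r in results}
    want = oracle_classify(rows, DESIGN, params, exclusions)
    assert got == want


def test_exhaustive_single_protein_profiles():
    """classify agrees with literal set operations on every count profile.

    Enumerates all 3^9 spectral-count profiles over 3 samples x 3
    replicates with per-replicate counts in {0, 1, 2} (unique peptides =
    spectral count, fixed high score), which exercises every branch of the
    cascade including reproducibility, exclusivity and the evidence floor.
    """
    params = FilterParams()
    for profile in itertools.product((0, 1, 2), repeat=9):
        rows = []
        for idx, sc in enumerate(profile):
            if sc == 0:
                continue
            sample = ("ctrl", "wt", "trap")[idx // 3]
            rows.append((sample, idx % 3 + 1, "P0", 100.0, sc, sc))
        _compare(rows, params)


@pytest.mark.parametrize("seed", range(50))
def test_oracle_agreement_on_random_three_protein_tables(seed):
    """Random scores/counts, including sub-threshold scores and rescue cases."""
    rng = random.Random(1000 + seed)
    _compare(random_rows(rng, n_proteins=3))


@pytest.mark.parametrize("seed", range(10))
def test_classification_is_per_protein_independent(seed):
    rng = random.Random(2000 + seed)
    rows = random_rows(rng, n_proteins=3)
    combined = by_id(run_cascade(make_table(DESIGN, rows)))
    for pid in {r[2] for r in rows}:
        alone = by_id(run_cascade(
            make_table(DESIGN, [r for r in rows if r[2] == pid])))
        assert alone[pid] == combined[pid]
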