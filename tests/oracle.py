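"""Brute-force reference classifier written as literal set operations.

Deliberately independent of the package's cascade implementation: works
directly on raw record tuples with explicit set algebra, so the two can be
compared on enumerated instances.
"""

from clptrap.trap_classify import Category


def oracle_classify(rows, design, params, exclusions=frozenset()):
    """rows: iterable of (sample, replicate, protein, score, unique, spectral).

    Returns {protein_id: (Category, trap_enriched, trap_exclusive, substrate)}.
    """
    ctrl, ref, trap = design.control, design.reference, design.trap
    rows = [r for r in rows if r[5] >= 1 and r[3] >= params.score_min]

    detected = {}  # (protein, sample) -> set of replicates
    unique = {}    # (protein, sample) -> summed unique peptides
    spectra = {}   # (protein, sample) -> summed spectral counts
    for sample, rep, pid, _score, up, sc in rows:
        detected.setdefault((pid, sample), set()).add(rep)
        unique[(pid, sample)] = unique.get((pid, sample), 0) + up
        spectra[(pid, sample)] = spectra.get((pid, sample), 0) + sc

    proteins = {pid for pid, _ in detected}

    def present(pid, sample):
        return len(detected.get((pid, sample), set())) >= params.min_replicates

    def mean_unique(pid, sample):
        return unique.get((pid, sample), 0) / design.n_replicates(sample)

    def ef(pid, num, den):
        d = spectra.get((pid, den), 0)
        return None if d == 0 else spectra.get((pid, num), 0) / d

    out = {}
    present_ctrl = {p for p in proteins if present(p, ctrl)}
    present_ref = {p for p in proteins if present(p, ref)}
    present_trap = {p for p in proteins if present(p, trap)}

    not_reproducible = proteins - present_ctrl - present_ref - present_trap

    rescued_ref = {
        p for p in present_ref & present_ctrl
        if ef(p, ref, ctrl) is not None and ef(p, ref, ctrl) > params.rescue_factor
    }
    rescued_trap = {
        p for p in present_trap & present_ctrl
        if ef(p, trap, ctrl) is not None and ef(p, trap, ctrl) > params.rescue_factor
    }
    cand_ref = (present_ref - present_ctrl) | rescued_ref
    cand_trap = (present_trap - present_ctrl) | rescued_trap
    background = present_ctrl - cand_ref - cand_trap

    both = cand_ref & cand_trap
    trap_by_ef = {
        p for p in both
        if ef(p, trap, ref) is not None and ef(p, trap, ref) > params.specific_factor
    }
    shared = both - trap_by_ef
    trap_only = cand_trap - cand_ref
    ref_only = (cand_ref - cand_trap) - not_reproducible

    floor = params.min_avg_unique_peptides
    for p in not_reproducible:
        out[p] = (Category.NOT_REPRODUCIBLE, False, False, False)
    for p in background:
        out[p] = (Category.BACKGROUND, False, False, False)
    for p in ref_only:
        out[p] = (Category.WT_PREFERENTIAL, False, False, False)
    for p in shared:
        if mean_unique(p, ref) > floor and mean_unique(p, trap) > floor:
            e = ef(p, trap, ref)
            out[p] = (Category.SHARED_INTERACTOR,
                      e is not None and e > params.enriched_factor, False, False)
        else:
            out[p] = (Category.LOW_EVIDENCE, False, False, False)
    for p in trap_by_ef | trap_only:
        if mean_unique(p, trap) > floor:
            out[p] = (Category.TRAP_SPECIFIC, False, p in trap_only,
                      p not in exclusions)
        else:
            out[p] = (Category.LOW_EVIDENCE, False, False, False)
    return out
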