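"""In-silico mutagenesis: edit operations and the packaged construct set."""

from __future__ import annotations

import pytest

from utrcode import (
    ConstructSpec,
    EditOp,
    UtrRecord,
    apply_construct,
    build_architecture,
    classify_pas,
    delete_spacer,
    enumerate_reporter_constructs,
    gap_distance,
    insert_cpe,
    mutate_cpe,
    mutate_pas,
    predict_profile,
    scan_motifs,
    truncate_distal,
)
from utrcode.engine import FREE, ONE_SIDED
from utrcode.motifs import default_patterns
from utrcode.mutate import PAS_MUTANT


def _gap_table(arch):
    """All same-pair element gaps keyed by label pair (for edit-invariance checks)."""
    els = list(arch.elements)
    return {
        (a.label, b.label): gap_distance(a, b)
        for i, a in enumerate(els)
        for b in els[i + 1 :]
        if not a.overlaps(b)
    }


# --- mutate_pas -------------------------------------------------------------


def test_mutate_pas_single_hexamer(patterns):
    rec = UtrRecord("toy", "GGCC" + "AATAAA" + "GGCC")
    arch = build_architecture(rec, scan_motifs(rec, patterns))
    rec2, arch2 = mutate_pas(rec, arch, "PAS1", patterns)
    assert rec2.sequence == "GGCC" + PAS_MUTANT + "GGCC"
    assert arch2.counts()["PAS"] == 0


def test_mutate_all_cpeb1_pas(fixtures, patterns):
    rec, arch = fixtures["Cpeb1"].record, fixtures["Cpeb1"].architecture
    for label in ("PAS3", "PAS2", "PAS1"):
        rec, arch = mutate_pas(rec, arch, label, patterns)
    assert arch.counts() == {"PAS": 0, "CPE": 4, "PBE": 1}


def test_mutating_missing_label_raises(fixtures, patterns):
    rec, arch = fixtures["Btg4"].record, fixtures["Btg4"].architecture
    rec, arch = mutate_pas(rec, arch, "PAS2", patterns)
    with pytest.raises(KeyError):
        mutate_pas(rec, arch, "PAS2", patterns)  # label no longer exists


# --- mutate_cpe -------------------------------------------------------------


def test_mutate_cpe_removes_motif_only(fixtures, patterns):
    rec, arch = fixtures["Btg4"].record, fixtures["Btg4"].architecture
    before = _gap_table(arch)
    rec2, arch2 = mutate_cpe(rec, arch, "CPE3", patterns)
    assert arch2.counts() == {"PAS": 2, "CPE": 2, "PBE": 0}
    assert len(rec2) == len(rec)  # length-preserving
    after = _gap_table(arch2)
    for pair, gap in after.items():
        assert before[pair] == gap  # untouched elements keep their gaps


def test_mutate_cpe_on_toy_heptamer(patterns):
    rec = UtrRecord("toy", "GCGC" + "TTTTAAT" + "GCGC")
    arch = build_architecture(rec, scan_motifs(rec, patterns))
    rec2, arch2 = mutate_cpe(rec, arch, "CPE1", patterns)
    assert arch2.counts()["CPE"] == 0
    assert len(rec2) == len(rec)


# --- delete_spacer ----------------------------------------------------------


@pytest.mark.parametrize("remaining", [50, 35, 15, 0])
def test_delete_spacer_exact_remaining_gap(fixtures, patterns, remaining):
    rec, arch = fixtures["Cpeb1"].record, fixtures["Cpeb1"].architecture
    rec2, arch2 = delete_spacer(rec, arch, "PAS1", "CPE1", remaining, patterns)
    assert gap_distance(arch2.get("PAS1"), arch2.get("CPE1")) == remaining
    assert arch2.counts() == arch.counts()
    # downstream pairwise gaps unchanged
    assert gap_distance(arch2.get("CPE1"), arch2.get("CPE2")) == gap_distance(
        arch.get("CPE1"), arch.get("CPE2")
    )


def test_delete_spacer_precondition_errors(fixtures, patterns):
    rec, arch = fixtures["Cpeb1"].record, fixtures["Cpeb1"].architecture
    current = gap_distance(arch.get("PAS1"), arch.get("CPE1"))
    with pytest.raises(ValueError):
        delete_spacer(rec, arch, "PAS1", "CPE1", current, patterns)
    with pytest.raises(ValueError, match="contains"):
        # the CPE4..PAS3 spacer holds the PBE
        delete_spacer(rec, arch, "CPE4", "PAS3", 10, patterns)


# --- insert_cpe -------------------------------------------------------------


@pytest.mark.parametrize(
    "gap,expected_call", [(35, ONE_SIDED), (50, FREE)], ids=["gap-35", "gap-50"]
)
def test_insert_cpe_flips_call_at_35_not_50(fixtures, patterns, cfg, gap, expected_call):
    rec, arch = fixtures["Cpeb1"].record, fixtures["Cpeb1"].architecture
    for label in ("PAS3", "PAS2"):
        rec, arch = mutate_pas(rec, arch, label, patterns)
    rec2, arch2 = insert_cpe(rec, arch, "PAS1", gap, patterns)
    assert arch2.counts()["CPE"] == 5
    assert len(rec2) == len(rec) + 7
    pas1 = arch2.get("PAS1")
    new_cpe = arch2.get("CPE1")  # inserted CPE is now the 5'-most after PAS1
    assert gap_distance(pas1, new_cpe) == gap
    assert classify_pas(arch2, pas1, cfg).call == expected_call


def test_insert_into_pas_free_architecture(patterns):
    rec = UtrRecord("toy", "GC" * 60)
    arch = build_architecture(rec, scan_motifs(rec, patterns))
    with pytest.raises(KeyError):
        insert_cpe(rec, arch, "PAS1", 10, patterns)


# --- truncate_distal --------------------------------------------------------


def test_truncate_cnot6l_keeps_distal_elements(fixtures, patterns):
    rec, arch = fixtures["Cnot6l"].record, fixtures["Cnot6l"].architecture
    rec2, arch2 = truncate_distal(rec, arch, 402, patterns)
    assert len(rec2) == 402
    assert arch2.counts() == {"PAS": 1, "CPE": 3, "PBE": 0}
    # re-based coordinates, preserved distal gaps
    assert gap_distance(arch2.get("CPE3"), arch2.get("PAS1")) == 10


def test_truncate_full_length_is_identity(fixtures, patterns):
    rec, arch = fixtures["Btg4"].record, fixtures["Btg4"].architecture
    rec2, arch2 = truncate_distal(rec, arch, len(rec), patterns)
    assert rec2.sequence == rec.sequence
    assert arch2 == arch


def test_truncate_out_of_range(fixtures, patterns):
    rec, arch = fixtures["Btg4"].record, fixtures["Btg4"].architecture
    with pytest.raises(ValueError):
        truncate_distal(rec, arch, 0, patterns)
    with pytest.raises(ValueError):
        truncate_distal(rec, arch, len(rec) + 1, patterns)


# --- apply_construct and the packaged set -----------------------------------


def test_empty_edit_list_returns_base(fixtures):
    spec = ConstructSpec("Cpeb1-as-is", "Cpeb1")
    rec, arch, log = apply_construct(spec, fixtures)
    assert rec == fixtures["Cpeb1"].record
    assert arch == fixtures["Cpeb1"].architecture
    assert log


def test_conflicting_edits_error_cites_index(fixtures):
    spec = ConstructSpec(
        "bad", "Btg4", (EditOp("MUTATE_CPE", "CPE3"), EditOp("MUTATE_CPE", "CPE3"))
    )
    with pytest.raises(ValueError, match="edit 2"):
        apply_construct(spec, fixtures)


def test_unknown_base_errors(fixtures):
    with pytest.raises(KeyError, match="unknown base"):
        apply_construct(ConstructSpec("x", "Gdf9"), fixtures)


def test_packaged_construct_set_is_complete_and_applicable(fixtures):
    specs = enumerate_reporter_constructs()
    names = [s.name for s in specs]
    assert len(specs) >= 28
    assert len(set(names)) == len(names)
    for spec in specs:  # closure: every spec applies cleanly
        rec, arch, _ = apply_construct(spec, fixtures)
        assert len(rec) > 0


def test_apply_construct_is_deterministic(fixtures):
    spec = next(
        s for s in enumerate_reporter_constructs() if s.name == "Cpeb1-ΔPAS1/3+ΔCPE1-4"
    )
    a = apply_construct(spec, fixtures)
    b = apply_construct(spec, fixtures)
    assert a[0] == b[0] and a[1] == b[1]


def test_independent_edits_commute(fixtures):
    fwd = ConstructSpec("f", "Btg4", (EditOp("MUTATE_CPE", "CPE3"), EditOp("MUTATE_PAS", "PAS2")))
    rev = ConstructSpec("r", "Btg4", (EditOp("MUTATE_PAS", "PAS2"), EditOp("MUTATE_CPE", "CPE3")))
    _, aa, _ = apply_construct(fwd, fixtures)
    _, ab, _ = apply_construct(rev, fixtures)
    assert {(e.element_class, e.start, e.end) for e in aa.elements} == {
        (e.element_class, e.start, e.end) for e in ab.elements
    }


def test_mutations_never_create_other_motifs(fixtures, patterns):
    # global rescan counts of the untouched classes stay fixed across the set
    for spec in enumerate_reporter_constructs():
        base_counts = fixtures[spec.base].architecture.counts()
        _, arch, _ = apply_construct(spec, fixtures)
        for cls in ("PAS", "CPE", "PBE"):
            assert arch.counts()[cls] <= base_counts[cls] + (
                1 if any(e.kind == "INSERT_CPE" for e in spec.edits) and cls == "CPE" else 0
            )


def test_key_construct_fates(fixtures, cfg):
    """Fate flips driven by single edits match the reporter outcomes."""
    by_name = {s.name: s for s in enumerate_reporter_constructs()}

    def fate(name):
        spec = by_name[name]
        _, arch, _ = apply_construct(spec, fixtures)
        return predict_profile(arch, cfg, reference=fixtures[spec.base].architecture).fate

    assert fate("Btg4-ΔCPE1/2/3") == "CONSTITUTIVE_GV"  # dormancy lifted
    assert fate("Cnot6l-ΔPAS1+ΔCPE4") == "GV_ACTIVE_BOOSTED"  # PAS2 freed
    assert fate("Cpeb1-ΔPAS1/2/3") == "INACTIVE"
    assert fate("Cnot6l-truncated-402") == "DORMANT_ACTIVATED"
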