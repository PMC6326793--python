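"""Rule engine: per-PAS classification, activities, fates, accessibility."""

from __future__ import annotations

import random

import pytest

from utrcode import (
    CisElement,
    CodeConfig,
    UtrArchitecture,
    classify_pas,
    cpsf_accessibility,
    gv_activity,
    pas_gv_activity,
    post_gvbd_activity,
    predict_profile,
)
from utrcode.engine import FLANKED, FREE, ONE_SIDED, PasContext


def arch_from_gaps(*placed: tuple[str, int], length: int | None = None) -> UtrArchitecture:
    """Tiny helper: elements given as (class, start); PAS=6 nt, CPE=7 nt."""
    sizes = {"PAS": 6, "CPE": 7, "PBE": 8}
    els = [CisElement(c, s, s + sizes[c]) for c, s in placed]
    n = length or (max(e.end for e in els) + 20)
    labeled = []
    counters = {"PAS": 0, "CPE": 0, "PBE": 0}
    for el in sorted(els, key=lambda e: e.start):
        counters[el.element_class] += 1
        labeled.append(
            CisElement(el.element_class, el.start, el.end,
                       label=f"{el.element_class}{counters[el.element_class]}")
        )
    return UtrArchitecture("toy", n, tuple(labeled))


# --- classification ---------------------------------------------------------


def test_cpeb1_fixture_calls(fixtures, cfg):
    arch = fixtures["Cpeb1"].architecture
    calls = {p.label: classify_pas(arch, p, cfg).call for p in arch.pas}
    assert calls == {"PAS1": FREE, "PAS2": FLANKED, "PAS3": FREE}


@pytest.mark.parametrize(
    "gap,expected",
    [(35, ONE_SIDED), (50, FREE), (40, ONE_SIDED), (41, FREE)],
    ids=["repressing-35", "free-50", "window-edge-in", "window-edge-out"],
)
def test_one_sided_window_boundary(cfg, gap, expected):
    arch = arch_from_gaps(("PAS", 10), ("CPE", 16 + gap))
    ctx = classify_pas(arch, arch.pas[0], cfg)
    assert ctx.call == expected


def test_flanked_requires_both_sides_within_flank_window(cfg):
    both = arch_from_gaps(("CPE", 0), ("PAS", 80), ("CPE", 150))
    assert classify_pas(both, both.pas[0], cfg).call == FLANKED  # gaps 73/64
    far_up = arch_from_gaps(("CPE", 0), ("PAS", 120), ("CPE", 160))
    assert classify_pas(far_up, far_up.pas[0], cfg).call == ONE_SIDED  # 113/34
    mid_only = arch_from_gaps(("PAS", 10), ("CPE", 66))  # gap 50 < w_flank
    assert classify_pas(mid_only, mid_only.pas[0], cfg).call == FREE


def test_classify_counts_and_nearest_gap(fixtures, cfg):
    arch = fixtures["Cpeb1"].architecture
    ctx = classify_pas(arch, arch.get("PAS2"), cfg)
    assert (ctx.n_up, ctx.n_down, ctx.nearest_gap) == (2, 2, 20)
    ctx1 = classify_pas(arch, arch.get("PAS1"), cfg)
    assert (ctx1.n_up, ctx1.n_down, ctx1.nearest_gap) == (0, 0, 386)


def test_classify_rejects_foreign_element(fixtures, cfg):
    arch = fixtures["Cpeb1"].architecture
    stray = CisElement("PAS", 0, 6, label="PASX")
    with pytest.raises(ValueError):
        classify_pas(arch, stray, cfg)


# --- per-PAS activity -------------------------------------------------------


@pytest.mark.parametrize(
    "call,n_down,n_down_one,gap,expected",
    [
        (FREE, 0, 0, None, 1.0),
        (FLANKED, 1, 1, 66, 0.0),
        (ONE_SIDED, 1, 1, 35, 0.5),
        (ONE_SIDED, 2, 2, 30, 0.25),
        (ONE_SIDED, 3, 3, 30, 0.0),
        (ONE_SIDED, 2, 1, 35, 0.5),  # 2nd CPE beyond w_one adds no repression
        (ONE_SIDED, 1, 1, 10, 0.0),  # occluded: nearest gap <= w_occlude
    ],
    ids=["free", "flanked", "one-cpe", "two-cpe", "three-cpe",
         "dose-counts-w-one-only", "occluded"],
)
def test_pas_gv_activity_rule(cfg, call, n_down, n_down_one, gap, expected):
    n_up = 1 if call == FLANKED else 0
    ctx = PasContext("PAS1", n_up, n_down, gap, call,
                     occluded=gap is not None and gap <= cfg.w_occlude,
                     n_down_one=n_down_one)
    assert pas_gv_activity(ctx, cfg) == expected


def test_activity_non_increasing_in_cpe_count(cfg):
    acts = [
        pas_gv_activity(
            PasContext("PAS1", 0, n, 35, ONE_SIDED, n_down_one=n), cfg
        )
        for n in range(1, 6)
    ]
    assert acts == sorted(acts, reverse=True)
    assert min(acts) >= 0.0


# --- transcript activity and normalization ---------------------------------


def test_wild_type_normalization_anchors(fixtures, cfg):
    cp = fixtures["Cpeb1"].architecture
    gv, _ = gv_activity(cp, cfg, reference=cp)
    assert gv == 1.0


def test_no_pas_architecture_scores_zero(cfg, caplog):
    arch = arch_from_gaps(("CPE", 10), ("CPE", 40))
    with caplog.at_level("WARNING"):
        gv, contexts = gv_activity(arch, cfg)
    assert gv == 0.0 and contexts == ()
    assert "no PAS" in caplog.text


def test_post_gvbd_stimulation_counts_flank_window_cpes(cfg):
    arch = arch_from_gaps(("CPE", 0), ("PAS", 30), ("CPE", 60))  # gaps 23/24
    post = post_gvbd_activity(arch, cfg)
    assert post == 1.0 + 2 * cfg.stim_per_cpe  # single PAS, 2 nearby CPEs


def test_stage_monotonicity_on_fixtures(fixtures, cfg):
    for fx in fixtures:
        arch = fx.architecture
        gv, _ = gv_activity(arch, cfg, reference=arch)
        post = post_gvbd_activity(arch, cfg, reference=arch)
        assert post >= gv


# --- fate assignment --------------------------------------------------------


def test_fixture_fates(fixtures, cfg):
    fates = {
        name: predict_profile(
            fixtures[name].architecture, cfg, reference=fixtures[name].architecture
        ).fate
        for name in fixtures.names()
    }
    assert fates == {
        "Cpeb1": "GV_ACTIVE_BOOSTED",
        "Btg4": "DORMANT_ACTIVATED",
        "Cnot6l": "GV_ACTIVE_BOOSTED",
    }


def test_degenerate_fates(cfg):
    lone = arch_from_gaps(("PAS", 50))
    p = predict_profile(lone, cfg)
    assert p.fate == "CONSTITUTIVE_GV"
    assert p.gv_activity == p.post_gvbd_activity == 1.0
    empty = UtrArchitecture("empty", 100, ())
    assert predict_profile(empty, cfg).fate == "INACTIVE"


def test_position_indifference_rigid_shift(cfg):
    base = arch_from_gaps(("PAS", 10), ("CPE", 51), ("CPE", 80), length=300)
    shifted = arch_from_gaps(("PAS", 110), ("CPE", 151), ("CPE", 180), length=400)
    pa, pb = predict_profile(base, cfg), predict_profile(shifted, cfg)
    assert (pa.gv_activity, pa.post_gvbd_activity, pa.fate) == (
        pb.gv_activity, pb.post_gvbd_activity, pb.fate,
    )


def test_adding_inwindow_cpe_never_raises_gv(cfg):
    rng = random.Random(7)
    for _ in range(50):
        pas_start = rng.randrange(120, 300)
        arch = arch_from_gaps(("PAS", pas_start), length=600)
        gv0, _ = gv_activity(arch, cfg)
        gap = rng.randrange(0, cfg.w_flank + 1)
        side = rng.choice([-1, 1])
        cpe_start = pas_start + 6 + gap if side > 0 else pas_start - gap - 7
        arch2 = arch_from_gaps(("PAS", pas_start), ("CPE", cpe_start), length=600)
        gv1, _ = gv_activity(arch2, cfg)
        assert gv1 <= gv0


# --- CPSF accessibility -----------------------------------------------------


def test_cpsf_accessibility_gv_and_post(fixtures, cfg):
    cp = fixtures["Cpeb1"].architecture
    assert not cpsf_accessibility(cp, cp.get("PAS2"), "GV", cfg)
    assert cpsf_accessibility(cp, cp.get("PAS1"), "GV", cfg).accessible
    assert cpsf_accessibility(cp, cp.get("PAS2"), "POST_GVBD", cfg).accessible
    cn = fixtures["Cnot6l"].architecture
    assert not cpsf_accessibility(cn, cn.get("PAS2"), "GV", cfg)  # occluded


def test_cpsf_partial_accessibility_one_sided(cfg):
    arch = arch_from_gaps(("PAS", 10), ("CPE", 51))  # one CPE at 35 nt
    acc = cpsf_accessibility(arch, arch.pas[0], "GV", cfg)
    assert acc.accessible and acc.partial


def test_cpsf_accessibility_rejects_bad_stage(fixtures, cfg):
    cp = fixtures["Cpeb1"].architecture
    with pytest.raises(ValueError, match="stage"):
        cpsf_accessibility(cp, cp.get("PAS1"), "MI", cfg)


# --- config validation ------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        {"w_one": 120},               # one-sided window beyond flank window
        {"w_occlude": 60},            # occlusion beyond one-sided window
        {"active_threshold": 0.0},
        {"dose_step": -0.1},
    ],
)
def test_config_invariants_enforced(kwargs):
    with pytest.raises(ValueError):
        CodeConfig(**kwargs)
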