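"""The combinatorial PAS/CPE code: per-PAS classification and stage-specific
translational activity.

Model summary
-------------
In a prophase-I-arrested (GV) oocyte, a PAS drives translation only if no
CPE sits close enough to mask it from CPSF4.  The engine encodes this with
three nested distance windows measured as edge-to-edge spacer lengths:

* ``w_flank`` (default 100 nt): a PAS with at least one CPE within this
  window on *each* side is FLANKED and fully repressed at GV.
* ``w_one`` (default 40 nt): a CPE within this window on exactly one side
  makes the PAS ONE_SIDED; repression is partial and dose-dependent.
* ``w_occlude`` (default 12 nt): a CPE essentially abutting the PAS fully
  occludes it regardless of side, silencing it at GV.

A one-sided CPE between ``w_one`` and ``w_flank`` does not repress on its
own (the conservative reading of the 50-nt spacer result).  After GVBD the
CPE-binding protein switches from repressor to stimulator: every PAS
becomes active and each nearby CPE adds ``stim_per_cpe`` to its output.
Activities are deterministic relative scores normalized to the reference
(wild-type) architecture's complement of GV-competent PASs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .scan import CisElement, UtrArchitecture, gap_distance

logger = logging.getLogger(__name__)

__all__ = [
    "CodeConfig",
    "PasContext",
    "TranslationProfile",
    "CpsfAccess",
    "classify_pas",
    "pas_gv_activity",
    "gv_activity",
    "post_gvbd_activity",
    "predict_profile",
    "cpsf_accessibility",
    "FREE",
    "ONE_SIDED",
    "FLANKED",
]

FREE = "FREE"
ONE_SIDED = "ONE_SIDED"
FLANKED = "FLANKED"

CONSTITUTIVE_GV = "CONSTITUTIVE_GV"
GV_ACTIVE_BOOSTED = "GV_ACTIVE_BOOSTED"
DORMANT_ACTIVATED = "DORMANT_ACTIVATED"
INACTIVE = "INACTIVE"


@dataclass(frozen=True)
class CodeConfig:
    """Tunable parameters of the combinatorial code (distances in nt).

    Defaults sit inside the brackets the reporter experiments pin down:
    one-sided repression acts at 35 nt but not at 50 nt (hence
    ``w_one=40``); flanked repression still acts at 66 nt (hence
    ``w_flank=100``); a single CPE at ~10 nt silences a PAS outright while
    15 nt leaves partial activity (hence ``w_occlude=12``).
    """

    w_one: int = 40
    w_flank: int = 100
    w_occlude: int = 12
    one_sided_penalty: float = 0.5
    dose_step: float = 0.25
    stim_per_cpe: float = 0.5
    active_threshold: float = 0.25
    #: GV calls for the validation report: PARTIAL is (partial_lo, partial_hi)
    partial_lo: float = 0.0
    partial_hi: float = 0.75

    def __post_init__(self) -> None:
        if not (0 <= self.w_occlude <= self.w_one <= self.w_flank):
            raise ValueError("require 0 <= w_occlude <= w_one <= w_flank")
        if min(self.one_sided_penalty, self.dose_step, self.stim_per_cpe) < 0:
            raise ValueError("weights must be >= 0")
        if not (0 < self.active_threshold < 1):
            raise ValueError("active_threshold must be in (0,1)")


@dataclass(frozen=True)
class PasContext:
    """Per-PAS summary of the CPE neighborhood at the GV stage."""

    pas_label: str
    n_up: int            # CPEs with gap <= w_flank upstream
    n_down: int          # CPEs with gap <= w_flank downstream
    nearest_gap: int | None  # nt to closest CPE anywhere on the UTR
    call: str            # FREE | ONE_SIDED | FLANKED
    occluded: bool = False  # nearest CPE within w_occlude
    n_up_one: int = 0    # CPEs with gap <= w_one upstream (repression dose)
    n_down_one: int = 0  # CPEs with gap <= w_one downstream

    @property
    def n_inwindow(self) -> int:
        return self.n_up + self.n_down

    @property
    def n_dose(self) -> int:
        return self.n_up_one + self.n_down_one


@dataclass(frozen=True)
class TranslationProfile:
    """Transcript-level prediction, wild-type-normalized relative units."""

    utr_id: str
    gv_activity: float
    post_gvbd_activity: float
    fate: str
    per_pas: tuple[PasContext, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class CpsfAccess:
    """CPSF4 accessibility of one PAS at one stage."""

    accessible: bool
    partial: bool = False  # accessible but partially repressed (one-sided)

    def __bool__(self) -> bool:
        return self.accessible


def _require_pas(arch: UtrArchitecture, pas: CisElement) -> None:
    if pas.element_class != "PAS" or pas not in arch.elements:
        raise ValueError(
            f"{arch.utr_id}: {pas.label or pas} is not a PAS of this architecture"
        )


def classify_pas(
    arch: UtrArchitecture, pas: CisElement, cfg: CodeConfig = CodeConfig()
) -> PasContext:
    """Classify one PAS by its CPE context.

    FLANKED: >= 1 CPE within ``w_flank`` on each side.  ONE_SIDED: exactly
    one side carries a CPE within ``w_one`` (and the other side none within
    ``w_flank``).  FREE otherwise, including CPEs present only beyond the
    applicable window.
    """
    _require_pas(arch, pas)
    n_up = n_down = n_up_one = n_down_one = 0
    nearest: int | None = None
    for cpe in arch.cpe:
        gap = gap_distance(pas, cpe) if not pas.overlaps(cpe) else 0
        nearest = gap if nearest is None else min(nearest, gap)
        upstream = cpe.start < pas.start
        if gap <= cfg.w_flank:
            if upstream:
                n_up += 1
                n_up_one += gap <= cfg.w_one
            else:
                n_down += 1
                n_down_one += gap <= cfg.w_one
    if n_up >= 1 and n_down >= 1:
        call = FLANKED
    elif n_up_one or n_down_one:
        call = ONE_SIDED
    else:
        call = FREE
    occluded = nearest is not None and nearest <= cfg.w_occlude
    return PasContext(
        pas_label=pas.label or "PAS?",
        n_up=n_up,
        n_down=n_down,
        nearest_gap=nearest,
        call=call,
        occluded=occluded,
        n_up_one=n_up_one,
        n_down_one=n_down_one,
    )


def pas_gv_activity(ctx: PasContext, cfg: CodeConfig = CodeConfig()) -> float:
    """GV-stage activity of one PAS in [0, 1].

    FREE -> 1.  FLANKED -> 0.  An occluding CPE (gap <= ``w_occlude``)
    -> 0 regardless of side.  ONE_SIDED -> ``max(0, 1 - one_sided_penalty
    - dose_step * (n_dose - 1))`` where ``n_dose`` counts the CPEs inside
    the one-sided repression window ``w_one``; non-increasing in the
    number of repressing CPEs.
    """
    if ctx.call == FREE:
        return 1.0
    if ctx.call == FLANKED or ctx.occluded:
        return 0.0
    return max(
        0.0, 1.0 - cfg.one_sided_penalty - cfg.dose_step * (max(ctx.n_dose, 1) - 1)
    )


def _contexts(arch: UtrArchitecture, cfg: CodeConfig) -> tuple[PasContext, ...]:
    return tuple(classify_pas(arch, p, cfg) for p in arch.pas)


def _denominator(
    arch: UtrArchitecture, cfg: CodeConfig, reference: UtrArchitecture | None
) -> int:
    """Normalizing PAS count.

    With a reference (the unedited construct backbone): the number of PASs
    that are GV-competent (nonzero activity) there; if the reference has
    none (fully dormant transcripts), fall back to its total PAS count.
    Stand-alone: the architecture's own PAS count, i.e. every PAS counted
    at full freedom — stable under CPE edits, which keeps activity
    monotone in repression.
    """
    ref = reference if reference is not None else arch
    n_total = len(ref.pas)
    if n_total == 0:
        return 1
    if reference is None:
        return n_total
    n_comp = sum(
        1 for c in _contexts(ref, cfg) if pas_gv_activity(c, cfg) > 0
    )
    return n_comp if n_comp > 0 else n_total


def gv_activity(
    arch: UtrArchitecture,
    cfg: CodeConfig = CodeConfig(),
    reference: UtrArchitecture | None = None,
) -> tuple[float, tuple[PasContext, ...]]:
    """Transcript GV activity plus per-PAS detail.

    PAS contributions are additive and equal; the sum is divided by the
    reference architecture's GV-competent PAS count (see
    :func:`_denominator`), anchoring a single free PAS of a two-competent-
    PAS transcript at 0.5.  No PAS -> 0.0 with a logged warning.
    """
    contexts = _contexts(arch, cfg)
    if not contexts:
        logger.warning("%s: no PAS in architecture; GV activity is 0", arch.utr_id)
        return 0.0, contexts
    total = sum(pas_gv_activity(c, cfg) for c in contexts)
    return total / _denominator(arch, cfg, reference), contexts


def post_gvbd_activity(
    arch: UtrArchitecture,
    cfg: CodeConfig = CodeConfig(),
    reference: UtrArchitecture | None = None,
) -> float:
    """Transcript activity after GVBD (MII endpoint).

    Every PAS becomes accessible (base activity 1) and gains
    ``stim_per_cpe`` per CPE within ``w_flank``; normalization as in
    :func:`gv_activity`.  Always >= the GV activity of the same
    architecture under the same config.
    """
    contexts = _contexts(arch, cfg)
    if not contexts:
        return 0.0
    total = sum(1.0 + cfg.stim_per_cpe * c.n_inwindow for c in contexts)
    return total / _denominator(arch, cfg, reference)


def predict_profile(
    arch: UtrArchitecture,
    cfg: CodeConfig = CodeConfig(),
    reference: UtrArchitecture | None = None,
    modifiers: tuple = (),
) -> TranslationProfile:
    """Transcript-level prediction: activities at both stages plus a fate.

    Fates: CONSTITUTIVE_GV (active at GV, no PAS near any CPE),
    GV_ACTIVE_BOOSTED (active at GV with at least one CPE-adjacent PAS, so
    translation strengthens after GVBD), DORMANT_ACTIVATED (silent at GV,
    active after GVBD), INACTIVE otherwise.

    ``modifiers`` is a hook for future element types (e.g. PBE-dependent
    effects): callables ``(arch, cfg, profile) -> profile`` applied in
    order.  The default rule set attaches no PBE effect.
    """
    gv, contexts = gv_activity(arch, cfg, reference)
    post = post_gvbd_activity(arch, cfg, reference)
    any_inwindow = any(c.n_inwindow > 0 for c in contexts)
    if gv >= cfg.active_threshold and not any_inwindow:
        fate = CONSTITUTIVE_GV
    elif gv >= cfg.active_threshold:
        fate = GV_ACTIVE_BOOSTED
    elif post >= cfg.active_threshold:
        fate = DORMANT_ACTIVATED
    else:
        fate = INACTIVE
    profile = TranslationProfile(
        utr_id=arch.utr_id,
        gv_activity=gv,
        post_gvbd_activity=post,
        fate=fate,
        per_pas=contexts,
    )
    for mod in modifiers:
        profile = mod(arch, cfg, profile)
    return profile


def cpsf_accessibility(
    arch: UtrArchitecture,
    pas: CisElement,
    stage: str,
    cfg: CodeConfig = CodeConfig(),
) -> CpsfAccess:
    """Whether CPSF4 can engage a PAS at a given stage.

    At GV a PAS is accessible iff it is FREE, or ONE_SIDED with residual
    activity > 0 (reported as partial).  After GVBD every PAS is
    accessible.
    """
    _require_pas(arch, pas)
    if stage not in ("GV", "POST_GVBD"):
        raise ValueError(f"stage must be GV or POST_GVBD, got {stage!r}")
    if stage == "POST_GVBD":
        return CpsfAccess(accessible=True)
    ctx = classify_pas(arch, pas, cfg)
    act = pas_gv_activity(ctx, cfg)
    if ctx.call == FREE:
        return CpsfAccess(accessible=True)
    if ctx.call == ONE_SIDED and act > 0:
        return CpsfAccess(accessible=True, partial=True)
    return CpsfAccess(accessible=False)
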