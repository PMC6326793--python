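"""Score engine predictions against the packaged observed outcomes.

`evaluate` rebuilds every packaged construct, predicts its translational
profile, maps the predicted GV activity onto the observed three-level
scale (SILENT: exactly 0; ACTIVE: >= the upper partial bound, default
0.75; PARTIAL: in between) and the predicted GV->MII change onto a
direction, and reports per-construct concordance.  `calibrate_external`
runs the element scanner over user-supplied real 3'-UTR sequences so the
default motif set can be compared against known element counts; it is
optional and the package bundles no external sequences.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from .engine import CodeConfig, predict_profile
from .motifs import MotifPattern, default_patterns
from .mutate import ConstructSpec, apply_construct, enumerate_reporter_constructs
from .scan import build_architecture, gap_distance, scan_motifs
from .synth import FixtureSet, bundled_fixtures
from .truth_table import NA, OBSERVED_OUTCOMES, TruthTableEntry

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordanceReport",
    "observed_truth_table",
    "gv_call",
    "mii_direction",
    "evaluate",
    "CalibrationResult",
    "calibrate_external",
]


def observed_truth_table() -> list[TruthTableEntry]:
    """The packaged observed-outcome table, one entry per construct."""
    return list(OBSERVED_OUTCOMES)


def gv_call(activity: float, cfg: CodeConfig) -> str:
    """Map a predicted relative GV activity onto the observed scale."""
    if activity == 0:
        return "SILENT"
    if activity >= cfg.partial_hi:
        return "ACTIVE"
    return "PARTIAL"


def mii_direction(gv: float, post: float, tol: float = 1e-9) -> str:
    """Predicted GV->MII direction of change for one construct."""
    if post > gv + tol:
        return "UP"
    if post < gv - tol:
        return "DOWN"
    return "UNCHANGED"


@dataclass(frozen=True)
class ConcordanceReport:
    """Per-construct prediction-vs-observation comparison."""

    n_constructs: int
    n_concordant: int           # GV-stage call agreement
    n_mii_scored: int
    n_mii_concordant: int
    rows: pd.DataFrame
    mismatches: tuple[str, ...] = field(default_factory=tuple)

    @property
    def concordance(self) -> float:
        return self.n_concordant / self.n_constructs if self.n_constructs else 0.0

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def evaluate(
    cfg: CodeConfig = CodeConfig(),
    fixtures: FixtureSet | None = None,
    constructs: list[ConstructSpec] | None = None,
    truth: list[TruthTableEntry] | None = None,
    patterns: list[MotifPattern] | None = None,
) -> ConcordanceReport:
    """Rebuild every construct, predict, and score against observations.

    Deterministic for a fixed config: two runs produce identical reports.
    Raises ``KeyError`` naming any construct that lacks a truth-table entry
    or fixture.
    """
    fixtures = bundled_fixtures(patterns) if fixtures is None else fixtures
    constructs = enumerate_reporter_constructs() if constructs is None else constructs
    truth = observed_truth_table() if truth is None else truth
    observed = {t.construct_name: t for t in truth}
    if not constructs:
        logger.warning("evaluate: empty construct list; nothing to score")
    rows = []
    mismatches = []
    for spec in constructs:
        if spec.name not in observed:
            raise KeyError(f"no observed outcome for construct {spec.name!r}")
        _, arch, _ = apply_construct(spec, fixtures, patterns)
        ref = fixtures[spec.base].architecture
        profile = predict_profile(arch, cfg, reference=ref)
        obs = observed[spec.name]
        pred_gv = gv_call(profile.gv_activity, cfg)
        # repression state of the construct: any PAS not fully free at GV
        pred_repr = (
            "REPRESSED"
            if any(c.call != "FREE" or c.occluded for c in profile.per_pas)
            else "NOT_REPRESSED"
        )
        gv_ok = pred_gv == obs.observed_gv and (
            obs.observed_repression == NA or pred_repr == obs.observed_repression
        )
        pred_mii = mii_direction(profile.gv_activity, profile.post_gvbd_activity)
        mii_scored = obs.observed_post_gvbd != NA
        mii_ok = (pred_mii == obs.observed_post_gvbd) if mii_scored else None
        if not gv_ok:
            mismatches.append(
                f"{spec.name} [{obs.panel}]: predicted {pred_gv}/{pred_repr} "
                f"(activity {profile.gv_activity:.3f}), observed {obs.observed_gv}"
                f"{'' if obs.observed_repression == NA else '/' + obs.observed_repression}"
                f" ({obs.basis})"
            )
        rows.append(
            {
                "construct": spec.name,
                "base": spec.base,
                "gv_activity": profile.gv_activity,
                "post_gvbd_activity": profile.post_gvbd_activity,
                "fate": profile.fate,
                "per_pas": ";".join(
                    f"{c.pas_label}:{c.call}" for c in profile.per_pas
                ),
                "predicted_gv": pred_gv,
                "observed_gv": obs.observed_gv,
                "predicted_repression": pred_repr,
                "observed_repression": obs.observed_repression,
                "gv_concordant": gv_ok,
                "predicted_mii": pred_mii,
                "observed_mii": obs.observed_post_gvbd,
                "mii_concordant": mii_ok,
                "panel": obs.panel,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "construct", "base", "gv_activity", "post_gvbd_activity", "fate",
            "per_pas", "predicted_gv", "observed_gv", "predicted_repression",
            "observed_repression", "gv_concordant",
            "predicted_mii", "observed_mii", "mii_concordant", "panel",
        ],
    )
    scored = [r for r in rows if r["mii_concordant"] is not None]
    return ConcordanceReport(
        n_constructs=len(rows),
        n_concordant=sum(r["gv_concordant"] for r in rows),
        n_mii_scored=len(scored),
        n_mii_concordant=sum(r["mii_concordant"] for r in scored),
        rows=df,
        mismatches=tuple(mismatches),
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Element counts on user-supplied real 3'-UTRs, or a skip notice."""

    skipped: bool
    message: str
    table: pd.DataFrame | None = None


def calibrate_external(
    fasta_path: str | os.PathLike | None,
    patterns: list[MotifPattern] | None = None,
) -> CalibrationResult:
    """Per-UTR PAS/CPE/PBE counts and nearest-CPE gaps on real sequences.

    The package bundles no genomic sequences; when ``fasta_path`` is None
    or missing this returns a skip notice rather than failing, keeping the
    default build download-free.
    """
    if fasta_path is None or not os.path.exists(fasta_path):
        return CalibrationResult(
            skipped=True,
            message=(
                "external calibration skipped: no 3'-UTR FASTA supplied "
                "(pass a file with real Cpeb1/Btg4/Cnot6l 3'-UTR sequences "
                "to compare element counts against the default motif set)"
            ),
        )
    from .io import read_utr_fasta

    patterns = default_patterns() if patterns is None else patterns
    rows = []
    for rec in read_utr_fasta(fasta_path):
        arch = build_architecture(rec, scan_motifs(rec, patterns))
        counts = arch.counts()
        for pas in arch.pas:
            gaps = [gap_distance(pas, c) for c in arch.cpe if not pas.overlaps(c)]
            rows.append(
                {
                    "utr_id": rec.id,
                    "utr_length": len(rec),
                    "n_pas": counts["PAS"],
                    "n_cpe": counts["CPE"],
                    "n_pbe": counts["PBE"],
                    "pas_label": pas.label,
                    "nearest_cpe_gap": min(gaps) if gaps else None,
                }
            )
        if not arch.pas:
            rows.append(
                {
                    "utr_id": rec.id,
                    "utr_length": len(rec),
                    "n_pas": 0,
                    "n_cpe": counts["CPE"],
                    "n_pbe": counts["PBE"],
                    "pas_label": None,
                    "nearest_cpe_gap": None,
                }
            )
    return CalibrationResult(
        skipped=False,
        message=f"scanned {len(set(r['utr_id'] for r in rows))} UTR(s)",
        table=pd.DataFrame(rows),
    )
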