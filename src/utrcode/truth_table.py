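"""Observed translational outcomes for the packaged reporter constructs.

Each entry records the qualitative outcome of one GFP-reporter
microinjection experiment on the corresponding 3'-UTR construct in mouse
oocytes, transcribed onto a three-level GV-stage scale plus a GV->MII
direction:

* ``observed_gv``: ACTIVE (translated at roughly wild-type level),
  PARTIAL (clearly translated but reduced — includes the single-free-PAS
  constructs reported at 40-50% of wild type and "partially de-repressed"
  CPE mutants), SILENT (no detectable reporter signal; includes CPE
  mutants described as only marginally de-repressed).
* ``observed_post_gvbd``: the construct's own GV->MII direction (UP /
  DOWN / UNCHANGED) where the experiment followed maturation, else NA.
* ``observed_repression``: for the spacing-series experiments, whose
  readout is specifically whether the focal PAS is repressed by the
  nearby CPE, REPRESSED / NOT_REPRESSED; NA elsewhere.

Levels are relative to each gene's own wild-type reporter.  ``panel``
names the experiment family; ``basis`` paraphrases the reported outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TruthTableEntry", "OBSERVED_OUTCOMES"]

ACTIVE, PARTIAL, SILENT = "ACTIVE", "PARTIAL", "SILENT"
UP, DOWN, UNCHANGED, NA = "UP", "DOWN", "UNCHANGED", "NA"
REPRESSED, NOT_REPRESSED = "REPRESSED", "NOT_REPRESSED"


@dataclass(frozen=True)
class TruthTableEntry:
    construct_name: str
    observed_gv: str
    observed_post_gvbd: str
    panel: str
    basis: str
    observed_repression: str = NA

    def __post_init__(self) -> None:
        if self.observed_gv not in (ACTIVE, PARTIAL, SILENT):
            raise ValueError(f"bad observed_gv {self.observed_gv!r}")
        if self.observed_post_gvbd not in (UP, DOWN, UNCHANGED, NA):
            raise ValueError(f"bad observed_post_gvbd {self.observed_post_gvbd!r}")
        if self.observed_repression not in (REPRESSED, NOT_REPRESSED, NA):
            raise ValueError(f"bad observed_repression {self.observed_repression!r}")
        if not self.panel:
            raise ValueError("panel must be non-empty")


def _e(name, gv, mii, panel, basis, repression=NA):
    return TruthTableEntry(name, gv, mii, panel, basis, repression)


_P_PAS1 = "Cpeb1 PAS single mutants"
_P_PASC = "Cpeb1 PAS combinations"
_P_CPEW = "Cpeb1 CPE mutants, full backbone"
_P_CPE2 = "Cpeb1 CPE mutants, PAS2-only backbone"
_P_SPAC = "Cpeb1 spacing series, PAS1-only backbone"
_P_PBE = "Cpeb1 PBE deletion"
_P_BTG = "Btg4 CPE series"
_P_CNOT = "Cnot6l PAS/CPE series"

OBSERVED_OUTCOMES: tuple[TruthTableEntry, ...] = (
    _e("Cpeb1-WT", ACTIVE, UP, _P_PAS1,
       "wild-type 3'-UTR translated at GV; translation rises further after release into maturation"),
    _e("Cpeb1-ΔPAS3", PARTIAL, NA, _P_PAS1,
       "distal-PAS knockout still translated, at the reduced single-free-PAS level"),
    _e("Cpeb1-ΔPAS1", PARTIAL, NA, _P_PAS1,
       "proximal-PAS knockout clearly reduced; distal PAS carries residual translation"),
    _e("Cpeb1-ΔPAS2", ACTIVE, NA, _P_PAS1,
       "middle-PAS knockout leaves GV translation unaffected"),
    _e("Cpeb1-ΔPAS2/3", PARTIAL, NA, _P_PASC,
       "PAS1 alone maintains 40-50% of wild-type GV activity"),
    _e("Cpeb1-ΔPAS1/2", PARTIAL, NA, _P_PASC,
       "PAS3 alone maintains 40-50% of wild-type GV activity"),
    _e("Cpeb1-ΔPAS1/3", SILENT, UP, _P_PASC,
       "PAS2 alone does not support GV translation; activated after meiotic resumption"),
    _e("Cpeb1-ΔPAS1/2/3", SILENT, NA, _P_PASC,
       "all PASs mutated: reporter no longer translated"),
    _e("Cpeb1-ΔCPE1-4", ACTIVE, NA, _P_CPEW,
       "removing all CPEs slightly raises GV translation (still at/above wild-type level)"),
    _e("Cpeb1-ΔPAS1/3+ΔCPE1-4", PARTIAL, NA, _P_CPE2,
       "removing the flanking CPEs restores PAS2-driven translation at single-PAS level"),
    _e("Cpeb1-ΔCPE1/2", PARTIAL, NA, _P_CPE2,
       "removing the two same-side CPEs partially de-represses PAS2"),
    _e("Cpeb1-ΔCPE2/4", SILENT, NA, _P_CPE2,
       "removing one CPE from each side leaves PAS2 flanked; de-repression marginal"),
    _e("Cpeb1-ΔPAS2/3+ΔCPE1-4", PARTIAL, UNCHANGED, _P_CPE2,
       "CPE removal does not change PAS1-driven translation at either stage"),
    _e("Cpeb1-spacer-50", PARTIAL, NA, _P_SPAC,
       "50-nt spacer to the nearest CPE leaves PAS1-driven translation unaffected",
       NOT_REPRESSED),
    _e("Cpeb1-spacer-35", PARTIAL, NA, _P_SPAC,
       "35-nt spacer: PAS1-driven translation impaired", REPRESSED),
    _e("Cpeb1-spacer-15", PARTIAL, NA, _P_SPAC,
       "15-nt spacer: PAS1-driven translation impaired", REPRESSED),
    _e("Cpeb1-CPE-insert-35", PARTIAL, NA, _P_SPAC,
       "extra CPE inserted 35 nt downstream of PAS1 markedly inhibits translation",
       REPRESSED),
    _e("Cpeb1-CPE-insert-50", PARTIAL, NA, _P_SPAC,
       "extra CPE inserted 50 nt downstream of PAS1 has no inhibitory effect",
       NOT_REPRESSED),
    _e("Cpeb1-ΔPBE", ACTIVE, UP, _P_PBE,
       "PBE deletion does not prevent GV translation or the post-GVBD increase"),
    _e("Btg4-WT", SILENT, UP, _P_BTG,
       "wild-type 3'-UTR dormant at GV, activated after meiotic resumption"),
    _e("Btg4-ΔCPE1", SILENT, NA, _P_BTG,
       "single upstream-CPE knockout: de-repression marginal, PASs remain flanked"),
    _e("Btg4-ΔCPE2", SILENT, NA, _P_BTG,
       "single upstream-CPE knockout: de-repression marginal, PASs remain flanked"),
    _e("Btg4-ΔCPE3", ACTIVE, NA, _P_BTG,
       "downstream-CPE knockout un-flanks the PASs: significant de-repression"),
    _e("Btg4-ΔCPE1/3", ACTIVE, NA, _P_BTG,
       "double knockout: further de-repression (dose-dependent series)"),
    _e("Btg4-ΔCPE1/2", ACTIVE, NA, _P_BTG,
       "double knockout: further de-repression (dose-dependent series)"),
    _e("Btg4-ΔCPE1/2/3", ACTIVE, NA, _P_BTG,
       "triple knockout: full de-repression at GV"),
    _e("Cnot6l-WT", ACTIVE, NA, _P_CNOT,
       "full-length 3'-UTR translated in GV oocytes (proximal PAS1-driven)"),
    _e("Cnot6l-ΔPAS1", SILENT, UP, _P_CNOT,
       "PAS1 knockout nearly abolishes GV translation; restored after resumption"),
    _e("Cnot6l-ΔPAS2", ACTIVE, NA, _P_CNOT,
       "PAS2 knockout does not affect GV translation"),
    _e("Cnot6l-ΔPAS1+ΔCPE4", ACTIVE, NA, _P_CNOT,
       "removing the closely adjacent CPE4 restores PAS2-driven translation"),
    _e("Cnot6l-ΔPAS1+ΔCPE2/3", SILENT, NA, _P_CNOT,
       "removing the distant CPE2/CPE3 fails to relieve PAS2 dormancy"),
    _e("Cnot6l-truncated-402", SILENT, UP, _P_CNOT,
       "distal 402-nt fragment dormant at GV, activated after resumption"),
)
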