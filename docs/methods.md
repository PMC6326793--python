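# Methods

## The biological model

In prophase-I-arrested (GV) mouse oocytes, translation of a stored
maternal mRNA requires de-novo cytoplasmic polyadenylation nucleated at a
polyadenylation signal (PAS) by the CPSF complex; CPSF4 is the subunit
that contacts the hexamer.  A cytoplasmic polyadenylation element (CPE)
recruits CPEB1, which masks a *nearby* PAS from CPSF4.  After germinal
vesicle breakdown (GVBD) the MAPK cascade phosphorylates and partially
degrades CPEB1 and the CPE switches from repressor to stimulator of
polyadenylation.  Two findings shape the rule set: (i) proximal PASs are
as effective as the 3′-most PAS — polyadenylation does not require the
PAS to sit at the end of the UTR — and (ii) repression is a function of
CPE–PAS spacing and CPE count, not of CPE presence per se.

The engine models the GV→MII transition as a discrete stage switch (the
endpoint of CPEB1 phosphorylation/degradation), not as kinetics, because
the underlying measurements are endpoint reporter intensities.  All
activities are deterministic relative scores; the package's stochasticity
lives entirely in the synthetic-sequence generator.

## Per-PAS classification and activity

Distances are edge-to-edge spacer lengths in nucleotides (`gap_distance`:
`downstream.start − upstream.end`; adjacent motifs have gap 0).  For a
PAS with CPE neighborhoods counted per side:

| call | condition | GV activity |
|---|---|---|
| FLANKED | ≥1 CPE with gap ≤ `w_flank` on each side | 0 |
| occluded | nearest CPE gap ≤ `w_occlude` (either side) | 0 |
| ONE_SIDED | ≥1 CPE with gap ≤ `w_one` on exactly one side | max(0, 1 − π − δ·(n₁ − 1)) |
| FREE | otherwise | 1 |

with `n₁` = number of CPEs inside `w_one` on the occupied side.  A CPE
between `w_one` and `w_flank` on one side only does not repress (the
conservative reading of the 50-nt spacer result); it still counts toward
flanking when the other side is occupied, and toward post-GVBD
stimulation.

CPSF4 accessibility mirrors activity: at GV a PAS is accessible iff FREE,
or ONE_SIDED with residual activity (reported as partial); after GVBD
every PAS present in the sequence is accessible; a mutated PAS no longer
exists in the architecture and is never accessible.

## Parameters (CodeConfig)

| parameter | default | unit | why |
|---|---|---|---|
| `w_one` | 40 | nt | one-sided repression acts at a 35-nt spacer, not at 50 nt; the default sits between the brackets |
| `w_flank` | 100 | nt | flanked repression still acts at 66 nt (near flank of the Btg4 PAS pair) and must cover the pair's far flank (≤ 99 nt in the packaged geometry) |
| `w_occlude` | 12 | nt | a single CPE ~10 nt from a PAS silences it outright (Cnot6l CPE4–PAS2), while a 15-nt spacer leaves partial activity; the default sits between those brackets |
| `one_sided_penalty` π | 0.5 | – | "partially de-repressed" one-sided outcomes; calibration knob |
| `dose_step` δ | 0.25 | – | graded multi-CPE repression; calibration knob |
| `stim_per_cpe` | 0.5 | – | post-GVBD boost per nearby CPE; magnitudes after GVBD are not claimed quantitative |
| `active_threshold` | 0.25 | – | minimum relative activity to call a transcript GV-active |
| `partial_hi` | 0.75 | – | GV-call mapping: ACTIVE ≥ 0.75, PARTIAL (0, 0.75), SILENT = 0 |

The repression **dose** counts CPEs inside `w_one`, not `w_flank`: the
distance data show that a CPE beyond the one-sided window contributes no
repression on its own, and counting it would make the scored outcomes
depend on the flanking window in ways the experiments contradict (a
wider `w_flank` would spuriously deepen one-sided repression).

The occlusion window is this package's one extension beyond a pure
two-window scheme.  A count-based one-sided formula is monotone in CPE
number, so it cannot make a *single* CPE fully silencing while *two* CPEs
leave partial activity — yet that is exactly what the data show when the
single CPE abuts the PAS (full dormancy at ~10 nt, partial impairment at
15–35 nt).  Occlusion encodes steric masking of CPSF4 by an abutting
CPEB1 footprint and silences the PAS at any dose.

## Transcript-level scores and fates

PAS contributions are additive and equal.  GV activity is the per-PAS sum
divided by the number of GV-competent PASs (nonzero activity) in the
wild-type reference architecture; this anchors the single-free-PAS
constructs at 0.5 of a two-competent-PAS wild type, matching the reported
40–50%.  A fully dormant reference (no competent PAS, e.g. Btg4) falls
back to its total PAS count, which is also the stand-alone normalization
(every PAS counted at full freedom) — chosen because it is stable under
CPE edits and keeps activity monotone in repression.  An alternative
max-over-PAS rule was rejected: it cannot express the ~50% single-PAS
level.

Post-GVBD, every PAS scores 1 + `stim_per_cpe`·(CPEs within `w_flank`),
same normalization; hence post ≥ GV for every architecture and config.

Fates: `CONSTITUTIVE_GV` (GV ≥ threshold, no PAS has any CPE within
`w_flank`), `GV_ACTIVE_BOOSTED` (GV ≥ threshold with ≥1 CPE-adjacent
PAS), `DORMANT_ACTIVATED` (GV < threshold, post ≥ threshold), `INACTIVE`
otherwise (in practice: no PAS, or a construct stripped of nearly all
reference activity).

## The packaged fixtures

`bundled_fixtures()` realizes the three UTR architectures over seeded,
motif-free backgrounds (GC 0.40, AT-rich and UTR-like; irrelevant to the
rules, fixed for reproducibility).  Constraints that are experimentally
stated and asserted exactly by the tests: Cpeb1 3 PAS + 4 CPE with
PAS1→CPE1 = 386 nt and CPE4→PAS3 = 228 nt and PAS2 inside the CPE
cluster; Btg4 2 PAS + 3 CPE with near flanks at 66 nt on both sides of
the close PAS pair; Cnot6l 1597 nt, 2 PAS + 4 CPE, CPE4→PAS2 = 10 nt
("closely adjacent"), CPE2/CPE3 upstream beyond `w_one`, and the distal
402 nt containing exactly CPE2–4 + PAS2.  Every other coordinate
(offsets, inter-CPE gaps, the Btg4 PAS1–PAS2 gap of 10 nt, the PBE
position, seeds) is a reconstructed filler value, commented as such in
`synth.py`; tests assert only the stated constraints, never the filler.

The generator fills background positions left-to-right, rejecting any
base that would complete a motif window touching the background
(including windows straddling motif junctions), so planted sequences
rescan to exactly the planted elements with no retries.  Randomness uses
the stdlib Mersenne generator with integer draws only, keyed by the
spec's seed, for cross-platform determinism.

What the synthetic data does *not* emulate: real UTR base composition
beyond GC content, RNA secondary structure, non-consensus/weak element
variants, and fluorescence/gel readouts.  Passing tests therefore show
that the code's geometry logic is implemented faithfully — not that the
windows generalize beyond the three measured UTRs.

## In-silico mutagenesis

Edits rewrite the sequence and re-verify by rescan that exactly the
intended element change occurred (untouched elements keep coordinates or
shift rigidly; no motif is gained or lost elsewhere).  PAS knockout is
the published AATAAA→AAGGAA substitution.  The CPE substitution used in
the original experiments is unpublished; this package uses T→G at the
three central positions (length-preserving, deterministic), with a fixed
scramble fallback, and the edit log flags these as reconstructed.  Spacer
deletions remove interior nucleotides centered on the spacer midpoint,
shifting the window base-by-base if a junction would form a motif;
insertions use the canonical heptamer TTTTAAT and normalize a flanking
background base to C if a junction would extend the motif.  Element
labels are positional and re-evaluated after every edit, so the packaged
constructs list highest ordinals first.

## Validation against observed outcomes

The truth table transcribes each reporter experiment onto a three-level
GV scale (ACTIVE / PARTIAL / SILENT, relative to that gene's wild-type
reporter), a GV→MII direction (UP / DOWN / UNCHANGED / NA) recorded only
where the experiment followed maturation, and — for the spacing series,
whose readout is specifically repression of the focal PAS — a
REPRESSED / NOT_REPRESSED state.  Transcription conventions: "marginal
de-repression" → SILENT; "partially de-repressed"/"impaired" → PARTIAL;
"significant"/"full de-repression" → ACTIVE; single-free-PAS constructs
→ PARTIAL (the 40–50% anchor).  Ordinal relations the experiments report
within a dose series (single < double < triple knockout) are noted in
the `basis` strings but not forced onto the three-level scale.

`evaluate()` scores a construct concordant when the predicted GV call
matches and, where a repression state is recorded, the predicted per-PAS
repression matches too.  With default parameters all packaged constructs
are concordant, and the property suite shows concordance is stable for
`w_one` ∈ [36, 49] and `w_flank` ∈ [99, 200].  The `w_flank` floor is
geometric: the far flank of the Btg4 PAS pair sits at up to 99 nt in the
packaged architecture, so any narrower flanking window un-flanks a
single-CPE mutant that the experiments show still repressed.

External calibration against real mouse 3′-UTR sequences is an optional,
user-supplied path (`calibrate_external`); the package bundles no
genomic sequences and skips cleanly without them.

## Numerical and degenerate-input choices

Activities are exact binary fractions (sums of quarters), so SILENT is an
exact `== 0` comparison.  Window boundaries are inclusive (gap ≤ window).
Zero-PAS architectures score 0 with a logged warning; empty construct
lists produce an empty report with a warning; unknown labels, overlapping
targets, out-of-range truncations and impossible spacer deletions raise
with the construct name and 1-based edit index.  Overlapping same-class
matches merge into one element (the code counts discrete elements);
cross-class overlaps are kept separate, and an overlapping CPE–PAS pair
is treated as gap 0.

## Problem sizes

The packaged suites use the sizes the artifact itself ships: 32
constructs, 100 seeded synthetic sequences (≤ 2 kb) for scanner/oracle
identity, and 200 random architectures for the monotonicity laws — ample
for exact combinatorial checks of a deterministic rule set.

## Known limitations

The windows are calibrated on three UTRs; real regulatory spacing varies
between transcripts, and UTR tertiary structure (not modeled) likely
contributes.  Post-GVBD magnitudes are not quantitative.  The PBE is
annotate-only (its deletion has no effect in the measured UTR); a
`modifiers` hook on `predict_profile` exists for attaching future
element effects.  Alternative polyadenylation, genome-wide UTR
extraction, and read-based poly(A) calling are out of scope.
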