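# utrcode

**The combinatorial 3′-UTR code for maternal-mRNA translational control in
mouse oocytes, as a scanner + rule-based predictor.**

Fully grown mammalian oocytes are transcriptionally silent: meiotic
maturation runs entirely on stored maternal mRNAs whose translation is
switched on and off by *cis*-elements in their 3′-UTRs.  Two elements do
most of the work — the **polyadenylation signal** (PAS, hexamer AAUAAA,
bound by the CPSF complex through its CPSF4 subunit) and the
**cytoplasmic polyadenylation element** (CPE, a U-rich motif bound by
CPEB1).  Before meiotic resumption a CPE sitting close to a PAS masks it
from CPSF4 and represses translation; after germinal vesicle breakdown
(GVBD) CPEB1 is phosphorylated and partially degraded, and the same CPEs
become stimulators.  Whether a given transcript is translated in the
GV-arrested oocyte, kept dormant, or boosted after GVBD is therefore a
function of the *number and spacing* of its PASs and CPEs.

`utrcode` implements that spacing code as a reusable artifact for people
studying post-transcriptional regulation in oocytes (or anyone who needs
a motif-architecture scanner with a rule engine on top):

* **scan** — find PAS/CPE/PBE occurrences (IUPAC patterns, sense strand)
  in FASTA 3′-UTRs; emit BED/GFF3; assemble `UtrArchitecture` objects.
* **predict** — classify every PAS by its CPE context and score
  transcript-level activity at the GV stage and after GVBD.
* **mutate** — rebuild reporter constructs in silico: PAS knockouts
  (AATAAA→AAGGAA), CPE knockouts, spacer deletions, CPE insertions,
  distal truncations.
* **simulate** — seeded, motif-free random backgrounds with planted
  element architectures, including packaged reconstructions of the mouse
  *Cpeb1*, *Btg4* and *Cnot6l* 3′-UTR architectures.
* **validate** — score predictions against the packaged table of observed
  reporter outcomes (~32 constructs).

## The model

Distances are edge-to-edge spacer lengths in nucleotides.  Each PAS *p*
is classified at the GV stage by three nested windows:

* **FLANKED** — ≥ 1 CPE within `w_flank` (100) on *each* side → activity 0.
* **ONE_SIDED** — ≥ 1 CPE within `w_one` (40) on exactly one side →
  activity `max(0, 1 − π − δ·(n−1))` with penalty `π = 0.5`, dose step
  `δ = 0.25`, and `n` the number of CPEs inside `w_one`.
* **occluded** — nearest CPE within `w_occlude` (12), abutting the PAS →
  activity 0 regardless of side.
* **FREE** — otherwise → activity 1.

Transcript GV activity is the sum of per-PAS activities divided by the
number of GV-competent PASs in the wild-type reference (a single free PAS
of a two-competent-PAS transcript scores 0.5, matching the reported
40–50% single-PAS level).  After GVBD every PAS scores 1 plus
`stim_per_cpe` (0.5) per CPE within `w_flank`, so post-GVBD activity is
never below GV activity.  Transcript fates: `CONSTITUTIVE_GV`,
`GV_ACTIVE_BOOSTED`, `DORMANT_ACTIVATED`, `INACTIVE`.

The windows are pinned by the reporter experiments: a one-sided CPE
represses at 35 nt but not at 50 nt; flanking CPEs still repress at
66 nt; a single abutting CPE (~10 nt) silences a PAS outright while
15 nt leaves partial activity.  See `docs/methods.md` for the full
parameter table and design rationale.

## Worked example

```python
from utrcode import bundled_fixtures, predict_profile

for fx in bundled_fixtures():
    p = predict_profile(fx.architecture, reference=fx.architecture)
    print(fx.record.id, round(p.gv_activity, 2),
          round(p.post_gvbd_activity, 2), p.fate)
```

prints

```
Cpeb1 1.0 2.5 GV_ACTIVE_BOOSTED
Btg4 0.0 2.5 DORMANT_ACTIVATED
Cnot6l 1.0 3.5 GV_ACTIVE_BOOSTED
```

*Cpeb1* (PAS1/PAS3 far from any CPE) and *Cnot6l* (free proximal PAS1)
are translated during GV arrest and boosted after GVBD; *Btg4*, whose two
PASs are both flanked by CPEs at 66 nt, stays dormant until meiotic
resumption.  The `examples/` directory has one narrative script per
capability (scanning, fate prediction, in-silico mutagenesis, concordance
scoring, synthetic UTR simulation); each prints the numbers it computes
and a line on what they mean.

A thin CLI wraps the same library surface:

```bash
utrcode scan --fasta utrs.fa --out-bed out.bed
utrcode predict --fasta utrs.fa --stage both
utrcode validate            # exits nonzero on any discordant construct
utrcode constructs          # list the packaged reporter matrix
```

## Limitations

The engine is a deterministic encoding of a spacing code measured on
three UTRs; window defaults sit inside experimentally bracketed ranges
but are config-exposed (`CodeConfig`, YAML via `load_config`).  RNA
secondary structure, CPEB1 kinetics, and additional regulators (Pumilio,
Musashi, Smaug) are out of scope; the PBE is annotated but attaches no
effect by default.
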