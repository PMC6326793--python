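"""Predict stage-specific translational fate for the three packaged UTRs.

For each architecture the engine classifies every PAS by its CPE context,
scores relative activity in the GV-arrested oocyte and after germinal
vesicle breakdown (GVBD), and assigns a transcript fate.
"""

from utrcode import bundled_fixtures, predict_profile

for fx in bundled_fixtures():
    arch = fx.architecture
    p = predict_profile(arch, reference=arch)
    calls = ", ".join(f"{c.pas_label}={c.call}{'*' if c.occluded else ''}"
                      for c in p.per_pas)
    print(f"{arch.utr_id:8s} GV={p.gv_activity:4.2f}  post-GVBD={p.post_gvbd_activity:4.2f}  "
          f"{p.fate:18s} [{calls}]")

print()
print("GV/post-GVBD are wild-type-normalized relative activities; '*' marks a")
print("PAS occluded by an abutting CPE.  Cpeb1 and Cnot6l carry a CPE-free PAS")
print("and are translated while arrested (and boosted after GVBD); every Btg4")
print("PAS is flanked by CPEs, so Btg4 stays dormant until meiotic resumption.")
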