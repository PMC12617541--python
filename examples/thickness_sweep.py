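"""Dose assessment across the 1-2 mm coating-thickness sweep.

Runs the full factorial (2 materials x 2 pH x 5 thicknesses) and writes the
machine-readable report. The design question: is there a thickness that
blocks release at vaginal resting pH (4) yet delivers the spermicidal dose
once intercourse raises the pH to 7?
"""

from cugel import default_config, run_sweep, write_report

cfg = default_config()
report = run_sweep(cfg)
print(report.to_frame().to_string(index=False,
                                  float_format=lambda v: f"{v:.3g}"))

csv_path, json_path = write_report(report, "scratch_sweep", config=cfg)
print(f"\nreport written to {csv_path} and {json_path}")

ok = all(r.above_threshold == (r.ph == "7") for r in report.rows)
print("every thickness gates release on pH:", ok)

# Expected: all 10 pH-7 rows above the 1e-6 M threshold, all 10 pH-4 rows
# below it — the pH-gating principle holds across the whole sweep.
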