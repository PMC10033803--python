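"""Compare the packaged clinical table (3 PCOS vs 3 control subjects).

Runs a pooled-variance two-sided t-test per clinical variable and flags
p < 0.05. Significant rows (LH, E2, T, infertility duration, PRL, AMH and
antral follicle count) mark the hormonal profile that separates the groups.
"""

from ffevomics import compare_clinical_table

res = compare_clinical_table()
print(res.to_string(index=False, float_format=lambda v: f"{v:.6g}"))
print(f"\n{int(res['significant'].sum())} of {len(res)} variables differ at p < 0.05.")
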