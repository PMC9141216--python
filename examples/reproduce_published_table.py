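"""Recompute the published group table from the packaged per-sample data.

Loads the 60-row per-sample fixture (15 samples x 2 sides x 2 instruments),
recomputes every group mean, SD, index and above-vs-below test, and prints
them next to the published numbers.  A low RILATE means only a small fraction
of the >50 degC zone actually necrotised; 'above' and 'below' refer to the
two sides of the closed instrument branches.
"""

from rilate import format_report, reproduce_table1

report = reproduce_table1()
print(format_report(report))
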