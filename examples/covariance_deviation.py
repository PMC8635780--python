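"""Covariance-deviation analysis on a synthetic matched cohort.

Simulates 11 patients and 24 controls whose six-region thickness table
follows the default group moments; patients carry a hub covariance
structure (lingual gyrus) absent in controls.  Each patient-group pair
correlation is tested against the bootstrapped 99% CI of the control
correlation (1000 resamples of 11 controls, drawn with replacement).
"""

from corticovar import synthetic
from corticovar.covariance import deviation_report

meta = synthetic.make_cohort_meta(11, 24, seed=7)
table = synthetic.simulate_region_table(meta, seed=7)
report = deviation_report(table, iters=1000, level=0.99, seed=7)

print(report.round(3).to_string(index=False))
flagged = report[report.flagged]
print(f"\n{len(flagged)} of {len(report)} pairs flagged: the patient "
      "correlation falls outside the control bootstrap CI and is itself "
      "significant at p < 0.05. At n=11 patients the power for even large "
      "injected differences is modest, mirroring small-cohort reality.")
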