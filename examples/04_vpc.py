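"""Visual predictive check: simulate replicate trials under the design of a
dataset and compare observed percentiles with simulated 95% bands.

When the data were generated from the same model (as here), observed
percentiles should fall inside the bands almost everywhere.
"""

from il13pkpd import default_design, generate_trial, reference_model, vpc

pop = reference_model()
data, _ = generate_trial(default_design(), pop, seed=11)
result = vpc(data, pop, n_sim=200, seed=0)

for panel, df in result.panels.items():
    print(f"{panel:12s}: {len(df):2d} time bins, "
          f"coverage {result.coverage(panel):.2f}")
print("(coverage = fraction of observed 10/50/90th percentiles inside the "
      "simulated 95% confidence bands)")
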