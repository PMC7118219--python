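"""Simulate one presynaptic-LTD experiment and localize its expression.

A connection with n = 5 release sites and quantal amplitude q = 0.35 mV is
stimulated every 10 s; after 60 baseline sweeps the release probability
drops from 0.55 to 0.4 (presynaptic LTD) and 240 more sweeps follow.
CV analysis should place the experiment below the unity diagonal of the
normalized 1/CV^2-versus-mean plot, i.e. call the locus presynaptic.
"""

from cvlocus import ExperimentDesign, default_ltd_scenario, simulate_experiment
from cvlocus.analysis import analyze_series

series = simulate_experiment(
    ExperimentDesign(), default_ltd_scenario(), seed=0
)
result = analyze_series(series)

print(f"baseline mean: {series.baseline.mean():.3f} mV "
      f"(theory n*p*q = 5*0.55*0.35 = 0.9625 mV)")
print(f"post mean:     {series.post.mean():.3f} mV (theory 0.7000 mV)")
print(f"mu_norm = {result.point.mu_norm:.3f}   "
      "(normalized strength change; < 1 means LTD)")
print(f"1/CV^2_norm = {result.point.inv_cv2_norm:.3f}   "
      "(proxy for the release-probability change)")
print(f"phi = {result.phi_deg:+.1f} deg   "
      "(angle from the diagonal; positive = presynaptic side)")
print(f"direction = {result.direction}, locus = {result.locus}")
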