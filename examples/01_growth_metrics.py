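"""Population-level lag metrics from a single diauxic growth curve.

Generates a synthetic plate-reader curve with a known growth-rate trough,
then recovers MaxR (maximal rate on glucose), GMR (geometric-mean rate
across the carbon shift), and the trough depth/position, comparing each
against the generator's analytic ground truth.
"""

from lagfit.growth import gmr, lag_locus, max_rate, smooth_and_differentiate, summarize_curve
from lagfit.synth import DiauxicParams, gen_diauxic_curve

params = DiauxicParams(mu1=0.45, mu2=0.20, trough_rate=0.05, noise_sd=0.01)
curve, truth = gen_diauxic_curve(params, seed=7, well_id="A1", strain="demo", condition="LG")

summary = summarize_curve(curve, smoothing=0.35)

print(f"samples: {len(curve.time_h)} (every 15 min)")
print(f"MaxR  estimated {summary.max_rate:.3f}/h   true {truth.max_rate:.3f}/h")
print(f"GMR   estimated {summary.gmr:.3f}/h   true {truth.gmr:.3f}/h")
print(f"GMR/MaxR (relative GMR): {summary.gmr_norm:.3f}")
print(f"trough: rate {summary.min_rate:.3f}/h at OD {summary.od_at_min:.3f} "
      f"(injected at OD {truth.od_trough:.3f})")
print()
print("GMR well below MaxR and a trough inside the 0.15-0.75 OD band mean this")
print("strain pays a substantial lag-phase cost when switching carbon sources.")
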