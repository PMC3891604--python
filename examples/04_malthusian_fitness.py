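"""Malthusian fitness from labelled competition counts.

Simulates a labelled two-strain competition, samples 50,000 cytometry
events per time point with a small label-misclassification rate, corrects
the counts, and computes Lenski-style Malthusian fitness of the query
strain relative to the reference.
"""

import numpy as np

from lagfit.competition import ErrorRates, malthusian_fitness, proportion_series
from lagfit.simulate import EnvSchedule, SimConfig
from lagfit.synth import archetype_pair, gen_competition_counts

rates = ErrorRates(e_qr=2e-4, e_rq=2e-4)  # < 1/5000 events, as in controls
query, reference = archetype_pair()
table, sim = gen_competition_counts(
    [query, reference], EnvSchedule.cycles(8.0, 16.0, 1), [0.5, 0.5],
    error_rates=rates, n_events=50_000, observe_every_h=8.0,
    config=SimConfig(seed=4, n_cells=20_000), seed=4,
)

series = proportion_series(table, rates)
print("corrected query fraction over the cycle:")
for t, p in series.itertuples(index=False):
    print(f"  t = {t:5.1f} h   p_query = {p:.4f}")

res = malthusian_fitness(table.iloc[0], table.iloc[-1], rates=rates)
print(f"\nw_query = {res.w_query:.3f}, w_reference = {res.w_reference:.3f}")
print(f"relative fitness w_q/w_r = {res.rel_fitness:.4f}")
true_ratio = np.log(sim.N[-1, 0] / sim.N[0, 0]) / np.log(sim.N[-1, 1] / sim.N[0, 1])
print(f"(simulator's realised ln-fold ratio: {true_ratio:.4f})")
winner = "query" if res.rel_fitness > 1 else "reference"
print(f"\nThe {winner} strain out-grew its competitor over this cycle: the")
print("short-lag advantage in 8 h of maltose did not quite offset 16 h of")
print("slower glucose growth, consistent with the proportion trajectory above.")
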