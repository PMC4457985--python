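"""Altitude cline of the protective-allele score across a population panel.

Simulates a worldwide-style panel of 20 populations spanning 0-4,000 m in
which the protective-allele frequency at both score loci rises
logistically with altitude, then summarises scores per population and
rank-correlates them with altitude.
"""

import clinescreen as cs

spec = cs.reference_panel_spec(n_populations=20, samples_per_population=30, seed=42)
gm, samples = cs.gen_panel(spec)

cfg = cs.ScoreConfig(
    loci=(cs.ScoreLocus("rs480902", "T", "C"), cs.ScoreLocus("rs1063856", "T", "C"))
)
summaries = cs.summarize_populations(cs.score_samples(gm, cfg), samples)

print("population  altitude_m  mean_score  freq(score=4)")
for s in summaries[::4]:  # every 4th population
    print(f"{s.population_id:>10}  {s.altitude_m:>10.0f}  {s.mean_score:>10.2f}"
          f"  {s.freq_score_max:>13.2f}")

res = cs.cline_test(summaries)
for stat, r in res.items():
    print(f"\nSpearman {stat} vs altitude: rho = {r.rho:+.3f}, "
          f"p = {r.p_value:.2e} ({r.method}, n = {r.n})")
print()
print("A positive rho with small p says higher-altitude populations carry")
print("systematically higher protective-allele scores — the planted cline")
print("(protective frequency ~0.30 at sea level to ~0.76 at 4,000 m).")
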