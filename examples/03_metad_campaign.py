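"""A small metadynamics unbinding campaign with residence-time statistics.

Runs a few biased replicas per variant (hills of 0.2 kJ/mol, width 2
contacts, every 2 ps, at 300 K; unbinding = contacts < 200), then
compares residence times with a Mann-Whitney test.  The full study uses
30 replicas per variant; 6 keep this example quick.
"""
from metadhs import (
    MetadParams,
    build_complex,
    build_model,
    calibrate,
    equilibrate,
    path_fractions,
    residence_summary,
    run_campaign,
)

N_REPLICAS = 6
campaigns = {}
for variant, master_seed in (("human-like", 1), ("archaeal-like", 2)):
    system = calibrate(build_complex(variant, seed=7))
    model = build_model(system)
    state = equilibrate(system, model=model, seed=master_seed).state
    campaigns[variant] = run_campaign(system, MetadParams(), N_REPLICAS,
                                      master_seed, state=state, model=model)
    times = campaigns[variant].residence_times()
    print(f"{variant}: residence times (ps) = "
          f"{[round(t) for t in times]}")

summary = residence_summary(campaigns["human-like"].outcomes,
                            campaigns["archaeal-like"].outcomes, seed=0)
print(f"\nMann-Whitney U = {summary.statistic:.0f}, "
      f"two-sided p = {summary.p_value:.4f}, "
      f"longer residence: {summary.direction}")
human_exits = [o for o in campaigns["human-like"].outcomes if not o.censored]
print(f"human-like exit paths: {path_fractions(human_exits)}")
print(f"mean COM displacement at unbinding: "
      f"{sum(o.com_at_unbind for o in human_exits) / len(human_exits):.1f} Å")
# p < 0.05 with direction "human-like" reproduces the headline contrast:
# the inhibitor resides far longer in the human-like pocket.
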