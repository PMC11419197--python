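"""Power of decomposed vs standard interaction tests.

Simulates the two headline scenarios — a genotype x exposure interaction
acting on the mediator (upstream) and a genotype x mediator interaction
acting on the outcome (downstream) — and compares the Monte-Carlo
rejection rates of the decomposed tests with the standard exposure-outcome
test, alongside the closed-form non-central chi-square oracle.
"""

from gxedecomp import (
    PowerConfig,
    SimScenario,
    analytic_power,
    estimate_power,
    scenario_ncp,
)

config = PowerConfig(n_reps=1000, alpha=0.05, seed=42)

for kind in ("downstream", "upstream"):
    sc = SimScenario(kind, n=1000, maf=0.25, v_interaction=0.005, v_transmit=0.10)
    est = estimate_power(sc, config=config)
    print(f"\n{kind} scenario (interaction explains 0.5% of variance, "
          f"transmission path explains 10%):")
    for pw, e in est.items():
        oracle = analytic_power(scenario_ncp(sc, pw), config.alpha)
        print(f"  {pw:10s} power = {e.power:.3f} +/- {e.mc_se:.3f}   "
              f"(analytic {oracle:.3f})")
    decomposed = [pw for pw in est if pw != "standard"][0]
    print(f"  -> the {decomposed} test is "
          f"{est[decomposed].power / est['standard'].power:.1f}x more powerful: "
          "testing the leg of the pathway that carries the interaction avoids "
          "diluting the signal through the weak transmission step.")
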