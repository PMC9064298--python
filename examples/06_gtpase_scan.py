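"""GDP exposure and growth fluctuations: a GTPase-rate scan.

First calibrates the GDP weakening factor X so that an all-GDP lattice
shrinks at the configured target speed, then scans the hydrolysis rate
constant at 7.5 uM tubulin with the GTP-fit affinities.  Increasing GTPase
slows growth modestly but amplifies growth variance dramatically — the
signature of transient poisoning by GDP-terminated protofilaments.
"""
from mtgrowth import GTP_PARAMS
from mtgrowth.param_fit import calibrate_gdp_factor, gtpase_scan
from mtgrowth.protocols import DEFAULT_SHRINK_TARGET_NM_S

X = calibrate_gdp_factor(DEFAULT_SHRINK_TARGET_NM_S, GTP_PARAMS, seed=1)
print(f"GDP weakening factor X = {X:.0f} "
      f"(all-GDP shrinkage ~{DEFAULT_SHRINK_TARGET_NM_S:.0f} nm/s)\n")

scan = gtpase_scan([0.0, 0.003, 0.01, 0.02], GTP_PARAMS.replace(gdp_factor_X=X),
                   replicates=6, duration=600.0, base_seed=2)
cols = ["k_gtpase", "growth_rate", "growth_variance", "mean_terminal_gdp"]
print(scan[cols].round(3).to_string(index=False))
print("\nrate falls slowly, variance rises steeply with GDP exposure -- "
      "fluctuations are the sensitive readout.")
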