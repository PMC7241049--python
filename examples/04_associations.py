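"""Associations between kinetics, CH4 supply and methanotroph abundance.

Runs the full simulated study (incubations at 5% measurement noise), fits
per-site kinetics and regresses them against the CH4 gradient the sites
were planted on.
"""

import pandas as pd

from streammox.assoc import fit_linear, ks_vs_porewater_ratio
from streammox.pipeline import (
    fit_panel,
    mob_relative_abundance,
    simulate_panel,
)

panel = simulate_panel(n_sites=14, seed=1, noise_cv=0.05)
fits = fit_panel(panel["series"], seed=1)
sites = panel["sites"]

vmax = pd.Series({f.site_id: f.v_max for f in fits}, name="V_max")
ch4s = pd.Series({s.site_id: s.ch4_stream for s in sites}, name="ch4_stream")
mob = mob_relative_abundance(panel["otu_table"])

r1 = fit_linear(ch4s, vmax)
r2 = fit_linear(ch4s, mob)
ratio = ks_vs_porewater_ratio(
    fits, sites, exclude=[s.site_id for s in sites if s.ch4_pore < 1.0])

print(f"V_max ~ streamwater CH4:   r2 = {r1.r2:.2f}, p = {r1.p:.2g}")
print(f"MOB abund ~ streamwater CH4: r2 = {r2.r2:.2f}, p = {r2.p:.2g}")
print(f"K_S averages {ratio['mean_pct']:.0f}% of porewater CH4 "
      f"(range {ratio['min_pct']:.0f}-{ratio['max_pct']:.0f}%)")
print("-> both the activity (V_max) and the methanotroph community size")
print("   track the CH4 supply, and the half-saturation constants sit near")
print("   the porewater concentrations the organisms actually experience.")
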