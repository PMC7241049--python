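# streammox

Stream sediments oxidise methane before it reaches the atmosphere, and the
kinetics of that process track the CH4 supply of the stream, which in turn
follows catchment land use. `streammox` is a Python library for analysing
this link end to end: it inverts closed-chamber incubation time series to
Michaelis–Menten kinetics, converts headspace-equilibration gas readings to
dissolved concentrations, derives putative in-situ methane-oxidation (MOX)
and methanotrophic carbon-fixation rates, and maps the co-occurrence
structure of methane-oxidising bacteria (MOB) with an nMDS-based
"community landscape" (kernel density over OTU ordination scores, peak
calling, k-means MOB clustering, convex-hull co-occurrence, taxonomic
overrepresentation). A first-class synthetic-study generator plants known
ground truth — site gradients, chamber trajectories, OTU tables with two
MOB co-occurrence clusters — so every estimator ships with a recovery test.

It is written for microbial ecologists and biogeochemists who run sediment
incubations and amplicon surveys along environmental gradients.

## The core model

Sediment MOX follows Michaelis–Menten kinetics per unit sediment surface
area,

    V(S) = V_max · S / (K_S + S),

so dissolved CH4 in a closed, well-mixed chamber (sediment area A, water
volume V_w) obeys

    dC/dt = −(A/V_w) · V_max · C / (K_S + C),

with the implicit progress-curve solution
`K_S ln(C0/C) + (C0 − C) = (A/V_w) V_max t` between sampling events. Each
measurement withdraws 30 mL and replaces it with unamended streamwater; the
fitter corrects for these dilution jumps using the event ledger, fits
replicate chambers jointly, and reports `V_max = K_S = 0` when no
consumption is detectable. The putative in-situ rate is `V(S_ambient)`, and
carbon fixation is that rate times a carbon-use efficiency (default 0.5).

## Worked example

Simulate three replicate chambers at `V_max = 10 nmol m⁻² h⁻¹`,
`K_S = 3 µM` with 5% measurement noise and invert them
(`examples/02_simulate_and_fit_kinetics.py`):

```text
measured CH4 (uM), chamber 1: [14.71, 11.85, 8.46, 5.22, 2.54, 1.15, 0.36, 0.1, 0.02]
fitted V_max = 9.88 nmol m-2 h-1  (truth 10.0)
fitted K_S   = 2.97 uM             (truth 3.0)
putative in-situ MOX at S=0.4 uM: 1.17 nmol m-2 h-1
carbon fixation at 50% CUE:              0.59 nmol C m-2 h-1
```

The measured series decays from the ~15.6 µM concentration set by 1%-CH4
amendment; the fit recovers both parameters within a few percent, and the
in-situ extrapolation evaluates the fitted curve at ambient streamwater
CH4. The community half (`examples/03_community_landscape.py`) recovers the
planted MOB structure:

```text
excluded oligotrophic sites: ['Alp-2']
nMDS stress-1: 0.036
MOB clusters: sizes 23 and 7, 6 unassigned
cluster 1 hull contains 120 co-occurring non-MOB OTUs
```

i.e. the 23-OTU core cluster and the 7-OTU forest-restricted cluster come
back exactly, with the six sporadic methanotrophs left unassigned.

Each script in `examples/` is a narrative for one capability:
headspace conversion, kinetics fitting, the community landscape, and the
association layer. A thin CLI covers the same pipeline from the shell:
`streammox simulate | gas | kinetics | landscape | associate | report`.

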