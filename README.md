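# synstress

Deterministic simulator of stress-dependent synaptic plasticity: when does
a glutamatergic synapse undergo long-term potentiation (LTP), when
long-term depression (LTD), and how do glucocorticoids (stress) and the
coincidence of pre-/postsynaptic activity decide between them?

The package is for computational neuroscientists and systems biologists
who want a small, fully analyzable reaction-kinetics model of
NMDA-receptor-dependent plasticity: a library of composable layers, an
equilibrium/bifurcation engine, a registry of named in-silico experiments,
and a thin command-line front end.

## The model in brief

A cytosolic core couples NSF and short-tailed AMPA receptor subunits
(nonactivated R_S, activated R'_S) through state-dependent activation
kinetics,

    R_S + NSF  ⇌(k0, k4)  R'_S,

where k0 increases with activated homomers R'_S R'_S and k4 with
nonactivated heteromers R_S R_L — a double positive feedback with S-shaped
rate laws. Because the interaction term is shared by all three rate
equations, stationary states obey the complementary relation
p_NSF − z_NSF[NSF] = p_RS − z_RS[R_S] = z_R'S[R'_S], and the stationary
problem reduces to one scalar equation whose production blade P and decay
blade D intersect — at default parameters — in five points: three stable
(LTD, active, LTP) separated by two unstable ones. The NSF production rate
p_NSF is the bifurcation parameter: transiently raising it leaves only the
LTP state, lowering it only the LTD state, and the transition is not
undone when the rate returns — hysteresis as the substrate of memory.

Upstream, a signaling cascade converts the two experimental inputs into a
modulation of p_NSF and p_RS: presynaptic activity s(t) releases proBDNF
and (only under pre/post coincidence, gain σ) tPA, which converts proBDNF
to mature BDNF; cortisol C occupies MR and GR receptors
([C]/([C]+M), M_MR ≪ M_GR), which set TrkB and p75 receptor expression;
mBDNF·TrkB complexes raise and proBDNF·p75 complexes lower ribosomal
production. Transmission is read out from the membrane receptor pools,
s_in = 2([R'_SR'_S]mem + [R_SR_L]mem)·s.

Full LTP is a logical AND: it takes coincident activity (mBDNF high) *and*
low-normal cortisol (TrkB high). Stress attenuates LTP and deepens LTD.
See `docs/methods.md` for equations, parameter values and calibration.

## A worked example

```python
from synstress import ModelConfig, find_stationary_points, run_scenario

config = ModelConfig()

for p in find_stationary_points(config.core):
    print(f"[R'_S] = {p.RpS:.4f}  {p.stability.value:8s}  {p.label.value}")

ltp = run_scenario("correlated_low_cortisol", config)   # alias of fig4a
ltd = run_scenario("noncorrelated_high_cortisol", config)  # alias of fig5b
print(f"LTP run: fold = {ltp.fold_change:.3f}, terminal = {ltp.classification.value}")
print(f"LTD run: fold = {ltd.fold_change:.3f}, terminal = {ltd.classification.value}")
```

prints

```
[R'_S] = 0.2238  stable    LTD
[R'_S] = 0.3140  unstable  unlabeled
[R'_S] = 0.3957  stable    active
[R'_S] = 0.4269  unstable  unlabeled
[R'_S] = 0.5255  stable    LTP
LTP run: fold = 2.052, terminal = LTP
LTD run: fold = 0.101, terminal = LTD
```

The five rows are the tristable stationary structure of the core. The two
scenario lines are the headline experiments: correlated stimulation at
low-normal cortisol roughly doubles the probed transmission and commits
the synapse to the LTP attractor, while noncorrelated stimulation under
stress-level cortisol collapses it into LTD, far below half baseline.

The `examples/` directory holds one short script per capability
(stationary points, bifurcation sweep, the six cortisol × coincidence
scenarios, the heteromer-insertion knockout, the NSF intervention scan).

## Command line

```
synstress list-scenarios
synstress equilibria --out out/
synstress simulate --scenario fig4a --out out/
synstress sweep --pnsf-min 0.4 --pnsf-max 2.5 --steps 43 --out out/
synstress scan --magnitude 0.3 --out out/
```

Each run writes tidy CSV/JSON plus the fully resolved configuration, from
which it can be reproduced byte-for-byte.

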