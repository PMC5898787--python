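"""Bifurcation of the core under the NSF production rate.

Sweeps p_NSF across the fold structure: at low production only the LTD
state survives, at baseline the system is tristable, at high production
only LTP remains.  A transient excursion of p_NSF across a fold therefore
switches the synapse permanently — that is the model's account of
plasticity induction.
"""

from synstress import ModelConfig, pnsf_sweep

config = ModelConfig()
table = pnsf_sweep((0.4, 2.5), 43, config.core)

last = None
for p, pts, regime in zip(table.p_NSF_grid, table.points_per_p,
                          table.regime):
    if regime != last:
        stable = [q.RpS for q in pts if q.stability.value == "stable"]
        print(f"p_NSF = {p:5.3f}: {regime.value:16s} "
              f"stable [R_S-act] = {[round(x, 3) for x in stable]}")
        last = regime

lo, hi = table.fold_interval()
print(f"\ntristable window bracketed by p_NSF in ({lo:.3f}, {hi:.3f})")
# The two printed transitions are the folds at which the LTD-only and
# LTP-only regimes take over; the synapse's baseline p_NSF = 1 sits inside
# the tristable window between them.
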