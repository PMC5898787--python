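"""Stationary points of the AMPA-subunit activation core.

Finds all equilibria of the cytosolic core at the default (normalized)
parameters.  The three stable points are the memory states of the synapse:
low activated-subunit concentration = LTD, middle = active (neither
potentiated nor depressed), high = LTP.  The two unstable points are the
basin boundaries between them.
"""

from synstress import ModelConfig, find_stationary_points

config = ModelConfig()
points = find_stationary_points(config.core)

print(f"{'[R_S-act]':>10} {'[R_S]':>8} {'[NSF]':>8} {'stability':>10} {'label':>8}")
for p in points:
    print(f"{p.RpS:10.4f} {p.RS:8.4f} {p.NSF:8.4f} "
          f"{p.stability.value:>10} {p.label.value:>8}")

ltp = next(p for p in points if p.label.value == "LTP")
active = next(p for p in points if p.label.value == "active")
print(f"\nLTP/active homomer ratio (settled transmission fold): "
      f"{(ltp.RpS / active.RpS) ** 2:.3f}")
# Five rows, pattern stable/unstable/stable/unstable/stable: the synapse is
# tristable, and the homomer ratio sets how much stronger a potentiated
# synapse transmits than an active one.
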