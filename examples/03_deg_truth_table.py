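"""The coherency truth table for DEG direction labels.

An activation edge is coherent when both genes move the same way; an
inhibition edge when they move oppositely.  Exactly half of the eight
combinations are coherent.
"""
import itertools

import coherenet as cn

print(f"{'gene1':>6} {'gene2':>6} {'edge':>11}  call")
for d1, d2, s in itertools.product(("up", "down"), ("up", "down"), (1, -1)):
    call = cn.classify_deg_coherency(d1, d2, s)
    print(f"{d1:>6} {d2:>6} {'activation' if s == 1 else 'inhibition':>11}  {call}")
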