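"""Entropy production: how far from detailed balance a spike train runs.

Generates order-2 binary chains with a tunable irreversibility bias and
estimates the entropy production of their 5-bin macroframe transition
statistics. Bias 0 is a reversible (i.i.d.) chain whose estimate is pure
plug-in bias; increasing the bias drives the chain away from equilibrium
and the estimate up.
"""

import numpy as np

from spikedyn import entropy_production
from spikedyn.synthetic import gen_irreversible_series

print("bias   median entropy production (bits) over 20 seeds, n = 100k bins")
for bias in (0.0, 0.1, 0.2, 0.3, 0.4):
    vals = [
        entropy_production(gen_irreversible_series(bias, 100_000, seed=s))
        .entropy_production
        for s in range(20)
    ]
    print(f"{bias:.1f}    {np.median(vals):.4f}")

tm = entropy_production(gen_irreversible_series(0.4, 100_000, seed=0))
kept = int(tm.retained.sum())
print(f"\nat bias 0.4: {tm.n_frames} macroframes, {kept} reciprocal "
      f"transition pairs retained of {int((tm.counts > 0).sum())} observed")
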