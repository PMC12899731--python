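"""Re-parameterizable ghost block: training branches vs fused inference path.

Builds a block, runs a few training steps' worth of statistics, fuses it,
and verifies numerical equivalence plus the theoretical cost saving.
"""

import copy

import numpy as np

from shrimpdet.nn import autograd as ag
from shrimpdet.repghost import GhostConfig, RepGhostBlock, theoretical_cost

rng = np.random.default_rng(0)
cfg = GhostConfig(in_channels=16, out_channels=32, ratio=2,
                  primary_kernel=1, cheap_kernel=3)
block = RepGhostBlock(cfg, rng=rng, dtype=np.float64)

block.train()
for _ in range(5):                      # populate batch-norm running statistics
    block(ag.Tensor(rng.normal(size=(4, 16, 8, 8))))
block.eval()

fused = copy.deepcopy(block).fuse()
x = ag.Tensor(rng.normal(size=(2, 16, 8, 8)))
dev = np.abs(block(x).data - fused(x).data).max()
print(f"params: training form {block.num_params()}, fused form {fused.num_params()}")
print(f"max |train-mode - fused| over a random input: {dev:.2e}  (contract: <= 1e-5)")

ordinary, ghost = theoretical_cost(cfg, 8, 8)
print(f"MACs at 8x8: ordinary conv {ordinary}, ghost block {ghost} "
      f"({100 * (1 - ghost / ordinary):.0f}% cheaper)")
print("the fused block is a plain conv + depthwise conv — same arithmetic,"
      "\nno normalization branches left, which is what makes it deployable")
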