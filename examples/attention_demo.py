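"""Parameter-free three-branch attention on a toy feature map.

Builds an 8x8 single-channel map containing one bright elongated blob,
applies the attention and prints the branch fusion weights plus how much
the blob region is amplified relative to the background.
"""

import numpy as np

from shrimpdet.ensimam import (EnSimAMConfig, apply_ensimam, edge_attention,
                               fusion_weights, global_attention, local_attention)

x = np.zeros((1, 8, 8))
x[0, 3:5, 1:7] = 2.0          # a small elongated "particle" in the feature map

cfg = EnSimAMConfig()
wg, wl, we = fusion_weights(x, cfg)
print(f"fusion weights, literal L2 norm : global={wg[0]:.4f} local={wl[0]:.4f} "
      f"edge={we[0]:.4f}")
cfg_rms = EnSimAMConfig(fusion_norm="rms", eps_fusion=1.0)
wg2, wl2, we2 = fusion_weights(x, cfg_rms)
print(f"fusion weights, RMS + eps=1.0   : global={wg2[0]:.4f} local={wl2[0]:.4f} "
      f"edge={we2[0]:.4f}")
print("  -> data-derived, always summing to 1; nothing here is learned."
      "\n     With the literal L2 norm and a tiny eps, w_global saturates to ~1"
      "\n     (the documented degeneracy); RMS normalization with a comparable"
      "\n     eps keeps the local and edge branches in play.")

a_g = global_attention(x, cfg)[0]
a_l = local_attention(x, cfg)[0]
a_e = edge_attention(x, cfg)[0]
print(f"branch weights at the blob center  : global={a_g[3, 3]:.3f} "
      f"local={a_l[3, 3]:.3f} edge={a_e[3, 3]:.3f}")
print(f"branch weights in flat background  : global={a_g[0, 0]:.3f} "
      f"local={a_l[0, 0]:.3f} edge={a_e[0, 0]:.3f}")

y = apply_ensimam(x, cfg)
blob = y[0, 3:5, 1:7].mean() / x[0, 3:5, 1:7].mean()
print(f"mean multiplicative gain on the blob: {blob:.3f} (background stays at 0)")
print("high-energy neurons and edges are emphasised, which is what makes small,"
      "\ndense particles stand out against the tray mesh")
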