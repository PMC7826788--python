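"""Attention blocks on a toy feature map.

Builds channel, spatial, X and Y attention from explicit parameters,
prints the resulting weights/maps, and shows the residual-refinement
bound: for a non-negative feature map f, the refined output lies in
[f, 2f] because the fused map is a sigmoid in (0, 1).
"""

import numpy as np

import lungattn as la

rng = np.random.default_rng(0)

# a 2-channel 8x8 feature map
f = np.abs(rng.normal(size=(2, 8, 8)))

# --- channel attention: GAP -> MLP (hidden = max(1, round(r*C))) -> ReLU
cp = la.ChannelAttentionParams(
    w0=np.array([[0.5, 0.25]]),  # hidden width 1 for C=2, r=0.5
    w1=np.array([[1.0], [2.0]]),
    bn_eps=0.0,
)
fc = la.channel_attention(f, cp)
print("channel weights (one per channel):", np.round(fc.ravel(), 4))

# --- spatial attention: 3-scale pyramid with exactly five 3x3 convs
sp = la.SpatialAttentionParams(
    *[rng.normal(size=(2, 2, 3, 3)) * 0.3 for _ in range(5)],
    *[rng.normal(size=2) * 0.1 for _ in range(5)],
)
fs = la.spatial_attention(f, sp)
print("spatial map shape:", fs.shape, " range: [%.3f, %.3f]" % (fs.min(), fs.max()))

# --- X attention: sigmoid(spatial * channel), same-level fusion
mx = la.x_attention_map(f, cp, sp)
print("X map in (0,1):", bool((mx > 0).all() and (mx < 1).all()))

# --- Y attention: channel branch reads the *deeper* feature map
f_deep = rng.normal(size=(4, 4, 4))
cpy = la.ChannelAttentionParams(
    w0=rng.normal(size=(2, 4)), w1=rng.normal(size=(2, 2)), bn_eps=0.0
)
my = la.y_attention_map(f, f_deep, cpy, sp)
print("Y map shape matches shallow input:", my.shape == f.shape)

# --- residual refinement: out = m*f + f, bounded by [f, 2f] for f >= 0
out = la.residual_refine(f, mx)
print("refined within [f, 2f]:", bool((out >= f).all() and (out <= 2 * f).all()))
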