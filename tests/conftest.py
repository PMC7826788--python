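"""Shared fixtures: phantom datasets on disk and independent oracles.

The oracle helpers here are deliberately naive (nested python loops,
breadth-first flood fill) so they stay independent of the vectorized
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

import lungattn as la


# ---------------------------------------------------------------------------
# naive oracles


def oracle_conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Direct nested-loop 2-D convolution on a C x H x W array."""
    ci, h, wd = x.shape
    co, ci2, k, _ = w.shape
    assert ci == ci2
    xp = np.zeros((ci, h + 2 * pad, wd + 2 * pad))
    xp[:, pad : pad + h, pad : pad + wd] = x
    ho = (h + 2 * pad - k) // stride + 1
    wo = (wd + 2 * pad - k) // stride + 1
    out = np.zeros((co, ho, wo))
    for o in range(co):
        for i in range(ho):
            for j in range(wo):
                acc = b[o]
                for c in range(ci):
                    for ki in range(k):
                        for kj in range(k):
                            acc += w[o, c, ki, kj] * xp[c, i * stride + ki, j * stride + kj]
                out[o, i, j] = acc
    return out


def oracle_upsample_nearest(x: np.ndarray) -> np.ndarray:
    """x2 nearest-neighbour up-sampling of a C x H x W array by loops."""
    c, h, w = x.shape
    out = np.zeros((c, 2 * h, 2 * w))
    for ch in range(c):
        for i in range(2 * h):
            for j in range(2 * w):
                out[ch, i, j] = x[ch, i // 2, j // 2]
    return out


def oracle_spatial_attention(x: np.ndarray, p) -> np.ndarray:
    """Evaluate the spatial-attention graph with the naive primitives."""
    c1 = oracle_conv2d(x, p.down1_w, p.down1_b, 2, 1)
    c2 = oracle_conv2d(c1, p.down2_w, p.down2_b, 2, 1)
    b = oracle_conv2d(c2, p.coarse_w, p.coarse_b, 1, 1)
    e2 = oracle_conv2d(oracle_upsample_nearest(b) + c1, p.up2_w, p.up2_b, 1, 1)
    e1 = oracle_upsample_nearest(oracle_conv2d(e2, p.up1_w, p.up1_b, 1, 1))
    return e1 + x


def oracle_label_components(mask: np.ndarray) -> list[set]:
    """8-connected components of a binary mask via breadth-first flood fill."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for si in range(h):
        for sj in range(w):
            if mask[si, sj] and not seen[si, sj]:
                comp = set()
                queue = [(si, sj)]
                seen[si, sj] = True
                while queue:
                    i, j = queue.pop()
                    comp.add((i, j))
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] and not seen[ni, nj]:
                                seen[ni, nj] = True
                                queue.append((ni, nj))
                comps.append(comp)
    return comps


def oracle_keep_two(mask: np.ndarray) -> np.ndarray:
    """Reference post-processing built on the flood-fill oracle."""
    comps = oracle_label_components(mask)
    if len(comps) <= 2:
        return mask.copy()
    comps.sort(key=lambda c: (-len(c), min(c)))
    out = np.zeros_like(mask)
    for comp in comps[:2]:
        for i, j in comp:
            out[i, j] = 1
    return out


def finite_diff_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar-valued f at x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory):
    """Eight phantom pairs at 64x64 with a manifest, written once."""
    d = tmp_path_factory.mktemp("phantoms8")
    la.generate_dataset(8, 7, d)
    return d


@pytest.fixture(scope="session")
def phantom_manifest(phantom_dir):
    return la.read_manifest(phantom_dir / "manifest.csv")


@pytest.fixture(scope="session")
def smoke_training(phantom_manifest):
    """Desk-scale overfitting run used by the training-quality checks.

    Tiny encoder, attention at X(1)+X(2)+Y(1)+Y(2), 8 phantoms at
    64x64, 300 SGD iterations with batch 4, lr 0.01 and MSE loss.
    """
    from lungattn.phantom import SplitPlan

    ids = tuple(phantom_manifest["id"])
    plan = SplitPlan(fold=1, train=ids, val=(), test=ids)
    spec = la.NetworkSpec(placement=la.parse_placement("X(1)+X(2)+Y(1)+Y(2)"))
    net = la.build_network(spec, seed=7)
    cfg = la.TrainConfig(max_iterations=300, seed=7)
    result = la.train(net, phantom_manifest, plan, cfg)
    return net, result, phantom_manifest, ids
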