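"""Synthetic lung-phantom images, dataset manifests and split plans.

A phantom emulates the structure a chest radiograph presents to the
segmentation pipeline: two lobe-shaped fields (left and right lung),
each a single connected component, rendered darker than the surrounding
"tissue" (radiograph polarity; a flag flips it), with smoothly perturbed
boundaries, periodic rib-like stripes and additive Gaussian pixel
noise. Everything is reproducible from the spec's seed.

The split machinery realizes a five-fold protocol over one shuffled
ordering of the ids: five disjoint, exhaustive 20% test folds, and for
each fold a 70/10 (of the total) train/validation division of the
remainder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import measure

from .errors import GenerationError, ValidationError
from .imageops import write_gray_png, write_mask_png

__all__ = [
    "PhantomSpec",
    "SplitPlan",
    "generate_phantom",
    "generate_dataset",
    "read_manifest",
    "make_splits",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance parameters of one phantom image."""

    size: tuple[int, int] = (64, 64)
    lobe_ecc_range: tuple[float, float] = (1.4, 1.9)    # height/width of a lobe
    lobe_area_frac_range: tuple[float, float] = (0.08, 0.22)
    boundary_amp: float = 0.06          # radial perturbation, fraction of radius
    rib_contrast: float = 12.0          # gray levels of the stripe pattern
    noise_std: float = 6.0              # additive Gaussian noise, gray levels
    polarity: str = "dark_lungs"        # or "bright_lungs"
    seed: int = 0
    max_retries: int = 200


@dataclass(frozen=True)
class SplitPlan:
    """One cross-validation fold: disjoint train/validation/test id lists."""

    fold: int
    train: tuple
    val: tuple
    test: tuple


def _lobe_mask(shape, cy, cx, ry, rx, amp, rng) -> np.ndarray:
    """Star-convex lobe: ellipse with a low-order sinusoidal boundary wobble."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - cy) / ry
    dx = (xx - cx) / rx
    theta = np.arctan2(dy, dx)
    rho = np.ones_like(theta)
    for k in (2, 3, 4):
        rho += amp / 3.0 * rng.uniform(0.3, 1.0) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    return (dx * dx + dy * dy) <= rho * rho


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """One (image, mask) pair; the mask has exactly two connected components."""
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.lobe_area_frac_range
    # sample inside the admissible band so the boundary wobble cannot push
    # the realized area out of it
    margin = 0.12 * (hi - lo)
    for _ in range(spec.max_retries):
        mask = np.zeros((h, w), dtype=bool)
        ok = True
        for side in (-1, +1):  # left, right lobe
            frac = rng.uniform(lo + margin, hi - margin)
            ecc = rng.uniform(*spec.lobe_ecc_range)
            rx = math.sqrt(frac * h * w / (math.pi * ecc))
            ry = ecc * rx
            cx = (0.5 + side * rng.uniform(0.20, 0.26)) * w
            cy = rng.uniform(0.45, 0.58) * h
            grow = 1.0 + spec.boundary_amp
            # lobes must stay inside the frame and clear of the midline
            if side < 0 and cx + rx * grow >= w / 2 - 1:
                ok = False
                break
            if side > 0 and cx - rx * grow <= w / 2 + 1:
                ok = False
                break
            if cx - rx * grow < 1 or cx + rx * grow > w - 2:
                ok = False
                break
            if cy - ry * grow < 1 or cy + ry * grow > h - 2:
                ok = False
                break
            lobe = _lobe_mask((h, w), cy, cx, ry, rx, spec.boundary_amp, rng)
            if lobe.mean() < lo or lobe.mean() > hi:
                ok = False
                break
            mask |= lobe
        if not ok:
            continue
        _, n_comp = measure.label(mask, connectivity=2, return_num=True)
        total = mask.mean()
        if n_comp == 2 and 0.15 <= total <= 0.45:
            break
    else:
        raise GenerationError(
            f"no feasible two-lobe geometry within {spec.max_retries} retries (seed {spec.seed})"
        )

    lung, tissue = (85.0, 175.0) if spec.polarity == "dark_lungs" else (175.0, 85.0)
    img = np.where(mask, lung, tissue).astype(np.float64)
    img = gaussian_filter(img, sigma=1.0)  # soften the lobe boundary
    period = h / rng.uniform(6.0, 9.0)
    phase = rng.uniform(0, 2 * np.pi)
    yy = np.arange(h)[:, None]
    img += spec.rib_contrast * np.sin(2 * np.pi * yy / period + phase)
    img += rng.normal(0.0, spec.noise_std, size=(h, w))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, mask.astype(np.uint8)


def generate_dataset(
    n: int,
    base_seed: int,
    out_dir,
    spec: PhantomSpec | None = None,
) -> pd.DataFrame:
    """Write ``n`` image/mask PNG pairs plus a CSV manifest; deterministic.

    The manifest has columns (id, image_path, mask_path); paths are
    relative to the manifest's directory.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    spec = spec if spec is not None else PhantomSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        seed_i = (base_seed * 1_000_003 + i) % (2**31)
        img, mask = generate_phantom(replace(spec, seed=seed_i))
        img_name, mask_name = f"img_{i:04d}.png", f"mask_{i:04d}.png"
        write_gray_png(out / img_name, img)
        write_mask_png(out / mask_name, mask)
        rows.append({"id": f"p{i:04d}", "image_path": img_name, "mask_path": mask_name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_manifest(path) -> pd.DataFrame:
    """Read a manifest CSV, resolving image/mask paths against its directory."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("image_path", "mask_path"):
        df[col] = [str((path.parent / p).resolve()) for p in df[col]]
    return df


def make_splits(ids, seed: int) -> list[SplitPlan]:
    """Five rotating-test-fold plans with a 70/10/20 division per fold.

    The ids are shuffled once, partitioned into five disjoint test folds
    covering all ids (sizes differ by at most one, larger folds first);
    within each fold the remaining ids are split into train/validation
    targeting 70% and 10% of the *total*, leftovers assigned by largest
    fractional remainder.
    """
    ids = list(ids)
    n = len(ids)
    if n < 10:
        raise ValidationError(f"need at least 10 ids for a 70/10/20 five-fold plan, got {n}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    base, extra = divmod(n, 5)
    plans: list[SplitPlan] = []
    start = 0
    for k in range(5):
        t = base + (1 if k < extra else 0)
        test = order[start : start + t]
        start += t
        test_set = set(test)
        rest = [i for i in order if i not in test_set]
        q_train, q_val = 0.7 * n, 0.1 * n
        n_train, n_val = int(q_train), int(q_val)
        leftover = len(rest) - n_train - n_val
        # assign leftovers by largest fractional remainder (train wins ties)
        rema = [(q_train - n_train, 0), (q_val - n_val, 1)]
        rema.sort(key=lambda x: (-x[0], x[1]))
        for j in range(leftover):
            if rema[j % 2][1] == 0:
                n_train += 1
            else:
                n_val += 1
        plans.append(
            SplitPlan(
                fold=k + 1,
                train=tuple(rest[:n_train]),
                val=tuple(rest[n_train : n_train + n_val]),
                test=tuple(test),
            )
        )
    return plans
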