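"""Train an attention U-Net on phantoms and evaluate it.

A desk-scale run: 8 phantoms at 64x64, the tiny encoder preset, all
four shallow attention modules (X(1)+X(2)+Y(1)+Y(2)), 300 SGD
iterations with the standard regimen (batch 4, lr 0.01, momentum 0.9,
MSE loss).  The network overfits its training set, which is the point:
it demonstrates the full pipeline end to end in about a minute.
"""

import tempfile
from pathlib import Path

import lungattn as la
from lungattn.phantom import SplitPlan

with tempfile.TemporaryDirectory() as td:
    data_dir = Path(td)
    la.generate_dataset(n=8, base_seed=7, out_dir=data_dir)
    manifest = la.read_manifest(data_dir / "manifest.csv")
    ids = tuple(manifest["id"])
    # deliberately train and evaluate on the same 8 images (no held-out set)
    plan = SplitPlan(fold=1, train=ids, val=(), test=ids)

    spec = la.NetworkSpec(placement=la.parse_placement("X(1)+X(2)+Y(1)+Y(2)"))
    net = la.build_network(spec, seed=7)
    print(f"network: {spec.placement.label()}, {net.n_parameters():,} parameters")

    cfg = la.TrainConfig(max_iterations=300, eval_interval=50, seed=7)
    result = la.train(net, manifest, plan, cfg)
    for line in result.log:
        print(" ", line)

    res = la.evaluate(net, manifest, ids, threshold=0.5, keep_components=2)
    print(f"\ntrain-set macro dice={res.macro.dice:.4f} "
          f"sens={res.macro.sensitivity:.4f} ppv={res.macro.ppv:.4f}")
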