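"""Cross-validated ablation over attention placements.

Compares four placements (baseline, X(1), Y(1), full shallow set) over
five folds of 20 phantoms at a deliberately tiny budget (100 iterations
per fold) and prints the mean +/- std table.  With this budget the
numbers show the machinery, not converged performance; raise
max_iterations for a real comparison.  Runs in a few minutes on one CPU.
"""

import tempfile
from pathlib import Path

import lungattn as la

with tempfile.TemporaryDirectory() as td:
    data_dir = Path(td)
    la.generate_dataset(n=20, base_seed=21, out_dir=data_dir)
    manifest = la.read_manifest(data_dir / "manifest.csv")
    cfg = la.TrainConfig(max_iterations=100, eval_interval=50, seed=21)
    labels = ["baseline", "X(1)", "Y(1)", "X(1)+X(2)+Y(1)+Y(2)"]
    table = la.run_ablation(manifest, labels, cfg, n_folds=5, split_seed=21)
    print(table[["configuration", "dice", "sensitivity", "ppv"]].to_string(index=False))
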