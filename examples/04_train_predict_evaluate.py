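"""Full workflow: simulate data, train a model end to end, predict new
sequences and evaluate on a labeled independent set.

Mirrors the command-line flow (`stressmir simulate/train/predict/evaluate`)
from Python.  Artifacts (model, CV report, selection curve, resolved config,
run log) land in the output directory.
"""

import tempfile
from pathlib import Path

import stressmir as sm
from stressmir.cli import write_simulation

workdir = Path(tempfile.mkdtemp(prefix="stressmir_example_"))

# training data: 50 stress-responsive-like vs 50 background-like sequences
train_sim = sm.simulate(sm.SimSpec(n_per_class=50, effect=1.0, seed=1))
paths = write_simulation(train_sim, workdir / "train")

config = sm.RunConfig(
    mode="miRNA",
    positive_fasta=str(paths["pos"]),
    negative_fasta=str(paths["neg"]),
    out_dir=str(workdir / "run"),
    k_values=(2, 3),
    selection=True,
    selection_step=20,
    selection_grid_step=40,
    seed_balance=1,
    seed_folds=1,
    seed_selection=1,
)
output = sm.run_train(config)
print(f"cross-validated auROC: {output.cv_result.aggregate.auroc:.2f}")
print(f"selected features: {len(output.model.feature_names)}")

# an independent test set from the same generative process, fresh seed
test_sim = sm.simulate(sm.SimSpec(n_per_class=30, effect=1.0, seed=2))
test_paths = write_simulation(test_sim, workdir / "test")
mixed = workdir / "test_set.fasta"
mixed.write_text(
    test_paths["pos"].read_text() + test_paths["neg"].read_text()
)

table, rejected = sm.run_predict(output.paths["model"], str(mixed))
print(table.head(5).to_string(index=False))

bundle, _, _ = sm.run_evaluate(
    output.paths["model"], str(mixed), str(test_paths["truth"])
)
m = bundle.rounded()
print(
    f"independent test: Sen={m['sen']:.2f} Spe={m['spe']:.2f} Acc={m['acc']:.2f} "
    f"auROC={m['auroc']:.2f}"
)

# probability_positive is the Platt-calibrated chance a sequence is
# stress-responsive; the hard call uses the 0.5 threshold.
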