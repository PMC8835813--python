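"""End-to-end orchestration: clean -> encode -> balance -> select -> train
-> cross-validate, plus prediction and independent-test evaluation with a
persisted model.  The CLI is a thin wrapper over these functions; they are
equally usable from Python.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import sequence_io as sio
from .classifier import ModelArtifact, SVMConfig, grid_search, predict, train
from .errors import DataError, ValidationError
from .evaluation import CVResult, MetricsBundle, balance_dataset, compute_metrics, kfold_cv, loocv
from .feature_selection import rfe_rank, selection_curve, subsample_for_selection
from .pseknc import FeatureMatrix, PseKNCConfig, encode_dataset

METRIC_COLUMNS = ["Sen", "Spe", "Acc", "Pre", "F-score", "auROC", "auPRC"]


@dataclass
class RunConfig:
    """Resolved settings for one training run."""

    mode: str = "miRNA"  # miRNA | premiRNA | combined
    positive_fasta: str | None = None
    negative_fasta: str | None = None
    positive_precursor_fasta: str | None = None
    negative_precursor_fasta: str | None = None
    out_dir: str = "stressmir_run"
    # encoder
    k_values: tuple[int, ...] = (2, 3, 4, 5)
    lam: int = 3
    omega: float = 0.2
    # cleaning
    reduce_redundancy: bool = False
    identity_threshold: float = 0.80
    redundancy_joint: bool = False  # False: positives and negatives reduced separately
    # selection
    selection: bool = True
    selection_fraction: float = 0.5
    selection_step: int = 1
    selection_grid_step: int = 10
    # model
    grid_search: bool = False
    C: float = 1.0
    gamma: float | None = None
    # evaluation
    cv_scheme: str = "fivefold"  # fivefold | loocv
    folds: int = 5
    # seeds
    seed_balance: int = 0
    seed_folds: int = 0
    seed_selection: int = 0

    def pseknc_config(self) -> PseKNCConfig:
        return PseKNCConfig(k_values=tuple(self.k_values), lam=self.lam, omega=self.omega)

    def svm_config(self) -> SVMConfig:
        return SVMConfig(C=self.C, gamma=self.gamma, probability=True, seed=self.seed_folds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "k_values" in data:
            data["k_values"] = tuple(data["k_values"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["k_values"] = list(data["k_values"])
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)


def _log(stage: str, message: str, logfile=None) -> None:
    line = f"[{stage}] {message}"
    print(line, file=sys.stderr)
    if logfile is not None:
        logfile.write(line + "\n")


def load_training_manifest(config: RunConfig, logfile=None) -> sio.DatasetManifest:
    """Read, label, clean and (optionally) homology-reduce the inputs."""
    if not config.positive_fasta or not config.negative_fasta:
        raise ValidationError("training requires positive and negative FASTA inputs")
    role = "precursor" if config.mode == "premiRNA" else "mature"

    def _load(path, label, role):
        records = sio.read_fasta(path, role=role, label=label)
        cleaned, report = sio.clean_dataset(records)
        _log("clean", f"{path}: {report.splitlines()[-1]}", logfile)
        if config.reduce_redundancy and not config.redundancy_joint:
            before = len(cleaned)
            cleaned = sio.reduce_redundancy(cleaned, config.identity_threshold)
            _log(
                "reduce",
                f"{path}: {before} -> {len(cleaned)} at identity {config.identity_threshold}",
                logfile,
            )
        return cleaned

    pos = _load(config.positive_fasta, "positive", role)
    neg = _load(config.negative_fasta, "negative", role)
    records = pos + neg
    if config.reduce_redundancy and config.redundancy_joint:
        before = len(records)
        records = sio.reduce_redundancy(records, config.identity_threshold)
        _log("reduce", f"joint: {before} -> {len(records)}", logfile)
    mode = "premiRNA" if config.mode == "premiRNA" else "miRNA"
    manifest = sio.DatasetManifest(records=records, mode=mode)
    if config.mode == "combined":
        if not config.positive_precursor_fasta or not config.negative_precursor_fasta:
            raise ValidationError("combined mode requires precursor FASTA for both classes")
        pre_pos = _load(config.positive_precursor_fasta, "positive", "precursor")
        pre_neg = _load(config.negative_precursor_fasta, "negative", "precursor")
        pre_manifest = sio.DatasetManifest(records=pre_pos + pre_neg, mode="premiRNA")
        manifest = sio.pair_combined(manifest, pre_manifest)
        _log("pair", f"{len(manifest)} mature/precursor pairs", logfile)
    return manifest


@dataclass
class TrainOutput:
    model: ModelArtifact
    cv_result: CVResult
    curve: object | None
    ranking: object | None
    paths: dict[str, Path] = field(default_factory=dict)


def run_train(config: RunConfig) -> TrainOutput:
    """Execute the full training flow and write all artifacts to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        with open(out / "run.log", "w") as logfile:
            written.append(out / "run.log")
            t0 = time.time()
            config.to_yaml(out / "config.yaml")
            written.append(out / "config.yaml")

            manifest = load_training_manifest(config, logfile)
            pconfig = config.pseknc_config()
            matrix = encode_dataset(manifest, pconfig)
            _log("encode", f"{matrix.n} rows x {matrix.p} features", logfile)

            balanced = balance_dataset(matrix, seed=config.seed_balance)
            _log("balance", f"{matrix.n} -> {balanced.n} rows", logfile)

            ranking = None
            curve = None
            if config.selection:
                sel_matrix = subsample_for_selection(
                    balanced, config.selection_fraction, seed=config.seed_selection
                )
                ranking = rfe_rank(sel_matrix, step=config.selection_step)
                curve = selection_curve(
                    sel_matrix,
                    ranking,
                    grid_step=config.selection_grid_step,
                    folds=config.folds,
                    seed=config.seed_folds,
                )
                _log(
                    "select",
                    f"chose {curve.chosen_size}/{matrix.p} features "
                    f"(auROC {curve.auroc[curve.subset_sizes.index(curve.chosen_size)]:.2f})",
                    logfile,
                )
                balanced = balanced.select(curve.chosen_features)
                _write_ranking(ranking, out / "ranking.tsv")
                _write_curve(curve, out / "selection_curve.tsv")
                written += [out / "ranking.tsv", out / "selection_curve.tsv"]

            if config.grid_search:
                svm_config = grid_search(balanced, folds=config.folds, seed=config.seed_folds)
                _log("grid", f"C={svm_config.C}, gamma={svm_config.gamma}", logfile)
            else:
                svm_config = config.svm_config()

            if config.cv_scheme == "loocv":
                cv = loocv(balanced, svm_config)
            else:
                cv = kfold_cv(balanced, k=config.folds, model_config=svm_config,
                              seed=config.seed_folds)
            _log("cv", f"{cv.scheme}: auROC {cv.aggregate.auroc:.2f}", logfile)

            model = train(balanced, svm_config, encoder_fingerprint=pconfig.fingerprint())
            model.extra["pseknc_config"] = pconfig
            model.extra["mode"] = config.mode
            model.save(out / "model.joblib")
            written.append(out / "model.joblib")

            write_cv_report(cv, out / "cv_report.tsv")
            _write_fold_map(cv, out / "fold_map.tsv")
            written += [out / "cv_report.tsv", out / "fold_map.tsv"]
            _log("done", f"elapsed {time.time() - t0:.1f}s", logfile)
    except Exception:
        for path in written:  # no partial outputs
            path.unlink(missing_ok=True)
        raise
    return TrainOutput(
        model=model,
        cv_result=cv,
        curve=curve,
        ranking=ranking,
        paths={
            "model": out / "model.joblib",
            "cv_report": out / "cv_report.tsv",
            "config": out / "config.yaml",
        },
    )


def _write_ranking(ranking, path) -> None:
    pd.DataFrame(
        {"rank": range(1, len(ranking.ranked_features) + 1),
         "feature": ranking.ranked_features}
    ).to_csv(path, sep="\t", index=False)


def _write_curve(curve, path) -> None:
    pd.DataFrame(
        {"n_features": curve.subset_sizes, "auROC": curve.auroc, "auPRC": curve.auprc}
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def _write_fold_map(cv: CVResult, path) -> None:
    pd.DataFrame(
        {"id": list(cv.fold_assignment), "fold": list(cv.fold_assignment.values())}
    ).to_csv(path, sep="\t", index=False)


def metrics_row(bundle: MetricsBundle) -> dict[str, float]:
    rounded = bundle.rounded()
    return {
        "Sen": rounded["sen"], "Spe": rounded["spe"], "Acc": rounded["acc"],
        "Pre": rounded["pre"], "F-score": rounded["f_score"],
        "auROC": rounded["auroc"], "auPRC": rounded["auprc"],
    }


def write_cv_report(cv: CVResult, path) -> None:
    rows = [dict(subset="aggregate", **metrics_row(cv.aggregate))]
    rows += [
        dict(subset=f"fold{i}", **metrics_row(m)) for i, m in enumerate(cv.fold_metrics)
    ]
    pd.DataFrame(rows, columns=["subset"] + METRIC_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Prediction / independent-test evaluation with a stored model
# ---------------------------------------------------------------------------

def _encode_for_model(
    model: ModelArtifact,
    fasta: str,
    precursor_fasta: str | None,
    labels: dict[str, str] | None = None,
) -> tuple[FeatureMatrix, list[tuple[str, str]]]:
    """Encode input FASTA(s) under the model's own encoder settings.

    Returns the matrix of encodable records and an (id, reason) list of
    rejected records — rejects are reported, never silently dropped.
    """
    pconfig: PseKNCConfig = model.extra.get("pseknc_config") or PseKNCConfig()
    mode = model.extra.get("mode", "miRNA")
    role = "precursor" if mode == "premiRNA" else "mature"
    records = sio.read_fasta(fasta, role=role)
    if labels:
        records = sio.attach_labels(records, labels, strict=True)
    rejected: list[tuple[str, str]] = []
    usable: list[sio.SequenceRecord] = []
    for rec in records:
        if not rec.is_standard():
            rejected.append((rec.id, "non-standard residues"))
        elif rec.length < pconfig.min_length:
            rejected.append((rec.id, f"shorter than minimum length {pconfig.min_length}"))
        else:
            usable.append(rec)
    if mode == "combined":
        if precursor_fasta is None:
            raise ValidationError("combined-mode model needs a precursor FASTA too")
        pre = sio.read_fasta(precursor_fasta, role="precursor")
        if labels:
            pre = sio.attach_labels(pre, labels, strict=True)
        pre_by_id = {r.id: r for r in pre}
        paired, precursors = [], {}
        for rec in usable:
            mate = pre_by_id.get(rec.id)
            if mate is None:
                rejected.append((rec.id, "no matching precursor record"))
            elif not mate.is_standard():
                rejected.append((rec.id, "precursor has non-standard residues"))
            elif mate.length < pconfig.min_length:
                rejected.append((rec.id, "precursor shorter than minimum length"))
            else:
                paired.append(rec)
                precursors[rec.id] = mate
        manifest = sio.DatasetManifest(
            records=paired, mode="combined",
            pairing={r.id: r.id for r in paired}, precursors=precursors,
        )
    else:
        manifest = sio.DatasetManifest(
            records=usable, mode="premiRNA" if mode == "premiRNA" else "miRNA"
        )
    if not manifest.records:
        raise DataError("no sequence passed validation for prediction")
    return encode_dataset(manifest, pconfig), rejected


def run_predict(
    model_path, fasta, precursor_fasta=None
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Prediction table (id, predicted_class, probability_positive) + rejects."""
    model = ModelArtifact.load(model_path)
    pconfig: PseKNCConfig = model.extra.get("pseknc_config") or PseKNCConfig()
    matrix, rejected = _encode_for_model(model, fasta, precursor_fasta)
    table = predict(model, matrix, encoder_fingerprint=pconfig.fingerprint())
    return table, rejected


def run_evaluate(
    model_path, fasta, labels_path, precursor_fasta=None
) -> tuple[MetricsBundle, pd.DataFrame, list[tuple[str, str]]]:
    """Independent-test evaluation: metrics + prediction table + rejects."""
    model = ModelArtifact.load(model_path)
    labels = sio.read_labels(labels_path)
    matrix, rejected = _encode_for_model(model, fasta, precursor_fasta, labels=labels)
    table = predict(model, matrix)
    bundle = compute_metrics(
        [lab for lab in matrix.labels], table["probability_positive"].to_numpy()
    )
    return bundle, table, rejected
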