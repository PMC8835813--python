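"""Pseudo K-tuple nucleotide composition (PseKNC) encoding.

Each RNA sequence of length L is mapped, for every tuple size K, to a block
of 4^K + lambda features: the normalized K-tuple frequencies g_m followed by
lambda sequence-order correlation factors delta_j.  The j-th tier factor is
the average, over all window pairs j positions apart, of the mean squared
difference of the R physicochemical property values of the two tuples:

    delta_j = (1 / (L-K-j+1)) * sum_i Phi(i, i+j),
    Phi(i, i+j) = (1/R) * sum_r (phi_r(tuple_i) - phi_r(tuple_{i+j}))^2.

The block entries are

    theta_m = g_m / (sum_i g_i + omega * sum_j delta_j)          m <= 4^K
    theta_m = omega * delta_{m-4^K} / (sum_i g_i + omega * sum_j delta_j)

so every block is non-negative and sums to one.  At the defaults
K in {2,3,4,5}, lambda = 3, omega = 0.2, the blocks have 19, 67, 259 and
1027 entries, 1372 per sequence in total; paired mature+precursor encoding
concatenates both vectors into 2744 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .properties import ALPHABET, PropertyTable, all_tuples, default_table
from .sequence_io import DatasetManifest, SequenceRecord, normalize_sequence

_CODE = {c: i for i, c in enumerate(ALPHABET)}

DEFAULT_K_VALUES = (2, 3, 4, 5)
DEFAULT_LAMBDA = 3
DEFAULT_OMEGA = 0.2


@dataclass(frozen=True)
class PseKNCConfig:
    """Encoder settings: tuple sizes, correlation depth and weight.

    ``lam`` is the number of correlation tiers (how far apart two windows
    may sit, in positions) and ``omega`` the weight of the correlation
    entries relative to the frequency entries; both are shared across all
    K-blocks.
    """

    k_values: tuple[int, ...] = DEFAULT_K_VALUES
    lam: int = DEFAULT_LAMBDA
    omega: float = DEFAULT_OMEGA
    property_tables: dict[int, PropertyTable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.k_values:
            raise ValidationError("k_values must be non-empty")
        if any(k < 1 for k in self.k_values):
            raise ValidationError(f"tuple sizes must be >= 1, got {self.k_values}")
        if len(set(self.k_values)) != len(self.k_values):
            raise ValidationError(f"duplicate tuple sizes in {self.k_values}")
        if self.lam < 1:
            raise ValidationError(f"lambda must be >= 1, got {self.lam}")
        if self.omega <= 0:
            raise ValidationError(f"omega must be > 0, got {self.omega}")
        object.__setattr__(self, "k_values", tuple(sorted(self.k_values)))
        tables = dict(self.property_tables)
        for k in self.k_values:
            if k not in tables:
                tables[k] = default_table(k)
            elif tables[k].k != k:
                raise ValidationError(
                    f"property table for K={k} was built for K={tables[k].k}"
                )
        object.__setattr__(self, "property_tables", tables)

    @property
    def min_length(self) -> int:
        """Shortest encodable sequence: max(K) + lambda."""
        return max(self.k_values) + self.lam

    @property
    def n_features(self) -> int:
        return sum(4**k + self.lam for k in self.k_values)

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for k in self.k_values:
            names.extend(f"K{k}_{t}" for t in all_tuples(k))
            names.extend(f"K{k}_corr{j}" for j in range(1, self.lam + 1))
        return names

    def fingerprint(self) -> dict:
        """Hashable summary stored in model artifacts to detect mismatches."""
        return {
            "k_values": self.k_values,
            "lambda": self.lam,
            "omega": self.omega,
            "tables": tuple(self.property_tables[k].name for k in self.k_values),
        }


def _encode_to_ints(seq: str) -> np.ndarray:
    seq = normalize_sequence(seq)
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise DataError(f"non-standard residue {exc.args[0]!r} in sequence") from None


def _window_indices(codes: np.ndarray, k: int) -> np.ndarray:
    """Lexicographic index of every length-k window (step 1)."""
    n_win = len(codes) - k + 1
    idx = np.zeros(n_win, dtype=np.int64)
    for offset in range(k):
        idx = idx * 4 + codes[offset : offset + n_win]
    return idx


def ktuple_frequencies(seq: str, k: int) -> np.ndarray:
    """Normalized K-tuple frequencies over all 4^k tuples (sum to 1).

    Windows overlap with step 1; tuples absent from the sequence get 0.
    """
    codes = _encode_to_ints(seq)
    if len(codes) < k:
        raise ValidationError(
            f"sequence of length {len(codes)} is shorter than tuple size {k}"
        )
    idx = _window_indices(codes, k)
    counts = np.bincount(idx, minlength=4**k).astype(float)
    return counts / counts.sum()


def tier_correlation(seq: str, k: int, j: int, table: PropertyTable) -> float:
    """The j-th tier correlation factor delta_j (non-negative).

    Averages, over every pair of windows j positions apart, the mean squared
    property difference between the two tuples.
    """
    codes = _encode_to_ints(seq)
    length = len(codes)
    if j < 1:
        raise ValidationError(f"tier index must be >= 1, got {j}")
    if length < k + j:
        raise ValidationError(
            f"tier {j} with K={k} needs length >= {k + j}, got {length}"
        )
    idx = _window_indices(codes, k)
    props = table.matrix[idx]  # (n_windows, R)
    diffs = props[: len(idx) - j] - props[j:]
    return float(np.mean(diffs**2))


def encode_block(seq: str, k: int, config: PseKNCConfig) -> np.ndarray:
    """One K-block of 4^k + lambda pseudo-composition entries (sums to 1)."""
    table = config.property_tables.get(k) or default_table(k)
    g = ktuple_frequencies(seq, k)
    deltas = np.array(
        [tier_correlation(seq, k, j, table) for j in range(1, config.lam + 1)]
    )
    denom = g.sum() + config.omega * deltas.sum()
    return np.concatenate([g, config.omega * deltas]) / denom


def encode_sequence(seq: str | SequenceRecord, config: PseKNCConfig | None = None) -> np.ndarray:
    """Full PseKNC vector: K-blocks concatenated in ascending K.

    1372 values at the defaults.  Deterministic; feature names from
    ``config.feature_names()`` are stable across calls.
    """
    if config is None:
        config = PseKNCConfig()
    raw = seq.seq if isinstance(seq, SequenceRecord) else seq
    n = len(normalize_sequence(raw))
    if n < config.min_length:
        rid = f" (record {seq.id!r})" if isinstance(seq, SequenceRecord) else ""
        raise ValidationError(
            f"sequence of length {n}{rid} is too short to encode: "
            f"minimum length is {config.min_length} (max K + lambda)"
        )
    return np.concatenate([encode_block(raw, k, config) for k in config.k_values])


@dataclass
class FeatureMatrix:
    """Encoded dataset: one row per sequence (or pair), labels aligned."""

    X: np.ndarray
    feature_names: list[str]
    ids: list[str]
    labels: list[str | None]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValidationError("feature matrix must be 2-dimensional")
        if self.X.shape != (len(self.ids), len(self.feature_names)):
            raise ValidationError(
                f"shape {self.X.shape} inconsistent with {len(self.ids)} ids "
                f"and {len(self.feature_names)} feature names"
            )
        if len(self.labels) != len(self.ids):
            raise ValidationError("labels must align with rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("row ids must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def y(self) -> np.ndarray:
        """Labels as 1 (positive) / 0 (negative); raises if any is missing."""
        if any(lab is None for lab in self.labels):
            raise DataError("matrix has unlabeled rows")
        return np.array([1 if lab == "positive" else 0 for lab in self.labels])

    def select(self, names: list[str]) -> "FeatureMatrix":
        """Column subset in the given name order."""
        index = {f: i for i, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in index]
        if missing:
            raise ValidationError(f"unknown feature names: {missing[:5]}")
        cols = [index[f] for f in names]
        return FeatureMatrix(self.X[:, cols], list(names), list(self.ids), list(self.labels))

    def subset_rows(self, row_idx) -> "FeatureMatrix":
        row_idx = np.asarray(row_idx)
        return FeatureMatrix(
            self.X[row_idx],
            list(self.feature_names),
            [self.ids[i] for i in row_idx],
            [self.labels[i] for i in row_idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.feature_names)
        frame.insert(0, "id", self.ids)
        frame.insert(1, "label", [lab if lab is not None else "" for lab in self.labels])
        return frame

    def to_csv(self, path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        if list(frame.columns[:2]) != ["id", "label"]:
            raise ValidationError("feature table must start with 'id' and 'label' columns")
        labels = [lab if lab in ("positive", "negative") else None for lab in frame["label"]]
        return cls(
            frame.iloc[:, 2:].to_numpy(dtype=float),
            list(frame.columns[2:]),
            [str(i) for i in frame["id"]],
            labels,
        )

    @classmethod
    def from_csv(cls, path, sep: str = "\t") -> "FeatureMatrix":
        return cls.from_dataframe(pd.read_csv(path, sep=sep, keep_default_na=False))


def encode_dataset(manifest: DatasetManifest, config: PseKNCConfig | None = None) -> FeatureMatrix:
    """Encode every record (or mature/precursor pair) of a manifest.

    Combined mode concatenates the mature vector (``mat_`` prefix) with the
    paired precursor vector (``pre_`` prefix): 2744 columns at the defaults.
    """
    if config is None:
        config = PseKNCConfig()
    failures: list[str] = []
    rows: list[np.ndarray] = []
    for rec in manifest.records:
        try:
            vec = encode_sequence(rec, config)
            if manifest.mode == "combined":
                vec = np.concatenate([vec, encode_sequence(manifest.precursors[rec.id], config)])
            rows.append(vec)
        except (ValidationError, DataError):
            failures.append(rec.id)
    if failures:
        raise DataError(f"unencodable sequences: {failures}")
    if not rows:
        raise DataError("manifest holds no records to encode")
    base = config.feature_names()
    if manifest.mode == "combined":
        names = [f"mat_{f}" for f in base] + [f"pre_{f}" for f in base]
    else:
        names = base
    return FeatureMatrix(
        np.vstack(rows),
        names,
        [r.id for r in manifest.records],
        [r.label for r in manifest.records],
    )
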