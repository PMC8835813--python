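"""Physicochemical property tables for K-tuple nucleotides.

The correlation tiers of the pseudo K-tuple composition compare tuples
through R real-valued properties per tuple.  The bundled default for
dinucleotides is the standard set of six RNA helical parameters (rise,
roll, shift, slide, tilt, twist) from the crystallographic literature;
tables for K > 2 assign each K-tuple the mean of its K-1 overlapping
constituent dinucleotides' standardized values.  Every table is z-score
standardized (mean 0, variance 1 per property across the 4^K tuples) at
load time, which makes the correlation factors scale-free.  Custom tables
can be loaded from TSV to override the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
import pandas as pd

from .errors import ValidationError

ALPHABET = "ACGU"

# Six RNA dinucleotide helical parameters: rise (Å), roll (°), shift (Å),
# slide (Å), tilt (°), twist (°).  Reverse-complement pairs share values.
_DINUC_PROPERTY_NAMES = ("rise", "roll", "shift", "slide", "tilt", "twist")
_DINUC_PROPERTIES = {
    "AA": (3.18, 7.0, -0.08, -1.27, -0.8, 31.0),
    "AC": (3.24, 4.8, 0.23, -1.43, 0.8, 32.0),
    "AG": (3.30, 8.5, -0.04, -1.50, 0.5, 30.0),
    "AU": (3.24, 7.1, -0.06, -1.36, 1.1, 33.0),
    "CA": (3.09, 9.9, 0.11, -1.46, 1.0, 31.0),
    "CC": (3.32, 8.7, -0.01, -1.78, 0.3, 32.0),
    "CG": (3.30, 12.1, 0.30, -1.89, -0.1, 27.0),
    "CU": (3.30, 8.5, -0.04, -1.50, 0.5, 30.0),
    "GA": (3.38, 9.4, 0.07, -1.70, 1.3, 32.0),
    "GC": (3.22, 6.1, 0.07, -1.39, 0.0, 35.0),
    "GG": (3.32, 12.1, -0.01, -1.78, 0.3, 32.0),
    "GU": (3.24, 4.8, 0.23, -1.43, 0.8, 32.0),
    "UA": (3.26, 10.7, -0.02, -1.45, -0.2, 32.0),
    "UC": (3.38, 9.4, 0.07, -1.70, 1.3, 32.0),
    "UG": (3.09, 9.9, 0.11, -1.46, 1.0, 31.0),
    "UU": (3.18, 7.0, -0.08, -1.27, -0.8, 31.0),
}


def all_tuples(k: int) -> list[str]:
    """The 4^k K-tuples over {A, C, G, U} in lexicographic order."""
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def _standardize(matrix: np.ndarray) -> np.ndarray:
    """Z-score each column (property) over the tuples (rows)."""
    mean = matrix.mean(axis=0)
    std = matrix.std(axis=0)
    if np.any(std == 0):
        # A constant property carries no contrast; map it to all zeros so the
        # correlation factors it contributes are exactly zero.
        std = np.where(std == 0, 1.0, std)
    return (matrix - mean) / std


@dataclass(frozen=True)
class PropertyTable:
    """R standardized property values for every one of the 4^K tuples.

    ``matrix`` has one row per tuple (lexicographic ACGU order) and one
    column per property.
    """

    k: int
    property_names: tuple[str, ...]
    matrix: np.ndarray
    name: str = "custom"
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        tuples = all_tuples(self.k)
        if self.matrix.shape != (len(tuples), len(self.property_names)):
            raise ValidationError(
                f"property table for K={self.k}: expected shape "
                f"({len(tuples)}, {len(self.property_names)}), got {self.matrix.shape}"
            )
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(tuples)})

    @property
    def r(self) -> int:
        """Number of properties per tuple."""
        return len(self.property_names)

    def values(self, ktuple: str) -> np.ndarray:
        try:
            return self.matrix[self._index[ktuple]]
        except KeyError:
            raise ValidationError(f"unknown {self.k}-tuple {ktuple!r}") from None

    @classmethod
    def from_values(
        cls,
        k: int,
        property_names: tuple[str, ...],
        values: dict[str, tuple[float, ...]],
        name: str = "custom",
        standardize: bool = True,
    ) -> "PropertyTable":
        tuples = all_tuples(k)
        missing = [t for t in tuples if t not in values]
        if missing:
            raise ValidationError(
                f"property table for K={k}: missing {len(missing)} tuples "
                f"(first: {missing[:3]})"
            )
        matrix = np.array([values[t] for t in tuples], dtype=float)
        if matrix.shape[1] != len(property_names):
            raise ValidationError("every tuple must have one value per property")
        if standardize:
            matrix = _standardize(matrix)
        return cls(k=k, property_names=tuple(property_names), matrix=matrix, name=name)

    @classmethod
    def from_file(cls, path, name: str | None = None, standardize: bool = True) -> "PropertyTable":
        """Load a TSV with header ``tuple`` then R property names."""
        frame = pd.read_csv(path, sep="\t")
        if frame.columns[0] != "tuple":
            raise ValidationError(f"{path}: first column must be named 'tuple'")
        tuples = frame["tuple"].astype(str).str.upper().str.replace("T", "U")
        lengths = tuples.str.len().unique()
        if len(lengths) != 1:
            raise ValidationError(f"{path}: mixed tuple lengths {sorted(lengths)}")
        k = int(lengths[0])
        prop_names = tuple(frame.columns[1:])
        values = {
            t: tuple(row) for t, row in zip(tuples, frame.iloc[:, 1:].to_numpy(dtype=float))
        }
        return cls.from_values(
            k, prop_names, values, name=name or str(path), standardize=standardize
        )

    def to_file(self, path) -> None:
        frame = pd.DataFrame(self.matrix, columns=list(self.property_names))
        frame.insert(0, "tuple", all_tuples(self.k))
        frame.to_csv(path, sep="\t", index=False)


@lru_cache(maxsize=None)
def default_table(k: int) -> PropertyTable:
    """The bundled property table for tuple size ``k``.

    K=2 is the six-parameter RNA dinucleotide table; for K>2 each tuple
    inherits the mean of its K-1 constituent dinucleotides' z-values and the
    result is re-standardized over the 4^K tuples.
    """
    if k < 2:
        raise ValidationError(f"default property tables require K >= 2, got {k}")
    dinuc = PropertyTable.from_values(
        2, _DINUC_PROPERTY_NAMES, _DINUC_PROPERTIES, name="rna-helical-6"
    )
    if k == 2:
        return dinuc
    tuples = all_tuples(k)
    matrix = np.empty((len(tuples), dinuc.r))
    for i, t in enumerate(tuples):
        parts = [dinuc.values(t[j : j + 2]) for j in range(k - 1)]
        matrix[i] = np.mean(parts, axis=0)
    return PropertyTable(
        k=k,
        property_names=_DINUC_PROPERTY_NAMES,
        matrix=_standardize(matrix),
        name=f"rna-helical-6-mean-K{k}",
    )
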