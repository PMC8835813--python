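"""Synthetic labeled miRNA / pre-miRNA sequence sets with tunable separation.

Sequences are drawn from a first-order Markov chain over {A, U, G, C} (not
i.i.d., so the dinucleotide-correlation features of the encoder carry
signal, not just the frequency block).  Each class has a target nucleotide
composition; the ``effect`` knob in [0, 1] interpolates both classes'
compositions between their common midpoint (effect = 0, identical
distributions) and the full targets (effect = 1).  Defaults make the
positive class GC-rich and the negative class AU-rich at realistic lengths:
mature sequences 20-24 nt, precursors 80-120 nt.  Paired generation embeds
each mature sequence verbatim inside its precursor at a random offset,
mirroring how a mature miRNA sits within its hairpin precursor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .properties import ALPHABET
from .sequence_io import DatasetManifest, SequenceRecord

# composition vectors are over (A, C, G, U)
GC_RICH = (0.15, 0.35, 0.35, 0.15)
AU_RICH = (0.35, 0.15, 0.15, 0.35)


@dataclass(frozen=True)
class SimSpec:
    """Generator settings.

    ``stickiness`` blends a same-nucleotide repeat tendency into each Markov
    row, producing first-order correlation on top of the composition.
    """

    n_per_class: int = 200
    length_range_mature: tuple[int, int] = (20, 24)
    length_range_precursor: tuple[int, int] = (80, 120)
    positive_composition: tuple[float, float, float, float] = GC_RICH
    negative_composition: tuple[float, float, float, float] = AU_RICH
    effect: float = 1.0
    stickiness: float = 0.25
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        for name in ("length_range_mature", "length_range_precursor"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValidationError(f"invalid {name}: ({lo}, {hi})")
        for name in ("positive_composition", "negative_composition"):
            comp = np.asarray(getattr(self, name), dtype=float)
            if comp.shape != (4,) or np.any(comp < 0) or not np.isclose(comp.sum(), 1.0):
                raise ValidationError(
                    f"{name} must be 4 non-negative probabilities summing to 1"
                )
        if not 0.0 <= self.effect <= 1.0:
            raise ValidationError(f"effect must be in [0, 1], got {self.effect}")
        if not 0.0 <= self.stickiness < 1.0:
            raise ValidationError(f"stickiness must be in [0, 1), got {self.stickiness}")

    def class_composition(self, label: str) -> np.ndarray:
        """Target composition moved toward the class midpoint by 1 - effect."""
        pos = np.asarray(self.positive_composition)
        neg = np.asarray(self.negative_composition)
        mid = (pos + neg) / 2.0
        target = pos if label == "positive" else neg
        return mid + self.effect * (target - mid)


@dataclass
class SimResult:
    """Generated records plus the ground-truth label map."""

    mature: list[SequenceRecord]
    precursors: list[SequenceRecord] = field(default_factory=list)
    truth: dict[str, str] = field(default_factory=dict)

    def mature_manifest(self) -> DatasetManifest:
        return DatasetManifest(records=list(self.mature), mode="miRNA")

    def precursor_manifest(self) -> DatasetManifest:
        return DatasetManifest(records=list(self.precursors), mode="premiRNA")

    def combined_manifest(self) -> DatasetManifest:
        pre_by_id = {r.id: r for r in self.precursors}
        return DatasetManifest(
            records=list(self.mature),
            mode="combined",
            pairing={r.id: r.id for r in self.mature},
            precursors=pre_by_id,
        )


def _transition_matrix(comp: np.ndarray, stickiness: float) -> np.ndarray:
    rows = (1.0 - stickiness) * np.tile(comp, (4, 1)) + stickiness * np.eye(4)
    return rows


def _draw_chain(rng: np.random.Generator, length: int, comp: np.ndarray, stickiness: float) -> str:
    trans = _transition_matrix(comp, stickiness)
    states = np.empty(length, dtype=np.int64)
    states[0] = rng.choice(4, p=comp)
    for i in range(1, length):
        states[i] = rng.choice(4, p=trans[states[i - 1]])
    return "".join(ALPHABET[s] for s in states)


def simulate(spec: SimSpec) -> SimResult:
    """Generate the two labeled classes (and paired precursors if asked).

    Deterministic given ``spec.seed``.  In paired mode each precursor
    contains its mature sequence as an exact substring.
    """
    rng = np.random.default_rng(spec.seed)
    result = SimResult(mature=[], precursors=[], truth={})
    for label in ("positive", "negative"):
        comp = spec.class_composition(label)
        for i in range(spec.n_per_class):
            rid = f"{'pos' if label == 'positive' else 'neg'}_{i:04d}"
            lo, hi = spec.length_range_mature
            length = int(rng.integers(lo, hi + 1))
            seq = _draw_chain(rng, length, comp, spec.stickiness)
            result.mature.append(SequenceRecord(id=rid, seq=seq, role="mature", label=label))
            result.truth[rid] = label
            if spec.paired:
                plo, phi = spec.length_range_precursor
                total = int(rng.integers(max(plo, length), phi + 1))
                offset = int(rng.integers(0, total - length + 1))
                left = _draw_chain(rng, offset, comp, spec.stickiness) if offset else ""
                right_len = total - length - offset
                right = _draw_chain(rng, right_len, comp, spec.stickiness) if right_len else ""
                result.precursors.append(
                    SequenceRecord(
                        id=rid, seq=left + seq + right, role="precursor", label=label
                    )
                )
    return result


def write_truth(result: SimResult, path) -> None:
    """Ground-truth labels as ``id<TAB>label`` (readable by read_labels)."""
    with open(path, "w") as handle:
        for rid, label in result.truth.items():
            handle.write(f"{rid}\t{label}\n")
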