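"""Reading, validating, cleaning and pairing RNA sequence sets.

Sequences are mature miRNAs (~20-24 nt) or their hairpin precursors
(~80-120 nt) over the RNA alphabet {A, U, G, C}.  DNA-alphabet FASTA is
accepted: input is uppercased and T is normalized to U on read.  Cleaning
collapses exact duplicate sequences and drops records containing
non-standard residues; an optional greedy identity clusterer thins
near-identical sequences so cross-validation is not inflated by redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import DataError, ValidationError

RNA_ALPHABET = frozenset("ACGU")

ROLES = ("mature", "precursor")
LABELS = ("positive", "negative")


def normalize_sequence(raw: str) -> str:
    """Uppercase and convert the DNA alphabet to RNA (T -> U)."""
    return raw.strip().upper().replace("T", "U")


@dataclass(frozen=True)
class SequenceRecord:
    """One RNA sequence with identity, role and optional class label.

    The stored sequence is already uppercased and T->U normalized, but may
    still contain non-standard residues until :func:`clean_dataset` runs.
    """

    id: str
    seq: str
    role: str = "mature"
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record must have a non-empty id")
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        if self.role not in ROLES:
            raise ValidationError(
                f"record {self.id!r}: role must be one of {ROLES}, got {self.role!r}"
            )
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(
                f"record {self.id!r}: label must be one of {LABELS}, got {self.label!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def is_standard(self) -> bool:
        """True when every residue is in {A, U, G, C}."""
        return set(self.seq) <= RNA_ALPHABET


@dataclass
class DatasetManifest:
    """An ordered sequence collection plus its processing provenance.

    In ``combined`` mode, ``records`` holds the mature sequences and
    ``precursors`` the paired precursor record for each mature id (the two
    share the same record id, so they cannot live in one flat list without
    breaking id uniqueness); ``pairing`` maps mature id -> precursor id.
    """

    records: list[SequenceRecord]
    mode: str = "miRNA"
    pairing: dict[str, str] = field(default_factory=dict)
    precursors: dict[str, SequenceRecord] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("miRNA", "premiRNA", "combined"):
            raise ValidationError(f"unknown dataset mode {self.mode!r}")
        ids = [r.id for r in self.records]
        dupes = _duplicates(ids)
        if dupes:
            raise ValidationError(f"duplicate record ids in manifest: {sorted(dupes)}")
        if self.mode == "combined":
            for rec in self.records:
                if rec.id not in self.pairing or self.pairing[rec.id] not in self.precursors:
                    raise ValidationError(
                        f"combined mode: mature id {rec.id!r} lacks a paired precursor"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def log(self, message: str) -> None:
        self.provenance.append(message)


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# FASTA / label file I/O
# ---------------------------------------------------------------------------

def read_fasta(path, role: str = "mature", label: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into normalized records, preserving file order.

    ``role`` and ``label`` are stamped onto every record; labels may also be
    attached later from a TSV via :func:`read_labels` / :func:`attach_labels`.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValidationError(
                        f"{path}: not FASTA — line {lineno} should start with '>'"
                    )
                break
        else:
            raise ValidationError(f"{path}: empty file, no FASTA records")
    records = [
        SequenceRecord(id=entry.id, seq=normalize_sequence(str(entry.seq)), role=role, label=label)
        for entry in SeqIO.parse(path, "fasta")
    ]
    dupes = _duplicates([r.id for r in records])
    if dupes:
        raise ValidationError(f"{path}: duplicate record ids: {sorted(dupes)}")
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    SeqIO.write(
        (_BioRecord(Seq(r.seq), id=r.id, description="") for r in records),
        path,
        "fasta",
    )


def read_labels(path) -> dict[str, str]:
    """Read a two-column ``id<TAB>positive|negative`` file."""
    labels: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}: line {lineno}: expected 'id<TAB>label'")
            rid, lab = parts
            if lab not in LABELS:
                raise ValidationError(
                    f"{path}: line {lineno}: label must be one of {LABELS}, got {lab!r}"
                )
            if rid in labels:
                raise ValidationError(f"{path}: duplicate id {rid!r}")
            labels[rid] = lab
    return labels


def attach_labels(
    records: list[SequenceRecord], labels: dict[str, str], strict: bool = True
) -> list[SequenceRecord]:
    missing = [r.id for r in records if r.id not in labels]
    if missing and strict:
        raise DataError(f"no label for ids: {missing}")
    return [replace(r, label=labels.get(r.id, r.label)) for r in records]


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def clean_dataset(records: list[SequenceRecord]) -> tuple[list[SequenceRecord], str]:
    """Drop non-standard-residue records and collapse exact duplicates.

    Duplicate sequences keep the first occurrence.  The two filters commute,
    so application order does not affect the retained set.  Returns the
    retained records and a plain-text provenance report.
    """
    nonstandard = [r for r in records if not r.is_standard()]
    standard = [r for r in records if r.is_standard()]
    seen: set[str] = set()
    retained: list[SequenceRecord] = []
    for rec in standard:
        if rec.seq in seen:
            continue
        seen.add(rec.seq)
        retained.append(rec)
    n_dup = len(standard) - len(retained)
    report = (
        f"input: {len(records)} records\n"
        f"removed (non-standard residues): {len(nonstandard)}"
        f"{' [' + ', '.join(r.id for r in nonstandard) + ']' if nonstandard else ''}\n"
        f"removed (identical sequences): {n_dup}\n"
        f"retained: {len(retained)}"
    )
    if not retained:
        raise DataError("no sequences survive filtering")
    return retained, report


# ---------------------------------------------------------------------------
# Redundancy reduction (greedy identity clustering)
# ---------------------------------------------------------------------------

def _aligner() -> PairwiseAligner:
    # match=1, mismatch/gap=0: the optimal global score is the maximum number
    # of matched residues (the LCS length); end gaps are free by construction.
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = 0.0
    a.extend_gap_score = 0.0
    return a


def pairwise_identity(seq_a: str, seq_b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matches / alignment columns.

    With free mismatches/gaps the aligner can always gap a non-matching
    residue, so every co-optimal alignment realizes m = max matches with all
    other residues gapped, giving a canonical column count la + lb - m.
    """
    if aligner is None:
        aligner = _aligner()
    m = aligner.score(seq_a, seq_b)
    return m / (len(seq_a) + len(seq_b) - m)


def reduce_redundancy(
    records: list[SequenceRecord], identity_threshold: float = 0.80
) -> list[SequenceRecord]:
    """Greedy clustering in input order at the given identity threshold.

    A record is retained iff its identity to every already-retained record
    is strictly below the threshold.  This approximates, but does not
    reproduce, CD-HIT clusters; short sequences keep exact pairwise
    alignment cheap.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValidationError(
            f"identity threshold must be in (0, 1], got {identity_threshold}"
        )
    aligner = _aligner()
    retained: list[SequenceRecord] = []
    for rec in records:
        if all(
            pairwise_identity(rec.seq, kept.seq, aligner) < identity_threshold
            for kept in retained
        ):
            retained.append(rec)
    return retained


# ---------------------------------------------------------------------------
# Pairing mature + precursor sets
# ---------------------------------------------------------------------------

def pair_combined(
    mature: DatasetManifest, precursor: DatasetManifest, strict: bool = False
) -> DatasetManifest:
    """Build the combined manifest by shared record id.

    Ids present in only one input are dropped with a provenance warning
    (``strict=True`` raises instead).  Paired records must agree on label.
    """
    pre_by_id = {r.id: r for r in precursor.records}
    mat_ids = {r.id for r in mature.records}
    unmatched = sorted(
        [r.id for r in mature.records if r.id not in pre_by_id]
        + [rid for rid in pre_by_id if rid not in mat_ids]
    )
    if unmatched and strict:
        raise DataError(f"ids present in only one input: {unmatched}")
    pairs: list[SequenceRecord] = []
    precursors: dict[str, SequenceRecord] = {}
    for rec in mature.records:
        pre = pre_by_id.get(rec.id)
        if pre is None:
            continue
        if rec.label != pre.label:
            raise DataError(
                f"label disagreement for id {rec.id!r}: "
                f"mature={rec.label!r} precursor={pre.label!r}"
            )
        pairs.append(rec)
        precursors[rec.id] = pre
    manifest = DatasetManifest(
        records=pairs,
        mode="combined",
        pairing={r.id: r.id for r in pairs},
        precursors=precursors,
        provenance=list(mature.provenance) + list(precursor.provenance),
    )
    if unmatched:
        manifest.log(f"warning: dropped unpaired ids: {unmatched}")
    manifest.log(f"paired {len(pairs)} mature/precursor records")
    return manifest
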