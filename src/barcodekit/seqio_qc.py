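"""Sequence I/O and barcode quality control.

Reads and writes FASTA and specimen-metadata tables, enforces the
barcode-compliance rules used for mitochondrial COI fragments (length of
unambiguous sequence, absence of gaps and stop codons under the invertebrate
mitochondrial genetic code), and assembles a frame-anchored alignment matrix.

COI barcode fragments are indel-free protein-coding sequence, so column
homology can be established without progressive multiple alignment: each
record is anchored against a reference by ungapped sliding-window identity,
and the matrix is the intersection window of all records, with the codon
phase of the first column recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "SequenceRecord",
    "AlignmentMatrix",
    "QCResult",
    "FastaParseError",
    "QCError",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "attach_metadata",
    "filter_barcode_compliant",
    "translation_qc",
    "build_alignment",
    "INVERTEBRATE_MT_TABLE",
]

MARKERS = ("COI5", "COI3")
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")
UNAMBIGUOUS = frozenset("ACGT")
#: NCBI translation table 5, the invertebrate mitochondrial code.
INVERTEBRATE_MT_TABLE = 5

METADATA_COLUMNS = ("id", "marker", "country", "province", "region", "host", "species_label")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; the message names the offending line."""


class QCError(ValueError):
    """Raised when a QC precondition cannot be evaluated."""


@dataclass
class SequenceRecord:
    """One specimen/marker sequence with optional collection metadata.

    ``seq`` is upper-cased on construction and RNA ``U`` is mapped to ``T``;
    only IUPAC nucleotide codes, ``N`` and ``-`` are accepted.
    """

    id: str
    seq: str
    marker: str = "COI5"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        self.seq = self.seq.upper().replace("U", "T")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - IUPAC_CHARS
        if bad:
            raise ValueError(f"record {self.id!r} contains invalid symbols: {sorted(bad)}")

    def n_unambiguous(self) -> int:
        """Number of A/C/G/T bases (ambiguity codes, N and gaps excluded)."""
        return sum(1 for c in self.seq if c in UNAMBIGUOUS)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentMatrix:
    """Column-homologous matrix of equal-length records.

    ``frame_offset`` is the codon phase of column 1: the index (0-2) of the
    first column that begins a complete codon.
    """

    records: list
    ncol: int
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.ncol < 1:
            raise ValueError("alignment must have at least one column")
        for r in self.records:
            if len(r.seq) != self.ncol:
                raise ValueError(f"record {r.id!r} length {len(r.seq)} != ncol {self.ncol}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")

    @property
    def ids(self) -> list:
        return [r.id for r in self.records]

    @property
    def seqs(self) -> list:
        return [r.seq for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path, marker: str = "COI5") -> list:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are upper-cased with ``U`` mapped to ``T``.  Malformed input
    raises :class:`FastaParseError` naming the offending line; duplicate ids
    raise :class:`ValueError`.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    records: list = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), marker=marker))
    return records


def _validate_fasta_lines(path: Path) -> None:
    """Line-level structural check so errors can name the offending line."""
    in_record = False
    expecting_seq_header = None  # line number of header awaiting sequence
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FastaParseError(f"{path}:{lineno}: header line has no id")
                if expecting_seq_header is not None:
                    raise FastaParseError(
                        f"{path}:{expecting_seq_header}: header has no sequence lines"
                    )
                in_record = True
                expecting_seq_header = lineno
            else:
                if not in_record:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                expecting_seq_header = None
                bad = set(line.upper().replace("U", "T")) - IUPAC_CHARS
                if bad:
                    raise FastaParseError(
                        f"{path}:{lineno}: invalid sequence symbols {sorted(bad)}"
                    )
    if expecting_seq_header is not None:
        raise FastaParseError(f"{path}:{expecting_seq_header}: header has no sequence lines")


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    """Write records as FASTA (fixed line width, '\\n' newlines, deterministic)."""
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_metadata(path) -> pd.DataFrame:
    """Read the tab-separated specimen metadata table (must contain ``id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    if "id" not in df.columns:
        raise ValueError(f"metadata {path} lacks required column 'id'")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"metadata {path} has duplicate ids: {dups[:5]}")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def attach_metadata(records: Sequence[SequenceRecord], metadata: pd.DataFrame) -> None:
    """Copy metadata columns into each record's ``meta`` dict (in place)."""
    table = metadata.set_index("id")
    for rec in records:
        if rec.id in table.index:
            row = table.loc[rec.id]
            for col in table.columns:
                val = row[col]
                if val != "":
                    rec.meta[col] = val


def filter_barcode_compliant(records: Sequence[SequenceRecord], min_len: int = 500):
    """Split records into (kept, dropped) by unambiguous-base count.

    A record is kept when its count of A/C/G/T bases is strictly greater
    than ``min_len`` (the ">500 bp" barcode-compliance rule); ambiguity
    codes and N do not count toward the length.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept, dropped = [], []
    for rec in records:
        (kept if rec.n_unambiguous() > min_len else dropped).append(rec)
    return kept, dropped


@dataclass
class QCResult:
    passed: bool
    frame: int | None
    reasons: list

    def __bool__(self) -> bool:
        return self.passed


def _stop_codon_positions(seq: str, frame: int, stops: frozenset) -> list:
    out = []
    for ci, i in enumerate(range(frame, len(seq) - 2, 3)):
        if seq[i : i + 3] in stops:
            out.append(ci)
    return out


def translation_qc(
    record_or_seq,
    genetic_code: int = INVERTEBRATE_MT_TABLE,
    frame_offset="auto",
) -> QCResult:
    """Check that a coding fragment is free of gaps and stop codons.

    ``frame_offset`` may be 0, 1, 2 or ``"auto"``.  Auto mode picks the
    lowest stop-free frame (warning when several frames qualify) and fails
    when no frame is stop-free.  A stop codon at any complete codon is a
    failure: these markers are mid-gene fragments, so a terminal stop is as
    diagnostic of a frame or pseudogene problem as an internal one.
    """
    seq = record_or_seq.seq if isinstance(record_or_seq, SequenceRecord) else str(record_or_seq)
    seq = seq.upper().replace("U", "T")
    if len(seq) < 3:
        raise QCError("sequence shorter than one codon")
    stops = frozenset(CodonTable.unambiguous_dna_by_id[genetic_code].stop_codons)
    if "-" in seq:
        return QCResult(False, None, ["gap character present"])
    if frame_offset == "auto":
        per_frame = {f: _stop_codon_positions(seq, f, stops) for f in (0, 1, 2)}
        clean = [f for f in (0, 1, 2) if not per_frame[f]]
        if not clean:
            reasons = [
                f"frame {f}: stop codon at codon {per_frame[f][0]}" for f in (0, 1, 2)
            ]
            return QCResult(False, None, reasons)
        if len(clean) > 1:
            warnings.warn(
                f"multiple stop-free frames {clean}; choosing lowest offset {clean[0]}",
                stacklevel=2,
            )
        return QCResult(True, clean[0], [])
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1, 2 or 'auto'")
    positions = _stop_codon_positions(seq, frame_offset, stops)
    if positions:
        reasons = [
            f"stop codon {seq[frame_offset + 3 * ci: frame_offset + 3 * ci + 3]}"
            f" at codon {ci}"
            for ci in positions
        ]
        return QCResult(False, frame_offset, reasons)
    return QCResult(True, frame_offset, [])


# ---------------------------------------------------------------------------
# frame-anchored alignment

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _best_offset(ref: np.ndarray, qry: np.ndarray, max_shift: int) -> int:
    """Offset of ``qry`` relative to ``ref`` maximizing ungapped identity.

    Ties break toward the smallest |shift|, then the smallest shift, so the
    result is deterministic.
    """
    best = (-1, 0, 0)  # (matches, -abs(shift), -shift)
    best_s = 0
    for s in range(-max_shift, max_shift + 1):
        lo_r, hi_r = max(0, s), min(len(ref), s + len(qry))
        if hi_r - lo_r < 3:
            continue
        a = ref[lo_r:hi_r]
        b = qry[lo_r - s : hi_r - s]
        matches = int(np.count_nonzero((a == b) & (a < 4) & (b < 4)))
        key = (matches, -abs(s), -s)
        if key > best:
            best = key
            best_s = s
    if best[0] < 0:
        raise QCError("records share no overlapping window")
    return best_s


def build_alignment(records: Sequence[SequenceRecord], max_shift: int = 60) -> AlignmentMatrix:
    """Anchor same-marker coding records into a column-homologous matrix.

    Every record must pass :func:`translation_qc` (auto frame).  Each record
    is positioned against the longest record by ungapped identity, and all
    are trimmed to the intersection window; retained bases are never
    modified.  The codon phase of the window start (relative to the
    reference frame) is recorded as ``frame_offset``.
    """
    if not records:
        raise ValueError("no records to align")
    markers = {r.marker for r in records}
    if len(markers) > 1:
        raise ValueError(f"records mix markers {sorted(markers)}")
    frames = {}
    for rec in records:
        qc = translation_qc(rec, frame_offset="auto")
        if not qc:
            raise QCError(f"record {rec.id!r} fails translation QC: {qc.reasons}")
        frames[rec.id] = qc.frame
    ref = sorted(records, key=lambda r: (-len(r.seq), r.id))[0]
    ref_enc = _encode(ref.seq)
    offsets = {}
    for rec in records:
        offsets[rec.id] = 0 if rec.id == ref.id else _best_offset(ref_enc, _encode(rec.seq), max_shift)
    start = max(offsets[r.id] for r in records)
    end = min(offsets[r.id] + len(r.seq) for r in records)
    if end - start < 3:
        raise QCError("records share no overlapping window")
    trimmed = [
        SequenceRecord(
            id=r.id,
            seq=r.seq[start - offsets[r.id] : end - offsets[r.id]],
            marker=r.marker,
            meta=dict(r.meta),
        )
        for r in records
    ]
    frame_offset = (frames[ref.id] - start) % 3
    return AlignmentMatrix(records=trimmed, ncol=end - start, frame_offset=frame_offset)
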