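"""Intermediate formats for event-aligned signals and per-base alignments.

DRS reads are processed upstream by basecalling, transcriptome alignment
and re-squiggling; this module defines the two flat TSV dialects that carry
the results of those steps into the package, plus motif scanning on
reference FASTA.  All coordinates are 0-based on the transcript (forward
strand only -- DRS reads align to the transcriptome), and U is normalized
to T on ingest so that a single DNA alphabet is used internally.

Event-table TSV columns:
    read_id  transcript_id  ref_position  ref_base  signals
where ``signals`` is a comma-separated list of raw current values.  Rows of
one read are contiguous and sorted by position; a header line is required
and ``#`` comment lines are allowed.

Alignment-table TSV columns:
    read_id  transcript_id  ref_position  ref_base  status  base_quality  insertion_count
with status one of M (match), X (mismatch), D (deletion), I
(insertion-adjacent match).  Deletions carry the quality sentinel -1;
insertions, which have no reference position of their own, are counted on
the reference base immediately 5' of the inserted bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

DELETION_QUALITY_SENTINEL = -1

EVENT_TABLE_COLUMNS = ("read_id", "transcript_id", "ref_position", "ref_base", "signals")
ALIGNMENT_TABLE_COLUMNS = (
    "read_id",
    "transcript_id",
    "ref_position",
    "ref_base",
    "status",
    "base_quality",
    "insertion_count",
)

#: status tokens of the alignment-table dialect -> long names
STATUS_TOKENS = {"M": "match", "X": "mismatch", "D": "deletion", "I": "insertion-adjacent"}
_STATUS_FROM_NAME = {v: k for k, v in STATUS_TOKENS.items()}

#: IUPAC degenerate codes of the two m6A consensus motifs, on the DNA alphabet
MOTIF_CLASSES = {
    "RRACH": ("AG", "AG", "A", "C", "ACT"),
    "DRACH": ("AGT", "AG", "A", "C", "ACT"),
}


class FormatError(ValueError):
    """An intermediate file violates its documented dialect."""


def normalize_base(base: str) -> str:
    """Uppercase a nucleotide and map U to T."""
    b = base.upper()
    return "T" if b == "U" else b


def normalize_sequence(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


@dataclass(frozen=True)
class Event:
    """The raw-signal segment a re-squiggle step assigned to one reference base."""

    ref_position: int
    ref_base: str
    signals: tuple[float, ...]


@dataclass
class EventAlignedRead:
    """One read's ordered per-reference-base signal segments.

    ``read_median`` and ``read_mad`` are the robust location/scale of *all*
    signal values of the read, computed once at construction; they are the
    statistics used for per-read signal normalization.
    """

    read_id: str
    transcript_id: str
    events: list[Event]
    read_median: float = field(init=False)
    read_mad: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.events:
            raise FormatError(f"read {self.read_id}: no events")
        prev = None
        for ev in self.events:
            if not ev.signals:
                raise FormatError(
                    f"read {self.read_id}: empty signal list at position {ev.ref_position}"
                )
            if prev is not None and ev.ref_position != prev + 1:
                raise FormatError(
                    f"read {self.read_id}: positions not strictly increasing/contiguous "
                    f"({prev} -> {ev.ref_position})"
                )
            prev = ev.ref_position
        allsig = self.all_signals()
        self.read_median = float(np.median(allsig))
        self.read_mad = float(np.median(np.abs(allsig - self.read_median)))

    def all_signals(self) -> np.ndarray:
        return np.concatenate([np.asarray(ev.signals, dtype=float) for ev in self.events])

    @property
    def span(self) -> tuple[int, int]:
        """Half-open aligned span [start, end) on the transcript."""
        return self.events[0].ref_position, self.events[-1].ref_position + 1

    def events_by_position(self) -> dict[int, Event]:
        return {ev.ref_position: ev for ev in self.events}


@dataclass(frozen=True)
class BaseAlignmentRecord:
    """Alignment outcome of one reference base in one read.

    ``status`` is the long name (see :data:`STATUS_TOKENS`); deletions carry
    ``base_quality == -1`` (they have no basecalled base, hence no quality).
    """

    read_id: str
    transcript_id: str
    ref_position: int
    ref_base: str
    status: str
    base_quality: int
    insertion_count: int = 0

    def __post_init__(self) -> None:
        if self.status not in _STATUS_FROM_NAME:
            raise FormatError(f"unknown alignment status {self.status!r}")
        if self.status == "deletion":
            if self.base_quality != DELETION_QUALITY_SENTINEL:
                raise FormatError(
                    f"deletion at {self.transcript_id}:{self.ref_position} must carry "
                    f"the quality sentinel {DELETION_QUALITY_SENTINEL}"
                )
        elif self.base_quality < 0:
            raise FormatError(
                f"negative base quality {self.base_quality} at "
                f"{self.transcript_id}:{self.ref_position}"
            )
        if self.insertion_count < 0:
            raise FormatError("insertion_count must be >= 0")


@dataclass(frozen=True)
class CandidateSite:
    """A candidate m6A position: the central A of a motif-matching 5-mer."""

    transcript_id: str
    position: int
    fivemer: str
    motif_class: str

    def __post_init__(self) -> None:
        if len(self.fivemer) != 5 or self.fivemer[2] != "A":
            raise ValueError(f"5-mer {self.fivemer!r} is not centered on A")
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        if not fivemer_matches_motif(self.fivemer, self.motif_class):
            raise ValueError(f"{self.fivemer} does not match {self.motif_class}")
        if self.position < 2:
            raise ValueError("position must leave a full 5-mer context")


def fivemer_matches_motif(fivemer: str, motif_class: str) -> bool:
    pattern = MOTIF_CLASSES[motif_class]
    return len(fivemer) == 5 and all(b in allowed for b, allowed in zip(fivemer, pattern))


def scan_motif_sites(
    transcript_id: str,
    sequence: str,
    motif_class: str = "RRACH",
    tally: dict | None = None,
) -> list[CandidateSite]:
    """Enumerate every motif-matching 5-mer on a reference sequence.

    Windows containing ambiguous (non-ACGT) characters are skipped and
    counted under ``tally['ambiguous_windows']`` -- a dirty reference is a
    warning, not a fatal condition.  Every RRACH site is by construction
    also a DRACH site.
    """
    if motif_class not in MOTIF_CLASSES:
        raise ValueError(f"motif_class must be one of {sorted(MOTIF_CLASSES)}")
    seq = normalize_sequence(sequence)
    sites: list[CandidateSite] = []
    n_ambiguous = 0
    for pos in range(2, len(seq) - 2):
        window = seq[pos - 2 : pos + 3]
        if any(b not in "ACGT" for b in window):
            n_ambiguous += 1
            continue
        if window[2] == "A" and fivemer_matches_motif(window, motif_class):
            sites.append(CandidateSite(transcript_id, pos, window, motif_class))
    if n_ambiguous:
        logger.warning(
            "%s: skipped %d windows with ambiguous characters", transcript_id, n_ambiguous
        )
        if tally is not None:
            tally["ambiguous_windows"] = tally.get("ambiguous_windows", 0) + n_ambiguous
    return sites


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a multi-record FASTA as {id: sequence}, with U mapped to T."""
    return {rec.id: normalize_sequence(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, references: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in references.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# event tables


def _data_lines(fh: TextIO) -> Iterator[tuple[int, str]]:
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def write_event_table(path: str | Path, reads: Iterable[EventAlignedRead]) -> None:
    """Write reads to the event-table TSV dialect (lossless: floats via repr)."""
    with open(path, "w") as fh:
        fh.write("\t".join(EVENT_TABLE_COLUMNS) + "\n")
        for read in reads:
            for ev in read.events:
                sig = ",".join(repr(float(s)) for s in ev.signals)
                fh.write(
                    f"{read.read_id}\t{read.transcript_id}\t{ev.ref_position}\t{ev.ref_base}\t{sig}\n"
                )


def read_event_table(path: str | Path) -> Iterator[EventAlignedRead]:
    """Stream reads from an event-table TSV, grouping contiguous rows by read.

    Raises :class:`FormatError` naming the read and line on non-monotone
    positions, empty signal lists, or malformed rows.
    """
    with open(path) as fh:
        lines = _data_lines(fh)
        try:
            _, header = next(lines)
        except StopIteration:
            raise FormatError(f"{path}: empty event table") from None
        if tuple(header.split("\t")) != EVENT_TABLE_COLUMNS:
            raise FormatError(f"{path}: bad header {header!r}")
        current_key: tuple[str, str] | None = None
        events: list[Event] = []
        seen: set[tuple[str, str]] = set()
        for lineno, line in lines:
            parts = line.split("\t")
            if len(parts) != len(EVENT_TABLE_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(EVENT_TABLE_COLUMNS)} columns")
            read_id, transcript_id, pos_s, base, sig_s = parts
            try:
                pos = int(pos_s)
                signals = tuple(float(x) for x in sig_s.split(",")) if sig_s else ()
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if not signals:
                raise FormatError(f"{path}:{lineno}: read {read_id}: empty signal list")
            key = (read_id, transcript_id)
            if key != current_key:
                if current_key is not None:
                    yield EventAlignedRead(current_key[0], current_key[1], events)
                if key in seen:
                    raise FormatError(
                        f"{path}:{lineno}: rows of read {read_id} are not contiguous"
                    )
                seen.add(key)
                current_key, events = key, []
            if events and pos <= events[-1].ref_position:
                raise FormatError(
                    f"{path}:{lineno}: read {read_id}: position {pos} not increasing"
                )
            events.append(Event(pos, normalize_base(base), signals))
        if current_key is not None:
            yield EventAlignedRead(current_key[0], current_key[1], events)


# ---------------------------------------------------------------------------
# alignment tables


def write_alignment_table(path: str | Path, records: Iterable[BaseAlignmentRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_TABLE_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                f"{rec.read_id}\t{rec.transcript_id}\t{rec.ref_position}\t{rec.ref_base}\t"
                f"{_STATUS_FROM_NAME[rec.status]}\t{rec.base_quality}\t{rec.insertion_count}\n"
            )


def read_alignment_table(path: str | Path) -> Iterator[BaseAlignmentRecord]:
    """Stream per-base alignment records from the alignment-table TSV."""
    with open(path) as fh:
        lines = _data_lines(fh)
        try:
            _, header = next(lines)
        except StopIteration:
            raise FormatError(f"{path}: empty alignment table") from None
        if tuple(header.split("\t")) != ALIGNMENT_TABLE_COLUMNS:
            raise FormatError(f"{path}: bad header {header!r}")
        for lineno, line in lines:
            parts = line.split("\t")
            if len(parts) != len(ALIGNMENT_TABLE_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(ALIGNMENT_TABLE_COLUMNS)} columns"
                )
            read_id, transcript_id, pos_s, base, status_tok, qual_s, ins_s = parts
            if status_tok not in STATUS_TOKENS:
                raise FormatError(f"{path}:{lineno}: unknown status token {status_tok!r}")
            try:
                pos, qual, ins = int(pos_s), int(qual_s), int(ins_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            try:
                yield BaseAlignmentRecord(
                    read_id,
                    transcript_id,
                    pos,
                    normalize_base(base),
                    STATUS_TOKENS[status_tok],
                    qual,
                    ins,
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
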