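"""Per-read mutation records: parsing, signature filtering and counting.

The module consumes parsed per-read mutation records (one read per TSV
line — the output of an aligner-side mutation parser) and implements the
DMS mutation-signature filter at the heart of four-base DMS-MaP: G→A
single-nucleotide mismatches, multi-nucleotide mismatches spanning a G,
and all insertions/deletions are structurally uninformative (they
predominantly report N7-G methylation and reverse-transcription noise)
and are set to "no data", while G→C / G→T mismatches — the signature of
the informative N1-G adduct — and all A/C/U mismatches are retained.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import ReferenceStructure, normalize_sequence

__all__ = [
    "EventKind",
    "MutationEvent",
    "ReadRecord",
    "PositionCounts",
    "classify_event",
    "count_profile",
    "mutation_spectrum",
    "read_parsed_tsv",
    "write_parsed_tsv",
    "read_fasta",
    "write_counts_tsv",
]


class EventKind(enum.Enum):
    MISMATCH = "mismatch"
    INSERTION = "insertion"
    DELETION = "deletion"
    MULTI = "multi"


@dataclass(frozen=True)
class MutationEvent:
    """One mutation event on the reference coordinate system.

    ``left``/``right`` are 1-based positions of the first/last changed
    reference base.  ``read_seq`` is empty for a pure deletion; for a pure
    insertion ``ref_seq`` is empty and ``left == right`` anchors the
    insertion to the reference base 5' of the inserted sequence.
    """

    left: int
    right: int
    ref_seq: str
    read_seq: str

    def __post_init__(self) -> None:
        if self.left > self.right:
            raise ValueError(f"event left {self.left} > right {self.right}")
        object.__setattr__(self, "ref_seq", self.ref_seq.upper().replace("T", "U"))
        object.__setattr__(self, "read_seq", self.read_seq.upper().replace("T", "U"))

    @property
    def kind(self) -> EventKind:
        nr, nq = len(self.ref_seq), len(self.read_seq)
        if nr == 0 and nq > 0:
            return EventKind.INSERTION
        if nq < nr:
            return EventKind.DELETION
        if nq > nr:
            return EventKind.INSERTION
        if nr == 1:
            return EventKind.MISMATCH
        return EventKind.MULTI

    def changed_positions(self) -> list[int]:
        """Reference positions where the read base differs from reference."""
        k = self.kind
        if k is EventKind.MISMATCH:
            return [self.left]
        if k is EventKind.MULTI:
            return [
                self.left + off
                for off, (a, b) in enumerate(zip(self.ref_seq, self.read_seq))
                if a != b
            ]
        # indels: attribute to the whole reference span (anchor for insertions)
        return list(range(self.left, self.right + 1))


@dataclass
class ReadRecord:
    """One read's covered reference span and its classified events."""

    read_id: str
    span_start: int
    span_end: int
    events: list[MutationEvent] = field(default_factory=list)
    valid: np.ndarray | None = None  # over [span_start, span_end]; None = all valid

    def __post_init__(self) -> None:
        if self.span_start > self.span_end:
            raise ValueError("span_start > span_end")
        self.events = sorted(self.events, key=lambda e: e.left)
        prev_right = -1
        for ev in self.events:
            if ev.left < self.span_start or ev.right > self.span_end:
                raise ValueError(
                    f"read {self.read_id}: event [{ev.left},{ev.right}] outside "
                    f"span [{self.span_start},{self.span_end}]"
                )
            if ev.left <= prev_right:
                raise ValueError(f"read {self.read_id}: overlapping events")
            prev_right = ev.right
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if len(self.valid) != self.span_end - self.span_start + 1:
                raise ValueError("valid mask length != span length")


@dataclass
class PositionCounts:
    """Per-position tallies after signature filtering.

    ``retained_mut[i]`` counts reads with a retained mutation at 1-based
    position i+1, ``effective_depth[i]`` reads with valid data there, and
    ``filtered[i]`` reads whose data at the position was removed by the
    signature filter.  ``by_type`` holds unrounded per-type event counts
    (keys like "G>A", "ins", "del", "multi") for diagnostic spectra.
    """

    sequence: str
    retained_mut: np.ndarray
    effective_depth: np.ndarray
    filtered: np.ndarray
    by_type: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    def rate(self) -> np.ndarray:
        """Mutation rate retained_mut / effective_depth; NaN at zero depth."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.effective_depth > 0,
                self.retained_mut / np.maximum(self.effective_depth, 1),
                np.nan,
            )


class Classification(enum.Enum):
    RETAINED = "retained"
    NO_DATA = "no_data"


RETAINED = Classification.RETAINED
NO_DATA = Classification.NO_DATA


def classify_event(event: MutationEvent, mode: str = "dms") -> Classification:
    """Apply the four-base DMS mutation-signature filter to one event.

    In ``dms`` mode: a G→A single-nucleotide mismatch, any multi-nucleotide
    mismatch whose reference span contains a G, and every insertion or
    deletion are "no data"; every other mismatch (G→C, G→T, and all A/C/U
    mismatches) is retained.  In ``unfiltered`` mode every event is
    retained (traditional DMS-MaP behaviour).
    """
    if mode == "unfiltered":
        return RETAINED
    if mode != "dms":
        raise ValueError(f"unknown mode {mode!r}")
    kind = event.kind
    if kind in (EventKind.INSERTION, EventKind.DELETION):
        return NO_DATA
    if kind is EventKind.MULTI:
        return NO_DATA if "G" in event.ref_seq else RETAINED
    # single-nucleotide mismatch
    if event.ref_seq == "G" and event.read_seq == "A":
        return NO_DATA
    return RETAINED


def _event_type_label(event: MutationEvent) -> str:
    k = event.kind
    if k is EventKind.MISMATCH:
        return f"{event.ref_seq}>{event.read_seq}"
    if k is EventKind.INSERTION:
        return "ins"
    if k is EventKind.DELETION:
        return "del"
    return "multi"


def count_profile(
    reads: list[ReadRecord],
    sequence: str,
    mode: str = "dms",
    collect_types: bool = False,
) -> PositionCounts:
    """Accumulate per-position retained-mutation and depth counts.

    For each read, filtered (no-data) events clear the read's validity over
    the event's reference span; retained events increment ``retained_mut``
    at each changed position.  ``effective_depth`` counts reads with valid
    data at the position.  N positions never accumulate counts.
    """
    sequence = normalize_sequence(sequence)
    n = len(sequence)
    retained = np.zeros(n, dtype=np.int64)
    depth = np.zeros(n, dtype=np.int64)
    filt = np.zeros(n, dtype=np.int64)
    by_type: dict[str, np.ndarray] = {}
    n_mask = np.array([b == "N" for b in sequence])

    for read in reads:
        if read.span_start < 1 or read.span_end > n:
            raise ValueError(
                f"read {read.read_id} span [{read.span_start},{read.span_end}] "
                f"outside sequence of length {n}"
            )
        lo = read.span_start - 1
        hi = read.span_end
        valid = np.ones(hi - lo, dtype=bool) if read.valid is None else read.valid.copy()
        for ev in read.events:
            cls = classify_event(ev, mode)
            a, b = ev.left - 1 - lo, ev.right - lo
            if cls is NO_DATA:
                valid[a:b] = False
                filt[ev.left - 1 : ev.right] += 1
            else:
                for pos in ev.changed_positions():
                    if not n_mask[pos - 1]:
                        retained[pos - 1] += 1
                if collect_types:
                    lab = _event_type_label(ev)
                    arr = by_type.setdefault(lab, np.zeros(n, dtype=np.int64))
                    for pos in ev.changed_positions():
                        arr[pos - 1] += 1
        valid[n_mask[lo:hi]] = False
        depth[lo:hi] += valid

    return PositionCounts(sequence, retained, depth, filt, by_type)


MUTATION_TYPES = [
    "A>C", "A>G", "A>U",
    "C>A", "C>G", "C>U",
    "G>A", "G>C", "G>U",
    "U>A", "U>C", "U>G",
    "ins", "del", "multi",
]


def mutation_spectrum(
    reads: list[ReadRecord],
    sequence: str,
    structure: ReferenceStructure,
) -> pd.DataFrame:
    """Per-reference-base mutation-type rates split by pairing status.

    Counting is unfiltered (spectra diagnose the filter; they must not
    presuppose it).  Rates divide type-specific event counts at positions
    of a given base and pairing status by the summed effective depth at
    those positions.  Returns a long-format DataFrame with columns
    ``base, mut_type, paired, rate, n_events, depth``.
    """
    sequence = normalize_sequence(sequence)
    if len(structure) != len(sequence):
        raise ValueError("structure length != sequence length")
    counts = count_profile(reads, sequence, mode="unfiltered", collect_types=True)
    paired = structure.is_paired()
    base_arr = np.frombuffer(sequence.encode(), dtype="S1").astype("U1")
    low_data = not reads
    if low_data:
        warnings.warn("mutation_spectrum: empty read set, all rates 0", stacklevel=2)

    rows = []
    for base in "ACGU":
        sel_base = base_arr == base
        for is_paired in (True, False):
            sel = sel_base & (paired == is_paired)
            depth = int(counts.effective_depth[sel].sum())
            for mt in MUTATION_TYPES:
                if ">" in mt and not mt.startswith(base):
                    continue
                arr = counts.by_type.get(mt)
                n_ev = int(arr[sel].sum()) if arr is not None and sel.any() else 0
                rate = n_ev / depth if depth > 0 else 0.0
                rows.append(
                    dict(base=base, mut_type=mt, paired=is_paired,
                         rate=rate, n_events=n_ev, depth=depth)
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: parsed-mutation TSV dialect and FASTA

def _format_events(events: list[MutationEvent]) -> str:
    return ";".join(
        f"{e.left}|{e.right}|{e.ref_seq}|{e.read_seq}" for e in events
    )


def _parse_events(text: str) -> list[MutationEvent]:
    if not text:
        return []
    out = []
    for tok in text.split(";"):
        parts = tok.split("|")
        if len(parts) != 4:
            raise ValueError(f"bad event token {tok!r}")
        left, right, ref_seq, read_seq = parts
        out.append(MutationEvent(int(left), int(right), ref_seq, read_seq))
    return out


def write_parsed_tsv(reads: list[ReadRecord], path: str) -> None:
    """Write reads in the parsed-mutation TSV dialect.

    One read per line: ``read_id  span_start  span_end  events`` where
    ``events`` is a semicolon-delimited list of ``left|right|ref|read``
    tokens (empty field = no events).  ShapeMapper parsed-mutation output
    converts to this dialect with a small adapter.
    """
    with open(path, "w") as fh:
        fh.write("read_id\tspan_start\tspan_end\tevents\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.span_start}\t{r.span_end}\t{_format_events(r.events)}\n"
            )


def read_parsed_tsv(path: str) -> list[ReadRecord]:
    """Read the parsed-mutation TSV dialect written by :func:`write_parsed_tsv`."""
    reads = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: missing parsed-mutation header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            rid, start, end, events = parts
            reads.append(
                ReadRecord(rid, int(start), int(end), _parse_events(events))
            )
    return reads


def read_fasta(path: str) -> tuple[str, str]:
    """Read the first record of a FASTA file; returns (name, RNA sequence)."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(path, "fasta"))
    return rec.id, normalize_sequence(str(rec.seq))


def write_counts_tsv(counts: PositionCounts, path: str) -> None:
    """Write per-position counted-mutations TSV."""
    cols = {
        "position": np.arange(1, len(counts) + 1),
        "base": list(counts.sequence),
        "retained_mut": counts.retained_mut,
        "effective_depth": counts.effective_depth,
        "filtered": counts.filtered,
    }
    for mt in sorted(counts.by_type):
        cols[mt] = counts.by_type[mt]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str) -> PositionCounts:
    """Read a counted-mutations TSV back into :class:`PositionCounts`."""
    df = pd.read_csv(path, sep="\t")
    base_cols = {"position", "base", "retained_mut", "effective_depth", "filtered"}
    by_type = {
        c: df[c].to_numpy(dtype=np.int64) for c in df.columns if c not in base_cols
    }
    return PositionCounts(
        "".join(df["base"].astype(str)),
        df["retained_mut"].to_numpy(dtype=np.int64),
        df["effective_depth"].to_numpy(dtype=np.int64),
        df["filtered"].to_numpy(dtype=np.int64),
        by_type,
    )
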