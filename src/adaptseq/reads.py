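"""FASTQ parsing, demultiplexing and per-sample QC for the ssODN library.

A read is *valid* iff the 20-nt constant anchor is found, within
``anchor_mismatch_tol`` substitutions, at an offset implying a stagger pad
length present in the design (anchor start minus variable length).  The 35
bases preceding the anchor are the variable-region feature; the bases
following it are the i7 index used for demultiplexing.  Invalid and
unassigned reads are counted, never silently dropped.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import LibraryDesign

__all__ = [
    "ReadRecord",
    "QCReport",
    "ParseResult",
    "parse_fastq",
    "library_summary",
    "read_fastq_records",
]

DEFAULT_CUTOFFS = (1, 2, 5, 10)
DEFAULT_Q30_THRESHOLD = 0.85


@dataclass
class ReadRecord:
    """One sequencing read: id, bases and per-base Phred scores."""

    id: str
    bases: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality values"
            )
        if self.qualities and not (0 <= min(self.qualities) and max(self.qualities) <= 60):
            raise ValueError(f"read {self.id!r}: Phred values outside [0, 60]")


@dataclass
class QCReport:
    """Library summary metrics for one sample (or a whole run).

    ``unique_at_cutoffs`` maps a raw-count cutoff c to the number of unique
    sequences observed at least c times; it is non-increasing in c.
    ``mean_copies_per_sequence`` is total counts / unique sequences — the
    quantity that rises sharply as an enrichment collapses diversity.
    """

    total_reads: int = 0
    valid_reads: int = 0
    unique_sequences: int = 0
    unique_at_cutoffs: dict[int, int] = field(default_factory=dict)
    mean_copies_per_sequence: float = 0.0
    pct_bases_ge_q30: float = 0.0
    q30_pass: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["unique_at_cutoffs"] = {str(k): v for k, v in self.unique_at_cutoffs.items()}
        return d


@dataclass
class ParseResult:
    """Demultiplexed counts plus run- and sample-level accounting."""

    counts: dict[str, Counter]          # sample_id -> {variable region: count}
    sample_qc: dict[str, QCReport]
    run_qc: QCReport
    invalid_reads: int                  # anchor not found at any stagger
    unassigned_reads: int               # anchor found, index missing/ambiguous

    def write_qc_json(self, path: str | Path) -> None:
        payload = {
            "run": self.run_qc.to_dict(),
            "invalid_reads": self.invalid_reads,
            "unassigned_reads": self.unassigned_reads,
            "samples": {s: qc.to_dict() for s, qc in self.sample_qc.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq_records(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a plain or gzipped 4-line FASTQ file as ReadRecords.

    Malformed input raises a ValueError identifying the failing record.
    """
    n = 0
    try:
        with _open_maybe_gzip(path) as handle:
            for title, seq, qual in FastqGeneralIterator(handle):
                n += 1
                yield ReadRecord(
                    id=title.split()[0] if title else f"read{n}",
                    bases=seq.upper(),
                    qualities=[ord(c) - 33 for c in qual],
                )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ at record {n + 1}: {exc}") from exc


def _mismatches_at(read: str, pattern: str, start: int, tol: int) -> int:
    """Mismatch count of pattern against read[start:], early-exiting past tol."""
    m = 0
    for i, c in enumerate(pattern):
        if read[start + i] != c:
            m += 1
            if m > tol:
                return m
    return m


def _match_index(
    observed: str, index_to_sample: Mapping[str, str], tol: int
) -> str | None:
    """Assign an index read to a sample, or None if absent/ambiguous."""
    if tol == 0:
        return index_to_sample.get(observed)
    best: str | None = None
    n_hits = 0
    for idx, sample in index_to_sample.items():
        m = 0
        for a, b in zip(observed, idx):
            if a != b:
                m += 1
                if m > tol:
                    break
        else:
            n_hits += 1
            best = sample
    return best if n_hits == 1 else None


def parse_fastq(
    records: Iterable[ReadRecord] | str | Path,
    design: LibraryDesign,
    sample_sheet: Mapping[str, str] | None = None,
    anchor_mismatch_tol: int = 1,
    index_mismatch_tol: int = 1,
    q30_threshold: float = DEFAULT_Q30_THRESHOLD,
    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS,
) -> ParseResult:
    """Demultiplex reads into per-sample variable-region count tables.

    Parameters
    ----------
    records:
        Iterable of :class:`ReadRecord`, or a path to a (gzipped) FASTQ file.
    sample_sheet:
        Mapping i7 index sequence -> sample_id.  Defaults to the design's
        ``i7_indices`` inverted.
    anchor_mismatch_tol, index_mismatch_tol:
        Substitution tolerances for the constant anchor and the index.
        Defaults of 1 tolerate a single sequencing error.

    Anchor search walks the configured stagger offsets in increasing order
    and takes the first offset at which the anchor matches; the preceding
    ``variable_length`` bases become the counted feature.  A read whose
    index matches no sample — or more than one within tolerance — is
    counted as unassigned.
    """
    if anchor_mismatch_tol < 0 or index_mismatch_tol < 0:
        raise ValueError("mismatch tolerances must be >= 0")
    if isinstance(records, (str, Path)):
        records = read_fastq_records(records)

    if sample_sheet is None:
        index_to_sample = {idx: s for s, idx in design.i7_indices.items()}
    else:
        index_to_sample = dict(sample_sheet)
    if not index_to_sample:
        raise ValueError("no indices to demultiplex against")
    known = {idx: s for s, idx in design.i7_indices.items()}
    for idx, s in index_to_sample.items():
        if known and known.get(idx) != s:
            raise ValueError(
                f"sample sheet index {idx!r} -> {s!r} disagrees with the design"
            )
    index_len = len(next(iter(index_to_sample)))

    anchor = design.anchor
    var_len = design.variable_length
    offsets = sorted(design.stagger_offsets)

    counts: dict[str, Counter] = {s: Counter() for s in index_to_sample.values()}
    assigned_reads: Counter = Counter()
    total = 0
    invalid = 0
    unassigned = 0
    bases_total = 0
    bases_q30 = 0

    for rec in records:
        total += 1
        bases_total += len(rec.qualities)
        bases_q30 += sum(q >= 30 for q in rec.qualities)
        read = rec.bases

        found_offset = -1
        for off in offsets:
            astart = off + var_len
            if astart + len(anchor) > len(read):
                continue
            if _mismatches_at(read, anchor, astart, anchor_mismatch_tol) <= anchor_mismatch_tol:
                found_offset = off
                break
        if found_offset < 0:
            invalid += 1
            continue

        idx_start = found_offset + var_len + len(anchor)
        observed_idx = read[idx_start : idx_start + index_len]
        if len(observed_idx) < index_len:
            unassigned += 1
            continue
        sample = _match_index(observed_idx, index_to_sample, index_mismatch_tol)
        if sample is None:
            unassigned += 1
            continue

        variable = read[found_offset : found_offset + var_len]
        counts[sample][variable] += 1
        assigned_reads[sample] += 1

    pct_q30 = bases_q30 / bases_total if bases_total else 0.0
    sample_qc: dict[str, QCReport] = {}
    for sample, ctr in counts.items():
        if ctr:
            qc = library_summary(ctr, cutoffs=cutoffs)
        else:
            qc = QCReport()
        qc.total_reads = assigned_reads[sample]
        qc.valid_reads = assigned_reads[sample]
        qc.pct_bases_ge_q30 = pct_q30
        qc.q30_pass = pct_q30 >= q30_threshold
        sample_qc[sample] = qc

    pooled: Counter = Counter()
    for ctr in counts.values():
        pooled.update(ctr)
    run_qc = library_summary(pooled, cutoffs=cutoffs) if pooled else QCReport()
    run_qc.total_reads = total
    run_qc.valid_reads = total - invalid - unassigned
    run_qc.pct_bases_ge_q30 = pct_q30
    run_qc.q30_pass = pct_q30 >= q30_threshold

    return ParseResult(
        counts=counts,
        sample_qc=sample_qc,
        run_qc=run_qc,
        invalid_reads=invalid,
        unassigned_reads=unassigned,
    )


def library_summary(
    column: Mapping[str, int] | Counter,
    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS,
) -> QCReport:
    """Library population metrics for one sample's raw counts.

    mean copies per sequence = total counts / unique sequences; the cutoff
    table counts unique sequences with raw count >= c for each cutoff c.
    """
    if not column:
        raise ValueError("library_summary: empty count column")
    values = list(column.values())
    total = sum(values)
    if total <= 0:
        raise ValueError("library_summary: column total must be > 0")
    unique = len(values)
    return QCReport(
        total_reads=total,
        valid_reads=total,
        unique_sequences=unique,
        unique_at_cutoffs={c: sum(v >= c for v in values) for c in sorted(cutoffs)},
        mean_copies_per_sequence=total / unique,
    )
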