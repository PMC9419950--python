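"""Read-pair merging, structure filtering, and barcode demultiplexing.

Amplicon templates are short enough that the paired 150-nt reads always
overlap, so each pair is merged into a single consensus sequence before
anything else. Merged reads must then match the expected library
structure — a known 5-nt barcode, immediately followed by that sample's
forward-primer annealing part, and ending with the associated
reverse-primer annealing part — before being assigned to a sample.
Reads failing any stage are counted, never silently dropped: the
conservation identity

    input pairs = merge failures + structure rejects + demultiplexed

holds exactly on every run.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import ConfigError
from .sequtils import revcomp
from .synthetic import SampleSpec

DEFAULT_MIN_OVERLAP = 20
DEFAULT_MAX_MISMATCH_FRAC = 0.1
DEFAULT_MAX_PRIMER_MISMATCH = 1
BARCODE_LEN = 5


@dataclass
class MergedRead:
    id: str
    sequence: str
    quality: str
    overlap_length: int
    mismatches_in_overlap: int


@dataclass
class StructuredRead:
    """A merged read that passed the barcode/primer structure filter.

    ``insert`` is the amplicon-derived part: the barcode and, by default,
    the primer annealing parts are trimmed so that sequencing errors in
    primer regions can never be counted as locus indels downstream.
    """

    id: str
    sample_id: str
    insert: str
    barcode_ok: bool = True
    fwd_primer_ok: bool = True
    rev_primer_ok: bool = True


@dataclass
class Rejection:
    id: str
    reason: str  # "merge" | "barcode" | "fwd_primer" | "rev_primer"


# ---------------------------------------------------------------------------
# pair merging


def merge_pairs(
    r1_seq: str,
    r1_qual: str,
    r2_seq: str,
    r2_qual: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    read_id: str = "",
) -> MergedRead | None:
    """Merge a read pair by overlapping r1's 3' end with the 5' end of
    the reverse complement of r2.

    Every candidate overlap length from ``min_overlap`` up to the full
    shorter-read length is scored; the overlap minimising the mismatch
    fraction wins, ties broken by the longer overlap. Consensus bases in
    the overlap come from whichever read has the higher quality (r1 on
    ties). Returns ``None`` when no candidate satisfies
    ``max_mismatch_frac``.
    """
    if not r1_seq or not r2_seq:
        return None
    if not 0 <= max_mismatch_frac < 0.5:
        raise ConfigError("max_mismatch_frac must be in [0, 0.5)")
    rc2 = revcomp(r2_seq)
    rq2 = r2_qual[::-1]
    a1 = np.frombuffer(r1_seq.encode(), dtype="S1")
    a2 = np.frombuffer(rc2.encode(), dtype="S1")
    n1, n2 = len(r1_seq), len(rc2)
    max_l = min(n1, n2)
    if max_l < min_overlap:
        return None

    # scan longest-first: a zero-mismatch overlap cannot be beaten (ties
    # prefer the longer overlap, already visited), so stop there
    best: tuple[float, int, int] | None = None  # (frac, -L, mismatches)
    for length in range(max_l, min_overlap - 1, -1):
        mism = int((a1[n1 - length :] != a2[:length]).sum())
        frac = mism / length
        key = (frac, -length)
        if best is None or key < (best[0], best[1]):
            best = (frac, -length, mism)
        if mism == 0:
            break
    assert best is not None
    frac, neg_l, mism = best
    length = -neg_l
    if frac > max_mismatch_frac:
        return None

    # consensus across the overlap: higher-quality base wins, r1 on ties
    head_seq = r1_seq[: n1 - length]
    head_qual = r1_qual[: n1 - length]
    ov_seq = []
    ov_qual = []
    for k in range(length):
        b1, q1 = r1_seq[n1 - length + k], r1_qual[n1 - length + k]
        b2, q2 = rc2[k], rq2[k]
        if b1 == b2 or q1 >= q2:
            ov_seq.append(b1)
        else:
            ov_seq.append(b2)
        ov_qual.append(max(q1, q2))
    tail_seq = rc2[length:]
    tail_qual = rq2[length:]
    return MergedRead(
        id=read_id,
        sequence=head_seq + "".join(ov_seq) + tail_seq,
        quality=head_qual + "".join(ov_qual) + tail_qual,
        overlap_length=length,
        mismatches_in_overlap=mism,
    )


# ---------------------------------------------------------------------------
# structure filter


def _hamming_at_most(a: str, b: str, budget: int) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > budget:
                return False
    return True


def build_barcode_table(samples: list[SampleSpec]) -> dict[str, SampleSpec]:
    """Index samples by barcode, rejecting duplicate barcodes within a
    pool (they would make sample identity ambiguous)."""
    table: dict[str, SampleSpec] = {}
    for s in samples:
        if s.barcode in table:
            raise ConfigError(
                f"duplicate barcode {s.barcode!r} for samples "
                f"{table[s.barcode].sample_id!r} and {s.sample_id!r}"
            )
        table[s.barcode] = s
    return table


def filter_structure(
    read: MergedRead,
    barcode_table: dict[str, SampleSpec],
    max_primer_mismatch: int = DEFAULT_MAX_PRIMER_MISMATCH,
    trim: bool = True,
) -> StructuredRead | Rejection:
    """Check the expected read structure and assign a sample.

    The read must start with a known barcode (matched exactly — barcode
    errors must never reassign a read to another sample), immediately
    followed by that sample's forward-primer annealing part (up to
    ``max_primer_mismatch`` substitutions), and end with the reverse
    complement of the sample's reverse primer (same budget). With
    ``trim`` the returned insert excludes barcode and primer parts.
    """
    if not barcode_table:
        raise ConfigError("barcode table is empty")
    seq = read.sequence
    sample = barcode_table.get(seq[:BARCODE_LEN])
    if sample is None:
        return Rejection(read.id, "barcode")
    fwd = sample.fwd_primer
    if not _hamming_at_most(
        seq[BARCODE_LEN : BARCODE_LEN + len(fwd)], fwd, max_primer_mismatch
    ):
        return Rejection(read.id, "fwd_primer")
    rev_site = revcomp(sample.rev_primer)
    if not _hamming_at_most(
        seq[len(seq) - len(rev_site) :], rev_site, max_primer_mismatch
    ):
        return Rejection(read.id, "rev_primer")
    if trim:
        insert = seq[BARCODE_LEN + len(fwd) : len(seq) - len(rev_site)]
    else:
        insert = seq
    return StructuredRead(id=read.id, sample_id=sample.sample_id, insert=insert)


# ---------------------------------------------------------------------------
# demultiplexing


@dataclass
class DemuxResult:
    by_sample: dict[str, list[StructuredRead]]
    counts: dict[str, int]
    rejects: dict[str, int] = field(default_factory=dict)

    @property
    def accepted_total(self) -> int:
        return sum(self.counts.values())


def demultiplex(reads: Iterable[StructuredRead]) -> DemuxResult:
    """Partition structure-accepted reads by sample."""
    by_sample: dict[str, list[StructuredRead]] = {}
    counts: dict[str, int] = {}
    for read in reads:
        by_sample.setdefault(read.sample_id, []).append(read)
        counts[read.sample_id] = counts.get(read.sample_id, 0) + 1
    return DemuxResult(by_sample=by_sample, counts=counts)


# ---------------------------------------------------------------------------
# FASTQ I/O and the full preprocessing pass


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a FASTQ file, gzip or plain."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        n = 0
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            n += 1
            if not header.startswith("@") or not plus.startswith("+") or (
                len(seq) != len(qual)
            ):
                raise ValueError(f"malformed FASTQ record #{n} in {path}")
            yield header[1:].split()[0], seq, qual


@dataclass
class PreprocessReport:
    """Stage counts for one preprocessing pass. Satisfies
    ``total_pairs == merge_failures + structure_rejects + accepted``."""

    total_pairs: int
    merge_failures: int
    rejects_by_reason: dict[str, int]
    demux: DemuxResult

    @property
    def structure_rejects(self) -> int:
        return sum(self.rejects_by_reason.values())

    @property
    def accepted(self) -> int:
        return self.demux.accepted_total

    @property
    def conserved(self) -> bool:
        return (
            self.total_pairs
            == self.merge_failures + self.structure_rejects + self.accepted
        )


def preprocess_pairs(
    pairs: Iterable[tuple[str, str, str, str, str]],
    samples: list[SampleSpec],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    max_primer_mismatch: int = DEFAULT_MAX_PRIMER_MISMATCH,
    trim: bool = True,
) -> PreprocessReport:
    """Merge, structure-filter and demultiplex an iterable of
    ``(id, seq1, qual1, seq2, qual2)`` tuples."""
    table = build_barcode_table(samples)
    total = 0
    merge_failures = 0
    rejects: dict[str, int] = {}
    accepted: list[StructuredRead] = []
    for read_id, s1, q1, s2, q2 in pairs:
        total += 1
        merged = merge_pairs(
            s1, q1, s2, q2, min_overlap, max_mismatch_frac, read_id=read_id
        )
        if merged is None:
            merge_failures += 1
            continue
        result = filter_structure(merged, table, max_primer_mismatch, trim)
        if isinstance(result, Rejection):
            rejects[result.reason] = rejects.get(result.reason, 0) + 1
            continue
        accepted.append(result)
    return PreprocessReport(
        total_pairs=total,
        merge_failures=merge_failures,
        rejects_by_reason=rejects,
        demux=demultiplex(accepted),
    )


def iter_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str, str, str, str]]:
    """Iterate paired FASTQ files in lockstep as preprocess input."""
    for (id1, s1, q1), (id2, s2, q2) in zip(
        read_fastq(r1_path), read_fastq(r2_path), strict=True
    ):
        if id1 != id2:
            raise ValueError(f"unpaired reads: {id1!r} vs {id2!r}")
        yield id1, s1, q1, s2, q2
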