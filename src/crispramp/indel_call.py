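"""Alignment of demultiplexed reads to amplicon references and
CIGAR-based indel calling.

Reads are aligned with a *fit* alignment — the read is aligned globally,
the reference locally (free end gaps on the reference) — under affine gap
penalties, against every candidate amplicon in the pool. The
best-scoring locus wins; reads scoring below threshold, or tying between
two loci, are left unassigned rather than guessed. Insertions and
deletions are then read off the alignment's operation list (CIGAR
semantics) with reference coordinates and lengths, from which per-locus
position and length spectra are built.

Aligning to the handful of known amplicon references replaces
genome-wide read mapping: the loci are user-supplied, so nothing is
gained by searching a whole genome, and the pipeline stays free of
external aligner binaries. This is the one deliberate methodological
substitution in the pipeline.

Default scores (match +2, mismatch -3, gap open -8, gap extend -1,
where a length-L gap costs ``open + (L-1)*extend``) are chosen so that
isolated Q30-level substitution errors are absorbed as mismatches
rather than opening spurious gaps.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .errors import ValidationError
from .synthetic import AmpliconLocus

# CIGAR-style operations: M consumes both sequences (match or mismatch),
# I consumes read only (insertion to the reference), D consumes
# reference only (deletion from the reference).
OP_MATCH = "M"
OP_INS = "I"
OP_DEL = "D"


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0  # score of the first gap base
    gap_extend: float = -1.0  # each subsequent gap base
    min_score_frac: float = 0.5
    """Assignment threshold as a fraction of the perfect-match score
    (``match * read_length``)."""


@dataclass
class Alignment:
    read_id: str
    locus: str
    ref_start: int
    operations: list[tuple[str, int]]
    score: float

    def __post_init__(self) -> None:
        for op, length in self.operations:
            if op not in (OP_MATCH, OP_INS, OP_DEL):
                raise ValidationError(f"unknown operation {op!r}")
            if length < 1:
                raise ValidationError("zero-length alignment operation")
        for (a, _), (b, _) in zip(self.operations, self.operations[1:]):
            if a == b:
                raise ValidationError("adjacent same-type operations")

    @property
    def cigar(self) -> str:
        return "".join(f"{l}{op}" for op, l in self.operations)

    @property
    def ref_span(self) -> int:
        return sum(l for op, l in self.operations if op in (OP_MATCH, OP_DEL))

    @property
    def read_span(self) -> int:
        return sum(l for op, l in self.operations if op in (OP_MATCH, OP_INS))


@dataclass(frozen=True)
class IndelEvent:
    """A single insertion or deletion in reference coordinates.

    ``position`` is 0-based: a between-base index for insertions, the
    leftmost deleted base for deletions.
    """

    type: str  # "insertion" | "deletion"
    position: int
    length: int

    def __post_init__(self) -> None:
        if self.type not in ("insertion", "deletion"):
            raise ValidationError(f"bad indel type {self.type!r}")
        if self.length < 1:
            raise ValidationError("indel length must be >= 1")

    @property
    def signed_length(self) -> int:
        return self.length if self.type == "insertion" else -self.length


# ---------------------------------------------------------------------------
# pairwise fit alignment


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    # reference overhangs (query-row gaps at the ends) are free: the read
    # need only fit somewhere inside the amplicon
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            aligner.open_left_deletion_score = 0.0
            aligner.extend_left_deletion_score = 0.0
            aligner.open_right_deletion_score = 0.0
            aligner.extend_right_deletion_score = 0.0
        except AttributeError:  # Biopython < 1.86 naming
            aligner.query_left_open_gap_score = 0.0
            aligner.query_left_extend_gap_score = 0.0
            aligner.query_right_open_gap_score = 0.0
            aligner.query_right_extend_gap_score = 0.0
    return aligner


def _ops_from_biopython(aln) -> tuple[int, list[tuple[str, int]]]:
    """Convert a Biopython alignment into (ref_start, CIGAR operations),
    dropping free reference overhangs outside the aligned span."""
    blocks_t, blocks_q = aln.aligned  # target = reference, query = read
    ops: list[tuple[str, int]] = []
    ref_start = int(blocks_t[0][0])

    def push(op: str, length: int) -> None:
        if length <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    # read bases before the first aligned block are insertions
    push(OP_INS, int(blocks_q[0][0]))
    prev_t_end = prev_q_end = None
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        if prev_t_end is not None:
            push(OP_DEL, int(t0 - prev_t_end))
            push(OP_INS, int(q0 - prev_q_end))
        push(OP_MATCH, int(t1 - t0))
        prev_t_end, prev_q_end = t1, q1
    # read bases after the last aligned block
    push(OP_INS, int(len(aln.sequences[1]) - prev_q_end))
    return ref_start, ops


def fit_align(
    read: str,
    reference: str,
    params: AlignmentParams = AlignmentParams(),
    read_id: str = "",
    locus_name: str = "",
) -> Alignment:
    """Fit-align a read inside a reference and return the gapped
    alignment with CIGAR-style operations."""
    aligner = _make_aligner(params)
    aln = aligner.align(reference, read)[0]
    ref_start, ops = _ops_from_biopython(aln)
    return Alignment(
        read_id=read_id,
        locus=locus_name,
        ref_start=ref_start,
        operations=ops,
        score=float(aln.score),
    )


def fit_score(
    read: str, reference: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Optimal fit-alignment score only (cheaper than a full traceback)."""
    return float(_make_aligner(params).score(reference, read))


def align_read(
    insert: str,
    loci: Sequence[AmpliconLocus],
    params: AlignmentParams = AlignmentParams(),
    read_id: str = "",
) -> Alignment | None:
    """Assign a read to its best-scoring locus and return the alignment.

    Returns ``None`` (unassigned) when the best score falls below
    ``min_score_frac * match * len(insert)`` or when the two best loci
    tie — an ambiguous read must never be double-counted.
    """
    if not insert:
        raise ValidationError("empty read")
    if not loci:
        raise ValidationError("no candidate loci")
    scores = [fit_score(insert, l.reference, params) for l in loci]
    order = sorted(range(len(loci)), key=lambda i: scores[i], reverse=True)
    best = order[0]
    if scores[best] < params.min_score_frac * params.match * len(insert):
        return None
    if len(loci) > 1 and scores[order[1]] == scores[best]:
        return None
    return fit_align(
        insert,
        loci[best].reference,
        params,
        read_id=read_id,
        locus_name=loci[best].name,
    )


# ---------------------------------------------------------------------------
# indel extraction


def indels_from_cigar(aln: Alignment) -> list[IndelEvent]:
    """One event per insertion/deletion operation, in reference
    coordinates; match/mismatch operations yield nothing."""
    events = []
    ref_pos = aln.ref_start
    for op, length in aln.operations:
        if op == OP_MATCH:
            ref_pos += length
        elif op == OP_DEL:
            events.append(IndelEvent("deletion", ref_pos, length))
            ref_pos += length
        elif op == OP_INS:
            events.append(IndelEvent("insertion", ref_pos, length))
    return events


def read_has_indel(
    aln: Alignment, window: tuple[int, int] | None = None
) -> bool:
    """True iff the alignment contains at least one indel event —
    anywhere by default, or within the half-open reference ``window``."""
    events = indels_from_cigar(aln)
    if window is None:
        return bool(events)
    lo, hi = window
    return any(lo <= e.position < hi for e in events)


def indel_spectra(
    events: Iterable[IndelEvent], locus: AmpliconLocus
) -> tuple[Counter, Counter]:
    """Position spectrum (reference coordinate relative to the cut site)
    and signed-length spectrum (+insertion, -deletion)."""
    positions: Counter = Counter()
    lengths: Counter = Counter()
    for e in events:
        positions[e.position - locus.cut_position] += 1
        lengths[e.signed_length] += 1
    return positions, lengths


# ---------------------------------------------------------------------------
# batch calling


def call_reads(
    by_sample: dict[str, list],
    loci: Sequence[AmpliconLocus],
    params: AlignmentParams = AlignmentParams(),
    window_halfwidth: int | None = None,
) -> pd.DataFrame:
    """Align every demultiplexed read and tabulate per-read indel calls.

    Columns: read_id, sample_id, locus, assigned, has_indel, n_events,
    events (semicolon-joined ``type@pos:len``). With ``window_halfwidth``
    set, only events within that distance of the assigned locus's cut
    site count towards ``has_indel``; by default any indel in the read
    counts, mirroring whole-read CIGAR scoring.

    Identical inserts are aligned once and the result reused — amplicon
    pools contain many exact duplicate reads.
    """
    locus_by_name = {l.name: l for l in loci}
    cache: dict[str, tuple] = {}
    rows = []
    for sample_id, reads in by_sample.items():
        for read in reads:
            hit = cache.get(read.insert)
            if hit is None:
                aln = align_read(read.insert, loci, params)
                if aln is None:
                    hit = (None, None, None)
                else:
                    events = indels_from_cigar(aln)
                    hit = (aln.locus, events, aln)
                cache[read.insert] = hit
            locus_name, events, aln = hit
            if locus_name is None:
                rows.append(
                    {
                        "read_id": read.id,
                        "sample_id": sample_id,
                        "locus": "",
                        "assigned": False,
                        "has_indel": False,
                        "n_events": 0,
                        "events": "",
                    }
                )
                continue
            if window_halfwidth is not None:
                cut = locus_by_name[locus_name].cut_position
                window = (cut - window_halfwidth, cut + window_halfwidth)
                has = any(
                    window[0] <= e.position < window[1] for e in events
                )
            else:
                has = bool(events)
            rows.append(
                {
                    "read_id": read.id,
                    "sample_id": sample_id,
                    "locus": locus_name,
                    "assigned": True,
                    "has_indel": has,
                    "n_events": len(events),
                    "events": ";".join(
                        f"{e.type}@{e.position}:{e.length}" for e in events
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "sample_id",
            "locus",
            "assigned",
            "has_indel",
            "n_events",
            "events",
        ],
    )


def reconstruct_read(aln: Alignment, reference: str, read: str) -> str:
    """Rebuild the read from the reference plus the operation list —
    insertions take their bases from the read itself. Used to verify
    CIGAR round-trips."""
    out = []
    ref_pos = aln.ref_start
    read_pos = 0
    for op, length in aln.operations:
        if op == OP_MATCH:
            out.append(read[read_pos : read_pos + length])
            ref_pos += length
            read_pos += length
        elif op == OP_DEL:
            ref_pos += length
        elif op == OP_INS:
            out.append(read[read_pos : read_pos + length])
            read_pos += length
    return "".join(out)


def alignment_to_sam(
    alignments: Iterable[tuple[Alignment, str, str]],
    loci: Sequence[AmpliconLocus],
) -> str:
    """Render alignments as SAM text (proper @SQ header, CIGAR).

    Takes ``(alignment, read_seq, read_qual)`` triples. Soft-clips are
    never produced — reads align globally — so CIGAR strings contain
    only M/I/D.
    """
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for l in loci:
        lines.append(f"@SQ\tSN:{l.name}\tLN:{len(l.reference)}")
    for aln, seq, qual in alignments:
        lines.append(
            "\t".join(
                [
                    aln.read_id or "*",
                    "0",
                    aln.locus,
                    str(aln.ref_start + 1),
                    "60",
                    aln.cigar,
                    "*",
                    "0",
                    "0",
                    seq,
                    qual or "*",
                ]
            )
        )
    return "\n".join(lines) + "\n"
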