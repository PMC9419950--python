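"""Synthetic amplicon sequencing runs with known ground-truth editing.

Emulates the structure of a pooled CRISPR amplicon deep-sequencing
experiment: each sample's template molecules consist of a 5-nt inline
barcode followed by the amplicon (whose first bases are the forward
primer annealing part and whose last bases are the reverse complement of
the reverse primer annealing part). Cas9-induced indels are concentrated
at the cut site — 3 bp from the PAM-proximal protospacer boundary —
at a condition-dependent frequency, and paired 150-nt reads are taken
from the template ends with uniform substitution errors. A truth table
records per-read editing status so pipeline estimates can be compared
with exact ground truth.

Everything is deterministic given the master seed.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .sequtils import check_dna, revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: offset of the blunt cut from the PAM-proximal protospacer boundary
CUT_OFFSET = 3
PROTOSPACER_LEN = 20


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AmpliconLocus:
    """An on- or off-target amplicon reference.

    ``protospacer_interval`` is 0-based half-open on ``reference``;
    ``cut_position`` is a 0-based between-base index (the blunt cut falls
    between protospacer positions 17 and 18, i.e. 3 bp from the
    PAM-proximal end).
    """

    name: str
    role: str  # "on_target" | "off_target"
    reference: str
    protospacer_interval: tuple[int, int]
    protospacer_strand: str  # "+" | "-"
    pam: str
    cut_position: int

    def __post_init__(self) -> None:
        start, end = self.protospacer_interval
        if not (0 <= start < end <= len(self.reference)):
            raise ValidationError("protospacer interval outside reference")
        if self.protospacer_strand not in "+-":
            raise ValidationError("strand must be '+' or '-'")

    @property
    def protospacer(self) -> str:
        """Protospacer 5'->3' on its own strand."""
        start, end = self.protospacer_interval
        seq = self.reference[start:end]
        return seq if self.protospacer_strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class SampleSpec:
    """One experimental unit in a sequencing pool."""

    sample_id: str
    barcode: str  # 5 nt, inline at the 5' end of read 1
    fwd_primer: str
    rev_primer: str
    locus: str  # AmpliconLocus name
    inhibitor_kind: str = "none"
    relative_concentration: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if len(self.barcode) != 5:
            raise ValidationError("barcode must be exactly 5 nt")
        check_dna(self.barcode, "barcode")
        if self.relative_concentration < 0:
            raise ValidationError("relative_concentration must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Generation parameters for a simulated run.

    ``true_indel_rate`` may be a single rate applied to every sample or a
    mapping from sample_id to rate.
    """

    true_indel_rate: float | Mapping[str, float] = 0.4
    deletion_fraction: float = 0.6
    p_len: float = 0.3  # geometric indel-length parameter
    max_indel_len: int = 30
    jitter: int = 2  # indel position = cut +/- uniform(jitter)
    substitution_error_rate: float = 0.001
    read_length: int = 150
    n_reads: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.true_indel_rate.values()
            if isinstance(self.true_indel_rate, Mapping)
            else [self.true_indel_rate]
        )
        for r in rates:
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"true_indel_rate {r} outside [0, 1]")
        for name in ("deletion_fraction", "substitution_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} {v} outside [0, 1]")
        if not 0.0 < self.p_len <= 1.0:
            raise ConfigError("p_len must be in (0, 1]")
        if self.read_length < 1 or self.n_reads < 0:
            raise ConfigError("read_length/n_reads out of range")

    def rate_for(self, sample_id: str) -> float:
        if isinstance(self.true_indel_rate, Mapping):
            try:
                return self.true_indel_rate[sample_id]
            except KeyError:
                raise ConfigError(f"no true_indel_rate for {sample_id!r}")
        return self.true_indel_rate


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


# ---------------------------------------------------------------------------
# locus construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _embed_protospacer(
    rng: np.random.Generator,
    amplicon_length: int,
    protospacer: str,
    strand: str,
) -> tuple[str, tuple[int, int], str, int]:
    """Place protospacer+PAM into a fresh random amplicon.

    Returns (reference, interval, pam, cut_position). The site is kept
    away from the 20-nt primer annealing regions at either end.
    """
    amp = list(_random_seq(rng, amplicon_length))
    margin = 30
    start = int(
        rng.integers(margin, amplicon_length - margin - PROTOSPACER_LEN - 3)
    )
    end = start + PROTOSPACER_LEN
    pam = "ATGC"[int(rng.integers(4))] + "GG"
    if strand == "+":
        amp[start:end] = protospacer
        amp[end : end + 3] = pam
        cut = start + PROTOSPACER_LEN - CUT_OFFSET
    else:
        amp[start:end] = revcomp(protospacer)
        amp[start - 3 : start] = revcomp(pam)
        cut = start + CUT_OFFSET
    return "".join(amp), (start, end), pam, cut


def make_loci(
    seed: int,
    n_off_targets: int = 2,
    mismatches_per_off_target: int = 2,
    amplicon_length: int = 240,
) -> list[AmpliconLocus]:
    """One on-target locus plus off-target loci whose protospacers differ
    from the on-target protospacer at exactly the requested number of
    positions, each embedded in an otherwise unrelated random amplicon
    with a valid NGG PAM. Deterministic given ``seed``.
    """
    if n_off_targets < 0:
        raise ValidationError("n_off_targets must be >= 0")
    if not 0 <= mismatches_per_off_target <= PROTOSPACER_LEN:
        raise ValidationError(
            f"mismatches_per_off_target must be in [0, {PROTOSPACER_LEN}]"
        )
    rng = np.random.default_rng([seed, 101])
    on_protospacer = _random_seq(rng, PROTOSPACER_LEN)
    loci = []
    ref, interval, pam, cut = _embed_protospacer(
        rng, amplicon_length, on_protospacer, "+"
    )
    loci.append(
        AmpliconLocus(
            name="on_target",
            role="on_target",
            reference=ref,
            protospacer_interval=interval,
            protospacer_strand="+",
            pam=pam,
            cut_position=cut,
        )
    )
    for k in range(n_off_targets):
        proto = list(on_protospacer)
        positions = rng.choice(
            PROTOSPACER_LEN, size=mismatches_per_off_target, replace=False
        )
        for p in positions:
            alternatives = [b for b in "ACGT" if b != proto[p]]
            proto[p] = alternatives[int(rng.integers(3))]
        strand = "+" if rng.integers(2) == 0 else "-"
        ref, interval, pam, cut = _embed_protospacer(
            rng, amplicon_length, "".join(proto), strand
        )
        loci.append(
            AmpliconLocus(
                name=f"off_target_{k + 1}",
                role="off_target",
                reference=ref,
                protospacer_interval=interval,
                protospacer_strand=strand,
                pam=pam,
                cut_position=cut,
            )
        )
    return loci


# ---------------------------------------------------------------------------
# sample sheets

PRIMER_LEN = 20


def make_samples(
    loci: list[AmpliconLocus],
    conditions: list[dict] | None = None,
    seed: int = 0,
) -> list[SampleSpec]:
    """Build a sample sheet: one sample per (locus, condition) with a
    unique 5-nt barcode per pool. Primer annealing parts are the first
    and last 20 nt of each amplicon (reverse primer given 5'->3' on its
    own strand).

    ``conditions`` rows may carry ``inhibitor_kind``,
    ``relative_concentration`` and ``replicate``; the default is a single
    no-inhibitor condition.
    """
    if conditions is None:
        conditions = [{}]
    rng = np.random.default_rng([seed, 202])
    barcodes: set[str] = set()
    samples = []
    for cond_idx, cond in enumerate(conditions):
        for locus in loci:
            while True:
                bc = _random_seq(rng, 5)
                if bc not in barcodes:
                    barcodes.add(bc)
                    break
            rep = int(cond.get("replicate", 1))
            kind = str(cond.get("inhibitor_kind", "none"))
            conc = float(cond.get("relative_concentration", 0.0))
            samples.append(
                SampleSpec(
                    sample_id=f"{locus.name}.c{cond_idx}.r{rep}",
                    barcode=bc,
                    fwd_primer=locus.reference[:PRIMER_LEN],
                    rev_primer=revcomp(locus.reference[-PRIMER_LEN:]),
                    locus=locus.name,
                    inhibitor_kind=kind,
                    relative_concentration=conc,
                    replicate=rep,
                )
            )
    return samples


# ---------------------------------------------------------------------------
# read simulation


def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(arr.size) < error_rate
    n_err = int(mask.sum())
    if n_err:
        # substitute with a uniformly chosen *different* base
        current = arr[mask]
        subs = rng.choice(BASES, size=n_err)
        clash = subs == current
        while clash.any():
            subs[clash] = rng.choice(BASES, size=int(clash.sum()))
            clash = subs == current
        arr[mask] = subs
    return arr.tobytes().decode()


def simulate_sample(
    locus: AmpliconLocus,
    sample: SampleSpec,
    cfg: SimulationConfig,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate one sample's paired reads plus its truth-table rows.

    Each template is ``barcode + amplicon``; with probability
    ``true_indel_rate`` the amplicon carries exactly one indel at the cut
    site (type by ``deletion_fraction``, length geometric, position
    jittered by up to ``jitter`` bp). Read 1 is the first
    ``read_length`` bases of the template; read 2 the first
    ``read_length`` bases of its reverse complement. Per-base
    substitution errors are injected independently of the constant Q30
    qualities.
    """
    rng = np.random.default_rng(
        [cfg.seed, zlib.crc32(sample.sample_id.encode()) & 0x7FFFFFFF]
    )
    rate = cfg.rate_for(sample.sample_id)
    qual = "?" * cfg.read_length  # Phred+33 Q30
    ref = locus.reference
    cut = locus.cut_position
    pairs: list[ReadPair] = []
    truth_rows = []
    for i in range(cfg.n_reads):
        edited = bool(rng.random() < rate)
        indel_type = ""
        indel_len = 0
        indel_pos = -1
        amplicon = ref
        if edited:
            is_del = rng.random() < cfg.deletion_fraction
            indel_len = min(int(rng.geometric(cfg.p_len)), cfg.max_indel_len)
            indel_pos = cut + int(rng.integers(-cfg.jitter, cfg.jitter + 1))
            if is_del:
                indel_type = "deletion"
                amplicon = ref[:indel_pos] + ref[indel_pos + indel_len :]
            else:
                indel_type = "insertion"
                ins = _random_seq(rng, indel_len)
                amplicon = ref[:indel_pos] + ins + ref[indel_pos:]
        template = sample.barcode + amplicon
        if len(template) < cfg.read_length:
            raise ConfigError(
                f"template ({len(template)} nt) shorter than read length"
            )
        r1 = template[: cfg.read_length]
        r2 = revcomp(template)[: cfg.read_length]
        r1 = _apply_errors(rng, r1, cfg.substitution_error_rate)
        r2 = _apply_errors(rng, r2, cfg.substitution_error_rate)
        read_id = f"{sample.sample_id}:{i}"
        pairs.append(ReadPair(read_id, r1, qual, r2, qual))
        truth_rows.append(
            {
                "read_id": read_id,
                "sample_id": sample.sample_id,
                "locus": locus.name,
                "edited": edited,
                "indel_type": indel_type,
                "indel_len": indel_len,
                "indel_pos": indel_pos,
            }
        )
    return pairs, pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "sample_id",
            "locus",
            "edited",
            "indel_type",
            "indel_len",
            "indel_pos",
        ],
    )


# ---------------------------------------------------------------------------
# run writer / loaders


def _write_fastq_gz(path: Path, records: Iterable[tuple[str, str, str]]) -> None:
    # mtime pinned so identical seeds give byte-identical files
    with open(path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
            for read_id, seq, qual in records:
                gz.write(f"@{read_id}\n{seq}\n+\n{qual}\n".encode())


def loci_to_frame(loci: list[AmpliconLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [l.name for l in loci],
            "role": [l.role for l in loci],
            "protospacer_start": [l.protospacer_interval[0] for l in loci],
            "protospacer_end": [l.protospacer_interval[1] for l in loci],
            "protospacer_strand": [l.protospacer_strand for l in loci],
            "pam": [l.pam for l in loci],
            "cut_position": [l.cut_position for l in loci],
        }
    )


def samples_to_frame(samples: list[SampleSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "barcode": [s.barcode for s in samples],
            "fwd_primer": [s.fwd_primer for s in samples],
            "rev_primer": [s.rev_primer for s in samples],
            "locus": [s.locus for s in samples],
            "inhibitor_kind": [s.inhibitor_kind for s in samples],
            "relative_concentration": [
                s.relative_concentration for s in samples
            ],
            "replicate": [s.replicate for s in samples],
        }
    )


def write_run(
    loci: list[AmpliconLocus],
    samples: list[SampleSpec],
    cfg: SimulationConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a complete simulated run to ``out_dir``.

    Produces the reference FASTA, loci metadata TSV, sample sheet TSV,
    pooled paired FASTQ (R1/R2, gzip) and the truth TSV; returns a
    manifest of all paths. Byte-identical across reruns with the same
    inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_name = {l.name: l for l in loci}
    r1_records, r2_records = [], []
    truth_frames = []
    for sample in samples:
        try:
            locus = by_name[sample.locus]
        except KeyError:
            raise ConfigError(f"sample {sample.sample_id}: unknown locus")
        pairs, truth = simulate_sample(locus, sample, cfg)
        for p in pairs:
            r1_records.append((p.read_id, p.seq1, p.qual1))
            r2_records.append((p.read_id, p.seq2, p.qual2))
        truth_frames.append(truth)

    manifest = {
        "reference_fasta": out / "reference.fasta",
        "loci_tsv": out / "loci.tsv",
        "samples_tsv": out / "samples.tsv",
        "reads_r1": out / "reads_R1.fastq.gz",
        "reads_r2": out / "reads_R2.fastq.gz",
        "truth_tsv": out / "truth.tsv",
    }
    with open(manifest["reference_fasta"], "w") as fh:
        for l in loci:
            fh.write(f">{l.name}\n{l.reference}\n")
    loci_to_frame(loci).to_csv(manifest["loci_tsv"], sep="\t", index=False)
    samples_to_frame(samples).to_csv(
        manifest["samples_tsv"], sep="\t", index=False
    )
    _write_fastq_gz(manifest["reads_r1"], r1_records)
    _write_fastq_gz(manifest["reads_r2"], r2_records)
    truth_columns = [
        "read_id",
        "sample_id",
        "locus",
        "edited",
        "indel_type",
        "indel_len",
        "indel_pos",
    ]
    truth = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame(columns=truth_columns)
    )
    truth.to_csv(manifest["truth_tsv"], sep="\t", index=False)
    return manifest


def load_loci(fasta_path: str | Path, tsv_path: str | Path) -> list[AmpliconLocus]:
    """Rebuild :class:`AmpliconLocus` objects from a reference FASTA and
    the loci metadata TSV written by :func:`write_run`."""
    from Bio import SeqIO

    refs = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    meta = pd.read_csv(tsv_path, sep="\t", comment="#")
    loci = []
    for row in meta.itertuples():
        if row.name not in refs:
            raise ConfigError(f"locus {row.name!r} missing from FASTA")
        loci.append(
            AmpliconLocus(
                name=row.name,
                role=row.role,
                reference=refs[row.name],
                protospacer_interval=(
                    int(row.protospacer_start),
                    int(row.protospacer_end),
                ),
                protospacer_strand=row.protospacer_strand,
                pam=row.pam,
                cut_position=int(row.cut_position),
            )
        )
    return loci


def load_samples(tsv_path: str | Path) -> list[SampleSpec]:
    """Read a sample sheet TSV into :class:`SampleSpec` objects."""
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    return [
        SampleSpec(
            sample_id=str(row.sample_id),
            barcode=str(row.barcode),
            fwd_primer=str(row.fwd_primer),
            rev_primer=str(row.rev_primer),
            locus=str(row.locus),
            inhibitor_kind=str(row.inhibitor_kind),
            relative_concentration=float(row.relative_concentration),
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]
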