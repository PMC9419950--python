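"""Design of guide-complementary DNA oligo inhibitors of Cas9.

A Cas9 ribonucleoprotein (RNP) finds its target through the 20-nt spacer
of its guide RNA. A single-stranded DNA oligo complementary to the
PAM-proximal, spacer-derived part of the guide can base-pair with the
guide and block target engagement. Three design families are supported:

* ``L{n}`` — a plain core of *n* nucleotides (tested lengths 8 and 20):
  the reverse complement of the *n* PAM-proximal spacer bases, written
  5'->3'. Because the spacer is given 5'->3', "PAM-proximal" means its
  3' end.
* ``L{n}_PAM`` — the same core preceded by a 5' extension
  ``PAM + loop + revcomp(PAM)`` that folds back on itself to present a
  3-bp double-stranded PAM, mimicking a bona fide target and enabling
  inhibition of preformed RNP without a long incubation.
* ``SCRAMBLED`` — a seeded random permutation of a parent design used as
  a sequence-specificity control; it preserves base composition but is
  rejected if it retains long complementarity to the spacer.

All sequences are DNA over {A,C,G,T}, written 5'->3'.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass

import numpy as np

from .errors import AlphabetError, DegenerateInputError, ValidationError
from .sequtils import check_dna, revcomp

#: default fold-back linker between the 5' PAM arm and its complement
DEFAULT_LOOP = "TTTT"

#: a scrambled control must not retain a complementary run to the spacer
#: of at least this many nucleotides
SCRAMBLE_MAX_COMPLEMENT_RUN = 8


class InhibitorKind(str, enum.Enum):
    L20 = "L20"
    L8 = "L8"
    L20_PAM = "L20_PAM"
    L8_PAM = "L8_PAM"
    SCRAMBLED = "SCRAMBLED"


@dataclass(frozen=True)
class GuideSpec:
    """A guide RNA specification in DNA representation.

    Parameters
    ----------
    spacer:
        The 20-nt variable part of the guide, 5'->3', DNA alphabet.
    pam:
        The 3-nt protospacer-adjacent motif, matching N-G-G (SpCas9).
    """

    spacer: str
    pam: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacer", check_dna(self.spacer, "spacer"))
        object.__setattr__(self, "pam", check_dna(self.pam, "pam"))
        if len(self.spacer) != 20:
            raise ValidationError(
                f"spacer must be exactly 20 nt, got {len(self.spacer)}"
            )
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValidationError(f"pam must match NGG, got {self.pam!r}")


@dataclass(frozen=True)
class InhibitorDesign:
    """A designed inhibitor oligo (5'->3' DNA)."""

    kind: InhibitorKind
    core_length: int
    loop: str  # empty for non-PAM kinds
    sequence: str
    source_guide: GuideSpec
    seed: int | None = None  # set for scrambled designs only

    @property
    def name(self) -> str:
        """Short label, e.g. ``L8_PAM`` or ``SCRAMBLED_L20_seed7``."""
        if self.kind is InhibitorKind.SCRAMBLED:
            return f"SCRAMBLED_L{self.core_length}_seed{self.seed}"
        return self.kind.value


def design_inhibitor(
    guide: GuideSpec,
    core_length: int,
    pam_loop: bool = False,
    loop: str = DEFAULT_LOOP,
) -> InhibitorDesign:
    """Construct a guide-complementary inhibitor oligo.

    The core is the reverse complement of the ``core_length`` PAM-proximal
    (3'-most) spacer bases, written 5'->3'. With ``pam_loop`` the oligo is
    ``5'-[PAM]-[loop]-[revcomp(PAM)]-[core]-3'``: the 5' arm folds back
    onto the segment preceding the core, forming a 3-bp PAM duplex.

    Raises
    ------
    ValidationError
        If ``core_length`` is outside [1, 20] or the loop is empty when
        ``pam_loop`` is set.
    AlphabetError
        On non-ACGT symbols in the loop.
    """
    if not 1 <= core_length <= 20:
        raise ValidationError(
            f"core_length must be in [1, 20], got {core_length}"
        )
    core = revcomp(guide.spacer[-core_length:])
    if pam_loop:
        if not loop:
            raise ValidationError("loop must be non-empty for PAM-loop designs")
        loop = check_dna(loop, "loop")
        sequence = guide.pam + loop + revcomp(guide.pam) + core
        kind = InhibitorKind(f"L{core_length}_PAM")
    else:
        sequence = core
        loop = ""
        kind = InhibitorKind(f"L{core_length}")
    return InhibitorDesign(
        kind=kind,
        core_length=core_length,
        loop=loop,
        sequence=sequence,
        source_guide=guide,
    )


def _complementary_run(a: str, b: str, run: int) -> bool:
    """True if any length-``run`` window of *a* could base-pair
    (antiparallel, exact) with some window of *b*."""
    if len(a) < run or len(b) < run:
        return False
    return any(
        revcomp(a[i : i + run]) in b for i in range(len(a) - run + 1)
    )


def scramble_oligo(
    parent: InhibitorDesign,
    seed: int,
    max_complement_run: int = SCRAMBLE_MAX_COMPLEMENT_RUN,
    max_tries: int = 10_000,
) -> InhibitorDesign:
    """Seeded scrambled control: a uniform random permutation of the
    parent sequence, re-drawn until it (a) differs from the parent and
    (b) shares no contiguous complementary match of ``max_complement_run``
    or more nucleotides with the source spacer.

    Deterministic given ``seed``.

    Raises
    ------
    DegenerateInputError
        If the parent is a homopolymer (no distinct permutation exists).
    """
    seq = parent.sequence
    if len(seq) < 2:
        raise DegenerateInputError("parent sequence must be at least 2 nt")
    if len(set(seq)) == 1:
        raise DegenerateInputError(
            "homopolymer parent has no distinct permutation"
        )
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(seq.encode(), dtype="S1")
    spacer = parent.source_guide.spacer
    for _ in range(max_tries):
        perm = rng.permutation(letters)
        candidate = perm.tobytes().decode()
        if candidate == seq:
            continue
        if _complementary_run(candidate, spacer, max_complement_run):
            continue
        return dataclasses.replace(
            parent,
            kind=InhibitorKind.SCRAMBLED,
            sequence=candidate,
            seed=seed,
        )
    raise DegenerateInputError(
        f"no acceptable scramble found in {max_tries} draws"
    )


@dataclass(frozen=True)
class HairpinReport:
    """Result of checking the fold-back geometry of a PAM-loop design."""

    pam_duplex_ok: bool
    unintended_pairs: tuple[tuple[int, int, int], ...]
    """(start_i, start_j, length) triples of self-complementary runs of
    at least the threshold length, outside the intended PAM duplex."""

    @property
    def clean(self) -> bool:
        return self.pam_duplex_ok and not self.unintended_pairs


def hairpin_check(
    design: InhibitorDesign, min_unintended_run: int = 6
) -> HairpinReport:
    """Verify the intended PAM duplex of a PAM-loop design and scan for
    unintended self-complementarity.

    The intended duplex pairs the 5' arm (first 3 nt) with the 3 nt
    immediately preceding the core (antiparallel). Any other pair of
    mutually reverse-complementary windows of ``min_unintended_run`` nt
    or more is reported as an unintended pairing.

    Raises
    ------
    ValidationError
        If the design is not a PAM-loop kind.
    """
    if design.kind not in (InhibitorKind.L8_PAM, InhibitorKind.L20_PAM):
        raise ValidationError(
            f"hairpin_check requires a PAM-loop design, got {design.kind}"
        )
    seq = design.sequence
    arm = seq[:3]
    pre_core_start = 3 + len(design.loop)
    pre_core = seq[pre_core_start : pre_core_start + 3]
    pam_duplex_ok = revcomp(arm) == pre_core

    # exhaustive scan for self-complementary windows >= threshold,
    # excluding the intended arm/pre-core duplex itself
    n = len(seq)
    run = min_unintended_run
    hits: list[tuple[int, int, int]] = []
    for i in range(n - run + 1):
        window_rc = revcomp(seq[i : i + run])
        j = -1
        while True:
            j = seq.find(window_rc, j + 1)
            if j == -1:
                break
            if j <= i:  # count each (i, j) pair once, i < j
                continue
            hits.append((i, j, run))
    return HairpinReport(
        pam_duplex_ok=pam_duplex_ok, unintended_pairs=tuple(hits)
    )


def designs_to_fasta(designs: list[InhibitorDesign]) -> str:
    """Render designs as FASTA text, one record per design.

    Headers encode kind, core length, loop, and seed (scrambles).
    """
    lines = []
    for d in designs:
        header = f">{d.name} kind={d.kind.value} core={d.core_length}"
        if d.loop:
            header += f" loop={d.loop}"
        if d.seed is not None:
            header += f" seed={d.seed}"
        lines.append(header)
        lines.append(d.sequence)
    return "\n".join(lines) + "\n"
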