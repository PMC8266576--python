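"""Single-stranded REP hairpin model.

REP elements (Repetitive Extragenic Palindromes) are short palindromic DNA
sequences, typically preceded by a conserved tetranucleotide (most often
``GTAG``), that fold into stem-loop structures when single stranded.  Two
architectural groups are modelled here:

* **group 2** — longer imperfect palindromes whose stem is interrupted by a
  bulge of opposed non-Watson-Crick pairs (e.g. the *E. coli* y REP with its
  conserved A12/A13 against G26/C27 mispairs);
* **group 3** — short, perfect palindromes (e.g. the *S. maltophilia* Sm REP,
  an 8-bp stem with a 3-nt loop, or the *Marinomonas* Mb REP, a 5-bp stem
  with a 4-nt loop two bases downstream of GTAG).

The folding engine is purely combinatorial: arms are aligned gaplessly
against each other (no indels in the stem) and a "bulge" is represented as
opposed mismatched bases, which matches how all experimentally characterised
REP variants keep their two arm lengths equal.  Thermodynamic free-energy
minimisation is deliberately out of scope.

Coordinates
-----------
Within an element, positions are 1-based with the guide tetranucleotide at
positions 1-4 (the convention used for named bases such as T11 or G32 of the
y REP, G13 of the Sm REP loop, or T12/T13/N14/A15 of the Mb REP loop).
Genomic coordinates elsewhere in the package are 0-based half-open.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

__all__ = [
    "DNA_BASES",
    "revcomp",
    "complement",
    "is_wc",
    "FoldResult",
    "RepTemplateSpec",
    "RepStructure",
    "fold_rep",
    "build_rep_template",
    "classify_rep",
    "REP_SM",
    "REP_MB",
    "REP_EC_Y",
    "TEMPLATES",
    "InvalidSequenceError",
]

DNA_BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Watson-Crick pairs; anything else (including any pair involving N)
#: counts as a mismatch.
_WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or non-ACGTN characters."""


def complement(base: str) -> str:
    """Watson-Crick complement of a single base (N maps to N)."""
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (alphabet ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_wc(base5: str, base3: str) -> bool:
    """True iff ``base5 . base3`` is a Watson-Crick pair.  N never pairs."""
    return (base5, base3) in _WC_PAIRS


def _validate_seq(seq: str, *, allow_n: bool = True) -> None:
    if not seq:
        raise InvalidSequenceError("empty sequence")
    alphabet = set("ACGTN" if allow_n else DNA_BASES)
    bad = set(seq) - alphabet
    if bad:
        raise InvalidSequenceError(f"non-DNA characters in sequence: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Fold results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldResult:
    """Outcome of folding a single-stranded sequence into a stem-loop.

    ``start`` and ``end`` delimit the folded region (0-based half-open,
    relative to the input sequence): ``seq[start:start+stem_len]`` is the 5'
    arm, followed by the loop, with the 3' arm ending at ``end``.
    ``mismatch_positions`` are 0-based indices into the 5' arm whose opposed
    base in the 3' arm is not Watson-Crick.
    """

    folded: bool
    stem_len: int = 0
    loop_len: int = 0
    mismatch_positions: tuple[int, ...] = ()
    start: int = 0
    end: int = 0

    @property
    def mismatch_count(self) -> int:
        return len(self.mismatch_positions)

    def __post_init__(self) -> None:
        if self.stem_len < 0:
            raise ValueError("stem_len must be >= 0")
        if self.mismatch_count > self.stem_len:
            raise ValueError("more mismatches than stem pairs")


def fold_rep(
    seq: str,
    min_stem: int = 5,
    max_mismatches: int = 0,
    loop_range: tuple[int, int] = (3, 9),
    *,
    anchored: bool = False,
) -> FoldResult:
    """Fold ``seq`` into the best stem-loop under gapless arm alignment.

    Every decomposition ``seq[o:o+k] / loop / seq[o+k+l:o+2k+l]`` with
    ``k >= min_stem`` and ``l`` within ``loop_range`` is scored by aligning
    the 5' arm against the reverse complement of the 3' arm and counting
    non-Watson-Crick pairs.  Decompositions with more than
    ``max_mismatches`` such pairs are rejected.  Among the survivors the
    winner has the longest stem, then the shortest loop, then the 5'-most
    start; flanking bases outside the folded region are ignored.

    With ``anchored=True`` the 5' arm must begin at position 0 (used by the
    genome scanner, where the stem is anchored just downstream of the guide
    and spacer).

    Returns ``FoldResult(folded=False)`` if no decomposition qualifies.
    """
    _validate_seq(seq)
    loop_min, loop_max = loop_range
    if loop_min < 1:
        raise ValueError("loop length must be >= 1")
    if min_stem < 1:
        raise ValueError("min_stem must be >= 1")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")

    n = len(seq)
    best: tuple[int, int, int] | None = None  # (-k, l, offset) to minimise
    best_mm: tuple[int, ...] = ()
    offsets = (0,) if anchored else range(n)
    for o in offsets:
        avail = n - o
        for k in range(min_stem, (avail - loop_min) // 2 + 1):
            for l in range(loop_min, min(loop_max, avail - 2 * k) + 1):
                arm5 = seq[o : o + k]
                arm3 = seq[o + k + l : o + 2 * k + l]
                mm = tuple(
                    i for i in range(k) if not is_wc(arm5[i], arm3[k - 1 - i])
                )
                if len(mm) > max_mismatches:
                    continue
                key = (-k, l, o)
                if best is None or key < best:
                    best = key
                    best_mm = mm
    if best is None:
        return FoldResult(folded=False)
    k, l, o = -best[0], best[1], best[2]
    return FoldResult(
        folded=True,
        stem_len=k,
        loop_len=l,
        mismatch_positions=best_mm,
        start=o,
        end=o + 2 * k + l,
    )


def classify_rep(fold: FoldResult, min_stem: int = 5) -> str:
    """Classify a fold as ``"group2"``, ``"group3"`` or ``"unclassified"``.

    group 3: a perfect stem of at least ``min_stem`` pairs.  group 2: one or
    more mismatched pairs, all in the interior of the stem (a mispair at the
    outermost or innermost position is stem fraying, not a bulge, and leaves
    the fold unclassified).
    """
    if not fold.folded:
        raise ValueError("cannot classify an unfolded sequence")
    if fold.stem_len < min_stem:
        return "unclassified"
    if fold.mismatch_count == 0:
        return "group3"
    if all(0 < i < fold.stem_len - 1 for i in fold.mismatch_positions):
        return "group2"
    return "unclassified"


# ---------------------------------------------------------------------------
# Templates and concrete elements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepTemplateSpec:
    """Structural grammar of one REP family.

    ``mismatch_pairs`` lists 0-based 5'-arm indices at which the opposed
    bases must NOT form a Watson-Crick pair (the group-2 bulge).  A group-3
    spec must have none.  ``loop_seq`` optionally pins the loop to the
    family's wild-type sequence (e.g. GCT for the Sm REP, TTTA for Mb).
    """

    guide: str = "GTAG"
    spacer_len: int = 0
    stem_arm_len: int = 8
    loop_len: int = 3
    mismatch_pairs: tuple[int, ...] = ()
    group: int = 3
    loop_seq: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        _validate_seq(self.guide, allow_n=False)
        if len(self.guide) != 4:
            raise ValueError("guide must be a tetranucleotide")
        if not (0 <= self.spacer_len <= 3):
            raise ValueError("spacer_len must be within 0-3")
        if self.stem_arm_len < 1 or self.loop_len < 1:
            raise ValueError("stem and loop must be non-empty")
        if self.group not in (2, 3):
            raise ValueError("group must be 2 or 3")
        if self.group == 3 and self.mismatch_pairs:
            raise ValueError("a group-3 (perfect palindrome) spec cannot carry mismatches")
        if any(not 0 <= i < self.stem_arm_len for i in self.mismatch_pairs):
            raise ValueError("mismatch_pairs outside the stem arm")
        if self.loop_seq is not None and len(self.loop_seq) != self.loop_len:
            raise ValueError("loop_seq length disagrees with loop_len")

    @property
    def total_len(self) -> int:
        """Element length: guide + spacer + both arms + loop."""
        return len(self.guide) + self.spacer_len + 2 * self.stem_arm_len + self.loop_len

    # -- element coordinates (1-based, guide at 1-4) --------------------

    @property
    def guide_positions(self) -> tuple[int, ...]:
        return tuple(range(1, len(self.guide) + 1))

    @property
    def loop_positions(self) -> tuple[int, ...]:
        first = len(self.guide) + self.spacer_len + self.stem_arm_len + 1
        return tuple(range(first, first + self.loop_len))

    def arm5_position(self, arm_index: int) -> int:
        """Element position of 5'-arm base ``arm_index`` (0-based index)."""
        return len(self.guide) + self.spacer_len + arm_index + 1

    def arm3_position(self, arm_index: int) -> int:
        """Element position of the base opposed to 5'-arm index ``arm_index``."""
        k = self.stem_arm_len
        arm3_start = len(self.guide) + self.spacer_len + k + self.loop_len
        return arm3_start + (k - 1 - arm_index) + 1

    @property
    def bulge_positions(self) -> tuple[int, ...]:
        """Element positions of both strands of the bulge, 5' arm first."""
        fives = [self.arm5_position(i) for i in self.mismatch_pairs]
        threes = sorted(self.arm3_position(i) for i in self.mismatch_pairs)
        return tuple(fives + threes)


@dataclass(frozen=True)
class RepStructure:
    """A concrete REP element: guide + spacer + 5' arm + loop + 3' arm."""

    guide: str
    spacer: str
    arm5: str
    loop: str
    arm3: str
    mismatch_pairs: tuple[tuple[int, str, str], ...] = ()
    positions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.arm5) != len(self.arm3):
            raise ValueError("stem arms must have equal length")
        if len(self.loop) < 1:
            raise ValueError("loop must be non-empty")
        _validate_seq(self.guide, allow_n=False)
        if len(self.guide) != 4:
            raise ValueError("guide must be a tetranucleotide")
        k = len(self.arm5)
        for i, b5, b3 in self.mismatch_pairs:
            if not 0 <= i < k:
                raise ValueError("mismatch index outside the stem arm")
            if self.arm5[i] != b5 or self.arm3[k - 1 - i] != b3:
                raise ValueError("mismatch annotation disagrees with arm sequences")

    @property
    def seq(self) -> str:
        return self.guide + self.spacer + self.arm5 + self.loop + self.arm3

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, position: int) -> str:
        """Base at a 1-based element position (guide = positions 1-4)."""
        return self.seq[position - 1]


def build_rep_template(spec: RepTemplateSpec, seed: int) -> RepStructure:
    """Emit a random but valid element realising ``spec``.

    The same spec and seed always yield the same sequence.  The emitted
    element refolds exactly to the spec: ``fold_rep`` on the portion after
    guide+spacer, with ``min_stem=spec.stem_arm_len``,
    ``max_mismatches=len(spec.mismatch_pairs)`` and the loop length pinned,
    recovers the stem, loop and mismatch positions.
    """
    rng = random.Random(seed)
    arm5 = "".join(rng.choice(DNA_BASES) for _ in range(spec.stem_arm_len))
    arm3_list = list(revcomp(arm5))
    k = spec.stem_arm_len
    for i in spec.mismatch_pairs:
        non_wc = [b for b in DNA_BASES if b != complement(arm5[i])]
        arm3_list[k - 1 - i] = rng.choice(non_wc)
    arm3 = "".join(arm3_list)
    if spec.loop_seq is not None:
        loop = spec.loop_seq
    else:
        loop = "".join(rng.choice(DNA_BASES) for _ in range(spec.loop_len))
        if spec.loop_len >= 2 and is_wc(loop[0], loop[-1]):
            # keep the loop termini unpaired so the stem cannot creep inward
            loop = loop[:-1] + rng.choice(
                [b for b in DNA_BASES if not is_wc(loop[0], b)]
            )
    spacer = "".join(rng.choice(DNA_BASES) for _ in range(spec.spacer_len))
    mismatches = tuple(
        (i, arm5[i], arm3[k - 1 - i]) for i in sorted(spec.mismatch_pairs)
    )
    named = {}
    for i in spec.mismatch_pairs:
        named[f"bulge5_{spec.arm5_position(i)}"] = spec.arm5_position(i)
        named[f"bulge3_{spec.arm3_position(i)}"] = spec.arm3_position(i)
    return RepStructure(
        guide=spec.guide,
        spacer=spacer,
        arm5=arm5,
        loop=loop,
        arm3=arm3,
        mismatch_pairs=mismatches,
        positions=named,
    )


# ---------------------------------------------------------------------------
# Bundled REPtron templates
# ---------------------------------------------------------------------------

#: S. maltophilia K279a Sm REP: 23 nt in total — GTAG directly against an
#: 8-bp perfect palindrome with a 3-nt loop whose wild type is G13 C14 T15.
REP_SM = RepTemplateSpec(
    guide="GTAG", spacer_len=0, stem_arm_len=8, loop_len=3,
    group=3, loop_seq="GCT", name="sm",
)

#: Marinomonas sp. MWYL1 Mb REP: 5-bp perfect palindrome with a 4-nt loop
#: (wild type T12 T13 T14 A15), two spacer bases after GTAG; 20 nt in total.
REP_MB = RepTemplateSpec(
    guide="GTAG", spacer_len=2, stem_arm_len=5, loop_len=4,
    group=3, loop_seq="TTTA", name="mb",
)

#: E. coli MG1655 y REP (group 2): 13-bp arms around a 4-nt loop
#: (positions 18-21), with the conserved bulge of opposed mispairs at
#: element positions 12/13 against 26/27 (arm indices 7 and 8).
REP_EC_Y = RepTemplateSpec(
    guide="GTAG", spacer_len=0, stem_arm_len=13, loop_len=4,
    mismatch_pairs=(7, 8), group=2, name="ec-y",
)

TEMPLATES: dict[str, RepTemplateSpec] = {
    "sm": REP_SM,
    "mb": REP_MB,
    "ec-y": REP_EC_Y,
}
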