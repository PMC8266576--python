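"""Guide-anchored REP/BIME genome scanner and planted-truth fixtures.

A REP candidate is a guide occurrence (GTAG by default) followed, after a
short spacer, by a stem-loop foldable under the group's structural grammar.
The REP strand is the strand whose 5'->3' reading carries the guide
upstream of the palindrome; a plus-strand palindrome terminated by CTAC
(the guide's reverse complement) is an inverted REP (iREP) and is reported
as a minus-strand hit.  Adjacent REP/iREP pairs in inverse orientation
separated by a short linker form BIMEs.

All genomic coordinates are 0-based half-open; BED6 conversion is lossless
(name = REP/iREP, score = stem length, strand = element orientation).

Default parameter presets, by REP group:

* ``group2`` — min stem 8 bp, loop 3-9 nt, up to 2 mismatched (bulged)
  pairs, spacer 0-1 nt;
* ``group3`` — min stem 5 bp, loop 3-5 nt, perfect stems only, spacer
  0-3 nt.

These defaults describe the bundled model REPtrons, not genome-wide truth;
loop/stem length distributions in real genomes are wider than the presets.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rep_model import (
    DNA_BASES,
    FoldResult,
    RepTemplateSpec,
    build_rep_template,
    classify_rep,
    fold_rep,
    revcomp,
)

__all__ = [
    "ScanParams",
    "RepHit",
    "BimeHit",
    "PRESETS",
    "scan_genome",
    "scan_fasta",
    "pair_bimes",
    "plant_reps",
    "hits_to_bed",
    "bimes_to_bed",
    "hits_to_gff3",
]


@dataclass(frozen=True)
class ScanParams:
    """Scanner grammar parameters.

    ``max_stem`` bounds the arm-length search (the grammar itself is
    open-ended upward; 20 bp covers every characterised REP family with
    margin).
    """

    guide: str = "GTAG"
    spacer_range: tuple[int, int] = (0, 1)
    min_stem: int = 8
    loop_range: tuple[int, int] = (3, 9)
    max_mismatches: int = 2
    both_strands: bool = True
    max_stem: int = 20

    def __post_init__(self) -> None:
        if self.min_stem < 3:
            raise ValueError("min_stem must be >= 3")
        if self.spacer_range[0] > self.spacer_range[1] or self.spacer_range[0] < 0:
            raise ValueError("invalid spacer_range")
        if self.loop_range[0] > self.loop_range[1] or self.loop_range[0] < 1:
            raise ValueError("invalid loop_range")
        if self.max_stem < self.min_stem:
            raise ValueError("max_stem must be >= min_stem")
        if set(self.guide) - set(DNA_BASES):
            raise ValueError("guide must be an ACGT string")


PRESETS: dict[str, ScanParams] = {
    "group2": ScanParams(
        spacer_range=(0, 1), min_stem=8, loop_range=(3, 9), max_mismatches=2
    ),
    "group3": ScanParams(
        spacer_range=(0, 3), min_stem=5, loop_range=(3, 5), max_mismatches=0
    ),
}


@dataclass(frozen=True)
class RepHit:
    """One REP candidate: guide start to stem end, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str  # "+" (REP) | "-" (iREP on the scanned strand)
    fold: FoldResult
    group: str
    spacer_len: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def kind(self) -> str:
        return "REP" if self.strand == "+" else "iREP"


@dataclass(frozen=True)
class BimeHit:
    """A REP and an iREP in inverse orientation with a short linker."""

    rep: RepHit
    irep: RepHit
    linker_len: int

    def __post_init__(self) -> None:
        if self.rep.seq_id != self.irep.seq_id:
            raise ValueError("BIME partners must share a sequence")
        if self.rep.strand == self.irep.strand:
            raise ValueError("BIME partners must be in inverse orientation")
        if self.linker_len < 0:
            raise ValueError("linker_len must be >= 0")

    @property
    def seq_id(self) -> str:
        return self.rep.seq_id

    @property
    def interval(self) -> tuple[int, int]:
        s = min(self.rep.start, self.irep.start)
        e = max(self.rep.end, self.irep.end)
        return (s, e)


def _scan_plus(
    seq: str, seq_id: str, params: ScanParams, all_folds: bool = False
) -> list[RepHit]:
    """Plus-strand scan: guide + spacer + anchored stem-loop."""
    hits: list[RepHit] = []
    g = params.guide
    glen = len(g)
    pos = seq.find(g)
    while pos != -1:
        candidates: list[tuple[tuple[int, int, int], FoldResult, int]] = []
        for spacer in range(params.spacer_range[0], params.spacer_range[1] + 1):
            s0 = pos + glen + spacer
            win = seq[s0 : s0 + 2 * params.max_stem + params.loop_range[1]]
            if len(win) < 2 * params.min_stem + params.loop_range[0]:
                continue
            f = fold_rep(
                win,
                min_stem=params.min_stem,
                max_mismatches=params.max_mismatches,
                loop_range=params.loop_range,
                anchored=True,
            )
            if not f.folded:
                continue
            candidates.append(((-f.stem_len, f.loop_len, spacer), f, spacer))
        candidates.sort(key=lambda c: c[0])
        if not all_folds:
            candidates = candidates[:1]
        for _, f, spacer in candidates:
            end = pos + glen + spacer + f.end
            hits.append(
                RepHit(
                    seq_id=seq_id,
                    start=pos,
                    end=end,
                    strand="+",
                    fold=f,
                    group=classify_rep(f, min_stem=params.min_stem),
                    spacer_len=spacer,
                )
            )
        pos = seq.find(g, pos + 1)
    return hits


def scan_genome(
    records, params: ScanParams = PRESETS["group2"], all_folds: bool = False
) -> list[RepHit]:
    """Scan sequences for REP candidates under ``params``.

    ``records`` is an iterable of Biopython ``SeqRecord`` or ``(id, seq)``
    pairs.  At each guide occurrence only the tie-broken best fold (longest
    stem, then shortest loop, then smallest spacer) is reported unless
    ``all_folds`` is set, in which case every spacer's best fold is
    emitted.  Minus-strand hits (iREPs) are found by scanning the reverse
    complement and mapping coordinates back.  Hits are sorted by
    coordinate with leftmost-longest tie-breaking for overlaps.
    """
    items = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            items.append((rec.id, str(rec.seq).upper()))
        else:
            name, seq = rec
            items.append((name, seq.upper()))
    if not items:
        raise ValueError("no sequences to scan")
    hits: list[RepHit] = []
    for seq_id, seq in items:
        hits.extend(_scan_plus(seq, seq_id, params, all_folds))
        if params.both_strands:
            rc = revcomp(seq)
            for h in _scan_plus(rc, seq_id, params, all_folds):
                hits.append(
                    replace(h, start=len(seq) - h.end, end=len(seq) - h.start,
                            strand="-")
                )
    hits.sort(key=lambda h: (h.seq_id, h.start, -(h.end - h.start), h.strand))
    return hits


def scan_fasta(
    path: str | Path, params: ScanParams = PRESETS["group2"],
    all_folds: bool = False,
) -> list[RepHit]:
    """Scan a FASTA file (errors on an empty file)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    return scan_genome(records, params, all_folds)


def pair_bimes(hits: list[RepHit], max_linker: int = 50) -> list[BimeHit]:
    """Greedy left-to-right pairing of adjacent inverse-orientation hits.

    Consecutive hits on the same sequence in opposite orientation with a
    linker of at most ``max_linker`` nt form a BIME; each hit joins at most
    one BIME.
    """
    bimes: list[BimeHit] = []
    i = 0
    while i < len(hits) - 1:
        h1, h2 = hits[i], hits[i + 1]
        linker = h2.start - h1.end
        if (
            h1.seq_id == h2.seq_id
            and h1.strand != h2.strand
            and 0 <= linker <= max_linker
        ):
            rep, irep = (h1, h2) if h1.strand == "+" else (h2, h1)
            bimes.append(BimeHit(rep=rep, irep=irep, linker_len=linker))
            i += 2
        else:
            i += 1
    return bimes


# ---------------------------------------------------------------------------
# Planted-truth synthetic genomes
# ---------------------------------------------------------------------------


def plant_reps(
    genome_len: int,
    template: RepTemplateSpec,
    n_copies: int,
    n_bimes: int = 0,
    seed: int = 0,
    linker_range: tuple[int, int] = (5, 30),
    min_gap: int = 30,
    seq_id: str = "synthetic",
) -> tuple[SeqRecord, pd.DataFrame]:
    """Uniform-random genome with non-overlapping planted elements.

    Plants ``n_copies`` lone REPs on random strands plus ``n_bimes``
    REP+iREP pairs (plus-strand REP, then a linker, then the reverse
    complement of a second element).  Returns the sequence and a truth
    table (seq_id, start, end, strand, kind, bime_id) sorted by start.
    Raises if the elements cannot be placed without overlap.
    """
    rng = random.Random(seed)
    blocks: list[tuple[str, list[tuple[int, int, str, str]]]] = []
    for c in range(n_copies):
        elem = build_rep_template(template, rng.randrange(2**31)).seq
        strand = rng.choice("+-")
        seq = elem if strand == "+" else revcomp(elem)
        blocks.append((seq, [(0, len(elem), strand, "REP" if strand == "+" else "iREP")]))
    for b in range(n_bimes):
        e1 = build_rep_template(template, rng.randrange(2**31)).seq
        e2 = build_rep_template(template, rng.randrange(2**31)).seq
        linker = "".join(
            rng.choice(DNA_BASES)
            for _ in range(rng.randint(*linker_range))
        )
        seq = e1 + linker + revcomp(e2)
        blocks.append(
            (
                seq,
                [
                    (0, len(e1), "+", "REP"),
                    (len(e1) + len(linker), len(seq), "-", "iREP"),
                ],
            )
        )
    total = sum(len(s) for s, _ in blocks) + (len(blocks) + 1) * min_gap
    if total > genome_len:
        raise ValueError(
            f"genome of {genome_len} nt too small for {len(blocks)} planted "
            f"blocks ({total} nt needed including gaps)"
        )
    # place blocks left to right with random gaps
    slack = genome_len - sum(len(s) for s, _ in blocks) - (len(blocks) + 1) * min_gap
    gaps = [min_gap] * (len(blocks) + 1)
    for _ in range(slack):
        gaps[rng.randrange(len(gaps))] += 1
    rng.shuffle(blocks)
    genome_parts: list[str] = []
    truth_rows = []
    cursor = 0
    bime_id = 0
    for (block_seq, features), gap in zip(blocks, gaps):
        genome_parts.append("".join(rng.choice(DNA_BASES) for _ in range(gap)))
        cursor += gap
        is_bime = len(features) == 2
        if is_bime:
            bime_id += 1
        for off_s, off_e, strand, kind in features:
            truth_rows.append(
                {
                    "seq_id": seq_id,
                    "start": cursor + off_s,
                    "end": cursor + off_e,
                    "strand": strand,
                    "kind": kind,
                    "bime_id": bime_id if is_bime else 0,
                }
            )
        genome_parts.append(block_seq)
        cursor += len(block_seq)
    genome_parts.append("".join(rng.choice(DNA_BASES) for _ in range(gaps[-1])))
    genome = "".join(genome_parts)
    assert len(genome) == genome_len
    truth = pd.DataFrame(truth_rows).sort_values("start").reset_index(drop=True)
    record = SeqRecord(Seq(genome), id=seq_id, description="planted REP fixture")
    return record, truth


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------


def hits_to_bed(hits: list[RepHit]) -> str:
    """BED6: chrom, start, end, name (REP/iREP), score (stem bp), strand."""
    lines = [
        f"{h.seq_id}\t{h.start}\t{h.end}\t{h.kind}\t{h.fold.stem_len}\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def bimes_to_bed(bimes: list[BimeHit]) -> str:
    lines = []
    for b in bimes:
        s, e = b.interval
        lines.append(f"{b.seq_id}\t{s}\t{e}\tBIME\t{b.rep.fold.stem_len}\t+")
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_gff3(hits: list[RepHit], source: str = "reptron") -> str:
    """GFF3 with 1-based inclusive coordinates (lossless from BED)."""
    lines = ["##gff-version 3"]
    for i, h in enumerate(hits, 1):
        attrs = (
            f"ID=rep{i};Name={h.kind};group={h.group};"
            f"stem_len={h.fold.stem_len};loop_len={h.fold.loop_len};"
            f"mismatches={h.fold.mismatch_count};spacer_len={h.spacer_len}"
        )
        lines.append(
            "\t".join(
                [
                    h.seq_id,
                    source,
                    "repeat_region",
                    str(h.start + 1),
                    str(h.end),
                    str(h.fold.stem_len),
                    h.strand,
                    ".",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"
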