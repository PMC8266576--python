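"""Shared fixtures and independent brute-force oracles.

The oracles below deliberately avoid the package's own helpers (they carry
their own complement tables and enumeration loops) so that agreement with
the implementation is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import itertools
import random

import pytest

_ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_ORACLE_COMP[b] for b in reversed(seq))


def oracle_pairs(a: str, b: str) -> bool:
    return a in "ACGT" and _ORACLE_COMP[a] == b


def brute_force_fold(
    seq: str,
    min_stem: int,
    max_mismatches: int,
    loop_range: tuple[int, int],
    anchored: bool = False,
):
    """Enumerate every (offset, arm_len, loop_len) stem-loop decomposition.

    Returns (stem_len, loop_len, mismatch_positions, start, end) of the
    winner under longest-stem / shortest-loop / 5'-most tie-breaking, or
    None if no decomposition qualifies.
    """
    n = len(seq)
    candidates = []
    offsets = [0] if anchored else range(n)
    for o in offsets:
        for k in range(min_stem, n + 1):
            for l in range(loop_range[0], loop_range[1] + 1):
                if o + 2 * k + l > n:
                    continue
                arm5 = seq[o : o + k]
                arm3 = seq[o + k + l : o + 2 * k + l]
                mm = tuple(
                    i
                    for i in range(k)
                    if not oracle_pairs(arm5[i], arm3[k - 1 - i])
                )
                if len(mm) <= max_mismatches:
                    candidates.append((-k, l, o, mm))
    if not candidates:
        return None
    neg_k, l, o, mm = min(candidates)
    return (-neg_k, l, mm, o, o + 2 * -neg_k + l)


def oracle_guide_sites(guide: str) -> set[str]:
    """The two complementarity schemas, written out independently."""
    comp = _ORACLE_COMP
    linear = comp[guide[3]] + comp[guide[2]]
    cross = comp[guide[3]] + comp[guide[1]]
    return {linear, cross}


def all_guides():
    return ["".join(g) for g in itertools.product("ACGT", repeat=4)]


def brute_force_scan(
    seq: str,
    guide: str = "GTAG",
    spacer_range=(0, 1),
    min_stem: int = 8,
    loop_range=(3, 9),
    max_mismatches: int = 2,
    max_stem: int = 20,
    both_strands: bool = True,
):
    """O(n^2) scan: every guide occurrence x spacer x stem-loop decomposition.

    Returns a set of (start, end, strand) with the best candidate per guide
    occurrence (longest stem, then shortest loop, then smallest spacer),
    mirroring the scanner's reporting contract but via direct enumeration.
    """

    def one_strand(s: str):
        out = {}
        for i in range(len(s) - len(guide) + 1):
            if s[i : i + len(guide)] != guide:
                continue
            best = None
            for spacer in range(spacer_range[0], spacer_range[1] + 1):
                a0 = i + len(guide) + spacer
                for k in range(min_stem, max_stem + 1):
                    for l in range(loop_range[0], loop_range[1] + 1):
                        end = a0 + 2 * k + l
                        if end > len(s):
                            continue
                        # the scanner folds within a bounded window
                        if 2 * k + l > 2 * max_stem + loop_range[1]:
                            continue
                        arm5 = s[a0 : a0 + k]
                        arm3 = s[a0 + k + l : end]
                        mm = sum(
                            not oracle_pairs(arm5[j], arm3[k - 1 - j])
                            for j in range(k)
                        )
                        if mm <= max_mismatches:
                            key = (-k, l, spacer)
                            if best is None or key < best[0]:
                                best = (key, end)
            if best is not None:
                out[i] = best[1]
        return out

    hits = {(i, e, "+") for i, e in one_strand(seq).items()}
    if both_strands:
        rc = oracle_revcomp(seq)
        L = len(seq)
        hits |= {(L - e, L - i, "-") for i, e in one_strand(rc).items()}
    return hits


@pytest.fixture
def rng():
    return random.Random(20240917)


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
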