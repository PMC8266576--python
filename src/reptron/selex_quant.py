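"""Per-position enrichment statistics for CST-SELEX rounds.

Bulk sequencing of a SELEX pool yields, for each degenerate position, only
the fraction of reads carrying each base — linkage between positions is
lost.  Selection at a position is quantified against the initial pool:

* enrichment factor  ``E_N,0[p, b] = F_N[p, b] / F_0[p, b]`` — the ratio of
  base ``b``'s fraction at round N to its fraction at round 0;
* selection score    ``S[p] = V(E_N,0[p, ·])`` — the population variance
  (divide by 4) of the four enrichment factors at position ``p``.

A neutral position has all four enrichment factors near 1 and a score near
0; a selected position has one or more bases enriched (``log2 E > 0``) and
the remainder counter-selected (``log2 E < 0``).  Because the assay gives
no numeric score cutoff, the selected/neutral threshold is calibrated
empirically as a high quantile of the maximum score observed in neutral
(no-selection) simulations at the same sequencing depth.

Profiles are exchanged as TSV with columns
``position  A  C  G  T  round  depth``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "BaseProfile",
    "EnrichmentResult",
    "PositionClassification",
    "profile_from_reads",
    "enrichment",
    "calibrate_null_threshold",
    "classify_positions",
    "read_profiles_tsv",
    "write_profiles_tsv",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class BaseProfile:
    """Per-position base fractions for one SELEX round.

    ``fractions`` has shape (n_positions, 4) with columns A, C, G, T; every
    row sums to 1.  ``positions`` are 1-based element coordinates of the
    degenerate region; ``depth`` is the number of reads represented.
    """

    fractions: np.ndarray
    positions: tuple[int, ...]
    round_index: int
    depth: int
    #: Fraction of the previous round's molecules that survived the
    #: selection producing this round (1.0 for round 0).  Observable in the
    #: wet assay as the cleaved fraction; used to build a matched null.
    survival_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.survival_rate <= 1:
            raise ValueError("survival_rate must lie in (0, 1]")
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if f.ndim != 2 or f.shape[1] != 4:
            raise ValueError("fractions must be (positions x 4)")
        if f.shape[0] != len(self.positions):
            raise ValueError("positions length disagrees with fractions")
        if self.round_index < 0 or self.depth < 1:
            raise ValueError("round_index must be >= 0 and depth >= 1")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if np.max(np.abs(f.sum(axis=1) - 1.0)) > _ROW_SUM_TOL:
            raise ValueError("profile rows must each sum to 1")


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment factors and selection scores for one round comparison."""

    E: np.ndarray
    log2E: np.ndarray
    S: np.ndarray
    positions: tuple[int, ...]
    rounds_compared: tuple[int, int]


@dataclass(frozen=True)
class PositionClassification:
    """Selected/neutral call per position and per-base status.

    ``base_status`` holds, for each (position, base), one of ``enriched``,
    ``counter-selected`` or ``neutral``; bases at neutral positions are
    always neutral.
    """

    positions: tuple[int, ...]
    selected: np.ndarray  # bool, (P,)
    base_status: np.ndarray  # str, (P, 4)
    S: np.ndarray
    threshold: float

    @property
    def selected_positions(self) -> tuple[int, ...]:
        return tuple(p for p, s in zip(self.positions, self.selected) if s)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position": self.positions,
                "S": self.S,
                "selected": self.selected,
            }
        )
        for j, b in enumerate(BASES):
            df[f"status_{b}"] = self.base_status[:, j]
        return df


def profile_from_reads(
    reads: list[str],
    positions: list[int] | tuple[int, ...],
    round_index: int = 0,
) -> BaseProfile:
    """Empirical base fractions at 1-based ``positions`` over a read pool.

    All reads must have equal length.  ``N`` calls are excluded and the row
    renormalised over the observed A/C/G/T counts; positional linkage is
    discarded (a bulk-sequencing profile cannot capture associations
    between positions).
    """
    if not reads:
        raise ValueError("empty read set")
    length = len(reads[0])
    if any(len(r) != length for r in reads):
        raise ValueError("reads must all have the same length")
    if any(not 1 <= p <= length for p in positions):
        raise ValueError("positions outside read length")
    arr = np.frombuffer("".join(reads).encode(), dtype="S1").reshape(len(reads), length)
    counts = np.zeros((len(positions), 4), dtype=float)
    for row, p in enumerate(positions):
        col = arr[:, p - 1]
        for j, b in enumerate(BASES):
            counts[row, j] = np.count_nonzero(col == b.encode())
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("a position has no A/C/G/T calls (all N)")
    return BaseProfile(
        fractions=counts / totals[:, None],
        positions=tuple(positions),
        round_index=round_index,
        depth=len(reads),
    )


def enrichment(
    pN: BaseProfile, p0: BaseProfile, pseudocount: float | None = None
) -> EnrichmentResult:
    """Enrichment ``E_N,0 = (F_N + eps) / (F_0 + eps)`` and scores ``S``.

    ``pseudocount`` defaults to ``1 / (2 * p0.depth)`` — depth-scaled
    shrinkage that keeps the ratio finite when a base vanished from the
    initial pool.  Pass 0 for the raw ratio.  ``S`` is the population
    variance (ddof=0) of the four enrichment factors at each position.
    """
    if pN.positions != p0.positions:
        raise ValueError("profiles cover different positions")
    if pseudocount is None:
        pseudocount = 1.0 / (2.0 * p0.depth)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    E = (pN.fractions + pseudocount) / (p0.fractions + pseudocount)
    with np.errstate(divide="ignore"):
        log2E = np.log2(E)
    S = E.var(axis=1, ddof=0)
    return EnrichmentResult(
        E=E,
        log2E=log2E,
        S=S,
        positions=pN.positions,
        rounds_compared=(pN.round_index, p0.round_index),
    )


def calibrate_null_threshold(
    template,
    degenerate_positions,
    depth: int,
    n_sim: int = 100,
    quantile: float = 0.99,
    seed: int = 0,
    n_rounds: int = 1,
    survival_rate: float = 1.0,
) -> float:
    """Score threshold from matched neutral (no-selection) simulations.

    Runs ``n_sim`` independent SELEX simulations in which no position is
    selected, computes the per-position scores of round ``n_rounds``
    against round 0, and returns the requested quantile of the
    per-simulation maximum score.  Deterministic for a given seed.

    The null is *matched* to the experiment under analysis through
    ``n_rounds`` and ``survival_rate``: each neutral round passes the pool
    through a sequence-independent bottleneck at ``survival_rate`` (the
    overall cleaved fraction, observable in the assay) before unbiased
    reamplification.  Selection at required positions bottlenecks the pool
    and thereby inflates sampling variance at every position, including
    free ones; a null that ignores the bottleneck would call free positions
    selected.
    """
    from . import selex_sim  # local import: selex_sim depends on this module

    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for a stable quantile")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    neutral = selex_sim.neutral_spec(survival_rate=survival_rate)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_sim) % (2**31)
    max_scores = np.empty(n_sim)
    for i, s in enumerate(child_seeds):
        profiles = selex_sim.run_selex(
            template, degenerate_positions, neutral, n_rounds=n_rounds,
            depth=depth, seed=int(s),
        )
        res = enrichment(profiles[n_rounds], profiles[0])
        max_scores[i] = res.S.max()
    return float(np.quantile(max_scores, quantile))


def classify_positions(
    res: EnrichmentResult, threshold: float
) -> PositionClassification:
    """Call positions selected (``S >= threshold``) or neutral.

    At a selected position a base is ``enriched`` if ``log2 E > 0`` and
    ``counter-selected`` if ``log2 E < 0`` (exclusion of the base from the
    surviving pool); everything else is ``neutral``.
    """
    selected = res.S >= threshold
    status = np.full(res.E.shape, "neutral", dtype=object)
    for row in np.nonzero(selected)[0]:
        for j in range(4):
            if res.log2E[row, j] > 0:
                status[row, j] = "enriched"
            elif res.log2E[row, j] < 0:
                status[row, j] = "counter-selected"
    return PositionClassification(
        positions=res.positions,
        selected=selected,
        base_status=status,
        S=res.S,
        threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------


def write_profiles_tsv(profiles: list[BaseProfile], path: str | Path) -> None:
    """Write profiles as TSV (columns position, A, C, G, T, round, depth)."""
    frames = []
    for p in profiles:
        df = pd.DataFrame(p.fractions, columns=list(BASES))
        df.insert(0, "position", p.positions)
        df["round"] = p.round_index
        df["depth"] = p.depth
        df["survival"] = p.survival_rate
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path: str | Path) -> list[BaseProfile]:
    """Read profiles written by :func:`write_profiles_tsv`, sorted by round."""
    df = pd.read_csv(path, sep="\t", comment="#")
    profiles = []
    for rnd, sub in df.groupby("round"):
        sub = sub.sort_values("position")
        survival = float(sub["survival"].iloc[0]) if "survival" in sub else 1.0
        profiles.append(
            BaseProfile(
                fractions=sub[list(BASES)].to_numpy(dtype=float),
                positions=tuple(int(p) for p in sub["position"]),
                round_index=int(rnd),
                depth=int(sub["depth"].iloc[0]),
                survival_rate=survival,
            )
        )
    profiles.sort(key=lambda p: p.round_index)
    return profiles
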