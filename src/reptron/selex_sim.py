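"""Synthetic CST-SELEX: degenerate pools under REPtron substrate rules.

Simulates the experiment end to end: a pool of single-stranded substrates
degenerate at chosen element positions is subjected to rounds of selection
(cleavage + strand transfer survival) and unbiased reamplification, after
which only per-position base fractions are observable (bulk sequencing —
linkage between positions is discarded downstream).

Selection is modelled at the molecule level: each molecule survives a round
as a Bernoulli trial with probability equal to the product of its
per-position fitness weights times structural-rule indicators, and the
survivors are resampled with replacement back to the original depth
(unbiased amplification; no PCR bias or mutation).  This reproduces the
multinomial sampling noise visible in real SELEX rounds rather than
deterministic filtering.

The bundled fitness specs encode each REPtron's experimentally determined
substrate determinants in qualitative weights:

* ``ec-gtag``   — the *E. coli* guide is strictly required; any substitution
  abolishes cleavage (weight 0).
* ``ec-bulge``  — survival requires the bulge pairs to remain non-Watson-
  Crick: it is the unpaired state, not the sequence, that matters, and
  variants restoring a regular stem are eliminated.
* ``ec-y-loop`` — fully neutral: the y REP loop sequence is not selected.
* ``sm-gtag``   — graded guide tolerance: positions 1-2 reduce activity
  (weight 0.3 on mismatch); positions 3-4 are strictly required.
* ``sm-loop``   — only G13 of the 3-nt loop is required; C14/T15 are free.
* ``mb-loop-ct`` / ``mb-loop-ca`` — loop positions T12, T13 and A15 are
  required while position 14 is free, on substrates carrying a CT or a CA
  cleavage site respectively.

All randomness flows from a single explicit seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rep_model import (
    REP_EC_Y,
    REP_MB,
    REP_SM,
    RepTemplateSpec,
    build_rep_template,
    is_wc,
)
from .selex_quant import BASES, BaseProfile

__all__ = [
    "FitnessSpec",
    "Pool",
    "PoolExtinctError",
    "make_pool",
    "run_round",
    "run_selex",
    "profile_from_pool",
    "neutral_spec",
    "Reptron",
    "REPTRONS",
    "SCENARIOS",
    "Scenario",
    "pool_to_fasta",
]


class PoolExtinctError(RuntimeError):
    """No molecule survived a selection round."""


@dataclass(frozen=True)
class FitnessSpec:
    """Per-position and structural substrate-viability rules for one REPtron.

    ``required`` maps 1-based element positions to the single base with
    fitness 1 (any other base scores 0).  ``tolerated`` maps positions to
    base->weight tables (weights in (0, 1]; bases absent from the table
    score the table's ``'*'`` default, or 0).  Unlisted positions are free.
    ``require_unpaired`` lists 0-based 5'-arm indices whose opposed pair
    must be non-Watson-Crick for survival; ``require_perfect_stem`` demands
    every stem pair be Watson-Crick.  ``site_type`` records which cleavage
    site (CT or CA) the substrate series carries, where relevant.
    """

    name: str = "custom"
    required: dict[int, str] = field(default_factory=dict)
    tolerated: dict[int, dict[str, float]] = field(default_factory=dict)
    require_unpaired: tuple[int, ...] = ()
    require_perfect_stem: bool = False
    site_type: str | None = None
    #: Sequence-independent per-round survival probability multiplying every
    #: molecule's fitness (models overall cleavage efficiency; lets a
    #: neutral spec reproduce an experiment's bottleneck).
    baseline_survival: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_survival <= 1:
            raise ValueError("baseline_survival must lie in (0, 1]")
        for p, table in self.tolerated.items():
            for b, w in table.items():
                if not 0 < w <= 1:
                    raise ValueError(
                        f"tolerated weight for position {p} base {b} outside (0, 1]"
                    )
        if self.require_unpaired and self.require_perfect_stem:
            raise ValueError("cannot require both an unpaired pair and a perfect stem")

    def base_weight(self, position: int, base: str) -> float:
        """Fitness weight contributed by ``base`` at ``position``."""
        if position in self.required:
            return 1.0 if base == self.required[position] else 0.0
        if position in self.tolerated:
            table = self.tolerated[position]
            return table.get(base, table.get("*", 0.0))
        return 1.0

    @property
    def constrained_positions(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.required) | set(self.tolerated)))


@dataclass(frozen=True)
class Pool:
    """A SELEX pool, aggregated over sequence variants.

    The concrete element ``base_seq`` (from :func:`build_rep_template`)
    supplies every non-degenerate base; ``variants`` holds the base codes
    (0..3 = A, C, G, T) at ``degenerate_positions`` for each distinct
    variant, with ``counts`` molecules apiece.
    """

    template: RepTemplateSpec
    base_seq: str
    degenerate_positions: tuple[int, ...]
    variants: np.ndarray  # (V, d) uint8 codes into BASES
    counts: np.ndarray  # (V,) int
    round_index: int = 0
    #: Pre-amplification survivor count founding this round's pool
    #: (equals depth for a round-0 pool).
    founders: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.variants.shape[0] != self.counts.shape[0]:
            raise ValueError("variants/counts shape mismatch")

    @property
    def depth(self) -> int:
        return int(self.counts.sum())

    def variant_seq(self, v: int) -> str:
        seq = list(self.base_seq)
        for j, p in enumerate(self.degenerate_positions):
            seq[p - 1] = BASES[self.variants[v, j]]
        return "".join(seq)

    def sequences(self) -> list[str]:
        """Expand to one string per molecule (small pools / tests only)."""
        out: list[str] = []
        for v in range(self.variants.shape[0]):
            out.extend([self.variant_seq(v)] * int(self.counts[v]))
        return out


def make_pool(
    template: RepTemplateSpec,
    degenerate_positions: list[int] | tuple[int, ...],
    depth: int,
    seed: int,
) -> Pool:
    """Round-0 pool: template bases everywhere, uniform random bases at the
    degenerate positions, ``depth`` molecules in total."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    positions = tuple(int(p) for p in degenerate_positions)
    if any(not 1 <= p <= template.total_len for p in positions):
        raise ValueError("degenerate positions outside the template element")
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate degenerate positions")
    if len(positions) > 10:
        raise ValueError("more than 10 degenerate positions is not supported")
    element = build_rep_template(template, seed)
    d = len(positions)
    n_var = 4**d
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, np.full(n_var, 1.0 / n_var)) if d else np.array([depth])
    if d:
        grids = np.meshgrid(*([np.arange(4, dtype=np.uint8)] * d), indexing="ij")
        variants = np.stack([g.ravel() for g in grids], axis=1)
    else:
        variants = np.zeros((1, 0), dtype=np.uint8)
    return Pool(
        template=template,
        base_seq=element.seq,
        degenerate_positions=positions,
        variants=variants,
        counts=counts,
        round_index=0,
        founders=depth,
    )


def _variant_base(pool: Pool, position: int) -> np.ndarray:
    """Base code at an element position for every variant, shape (V,)."""
    if position in pool.degenerate_positions:
        j = pool.degenerate_positions.index(position)
        return pool.variants[:, j].astype(np.int64)
    code = BASES.index(pool.base_seq[position - 1])
    return np.full(pool.variants.shape[0], code, dtype=np.int64)


def variant_fitness(pool: Pool, spec: FitnessSpec) -> np.ndarray:
    """Survival probability of each variant under ``spec``, shape (V,)."""
    tpl = pool.template
    w = np.full(pool.variants.shape[0], spec.baseline_survival)
    for p in spec.constrained_positions:
        codes = _variant_base(pool, p)
        table = np.array([spec.base_weight(p, b) for b in BASES])
        w *= table[codes]
    pair_indices: tuple[int, ...] = ()
    if spec.require_perfect_stem:
        pair_indices = tuple(range(tpl.stem_arm_len))
    for i in set(spec.require_unpaired) | set(pair_indices):
        b5 = _variant_base(pool, tpl.arm5_position(i))
        b3 = _variant_base(pool, tpl.arm3_position(i))
        wc = np.array([[is_wc(a, b) for b in BASES] for a in BASES])[b5, b3]
        if i in spec.require_unpaired:
            w *= ~wc
        else:
            w *= wc
    return w


def run_round(pool: Pool, spec: FitnessSpec, seed: int) -> Pool:
    """One selection + amplification round.

    Each molecule survives with probability given by its fitness weight;
    survivors are resampled with replacement back to the original depth
    (depth is conserved across rounds).  Raises :class:`PoolExtinctError`
    if no molecule survives.
    """
    rng = np.random.default_rng(seed)
    w = variant_fitness(pool, spec)
    survivors = rng.binomial(pool.counts, w)
    total = survivors.sum()
    if total == 0:
        raise PoolExtinctError(
            f"pool extinct at round {pool.round_index + 1} under spec {spec.name!r}"
        )
    counts = rng.multinomial(pool.depth, survivors / total)
    return Pool(
        template=pool.template,
        base_seq=pool.base_seq,
        degenerate_positions=pool.degenerate_positions,
        variants=pool.variants,
        counts=counts,
        round_index=pool.round_index + 1,
        founders=int(total),
    )


def profile_from_pool(pool: Pool) -> BaseProfile:
    """Bulk-sequencing profile of a pool at its degenerate positions.

    Numerically identical to expanding the pool to reads and calling
    :func:`reptron.selex_quant.profile_from_reads`.
    """
    d = len(pool.degenerate_positions)
    fractions = np.zeros((d, 4))
    for j in range(d):
        fractions[j] = np.bincount(
            pool.variants[:, j], weights=pool.counts, minlength=4
        )
    fractions /= pool.depth
    survival = 1.0 if pool.founders is None else pool.founders / pool.depth
    return BaseProfile(
        fractions=fractions,
        positions=pool.degenerate_positions,
        round_index=pool.round_index,
        depth=pool.depth,
        survival_rate=survival,
    )


def run_selex(
    template: RepTemplateSpec,
    degenerate_positions: list[int] | tuple[int, ...],
    spec: FitnessSpec,
    n_rounds: int,
    depth: int,
    seed: int,
) -> list[BaseProfile]:
    """Simulate rounds 0..n_rounds and return one profile per round."""
    if n_rounds < 0:
        raise ValueError("n_rounds must be >= 0")
    seeds = np.random.SeedSequence(seed).generate_state(n_rounds + 1) % (2**31)
    pool = make_pool(template, degenerate_positions, depth, int(seeds[0]))
    profiles = [profile_from_pool(pool)]
    for r in range(n_rounds):
        pool = run_round(pool, spec, int(seeds[r + 1]))
        profiles.append(profile_from_pool(pool))
    return profiles


def neutral_spec(survival_rate: float = 1.0) -> FitnessSpec:
    """A no-selection spec: every position free, no structural rules.

    ``survival_rate`` applies a sequence-independent bottleneck per round,
    matching the overall cleaved fraction of the experiment being nulled.
    """
    return FitnessSpec(name="neutral", baseline_survival=survival_rate)


def pool_to_fasta(pool: Pool, path: str | Path) -> None:
    """Write distinct pool variants as FASTA with count annotations."""
    with open(path, "w") as fh:
        for v in np.argsort(-pool.counts):
            if pool.counts[v] == 0:
                continue
            fh.write(
                f">variant_{v} count={int(pool.counts[v])} "
                f"round={pool.round_index}\n{pool.variant_seq(int(v))}\n"
            )


# ---------------------------------------------------------------------------
# Bundled REPtron profiles and SELEX scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reptron:
    """One tnpA_REP / cognate-REP system.

    ``retargetable`` records whether changing guide bases redirects the
    cleavage site in vitro: true for Mb, false for Ec and Sm (attempts to
    change their cleavage sites did not succeed).
    """

    name: str
    template: RepTemplateSpec
    guide: str = "GTAG"
    retargetable: bool = False


REPTRONS: dict[str, Reptron] = {
    "ec": Reptron(name="ec", template=REP_EC_Y, retargetable=False),
    "sm": Reptron(name="sm", template=REP_SM, retargetable=False),
    "mb": Reptron(name="mb", template=REP_MB, retargetable=True),
}


@dataclass(frozen=True)
class Scenario:
    """A ready-to-run SELEX experiment: template + degenerate region + rules."""

    name: str
    template: RepTemplateSpec
    degenerate_positions: tuple[int, ...]
    spec: FitnessSpec


def _scenarios() -> dict[str, Scenario]:
    ec_gtag = FitnessSpec(name="ec-gtag", required={1: "G", 2: "T", 3: "A", 4: "G"})
    ec_bulge = FitnessSpec(name="ec-bulge", require_unpaired=(7, 8))
    sm_gtag = FitnessSpec(
        name="sm-gtag",
        required={3: "A", 4: "G"},
        tolerated={1: {"G": 1.0, "*": 0.3}, 2: {"T": 1.0, "*": 0.3}},
    )
    sm_loop = FitnessSpec(name="sm-loop", required={13: "G"})
    mb_loop = {12: "T", 13: "T", 15: "A"}
    return {
        "ec-gtag": Scenario("ec-gtag", REP_EC_Y, REP_EC_Y.guide_positions, ec_gtag),
        "ec-bulge": Scenario("ec-bulge", REP_EC_Y, REP_EC_Y.bulge_positions, ec_bulge),
        "ec-y-loop": Scenario(
            "ec-y-loop", REP_EC_Y, REP_EC_Y.loop_positions, neutral_spec()
        ),
        "sm-gtag": Scenario("sm-gtag", REP_SM, REP_SM.guide_positions, sm_gtag),
        "sm-loop": Scenario("sm-loop", REP_SM, REP_SM.loop_positions, sm_loop),
        "mb-loop-ct": Scenario(
            "mb-loop-ct",
            REP_MB,
            REP_MB.loop_positions,
            FitnessSpec(name="mb-loop-ct", required=dict(mb_loop), site_type="CT"),
        ),
        "mb-loop-ca": Scenario(
            "mb-loop-ca",
            REP_MB,
            REP_MB.loop_positions,
            FitnessSpec(name="mb-loop-ca", required=dict(mb_loop), site_type="CA"),
        ),
    }


SCENARIOS: dict[str, Scenario] = _scenarios()
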