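# Methods

This note documents the models implemented in `reptron`, the parameters
that matter, and the choices made where the design was genuinely open.

## REP hairpin model (`rep_model`)

A REP element is modelled as

```
guide (4 nt) · spacer (0–3 nt) · arm5 (k bp) · loop (≥1 nt) · arm3 (k bp)
```

with 1-based element coordinates placing the guide at positions 1–4 (so
named bases such as T11/G32 of the *E. coli* y REP, G13 of the Sm loop, or
T12/T13/N14/A15 of the Mb loop land on their conventional coordinates).

Folding is purely combinatorial, not thermodynamic. The engine enumerates
every decomposition `(offset, arm_len, loop_len)` of the input, aligns the
5′ arm gaplessly against the reverse complement of the 3′ arm, and counts
non-Watson–Crick pairs. A group-2 "bulge" is represented as opposed
mismatched bases at equal arm lengths — every experimentally characterised
REP variant keeps its two arm lengths equal, so indels in the stem are
excluded by construction. `N` pairs with nothing and always counts as a
mismatch.

Tie-breaking among qualifying folds is deterministic: longest stem, then
shortest loop, then 5′-most start. The scanner uses an `anchored` variant
in which the 5′ arm must begin immediately after the guide + spacer.

Classification: a fold with a perfect stem is group 3; a fold whose
mismatches all lie strictly inside the stem (not at the outermost or
innermost pair) is group 2; mispairs at a stem terminus are treated as
fraying, not a bulge, and leave the fold unclassified.

Bundled templates: Sm (8-bp arms, GCT loop, no spacer; 23 nt in total),
Mb (5-bp arms, TTTA loop, 2-nt spacer; 20 nt), and the group-2 y REP
(13-bp arms, 4-nt loop at positions 18–21, opposed mispairs at positions
12/13 against 26/27). The exact y consensus stem sequence is not fixed by
the sources this package models, so y elements are generated randomly
subject to the structural grammar; tests and simulations depend only on
the grammar, not on a particular stem sequence.

`build_rep_template` guarantees a round trip: the emitted sequence refolds
to exactly the requested stem, loop and mismatch set. When the loop is
random and at least 2 nt, its terminal bases are chosen non-complementary
so the stem cannot creep into the loop under permissive loop ranges.

## Cleavage-site selection and CST (`cleavage_model`)

The cleavage dinucleotide D1·D2 is selected by complementarity with the
guide g1g2g3g4. Two schemas operate, and both fix D1 = comp(g4):

| schema | D2        | GTAG example |
|--------|-----------|--------------|
| linear | comp(g3)  | CT           |
| cross  | comp(g2)  | CA           |

When the schemas agree (e.g. GTTG → CA twice) the prediction is
deduplicated and labelled `linear`. Predictions are binary: relative
efficiencies between retargeted sites are not modelled because no rate
constants are available. The bundled REPtron profiles flag Ec and Sm as
non-retargetable — in those systems changing the guide does not move the
cleavage site — while Mb is retargetable.

CST enumeration reports one product per occurrence of a predicted
dinucleotide lying entirely within `window` nt of either flank of the
stem-loop interval (default 10 nt, reflecting cleavage "in proximity" to
the structure; `window=inf` reports distant discrete sites). `cut_pos` is
the index of D2, i.e. cleavage 5′ of D2, so a joined attacker ends up
abutted to the T of a C|T site. Strand transfer requires the attacker's 3′
base to equal D1 (the obligatory C for CT/CA sites) and therefore always
reconstitutes D1·D2 across the junction. An inactive (Tyr→Phe) enzyme
yields no products.

## SELEX statistics (`selex_quant`)

For round N against round 0:

* enrichment factor `E_N,0[p,b] = (F_N[p,b] + ε) / (F_0[p,b] + ε)`;
* selection score `S[p] = Var(E_N,0[p,·])`, the **population** variance
  (divide by 4) over the four bases.

The pseudocount defaults to `ε = 1/(2·depth)` (depth-scaled shrinkage that
keeps the ratio finite when a base vanished from the initial pool); pass 0
for the raw ratio. With ε = 0, a uniform round 0 and a pure round N give
E = (4, 0, 0, 0) and S = 3 exactly. Multi-round experiments are always
compared against round 0, never chained between consecutive rounds.
Profiles carry per-position fractions only: bulk sequencing cannot capture
associations between positions, so no linkage inference is attempted.

### Selected/neutral threshold: a matched null

No numeric score cutoff exists for "selected"; the threshold is calibrated
empirically as the 0.99 quantile of the maximum position score across ≥100
neutral simulations. Crucially the null is *matched* to the experiment in
two respects:

1. the same number of rounds (resampling noise accumulates per round);
2. the same sequence-independent per-round survival rate
   (`FitnessSpec.baseline_survival`).

The second point matters: strong selection at required positions
bottlenecks the pool (e.g. three strictly required positions leave ~1/64
of molecules), and amplification back to full depth does not restore the
lost information, so sampling variance is inflated at *every* position,
including free ones. A null calibrated without the bottleneck would call
free positions selected. The overall survival rate corresponds to the
cleaved fraction of substrate, which is directly observable in the assay,
so conditioning the null on it uses no unobservable information. Simulated
profiles record their realised per-round survival in the profile TSV
(`survival` column); the CLI uses its geometric mean when calibrating.

At a selected position, a base with `log2 E < 0` is called
counter-selected (excluded from the surviving pool) and one with
`log2 E > 0` enriched.

## SELEX simulator (`selex_sim`)

Selection is molecule-level Bernoulli survival: each molecule's survival
probability is `baseline_survival ×` the product of its per-position
weights `×` structural-rule indicators; survivors are resampled with
replacement to the original depth (unbiased amplification). Depth is
conserved across rounds. A round in which nothing survives raises an
explicit pool-extinction error. Internally pools are aggregated over the
4^d sequence variants of the degenerate region (d ≤ 10), which makes the
per-round update a pair of vectorised binomial/multinomial draws that is
mathematically identical to simulating molecules one by one.

Weight choices encode the wet observations qualitatively: strictly
required bases (weight 0 on mismatch) where substitutions abolished
activity; graded weights 0.3 for Sm guide positions 1–2, where mutations
reduced but did not abolish cleavage; free positions where no enrichment
was observed. The Ec bulge rule constrains *pairing state*, not sequence:
any variant restoring a Watson–Crick pair at the bulge is eliminated.
True per-round wet survival rates are unknown; weights are qualitative
encodings of gel-intensity descriptions and are configurable.

What the simulator does **not** emulate: PCR bias and mutation, attacker
oligonucleotide evolution, binding constants, and any linkage-dependent
selection (epistasis between positions beyond the structural pairing
rules). Passing recovery tests therefore demonstrates that the statistics
recover position-wise determinants under multinomial sampling noise and
selection bottlenecks — not that they would resolve combinatorial
selection in real pools, which bulk profiles cannot express in principle.

## Genome scanner (`genome_scan`)

A hit is a guide occurrence + spacer + anchored fold under the preset
grammar; only the tie-broken best fold per guide occurrence is reported
(longest stem, shortest loop, smallest spacer). Minus-strand hits (iREPs;
plus-strand palindromes terminated by CTAC) are found by scanning the
reverse complement and mapping coordinates, which makes strand symmetry
exact. Coordinates are 0-based half-open; BED6 output is lossless and GFF3
uses 1-based inclusive coordinates.

Presets: group 2 (min stem 8 bp, loop 3–9 nt, ≤2 mismatches, spacer
0–1 nt) and group 3 (min stem 5 bp, loop 3–5 nt, perfect stems, spacer
0–3 nt). The arm search is bounded at `max_stem` = 20 bp, a package
decision covering every characterised family with margin; genome-wide
stem/loop distributions are wider than these presets, which are defaults,
not facts. BIME pairing is greedy left-to-right over coordinate-sorted
hits: adjacent opposite-orientation hits with a linker ≤ `max_linker`
(default 50 nt) pair, and each hit joins at most one BIME.

Planted-truth genomes place non-overlapping elements (and REP–linker–iREP
blocks) into uniform-random background with ≥30 nt gaps. Random background
can still produce chance hits — precision on seeded backgrounds is what
the scanner's false-positive tests quantify — but recall of planted
elements at matching parameters is exact.

## Problem sizes and randomness

Test and acceptance runs use depth 10,000 for SELEX simulations (matching
the degenerate-pool analyses being modelled), 100 seeded replicates for
recovery rates, 100-simulation null calibrations, and scan fixtures of
0.5–8 kb against an O(n²) brute-force oracle. These sizes give stable
statistics while keeping the full suite under ten seconds on one core.
Every stochastic routine takes one explicit integer seed; child seeds are
derived with `numpy.random.SeedSequence`, and identical seeds reproduce
byte-identical outputs.

## Known limitations

* Folding is combinatorial; no free energies, RNA rules or pseudoknots.
* Cleavage predictions are binary; retargeting efficiency is not scored.
* The y REP consensus stem is randomised within its grammar (see above).
* Fitness weights are qualitative; absolute survival rates are arbitrary
  up to the observable cleaved fraction.
* The scanner reports one fold per guide occurrence by default; truly
  overlapping alternative folds are suppressed unless requested.
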