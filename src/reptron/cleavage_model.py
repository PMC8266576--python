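"""Guide-directed cleavage-site prediction and CST product enumeration.

TnpA_REP, the HuH-superfamily transposase domesticated in REPtrons, cleaves
single-stranded REP substrates at a dinucleotide chosen by DNA-DNA
complementarity with the 'guide' tetranucleotide (g1 g2 g3 g4, canonically
G T A G) that lies 5' of the palindrome — the same site-selection logic as
in the related IS200/IS605 transposases.  Two pairing schemas operate:

* **linear**  — the site pairs with g3 g4:  D1 = comp(g4), D2 = comp(g3);
* **cross**   — the site pairs with g2 and g4:  D1 = comp(g4), D2 = comp(g2).

For the canonical GTAG guide this yields CT (linear) and CA (cross); both
schemas always agree on the first base of the site.  Predictions are binary:
relative cleavage efficiencies between retargeted sites are not modelled.

The CST (Cleavage and Strand Transfer) assay is modelled by enumerating
predicted dinucleotides in windows flanking the stem-loop (cleavage occurs
mainly in proximity, 5' or 3' of the REP structure) and, for strand
transfer, joining an attacking oligonucleotide immediately 5' of the base 3'
of the cut.  The attacker's 3' base must equal D1 (obligatorily a C for
CT/CA sites), which reconstitutes the cleavage dinucleotide across the
junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .rep_model import DNA_BASES, InvalidSequenceError, _validate_seq, complement

__all__ = [
    "GuideModel",
    "CleavagePrediction",
    "Substrate",
    "CleavageProduct",
    "predict_cleavage_dinucleotides",
    "enumerate_cleavage_products",
    "strand_transfer",
    "StrandTransferError",
    "example_mb_substrate",
    "DEFAULT_WINDOW",
]

#: Default search distance (nt) from each flank of the stem-loop interval.
#: Distant discrete sites exist but are off by default; pass
#: ``window=math.inf`` to report them.
DEFAULT_WINDOW = 10


class StrandTransferError(ValueError):
    """Attacking oligonucleotide rejected (3' base does not match D1)."""


@dataclass(frozen=True)
class GuideModel:
    """A guide tetranucleotide g1..g4 (canonical GTAG)."""

    guide: str = "GTAG"

    def __post_init__(self) -> None:
        if len(self.guide) != 4 or set(self.guide) - set(DNA_BASES):
            raise InvalidSequenceError(
                f"guide must be a 4-letter ACGT string, got {self.guide!r}"
            )


@dataclass(frozen=True)
class CleavagePrediction:
    """A predicted cleavage dinucleotide D1 D2 and the schema that chose it.

    When the linear and cross schemas agree on the same dinucleotide the
    deduplicated prediction is labelled ``linear``.
    """

    site: str
    mode: str  # "linear" | "cross"


@dataclass(frozen=True)
class Substrate:
    """A single-stranded (5'->3') CST substrate.

    ``rep_interval`` is the 0-based half-open span of the stem-loop.
    ``active_enzyme=False`` models catalytic Tyr->Phe mutants
    (e.g. Y115F/Y125F/Y130F), which bind but never cleave.
    """

    seq: str
    rep_interval: tuple[int, int]
    active_enzyme: bool = True
    seq_id: str = "substrate"

    def __post_init__(self) -> None:
        _validate_seq(self.seq)
        s, e = self.rep_interval
        if not (0 <= s <= e <= len(self.seq)):
            raise ValueError("rep_interval outside substrate bounds")


@dataclass(frozen=True)
class CleavageProduct:
    """One cleavage event: the strand is nicked between D1 and D2.

    ``cut_pos`` is the 0-based index of D2 (cleavage 5' of D2, i.e. the
    attacking oligonucleotide ends up abutted to the T of a C|T site).
    """

    substrate: Substrate
    cut_pos: int
    site: str
    side: str  # "5prime" | "3prime"
    joined_seq: str | None = None

    def __post_init__(self) -> None:
        seq = self.substrate.seq
        if seq[self.cut_pos - 1 : self.cut_pos + 1] != self.site:
            raise ValueError("cut_pos does not sit between the site dinucleotide")


def predict_cleavage_dinucleotides(guide: GuideModel | str) -> frozenset[CleavagePrediction]:
    """Predict the cleavage dinucleotide(s) selected by a guide.

    Returns the linear and cross predictions, deduplicated when both
    schemas yield the same dinucleotide (e.g. GTTG -> CA only).
    """
    if isinstance(guide, str):
        guide = GuideModel(guide)
    g1, g2, g3, g4 = guide.guide
    d1 = complement(g4)
    linear = d1 + complement(g3)
    cross = d1 + complement(g2)
    preds = {CleavagePrediction(site=linear, mode="linear")}
    if cross != linear:
        preds.add(CleavagePrediction(site=cross, mode="cross"))
    return frozenset(preds)


def enumerate_cleavage_products(
    sub: Substrate,
    guide: GuideModel | str,
    window: int | float = DEFAULT_WINDOW,
) -> list[CleavageProduct]:
    """Enumerate cleavage products on a substrate under the guide model.

    One product is emitted per occurrence of any predicted dinucleotide
    lying entirely within ``window`` nt of either flank of
    ``sub.rep_interval`` (5' flank: ``[rep_start - window, rep_start)``;
    3' flank: ``[rep_end, rep_end + window)``).  An inactive enzyme yields
    no products; a substrate lacking every predicted dinucleotide in range
    yields an empty list.  Products are sorted by cut position.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if not sub.active_enzyme:
        return []
    sites = {p.site for p in predict_cleavage_dinucleotides(guide)}
    rs, re_ = sub.rep_interval
    lo5 = 0 if math.isinf(window) else max(0, rs - int(window))
    hi3 = len(sub.seq) if math.isinf(window) else min(len(sub.seq), re_ + int(window))
    products: list[CleavageProduct] = []
    for i in range(len(sub.seq) - 1):
        dinuc = sub.seq[i : i + 2]
        if dinuc not in sites:
            continue
        if lo5 <= i and i + 2 <= rs:
            side = "5prime"
        elif re_ <= i and i + 2 <= hi3:
            side = "3prime"
        else:
            continue
        products.append(
            CleavageProduct(substrate=sub, cut_pos=i + 1, site=dinuc, side=side)
        )
    products.sort(key=lambda p: p.cut_pos)
    return products


def strand_transfer(product: CleavageProduct, attacker: str) -> str:
    """Join an attacking oligonucleotide to the cleaved substrate.

    The attacker's 3'-OH resolves the 5'P-tyrosine intermediate, fusing the
    attacker immediately 5' of the base 3' of the cut.  The attacker's 3'
    base must equal D1 of the cleavage site (for C|T and C|A sites this is
    the obligatory C); otherwise the transfer is refused.  The returned
    joint therefore reconstitutes D1 D2 across the junction.
    """
    _validate_seq(attacker)
    d1 = product.site[0]
    if attacker[-1] != d1:
        raise StrandTransferError(
            f"attacker 3' base {attacker[-1]!r} does not match the cleavage-site "
            f"first base {d1!r}"
        )
    return attacker + product.substrate.seq[product.cut_pos :]


def example_mb_substrate(
    active_enzyme: bool = True, ct_to_tt: bool = False
) -> Substrate:
    """The 55-nt Mb-style demonstration substrate.

    Carries the Mb hairpin (5-bp arms, TTTA loop) preceded by GTAG + 2-nt
    spacer, with exactly one CT and one CA dinucleotide inside the default
    10-nt search window on each flank — four cleavage products in total for
    the canonical guide.  ``ct_to_tt=True`` mutates both CT sites to TT,
    leaving the two CA-site products only.
    """
    hairpin = "GGGCC" + "TTTA" + "GGCCC"  # 5-bp perfect stem, 4-nt loop
    left_pad = "GTGTGTGTGTG"              # outside the 5' window
    left_win = "CTCA" + "GTAG" + "GG"     # one CT, one CA, guide, spacer
    right_win = "GGCTGGCAGG"              # one CT, one CA
    right_pad = "GTGTGTGTGG"
    if ct_to_tt:
        left_win = left_win.replace("CT", "TT")
        right_win = right_win.replace("CT", "TT")
    seq = left_pad + left_win + hairpin + right_win + right_pad
    rs = len(left_pad) + len(left_win)
    return Substrate(
        seq=seq,
        rep_interval=(rs, rs + len(hairpin)),
        active_enzyme=active_enzyme,
        seq_id="mb-demo-55nt",
    )
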