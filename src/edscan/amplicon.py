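"""Amplicon deep-sequencing variant screening.

Variants are called from a per-position base-call tally with a strict
frequency-threshold reporting rule (default: report only when the
variant fraction strictly exceeds 10%), classified into the canonical
RNA-editing classes (A-to-G for A-to-I editing, C-to-T for C-to-U
editing; everything else non-canonical, judged in transcript
orientation), and sequencing-based fractions can be compared against
allele-specific qPCR estimates of the same samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .genemodel import GeneModel
from .pileup import BaseCallTally

__all__ = [
    "VariantCall",
    "MethodComparison",
    "call_variants",
    "classify_canonical",
    "compare_methods",
]

A_TO_G = "A_to_G"
C_TO_T = "C_to_T"
NON_CANONICAL = "non_canonical"


@dataclass(frozen=True)
class VariantCall:
    """A transcript variant exceeding the reporting threshold."""

    cds_pos: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    fraction: float
    canonical_class: str
    confirmed: bool | None = None  # optional orthogonal (e.g. Sanger) annotation


@dataclass(frozen=True)
class MethodComparison:
    """Sequencing- versus qPCR-based editing fractions, paired by sample."""

    pairs: tuple[tuple[float, float], ...]  # (qpcr_fraction, seq_fraction)
    per_pair_excess: tuple[float, ...]  # seq/qpcr - 1
    mean_relative_excess: float  # mean of per-pair excesses
    ratio_of_means: float  # mean(seq)/mean(qpcr) - 1


def classify_canonical(ref: str, alt: str) -> str:
    """Canonical editing class of a substitution in transcript
    orientation: A->G, C->T, or non-canonical (antisense changes such
    as G->A are not counted)."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError("ref and alt must be A/C/G/T")
    if ref == alt:
        raise ValueError("ref equals alt: not a substitution")
    if (ref, alt) == ("A", "G"):
        return A_TO_G
    if (ref, alt) == ("C", "T"):
        return C_TO_T
    return NON_CANONICAL


def call_variants(
    tally: BaseCallTally,
    model: GeneModel,
    threshold: float | str = 0.10,
    min_depth: int = 100,
    cds_positions: Sequence[int] | None = None,
) -> list[VariantCall]:
    """Report every (position, non-reference base) whose fraction
    strictly exceeds ``threshold`` at depth >= ``min_depth``.

    The threshold comparison is done in exact rational arithmetic
    (alt_count * q > p * depth for threshold p/q), so a fraction of
    exactly the threshold is never reported. Ambiguous calls never
    produce variants but stay in the depth denominator.
    """
    thr = Fraction(str(threshold))
    if not 0 <= thr < 1:
        raise ValueError("threshold must be in [0, 1)")
    positions = cds_positions if cds_positions is not None else range(1, len(tally) + 1)
    calls: list[VariantCall] = []
    for pos in positions:
        depth = tally.depth(pos)
        if depth < max(min_depth, 1):
            continue
        ref = model.transcript_base(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            alt_count = tally.count(pos, alt)
            if Fraction(alt_count, depth) > thr:
                calls.append(
                    VariantCall(
                        cds_pos=pos,
                        ref=ref,
                        alt=alt,
                        alt_count=alt_count,
                        depth=depth,
                        fraction=alt_count / depth,
                        canonical_class=classify_canonical(ref, alt),
                    )
                )
    return calls


def compare_methods(pairs: Sequence[tuple[float, float]]) -> MethodComparison:
    """Relative excess of sequencing-based over qPCR-based fractions.

    Each pair is (qpcr_fraction, seq_fraction); per-pair excess is
    seq/qpcr - 1. Both the mean of per-pair excesses and the
    ratio-of-means summary are reported, since 'X% higher on average'
    is ambiguous between the two. Pairs with zero qPCR fraction are
    skipped with a warning.
    """
    kept = []
    for q, s in pairs:
        if q <= 0:
            warnings.warn(f"skipping pair with non-positive qPCR fraction ({q}, {s})", stacklevel=2)
            continue
        kept.append((float(q), float(s)))
    if not kept:
        raise ValueError("no pair with positive qPCR fraction")
    excesses = tuple(s / q - 1.0 for q, s in kept)
    mean_q = sum(q for q, _ in kept) / len(kept)
    mean_s = sum(s for _, s in kept) / len(kept)
    return MethodComparison(
        pairs=tuple(kept),
        per_pair_excess=excesses,
        mean_relative_excess=sum(excesses) / len(excesses),
        ratio_of_means=mean_s / mean_q - 1.0,
    )
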