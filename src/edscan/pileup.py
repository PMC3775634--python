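"""Per-position base-call tallies over a CDS and the site-vs-background
editing test.

Aligned reads (SAM/BAM) are tallied per CDS position into five
categories — A, C, G, T and ambiguous — in transcript orientation
(bases over minus-strand genes are complemented). The editing fraction
at a target site is compared against the pooled fraction of the same
base change at every CDS position carrying the same reference base (the
background sequencing-error null) with a two-tailed Yates-corrected
chi-square test.

Note on filters: the base-quality floor (default Phred 13) approximates
the behaviour of samtools mpileup's default quality weighting; base
alignment quality (BAQ) recalibration itself is not reimplemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .genemodel import COMPLEMENT, GeneModel

__all__ = [
    "CATEGORIES",
    "ReadFilterConfig",
    "BaseCallTally",
    "SiteEditingCall",
    "UndefinedStatisticError",
    "tally_from_alignments",
    "site_fraction",
    "background_fraction",
    "yates_chi_square",
    "call_editing_site",
    "write_tally_tsv",
    "read_tally_tsv",
    "read_snp_positions",
]

CATEGORIES = ("A", "C", "G", "T", "ambiguous")
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


class UndefinedStatisticError(ValueError):
    """Raised when a fraction or test is undefined (zero depth/marginal)."""


@dataclass(frozen=True)
class ReadFilterConfig:
    """Filters applied to alignments and base calls before tallying."""

    min_base_quality: int = 13
    min_mapping_quality: int = 0
    exclude_duplicates: bool = True
    exclude_secondary_supplementary: bool = True
    collapse_mate_overlap: bool = False

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.min_mapping_quality < 0:
            raise ValueError("quality thresholds must be >= 0")


@dataclass
class BaseCallTally:
    """Per-CDS-position counts of the five base-call categories.

    ``counts`` has shape (CDS length, 5) with columns ordered as
    :data:`CATEGORIES`, all in transcript orientation. ``filtered_depth``
    at a position is the row sum: every filter-passing aligned base (or
    deletion/skip, as ambiguous) contributes to exactly one category.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 5:
            raise ValueError("counts must have shape (cds_length, 5)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def zeros(cls, cds_length: int) -> "BaseCallTally":
        return cls(np.zeros((cds_length, 5), dtype=np.int64))

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def filtered_depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def count(self, pos: int, category: str) -> int:
        return int(self.counts[pos - 1, _CAT_INDEX[category]])

    def depth(self, pos: int) -> int:
        return int(self.counts[pos - 1].sum())

    def add(self, pos: int, category: str, n: int = 1) -> None:
        self.counts[pos - 1, _CAT_INDEX[category]] += n

    def to_dataframe(self, model: GeneModel | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(CATEGORIES))
        df.insert(0, "cds_pos", np.arange(1, len(self) + 1))
        if model is not None:
            gpos = [model.map_cds_to_genome(p)[0] + 1 for p in df["cds_pos"]]  # 1-based out
            df.insert(1, "genomic_pos", gpos)
            df.insert(2, "ref", list(model.cds_sequence))
        df["depth"] = self.filtered_depth
        return df


@dataclass(frozen=True)
class SiteEditingCall:
    """Editing fraction at one site versus the pooled background null."""

    site: int
    ref_base: str
    edited_base: str
    edited_count: int
    site_depth: int
    site_fraction: float
    background_edited: int
    background_depth: int
    background_fraction: float
    chi2: float
    p_value: float
    snp_overlap: bool


def tally_from_alignments(
    alignment_source: str | Path | pysam.AlignmentFile,
    model: GeneModel,
    filters: ReadFilterConfig | None = None,
) -> BaseCallTally:
    """Tally filter-passing base calls over the model's CDS.

    Accepts a SAM/BAM path or an open :class:`pysam.AlignmentFile`;
    alignments are streamed (no index required). Deletions, reference
    skips and N calls count as ambiguous; bases below the base-quality
    floor are excluded entirely.
    """
    filters = filters or ReadFilterConfig()
    own = not isinstance(alignment_source, pysam.AlignmentFile)
    af = (
        pysam.AlignmentFile(str(alignment_source), "r", check_sq=False)
        if own
        else alignment_source
    )
    try:
        if model.chrom not in af.references:
            raise ValueError(f"chromosome {model.chrom!r} absent from alignment header")
        tally = BaseCallTally.zeros(model.cds_length)
        minus = model.strand == "-"
        seen: set[tuple[str, int]] | None = set() if filters.collapse_mate_overlap else None
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or af.get_reference_name(read.reference_id) != model.chrom:
                continue
            if filters.exclude_duplicates and read.is_duplicate:
                continue
            if filters.exclude_secondary_supplementary and (
                read.is_secondary or read.is_supplementary
            ):
                continue
            if read.mapping_quality < filters.min_mapping_quality:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            for qpos, rpos in read.get_aligned_pairs():
                if rpos is None:
                    continue
                cds_pos = model.map_genome_to_cds(rpos)
                if cds_pos is None:
                    continue
                if seen is not None:
                    key = (read.query_name, cds_pos)
                    if key in seen:
                        continue
                    seen.add(key)
                if qpos is None:  # deletion or reference skip
                    tally.add(cds_pos, "ambiguous")
                    continue
                if quals is not None and quals[qpos] < filters.min_base_quality:
                    continue
                base = seq[qpos].upper()
                if base not in "ACGT":
                    tally.add(cds_pos, "ambiguous")
                    continue
                tally.add(cds_pos, COMPLEMENT[base] if minus else base)
        return tally
    finally:
        if own:
            af.close()


def site_fraction(
    tally: BaseCallTally,
    site: int,
    edited_base: str,
    include_ambiguous_in_depth: bool = True,
) -> tuple[float, int, int]:
    """Editing fraction at one c. position: (fraction, edited, depth).

    By default ambiguous calls stay in the depth denominator (they are
    one of the five tally categories); pass
    ``include_ambiguous_in_depth=False`` for a called-bases-only
    denominator.
    """
    edited = tally.count(site, edited_base.upper())
    depth = tally.depth(site)
    if not include_ambiguous_in_depth:
        depth -= tally.count(site, "ambiguous")
    if depth == 0:
        raise UndefinedStatisticError(f"zero filtered depth at c.{site}")
    return edited / depth, edited, depth


def background_fraction(
    tally: BaseCallTally,
    model: GeneModel,
    ref_base: str = "C",
    edited_base: str = "T",
    include_query_site: bool = True,
    query_site: int | None = None,
    min_depth: int = 1,
    include_ambiguous_in_depth: bool = True,
) -> tuple[float, int, int]:
    """Pooled edited-base fraction over every CDS position whose
    transcript-orientation reference equals ``ref_base``.

    With ``include_query_site`` (default, matching pooling over *all*
    same-base positions) the target site stays in the pool; pass
    ``include_query_site=False`` with ``query_site`` for a cleaner null.
    """
    positions = model.positions_with_base(ref_base)
    if not include_query_site:
        if query_site is None:
            raise ValueError("query_site required when include_query_site is False")
        positions = tuple(p for p in positions if p != query_site)
    edited_sum = depth_sum = 0
    for p in positions:
        depth = tally.depth(p)
        if not include_ambiguous_in_depth:
            depth -= tally.count(p, "ambiguous")
        if depth < min_depth:
            continue
        edited_sum += tally.count(p, edited_base.upper())
        depth_sum += depth
    if depth_sum == 0:
        raise UndefinedStatisticError(
            f"no {ref_base}-bearing position with depth >= {min_depth}"
        )
    return edited_sum / depth_sum, edited_sum, depth_sum


def yates_chi_square(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-tailed chi-square with Yates continuity correction on the
    2x2 table [[a, b], [c, d]].

    chi2 = N(|ad-bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)), clipped to 0
    when the correction saturates; p from chi-square with 1 df.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if n == 0 or 0 in margins:
        raise UndefinedStatisticError("chi-square undefined: zero marginal total")
    diff = abs(a * d - b * c) - n / 2.0
    if diff <= 0:
        return 0.0, 1.0
    chi2 = n * diff * diff / float(np.prod([float(m) for m in margins]))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def call_editing_site(
    tally: BaseCallTally,
    model: GeneModel,
    site: int,
    edited_base: str = "T",
    snp_positions: Iterable[tuple[str, int]] | Sequence[int] = (),
    include_query_site: bool = True,
    min_depth: int = 1,
    include_ambiguous_in_depth: bool = True,
) -> SiteEditingCall:
    """Full site call: fraction, pooled background and chi-square test.

    ``snp_positions`` may be (chrom, 0-based genomic position) pairs or
    bare genomic positions; ``snp_overlap`` flags a known polymorphism
    at the site's genomic position.
    """
    ref_base = model.transcript_base(site)
    frac, edited, depth = site_fraction(tally, site, edited_base, include_ambiguous_in_depth)
    bg_frac, bg_edited, bg_depth = background_fraction(
        tally,
        model,
        ref_base=ref_base,
        edited_base=edited_base,
        include_query_site=include_query_site,
        query_site=site,
        min_depth=min_depth,
        include_ambiguous_in_depth=include_ambiguous_in_depth,
    )
    chi2, p = yates_chi_square(edited, depth - edited, bg_edited, bg_depth - bg_edited)
    gpos = model.map_cds_to_genome(site)[0]
    overlap = False
    for snp in snp_positions:
        if isinstance(snp, tuple):
            chrom, pos = snp
            if chrom == model.chrom and int(pos) == gpos:
                overlap = True
        elif int(snp) == gpos:
            overlap = True
    return SiteEditingCall(
        site=site,
        ref_base=ref_base,
        edited_base=edited_base.upper(),
        edited_count=edited,
        site_depth=depth,
        site_fraction=frac,
        background_edited=bg_edited,
        background_depth=bg_depth,
        background_fraction=bg_frac,
        chi2=chi2,
        p_value=p,
        snp_overlap=overlap,
    )


# -- IO ----------------------------------------------------------------


def write_tally_tsv(tally: BaseCallTally, path: str | Path, model: GeneModel | None = None) -> None:
    tally.to_dataframe(model).to_csv(path, sep="\t", index=False)


def read_tally_tsv(path: str | Path) -> BaseCallTally:
    df = pd.read_csv(path, sep="\t")
    return BaseCallTally(df[list(CATEGORIES)].to_numpy())


def read_snp_positions(path: str | Path) -> list[tuple[str, int]]:
    """Read SNP genomic positions from a VCF or a 2-column TSV
    (chrom, 1-based position); returns (chrom, 0-based) pairs."""
    path = Path(path)
    text = path.read_text()
    out: list[tuple[str, int]] = []
    if text.startswith("##fileformat=VCF"):
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                out.append((rec.chrom, rec.pos - 1))
        return out
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, pos = line.split("\t")[:2]
        out.append((chrom, int(pos) - 1))
    return out
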