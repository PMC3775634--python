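"""Strand-aware gene models: CDS <-> genome coordinate mapping, codon
consequences of single-base edits, and in-silico restriction digests.

A :class:`GeneModel` ties a coding sequence (in transcript orientation,
HGVS-style c. numbering starting at the first base of the start codon) to
its genomic exon layout. Genomic coordinates are 0-based half-open
internally; any 1-based positions appear only in formatted output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "Consequence",
    "DigestResult",
    "CoordinateError",
    "ModelConsistencyError",
    "digest_amplicon",
    "edit_destroys_site",
    "COMPLEMENT",
]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

TAQ1_SITE = "TCGA"


class CoordinateError(ValueError):
    """A position falls outside the model's coordinate system."""


class ModelConsistencyError(ValueError):
    """The model's sequence and genomic intervals disagree."""


def _check_intervals(name: str, intervals: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    out = tuple((int(s), int(e)) for s, e in intervals)
    prev_end = -1
    for s, e in out:
        if not 0 <= s < e:
            raise ModelConsistencyError(f"{name}: bad interval ({s}, {e})")
        if s < prev_end:
            raise ModelConsistencyError(f"{name}: intervals overlap or are unsorted")
        prev_end = e
    return out


@dataclass(frozen=True)
class Consequence:
    """Protein-level consequence of a single-base change in the CDS."""

    codon_number: int
    codon_offset: int  # 1, 2 or 3 within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str  # synonymous | missense | nonsense


@dataclass(frozen=True)
class DigestResult:
    """Fragments produced by an in-silico restriction digest."""

    amplicon_length: int
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]


@dataclass(frozen=True)
class GeneModel:
    """A coding gene on a genome.

    Parameters
    ----------
    gene_id : str
        Identifier for the transcript/gene.
    chrom : str
        Reference sequence name.
    strand : str
        ``"+"`` or ``"-"``.
    exons : sequence of (start, end)
        Genomic exon intervals, 0-based half-open, sorted ascending and
        non-overlapping.
    cds_genomic_span : sequence of (start, end)
        Sub-intervals of the exons covered by the CDS.
    cds_sequence : str
        The coding sequence in transcript orientation (A/C/G/T only,
        length divisible by 3). For minus-strand genes this is the
        reverse complement of the plus-strand genomic bases over
        ``cds_genomic_span``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_genomic_span: tuple[tuple[int, int], ...]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelConsistencyError(f"strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "exons", _check_intervals("exons", self.exons))
        object.__setattr__(
            self, "cds_genomic_span", _check_intervals("cds_genomic_span", self.cds_genomic_span)
        )
        seq = self.cds_sequence.upper()
        object.__setattr__(self, "cds_sequence", seq)
        if set(seq) - set("ACGT"):
            raise ModelConsistencyError("cds_sequence contains non-ACGT characters")
        span_len = sum(e - s for s, e in self.cds_genomic_span)
        if span_len != len(seq):
            raise ModelConsistencyError(
                f"cds_sequence length {len(seq)} != genomic span length {span_len}"
            )
        if len(seq) % 3 != 0:
            raise ModelConsistencyError("CDS length must be divisible by 3")
        for cs, ce in self.cds_genomic_span:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ModelConsistencyError("CDS span not contained in a single exon")

    # -- derived coordinate tables ------------------------------------

    @cached_property
    def _genomic_by_cds(self) -> tuple[int, ...]:
        """Genomic position of each CDS base, in transcript order."""
        positions: list[int] = []
        if self.strand == "+":
            for s, e in self.cds_genomic_span:
                positions.extend(range(s, e))
        else:
            for s, e in reversed(self.cds_genomic_span):
                positions.extend(range(e - 1, s - 1, -1))
        return tuple(positions)

    @cached_property
    def _cds_by_genomic(self) -> dict[int, int]:
        return {g: i + 1 for i, g in enumerate(self._genomic_by_cds)}

    # -- properties ----------------------------------------------------

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    def transcript_base(self, pos: int) -> str:
        """Reference base at c. position ``pos`` in transcript orientation."""
        self._check_pos(pos)
        return self.cds_sequence[pos - 1]

    def _check_pos(self, pos: int) -> None:
        if not 1 <= pos <= self.cds_length:
            raise CoordinateError(f"c.{pos} outside CDS of length {self.cds_length}")

    # -- operations ----------------------------------------------------

    def map_cds_to_genome(self, pos: int) -> tuple[int, str, str]:
        """Map a c. position to the genome.

        Returns ``(genomic_pos, plus_strand_base, transcript_base)``;
        the two bases are identical for plus-strand genes and
        complementary for minus-strand genes.
        """
        self._check_pos(pos)
        gpos = self._genomic_by_cds[pos - 1]
        tbase = self.cds_sequence[pos - 1]
        pbase = tbase if self.strand == "+" else COMPLEMENT[tbase]
        return gpos, pbase, tbase

    def map_genome_to_cds(self, gpos: int, chrom: str | None = None) -> int | None:
        """Inverse of :meth:`map_cds_to_genome`; ``None`` for non-coding
        (intronic or outside) positions."""
        if chrom is not None and chrom != self.chrom:
            raise CoordinateError(f"position on {chrom}, model on {self.chrom}")
        return self._cds_by_genomic.get(int(gpos))

    def count_base_positions(self, base: str) -> int:
        """Number of CDS positions whose transcript-orientation reference
        base equals ``base``."""
        base = base.upper()
        if base not in "ACGT" or len(base) != 1:
            raise ValueError(f"base must be one of A/C/G/T, got {base!r}")
        return self.cds_sequence.count(base)

    def positions_with_base(self, base: str) -> tuple[int, ...]:
        """All c. positions carrying ``base`` in transcript orientation."""
        base = base.upper()
        return tuple(i + 1 for i, b in enumerate(self.cds_sequence) if b == base)

    def consequence_of_edit(self, pos: int, alt: str) -> Consequence:
        """Codon-level consequence of substituting ``alt`` at c. ``pos``."""
        self._check_pos(pos)
        alt = alt.upper()
        if alt not in "ACGT":
            raise ValueError(f"alt must be one of A/C/G/T, got {alt!r}")
        ref = self.cds_sequence[pos - 1]
        if alt == ref:
            raise ValueError(f"alt base equals the reference base {ref} at c.{pos}")
        codon_number = (pos - 1) // 3 + 1
        codon_offset = (pos - 1) % 3 + 1
        start = (codon_number - 1) * 3
        ref_codon = self.cds_sequence[start : start + 3]
        alt_codon = ref_codon[: codon_offset - 1] + alt + ref_codon[codon_offset:]
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if alt_aa == ref_aa:
            effect = "synonymous"
        elif alt_aa == "*" and ref_aa != "*":
            effect = "nonsense"
        else:
            effect = "missense"
        return Consequence(codon_number, codon_offset, ref_codon, alt_codon, ref_aa, alt_aa, effect)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "chrom": self.chrom,
            "strand": self.strand,
            "exons": [list(x) for x in self.exons],
            "cds_genomic_span": [list(x) for x in self.cds_genomic_span],
            "cds_sequence": self.cds_sequence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        return cls(
            gene_id=d["gene_id"],
            chrom=d["chrom"],
            strand=d["strand"],
            exons=tuple(tuple(x) for x in d["exons"]),
            cds_genomic_span=tuple(tuple(x) for x in d["cds_genomic_span"]),
            cds_sequence=d["cds_sequence"],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_bed12(cls, bed_path: str | Path, fasta_path: str | Path, gene_id: str | None = None) -> "GeneModel":
        """Build a model from a BED12 record plus a genome FASTA.

        Exons come from the block structure, the CDS from
        thickStart/thickEnd; the record whose name matches ``gene_id``
        is used (the first record when ``gene_id`` is None).
        """
        from Bio import SeqIO

        record = None
        for line in Path(bed_path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError("BED12 record requires 12 fields")
            if gene_id is None or f[3] == gene_id:
                record = f
                break
        if record is None:
            raise ValueError(f"no BED12 record named {gene_id!r} in {bed_path}")
        chrom, start = record[0], int(record[1])
        name, strand = record[3], record[5]
        thick_start, thick_end = int(record[6]), int(record[7])
        sizes = [int(x) for x in record[10].rstrip(",").split(",")]
        starts = [int(x) for x in record[11].rstrip(",").split(",")]
        exons = tuple((start + o, start + o + sz) for o, sz in zip(starts, sizes))
        cds_span = tuple(
            (max(s, thick_start), min(e, thick_end))
            for s, e in exons
            if max(s, thick_start) < min(e, thick_end)
        )
        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
        if chrom not in seqs:
            raise ValueError(f"chromosome {chrom} not in {fasta_path}")
        genome = seqs[chrom]
        plus = "".join(genome[s:e] for s, e in cds_span)
        cds = plus if strand == "+" else str(Seq(plus).reverse_complement())
        return cls(name, chrom, strand, exons, cds_span, cds)


# -- in-silico RFLP ----------------------------------------------------


def digest_amplicon(
    sequence: str, recognition_site: str = TAQ1_SITE, cut_offset: int = 1
) -> DigestResult:
    """Digest an amplicon at every occurrence of ``recognition_site``.

    The cut is placed ``cut_offset`` bases into each occurrence (default
    T^CGA for Taq1). Occurrences are scanned left to right; after an
    accepted occurrence scanning resumes past it, so overlapping
    occurrences resolve left-to-right. With no occurrence the amplicon
    is returned as a single fragment.
    """
    sequence = sequence.upper()
    site = recognition_site.upper()
    if not site:
        raise ValueError("recognition_site must be non-empty")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset must lie within the recognition site")
    cuts: list[int] = []
    i = sequence.find(site)
    while i != -1:
        cut = i + cut_offset
        if 0 < cut < len(sequence):
            cuts.append(cut)
        i = sequence.find(site, i + len(site))
    bounds = [0] + cuts + [len(sequence)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(len(sequence), tuple(cuts), fragments)


def edit_destroys_site(
    sequence: str,
    pos_in_sequence: int,
    alt: str,
    recognition_site: str = TAQ1_SITE,
) -> bool:
    """Whether substituting ``alt`` at 0-based ``pos_in_sequence`` removes
    at least one recognition-site occurrence overlapping that position.

    Only destruction is tested; a substitution that creates a new site
    elsewhere does not affect the result.
    """
    sequence = sequence.upper()
    site = recognition_site.upper()
    alt = alt.upper()
    if not 0 <= pos_in_sequence < len(sequence):
        raise CoordinateError(f"position {pos_in_sequence} outside sequence")
    edited = sequence[:pos_in_sequence] + alt + sequence[pos_in_sequence + 1 :]
    for start in range(max(0, pos_in_sequence - len(site) + 1), pos_in_sequence + 1):
        if sequence[start : start + len(site)] == site and edited[start : start + len(site)] != site:
            return True
    return False
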