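"""Synthetic SDHB-like fixtures.

Everything here is synthetic: a deterministic generator builds a
minus-strand, multi-exon coding gene that reproduces the structural
features of the human SDHB coding region relevant to C-to-U editing
analysis — an 843 bp CDS with exactly 213 cytosine-bearing positions,
codon 46 = CGA (arginine) whose c.136 cytosine sits inside the sole
Taq1 recognition site (TCGA) of the region, and c.136 falling in the
second exon — without bundling any RefSeq sequence. The accompanying
amplicon builders yield a 285 bp cDNA amplicon and a 233 bp genomic
amplicon whose Taq1 digests give 159+126 bp and 131+102 bp fragments.

Edit of c.136 C>T converts CGA (Arg) to TGA (stop): the R46X nonsense
class, and destroys the Taq1 site.
"""

from __future__ import annotations

import numpy as np

from .genemodel import COMPLEMENT, GeneModel, TAQ1_SITE

__all__ = [
    "EDIT_CDS_POS",
    "synthetic_sdhb_like_locus",
    "synthetic_sdhb_like_model",
    "synthetic_cdna_amplicon",
    "synthetic_gdna_amplicon",
    "write_reference_fasta",
]

#: c. position of the edited cytosine (codon 46, offset 1).
EDIT_CDS_POS = 136

_CDS_LENGTH = 843  # 280 codons + stop
_N_C_POSITIONS = 213
# transcript-order CDS lengths per exon; c.136 falls in exon 2 (c.73-218)
_EXON_CDS_LENGTHS = (72, 146, 100, 94, 125, 96, 120, 90)
_INTRON_LENGTH = 80
_FLANK = 150
_CHROM = "chr1_synthetic"

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def _revcomp(s: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(s))


def _build_cds(rng: np.random.Generator) -> str:
    """Assemble the synthetic CDS under its structural constraints."""
    codons = ["ATG"]  # start
    non_stop = [a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS]
    for i in range(2, 281):
        codons.append(non_stop[rng.integers(len(non_stop))])
    codons.append("TAA")  # stop; codon 281
    codons[44] = "ACT"  # codon 45 ends in T -> TCGA spans c.135-138
    codons[45] = "CGA"  # codon 46: Arg; C>T gives TGA (R46X)
    seq = list("".join(codons))
    assert len(seq) == _CDS_LENGTH

    fixed = set(range(0, 3)) | set(range(132, 138)) | set(range(840, 843))

    def codon_ok(s: list[str], i: int) -> bool:
        c0 = (i // 3) * 3
        return "".join(s[c0 : c0 + 3]) not in _STOPS

    def mutable(i: int) -> bool:
        return i not in fixed

    for _ in range(200):  # iterate scrubbing + composition adjustment to a fixed point
        changed = False
        # remove every TCGA occurrence except the target one at index 134
        text = "".join(seq)
        i = text.find(TAQ1_SITE)
        while i != -1:
            if i != 134:
                for j in range(i, i + 4):
                    if not mutable(j):
                        continue
                    old = seq[j]
                    for alt in rng.permutation(list(_BASES)):
                        if alt == old:
                            continue
                        seq[j] = alt
                        if codon_ok(seq, j):
                            changed = True
                            break
                        seq[j] = old
                    if changed:
                        break
                text = "".join(seq)
            i = text.find(TAQ1_SITE, i + 1)
        # steer cytosine count to the target
        n_c = seq.count("C")
        idx = rng.permutation(_CDS_LENGTH)
        for j in idx:
            if n_c == _N_C_POSITIONS:
                break
            if not mutable(j):
                continue
            old = seq[j]
            if n_c < _N_C_POSITIONS and old != "C":
                seq[j] = "C"
                if codon_ok(seq, j) and TAQ1_SITE not in "".join(seq[max(0, j - 3) : j + 4]):
                    n_c += 1
                    changed = True
                else:
                    seq[j] = old
            elif n_c > _N_C_POSITIONS and old == "C":
                for alt in rng.permutation(["A", "G", "T"]):
                    seq[j] = alt
                    if codon_ok(seq, j) and TAQ1_SITE not in "".join(seq[max(0, j - 3) : j + 4]):
                        n_c -= 1
                        changed = True
                        break
                    seq[j] = old
        text = "".join(seq)
        extra_sites = sum(1 for k in range(len(text) - 3) if text[k : k + 4] == TAQ1_SITE and k != 134)
        if text.count("C") == _N_C_POSITIONS and extra_sites == 0 and not changed:
            break
    text = "".join(seq)
    assert text.count("C") == _N_C_POSITIONS
    assert text[134:138] == TAQ1_SITE
    return text


def _scrub_site(seq: list[str], protected: set[int], rng: np.random.Generator) -> None:
    """Mutate non-protected bases until no TCGA occurrence outside the
    protected window remains."""
    for _ in range(200):
        text = "".join(seq)
        hit = None
        i = text.find(TAQ1_SITE)
        while i != -1:
            window = set(range(i, i + 4))
            if not window <= protected:
                hit = next(j for j in range(i, i + 4) if j not in protected)
                break
            i = text.find(TAQ1_SITE, i + 1)
        if hit is None:
            return
        old = seq[hit]
        seq[hit] = rng.choice([b for b in _BASES if b != old])
    raise RuntimeError("failed to scrub recognition sites")  # pragma: no cover


def synthetic_sdhb_like_locus(seed: int = 136) -> tuple[GeneModel, str]:
    """Deterministically generate the synthetic locus.

    Returns the minus-strand :class:`GeneModel` and the plus-strand
    sequence of its synthetic mini-contig (exons, 80 bp introns and
    150 bp flanks).
    """
    rng = np.random.default_rng(seed)
    cds = _build_cds(rng)

    genomic_lengths = tuple(reversed(_EXON_CDS_LENGTHS))
    exons = []
    pos = _FLANK
    for length in genomic_lengths:
        exons.append((pos, pos + length))
        pos += length + _INTRON_LENGTH
    contig_len = exons[-1][1] + _FLANK

    # plus-strand CDS bases laid ascending = revcomp of the transcript CDS
    plus_cds = _revcomp(cds)
    genome = list(rng.choice(list(_BASES), size=contig_len))
    offset = 0
    cds_plus_indices: set[int] = set()
    for s, e in exons:
        genome[s:e] = list(plus_cds[offset : offset + (e - s)])
        cds_plus_indices.update(range(s, e))
        offset += e - s

    # the target Taq1 site occupies 4 consecutive genomic bases within exon 2
    model = GeneModel("SDHB_synthetic", _CHROM, "-", tuple(exons), tuple(exons), cds)
    site_g = sorted(model.map_cds_to_genome(p)[0] for p in range(135, 139))
    protected = cds_plus_indices | set(site_g)
    _scrub_site(genome, protected, rng)
    return model, "".join(genome)


def synthetic_sdhb_like_model(seed: int = 136) -> GeneModel:
    """The synthetic SDHB-like gene model alone."""
    return synthetic_sdhb_like_locus(seed)[0]


def synthetic_cdna_amplicon(model: GeneModel, seed: int = 136) -> tuple[str, int]:
    """285 bp synthetic cDNA (RT-PCR) amplicon spanning the edit site.

    Returns ``(sequence, edit_offset)`` where ``edit_offset`` is the
    0-based position of the c.136 cytosine. The single Taq1 site is cut
    into 159 + 126 bp fragments; the C>T edit destroys it.
    """
    rng = np.random.default_rng(seed + 1)
    utr = list(rng.choice(list(_BASES), size=24))
    body = model.cds_sequence[:261]
    amplicon = utr + list(body)
    protected = set(range(24, 285))
    _scrub_site(amplicon, protected, rng)
    seq = "".join(amplicon)
    assert len(seq) == 285 and seq[158:162] == TAQ1_SITE
    return seq, 159


def synthetic_gdna_amplicon(model: GeneModel, genome: str) -> tuple[str, int]:
    """233 bp synthetic genomic-DNA amplicon around exon 2, in transcript
    orientation.

    Returns ``(sequence, edit_offset)``; the single Taq1 site is cut
    into 131 + 102 bp fragments.
    """
    exon2 = sorted(model.exons)[-2]  # second exon in transcript order (minus strand)
    s2, e2 = exon2
    seq = _revcomp(genome[s2 - 19 : e2 + 68])
    assert len(seq) == 233 and seq[130:134] == TAQ1_SITE
    return seq, 131


def write_reference_fasta(path, genome: str, chrom: str = _CHROM, width: int = 70) -> None:
    """Write the synthetic contig as an uncompressed FASTA file."""
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), width):
            fh.write(genome[i : i + width] + "\n")
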