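"""Shared fixtures: the synthetic SDHB-like locus and random multi-exon
gene models with brute-force coordinate oracles."""

from __future__ import annotations

import numpy as np
import pytest

from edscan.fixtures import synthetic_sdhb_like_locus
from edscan.genemodel import COMPLEMENT, GeneModel

BASES = "ACGT"


def revcomp(s: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(s))


def random_locus(
    rng: np.random.Generator,
    n_exons: int = 3,
    strand: str = "+",
    min_exon: int = 9,
    max_exon: int = 60,
    intron: int = 25,
    flank: int = 40,
) -> tuple[GeneModel, str]:
    """Random consistent (model, plus-strand genome) pair; CDS length is
    forced to a multiple of 3 by trimming the last exon."""
    lengths = [int(rng.integers(min_exon, max_exon + 1)) for _ in range(n_exons)]
    excess = sum(lengths) % 3
    lengths[-1] -= excess
    exons = []
    pos = flank
    for ln in lengths:
        exons.append((pos, pos + ln))
        pos += ln + intron
    genome = "".join(rng.choice(list(BASES), size=pos + flank))
    plus_cds = "".join(genome[s:e] for s, e in exons)
    cds = plus_cds if strand == "+" else revcomp(plus_cds)
    model = GeneModel("rand", "chrT", strand, tuple(exons), tuple(exons), cds)
    return model, genome


def brute_force_cds_map(exons, strand) -> list[int]:
    """Per-base enumeration oracle: genomic position of each c. position,
    independent of the model's own arithmetic."""
    genomic = [g for s, e in sorted(exons) for g in range(s, e)]
    if strand == "-":
        genomic = genomic[::-1]
    return genomic


@pytest.fixture(scope="session")
def sdhb_locus():
    return synthetic_sdhb_like_locus()


@pytest.fixture(scope="session")
def sdhb_model(sdhb_locus):
    return sdhb_locus[0]
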