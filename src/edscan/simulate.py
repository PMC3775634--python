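"""Forward simulators for every input the pipeline consumes.

All generators take explicit seeds (no hidden global state) and return
a *truth record* alongside their output, so estimator validation can
compare against the simulated ground truth rather than re-deriving it
from the outputs.

Three layers:

* read/pileup simulation over a :class:`~edscan.genemodel.GeneModel`
  with per-site true editing fractions and a uniform sequencing-error
  spectrum (each wrong base at rate epsilon/3);
* a qPCR plate simulator under a (1+E)-fold-per-cycle amplification
  model with Gaussian well noise and allele-specific cross-reactivity
  (false-positive amplification of wild-type template, sub-unity
  recovery of edited template);
* a paired-donor cohort generator with donor-level log-normal baseline
  variation, a hypoxia effect multiplier, condition-specific day
  profiles (normoxic peak on days 5-7, hypoxic peak on day 2) and a
  positive link between monocyte (CD14+) fraction and editing rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .asqpcr import ALLELE_T, TOTAL, CpWell
from .cohort import DonorMeasurement
from .genemodel import COMPLEMENT, GeneModel
from .pileup import BaseCallTally

__all__ = [
    "PileupSimConfig",
    "QpcrSimConfig",
    "CohortSimConfig",
    "simulate_alignments",
    "simulate_tally",
    "simulate_qpcr_plate",
    "simulate_dilution_series",
    "simulate_cohort",
]


@dataclass(frozen=True)
class PileupSimConfig:
    """Configuration for read/pileup simulation over a gene model."""

    model: GeneModel
    reference: str  # plus-strand sequence of the model's contig
    seed: int
    depth: int = 1000
    error_rate: float = 0.001  # per-base; uniform over the 3 wrong bases
    edits: Mapping[int, float] = field(default_factory=dict)  # c.pos -> fraction
    read_length: int = 50
    poisson_depth: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        for pos, f in self.edits.items():
            if not 0 <= f <= 1:
                raise ValueError(f"edit fraction at c.{pos} must be in [0, 1]")
            self.model.transcript_base(pos)  # validates the position


@dataclass(frozen=True)
class QpcrSimConfig:
    """Forward model of the allele-specific qPCR assay."""

    seed: int
    efficiency: float = 1.0  # E; per-cycle fold increase is 1 + E
    threshold_constant: float = 1e6  # template amount at which Cp = 0
    noise_sd: float = 0.1  # cycles
    replicates: int = 3
    allele_fp: float = 0.0138  # apparent amplification of wild-type template
    allele_recovery: float = 0.91  # apparent recovery of pure edited template

    def __post_init__(self) -> None:
        if self.efficiency <= 0:
            raise ValueError("efficiency must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.allele_fp < self.allele_recovery <= 1.2:
            raise ValueError("requires 0 <= allele_fp < allele_recovery <= 1.2")


@dataclass(frozen=True)
class CohortSimConfig:
    """Paired-donor cohort generator settings.

    Defaults emulate the observed study structure: median uncultured
    editing around 2%, normoxic induction peaking days 5-7 at roughly
    five-fold, a hypoxia multiplier with median 5 peaking on day 2, and
    a CD14+ fraction around 27% weakly positively linked to editing.
    """

    seed: int
    n_donors: int = 14
    baseline_median: float = 0.02
    baseline_sigma: float = 0.6  # log-scale SD of donor baselines
    hypoxia_multiplier_median: float = 5.0
    hypoxia_multiplier_sigma: float = 0.4
    normoxia_day_profile: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 1.2, 3: 1.8, 5: 4.5, 6: 5.0, 7: 5.0}
    )
    hypoxia_day_profile: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 1.0, 3: 0.8}
    )
    cd14_beta: tuple[float, float] = (2.2, 5.8)  # mean ~ 0.275
    cd14_link: float = 2.0  # relative editing change per unit CD14 fraction
    noise_sigma: float = 0.25  # log-scale multiplicative measurement noise


# -- pileup / reads ----------------------------------------------------


def _plus_strand_edit_base(model: GeneModel, edited_base: str) -> str:
    return edited_base if model.strand == "+" else COMPLEMENT[edited_base]


def simulate_alignments(
    cfg: PileupSimConfig,
    sam_path: str | Path,
    edited_base: str = "T",
) -> dict:
    """Simulate single-end, fully-matching reads over the locus and
    write them as SAM, plus-strand genomic orientation regardless of
    gene strand.

    Each read descends from a molecule that is edited at a covered edit
    site with that site's true fraction; sequencing errors are applied
    i.i.d. per base. The returned truth record stores, per edit site,
    the number of covering molecules and how many of them were edited.
    """
    rng = np.random.default_rng(cfg.seed)
    model, genome, L = cfg.model, cfg.reference.upper(), cfg.read_length
    if len(genome) < L:
        raise ValueError("reference shorter than read length")
    gene_start = min(s for s, _ in model.exons)
    gene_end = max(e for _, e in model.exons)
    lo = max(0, gene_start - L + 1)
    hi = min(len(genome) - L, gene_end - 1)
    region_len = hi + 1 - lo + L - 1
    n_reads = int(math.ceil(cfg.depth * region_len / L))
    # genomic position and plus-strand edited base per edit site
    site_g = {
        pos: (model.map_cds_to_genome(pos)[0], _plus_strand_edit_base(model, edited_base))
        for pos in cfg.edits
    }
    truth = {pos: {"covered": 0, "edited": 0} for pos in cfg.edits}
    bases = np.array(list("ACGT"))
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": model.chrom, "LN": len(genome)}],
    }
    starts = rng.integers(lo, hi + 1, size=n_reads)
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for i, s in enumerate(starts):
            s = int(s)
            seq = list(genome[s : s + L])
            for pos, (g, plus_alt) in site_g.items():
                if s <= g < s + L:
                    truth[pos]["covered"] += 1
                    if rng.random() < cfg.edits[pos]:
                        truth[pos]["edited"] += 1
                        seq[g - s] = plus_alt
            if cfg.error_rate > 0:
                err = rng.random(L) < cfg.error_rate
                for j in np.flatnonzero(err):
                    others = [b for b in "ACGT" if b != seq[j]]
                    seq[j] = others[rng.integers(3)]
            a = pysam.AlignedSegment()
            a.query_name = f"sim{i:07d}"
            a.query_sequence = "".join(seq)
            a.flag = 0
            a.reference_id = 0
            a.reference_start = s
            a.mapping_quality = 60
            a.cigartuples = [(0, L)]
            a.query_qualities = pysam.qualitystring_to_array("I" * L)
            out.write(a)
    return {
        "n_reads": n_reads,
        "read_length": L,
        "seed": cfg.seed,
        "sites": truth,
        "edited_base": edited_base,
    }


def simulate_tally(cfg: PileupSimConfig, edited_base: str = "T") -> tuple[BaseCallTally, dict]:
    """Multinomial per-position tally, marginally matching the pileup of
    :func:`simulate_alignments` without emitting reads.

    At an edit site with fraction f and error rate eps, the edited base
    is observed with probability f(1-eps) + (1-f)eps/3, the reference
    with (1-f)(1-eps) + f eps/3, and each other base with eps/3.
    """
    rng = np.random.default_rng(cfg.seed)
    model, eps = cfg.model, cfg.error_rate
    L = model.cds_length
    counts = np.zeros((L, 5), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    depths = (
        rng.poisson(cfg.depth, size=L) if cfg.poisson_depth else np.full(L, cfg.depth, dtype=np.int64)
    )
    for pos in range(1, L + 1):
        ref = model.cds_sequence[pos - 1]
        p = np.zeros(5)
        f = cfg.edits.get(pos, 0.0)
        for b in "ACGT":
            if b == ref:
                p[base_idx[b]] = (1 - f) * (1 - eps) + (f * eps / 3 if b != edited_base else 0.0)
            elif f > 0 and b == edited_base:
                p[base_idx[b]] = f * (1 - eps) + (1 - f) * eps / 3
            else:
                p[base_idx[b]] = eps / 3
        if f > 0 and ref == edited_base:  # degenerate: edit equals reference
            p = np.zeros(5)
            p[base_idx[ref]] = 1 - eps
            p[[i for i in range(4) if i != base_idx[ref]]] = eps / 3
        counts[pos - 1] = rng.multinomial(depths[pos - 1], p)
    truth = {
        "seed": cfg.seed,
        "depths": depths.tolist(),
        "edits": dict(cfg.edits),
        "error_rate": eps,
        "edited_base": edited_base,
    }
    return BaseCallTally(counts), truth


# -- qPCR --------------------------------------------------------------


def _cp(amount: float, cfg: QpcrSimConfig) -> float:
    return math.log(cfg.threshold_constant / amount, 1.0 + cfg.efficiency)


def simulate_qpcr_plate(
    samples: Sequence[tuple[str, float, float]],
    cfg: QpcrSimConfig,
) -> tuple[list[CpWell], dict]:
    """Simulate TOTAL and ALLELE_T replicate wells for each
    (sample_id, total_amount, true_edited_fraction) sample.

    The allele assay sees f*recovery + (1-f)*fp of the total template;
    Cp is log base (1+E) of (threshold_constant / template) plus
    Gaussian well noise. Zero effective template yields no well; such
    wells are listed in the truth record under ``no_amplification``.
    """
    rng = np.random.default_rng(cfg.seed)
    wells: list[CpWell] = []
    no_amp: list[tuple[str, str]] = []
    truth_samples = {}
    for sample_id, amount, f in samples:
        if amount <= 0:
            raise ValueError("template amounts must be > 0")
        if not 0 <= f <= 1:
            raise ValueError("true edited fraction must be in [0, 1]")
        eff = {
            TOTAL: amount,
            ALLELE_T: amount * (f * cfg.allele_recovery + (1 - f) * cfg.allele_fp),
        }
        truth_samples[sample_id] = {"amount": amount, "fraction": f, "effective": dict(eff)}
        for assay, template in eff.items():
            if template <= 0:
                no_amp.append((sample_id, assay))
                continue
            base_cp = _cp(template, cfg)
            for rep in range(1, cfg.replicates + 1):
                cp = base_cp + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0)
                wells.append(CpWell(sample_id, assay, rep, cp))
    truth = {"seed": cfg.seed, "samples": truth_samples, "no_amplification": no_amp}
    return wells, truth


def simulate_dilution_series(
    cfg: QpcrSimConfig,
    n_steps: int = 8,
    dilution_factor: float = 8.0,
    top_amount: float = 1.0,
    assay: str = TOTAL,
    sample_id: str = "standard",
) -> tuple[list[CpWell], dict]:
    """Serial-dilution standard curve wells for efficiency calibration."""
    rng = np.random.default_rng(cfg.seed)
    wells = []
    amounts = []
    for step in range(n_steps):
        amount = top_amount / dilution_factor**step
        amounts.append(amount)
        base_cp = _cp(amount, cfg)
        for rep in range(1, cfg.replicates + 1):
            cp = base_cp + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0)
            wells.append(CpWell(sample_id, assay, rep, cp, template_amount=amount, dilution_step=step))
    truth = {
        "seed": cfg.seed,
        "efficiency": cfg.efficiency,
        "dilution_factor": dilution_factor,
        "amounts": amounts,
        "cycles_per_step": math.log(dilution_factor, 1.0 + cfg.efficiency),
    }
    return wells, truth


# -- cohort ------------------------------------------------------------


def simulate_cohort(cfg: CohortSimConfig) -> tuple[list[DonorMeasurement], dict]:
    """Generate a paired-donor cohort table.

    Per donor: an uncultured day-0 baseline, normoxic measurements over
    the normoxia day profile and hypoxic measurements (sharing the same
    donor baseline) over the hypoxia day profile scaled by the donor's
    hypoxia multiplier, all with multiplicative log-normal measurement
    noise, clipped to [0, 0.99].
    """
    rng = np.random.default_rng(cfg.seed)
    rows: list[DonorMeasurement] = []
    truth_donors = {}
    mean_cd14 = cfg.cd14_beta[0] / sum(cfg.cd14_beta)

    def noisy(value: float) -> float:
        if cfg.noise_sigma > 0:
            value *= math.exp(rng.normal(0.0, cfg.noise_sigma))
        return float(np.clip(value, 0.0, 0.99))

    for i in range(cfg.n_donors):
        donor = f"D{i + 1:03d}"
        baseline = cfg.baseline_median * math.exp(rng.normal(0.0, cfg.baseline_sigma))
        hmult = cfg.hypoxia_multiplier_median * math.exp(
            rng.normal(0.0, cfg.hypoxia_multiplier_sigma)
        )
        cd14 = float(rng.beta(*cfg.cd14_beta))
        link = max(0.0, 1.0 + cfg.cd14_link * (cd14 - mean_cd14))
        truth_donors[donor] = {
            "baseline": baseline,
            "hypoxia_multiplier": hmult,
            "cd14_fraction": cd14,
            "cd14_link_factor": link,
        }
        rows.append(
            DonorMeasurement(donor, "uncultured", 0, "total", noisy(baseline * link), cd14)
        )
        for day, mult in sorted(cfg.normoxia_day_profile.items()):
            rows.append(
                DonorMeasurement(
                    donor, "normoxia", day, "total", noisy(baseline * link * mult), cd14
                )
            )
        for day, mult in sorted(cfg.hypoxia_day_profile.items()):
            rows.append(
                DonorMeasurement(
                    donor,
                    "hypoxia",
                    day,
                    "supernatant",
                    noisy(baseline * link * hmult * mult),
                    cd14,
                )
            )
    truth = {"seed": cfg.seed, "donors": truth_donors}
    return rows, truth
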