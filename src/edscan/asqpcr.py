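"""Allele-specific qPCR quantification of edited transcripts.

The edited-transcript fraction is estimated from the crossing-point
difference between a total-transcript assay and an allele-specific
(edited-allele) assay:

    fraction = (1 + E) ** (Cp_total - Cp_allele)

With the default efficiency E = 1 (perfect per-cycle doubling) this is
2**dCp. Amplification efficiency can instead be measured from a serial
dilution standard curve, and assay specificity (false-positive
amplification on wild-type template; recovery on pure edited template)
can be characterised from control runs and optionally unmixed out of
observed estimates. Relative expression between conditions uses the
standard 2**-ddCt method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CpWell",
    "EditingEstimate",
    "StandardCurve",
    "SpecificityProfile",
    "aggregate_replicates",
    "estimate_editing_fraction",
    "estimate_from_wells",
    "efficiency_from_dilution_series",
    "specificity_from_controls",
    "correct_estimate",
    "ddct_relative_expression",
    "read_plate_tsv",
]

TOTAL = "TOTAL"
ALLELE_T = "ALLELE_T"


@dataclass(frozen=True)
class CpWell:
    """One qPCR well: a crossing-point measurement."""

    sample_id: str
    assay: str  # TOTAL or ALLELE_T
    replicate: int
    cp: float
    template_amount: float | None = None
    dilution_step: int | None = None

    def __post_init__(self) -> None:
        if self.cp <= 0:
            raise ValueError("Cp must be positive")
        if self.assay not in (TOTAL, ALLELE_T):
            raise ValueError(f"assay must be {TOTAL} or {ALLELE_T}, got {self.assay!r}")


@dataclass(frozen=True)
class EditingEstimate:
    """Edited-transcript fraction for one sample from mean Cp values."""

    sample_id: str
    mean_cp_total: float
    mean_cp_allele: float
    delta_cp: float  # mean_cp_total - mean_cp_allele
    fraction: float
    n_wells: int
    clipped: bool = False


@dataclass(frozen=True)
class StandardCurve:
    """Serial-dilution calibration of amplification efficiency."""

    dilution_factor: float
    cp_by_step: tuple[float, ...]
    slope_per_step: float  # cycles per dilution step
    efficiency: float  # E = d**(1/slope) - 1
    r2: float
    amount_range: tuple[float, float] | None = None


@dataclass(frozen=True)
class SpecificityProfile:
    """Apparent fractions on pure control templates."""

    false_positive_fraction: float  # on 100% wild-type template
    recovery: float  # on 100% edited template

    def __post_init__(self) -> None:
        if not 0 <= self.false_positive_fraction < self.recovery <= 1.2:
            raise ValueError(
                "requires 0 <= false_positive_fraction < recovery <= 1.2 "
                f"(got {self.false_positive_fraction}, {self.recovery})"
            )


def aggregate_replicates(
    wells: Iterable[CpWell], sd_warn_threshold: float = 0.5
) -> pd.DataFrame:
    """Mean and SD of Cp per (sample, assay) across replicate wells.

    Replicates are averaged on the Cp (cycle) scale. The ``outlier``
    column flags replicate sets whose SD exceeds the threshold
    (default 0.5 cycles); SD is NaN for single wells.
    """
    rows = [(w.sample_id, w.assay, w.cp) for w in wells]
    if not rows:
        raise ValueError("no wells supplied")
    df = pd.DataFrame(rows, columns=["sample_id", "assay", "cp"])
    agg = (
        df.groupby(["sample_id", "assay"])["cp"]
        .agg(mean_cp="mean", sd_cp="std", n_wells="count")
        .reset_index()
    )
    agg["outlier"] = agg["sd_cp"] > sd_warn_threshold
    return agg


def estimate_editing_fraction(
    cp_total: float,
    cp_allele: float,
    efficiency: float = 1.0,
    sample_id: str = "",
    n_wells: int = 0,
) -> EditingEstimate:
    """Edited fraction from mean total and allele-specific Cp values.

    fraction = (1 + efficiency) ** (cp_total - cp_allele); the default
    efficiency of 1.0 assumes perfect per-cycle doubling. Fractions
    above 1 (inverted delta-Cp, an assay anomaly) are clipped to 1 with
    a warning.
    """
    if efficiency <= 0:
        raise ValueError("efficiency must be positive")
    delta = cp_total - cp_allele
    fraction = (1.0 + efficiency) ** delta
    clipped = False
    if fraction > 1.0:
        warnings.warn(
            f"estimated fraction {fraction:.4g} > 1 (delta_cp = {delta:.3g} > 0); clipping",
            stacklevel=2,
        )
        fraction, clipped = 1.0, True
    return EditingEstimate(sample_id, cp_total, cp_allele, delta, fraction, n_wells, clipped)


def estimate_from_wells(
    wells: Iterable[CpWell], efficiency: float = 1.0
) -> list[EditingEstimate]:
    """Per-sample estimates from a plate of replicate wells.

    Each sample needs both a TOTAL and an ALLELE_T assay; samples
    missing one are reported as a pairing error.
    """
    agg = aggregate_replicates(wells)
    out: list[EditingEstimate] = []
    for sample_id, grp in agg.groupby("sample_id"):
        by_assay = grp.set_index("assay")
        if TOTAL not in by_assay.index or ALLELE_T not in by_assay.index:
            raise ValueError(f"sample {sample_id!r} lacks a {TOTAL}/{ALLELE_T} assay pair")
        out.append(
            estimate_editing_fraction(
                float(by_assay.loc[TOTAL, "mean_cp"]),
                float(by_assay.loc[ALLELE_T, "mean_cp"]),
                efficiency=efficiency,
                sample_id=str(sample_id),
                n_wells=int(by_assay["n_wells"].sum()),
            )
        )
    return out


def efficiency_from_dilution_series(
    wells: Sequence[CpWell], dilution_factor: float = 8.0
) -> StandardCurve:
    """Fit amplification efficiency from a serial dilution series.

    Mean Cp per dilution step is regressed on the step index; the
    per-step Cp increment gives E = d**(1/slope) - 1 for a d-fold
    series (3.0 cycles/step at 8-fold means perfect doubling).
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    steps = sorted({w.dilution_step for w in wells if w.dilution_step is not None})
    if len(steps) < 3:
        raise ValueError("need at least 3 dilution steps")
    mean_cp = []
    for s in steps:
        cps = [w.cp for w in wells if w.dilution_step == s]
        mean_cp.append(float(np.mean(cps)))
    diffs = np.diff(mean_cp)
    if (diffs <= 0).any():
        warnings.warn("Cp not monotone increasing with dilution step", stacklevel=2)
    fit = stats.linregress(steps, mean_cp)
    if fit.slope <= 0:
        raise ValueError(f"invalid standard curve: slope {fit.slope:.3g} <= 0")
    efficiency = dilution_factor ** (1.0 / fit.slope) - 1.0
    amounts = [w.template_amount for w in wells if w.template_amount is not None]
    amount_range = (min(amounts), max(amounts)) if amounts else None
    return StandardCurve(
        dilution_factor=dilution_factor,
        cp_by_step=tuple(mean_cp),
        slope_per_step=float(fit.slope),
        efficiency=float(efficiency),
        r2=float(fit.rvalue**2),
        amount_range=amount_range,
    )


def specificity_from_controls(
    wildtype_runs: Sequence[float], edited_runs: Sequence[float]
) -> SpecificityProfile:
    """Assay specificity from apparent fractions on pure templates:
    mean apparent fraction on 100% wild-type (false positive) and on
    100% edited template (recovery)."""
    if not wildtype_runs or not edited_runs:
        raise ValueError("need at least one run per control template")
    return SpecificityProfile(
        false_positive_fraction=float(np.mean(wildtype_runs)),
        recovery=float(np.mean(edited_runs)),
    )


def correct_estimate(observed: float, profile: SpecificityProfile) -> float:
    """Linear unmixing of an observed apparent fraction given assay
    specificity: (observed - fp) / (recovery - fp), clipped to [0, 1].

    Off by default in reporting; the uncorrected estimate is the
    stringent choice (a lower bound on the true editing rate).
    """
    span = profile.recovery - profile.false_positive_fraction
    if span <= 0:
        raise ValueError("invalid profile: recovery <= false_positive_fraction")
    return float(np.clip((observed - profile.false_positive_fraction) / span, 0.0, 1.0))


def ddct_relative_expression(
    cp_target_case: float,
    cp_ref_case: float,
    cp_target_ctrl: float,
    cp_ref_ctrl: float,
) -> float:
    """Fold change by the 2**-ddCt method against a housekeeping gene."""
    ddct = (cp_target_case - cp_ref_case) - (cp_target_ctrl - cp_ref_ctrl)
    return float(2.0 ** (-ddct))


def read_plate_tsv(path: str | Path) -> list[CpWell]:
    """Read a plate table (sample_id, assay, replicate, cp, optional
    template_amount and dilution_step columns)."""
    df = pd.read_csv(path, sep="\t")
    wells = []
    for row in df.itertuples(index=False):
        wells.append(
            CpWell(
                sample_id=str(row.sample_id),
                assay=str(row.assay),
                replicate=int(row.replicate),
                cp=float(row.cp),
                template_amount=(
                    float(row.template_amount)
                    if "template_amount" in df.columns and not pd.isna(row.template_amount)
                    else None
                ),
                dilution_step=(
                    int(row.dilution_step)
                    if "dilution_step" in df.columns and not pd.isna(row.dilution_step)
                    else None
                ),
            )
        )
    return wells
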