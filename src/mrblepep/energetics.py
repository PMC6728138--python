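"""Binding free-energy differences, cross-assay calibration, and epistasis.

Relative affinities are expressed as binding free-energy differences against a
reference peptide,

    ddG = R T ln(Kd_i / Kd_ref)      [kcal/mol]

with R = 1.987e-3 kcal/(mol K).  Because the assay's apparent Kds share a
common multiplicative shift within one experiment, ddG values are comparable
across assays, and absolute affinities are recovered by anchoring each assay to
a reference peptide of known Kd (default: 980 nM for the high-affinity PVIVIT
reference).  Non-additivity between two substitutions is quantified by
double-mutant-cycle (DMC) interaction energies, and replicate agreement by the
squared Pearson correlation of matched ddG vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binding_fit import FitResult, NONSPECIFIC, NON_SATURATING

R_KCAL = 1.987e-3  # gas constant, kcal mol^-1 K^-1
DEFAULT_TEMPERATURE_K = 298.15
#: Literature dissociation constant of the PVIVIT reference peptide, nM.
DEFAULT_KD_REF_NM = 980.0


class CalibrationError(ValueError):
    """Reference peptide missing or QC-flagged; calibration refused."""


class IncompleteCycleError(ValueError):
    """A double-mutant cycle is missing one of its four corners."""


class InsufficientDataError(ValueError):
    """Too few shared variants for a concordance estimate."""


def delta_delta_g(
    kd_i: float, kd_ref: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """ddG = RT ln(kd_i / kd_ref), kcal/mol; antisymmetric in its arguments."""
    if kd_i <= 0 or kd_ref <= 0:
        raise ValueError("dissociation constants must be > 0")
    return R_KCAL * temperature * math.log(kd_i / kd_ref)


def fold_change(kd_a: float, kd_b: float) -> float:
    """kd_a / kd_b; values > 1 mean b binds more tightly than a."""
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("dissociation constants must be > 0")
    return kd_a / kd_b


@dataclass
class EnergeticsRow:
    """ddG vs. reference plus the calibrated absolute Kd for one variant."""

    variant_id: str
    ddg: float
    kd_calibrated_nM: float
    fold_change_vs_ref: float
    reference_id: str
    ddg_lo: float = np.nan
    ddg_hi: float = np.nan
    flags: set[str] = field(default_factory=set)


def calibrate_absolute(
    results: Sequence[FitResult],
    reference_id: str,
    kd_ref_literature: float = DEFAULT_KD_REF_NM,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> list[EnergeticsRow]:
    """Anchor an assay's fitted Kds to a reference of known affinity.

    ``kd_calibrated_i = kd_ref_literature * (kd_fit_i / kd_fit_ref)`` — a pure
    rescaling, so ddG values and rank order are identical before and after
    calibration.  Refused when the reference is absent or carries a
    NONSPECIFIC/NON_SATURATING flag.  Bootstrap Kd intervals, when present,
    propagate through the (monotone) log transform to ddG intervals.
    """
    ref = [r for r in results if r.variant_id == reference_id]
    if not ref:
        raise CalibrationError(f"reference {reference_id!r} not in fit results")
    ref_fit = ref[0]
    bad = ref_fit.flags & {NONSPECIFIC, NON_SATURATING}
    if bad:
        raise CalibrationError(f"reference {reference_id!r} flagged {sorted(bad)}")
    rows = []
    for r in results:
        ddg = delta_delta_g(r.kd_nM, ref_fit.kd_nM, temperature)
        rows.append(
            EnergeticsRow(
                variant_id=r.variant_id,
                ddg=ddg,
                kd_calibrated_nM=kd_ref_literature * (r.kd_nM / ref_fit.kd_nM),
                fold_change_vs_ref=fold_change(r.kd_nM, ref_fit.kd_nM),
                reference_id=reference_id,
                ddg_lo=(
                    delta_delta_g(r.kd_lo, ref_fit.kd_nM, temperature)
                    if np.isfinite(r.kd_lo)
                    else np.nan
                ),
                ddg_hi=(
                    delta_delta_g(r.kd_hi, ref_fit.kd_nM, temperature)
                    if np.isfinite(r.kd_hi)
                    else np.nan
                ),
                flags=set(r.flags),
            )
        )
    return rows


@dataclass
class DMCResult:
    """Double-mutant-cycle interaction energy (kcal/mol).

    ``interaction_energy = ddg_ab - ddg_a - ddg_b`` is zero exactly when the
    two substitutions act additively; positive values mean the double mutant is
    less stable (binds more weakly) than additivity predicts.
    """

    cycle: tuple[str, str, str, str]  # (wt, a, b, ab)
    ddg_a: float
    ddg_b: float
    ddg_ab: float
    interaction_energy: float


def dmc_interaction(
    ddg_a: float,
    ddg_b: float,
    ddg_ab: float,
    cycle: tuple[str, str, str, str] = ("WT", "A", "B", "AB"),
) -> DMCResult:
    """Interaction energy from single and double ddGs on a common reference.

    Invariant to the choice of reference corner: any constant shift of all
    three ddGs relative to the wild type cancels in the difference.
    """
    return DMCResult(
        cycle=cycle,
        ddg_a=ddg_a,
        ddg_b=ddg_b,
        ddg_ab=ddg_ab,
        interaction_energy=ddg_ab - ddg_a - ddg_b,
    )


def dmc_from_energetics(
    rows: Sequence[EnergeticsRow],
    wt_id: str,
    a_id: str,
    b_id: str,
    ab_id: str,
) -> DMCResult:
    """Assemble a cycle from an energetics table (corners re-referenced to WT)."""
    table = {r.variant_id: r for r in rows}
    missing = [v for v in (wt_id, a_id, b_id, ab_id) if v not in table]
    if missing:
        raise IncompleteCycleError(f"cycle corners missing from energetics: {missing}")
    for v in (wt_id, a_id, b_id, ab_id):
        bad = table[v].flags & {NONSPECIFIC, NON_SATURATING}
        if bad:
            raise IncompleteCycleError(f"cycle corner {v!r} flagged {sorted(bad)}")
    ddg_wt = table[wt_id].ddg
    return dmc_interaction(
        table[a_id].ddg - ddg_wt,
        table[b_id].ddg - ddg_wt,
        table[ab_id].ddg - ddg_wt,
        cycle=(wt_id, a_id, b_id, ab_id),
    )


@dataclass
class ConcordanceResult:
    r_squared: float
    slope: float
    intercept: float
    n: int


def replicate_concordance(
    ddg_rep1: Sequence[float], ddg_rep2: Sequence[float]
) -> ConcordanceResult:
    """Squared Pearson correlation (plus regression line) between matched
    replicate ddG vectors; the slope carries the sign."""
    x = np.asarray(ddg_rep1, dtype=float)
    y = np.asarray(ddg_rep2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("replicate vectors must be matched")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 shared variants")
    fit = stats.linregress(x, y)
    return ConcordanceResult(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(x),
    )


def energetics_to_frame(rows: Sequence[EnergeticsRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "ddg": r.ddg,
                "ddg_lo": r.ddg_lo,
                "ddg_hi": r.ddg_hi,
                "kd_calibrated_nM": r.kd_calibrated_nM,
                "fold_change_vs_ref": r.fold_change_vs_ref,
                "reference_id": r.reference_id,
                "flags": ";".join(sorted(r.flags)),
            }
            for r in rows
        ]
    )


def energetics_to_csv(rows: Sequence[EnergeticsRow], path: str | Path) -> None:
    energetics_to_frame(rows).to_csv(path, index=False)


def energetics_from_csv(path: str | Path) -> list[EnergeticsRow]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        EnergeticsRow(
            variant_id=row["variant_id"],
            ddg=float(row["ddg"]),
            kd_calibrated_nM=float(row["kd_calibrated_nM"]),
            fold_change_vs_ref=float(row["fold_change_vs_ref"]),
            reference_id=row["reference_id"],
            ddg_lo=float(row["ddg_lo"]) if row["ddg_lo"] != "" else np.nan,
            ddg_hi=float(row["ddg_hi"]) if row["ddg_hi"] != "" else np.nan,
            flags=set(f for f in str(row["flags"]).split(";") if f),
        )
        for _, row in df.iterrows()
    ]
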