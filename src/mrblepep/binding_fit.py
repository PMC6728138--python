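"""Two-step global Langmuir regression for multiplexed bead binding series.

The binding model is the single-site isotherm

    I_i(c) = Imax * c / (Kd_i + c)

with one saturation intensity ``Imax`` shared by every peptide in an assay
(constant binding stoichiometry) and a per-peptide dissociation constant
``Kd_i``.  Free protein concentration is approximated by total concentration
(bead-bound peptide is scarce relative to Kd).

Step 1 estimates the global ``Imax`` by jointly fitting the top 80% highest-
intensity series (the series near saturation are the ones that constrain the
plateau).  Step 2 refits every series with ``Imax`` fixed, one ``Kd`` each.
Uncertainties come from a bead-level bootstrap: beads are resampled with
replacement within each concentration, medians recomputed, and the Kd refit.

QC flags: NONSPECIFIC (control assays — binding-deficient protein mutant or
antibody alone — light up above a fraction of Imax), NON_SATURATING (fitted
fraction bound at the top concentration is below a floor, so the Kd is only a
qualitative lower-bound estimate), and LOW_SIGNAL (no signal above background;
the reported Kd is a lower bound at the maximum assayed concentration).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .decoding import UNASSIGNED
from .synthetic_data import CodeMap

logger = logging.getLogger(__name__)

KD_BOUNDS_NM = (1e-2, 1e6)

NONSPECIFIC = "NONSPECIFIC"
NON_SATURATING = "NON_SATURATING"
LOW_SIGNAL = "LOW_SIGNAL"
UNTESTED = "UNTESTED"


class FitError(RuntimeError):
    """Optimizer failed to converge; diagnostics in the message."""


@dataclass
class BindingSeries:
    """Median binding intensity vs. concentration for one code or peptide."""

    variant_id: str
    conc_nM: np.ndarray
    median_intensity: np.ndarray
    n_beads: np.ndarray
    code_id: str | None = None  # None for a merged per-peptide series
    assay_id: str = ""
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.conc_nM = np.asarray(self.conc_nM, dtype=float)
        self.median_intensity = np.asarray(self.median_intensity, dtype=float)
        self.n_beads = np.asarray(self.n_beads, dtype=int)
        if len(set(self.conc_nM.tolist())) != len(self.conc_nM):
            raise ValueError("concentrations within a series must be distinct")
        if np.any(self.n_beads < 1):
            raise ValueError("each point needs at least one bead")


@dataclass
class FitResult:
    """Per-peptide Kd estimate under the shared-Imax model, with QC flags.

    A result flagged NON_SATURATING or LOW_SIGNAL carries lower-bound
    semantics: the true Kd is at least of the reported order, not a point
    estimate.
    """

    variant_id: str
    kd_nM: float
    imax_global: float
    kd_lo: float = np.nan
    kd_hi: float = np.nan
    flags: set[str] = field(default_factory=set)
    residual_norm: float = np.nan
    code_id: str | None = None
    assay_id: str = ""


def _langmuir(conc: np.ndarray, kd: float, imax: float) -> np.ndarray:
    return imax * conc / (kd + conc)


def aggregate_series(
    beads: pd.DataFrame,
    assignments: pd.DataFrame,
    code_map: CodeMap,
    by: str = "peptide",
    min_beads: int = 5,
) -> list[BindingSeries]:
    """Collapse assigned beads to median-intensity series.

    ``by='code'`` keeps each spectral code separate; ``by='peptide'`` pools
    beads across codes carrying the same peptide (sequences are synthesized on
    several codes, e.g. triplicate code sets).  Points with fewer than
    ``min_beads`` beads mark the series LOW_SIGNAL but are retained.
    """
    if by not in ("code", "peptide"):
        raise ValueError("by must be 'code' or 'peptide'")
    merged = beads.merge(assignments[["bead_id", "code_id"]], on="bead_id", how="inner")
    merged = merged[merged["code_id"] != UNASSIGNED]
    pep_of = dict(zip(code_map.code_ids, code_map.peptides))
    merged["variant_id"] = merged["code_id"].map(pep_of)

    key = "code_id" if by == "code" else "variant_id"
    out: list[BindingSeries] = []
    for name, grp in merged.groupby(key, sort=True):
        agg = (
            grp.groupby("conc_nM")["intensity"]
            .agg(median_intensity="median", n_beads="size")
            .reset_index()
            .sort_values("conc_nM")
        )
        flags = {LOW_SIGNAL} if (agg["n_beads"] < min_beads).any() else set()
        out.append(
            BindingSeries(
                variant_id=grp["variant_id"].iloc[0],
                conc_nM=agg["conc_nM"].to_numpy(),
                median_intensity=agg["median_intensity"].to_numpy(),
                n_beads=agg["n_beads"].to_numpy(),
                code_id=str(name) if by == "code" else None,
                assay_id=str(grp["assay_id"].iloc[0]),
                flags=flags,
            )
        )
    return out


def fit_global_imax(
    series: Sequence[BindingSeries],
    top_fraction: float = 0.8,
    background: float = 0.0,
) -> float:
    """Global saturation intensity from the brightest series.

    Series are ranked by their maximum median intensity; the top
    ``top_fraction`` are jointly fit with one shared Imax and one Kd each.
    """
    if len(series) < 2:
        raise ValueError("need at least two series to fit a global Imax")
    ranked = sorted(series, key=lambda s: s.median_intensity.max(), reverse=True)
    k = max(2, ceil(top_fraction * len(ranked)))
    selected = ranked[:k]
    for s in selected:
        if len(s.conc_nM) < 3:
            raise ValueError(f"series {s.variant_id} has < 3 concentrations")

    y = [s.median_intensity - background for s in selected]
    peak = max(arr.max() for arr in y)
    lo, hi = np.log10(KD_BOUNDS_NM)

    def guess_kd(s: BindingSeries, yi: np.ndarray) -> float:
        half = 0.5 * peak
        above = s.conc_nM[yi >= half]
        return float(above.min()) if len(above) else float(s.conc_nM.max())

    x0 = np.concatenate(
        [[np.log10(peak * 1.05)], [np.clip(np.log10(guess_kd(s, yi)), lo, hi) for s, yi in zip(selected, y)]]
    )
    bounds = (
        np.concatenate([[np.log10(peak * 0.2)], np.full(k, lo)]),
        np.concatenate([[np.log10(peak * 1e3)], np.full(k, hi)]),
    )

    def residuals(theta: np.ndarray) -> np.ndarray:
        imax = 10 ** theta[0]
        kds = 10 ** theta[1:]
        return np.concatenate(
            [_langmuir(s.conc_nM, kd, imax) - yi for s, kd, yi in zip(selected, kds, y)]
        )

    sol = least_squares(
        residuals, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000
    )
    if not sol.success:
        raise FitError(f"global Imax fit did not converge: {sol.message}")
    return float(10 ** sol.x[0])


def _fit_kd_single(
    conc: np.ndarray,
    y: np.ndarray,
    imax: float,
    bounds: tuple[float, float] = KD_BOUNDS_NM,
    coarse: int = 256,
) -> tuple[float, float]:
    """One-parameter least-squares Kd fit with Imax fixed.

    A coarse log-spaced scan brackets the global minimum, then a bounded
    scalar minimization polishes it.  Returns (kd, residual_norm).
    """
    lg = np.linspace(np.log10(bounds[0]), np.log10(bounds[1]), coarse)
    pred = imax * conc[None, :] / (10 ** lg[:, None] + conc[None, :])
    sse = ((pred - y[None, :]) ** 2).sum(axis=1)
    i = int(np.argmin(sse))
    a, b = lg[max(i - 1, 0)], lg[min(i + 1, coarse - 1)]

    def obj(logkd: float) -> float:
        return float(((_langmuir(conc, 10**logkd, imax) - y) ** 2).sum())

    sol = minimize_scalar(obj, bounds=(a, b), method="bounded", options={"xatol": 1e-10})
    kd = float(10**sol.x)
    return kd, float(np.sqrt(sol.fun))


def fit_kds(
    series: Sequence[BindingSeries],
    imax_global: float,
    background: float = 0.0,
    kd_bounds: tuple[float, float] = KD_BOUNDS_NM,
) -> list[FitResult]:
    """Per-series Kd fits with the global Imax fixed (step 2).

    Series whose background-subtracted intensities are all <= 0 are flagged
    LOW_SIGNAL; their Kd is reported as a lower bound at the maximum assayed
    concentration.
    """
    if imax_global <= 0:
        raise ValueError("imax_global must be > 0")
    results = []
    for s in series:
        y = s.median_intensity - background
        flags = set(s.flags)
        if np.all(y <= 0):
            flags.add(LOW_SIGNAL)
            results.append(
                FitResult(
                    variant_id=s.variant_id,
                    kd_nM=float(s.conc_nM.max()),
                    imax_global=imax_global,
                    flags=flags,
                    residual_norm=np.nan,
                    code_id=s.code_id,
                    assay_id=s.assay_id,
                )
            )
            continue
        kd, rnorm = _fit_kd_single(s.conc_nM, y, imax_global, kd_bounds)
        results.append(
            FitResult(
                variant_id=s.variant_id,
                kd_nM=kd,
                imax_global=imax_global,
                flags=flags,
                residual_norm=rnorm,
                code_id=s.code_id,
                assay_id=s.assay_id,
            )
        )
    return results


def bootstrap_kd(
    beads: pd.DataFrame,
    imax_global: float,
    n_boot: int = 500,
    seed: int = 0,
    background: float = 0.0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> tuple[float, float]:
    """Percentile bootstrap interval for one series' Kd.

    ``beads`` holds the per-bead rows (``conc_nM``, ``intensity``) for a single
    code or peptide.  Beads are resampled with replacement within each
    concentration, group medians recomputed, and Kd refit.  Seeded and
    reproducible.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    groups = sorted(beads.groupby("conc_nM"), key=lambda kv: kv[0])
    conc = np.array([c for c, _ in groups])
    samples = [g["intensity"].to_numpy(dtype=float) for _, g in groups]
    if any(len(s) == 1 for s in samples):
        warnings.warn(
            "bootstrap with a single bead at some concentration: interval may be unreliable",
            stacklevel=2,
        )
    med = np.empty((n_boot, len(conc)))
    for j, s in enumerate(samples):
        idx = rng.integers(0, len(s), size=(n_boot, len(s)))
        med[:, j] = np.median(s[idx], axis=1)
    kds = np.array(
        [_fit_kd_single(conc, med[b] - background, imax_global)[0] for b in range(n_boot)]
    )
    lo, hi = np.percentile(kds, ci)
    return float(lo), float(hi)


def control_medians(
    control_beads: pd.DataFrame,
    assignments: pd.DataFrame,
    code_map: CodeMap,
) -> dict[str, float]:
    """Per-peptide median control intensity (single-concentration assay)."""
    series = aggregate_series(control_beads, assignments, code_map, by="peptide", min_beads=1)
    return {s.variant_id: float(np.median(s.median_intensity)) for s in series}


def flag_nonspecific(
    fit: FitResult,
    nir_median: float | None,
    antibody_median: float | None,
    threshold_fraction: float = 0.2,
    background: float = 0.0,
) -> set[str]:
    """NONSPECIFIC when either control's background-subtracted median exceeds
    ``threshold_fraction * Imax``; UNTESTED when both controls are missing."""
    flags = set(fit.flags)
    if nir_median is None and antibody_median is None:
        flags.add(UNTESTED)
        return flags
    limit = threshold_fraction * fit.imax_global
    for med in (nir_median, antibody_median):
        if med is not None and (med - background) > limit:
            flags.add(NONSPECIFIC)
    return flags


def flag_saturation(
    fit: FitResult, series: BindingSeries, min_fraction_bound: float = 0.5
) -> set[str]:
    """NON_SATURATING when fitted fraction bound at the top concentration is
    strictly below ``min_fraction_bound`` (Kd exactly equal to the top
    concentration — fraction 0.5 — is not flagged)."""
    flags = set(fit.flags)
    cmax = float(series.conc_nM.max())
    if cmax / (fit.kd_nM + cmax) < min_fraction_bound:
        flags.add(NON_SATURATING)
    return flags


def estimate_background(antibody_beads: pd.DataFrame | None) -> float:
    """Per-assay constant background: overall median of the antibody-only
    control (most peptides carry no specific signal there), else 0."""
    if antibody_beads is None or len(antibody_beads) == 0:
        return 0.0
    return float(antibody_beads["intensity"].median())


def estimate_peptide_concentration(n_species: int, total_nM: float = 20.0) -> float:
    """Diagnostic estimate of per-peptide concentration in a pooled assay
    (total peptide ~20 nM split across the species probed); logged, not
    corrected for, since it is far below typical Kd values."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    value = total_nM / n_species
    logger.info("estimated per-peptide concentration: %.3f nM", value)
    return value


# ---------------------------------------------------------------------------
# I/O


def results_to_frame(results: Sequence[FitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "code_id": r.code_id if r.code_id is not None else "",
                "assay_id": r.assay_id,
                "kd_nM": r.kd_nM,
                "kd_lo": r.kd_lo,
                "kd_hi": r.kd_hi,
                "imax_global": r.imax_global,
                "flags": ";".join(sorted(r.flags)),
                "residual_norm": r.residual_norm,
            }
            for r in results
        ]
    )


def results_to_csv(results: Sequence[FitResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def results_from_csv(path: str | Path) -> list[FitResult]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            FitResult(
                variant_id=row["variant_id"],
                kd_nM=float(row["kd_nM"]),
                imax_global=float(row["imax_global"]),
                kd_lo=float(row["kd_lo"]) if row["kd_lo"] != "" else np.nan,
                kd_hi=float(row["kd_hi"]) if row["kd_hi"] != "" else np.nan,
                flags=set(f for f in str(row["flags"]).split(";") if f),
                residual_norm=float(row["residual_norm"]) if row["residual_norm"] != "" else np.nan,
                code_id=row["code_id"] or None,
                assay_id=str(row["assay_id"]),
            )
        )
    return out
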