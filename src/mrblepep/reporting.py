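"""Affinity-landscape summaries, figures, and the end-to-end pipeline.

Builds the position x residue ddG landscape matrix from an energetics table,
derives scaled-logo weights from it, estimates the surface peptide density from
a streptavidin saturation measurement, and chains simulate -> decode -> fit ->
energetics -> report into one reproducible run directory with a manifest.
Figures are always derived from a CSV twin and never recompute values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import binding_fit, decoding, energetics, library_design, synthetic_data
from .binding_fit import NON_SATURATING, NONSPECIFIC
from .energetics import EnergeticsRow
from .library_design import EXTENDED_ALPHABET, MOTIF_POSITIONS, PeptideVariant, Scaffold

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23

MEASURED, MISSING, FLAGGED = "measured", "missing", "flagged"


@dataclass
class LandscapeMatrix:
    """ddG (vs. scaffold wild type) per residue per motif position.

    ``values`` is residues x positions (kcal/mol, NaN where not measured);
    ``status`` marks each cell measured / missing / flagged.  Flagged cells are
    never rendered as 0 — they are excluded from the color scale entirely.
    """

    scaffold_name: str
    values: pd.DataFrame
    status: pd.DataFrame


def build_landscape(
    rows: Sequence[EnergeticsRow],
    library: Sequence[PeptideVariant],
    scaffold: Scaffold,
) -> LandscapeMatrix:
    """Arrange single-substitution ddGs into a residue x position matrix.

    Cells hold ``ddg(variant) - ddg(WT)`` so the wild-type residue at every
    measured position is exactly 0.  Variants with more than one substitution
    are excluded with a warning; QC-flagged variants are marked FLAGGED.
    """
    ddg_by_id = {r.variant_id: r for r in rows}
    residues = list(EXTENDED_ALPHABET)
    positions = list(MOTIF_POSITIONS)
    values = pd.DataFrame(np.nan, index=residues, columns=positions)
    status = pd.DataFrame(MISSING, index=residues, columns=positions)

    wt_id = library_design.variant_id_for(scaffold.name, [])
    ddg_wt = ddg_by_id[wt_id].ddg if wt_id in ddg_by_id else 0.0

    measured_positions = set()
    for variant in library:
        if variant.is_wild_type:
            continue
        if len(variant.substitutions) != 1:
            logger.warning("excluding multi-substitution variant %s", variant.variant_id)
            continue
        row = ddg_by_id.get(variant.variant_id)
        if row is None:
            continue
        (position, residue), = variant.substitutions
        if row.flags & {NONSPECIFIC, NON_SATURATING}:
            status.loc[residue, position] = FLAGGED
            continue
        values.loc[residue, position] = row.ddg - ddg_wt
        status.loc[residue, position] = MEASURED
        measured_positions.add(position)

    for position in measured_positions:
        wt_res = scaffold.residue_at(position)
        values.loc[wt_res, position] = 0.0
        status.loc[wt_res, position] = MEASURED
    return LandscapeMatrix(scaffold.name, values, status)


def scaled_logo_weights(matrix: LandscapeMatrix) -> pd.DataFrame:
    """Per-position residue heights for a scaled sequence logo.

    At each measured position, height(residue) is proportional to
    ``max(0, -ddG + offset)`` with the offset equal to the largest measured
    destabilization there, so every height is non-negative; heights are then
    normalized to sum to 1.  Stabilizing residues (ddG < 0) dominate.  The
    weights are shift-invariant: adding a constant to a position's ddGs leaves
    them unchanged.  All-missing positions are omitted; a position where every
    residue is equivalent gets uniform heights.
    """
    heights: dict[int, pd.Series] = {}
    for position in matrix.values.columns:
        col = matrix.values[position].dropna()
        if col.empty:
            continue
        raw = np.maximum(0.0, -col + col.max())
        total = raw.sum()
        if total == 0:  # all residues equal -> uninformative position
            raw = pd.Series(1.0, index=col.index)
            total = raw.sum()
        heights[position] = raw / total
    out = pd.DataFrame(heights).reindex(matrix.values.index)
    out.columns.name = "position"
    return out


def peptide_density(saturating_conc_nM: float, volume_L: float, n_beads: int) -> float:
    """Peptide molecules per bead from a streptavidin saturation point:
    ``conc * volume * N_A / n_beads``."""
    if saturating_conc_nM <= 0 or volume_L <= 0:
        raise ValueError("concentration and volume must be > 0")
    if n_beads <= 0:
        raise ValueError("n_beads must be > 0")
    return saturating_conc_nM * 1e-9 * volume_L * AVOGADRO / n_beads


def round_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


# ---------------------------------------------------------------------------
# Figures (derived strictly from already-computed tables)


def plot_heatmap(
    matrix: LandscapeMatrix, path_base: str | Path, clip_kcal: float = 2.5
) -> list[Path]:
    """Symmetric-scale ddG heat map; flagged/missing cells drawn in grey."""
    vals = matrix.values.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(0.5 * vals.shape[1] + 2, 0.3 * vals.shape[0] + 1.5))
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(vals, cmap=cmap, vmin=-clip_kcal, vmax=clip_kcal, aspect="auto")
    ax.set_xticks(range(vals.shape[1]), [str(c) for c in matrix.values.columns])
    ax.set_yticks(range(vals.shape[0]), list(matrix.values.index))
    flagged = matrix.status.to_numpy() == FLAGGED
    for i, j in zip(*np.nonzero(flagged)):
        ax.text(j, i, "x", ha="center", va="center", fontsize=7)
    ax.set_xlabel("motif position")
    fig.colorbar(im, ax=ax, label=r"$\Delta\Delta G$ (kcal/mol)")
    ax.set_title(f"{matrix.scaffold_name} substitution landscape")
    return _save_figure(fig, path_base)


def plot_logo(weights: pd.DataFrame, path_base: str | Path) -> list[Path]:
    """Stacked-bar scaled logo from precomputed per-position weights."""
    fig, ax = plt.subplots(figsize=(0.8 * weights.shape[1] + 2, 3))
    palette = plt.get_cmap("tab20")
    colors = {res: palette(i % 20) for i, res in enumerate(weights.index)}
    for x, position in enumerate(weights.columns):
        col = weights[position].dropna().sort_values()
        bottom = 0.0
        for res, h in col.items():
            if h <= 0:
                continue
            ax.bar(x, h, bottom=bottom, color=colors[res], width=0.8)
            if h > 0.08:
                ax.text(x, bottom + h / 2, res, ha="center", va="center", fontsize=8)
            bottom += h
    ax.set_xticks(range(weights.shape[1]), [str(c) for c in weights.columns])
    ax.set_xlabel("motif position")
    ax.set_ylabel("scaled weight")
    return _save_figure(fig, path_base)


def _save_figure(fig, path_base: str | Path) -> list[Path]:
    base = Path(path_base)
    paths = []
    for ext in ("png", "svg"):
        p = base.with_suffix(f".{ext}")
        fig.savefig(p, dpi=150, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


# ---------------------------------------------------------------------------
# End-to-end pipeline


def default_config() -> dict:
    """Demo configuration: a PVIVIT position-2/position-9 substitution scan."""
    return {
        "seed": 0,
        "scaffold": {"name": "PVIVIT", "sequence": "MAGPHPVIVITGPHEE", "core_offset": 5},
        "library": {
            "positions": [2, 9],
            "alphabet": EXTENDED_ALPHABET,
            "include_wt": True,
        },
        "truth": {
            "kd_range_nM": [30.0, 3000.0],
            "kd_wt_nM": 400.0,  # reference (wild-type) affinity is pinned
            "imax": 1000.0,
            "sticky": {"PVIVIT_2R": 0.5},
        },
        "assay": {
            "concentrations": list(synthetic_data.DEFAULT_CONCENTRATIONS),
            "beads_per_code": 100,
            "background": 10.0,
            "intensity_sigma": 0.15,
            "ratio_sigma": 0.03,
        },
        "codes": {"n_channels": 3, "levels_per_channel": 4},
        "decode": {"min_confidence": 0.95, "max_distance": 3.0},
        "fit": {"top_fraction": 0.8, "nonspecific_threshold": 0.2, "min_fraction_bound": 0.5},
        "energetics": {"kd_ref_nM": 980.0, "temperature_K": 298.15},
        "controls": True,
    }


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: Mapping, outdir: str | Path) -> Path:
    """Execute simulate -> decode -> fit -> energetics -> report.

    Writes every table as CSV, figures as PNG+SVG twins of their CSVs, and a
    run manifest (config hash, seed, package version).  Tabular outputs are
    bit-identical when re-run with the same config.
    """
    from . import __version__

    cfg = json.loads(json.dumps(dict(config)))  # deep copy, JSON-clean
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stage = "setup"
    try:
        stage = "library"
        sc = cfg["scaffold"]
        scaffold = Scaffold(sc["name"], sc["sequence"], int(sc["core_offset"]))
        lib_cfg = cfg["library"]
        library = library_design.single_substitution_library(
            scaffold,
            lib_cfg["positions"],
            lib_cfg.get("alphabet", EXTENDED_ALPHABET),
            include_wt=lib_cfg.get("include_wt", True),
        )
        library_design.library_to_csv(library, out / "library.csv")
        peptides = [v.variant_id for v in library]

        stage = "simulate"
        tcfg = cfg["truth"]
        wt_variant = library_design.variant_id_for(scaffold.name, [])
        overrides = (
            {wt_variant: float(tcfg["kd_wt_nM"])} if "kd_wt_nM" in tcfg else {}
        )
        truth = synthetic_data.make_ground_truth(
            peptides,
            kd_range_nM=tuple(tcfg.get("kd_range_nM", (30.0, 3000.0))),
            imax_true=float(tcfg.get("imax", 1000.0)),
            sticky=tcfg.get("sticky", {}),
            seed=seed,
            kd_overrides=overrides,
        )
        truth.to_json(out / "ground_truth.json")
        ccfg = cfg.get("codes", {})
        code_map = synthetic_data.make_code_map(
            len(peptides),
            n_channels=int(ccfg.get("n_channels", 3)),
            levels_per_channel=int(ccfg.get("levels_per_channel", 4)),
            seed=seed,
            peptides=peptides,
            ratio_cv=float(cfg["assay"].get("ratio_sigma", 0.03)),
        )
        code_map.to_json(out / "code_map.json")
        acfg = cfg["assay"]
        design = synthetic_data.AssayDesign(
            concentrations=tuple(acfg["concentrations"]),
            beads_per_code=int(acfg["beads_per_code"]),
            assay_id="binding",
            background=float(acfg.get("background", 10.0)),
            intensity_sigma=float(acfg.get("intensity_sigma", 0.15)),
            ratio_sigma=float(acfg.get("ratio_sigma", 0.03)),
            seed=seed,
        )
        beads = synthetic_data.simulate_assay(code_map, truth, design)
        synthetic_data.beads_to_csv(beads, out / "beads_binding.csv")
        controls: dict[str, pd.DataFrame] = {}
        if cfg.get("controls", True):
            for i, kind in enumerate(("NIR_control", "antibody_only")):
                cdesign = synthetic_data.control_design(kind, design, seed=seed + 1 + i)
                controls[kind] = synthetic_data.simulate_assay(code_map, truth, cdesign)
                synthetic_data.beads_to_csv(controls[kind], out / f"beads_{kind}.csv")

        stage = "decode"
        dcfg = cfg.get("decode", {})
        assignments = decoding.decode_bead_table(
            beads,
            code_map,
            min_confidence=float(dcfg.get("min_confidence", 0.95)),
            max_distance=float(dcfg.get("max_distance", 3.0)),
        )
        assignments.to_csv(out / "assignments.csv", index=False)
        control_assign = {
            kind: decoding.decode_bead_table(tbl, code_map) for kind, tbl in controls.items()
        }

        stage = "fit"
        fcfg = cfg.get("fit", {})
        background = binding_fit.estimate_background(controls.get("antibody_only"))
        series = binding_fit.aggregate_series(beads, assignments, code_map, by="peptide")
        imax = binding_fit.fit_global_imax(
            series, top_fraction=float(fcfg.get("top_fraction", 0.8)), background=background
        )
        binding_fit.estimate_peptide_concentration(len(peptides))
        results = binding_fit.fit_kds(series, imax, background=background)
        series_by_id = {s.variant_id: s for s in series}
        nir_medians = (
            binding_fit.control_medians(controls["NIR_control"], control_assign["NIR_control"], code_map)
            if "NIR_control" in controls
            else {}
        )
        ab_medians = (
            binding_fit.control_medians(
                controls["antibody_only"], control_assign["antibody_only"], code_map
            )
            if "antibody_only" in controls
            else {}
        )
        for r in results:
            r.flags = binding_fit.flag_nonspecific(
                r,
                nir_medians.get(r.variant_id) if controls else None,
                ab_medians.get(r.variant_id) if controls else None,
                threshold_fraction=float(fcfg.get("nonspecific_threshold", 0.2)),
                background=background,
            )
            r.flags = binding_fit.flag_saturation(
                r, series_by_id[r.variant_id], float(fcfg.get("min_fraction_bound", 0.5))
            )
        binding_fit.results_to_csv(results, out / "fits.csv")

        stage = "energetics"
        ecfg = cfg.get("energetics", {})
        wt_id = library_design.variant_id_for(scaffold.name, [])
        rows = energetics.calibrate_absolute(
            results,
            reference_id=wt_id,
            kd_ref_literature=float(ecfg.get("kd_ref_nM", 980.0)),
            temperature=float(ecfg.get("temperature_K", 298.15)),
        )
        energetics.energetics_to_csv(rows, out / "energetics.csv")

        stage = "report"
        matrix = build_landscape(rows, library, scaffold)
        matrix.values.to_csv(out / "landscape.csv")
        matrix.status.to_csv(out / "landscape_status.csv")
        plot_heatmap(matrix, out / "landscape_heatmap")
        weights = scaled_logo_weights(matrix)
        weights.to_csv(out / "logo_weights.csv")
        plot_logo(weights, out / "logo")

        manifest = {
            "config": cfg,
            "config_hash": _config_hash(cfg),
            "seed": seed,
            "version": __version__,
            "imax_global": imax,
            "background": background,
            "n_beads": int(len(beads)),
            "n_peptides": len(peptides),
            "tables": sorted(p.name for p in out.glob("*.csv")),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception as exc:  # partial outputs are left in place for inspection
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
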