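"""Ground-truth simulation of spectrally encoded bead binding assays.

Emulates a multiplexed bead assay in which each hydrogel bead carries a
spectral code (ratios of three coding lanthanide channels against an internal
standard channel) that maps 1:1 to a peptide sequence.  Beads are incubated
with a protein across a concentration series; per-bead bound-protein
fluorescence follows a single-site Langmuir isotherm with a saturation
intensity shared by all peptides, perturbed by multiplicative lognormal
bead-to-bead noise.  Control assays (a binding-deficient protein mutant and
labeled antibody alone) carry only background plus a per-peptide nonspecific
signal fraction.

Defaults mirror the study conditions: a 48-plex code library, ~100 beads per
sequence, and the six-point dilution series 2000, 1000, 500, 250, 125,
62.5 nM with controls at a single 250 nM concentration.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Printed protein dilution series, nM.
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (2000.0, 1000.0, 500.0, 250.0, 125.0, 62.5)
#: Single high concentration used for control assays, nM.
CONTROL_CONCENTRATION_NM = 250.0

ASSAY_KINDS = ("binding", "NIR_control", "antibody_only")

#: Fixed table column order for bead records.
BEAD_COLUMNS_FIXED = ("bead_id", "assay_id", "assay_kind", "conc_nM")


class CapacityError(ValueError):
    """More codes requested than the level grid can supply."""


class GeometryError(ValueError):
    """Beads cannot be packed into the requested image frame."""


def langmuir_intensity(kd, imax, conc):
    """Single-site Langmuir isotherm: ``imax * conc / (kd + conc)``.

    Monotone increasing in ``conc`` and saturating at ``imax``.  ``kd`` is the
    dissociation constant in the same units as ``conc`` (nM throughout this
    package); free ligand is approximated by total ligand (the bead-bound
    peptide is scarce relative to Kd).
    """
    kd = np.asarray(kd, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("kd must be > 0")
    if np.any(conc < 0):
        raise ValueError("conc must be >= 0")
    out = np.asarray(imax, dtype=float) * conc / (kd + conc)
    return float(out) if out.ndim == 0 else out


@dataclass
class CodeMap:
    """Registry mapping each spectral code to its target ratio vector and peptide.

    ``targets`` is an ``(n_codes, n_channels)`` array of coding-channel
    intensity ratios relative to the internal standard.
    """

    code_ids: list[str]
    targets: np.ndarray
    peptides: list[str]
    channels: list[str]
    ratio_cv: float

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        if len(set(self.code_ids)) != len(self.code_ids):
            raise ValueError("code_ids must be unique")
        if not (len(self.code_ids) == self.targets.shape[0] == len(self.peptides)):
            raise ValueError("code_ids, targets and peptides must align")
        if self.targets.shape[1] != len(self.channels):
            raise ValueError("targets width must match channel count")
        self._check_separation()

    def _check_separation(self) -> None:
        n = len(self.code_ids)
        if n < 2:
            return
        d = np.linalg.norm(self.targets[:, None, :] - self.targets[None, :, :], axis=-1)
        min_sep = d[~np.eye(n, dtype=bool)].min()
        if min_sep <= 3.0 * self.ratio_cv:
            raise ValueError(
                f"code separation {min_sep:.4f} <= 3 x ratio_cv ({3 * self.ratio_cv:.4f}); "
                "decoding would be ill-posed"
            )

    @property
    def n_codes(self) -> int:
        return len(self.code_ids)

    def peptide_of(self, code_id: str) -> str:
        return self.peptides[self.code_ids.index(code_id)]

    def codes_for_peptide(self, variant_id: str) -> list[str]:
        return [c for c, p in zip(self.code_ids, self.peptides) if p == variant_id]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channels": self.channels,
            "ratio_cv": self.ratio_cv,
            "codes": [
                {"code_id": c, "ratio_vector": t.tolist(), "peptide": p}
                for c, t, p in zip(self.code_ids, self.targets, self.peptides)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CodeMap":
        payload = json.loads(Path(path).read_text())
        codes = payload["codes"]
        return cls(
            code_ids=[c["code_id"] for c in codes],
            targets=np.array([c["ratio_vector"] for c in codes], dtype=float),
            peptides=[c["peptide"] for c in codes],
            channels=list(payload["channels"]),
            ratio_cv=float(payload["ratio_cv"]),
        )


def make_code_map(
    n_codes: int,
    n_channels: int = 3,
    levels_per_channel: int = 4,
    seed: int = 0,
    peptides: Sequence[str] | None = None,
    ratio_cv: float = 0.03,
    channels: Sequence[str] | None = None,
    level_range: tuple[float, float] = (0.2, 1.0),
) -> CodeMap:
    """Draw ``n_codes`` distinct ratio vectors from a grid of discrete levels.

    Levels are evenly spaced over ``level_range`` in every coding channel; the
    codes are a seeded random subset of the full lattice, so the map is
    deterministic for a fixed seed and the pairwise separation exceeds
    3 x ``ratio_cv`` by construction (the grid spacing dominates the noise).
    """
    if levels_per_channel**n_channels < n_codes:
        raise CapacityError(
            f"{n_codes} codes need more than a {levels_per_channel}^{n_channels} grid"
        )
    if levels_per_channel == 1:
        levels = np.array([np.mean(level_range)])
    else:
        levels = np.linspace(level_range[0], level_range[1], levels_per_channel)
    grid = np.array(list(itertools.product(levels, repeat=n_channels)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(grid), size=n_codes, replace=False)
    idx.sort()  # canonical order; the random subset choice is what varies
    targets = grid[idx]
    if peptides is None:
        peptides = [f"pep{i:03d}" for i in range(n_codes)]
    if len(peptides) != n_codes:
        raise ValueError("peptides must match n_codes")
    if channels is None:
        channels = [f"ln{i+1}" for i in range(n_channels)]
    code_ids = [f"C{i:03d}" for i in range(n_codes)]
    return CodeMap(code_ids, targets, list(peptides), list(channels), ratio_cv)


@dataclass
class GroundTruth:
    """Generative truth: per-peptide Kd, nonspecific fractions, shared Imax."""

    kd_true: dict[str, float]
    imax_true: float = 1000.0
    nonspecific: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for pep, kd in self.kd_true.items():
            if kd <= 0:
                raise ValueError(f"kd_true[{pep!r}] must be > 0")
        for pep, frac in self.nonspecific.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"nonspecific[{pep!r}] must be in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def make_ground_truth(
    peptides: Sequence[str],
    kd_range_nM: tuple[float, float] = (30.0, 3000.0),
    imax_true: float = 1000.0,
    sticky: Mapping[str, float] | None = None,
    seed: int = 0,
    log_spaced: bool = False,
    kd_overrides: Mapping[str, float] | None = None,
) -> GroundTruth:
    """Assign true Kds to peptides, log-uniform (or log-spaced) over a range.

    ``sticky`` maps selected peptides to a nonspecific control-signal fraction
    of Imax (emulating e.g. antibody cross-reactive basic-rich sequences);
    ``kd_overrides`` pins chosen peptides (e.g. a reference of known affinity)
    to fixed Kds.
    """
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(kd_range_nM[0]), np.log10(kd_range_nM[1])
    if log_spaced:
        kds = np.logspace(lo, hi, len(peptides))
    else:
        kds = 10 ** rng.uniform(lo, hi, size=len(peptides))
    kd_true = {p: float(k) for p, k in zip(peptides, kds)}
    for p, k in (kd_overrides or {}).items():
        kd_true[p] = float(k)
    return GroundTruth(
        kd_true=kd_true,
        imax_true=imax_true,
        nonspecific=dict(sticky or {}),
        seed=seed,
    )


@dataclass
class AssayDesign:
    """One simulated assay: concentration series, bead counts and noise."""

    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    beads_per_code: int = 100
    assay_kind: str = "binding"
    assay_id: str = "assay1"
    imax_true: float | None = None  # overrides GroundTruth.imax_true when set
    background: float = 10.0
    intensity_sigma: float = 0.15  # lognormal sigma, per bead
    ratio_sigma: float = 0.03  # Gaussian sigma per coding channel
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(conc <= 0) or len(set(conc.tolist())) != len(conc):
            raise ValueError("concentrations must be strictly positive and distinct")
        if self.beads_per_code < 1:
            raise ValueError("beads_per_code must be >= 1")
        if self.intensity_sigma < 0 or self.ratio_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.assay_kind not in ASSAY_KINDS:
            raise ValueError(f"assay_kind must be one of {ASSAY_KINDS}")


def control_design(kind: str, template: AssayDesign | None = None, **overrides) -> AssayDesign:
    """A control assay (``NIR_control`` or ``antibody_only``) at 250 nM."""
    base = asdict(template) if template is not None else asdict(AssayDesign())
    base.update(
        concentrations=(CONTROL_CONCENTRATION_NM,),
        assay_kind=kind,
        assay_id=overrides.pop("assay_id", kind),
    )
    base.update(overrides)
    base["concentrations"] = tuple(base["concentrations"])
    return AssayDesign(**base)


def simulate_assay(code_map: CodeMap, truth: GroundTruth, design: AssayDesign) -> pd.DataFrame:
    """Simulate one bead table: one row per bead per concentration.

    Binding assays draw ``intensity = background + langmuir_mean * LN(sigma)``
    where LN is lognormal with median 1, so per-group medians equal the noise-
    free signal.  Control assays replace the Langmuir mean with the peptide's
    nonspecific fraction of Imax.  Realized ratio vectors are the code targets
    plus isotropic Gaussian noise.  Fully reproducible for a fixed design seed.
    """
    missing = [p for p in code_map.peptides if p not in truth.kd_true]
    if missing:
        raise KeyError(f"peptides missing from ground truth: {missing[:5]}")
    rng = np.random.default_rng(design.seed)
    imax = design.imax_true if design.imax_true is not None else truth.imax_true
    conc = np.asarray(design.concentrations, dtype=float)
    n_codes, n_conc, n_beads = code_map.n_codes, len(conc), design.beads_per_code
    n_rows = n_codes * n_conc * n_beads

    code_idx = np.repeat(np.arange(n_codes), n_conc * n_beads)
    conc_col = np.tile(np.repeat(conc, n_beads), n_codes)
    kd = np.array([truth.kd_true[p] for p in code_map.peptides])

    if design.assay_kind == "binding":
        mean = langmuir_intensity(kd[code_idx], imax, conc_col)
    else:
        ns = np.array([truth.nonspecific.get(p, 0.0) for p in code_map.peptides])
        mean = ns[code_idx] * imax
    lognoise = np.exp(rng.normal(0.0, design.intensity_sigma, size=n_rows))
    intensity = design.background + mean * lognoise

    ratios = code_map.targets[code_idx] + rng.normal(
        0.0, design.ratio_sigma, size=(n_rows, len(code_map.channels))
    )

    df = pd.DataFrame(
        {
            "bead_id": np.arange(n_rows),
            "assay_id": design.assay_id,
            "assay_kind": design.assay_kind,
            "conc_nM": conc_col,
        }
    )
    for j, ch in enumerate(code_map.channels):
        df[f"ratio_{ch}"] = ratios[:, j]
    df["intensity"] = intensity
    # ground-truth columns, for scoring simulations; not consumed by the pipeline
    df["code_true"] = [code_map.code_ids[i] for i in code_idx]
    return df


def beads_to_csv(beads: pd.DataFrame, path: str | Path) -> None:
    beads.to_csv(path, index=False)


def beads_from_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Optional image rendering


@dataclass
class ImageGeometry:
    """Frame size and bead disc geometry for rendered synthetic images."""

    shape: tuple[int, int] = (256, 256)
    bead_radius: int = 6
    margin: int = 2  # minimum gap between disc edges and between disc and frame
    standard_intensity: float = 5000.0
    brightfield_background: float = 1000.0
    brightfield_bead: float = 300.0


def render_bead_images(
    beads: pd.DataFrame,
    code_map: CodeMap,
    geometry: ImageGeometry | None = None,
    seed: int = 0,
    max_attempts: int = 200,
):
    """Render beads as non-overlapping uniform discs in a multichannel stack.

    Channels are ``brightfield``, ``binding``, one per coding lanthanide, and
    the internal ``standard``.  Coding-channel disc intensity is the bead's
    realized ratio times the standard intensity, so median extraction followed
    by ratio computation reproduces the input table.  Returns
    ``(stack, labels, channel_names, placements)`` where ``labels`` assigns
    pixels to bead table rows (label k = row k-1, 0 = background).
    """
    geometry = geometry or ImageGeometry()
    h, w = geometry.shape
    r, gap = geometry.bead_radius, geometry.margin
    rng = np.random.default_rng(seed)
    n = len(beads)

    channel_names = ["brightfield", "binding"] + list(code_map.channels) + ["standard"]
    stack = np.zeros((len(channel_names), h, w), dtype=np.float32)
    stack[0] = geometry.brightfield_background
    labels = np.zeros((h, w), dtype=np.int32)
    if n == 0:
        return stack, labels, channel_names, []

    centers: list[tuple[int, int]] = []
    for _ in range(n):
        for _attempt in range(max_attempts):
            cy = int(rng.integers(r + gap, h - r - gap))
            cx = int(rng.integers(r + gap, w - r - gap))
            if all((cy - y) ** 2 + (cx - x) ** 2 >= (2 * r + gap) ** 2 for y, x in centers):
                centers.append((cy, cx))
                break
        else:
            raise GeometryError(
                f"could not place {n} beads of radius {r} in a {h}x{w} frame"
            )

    yy, xx = np.mgrid[0:h, 0:w]
    ratio_cols = [f"ratio_{ch}" for ch in code_map.channels]
    for k, ((cy, cx), (_, row)) in enumerate(zip(centers, beads.iterrows()), start=1):
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        labels[disc] = k
        stack[0][disc] = geometry.brightfield_bead
        stack[1][disc] = row["intensity"]
        for j, col in enumerate(ratio_cols):
            stack[2 + j][disc] = row[col] * geometry.standard_intensity
        stack[-1][disc] = geometry.standard_intensity
    return stack, labels, channel_names, centers


def write_image_stack(
    stack: np.ndarray,
    channel_names: Sequence[str],
    path: str | Path,
    sidecar: Mapping | None = None,
) -> None:
    """Write a multichannel stack as multi-page TIFF with a JSON sidecar."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))
    meta = {"channels": list(channel_names)}
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))
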