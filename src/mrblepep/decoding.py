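"""Code calling: bead segmentation, median extraction, and code assignment.

Bead boundaries are found in the bright-field channel; per-bead, per-channel
median pixel intensities are extracted; coding-channel medians are divided by
the internal-standard channel to give a ratio vector (so results are invariant
to overall illumination scale); and each bead is assigned to the spectral code
whose target ratio vector it matches, under a Gaussian mixture with means fixed
at the code-map targets and a shared diagonal covariance estimated from the
data.  Beads whose posterior confidence or Mahalanobis distance fails the
thresholds are UNASSIGNED and dropped from downstream analysis.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .synthetic_data import CodeMap

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

#: Variance floor: keeps the mixture well-defined on noiseless data.
_VAR_FLOOR = 1e-12


def segment_beads(
    stack: np.ndarray,
    channel_names: Sequence[str],
    radius_band: tuple[float, float] = (2.0, 50.0),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment bead discs from the bright-field channel.

    Beads appear darker than background in bright field.  Regions whose
    equivalent radius falls outside ``radius_band`` (pixels) are discarded.
    Returns a relabeled label image and a region table (label, centroid,
    radius).
    """
    if "brightfield" not in channel_names:
        raise ValueError("stack must contain a 'brightfield' channel")
    bf = np.asarray(stack[list(channel_names).index("brightfield")], dtype=float)
    if bf.max() == bf.min():
        return np.zeros(bf.shape, dtype=np.int32), pd.DataFrame(
            columns=["label", "centroid_y", "centroid_x", "radius"]
        )
    mask = bf < threshold_otsu(bf)
    raw = sk_label(mask)
    labels = np.zeros_like(raw, dtype=np.int32)
    rows = []
    next_label = 1
    for region in regionprops(raw):
        radius = np.sqrt(region.area / np.pi)
        if not (radius_band[0] <= radius <= radius_band[1]):
            continue
        labels[raw == region.label] = next_label
        cy, cx = region.centroid
        rows.append(
            {"label": next_label, "centroid_y": cy, "centroid_x": cx, "radius": radius}
        )
        next_label += 1
    return labels, pd.DataFrame(rows, columns=["label", "centroid_y", "centroid_x", "radius"])


def extract_medians(
    labels: np.ndarray, stack: np.ndarray, channel_names: Sequence[str]
) -> pd.DataFrame:
    """Per-bead median pixel intensity in every channel.

    Medians are robust to salt-and-pepper outliers inside a disc.  Empty
    regions are skipped with a logged warning.
    """
    if labels.shape != stack.shape[1:]:
        raise ValueError("label image does not match stack geometry")
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        if not mask.any():  # pragma: no cover - unique() precludes this
            logger.warning("empty region %d skipped", lab)
            continue
        row = {"bead_id": int(lab)}
        for j, ch in enumerate(channel_names):
            row[ch] = float(np.median(stack[j][mask]))
        rows.append(row)
    return pd.DataFrame(rows, columns=["bead_id", *channel_names])


def ratios_from_medians(
    medians: pd.DataFrame,
    coding_channels: Sequence[str],
    standard_channel: str = "standard",
    standard_floor: float = 1e-6,
) -> pd.DataFrame:
    """Divide coding-channel medians by the internal standard.

    Beads whose standard-channel median is below ``standard_floor`` get NaN
    ratios (they will be UNASSIGNED).  Scale-invariant by construction.
    """
    std = medians[standard_channel].to_numpy(dtype=float)
    ok = std > standard_floor
    out = pd.DataFrame({"bead_id": medians["bead_id"]})
    for ch in coding_channels:
        ratio = np.full(len(medians), np.nan)
        ratio[ok] = medians.loc[ok, ch].to_numpy(dtype=float) / std[ok]
        out[f"ratio_{ch}"] = ratio
    return out


def _fixed_mean_gmm(
    x: np.ndarray, means: np.ndarray, n_iter: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior assignment under a GMM with fixed means and shared diagonal cov.

    Returns (best_index, confidence, mahalanobis_distance) per row.  The shared
    per-channel variance is re-estimated from residuals to the current hard
    assignment for ``n_iter`` rounds; on degenerate (noiseless) data the
    variance floors out and assignment reduces to nearest centroid.
    """
    # nearest-centroid initialization
    d2 = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=-1)
    best = d2.argmin(axis=1)
    var = np.full(x.shape[1], 1.0)
    for _ in range(n_iter):
        resid = x - means[best]
        var = np.maximum((resid**2).mean(axis=0), _VAR_FLOOR)
        m2 = (((x[:, None, :] - means[None, :, :]) ** 2) / var).sum(axis=-1)
        best = m2.argmin(axis=1)
    if np.any(var <= _VAR_FLOOR * 1.01):
        logger.warning("degenerate ratio covariance; using nearest-centroid fallback")
    loglik = -0.5 * m2  # equal priors, shared covariance: constant terms cancel
    conf = np.exp(loglik[np.arange(len(x)), best] - logsumexp(loglik, axis=1))
    dist = np.sqrt(m2[np.arange(len(x)), best])
    return best, conf, dist


def assign_codes(
    ratios: pd.DataFrame,
    code_map: CodeMap,
    min_confidence: float = 0.95,
    max_distance: float = 3.0,
) -> pd.DataFrame:
    """Assign each bead's ratio vector to a spectral code.

    ``ratios`` must carry ``bead_id`` plus ``ratio_<channel>`` columns matching
    the code map.  A bead is UNASSIGNED when its posterior confidence falls
    below ``min_confidence``, its Mahalanobis distance to the assigned centroid
    exceeds ``max_distance``, or any ratio is NaN.  Deterministic.
    """
    cols = [f"ratio_{ch}" for ch in code_map.channels]
    missing = [c for c in cols if c not in ratios.columns]
    if missing:
        raise ValueError(f"ratio table lacks columns {missing}")
    x = ratios[cols].to_numpy(dtype=float)
    valid = ~np.isnan(x).any(axis=1)

    code_id = np.full(len(x), UNASSIGNED, dtype=object)
    confidence = np.zeros(len(x))
    distance = np.full(len(x), np.inf)
    if valid.any():
        best, conf, dist = _fixed_mean_gmm(x[valid], code_map.targets)
        ok = (conf >= min_confidence) & (dist <= max_distance)
        ids = np.array(code_map.code_ids, dtype=object)
        assigned = np.where(ok, ids[best], UNASSIGNED)
        code_id[valid] = assigned
        confidence[valid] = conf
        distance[valid] = dist
    return pd.DataFrame(
        {
            "bead_id": ratios["bead_id"].to_numpy(),
            "code_id": code_id,
            "confidence": confidence,
            "distance": distance,
        }
    )


def decode_bead_table(
    beads: pd.DataFrame,
    code_map: CodeMap,
    min_confidence: float = 0.95,
    max_distance: float = 3.0,
) -> pd.DataFrame:
    """Assign codes directly from a tabular bead record (ratio columns present)."""
    cols = ["bead_id"] + [f"ratio_{ch}" for ch in code_map.channels]
    return assign_codes(beads[cols], code_map, min_confidence, max_distance)


def decode_image_stack(
    stack: np.ndarray,
    channel_names: Sequence[str],
    code_map: CodeMap,
    min_confidence: float = 0.95,
    max_distance: float = 3.0,
    radius_band: tuple[float, float] = (2.0, 50.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment, extract medians, and assign codes for one image stack.

    Returns (per-bead channel medians incl. binding intensity, assignments).
    """
    labels, _ = segment_beads(stack, channel_names, radius_band)
    medians = extract_medians(labels, stack, channel_names)
    ratios = ratios_from_medians(medians, code_map.channels)
    assignments = assign_codes(ratios, code_map, min_confidence, max_distance)
    return medians, assignments
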