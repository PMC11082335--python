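"""Intensity-threshold segmentation of the 4th-ventricle CSF region.

The ventricle appears as a bright CSF plateau on the temporal-mean EPI
slice.  The operator supplies the target slice pair and a bounding box;
inside the box the CSF mask is taken automatically by thresholding the
temporal-mean intensity (90th in-box percentile by default, with fixed and
Otsu policies available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import AcquisitionProtocol

__all__ = [
    "BoundingBox",
    "ThresholdPolicy",
    "CsfRoi",
    "SegmentationError",
    "segment_csf_roi",
    "voxel_volume",
    "compare_roi_sizes",
]


class SegmentationError(ValueError):
    """Raised when thresholding yields no usable CSF mask."""


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive in-plane voxel bounds (x0..x1, y0..y1) of the search box."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValueError(f"degenerate bounding box {self}")

    @classmethod
    def parse(cls, text: str) -> "BoundingBox":
        parts = text.split(",")
        if len(parts) != 4:
            raise ValueError(f"bbox must be 'x0,y0,x1,y1', got {text!r}")
        return cls(*(int(p) for p in parts))

    def __str__(self) -> str:
        return f"{self.x0},{self.y0},{self.x1},{self.y1}"


@dataclass(frozen=True)
class ThresholdPolicy:
    """How the in-box CSF threshold is chosen.

    kind "otsu" (default: between-class variance maximiser, robust to the
    CSF fraction of the box), "percentile" (value = percentile of in-box
    intensities) or "fixed" (value = absolute threshold).
    """

    kind: str = "otsu"
    value: float = 90.0

    def __post_init__(self) -> None:
        if self.kind not in ("percentile", "fixed", "otsu"):
            raise ValueError(f"unknown threshold policy kind {self.kind!r}")
        if self.kind == "percentile" and not 0 <= self.value <= 100:
            raise ValueError("percentile must be in [0, 100]")


@dataclass(frozen=True)
class CsfRoi:
    """Per-slice CSF mask with its voxel count and volume."""

    slice_idx: int
    mask: np.ndarray  # boolean, full slice shape
    n_voxels: int
    voxel_volume_mm3: float

    @property
    def roi_volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


def _otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's between-class variance maximiser on a 1-D sample."""
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    between[~np.isfinite(between)] = -np.inf
    # the criterion is flat across the gap between well-separated modes;
    # take the middle of the plateau so the threshold sits mid-gap
    best = np.flatnonzero(between >= between.max() - 1e-12 * abs(between.max()))
    return float(edges[int(round(best.mean())) + 1])


def segment_csf_roi(
    mean_slice_image: np.ndarray,
    bbox: BoundingBox,
    policy: ThresholdPolicy = ThresholdPolicy(),
    *,
    slice_idx: int = 0,
    voxel_volume_mm3: float = 1.0,
) -> CsfRoi:
    """Threshold the temporal-mean slice inside the bounding box.

    The mask contains the in-box voxels whose mean intensity reaches the
    policy's threshold.  Voxels tied with the threshold are included.
    Raises :class:`SegmentationError` for an all-zero box or an empty mask.
    """
    img = np.asarray(mean_slice_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("mean_slice_image must be 2-D")
    nx, ny = img.shape
    if not (0 <= bbox.x0 <= bbox.x1 < nx and 0 <= bbox.y0 <= bbox.y1 < ny):
        raise ValueError(f"bounding box {bbox} outside image bounds {img.shape}")
    inbox = img[bbox.x0 : bbox.x1 + 1, bbox.y0 : bbox.y1 + 1]
    if not np.any(inbox > 0):
        raise SegmentationError(
            f"no positive intensity inside bbox {bbox} on slice {slice_idx}; "
            "revise the bounding box or slice selection"
        )
    if policy.kind == "percentile":
        threshold = float(np.percentile(inbox, policy.value))
    elif policy.kind == "fixed":
        threshold = policy.value
    elif np.ptp(inbox) == 0.0:  # uniform box: Otsu degenerate, keep all
        threshold = float(inbox.flat[0])
    else:
        threshold = _otsu_threshold(inbox.ravel())
    mask = np.zeros_like(img, dtype=bool)
    mask[bbox.x0 : bbox.x1 + 1, bbox.y0 : bbox.y1 + 1] = inbox >= threshold
    n_voxels = int(mask.sum())
    if n_voxels == 0:
        raise SegmentationError(
            f"empty CSF mask at threshold {threshold:.4g} inside bbox {bbox}; "
            "lower the threshold or revise the bounding box"
        )
    return CsfRoi(
        slice_idx=slice_idx,
        mask=mask,
        n_voxels=n_voxels,
        voxel_volume_mm3=voxel_volume_mm3,
    )


def voxel_volume(protocol: AcquisitionProtocol) -> float:
    """Volume of one voxel in mm^3 (in-plane edge squared times thickness)."""
    return protocol.inplane_res_mm**2 * protocol.slice_thickness_mm


def compare_roi_sizes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group summary and pairwise t-tests of CSF ROI voxel counts.

    ``cohort`` is a DataFrame with columns ``group`` and ``n_voxels``.
    Returns the per-group mean +/- SD table; pairwise pooled two-sample
    t-tests are attached under the ``attrs['pairwise']`` key.
    """
    from .stats import two_sample_t

    df = cohort[["group", "n_voxels"]].dropna()
    counts = df.groupby("group")["n_voxels"]
    if (counts.size() < 2).any():
        small = counts.size()[counts.size() < 2].index.tolist()
        raise ValueError(f"groups with <2 subjects cannot be compared: {small}")
    summary = counts.agg(["count", "mean", "std"]).rename(
        columns={"count": "n", "std": "sd"}
    )
    pairwise = []
    names = list(summary.index)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            comp = two_sample_t(
                df.loc[df.group == a, "n_voxels"].to_numpy(),
                df.loc[df.group == b, "n_voxels"].to_numpy(),
                measure="n_voxels",
                groups=(a, b),
            )
            pairwise.append(comp)
    summary.attrs["pairwise"] = pairwise
    return summary
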