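"""Manifests, configuration, and the end-to-end subject pipeline.

A study run is: subject manifest (TSV) + run configuration (YAML) ->
per-subject ROI segmentation, alpha calibration and pulsation series ->
results table -> group statistics, with a provenance record (config hash,
seeds, version) sufficient to reproduce the outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import AcquisitionProtocol, interslice_interval
from .bloch import TissueParams, calibrate_alpha
from .metric import (
    DEFAULT_N_DISCARD,
    SliceSignals,
    compute_csfpulse_series,
    temporal_highpass,
)
from .roi import BoundingBox, ThresholdPolicy, segment_csf_roi, voxel_volume
from .stats import (
    anova_bonferroni,
    bootstrap_pairwise,
    fisher_exact_2x2,
    residualize_age,
    two_sample_t,
)

__all__ = [
    "RunConfig",
    "ManifestError",
    "PipelineError",
    "read_manifest",
    "process_subject",
    "run_pipeline",
]

log = logging.getLogger("csfpulse")

REQUIRED_COLUMNS = ("subject_id", "image_path", "group", "lower_slice", "bbox")


class ManifestError(ValueError):
    """Raised for structurally invalid subject manifests."""


class PipelineError(RuntimeError):
    """Raised after the run when one or more subjects failed a stage."""


@dataclass(frozen=True)
class RoiConfig:
    threshold_kind: str = "otsu"
    threshold_value: float = 90.0
    #: "total" = n_voxels * voxel volume of the upper target slice;
    #: "per_voxel" = a single voxel's volume (the literal reading).
    roi_volume_mode: str = "total"

    def __post_init__(self) -> None:
        if self.roi_volume_mode not in ("total", "per_voxel"):
            raise ValueError(f"unknown roi_volume_mode {self.roi_volume_mode!r}")


@dataclass(frozen=True)
class MetricConfig:
    n_discard: int = DEFAULT_N_DISCARD
    highpass_hz: float | None = None
    alpha_method: str = "closed_form"


@dataclass(frozen=True)
class StatsConfig:
    bootstrap_B: int = 10_000
    seed: int = 1
    equal_var: bool = True


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a pipeline run, loadable from a YAML file."""

    protocol: AcquisitionProtocol = AcquisitionProtocol()
    tissue: TissueParams = TissueParams()
    roi: RoiConfig = RoiConfig()
    metric: MetricConfig = MetricConfig()
    stats: StatsConfig = StatsConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            protocol=AcquisitionProtocol(**raw.get("acquisition", {})),
            tissue=TissueParams(**raw.get("tissue", {})),
            roi=RoiConfig(**raw.get("roi", {})),
            metric=MetricConfig(**raw.get("metric", {})),
            stats=StatsConfig(**raw.get("stats", {})),
        )

    def to_dict(self) -> dict:
        return {
            "acquisition": dataclasses.asdict(self.protocol),
            "tissue": dataclasses.asdict(self.tissue),
            "roi": dataclasses.asdict(self.roi),
            "metric": dataclasses.asdict(self.metric),
            "stats": dataclasses.asdict(self.stats),
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def read_manifest(
    path: str | Path, protocol: AcquisitionProtocol | None = None
) -> pd.DataFrame:
    """Load and validate a subject manifest TSV.

    Required columns: subject_id, image_path, group, lower_slice, bbox.
    Collects all offending rows into one descriptive error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing required column(s): {missing}")
    if df.empty:
        raise ManifestError("manifest contains no subjects")
    problems: list[str] = []
    dup = df.subject_id[df.subject_id.duplicated()].unique().tolist()
    if dup:
        problems.append(f"duplicate subject_id(s): {dup}")
    for line, row in df.iterrows():
        try:
            BoundingBox.parse(str(row.bbox))
        except (ValueError, TypeError) as exc:
            problems.append(f"row {line}: unparseable bbox {row.bbox!r} ({exc})")
        try:
            lower = int(row.lower_slice)
        except (ValueError, TypeError):
            problems.append(f"row {line}: lower_slice {row.lower_slice!r} not an int")
            continue
        if protocol is not None and not 1 <= lower < protocol.n_slices:
            problems.append(
                f"row {line}: lower_slice {lower} outside 1.."
                f"{protocol.n_slices - 1} (slice {protocol.n_slices} has no "
                "adjacent upper slice)"
            )
    if problems:
        raise ManifestError("invalid manifest:\n  " + "\n  ".join(problems))
    return df


def process_subject(row: pd.Series, config: RunConfig) -> dict:
    """Run one subject: load image, discard frames, ROI, alpha, metric.

    ``row`` is a manifest row; returns the subject's results record.
    """
    p = config.protocol
    img = nib.load(str(row.image_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{row.image_path}: expected a 4D image, got {data.ndim}D")
    if data.shape[2] != p.n_slices:
        raise ValueError(
            f"{row.image_path}: {data.shape[2]} slices on the third axis, "
            f"protocol says {p.n_slices}"
        )
    lower = int(row.lower_slice)
    pair = interslice_interval(p, lower)
    bbox = BoundingBox.parse(str(row.bbox))
    policy = ThresholdPolicy(config.roi.threshold_kind, config.roi.threshold_value)
    n_discard = config.metric.n_discard
    vv = voxel_volume(p)

    retained = data[:, :, :, n_discard:]
    rois = {}
    for idx in (lower, lower + 1):
        mean_img = retained[:, :, idx - 1, :].mean(axis=-1)
        rois[idx] = segment_csf_roi(
            mean_img, bbox, policy, slice_idx=idx, voxel_volume_mm3=vv
        )
    signals = {
        idx: data[:, :, idx - 1, :][rois[idx].mask].mean(axis=0)
        for idx in (lower, lower + 1)
    }
    if config.metric.highpass_hz is not None:
        signals = {
            idx: temporal_highpass(s, config.metric.highpass_hz, p.tr_ms)
            for idx, s in signals.items()
        }
    cal = calibrate_alpha(p, config.tissue, pair, method=config.metric.alpha_method)
    upper_roi = rois[lower + 1]
    roi_volume = (
        upper_roi.roi_volume_mm3 if config.roi.roi_volume_mode == "total" else vv
    )
    series = compute_csfpulse_series(
        SliceSignals(
            s_lower=signals[lower], s_upper=signals[lower + 1], n_discard=n_discard
        ),
        cal,
        roi_volume,
    )
    return {
        "subject_id": row.subject_id,
        "group": row.get("group", ""),
        "lower_slice": lower,
        "inter_tr_ms": pair.inter_tr_ms,
        "alpha": cal.alpha,
        "n_voxels": upper_roi.n_voxels,
        "roi_volume_mm3": roi_volume,
        "mean_pulse": series.mean_pulse,
        "abs_z_mean": series.abs_z_mean if series.abs_z_mean is not None else np.nan,
        "positive_ratio": series.positive_ratio,
        "series": series,
    }


def _group_statistics(results: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """All-pairs group comparisons of the derived measures."""
    comparisons = []
    names = [g for g, sub in results.groupby("group") if len(sub) >= 2]
    measures = ["mean_pulse", "abs_z_mean", "positive_ratio", "n_voxels"]
    if "age" in results.columns and results["age"].notna().all():
        results = results.copy()
        results["mean_pulse_age_adj"] = residualize_age(results, "mean_pulse")
        measures.append("mean_pulse_age_adj")
    for measure in measures:
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                xa = results.loc[results.group == a, measure].dropna().to_numpy()
                xb = results.loc[results.group == b, measure].dropna().to_numpy()
                if xa.size < 2 or xb.size < 2:
                    continue
                comparisons.append(
                    two_sample_t(
                        xa, xb, equal_var=config.stats.equal_var,
                        measure=measure, groups=(a, b),
                    )
                )
                comparisons.append(
                    bootstrap_pairwise(
                        xa, xb, B=config.stats.bootstrap_B,
                        seed=config.stats.seed, measure=measure, groups=(a, b),
                    )
                )
        if len(names) >= 3:
            samples = {
                g: results.loc[results.group == g, measure].dropna().to_numpy()
                for g in names
            }
            if all(s.size >= 2 for s in samples.values()):
                omnibus, pairwise = anova_bonferroni(samples, measure=measure)
                comparisons.extend([omnibus, *pairwise])
    if "gender" in results.columns:
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                table = [
                    [
                        int((results.gender[results.group == g] == "M").sum()),
                        int((results.gender[results.group == g] == "F").sum()),
                    ]
                    for g in (a, b)
                ]
                comparisons.append(fisher_exact_2x2(table, groups=(a, b)))
    return pd.DataFrame([dataclasses.asdict(c) for c in comparisons])


def run_pipeline(
    config: RunConfig, manifest: pd.DataFrame, out_dir: str | Path
) -> pd.DataFrame:
    """Process every manifest subject, write results, run group statistics.

    Per-subject failures are logged and collected; remaining subjects still
    run, outputs are written, and a :class:`PipelineError` summarising the
    failures is raised at the end (the CLI maps it to a nonzero exit).
    """
    if manifest.empty:
        raise ManifestError("manifest contains no subjects")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, failures = [], []
    demo_cols = [
        c for c in ("age", "gender", "education", "mmse", "duration", "updrs")
        if c in manifest.columns
    ]
    for _, row in manifest.iterrows():
        t0 = time.perf_counter()
        try:
            rec = process_subject(row, config)
        except Exception as exc:  # noqa: BLE001 - reported per subject
            log.error("subject %s failed: %s", row.subject_id, exc)
            failures.append((str(row.subject_id), str(exc)))
            continue
        series = rec.pop("series")
        pd.DataFrame(
            {"raw": series.raw, "clamped": series.clamped}
        ).to_csv(out_dir / f"{row.subject_id}_series.csv", index=False)
        for c in demo_cols:
            rec[c] = row[c]
        rows.append(rec)
        log.info(
            "subject %s: %d ROI voxels, mean pulse %.3f (%.2f s)",
            row.subject_id, rec["n_voxels"], rec["mean_pulse"],
            time.perf_counter() - t0,
        )
    results = pd.DataFrame(rows)
    results.to_csv(out_dir / "results.tsv", sep="\t", index=False)
    if not results.empty and results.group.nunique() >= 2:
        comparisons = _group_statistics(results, config)
        comparisons.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
    provenance = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stats_seed": config.stats.seed,
        "n_subjects": int(len(manifest)),
        "n_failed": len(failures),
        "failures": failures,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    if failures:
        raise PipelineError(
            f"{len(failures)} subject(s) failed: "
            + "; ".join(f"{s} ({e})" for s, e in failures)
        )
    return results
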