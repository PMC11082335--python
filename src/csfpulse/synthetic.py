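"""Synthetic 4D EPI phantoms and study cohorts with known pulsation.

The phantom is a tissue-background volume containing a bright CSF tube (the
4th ventricle) spanning several slices.  Each in-tube slice's signal
follows the interslice flow-saturation forward model: a programmable
velocity waveform, evaluated at that slice's excitation instant, sets the
exchanged-volume fraction through the capture response, and the fraction
sets the paired-slice signal ratio.  The bottom tube slice has no moving
CSF below it and stays at the static steady state, which makes it the
unmodulated reference slice the pulsation estimator assumes.

The cohort generator reproduces the study's group structure (healthy
controls and Parkinson's-disease dementia low-/high-risk groups, n =
17/16/19) with demographics drawn from the published group moments, and
maps each subject's target mean pulsation to a waveform amplitude by
inverting the expected clamped estimator output under the generator's own
noise model.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .acquisition import (
    AcquisitionProtocol,
    acquisition_slot,
    interslice_interval,
)
from .bloch import (
    TissueParams,
    calibrate_alpha,
    capture_fraction,
    pair_signal_ratio,
    steady_state_signal,
)
from .metric import DEFAULT_N_DISCARD, SliceSignals, compute_csfpulse_series
from .roi import voxel_volume

__all__ = [
    "VelocityWaveform",
    "VentricleGeometry",
    "PhantomSpec",
    "GroupSpec",
    "CohortSpec",
    "SpecError",
    "generate_phantom",
    "simulate_pair_signals",
    "generate_cohort",
    "default_cohort_spec",
]


class SpecError(ValueError):
    """Raised for infeasible or inconsistent synthetic-data specifications."""


@dataclass(frozen=True)
class VelocityWaveform:
    """Through-plane CSF velocity as a function of time.

    Kinds: ``constant`` (v0), ``sinusoid`` (v0 + A sin(2 pi f t + phase)),
    ``sinusoid_plus_jitter`` (adds Gaussian jitter of SD ``jitter_sd``).
    Positive velocity is ascending (toward higher slice index).  The
    default frequency, 1.05 Hz, is cardiac-like and is aliased by the 2 s
    TR to a slow 0.05 Hz apparent oscillation, as in real sampling.
    """

    kind: str = "sinusoid"
    v0_mm_s: float = 0.0
    amplitude_mm_s: float = 0.0
    freq_hz: float = 1.05
    phase: float = 0.0
    jitter_sd_mm_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoid", "sinusoid_plus_jitter"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")

    def evaluate(self, t_s, rng: np.random.Generator | None = None) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        if self.kind == "constant":
            v = np.full(t.shape, self.v0_mm_s)
        else:
            v = self.v0_mm_s + self.amplitude_mm_s * np.sin(
                2.0 * math.pi * self.freq_hz * t + self.phase
            )
            if self.kind == "sinusoid_plus_jitter":
                if rng is None:
                    raise ValueError("jittered waveform needs an RNG")
                v = v + rng.normal(0.0, self.jitter_sd_mm_s, size=t.shape)
        if not np.all(np.isfinite(v)):
            raise ValueError("waveform produced non-finite velocities")
        return v


@dataclass(frozen=True)
class VentricleGeometry:
    """Bright CSF tube: in-plane center/extent and the slice span it covers.

    If ``n_voxels`` is given the cross-section is the ``n_voxels`` in-plane
    voxels nearest the center (exact count, deterministic tie-break);
    otherwise all voxels within ``radius_vox`` of the center.
    """

    center_xy: tuple[int, int] = (40, 40)
    radius_vox: float = 2.0
    slice_span: tuple[int, int] = (8, 11)  # 1-based inclusive
    n_voxels: int | None = None

    def __post_init__(self) -> None:
        if self.slice_span[1] < self.slice_span[0]:
            raise ValueError("slice_span must be (low, high) with low <= high")
        if self.radius_vox < 1 and self.n_voxels is None:
            raise ValueError("radius_vox must be >= 1 voxel")
        if self.n_voxels is not None and self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")

    def cross_section(self, shape_xy: tuple[int, int]) -> np.ndarray:
        nx, ny = shape_xy
        xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        d2 = (xx - self.center_xy[0]) ** 2 + (yy - self.center_xy[1]) ** 2
        mask = np.zeros((nx, ny), dtype=bool)
        if self.n_voxels is None:
            mask[d2 <= self.radius_vox**2] = True
        else:
            flat = np.lexsort((yy.ravel(), xx.ravel(), d2.ravel()))
            mask.ravel()[flat[: self.n_voxels]] = True
        if not mask.any():
            raise SpecError("ventricle cross-section contains no voxels")
        return mask

    def suggested_bbox(self, shape_xy: tuple[int, int], pad: int = 4) -> str:
        cx, cy = self.center_xy
        x0, y0 = max(cx - pad, 0), max(cy - pad, 0)
        x1 = min(cx + pad, shape_xy[0] - 1)
        y1 = min(cy + pad, shape_xy[1] - 1)
        return f"{x0},{y0},{x1},{y1}"


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to synthesise one subject's 4D EPI series."""

    protocol: AcquisitionProtocol = AcquisitionProtocol()
    ventricle: VentricleGeometry = VentricleGeometry()
    tissue: TissueParams = TissueParams()
    waveform: VelocityWaveform = VelocityWaveform()
    background_level: float = 0.12  # tissue intensity relative to CSF m0
    noise_sd: float = 0.0  # additive Gaussian SD relative to CSF steady signal
    seed: int = 0
    shape_xy: tuple[int, int] = (80, 80)
    target_lower_slice: int = 8
    dtype: str = "float64"  # stored NIfTI dtype; float64 keeps ratios exact

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.ventricle.slice_span
        if not (lo <= self.target_lower_slice and self.target_lower_slice + 1 <= hi):
            raise SpecError(
                f"target pair ({self.target_lower_slice}, "
                f"{self.target_lower_slice + 1}) outside ventricle span {lo}..{hi}"
            )
        if hi > self.protocol.n_slices:
            raise SpecError("ventricle span exceeds the slice count")


def _excitation_times_s(protocol: AcquisitionProtocol, slice_idx: int) -> np.ndarray:
    """Excitation instants of one slice across all measurements, seconds."""
    slot = acquisition_slot(protocol, slice_idx)
    offsets = (slot - 1) * protocol.slot_duration_ms
    n = np.arange(protocol.n_measurements)
    return (n * protocol.tr_ms + offsets) / 1000.0


def generate_phantom(spec: PhantomSpec) -> tuple[nib.Nifti1Image, dict]:
    """Synthesise a 4D phantom and its ground-truth record.

    Returns a NIfTI-1 image of shape ``(nx, ny, n_slices, n_measurements)``
    (float32, voxel sizes from the protocol) and a truth dict holding the
    target pair's per-measurement velocity, exchanged fraction and pulsed
    volume, plus the geometry and calibration that generated them.
    Deterministic for a fixed seed.
    """
    p = spec.protocol
    rng = np.random.default_rng(spec.seed)
    s_static = steady_state_signal(spec.tissue, p.tr_ms)
    cross = spec.ventricle.cross_section(spec.shape_xy)
    k = int(cross.sum())
    vv = voxel_volume(p)

    data = np.full(
        (*spec.shape_xy, p.n_slices, p.n_measurements),
        spec.background_level * spec.tissue.m0,
        dtype=np.float64,
    )
    lo, hi = spec.ventricle.slice_span
    truth_slices: dict[int, dict] = {}
    for j in range(lo, hi + 1):
        t_j = _excitation_times_s(p, j)
        if j == lo:
            sig = np.full(p.n_measurements, s_static)
            truth_slices[j] = {"fraction": np.zeros(p.n_measurements)}
        else:
            pair_j = interslice_interval(p, j - 1)
            alpha_j = calibrate_alpha(p, spec.tissue, pair_j).alpha
            v_j = spec.waveform.evaluate(t_j, rng)
            f_j = capture_fraction(v_j, pair_j, p)
            sig = s_static * pair_signal_ratio(f_j, alpha_j)
            truth_slices[j] = {
                "velocity_mm_s": v_j,
                "fraction": f_j,
                "alpha": alpha_j,
                "inter_tr_ms": pair_j.inter_tr_ms,
            }
        data[cross, j - 1, :] = sig[None, :]
    if spec.noise_sd > 0:
        data += rng.normal(
            0.0, spec.noise_sd * s_static * spec.tissue.m0, size=data.shape
        )

    res = p.inplane_res_mm
    affine = np.diag([res, res, p.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(data.astype(np.dtype(spec.dtype)), affine)
    img.header.set_zooms((res, res, p.slice_thickness_mm, p.tr_ms / 1000.0))

    upper = spec.target_lower_slice + 1
    tgt = truth_slices[upper]
    roi_volume = k * vv
    truth = {
        "target_lower_slice": spec.target_lower_slice,
        "target_upper_slice": upper,
        "inter_tr_ms": tgt["inter_tr_ms"],
        "alpha": tgt["alpha"],
        "n_voxels_cross_section": k,
        "voxel_volume_mm3": vv,
        "roi_volume_mm3": roi_volume,
        "velocity_mm_s": tgt["velocity_mm_s"].tolist(),
        "fraction": tgt["fraction"].tolist(),
        "pulsed_volume_mm3": (tgt["fraction"] * roi_volume).tolist(),
        "background_level": spec.background_level,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "suggested_bbox": spec.ventricle.suggested_bbox(spec.shape_xy),
        "waveform": dataclasses.asdict(spec.waveform),
    }
    return img, truth


def simulate_pair_signals(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[SliceSignals, dict]:
    """Signal-level shortcut: the target pair's ROI-mean series only.

    Produces the same forward model as :func:`generate_phantom` for the
    target pair, with ROI-mean noise (voxel noise attenuated by the square
    root of the cross-section count) instead of a full 4D volume.
    """
    p = spec.protocol
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    s_static = steady_state_signal(spec.tissue, p.tr_ms)
    k = int(spec.ventricle.cross_section(spec.shape_xy).sum())
    pair = interslice_interval(p, spec.target_lower_slice)
    alpha = calibrate_alpha(p, spec.tissue, pair).alpha
    t = _excitation_times_s(p, pair.upper_slice)
    v = spec.waveform.evaluate(t, rng)
    f = capture_fraction(v, pair, p)
    s_upper = s_static * pair_signal_ratio(f, alpha)
    s_lower = np.full(p.n_measurements, s_static)
    if spec.noise_sd > 0:
        sd = spec.noise_sd * s_static * spec.tissue.m0 / math.sqrt(k)
        s_lower = s_lower + rng.normal(0.0, sd, p.n_measurements)
        s_upper = s_upper + rng.normal(0.0, sd, p.n_measurements)
    roi_volume = k * voxel_volume(p)
    truth = {
        "alpha": alpha,
        "n_voxels": k,
        "roi_volume_mm3": roi_volume,
        "fraction": f,
        "pulsed_volume_mm3": f * roi_volume,
    }
    return SliceSignals(s_lower=s_lower, s_upper=s_upper), truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One study group's size, demographic moments and pulsation target.

    ``pulse_se`` is the standard error of the group mean pulsation (the
    form the study tables report); the per-subject SD is
    ``pulse_se * sqrt(n)``.  ``roi_sd`` is a cross-subject SD of the ROI
    voxel count.  Missing instruments (e.g. MMSE for controls) are None.
    """

    name: str
    n: int
    age_mean: float
    age_sd: float
    n_male: int
    n_female: int
    education_mean: float
    education_sd: float
    pulse_mean: float
    pulse_se: float
    roi_mean: float
    roi_sd: float
    mmse_mean: float | None = None
    mmse_sd: float | None = None
    duration_mean: float | None = None
    duration_sd: float | None = None
    updrs_mean: float | None = None
    updrs_sd: float | None = None
    n_updrs: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.n_male + self.n_female != self.n:
            raise ValueError(
                f"gender counts {self.n_male}+{self.n_female} != n={self.n}"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generation settings shared by all groups."""

    groups: tuple[GroupSpec, ...]
    seed: int = 0
    protocol: AcquisitionProtocol = AcquisitionProtocol()
    tissue: TissueParams = TissueParams()
    target_lower_slice: int = 8
    ventricle_span: tuple[int, int] = (8, 11)
    noise_sd: float = 0.01
    shape_xy: tuple[int, int] = (80, 80)
    waveform_kind: str = "sinusoid"
    freq_hz: float = 1.05

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The study's cohort: HC / PDD-L / PDD-H group structure and moments."""
    hc = GroupSpec(
        name="HC", n=17, age_mean=72.3, age_sd=7.4, n_male=10, n_female=7,
        education_mean=10.1, education_sd=3.4,
        pulse_mean=6.6, pulse_se=0.86, roi_mean=6.2, roi_sd=3.9,
    )
    pddl = GroupSpec(
        name="PDD-L", n=16, age_mean=69.2, age_sd=9.3, n_male=11, n_female=5,
        education_mean=8.3, education_sd=5.4,
        pulse_mean=11.9, pulse_se=2.2, roi_mean=10.1, roi_sd=4.3,
        mmse_mean=26.1, mmse_sd=4.0, duration_mean=11.8, duration_sd=8.5,
        updrs_mean=29.4, updrs_sd=6.5, n_updrs=11,
    )
    pddh = GroupSpec(
        name="PDD-H", n=19, age_mean=75.3, age_sd=7.7, n_male=13, n_female=6,
        education_mean=7.9, education_sd=5.5,
        pulse_mean=15.6, pulse_se=2.6, roi_mean=9.4, roi_sd=3.7,
        mmse_mean=21.7, mmse_sd=4.0, duration_mean=20.7, duration_sd=16.1,
        updrs_mean=26.5, updrs_sd=8.1, n_updrs=15,
    )
    return CohortSpec(groups=(hc, pddl, pddh), seed=seed)


def _expected_clamped_mean(
    mu: np.ndarray, sigma: float
) -> float:
    """E[max(X, 0)] averaged over measurements, X ~ N(mu_n, sigma)."""
    if sigma <= 0:
        return float(np.mean(np.maximum(mu, 0.0)))
    z = mu / sigma
    return float(np.mean(mu * norm.cdf(z) + sigma * norm.pdf(z)))


def _solve_amplitude(
    target_mean_pulse: float,
    phase: float,
    spec: CohortSpec,
    roi_volume: float,
    k: int,
    alpha: float,
    pair,
    clamp_target: bool = False,
) -> tuple[float, float]:
    """Waveform amplitude whose expected clamped estimator mean hits the target.

    Within the rising branch of the capture response the per-measurement
    mean is linear in the amplitude; the expectation additionally accounts
    for the clamp acting on estimator noise.  Targets outside the feasible
    band (below the clamp's noise floor or above the capture-response
    maximum) raise :class:`SpecError`, or, with ``clamp_target``, are
    truncated to the nearest feasible value.  Returns (amplitude,
    effective target).
    """
    p = spec.protocol
    t = _excitation_times_s(p, pair.upper_slice)[DEFAULT_N_DISCARD:]
    s = np.sin(2.0 * math.pi * spec.freq_hz * t + phase)
    c = pair.inter_tr_ms / 1000.0 / p.slice_thickness_mm  # fraction per mm/s
    # estimator noise SD per measurement, in volume units
    sigma = (
        (1.0 / alpha - 1.0)
        * math.sqrt(2.0)
        * spec.noise_sd
        / math.sqrt(k)
        * roi_volume
    )
    v_fold = p.slice_thickness_mm / (pair.inter_tr_ms / 1000.0)  # mm/s

    def expected(amplitude: float) -> float:
        return _expected_clamped_mean(roi_volume * c * amplitude * s, sigma)

    e_floor, e_max = expected(0.0), expected(v_fold)
    target = target_mean_pulse
    if clamp_target:
        target = float(np.clip(target, e_floor * 1.02 + 1e-9, e_max * 0.98))
    elif target < e_floor:
        raise SpecError(
            f"target mean pulse {target:.3g} below the noise floor of the "
            f"clamped estimator ({e_floor:.3g})"
        )
    elif target > e_max:
        raise SpecError(
            f"target mean pulse {target:.3g} exceeds the capture response "
            f"maximum {e_max:.3g} (amplitude {v_fold:.3g} mm/s)"
        )
    if target <= e_floor:
        return 0.0, target
    return float(brentq(lambda a: expected(a) - target, 0.0, v_fold,
                        xtol=1e-10)), target


def generate_cohort(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
    image_mode: str = "signal",
) -> pd.DataFrame:
    """Draw a full synthetic cohort; returns the subject manifest.

    ``image_mode``:
        * ``"signal"`` — per-subject pair signals are simulated at the ROI
          level and the derived measures (mean_pulse, abs_z_mean,
          positive_ratio) are computed immediately; no images written.
        * ``"nifti"`` — one 4D phantom per subject is written under
          ``out_dir`` and the manifest points at the files (derived
          measures are left to the processing pipeline).
        * ``"none"`` — demographics and generation parameters only.

    Deterministic for a fixed ``spec.seed``.
    """
    if image_mode not in ("signal", "nifti", "none"):
        raise ValueError(f"unknown image_mode {image_mode!r}")
    if image_mode == "nifti" and out_dir is None:
        raise ValueError("image_mode='nifti' requires out_dir")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(spec.seed)
    p = spec.protocol
    pair = interslice_interval(p, spec.target_lower_slice)
    alpha = calibrate_alpha(p, spec.tissue, pair).alpha
    vv = voxel_volume(p)
    rows = []
    sid = 0
    for g in spec.groups:
        genders = np.array(["M"] * g.n_male + ["F"] * g.n_female)
        rng.shuffle(genders)
        updrs_subjects = (
            set(rng.choice(g.n, size=g.n_updrs, replace=False).tolist())
            if g.n_updrs is not None
            else set(range(g.n))
        )
        for i in range(g.n):
            sid += 1
            subject_id = f"sub-{sid:03d}"
            age = rng.normal(g.age_mean, g.age_sd)
            education = max(0.0, rng.normal(g.education_mean, g.education_sd))
            mmse = (
                float(np.clip(rng.normal(g.mmse_mean, g.mmse_sd), 0, 30))
                if g.mmse_mean is not None
                else np.nan
            )
            duration = (
                max(0.0, rng.normal(g.duration_mean, g.duration_sd))
                if g.duration_mean is not None
                else np.nan
            )
            updrs = (
                max(0.0, rng.normal(g.updrs_mean, g.updrs_sd))
                if g.updrs_mean is not None and i in updrs_subjects
                else np.nan
            )
            k = int(max(2, round(rng.normal(g.roi_mean, g.roi_sd))))
            roi_volume = k * vv
            sd_pulse = g.pulse_se * math.sqrt(g.n)
            target_pulse = max(0.0, rng.normal(g.pulse_mean, sd_pulse))
            phase = float(rng.uniform(0.0, 2.0 * math.pi))
            amplitude, target_pulse = _solve_amplitude(
                target_pulse, phase, spec, roi_volume, k, alpha, pair,
                clamp_target=True,
            )
            waveform = VelocityWaveform(
                kind=spec.waveform_kind,
                amplitude_mm_s=amplitude,
                freq_hz=spec.freq_hz,
                phase=phase,
            )
            sub_seed = int(rng.integers(0, 2**31 - 1))
            phantom = PhantomSpec(
                protocol=p,
                ventricle=VentricleGeometry(
                    center_xy=(spec.shape_xy[0] // 2, spec.shape_xy[1] // 2),
                    slice_span=spec.ventricle_span,
                    n_voxels=k,
                ),
                tissue=spec.tissue,
                waveform=waveform,
                noise_sd=spec.noise_sd,
                seed=sub_seed,
                shape_xy=spec.shape_xy,
                target_lower_slice=spec.target_lower_slice,
            )
            row = {
                "subject_id": subject_id,
                "group": g.name,
                "image_path": "",
                "lower_slice": spec.target_lower_slice,
                "bbox": phantom.ventricle.suggested_bbox(spec.shape_xy),
                "age": age,
                "gender": genders[i],
                "education": education,
                "mmse": mmse,
                "duration": duration,
                "updrs": updrs,
                "n_voxels": k,
                "roi_volume_mm3": roi_volume,
                "truth_mean_pulse": target_pulse,
                "waveform_amplitude_mm_s": amplitude,
                "waveform_phase": phase,
                "seed": sub_seed,
            }
            if image_mode == "signal":
                signals, _ = simulate_pair_signals(phantom)
                series = compute_csfpulse_series(signals, alpha, roi_volume)
                row["mean_pulse"] = series.mean_pulse
                row["abs_z_mean"] = (
                    series.abs_z_mean if series.abs_z_mean is not None else np.nan
                )
                row["positive_ratio"] = series.positive_ratio
            elif image_mode == "nifti":
                img, _ = generate_phantom(phantom)
                path = out_dir / f"{subject_id}.nii"
                nib.save(img, str(path))
                row["image_path"] = str(path)
            rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.tsv", sep="\t", index=False)
    return manifest
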