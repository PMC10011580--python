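"""Synthetic multimodal MRI phantoms and longitudinal cohorts.

The phantom generator emulates the statistical structure the segmentation
and endpoint pipelines assume, without any clinical data:

* an ellipsoidal "brain" support inside a 32x96x96 grid at (3, 1, 1) mm
  spacing (skull-stripped background = 0);
* lesions as randomly deformed ellipsoids, non-overlapping and crisp, with
  voxel counts drawn from a log-normal truncated at >= 3 voxels whose
  defaults put ~40% of lesions at <= 10 voxels and ~85% at <= 50 voxels —
  the small-lesion-dominated regime of MS trial cohorts;
* modality contrast in units of the background noise scale: lesions are
  strongly hyperintense on FLAIR (+3 SD) and T2w (+2.5 SD) and mildly
  hypointense on T1p (-1 SD).

The cohort generator produces per-visit total-lesion-volume trajectories
with per-arm multiplicative drift and log-normal noise, plus time-to-event
outcomes from an exponential proportional-hazards model whose linear
predictor depends on log baseline TLV, arm, and covariates — the structure
the ANCOVA / Cox / Kaplan-Meier endpoint analyses assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume_io import CHANNEL_ORDER, LesionMask, MultimodalVolume, VolumeGrid

__all__ = ["PhantomParams", "CohortParams", "generate_subject",
           "sample_lesion_sizes", "generate_cohort"]


@dataclass
class PhantomParams:
    grid: VolumeGrid = field(
        default_factory=lambda: VolumeGrid((32, 96, 96), (3.0, 1.0, 1.0)))
    n_lesions_mean: float = 8.0          # Poisson rate per subject
    size_log_mu: float = float(np.log(12.0))   # log-normal over voxels
    size_log_sigma: float = 1.1
    min_lesion_voxels: int = 3
    contrast: dict = field(default_factory=lambda: {
        "T1p": -1.0, "T2w": 2.5, "FLAIR": 3.0})  # mean shift in SD units
    base_intensity: dict = field(default_factory=lambda: {
        "T1p": 120.0, "T2w": 90.0, "FLAIR": 100.0})
    intensity_scale: float = 10.0        # reference SD for the shifts
    noise_sd: float = 10.0
    max_placement_tries: int = 200


def sample_lesion_sizes(n: int, params: PhantomParams,
                        rng: np.random.Generator) -> np.ndarray:
    """Voxel counts from the truncated log-normal (>= min_lesion_voxels)."""
    sizes = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = np.rint(rng.lognormal(params.size_log_mu,
                                     params.size_log_sigma,
                                     size=2 * (n - filled))).astype(int)
        draw = draw[draw >= params.min_lesion_voxels]
        take = min(len(draw), n - filled)
        sizes[filled:filled + take] = draw[:take]
        filled += take
    return sizes


def _brain_support(grid: VolumeGrid) -> np.ndarray:
    shape = np.array(grid.shape)
    center = (shape - 1) / 2.0
    semi = shape * 0.45
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d = (((zz - center[0]) / semi[0]) ** 2
         + ((yy - center[1]) / semi[1]) ** 2
         + ((xx - center[2]) / semi[2]) ** 2)
    return d <= 1.0


def _lesion_stamp(target_voxels: int, spacing, rng: np.random.Generator):
    """Rasterised deformed ellipsoid with roughly ``target_voxels`` voxels.

    The ellipsoid is near-spherical in mm; semi-axes are divided by the
    voxel spacing, so in-plane extent dominates at (3, 1, 1) mm.
    """
    vox_vol = float(np.prod(spacing))
    r_mm = (3.0 * target_voxels * vox_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    # random anisotropic deformation preserving volume
    f = rng.uniform(0.75, 1.35, size=3)
    f /= np.prod(f) ** (1 / 3)
    semi_vox = np.maximum(r_mm * f / np.asarray(spacing), 0.45)
    ext = np.ceil(semi_vox).astype(int)
    axes = [np.arange(-e, e + 1) for e in ext]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    d = ((zz / semi_vox[0]) ** 2 + (yy / semi_vox[1]) ** 2
         + (xx / semi_vox[2]) ** 2)
    return d <= 1.0


def generate_subject(params: PhantomParams | None = None,
                     seed: int | np.random.Generator = 0,
                     n_lesions: int | None = None):
    """One synthetic subject: (MultimodalVolume, LesionMask).

    Lesions are placed without overlap (one-voxel exclusion margin so the
    declared component count survives 18-connectivity labelling); if
    placement keeps failing after bounded retries the lesion count is
    reduced with a warning.
    """
    import warnings

    params = params or PhantomParams()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    grid = params.grid
    support = _brain_support(grid)
    if n_lesions is None:
        n_lesions = int(rng.poisson(params.n_lesions_mean))
    sizes = sample_lesion_sizes(n_lesions, params, rng)
    mask = np.zeros(grid.shape, dtype=np.uint8)
    blocked = ~support  # lesions plus a margin around them
    placed = 0
    for size in sizes:
        ok = False
        for _ in range(params.max_placement_tries):
            stamp = _lesion_stamp(int(size), grid.spacing_mm, rng)
            ez, ey, ex = [(s - 1) // 2 for s in stamp.shape]
            lo = np.array([ez, ey, ex]) + 1
            hi = np.array(grid.shape) - np.array(stamp.shape) + lo - 1
            if np.any(hi < lo):
                continue
            pos = np.array([rng.integers(l, h + 1)
                            for l, h in zip(lo, hi)])
            sl = tuple(slice(p - o, p - o + s)
                       for p, o, s in zip(pos, [ez, ey, ex], stamp.shape))
            region_blocked = blocked[sl]
            if (stamp & region_blocked).any():
                continue
            if stamp.sum() < params.min_lesion_voxels:
                continue
            mask[sl][stamp] = 1
            # margin: block a one-voxel-dilated box around the stamp
            msl = tuple(slice(max(s.start - 1, 0), s.stop + 1) for s in sl)
            blocked[msl] = True
            ok = True
            placed += 1
            break
        if not ok:
            warnings.warn(
                f"could not place a {size}-voxel lesion; reducing count "
                f"from {n_lesions} to {placed}")
    channels = {}
    for name in CHANNEL_ORDER:
        base = params.base_intensity[name]
        shift = params.contrast[name] * params.intensity_scale
        img = np.where(support, base, 0.0)
        img = img + shift * mask
        if params.noise_sd > 0:
            img = img + np.where(support,
                                 rng.normal(0, params.noise_sd, grid.shape),
                                 0.0)
        channels[name] = np.where(support, img, 0.0).astype(np.float32)
    return MultimodalVolume(grid, channels), LesionMask(grid, mask)


@dataclass
class CohortParams:
    n_patients: int = 200
    arm_ratio: float = 0.5               # fraction assigned to treatment
    visit_weeks: tuple[int, ...] = (0, 24, 48, 120)
    baseline_tlv_log_mu: float = float(np.log(6.0))   # mL; mean ~ 10 mL
    baseline_tlv_log_sigma: float = 1.0
    drift_treatment_per_week: float = -0.00025  # ~ -3% at week 120
    drift_control_per_week: float = 0.00085     # ~ +11% at week 120
    visit_noise_log_sd: float = 0.05
    hazard_log_tlv: float = float(np.log(1.2))  # per unit log TLV (mL)
    hazard_arm: float = float(np.log(0.8))      # treatment effect
    baseline_hazard_per_week: float = 0.0012    # ~ 14% events by week 120
    followup_weeks: float = 120.0
    age_mean: float = 44.0
    age_sd: float = 8.0
    p_male: float = 0.5
    p_region_us: float = 0.3
    p_edss_high: float = 0.35


def generate_cohort(params: CohortParams | None = None,
                    seed: int | np.random.Generator = 0):
    """Synthetic longitudinal cohort.

    Returns ``(visits, patients)`` DataFrames: per-visit rows
    (patient_id, arm, week, tlv_uL) and per-patient rows with baseline TLV,
    covariates and (time_weeks, event) from the exponential
    proportional-hazards model.
    """
    params = params or CohortParams()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = params.n_patients
    n_treat = int(round(n * params.arm_ratio))
    arms = np.array(["treatment"] * n_treat + ["control"] * (n - n_treat))
    rng.shuffle(arms)
    baseline_ml = rng.lognormal(params.baseline_tlv_log_mu,
                                params.baseline_tlv_log_sigma, n)
    age = rng.normal(params.age_mean, params.age_sd, n)
    male = rng.random(n) < params.p_male
    region_us = rng.random(n) < params.p_region_us
    edss_high = rng.random(n) < params.p_edss_high

    visit_rows = []
    for i in range(n):
        drift = (params.drift_treatment_per_week if arms[i] == "treatment"
                 else params.drift_control_per_week)
        for w in params.visit_weeks:
            tlv = baseline_ml[i] * (1.0 + drift) ** w
            if w > 0 and params.visit_noise_log_sd > 0:
                tlv *= np.exp(rng.normal(0, params.visit_noise_log_sd))
            visit_rows.append((f"P{i:04d}", arms[i], int(w), tlv * 1000.0))
    visits = pd.DataFrame(visit_rows,
                          columns=["patient_id", "arm", "week", "tlv_uL"])

    # exponential PH event times
    eta = (params.hazard_log_tlv * np.log(baseline_ml)
           + params.hazard_arm * (arms == "treatment"))
    lam = params.baseline_hazard_per_week * np.exp(eta)
    raw_t = rng.exponential(1.0 / np.maximum(lam, 1e-12))
    event = raw_t <= params.followup_weeks
    time = np.minimum(raw_t, params.followup_weeks)
    patients = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "arm": arms,
        "baseline_tlv_mL": baseline_ml,
        "baseline_tlv_uL": baseline_ml * 1000.0,
        "age": age,
        "sex": np.where(male, "M", "F"),
        "region": np.where(region_us, "US", "ROW"),
        "edss_group": np.where(edss_high, ">=4", "<4"),
        "time_weeks": np.maximum(time, 1e-6),
        "event": event.astype(int),
    })
    return visits, patients
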