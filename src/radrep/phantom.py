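"""Synthetic PET cohort simulation with dual half-count reconstruction.

The simulation stands in for clinical list-mode acquisition: an activity map
(brain-like uniform background plus a textured spherical tumor) is PSF-blurred,
converted to expected counts, Poisson-sampled, and the detected events are
split into two statistically independent halves, each reconstructed back to an
image.  The two halves form a test/retest pair of the same subject.

Event splitting uses per-event Bernoulli(1/2) thinning, which for Poisson
counts yields *exactly* independent Poisson halves with half the mean — the
statistical idealization of splitting a list-mode stream by alternating time
stamps.  A deterministic alternating split is available for sensitivity
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import GridImage, gaussian_smooth_mm

__all__ = [
    "PhantomSpec",
    "GroupSpec",
    "CohortSpec",
    "CohortSubject",
    "FrameSchedule",
    "default_frame_schedule",
    "make_phantom",
    "simulate_counts",
    "split_events",
    "reconstruct_image",
    "simulate_pair",
    "simulate_cohort",
    "radius_for_volume_ml",
    "volume_ml_for_radius",
]


# --------------------------------------------------------------------------- specs
@dataclass
class PhantomSpec:
    """Geometry and uptake parameters for a single-subject phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_uptake: float = 1.0
    tumor_center: tuple[float, float, float] = (88.0, 63.0, 63.0)
    tumor_radius: float = 14.0
    tbr_contrast: float = 2.0
    texture_scale: float = 6.0
    texture_amplitude: float = 0.2
    psf_fwhm: float = 4.0
    exposure: float = 500.0

    def validate(self) -> None:
        if self.background_uptake <= 0:
            raise ValueError("background_uptake must be > 0")
        if self.tbr_contrast <= 1:
            raise ValueError("tbr_contrast must be > 1 for a detectable tumor")
        if not (0 <= self.texture_amplitude < 1):
            raise ValueError("texture_amplitude must be in [0, 1)")
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.tumor_radius <= 0:
            raise ValueError("tumor_radius must be > 0")
        if self.exposure <= 0:
            raise ValueError("exposure must be > 0")
        extent = [self.spacing[ax] * (self.shape[ax] - 1) for ax in range(3)]
        for ax in range(3):
            c = self.tumor_center[ax]
            if c - self.tumor_radius < 0 or c + self.tumor_radius > extent[ax]:
                raise ValueError(
                    f"tumor sphere (center {self.tumor_center}, radius {self.tumor_radius}) "
                    f"does not fit inside the grid along axis {ax}"
                )


@dataclass
class GroupSpec:
    """Per-genotype-group distribution of tumor volume and texture."""

    label: str
    n_subjects: int
    volume_mean_ml: float = 14.0
    volume_sd_ml: float = 4.0
    volume_range_ml: tuple[float, float] = (1.4, 33.0)
    texture_amplitude: float = 0.2
    texture_scale: float = 6.0
    tbr_contrast: float = 2.0


@dataclass
class CohortSpec:
    """A two-group (or more) synthetic cohort definition."""

    groups: list[GroupSpec] = field(
        default_factory=lambda: [
            GroupSpec("wildtype", 30, volume_mean_ml=21.4, texture_amplitude=0.15),
            GroupSpec("mutant", 20, volume_mean_ml=16.7, texture_amplitude=0.35),
        ]
    )
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_uptake: float = 1.0
    psf_fwhm: float = 4.0
    exposure: float = 500.0
    post_smoothing_fwhm: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        for g in self.groups:
            if g.n_subjects < 2:
                raise ValueError(
                    f"group {g.label!r} has n={g.n_subjects} < 2; the ICC needs at least two subjects"
                )
            if g.volume_mean_ml <= 0:
                raise ValueError("tumor volumes must be positive")


@dataclass
class CohortSubject:
    """One simulated subject: reconstructed test/retest pair plus truth."""

    subject_id: str
    genotype: str
    true_volume_ml: float
    test: GridImage
    retest: GridImage
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if not self.test.same_grid(self.retest):
            raise ValueError("test and retest images must share one grid")


# ------------------------------------------------------------------ frame schedule
@dataclass(frozen=True)
class FrameSchedule:
    """Dynamic acquisition frame durations in minutes."""

    durations_min: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.durations_min):
            raise ValueError("frame durations must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.durations_min)

    @property
    def total_minutes(self) -> float:
        return float(sum(self.durations_min))

    def window(self, start_min: float, stop_min: float) -> tuple[int, int]:
        """Frame index range [i, j) fully covering [start, stop] minutes."""
        edges = np.concatenate([[0.0], np.cumsum(self.durations_min)])
        if start_min < 0 or stop_min > edges[-1] or start_min >= stop_min:
            raise ValueError("window outside the acquisition")
        i = int(np.searchsorted(edges, start_min, side="right") - 1)
        j = int(np.searchsorted(edges, stop_min, side="left"))
        return i, j


def default_frame_schedule() -> FrameSchedule:
    """The default 16-frame dynamic schedule: 5 x 1 min, 5 x 3 min, 6 x 5 min."""
    return FrameSchedule(tuple([1.0] * 5 + [3.0] * 5 + [5.0] * 6))


# ------------------------------------------------------------------ helpers
def radius_for_volume_ml(volume_ml: float) -> float:
    """Sphere radius (mm) with the given volume in mL."""
    return float((3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def volume_ml_for_radius(radius_mm: float) -> float:
    """Sphere volume (mL) for the given radius in mm."""
    return float(4.0 / 3.0 * np.pi * radius_mm**3 / 1000.0)


def _sphere_mask(shape, spacing, center, radius) -> np.ndarray:
    axes = [spacing[ax] * np.arange(shape[ax]) - center[ax] for ax in range(3)]
    d2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    return d2 <= radius**2


# ------------------------------------------------------------------ operations
def make_phantom(spec: PhantomSpec, seed: int) -> GridImage:
    """Build the noiseless activity map for one subject.

    Background voxels carry ``background_uptake``; tumor voxels carry
    ``tbr_contrast * background_uptake`` modulated by a smooth multiplicative
    random texture field (Gaussian-smoothed white noise with correlation
    length ``texture_scale`` mm, renormalized to unit standard deviation and
    scaled by ``texture_amplitude``).  The final map is blurred with a
    Gaussian PSF of ``psf_fwhm`` mm.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    values = np.full(spec.shape, float(spec.background_uptake))
    tumor = _sphere_mask(spec.shape, spec.spacing, spec.tumor_center, spec.tumor_radius)
    if not tumor.any():
        raise ValueError("tumor sphere contains no voxel")

    modulation = np.ones(spec.shape)
    if spec.texture_amplitude > 0:
        from scipy import ndimage

        noise = rng.standard_normal(spec.shape)
        sigma_vox = [spec.texture_scale / s for s in spec.spacing]
        smooth = ndimage.gaussian_filter(noise, sigma_vox, mode="wrap")
        sd = smooth.std()
        if sd > 0:
            smooth /= sd
        modulation = 1.0 + spec.texture_amplitude * smooth

    values[tumor] = spec.tbr_contrast * spec.background_uptake * modulation[tumor]
    if (values < 0).any():
        warnings.warn("texture modulation produced negative uptake; clipping to 0")
        np.clip(values, 0.0, None, out=values)

    image = GridImage(values, spacing=spec.spacing, unit="activity")
    image.meta["tumor_mask_true"] = tumor
    if spec.psf_fwhm > 0:
        blurred = gaussian_smooth_mm(image, spec.psf_fwhm)
        blurred.meta["tumor_mask_true"] = tumor
        return blurred
    return image


def simulate_counts(activity: GridImage, exposure: float, seed: int) -> GridImage:
    """Poisson count realization: counts ~ Poisson(exposure * activity) per voxel."""
    if exposure <= 0:
        raise ValueError("exposure must be > 0")
    vals = np.asarray(activity.values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("activity map contains non-finite values")
    if (vals < 0).any():
        raise ValueError("activity map contains negative values")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(exposure * vals)
    out = activity.with_values(counts, unit="counts")
    out.meta["exposure"] = float(exposure)
    return out


def split_events(counts: GridImage, seed: int, mode: str = "thinning") -> tuple[GridImage, GridImage]:
    """Split detected events into two independent halves.

    ``mode="thinning"`` assigns each event to half A with probability 1/2
    (independent Poisson halves).  ``mode="alternate"`` splits each voxel's
    events deterministically as evenly as possible (sensitivity option).
    Both modes conserve counts exactly: halfA + halfB == counts voxelwise.
    """
    vals = np.asarray(counts.values)
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts image must hold integers")
        vals = np.round(vals).astype(np.int64)
    if (vals < 0).any():
        raise ValueError("counts must be >= 0")

    if mode == "thinning":
        rng = np.random.default_rng(seed)
        half_a = rng.binomial(vals, 0.5)
    elif mode == "alternate":
        half_a = (vals + 1) // 2
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    half_b = vals - half_a
    a = counts.with_values(half_a, unit="counts")
    b = counts.with_values(half_b, unit="counts")
    exposure = counts.meta.get("exposure")
    if exposure is not None:
        a.meta["exposure"] = exposure / 2.0
        b.meta["exposure"] = exposure / 2.0
    return a, b


def reconstruct_image(counts: GridImage, exposure: float, post_smoothing_fwhm: float = 0.0) -> GridImage:
    """Normalize counts back to activity units, with optional Gaussian smoothing.

    Stands in for iterative reconstruction: image = counts / exposure, which
    is unbiased for the (PSF-blurred) activity map.
    """
    if exposure <= 0:
        raise ValueError("exposure must be > 0")
    img = counts.with_values(np.asarray(counts.values, dtype=float) / exposure, unit="activity")
    img.meta.pop("exposure", None)
    if post_smoothing_fwhm > 0:
        img = gaussian_smooth_mm(img, post_smoothing_fwhm)
    return img


def simulate_pair(
    spec: PhantomSpec, seed: int, post_smoothing_fwhm: float = 0.0, split_mode: str = "thinning"
) -> tuple[GridImage, GridImage, GridImage]:
    """Full single-subject path: phantom -> counts -> split -> two reconstructions.

    Returns ``(activity_map, test, retest)``.
    """
    ss = np.random.SeedSequence(seed)
    s_phantom, s_counts, s_split = [int(c.generate_state(1)[0]) for c in ss.spawn(3)]
    activity = make_phantom(spec, s_phantom)
    counts = simulate_counts(activity, spec.exposure, s_counts)
    half_a, half_b = split_events(counts, s_split, mode=split_mode)
    test = reconstruct_image(half_a, spec.exposure / 2.0, post_smoothing_fwhm)
    retest = reconstruct_image(half_b, spec.exposure / 2.0, post_smoothing_fwhm)
    test.meta["tumor_mask_true"] = activity.meta.get("tumor_mask_true")
    return activity, test, retest


def _subject_seed(master_seed: int, index: int) -> int:
    # counter-based: adding subjects never reshuffles earlier ones
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def simulate_cohort(spec: CohortSpec) -> list[CohortSubject]:
    """Simulate every subject of a cohort, deterministically from the master seed."""
    spec.validate()
    subjects: list[CohortSubject] = []
    index = 0
    extent = [spec.spacing[ax] * (spec.shape[ax] - 1) for ax in range(3)]
    # tumor sits off-center along axis 0; background sphere mirrors it (segmentation)
    center = (0.70 * extent[0], 0.5 * extent[1], 0.5 * extent[2])
    for group in spec.groups:
        for _ in range(group.n_subjects):
            seed = _subject_seed(spec.seed, index)
            rng = np.random.default_rng(seed)
            volume = _truncated_normal(
                rng, group.volume_mean_ml, group.volume_sd_ml, *group.volume_range_ml
            )
            pspec = PhantomSpec(
                shape=spec.shape,
                spacing=spec.spacing,
                background_uptake=spec.background_uptake,
                tumor_center=center,
                tumor_radius=radius_for_volume_ml(volume),
                tbr_contrast=group.tbr_contrast,
                texture_scale=group.texture_scale,
                texture_amplitude=group.texture_amplitude,
                psf_fwhm=spec.psf_fwhm,
                exposure=spec.exposure,
            )
            _, test, retest = simulate_pair(
                pspec, _subject_seed(spec.seed, index + 1_000_000), spec.post_smoothing_fwhm
            )
            subjects.append(
                CohortSubject(
                    subject_id=f"sub-{index:03d}",
                    genotype=group.label,
                    true_volume_ml=volume,
                    test=test,
                    retest=retest,
                    spec=pspec,
                )
            )
            index += 1
    return subjects
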