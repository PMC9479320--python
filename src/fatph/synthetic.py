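"""Seeded synthetic HU patch cohorts and small fixtures with known topology.

No public CT dataset accompanies the analysis this package implements, so the
study conditions are emulated by a stationary Gaussian random-field texture
model: each patch is i.i.d. normal noise in Hounsfield units, optionally
smoothed with a Gaussian kernel (periodic boundary, variance renormalized so
the marginal sd is preserved), then clipped to the valid CT range.

Two default groups are provided:

* ``fat`` — mean −110 HU, sd 25 HU, smoothing σ = 2 px.  Almost every pixel
  falls in the adipose window [−190, −30] HU and the field is spatially
  smooth, so thresholded structure forms a few large connected blobs.
* ``nonfat`` — mean −10 HU, sd 45 HU, no smoothing.  Only ~1/3 of pixels fall
  in the window and values are spatially independent, so thresholded
  structure is scattered and fragmented.

Per-patch random streams are derived from ``numpy.random.SeedSequence`` with
spawn key (group, subject, patch), so a cohort is bit-reproducible from its
base seed and individual patches are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, UsageError

HU_MIN = -1024.0
HU_MAX = 3071.0

GROUP_CODES = {"fat": 0, "nonfat": 1}

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "GeneratorConfig",
    "SyntheticCohort",
    "fat_config",
    "nonfat_config",
    "generate_patch",
    "generate_cohort",
    "make_fixture",
    "write_cohort",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic patch generator for one group.

    Parameters
    ----------
    group_label:
        Either ``"fat"`` or ``"nonfat"``; enters the per-patch seed derivation.
    n_subjects:
        Number of subjects in the group (default 8).
    patches_per_subject:
        Patches generated per subject (default 36).
    patch_size:
        Side length of the square patch in pixels (default 32, minimum 4).
    mean_hu, sd_hu:
        Mean and marginal standard deviation of the Gaussian texture, in HU.
    smoothing_sigma:
        Gaussian correlation length in pixels; 0 disables smoothing.
    seed:
        Base seed for the whole group.
    """

    group_label: str
    n_subjects: int = 8
    patches_per_subject: int = 36
    patch_size: int = 32
    mean_hu: float = -110.0
    sd_hu: float = 25.0
    smoothing_sigma: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.group_label not in GROUP_CODES:
            raise ConfigurationError(
                f"group_label must be one of {sorted(GROUP_CODES)}, "
                f"got {self.group_label!r}"
            )
        for name in ("n_subjects", "patches_per_subject"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        if not isinstance(self.patch_size, (int, np.integer)) or self.patch_size < 4:
            raise ConfigurationError(
                f"patch_size must be an integer >= 4, got {self.patch_size!r}"
            )
        for name in ("mean_hu", "sd_hu", "smoothing_sigma"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ConfigurationError(f"{name} must be finite, got {v!r}")
        if self.sd_hu < 0:
            raise ConfigurationError(f"sd_hu must be nonnegative, got {self.sd_hu!r}")
        if self.smoothing_sigma < 0:
            raise ConfigurationError(
                f"smoothing_sigma must be nonnegative, got {self.smoothing_sigma!r}"
            )


def fat_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Default configuration of the epicardial-fat group."""
    return replace(
        GeneratorConfig(group_label="fat", seed=seed),
        **overrides,
    )


def nonfat_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Default configuration of the non-fat group."""
    return replace(
        GeneratorConfig(
            group_label="nonfat",
            mean_hu=-10.0,
            sd_hu=45.0,
            smoothing_sigma=0.0,
            seed=seed,
        ),
        **overrides,
    )


def _patch_seed_sequence(config: GeneratorConfig, subject_id: int, patch_index: int):
    return np.random.SeedSequence(
        entropy=int(config.seed) & 0x7FFFFFFF,
        spawn_key=(GROUP_CODES[config.group_label], int(subject_id), int(patch_index)),
    )


def patch_seed(config: GeneratorConfig, subject_id: int, patch_index: int) -> int:
    """Derived 32-bit seed of a single patch (recorded in cohort manifests)."""
    return int(_patch_seed_sequence(config, subject_id, patch_index).generate_state(1)[0])


def _wrap_attenuation(sigma: float, size: int) -> float:
    """l2 norm of the periodic Gaussian kernel on a size x size grid.

    Smoothing white noise multiplies its sd by this factor; dividing by it
    restores the marginal sd exactly under periodic boundary conditions.
    """
    impulse = np.zeros((size, size))
    impulse[size // 2, size // 2] = 1.0
    kernel = gaussian_filter(impulse, sigma=sigma, mode="wrap")
    return float(np.sqrt(np.sum(kernel**2)))


def generate_patch(
    config: GeneratorConfig, subject_id: int, patch_index: int
) -> np.ndarray:
    """Generate one ``patch_size x patch_size`` HU patch.

    The patch is ``mean_hu`` plus stationary Gaussian texture with marginal sd
    ``sd_hu`` and correlation length ``smoothing_sigma``, clipped to the valid
    CT range [−1024, 3071] HU.  Identical (config, subject, patch) triples
    yield bit-identical arrays.
    """
    config.validate()
    rng = np.random.default_rng(_patch_seed_sequence(config, subject_id, patch_index))
    noise = rng.normal(0.0, config.sd_hu, (config.patch_size, config.patch_size))
    if config.smoothing_sigma > 0 and config.sd_hu > 0:
        noise = gaussian_filter(noise, sigma=config.smoothing_sigma, mode="wrap")
        noise /= _wrap_attenuation(config.smoothing_sigma, config.patch_size)
    patch = config.mean_hu + noise
    return np.clip(patch, HU_MIN, HU_MAX)


@dataclass(frozen=True)
class SyntheticCohort:
    """An ordered collection of (subject_id, patch_index, patch) triples."""

    patches: tuple  # tuple of (subject_id, patch_index, np.ndarray)
    config: GeneratorConfig

    def __post_init__(self):
        expected = self.config.n_subjects * self.config.patches_per_subject
        if len(self.patches) != expected:
            raise ConfigurationError(
                f"cohort has {len(self.patches)} patches, expected {expected}"
            )
        s = self.config.patch_size
        for _, _, patch in self.patches:
            if patch.shape != (s, s):
                raise ConfigurationError(
                    f"patch shape {patch.shape} != ({s}, {s})"
                )

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def subject_ids(self) -> tuple:
        return tuple(sorted({sid for sid, _, _ in self.patches}))

    def subject_patches(self, subject_id: int) -> list:
        """Patches of one subject, in patch-index order."""
        out = [(pi, p) for sid, pi, p in self.patches if sid == subject_id]
        return [p for _, p in sorted(out, key=lambda t: t[0])]


def _build_cohort(config: GeneratorConfig, subject_ids: Sequence[int]) -> SyntheticCohort:
    patches = []
    for sid in subject_ids:
        for pi in range(config.patches_per_subject):
            patches.append((sid, pi, generate_patch(config, sid, pi)))
    return SyntheticCohort(patches=tuple(patches), config=config)


def generate_cohort(
    config_fat: GeneratorConfig,
    config_nonfat: GeneratorConfig,
    subject_ids_fat: Sequence[int] | None = None,
    subject_ids_nonfat: Sequence[int] | None = None,
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Generate the two group cohorts with disjoint subject identifiers.

    Subject ids default to 0..n_fat-1 for the fat group and n_fat..n_fat+n_nonfat-1
    for the non-fat group; explicit id sequences may be passed but must not
    overlap.
    """
    config_fat.validate()
    config_nonfat.validate()
    if config_fat.group_label == config_nonfat.group_label:
        raise ConfigurationError("the two cohorts must have distinct group labels")
    if subject_ids_fat is None:
        subject_ids_fat = range(config_fat.n_subjects)
    if subject_ids_nonfat is None:
        subject_ids_nonfat = range(
            config_fat.n_subjects, config_fat.n_subjects + config_nonfat.n_subjects
        )
    subject_ids_fat = list(subject_ids_fat)
    subject_ids_nonfat = list(subject_ids_nonfat)
    if len(subject_ids_fat) != config_fat.n_subjects:
        raise ConfigurationError("subject_ids_fat length does not match n_subjects")
    if len(subject_ids_nonfat) != config_nonfat.n_subjects:
        raise ConfigurationError("subject_ids_nonfat length does not match n_subjects")
    if set(subject_ids_fat) & set(subject_ids_nonfat):
        raise ConfigurationError("subject id spaces of the two groups overlap")
    return (
        _build_cohort(config_fat, subject_ids_fat),
        _build_cohort(config_nonfat, subject_ids_nonfat),
    )


def make_fixture(name: str):
    """Small analytic fixtures with known homology.

    ``circle``
        20 points evenly spaced on the unit circle (point cloud, one loop).
    ``annulus_image``
        32×32 image whose pixels at radius 6..9 from the center are −100 HU
        and all others +100 HU; the adipose-window mask is a single
        1-connected ring (β0 = 1, β1 = 1).
    ``two_clusters``
        two tight 5-point clusters 10 px apart (β0 = 2 at small scale).
    ``grid``
        the 4 corners of the unit square (one Rips loop born at 1, filled
        at √2).
    """
    if name == "circle":
        theta = 2 * np.pi * np.arange(20) / 20
        return np.column_stack([np.cos(theta), np.sin(theta)])
    if name == "annulus_image":
        n = 32
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - c, yy - c)
        img = np.full((n, n), 100.0)
        img[(r >= 6) & (r <= 9)] = -100.0
        return img
    if name == "two_clusters":
        cross = np.array([(0.0, 0.0), (0.2, 0.0), (-0.2, 0.0), (0.0, 0.2), (0.0, -0.2)])
        return np.vstack([cross, cross + np.array([10.0, 0.0])])
    if name == "grid":
        return np.array([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)])
    raise UsageError(f"unknown fixture {name!r}")


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a cohort as per-patch CSV grids plus a TSV manifest.

    Files follow ``{group}_{subject:02d}_{patch:02d}.csv`` (row-major,
    comma-separated); the manifest records group, subject, patch, path and the
    derived per-patch seed.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, pi, patch in cohort.patches:
        fname = f"{cohort.config.group_label}_{sid:02d}_{pi:02d}.csv"
        np.savetxt(out_dir / fname, patch, fmt="%.10g", delimiter=",")
        rows.append(
            (
                cohort.config.group_label,
                sid,
                pi,
                fname,
                patch_seed(cohort.config, sid, pi),
            )
        )
    manifest = out_dir / f"manifest_{cohort.config.group_label}.tsv"
    with open(manifest, "w") as fh:
        fh.write("group\tsubject\tpatch\tpath\tseed\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return manifest
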