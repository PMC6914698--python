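"""Synthetic two-cohort MRI phantom generation.

Emulates the data layout of a lifespan white-matter study: an "older" cohort
with FLAIR-like anatomical images, diffusion-weighted imaging (DWI) and
ground-truth lesion masks, and a "young" cohort with DWI only. Both cohorts
share one grid (spatial normalization is assumed done), one tissue phantom,
one lesion-probability field, and one per-voxel principal diffusion axis, so
maps are voxelwise comparable across subjects and cohorts.

The generative model, in order:

1. A nested-ellipsoid anatomy: central CSF ventricle inside a white-matter
   (WM) compartment, wrapped in a gray-matter (GM) shell, background outside.
2. A lesion-probability field p(v) in [0, max_p]: exponential decay with
   distance from the ventricle surface (periventricular predominance) times a
   linear anterior gain (frontal predominance).
3. Per-subject lesion masks: a smoothed Gaussian latent field thresholded at
   the exact per-voxel quantile of its own marginal distribution, so lesions
   are spatially contiguous blobs while the voxelwise positive rate across
   subjects equals p(v) exactly.
4. A normative microstructure field: in WM, true FA is the affine ramp
   fa0 - beta * p(v) (areas that frequently lesion have normatively lower
   FA, the hypothesis under study); GM and CSF get fixed low FA.
5. Per-subject severity gamma_s (mean 1): scales the subject's lesion rate
   (min(1, gamma_s * p), leaving the cross-subject marginal at p) and deepens
   the within-lesion FA reduction (lesion_depth * gamma_s). Heavier lesion
   burden therefore co-occurs with lower FA inside lesions, the damage
   progression the downstream regression is designed to detect.
6. Images: FLAIR = tissue mean + lesion contrast + iid Gaussian noise;
   DWI = mono-exponential signals from an axially symmetric tensor with
   Rician (magnitude) noise at the configured SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage, special

from .dti import DwiDataset
from . import io as wio

__all__ = [
    "BACKGROUND", "CSF", "WM", "GM",
    "PhantomAnatomy", "LesionProbabilityField", "MicrostructureField",
    "CohortConfig", "SyntheticCohort",
    "make_phantom_anatomy", "make_lesion_probability_field",
    "sample_lesion_mask", "make_flair_image",
    "eigenvalues_for_fa_md", "fibonacci_directions", "make_dwi",
    "principal_axes", "make_microstructure_field",
    "simulate_cohort", "generate_cohorts",
]

BACKGROUND, CSF, WM, GM = 0, 1, 2, 3

# rng stream tags: keep stable so per-subject data are pure functions of
# (config, seed) regardless of the order subjects are realized in
_TAG_AXES, _TAG_SEVERITY, _TAG_LESION, _TAG_FLAIR, _TAG_DWI_OLD, _TAG_DWI_YOUNG = (
    1, 2, 10, 11, 12, 20)


def _rng(seed: int, tag: int, idx: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, tag, idx])


@dataclass
class PhantomAnatomy:
    """Tissue label grid: 0 background, 1 CSF ventricle, 2 WM, 3 GM."""

    label_grid: np.ndarray
    voxel_size_mm: tuple

    @property
    def shape(self):
        return self.label_grid.shape

    @property
    def brain(self) -> np.ndarray:
        return self.label_grid != BACKGROUND

    @property
    def white_matter(self) -> np.ndarray:
        return self.label_grid == WM

    @property
    def gray_matter(self) -> np.ndarray:
        return self.label_grid == GM

    @property
    def ventricle(self) -> np.ndarray:
        return self.label_grid == CSF


@dataclass
class LesionProbabilityField:
    """Per-voxel lesion probability; zero outside its (brain) support."""

    p: np.ndarray
    max_p: float
    voxel_size_mm: tuple


@dataclass
class MicrostructureField:
    """Ground-truth FA and mean diffusivity (mm^2/s) per voxel."""

    fa_true: np.ndarray
    md_true: np.ndarray


def _ellipsoid(shape, semi_axes_vox) -> np.ndarray:
    """Boolean ellipsoid centred on the grid centre."""
    coords = np.ogrid[tuple(slice(0, n) for n in shape)]
    center = [(n - 1) / 2.0 for n in shape]
    q = sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords, center, semi_axes_vox))
    return q <= 1.0


def make_phantom_anatomy(shape=(48, 48, 48), voxel_size_mm=(2.0, 2.0, 2.0),
                         seed: int = 0) -> PhantomAnatomy:
    """Deterministic nested-ellipsoid head phantom.

    The seed jitters the compartment semi-axes by a few percent (the centre
    stays on the grid centre, so the phantom is mirror-symmetric about every
    axis). Requires every dimension >= 16 so the three nested compartments
    each contain voxels.
    """
    shape = tuple(int(n) for n in shape)
    if min(shape) < 16:
        raise ValueError(f"shape {shape} too small: need >= 16 voxels per axis")
    rng = _rng(seed, 0)
    jitter = 1.0 + 0.03 * rng.uniform(-1, 1, size=9).reshape(3, 3)
    half = np.array([(n - 1) / 2.0 for n in shape])
    brain_ax = 0.90 * half * jitter[0]
    wm_ax = 0.72 * half * jitter[1]
    # ventricle elongated along the anterior-posterior (y) axis; generously
    # sized (aged, atrophic brain) so the dark-CSF tail spreads the brain
    # intensity distribution the way real FLAIR histograms are spread
    vent_ax = np.array([0.39, 0.63, 0.36]) * half * jitter[2]

    labels = np.zeros(shape, dtype=np.int16)
    labels[_ellipsoid(shape, brain_ax)] = GM
    labels[_ellipsoid(shape, wm_ax)] = WM
    labels[_ellipsoid(shape, vent_ax)] = CSF

    n_wm = int(np.sum(labels == WM))
    n_csf = int(np.sum(labels == CSF))
    if not (0 < n_csf < n_wm):
        raise ValueError("degenerate phantom: compartments collapsed")
    return PhantomAnatomy(label_grid=labels, voxel_size_mm=tuple(voxel_size_mm))


def make_lesion_probability_field(anatomy: PhantomAnatomy, max_p: float = 0.22,
                                  anterior_weight: float = 1.6,
                                  decay_mm: float = 24.0,
                                  restrict_to_wm: bool = True) -> LesionProbabilityField:
    """Periventricular, anterior-weighted lesion-probability field.

    p decays exponentially (length ``decay_mm``) with Euclidean distance from
    the ventricle surface and is scaled by a linear gain rising from 1 at the
    posterior face to ``anterior_weight`` at the anterior face (axis 1, larger
    index = anterior). The field is renormalized so its maximum equals
    ``max_p`` and is zero outside the support (white matter by default; the
    whole brain when ``restrict_to_wm`` is False, which lets lesions
    "contaminate" gray matter).
    """
    if not (0.0 < max_p <= 1.0):
        raise ValueError(f"max_p must lie in (0, 1], got {max_p}")
    if decay_mm <= 0:
        raise ValueError("decay_mm must be positive")
    support = anatomy.white_matter if restrict_to_wm else (anatomy.brain & ~anatomy.ventricle)
    dist = ndimage.distance_transform_edt(~anatomy.ventricle,
                                          sampling=anatomy.voxel_size_mm)
    base = np.exp(-dist / decay_mm)
    ny = anatomy.shape[1]
    yfrac = (np.arange(ny) / (ny - 1))[None, :, None]
    gain = 1.0 + (anterior_weight - 1.0) * yfrac
    p = np.where(support, base * gain, 0.0)
    peak = p.max()
    if peak <= 0:
        raise ValueError("empty lesion support")
    p *= max_p / peak
    return LesionProbabilityField(p=p, max_p=float(max_p),
                                  voxel_size_mm=anatomy.voxel_size_mm)


def _latent_marginal_sd(shape, sigma_vox) -> float:
    """Marginal SD of white noise after periodic Gaussian smoothing.

    Equals the l2 norm of the (periodic) smoothing kernel, obtained by
    filtering a unit impulse.
    """
    if np.all(np.asarray(sigma_vox) <= 0):
        return 1.0
    imp = np.zeros(shape)
    imp[tuple(n // 2 for n in shape)] = 1.0
    ker = ndimage.gaussian_filter(imp, sigma=sigma_vox, mode="wrap")
    return float(np.sqrt(np.sum(ker ** 2)))


def sample_lesion_mask(field: LesionProbabilityField, smoothing_mm: float,
                       seed: int, rate_scale: float = 1.0) -> np.ndarray:
    """Draw one subject's binary lesion mask.

    A standard-normal latent field is smoothed with a periodic Gaussian kernel
    (``smoothing_mm`` FWHM-free sigma, in mm) and thresholded voxelwise
    against the exact quantile of its own marginal N(0, s^2) distribution, so
    the marginal positive rate at voxel v equals ``min(1, rate_scale * p(v))``
    while lesions remain spatially contiguous blobs. ``rate_scale`` is the
    per-subject severity multiplier; the default 1 reproduces p exactly.
    """
    if rate_scale < 0:
        raise ValueError("rate_scale must be non-negative")
    rate = np.clip(rate_scale * field.p, 0.0, 1.0)
    rng = _rng(seed, _TAG_LESION)
    latent = rng.standard_normal(field.p.shape)
    sigma_vox = tuple(smoothing_mm / vs for vs in field.voxel_size_mm)
    if smoothing_mm > 0:
        latent = ndimage.gaussian_filter(latent, sigma=sigma_vox, mode="wrap")
        latent /= _latent_marginal_sd(field.p.shape, sigma_vox)
    u = special.ndtr(latent)          # uniform(0,1) marginally, exactly
    return u < rate


def make_flair_image(anatomy: PhantomAnatomy, lesion_mask: np.ndarray,
                     tissue_means: dict, lesion_contrast: float,
                     noise_sd: float, seed: int) -> np.ndarray:
    """FLAIR stand-in: tissue mean + lesion hyperintensity + Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    labels = anatomy.label_grid
    present = np.unique(labels)
    missing = [int(l) for l in present if int(l) not in tissue_means]
    if missing:
        raise ValueError(f"tissue_means missing labels {missing}")
    img = np.zeros(labels.shape, dtype=float)
    for lab, mean in tissue_means.items():
        img[labels == lab] = mean
    img[np.asarray(lesion_mask, bool)] += lesion_contrast
    if noise_sd > 0:
        img += noise_sd * _rng(seed, _TAG_FLAIR).standard_normal(labels.shape)
    return img


def eigenvalues_for_fa_md(fa_target, md_target):
    """Eigenvalues (l1, l2, l3) of the axially symmetric tensor (l2 = l3)
    with the requested FA and mean diffusivity.

    Closed form: with l1 = md (1 + 2a), l2 = l3 = md (1 - a), the FA formula
    reduces to FA = 3a / sqrt(3 + 6 a^2), inverted by
    a = FA sqrt(3) / sqrt(9 - 6 FA^2). Requires 0 <= FA < 1 (FA = 1 needs a
    zero eigenvalue) and md > 0.
    """
    fa = np.asarray(fa_target, dtype=float)
    md = np.asarray(md_target, dtype=float)
    if np.any(fa < 0) or np.any(fa >= 1):
        raise ValueError("fa_target must lie in [0, 1)")
    if np.any(md <= 0):
        raise ValueError("md_target must be positive")
    a = fa * np.sqrt(3.0) / np.sqrt(9.0 - 6.0 * fa ** 2)
    l1 = md * (1.0 + 2.0 * a)
    l23 = md * (1.0 - a)
    return l1, l23, l23.copy() if isinstance(l23, np.ndarray) else l23


def fibonacci_directions(n: int) -> np.ndarray:
    """n deterministic, well-spread unit vectors (spherical Fibonacci spiral)."""
    if n < 6:
        raise ValueError("need at least 6 gradient directions")
    i = np.arange(n) + 0.5
    z = 1.0 - i / n                      # upper hemisphere: antipodal dirs are
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i   # equivalent for diffusion
    r = np.sqrt(1.0 - z ** 2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def principal_axes(shape, seed: int) -> np.ndarray:
    """Seeded random unit principal-diffusion axis per voxel, (x,y,z,3)."""
    rng = _rng(seed, _TAG_AXES)
    v = rng.standard_normal(tuple(shape) + (3,))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def make_dwi(micro: MicrostructureField, anatomy: PhantomAnatomy,
             b_value: float, n_directions: int, s0: float, snr: float,
             seed: int, axes: np.ndarray | None = None,
             rng_tag: int = _TAG_DWI_OLD) -> DwiDataset:
    """Simulate one subject's DWI from the microstructure field.

    Signals follow S_i = s0 exp(-b g_i^T D g_i) with D the axially symmetric
    tensor realizing (fa_true, md_true) about the per-voxel principal axis.
    Noise is Rician: the magnitude of the noiseless signal perturbed by
    complex Gaussian noise of SD s0/snr per channel; ``snr=numpy.inf`` gives
    noiseless data. One leading b=0 volume is always included.
    """
    if b_value <= 0:
        raise ValueError("b_value must be positive")
    dirs = fibonacci_directions(n_directions)
    if axes is None:
        axes = principal_axes(anatomy.shape, seed)
    mask = anatomy.brain
    fa = np.clip(micro.fa_true[mask], 0.0, 0.995)
    md = micro.md_true[mask]
    l1, l2, _ = eigenvalues_for_fa_md(fa, md)
    ax = axes[mask]                                  # (n_vox, 3)

    n_vol = n_directions + 1
    signal = np.zeros(anatomy.shape + (n_vol,), dtype=float)
    sig_brain = np.empty((fa.size, n_vol))
    sig_brain[:, 0] = s0
    for i, g in enumerate(dirs, start=1):
        proj2 = (ax @ g) ** 2
        adc = l2 + (l1 - l2) * proj2                 # g^T D g for unit g
        sig_brain[:, i] = s0 * np.exp(-b_value * adc)
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive or infinite")
        sigma = s0 / snr
        rng = _rng(seed, rng_tag)
        n1 = rng.standard_normal(sig_brain.shape)
        n2 = rng.standard_normal(sig_brain.shape)
        sig_brain = np.hypot(sig_brain + sigma * n1, sigma * n2)
    signal[mask] = sig_brain

    bvals = np.concatenate([[0.0], np.full(n_directions, float(b_value))])
    bvecs = np.vstack([np.zeros(3), dirs])
    return DwiDataset(signal=signal, bvals=bvals, bvecs=bvecs,
                      brain_mask=mask, voxel_size_mm=anatomy.voxel_size_mm)


def make_microstructure_field(anatomy: PhantomAnatomy,
                              field: LesionProbabilityField,
                              fa0: float = 0.45, beta: float = 0.30,
                              fa_gm: float = 0.15, fa_csf: float = 0.03,
                              md_wm: float = 0.75e-3, md_gm: float = 0.85e-3,
                              md_csf: float = 3.0e-3) -> MicrostructureField:
    """Normative microstructure: fa_true = fa0 - beta * p inside white matter."""
    labels = anatomy.label_grid
    fa = np.zeros(labels.shape)
    md = np.full(labels.shape, 1e-3)
    fa[labels == GM] = fa_gm
    fa[labels == CSF] = fa_csf
    md[labels == WM] = md_wm
    md[labels == GM] = md_gm
    md[labels == CSF] = md_csf
    wm = labels == WM
    fa[wm] = fa0 - beta * field.p[wm]
    if np.any(fa[wm] < 0) or np.any(fa[wm] >= 1):
        raise ValueError("fa0/beta/max_p combination leaves WM FA outside [0, 1)")
    return MicrostructureField(fa_true=fa, md_true=md)


@dataclass
class CohortConfig:
    """Study conditions for one synthetic two-cohort dataset.

    Acquisition constants mirror a 3T protocol: b = 800 s/mm^2 with 16
    directions for the older cohort and 56 for the young cohort. Cohort sizes
    and grid default to a desk-scale study (60 older / 20 young subjects on a
    48^3 grid of 2 mm voxels).
    """

    n_old: int = 60
    n_young: int = 20
    shape: tuple = (48, 48, 48)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    seed: int = 0
    # FLAIR model
    tissue_means: dict = field(default_factory=lambda: {
        BACKGROUND: 0.0, CSF: 10.0, WM: 100.0, GM: 92.0})
    lesion_contrast: float = 45.0
    flair_noise_sd: float = 15.0
    # DWI model
    b_value: float = 800.0
    n_directions_old: int = 16
    n_directions_young: int = 56
    s0: float = 1000.0
    snr_dwi: float = 20.0
    # microstructure / lesion model
    fa0: float = 0.45
    beta: float = 0.30
    max_p: float = 0.22
    anterior_weight: float = 1.6
    lesion_decay_mm: float = 24.0
    lesion_smoothing_mm: float = 3.0
    lesion_depth: float = 0.06
    severity_sd: float = 0.40
    restrict_lesions_to_wm: bool = True

    def __post_init__(self):
        if self.n_old < 2 or self.n_young < 2:
            raise ValueError("need at least 2 subjects per cohort")
        if self.lesion_contrast <= 0:
            raise ValueError("lesion_contrast must be positive")
        if self.b_value <= 0:
            raise ValueError("b_value must be positive")
        if self.n_directions_old < 6 or self.n_directions_young < 6:
            raise ValueError("need at least 6 gradient directions")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        d["tissue_means"] = {int(k): float(v) for k, v in self.tissue_means.items()}
        return d


@dataclass
class SyntheticCohort:
    """Shared cohort-level objects plus on-demand per-subject realizations.

    Per-subject data are generated lazily (seeded by subject index) so a full
    cohort never needs to reside in memory at once.
    """

    config: CohortConfig
    anatomy: PhantomAnatomy
    lesion_field: LesionProbabilityField
    micro: MicrostructureField
    axes: np.ndarray
    severities: np.ndarray

    def old_lesion_mask(self, i: int) -> np.ndarray:
        self._check(i, self.config.n_old)
        return sample_lesion_mask(self.lesion_field, self.config.lesion_smoothing_mm,
                                  seed=self._seed(i), rate_scale=self.severities[i])

    def old_flair(self, i: int, lesion_mask: np.ndarray | None = None) -> np.ndarray:
        if lesion_mask is None:
            lesion_mask = self.old_lesion_mask(i)
        return make_flair_image(self.anatomy, lesion_mask, self.config.tissue_means,
                                self.config.lesion_contrast,
                                self.config.flair_noise_sd, seed=self._seed(i))

    def old_dwi(self, i: int, lesion_mask: np.ndarray | None = None) -> DwiDataset:
        if lesion_mask is None:
            lesion_mask = self.old_lesion_mask(i)
        micro = self._damaged_micro(lesion_mask, self.severities[i])
        return make_dwi(micro, self.anatomy, self.config.b_value,
                        self.config.n_directions_old, self.config.s0,
                        self.config.snr_dwi, seed=self._seed(i),
                        axes=self.axes, rng_tag=_TAG_DWI_OLD)

    def young_dwi(self, j: int) -> DwiDataset:
        self._check(j, self.config.n_young)
        return make_dwi(self.micro, self.anatomy, self.config.b_value,
                        self.config.n_directions_young, self.config.s0,
                        self.config.snr_dwi, seed=self._seed(j),
                        axes=self.axes, rng_tag=_TAG_DWI_YOUNG)

    def _damaged_micro(self, lesion_mask, severity) -> MicrostructureField:
        fa = self.micro.fa_true.copy()
        les = np.asarray(lesion_mask, bool)
        fa[les] = np.maximum(fa[les] - self.config.lesion_depth * severity, 0.02)
        return MicrostructureField(fa_true=fa, md_true=self.micro.md_true)

    def _seed(self, i: int) -> int:
        # subject index folded into the stream index, base seed shared
        return self.config.seed + (i << 8) % (1 << 20)

    @staticmethod
    def _check(i, n):
        if not (0 <= i < n):
            raise IndexError(f"subject index {i} out of range [0, {n})")


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Build the shared cohort-level objects for a configuration."""
    anatomy = make_phantom_anatomy(config.shape, config.voxel_size_mm, seed=config.seed)
    lesion_field = make_lesion_probability_field(
        anatomy, max_p=config.max_p, anterior_weight=config.anterior_weight,
        decay_mm=config.lesion_decay_mm,
        restrict_to_wm=config.restrict_lesions_to_wm)
    micro = make_microstructure_field(anatomy, lesion_field,
                                      fa0=config.fa0, beta=config.beta)
    axes = principal_axes(config.shape, seed=config.seed)
    if config.severity_sd > 0:
        k = 1.0 / config.severity_sd ** 2
        sev = _rng(config.seed, _TAG_SEVERITY).gamma(shape=k, scale=1.0 / k,
                                                     size=config.n_old)
        sev = np.minimum(sev, 1.0 / max(config.max_p, 1e-9))
    else:
        sev = np.ones(config.n_old)
    return SyntheticCohort(config=config, anatomy=anatomy, lesion_field=lesion_field,
                           micro=micro, axes=axes, severities=sev)


def generate_cohorts(config: CohortConfig, out_dir) -> "pd.DataFrame":
    """Write the full synthetic dataset to ``out_dir`` and return the manifest.

    Per older subject: FLAIR, DWI + gradient tables, ground-truth lesion mask.
    Per young subject: DWI + gradient tables. Shared: tissue labels, brain and
    WM masks, the lesion-probability field and the true FA/MD maps. The
    manifest (TSV) lists one row per written file.
    """
    import pandas as pd  # noqa: F401  (re-exported type in docstring)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    vs = config.voxel_size_mm
    rows = []

    def _add(subject_id, coh, modality, path, seed):
        rows.append(dict(subject_id=subject_id, cohort=coh, modality=modality,
                         path=str(path), seed=seed))

    a = cohort.anatomy
    shared = {
        "tissue_labels": (a.label_grid, np.int16),
        "brain_mask": (a.brain.astype(np.uint8), np.uint8),
        "wm_mask": (a.white_matter.astype(np.uint8), np.uint8),
        "lesion_probability": (cohort.lesion_field.p, np.float32),
        "fa_true": (cohort.micro.fa_true, np.float32),
        "md_true": (cohort.micro.md_true, np.float32),
    }
    for name, (arr, dt) in shared.items():
        p = out / f"{name}.nii"
        wio.save_volume(p, arr, vs, dtype=dt)
        _add("shared", "shared", name, p, config.seed)

    for i in range(config.n_old):
        sid = f"old{i:04d}"
        seed_i = cohort._seed(i)
        les = cohort.old_lesion_mask(i)
        p = out / f"{sid}_lesion_mask.nii"
        wio.save_volume(p, les.astype(np.uint8), vs, dtype=np.uint8)
        _add(sid, "old", "lesion_mask", p, seed_i)
        p = out / f"{sid}_flair.nii"
        wio.save_volume(p, cohort.old_flair(i, les), vs, dtype=np.float32)
        _add(sid, "old", "flair", p, seed_i)
        dwi = cohort.old_dwi(i, les)
        p = out / f"{sid}_dwi.nii"
        wio.save_volume(p, dwi.signal, vs, dtype=np.float32)
        _add(sid, "old", "dwi", p, seed_i)
        bp, gp = out / f"{sid}.bval", out / f"{sid}.bvec"
        wio.write_gradient_table(bp, gp, dwi.bvals, dwi.bvecs)
        _add(sid, "old", "bvals", bp, seed_i)
        _add(sid, "old", "bvecs", gp, seed_i)

    for j in range(config.n_young):
        sid = f"young{j:04d}"
        seed_j = cohort._seed(j)
        dwi = cohort.young_dwi(j)
        p = out / f"{sid}_dwi.nii"
        wio.save_volume(p, dwi.signal, vs, dtype=np.float32)
        _add(sid, "young", "dwi", p, seed_j)
        bp, gp = out / f"{sid}.bval", out / f"{sid}.bvec"
        wio.write_gradient_table(bp, gp, dwi.bvals, dwi.bvecs)
        _add(sid, "young", "bvals", bp, seed_j)
        _add(sid, "young", "bvecs", gp, seed_j)

    return wio.write_manifest(out / "manifest.tsv", rows)
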