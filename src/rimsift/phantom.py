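"""Synthetic co-registered T1 phantom with ground-truth lesion masks.

The phantom is not an anatomical brain model: it is an intensity phantom.
A cubic "brain" of normal-appearing tissue is seeded with non-overlapping
spherical lesions whose voxel intensities are drawn from class-specific
mixtures already living on the 0-100 standard intensity scale:

* non-phase-rim white-matter lesions (nPR-WML): a unimodal distribution
  with a sharp mode at 64.8 — a narrow Gaussian core plus a broad,
  low-amplitude Gaussian pedestal whose width is calibrated so that 0.5%
  of the class mass falls below intensity 25 (the deeply hypointense
  segment);
* phase-rim lesions (PRL): a bimodal mixture, 14% deeply hypointense
  (mode 0.9) and 86% in a lesional hump at 60.2, with the hypointense
  component placed preferentially in the outer shell of each sphere to
  mimic a T1-dark rim;
* contrast-enhancing lesions: nPR-WML-like pre-contrast, but bright
  (mean > 80) on the post-contrast volume;
* tiny lesions: 1-7 voxel clusters, i.e. below 1 mm^3 at 0.5 mm isotropic
  spacing, which the volume filter must discard.

An optional multiplicative low-frequency bias field and a global affine
intensity distortion give the histogram-normalization stage something
nontrivial to undo.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.stats import norm

from .imgio import BinaryMask, Volume, write_mask, write_volume

__all__ = [
    "PRL",
    "NPRWML",
    "NprwmlMix",
    "PrlMix",
    "PhantomSpec",
    "PhantomSet",
    "generate_phantom",
    "sample_lesion_intensities",
]

PRL = "PRL"
NPRWML = "nPR-WML"

_MAX_PLACEMENT_ATTEMPTS = 1000

# Fixed 2x2x2 fill order for sub-1 mm^3 clusters; every prefix is
# 26-connected (all offsets are mutually within Chebyshev distance 1).
_TINY_OFFSETS = np.array(
    [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1)]
)


@dataclass(frozen=True)
class NprwmlMix:
    """Unimodal nPR-WML intensity model: sharp core + broad pedestal.

    The pedestal (tail) shares the core mean, keeping the density unimodal,
    and carries the deeply hypointense mass: with the defaults the analytic
    fraction below intensity 25 is 0.50%.
    """

    mean: float = 64.8
    sd: float = 3.0
    tail_weight: float = 0.10
    tail_sd: float = 24.2

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        take_tail = rng.random(n) < self.tail_weight
        out = rng.normal(self.mean, self.sd, n)
        out[take_tail] = rng.normal(self.mean, self.tail_sd, int(take_tail.sum()))
        return out

    def mass_below(self, cutoff: float) -> float:
        return float(
            (1.0 - self.tail_weight) * norm.cdf((cutoff - self.mean) / self.sd)
            + self.tail_weight * norm.cdf((cutoff - self.mean) / self.tail_sd)
        )


@dataclass(frozen=True)
class PrlMix:
    """Bimodal PRL intensity model: hypointense rim + lesional hump."""

    hypo_mean: float = 0.9
    hypo_sd: float = 3.0
    hyper_mean: float = 60.2
    hyper_sd: float = 3.5
    hypo_weight: float = 0.14

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        take_hypo = rng.random(n) < self.hypo_weight
        out = rng.normal(self.hyper_mean, self.hyper_sd, n)
        out[take_hypo] = rng.normal(self.hypo_mean, self.hypo_sd, int(take_hypo.sum()))
        return out

    def mass_below(self, cutoff: float) -> float:
        return float(
            self.hypo_weight * norm.cdf((cutoff - self.hypo_mean) / self.hypo_sd)
            + (1.0 - self.hypo_weight) * norm.cdf((cutoff - self.hyper_mean) / self.hyper_sd)
        )

    @property
    def mean(self) -> float:
        """Closed-form mixture mean w*mu_hypo + (1-w)*mu_hyper."""
        return self.hypo_weight * self.hypo_mean + (1 - self.hypo_weight) * self.hyper_mean


@dataclass
class PhantomSpec:
    """Everything needed to generate one phantom subject, reproducibly.

    The background sd is chosen so that the brain-wide p1/p99 landmarks sit
    analytically at ~0/100: the phantom is born on its own standard scale,
    so normalization of an undistorted phantom is close to the identity.
    """

    grid_shape: tuple = (96, 96, 96)
    voxel_size_mm: float = 0.5
    n_nprwml: int = 60
    n_prl: int = 25
    n_enhancing: int = 3
    n_tiny: int = 3
    lesion_radius_range_mm: tuple = (1.5, 3.0)
    nprwml_mix: NprwmlMix = field(default_factory=NprwmlMix)
    prl_mix: PrlMix = field(default_factory=PrlMix)
    background_mean: float = 50.0
    background_sd: float = 21.5
    enhancing_post_mean: float = 90.0
    bias_field_amplitude: float = 0.0
    distortion_scale: float = 1.0
    distortion_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.lesion_radius_range_mm = tuple(float(r) for r in self.lesion_radius_range_mm)
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive sizes, got {self.grid_shape}")
        for name in ("n_nprwml", "n_prl", "n_enhancing", "n_tiny"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.lesion_radius_range_mm
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range_mm must be positive and ordered")
        if not 0.0 <= self.prl_mix.hypo_weight <= 1.0:
            raise ValueError("PRL hypo weight must lie in [0, 1]")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.distortion_scale <= 0:
            raise ValueError("distortion_scale must be positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["lesion_radius_range_mm"] = list(self.lesion_radius_range_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "nprwml_mix" in d and isinstance(d["nprwml_mix"], dict):
            d["nprwml_mix"] = NprwmlMix(**d["nprwml_mix"])
        if "prl_mix" in d and isinstance(d["prl_mix"], dict):
            d["prl_mix"] = PrlMix(**d["prl_mix"])
        return cls(**d)


@dataclass
class PhantomSet:
    """Generated volumes, ground-truth masks and the planting record."""

    t1_pre: Volume
    t1_post: Volume
    total_lesion_mask: BinaryMask
    prl_mask: BinaryMask
    truth_table: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_volume(self.t1_pre, outdir / "t1_pre.nii.gz")
        write_volume(self.t1_post, outdir / "t1_post.nii.gz")
        write_mask(self.total_lesion_mask, outdir / "total_lesion_mask.nii.gz")
        write_mask(self.prl_mask, outdir / "prl_mask.nii.gz")
        self.truth_table.to_csv(outdir / "truth_table.tsv", sep="\t", index=False)


def _sphere_offsets(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Voxel-index offsets whose centers lie within radius_mm of the origin."""
    r_vox = int(np.floor(radius_mm / voxel_size_mm))
    ax = np.arange(-r_vox, r_vox + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    d2 = (dx**2 + dy**2 + dz**2) * voxel_size_mm**2
    keep = d2 <= radius_mm**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def _place(occupied: np.ndarray, offsets: np.ndarray, rng: np.random.Generator,
           what: str) -> np.ndarray:
    """Rejection-sample a center so the voxel set keeps a 1-voxel Chebyshev
    gap from everything already placed (lesions stay 26-disconnected)."""
    shape = np.array(occupied.shape)
    omin, omax = offsets.min(axis=0), offsets.max(axis=0)
    lo = -omin + 1  # keep a 1-voxel border to the grid edge as well
    hi = shape - omax - 1
    if np.any(hi <= lo):
        raise ValueError(f"grid too small to place {what}")
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        center = np.array([rng.integers(l, h) for l, h in zip(lo, hi)])
        vox = center + offsets
        bmin, bmax = vox.min(axis=0) - 1, vox.max(axis=0) + 2
        local = np.zeros(tuple(bmax - bmin), dtype=bool)
        local[tuple((vox - bmin).T)] = True
        grown = binary_dilation(local, structure=np.ones((3, 3, 3), dtype=bool))
        region = occupied[bmin[0]:bmax[0], bmin[1]:bmax[1], bmin[2]:bmax[2]]
        if not np.any(grown & region):
            occupied[tuple(vox.T)] = True
            return vox
    raise RuntimeError(
        f"could not place {what} after {_MAX_PLACEMENT_ATTEMPTS} attempts; "
        "reduce lesion counts or radii, or enlarge the grid"
    )


def _bias_field(shape: tuple, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * f, max|f| = 1: a sum of
    three low-order separable cosine modes with random phases/weights."""
    if amplitude == 0:
        return np.ones(shape)
    grids = np.meshgrid(*[np.linspace(0, 1, s) for s in shape], indexing="ij")
    f = np.zeros(shape)
    for _ in range(3):
        freqs = rng.integers(1, 3, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        w = rng.uniform(0.3, 1.0)
        mode = np.ones(shape)
        for g, k, ph in zip(grids, freqs, phases):
            mode = mode * np.cos(np.pi * k * g + ph)
        f += w * mode
    f /= np.max(np.abs(f))
    return 1.0 + amplitude * f


def generate_phantom(spec: PhantomSpec) -> PhantomSet:
    """Generate one phantom subject. Identical spec (incl. seed) gives
    bit-identical output arrays."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    vox = spec.voxel_size_mm

    t1_pre = rng.normal(spec.background_mean, spec.background_sd, shape)
    occupied = np.zeros(shape, dtype=bool)
    total = np.zeros(shape, dtype=np.uint8)
    prl = np.zeros(shape, dtype=np.uint8)
    post_override: list[tuple[np.ndarray, np.ndarray]] = []
    records = []

    plan = (
        [(NPRWML, "nprwml")] * spec.n_nprwml
        + [(PRL, "prl")] * spec.n_prl
        + [(NPRWML, "enhancing")] * spec.n_enhancing
        + [(NPRWML, "tiny")] * spec.n_tiny
    )
    for idx, (class_label, planted_type) in enumerate(plan, start=1):
        if planted_type == "tiny":
            k = int(rng.integers(1, len(_TINY_OFFSETS) + 1))
            offsets = _TINY_OFFSETS[:k]
            radius_mm = np.nan
        else:
            radius_mm = float(rng.uniform(*spec.lesion_radius_range_mm))
            offsets = _sphere_offsets(radius_mm, vox)
        voxels = _place(occupied, offsets, rng,
                        f"lesion {idx} ({planted_type}, {len(offsets)} voxels)")
        n = len(voxels)
        n_hypo = 0
        if class_label == PRL:
            n_hypo = int((rng.random(n) < spec.prl_mix.hypo_weight).sum())
            vals = np.empty(n)
            vals[:] = rng.normal(spec.prl_mix.hyper_mean, spec.prl_mix.hyper_sd, n)
            if n_hypo:
                # hypointense draws go to the outer third of the radius first
                d = np.linalg.norm((voxels - voxels.mean(axis=0)) * vox, axis=1)
                shell = np.argsort(-d)  # outermost voxels first
                hypo_idx = shell[:n_hypo]
                vals[hypo_idx] = rng.normal(
                    spec.prl_mix.hypo_mean, spec.prl_mix.hypo_sd, n_hypo
                )
            prl[tuple(voxels.T)] = 1
        else:
            vals = spec.nprwml_mix.sample(rng, n)
        t1_pre[tuple(voxels.T)] = vals
        total[tuple(voxels.T)] = 1
        if planted_type == "enhancing":
            post_override.append(
                (voxels, rng.normal(spec.enhancing_post_mean, spec.nprwml_mix.sd, n))
            )
        cx, cy, cz = voxels.mean(axis=0)
        records.append(
            dict(lesion_id=idx, planted_class=class_label, planted_type=planted_type,
                 cx=cx, cy=cy, cz=cz, radius_mm=radius_mm, n_voxels=n, n_hypo=n_hypo)
        )

    t1_post = t1_pre.copy()
    for voxels, vals in post_override:
        t1_post[tuple(voxels.T)] = vals

    if spec.bias_field_amplitude:
        field_arr = _bias_field(shape, spec.bias_field_amplitude, rng)
        t1_pre = t1_pre * field_arr
        t1_post = t1_post * field_arr
    t1_pre = spec.distortion_scale * t1_pre + spec.distortion_offset
    t1_post = spec.distortion_scale * t1_post + spec.distortion_offset

    aff = spec.affine
    truth = pd.DataFrame(
        records,
        columns=["lesion_id", "planted_class", "planted_type", "cx", "cy", "cz",
                 "radius_mm", "n_voxels", "n_hypo"],
    )
    return PhantomSet(
        t1_pre=Volume(t1_pre, aff),
        t1_post=Volume(t1_post, aff),
        total_lesion_mask=BinaryMask(total, aff),
        prl_mask=BinaryMask(prl, aff),
        truth_table=truth,
    )


def sample_lesion_intensities(class_label: str, n: int,
                              spec: PhantomSpec | None = None,
                              seed: int = 0) -> np.ndarray:
    """I.i.d. draws from a lesion class's configured intensity distribution.

    Gives direct unit-test and calibration access to the generative
    mixtures without rasterizing a phantom.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    spec = spec if spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    if class_label == PRL:
        return spec.prl_mix.sample(rng, n)
    if class_label == NPRWML:
        return spec.nprwml_mix.sample(rng, n)
    raise ValueError(f"unknown lesion class {class_label!r}; expected {PRL!r} or {NPRWML!r}")
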