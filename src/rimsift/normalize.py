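"""Piecewise-linear histogram-matching intensity normalization.

Two-phase Nyul-Udupa scheme. Training: for every cohort image, intensity
landmarks (percentiles of the in-mask voxels) are computed and affinely
rescaled so the p1/p99 landmarks hit the ends of the standard scale; the
rescaled interior landmarks are averaged across images into a standard
scale template. Application: an image's own landmarks are mapped onto the
template values by continuous piecewise-linear interpolation, with the
first/last segments extended linearly beyond p1/p99 so that deep
hypointense tails are stretched, never clipped — the whole analysis
depends on that tail surviving normalization.

The canonical landmark configuration is the deciles anchored by p1/p99 on
a 0-100 scale; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._stats import percentile
from .imgio import BinaryMask, Volume

__all__ = [
    "DEFAULT_PERCENTILES",
    "StandardScale",
    "train_template",
    "apply_template",
    "save_template",
    "load_template",
]

DEFAULT_PERCENTILES = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 99.0)
_FORMAT_VERSION = 1


@dataclass
class StandardScale:
    """A trained normalization template.

    standard_values are on the standard scale: strictly increasing, with
    the first and last equal to the ends of scale_range.
    """

    landmark_percentiles: tuple
    standard_values: tuple
    scale_range: tuple = (0.0, 100.0)
    contrast_tag: str = "pre"

    def __post_init__(self) -> None:
        self.landmark_percentiles = tuple(float(p) for p in self.landmark_percentiles)
        self.standard_values = tuple(float(v) for v in self.standard_values)
        self.scale_range = tuple(float(s) for s in self.scale_range)
        p = np.array(self.landmark_percentiles)
        v = np.array(self.standard_values)
        if p.size != v.size:
            raise ValueError("landmark_percentiles and standard_values differ in length")
        if p.size < 2 or np.any(np.diff(p) <= 0) or p[0] <= 0 or p[-1] >= 100:
            raise ValueError("percentiles must be strictly increasing within (0, 100)")
        if np.any(np.diff(v) <= 0):
            raise ValueError("standard_values must be strictly increasing")
        s_min, s_max = self.scale_range
        if not (np.isclose(v[0], s_min) and np.isclose(v[-1], s_max)):
            raise ValueError("standard_values must span scale_range exactly")


def _landmarks(image: Volume, mask: BinaryMask, percentiles: Sequence[float]) -> np.ndarray:
    vals = image.data[mask.data > 0]
    if vals.size == 0:
        raise ValueError("normalization mask is empty")
    if np.unique(vals).size < len(percentiles):
        raise ValueError(
            f"mask holds only {np.unique(vals).size} distinct intensities; "
            f"need at least {len(percentiles)} for the landmark set"
        )
    lm = percentile(vals, list(percentiles))
    if np.any(np.diff(lm) <= 0):
        raise ValueError("image landmarks are not strictly increasing (degenerate histogram)")
    return np.asarray(lm, dtype=float)


def train_template(images: Sequence[Volume], masks: Sequence[BinaryMask],
                   percentiles: Sequence[float] = DEFAULT_PERCENTILES,
                   scale_range: Sequence[float] = (0.0, 100.0),
                   contrast_tag: str = "pre") -> StandardScale:
    """Train a standard-scale template from a cohort of masked images.

    Each image's landmarks are affinely mapped so its first/last landmark
    hit the scale ends; the mapped landmark vectors are averaged. Training
    is invariant to per-image affine intensity transforms a*x+b (a>0).
    """
    if len(images) == 0:
        raise ValueError("need at least one training image")
    if len(images) != len(masks):
        raise ValueError("images and masks differ in length")
    s_min, s_max = float(scale_range[0]), float(scale_range[1])
    mapped = []
    for img, msk in zip(images, masks):
        lm = _landmarks(img, msk, percentiles)
        mapped.append((lm - lm[0]) / (lm[-1] - lm[0]) * (s_max - s_min) + s_min)
    values = np.mean(mapped, axis=0)
    values[0], values[-1] = s_min, s_max  # exact ends, immune to float drift
    if np.any(np.diff(values) <= 0):
        raise ValueError("averaged landmarks are not monotone: degenerate cohort")
    return StandardScale(tuple(percentiles), tuple(values),
                         (s_min, s_max), contrast_tag)


def _piecewise_map(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Monotone piecewise-linear map through (xp, fp) with linear
    extrapolation beyond both ends (no clipping)."""
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    if np.any(lo):
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y[lo] = fp[0] + (x[lo] - xp[0]) * slope
    hi = x > xp[-1]
    if np.any(hi):
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[hi] = fp[-1] + (x[hi] - xp[-1]) * slope
    return y


def apply_template(image: Volume, mask: BinaryMask, template: StandardScale) -> Volume:
    """Map an image onto the standard scale of a trained template.

    The image's own in-mask landmarks define the interpolation knots; the
    map is applied to every voxel (in- and out-of-mask alike) and is
    monotone non-decreasing by construction.
    """
    xp = _landmarks(image, mask, template.landmark_percentiles)
    fp = np.asarray(template.standard_values)
    data = _piecewise_map(image.data.ravel().astype(float), xp, fp).reshape(image.shape)
    return Volume(data=data, affine=image.affine)


def save_template(template: StandardScale, path) -> None:
    """Versioned plain-text persistence: key-value header + two aligned rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"version: {_FORMAT_VERSION}",
        f"contrast_tag: {template.contrast_tag}",
        f"scale_range: {template.scale_range[0]:.17g} {template.scale_range[1]:.17g}",
        "percentiles: " + " ".join(f"{p:.17g}" for p in template.landmark_percentiles),
        "standard_values: " + " ".join(f"{v:.17g}" for v in template.standard_values),
    ]
    path.write_text("\n".join(lines) + "\n")


def load_template(path) -> StandardScale:
    fields = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"malformed template line: {line!r}")
        key, _, rest = line.partition(":")
        fields[key.strip()] = rest.strip()
    try:
        if int(fields["version"]) != _FORMAT_VERSION:
            raise ValueError(f"unsupported template version {fields['version']}")
        return StandardScale(
            landmark_percentiles=tuple(float(x) for x in fields["percentiles"].split()),
            standard_values=tuple(float(x) for x in fields["standard_values"].split()),
            scale_range=tuple(float(x) for x in fields["scale_range"].split()),
            contrast_tag=fields["contrast_tag"],
        )
    except KeyError as e:
        raise ValueError(f"template file missing field {e}") from e
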