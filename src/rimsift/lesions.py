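"""From binary lesion maps to a per-lesion feature table.

The non-phase-rim map is the total lesion map minus the PRL map; each map
is split into connected components (default 26-connectivity, matching the
3D behaviour of the usual cluster utilities), and every component yields
one record: voxel count, volume, mean normalized post-contrast intensity
(the enhancement screen) and the 5th-percentile normalized pre-contrast
intensity p5 — the classifying statistic, probing the hypointense-most
voxels of the lesion while staying robust to single-voxel outliers.

Exclusion filters mirror the study design: lesions under 1 mm^3 are
discarded (segmentation noise), as are lesions whose mean post-contrast
intensity exceeds 80 (contrast-enhancing, i.e. acutely inflamed, whose
T1 hypointensity is transient and must not be mistaken for a chronic
black hole).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from ._stats import percentile
from .imgio import BinaryMask, Volume, check_compatible

__all__ = [
    "LabelMap",
    "LesionRecord",
    "FilterSpec",
    "subtract_prl",
    "label_components",
    "extract_features",
    "filter_lesions",
    "records_to_table",
    "table_to_records",
    "write_table",
    "read_table",
]

TABLE_COLUMNS = ["lesion_id", "class", "n_voxels", "volume_mm3", "mean_t1post", "p5_t1pre"]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class LabelMap:
    """Integer component map: 0 background, labels contiguous 1..K.

    Labels are ordered by each component's first voxel in lexicographic
    (C-order) grid order, so labeling is deterministic across runs.
    """

    data: np.ndarray
    affine: np.ndarray
    connectivity: int
    n_labels: int


@dataclass
class LesionRecord:
    lesion_id: int
    class_label: str
    n_voxels: int
    volume_mm3: float
    mean_t1post: float
    p5_t1pre: float


@dataclass
class FilterSpec:
    """Exclusion thresholds; removal is strict ("under" / "greater than")."""

    min_volume_mm3: float = 1.0
    max_mean_t1post: float = 80.0

    def __post_init__(self) -> None:
        if self.min_volume_mm3 <= 0 or self.max_mean_t1post <= 0:
            raise ValueError("filter thresholds must be positive")


def subtract_prl(total: BinaryMask, prl: BinaryMask) -> BinaryMask:
    """nPR-WML map = total AND NOT prl."""
    check_compatible(total, prl)
    out = (total.data > 0) & ~(prl.data > 0)
    return BinaryMask(data=out.astype(np.uint8), affine=total.affine)


def label_components(mask: BinaryMask, connectivity: int = 26) -> LabelMap:
    """Connected-component labeling with deterministic label order."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}, got {connectivity}")
    raw, n = ndimage.label(mask.data > 0, structure=_STRUCTURES[connectivity])
    if n:
        # relabel by first occurrence in C-order flat scan
        flat = raw.ravel()
        nz = np.flatnonzero(flat)
        first = np.full(n + 1, flat.size, dtype=np.int64)
        # reversed scan: earlier indices overwrite later ones
        first[flat[nz[::-1]]] = nz[::-1]
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=raw.dtype)
        remap[1 + order] = np.arange(1, n + 1)
        raw = remap[raw]
    return LabelMap(data=raw, affine=mask.affine, connectivity=connectivity, n_labels=int(n))


def extract_features(labels: LabelMap, class_label: str,
                     t1pre: Volume, t1post: Volume) -> list[LesionRecord]:
    """One LesionRecord per component: volume, mean post, p5 pre."""
    check_compatible(Volume(labels.data.astype(float), labels.affine), t1pre, t1post)
    voxvol = t1pre.voxel_volume_mm3
    records = []
    for lab in range(1, labels.n_labels + 1):
        sel = labels.data == lab
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"label {lab} has no voxels: malformed label map")
        pre_vals = t1pre.data[sel]
        records.append(
            LesionRecord(
                lesion_id=lab,
                class_label=class_label,
                n_voxels=n,
                volume_mm3=n * voxvol,
                mean_t1post=float(t1post.data[sel].mean()),
                p5_t1pre=float(percentile(pre_vals, 5)),
            )
        )
    return records


def filter_lesions(records: list[LesionRecord], spec: FilterSpec | None = None
                   ) -> tuple[list[LesionRecord], dict]:
    """Apply the exclusion filters; returns (kept, per-rule removal counts).

    A lesion failing both rules is attributed to the volume rule (the
    rules are applied in that order); boundary values are kept — removal
    requires volume strictly under the minimum or mean post-contrast
    intensity strictly over the maximum.
    """
    spec = spec or FilterSpec()
    kept = []
    counts = {"removed_small": 0, "removed_enhancing": 0}
    for rec in records:
        if rec.volume_mm3 < spec.min_volume_mm3:
            counts["removed_small"] += 1
        elif rec.mean_t1post > spec.max_mean_t1post:
            counts["removed_enhancing"] += 1
        else:
            kept.append(rec)
    return kept, counts


def records_to_table(records: list[LesionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(lesion_id=r.lesion_id, **{"class": r.class_label},
                 n_voxels=r.n_voxels, volume_mm3=r.volume_mm3,
                 mean_t1post=r.mean_t1post, p5_t1pre=r.p5_t1pre)
            for r in records
        ],
        columns=TABLE_COLUMNS,
    )


def table_to_records(table: pd.DataFrame) -> list[LesionRecord]:
    return [
        LesionRecord(int(row.lesion_id), str(row["class"]), int(row.n_voxels),
                     float(row.volume_mm3), float(row.mean_t1post), float(row.p5_t1pre))
        for _, row in table.iterrows()
    ]


def write_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"lesion table missing columns: {sorted(missing)}")
    return table
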