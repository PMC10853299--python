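"""One reproducible run: phantom -> normalize -> lesions -> analyze -> classify.

The run either generates a phantom subject or loads four co-registered
NIfTI inputs (pre/post T1, total lesion mask, PRL mask), trains pre- and
post-contrast normalization templates on the brain mask (all nonzero
voxels), maps both volumes onto the standard scale, tabulates per-lesion
features, applies the exclusion filters, computes the voxel-wise group
histograms and rank contrast, fits the specificity-constrained p5 cutoff
classifier and writes every intermediate artifact plus a single JSON
report. The report is a pure function of the config: identical configs
produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import NPRWML, PRL, P5RimClassifier
from .groupstats import (DEFAULT_BIN_WIDTH, DEFAULT_DEEP_CUTOFF,
                         DEFAULT_SMOOTH_WINDOW, group_histogram, summarize_group,
                         wilcoxon_rank_sum)
from .imgio import BinaryMask, read_mask, read_volume, write_volume, check_compatible
from .lesions import (FilterSpec, extract_features, filter_lesions,
                      label_components, records_to_table, subtract_prl, write_table)
from .normalize import apply_template, save_template, train_template
from .phantom import PhantomSpec, generate_phantom

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("rimsift")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run. Exactly one input source:
    a phantom spec, or paths to four co-registered NIfTI files."""

    outdir: str = "rimsift_run"
    seed: int = 0
    phantom: PhantomSpec | None = None
    inputs: dict | None = None  # keys: t1_pre, t1_post, total_mask, prl_mask
    filter: FilterSpec = field(default_factory=FilterSpec)
    bin_width: float = DEFAULT_BIN_WIDTH
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    deep_cutoff: float = DEFAULT_DEEP_CUTOFF
    connectivity: int = 26
    spec_constraint: float = 0.95
    split_fraction: float = 0.5

    def __post_init__(self) -> None:
        if (self.phantom is None) == (self.inputs is None):
            raise ValueError("exactly one of phantom or inputs must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if raw.get("phantom") is not None:
            raw["phantom"] = PhantomSpec.from_dict(raw["phantom"])
        if raw.get("filter") is not None:
            raw["filter"] = FilterSpec(**raw["filter"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir, "seed": self.seed,
            "phantom": self.phantom.to_dict() if self.phantom else None,
            "inputs": self.inputs,
            "filter": {"min_volume_mm3": self.filter.min_volume_mm3,
                       "max_mean_t1post": self.filter.max_mean_t1post},
            "bin_width": self.bin_width, "smooth_window": self.smooth_window,
            "deep_cutoff": self.deep_cutoff, "connectivity": self.connectivity,
            "spec_constraint": self.spec_constraint,
            "split_fraction": self.split_fraction,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _summary_dict(s) -> dict:
    return {
        "modes": list(s.mode_locations),
        "n_modes": len(s.mode_locations),
        "intermode_minimum": s.intermode_minimum,
        "deep_cutoff": s.deep_cutoff,
        "deep_fraction": s.deep_fraction,
    }


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns the report dict (also written
    to <outdir>/report.json). Any stage failure aborts with its name."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    report: dict = {"rimsift_version": __version__,
                    "config_hash": config.config_hash(),
                    "config": config.to_dict()}
    stage = "inputs"
    try:
        if config.phantom is not None:
            stage = "phantom"
            log.info("stage phantom: generating synthetic subject")
            spec = config.phantom
            if spec.seed != config.seed:
                spec = PhantomSpec.from_dict({**spec.to_dict(), "seed": config.seed})
            pset = generate_phantom(spec)
            pset.write(out / "phantom")
            t1_pre, t1_post = pset.t1_pre, pset.t1_post
            total_mask, prl_mask = pset.total_lesion_mask, pset.prl_mask
            truth = pset.truth_table
            report["phantom"] = {
                "n_lesions_planted": int(len(truth)),
                "planted_by_type": truth["planted_type"].value_counts().to_dict(),
            }
        else:
            log.info("stage inputs: loading volumes")
            t1_pre = read_volume(config.inputs["t1_pre"])
            t1_post = read_volume(config.inputs["t1_post"])
            total_mask = read_mask(config.inputs["total_mask"])
            prl_mask = read_mask(config.inputs["prl_mask"])
            truth = None
        check_compatible(t1_pre, t1_post, total_mask, prl_mask)

        stage = "normalize"
        log.info("stage normalize: training and applying standard-scale templates")
        brain = BinaryMask((t1_pre.data != 0).astype(np.uint8), t1_pre.affine)
        tmpl_pre = train_template([t1_pre], [brain], contrast_tag="pre")
        tmpl_post = train_template([t1_post], [brain], contrast_tag="post")
        save_template(tmpl_pre, out / "template_pre.txt")
        save_template(tmpl_post, out / "template_post.txt")
        norm_pre = apply_template(t1_pre, brain, tmpl_pre)
        norm_post = apply_template(t1_post, brain, tmpl_post)
        write_volume(norm_pre, out / "t1_pre_norm.nii.gz")
        write_volume(norm_post, out / "t1_post_norm.nii.gz")

        stage = "lesions"
        log.info("stage lesions: component isolation and feature extraction")
        nprwml_mask = subtract_prl(total_mask, prl_mask)
        recs = []
        for mask, label in ((prl_mask, PRL), (nprwml_mask, NPRWML)):
            if mask.n_voxels:
                labels = label_components(mask, config.connectivity)
                recs.extend(extract_features(labels, label, norm_pre, norm_post))
        for i, r in enumerate(recs, start=1):  # unique ids across both maps
            r.lesion_id = i
        kept, removal_counts = filter_lesions(recs, config.filter)
        table = records_to_table(kept)
        write_table(records_to_table(recs), out / "lesion_table_raw.tsv")
        write_table(table, out / "lesion_table.tsv")
        report["lesions"] = {
            "n_components": len(recs),
            "n_kept": len(kept),
            "removed_small": removal_counts["removed_small"],
            "removed_enhancing": removal_counts["removed_enhancing"],
            "n_prl": int((table["class"] == PRL).sum()),
            "n_nprwml": int((table["class"] == NPRWML).sum()),
        }
        log.info("lesions: %d components, %d kept (%d small, %d enhancing removed)",
                 len(recs), len(kept), removal_counts["removed_small"],
                 removal_counts["removed_enhancing"])

        stage = "analyze"
        log.info("stage analyze: voxel-wise group histograms and rank contrast")
        voxels = {}
        for mask, label in ((prl_mask, PRL), (nprwml_mask, NPRWML)):
            voxels[label] = norm_pre.data[mask.data > 0]
        group_sums = {}
        for label, vals in voxels.items():
            hist = group_histogram(vals, config.bin_width, group=label)
            hist.write(out / f"histogram_{label.replace('-', '_')}.tsv")
            group_sums[label] = summarize_group(
                vals, config.bin_width, config.smooth_window,
                config.deep_cutoff, group=label)
        w_stat, w_p = wilcoxon_rank_sum(
            table.loc[table["class"] == PRL, "p5_t1pre"],
            table.loc[table["class"] == NPRWML, "p5_t1pre"],
        )
        report["voxelwise"] = {label: _summary_dict(s) for label, s in group_sums.items()}
        report["lesionwise_contrast"] = {"wilcoxon_statistic": w_stat,
                                         "wilcoxon_p": w_p}

        stage = "classify"
        log.info("stage classify: stratified split and cutoff selection")
        results = P5RimClassifier(table, config.spec_constraint).fit(
            fraction=config.split_fraction, seed=config.seed)
        report["classifier"] = results.to_dict()
        (out / "classifier_summary.txt").write_text(results.summary() + "\n")
    except Exception as e:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {e}") from e

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    log.info("run complete: %s", out / "report.json")
    return report


def _setup_logging(logfile: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers
                    if not isinstance(h, logging.FileHandler)]
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
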