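"""The lesion-wise p5 intensity classifier.

A single-feature threshold classifier: a lesion is called a phase-rim
lesion (PRL) when the 5th percentile of its normalized pre-contrast T1
intensities falls strictly below a cutoff. The cutoff is selected on a
stratified training half by an exhaustive specificity-constrained ROC
search: among all candidate cutoffs (midpoints between consecutive
observed p5 values, plus degenerate sentinels) whose training specificity
meets the constraint, the one maximizing sensitivity wins; ties go to the
higher specificity, then to the lower cutoff. Specificity is constrained
rather than balanced because PRLs are rare (~1:27 class imbalance): any
loss of specificity floods the detections with false positives.

The module exposes the individual operations and, on top of them, a
statsmodels-flavoured model object:

>>> model = P5RimClassifier(table, spec_constraint=0.95)
>>> res = model.fit(seed=7)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._stats import round_half_up
from .phantom import NPRWML, PRL

__all__ = [
    "SplitResult",
    "CutoffModel",
    "ConfusionMetrics",
    "stratified_split",
    "select_cutoff",
    "evaluate",
    "fisher_exact",
    "P5RimClassifier",
    "RimClassifierResults",
]


@dataclass
class SplitResult:
    train: pd.DataFrame
    test: pd.DataFrame
    seed: int
    fraction: float


@dataclass
class CutoffModel:
    """A selected threshold: predict PRL iff p5 < cutoff."""

    cutoff: float
    spec_constraint: float
    train_sensitivity: float
    train_specificity: float
    direction: str = "below"

    def predict(self, p5_values) -> np.ndarray:
        """True where a lesion is called PRL. p5 == cutoff predicts negative."""
        return np.asarray(p5_values, dtype=float) < self.cutoff


@dataclass
class ConfusionMetrics:
    """Confusion counts with derived proportions; undefined ratios are None
    and listed in ``undefined`` rather than silently reported as 0."""

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    f1: float | None = None
    fisher_p: float | None = None
    undefined: tuple = ()

    @classmethod
    def from_counts(cls, tp: int, fn: int, fp: int, tn: int,
                    with_fisher: bool = True) -> "ConfusionMetrics":
        def ratio(num, den):
            return num / den if den > 0 else None

        sens = ratio(tp, tp + fn)
        spec = ratio(tn, tn + fp)
        ppv = ratio(tp, tp + fp)
        npv = ratio(tn, tn + fn)
        f1 = None
        if ppv is not None and sens is not None and (ppv + sens) > 0:
            f1 = 2 * ppv * sens / (ppv + sens)
        und = tuple(
            name for name, v in
            [("sensitivity", sens), ("specificity", spec), ("ppv", ppv),
             ("npv", npv), ("f1", f1)] if v is None
        )
        fp_val = fisher_exact([[tp, fn], [fp, tn]]) if with_fisher else None
        return cls(tp=tp, fn=fn, fp=fp, tn=tn, sensitivity=sens, specificity=spec,
                   ppv=ppv, npv=npv, f1=f1, fisher_p=fp_val, undefined=und)

    def rounded(self, ndigits: int = 3) -> dict:
        """Metrics rounded half-up to reporting precision."""
        out = {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}
        for name in ("sensitivity", "specificity", "ppv", "npv", "f1", "fisher_p"):
            v = getattr(self, name)
            out[name] = None if v is None else round_half_up(v, ndigits)
        return out


def _require_columns(table: pd.DataFrame) -> None:
    for col in ("class", "p5_t1pre"):
        if col not in table.columns:
            raise ValueError(f"lesion table lacks required column {col!r}")


def stratified_split(table: pd.DataFrame, fraction: float = 0.5,
                     seed: int = 0) -> SplitResult:
    """Per-class random split; odd class counts favor the training half.

    With 39 PRLs and 1075 nPR-WMLs at fraction 0.5 this yields 20/538 in
    training and 19/537 in test for every seed.
    """
    _require_columns(table)
    if table.empty:
        raise ValueError("cannot split an empty lesion table")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    for label in (PRL, NPRWML):
        idx = table.index[table["class"] == label].to_numpy()
        if idx.size == 0:
            raise ValueError(f"class {label!r} has no lesions; cannot stratify")
        perm = rng.permutation(idx)
        n_train = int(np.ceil(idx.size * fraction))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return SplitResult(train=table.loc[sorted(train_idx)],
                       test=table.loc[sorted(test_idx)],
                       seed=seed, fraction=fraction)


def _counts_at(cutoff: float, p5: np.ndarray, is_prl: np.ndarray):
    pred = p5 < cutoff
    tp = int(np.sum(pred & is_prl))
    fn = int(np.sum(~pred & is_prl))
    fp = int(np.sum(pred & ~is_prl))
    tn = int(np.sum(~pred & ~is_prl))
    return tp, fn, fp, tn


def select_cutoff(train: pd.DataFrame, spec_constraint: float = 0.95) -> CutoffModel:
    """Exhaustive specificity-constrained ROC cutoff search on training data.

    Candidates are midpoints between consecutive sorted unique p5 values,
    plus two finite sentinels realizing the all-negative (cutoff = min p5)
    and all-positive (cutoff = max p5 + 1) rules.
    """
    _require_columns(train)
    is_prl = (train["class"] == PRL).to_numpy()
    p5 = train["p5_t1pre"].to_numpy(dtype=float)
    if not is_prl.any() or is_prl.all():
        raise ValueError("training data must contain both classes")
    uniq = np.unique(p5)
    candidates = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1.0]])

    best = None
    for c in candidates:
        tp, fn, fp, tn = _counts_at(c, p5, is_prl)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        if spec < spec_constraint:
            continue
        key = (sens, spec, -c)  # max sens, then max spec, then lowest cutoff
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    if best is None:
        raise ValueError(
            f"no cutoff attains training specificity >= {spec_constraint}; "
            "lower the constraint"
        )
    _, cutoff, sens, spec = best
    return CutoffModel(cutoff=float(cutoff), spec_constraint=spec_constraint,
                       train_sensitivity=sens, train_specificity=spec)


def evaluate(test: pd.DataFrame, model: CutoffModel) -> ConfusionMetrics:
    """Apply a fitted cutoff to held-out lesions and tabulate the result."""
    _require_columns(test)
    if test.empty:
        raise ValueError("test table is empty")
    is_prl = (test["class"] == PRL).to_numpy()
    p5 = test["p5_t1pre"].to_numpy(dtype=float)
    tp, fn, fp, tn = _counts_at(model.cutoff, p5, is_prl)
    return ConfusionMetrics.from_counts(tp, fn, fp, tn)


def fisher_exact(table2x2) -> float:
    """Two-sided Fisher exact p: the total probability of all tables with
    the observed margins whose hypergeometric probability does not exceed
    the observed table's."""
    t = np.asarray(table2x2)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    if t.sum() == 0:
        raise ValueError("grand total must be positive")
    return float(scipy.stats.fisher_exact(t, alternative="two-sided")[1])


class P5RimClassifier:
    """Threshold model for PRL detection from a lesion feature table.

    Parameters
    ----------
    table : DataFrame
        Lesion table with at least ``class`` and ``p5_t1pre`` columns.
    spec_constraint : float
        Minimum training specificity the selected cutoff must attain.
    """

    def __init__(self, table: pd.DataFrame, spec_constraint: float = 0.95):
        _require_columns(table)
        self.table = table.reset_index(drop=True)
        self.spec_constraint = float(spec_constraint)

    @classmethod
    def from_tsv(cls, path, spec_constraint: float = 0.95) -> "P5RimClassifier":
        from .lesions import read_table

        return cls(read_table(path), spec_constraint)

    def fit(self, fraction: float = 0.5, seed: int = 0) -> "RimClassifierResults":
        split = stratified_split(self.table, fraction=fraction, seed=seed)
        cut = select_cutoff(split.train, self.spec_constraint)
        metrics = evaluate(split.test, cut)
        return RimClassifierResults(model=self, split=split, cutoff_model=cut,
                                    test_metrics=metrics)


@dataclass
class RimClassifierResults:
    """Fitted cutoff, split bookkeeping and held-out evaluation."""

    model: P5RimClassifier
    split: SplitResult
    cutoff_model: CutoffModel
    test_metrics: ConfusionMetrics

    @property
    def cutoff(self) -> float:
        return self.cutoff_model.cutoff

    def predict(self, p5_values) -> np.ndarray:
        return self.cutoff_model.predict(p5_values)

    def to_dict(self) -> dict:
        c = self.split
        return {
            "split": {
                "seed": c.seed, "fraction": c.fraction,
                "train_prl": int((c.train["class"] == PRL).sum()),
                "train_nprwml": int((c.train["class"] == NPRWML).sum()),
                "test_prl": int((c.test["class"] == PRL).sum()),
                "test_nprwml": int((c.test["class"] == NPRWML).sum()),
            },
            "cutoff": self.cutoff,
            "spec_constraint": self.cutoff_model.spec_constraint,
            "train_sensitivity": self.cutoff_model.train_sensitivity,
            "train_specificity": self.cutoff_model.train_specificity,
            "test": self.test_metrics.rounded(),
        }

    def summary(self) -> str:
        d = self.to_dict()
        t = d["test"]
        lines = [
            "p5 intensity PRL classifier",
            "===========================",
            f"train: {d['split']['train_prl']} PRL / {d['split']['train_nprwml']} nPR-WML"
            f"   test: {d['split']['test_prl']} PRL / {d['split']['test_nprwml']} nPR-WML",
            f"cutoff (predict PRL if p5 < cutoff): {d['cutoff']:.3f}",
            f"training sensitivity {d['train_sensitivity']:.3f}  "
            f"specificity {d['train_specificity']:.3f} (constraint >= {d['spec_constraint']})",
            "test confusion matrix: "
            f"tp={t['tp']} fn={t['fn']} fp={t['fp']} tn={t['tn']}",
            "test metrics: "
            + "  ".join(
                f"{k}={t[k] if t[k] is not None else 'undefined'}"
                for k in ("sensitivity", "specificity", "ppv", "npv", "f1")
            ),
            f"Fisher exact p = {t['fisher_p']:.3g}" if t["fisher_p"] is not None else "",
        ]
        return "\n".join(line for line in lines if line)
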