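"""Pixel-level segmentation metrics and Fisher's LSD multiple comparison.

Metrics treat the PTC label (2) as the positive class and everything else
as negative. Per-slide records are macro-averaged across a cohort by
default (micro/pooled-pixel averaging is available); method-vs-method
differences are assessed with one-way-ANOVA-pooled pairwise t tests
(Fisher's Least Significant Difference, no multiplicity adjustment).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .slide_io import SlideMask, read_slide_mask

__all__ = ["ConfusionCounts", "MetricsRecord", "LSDComparison",
           "confusion", "metrics", "lsd_test", "evaluate_cohort"]

POSITIVE_LABEL = 2
METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "jaccard")


@dataclass
class ConfusionCounts:
    """Pixel confusion counts for the positive (PTC) class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __iadd__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        self.tn += other.tn
        return self


@dataclass
class MetricsRecord:
    slide_id: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    jaccard: float


@dataclass
class LSDComparison:
    """One pairwise row of the post-hoc table."""

    metric: str
    group_i: str
    group_j: str
    mean_diff: float  # mean(I) − mean(J)
    std_error: float
    p_value: float
    ci_low: float
    ci_high: float
    df: int
    degenerate: bool = False  # zero pooled within-group variance


def _as_labels(mask) -> np.ndarray:
    if isinstance(mask, SlideMask):
        return mask.labels
    if isinstance(mask, (str, Path)):
        return read_slide_mask(mask).labels
    return np.asarray(mask)


def confusion(pred, truth, positive_label: int = POSITIVE_LABEL,
              block_px: int = 2048) -> ConfusionCounts:
    """Exact streaming confusion counts between two label masks.

    Masks may be arrays, :class:`SlideMask` objects, or paths to mask
    TIFFs; counting proceeds block-wise so the two masks are never
    compared as single dense boolean arrays.
    """
    p = _as_labels(pred)
    t = _as_labels(truth)
    if p.shape != t.shape:
        raise ValueError(f"mask dimensions differ: {p.shape} vs {t.shape}")
    out = ConfusionCounts()
    h, w = p.shape
    for y0 in range(0, h, block_px):
        for x0 in range(0, w, block_px):
            pb = np.asarray(p[y0:y0 + block_px, x0:x0 + block_px]) == positive_label
            tb = np.asarray(t[y0:y0 + block_px, x0:x0 + block_px]) == positive_label
            tp = int(np.count_nonzero(pb & tb))
            fp = int(np.count_nonzero(pb)) - tp
            fn = int(np.count_nonzero(tb)) - tp
            out += ConfusionCounts(tp=tp, fp=fp, fn=fn,
                                   tn=pb.size - tp - fp - fn)
    return out


def metrics(counts: ConfusionCounts, slide_id: str = "") -> MetricsRecord:
    """The five segmentation metrics from confusion counts.

    Conventions for empty denominators: a slide where both truth and
    prediction contain zero positives scores 1.0 on precision, recall,
    F1 and Jaccard (a correctly-empty prediction is perfect); any other
    empty denominator yields 0. F1 and Jaccard always satisfy
    ``f1 = 2·J/(1+J)``.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    total = counts.total
    if total <= 0:
        raise ValueError("confusion counts are empty")
    accuracy = (tp + tn) / total
    if tp + fn == 0 and fp == 0:
        precision = recall = f1 = jaccard = 1.0
    else:
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        jaccard = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    return MetricsRecord(slide_id=slide_id, accuracy=accuracy,
                         precision=precision, recall=recall, f1=f1,
                         jaccard=jaccard)


def lsd_test(groups: Mapping[str, Sequence[float]],
             metric: str = "") -> List[LSDComparison]:
    """Fisher's LSD: pairwise t tests on the pooled ANOVA error term.

    With groups of sizes ``n_i`` totalling ``N`` over ``k`` groups, the
    pooled mean square error has ``N − k`` degrees of freedom and each
    pair (I, J) is tested with
    ``t = (m_I − m_J) / sqrt(MSE·(1/n_I + 1/n_J))`` (two-sided), with a
    95% confidence interval ``diff ± t_{0.975,df}·SE``. No multiplicity
    adjustment is applied.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = {g: np.asarray(groups[g], dtype=np.float64) for g in names}
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs at least two values")
    n_total = sum(v.size for v in data.values())
    k = len(names)
    df = n_total - k
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    mse = ss_within / df
    degenerate = mse == 0.0

    out: List[LSDComparison] = []
    tcrit = stats.t.ppf(0.975, df)
    for gi, gj in itertools.combinations(names, 2):
        vi, vj = data[gi], data[gj]
        diff = vi.mean() - vj.mean()
        se = float(np.sqrt(mse * (1.0 / vi.size + 1.0 / vj.size)))
        if se == 0.0:
            tstat = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
            p = 1.0 if diff == 0.0 else 0.0
        else:
            tstat = diff / se
            p = 2.0 * float(stats.t.sf(abs(tstat), df))
        half = tcrit * se
        out.append(LSDComparison(
            metric=metric, group_i=gi, group_j=gj, mean_diff=float(diff),
            std_error=se, p_value=p, ci_low=float(diff - half),
            ci_high=float(diff + half), df=df, degenerate=degenerate))
    return out


def _records_frame(records: List[dict]) -> pd.DataFrame:
    return pd.DataFrame.from_records(records)


def evaluate_cohort(
    pred_masks: Mapping,
    truth_masks: Mapping,
    slide_types: Optional[Mapping[str, str]] = None,
    positive_label: int = POSITIVE_LABEL,
    average: str = "macro",
    out_dir: Optional[Union[str, Path]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Score a cohort of slides, optionally across several methods.

    ``pred_masks`` is either ``{slide_id: mask}`` (single method) or
    ``{method: {slide_id: mask}}``. ``truth_masks`` maps slide id to the
    reference mask. ``slide_types`` (e.g. FNA/TP preparation type)
    stratifies the summary; without it only the "All" stratum is
    reported. Returns ``(per_slide, summary, lsd)`` tables; the LSD table
    is non-empty when at least two methods with two slides each are
    present. ``average="micro"`` pools pixels within each summary cell
    instead of averaging per-slide metrics.
    """
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")
    first = next(iter(pred_masks.values()), None)
    if not isinstance(first, Mapping):
        pred_masks = {"method": pred_masks}

    per_slide_rows: List[dict] = []
    counts_store: Dict[Tuple[str, str], ConfusionCounts] = {}
    for method, slides in pred_masks.items():
        missing = sorted(set(truth_masks) - set(slides)) + \
                  sorted(set(slides) - set(truth_masks))
        if missing:
            raise ValueError(
                f"method {method!r}: prediction/truth slide sets differ "
                f"for ids {missing}")
        for sid in slides:
            cc = confusion(slides[sid], truth_masks[sid], positive_label)
            counts_store[(method, sid)] = cc
            rec = metrics(cc, slide_id=sid)
            row = {"method": method, "slide_id": sid,
                   "type": (slide_types or {}).get(sid, "All")}
            row.update({m: getattr(rec, m) for m in METRIC_NAMES})
            per_slide_rows.append(row)
    per_slide = _records_frame(per_slide_rows)

    summary_rows: List[dict] = []
    strata = ["All"] + (sorted(set(slide_types.values())) if slide_types else [])
    for method in pred_masks:
        sub_m = per_slide[per_slide["method"] == method]
        for stratum in strata:
            sub = sub_m if stratum == "All" else sub_m[sub_m["type"] == stratum]
            if sub.empty:
                continue
            row = {"method": method, "stratum": stratum, "n_slides": len(sub)}
            if average == "macro":
                row.update({m: float(sub[m].mean()) for m in METRIC_NAMES})
            else:
                pooled = ConfusionCounts()
                for sid in sub["slide_id"]:
                    pooled += counts_store[(method, sid)]
                rec = metrics(pooled)
                row.update({m: getattr(rec, m) for m in METRIC_NAMES})
            summary_rows.append(row)
    summary = _records_frame(summary_rows)

    lsd_rows: List[dict] = []
    methods = list(pred_masks)
    if len(methods) >= 2 and all(
            (per_slide["method"] == m).sum() >= 2 for m in methods):
        for m in METRIC_NAMES:
            groups = {meth: per_slide.loc[per_slide["method"] == meth, m].tolist()
                      for meth in methods}
            for comp in lsd_test(groups, metric=m):
                lsd_rows.append(comp.__dict__.copy())
    lsd = _records_frame(lsd_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_slide.to_csv(out_dir / "per_slide.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
        lsd.to_csv(out_dir / "lsd.csv", index=False)
    return per_slide, summary, lsd
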