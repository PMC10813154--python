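"""Individual-feature discrimination stage.

For every unordered pair of diagnostic groups and every feature-matrix
column, this stage runs distribution checks (Kolmogorov-Smirnov
normality, Levene homoscedasticity), a two-sided Mann-Whitney screen at
alpha = 0.05, and a single-feature leave-one-out classifier ("XROC"),
reporting accuracy and positive-class recall per column plus a
best-per-comparison table and per-feature significance counts.

The positive class of a comparison is its first-named group, which is
how a swamped minority class can show 0% recall next to high accuracy
on strongly imbalanced cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES
from .matrix import FeatureMatrix, parse_column
from .records import GroupLabel

__all__ = ["BinaryComparison", "DEFAULT_GROUP_ORDER", "enumerate_comparisons",
           "check_parametric_assumptions", "mann_whitney", "xroc_classify",
           "run_individual_stage"]

#: Canonical ordering of the 8 groups for comparison naming.  Rarer
#: classes come first, so the first-named (positive) class of each pair
#: is the minority in the imbalanced reference cohort.
DEFAULT_GROUP_ORDER: tuple[GroupLabel, ...] = (
    GroupLabel.VHD, GroupLabel.M, GroupLabel.MI, GroupLabel.MH,
    GroupLabel.HC, GroupLabel.Dis, GroupLabel.CardMyo, GroupLabel.BBB,
)


@dataclass(frozen=True)
class BinaryComparison:
    """One unordered pair of groups; the first-named group is positive."""

    group_a: GroupLabel
    group_b: GroupLabel

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("comparison groups must differ")

    @property
    def label(self) -> str:
        return f"{self.group_a.value}vs.{self.group_b.value}"


def enumerate_comparisons(groups) -> list[BinaryComparison]:
    """All unordered group pairs in deterministic (input) order."""
    groups = [GroupLabel(g) for g in groups]
    if len(set(groups)) != len(groups):
        raise ValueError("duplicate groups in comparison list")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    return [BinaryComparison(a, b) for a, b in combinations(groups, 2)]


def check_parametric_assumptions(a, b, alpha: float = 0.05) -> tuple[bool, bool]:
    """(normal, homoscedastic) gate for parametric testing.

    Normality uses a Kolmogorov-Smirnov test of each standardised
    sample against the standard normal; homoscedasticity uses Levene's
    test.  Samples smaller than 3 are flagged indeterminate and treated
    as assumption-failed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        return False, False

    def ks_normal(x: np.ndarray) -> bool:
        sd = np.std(x, ddof=1)
        if sd == 0:
            return False
        z = (x - np.mean(x)) / sd
        return stats.kstest(z, "norm").pvalue >= alpha

    normal = ks_normal(a) and ks_normal(b)
    homoscedastic = stats.levene(a, b).pvalue >= alpha
    return normal, homoscedastic


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney p-value.

    Uses the exact null distribution when n_a * n_b <= 400 and there
    are no ties, otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Mann-Whitney requires non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def _loocv_nearest_mean(values: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Held-out class of each sample under the nearest-training-mean rule."""
    n = len(values)
    sum_a, n_a = values[is_a].sum(), int(is_a.sum())
    sum_b, n_b = values[~is_a].sum(), n - n_a
    pred = np.empty(n, dtype=bool)
    for i in range(n):
        if is_a[i]:
            ca, na = sum_a - values[i], n_a - 1
            cb, nb = sum_b, n_b
        else:
            ca, na = sum_a, n_a
            cb, nb = sum_b - values[i], n_b - 1
        if na == 0:      # fold emptied class a -> must predict b
            pred[i] = False
        elif nb == 0:
            pred[i] = True
        else:
            pred[i] = abs(values[i] - ca / na) < abs(values[i] - cb / nb)
    return pred


def _loocv_roc_threshold(values: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Held-out class under a training-fold Youden-optimal threshold."""
    n = len(values)
    pred = np.empty(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        v, lab = values[mask], is_a[mask]
        if lab.all() or not lab.any():
            pred[i] = lab.all()
            continue
        direction = 1.0 if v[lab].mean() >= v[~lab].mean() else -1.0
        sv = np.sort(np.unique(v * direction))
        cuts = np.concatenate([[sv[0] - 1.0], (sv[:-1] + sv[1:]) / 2.0,
                               [sv[-1] + 1.0]])
        vd = v * direction
        best_cut, best_j = cuts[0], -np.inf
        for cut in cuts:
            sens = np.mean(vd[lab] > cut)
            spec = np.mean(vd[~lab] <= cut)
            j = sens + spec - 1.0
            if j > best_j:
                best_j, best_cut = j, cut
        pred[i] = values[i] * direction > best_cut
    return pred


def xroc_classify(a, b, rule: str = "nearest_mean") -> tuple[float, float]:
    """Single-feature LOOCV classification of two samples.

    Returns ``(accuracy %, recall %)``, recall taken on the positive
    class ``a``.  ``rule="nearest_mean"`` (default) assigns each
    held-out value to the class with the nearer training-fold mean;
    ``rule="roc_threshold"`` uses the training-fold Youden-optimal cut.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) + len(b) < 3:
        raise ValueError("LOOCV needs at least 3 pooled samples")
    values = np.concatenate([a, b])
    is_a = np.zeros(len(values), dtype=bool)
    is_a[: len(a)] = True
    if rule == "nearest_mean":
        pred = _loocv_nearest_mean(values, is_a)
    elif rule == "roc_threshold":
        pred = _loocv_roc_threshold(values, is_a)
    else:
        raise ValueError(f"unknown XROC rule {rule!r}")
    accuracy = float(np.mean(pred == is_a) * 100.0)
    recall = float(np.mean(pred[is_a]) * 100.0) if is_a.any() else 0.0
    return accuracy, recall


def run_individual_stage(
    matrix: FeatureMatrix,
    comparisons: list[BinaryComparison] | None = None,
    alpha: float = 0.05,
    rule: str = "nearest_mean",
    mtc: str = "none",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Screen every (comparison x column) cell of the matrix.

    Returns ``(results, best, counts)``:

    * ``results`` — one row per cell with the Mann-Whitney p-value,
      its significance at ``alpha`` (optionally Benjamini-Hochberg
      adjusted within each comparison when ``mtc="bh"``), and the XROC
      accuracy and recall;
    * ``best`` — the best cell per comparison, selected by accuracy,
      then recall, then lexicographic column name;
    * ``counts`` — per-comparison significant-column counts per
      original feature (plus Total row and column).
    """
    if comparisons is None:
        seen = set(matrix.groups.astype(str))
        order = [g for g in DEFAULT_GROUP_ORDER if g.value in seen]
        comparisons = enumerate_comparisons(order)
    rows = []
    labels = matrix.groups.astype(str).to_numpy()
    data = matrix.data.to_numpy(dtype=float)
    columns = list(matrix.data.columns)
    for comp in comparisons:
        mask_a = labels == comp.group_a.value
        mask_b = labels == comp.group_b.value
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            warnings.warn(
                f"comparison {comp.label}: a group has < 2 records; skipped",
                stacklevel=2,
            )
            continue
        pvals = np.empty(len(columns))
        accs = np.empty(len(columns))
        recs = np.empty(len(columns))
        for j in range(len(columns)):
            va, vb = data[mask_a, j], data[mask_b, j]
            pvals[j] = mann_whitney(va, vb)
            accs[j], recs[j] = xroc_classify(va, vb, rule=rule)
        if mtc == "bh":
            adj = stats.false_discovery_control(pvals, method="bh")
            significant = adj < alpha
        elif mtc == "none":
            significant = pvals < alpha
        else:
            raise ValueError(f"unknown multiple-testing mode {mtc!r}")
        for j, col in enumerate(columns):
            rows.append({
                "comparison": comp.label, "column": col,
                "p_value": pvals[j], "significant": bool(significant[j]),
                "xroc_accuracy": accs[j], "xroc_recall": recs[j],
            })
    results = pd.DataFrame(rows)
    if results.empty:
        raise ValueError("no comparison had enough records")

    best_rows = []
    for comp_label, sub in results.groupby("comparison", sort=False):
        sub = sub.sort_values(
            by=["xroc_accuracy", "xroc_recall", "column"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        top = sub.iloc[0]
        lead, feature, m, stat = parse_column(top["column"])
        best_rows.append({
            "comparison": comp_label, "feature": feature, "compressor": stat,
            "subband": m, "lead": lead,
            "p_value": top["p_value"] if top["significant"] else np.nan,
            "significant": bool(top["significant"]),
            "recall": top["xroc_recall"], "accuracy": top["xroc_accuracy"],
        })
    best = pd.DataFrame(best_rows)

    count_rows = []
    for comp_label, sub in results.groupby("comparison", sort=False):
        sig = sub[sub["significant"]]
        feat_of = sig["column"].map(lambda c: parse_column(c)[1])
        row = {"comparison": comp_label}
        for f in FEATURE_NAMES:
            row[f] = int((feat_of == f).sum())
        row["Total"] = int(len(sig))
        count_rows.append(row)
    counts = pd.DataFrame(count_rows)
    total = {"comparison": "Total"}
    for f in list(FEATURE_NAMES) + ["Total"]:
        total[f] = int(counts[f].sum())
    counts = pd.concat([counts, pd.DataFrame([total])], ignore_index=True)
    return results, best, counts
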