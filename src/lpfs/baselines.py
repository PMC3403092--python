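"""Comparison feature-selection methods: t-statistic, fold change, SVM-RFE.

Filter baselines score features one at a time (two-sample t-statistic on the
log scale, raw fold change, absolute log-fold-change with a cutoff); SVM-RFE
is the wrapper baseline, recursively eliminating the features a linear
max-margin classifier weighs least.

Conventions the callers must respect: t_statistic and rank_by_abs_logfc
expect log-scale data; fold_change expects raw (unlogged) intensities.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .io_profiles import GroupedDataset

__all__ = [
    "FeatureStats",
    "RFEResult",
    "t_statistic",
    "t_pvalue",
    "fold_change",
    "rank_by_abs_logfc",
    "svm_rfe",
    "feature_stats",
]


def _group_check(ds: GroupedDataset) -> None:
    if ds.m1 < 2 or ds.m2 < 2:
        raise ValueError("both groups need >= 2 samples")


def t_statistic(ds_log: GroupedDataset) -> np.ndarray:
    """Signal-to-noise two-sample statistic T_i = (xbar_i - ybar_i) / s_i.

    s_i is the pooled two-group standard deviation
    sqrt(((m1-1) s_case^2 + (m2-1) s_ctrl^2) / (m1 + m2 - 2)); note there is
    no sqrt(1/m1 + 1/m2) factor, so this is the plain mean-difference-over-sd
    form rather than the textbook t. Input must be on the log scale.

    Zero pooled sd with a nonzero mean difference yields a signed infinity
    sentinel (ranks above every finite value); zero sd with zero difference
    yields 0.
    """
    _group_check(ds_log)
    diff = ds_log.T.mean(axis=0) - ds_log.F.mean(axis=0)
    var_case = ds_log.T.var(axis=0, ddof=1)
    var_ctrl = ds_log.F.var(axis=0, ddof=1)
    pooled = np.sqrt(
        ((ds_log.m1 - 1) * var_case + (ds_log.m2 - 1) * var_ctrl)
        / (ds_log.m1 + ds_log.m2 - 2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / pooled
    zero_sd = pooled == 0
    t[zero_sd & (diff > 0)] = np.inf
    t[zero_sd & (diff < 0)] = -np.inf
    t[zero_sd & (diff == 0)] = 0.0
    return t


def t_pvalue(T, df: int, sided: str = "one"):
    """Student-t tail probability for a statistic treated as t-distributed.

    One-sided: P(t_df > T). Two-sided: 2 * P(t_df > |T|). df conventionally
    m1 + m2 - 2.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    T = np.asarray(T, dtype=float)
    if sided == "one":
        p = stats.t.sf(T, df)
    elif sided == "two":
        p = 2.0 * stats.t.sf(np.abs(T), df)
    else:
        raise ValueError(f"sided must be one or two, got {sided!r}")
    return float(p) if p.ndim == 0 else p


def fold_change(ds_raw: GroupedDataset) -> np.ndarray:
    """FC_i = (raw case mean) / (raw control mean), per feature."""
    _group_check(ds_raw)
    mean_case = ds_raw.T.mean(axis=0)
    mean_ctrl = ds_raw.F.mean(axis=0)
    bad = np.flatnonzero(mean_ctrl <= 0)
    if bad.size:
        raise ValueError(
            f"control mean is non-positive for feature "
            f"{ds_raw.feature_ids[bad[0]]!r}; fold change undefined"
        )
    return mean_case / mean_ctrl


def rank_by_abs_logfc(ds_log: GroupedDataset, cutoff: float = 2.0):
    """Rank features by |log-scale mean difference|; select those above cutoff.

    The log-scale difference of group means is the fold change of
    log-transformed data. Returns (order, selected): ``order`` lists feature
    indices by descending score (ties broken by index), ``selected`` the
    indices with score strictly above ``cutoff`` in that same order.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    _group_check(ds_log)
    score = np.abs(ds_log.T.mean(axis=0) - ds_log.F.mean(axis=0))
    order = sorted(range(score.size), key=lambda i: (-score[i], i))
    selected = [i for i in order if score[i] > cutoff]
    return order, selected


@dataclasses.dataclass(frozen=True)
class RFEResult:
    """SVM-RFE output.

    ``ranking`` lists feature indices from most to least important
    (survivors first, then features in reverse elimination order);
    ``rank`` maps feature index -> 1-based importance rank;
    ``accuracy_curve`` maps retained-set size -> leave-one-out accuracy of
    the linear SVM on the features retained at that size.
    """

    ranking: tuple[int, ...]
    rank: np.ndarray
    accuracy_curve: dict[int, float]
    surviving: tuple[int, ...]


def _svm_loo_accuracy(X: np.ndarray, y: np.ndarray, C: float) -> float:
    correct = 0
    for i in range(X.shape[0]):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[i] = False
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[mask], y[mask])
        correct += int(clf.predict(X[i : i + 1])[0] == y[i])
    return correct / X.shape[0]


def svm_rfe(
    ds: GroupedDataset,
    step: int = 1,
    stop_at: int = 1,
    seed: int = 0,
    C: float = 1.0,
    accuracy_curve: bool = True,
) -> RFEResult:
    """Recursive feature elimination with a linear max-margin classifier.

    At each round a linear SVM (regularization constant ``C``) is fitted on
    the currently retained features and the ``step`` features with the
    smallest squared weights are discarded, until ``stop_at`` features
    remain. Later-eliminated features are more important. Deterministic
    given the data (``seed`` is accepted for interface uniformity; the
    hard-margin fit itself has no randomness).
    """
    _group_check(ds)
    if step < 1:
        raise ValueError("step must be >= 1")
    if not 1 <= stop_at <= ds.n:
        raise ValueError("stop_at must be in [1, n]")
    X = np.vstack([ds.T, ds.F])
    y = np.concatenate([np.ones(ds.m1), np.zeros(ds.m2)])
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("all features have zero variance; RFE is degenerate")
    remaining = list(range(ds.n))
    eliminated: list[int] = []  # chronological elimination order
    curve: dict[int, float] = {}
    while len(remaining) > stop_at:
        Xr = X[:, remaining]
        if accuracy_curve:
            curve[len(remaining)] = _svm_loo_accuracy(Xr, y, C)
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xr, y)
        w2 = np.asarray(clf.coef_).ravel() ** 2
        n_drop = min(step, len(remaining) - stop_at)
        # smallest squared weight first; ties broken by feature index
        drop_local = sorted(range(len(remaining)), key=lambda j: (w2[j], remaining[j]))[:n_drop]
        for j in sorted(drop_local, reverse=True):
            eliminated.append(remaining.pop(j))
    if accuracy_curve and remaining:
        curve[len(remaining)] = _svm_loo_accuracy(X[:, remaining], y, C)
    ranking = tuple(remaining) + tuple(reversed(eliminated))
    rank = np.empty(ds.n, dtype=int)
    for pos, feat in enumerate(ranking, start=1):
        rank[feat] = pos
    return RFEResult(
        ranking=ranking,
        rank=rank,
        accuracy_curve=curve,
        surviving=tuple(remaining),
    )


def feature_stats(ds_raw: GroupedDataset, ds_log: GroupedDataset) -> pd.DataFrame:
    """Per-feature summary table combining the filter statistics.

    Columns: log-scale group means, pooled sd, t statistic, raw group
    means, fold change, absolute log-fold-change, and per-method ranks
    (1 = top).
    """
    t = t_statistic(ds_log)
    fc = fold_change(ds_raw)
    abs_lfc = np.abs(ds_log.T.mean(axis=0) - ds_log.F.mean(axis=0))
    var_case = ds_log.T.var(axis=0, ddof=1)
    var_ctrl = ds_log.F.var(axis=0, ddof=1)
    pooled = np.sqrt(
        ((ds_log.m1 - 1) * var_case + (ds_log.m2 - 1) * var_ctrl)
        / (ds_log.m1 + ds_log.m2 - 2)
    )
    df = pd.DataFrame(
        {
            "feature_id": list(ds_log.feature_ids),
            "mean_case": ds_log.T.mean(axis=0),
            "mean_control": ds_log.F.mean(axis=0),
            "sd": pooled,
            "t": t,
            "mean_case_raw": ds_raw.T.mean(axis=0),
            "mean_control_raw": ds_raw.F.mean(axis=0),
            "fc": fc,
            "abs_log_fc": abs_lfc,
        }
    )
    if ds_log.ppm is not None:
        df.insert(1, "ppm", ds_log.ppm)
    df["rank_t"] = (-np.abs(df["t"])).rank(method="first").astype(int)
    df["rank_fc"] = (-np.maximum(df["fc"], 1.0 / df["fc"])).rank(method="first").astype(int)
    df["rank_abs_log_fc"] = (-df["abs_log_fc"]).rank(method="first").astype(int)
    return df


FeatureStats = pd.DataFrame  # the canonical container for per-feature stats
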