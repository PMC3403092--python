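"""Nearest-centroid classification under the L1 metric, with leave-one-out folds.

The classifier keeps one prototype per class — the arithmetic mean profile —
and assigns a sample to the class whose prototype is nearest in L1 (city-block)
distance, a metric robust to the outlier bins common in NMR profiles. Training
is O(m*n); classification is O(n) per class.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np

from .io_profiles import CASE, CONTROL, GroupedDataset

__all__ = [
    "CentroidModel",
    "LooFold",
    "compute_centroid",
    "l1_distance",
    "classify",
    "loo_folds",
    "loo_accuracy",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class CentroidModel:
    """Class prototypes: case centroid mu_T and control centroid mu_F."""

    mu_T: np.ndarray
    mu_F: np.ndarray
    feature_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        mu_T = np.asarray(self.mu_T, dtype=float)
        mu_F = np.asarray(self.mu_F, dtype=float)
        if mu_T.shape != mu_F.shape or mu_T.ndim != 1:
            raise ValueError("centroids must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(mu_T)) and np.all(np.isfinite(mu_F))):
            raise ValueError("centroids must be finite")
        object.__setattr__(self, "mu_T", mu_T)
        object.__setattr__(self, "mu_F", mu_F)

    @classmethod
    def fit(cls, ds: GroupedDataset) -> "CentroidModel":
        return cls(
            mu_T=compute_centroid(ds.T),
            mu_F=compute_centroid(ds.F),
            feature_ids=ds.feature_ids,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "mu_T": self.mu_T.tolist(),
                "mu_F": self.mu_F.tolist(),
                "feature_ids": list(self.feature_ids) if self.feature_ids else None,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CentroidModel":
        d = json.loads(text)
        fids = d.get("feature_ids")
        return cls(
            mu_T=np.asarray(d["mu_T"], dtype=float),
            mu_F=np.asarray(d["mu_F"], dtype=float),
            feature_ids=None if fids is None else tuple(fids),
        )


@dataclasses.dataclass(frozen=True)
class LooFold:
    """One leave-one-out fold: the held-out sample and the fold centroids.

    The held-out sample is removed from *its own* group's centroid only; the
    opposite group's centroid uses all of that group's samples.
    """

    held_out_group: str  # "case" or "control"
    held_out_index: int  # row index within its group matrix
    sample: np.ndarray
    mu_T_fold: np.ndarray
    mu_F_fold: np.ndarray


def compute_centroid(samples: np.ndarray) -> np.ndarray:
    """Columnwise arithmetic mean of an m x n sample matrix."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] == 0:
        raise ValueError("need a non-empty 2-D sample matrix")
    return samples.mean(axis=0)


def l1_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Sum of absolute coordinate differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).sum())


def classify(sample: np.ndarray, model: CentroidModel) -> str:
    """Assign ``sample`` to the class with the nearest centroid in L1.

    Exact ties are resolved to control (the no-effect class) with a logged
    warning: favoring the null is the conservative call for biomarker work.
    """
    d_case = l1_distance(sample, model.mu_T)
    d_control = l1_distance(sample, model.mu_F)
    if d_case == d_control:
        logger.warning(
            "sample equidistant from both centroids (L1 = %g); assigning control",
            d_case,
        )
        return CONTROL
    return CASE if d_case < d_control else CONTROL


def loo_folds(ds: GroupedDataset) -> list[LooFold]:
    """One fold per sample, m1 + m2 in total, case samples first.

    When a case sample is held out, mu_T is recomputed over the remaining
    m1 - 1 case samples while mu_F averages all m2 controls (and
    symmetrically for held-out controls).
    """
    mu_T = compute_centroid(ds.T)
    mu_F = compute_centroid(ds.F)
    folds: list[LooFold] = []
    for k in range(ds.m1):
        rest = np.delete(ds.T, k, axis=0)
        folds.append(
            LooFold(
                held_out_group=CASE,
                held_out_index=k,
                sample=ds.T[k],
                mu_T_fold=compute_centroid(rest),
                mu_F_fold=mu_F,
            )
        )
    for k in range(ds.m2):
        rest = np.delete(ds.F, k, axis=0)
        folds.append(
            LooFold(
                held_out_group=CONTROL,
                held_out_index=k,
                sample=ds.F[k],
                mu_T_fold=mu_T,
                mu_F_fold=compute_centroid(rest),
            )
        )
    return folds


def loo_accuracy(ds: GroupedDataset) -> float:
    """Leave-one-out accuracy of the plain nearest-centroid classifier."""
    correct = 0
    for fold in loo_folds(ds):
        model = CentroidModel(mu_T=fold.mu_T_fold, mu_F=fold.mu_F_fold)
        if classify(fold.sample, model) == fold.held_out_group:
            correct += 1
    return correct / (ds.m1 + ds.m2)
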