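"""Profile tables, labels, and the standard binned-NMR preprocessing chain.

A *profile matrix* is a samples x features table of nonnegative spectral
intensities (e.g. 0.01-ppm chemical-shift bins of a 1H NMR plasma spectrum).
This module reads and writes such tables, applies the conventional
preprocessing steps — solvent-region exclusion, constant-sum (total-area)
normalization, log transform, Pareto scaling — and splits a labeled table
into the case/control pair consumed by the selection machinery.

Preprocessing order matters: region exclusion must precede constant-sum
normalization, because normalizing first lets excluded bins contribute to the
per-sample total (the two operations do not commute; see the tests).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "GroupedDataset",
    "ProfileParseError",
    "ProfileValidationError",
    "read_profile_table",
    "write_profile_table",
    "read_labels",
    "read_annotation",
    "exclude_ppm_window",
    "normalize_constant_sum",
    "log_transform",
    "pareto_scale",
    "split_groups",
]

CASE = "case"
CONTROL = "control"


class ProfileParseError(ValueError):
    """A cell in a profile table could not be parsed as a number."""


class ProfileValidationError(ValueError):
    """A profile table violates a structural invariant."""


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ProfileValidationError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclasses.dataclass(frozen=True)
class ProfileMatrix:
    """Samples x features intensity matrix with ids and optional ppm axis.

    Parameters
    ----------
    values
        Array of shape (n_samples, n_features); finite reals. Raw
        intensities are nonnegative; log-transformed or Pareto-scaled
        matrices (``raw=False``) may contain negative entries.
    sample_ids, feature_ids
        Unique string identifiers for rows and columns.
    ppm
        Optional per-feature chemical shift in ppm.
    raw
        Whether the matrix is still on the raw (nonnegative) intensity
        scale. Cleared by :func:`log_transform` and :func:`pareto_scale`.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    ppm: np.ndarray | None = None
    raw: bool = True

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        if values.ndim != 2:
            raise ProfileValidationError(f"values must be 2-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ProfileValidationError("values contain non-finite entries")
        if self.raw and np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ProfileValidationError(
                f"negative raw intensity at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if len(self.sample_ids) != values.shape[0]:
            raise ProfileValidationError("sample_ids length does not match values")
        if len(self.feature_ids) != values.shape[1]:
            raise ProfileValidationError("feature_ids length does not match values")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if self.ppm is not None:
            ppm = np.asarray(self.ppm, dtype=float)
            if ppm.shape != (values.shape[1],):
                raise ProfileValidationError("ppm length does not match n_features")
            object.__setattr__(self, "ppm", ppm)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def with_values(self, values: np.ndarray, raw: bool | None = None) -> "ProfileMatrix":
        return dataclasses.replace(
            self, values=values, raw=self.raw if raw is None else raw
        )


@dataclasses.dataclass(frozen=True)
class GroupedDataset:
    """Case matrix T (m1 x n) and control matrix F (m2 x n) on one feature axis."""

    T: np.ndarray
    F: np.ndarray
    feature_ids: tuple[str, ...]
    ppm: np.ndarray | None = None
    case_ids: tuple[str, ...] = ()
    control_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        if T.ndim != 2 or F.ndim != 2 or T.shape[1] != F.shape[1]:
            raise ProfileValidationError("T and F must be 2-D with a shared feature axis")
        if T.shape[1] != len(self.feature_ids):
            raise ProfileValidationError("feature_ids length does not match matrices")
        if T.shape[0] < 2 or F.shape[0] < 2:
            raise ProfileValidationError(
                "each group needs >= 2 samples (leave-one-out centroids require "
                "at least one remaining sample per class)"
            )
        if self.ppm is not None:
            ppm = np.asarray(self.ppm, dtype=float)
            if ppm.shape != (T.shape[1],):
                raise ProfileValidationError("ppm length does not match n features")
            object.__setattr__(self, "ppm", ppm)

    @property
    def m1(self) -> int:
        return self.T.shape[0]

    @property
    def m2(self) -> int:
        return self.F.shape[0]

    @property
    def n(self) -> int:
        return self.T.shape[1]

    def restrict(self, feature_indices) -> "GroupedDataset":
        """Return a copy keeping only the given feature columns (in the given order)."""
        idx = np.asarray(list(feature_indices), dtype=int)
        return GroupedDataset(
            T=self.T[:, idx],
            F=self.F[:, idx],
            feature_ids=tuple(self.feature_ids[i] for i in idx),
            ppm=None if self.ppm is None else self.ppm[idx],
            case_ids=self.case_ids,
            control_ids=self.control_ids,
        )


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_profile_table(
    path,
    orientation: str = "samples_in_rows",
    delimiter: str | None = None,
    ppm: np.ndarray | None = None,
    raw: bool = True,
) -> ProfileMatrix:
    """Read a CSV/TSV profile table into a :class:`ProfileMatrix`.

    The first column holds row ids and the header row holds column ids.
    With ``orientation="features_in_rows"`` the table is transposed after
    reading so that samples always end up in rows.
    """
    if orientation not in {"samples_in_rows", "features_in_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _sep_for(path, delimiter)
    with open(path) as fh:
        header = [tok.strip() for tok in fh.readline().rstrip("\n").split(sep)][1:]
    _check_unique(header, "column")  # pandas silently mangles duplicate headers
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in header]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ProfileParseError(
            f"non-numeric value {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    if orientation == "features_in_rows":
        numeric = numeric.T
    return ProfileMatrix(
        values=numeric.to_numpy(dtype=float),
        sample_ids=tuple(numeric.index),
        feature_ids=tuple(numeric.columns),
        ppm=ppm,
        raw=raw,
    )


def write_profile_table(pm: ProfileMatrix, path, delimiter: str | None = None) -> None:
    """Write samples-in-rows CSV/TSV mirroring the input conventions."""
    path = Path(path)
    pm.to_dataframe().to_csv(path, sep=_sep_for(path, delimiter), index_label="sample_id")


def read_labels(path, delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column (sample_id, group) table; group must be case/control."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, delimiter))
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "sample_id" not in cols or "group" not in cols:
        raise ProfileValidationError(
            f"labels file {path} must have columns sample_id, group"
        )
    labels: dict[str, str] = {}
    for _, row in df.iterrows():
        group = str(row["group"]).strip().lower()
        if group not in {CASE, CONTROL}:
            raise ProfileValidationError(
                f"group for sample {row['sample_id']!r} must be case or control, "
                f"got {row['group']!r}"
            )
        labels[str(row["sample_id"])] = group
    return labels


def read_annotation(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a feature annotation table (feature_id, ppm[, name])."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, delimiter))
    df.columns = [c.strip().lower() for c in df.columns]
    if "feature_id" not in df.columns or "ppm" not in df.columns:
        raise ProfileValidationError(
            f"annotation file {path} must have columns feature_id, ppm"
        )
    df["feature_id"] = df["feature_id"].astype(str)
    df["ppm"] = pd.to_numeric(df["ppm"])
    return df


def exclude_ppm_window(pm: ProfileMatrix, lo: float, hi: float) -> ProfileMatrix:
    """Drop every feature with chemical shift in the closed window [lo, hi].

    Standard use: removing the residual-water region (4.6-5.1 ppm) before
    normalization, so solvent signal never contributes to per-sample totals.
    """
    if pm.ppm is None:
        raise ProfileValidationError("exclude_ppm_window needs a ppm annotation")
    if not lo < hi:
        raise ValueError(f"window requires lo < hi, got [{lo}, {hi}]")
    keep = ~((pm.ppm >= lo) & (pm.ppm <= hi))
    if not keep.any():
        raise ProfileValidationError(
            f"ppm window [{lo}, {hi}] removes every feature; no features remain"
        )
    return ProfileMatrix(
        values=pm.values[:, keep],
        sample_ids=pm.sample_ids,
        feature_ids=tuple(f for f, k in zip(pm.feature_ids, keep) if k),
        ppm=pm.ppm[keep],
        raw=pm.raw,
    )


def normalize_constant_sum(pm: ProfileMatrix, total: float = 1.0) -> ProfileMatrix:
    """Scale each sample so its intensities sum to ``total`` (total-area normalization).

    Idempotent: renormalizing an already-normalized matrix changes nothing
    beyond float round-off.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    sums = pm.values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        raise ProfileValidationError(
            f"sample {pm.sample_ids[bad[0]]!r} has non-positive total intensity"
        )
    return pm.with_values(pm.values * (total / sums)[:, None])


def log_transform(pm: ProfileMatrix, base: float = 2.0, pseudocount: float = 0.0) -> ProfileMatrix:
    """Elementwise log_base(value + pseudocount)."""
    if base <= 0 or base == 1:
        raise ValueError("log base must be positive and != 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    shifted = pm.values + pseudocount
    if np.any(shifted <= 0):
        i, j = np.argwhere(shifted <= 0)[0]
        raise ProfileValidationError(
            f"log of non-positive value at sample {pm.sample_ids[i]!r}, feature "
            f"{pm.feature_ids[j]!r}; consider a positive pseudocount"
        )
    return pm.with_values(np.log(shifted) / np.log(base), raw=False)


def pareto_scale(pm: ProfileMatrix) -> ProfileMatrix:
    """Mean-center each feature and divide by the square root of its sd (ddof=1).

    Pareto scaling shrinks the dominance of high-variance bins less
    aggressively than unit-variance scaling: the scaled column variance
    equals the original column sd. Zero-variance columns become all zeros.
    """
    if pm.n_samples < 2:
        raise ProfileValidationError("pareto_scale needs at least 2 samples")
    mean = pm.values.mean(axis=0)
    sd = pm.values.std(axis=0, ddof=1)
    centered = pm.values - mean
    scale = np.sqrt(sd, where=sd > 0, out=np.ones_like(sd))
    out = np.where(sd > 0, centered / scale, 0.0)
    return pm.with_values(out, raw=False)


def split_groups(pm: ProfileMatrix, labels: Mapping[str, str]) -> GroupedDataset:
    """Split a labeled profile matrix into the case/control :class:`GroupedDataset`."""
    missing = [s for s in pm.sample_ids if s not in labels]
    if missing:
        raise ProfileValidationError(f"unlabeled sample(s): {missing}")
    bad = {s: g for s, g in labels.items() if s in pm.sample_ids and g not in {CASE, CONTROL}}
    if bad:
        raise ProfileValidationError(f"labels must be case/control, got {bad}")
    case_rows = [i for i, s in enumerate(pm.sample_ids) if labels[s] == CASE]
    control_rows = [i for i, s in enumerate(pm.sample_ids) if labels[s] == CONTROL]
    if len(case_rows) < 2 or len(control_rows) < 2:
        raise ProfileValidationError(
            f"need >= 2 samples per group for leave-one-out, got "
            f"{len(case_rows)} case / {len(control_rows)} control"
        )
    return GroupedDataset(
        T=pm.values[case_rows],
        F=pm.values[control_rows],
        feature_ids=pm.feature_ids,
        ppm=pm.ppm,
        case_ids=tuple(pm.sample_ids[i] for i in case_rows),
        control_ids=tuple(pm.sample_ids[i] for i in control_rows),
    )
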