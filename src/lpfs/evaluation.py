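"""Descriptive comparison of selection results across methods and runs.

Covers the reporting side of a biomarker study: volcano-style per-feature
summaries (mean shift vs dispersion), venn-region overlaps between up to
four selected sets, control-experiment filtering (removing markers that also
appear in a sham/temporal-drift run), and recovery metrics against a known
planted truth.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .io_profiles import GroupedDataset

__all__ = [
    "SelectionResult",
    "VennResult",
    "RecoveryMetrics",
    "volcano_table",
    "overlap_venn",
    "control_filter",
    "recovery_metrics",
    "read_external_selection",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SelectionResult:
    """One method's selected feature set on one run, with provenance."""

    method: str
    label: str
    selected: frozenset[str]
    scores: dict[str, float] | None = None
    accuracy: float | None = None
    parameters: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "selected", frozenset(str(f) for f in self.selected))


@dataclasses.dataclass(frozen=True)
class VennResult:
    """Region counts for 2-4 sets plus the pairwise Jaccard table.

    ``regions`` maps a membership tuple (one bool per input set, in order)
    to the number of features exactly in that combination of sets; the
    all-False region is omitted. Region counts sum to |union|.
    """

    labels: tuple[str, ...]
    regions: dict[tuple[bool, ...], int]
    jaccard: pd.DataFrame


def volcano_table(ds_log: GroupedDataset) -> pd.DataFrame:
    """Per-feature mean difference (case - control) vs pooled sd.

    The classic scatter for eyeballing marker quality: good biomarkers sit
    far left or right (large shift) and low (small dispersion).
    """
    diff = ds_log.T.mean(axis=0) - ds_log.F.mean(axis=0)
    var_case = ds_log.T.var(axis=0, ddof=1)
    var_ctrl = ds_log.F.var(axis=0, ddof=1)
    pooled = np.sqrt(
        ((ds_log.m1 - 1) * var_case + (ds_log.m2 - 1) * var_ctrl)
        / (ds_log.m1 + ds_log.m2 - 2)
    )
    df = pd.DataFrame(
        {
            "feature_id": list(ds_log.feature_ids),
            "mean_difference": diff,
            "pooled_sd": pooled,
        }
    )
    if ds_log.ppm is not None:
        df.insert(1, "ppm", ds_log.ppm)
    return df


def overlap_venn(results: list[SelectionResult]) -> VennResult:
    """Exact region counts for the venn diagram of 2-4 selected sets."""
    if not 2 <= len(results) <= 4:
        raise ValueError(
            f"venn overlap supports 2-4 sets, got {len(results)}; "
            "use the pairwise Jaccard table for larger comparisons"
        )
    labels = tuple(r.label for r in results)
    sets = [r.selected for r in results]
    union = frozenset().union(*sets)
    regions: dict[tuple[bool, ...], int] = {}
    for membership in itertools.product([True, False], repeat=len(sets)):
        if not any(membership):
            continue
        region = union
        for s, inside in zip(sets, membership):
            region = region & s if inside else region - s
        regions[membership] = len(region)
    jac = pd.DataFrame(np.eye(len(sets)), index=labels, columns=labels)
    for i, j in itertools.combinations(range(len(sets)), 2):
        u = len(sets[i] | sets[j])
        v = len(sets[i] & sets[j]) / u if u else 1.0
        jac.iat[i, j] = jac.iat[j, i] = v
    return VennResult(labels=labels, regions=regions, jaccard=jac)


def control_filter(treatment: SelectionResult, sham: SelectionResult) -> SelectionResult:
    """Drop treatment markers that a sham/control run also selects.

    Markers appearing in the sham run reflect drift or handling effects
    rather than the treatment; the removals are recorded in
    ``parameters["removed_by_control"]``. Idempotent.
    """
    removed = sorted(treatment.selected & sham.selected)
    kept = treatment.selected - sham.selected
    if not kept and treatment.selected:
        logger.warning(
            "control filter removed every selected feature of %s (sham run %s "
            "covers the full selection)",
            treatment.label,
            sham.label,
        )
    params = dict(treatment.parameters)
    params["removed_by_control"] = removed
    params["control_run"] = sham.label
    return dataclasses.replace(treatment, selected=kept, parameters=params)


@dataclasses.dataclass(frozen=True)
class RecoveryMetrics:
    """Set precision/recall of a selection against the planted truth.

    An empty selection gets precision 0.0 with ``empty_selection`` set,
    rather than NaN, so aggregate tables stay numeric.
    """

    precision: float
    recall: float
    exact_match: bool
    empty_selection: bool = False


def recovery_metrics(selected, planted) -> RecoveryMetrics:
    selected = frozenset(selected)
    planted = frozenset(planted)
    hit = len(selected & planted)
    if not selected:
        return RecoveryMetrics(
            precision=0.0,
            recall=0.0 if planted else 1.0,
            exact_match=selected == planted,
            empty_selection=True,
        )
    precision = hit / len(selected)
    recall = hit / len(planted) if planted else 1.0
    return RecoveryMetrics(
        precision=precision, recall=recall, exact_match=selected == planted
    )


def read_external_selection(path, method: str = "external", label: str | None = None) -> SelectionResult:
    """Load a third-party tool's selected-feature list from a one-column CSV.

    The file needs a ``feature_id`` column (extra columns are kept as
    scores when a numeric ``score`` column is present). This is how
    selections from tools not reimplemented here enter the comparison
    reports.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "feature_id" not in df.columns:
        raise ValueError(f"external selection {path} needs a feature_id column")
    scores = None
    if "score" in df.columns:
        scores = {str(f): float(s) for f, s in zip(df["feature_id"], df["score"])}
    return SelectionResult(
        method=method,
        label=label or path.stem,
        selected=frozenset(str(f) for f in df["feature_id"]),
        scores=scores,
    )
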