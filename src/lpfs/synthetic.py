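"""Seeded generator of two-group profiles with planted biomarkers.

Emulates the structure of a binned 1H NMR plasma study — ~400 chemical-shift
bins, two groups of ~10 subjects — with a small planted subset of features
whose group means differ by a stated multiple of that feature's own noise sd.
Every downstream module is testable against the known ground truth without
any external data.

Defaults: per-feature baselines uniform on (0.5, 1.5) arbitrary intensity
units and noise sds uniform on (0.02, 0.1), so a 4-sigma planted shift stays
far from the zero-intensity boundary and the nominal effect size survives
truncation essentially unchanged.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .io_profiles import GroupedDataset

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "generate_null", "planted_spec"]


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic two-group dataset.

    ``planted`` holds (feature index, shift in units of that feature's noise
    sd, direction +1/-1) triples; the shift moves the case-group mean.
    """

    n_features: int = 400
    m1: int = 10
    m2: int = 10
    planted: tuple[tuple[int, float, int], ...] = ()
    noise_sd_range: tuple[float, float] = (0.02, 0.1)
    baseline_range: tuple[float, float] = (0.5, 1.5)
    lognormal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.m1 < 2 or self.m2 < 2:
            raise ValueError("need n_features >= 1 and >= 2 samples per group")
        idx = [p[0] for p in self.planted]
        if len(set(idx)) != len(idx):
            raise ValueError("planted feature indices must be distinct")
        if any(not 0 <= i < self.n_features for i in idx):
            raise ValueError("planted feature index out of range")
        if any(p[2] not in (-1, 1) for p in self.planted):
            raise ValueError("planted direction must be +1 or -1")
        if not 0 < self.baseline_range[0] <= self.baseline_range[1]:
            raise ValueError("baseline range must be positive and ordered")
        if not 0 < self.noise_sd_range[0] <= self.noise_sd_range[1]:
            raise ValueError("noise sd range must be positive and ordered")


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a generated dataset: what was planted, and where."""

    planted: frozenset[int]
    mean_case: np.ndarray
    mean_control: np.ndarray
    spec: SyntheticSpec

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": sorted(self.planted),
                "mean_case": self.mean_case.tolist(),
                "mean_control": self.mean_control.tolist(),
                "seed": self.spec.seed,
                "n_features": self.spec.n_features,
                "m1": self.spec.m1,
                "m2": self.spec.m2,
            }
        )


def planted_spec(
    seed: int,
    n_features: int = 400,
    m1: int = 10,
    m2: int = 10,
    n_planted: int = 4,
    shift: float = 4.0,
    **kwargs,
) -> SyntheticSpec:
    """Spec with ``n_planted`` markers at random positions and directions.

    The marker positions/directions are drawn from ``seed`` so the whole
    dataset remains reproducible from one integer.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_features, size=n_planted, replace=False)
    dirs = rng.choice([-1, 1], size=n_planted)
    planted = tuple((int(i), float(shift), int(d)) for i, d in zip(idx, dirs))
    return SyntheticSpec(
        n_features=n_features, m1=m1, m2=m2, planted=planted, seed=seed, **kwargs
    )


def generate(spec: SyntheticSpec) -> tuple[GroupedDataset, SyntheticTruth]:
    """Draw one dataset from the spec; bit-identical for equal specs.

    Feature i gets baseline b_i ~ U(baseline_range) and noise sd
    sigma_i ~ U(noise_sd_range). Controls draw Normal(b_i, sigma_i); cases
    draw Normal(b_i + shift * sigma_i * direction, sigma_i) at planted
    features and the control law elsewhere. Draws are truncated at zero
    (clipped) so raw-scale operations — fold change, constant-sum
    normalization — remain applicable.
    """
    rng = np.random.default_rng(spec.seed)
    b = rng.uniform(*spec.baseline_range, size=spec.n_features)
    sigma = rng.uniform(*spec.noise_sd_range, size=spec.n_features)
    mean_control = b.copy()
    mean_case = b.copy()
    for i, shift, direction in spec.planted:
        mean_case[i] = b[i] + shift * sigma[i] * direction
    if spec.lognormal:
        # heavier-tailed variant: match mean and sd on the log-intensity scale
        T = np.exp(rng.normal(np.log(mean_case), sigma / mean_case, size=(spec.m1, spec.n_features)))
        F = np.exp(rng.normal(np.log(mean_control), sigma / mean_control, size=(spec.m2, spec.n_features)))
    else:
        T = rng.normal(mean_case, sigma, size=(spec.m1, spec.n_features))
        F = rng.normal(mean_control, sigma, size=(spec.m2, spec.n_features))
    T = np.clip(T, 0.0, None)
    F = np.clip(F, 0.0, None)
    ppm = np.round(np.linspace(0.4, 0.4 + 0.01 * (spec.n_features - 1), spec.n_features), 2)
    ds = GroupedDataset(
        T=T,
        F=F,
        feature_ids=tuple(f"bin{i:03d}" for i in range(spec.n_features)),
        ppm=ppm,
        case_ids=tuple(f"case{j:02d}" for j in range(spec.m1)),
        control_ids=tuple(f"ctrl{j:02d}" for j in range(spec.m2)),
    )
    truth = SyntheticTruth(
        planted=frozenset(p[0] for p in spec.planted),
        mean_case=mean_case,
        mean_control=mean_control,
        spec=spec,
    )
    return ds, truth


def generate_null(spec: SyntheticSpec) -> tuple[GroupedDataset, SyntheticTruth]:
    """Same generator with nothing planted: the two groups are exchangeable."""
    return generate(dataclasses.replace(spec, planted=()))
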