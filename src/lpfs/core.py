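"""LPFS: joint feature selection and classification as a linear program.

The selector asks for a 0/1 indicator vector x over features such that the
nearest-centroid classifier, restricted to the selected features, classifies
every validated sample correctly — while using as few features as possible.
Per validated sample l the correctness condition is linear in x: with fold
centroids mu_T, mu_F and per-coordinate gaps

    g_li = |s_li - mu_F_i| - |s_li - mu_T_i|   (case sample; sign flipped
                                                for a control sample)

the sample is correctly classified exactly when sum_i g_li * x_i > 0. A
nonnegative slack ("tolerable error") y_l absorbs violations, and the two
goals — few features, few errors — are scalarized with a trade-off lambda:

    min  sum_i x_i + lambda * sum_l y_l
    s.t. g_l . x + y_l >= delta      for every validated sample l
         0 <= x_i <= x_upper,  y_l >= 0

The strict inequality of the exact model cannot enter an LP, so a positive
margin delta replaces it; without the margin x = 0, y = 0 would always be
feasible and trivially optimal. Validation structure is either
leave-one-out (fold centroids exclude the held-out sample from its own
group; one constraint per sample) or resubstitution (centroids on all
samples; optimistic, "information leak").

The binary program is NP-hard in general; relaxing x_i to [0, x_upper]
gives a linear program whose optimal x_i (the LPFS score) ranks feature
importance, with strictly positive support read as the selected set. An
exhaustive enumerator over binary x, with the closed-form optimal slacks
y_l = max(0, delta - g_l . x), serves as the exact oracle at small n.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import linprog

from .centroid import CentroidModel, classify, compute_centroid, loo_folds
from .io_profiles import CASE, CONTROL, GroupedDataset

__all__ = [
    "LPFSProblem",
    "LPFSSolution",
    "LambdaPathResult",
    "distance_gap",
    "build_loo_problem",
    "build_resub_problem",
    "solve_lp",
    "solve_ilp_exhaustive",
    "select_features",
    "accuracy_from_errors",
    "posthoc_loo_accuracy",
    "lambda_path",
    "export_lp",
    "DEFAULT_LAMBDA_GRID",
]

logger = logging.getLogger(__name__)

# 25 log-spaced points spanning the x=0 regime through the separable regime
# on row-normalized problems.
DEFAULT_LAMBDA_GRID: np.ndarray = np.logspace(-2.0, 3.0, 25)

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
NUMERIC_FAILURE = "numeric_failure"


@dataclasses.dataclass(frozen=True)
class LPFSProblem:
    """Assembled constraint system g_l . x + y_l >= delta.

    Attributes
    ----------
    G
        Gap matrix, L x n; one row per validated sample.
    delta
        Positive margin replacing the exact model's strict inequalities.
    lam
        Trade-off weight converting classification error into the same
        currency as feature count.
    x_upper
        Upper bound on each feature score (np.inf for unbounded).
    row_scale
        Per-row factors the raw gap rows were divided by (None if rows were
        left unscaled).
    validation
        "loo" or "resubstitution".
    """

    G: np.ndarray
    delta: float
    lam: float
    x_upper: float = 1.0
    row_scale: np.ndarray | None = None
    validation: str = "loo"
    row_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        if G.ndim != 2 or not np.all(np.isfinite(G)):
            raise ValueError("G must be a finite 2-D matrix")
        object.__setattr__(self, "G", G)
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if not self.lam > 0:
            raise ValueError("lambda must be positive")
        if not self.x_upper > 0:
            raise ValueError("x_upper must be positive")

    @property
    def n_constraints(self) -> int:
        return self.G.shape[0]

    @property
    def n_features(self) -> int:
        return self.G.shape[1]

    def with_lambda(self, lam: float) -> "LPFSProblem":
        return dataclasses.replace(self, lam=lam)


@dataclasses.dataclass
class LPFSSolution:
    """Solver output: feature scores, tolerable errors, and derived summaries."""

    x: np.ndarray
    y: np.ndarray
    objective: float
    solver_status: str
    selected: list[int] = dataclasses.field(default_factory=list)
    n_correct: int = 0
    n_wrong: int = 0
    accuracy: float = float("nan")

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def distance_gap(
    sample: np.ndarray, group: str, mu_T: np.ndarray, mu_F: np.ndarray
) -> np.ndarray:
    """Per-feature classification gap of one validated sample.

    For a case sample g_i = |s_i - mu_F_i| - |s_i - mu_T_i|; for a control
    sample the sign flips. A positive entry means feature i pushes the
    sample toward its correct class, so every constraint takes the uniform
    form g . x + y >= delta.
    """
    sample = np.asarray(sample, dtype=float)
    mu_T = np.asarray(mu_T, dtype=float)
    mu_F = np.asarray(mu_F, dtype=float)
    if not (sample.shape == mu_T.shape == mu_F.shape):
        raise ValueError("sample and centroids must share one length")
    gap = np.abs(sample - mu_F) - np.abs(sample - mu_T)
    if group == CASE:
        return gap
    if group == CONTROL:
        return -gap
    raise ValueError(f"group must be case or control, got {group!r}")


def _finalize_rows(
    rows: list[np.ndarray],
    labels: list[str],
    delta: float,
    lam: float,
    row_normalize: bool,
    x_upper: float,
    validation: str,
) -> LPFSProblem:
    G = np.vstack(rows)
    row_scale = None
    if row_normalize:
        scale = np.abs(G).mean(axis=1)
        dead = np.flatnonzero(scale == 0)
        if dead.size:
            raise ValueError(
                f"constraint row for sample {labels[dead[0]]!r} is identically "
                "zero; it cannot be normalized (sample coincides with both "
                "centroid gaps)"
            )
        G = G / scale[:, None]
        row_scale = scale
    return LPFSProblem(
        G=G,
        delta=delta,
        lam=lam,
        x_upper=x_upper,
        row_scale=row_scale,
        validation=validation,
        row_labels=tuple(labels),
    )


def build_loo_problem(
    ds: GroupedDataset,
    lam: float,
    delta: float = 1.0,
    row_normalize: bool = True,
    x_upper: float = 1.0,
) -> LPFSProblem:
    """Constraint system with leave-one-out validation structure.

    One row per sample (L = m1 + m2): the held-out sample's own group
    centroid is recomputed without it, the opposite centroid keeps all its
    samples, and the row is the resulting distance gap. With
    ``row_normalize`` each row is divided by its mean absolute entry, which
    makes delta and lambda scale-free (one lambda grid works across
    datasets and intensity units).
    """
    rows, labels = [], []
    for fold in loo_folds(ds):
        rows.append(
            distance_gap(fold.sample, fold.held_out_group, fold.mu_T_fold, fold.mu_F_fold)
        )
        labels.append(f"{fold.held_out_group}[{fold.held_out_index}]")
    return _finalize_rows(rows, labels, delta, lam, row_normalize, x_upper, "loo")


def build_resub_problem(
    ds: GroupedDataset,
    lam: float,
    delta: float = 1.0,
    row_normalize: bool = True,
    x_upper: float = 1.0,
) -> LPFSProblem:
    """Resubstitution variant: centroids computed once on all samples.

    Optimistic by construction — every validated sample also shaped the
    centroids it is tested against — so its optimum is never harder than
    the leave-one-out optimum on the same data.
    """
    mu_T = compute_centroid(ds.T)
    mu_F = compute_centroid(ds.F)
    rows, labels = [], []
    for k in range(ds.m1):
        rows.append(distance_gap(ds.T[k], CASE, mu_T, mu_F))
        labels.append(f"case[{k}]")
    for k in range(ds.m2):
        rows.append(distance_gap(ds.F[k], CONTROL, mu_T, mu_F))
        labels.append(f"control[{k}]")
    return _finalize_rows(rows, labels, delta, lam, row_normalize, x_upper, "resubstitution")


def select_features(sol: LPFSSolution, tol: float = 1e-8) -> list[int]:
    """Indices with score x_i > tol, sorted by descending score.

    The strictly-positive support of the relaxed solution is read as the
    selected biomarker set; no magnitude cutoff beyond numerical zero is
    applied, since informative scores can be small fractions.
    """
    idx = np.flatnonzero(sol.x > tol)
    return sorted(idx.tolist(), key=lambda i: (-sol.x[i], i))


def accuracy_from_errors(sol: LPFSSolution, tol_correct: float) -> float:
    """Internal accuracy read off the slack variables.

    A sample counts as correctly classified when its tolerable error y_l is
    numerically zero (<= tol_correct). Sets n_correct/n_wrong/accuracy on
    the solution and returns the accuracy.
    """
    L = sol.y.size
    n1 = int(np.sum(sol.y <= tol_correct))
    sol.n_correct = n1
    sol.n_wrong = L - n1
    sol.accuracy = n1 / L if L else float("nan")
    return sol.accuracy


def _summarize(problem: LPFSProblem, sol: LPFSSolution, tol: float = 1e-8) -> LPFSSolution:
    sol.selected = select_features(sol, tol)
    accuracy_from_errors(sol, tol_correct=1e-6 * problem.delta)
    return sol


def solve_lp(problem: LPFSProblem, selection_tol: float = 1e-8) -> LPFSSolution:
    """Solve the continuous relaxation with HiGHS.

    Variables are [x (n), y (L)]; objective sum(x) + lam * sum(y);
    constraints G x + y >= delta rewritten for the solver as
    -(G x + y) <= -delta. Non-optimal solver terminations are surfaced in
    ``solver_status``, never silently.
    """
    L, n = problem.G.shape
    c = np.concatenate([np.ones(n), problem.lam * np.ones(L)])
    A_ub = np.hstack([-problem.G, -np.eye(L)])
    b_ub = np.full(L, -problem.delta)
    x_hi = None if np.isinf(problem.x_upper) else problem.x_upper
    bounds = [(0.0, x_hi)] * n + [(0.0, None)] * L
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if res.status == 0:
        status = OPTIMAL
        x = np.asarray(res.x[:n])
        y = np.asarray(res.x[n:])
        objective = float(res.fun)
    else:
        status = {2: INFEASIBLE, 3: UNBOUNDED}.get(res.status, NUMERIC_FAILURE)
        logger.warning("LP solver returned %s: %s", status, res.message)
        x = np.zeros(n)
        y = np.zeros(L)
        objective = float("nan")
    sol = LPFSSolution(x=x, y=y, objective=objective, solver_status=status)
    return _summarize(problem, sol, tol=selection_tol)


def solve_ilp_exhaustive(
    problem: LPFSProblem, max_n: int = 20, selection_tol: float = 1e-8
) -> LPFSSolution:
    """Exact binary optimum by enumeration of all 2^n indicator vectors.

    For fixed binary x the optimal slacks are closed-form,
    y_l = max(0, delta - g_l . x), so each assignment is scored directly;
    no branch-and-bound is needed at the problem sizes this oracle serves.
    Ties are broken toward the lexicographically smallest assignment.
    """
    L, n = problem.G.shape
    if n > max_n:
        raise ValueError(f"exhaustive enumeration refused for n = {n} > max_n = {max_n}")
    if problem.x_upper < 1.0:
        raise ValueError("binary enumeration uses x_i in {0, 1}; needs x_upper >= 1")
    best_obj = np.inf
    best_x: np.ndarray | None = None
    best_y: np.ndarray | None = None
    # enumerate in chunks to bound memory at larger n
    total = 1 << n
    chunk = min(total, 1 << 14)
    bit_weights = 1 << np.arange(n)
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total))
        X = ((codes[:, None] & bit_weights[None, :]) > 0).astype(float)
        margins = X @ problem.G.T  # (chunk, L)
        Y = np.maximum(0.0, problem.delta - margins)
        objs = X.sum(axis=1) + problem.lam * Y.sum(axis=1)
        k = int(np.argmin(objs))
        if objs[k] < best_obj - 1e-15:
            best_obj = float(objs[k])
            best_x = X[k]
            best_y = Y[k]
    assert best_x is not None and best_y is not None
    sol = LPFSSolution(
        x=best_x, y=best_y, objective=best_obj, solver_status=OPTIMAL
    )
    return _summarize(problem, sol, tol=selection_tol)


def posthoc_loo_accuracy(ds: GroupedDataset, selected) -> float:
    """Leave-one-out accuracy of the plain nearest-centroid classifier
    restricted to ``selected`` feature indices.

    This is the externally reportable accuracy: the selected set is reused
    as a binary mask in an ordinary unweighted centroid classifier,
    independent of the LP's slack variables.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("posthoc_loo_accuracy needs a non-empty feature selection")
    correct = 0
    for fold in loo_folds(ds):
        model = CentroidModel(
            mu_T=fold.mu_T_fold[selected], mu_F=fold.mu_F_fold[selected]
        )
        if classify(fold.sample[selected], model) == fold.held_out_group:
            correct += 1
    return correct / (ds.m1 + ds.m2)


@dataclasses.dataclass(frozen=True)
class LambdaPathResult:
    """Per-lambda solutions plus the chosen trade-off.

    ``entries`` holds (lambda, solution, posthoc LOO accuracy) triples;
    entries whose solve failed carry accuracy NaN. The chosen lambda
    maximizes posthoc LOO accuracy, with ties broken by fewest selected
    features, then smallest lambda.
    """

    lambdas: tuple[float, ...]
    solutions: tuple[LPFSSolution, ...]
    posthoc_accuracies: tuple[float, ...]
    chosen_index: int

    @property
    def chosen_lambda(self) -> float:
        return self.lambdas[self.chosen_index]

    @property
    def chosen_solution(self) -> LPFSSolution:
        return self.solutions[self.chosen_index]

    @property
    def chosen_accuracy(self) -> float:
        return self.posthoc_accuracies[self.chosen_index]


def lambda_path(
    ds: GroupedDataset,
    grid=None,
    delta: float = 1.0,
    validation: str = "loo",
    row_normalize: bool = True,
    x_upper: float = 1.0,
) -> LambdaPathResult:
    """Solve the LP across a lambda grid and pick the best trade-off.

    Each lambda is solved independently; for each optimal solution the
    posthoc leave-one-out accuracy of its selected set is computed (0.0 is
    recorded for an empty selection — no classifier can be built from it).
    Solver failures at individual grid points are recorded and skipped,
    not fatal.
    """
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    builder = {"loo": build_loo_problem, "resubstitution": build_resub_problem}.get(validation)
    if builder is None:
        raise ValueError(f"validation must be loo or resubstitution, got {validation!r}")
    base = builder(ds, lam=float(grid[0]), delta=delta,
                   row_normalize=row_normalize, x_upper=x_upper)
    solutions: list[LPFSSolution] = []
    accuracies: list[float] = []
    for lam in grid:
        sol = solve_lp(base.with_lambda(float(lam)))
        solutions.append(sol)
        if sol.solver_status != OPTIMAL:
            accuracies.append(float("nan"))
        elif not sol.selected:
            accuracies.append(0.0)
        else:
            accuracies.append(posthoc_loo_accuracy(ds, sol.selected))
    finite = [i for i, a in enumerate(accuracies) if np.isfinite(a)]
    if not finite:
        raise RuntimeError("every lambda grid point failed to solve")
    chosen = min(
        finite,
        key=lambda i: (-accuracies[i], solutions[i].n_selected, grid[i]),
    )
    return LambdaPathResult(
        lambdas=tuple(float(v) for v in grid),
        solutions=tuple(solutions),
        posthoc_accuracies=tuple(accuracies),
        chosen_index=chosen,
    )


def export_lp(problem: LPFSProblem, path) -> None:
    """Write the assembled problem in CPLEX-LP text format for external solvers."""
    L, n = problem.G.shape
    lines = ["Minimize", " obj: " + " + ".join(
        [f"x{i}" for i in range(n)] + [f"{problem.lam:.17g} y{l}" for l in range(L)]
    ), "Subject To"]
    for l in range(L):
        terms = []
        for i in range(n):
            coef = problem.G[l, i]
            if coef == 0:
                continue
            sign = "+" if coef >= 0 else "-"
            terms.append(f"{sign} {abs(coef):.17g} x{i}")
        terms.append("+ y" + str(l))
        body = " ".join(terms).lstrip("+ ")
        lines.append(f" c{l}: {body} >= {problem.delta:.17g}")
    lines.append("Bounds")
    for i in range(n):
        hi = "+inf" if np.isinf(problem.x_upper) else f"{problem.x_upper:.17g}"
        lines.append(f" 0 <= x{i} <= {hi}")
    for l in range(L):
        lines.append(f" 0 <= y{l}")
    lines.append("End")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
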