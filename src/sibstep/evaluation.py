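"""Cross-validated prediction accuracy and the c2-omission bias arithmetic.

The protocol is k-fold cross-validation repeated r times (5 x 5 = 25 runs
by default): phenotypes of the validation fold are masked, the mixed model
is solved on the training records only (relationship matrices untouched),
and the EBVs of validation animals are correlated with their phenotypes.
Accuracy is that correlation divided by sqrt(h2).  The bias of omitting
the common full-sib term is reported as the percent difference between the
without-c2 and with-c2 accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .mixed_model import DesignMatrices, ModelSpec, VarianceComponents, solve_mme
from .pedigree import Pedigree

__all__ = [
    "FoldPlan",
    "CVResult",
    "make_folds",
    "cross_validate",
    "accuracy",
    "bias_percent",
    "ebv_rank_correlation",
    "report_tables",
]

H2_FLOOR = 1e-6


@dataclass
class FoldPlan:
    """r replicates of a k-fold partition of n records."""

    n: int
    k: int
    r: int
    seed: int
    assignments: list[np.ndarray] = field(default_factory=list)  # fold id per record

    @property
    def total_runs(self) -> int:
        return self.k * self.r

    def validation_indices(self):
        """Yield (replicate, fold, validation row indices) for all runs."""
        for rep, a in enumerate(self.assignments):
            for f in range(self.k):
                yield rep, f, np.flatnonzero(a == f)

    def fold_sizes(self, rep: int = 0) -> np.ndarray:
        return np.bincount(self.assignments[rep], minlength=self.k)


def make_folds(n: int, k: int, r: int, seed: int) -> FoldPlan:
    """Uniformly random repeated k-fold partition; fold sizes differ by <= 1
    (the first n mod k folds take the extra record)."""
    if not (n >= k >= 2):
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    if r < 1:
        raise ValueError("r must be >= 1")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n, k)
    sizes = np.full(k, base)
    sizes[:extra] += 1
    labels = np.repeat(np.arange(k), sizes)
    plan = FoldPlan(n, k, r, seed)
    for _ in range(r):
        a = labels.copy()
        rng.shuffle(a)
        plan.assignments.append(a)
    return plan


def accuracy(r_y_yhat: float, h2: float) -> float:
    """Prediction accuracy r / sqrt(h2)."""
    if not H2_FLOOR < h2 <= 1.0:
        raise ValueError(f"heritability {h2} outside ({H2_FLOOR}, 1]")
    return float(r_y_yhat) / float(np.sqrt(h2))


def bias_percent(acc_without_c2: float, acc_with_c2: float) -> float:
    """100 x (acc_without - acc_with) / acc_with, the upward-bias percent."""
    if acc_with_c2 == 0:
        raise ZeroDivisionError("with-c2 accuracy is zero")
    return 100.0 * (acc_without_c2 - acc_with_c2) / acc_with_c2


def ebv_rank_correlation(ebv_a: pd.Series, ebv_b: pd.Series) -> tuple[float, float]:
    """(Pearson, Spearman) correlation of two EBV sets over common animals."""
    common = ebv_a.index.intersection(ebv_b.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common animals; need at least 3")
    x = ebv_a.loc[common].to_numpy(float)
    y = ebv_b.loc[common].to_numpy(float)
    pear = float(stats.pearsonr(x, y).statistic)
    spear = float(stats.spearmanr(x, y).statistic)
    return pear, spear


@dataclass
class CVResult:
    runs: pd.DataFrame  # replicate, fold, n_val, r, accuracy
    h2: float
    label: dict = field(default_factory=dict)

    @property
    def mean_r(self) -> float:
        return float(self.runs["r"].mean())

    @property
    def mean_accuracy(self) -> float:
        return float(self.runs["accuracy"].mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.runs["accuracy"].std(ddof=1)) if len(self.runs) > 1 else 0.0


def _subset_design(design: DesignMatrices, rows: np.ndarray) -> tuple[DesignMatrices, np.ndarray]:
    """Training-row design; factor levels absent from training are dropped
    (their effects are taken as 0 when adjusting validation records)."""
    X = design.X[rows]
    keep = np.ptp(X, axis=0) > 0
    keep[design.x_names.index("intercept")] = True
    sub = DesignMatrices(
        X[:, keep],
        [nm for nm, k in zip(design.x_names, keep) if k],
        design.Z[rows],
        None if design.W is None else design.W[rows],
        design.family_levels,
        design.record_animal_code[rows],
    )
    return sub, keep


def cross_validate(
    data: pd.DataFrame,
    ped: Pedigree,
    K_inv: sparse.spmatrix,
    logdet_K: float,
    spec: ModelSpec,
    varcomp: VarianceComponents,
    fold_plan: FoldPlan,
    h2: float | None = None,
    adjust_fixed: bool = True,
    label: dict | None = None,
) -> CVResult:
    """Run the repeated k-fold protocol at fixed variance components.

    Validation phenotypes never enter the training MME; EBVs (u only —
    family effects are never part of the predictor) of validation animals
    are correlated with their phenotypes, by default pre-adjusted for the
    fixed effects estimated on the training records.  ``h2`` defaults to
    the heritability implied by ``varcomp``.
    """
    from .mixed_model import build_design

    if fold_plan.n != len(data):
        raise ValueError("fold plan was built for a different record count")
    h2_use = varcomp.h2 if h2 is None else h2
    design = build_design(data, spec, ped)
    y = data[spec.response].to_numpy(float)
    rows_all = np.arange(len(data))
    out = []
    for rep, fold, val in fold_plan.validation_indices():
        train = np.setdiff1d(rows_all, val)
        sub, keep = _subset_design(design, train)
        sol = solve_mme(y[train], sub, K_inv, varcomp, animal_ids=ped.ids, logdet_K=logdet_K)
        u_val = sol.u.to_numpy()[design.record_animal_code[val] - 1]
        y_val = y[val].copy()
        if adjust_fixed:
            b_full = np.zeros(design.X.shape[1])
            b_full[keep] = sol.b.to_numpy()
            y_val = y_val - design.X[val] @ b_full
        if np.std(y_val) == 0 or np.std(u_val) == 0:
            continue  # degenerate validation set: skipped
        r = float(np.corrcoef(u_val, y_val)[0, 1])
        out.append(
            dict(replicate=rep, fold=fold, n_val=len(val), r=r, accuracy=accuracy(r, h2_use))
        )
    return CVResult(pd.DataFrame(out), h2_use, label=dict(label or {}))


def report_tables(results: list[CVResult]) -> pd.DataFrame:
    """Accuracy table in the Method x (without c2 | with c2 | difference)
    layout.

    Results are grouped by every label key except ``c2``; the difference
    percent is computed from the unrounded accuracies and then rounded to
    one decimal (accuracies themselves display with four).
    """
    if not results:
        raise ValueError("no results to report")
    rows: dict[tuple, dict] = {}
    for res in results:
        lab = dict(res.label)
        has_c2 = lab.pop("c2", True)
        key = tuple(sorted(lab.items()))
        row = rows.setdefault(key, dict(lab))
        tag = "with_c2" if has_c2 else "without_c2"
        row[f"{tag}_mean"] = res.mean_accuracy
        row[f"{tag}_sd"] = res.sd_accuracy
    table = []
    for row in rows.values():
        if "with_c2_mean" in row and "without_c2_mean" in row:
            row["difference_pct"] = round(
                bias_percent(row["without_c2_mean"], row["with_c2_mean"]), 1
            )
        out = dict(row)
        for kname in ("without_c2_mean", "without_c2_sd", "with_c2_mean", "with_c2_sd"):
            if kname in out:
                out[kname] = round(out[kname], 4)
        table.append(out)
    lead = [c for c in ("method", "genotype", "traits") if any(c in r for r in table)]
    df = pd.DataFrame(table)
    cols = lead + [c for c in df.columns if c not in lead]
    return df[cols]
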