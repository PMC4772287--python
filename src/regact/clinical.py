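"""Clinical models: Breslow-thickness LAD regression, thickness staging
subgroups, and cross-validated maximally-selected survival cutpoints.

Breslow thickness (depth of the primary tumour, mm) is modelled as a linear
function of the expression of a small set of genes, fitted by least absolute
deviations and scored by leave-one-out cross-validation — the same machinery
as the regulator model, with raw gene expression (not activities) as
regressors.

The survival cutpoint procedure mimics maximally-selected rank statistics:
over candidate thresholds on a gene's expression (observed values, with at
least a minimum fraction of samples on each side), it computes the
standardized two-sample log-rank statistic for the split "expression below
threshold vs at-or-above threshold" and keeps the threshold maximising the
absolute standardized statistic.  A 10-fold cross-validation wrapper runs the
scan on each training portion and takes the median of the fold cutoffs; the
final log-rank statistic is evaluated at that cutoff on the full cohort.

Because the training folds overlap heavily, the cross-validated cutoff is
still effectively selected to maximise the statistic, so the final p-value
must account for maximal selection: the reported ``logrank_p`` uses the
Lausen–Schumacher (1992) approximation for the supremum of the standardized
log-rank process over the allowed split range (the approximation behind R's
maxstat p-values).  The naive log-rank p at the same cutoff is kept as
``logrank_p_uncorrected``; under a null of no survival difference it is
grossly anti-conservative (simulation: ~35 % rejection at the 5 % level),
while the corrected p holds the nominal level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import UndefinedCorrelationError
from .milp import FittedLinearModel, RegressionProblem, fit_lad_subset, loo_cv_performance

__all__ = [
    "CutpointResult",
    "fit_thickness_model",
    "thickness_subgroups",
    "maxstat_cutpoint",
    "maxstat_cutpoint_cv",
    "maxstat_p_value",
    "logrank_test",
    "group_compare",
]


def fit_thickness_model(
    expr3: pd.DataFrame,
    breslow: pd.Series,
    cv: bool = True,
) -> Tuple[FittedLinearModel, Optional[float]]:
    """LAD fit of thickness on gene expression rows; returns the model and,
    when ``cv`` is set, the pooled LOO-CV Pearson correlation."""
    if expr3.shape[1] < 4:
        raise ValueError("need at least 4 samples with complete data")
    if np.ptp(breslow.to_numpy(dtype=float)) == 0:
        raise UndefinedCorrelationError("thickness is constant; correlation undefined")
    problem = RegressionProblem(expr3, breslow)
    model = fit_lad_subset(problem, k=expr3.shape[0])
    cv_pcc = loo_cv_performance(problem, k=expr3.shape[0])[0] if cv else None
    return model, cv_pcc


def thickness_subgroups(
    breslow: pd.Series,
    thin_max: float = 1.0,
    thick_min: float = 4.0,
) -> Dict[str, pd.Index]:
    """Partition samples into T-stage thickness groups.

    Convention: thin ≤ ``thin_max`` mm, intermediate (``thin_max``,
    ``thick_min``] mm, thick > ``thick_min`` mm.  Samples without a
    thickness value are excluded (count logged via warning).
    """
    vals = breslow.astype(float)
    missing = int(vals.isna().sum())
    if missing:
        warnings.warn(f"excluding {missing} samples without Breslow thickness")
        vals = vals.dropna()
    if (vals <= 0).any():
        bad = vals.index[vals <= 0][0]
        raise ValueError(f"non-positive Breslow thickness for sample {bad!r}")
    return {
        "thin": vals.index[vals <= thin_max],
        "intermediate": vals.index[(vals > thin_max) & (vals <= thick_min)],
        "thick": vals.index[vals > thick_min],
    }


def _standardized_logrank(
    time: np.ndarray, event: np.ndarray, below: np.ndarray
) -> np.ndarray:
    """Standardized log-rank statistic Z = U/sqrt(V) for each candidate split.

    ``below`` is an (n_samples × n_candidates) boolean matrix marking group
    membership (expression below the candidate threshold).  Vectorised over
    candidates; ties in event times are handled by grouping.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order].astype(float)
    g = below[order].astype(float)  # n × c
    # unique event-time blocks
    uniq, first = np.unique(t, return_index=True)
    # at-risk counts just before each unique time: reverse cumulative sums
    n_total = len(t)
    at_risk_total = n_total - first  # samples with time >= uniq[i]
    # group at-risk: suffix sums of g
    g_suffix = np.vstack([np.flipud(np.cumsum(np.flipud(g), axis=0)), np.zeros((1, g.shape[1]))])
    n1 = g_suffix[first]  # c per block
    d_tot = np.add.reduceat(d, first)
    d1 = np.add.reduceat(g * d[:, None], first, axis=0)
    n_tot = at_risk_total.astype(float)
    frac = n1 / n_tot[:, None]
    U = (d1 - d_tot[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        hyper = np.where(
            n_tot[:, None] > 1,
            d_tot[:, None] * frac * (1 - frac) * (n_tot[:, None] - d_tot[:, None]) / (n_tot[:, None] - 1),
            0.0,
        )
    V = hyper.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(V > 0, U / np.sqrt(V), 0.0)
    return Z


def maxstat_cutpoint(
    expression: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    min_group_frac: float = 0.1,
) -> float:
    """Threshold on expression maximising |standardized log-rank| over
    candidate splits leaving at least ``min_group_frac`` of samples per side.

    Candidates are observed expression values c, splitting into x < c vs
    x ≥ c, so the cutpoint transforms exactly under monotone maps of the
    expression scale.
    """
    x = np.asarray(expression, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(x)
    min_count = max(1, int(np.ceil(min_group_frac * n)))
    cands = np.unique(x)
    n_below = np.searchsorted(np.sort(x), cands, side="left")
    ok = (n_below >= min_count) & (n - n_below >= min_count)
    cands = cands[ok]
    if cands.size == 0:
        raise ValueError("all candidate splits are degenerate")
    below = x[:, None] < cands[None, :]
    Z = _standardized_logrank(time, event, below)
    return float(cands[int(np.argmax(np.abs(Z)))])


def maxstat_p_value(b: float, min_frac: float = 0.1) -> float:
    """Lausen–Schumacher (1992) tail approximation for the maximally
    selected standardized log-rank statistic.

    Approximates P(sup |Z(ρ)| > b) for split proportions ρ in
    [``min_frac``, 1 − ``min_frac``]; clipped to [0, 1], returning 1 for
    b ≤ 1 where the approximation is vacuous.
    """
    if b <= 1.0:
        return 1.0
    e1, e2 = min_frac, 1.0 - min_frac
    log_odds = np.log((e2 * (1 - e1)) / (e1 * (1 - e2)))
    phi = stats.norm.pdf(b)
    p = phi * (b - 1.0 / b) * log_odds + 4.0 * phi / b
    return float(min(1.0, max(0.0, p)))


def _median_low(values) -> float:
    """Lower median: always an element of the list, so the combined cutoff
    stays an observed candidate value and commutes with monotone transforms."""
    s = sorted(values)
    return float(s[(len(s) - 1) // 2])


@dataclass
class CutpointResult:
    cutoff: float
    fold_cutoffs: list
    logrank_p: float  # selection-corrected (Lausen–Schumacher)
    group_sizes: Tuple[int, int]  # (below, at-or-above)
    logrank_p_uncorrected: float = float("nan")


def maxstat_cutpoint_cv(
    expression: pd.Series,
    survival_time: pd.Series,
    event: pd.Series,
    folds: int = 10,
    seed: int = 0,
    min_group_frac: float = 0.1,
) -> CutpointResult:
    """Cross-validated maximally-selected cutpoint.

    Folds are seeded and stratified by event status so no training portion is
    event-free.  The per-fold scan runs on the training samples only; the
    final cutoff is the (lower) median of the fold cutoffs.  The standardized
    log-rank statistic at that cutoff on all samples gives ``logrank_p``
    after correction for maximal selection (see :func:`maxstat_p_value`);
    the naive test is reported as ``logrank_p_uncorrected``.
    """
    x = expression.to_numpy(dtype=float)
    t = survival_time.to_numpy(dtype=float)
    e = event.to_numpy(dtype=int)
    n = len(x)
    if n < 30:
        raise ValueError("need at least 30 samples")
    if e.sum() < 10:
        raise ValueError("need at least 10 events")
    if np.ptp(x) == 0:
        raise ValueError("expression is constant")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    for mask in (e == 1, e == 0):
        idx = np.flatnonzero(mask)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % folds
    fold_cutoffs = []
    for f in range(folds):
        train = fold_of != f
        fold_cutoffs.append(maxstat_cutpoint(x[train], t[train], e[train], min_group_frac))
    cutoff = _median_low(fold_cutoffs)
    below = x < cutoff
    z = float(_standardized_logrank(t, e, below[:, None])[0])
    return CutpointResult(
        cutoff=cutoff,
        fold_cutoffs=fold_cutoffs,
        logrank_p=maxstat_p_value(abs(z), min_group_frac),
        group_sizes=(int(below.sum()), int((~below).sum())),
        logrank_p_uncorrected=logrank_test(t, e, below),
    )


def logrank_test(time, event, group) -> float:
    """Two-group log-rank chi-square p-value (lifelines backend)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    if group.all() or (~group).all():
        raise ValueError("log-rank test needs two nonempty groups")
    res = _ll_logrank(time[group], time[~group], event[group], event[~group])
    return float(res.p_value)


def group_compare(values_a, values_b, test: str = "wilcoxon") -> float:
    """Two-group comparison p-value: Wilcoxon rank-sum or Student's t."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    if test == "wilcoxon":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if test == "t":
        return float(stats.ttest_ind(a, b).pvalue)
    raise ValueError(f"unknown test {test!r}; use 'wilcoxon' or 't'")
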