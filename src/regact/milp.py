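"""Cardinality-constrained least-absolute-deviation (LAD) regression.

The response (expression of the modelled gene across samples) is predicted
from TF activities by a linear model

    g̃_j = β0 + Σ_t β_t · act_{t,j}

fitted by minimising Σ_j e_j with e_j ≥ |g_j − g̃_j|, subject to at most k
nonzero coefficients.  The cardinality constraint is encoded with binary
indicators z_t and big-M bounds −M·z_t ≤ β_t ≤ M·z_t, Σ_t z_t ≤ k, and the
resulting mixed-integer linear program is solved to global optimality with
HiGHS (``scipy.optimize.milp``).  For a fixed support (k = 0 or k ≥ T) the
problem is a plain LP and is solved directly.

A bottom-up scan refits the model for k = 1, 2, …, letting the solver choose
the support freely at each k (selected sets need not be nested), and scores
each k by leave-one-out cross-validation: the Pearson correlation between
pooled held-out predictions and the measured response.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .errors import SolverError, UndefinedCorrelationError

__all__ = [
    "RegressionProblem",
    "FittedLinearModel",
    "ScanResult",
    "fit_lad_subset",
    "loo_cv_performance",
    "bottom_up_scan",
    "transfer_predict",
    "activity_response_correlation",
    "pearson",
]

#: default big-M bound on coefficients; generous for z-scored data where
#: plausible |β| is O(1), tight enough to keep the LP relaxation useful.
DEFAULT_BIG_M = 1e3
DEFAULT_GAP = 1e-6


def pearson(x, y) -> float:
    """Pearson correlation that refuses constant inputs explicitly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class RegressionProblem:
    """Aligned activities (T × l) and response (length l)."""

    effects: pd.DataFrame
    response: pd.Series

    def __post_init__(self) -> None:
        if list(self.effects.columns) != list(self.response.index):
            raise ValueError("sample labels of effects and response must match and align")
        if not np.all(np.isfinite(self.effects.to_numpy())):
            raise ValueError("effects contain non-finite values")
        if not np.all(np.isfinite(self.response.to_numpy(dtype=float))):
            raise ValueError("response contains non-finite values")

    @property
    def n_regressors(self) -> int:
        return self.effects.shape[0]

    @property
    def n_samples(self) -> int:
        return self.effects.shape[1]

    def subset_samples(self, samples) -> "RegressionProblem":
        return RegressionProblem(self.effects[samples], self.response[samples])


@dataclass
class FittedLinearModel:
    """LAD fit: intercept, sparse coefficients and diagnostics."""

    intercept: float
    coefficients: pd.Series  # one entry per regressor, zero if unselected
    k: int
    objective: float
    per_sample_error: pd.Series
    predictions: pd.Series
    meta: dict = field(default_factory=dict)

    @property
    def selected(self) -> list:
        return list(self.coefficients.index[self.coefficients != 0.0])

    def predict(self, effects: pd.DataFrame) -> pd.Series:
        missing = [t for t in self.selected if t not in effects.index]
        if missing:
            raise KeyError(f"effects matrix is missing selected TFs: {missing}")
        coef = self.coefficients[self.coefficients != 0.0]
        pred = self.intercept + coef.to_numpy() @ effects.loc[coef.index].to_numpy()
        return pd.Series(pred, index=effects.columns, name="predicted")

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients.to_dict(),
                "k": self.k,
                "objective": self.objective,
                "meta": self.meta,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedLinearModel":
        d = json.loads(text)
        coef = pd.Series(d["coefficients"], dtype=float)
        return cls(
            intercept=float(d["intercept"]),
            coefficients=coef,
            k=int(d["k"]),
            objective=float(d["objective"]),
            per_sample_error=pd.Series(dtype=float),
            predictions=pd.Series(dtype=float),
            meta=d.get("meta", {}),
        )


def _lad_lp(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float]:
    """Unconstrained LAD on design X (l × p, first column ones) via LP."""
    l, p = X.shape
    c = np.concatenate([np.zeros(p), np.ones(l)])
    A = sp.vstack(
        [
            sp.hstack([sp.csr_matrix(X), -sp.eye(l)]),
            sp.hstack([sp.csr_matrix(-X), -sp.eye(l)]),
        ]
    )
    b = np.concatenate([y, -y])
    bounds = [(None, None)] * p + [(0, None)] * l
    res = linprog(c, A_ub=A, b_ub=b, bounds=bounds, method="highs")
    if res.status != 0:
        raise SolverError(f"LP solver failed with status {res.status}: {res.message}")
    return res.x[:p], float(res.fun)


def fit_lad_subset(
    problem: RegressionProblem,
    k: int,
    big_m: float = DEFAULT_BIG_M,
    gap: float = DEFAULT_GAP,
) -> FittedLinearModel:
    """Globally optimal LAD fit with at most ``k`` nonzero coefficients."""
    T, l = problem.n_regressors, problem.n_samples
    if not 0 <= k <= T:
        raise ValueError(f"k must be in [0, {T}], got {k}")
    if l < 2:
        raise ValueError("need at least 2 samples")
    y = problem.response.to_numpy(dtype=float)
    A = problem.effects.to_numpy(dtype=float)
    tf_index = problem.effects.index
    meta = {"solver": "highs", "big_m": big_m, "gap": gap}

    if k == 0:
        beta0 = float(np.median(y))
        beta = np.zeros(T)
    elif k >= T:
        coefs, _ = _lad_lp(np.column_stack([np.ones(l), A.T]), y)
        beta0, beta = float(coefs[0]), coefs[1:]
    else:
        beta0, beta = _milp_fit(A, y, k, big_m, gap)
        if np.any(np.abs(beta) > 0.9 * big_m):
            warnings.warn(
                f"a coefficient exceeds 0.9*big_m={0.9 * big_m:g}; "
                "increase big_m and refit",
                RuntimeWarning,
            )
    pred = beta0 + beta @ A
    err = np.abs(y - pred)
    return FittedLinearModel(
        intercept=beta0,
        coefficients=pd.Series(beta, index=tf_index),
        k=k,
        objective=float(err.sum()),
        per_sample_error=pd.Series(err, index=problem.response.index),
        predictions=pd.Series(pred, index=problem.response.index),
        meta=meta,
    )


def _milp_fit(A: np.ndarray, y: np.ndarray, k: int, big_m: float, gap: float):
    """HiGHS MILP: variables [β0, β (T), e (l), z (T)]."""
    T, l = A.shape
    c = np.concatenate([np.zeros(1 + T), np.ones(l), np.zeros(T)])
    X = np.column_stack([np.ones(l), A.T])  # l × (1+T)
    con = sp.vstack(
        [
            # residual envelopes: ±(Xβ − y) ≤ e
            sp.hstack([sp.csr_matrix(X), -sp.eye(l), sp.csr_matrix((l, T))]),
            sp.hstack([sp.csr_matrix(-X), -sp.eye(l), sp.csr_matrix((l, T))]),
            # indicator link: |β_t| ≤ M z_t
            sp.hstack([sp.csr_matrix((T, 1)), sp.eye(T), sp.csr_matrix((T, l)), -big_m * sp.eye(T)]),
            sp.hstack([sp.csr_matrix((T, 1)), -sp.eye(T), sp.csr_matrix((T, l)), -big_m * sp.eye(T)]),
            # cardinality: Σ z_t ≤ k
            sp.hstack([sp.csr_matrix((1, 1 + T + l)), sp.csr_matrix(np.ones((1, T)))]),
        ]
    ).tocsc()
    ub = np.concatenate([y, -y, np.zeros(2 * T), [k]])
    lb_var = np.concatenate([[-np.inf] * (1 + T), np.zeros(l), np.zeros(T)])
    ub_var = np.concatenate([[np.inf] * (1 + T), [np.inf] * l, np.ones(T)])
    integrality = np.concatenate([np.zeros(1 + T + l), np.ones(T)])
    with warnings.catch_warnings():
        # the tolerance options are valid HiGHS options that scipy merely
        # does not document; it forwards them verbatim with a warning
        warnings.filterwarnings("ignore", message="Unrecognized options")
        res = milp(
            c,
            constraints=LinearConstraint(con, -np.inf, ub),
            integrality=integrality,
            bounds=Bounds(lb_var, ub_var),
            options={
                "mip_rel_gap": gap,
                "mip_feasibility_tolerance": 1e-9,
            },
        )
    if res.status != 0:
        raise SolverError(f"MILP solver failed with status {res.status}: {res.message}")
    # polish: exact LP refit on the selected support removes big-M dust
    # (an integrality-tolerance z still admits |β| up to M·tol otherwise)
    z = res.x[1 + T + l :]
    support = np.flatnonzero(z > 0.5)
    coefs, _ = _lad_lp(np.column_stack([np.ones(l), A[support].T]), y)
    beta = np.zeros(T)
    beta0 = float(coefs[0])
    beta[support] = coefs[1:]
    return beta0, beta


def loo_cv_performance(
    problem: RegressionProblem,
    k: int,
    **solver_kwargs,
) -> Tuple[float, pd.Series]:
    """Leave-one-out CV: refit (with free support selection) per left-out
    sample and return the pooled Pearson correlation between held-out
    predictions and the measured response, plus the predictions."""
    if problem.n_samples < 3:
        raise ValueError("LOO-CV needs at least 3 samples")
    y = problem.response
    if np.ptp(y.to_numpy(dtype=float)) == 0:
        raise UndefinedCorrelationError("response is constant; correlation undefined")
    preds = {}
    samples = list(problem.effects.columns)
    for j in samples:
        train = [s for s in samples if s != j]
        model = fit_lad_subset(problem.subset_samples(train), k, **solver_kwargs)
        preds[j] = float(model.predict(problem.effects[[j]]).iloc[0])
    pred = pd.Series(preds)[samples]
    return pearson(pred, y), pred


@dataclass
class ScanResult:
    """One row per cardinality k of a bottom-up scan."""

    rows: list  # of dicts: k, selected, model, cv_pcc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "k": r["k"],
                    "selected": ",".join(map(str, r["selected"])),
                    "objective": r["model"].objective,
                    "cv_pcc": r["cv_pcc"],
                }
                for r in self.rows
            ]
        )


def bottom_up_scan(
    problem: RegressionProblem,
    k_max: int,
    cv: bool = True,
    **solver_kwargs,
) -> ScanResult:
    """Fit k = 1..k_max independently (no forced nesting); optionally score
    each k by LOO-CV."""
    if not 1 <= k_max <= problem.n_regressors:
        raise ValueError(f"k_max must be in [1, {problem.n_regressors}], got {k_max}")
    rows = []
    for k in range(1, k_max + 1):
        model = fit_lad_subset(problem, k, **solver_kwargs)
        cv_pcc = loo_cv_performance(problem, k, **solver_kwargs)[0] if cv else None
        rows.append({"k": k, "selected": model.selected, "model": model, "cv_pcc": cv_pcc})
    return ScanResult(rows)


def transfer_predict(
    model: FittedLinearModel,
    effects_new: pd.DataFrame,
    response_new: pd.Series,
) -> Tuple[pd.Series, float]:
    """Apply frozen coefficients to a new cohort and report the Pearson
    correlation against its measured response."""
    pred = model.predict(effects_new)
    return pred, pearson(pred, response_new)


def activity_response_correlation(
    effects: pd.DataFrame, response: pd.Series
) -> pd.Series:
    """Per-TF Pearson correlation of activity with the response, sorted by
    descending |r|; constant activity rows are reported as NaN."""
    y = response.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise UndefinedCorrelationError("response is constant; correlation undefined")
    out = {}
    for tf, row in effects.iterrows():
        x = row.to_numpy(dtype=float)
        out[tf] = np.nan if np.ptp(x) == 0 else float(stats.pearsonr(x, y).statistic)
    ser = pd.Series(out, name="pcc")
    return ser.reindex(ser.abs().sort_values(ascending=False, kind="stable").index)
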