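"""Per-sample TF activity: the edge-strength-weighted mean of target expression.

The activity of TF *t* in sample *j* is

    act_{t,j} = Σ_i es_{t,i} · g_{i,j} / Σ_i es_{t,i}

over the TF's annotated targets with positive edge strength, where g is
z-scored expression.  Being a weighted mean, the activity is bounded by the
targets' expression range and invariant to rescaling a TF's weights.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import UndefinedActivityError

__all__ = ["tf_activity", "activity_matrix"]


def tf_activity(es_row: Mapping[str, float], expr_column: Mapping[str, float]) -> float:
    """Weighted-mean activity for one TF in one sample.

    Targets absent from ``expr_column`` are dropped from numerator and
    denominator alike (renormalisation).  Raises
    :class:`UndefinedActivityError` when no target with positive weight
    overlaps the expression column.
    """
    num = 0.0
    den = 0.0
    for gene, w in es_row.items():
        if w > 0 and gene in expr_column:
            num += w * expr_column[gene]
            den += w
    if den <= 0:
        raise UndefinedActivityError("undefined activity: no targets with positive weight")
    return num / den


def activity_matrix(
    edges,
    expr: pd.DataFrame,
    tfs: Optional[Sequence[str]] = None,
    exclude_target: Optional[str] = None,
) -> pd.DataFrame:
    """Activities for every requested TF across all samples of ``expr``.

    Parameters
    ----------
    edges
        :class:`~regact.evidence.EdgeStrengthTable`.
    expr
        Gene × sample expression matrix (z-scores).
    tfs
        TFs to evaluate; defaults to every TF in ``edges``.
    exclude_target
        Gene to drop from every TF's target set before averaging.  Used to
        keep the modelled gene itself out of its regulators' activities so
        the response cannot leak into the predictors.
    """
    if tfs is None:
        tfs = edges.tfs
    rows = {}
    for tf in tfs:
        weights = edges.targets_of(tf)
        if exclude_target is not None:
            weights = weights.drop(exclude_target, errors="ignore")
        weights = weights[weights.index.isin(expr.index)]
        if weights.empty or weights.sum() <= 0:
            raise UndefinedActivityError(f"undefined activity for TF {tf!r}: no usable targets")
        sub = expr.loc[weights.index]
        rows[tf] = weights.to_numpy() @ sub.to_numpy() / weights.sum()
    out = pd.DataFrame.from_dict(rows, orient="index", columns=expr.columns)
    out.index.name = "tf_id"
    return out.loc[list(tfs)]
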