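"""Relative qPCR quantification: ΔΔCt fold changes from Ct triplicates.

Per condition, the median Ct over technical replicates is taken for the gene
of interest (GOI) and the housekeeping gene (HK); ΔCt = median Ct_GOI −
median Ct_HK normalises the GOI to the housekeeping control, ΔΔCt =
ΔCt_treated − ΔCt_control normalises the treated condition to the control,
and the fold change is 2^(−ΔΔCt).  Note the second difference is taken on
ΔCt values (Livak method), so adding a constant to every Ct cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Sequence

import pandas as pd

__all__ = ["CtMeasurement", "delta_ct", "fold_change", "fold_change_table"]


@dataclass(frozen=True)
class CtMeasurement:
    """Ct technical replicates for one sample/condition."""

    goi_ct: Sequence[float]
    hk_ct: Sequence[float]
    condition: str = ""

    def __post_init__(self) -> None:
        for name, vals in (("goi_ct", self.goi_ct), ("hk_ct", self.hk_ct)):
            if len(vals) == 0:
                raise ValueError(f"{name}: need at least one replicate")
            if any(not 0 < v < 50 for v in vals):
                raise ValueError(f"{name}: Ct values must lie in (0, 50)")


def delta_ct(m: CtMeasurement) -> float:
    """Median-of-replicates ΔCt = Ct_GOI − Ct_HK."""
    return median(m.goi_ct) - median(m.hk_ct)


def fold_change(treated: CtMeasurement, control: CtMeasurement) -> float:
    """Fold change 2^(−ΔΔCt) of the treated condition relative to control."""
    ddct = delta_ct(treated) - delta_ct(control)
    return 2.0 ** (-ddct)


def fold_change_table(
    ct: pd.DataFrame,
    goi: str,
    hk: str,
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-sample fold changes from a long Ct table.

    ``ct`` has columns sample, condition, gene, ct.  Every non-control
    condition of a sample is compared against that sample's control.  The
    result carries one row per (sample, condition) with the fold change;
    summarising across biological replicates is left to the caller (both the
    mean of fold changes and the fold change of the mean ΔΔCt are
    legitimate; they differ, so neither is imposed here).
    """
    required = {"sample", "condition", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    rows = []
    for sample, sub in ct.groupby("sample"):
        def _measure(cond: str) -> CtMeasurement:
            block = sub[sub["condition"] == cond]
            return CtMeasurement(
                goi_ct=block.loc[block["gene"] == goi, "ct"].tolist(),
                hk_ct=block.loc[block["gene"] == hk, "ct"].tolist(),
                condition=cond,
            )

        control = _measure(control_label)
        for cond in sub["condition"].unique():
            if cond == control_label:
                continue
            rows.append(
                {
                    "sample": sample,
                    "condition": cond,
                    "fold_change": fold_change(_measure(cond), control),
                }
            )
    return pd.DataFrame(rows)
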