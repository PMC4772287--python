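"""Integration of TF→target binding evidence into edge strengths.

Evidence for a transcription factor binding the promoter of a target gene
comes from four kinds of sources: curated interaction databases (direct and
indirect annotations, split by activation/inhibition), a ChIP-experiment
compendium (ChEA-style), ChIP peak calls from a genome-wide consortium
(ENCODE-style, collapsed to a binary TF-by-target matrix), and a
position-weight-matrix promoter score (total binding affinity, TBA) reported
as a z-score.

A TF/target pair is *reliable* if

(i)  the pair carries a "direct" curated annotation (activation or
     inhibition), or
(ii) the pair is supported by at least two of: an "indirect" curated
     annotation, the ChIP compendium, the consortium ChIP matrix, and a TBA
     z-score ≥ 1.

For reliable pairs the edge strength ``es`` is the number of set flags among
{ChIP compendium, direct activation, direct inhibition, indirect activation,
indirect inhibition}, plus the TBA z-score itself when it is ≥ 1.  The
consortium ChIP matrix contributes to reliability only, not to the count
(configurable).  Unreliable pairs have ``es = 0`` and are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "EvidenceRecord",
    "EdgeStrengthTable",
    "collapse_encode",
    "is_reliable",
    "edge_strength",
    "build_edge_table",
]


@dataclass(frozen=True)
class EvidenceRecord:
    """All binding evidence for one (TF, target) pair.

    ``tba_z`` is the promoter-wide total-binding-affinity z-score; ``None``
    means the score is unavailable, which is treated as "not ≥ 1" rather
    than as zero.
    """

    tf_id: str
    target_id: str
    metacore_direct_activation: bool = False
    metacore_direct_inhibition: bool = False
    metacore_indirect_activation: bool = False
    metacore_indirect_inhibition: bool = False
    chea: bool = False
    encode: bool = False
    tba_z: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tba_z is not None and not math.isfinite(self.tba_z):
            raise ValueError(
                f"tba_z must be finite for pair ({self.tf_id}, {self.target_id})"
            )

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.tf_id, self.target_id)


def is_reliable(rec: EvidenceRecord) -> bool:
    """Apply the two reliability criteria to a single evidence record."""
    if rec.metacore_direct_activation or rec.metacore_direct_inhibition:
        return True
    indirect = rec.metacore_indirect_activation or rec.metacore_indirect_inhibition
    tba_hit = rec.tba_z is not None and rec.tba_z >= 1.0
    n_support = sum((indirect, rec.chea, rec.encode, tba_hit))
    return n_support >= 2


def edge_strength(rec: EvidenceRecord, include_encode_in_count: bool = False) -> float:
    """Numeric edge strength of a pair; 0 for unreliable pairs.

    Counted categories: ChIP compendium plus the four curated categories.
    The consortium ChIP flag counts only if ``include_encode_in_count``.
    A TBA z-score ≥ 1 is added to the count.
    """
    if not is_reliable(rec):
        return 0.0
    count = sum(
        (
            rec.chea,
            rec.metacore_direct_activation,
            rec.metacore_direct_inhibition,
            rec.metacore_indirect_activation,
            rec.metacore_indirect_inhibition,
        )
    )
    if include_encode_in_count and rec.encode:
        count += 1
    es = float(count)
    if rec.tba_z is not None and rec.tba_z >= 1.0:
        es += rec.tba_z
    return es


def collapse_encode(
    raw_hits: Iterable[Tuple[str, str, object]],
) -> pd.DataFrame:
    """Collapse a redundant binary ChIP hit list to one row per target.

    ``raw_hits`` are ``(tf_id, target_id, source_row_id)`` triples from a
    matrix that may list the same target gene in several rows and the same
    TF in several columns.  Duplicate target rows are combined by
    *intersection* of their hits; duplicate TF columns are combined by
    *union*.  Returns a target × TF 0/1 integer DataFrame.
    """
    hits = list(raw_hits)
    if not hits:
        return pd.DataFrame(dtype=int)
    # union over duplicate TF columns is implicit: a hit from any copy of the
    # column lands in the same (row, tf) cell.
    per_row: dict[str, dict[object, set]] = {}
    tf_order: dict[str, None] = {}
    target_order: dict[str, None] = {}
    for tf, target, row_id in hits:
        per_row.setdefault(target, {}).setdefault(row_id, set()).add(tf)
        tf_order.setdefault(tf, None)
        target_order.setdefault(target, None)
    tfs = list(tf_order)
    out = pd.DataFrame(0, index=list(target_order), columns=tfs, dtype=int)
    for target, rows in per_row.items():
        consistent = set.intersection(*rows.values())
        for tf in consistent:
            out.loc[target, tf] = 1
    return out


@dataclass
class EdgeStrengthTable:
    """Sparse nonnegative TF-by-target weights; absent pair means ``es = 0``."""

    es: pd.Series = field(
        default_factory=lambda: pd.Series(
            dtype=float,
            index=pd.MultiIndex.from_tuples([], names=["tf_id", "target_id"]),
        )
    )

    def __post_init__(self) -> None:
        if not isinstance(self.es.index, pd.MultiIndex) or self.es.index.nlevels != 2:
            raise ValueError("es must be indexed by (tf_id, target_id)")
        self.es.index = self.es.index.set_names(["tf_id", "target_id"])
        if self.es.index.has_duplicates:
            dup = self.es.index[self.es.index.duplicated()][0]
            raise ValueError(f"duplicate (tf, target) pair: {dup}")
        if (self.es < 0).any():
            raise ValueError("edge strengths must be nonnegative")

    def __len__(self) -> int:
        return int((self.es > 0).sum())

    @property
    def tfs(self) -> list:
        return list(self.es.index.get_level_values("tf_id").unique())

    def strength(self, tf_id: str, target_id: str) -> float:
        return float(self.es.get((tf_id, target_id), 0.0))

    def targets_of(self, tf_id: str) -> pd.Series:
        """Positive weights of one TF, indexed by target gene."""
        if tf_id not in self.es.index.get_level_values("tf_id"):
            return pd.Series(dtype=float)
        row = self.es.xs(tf_id, level="tf_id")
        return row[row > 0]

    def to_frame(self) -> pd.DataFrame:
        return self.es.rename("es").reset_index()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EdgeStrengthTable":
        es = frame.set_index(["tf_id", "target_id"])["es"].astype(float)
        return cls(es)


def build_edge_table(records: Sequence[EvidenceRecord], **kwargs) -> EdgeStrengthTable:
    """Evaluate edge strengths for a batch of records; keep positive entries.

    Raises ``ValueError`` naming the pair when a (tf, target) pair occurs
    more than once.
    """
    seen = set()
    entries = {}
    for rec in records:
        if rec.pair in seen:
            raise ValueError(f"duplicate (tf, target) pair: {rec.pair}")
        seen.add(rec.pair)
        es = edge_strength(rec, **kwargs)
        if es > 0:
            entries[rec.pair] = es
    if not entries:
        return EdgeStrengthTable()
    idx = pd.MultiIndex.from_tuples(entries.keys(), names=["tf_id", "target_id"])
    return EdgeStrengthTable(pd.Series(list(entries.values()), index=idx, dtype=float))
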