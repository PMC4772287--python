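"""Readers, writers, normalization chains and missing-data policy.

TSV dialect: tab-separated, UTF-8, header row required, ``#`` comment lines,
``NA`` for missing values.  Gene identifiers are case-sensitive symbols.
Every writer prepends a provenance comment header (tool version and a hash
of the options that produced the file).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .evidence import EdgeStrengthTable, EvidenceRecord

__version__ = "0.1.0"

logger = logging.getLogger("regact")

__all__ = [
    "znormalize_genes",
    "hoek_normalize",
    "impute_and_filter",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_edges_tsv",
    "write_edges_tsv",
    "read_clinical_tsv",
    "read_evidence_tables",
    "PipelineConfig",
]


def znormalize_genes(m: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Z-score each gene row (population sd by default).

    Constant rows cannot be z-scored; they are dropped with a warning and
    the count is logged.
    """
    vals = m.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.any():
        n = int(constant.sum())
        warnings.warn(f"dropping {n} constant gene rows (cannot be z-scored)")
        logger.info("znormalize_genes: dropped %d constant rows", n)
        m = m.loc[~constant]
        vals = vals[~constant]
        sd = sd[~constant]
    centered = vals - vals.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered / sd[:, None], index=m.index, columns=m.columns)


def hoek_normalize(raw: pd.DataFrame, floor: float = 0.01) -> pd.DataFrame:
    """MAS5-style post-processing chain for raw intensity matrices.

    Floor at ``floor`` → divide each sample by its 50th percentile →
    divide each gene by its median across samples → z-score per gene.
    """
    vals = raw.to_numpy(dtype=float)
    vals = np.maximum(vals, floor)
    sample_p50 = np.percentile(vals, 50, axis=0)
    if np.any(sample_p50 <= 0):
        raise ValueError("non-positive sample 50th percentile")
    vals = vals / sample_p50[None, :]
    gene_med = np.median(vals, axis=1)
    if np.any(gene_med <= 0):
        raise ValueError("non-positive gene median")
    vals = vals / gene_med[:, None]
    return znormalize_genes(pd.DataFrame(vals, index=raw.index, columns=raw.columns))


def impute_and_filter(
    m: pd.DataFrame,
    max_missing_per_sample: Optional[int] = None,
) -> pd.DataFrame:
    """Drop high-missingness samples, then mean-impute per gene.

    ``max_missing_per_sample`` defaults to 10 % of the gene count.  A gene
    with no observed value at all cannot be imputed and raises.
    """
    if max_missing_per_sample is None:
        max_missing_per_sample = int(np.ceil(0.1 * m.shape[0]))
    missing_per_sample = m.isna().sum(axis=0)
    drop = missing_per_sample.index[missing_per_sample > max_missing_per_sample]
    if len(drop):
        logger.info(
            "impute_and_filter: excluding samples %s (missing counts %s)",
            list(drop),
            missing_per_sample[drop].tolist(),
        )
        warnings.warn(f"excluding {len(drop)} high-missingness samples: {list(drop)}")
        m = m.drop(columns=drop)
    all_missing = m.isna().all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"gene {m.index[all_missing][0]!r} has no observed values; cannot impute"
        )
    return m.apply(lambda row: row.fillna(row.mean()), axis=1)


# ---------------------------------------------------------------------------
# TSV I/O


def _provenance(meta: Dict) -> list:
    digest = hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    lines = [f"# regact {__version__} config_hash={digest}"]
    lines += [f"# {k}={v}" for k, v in sorted(meta.items())]
    return lines


def _write_with_header(df: pd.DataFrame, path, meta: Dict, index: bool) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for line in _provenance(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", na_rep="NA", index=index)


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values="NA")
    df.index.name = "gene_id"
    return df


def write_expression_tsv(expr: pd.DataFrame, path, **meta) -> None:
    _write_with_header(expr, path, meta, index=True)


def read_edges_tsv(path) -> EdgeStrengthTable:
    df = pd.read_csv(path, sep="\t", comment="#", na_values="NA")
    return EdgeStrengthTable.from_frame(df)


def write_edges_tsv(edges: EdgeStrengthTable, path, **meta) -> None:
    _write_with_header(edges.to_frame(), path, meta, index=False)


def read_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values="NA", index_col="sample_id")
    if (df["survival_time_days"] < 0).any():
        raise ValueError("negative survival times")
    return df


_FLAG_SOURCES = (
    "metacore_direct_activation",
    "metacore_direct_inhibition",
    "metacore_indirect_activation",
    "metacore_indirect_inhibition",
    "chea",
    "encode",
)


def read_evidence_tables(tba: Optional[str] = None, **source_paths) -> list:
    """Merge per-source TSVs into evidence records.

    Each flag source is a TSV with columns ``tf_id``, ``target_id``; the TBA
    source additionally has a ``value`` column (z-score).  Keyword names
    must match the record flag fields.
    """
    unknown = set(source_paths) - set(_FLAG_SOURCES)
    if unknown:
        raise ValueError(f"unknown evidence sources: {sorted(unknown)}")
    flags: Dict[tuple, dict] = {}
    for source, path in source_paths.items():
        df = pd.read_csv(path, sep="\t", comment="#")
        for tf, target in df[["tf_id", "target_id"]].itertuples(index=False):
            flags.setdefault((tf, target), {})[source] = True
    tba_vals: Dict[tuple, float] = {}
    if tba is not None:
        df = pd.read_csv(tba, sep="\t", comment="#")
        for tf, target, value in df[["tf_id", "target_id", "value"]].itertuples(index=False):
            tba_vals[(tf, target)] = float(value)
            flags.setdefault((tf, target), {})
    return [
        EvidenceRecord(tf, target, tba_z=tba_vals.get((tf, target)), **fl)
        for (tf, target), fl in sorted(flags.items())
    ]


@dataclass
class PipelineConfig:
    """Options for an end-to-end run; round-trips through JSON/YAML."""

    target_gene: str = "MITF"
    k_max: int = 2
    big_m: float = 1e3
    gap: float = 1e-6
    seed: int = 0
    normalization: str = "none"  # none | zscore | hoek
    max_missing_per_sample: Optional[int] = None
    cv_folds: int = 10
    thin_max_mm: float = 1.0
    thick_min_mm: float = 4.0
    exclude_target_from_activity: bool = True

    def __post_init__(self) -> None:
        if self.k_max < 0:
            raise ValueError("k_max must be nonnegative")
        if self.gap <= 0 or self.big_m <= 0:
            raise ValueError("gap and big_m must be positive")
        if self.normalization not in ("none", "zscore", "hoek"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if not 0 < self.thin_max_mm < self.thick_min_mm:
            raise ValueError("thickness boundaries must satisfy 0 < thin < thick")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)
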