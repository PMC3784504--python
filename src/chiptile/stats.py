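"""Phenotype-frequency and ChIP-qPCR statistics.

Pearson's chi-square test of independence on condition x outcome count
tables (e.g. resolved / unresolved sister chromatids across knockdowns), and
relative ChIP-qPCR enrichment of a condition against a mock-treated
reference, summarised as mean ratio with its standard error across
biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def chi2_independence(table, yates: bool = False) -> Chi2Result:
    """Pearson chi-square test of independence on an r x c count table.

    Expected counts come from the marginal products; df = (r-1)(c-1). No
    continuity correction by default; ``yates`` enables it for 2x2 tables.
    A zero row or column marginal leaves expected counts undefined and is
    rejected.
    """
    counts = np.asarray(
        table.to_numpy() if isinstance(table, pd.DataFrame) else table, dtype=float
    )
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ConfigurationError("count table must be at least 2x2")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ConfigurationError("counts must be finite and non-negative")
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ConfigurationError("zero marginal: expected counts undefined")
    res = sps.chi2_contingency(counts, correction=yates)
    return Chi2Result(
        statistic=float(res.statistic), df=int(res.dof), p_value=float(res.pvalue)
    )


def relative_enrichment(
    data: pd.DataFrame,
    reference: str,
    region_col: str = "region",
    condition_col: str = "condition",
    value_col: str = "value",
) -> pd.DataFrame:
    """ChIP-qPCR signals expressed relative to a reference condition.

    ``data`` is long-form: one row per (region, condition, replicate
    measurement). Per region, every non-reference replicate value is divided
    by the mean reference signal of that region; the result reports the mean
    ratio, its S.E.M. (sample SD / sqrt(n); undefined for n = 1) and n, per
    (region, condition).
    """
    for col in (region_col, condition_col, value_col):
        if col not in data.columns:
            raise ConfigurationError(f"missing column {col!r}")
    if reference not in set(data[condition_col]):
        raise ConfigurationError(f"reference condition {reference!r} not in data")

    rows = []
    for region, region_df in data.groupby(region_col, sort=False):
        ref_values = region_df.loc[
            region_df[condition_col] == reference, value_col
        ].to_numpy(dtype=float)
        if ref_values.size == 0:
            raise ConfigurationError(f"region {region!r} has no reference measurements")
        ref = float(ref_values.mean())
        if ref <= 0:
            raise ConfigurationError(f"non-positive reference signal in region {region!r}")
        for condition, cond_df in region_df.groupby(condition_col, sort=False):
            if condition == reference:
                continue
            ratios = cond_df[value_col].to_numpy(dtype=float) / ref
            n = ratios.size
            sem = float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            rows.append(
                {
                    region_col: region,
                    condition_col: condition,
                    "mean_ratio": float(ratios.mean()),
                    "sem": sem,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
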