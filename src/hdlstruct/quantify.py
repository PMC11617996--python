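"""Label-free quantification statistics for protein- and peptide-level tables.

The processing order is fixed and mirrors standard LFQ practice:
log2 transform -> missingness filter -> median normalization -> downshifted
Gaussian imputation -> two-sample t-test. Missing values are assumed
left-censored (low-abundance features drop below the detection limit),
which is what the downshifted imputation model encodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

PIPELINE_ORDER = ("log2", "filter", "normalize", "impute", "test")


@dataclass
class QuantTable:
    """Feature x sample intensity matrix with a sample design.

    ``values``: DataFrame, rows = feature ids, columns = sample ids, NaN =
    missing. ``design``: DataFrame indexed by sample id with columns
    ``group`` and (optionally) ``dose``. ``space`` is "raw" or "log2".
    """

    values: pd.DataFrame
    design: pd.DataFrame
    space: str = "log2"

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.design.index):
            missing = set(self.values.columns) ^ set(self.design.index)
            raise ValueError(f"sample mismatch between values and design: {missing}")
        if "group" not in self.design.columns:
            raise ValueError("design requires a 'group' column")
        if self.space == "raw" and (self.values < 0).any().any():
            raise ValueError("negative raw intensities")

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.design["group"]))

    def group_samples(self, group: str) -> list[str]:
        samples = list(self.design.index[self.design["group"] == group])
        if not samples:
            raise KeyError(f"no samples in group {group!r}")
        return samples


def log2_transform(table: QuantTable) -> QuantTable:
    """Raw intensities to log2; zeros become missing."""
    if table.space == "log2":
        return table
    vals = table.values.where(table.values > 0)
    return replace(table, values=np.log2(vals), space="log2")


def filter_missingness(table: QuantTable, max_missing_fraction: float = 0.5
                       ) -> QuantTable:
    """Keep a feature iff at least one group observes it in >= 1 - ``max
    missing fraction`` of that group's samples."""
    if table.values.empty:
        raise ValueError("empty table")
    keep = pd.Series(False, index=table.values.index)
    for group in table.groups:
        cols = table.group_samples(group)
        frac_missing = table.values[cols].isna().mean(axis=1)
        keep |= frac_missing <= max_missing_fraction
    dropped = (~keep).sum()
    if dropped:
        log.info("missingness filter dropped %d/%d features", dropped, len(keep))
    return replace(table, values=table.values.loc[keep].copy())


def median_normalize(table: QuantTable) -> QuantTable:
    """Shift each sample so its observed median equals the grand median of
    the pre-normalization sample medians (log2 space, additive shift)."""
    if table.space != "log2":
        raise ValueError("median_normalize expects a log2 table")
    medians = table.values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"sample(s) with no observed values: {bad}")
    target = float(np.median(medians))
    shifted = table.values + (target - medians)
    out_medians = shifted.median(axis=0, skipna=True)
    assert np.allclose(out_medians, target, atol=1e-9), "median equalization failed"
    return replace(table, values=shifted)


def impute_downshift(table: QuantTable, width: float = 0.3, shift: float = 1.8,
                     seed: int | None = 0) -> QuantTable:
    """Impute missing entries per sample from a downshifted Gaussian.

    For each sample column with observed mean m and standard deviation s,
    missing entries are drawn from Normal(m - shift*s, (width*s)^2) —
    the left-censoring model of the standard perseus-style workflow.
    Observed entries are untouched; a fixed seed gives identical output.
    """
    rng = np.random.default_rng(seed)
    vals = table.values.copy()
    for col in vals.columns:
        column = vals[col]
        mask = column.isna()
        if not mask.any():
            continue
        observed = column.dropna()
        if len(observed) < 2:
            raise ValueError(f"sample {col!r} has fewer than 2 observed values")
        m, s = float(observed.mean()), float(observed.std(ddof=1))
        draws = rng.normal(m - shift * s, width * s, size=int(mask.sum()))
        vals.loc[mask, col] = draws
    return replace(table, values=vals)


def differential(table: QuantTable, control_group: str,
                 experimental_group: str, alpha: float = 0.05,
                 equal_var: bool = True) -> pd.DataFrame:
    """Two-sample t-test per feature; log2fc = mean(exp) - mean(control).

    Returns a DataFrame with columns ``feature_id``, ``log2fc``,
    ``p_value``, ``significant`` (p < alpha). Student's pooled-variance
    test by default; pass ``equal_var=False`` for Welch.
    """
    ctrl = table.group_samples(control_group)
    expt = table.group_samples(experimental_group)
    if len(ctrl) < 2 or len(expt) < 2:
        raise ValueError("each group needs >= 2 samples for testing")
    a = table.values[expt].to_numpy(dtype=float)
    b = table.values[ctrl].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("differential expects a complete (imputed) table")
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    tstat, pval = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    # identical groups: zero variance yields nan; no evidence of change
    pval = np.where(np.isnan(pval) & np.isclose(log2fc, 0.0), 1.0, pval)
    out = pd.DataFrame(
        {
            "feature_id": table.values.index,
            "log2fc": log2fc,
            "p_value": pval,
            "significant": pval < alpha,
        }
    ).reset_index(drop=True)
    return out


def benjamini_hochberg(results: pd.DataFrame, alpha: float = 0.05
                       ) -> pd.DataFrame:
    """Optional FDR control; adds ``q_value`` and re-derives significance."""
    p = results["p_value"].to_numpy()
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = results.copy()
    out.loc[out.index[order], "q_value"] = np.clip(q, 0, 1)
    out["significant"] = out["q_value"] < alpha
    return out
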