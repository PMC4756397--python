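"""Cross-tissue correlation, cohort concordance, and BS decomposition.

The decomposition splits each cross-tissue difference in BS betas into an
oxBS (true 5mC) component and a delta-beta (5hmC) component; the two sum to
the BS difference exactly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import EmptyInputError, ValidationError
from .hmc_calling import HmcCallSet


@dataclass
class ConcordanceResult:
    r: float
    r_squared: float
    adjusted_r_squared: float
    p_value: float
    n: int
    median_abs_difference: float | None = None  # percentage points (delta-beta x 100)


def _pearson(x: np.ndarray, y: np.ndarray) -> ConcordanceResult:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise EmptyInputError(f"only {n} complete pairs; need >= 3")
    r, p = stats.pearsonr(x, y)
    r2 = r * r
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return ConcordanceResult(float(r), float(r2), float(adj), float(p), int(n))


def cross_tissue_correlation(callset: HmcCallSet, anchor_tissue: str) -> ConcordanceResult:
    """Fit of other-tissue mean delta-beta on the anchor tissue's, over the
    anchor's detectable probes."""
    mean = callset.tissue_mean_delta
    if anchor_tissue not in mean.columns:
        raise ValidationError(f"unknown tissue {anchor_tissue!r}")
    others = [t for t in mean.columns if t != anchor_tissue]
    if not others:
        raise EmptyInputError("need a second tissue")
    probes = callset.detectable_probes(anchor_tissue)
    if len(probes) == 0:
        raise EmptyInputError(f"no detectable probes in {anchor_tissue}")
    x = mean.loc[probes, anchor_tissue].to_numpy()
    y = mean.loc[probes, others[0]].to_numpy()
    return _pearson(x, y)


def validate_concordance(
    discovery_levels: pd.Series,
    validation_callset: HmcCallSet,
    tissue: str,
) -> ConcordanceResult:
    """Pearson concordance of discovery vs validation tissue-mean delta-beta
    at the listed probes; median |difference| reported in percentage points."""
    val_mean = validation_callset.tissue_mean_delta
    if tissue not in val_mean.columns:
        raise ValidationError(f"unknown tissue {tissue!r}")
    shared = discovery_levels.index.intersection(val_mean.index)
    if len(shared) < 3:
        raise EmptyInputError(f"only {len(shared)} shared probes; need >= 3")
    x = discovery_levels.loc[shared].to_numpy(dtype=float)
    y = val_mean.loc[shared, tissue].to_numpy()
    res = _pearson(x, y)
    ok = ~(np.isnan(x) | np.isnan(y))
    res.median_abs_difference = float(np.median(np.abs(x[ok] - y[ok])) * 100.0)
    return res


def count_significant_differences(
    probes,
    callset: HmcCallSet,
    alpha: float = 0.05,
) -> tuple[int, pd.Series]:
    """Probes (of those present) whose per-donor delta-beta differs between
    tissues by an unpaired two-sided t-test at ``alpha``."""
    tissues = callset.tissues
    if len(tissues) < 2:
        raise EmptyInputError("need both tissues")
    shared = pd.Index(probes).intersection(callset.delta_beta.index)
    if len(shared) == 0:
        raise EmptyInputError("no listed probes present in callset")
    a = callset.delta_beta.loc[shared, callset.pairs_of(tissues[0])].to_numpy()
    b = callset.delta_beta.loc[shared, callset.pairs_of(tissues[1])].to_numpy()
    pvals = stats.ttest_ind(a, b, axis=1, nan_policy="omit").pvalue
    pser = pd.Series(np.asarray(pvals, dtype=float), index=shared)
    return int((pser < alpha).sum()), pser


def decompose_bs_differences(callset: HmcCallSet, n: int = 1000) -> tuple[pd.DataFrame, dict]:
    """Top-n cross-tissue BS-beta differences split into 5mC and 5hmC parts.

    driver = "hmc" iff the delta-beta component exceeds the oxBS component in
    absolute value. Also reports the Pearson correlation between BS and oxBS
    differences over the top-n probes.
    """
    if callset.tissue_mean_bs is None or callset.tissue_mean_oxbs is None:
        raise ValidationError("callset lacks per-tissue BS/oxBS means; recall with betas and pairs")
    t0, t1 = callset.tissues[0], callset.tissues[1]
    bs_diff = callset.tissue_mean_bs[t0] - callset.tissue_mean_bs[t1]
    mc_diff = callset.tissue_mean_oxbs[t0] - callset.tissue_mean_oxbs[t1]
    hmc_diff = callset.tissue_mean_delta[t0] - callset.tissue_mean_delta[t1]

    order = pd.DataFrame({"abs_bs": bs_diff.abs()}).dropna()
    order = order.loc[order.index.sort_values()].sort_values("abs_bs", ascending=False, kind="mergesort")
    top = order.head(n).index

    records = pd.DataFrame(
        {
            "bs_diff": bs_diff.loc[top],
            "mc_diff": mc_diff.loc[top],
            "hmc_diff": hmc_diff.loc[top],
        }
    )
    resid = (records["bs_diff"] - records["mc_diff"] - records["hmc_diff"]).abs()
    assert float(resid.max()) < 1e-9, "decomposition identity violated"
    records["driver"] = np.where(records["hmc_diff"].abs() > records["mc_diff"].abs(), "hmc", "mc")

    if len(records) >= 2 and records["bs_diff"].nunique() > 1 and records["mc_diff"].nunique() > 1:
        r, p = stats.pearsonr(records["bs_diff"], records["mc_diff"])
    else:
        r, p = np.nan, np.nan
    summary = {
        "n": int(len(records)),
        "n_hmc_driven": int((records["driver"] == "hmc").sum()),
        "r_bs_vs_mc": float(r),
        "p_bs_vs_mc": float(p),
    }
    return records, summary
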