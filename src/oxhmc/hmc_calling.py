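"""Delta-beta computation, empirical detection threshold, and 5hmC calls.

The per-sample 5hmC proxy is delta-beta = beta(BS) - beta(oxBS). Technical
noise produces a negative tail at 5hmC-free probes; the detection threshold
tau is the absolute q-quantile of the pooled strictly-negative delta-beta
values (default q = 0.05), applied to per-tissue mean delta-beta with a
strict inequality.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    BetaMatrix,
    EmptyInputError,
    PairedSampleSet,
    TISSUES,
    ValidationError,
)


@dataclass
class HmcCallSet:
    """Per-pair delta-beta plus pooled threshold and per-tissue calls."""

    delta_beta: pd.DataFrame          # probes x pair_ids
    pair_meta: pd.DataFrame           # index pair_id: donor_id, tissue
    tau: float
    tissue_mean_delta: pd.DataFrame   # probes x tissues
    detectable: pd.DataFrame          # probes x tissues, bool
    tissue_mean_oxbs: pd.DataFrame | None = None
    tissue_mean_bs: pd.DataFrame | None = None

    @property
    def tissues(self) -> list[str]:
        return list(self.tissue_mean_delta.columns)

    def pairs_of(self, tissue: str) -> list[str]:
        return list(self.pair_meta.index[self.pair_meta["tissue"] == tissue])

    def detectable_probes(self, which: str) -> pd.Index:
        det = self.detectable
        if which in det.columns:
            mask = det[which]
        elif which == "union":
            mask = det.any(axis=1)
        elif which == "intersection":
            mask = det.all(axis=1)
        else:
            raise ValueError(f"unknown probe set {which!r}")
        return det.index[mask]


def compute_delta_beta(pairs: PairedSampleSet, betas: BetaMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Delta-beta per probe and pair, with the pair metadata frame.

    Missing in either arm propagates to missing delta-beta.
    """
    cols = {}
    meta = []
    for p in pairs.pairs:
        for arm in (p.bs_cegx, p.oxbs_cegx):
            if arm not in betas.data.columns:
                raise ValidationError(f"pair references unknown sample {arm!r}")
        cols[p.pair_id] = betas.data[p.bs_cegx] - betas.data[p.oxbs_cegx]
        meta.append({"pair_id": p.pair_id, "donor_id": p.donor_id, "tissue": p.tissue})
    delta = pd.DataFrame(cols, index=betas.probe_ids)
    pair_meta = pd.DataFrame(meta).set_index("pair_id")
    return delta, pair_meta


def estimate_threshold(delta_beta: pd.DataFrame, mode: str = "negative_tail", q: float = 0.05) -> float:
    """Empirical detection threshold tau from pooled delta-beta values.

    negative_tail: tau = |q-quantile of the pooled strictly negative values|;
    all_values:    tau = |q-quantile of all pooled values|.
    Quantile convention: linear interpolation at q*(n-1).
    """
    pooled = delta_beta.to_numpy().ravel()
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise EmptyInputError("no delta-beta values")
    if mode == "negative_tail":
        neg = pooled[pooled < 0]
        if neg.size == 0:
            raise EmptyInputError(
                "no negative delta-beta values; consider mode='all_values'"
            )
        return float(abs(np.quantile(neg, q)))
    if mode == "all_values":
        return float(abs(np.quantile(pooled, q)))
    raise ValueError(f"unknown threshold mode {mode!r}")


def call_detectable(
    delta_beta: pd.DataFrame,
    pair_meta: pd.DataFrame,
    tau: float,
    betas: BetaMatrix | None = None,
    pairs: PairedSampleSet | None = None,
) -> HmcCallSet:
    """Per-tissue mean delta-beta and strict-threshold 'detectable' calls.

    When the source beta matrix and pairing are supplied, per-tissue mean
    oxBS (true 5mC) and BS betas are carried along for the decomposition and
    metagene stages.
    """
    tissues = [t for t in TISSUES if (pair_meta["tissue"] == t).any()]
    if not tissues:
        raise EmptyInputError("no tissues present in pair metadata")
    extra = set(pair_meta["tissue"]) - set(TISSUES)
    if extra:
        raise ValidationError(f"unknown tissue(s): {sorted(extra)}")
    mean = pd.DataFrame(
        {t: delta_beta[pair_meta.index[pair_meta["tissue"] == t]].mean(axis=1) for t in tissues}
    )
    detectable = mean > tau
    detectable = detectable.fillna(False)

    mean_ox = mean_bs = None
    if betas is not None and pairs is not None:
        ox_cols = {}
        bs_cols = {}
        for t in tissues:
            tp = pairs.by_tissue(t)
            ox_cols[t] = betas.data[[p.oxbs_cegx for p in tp]].mean(axis=1)
            bs_cols[t] = betas.data[[p.bs_cegx for p in tp]].mean(axis=1)
        mean_ox = pd.DataFrame(ox_cols)
        mean_bs = pd.DataFrame(bs_cols)

    return HmcCallSet(
        delta_beta=delta_beta,
        pair_meta=pair_meta,
        tau=float(tau),
        tissue_mean_delta=mean,
        detectable=detectable,
        tissue_mean_oxbs=mean_ox,
        tissue_mean_bs=mean_bs,
    )


def inclusion_exclusion(n_a: int, n_b: int, n_union: int | None = None, n_both: int | None = None) -> dict:
    """Complete {n_a, n_b, n_both, n_union} from three known members."""
    if n_both is None and n_union is None:
        raise ValueError("one of n_union / n_both is required")
    if n_both is None:
        n_both = n_a + n_b - n_union
    n_union = n_a + n_b - n_both
    return {
        "n_a": n_a,
        "n_b": n_b,
        "n_both": n_both,
        "n_union": n_union,
        "n_a_only": n_a - n_both,
        "n_b_only": n_b - n_both,
    }


def summarize_sets(callset: HmcCallSet) -> dict:
    """Detectable-set counts per tissue plus exact union/intersection splits."""
    det = callset.detectable
    if det.shape[1] < 2:
        raise EmptyInputError("summarize_sets needs both tissues")
    pfc, cbl = det.columns[0], det.columns[1]
    n_both = int((det[pfc] & det[cbl]).sum())
    out = inclusion_exclusion(int(det[pfc].sum()), int(det[cbl].sum()), n_both=n_both)
    return {
        "n_pfc": out["n_a"],
        "n_cbl": out["n_b"],
        "n_both": out["n_both"],
        "n_union": out["n_union"],
        "n_pfc_only": out["n_a_only"],
        "n_cbl_only": out["n_b_only"],
    }


def rank_sites(
    callset: HmcCallSet,
    by: str,
    tissue: str | None = None,
    n: int = 1000,
) -> pd.DataFrame:
    """Ranked probe lists: highest level, most variable, or TS-HMPs.

    level:              tissue mean delta-beta, descending.
    variability:        SD of delta-beta across donors within tissue, descending.
    tissue_difference:  |mean(PFC) - mean(CBL)| descending over the union of
                        detectable probes; signed difference and the higher
                        tissue are retained.
    Ties break by probe_id ascending.
    """
    if by in ("level", "variability"):
        if tissue is None:
            raise ValueError(f"ranking by {by!r} requires a tissue")
        pool = callset.detectable_probes(tissue)
        if by == "level":
            stat = callset.tissue_mean_delta.loc[pool, tissue]
        else:
            cols = callset.pairs_of(tissue)
            stat = callset.delta_beta.loc[pool, cols].std(axis=1, ddof=1)
        frame = pd.DataFrame({"statistic": stat})
    elif by == "tissue_difference":
        pool = callset.detectable_probes("union")
        mean = callset.tissue_mean_delta.loc[pool]
        t0, t1 = mean.columns[0], mean.columns[1]
        signed = mean[t0] - mean[t1]
        frame = pd.DataFrame(
            {
                "statistic": signed.abs(),
                "signed_difference": signed,
                "higher_tissue": np.where(signed > 0, t0, t1),
            }
        )
    else:
        raise ValueError(f"unknown ranking {by!r}")

    if n > len(frame):
        warnings.warn(f"requested top {n} but pool has only {len(frame)} probes")
        n = len(frame)
    # mergesort is stable; pre-sort index ascending so ties resolve by probe_id
    frame = frame.loc[frame.index.sort_values()].sort_values(
        by="statistic", ascending=False, kind="mergesort"
    )
    return frame.head(n)
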