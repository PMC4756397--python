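"""Sample/probe filtering and concordance checks preceding 5hmC calling."""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix, DetectionPMatrix, EmptyInputError, SampleSheet, ValidationError


@dataclass
class QcReport:
    n_input_probes: int = 0
    n_input_samples: int = 0
    removed_samples: list[dict] = field(default_factory=list)
    removed_probes: dict[str, list[str]] = field(default_factory=dict)
    kit_concordance: dict[str, dict] = field(default_factory=dict)
    genotype: dict | None = None

    @property
    def removed_probe_counts(self) -> dict[str, int]:
        return {reason: len(ids) for reason, ids in self.removed_probes.items()}

    def merged(self, other: "QcReport") -> "QcReport":
        out = QcReport(
            n_input_probes=self.n_input_probes or other.n_input_probes,
            n_input_samples=self.n_input_samples or other.n_input_samples,
            removed_samples=self.removed_samples + other.removed_samples,
            removed_probes={**self.removed_probes},
            kit_concordance={**self.kit_concordance, **other.kit_concordance},
            genotype=self.genotype or other.genotype,
        )
        for reason, ids in other.removed_probes.items():
            out.removed_probes.setdefault(reason, []).extend(ids)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_input_probes": self.n_input_probes,
            "n_input_samples": self.n_input_samples,
            "removed_samples": self.removed_samples,
            "removed_probe_counts": self.removed_probe_counts,
            "kit_concordance": self.kit_concordance,
            "genotype": self.genotype,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def pfilter(
    betas: BetaMatrix,
    detp: DetectionPMatrix,
    site_alpha: float = 0.05,
    fail_fraction: float = 0.05,
) -> tuple[BetaMatrix, QcReport]:
    """Detection-p based filtering, sample-wise first, then probe-wise.

    A sample is dropped when more than ``fail_fraction`` of its sites have
    detection p >= ``site_alpha``; then a probe is dropped when it fails in
    more than ``fail_fraction`` of the remaining samples.
    """
    if betas.shape != detp.shape or not betas.probe_ids.equals(detp.probe_ids) or not betas.sample_ids.equals(detp.sample_ids):
        raise ValidationError("beta and detection-p matrices are not aligned")
    report = QcReport(n_input_probes=betas.shape[0], n_input_samples=betas.shape[1])
    failed = detp.data.to_numpy() >= site_alpha

    sample_frac = failed.mean(axis=0)
    keep_samples = sample_frac <= fail_fraction
    for sid, frac in zip(betas.sample_ids[~keep_samples], sample_frac[~keep_samples]):
        report.removed_samples.append(
            {"sample_id": sid, "reason": "detection-p", "fail_fraction": float(frac)}
        )
    if not keep_samples.any():
        raise EmptyInputError("pfilter removed every sample")

    probe_frac = failed[:, keep_samples].mean(axis=1)
    keep_probes = probe_frac <= fail_fraction
    report.removed_probes["detection-p"] = list(betas.probe_ids[~keep_probes])

    filtered = BetaMatrix(betas.data.loc[keep_probes, keep_samples])
    return filtered, report


def mask_probes(
    betas: BetaMatrix, ann: pd.DataFrame, on_unannotated: str = "warn"
) -> tuple[BetaMatrix, QcReport]:
    """Drop rs-genotyping probes and SNP/cross-reactive masked probes."""
    report = QcReport(n_input_probes=betas.shape[0], n_input_samples=betas.shape[1])
    probes = betas.probe_ids
    known = probes.isin(ann.index)
    if not known.all():
        unannotated = list(probes[~known])
        if on_unannotated == "error":
            raise ValidationError(f"{len(unannotated)} probe(s) missing from annotation")
        warnings.warn(f"{len(unannotated)} probe(s) missing from annotation; kept")
    sub = ann.reindex(probes)
    is_rs = sub["is_snp_probe"].eq(True).to_numpy()
    is_masked = sub["masked"].eq(True).to_numpy() & ~is_rs
    report.removed_probes["rs-probe"] = list(probes[is_rs])
    report.removed_probes["masked"] = list(probes[is_masked])
    keep = ~(is_rs | is_masked)
    return BetaMatrix(betas.data.loc[keep]), report


def kit_concordance(bs_zymo: pd.DataFrame, bs_cegx: pd.DataFrame) -> dict:
    """R-squared between probe-wise mean betas of the two BS conversion kits.

    p-value from the t-transform of Pearson r with n - 2 df.
    """
    shared = bs_zymo.index.intersection(bs_cegx.index)
    if len(shared) < 3:
        raise EmptyInputError(f"only {len(shared)} shared probes; need >= 3")
    x = bs_zymo.loc[shared].mean(axis=1).to_numpy()
    y = bs_cegx.loc[shared].mean(axis=1).to_numpy()
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        raise EmptyInputError("fewer than 3 complete probe pairs")
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / max(1.0 - r * r, np.finfo(float).tiny))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return {"r": r, "r_squared": r * r, "p_value": p, "n": n}


@dataclass
class GenotypeConcordance:
    sample_corr: pd.DataFrame
    donor_corr: pd.DataFrame
    min_same_donor_r: float
    max_cross_donor_r: float
    flagged_pairs: list[tuple[str, str]]

    @property
    def ok(self) -> bool:
        return not self.flagged_pairs


def genotype_concordance(rs_betas: pd.DataFrame, sheet: SampleSheet) -> GenotypeConcordance:
    """Pairwise Pearson correlation of rs-probe betas across samples.

    Same-donor sample pairs should outrank every cross-donor pair; a donor
    pair is flagged when any cross-donor correlation reaches the minimum
    same-donor correlation.
    """
    if rs_betas.shape[0] < 5:
        raise EmptyInputError(f"only {rs_betas.shape[0]} rs-probes; need >= 5")
    samples = [s for s in sheet.data["sample_id"] if s in rs_betas.columns]
    corr = rs_betas.loc[:, samples].corr()
    donor_of = dict(zip(sheet.data["sample_id"], sheet.data["donor_id"]))

    same, cross = [], []
    cross_by_donorpair: dict[tuple[str, str], float] = {}
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            r = float(corr.at[a, b])
            if donor_of[a] == donor_of[b]:
                same.append(r)
            else:
                cross.append(r)
                key = tuple(sorted((donor_of[a], donor_of[b])))
                cross_by_donorpair[key] = max(r, cross_by_donorpair.get(key, -np.inf))

    donors = sorted(set(donor_of[s] for s in samples))
    donor_corr = pd.DataFrame(np.nan, index=donors, columns=donors)
    for a in samples:
        for b in samples:
            da, db = donor_of[a], donor_of[b]
            r = float(corr.at[a, b])
            prev = donor_corr.at[da, db]
            donor_corr.at[da, db] = r if np.isnan(prev) else max(prev, r)

    min_same = float(min(same)) if same else np.nan
    max_cross = float(max(cross)) if cross else np.nan
    flagged = [
        pair for pair, r in cross_by_donorpair.items() if same and r >= min_same
    ]
    return GenotypeConcordance(corr, donor_corr, min_same, max_cross, sorted(flagged))
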