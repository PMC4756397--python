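"""Fisher's-exact enrichment of probe sets across genomic-feature strata.

The 2x2 convention is the inclusive background: [a, n-a; A, N-A] where the
foreground (a of n) is also counted inside the background (A of N). The odds
ratio is the cross-product on that table, the 95% CI is the Woolf logit
interval, and the p-value is the two-sided Fisher exact probability.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ALT_EVENTS, CGI_FEATURES, EmptyInputError, GENE_FEATURES, ValidationError

Z95 = 1.959963984540054


@dataclass
class EnrichmentResult:
    feature: str
    a: int          # foreground probes with feature
    n: int          # foreground size
    A: int          # background probes with feature
    N: int          # background size
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    flag: str | None = None


def fisher_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_enrichment(a: int, n: int, A: int, N: int, feature: str = "") -> EnrichmentResult:
    """Inclusive-background enrichment for one feature."""
    if not (0 <= a <= n and 0 <= A <= N):
        raise ValidationError(f"inconsistent counts a={a}, n={n}, A={A}, N={N}")
    b, d = n - a, N - A
    p = fisher_pvalue(a, b, A, d)
    flag = None
    if a == 0 or b == 0 or A == 0 or d == 0:
        flag = "zero_cell"
        if a == 0 or d == 0:
            oratio = 0.0 if a == 0 else math.inf
        else:
            oratio = math.inf if b == 0 else 0.0
        # one-sided Woolf interval from the three non-zero cells
        cells = [x for x in (a, b, A, d) if x > 0]
        se = math.sqrt(sum(1.0 / x for x in cells))
        if oratio == 0.0:
            anchor = (max(a, 0.5) / max(b, 0.5)) / (A / d) if A and d else 0.0
            lo, hi = 0.0, anchor * math.exp(Z95 * se) if anchor else 0.0
        else:
            anchor = (max(a, 0.5) / max(b, 0.5)) / (max(A, 0.5) / max(d, 0.5))
            lo, hi = anchor * math.exp(-Z95 * se), math.inf
        return EnrichmentResult(feature, a, n, A, N, oratio, lo, hi, p, flag)
    oratio = (a / b) / (A / d)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / A + 1.0 / d)
    lo = oratio * math.exp(-Z95 * se)
    hi = oratio * math.exp(Z95 * se)
    return EnrichmentResult(feature, a, n, A, N, oratio, lo, hi, p, None)


_STRATA = ("cgi", "gene", "tfbs", "dhs", "alt_events")


def enrich(
    foreground,
    background,
    ann: pd.DataFrame,
    stratum: str,
    inclusive: bool = True,
) -> list[EnrichmentResult]:
    """Per-feature enrichment of a probe set against a background set.

    For ``alt_events`` both sets are first restricted to alt-annotated
    probes, and a probe contributes to every event it carries.
    """
    if stratum not in _STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    fg = pd.Index(sorted(set(foreground)))
    bg = pd.Index(sorted(set(background)))
    if len(fg) == 0:
        raise EmptyInputError("empty foreground")
    if not fg.isin(bg).all():
        raise ValidationError("foreground is not a subset of background")
    missing = bg[~bg.isin(ann.index)]
    if len(missing):
        raise ValidationError(f"{len(missing)} background probe(s) missing from annotation")

    fg_ann = ann.loc[fg]
    bg_ann = ann.loc[bg]

    if stratum == "alt_events":
        fg_ann = fg_ann[fg_ann["alt_events"].map(len) > 0]
        bg_ann = bg_ann[bg_ann["alt_events"].map(len) > 0]
        if len(fg_ann) == 0:
            raise EmptyInputError("no alt-annotated probes in foreground")
        features = [(ev, lambda df, ev=ev: df["alt_events"].map(lambda s: ev in s)) for ev in ALT_EVENTS]
    elif stratum == "cgi":
        features = [(f, lambda df, f=f: df["cgi_feature"] == f) for f in CGI_FEATURES]
    elif stratum == "gene":
        features = [(f, lambda df, f=f: df["gene_feature"] == f) for f in GENE_FEATURES]
    elif stratum == "tfbs":
        features = [("tfbs", lambda df: df["tfbs"])]
    else:
        features = [("dhs", lambda df: df["dhs"])]

    n, N = len(fg_ann), len(bg_ann)
    out = []
    for name, pred in features:
        a = int(pred(fg_ann).sum())
        A = int(pred(bg_ann).sum())
        if not inclusive:
            A, N_eff = A - a, N - n
            out.append(fisher_enrichment(a, n, A, N_eff, feature=name))
        else:
            out.append(fisher_enrichment(a, n, A, N, feature=name))
    return out


def results_to_frame(results: list[EnrichmentResult], **extra) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "feature": r.feature,
                "a": r.a,
                "n": r.n,
                "A": r.A,
                "N": r.N,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "flag": r.flag,
            }
            for r in results
        ]
    )
    for k, v in extra.items():
        df.insert(0, k, v)
    return df


def _all_strata(fg, bg, ann) -> pd.DataFrame:
    frames = []
    for stratum in _STRATA:
        try:
            res = enrich(fg, bg, ann, stratum)
        except EmptyInputError:
            continue
        frames.append(results_to_frame(res, stratum=stratum))
    return pd.concat(frames, ignore_index=True)


def enrichment_tables(
    callset,
    rankings: dict,
    ann: pd.DataFrame,
    qc_background,
) -> dict[str, pd.DataFrame]:
    """The four enrichment tables of the analysis.

    detectable_vs_array: detectable probes per tissue vs QC-passing probes.
    top_level:           top-ranked by 5hmC level per tissue vs all
                         detectable-in-brain probes.
    tshmp:               top tissue-difference probes vs detectable-in-brain.
    top_variable:        most inter-individually variable per tissue vs
                         detectable-in-brain.

    ``rankings`` carries the outputs of :func:`oxhmc.hmc_calling.rank_sites`
    keyed ("level", tissue), ("variability", tissue), ("tissue_difference",).
    """
    detectable_union = callset.detectable_probes("union")
    tissues = callset.tissues
    tables = {}

    frames = []
    for t in tissues:
        fg = callset.detectable_probes(t)
        frames.append(_all_strata(fg, qc_background, ann).assign(foreground=t))
    tables["detectable_vs_array"] = pd.concat(frames, ignore_index=True)

    frames = []
    for t in tissues:
        fg = rankings[("level", t)].index
        frames.append(_all_strata(fg, detectable_union, ann).assign(foreground=t))
    tables["top_level"] = pd.concat(frames, ignore_index=True)

    fg = rankings[("tissue_difference",)].index
    tables["tshmp"] = _all_strata(fg, detectable_union, ann).assign(foreground="tshmp")

    frames = []
    for t in tissues:
        fg = rankings[("variability", t)].index
        frames.append(_all_strata(fg, detectable_union, ann).assign(foreground=t))
    tables["top_variable"] = pd.concat(frames, ignore_index=True)
    return tables
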