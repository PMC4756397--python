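"""Fully in-silico inputs with known truth for every pipeline stage.

The generator emulates paired BS/oxBS betas for two brain tissues across a
discovery and a validation cohort: per-probe true 5mC and 5hmC, Gaussian
technical noise clipped to [0, 1] (so 5hmC-free probes show a negative
delta-beta tail), feature annotation with configurable enrichment, rs
genotyping probes, and gene-set files with optional probe-count confounding.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    ALT_EVENTS,
    BetaMatrix,
    CGI_FEATURES,
    COHORTS,
    DetectionPMatrix,
    GENE_FEATURES,
    SampleSheet,
    TISSUES,
    ValidationError,
    normalize_annotation,
)

# Default marginals follow the composition of a QC-passed 450K analysis set.
DEFAULT_CGI_PROBS = {
    "island": 0.323,
    "shore": 0.233,
    "shelf": 0.088,
    "outside": 0.332,
    "unannotated": 0.024,
}
DEFAULT_GENE_PROBS = {
    "intergenic": 0.140,
    "distal_promoter": 0.045,
    "proximal_promoter": 0.396,
    "gene_body": 0.377,
    "downstream": 0.018,
    "unannotated": 0.024,
}
DEFAULT_TFBS_P = 0.492
DEFAULT_DHS_P = 0.133
DEFAULT_ALT_P = 0.371
DEFAULT_EVENT_PROBS = {
    "A3SS": 0.024,
    "A5SS": 0.024,
    "AFE": 0.418,
    "ALE": 0.065,
    "CE": 0.434,
    "CNE": 0.149,
    "EI": 0.001,
    "II": 0.200,
    "IR": 0.117,
    "MXE": 0.094,
}

TISSUE_SHORT = {"prefrontal_cortex": "pfc", "cerebellum": "cbl"}


def _categorical(rng, probs: dict[str, float], n: int, allowed) -> np.ndarray:
    keys = [k for k in allowed if k in probs]
    p = np.array([probs[k] for k in keys], dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValidationError("invalid probability vector")
    p = p / p.sum()
    return rng.choice(np.array(keys, dtype=object), size=n, p=p)


def generate_annotation(
    n_probes: int,
    feature_probs: dict | None = None,
    n_genes: int | None = None,
    n_rs_probes: int = 50,
    masked_fraction: float = 0.02,
    n_chroms: int = 5,
    flank: int = 5000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic probe annotation plus gene models on a toy genome.

    Exclusive strata are sampled categorically from ``feature_probs``
    (defaults above); TFBS/DHS/alt events are independent with the stated
    marginals; gene symbols come from positional overlap (gene +/- flank).
    """
    rng = np.random.default_rng(seed)
    fp = feature_probs or {}
    cgi_probs = fp.get("cgi", DEFAULT_CGI_PROBS)
    gene_probs = fp.get("gene", DEFAULT_GENE_PROBS)
    tfbs_p = fp.get("tfbs", DEFAULT_TFBS_P)
    dhs_p = fp.get("dhs", DEFAULT_DHS_P)
    alt_p = fp.get("alt", DEFAULT_ALT_P)
    event_probs = fp.get("alt_events", DEFAULT_EVENT_PROBS)

    if n_genes is None:
        n_genes = max(20, n_probes // 25)

    # Gene models tiled across chromosomes with gaps, random strand/length.
    genes = []
    per_chrom = int(np.ceil(n_genes / n_chroms))
    g = 0
    for c in range(n_chroms):
        cursor = 10_000
        for _ in range(per_chrom):
            if g >= n_genes:
                break
            length = int(rng.integers(2_000, 20_000))
            genes.append(
                {
                    "gene_id": f"GENE{g:05d}",
                    "chrom": f"chr{c + 1}",
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "tx_start": cursor,
                    "tx_end": cursor + length,
                }
            )
            cursor += length + int(rng.integers(12_000, 30_000))
            g += 1
    genes_df = pd.DataFrame(genes)
    chrom_span = {
        c: int(genes_df.loc[genes_df["chrom"] == c, "tx_end"].max() + 20_000)
        for c in genes_df["chrom"].unique()
    }

    chroms = rng.choice(genes_df["chrom"].unique(), size=n_probes)
    pos = np.array([rng.integers(1, chrom_span[c]) for c in chroms], dtype=int)

    cgi = _categorical(rng, cgi_probs, n_probes, CGI_FEATURES)
    genef = _categorical(rng, gene_probs, n_probes, GENE_FEATURES)
    tfbs = rng.random(n_probes) < tfbs_p
    dhs = rng.random(n_probes) < dhs_p
    is_alt = rng.random(n_probes) < alt_p
    events = []
    ev_names = [e for e in ALT_EVENTS if e in event_probs]
    ev_p = np.array([event_probs[e] for e in ev_names])
    draws = rng.random((n_probes, len(ev_names))) < ev_p
    for i in range(n_probes):
        if not is_alt[i]:
            events.append(frozenset())
            continue
        chosen = frozenset(e for e, hit in zip(ev_names, draws[i]) if hit)
        if not chosen:
            chosen = frozenset({ev_names[int(np.argmax(ev_p))]})
        events.append(chosen)

    # gene symbols by positional overlap
    gene_sets = []
    by_chrom = {c: grp for c, grp in genes_df.groupby("chrom")}
    for c, p in zip(chroms, pos):
        grp = by_chrom[c]
        hit = grp[(grp["tx_start"] - flank <= p) & (p <= grp["tx_end"] + flank)]
        gene_sets.append(frozenset(hit["gene_id"]))

    masked = rng.random(n_probes) < masked_fraction
    ann = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "cgi_feature": cgi,
            "gene_feature": genef,
            "tfbs": tfbs,
            "dhs": dhs,
            "alt_events": events,
            "genes": gene_sets,
            "is_snp_probe": False,
            "masked": masked,
        },
        index=pd.Index([f"cg{i:07d}" for i in range(n_probes)], name="probe_id"),
    )

    if n_rs_probes:
        rs = pd.DataFrame(
            {
                "chrom": rng.choice(genes_df["chrom"].unique(), size=n_rs_probes),
                "pos": rng.integers(1, 10_000, size=n_rs_probes),
                "cgi_feature": "unannotated",
                "gene_feature": "unannotated",
                "tfbs": False,
                "dhs": False,
                "alt_events": [frozenset()] * n_rs_probes,
                "genes": [frozenset()] * n_rs_probes,
                "is_snp_probe": True,
                "masked": False,
            },
            index=pd.Index([f"rs{i:07d}" for i in range(n_rs_probes)], name="probe_id"),
        )
        ann = pd.concat([ann, rs])
    return normalize_annotation(ann), genes_df


@dataclass
class SyntheticTruth:
    ann: pd.DataFrame
    genes: pd.DataFrame
    true_mc: pd.Series                 # per probe
    true_hmc: pd.DataFrame             # probes x tissues
    noise_sd: float
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def hydroxylated(self) -> pd.Series:
        return self.true_hmc.max(axis=1) > 0

    def write(self, path) -> None:
        out = pd.DataFrame({"true_mc": self.true_mc})
        for t in self.true_hmc.columns:
            out[f"true_hmc_{TISSUE_SHORT.get(t, t)}"] = self.true_hmc[t]
        out.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6f")


def _feature_mask(ann: pd.DataFrame, key: str) -> np.ndarray:
    """Feature selector keys: 'cgi:island', 'gene:gene_body', 'tfbs', 'dhs',
    'alt:CE'."""
    if key == "tfbs":
        return ann["tfbs"].to_numpy()
    if key == "dhs":
        return ann["dhs"].to_numpy()
    kind, _, value = key.partition(":")
    if kind == "cgi":
        return (ann["cgi_feature"] == value).to_numpy()
    if kind == "gene":
        return (ann["gene_feature"] == value).to_numpy()
    if kind == "alt":
        return ann["alt_events"].map(lambda s: value in s).to_numpy()
    raise ValidationError(f"unknown feature key {key!r}")


def generate_truth(
    ann: pd.DataFrame,
    f: float = 0.2,
    tissue_effect: float = 0.05,
    feature_rr: dict[str, float] | None = None,
    hmc_range: tuple[float, float] = (0.10, 0.35),
    noise_sd: float = 0.025,
    mc_modes: tuple[float, float] = (0.2, 0.8),
    mc_sd: float = 0.08,
    seed: int = 0,
) -> SyntheticTruth:
    """Per-probe true 5mC and per-tissue true 5hmC.

    A probe is hydroxymethylated with baseline odds f/(1-f) multiplied by
    ``feature_rr`` for each feature it carries; true 5hmC is uniform on
    ``hmc_range`` with a cerebellum increment of ``tissue_effect``; true 5mC
    is a two-mode Gaussian mixture; mc + hmc <= 1 is enforced by truncating
    mc.
    """
    if not 0 <= f <= 1:
        raise ValidationError("f must be in [0, 1]")
    rng = np.random.default_rng(seed)
    analysis = (~ann["is_snp_probe"]).to_numpy()
    n = len(ann)

    if f in (0.0, 1.0):
        p_h = np.full(n, f)
    else:
        odds = np.full(n, f / (1.0 - f))
        for key, rr in (feature_rr or {}).items():
            if rr < 0:
                raise ValidationError("relative risk must be >= 0")
            odds[_feature_mask(ann, key)] *= rr
        p_h = odds / (1.0 + odds)
    hydro = (rng.random(n) < p_h) & analysis

    base = np.zeros(n)
    base[hydro] = rng.uniform(hmc_range[0], hmc_range[1], size=int(hydro.sum()))
    hmc = pd.DataFrame(0.0, index=ann.index, columns=list(TISSUES))
    hmc.loc[hydro, "prefrontal_cortex"] = base[hydro]
    hmc.loc[hydro, "cerebellum"] = np.clip(base[hydro] + tissue_effect, 0.0, None)

    comp = rng.random(n) < 0.5
    mc = np.where(comp, mc_modes[0], mc_modes[1]) + rng.normal(0.0, mc_sd, size=n)
    mc = np.clip(mc, 0.02, 0.98)
    hmax = hmc.max(axis=1).to_numpy()
    if (hmax >= 1.0).any():
        raise ValidationError("tissue effect pushes true 5hmC above 1")
    mc = np.minimum(mc, 1.0 - hmax)
    mc[~analysis] = np.nan  # rs probes carry genotypes, not methylation

    return SyntheticTruth(
        ann=ann,
        genes=pd.DataFrame(),
        true_mc=pd.Series(mc, index=ann.index),
        true_hmc=hmc,
        noise_sd=noise_sd,
        seed=seed,
        params={
            "f": f,
            "tissue_effect": tissue_effect,
            "feature_rr": dict(feature_rr or {}),
            "hmc_range": hmc_range,
        },
    )


@dataclass
class SimulatedDataset:
    betas: BetaMatrix
    detp: DetectionPMatrix
    sheet: SampleSheet
    truth: SyntheticTruth


def generate_betas(
    truth: SyntheticTruth,
    n_donors: dict[str, int] | None = None,
    noise_sd: float | None = None,
    arms: tuple[str, ...] = ("bs_cegx", "oxbs_cegx", "bs_zymo"),
    detp_fail_rate: float = 0.0,
    rs_noise_sd: float = 0.02,
    seed: int = 0,
) -> SimulatedDataset:
    """Per-sample beta/detection-p matrices and the matching sample sheet.

    beta(oxBS) = clip(mc + e1), beta(BS) = clip(mc + hmc + e2) with
    independent N(0, noise_sd^2) noise per column; rs probes get trimodal
    genotype betas (0.05/0.5/0.95) fixed per donor across tissues and arms.
    """
    if n_donors is None:
        n_donors = {"discovery": 8, "validation": 18}
    sd = truth.noise_sd if noise_sd is None else noise_sd
    if sd <= 0:
        raise ValidationError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    ann = truth.ann
    is_rs = ann["is_snp_probe"].to_numpy()
    n_probes = len(ann)

    columns: dict[str, np.ndarray] = {}
    detp_cols: dict[str, np.ndarray] = {}
    rows = []
    for cohort in COHORTS:
        if cohort not in n_donors or n_donors[cohort] <= 0:
            continue
        for d in range(n_donors[cohort]):
            donor = f"{cohort[:3]}D{d:02d}"
            genotypes = rng.choice([0.05, 0.5, 0.95], size=int(is_rs.sum()), p=[0.25, 0.5, 0.25])
            for tissue in TISSUES:
                mc = truth.true_mc.to_numpy()
                hmc = truth.true_hmc[tissue].to_numpy()
                for arm in arms:
                    sid = f"{donor}_{TISSUE_SHORT[tissue]}_{arm}"
                    signal = mc if arm == "oxbs_cegx" else mc + hmc
                    beta = np.clip(signal + rng.normal(0.0, sd, size=n_probes), 0.0, 1.0)
                    if is_rs.any():
                        beta[is_rs] = np.clip(
                            genotypes + rng.normal(0.0, rs_noise_sd, size=int(is_rs.sum())),
                            0.0,
                            1.0,
                        )
                    columns[sid] = beta
                    detp = rng.uniform(0.0, 0.01, size=n_probes)
                    if detp_fail_rate > 0:
                        fail = rng.random(n_probes) < detp_fail_rate
                        detp[fail] = rng.uniform(0.05, 1.0, size=int(fail.sum()))
                    detp_cols[sid] = detp
                    rows.append(
                        {
                            "sample_id": sid,
                            "donor_id": donor,
                            "tissue": tissue,
                            "treatment": arm,
                            "cohort": cohort,
                        }
                    )

    betas = BetaMatrix(pd.DataFrame(columns, index=ann.index))
    detp = DetectionPMatrix(pd.DataFrame(detp_cols, index=ann.index))
    sheet = SampleSheet(pd.DataFrame(rows))
    return SimulatedDataset(betas=betas, detp=detp, sheet=sheet, truth=truth)


def generate_pathways(
    gene_ids,
    probes_per_gene: pd.Series | None = None,
    n_pathways: int = 100,
    size_range: tuple[int, int] = (10, 2000),
    confounding_strength: float = 0.0,
    n_signal: int = 0,
    seed: int = 0,
) -> tuple[dict[str, frozenset], list[str]]:
    """Random gene sets with sizes log-uniform in ``size_range``.

    With ``confounding_strength`` > 0, membership probability scales with
    exp(strength * z(n_probes)), tying pathways to probe-rich genes. The
    first ``n_signal`` pathway ids are returned as designated signal sets.
    """
    gene_ids = list(gene_ids)
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    hi = min(hi, len(gene_ids))
    if lo > hi or lo < 1:
        raise ValidationError(f"infeasible size range ({lo}, {hi}) for {len(gene_ids)} genes")

    weights = np.ones(len(gene_ids))
    if confounding_strength != 0.0:
        if probes_per_gene is None:
            raise ValidationError("confounding requires probes_per_gene")
        npb = probes_per_gene.reindex(gene_ids).fillna(1.0).to_numpy(dtype=float)
        z = (npb - npb.mean()) / max(npb.std(), 1e-12)
        weights = np.exp(confounding_strength * z)
    weights = weights / weights.sum()

    pathways = {}
    for i in range(n_pathways):
        size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        size = min(max(size, lo), hi)
        members = rng.choice(gene_ids, size=size, replace=False, p=weights)
        pathways[f"PW{i:04d}"] = frozenset(members.tolist())
    signal = [f"PW{i:04d}" for i in range(min(n_signal, n_pathways))]
    return pathways, signal


def make_test_list(
    gene_ids,
    base_rate: float = 0.2,
    probes_per_gene: pd.Series | None = None,
    confounding_strength: float = 0.0,
    signal_genes=frozenset(),
    signal_odds: float = 1.0,
    seed: int = 0,
) -> set[str]:
    """Gene test list with optional probe-count confounding and enrichment of
    designated signal genes by an odds multiplier."""
    gene_ids = list(gene_ids)
    rng = np.random.default_rng(seed)
    odds = np.full(len(gene_ids), base_rate / (1.0 - base_rate))
    if confounding_strength != 0.0:
        if probes_per_gene is None:
            raise ValidationError("confounding requires probes_per_gene")
        npb = probes_per_gene.reindex(gene_ids).fillna(1.0).to_numpy(dtype=float)
        z = (npb - npb.mean()) / max(npb.std(), 1e-12)
        odds *= np.exp(confounding_strength * z)
    sig = np.array([g in signal_genes for g in gene_ids])
    odds[sig] *= signal_odds
    p = odds / (1.0 + odds)
    return {g for g, hit in zip(gene_ids, rng.random(len(gene_ids)) < p) if hit}
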