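"""Data model, readers/writers and sample pairing.

Beta and detection-p matrices are probes x samples tables (TSV canonical,
comma accepted by sniffing). Annotation coordinates are stored 1-based as in
array manifests; all BED output is 0-based half-open.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TISSUES = ("prefrontal_cortex", "cerebellum")
TREATMENTS = ("bs_zymo", "bs_cegx", "oxbs_cegx")
COHORTS = ("discovery", "validation")
CGI_FEATURES = ("island", "shore", "shelf", "outside", "unannotated")
GENE_FEATURES = (
    "intergenic",
    "distal_promoter",
    "proximal_promoter",
    "gene_body",
    "downstream",
    "unannotated",
)
ALT_EVENTS = ("A3SS", "A5SS", "AFE", "ALE", "CE", "CNE", "EI", "II", "IR", "MXE")

SHEET_COLUMNS = ("sample_id", "donor_id", "tissue", "treatment", "cohort")


class FormatError(ValueError):
    """Structural problem in an input file (duplicate ids, bad header...)."""


class ValidationError(ValueError):
    """Well-formed input carrying invalid values."""


class EmptyInputError(ValueError):
    """An operation was left with nothing to work on."""


def _sniff_sep(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _check_unique(values: Iterable[str], what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise FormatError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass
class _Matrix:
    """Base for probes x samples value matrices backed by a DataFrame."""

    data: pd.DataFrame
    _lo: float = field(default=0.0, repr=False)
    _hi: float = field(default=1.0, repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe id")
        _check_unique(self.data.columns, "sample id")
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < self._lo) | (vals > self._hi)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"value {vals[i, j]!r} out of [{self._lo}, {self._hi}] at "
                f"probe {self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def write(self, path: str | Path, float_format: str = "%.6f") -> None:
        self.data.to_csv(
            path, sep="\t", index_label="probe_id", float_format=float_format, na_rep="NA"
        )


class BetaMatrix(_Matrix):
    """Methylation beta values in [0, 1]; NaN marks missing."""


class DetectionPMatrix(_Matrix):
    """Detection p-values in [0, 1], same shape/keys as the beta matrix."""


def _read_matrix(path: str | Path, cls, missing_token: str = "NA"):
    path = Path(path)
    sep = _sniff_sep(path)
    with open(path, "r", newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    _check_unique(header[1:], "sample id")
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=[missing_token, ""], keep_default_na=False
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate probe id: {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric value in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return cls(df)


def read_beta_matrix(path: str | Path, missing_token: str = "NA") -> BetaMatrix:
    return _read_matrix(path, BetaMatrix, missing_token)


def read_detection_p_matrix(path: str | Path, missing_token: str = "NA") -> DetectionPMatrix:
    return _read_matrix(path, DetectionPMatrix, missing_token)


@dataclass
class SampleSheet:
    """Sample metadata: one row per array, keyed by sample_id."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SHEET_COLUMNS) - set(self.data.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        df = self.data.loc[:, list(SHEET_COLUMNS)].astype(str).reset_index(drop=True)
        _check_unique(df["sample_id"], "sample id")
        for col, allowed in (("tissue", TISSUES), ("treatment", TREATMENTS), ("cohort", COHORTS)):
            bad = set(df[col]) - set(allowed)
            if bad:
                raise ValidationError(f"invalid {col} value(s): {sorted(bad)}")
        dup = df.duplicated(subset=["donor_id", "tissue", "treatment", "cohort"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise ValidationError(
                "more than one sample for donor "
                f"{row['donor_id']!r}, {row['tissue']}, {row['treatment']}, {row['cohort']}"
            )
        self.data = df

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    def subset(self, mask) -> "SampleSheet":
        return SampleSheet(self.data.loc[mask].reset_index(drop=True))

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep=_sniff_sep(Path(path)), dtype=str))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tx_start: int  # 1-based inclusive
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.tx_start > self.tx_end:
            raise ValidationError(f"tx_start > tx_end for {self.gene_id}")


GENE_COLUMNS = ("gene_id", "chrom", "strand", "tx_start", "tx_end")


def read_gene_models(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(Path(path)))
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"gene model table missing columns: {sorted(missing)}")
    _check_unique(df["gene_id"], "gene id")
    if (df["tx_start"] > df["tx_end"]).any():
        raise ValidationError("gene with tx_start > tx_end")
    return df.loc[:, list(GENE_COLUMNS)]


def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    genes.loc[:, list(GENE_COLUMNS)].to_csv(path, sep="\t", index=False)


ANNOTATION_COLUMNS = (
    "probe_id",
    "chrom",
    "pos",
    "cgi_feature",
    "gene_feature",
    "tfbs",
    "dhs",
    "alt_events",
    "genes",
    "is_snp_probe",
    "masked",
)


def _parse_setfield(value) -> frozenset:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value in ("", "."):
        return frozenset()
    if isinstance(value, frozenset):
        return value
    return frozenset(str(value).split(";"))


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation table into a frame indexed by probe_id.

    ``alt_events`` and ``genes`` are semicolon-joined in the file and parsed
    to frozensets; booleans accept 0/1 or True/False.
    """
    df = pd.read_csv(path, sep=_sniff_sep(Path(path)), dtype={"probe_id": str, "chrom": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    _check_unique(df["probe_id"], "probe id")
    df = df.set_index("probe_id")
    return normalize_annotation(df)


def normalize_annotation(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("tfbs", "dhs", "is_snp_probe", "masked"):
        df[col] = df[col].astype(bool)
    for col in ("alt_events", "genes"):
        df[col] = df[col].map(_parse_setfield)
    bad_cgi = set(df["cgi_feature"]) - set(CGI_FEATURES)
    if bad_cgi:
        raise ValidationError(f"unknown cgi_feature value(s): {sorted(bad_cgi)}")
    bad_gene = set(df["gene_feature"]) - set(GENE_FEATURES)
    if bad_gene:
        raise ValidationError(f"unknown gene_feature value(s): {sorted(bad_gene)}")
    bad_alt = set().union(*df["alt_events"]) - set(ALT_EVENTS) if len(df) else set()
    if bad_alt:
        raise ValidationError(f"unknown alternative-transcription event(s): {sorted(bad_alt)}")
    return df


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    for col in ("alt_events", "genes"):
        out[col] = out[col].map(lambda s: ";".join(sorted(s)))
    for col in ("tfbs", "dhs", "is_snp_probe", "masked"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index_label="probe_id")


@dataclass(frozen=True)
class SamplePair:
    """BS/oxBS (CEGX) column pair for one (donor, tissue)."""

    donor_id: str
    tissue: str
    bs_cegx: str
    oxbs_cegx: str
    bs_zymo: str | None = None

    @property
    def pair_id(self) -> str:
        return f"{self.donor_id}|{self.tissue}"


@dataclass
class PairedSampleSet:
    pairs: list[SamplePair]
    unpaired: list[tuple[str, str]] = field(default_factory=list)

    @property
    def pair_ids(self) -> list[str]:
        return [p.pair_id for p in self.pairs]

    def by_tissue(self, tissue: str) -> list[SamplePair]:
        return [p for p in self.pairs if p.tissue == tissue]


def pair_samples(betas: BetaMatrix, sheet: SampleSheet, cohort: str | None = None) -> PairedSampleSet:
    """Match BS-CEGX and oxBS-CEGX columns per (donor, tissue).

    Incomplete (donor, tissue) groups are reported in ``unpaired`` rather than
    raising; zero complete pairs is an error.
    """
    df = sheet.data
    if cohort is not None:
        df = df[df["cohort"] == cohort]
    unknown = set(df["sample_id"]) - set(betas.sample_ids)
    if unknown:
        raise ValidationError(f"sample sheet references unknown sample id(s): {sorted(unknown)}")
    pairs: list[SamplePair] = []
    unpaired: list[tuple[str, str]] = []
    for (donor, tissue), grp in sorted(df.groupby(["donor_id", "tissue"], sort=True), key=lambda kv: kv[0]):
        arms = dict(zip(grp["treatment"], grp["sample_id"]))
        if "bs_cegx" in arms and "oxbs_cegx" in arms:
            pairs.append(
                SamplePair(donor, tissue, arms["bs_cegx"], arms["oxbs_cegx"], arms.get("bs_zymo"))
            )
        else:
            for sid in grp["sample_id"]:
                unpaired.append((sid, f"incomplete pair for ({donor}, {tissue})"))
    if not pairs:
        raise EmptyInputError("no complete BS/oxBS sample pairs")
    return PairedSampleSet(pairs=pairs, unpaired=unpaired)


def write_bed(callset, ann: pd.DataFrame, path: str | Path, probes: Sequence[str] | None = None) -> int:
    """Export per-tissue mean delta-beta as a BED6 track (0-based, half-open).

    Each CpG becomes a 2-bp interval [pos-1, pos+1). Probes lacking
    coordinates are skipped; the number skipped is returned.
    """
    mean = callset.tissue_mean_delta
    if probes is None:
        probes = list(mean.index[callset.detectable.any(axis=1)])
    rows = []
    skipped = 0
    for probe in probes:
        if probe not in ann.index:
            skipped += 1
            continue
        chrom, pos = ann.at[probe, "chrom"], ann.at[probe, "pos"]
        if pd.isna(chrom) or pd.isna(pos):
            skipped += 1
            continue
        means = mean.loc[probe]
        name = probe + "".join(f"|{t}={means[t]:.4f}" for t in mean.columns)
        score = int(round(1000 * float(np.clip(np.nanmax(means.to_numpy()), 0.0, 1.0))))
        rows.append((str(chrom), int(pos) - 1, int(pos) + 1, name, score, "."))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write('track name="oxhmc_mean_delta" description="per-tissue mean delta-beta (BS - oxBS)"\n')
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")
    if skipped:
        warnings.warn(f"write_bed: skipped {skipped} probe(s) without coordinates")
    return skipped
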