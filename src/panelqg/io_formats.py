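"""Readers and writers for every external table the pipeline touches.

All coordinates are held 0-based half-open internally; 1-based inclusive
conventions appear only at the GFF/VCF boundary.  Output tables use a fixed
column order, ``.`` decimal separator and 6 significant digits so reruns are
byte-diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

SEXES = ("M", "F")
STATUSES = ("dead", "censored")
TREATMENTS = ("pathogen", "control")

INVERSION_NAMES = ("In2Lt", "In2RNS", "In3RP", "In3RK", "In3RMo")

EVENT_COLUMNS = ["line_id", "sex", "replicate_id", "time_h", "status", "treatment"]
COVARIATE_COLUMNS = ["line_id", "wolbachia", *INVERSION_NAMES]

FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """A file does not match the declared external format."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

@dataclass
class EventTable:
    """Per-fly time-to-death records.

    ``df`` has columns line_id, sex, replicate_id, time_h, status, treatment.
    Times are hours; status is 'dead' or 'censored'.
    """

    df: pd.DataFrame
    scoring_grid_h: float | None = None

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.df)

    def pathogen_only(self) -> "EventTable":
        return EventTable(self.df[self.df["treatment"] == "pathogen"].copy(),
                          self.scoring_grid_h)

    def summary_counts(self) -> dict:
        df = self.df
        return {
            "records": len(df),
            "lines": df["line_id"].nunique(),
            "sexes": df["sex"].nunique(),
            "replicates": df.groupby(["line_id", "sex"])["replicate_id"].nunique().sum(),
            "deaths": int((df["status"] == "dead").sum()),
            "censored": int((df["status"] == "censored").sum()),
        }


def read_events(path, scoring_grid_hours: float | None = None) -> EventTable:
    """Read a per-fly event CSV, validating tokens and the scoring grid.

    Rows whose time does not sit on the declared grid are rejected with
    their (0-based) row indices listed in the error.
    """
    df = pd.read_csv(path, dtype={"line_id": str, "replicate_id": str})
    _require_columns(df, EVENT_COLUMNS, "events CSV")
    df = df[EVENT_COLUMNS].copy()

    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValidationError(
            f"unknown sex token(s) {sorted(df.loc[bad_sex, 'sex'].unique())} "
            f"at rows {df.index[bad_sex].tolist()}")
    bad_status = ~df["status"].isin(STATUSES)
    if bad_status.any():
        raise ValidationError(
            f"status must be one of {STATUSES}; offending rows "
            f"{df.index[bad_status].tolist()}")
    bad_trt = ~df["treatment"].isin(TREATMENTS)
    if bad_trt.any():
        raise ValidationError(
            f"treatment must be one of {TREATMENTS}; offending rows "
            f"{df.index[bad_trt].tolist()}")

    df["time_h"] = pd.to_numeric(df["time_h"])
    if (df["time_h"] < 0).any():
        raise ValidationError(
            f"negative times at rows {df.index[df['time_h'] < 0].tolist()}")

    if scoring_grid_hours is not None:
        off = ~np.isclose(np.mod(df["time_h"], scoring_grid_hours), 0) & \
            ~np.isclose(np.mod(df["time_h"], scoring_grid_hours), scoring_grid_hours)
        if off.any():
            raise ValidationError(
                f"times off the {scoring_grid_hours}-h scoring grid at rows "
                f"{df.index[off].tolist()}")

    table = EventTable(df, scoring_grid_hours)
    logger.info("read_events: %s", table.summary_counts())
    return table


def write_events(table: EventTable, path) -> None:
    df = table.df[EVENT_COLUMNS]
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------------------
# Genotype panels
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Biallelic markers x inbred lines, homozygous dosages in {0, 2, NaN}.

    ``markers`` has columns chrom, pos (1-based), ref, alt and, derived on
    construction, ``maf`` and ``minor_lines`` (count of lines carrying the
    minor allele) and ``minor_is_alt``.  ``dosage`` is a float ndarray of
    shape (n_markers, n_lines) with NaN for missing.
    """

    markers: pd.DataFrame
    line_ids: list[str]
    dosage: np.ndarray
    n_het_masked: int = 0

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        valid = np.isin(self.dosage, (0.0, 2.0)) | np.isnan(self.dosage)
        if not valid.all():
            raise ValidationError("dosages must be 0, 2 or missing")
        self._derive_maf()

    def _derive_maf(self) -> None:
        d = self.dosage
        with np.errstate(invalid="ignore"):
            n_called = np.sum(~np.isnan(d), axis=1).astype(float)
            n_alt = np.nansum(d == 2.0, axis=1).astype(float)
        alt_freq = np.divide(n_alt, n_called, out=np.full(d.shape[0], np.nan),
                             where=n_called > 0)
        # ties broken toward alt: alt is the minor allele when freq <= 0.5
        minor_is_alt = alt_freq <= 0.5
        maf = np.where(minor_is_alt, alt_freq, 1.0 - alt_freq)
        minor_lines = np.where(minor_is_alt, n_alt, n_called - n_alt)
        self.markers["maf"] = maf
        self.markers["minor_lines"] = minor_lines.astype(int)
        self.markers["minor_is_alt"] = minor_is_alt

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def marker_ids(self) -> pd.Series:
        m = self.markers
        return (m["chrom"].astype(str) + ":" + m["pos"].astype(str)
                + ":" + m["ref"] + ":" + m["alt"])


@dataclass
class CovariateTable:
    """Line-level covariates: Wolbachia infection and 5 inversion genotypes."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.df, COVARIATE_COLUMNS, "covariates")
        if self.df["line_id"].duplicated().any():
            raise ValidationError("duplicate line_id rows in covariate table")
        self.df = self.df.reset_index(drop=True)

    @property
    def line_ids(self) -> list[str]:
        return self.df["line_id"].tolist()


def read_genotype_panel(path, format: str = "tsv") -> GenotypePanel:
    if format == "tsv":
        return _read_panel_tsv(path)
    if format == "vcf":
        return _read_panel_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_panel_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    _require_columns(df, ["chrom", "pos", "ref", "alt"], "genotype TSV")
    line_ids = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    if not line_ids:
        raise FormatError("genotype TSV has no line columns")
    dosage = df[line_ids].to_numpy(dtype=float)
    ok = np.isin(dosage, (0.0, 2.0)) | np.isnan(dosage)
    if not ok.all():
        bad = sorted(set(dosage[~ok].tolist()))
        raise ValidationError(f"dosage tokens outside {{0,2,NA}}: {bad}")
    markers = df[["chrom", "pos", "ref", "alt"]].copy()
    return GenotypePanel(markers, [str(s) for s in line_ids], dosage)


def _read_panel_vcf(path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    rows, dosages = [], []
    n_skipped_multi = 0
    n_het = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped_multi += 1
            continue
        gt = np.asarray(var.gt_types)  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        d = np.full(len(line_ids), np.nan)
        d[gt == 0] = 0.0
        d[gt == 3] = 2.0
        n_het += int((gt == 1).sum())
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosages.append(d)
    if n_skipped_multi:
        logger.warning("skipped %d multi-allelic VCF records", n_skipped_multi)
    if n_het:
        logger.warning("masked %d heterozygous calls to missing", n_het)
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = np.vstack(dosages) if dosages else np.empty((0, len(line_ids)))
    return GenotypePanel(markers, line_ids, dosage, n_het_masked=n_het)


def write_genotype_panel(panel: GenotypePanel, path) -> None:
    out = panel.markers[["chrom", "pos", "ref", "alt"]].copy()
    for j, lid in enumerate(panel.line_ids):
        col = panel.dosage[:, j]
        out[lid] = [("NA" if np.isnan(v) else str(int(v))) for v in col]
    out.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def read_covariates(path) -> CovariateTable:
    df = pd.read_csv(path, dtype={"line_id": str})
    return CovariateTable(df)


def write_covariates(cov: CovariateTable, path) -> None:
    cov.df[COVARIATE_COLUMNS].to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

FEATURE_TYPES = ("exon_cds", "intron", "utr5", "utr3")

GFF_TYPE_MAP = {
    "CDS": "exon_cds",
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
    "intron": "intron",
}


@dataclass
class GeneModelSet:
    """Gene spans with typed sub-features, 0-based half-open.

    ``genes``: gene_id, chrom, strand, start, end.
    ``features``: gene_id, chrom, type, start, end and optional codon context
    (ref_codon, codon_pos 1..3) for CDS intervals.  Introns not listed in the
    source are inferred as gaps between a gene's CDS/UTR features.
    """

    genes: pd.DataFrame
    features: pd.DataFrame
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        self.features = self.features.reset_index(drop=True)
        for col in ("ref_codon", "codon_pos"):
            if col not in self.features.columns:
                self.features[col] = None
        self._validate()
        self._build_trees()

    def _validate(self) -> None:
        g = self.genes.set_index("gene_id")
        for _, f in self.features.iterrows():
            span = g.loc[f["gene_id"]]
            if f["start"] < span["start"] or f["end"] > span["end"]:
                raise ValidationError(
                    f"sub-feature outside gene span for gene {f['gene_id']}")
        bad = self.genes[self.genes["start"] >= self.genes["end"]]
        if len(bad):
            raise ValidationError(f"invalid gene spans: {bad['gene_id'].tolist()}")

    def _build_trees(self) -> None:
        self._trees = {"gene": {}, "feature": {}}
        for chrom, sub in self.genes.groupby("chrom"):
            t = IntervalTree()
            for idx, row in sub.iterrows():
                t[row["start"]:row["end"]] = idx
            self._trees["gene"][chrom] = t
        for chrom, sub in self.features.groupby("chrom"):
            t = IntervalTree()
            for idx, row in sub.iterrows():
                t[row["start"]:row["end"]] = idx
            self._trees["feature"][chrom] = t

    def genes_at(self, chrom: str, pos0: int) -> pd.DataFrame:
        t = self._trees["gene"].get(chrom)
        if t is None:
            return self.genes.iloc[0:0]
        idx = sorted(iv.data for iv in t[pos0])
        return self.genes.loc[idx]

    def features_at(self, chrom: str, pos0: int) -> pd.DataFrame:
        t = self._trees["feature"].get(chrom)
        if t is None:
            return self.features.iloc[0:0]
        idx = sorted(iv.data for iv in t[pos0])
        return self.features.loc[idx]

    def genes_near(self, chrom: str, pos0: int, flank: int = 1000) -> pd.DataFrame:
        """Genes whose span is within ``flank`` bp of the position (inclusive)."""
        t = self._trees["gene"].get(chrom)
        if t is None:
            return self.genes.iloc[0:0]
        idx = sorted(iv.data for iv in t[pos0 - flank:pos0 + flank + 1])
        return self.genes.loc[idx]


def _infer_introns(genes: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Fill gaps between a gene's typed features with intron intervals."""
    extra = []
    for gid, sub in features.groupby("gene_id"):
        if (sub["type"] == "intron").any():
            continue  # source declared its own introns
        span = genes.loc[genes["gene_id"] == gid].iloc[0]
        ivs = sorted(zip(sub["start"], sub["end"]))
        cur = None
        for s, e in ivs:
            if cur is not None and s > cur:
                extra.append({"gene_id": gid, "chrom": span["chrom"],
                              "type": "intron", "start": cur, "end": s})
            cur = e if cur is None else max(cur, e)
    if extra:
        features = pd.concat([features, pd.DataFrame(extra)], ignore_index=True)
    return features


def read_gene_models(path, format: str = "gff_subset") -> GeneModelSet:
    if format == "gff_subset":
        return _read_gff_subset(path)
    if format == "bed_like":
        return _read_bed_like(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _parse_gff_attrs(s: str) -> dict:
    out = {}
    for part in str(s).split(";"):
        part = part.strip()
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def _read_gff_subset(path) -> GeneModelSet:
    cols = ["chrom", "source", "type", "start", "end",
            "score", "strand", "frame", "attrs"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols,
                     dtype={"chrom": str})
    genes, feats = [], []
    for _, row in df.iterrows():
        attrs = _parse_gff_attrs(row["attrs"])
        start0, end0 = int(row["start"]) - 1, int(row["end"])  # GFF is 1-based inclusive
        if start0 >= end0:
            raise ValidationError(f"invalid interval {row['start']}..{row['end']}")
        if row["type"] == "gene":
            genes.append({"gene_id": attrs.get("ID", f"gene{len(genes)}"),
                          "chrom": row["chrom"], "strand": row["strand"],
                          "start": start0, "end": end0})
        elif row["type"] in GFF_TYPE_MAP:
            feats.append({"gene_id": attrs.get("Parent", attrs.get("ID", "")),
                          "chrom": row["chrom"],
                          "type": GFF_TYPE_MAP[row["type"]],
                          "start": start0, "end": end0,
                          "ref_codon": attrs.get("ref_codon"),
                          "codon_pos": (int(attrs["codon_pos"])
                                        if "codon_pos" in attrs else None)})
        elif row["type"] == "exon":
            pass  # exon outlines are redundant with CDS/UTR typing
    gdf = pd.DataFrame(genes)
    fdf = pd.DataFrame(feats, columns=["gene_id", "chrom", "type", "start", "end",
                                      "ref_codon", "codon_pos"])
    fdf = _infer_introns(gdf, fdf)
    return GeneModelSet(gdf, fdf)


def _read_bed_like(path) -> GeneModelSet:
    """BED-like TSV: chrom, start, end, gene_id, strand, type per row.

    ``type`` is 'gene' for the span row or one of the internal feature types;
    coordinates are already 0-based half-open.  Optional 7th/8th columns carry
    ref_codon and codon_pos for CDS rows.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str},
                     names=["chrom", "start", "end", "gene_id", "strand",
                            "type", "ref_codon", "codon_pos"])
    genes = df[df["type"] == "gene"][["gene_id", "chrom", "strand", "start", "end"]]
    feats = df[df["type"] != "gene"][
        ["gene_id", "chrom", "type", "start", "end", "ref_codon", "codon_pos"]]
    bad = set(feats["type"]) - set(FEATURE_TYPES)
    if bad:
        raise ValidationError(f"unknown feature types {sorted(bad)}")
    feats = _infer_introns(genes.reset_index(drop=True), feats.reset_index(drop=True))
    return GeneModelSet(genes, feats)


def write_gene_models_bed_like(models: GeneModelSet, path) -> None:
    rows = []
    for _, g in models.genes.iterrows():
        rows.append([g["chrom"], g["start"], g["end"], g["gene_id"],
                     g["strand"], "gene", "", ""])
    strand = models.genes.set_index("gene_id")["strand"]
    for _, f in models.features.iterrows():
        rows.append([f["chrom"], f["start"], f["end"], f["gene_id"],
                     strand.get(f["gene_id"], "."), f["type"],
                     f["ref_codon"] if f["ref_codon"] is not None else "",
                     int(f["codon_pos"]) if f["codon_pos"] is not None and
                     not pd.isna(f["codon_pos"]) else ""])
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False,
                              lineterminator="\n")
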