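"""Single-marker association on line means with covariate adjustment.

The association observations are line-level phenotypes (mean LT50 or CV_E),
not per-fly records, matching how inbred-panel studies feed line means to a
marker scan.  Adjustment is two-step: residualize the phenotype on Wolbachia
infection and the five major inversion indicators, then regress the adjusted
values on homozygous dosage per marker by OLS.  The reported effect is the
model-implied difference between major- and minor-allele homozygote classes,
so a NEGATIVE effect means minor-allele homozygotes survive longer.

This intentionally treats panel lines as exchangeable: there is no kinship or
genomic-control correction, and nominal P values are reported with fixed
discovery thresholds (1e-5, 1e-6) rather than an FDR.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_formats import CovariateTable, GenotypePanel, INVERSION_NAMES

logger = logging.getLogger(__name__)

ASSOC_COLUMNS = ["chrom", "pos", "ref", "alt", "pheno_variant", "effect",
                 "se", "p", "maf", "minor_lines", "n", "flag"]

PHENO_VARIANTS = ("male", "female", "average", "difference")


class AdjustResult:
    """Covariate-adjusted line values plus per-covariate marginal tests."""

    def __init__(self, adjusted: pd.Series, covariate_pvalues: dict,
                 dropped_lines: list, dropped_covariates: list):
        self.adjusted = adjusted
        self.covariate_pvalues = covariate_pvalues
        self.dropped_lines = dropped_lines
        self.dropped_covariates = dropped_covariates


def adjust_phenotype(line_values: pd.Series,
                     covariates: CovariateTable) -> AdjustResult:
    """Residualize line values on Wolbachia + 5 inversion indicators.

    Returns residuals re-centered at the grand mean, with each covariate's
    marginal (t-test) P from the joint fit.  Lines without covariates are
    dropped and counted; collinear covariate columns are dropped with a
    warning.
    """
    cov = covariates.df.set_index("line_id")
    values = line_values.dropna()
    common = values.index.intersection(cov.index)
    dropped = sorted(set(values.index) - set(common))
    if dropped:
        logger.info("adjust_phenotype: dropped %d line(s) without covariates",
                    len(dropped))
    y = values.loc[common].astype(float)
    X = cov.loc[common, ["wolbachia", *INVERSION_NAMES]].astype(float)

    kept_cols, dropped_cols = [], []
    for col in X.columns:
        trial = X[kept_cols + [col]].to_numpy()
        trial = np.column_stack([np.ones(len(trial)), trial])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept_cols.append(col)
        else:
            dropped_cols.append(col)
    if dropped_cols:
        warnings.warn(f"dropped collinear covariate(s): {dropped_cols}")

    design = sm.add_constant(X[kept_cols], has_constant="add")
    fit = sm.OLS(y, design).fit()
    adjusted = pd.Series(fit.resid + y.mean(), index=common, name=values.name)
    pvals = {c: float(fit.pvalues[c]) for c in kept_cols}
    return AdjustResult(adjusted, pvals, dropped, dropped_cols)


def phenotype_variants(summaries: pd.DataFrame,
                       metric: str = "lt50_h") -> dict:
    """Male / female / sex-average / sex-difference line phenotypes."""
    wide = summaries.pivot_table(index="line_id", columns="sex", values=metric)
    out = {}
    if "M" in wide:
        out["male"] = wide["M"]
    if "F" in wide:
        out["female"] = wide["F"]
    if "M" in wide and "F" in wide:
        out["average"] = (wide["M"] + wide["F"]) / 2.0
        out["difference"] = wide["M"] - wide["F"]
    return out


def marker_scan(adjusted: pd.Series, panel: GenotypePanel,
                min_minor_lines: int = 4,
                pheno_variant: str = "average") -> pd.DataFrame:
    """OLS of adjusted line values on dosage, marker by marker.

    Markers whose minor-allele line count (among phenotyped, complete-case
    lines) falls below ``min_minor_lines`` are skipped; the returned frame's
    ``.attrs["skipped"]`` counts the reasons.  Zero residual variance marks
    the record with flag "boundary" rather than P = 0.
    """
    order = [panel.line_ids.index(l) for l in adjusted.index
             if l in panel.line_ids]
    lines_used = [panel.line_ids[i] for i in order]
    y_all = adjusted.loc[lines_used].to_numpy(dtype=float)
    D = panel.dosage[:, order]

    records = []
    skipped = {"below_minor_line_threshold": 0, "monomorphic": 0}
    markers = panel.markers
    for k in range(panel.n_markers):
        d = D[k]
        mask = ~np.isnan(d) & ~np.isnan(y_all)
        d_k, y_k = d[mask], y_all[mask]
        n = len(y_k)
        n_alt = int(np.sum(d_k == 2.0))
        minor_is_alt = n_alt <= n - n_alt
        minor_count = n_alt if minor_is_alt else n - n_alt
        if minor_count == 0:
            skipped["monomorphic"] += 1
            continue
        if minor_count < min_minor_lines:
            skipped["below_minor_line_threshold"] += 1
            continue

        d_c = d_k - d_k.mean()
        sxx = float(np.sum(d_c ** 2))
        beta = float(np.sum(d_c * y_k) / sxx)
        resid = y_k - y_k.mean() - beta * d_c
        dof = n - 2
        s2 = float(np.sum(resid ** 2) / dof) if dof > 0 else float("nan")
        flag = ""
        if s2 <= 0 or not np.isfinite(s2):
            flag = "boundary"
            se_beta = 0.0
            p = float("nan")
        else:
            se_beta = float(np.sqrt(s2 / sxx))
            t = beta / se_beta
            p = float(2 * stats.t.sf(abs(t), dof))
        sign = -1.0 if minor_is_alt else 1.0
        row = markers.iloc[k]
        records.append({
            "chrom": row["chrom"], "pos": row["pos"], "ref": row["ref"],
            "alt": row["alt"], "pheno_variant": pheno_variant,
            "effect": sign * 2.0 * beta, "se": 2.0 * se_beta, "p": p,
            "maf": minor_count / n, "minor_lines": minor_count, "n": n,
            "flag": flag,
        })
    out = pd.DataFrame(records, columns=ASSOC_COLUMNS)
    out.attrs["skipped"] = skipped
    return out


def scan_all_variants(summaries: pd.DataFrame, panel: GenotypePanel,
                      covariates: CovariateTable, metric: str = "lt50_h",
                      min_minor_lines: int = 4) -> pd.DataFrame:
    """Adjust and scan every sex variant of a line phenotype; long table."""
    frames = []
    for variant, values in phenotype_variants(summaries, metric).items():
        adj = adjust_phenotype(values, covariates)
        frames.append(marker_scan(adj.adjusted, panel, min_minor_lines,
                                  pheno_variant=variant))
    return pd.concat(frames, ignore_index=True)


def maf_effect_spectrum(records: pd.DataFrame, p_threshold: float = 1e-5,
                        maf_split: float = 0.2,
                        bins: int = 5) -> dict:
    """Allele-frequency / effect-size spectrum of significant associations."""
    sig = records[(records["p"] < p_threshold) & records["p"].notna()]
    n = len(sig)
    frac_rare = float((sig["maf"] < maf_split).mean()) if n else float("nan")
    binned = None
    if n:
        cut = pd.cut(sig["maf"], np.linspace(0, 0.5, bins + 1),
                     include_lowest=True)
        binned = (sig.assign(abs_effect=sig["effect"].abs())
                  .groupby(cut, observed=False)["abs_effect"]
                  .agg(["count", "mean"]).reset_index(names="maf_bin"))
        binned["maf_bin"] = binned["maf_bin"].astype(str)
    return {
        "n_significant": n,
        "fraction_maf_below_split": frac_rare,
        "maf_split": maf_split,
        "n_negative_effects": int((sig["effect"] < 0).sum()),
        "n_positive_effects": int((sig["effect"] > 0).sum()),
        "binned": binned,
    }


def minor_allele_load(panel: GenotypePanel, significant: pd.DataFrame,
                      line_phenotypes: pd.Series,
                      split_at: float | None = None) -> dict:
    """Per-line count of minor alleles over a significant marker set.

    Correlates the load with the phenotype overall and, when ``split_at`` is
    given, separately below/above the split (the susceptible/resistant
    dissection; a U-shaped placement gives near-zero overall r with split
    correlations of opposite sign).
    """
    if len(line_phenotypes.dropna()) < 3:
        raise ValueError("need >= 3 phenotyped lines")
    if significant.empty:
        raise ValueError("need >= 1 significant marker")
    mid = panel.marker_ids()
    key = (significant["chrom"].astype(str) + ":" + significant["pos"].astype(str)
           + ":" + significant["ref"] + ":" + significant["alt"])
    rows = mid[mid.isin(set(key))].index.to_numpy()
    D = panel.dosage[rows]
    minor_is_alt = panel.markers["minor_is_alt"].to_numpy()[rows]
    carries = np.where(minor_is_alt[:, None], D == 2.0, D == 0.0)
    carries = np.where(np.isnan(D), False, carries)
    load = pd.Series(carries.sum(axis=0), index=panel.line_ids, name="load")

    merged = pd.concat([load, line_phenotypes.rename("pheno")], axis=1).dropna()
    out = {"load": load, "n_markers": len(rows), "n_lines": len(merged)}
    if merged["load"].nunique() < 2:
        out["overall"] = {"r": float("nan"), "p": float("nan"),
                          "flag": "load_constant"}
        return out
    r, p = stats.pearsonr(merged["load"], merged["pheno"])
    out["overall"] = {"r": float(r), "p": float(p)}
    if split_at is not None:
        for name, sub in [("below_split", merged[merged["pheno"] < split_at]),
                          ("above_split", merged[merged["pheno"] >= split_at])]:
            if len(sub) >= 3 and sub["load"].nunique() > 1:
                r_s, p_s = stats.pearsonr(sub["load"], sub["pheno"])
                out[name] = {"r": float(r_s), "p": float(p_s), "n": len(sub)}
            else:
                out[name] = {"r": float("nan"), "p": float("nan"),
                             "n": len(sub), "flag": "insufficient"}
    return out


def overlap_hits(records_a: pd.DataFrame, records_b: pd.DataFrame,
                 p_threshold: float = 1e-5,
                 marker_to_gene: dict | None = None) -> dict:
    """Markers (and genes, given a map) significant in both scans."""
    def sig_keys(rec):
        sig = rec[(rec["p"] < p_threshold) & rec["p"].notna()]
        return set(sig["chrom"].astype(str) + ":" + sig["pos"].astype(str)
                   + ":" + sig["ref"] + ":" + sig["alt"])

    ka, kb = sig_keys(records_a), sig_keys(records_b)
    shared = sorted(ka & kb)
    universe_a = set(records_a["chrom"].astype(str) + ":"
                     + records_a["pos"].astype(str))
    universe_b = set(records_b["chrom"].astype(str) + ":"
                     + records_b["pos"].astype(str))
    if not (universe_a & universe_b):
        warnings.warn("scans cover disjoint marker universes; overlap 0 of 0")
    out = {"shared_markers": shared, "n_sig_a": len(ka), "n_sig_b": len(kb)}
    if marker_to_gene is not None:
        genes = lambda keys: {marker_to_gene[k] for k in keys
                              if k in marker_to_gene}
        out["shared_genes"] = sorted(genes(ka) & genes(kb))
    return out


def write_associations(records: pd.DataFrame, path) -> None:
    records[ASSOC_COLUMNS].to_csv(path, sep="\t", index=False,
                                  float_format="%.6g", lineterminator="\n")
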