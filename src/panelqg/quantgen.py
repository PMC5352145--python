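"""Variance partitioning and broad-sense heritability for inbred-panel survival.

Two ANOVA models are supported.  Pooled over sexes,

    Y = mu + S + L + S x L + e

with sex S fixed and line L and the interaction random; single-sex data
reduce to the one-way random model Y = mu + L + e.  Components come from the
method of moments (equating observed to expected mean squares); with
unbalanced cell counts the EMS coefficient is the harmonic mean of the cell
sizes (classical unweighted-means approximation).  The line and sex terms
are tested over the sex-by-line mean square, the interaction over error.

Broad-sense heritability is H2 = (s2_L + s2_SL) / (s2_L + s2_SL + s2_E) for
the pooled model and H2 = s2_L / (s2_L + s2_E) for a single sex.  The same
one-way machinery applied to replicate-level ln(sigma_E) gives heritability
of micro-environmental plasticity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    pass


class ZeroVarianceError(ValueError):
    pass


@dataclass
class VarianceComponents:
    model: str
    table: pd.DataFrame                 # source, df, ms, f, p
    components: dict                    # term -> variance estimate (truncated)
    truncated: list = field(default_factory=list)
    n_effective: float = float("nan")   # harmonic-mean cell size

    def to_report(self) -> dict:
        return {
            "model": self.model,
            "anova": self.table.to_dict(orient="records"),
            "variance_components": self.components,
            "truncated_terms": self.truncated,
            "effective_cell_size": self.n_effective,
            "H2": broad_sense_heritability(self),
        }


def _harmonic_mean(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    return float(len(counts) / np.sum(1.0 / counts))


def _truncate(value: float, term: str, truncated: list) -> float:
    if value < 0:
        truncated.append(term)
        return 0.0
    return value


def anova_mixed(values, line, sex=None, model: str = "single_sex") -> VarianceComponents:
    """Partition phenotypic variance among lines (and sex, sex-by-line).

    ``values`` are per-fly uncensored death times (or any response); ``line``
    and ``sex`` are parallel label arrays.  ``model`` is "pooled_sex" or
    "single_sex".
    """
    values = np.asarray(values, dtype=float)
    line = np.asarray(line)
    if np.ptp(values) == 0:
        raise ZeroVarianceError("all responses identical")
    if model == "single_sex":
        return _anova_one_way(values, line)
    if model == "pooled_sex":
        if sex is None:
            raise DesignError("pooled_sex model needs a sex array")
        return _anova_two_way(values, line, np.asarray(sex))
    raise ValueError(f"unknown model {model!r}")


def _anova_one_way(values: np.ndarray, line: np.ndarray) -> VarianceComponents:
    df = pd.DataFrame({"y": values, "line": line})
    sizes = df.groupby("line").size()
    singletons = sizes[sizes < 2].index
    if len(singletons):
        warnings.warn(f"dropping {len(singletons)} line(s) with a single "
                      "observation")
        df = df[~df["line"].isin(singletons)]
    groups = df.groupby("line")["y"]
    a = groups.ngroups
    if a < 2:
        raise DesignError("need >= 2 lines with >= 2 observations")
    n = len(df)
    grand = df["y"].mean()
    means, counts = groups.mean(), groups.size()
    ss_line = float(np.sum(counts * (means - grand) ** 2))
    ss_err = float(np.sum((df["y"] - groups.transform("mean")) ** 2))
    df_line, df_err = a - 1, n - a
    ms_line, ms_err = ss_line / df_line, ss_err / df_err
    f = ms_line / ms_err
    p = float(stats.f.sf(f, df_line, df_err))
    n_h = _harmonic_mean(counts.to_numpy())
    truncated: list = []
    comp = {
        "error": ms_err,
        "line": _truncate((ms_line - ms_err) / n_h, "line", truncated),
    }
    table = pd.DataFrame([
        {"source": "Line", "df": df_line, "ms": ms_line, "f": f, "p": p},
        {"source": "Error", "df": df_err, "ms": ms_err, "f": np.nan, "p": np.nan},
    ])
    return VarianceComponents("single_sex", table, comp, truncated, n_h)


def _anova_two_way(values: np.ndarray, line: np.ndarray,
                   sex: np.ndarray) -> VarianceComponents:
    df = pd.DataFrame({"y": values, "line": line, "sex": sex})
    # keep lines observed in both sexes with >= 1 obs per cell
    cells = df.groupby(["line", "sex"]).size().unstack(fill_value=0)
    keep = cells[(cells > 0).all(axis=1)].index
    dropped = set(cells.index) - set(keep)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} line(s) missing a sex cell")
        df = df[df["line"].isin(keep)]
    lines = sorted(df["line"].unique())
    sexes = sorted(df["sex"].unique())
    a, s = len(lines), len(sexes)
    if a < 2 or s != 2:
        raise DesignError("pooled model needs >= 2 lines and exactly 2 sexes")

    cell = df.groupby(["line", "sex"])["y"]
    cell_means = cell.mean().unstack()          # lines x sexes
    cell_counts = cell.size().unstack()
    n_h = _harmonic_mean(cell_counts.to_numpy().ravel())
    m = cell_means.to_numpy()
    line_means = m.mean(axis=1)
    sex_means = m.mean(axis=0)
    grand = m.mean()

    ss_sex = n_h * a * float(np.sum((sex_means - grand) ** 2))
    ss_line = n_h * s * float(np.sum((line_means - grand) ** 2))
    inter = m - line_means[:, None] - sex_means[None, :] + grand
    ss_sl = n_h * float(np.sum(inter ** 2))
    ss_err = float(np.sum((df["y"] - cell.transform("mean")) ** 2))

    df_sex, df_line, df_sl = s - 1, a - 1, (a - 1) * (s - 1)
    df_err = len(df) - a * s
    ms_sex, ms_line = ss_sex / df_sex, ss_line / df_line
    ms_sl, ms_err = ss_sl / df_sl, ss_err / df_err

    f_line = ms_line / ms_sl
    f_sex = ms_sex / ms_sl
    f_sl = ms_sl / ms_err
    p_line = float(stats.f.sf(f_line, df_line, df_sl))
    p_sex = float(stats.f.sf(f_sex, df_sex, df_sl))
    p_sl = float(stats.f.sf(f_sl, df_sl, df_err))

    truncated: list = []
    comp = {
        "error": ms_err,
        "sexline": _truncate((ms_sl - ms_err) / n_h, "sexline", truncated),
        "line": _truncate((ms_line - ms_sl) / (s * n_h), "line", truncated),
    }
    table = pd.DataFrame([
        {"source": "Sex", "df": df_sex, "ms": ms_sex, "f": f_sex, "p": p_sex},
        {"source": "Line", "df": df_line, "ms": ms_line, "f": f_line, "p": p_line},
        {"source": "Sex*Line", "df": df_sl, "ms": ms_sl, "f": f_sl, "p": p_sl},
        {"source": "Error", "df": df_err, "ms": ms_err, "f": np.nan, "p": np.nan},
    ])
    return VarianceComponents("pooled_sex", table, comp, truncated, n_h)


def heritability_from_components(sigma_l2: float, sigma_e2: float,
                                 sigma_sl2: float = 0.0) -> float:
    """H2 = (s2_L + s2_SL) / (s2_L + s2_SL + s2_E); sex term 0 for one sex."""
    total = sigma_l2 + sigma_sl2 + sigma_e2
    if total == 0:
        raise ZeroVarianceError("all components zero; H2 undefined")
    h2 = (sigma_l2 + sigma_sl2) / total
    return float(h2)


def broad_sense_heritability(vc: VarianceComponents) -> float:
    comp = vc.components
    return heritability_from_components(
        comp["line"], comp["error"], comp.get("sexline", 0.0))


def covariate_anova(values, sex, line, infection_status) -> VarianceComponents:
    """Factorial mixed ANOVA Y = mu + S + I + SxI + L(I) + SxL(I) + e.

    ``infection_status`` is a per-observation (or per-line, broadcastable)
    label, e.g. Wolbachia presence.  Line is nested in infection status; the
    infection main effect is tested over the nested-line mean square.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "sex": np.asarray(sex), "line": np.asarray(line),
                       "inf": np.asarray(infection_status)})
    groups = sorted(df["inf"].unique())
    if len(groups) < 2:
        raise DesignError("both infection states must be represented")
    per_line = df.groupby("line")["inf"].nunique()
    if (per_line > 1).any():
        raise DesignError("a line appears in more than one infection state")

    cell = df.groupby(["line", "sex"])["y"]
    cm = cell.mean().unstack()
    counts = cell.size().unstack()
    if cm.isna().any().any():
        missing = cm[cm.isna().any(axis=1)].index.tolist()
        raise DesignError(f"lines missing a sex cell: {missing}")
    n_h = _harmonic_mean(counts.to_numpy().ravel())
    line_inf = df.groupby("line")["inf"].first().loc[cm.index]
    sexes = list(cm.columns)
    s = len(sexes)
    a = len(cm)
    g = len(groups)

    grand = cm.to_numpy().mean()
    sex_means = cm.mean(axis=0)
    inf_means = cm.groupby(line_inf).apply(lambda sub: sub.to_numpy().mean())
    n_lines_per_inf = line_inf.value_counts()
    line_means = cm.mean(axis=1)
    # sex x infection cell means of line-level cell means
    si_means = cm.groupby(line_inf).mean()   # inf x sex

    ss_sex = n_h * a * float(np.sum((sex_means - grand) ** 2))
    ss_inf = n_h * s * float(np.sum(
        n_lines_per_inf[inf_means.index] * (inf_means - grand) ** 2))
    ss_si = 0.0
    for i in groups:
        for sx in sexes:
            dev = si_means.loc[i, sx] - sex_means[sx] - inf_means[i] + grand
            ss_si += n_lines_per_inf[i] * dev ** 2
    ss_si *= n_h
    ss_linf = n_h * s * float(np.sum(
        (line_means - inf_means[line_inf].to_numpy()) ** 2))
    ss_slinf = 0.0
    for lid in cm.index:
        i = line_inf[lid]
        for sx in sexes:
            dev = (cm.loc[lid, sx] - line_means[lid]
                   - si_means.loc[i, sx] + inf_means[i])
            ss_slinf += dev ** 2
    ss_slinf *= n_h
    ss_err = float(np.sum((df["y"] - cell.transform("mean")) ** 2))

    df_sex, df_inf, df_si = s - 1, g - 1, (s - 1) * (g - 1)
    df_linf = a - g
    df_slinf = (a - g) * (s - 1)
    df_err = len(df) - a * s
    ms = {
        "Sex": ss_sex / df_sex, "Infection": ss_inf / df_inf,
        "Sex*Infection": ss_si / df_si, "Line(Inf)": ss_linf / df_linf,
        "Sex*Line(Inf)": ss_slinf / df_slinf, "Error": ss_err / df_err,
    }
    rows = []
    for term, num_df, den_term, den_df in [
            ("Sex", df_sex, "Sex*Line(Inf)", df_slinf),
            ("Infection", df_inf, "Line(Inf)", df_linf),
            ("Sex*Infection", df_si, "Sex*Line(Inf)", df_slinf),
            ("Line(Inf)", df_linf, "Sex*Line(Inf)", df_slinf),
            ("Sex*Line(Inf)", df_slinf, "Error", df_err)]:
        f = ms[term] / ms[den_term]
        rows.append({"source": term, "df": num_df, "ms": ms[term], "f": f,
                     "p": float(stats.f.sf(f, num_df, den_df))})
    rows.append({"source": "Error", "df": df_err, "ms": ms["Error"],
                 "f": np.nan, "p": np.nan})
    table = pd.DataFrame(rows)

    truncated: list = []
    comp = {
        "error": ms["Error"],
        "sexline": _truncate((ms["Sex*Line(Inf)"] - ms["Error"]) / n_h,
                             "sexline", truncated),
        "line": _truncate((ms["Line(Inf)"] - ms["Sex*Line(Inf)"]) / (s * n_h),
                          "line", truncated),
    }
    return VarianceComponents("covariate_nested", table, comp, truncated, n_h)


def infection_p_value(vc: VarianceComponents) -> float:
    """P for the infection-status main effect from a covariate_anova table."""
    row = vc.table[vc.table["source"] == "Infection"]
    return float(row["p"].iloc[0])


def levene_test(groups, center: str = "mean") -> tuple[float, float]:
    """Heterogeneity of within-group variance (classic Levene by default).

    ``groups`` is an iterable of 1-d arrays, one per line; groups with fewer
    than 2 observations are dropped with a warning.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    groups = [np.asarray(g, dtype=float) for g in groups]
    kept = [g for g in groups if len(g) >= 2]
    if len(kept) < len(groups):
        warnings.warn("dropped group(s) with < 2 observations")
    if len(kept) < 2:
        raise DesignError("need >= 2 groups with >= 2 observations")
    stat, p = stats.levene(*kept, center=center)
    return float(stat), float(p)


def variance_level_heritability(rep_ln_sigma: pd.DataFrame,
                                sex: str | None = None
                                ) -> tuple[float, VarianceComponents]:
    """Heritability of micro-environmental plasticity.

    Input is the replicate-tube table from ``survival.replicate_ln_sigma``
    (one ln(sigma_E) observation per line x sex x tube).  A one-way
    random-effects ANOVA on ln(sigma_E) across lines gives
    H2 = s2_L / (s2_L + s2_E).
    """
    df = rep_ln_sigma.dropna(subset=["ln_sigma_e"])
    if sex is not None:
        df = df[df["sex"] == sex]
    vc = anova_mixed(df["ln_sigma_e"], df["line_id"], model="single_sex")
    return broad_sense_heritability(vc), vc


def cross_sex_correlation(summaries: pd.DataFrame,
                          value: str = "lt50_h") -> tuple[float, float, int]:
    """Pearson correlation between male and female line values."""
    wide = summaries.pivot_table(index="line_id", columns="sex", values=value)
    wide = wide.dropna()
    n_excluded = summaries["line_id"].nunique() - len(wide)
    if n_excluded:
        logger.info("cross_sex_correlation: %d line(s) missing a sex", n_excluded)
    if len(wide) < 3 or "M" not in wide or "F" not in wide:
        raise DesignError("need >= 3 lines summarized in both sexes")
    r, p = stats.pearsonr(wide["M"], wide["F"])
    return float(r), float(p), len(wide)
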