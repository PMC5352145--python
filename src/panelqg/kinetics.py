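"""Within-host pathogen kinetics: CFU time courses and pathogen-fitness traits.

Per-line colony-forming-unit trajectories (mean over the sampled flies at
each 12-h time point) are reduced to threshold-crossing times — the first
grid time at which the mean load STRICTLY exceeds the threshold — and
related to host survival phenotypes.  Summary-statistic group comparisons
use Welch's t (the printed standard errors make equal variances untenable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CFU_COLUMNS = ["line_id", "fly_id", "time_h", "cfu"]


class EmptyInputError(ValueError):
    pass


def read_cfu(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"line_id": str})
    missing = [c for c in CFU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CFU CSV missing column(s) {missing}")
    if (df["cfu"] < 0).any():
        raise ValueError("CFU counts must be non-negative")
    return df[CFU_COLUMNS]


def write_cfu(df: pd.DataFrame, path) -> None:
    df[CFU_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def mean_trajectories(cfu: pd.DataFrame) -> pd.DataFrame:
    """Per-line mean CFU at each observation time (lines x times)."""
    return cfu.groupby(["line_id", "time_h"])["cfu"].mean().unstack()


def threshold_crossing_time(cfu: pd.DataFrame, threshold: float) -> pd.Series:
    """First grid time with mean CFU > threshold, per line; NaN = never."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if cfu.empty:
        raise EmptyInputError("empty CFU table")
    traj = mean_trajectories(cfu)
    times = traj.columns.to_numpy(dtype=float)
    out = {}
    for lid, row in traj.iterrows():
        above = row.to_numpy() > threshold
        out[lid] = float(times[np.argmax(above)]) if above.any() else float("nan")
    return pd.Series(out, name=f"crossing_{threshold:g}")


def kinetics_phenotype_correlation(crossing_times: pd.Series,
                                   line_lt50s: pd.Series
                                   ) -> tuple[float, float, int]:
    """Pearson r of crossing time vs LT50; never-crossed lines excluded."""
    merged = pd.concat([crossing_times.rename("x"),
                        line_lt50s.rename("y")], axis=1).dropna()
    if len(merged) < 3:
        raise EmptyInputError("need >= 3 lines with both quantities")
    r, p = stats.pearsonr(merged["x"], merged["y"])
    return float(r), float(p), len(merged)


def two_group_summary_t(mean1: float, se1: float, n1: int,
                        mean2: float, se2: float, n2: int
                        ) -> tuple[float, float, float]:
    """Welch t from summary statistics (SD recovered as SE * sqrt(n))."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    res = stats.ttest_ind_from_stats(mean1, se1 * np.sqrt(n1), n1,
                                     mean2, se2 * np.sqrt(n2), n2,
                                     equal_var=False)
    v1, v2 = se1 ** 2, se2 ** 2
    dof = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return float(res.statistic), float(dof), float(res.pvalue)
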