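"""Cross-trait correlations over panel lines with family-wise error control.

Pairwise Pearson correlations (Spearman selectable) on a lines x traits
table, with pairwise-complete deletion — public panel traits rarely cover
identical line subsets, so each pair keeps its own n.  The Holm-Bonferroni
step-down controls the family-wise error rate across the declared family of
pairs.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Step-down rejection flags in input order.

    Sort ascending; reject p_(i) while p_(i) <= alpha / (m - i + 1); stop at
    the first failure.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject


def trait_matrix(line_trait_table: pd.DataFrame, family_alpha: float = 0.05,
                 method: str = "pearson") -> pd.DataFrame:
    """All pairwise trait correlations with Holm flags across the family.

    ``line_trait_table`` is lines x traits (missing cells NaN).  Traits with
    fewer than 3 non-missing lines are excluded with a warning; each pair is
    computed on its pairwise-complete lines.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    table = line_trait_table.copy()
    thin = [c for c in table.columns if table[c].notna().sum() < 3]
    if thin:
        warnings.warn(f"excluding trait(s) with < 3 lines: {thin}")
        table = table.drop(columns=thin)
    if table.shape[1] < 2:
        raise ValueError("need >= 2 usable traits")

    rows = []
    for a, b in combinations(table.columns, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            rows.append({"trait_a": a, "trait_b": b, "r": np.nan,
                         "p": np.nan, "n": len(sub)})
            continue
        r, p = corr(sub[a], sub[b])
        rows.append({"trait_a": a, "trait_b": b, "r": float(r),
                     "p": float(p), "n": len(sub)})
    out = pd.DataFrame(rows)
    testable = out["p"].notna()
    flags = np.zeros(len(out), dtype=bool)
    if testable.any():
        flags[testable.to_numpy()] = holm_bonferroni(
            out.loc[testable, "p"], family_alpha)
    out["holm_pass"] = flags
    return out


def write_trait_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g",
                   lineterminator="\n")
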