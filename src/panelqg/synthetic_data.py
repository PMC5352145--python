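"""Synthetic inbred-panel data with the statistical structure the pipeline assumes.

The generator emulates a DGRP-style experiment: 100-200 fully inbred lines,
two sexes, a few replicate tubes of ~20 flies scored on a 12-hour grid after
pathogen challenge.  Death times carry additive line, sex and sex-by-line
location effects plus marker effects, and a line-specific residual scale so
that micro-environmental plasticity (within-line spread) is itself heritable.
Every generator is a pure function of its spec and seed, and the realized
effects are returned as ground truth for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import polygamma

from .io_formats import (CovariateTable, EventTable, GenotypePanel,
                         COVARIATE_COLUMNS, INVERSION_NAMES)


class ConfigurationError(ValueError):
    pass


def ln_sigma_sampling_variance(n: int) -> float:
    """Exact sampling variance of ln(sigma-hat) for n normal observations.

    For s^2 on nu = n-1 df, ln(s) = 0.5*ln(chi2_nu/nu) + ln(sigma), whose
    variance is trigamma(nu/2)/4.  This is what the replicate-level ln(sigma)
    "error" variance converges to when every line shares one true sigma.
    """
    if n < 2:
        raise ConfigurationError("need >= 2 observations per replicate")
    return float(polygamma(1, (n - 1) / 2.0)) / 4.0


def dispersion_for_variance_h2(target_h2: float, flies_per_replicate: int) -> float:
    """Line-level SD of ln(sigma) yielding a chosen variance-level heritability.

    Solves tau^2 / (tau^2 + V_e) = target_h2 where V_e is the analytic
    sampling variance of a replicate's ln(sigma-hat); returns tau.
    """
    if not 0 <= target_h2 < 1:
        raise ConfigurationError("target variance-level H2 must be in [0, 1)")
    v_e = ln_sigma_sampling_variance(flies_per_replicate)
    return float(np.sqrt(target_h2 / (1.0 - target_h2) * v_e))


@dataclass
class ArchitectureSpec:
    """Genetic architecture and design of a simulated panel experiment.

    Location parameters are in hours when ``family="normal"`` and in
    log-hours when ``family="lognormal"`` (the default family: positive
    support, location and scale separate cleanly).  ``mean_effects`` follow
    the sign convention that a NEGATIVE effect makes minor-allele carriers
    survive longer.
    """

    n_lines: int = 150
    n_markers: int = 1000
    # minor-allele frequency spectrum: maf = 0.5 * Beta(a, b), skewed rare
    maf_beta_a: float = 0.8
    maf_beta_b: float = 3.0
    fixed_maf: float | None = None
    ld_block_size: int = 1
    # genetics of the mean (latent scale: log-hours for the lognormal family,
    # hours for the normal family).  The lognormal defaults put the mean LT50
    # near 5.3 days with line SD ~0.58 d and within-line SD ~0.96 d.
    n_mean_causal: int = 0
    mean_effect_size: float = 0.0       # common |effect|; per-marker draws +- this
    mean_effect_sign_frac_neg: float = 0.7  # most minor alleles raise survival
    line_var: float = 0.012
    sexline_var: float = 0.004
    resid_var: float = 0.033
    target_mean_h2: float | None = None  # overrides line_var if set
    # genetics of the variance
    n_var_causal: int = 0
    var_effect_mult: float = 1.0         # multiplicative effect on sigma per minor hom
    line_disp_sd: float = 0.0            # SD of lognormal line noise on sigma
    target_variance_h2: float | None = None  # overrides line_disp_sd if set
    # design
    sex_effect: float = 0.038            # added to males (males slightly hardier)
    mu: float = 4.844                    # baseline location; exp(4.844) h ~ 5.3 d
    replicates: int = 3
    flies_per_replicate: int = 20
    scoring_grid_h: float = 12.0
    censor_horizon_h: float | None = None
    family: str = "lognormal"
    # covariates
    wolbachia_prob: float = 0.5
    inversion_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2 or self.n_markers < 1:
            raise ConfigurationError("need >= 2 lines and >= 1 marker")
        if max(self.n_mean_causal, self.n_var_causal) > self.n_markers:
            raise ConfigurationError("causal marker count exceeds n_markers")
        if min(self.line_var, self.sexline_var, self.resid_var) < 0:
            raise ConfigurationError("variances must be non-negative")
        if self.family not in ("normal", "lognormal"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.target_mean_h2 is not None:
            if not 0 <= self.target_mean_h2 < 1:
                raise ConfigurationError("target_mean_h2 must be in [0, 1)")
            self.line_var = (self.target_mean_h2 / (1 - self.target_mean_h2)
                             * self.resid_var)
        if self.target_variance_h2 is not None:
            self.line_disp_sd = dispersion_for_variance_h2(
                self.target_variance_h2, self.flies_per_replicate)

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureSpec":
        import yaml
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Realized effects behind a simulated event table."""

    line_ids: list[str]
    line_effects: np.ndarray          # location, incl. causal-marker part
    sexline_effects: dict             # sex -> ndarray over lines
    line_sigma: np.ndarray            # residual scale per line
    mean_causal: pd.DataFrame         # marker_index, effect
    var_causal: pd.DataFrame          # marker_index, multiplier
    realized: dict = field(default_factory=dict)

    def recompute_components(self) -> dict:
        out = {
            "line_var": float(np.var(self.line_effects, ddof=1)),
            "resid_var": float(np.mean(self.line_sigma ** 2)),
        }
        stacked = np.array([v for v in self.sexline_effects.values()])
        if stacked.size and stacked.shape[0] > 1:
            out["sexline_var"] = float(np.var(stacked, ddof=1))
        else:
            out["sexline_var"] = 0.0
        return out

    def to_json(self, path) -> None:
        payload = {
            "line_ids": self.line_ids,
            "line_effects": self.line_effects.tolist(),
            "sexline_effects": {k: v.tolist() for k, v in self.sexline_effects.items()},
            "line_sigma": self.line_sigma.tolist(),
            "mean_causal": self.mean_causal.to_dict(orient="list"),
            "var_causal": self.var_causal.to_dict(orient="list"),
            "realized": self.realized,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _line_ids(n: int) -> list[str]:
    return [f"L{i:03d}" for i in range(1, n + 1)]


def simulate_panel(spec: ArchitectureSpec,
                   seed: int | None = None) -> tuple[GenotypePanel, CovariateTable]:
    """Sample a homozygous genotype panel and line covariates.

    Alt is simulated as the minor allele (frequency = the drawn MAF); within
    an LD block all markers read the same latent per-line uniform, so block
    size 1 gives independent markers.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ids = _line_ids(spec.n_lines)
    if spec.fixed_maf is not None:
        maf = np.full(spec.n_markers, spec.fixed_maf)
    else:
        maf = 0.5 * rng.beta(spec.maf_beta_a, spec.maf_beta_b, size=spec.n_markers)
        maf = np.clip(maf, 1e-4, 0.5)

    n_blocks = int(np.ceil(spec.n_markers / spec.ld_block_size))
    latent = rng.uniform(size=(n_blocks, spec.n_lines))
    block_of = np.arange(spec.n_markers) // spec.ld_block_size
    dosage = (latent[block_of, :] < maf[:, None]).astype(float) * 2.0

    markers = pd.DataFrame({
        "chrom": "2L",
        "pos": np.arange(1, spec.n_markers + 1) * 100,
        "ref": "A",
        "alt": "T",
    })
    panel = GenotypePanel(markers, ids, dosage)

    cov = pd.DataFrame({"line_id": ids})
    cov["wolbachia"] = rng.binomial(1, spec.wolbachia_prob, spec.n_lines)
    for inv in INVERSION_NAMES:
        cov[inv] = rng.binomial(1, spec.inversion_prob, spec.n_lines)
    return panel, CovariateTable(cov[COVARIATE_COLUMNS])


def simulate_survival(panel: GenotypePanel, covariates: CovariateTable,
                      spec: ArchitectureSpec,
                      seed: int | None = None) -> tuple[EventTable, SimTruth]:
    """Simulate per-fly death times for the panel under ``spec``.

    Location per fly: mu + sex + line + sex-by-line + sum of mean-marker
    effects (a negative effect lengthens minor-carrier survival).  Scale per
    fly: sqrt(resid_var) scaled by variance-marker multipliers and lognormal
    line noise, so ln(sigma_line) is linear in the variance effects.  Times
    are rounded UP to the scoring grid (12-h checks discover deaths late) and
    censored at the horizon when one is set.
    """
    if panel.n_lines != spec.n_lines:
        raise ConfigurationError("panel size does not match spec.n_lines")
    if spec.resid_var < 0:
        raise ConfigurationError("resid_var must be non-negative")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ids = panel.line_ids
    L = spec.n_lines

    mean_idx = rng.choice(spec.n_markers, spec.n_mean_causal, replace=False) \
        if spec.n_mean_causal else np.array([], dtype=int)
    signs = np.where(rng.uniform(size=spec.n_mean_causal)
                     < spec.mean_effect_sign_frac_neg, -1.0, 1.0)
    mean_eff = signs * spec.mean_effect_size
    remaining = np.setdiff1d(np.arange(spec.n_markers), mean_idx)
    var_idx = rng.choice(remaining, spec.n_var_causal, replace=False) \
        if spec.n_var_causal else np.array([], dtype=int)

    line_eff = rng.normal(0.0, np.sqrt(spec.line_var), L)
    # stored effect is the major-minus-minor class difference, so a minor
    # homozygote (dosage 2 of the simulated minor/alt allele) gets -effect
    if len(mean_idx):
        causal_part = (panel.dosage[mean_idx, :] / 2.0).T @ (-mean_eff)
        line_eff = line_eff + causal_part
    sexline = {s: rng.normal(0.0, np.sqrt(spec.sexline_var), L)
               if spec.sexline_var > 0 else np.zeros(L) for s in ("M", "F")}

    if spec.resid_var == 0:
        sigma = np.zeros(L)  # fully degenerate within-line spread
    else:
        log_sigma = 0.5 * np.log(spec.resid_var) * np.ones(L)
        if len(var_idx):
            log_sigma = log_sigma + (panel.dosage[var_idx, :] / 2.0).T \
                @ (np.log(spec.var_effect_mult) * np.ones(len(var_idx)))
        if spec.line_disp_sd > 0:
            log_sigma = log_sigma + rng.normal(0.0, spec.line_disp_sd, L)
        sigma = np.exp(log_sigma)

    rows = []
    for li, lid in enumerate(ids):
        for sex in ("M", "F"):
            loc = (spec.mu + line_eff[li] + sexline[sex][li]
                   + (spec.sex_effect if sex == "M" else 0.0))
            for rep in range(1, spec.replicates + 1):
                latent = rng.normal(loc, sigma[li], spec.flies_per_replicate)
                times = np.exp(latent) if spec.family == "lognormal" else latent
                times = np.maximum(times, 1e-9)
                grid = spec.scoring_grid_h
                times = np.ceil(times / grid) * grid
                times = np.maximum(times, grid)  # discovery takes one check
                status = np.full(len(times), "dead", dtype=object)
                if spec.censor_horizon_h is not None:
                    over = times > spec.censor_horizon_h
                    times[over] = spec.censor_horizon_h
                    status[over] = "censored"
                for t, st in zip(times, status):
                    rows.append((lid, sex, f"R{rep}", float(t), st, "pathogen"))

    df = pd.DataFrame(rows, columns=["line_id", "sex", "replicate_id",
                                     "time_h", "status", "treatment"])
    truth = SimTruth(
        line_ids=ids,
        line_effects=line_eff,
        sexline_effects=sexline,
        line_sigma=sigma,
        mean_causal=pd.DataFrame({"marker_index": mean_idx, "effect": mean_eff}),
        var_causal=pd.DataFrame({"marker_index": var_idx,
                                 "multiplier": np.full(len(var_idx),
                                                       spec.var_effect_mult)}),
    )
    truth.realized = truth.recompute_components()
    return EventTable(df, spec.scoring_grid_h), truth


@dataclass
class CFUSpec:
    """Phenomenological logistic within-host growth on a 12-h sampling grid."""

    carrying_capacity: float = 1e4
    growth_rate: float = 0.25       # per hour at the inflection
    lag_offset_h: float = -36.0     # lag = LT50 + lag_offset
    inflection_after_lag_h: float = 24.0
    noise_sd_log: float = 0.3       # multiplicative lognormal count noise
    flies_per_line: int = 10
    grid_h: float = 12.0
    horizon_h: float = 240.0
    seed: int = 0


def simulate_cfu(line_resistance_scores: pd.Series, spec: CFUSpec | None = None,
                 seed: int | None = None) -> pd.DataFrame:
    """Simulate per-fly CFU time courses; lag tracks each line's expected LT50.

    Returns a long table line_id, fly_id, time_h, cfu.  Threshold-crossing
    times are positively associated with the resistance score by construction.
    """
    spec = spec or CFUSpec()
    if (line_resistance_scores < 0).any():
        raise ConfigurationError("resistance scores must be non-negative")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    times = np.arange(0.0, spec.horizon_h + spec.grid_h, spec.grid_h)
    rows = []
    for lid, score in line_resistance_scores.items():
        lag = score + spec.lag_offset_h
        t_mid = lag + spec.inflection_after_lag_h
        base = spec.carrying_capacity / (
            1.0 + np.exp(-spec.growth_rate * (times - t_mid)))
        base[times < lag] = 0.0
        for fly in range(1, spec.flies_per_line + 1):
            noisy = base * np.exp(rng.normal(0.0, spec.noise_sd_log, len(times))) \
                if spec.noise_sd_log > 0 else base
            counts = np.round(noisy).astype(int)
            for t, c in zip(times, counts):
                rows.append((lid, fly, float(t), int(c)))
    return pd.DataFrame(rows, columns=["line_id", "fly_id", "time_h", "cfu"])
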