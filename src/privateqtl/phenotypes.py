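"""Lineage-level BLUPs and hierarchical size indices.

Individual log-size records are turned into four BLUP means per lineage
(female/male x fed/starved), from which the derived indices follow by
arithmetic:

    sex-averaged size      b_lineage = (b_female + b_male) / 2
    sexual size dimorphism SSD       = b_female - b_male        (per diet)
    plasticity             delta     = b_fed - b_starved        (per sex)
    sex-averaged plasticity          = (delta_f + delta_m) / 2
    sex-specific plasticity SSP      = delta_f - delta_m
                                     = SSD_fed - SSD_starved    (identity)

The BLUP model is fitted separately within each diet stratum: fixed sex,
a correlated lineage (intercept, sex-slope) random effect, and a crossed
random block intercept, by REML.  Because SSD and SSP share the fed
BLUPs, an independent plasticity index is also computed per sex as the
residual of an OLS regression of the starved BLUP on the fed BLUP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import LmmResult, RandomTerm, fit_crossed_lmm
from .simdata import DIET_LEVELS, SEX_CONTRAST, VarianceComponents

BLUP_COLUMNS = ["b_female_fed", "b_female_starved", "b_male_fed", "b_male_starved"]

INDEX_COLUMNS = BLUP_COLUMNS + [
    "b_lineage_fed", "b_lineage_starved",
    "ssd_fed", "ssd_starved",
    "delta_female", "delta_male", "delta_lineage", "ssp",
    "delta_female_indep", "delta_male_indep", "ssp_indep",
]


def filter_groups(records: pd.DataFrame, min_n: int = 10
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop lineage x sex x diet groups with fewer than ``min_n`` records.

    Returns the retained records and a drop report (one row per removed
    group, with its count).
    """
    if records.empty:
        raise ValueError("records is empty")
    counts = records.groupby(["lineage_id", "sex", "diet"], observed=True).size()
    small = counts[counts < min_n]
    report = small.rename("n_records").reset_index()
    if small.empty:
        return records.copy(), report
    key = pd.MultiIndex.from_frame(records[["lineage_id", "sex", "diet"]])
    keep = ~key.isin(small.index)
    out = records.loc[keep].copy()
    if out.empty:
        warnings.warn("all groups removed by the size filter", stacklevel=2)
    return out, report


def remove_block_effects(records: pd.DataFrame) -> pd.DataFrame:
    """Residualize size on block (equivalent to per-block centering).

    After this the per-block mean of ``size_log`` is zero; a regression
    on the block factor yields exactly these residuals.
    """
    if "block" not in records.columns:
        raise ValueError("records lack a 'block' column")
    out = records.copy()
    out["size_log"] = records["size_log"] - records.groupby("block")["size_log"].transform("mean")
    return out


@dataclass
class BlupDiagnostics:
    """Per-stratum convergence and variance-component estimates."""

    converged: dict[str, bool] = field(default_factory=dict)
    fallback: dict[str, str] = field(default_factory=dict)
    variance_components: dict[str, dict[str, float]] = field(default_factory=dict)
    fits: dict[str, LmmResult] = field(default_factory=dict)

    def vc_frame(self) -> pd.DataFrame:
        rows = []
        for stratum, vcs in self.variance_components.items():
            for name, val in vcs.items():
                rows.append((stratum, name, val))
        return pd.DataFrame(rows, columns=["stratum", "component", "variance"])


def estimate_blups(
    records: pd.DataFrame,
    variance_components: VarianceComponents | None = None,
) -> tuple[pd.DataFrame, BlupDiagnostics]:
    """Fit the BLUP model per diet stratum and extract the four means.

    For each stratum the model is ``size ~ sex`` with a correlated
    lineage (intercept, sex) random effect and a random block intercept.
    The BLUP for a lineage x sex is the fitted fixed part plus the
    lineage's predicted intercept and sex deviation (block effects
    average to zero).  Lineages absent for a sex within a stratum get a
    missing BLUP there.

    If ``variance_components`` is given, the generative variances are
    used directly instead of REML estimates (fixed-variance prediction).
    """
    if records["lineage_id"].nunique() < 2:
        raise ValueError("need at least 2 lineages")
    if records["sex"].nunique() < 2:
        raise ValueError("both sexes must be present")

    lineages = sorted(records["lineage_id"].unique())
    blups = pd.DataFrame(index=pd.Index(lineages, name="lineage_id"),
                         columns=BLUP_COLUMNS, dtype=float)
    diag = BlupDiagnostics()

    for diet in DIET_LEVELS:
        sub = records[records["diet"] == diet]
        if sub.empty:
            diag.converged[diet] = False
            diag.fallback[diet] = "no-data"
            continue
        lin_codes, lin_levels = pd.factorize(sub["lineage_id"], sort=True)
        s = sub["sex"].map(SEX_CONTRAST).to_numpy(float)
        y = sub["size_log"].to_numpy(float)
        X = np.column_stack([np.ones_like(s), s])
        terms = [RandomTerm("lineage", np.column_stack([np.ones_like(s), s]),
                            lin_codes, "un")]
        blocks = sub["block"].astype(str)
        blk_codes, _ = pd.factorize(blocks, sort=True)
        if blocks.nunique() > 1:
            terms.append(RandomTerm("block", np.ones((len(s), 1)), blk_codes, "diag"))

        fallback = "none"
        if variance_components is not None:
            vc = variance_components
            gam = {
                "lineage": np.array([
                    [vc.var_lineage_intercept, 0.0],
                    [0.0, vc.var_sex_slope],
                ]) / vc.var_residual,
                "block": np.array([[vc.var_block]]) / vc.var_residual,
            }
            fit = fit_crossed_lmm(y, X, terms, names=["1", "S"], fix_gamma=gam)
        else:
            fit = fit_crossed_lmm(y, X, terms, names=["1", "S"])
            if not fit.converged:
                terms_d = [RandomTerm(t.name, t.Z, t.levels, "diag") for t in terms]
                fit = fit_crossed_lmm(y, X, terms_d, names=["1", "S"])
                fallback = "diagonal"
            if not fit.converged:
                raise RuntimeError(f"BLUP model did not converge in stratum {diet!r}")

        diag.converged[diet] = fit.converged
        diag.fallback[diet] = fallback
        diag.fits[diet] = fit
        vcs = {"lineage_intercept": float(fit.vc["lineage"][0, 0]),
               "sex_slope": float(fit.vc["lineage"][1, 1]),
               "intercept_sex_cov": float(fit.vc["lineage"][0, 1]),
               "residual": float(fit.sigma2)}
        if "block" in fit.vc:
            vcs["block"] = float(fit.vc["block"][0, 0])
        diag.variance_components[diet] = vcs

        present = sub.groupby(["lineage_id", "sex"], observed=True).size()
        b0, bS = fit.params
        for li, lid in enumerate(lin_levels):
            u = fit.blups["lineage"][li]
            for sex, col in (("F", f"b_female_{diet}"), ("M", f"b_male_{diet}")):
                if (lid, sex) in present.index:
                    sc = SEX_CONTRAST[sex]
                    blups.loc[lid, col] = b0 + sc * bS + u[0] + sc * u[1]
    return blups.reset_index(), diag


def derive_indices(blups: pd.DataFrame) -> pd.DataFrame:
    """Populate the hierarchical indices from the four BLUPs per lineage.

    Lineages missing any BLUP get missing indices and ``complete=False``.
    """
    out = blups.copy()
    ff, fs = out["b_female_fed"], out["b_female_starved"]
    mf, ms = out["b_male_fed"], out["b_male_starved"]
    out["b_lineage_fed"] = (ff + mf) / 2.0
    out["b_lineage_starved"] = (fs + ms) / 2.0
    out["ssd_fed"] = ff - mf
    out["ssd_starved"] = fs - ms
    out["delta_female"] = ff - fs
    out["delta_male"] = mf - ms
    out["delta_lineage"] = (out["delta_female"] + out["delta_male"]) / 2.0
    out["ssp"] = out["delta_female"] - out["delta_male"]
    out["complete"] = out[BLUP_COLUMNS].notna().all(axis=1)
    return out


def independent_plasticity(summaries: pd.DataFrame) -> pd.DataFrame:
    """Add the fed-independent plasticity indices.

    Per sex, the starved BLUP is regressed on the fed BLUP across
    lineages by OLS; the residuals are the independent plasticity index,
    and ``ssp_indep`` applies the SSP difference to them.  Residuals are
    exactly orthogonal to the fed BLUPs within sex.
    """
    out = summaries.copy()
    complete = out[BLUP_COLUMNS].notna().all(axis=1)
    if complete.sum() < 3:
        raise ValueError("need >= 3 lineages with complete BLUPs")
    for sex, fed_col, st_col in (("female", "b_female_fed", "b_female_starved"),
                                 ("male", "b_male_fed", "b_male_starved")):
        x = out.loc[complete, fed_col].to_numpy(float)
        yv = out.loc[complete, st_col].to_numpy(float)
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
        out.loc[complete, f"delta_{sex}_indep"] = yv - A @ coef
    out["ssp_indep"] = out["delta_female_indep"] - out["delta_male_indep"]
    return out


def summarize_lineages(
    records: pd.DataFrame,
    min_n: int = 10,
    variance_components: VarianceComponents | None = None,
) -> tuple[pd.DataFrame, BlupDiagnostics, pd.DataFrame]:
    """Full phenotype stage: filter, BLUPs, indices, independent indices."""
    kept, report = filter_groups(records, min_n=min_n)
    blups, diag = estimate_blups(kept, variance_components=variance_components)
    summary = derive_indices(blups)
    summary = independent_plasticity(summary)
    return summary, diag, report
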