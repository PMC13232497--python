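"""Stage-2 per-marker mixed-model GWAS on individual records.

Each phenotype in the trait hierarchy maps to a specific mixed model
whose *target term* is the fixed-effect interaction that carries that
phenotype's genetic signal:

===========================  ==============================  =========
phenotype                    fixed terms                     target
===========================  ==============================  =========
single-sex/diet size         G                               G
sex-averaged size (per diet) S + G                           G
SSD (per diet)               S + G + S:G                     S:G
plasticity (per sex)         D + G + D:G                     D:G
sex-averaged plasticity      S + D + G + S:D + S:G + D:G     D:G
SSP                          ... + S:D:G (full model)        S:D:G
===========================  ==============================  =========

Random structure: lineage intercept plus the sex/diet/sex-by-diet
slopes matching the strata the phenotype spans.  Sex is coded +1/2
(female) / -1/2 (male), diet +1/2 (fed) / -1/2 (starved) and genotype
0 (major) / 1 (minor class), so the target coefficient is directly the
minor-vs-major difference of the phenotype's defining contrast, in log
units.

The two-step procedure screens all markers at the lineage level first
(:mod:`privateqtl.assoc_screen`), then fits the mixed model only on the
top-k union, with lineage covariates (Wolbachia, inversions, PCs)
entered in place of genotype, tested interaction-first and eliminated
if non-significant.  Candidates are markers with target-term p below
1e-5.  Two diagnostics probe the screen's completeness: the rank-
accumulation curve of MLM hits over stage-1 ranks, and a random-subset
control drawn from outside the top set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc_screen import screen_all, select_top
from .lmm import LmmResult, fit_grouped_lmm
from .simdata import DIET_CONTRAST, SEX_CONTRAST, LineageCovariates, PanelGenotypes

CANDIDATE_THRESHOLD = 1e-5

#: phenotype name -> (record subset, fixed terms, random terms, target)
_SPEC_TABLE: dict[str, tuple[dict, list[str], list[str], str]] = {}
for _sex, _sx in (("female", "F"), ("male", "M")):
    for _diet in ("fed", "starved"):
        _SPEC_TABLE[f"size_{_sex}_{_diet}"] = (
            {"sex": _sx, "diet": _diet}, ["G"], ["1"], "G")
for _diet in ("fed", "starved"):
    _SPEC_TABLE[f"size_{_diet}"] = ({"diet": _diet}, ["S", "G"], ["1"], "G")
    _SPEC_TABLE[f"ssd_{_diet}"] = (
        {"diet": _diet}, ["S", "G", "S:G"], ["1", "S"], "S:G")
for _sex, _sx in (("female", "F"), ("male", "M")):
    _SPEC_TABLE[f"delta_{_sex}"] = (
        {"sex": _sx}, ["D", "G", "D:G"], ["1", "D"], "D:G")
_SPEC_TABLE["delta_lineage"] = (
    {}, ["S", "D", "G", "S:D", "S:G", "D:G"], ["1", "S", "D", "S:D"], "D:G")
_SPEC_TABLE["ssp"] = (
    {}, ["S", "D", "G", "S:D", "S:G", "D:G", "S:D:G"],
    ["1", "S", "D", "S:D"], "S:D:G")

#: lineage-summary columns screened at stage 1 for each phenotype
SCREEN_INDEX = {
    "size_female_fed": ["b_female_fed"], "size_female_starved": ["b_female_starved"],
    "size_male_fed": ["b_male_fed"], "size_male_starved": ["b_male_starved"],
    "size_fed": ["b_lineage_fed"], "size_starved": ["b_lineage_starved"],
    "ssd_fed": ["ssd_fed"], "ssd_starved": ["ssd_starved"],
    "delta_female": ["delta_female"], "delta_male": ["delta_male"],
    "delta_lineage": ["delta_lineage"],
    "ssp": ["ssp", "ssp_indep"],
}


@dataclass
class MlmSpec:
    """Mixed-model form for one phenotype."""

    phenotype_name: str
    subset: dict[str, str]
    fixed_terms: list[str]
    random_terms: list[str]
    target_term: str

    def __post_init__(self) -> None:
        if self.target_term not in self.fixed_terms:
            raise ValueError("target term must be a fixed term")


def build_spec(phenotype_name: str) -> MlmSpec:
    """Return the mixed-model specification for a phenotype name."""
    try:
        subset, fixed, random, target = _SPEC_TABLE[phenotype_name]
    except KeyError:
        raise ValueError(
            f"unknown phenotype {phenotype_name!r}; "
            f"known: {sorted(_SPEC_TABLE)}") from None
    return MlmSpec(phenotype_name, dict(subset), list(fixed), list(random), target)


def _term_column(term: str, s: np.ndarray, d: np.ndarray,
                 marker_vals: np.ndarray) -> np.ndarray:
    col = np.ones_like(s)
    for f in term.split(":"):
        if f == "S":
            col = col * s
        elif f == "D":
            col = col * d
        elif f in ("G", "x"):
            col = col * marker_vals
        elif f == "1":
            pass
        else:
            raise ValueError(f"unknown factor {f!r} in term {term!r}")
    return col


class _ModelData:
    """Cached per-phenotype design pieces shared across marker fits."""

    def __init__(self, records: pd.DataFrame, spec: MlmSpec,
                 covariates: LineageCovariates | None,
                 retained_covariates: list[tuple[str, str]]):
        sub = records
        for col, val in spec.subset.items():
            sub = sub[sub[col] == val]
        if sub.empty:
            raise ValueError(f"no records in subset {spec.subset!r}")
        self.spec = spec
        self.y = sub["size_log"].to_numpy(float)
        self.s = sub["sex"].map(SEX_CONTRAST).to_numpy(float)
        self.d = sub["diet"].map(DIET_CONTRAST).to_numpy(float)
        codes, levels = pd.factorize(sub["lineage_id"], sort=True)
        self.lin_codes = codes
        self.lineage_ids = list(levels)
        ones = np.ones_like(self.s)
        self.Z = np.column_stack(
            [_term_column(t, self.s, self.d, ones) for t in spec.random_terms])
        base_terms = [t for t in spec.fixed_terms if "G" not in t.split(":")]
        self.g_terms = [t for t in spec.fixed_terms if "G" in t.split(":")]
        cols = [ones] + [_term_column(t, self.s, self.d, ones) for t in base_terms]
        names = ["1"] + base_terms
        if retained_covariates:
            cov_frame = covariates.as_frame().loc[self.lineage_ids]
            for cov_name, term in retained_covariates:
                cv = cov_frame[cov_name].to_numpy(float)[codes]
                cols.append(_term_column(term, self.s, self.d, cv))
                names.append(f"{cov_name}[{term}]")
        self.base_X = np.column_stack(cols)
        self.base_names = names

    def design_for(self, dose: pd.Series) -> tuple | None:
        """Row mask, X, names for one marker; None if monomorphic."""
        g_lin = dose.reindex(self.lineage_ids).to_numpy(float) / 2.0
        g = g_lin[self.lin_codes]
        keep = ~np.isnan(g)
        g_kept = g[keep]
        if g_kept.size == 0 or np.ptp(g_kept) == 0.0:
            return None
        s, d = self.s[keep], self.d[keep]
        Xg = np.column_stack(
            [_term_column(t, s, d, g_kept) for t in self.g_terms])
        X = np.column_stack([self.base_X[keep], Xg])
        names = self.base_names + self.g_terms
        codes = pd.factorize(self.lin_codes[keep], sort=True)[0]
        n_lineages = int(np.sum(~np.isnan(g_lin)))
        return keep, X, names, codes, n_lineages


@dataclass
class MarkerFit:
    marker_id: str
    effect: float
    se: float
    p_value: float
    fallback: int               # 0 unstructured, 1 diagonal, 2 intercept-only
    converged: bool
    n_lineages_used: int
    status: str = "ok"
    fit: LmmResult | None = None


def _fit_with_ladder(md: _ModelData, y, X, names, Z, codes,
                     start=None) -> tuple[LmmResult, int]:
    res = fit_grouped_lmm(y, X, Z, codes, names=names, structure="un",
                          start=start)
    if res.converged:
        return res, 0
    res = fit_grouped_lmm(y, X, Z, codes, names=names, structure="diag")
    if res.converged:
        return res, 1
    res = fit_grouped_lmm(y, X, Z[:, :1], codes, names=names, structure="diag")
    return res, 2


def fit_marker_mlm(
    records: pd.DataFrame,
    dose: pd.Series,
    spec: MlmSpec,
    covariates: LineageCovariates | None = None,
    retained_covariates: list[tuple[str, str]] | None = None,
    _model_data: _ModelData | None = None,
    _start=None,
) -> MarkerFit:
    """Fit the phenotype's mixed model for one marker.

    ``dose`` maps lineage id to the 0/2 call; lineages with a missing
    call are excluded for this marker only.  Reports the Wald z-test of
    the target term, with the unstructured -> diagonal -> intercept-only
    fallback ladder on non-convergence.
    """
    md = _model_data or _ModelData(records, spec, covariates,
                                   retained_covariates or [])
    built = md.design_for(dose)
    mid = str(dose.name)
    if built is None:
        return MarkerFit(mid, np.nan, np.nan, np.nan, 0, False, 0,
                         status="monomorphic")
    keep, X, names, codes, n_lineages = built
    res, fallback = _fit_with_ladder(md, md.y[keep], X, names, md.Z[keep],
                                     codes, start=_start)
    est, se, p = res.wald(spec.target_term)
    return MarkerFit(mid, est, se, p, fallback, res.converged, n_lineages,
                     fit=res)


def select_covariates(
    records: pd.DataFrame,
    covariates: LineageCovariates | None,
    spec: MlmSpec,
    alpha: float = 0.05,
) -> list[tuple[str, str]]:
    """Backward-eliminate lineage covariates from the phenotype's model.

    Each covariate is substituted for genotype in the model; its
    interaction terms are tested first (highest order, least significant
    removed) and then its additive term, each dropped when p >= alpha.
    Returns the retained ``(covariate, term)`` pairs, fixed for all
    subsequent marker fits.  Constant covariates are excluded.
    """
    if covariates is None:
        return []
    md_probe = _ModelData(records, spec, None, [])
    cov_frame = covariates.as_frame().loc[md_probe.lineage_ids]
    retained: list[tuple[str, str]] = []
    cov_term_templates = [t.replace("G", "x") for t in md_probe.g_terms]

    def order(t: str) -> int:
        return len(t.split(":"))

    for cov_name in cov_frame.columns:
        vals = cov_frame[cov_name].to_numpy(float)
        if np.ptp(vals) == 0.0:
            continue
        terms = sorted(cov_term_templates, key=order, reverse=True)
        current = list(terms)
        while current:
            # refit with the currently retained covariate terms
            res = _fit_covariate_model(md_probe, vals, cov_name, current)
            max_order = max(order(t) for t in current)
            testable = [t for t in current if order(t) == max_order] \
                if max_order > 1 else [t for t in current]
            pvals = {t: res.wald(f"{cov_name}[{t}]")[2] for t in testable}
            worst = max(pvals, key=lambda t: (pvals[t] if np.isfinite(pvals[t]) else 2.0))
            if not np.isfinite(pvals[worst]) or pvals[worst] >= alpha:
                current.remove(worst)
            else:
                break
        retained.extend((cov_name, t) for t in sorted(current, key=order))
    return retained


def _fit_covariate_model(md: _ModelData, vals: np.ndarray, cov_name: str,
                         terms: list[str]) -> LmmResult:
    cv = vals[md.lin_codes]
    cols = [md.base_X]
    names = list(md.base_names)
    for t in terms:
        cols.append(_term_column(t, md.s, md.d, cv)[:, None])
        names.append(f"{cov_name}[{t}]")
    X = np.column_stack(cols)
    res = fit_grouped_lmm(md.y, X, md.Z, md.lin_codes, names=names,
                          structure="un")
    if not res.converged:
        res = fit_grouped_lmm(md.y, X, md.Z, md.lin_codes, names=names,
                              structure="diag")
    return res


def mlm_scan(
    records: pd.DataFrame,
    panel: PanelGenotypes,
    marker_ids: list[str],
    spec: MlmSpec,
    covariates: LineageCovariates | None = None,
    retained_covariates: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Fit the phenotype's mixed model over a list of markers.

    Successive fits warm-start the variance optimization from the
    previous marker's solution.
    """
    md = _ModelData(records, spec, covariates, retained_covariates or [])
    rows = []
    start = None
    for mid in marker_ids:
        j = panel.marker_index(mid)
        fit = fit_marker_mlm(records, panel.dose(mid), spec,
                             _model_data=md, _start=start)
        if fit.fit is not None and fit.fallback == 0 and fit.converged:
            start = fit.fit.theta
        rows.append((mid, panel.chrom[j], int(panel.pos[j]), fit.effect,
                     fit.se, fit.p_value, fit.fallback, fit.converged,
                     fit.n_lineages_used, fit.status))
    df = pd.DataFrame(rows, columns=[
        "marker_id", "chrom", "pos", "effect", "se", "p_value", "fallback",
        "converged", "n_lineages_used", "status"])
    df["target_term"] = spec.target_term
    df.attrs["phenotype_name"] = spec.phenotype_name
    return df


@dataclass
class TwoStepResult:
    phenotype_name: str
    stage1_tables: dict[str, pd.DataFrame]
    top_set: set[str]
    retained_covariates: list[tuple[str, str]]
    mlm_table: pd.DataFrame
    candidates: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)


def run_two_step(
    panel: PanelGenotypes,
    covariates: LineageCovariates | None,
    records: pd.DataFrame,
    lineage_summary: pd.DataFrame,
    phenotype_name: str,
    k: int = 10_000,
    threshold: float = CANDIDATE_THRESHOLD,
    alpha_covariates: float = 0.05,
    min_minor_lineages: int = 4,
) -> TwoStepResult:
    """Screen -> top-k union -> per-marker MLM -> candidate set.

    ``records`` should already be block-residualized (the screen uses
    BLUP indices from ``lineage_summary``, which handle block as a
    random intercept).
    """
    spec = build_spec(phenotype_name)
    index_cols = SCREEN_INDEX[phenotype_name]
    summary = lineage_summary.set_index("lineage_id")
    stage1 = {}
    for col in index_cols:
        pheno = summary[col].rename(col)
        stage1[col] = screen_all(panel, covariates, pheno,
                                 min_minor_lineages=min_minor_lineages)
    k_eff = min(k, min(int(t["p_value"].notna().sum()) for t in stage1.values()))
    top = select_top(list(stage1.values()), k=k_eff)
    retained = select_covariates(records, covariates, spec,
                                 alpha=alpha_covariates)
    ordered = [m for m in panel.marker_ids if m in top]
    mlm = mlm_scan(records, panel, ordered, spec, covariates, retained)
    cand = mlm[(mlm["p_value"] < threshold) & (mlm["status"] == "ok")]
    counts = {
        "n_markers": panel.n_markers,
        "n_screened": int(stage1[index_cols[0]]["p_value"].notna().sum()),
        "n_top": len(top),
        "n_mlm_fitted": int((mlm["status"] == "ok").sum()),
        "n_candidates": len(cand),
    }
    return TwoStepResult(phenotype_name, stage1, top, retained, mlm,
                         cand.reset_index(drop=True), counts)


def rank_accumulation(
    stage1: pd.DataFrame,
    mlm: pd.DataFrame,
    threshold: float = CANDIDATE_THRESHOLD,
) -> tuple[pd.DataFrame, int]:
    """Cumulative MLM hits as a function of stage-1 rank.

    Both tables must cover the same markers.  Returns the step curve
    (rank, cumulative hit count) and the plateau rank: the smallest rank
    attaining the final count (0 when there are no hits).
    """
    s1 = stage1.dropna(subset=["rank"])[["marker_id", "rank"]]
    mp = mlm.set_index("marker_id")["p_value"]
    missing = set(s1["marker_id"]) - set(mp.index)
    if missing:
        raise ValueError(f"{len(missing)} stage-1 markers absent from MLM table")
    merged = s1.sort_values("rank").reset_index(drop=True)
    hits = (mp.reindex(merged["marker_id"]).to_numpy() < threshold)
    cum = np.cumsum(hits.astype(int))
    curve = pd.DataFrame({"rank": merged["rank"].astype(int),
                          "cumulative_hits": cum})
    total = int(cum[-1]) if len(cum) else 0
    plateau = int(curve.loc[curve["cumulative_hits"] == total, "rank"].iloc[0]) \
        if total > 0 else 0
    return curve, plateau


def random_control(
    panel: PanelGenotypes,
    excluded: set[str],
    k: int,
    records: pd.DataFrame,
    spec: MlmSpec,
    covariates: LineageCovariates | None = None,
    retained_covariates: list[tuple[str, str]] | None = None,
    threshold: float = CANDIDATE_THRESHOLD,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """MLM on k markers sampled from outside the top set (negative control)."""
    pool = [m for m in panel.marker_ids if m not in excluded]
    if len(pool) < k:
        raise ValueError(f"remaining pool ({len(pool)}) smaller than k={k}")
    rng = np.random.default_rng(seed)
    sample = sorted(rng.choice(pool, size=k, replace=False).tolist())
    table = mlm_scan(records, panel, sample, spec, covariates,
                     retained_covariates)
    ok = table[table["status"] == "ok"]
    summary = {
        "n_fitted": len(ok),
        "min_p": float(ok["p_value"].min()) if len(ok) else float("nan"),
        "n_hits": int((ok["p_value"] < threshold).sum()),
        "threshold": threshold,
    }
    return table, summary
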