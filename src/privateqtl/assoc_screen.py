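"""Stage-1 lineage-level association screen.

Emulates a DGRP2-style rapid GWAS: for each marker, an ordinary linear
model of the lineage-level phenotype on the major/minor allele class,
with Wolbachia status, inversion statuses and relatedness PCs as
additive covariates.  With no covariates and balanced allele classes
the allele test is exactly the pooled two-sample t-test.

Markers with fewer than ``min_minor_lineages`` lineages in either
allele class (after dropping missing calls) are skipped, mirroring
conventional panel MAF floors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import LineageCovariates, PanelGenotypes


@dataclass
class AssocResult:
    """Per-marker association record."""

    marker_id: str
    phenotype_name: str
    stage: str                  # "screen" or "mlm"
    target_term: str
    effect: float               # minor-vs-major difference, log units
    se: float
    p_value: float
    n_lineages_used: int
    covariates_kept: list[str]
    status: str = "ok"          # "ok", "low-MAF", "monomorphic", ...


def _covariate_matrix(covariates: LineageCovariates | None,
                      lineage_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((len(lineage_ids), 0)), []
    df = covariates.as_frame().loc[lineage_ids]
    return df.to_numpy(float), list(df.columns)


def _ols_allele_test(yv: np.ndarray, allele: np.ndarray, C: np.ndarray
                     ) -> tuple[float, float, float]:
    """OLS of phenotype on allele + covariates; allele-coefficient t-test."""
    X = np.column_stack([np.ones_like(allele), allele, C])
    n, p = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    dfres = n - rank
    if dfres <= 0:
        return float(coef[1]), float("nan"), float("nan")
    s2 = float(resid @ resid) / dfres
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(max(s2 * XtX_inv[1, 1], 0.0)))
    if se == 0.0:
        return float(coef[1]), 0.0, 1.0
    t = coef[1] / se
    return float(coef[1]), se, float(2.0 * stats.t.sf(abs(t), dfres))


def screen_marker(
    panel: PanelGenotypes,
    covariates: LineageCovariates | None,
    phenotype: pd.Series,
    marker_id: str,
    min_minor_lineages: int = 4,
) -> AssocResult:
    """Screen one marker against a per-lineage phenotype.

    ``phenotype`` is indexed by lineage id; lineages with a missing call
    or missing phenotype are dropped for this marker only.
    """
    dose = panel.dose(marker_id)
    joint = pd.DataFrame({"y": phenotype, "dose": dose}).dropna()
    lineages = list(joint.index)
    allele = (joint["dose"].to_numpy() / 2.0)
    n_minor = int(allele.sum())
    n_major = len(allele) - n_minor
    cov_names: list[str] = []
    if min(n_minor, n_major) < min_minor_lineages:
        return AssocResult(marker_id, phenotype.name or "", "screen", "allele",
                           float("nan"), float("nan"), float("nan"),
                           len(allele), cov_names, status="low-MAF")
    yv = joint["y"].to_numpy(float)
    if np.ptp(yv) == 0.0:
        return AssocResult(marker_id, phenotype.name or "", "screen", "allele",
                           0.0, 0.0, 1.0, len(allele), cov_names,
                           status="zero-variance")
    C, cov_names = _covariate_matrix(covariates, lineages)
    effect, se, p = _ols_allele_test(yv, allele, C)
    return AssocResult(marker_id, phenotype.name or "", "screen", "allele",
                       effect, se, p, len(allele), cov_names)


def screen_all(
    panel: PanelGenotypes,
    covariates: LineageCovariates | None,
    phenotype: pd.Series,
    min_minor_lineages: int = 4,
) -> pd.DataFrame:
    """Screen every marker; ranked ascending by p, ties broken by (chrom, pos).

    Returns a frame with one row per marker (skips included with their
    reason); tested markers carry 1-based ranks.
    """
    rows = []
    for j, mid in enumerate(panel.marker_ids):
        r = screen_marker(panel, covariates, phenotype, mid,
                          min_minor_lineages=min_minor_lineages)
        rows.append((mid, panel.chrom[j], int(panel.pos[j]), r.effect, r.se,
                     r.p_value, r.n_lineages_used, r.status))
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "effect",
                                     "se", "p_value", "n_lineages_used",
                                     "status"])
    df = df.sort_values(["p_value", "chrom", "pos"], na_position="last",
                        kind="mergesort").reset_index(drop=True)
    tested = df["p_value"].notna()
    df["rank"] = np.nan
    df.loc[tested, "rank"] = np.arange(1, int(tested.sum()) + 1)
    df.attrs["phenotype_name"] = phenotype.name or ""
    return df


def select_top(tables: list[pd.DataFrame], k: int = 10_000) -> set[str]:
    """Union of the k lowest-p markers per table (boundary ties included)."""
    union: set[str] = set()
    for tab in tables:
        tested = tab.dropna(subset=["p_value"])
        if k > len(tested):
            raise ValueError(f"k={k} exceeds {len(tested)} tested markers")
        cutoff = tested["p_value"].nsmallest(k).max()
        union |= set(tested.loc[tested["p_value"] <= cutoff, "marker_id"])
    return union
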