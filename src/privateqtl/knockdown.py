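"""Factorial analysis of RNAi knockdown validation experiments.

Each experiment compares knockdown ("experimental") against control
flies across the sex x diet design.  The full fixed-effects factorial

    size ~ S + D + T + S:D + S:T + D:T + S:D:T

is fitted by OLS (one cross per gene; no random effects), then reduced
by backward elimination: the least significant highest-order
interaction involving fly type is dropped (p >= alpha, refitting each
time), never removing a term contained in a retained higher-order term.
Sex, diet and their interaction always stay in the model.

The retained type terms classify what the knockdown affects:
S:D:T -> sex-specific plasticity (SSP); otherwise D:T -> plasticity
and/or S:T -> SSD; otherwise T -> body size; none retained -> no
detected effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simdata import DIET_CONTRAST, SEX_CONTRAST

TYPE_CONTRAST = {"experimental": 0.5, "control": -0.5}

ALL_TERMS = ("S", "D", "T", "S:D", "S:T", "D:T", "S:D:T")
_T_TERMS = ("T", "S:T", "D:T", "S:D:T")

_CLASSIFICATION = {"S:D:T": "SSP", "D:T": "plasticity", "S:T": "SSD", "T": "size"}


def _order(term: str) -> int:
    return term.count(":") + 1


def _contains(outer: str, inner: str) -> bool:
    return set(inner.split(":")) < set(outer.split(":"))


def _design(records: pd.DataFrame, terms: tuple[str, ...] | list[str]
            ) -> tuple[np.ndarray, list[str]]:
    s = records["sex"].map(SEX_CONTRAST).to_numpy(float)
    d = records["diet"].map(DIET_CONTRAST).to_numpy(float)
    t = records["fly_type"].map(TYPE_CONTRAST).to_numpy(float)
    fac = {"S": s, "D": d, "T": t}
    cols = [np.ones_like(s)]
    names = ["1"]
    for term in terms:
        col = np.ones_like(s)
        for f in term.split(":"):
            col = col * fac[f]
        cols.append(col)
        names.append(term)
    return np.column_stack(cols), names


@dataclass
class FactorialFit:
    """Full factorial fit with drop-one per-term p-values."""

    records: pd.DataFrame
    result: sm.regression.linear_model.RegressionResultsWrapper
    term_names: list[str]
    pvalues: dict[str, float]

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.result.params, index=["1"] + list(self.term_names))


def _fit_terms(records: pd.DataFrame, terms):
    X, names = _design(records, terms)
    return sm.OLS(records["size_log"].to_numpy(float), X).fit(), names


def _drop_one_p(records: pd.DataFrame, terms: list[str], term: str) -> float:
    """Model-comparison F-test p for removing ``term`` from ``terms``."""
    full, _ = _fit_terms(records, terms)
    reduced, _ = _fit_terms(records, [t for t in terms if t != term])
    f, p, _ = full.compare_f_test(reduced)
    return float(p)


def fit_factorial(records: pd.DataFrame) -> FactorialFit:
    """Fit the full sex x diet x type factorial by OLS.

    Requires all eight design cells populated.  Per-term p-values are
    drop-one model-comparison F-tests (Type-III with the +/-1/2 contrast
    coding used throughout).
    """
    required = {"sex", "diet", "fly_type", "size_log"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    cells = records.groupby(["sex", "diet", "fly_type"], observed=True).size()
    if len(cells) < 8:
        have = set(cells.index)
        missing = [c for c in
                   ((s, d, t) for s in ("F", "M") for d in ("fed", "starved")
                    for t in ("experimental", "control")) if c not in have]
        raise ValueError(f"empty design cells: {missing}")
    res, _ = _fit_terms(records, ALL_TERMS)
    pvals = {t: _drop_one_p(records, list(ALL_TERMS), t) for t in ALL_TERMS}
    return FactorialFit(records, res, list(ALL_TERMS), pvals)


@dataclass
class KnockdownResult:
    gene: str
    reduction_path: list[tuple[str, float]]
    final_terms: list[str]
    full_fit_pvalues: dict[str, float]
    classification: set[str] = field(default_factory=set)


def backward_reduce(fit: FactorialFit, alpha: float = 0.05,
                    gene: str = "") -> KnockdownResult:
    """Backward-eliminate non-significant type terms and classify.

    Only terms involving fly type are candidates for removal; at each
    step the least significant currently-highest-order removable term
    with p >= alpha is dropped and the model refit.  Ties in "least
    significant" break toward higher order, then lexicographic name.
    """
    records = fit.records
    terms = list(ALL_TERMS)
    path: list[tuple[str, float]] = []
    while True:
        removable = [t for t in terms if t in _T_TERMS
                     and not any(_contains(o, t) for o in terms if o != t)]
        if not removable:
            break
        max_ord = max(_order(t) for t in removable)
        at_top = [t for t in removable if _order(t) == max_ord]
        pvals = {t: _drop_one_p(records, terms, t) for t in at_top}
        worst = max(sorted(pvals), key=lambda t: pvals[t])
        if pvals[worst] < alpha:
            break
        terms.remove(worst)
        path.append((worst, pvals[worst]))

    retained_t = [t for t in terms if t in _T_TERMS]
    if "S:D:T" in retained_t:
        classification = {"SSP"}
    elif {"D:T", "S:T"} & set(retained_t):
        classification = {_CLASSIFICATION[t] for t in retained_t
                          if t in ("D:T", "S:T")}
    elif "T" in retained_t:
        classification = {"size"}
    else:
        classification = {"none"}
    return KnockdownResult(gene=gene, reduction_path=path, final_terms=terms,
                           full_fit_pvalues=dict(fit.pvalues),
                           classification=classification)


def analyze_knockdown(records: pd.DataFrame, gene: str = "",
                      alpha: float = 0.05) -> KnockdownResult:
    """Full fit plus backward reduction for one knockdown experiment."""
    return backward_reduce(fit_factorial(records), alpha=alpha, gene=gene)


def simulate_knockdown(
    n_per_cell: int = 25,
    effects: dict[str, float] | None = None,
    sigma: float = 0.1,
    fixed: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one knockdown experiment on the contrast scale.

    ``effects`` maps type terms ("T", "S:T", "D:T", "S:D:T") to their
    contrast-scale effects (e.g. an "S:D:T" effect is the experimental-
    minus-control difference in SSP).  ``fixed`` overrides the baseline
    sex/diet structure.
    """
    effects = effects or {}
    fixed = {"1": 0.95, "S": 0.18, "D": 0.25, "S:D": 0.02, **(fixed or {})}
    rng = np.random.default_rng(seed)
    rows = []
    for sex in ("F", "M"):
        for diet in ("fed", "starved"):
            for ftype in ("experimental", "control"):
                s, d = SEX_CONTRAST[sex], DIET_CONTRAST[diet]
                t = TYPE_CONTRAST[ftype]
                mu = (fixed["1"] + s * fixed["S"] + d * fixed["D"]
                      + s * d * fixed["S:D"]
                      + t * effects.get("T", 0.0)
                      + s * t * effects.get("S:T", 0.0)
                      + d * t * effects.get("D:T", 0.0)
                      + s * d * t * effects.get("S:D:T", 0.0))
                y = mu + rng.normal(0.0, sigma, n_per_cell)
                for v in y:
                    rows.append((sex, diet, ftype, v))
    return pd.DataFrame(rows, columns=["sex", "diet", "fly_type", "size_log"])
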