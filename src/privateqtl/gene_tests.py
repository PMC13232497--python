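"""Gene-level association and gene-set enrichment.

The gene-based test aggregates marker-level mixed-model p-values within
a gene, VEGAS style: each p is converted to a 1-df chi-square value
``X_i = F^-1(1 - p_i)``, the values are summed over the gene's
polymorphic markers, and the sum is referred to an empirical null built
by drawing multivariate-normal vectors with the gene's LD correlation
structure, squaring, and summing.  Under identity LD the null is
exactly chi-square with one df per marker, which anchors the Monte
Carlo machinery to an analytic reference.

The gene-set enrichment test summarizes each gene by its minimum marker
p-value, takes the mean over the set, and compares it to means of
randomly drawn same-size gene sets from the tested universe (small
means = enrichment, one-sided).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import PanelGenotypes

ANNOTATION_WINDOW_BP = 2000
GENE_CANDIDATE_THRESHOLD = 1e-5


def assign_snps_to_genes(annotation: pd.DataFrame,
                         marker_ids: list[str] | set[str]) -> dict[str, list[str]]:
    """Map gene id -> markers, excluding intergenic markers.

    A marker annotated to several genes appears under each; markers
    missing from the annotation are excluded with a warning.  Non-genic
    markers beyond the 2 kb flanking window (annotation distance) are
    treated as intergenic.
    """
    marker_ids = list(marker_ids)
    ann = annotation[annotation["marker_id"].isin(marker_ids)]
    unknown = set(marker_ids) - set(annotation["marker_id"])
    if unknown:
        warnings.warn(f"{len(unknown)} markers missing from annotation; excluded",
                      stacklevel=2)
    genic = ann[(ann["gene_id"] != "intergenic")
                & (ann["distance"].abs() <= ANNOTATION_WINDOW_BP)]
    out: dict[str, list[str]] = {}
    for gene, grp in genic.groupby("gene_id", sort=True):
        out[str(gene)] = sorted(set(grp["marker_id"]))
    return out


def gene_statistic(p_values: np.ndarray,
                   polymorphic: np.ndarray | None = None
                   ) -> tuple[np.ndarray, float]:
    """Chi-square-converted marker values and their sum for one gene.

    Monomorphic markers are skipped; p = 0 is clamped to the smallest
    positive double (the inverse CDF would be infinite).
    """
    p = np.asarray(p_values, float)
    if polymorphic is not None:
        p = p[np.asarray(polymorphic, bool)]
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0.0):
        warnings.warn("p = 0 clamped to the smallest positive value", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    x = stats.chi2.isf(p, df=1)
    return x, float(np.sum(x))


def ld_matrix(panel: PanelGenotypes, marker_ids: list[str],
              eig_floor: float = 1e-8) -> tuple[np.ndarray, list[str]]:
    """Positive-definite genotype correlation matrix for a marker set.

    Pearson correlations of the call columns over pairwise-complete
    lineages; constant columns are dropped; eigenvalues are floored at
    ``eig_floor`` and the matrix rescaled to unit diagonal.  Returns the
    repaired matrix and the markers actually used.
    """
    cols = [panel.marker_index(m) for m in marker_ids]
    G = panel.calls[:, cols]
    keep = []
    for j in range(G.shape[1]):
        col = G[:, j]
        obs = col[~np.isnan(col)]
        if obs.size >= 3 and np.ptp(obs) > 0:
            keep.append(j)
    if not keep:
        raise ValueError("no usable (polymorphic) markers for LD matrix")
    G = G[:, keep]
    used = [marker_ids[j] for j in keep]
    R = pd.DataFrame(G).corr(min_periods=3).to_numpy()
    R = np.where(np.isnan(R), 0.0, R)
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min() < eig_floor:
        w = np.maximum(w, eig_floor)
        R = (V * w) @ V.T
        dd = np.sqrt(np.diag(R))
        R = R / np.outer(dd, dd)
        np.fill_diagonal(R, 1.0)
    return R, used


def vegas_empirical_p(
    observed_statistic: float,
    ld: np.ndarray,
    n_reps: int = 1_000_000,
    seed: int | np.random.Generator = 0,
    tail: str = "upper",
    add_one: bool = False,
    _chunk: int = 200_000,
) -> float:
    """Empirical p of a gene statistic against the MVN-squared-sum null.

    ``tail='upper'`` (default) counts null sums >= observed, so small p
    means strong association; ``tail='lower'`` counts null sums
    <= observed.  ``add_one`` applies the (1+count)/(1+n) correction.
    """
    if n_reps < 1000:
        raise ValueError("n_reps must be >= 1000")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    ld = np.atleast_2d(np.asarray(ld, float))
    try:
        L = np.linalg.cholesky(ld)
    except np.linalg.LinAlgError:
        raise ValueError("LD matrix is not positive-definite; "
                         "use ld_matrix() to repair it") from None
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    k = ld.shape[0]
    count = 0
    done = 0
    while done < n_reps:
        m = min(_chunk, n_reps - done)
        Z = rng.standard_normal((m, k)) @ L.T
        T = np.einsum("ij,ij->i", Z, Z)
        if tail == "upper":
            count += int(np.sum(T >= observed_statistic))
        else:
            count += int(np.sum(T <= observed_statistic))
        done += m
    if add_one:
        return (1 + count) / (1 + n_reps)
    return count / n_reps


@dataclass
class GeneAssocResult:
    gene_id: str
    snp_ids: list[str]
    chi2_values: np.ndarray
    observed_statistic: float
    n_replicates: int
    empirical_p: float
    tail_convention: str = "upper"


def run_vegas(
    panel: PanelGenotypes,
    annotation: pd.DataFrame,
    mlm_table: pd.DataFrame,
    threshold: float = GENE_CANDIDATE_THRESHOLD,
    n_reps: int = 1_000_000,
    seed: int = 0,
    tail: str = "upper",
    add_one: bool = False,
) -> pd.DataFrame:
    """Gene-based test over all genes covered by the MLM table.

    Returns one row per gene with the observed statistic, empirical p
    and candidate flag; genes with zero polymorphic tested markers are
    omitted.  Per-gene null streams derive from ``seed`` and the gene's
    order, so results do not depend on iteration order.
    """
    if threshold < 1.0 / n_reps:
        warnings.warn(
            f"n_reps={n_reps} cannot resolve the candidate threshold "
            f"{threshold}; the smallest nonzero empirical p is {1.0 / n_reps}",
            stacklevel=2)
    tested = mlm_table[mlm_table["status"] == "ok"].set_index("marker_id")
    gene_map = assign_snps_to_genes(annotation, list(tested.index))
    rows = []
    for gi, (gene, markers) in enumerate(sorted(gene_map.items())):
        try:
            R, used = ld_matrix(panel, markers)
        except ValueError:
            continue
        p = tested.loc[used, "p_value"].to_numpy(float)
        ok = np.isfinite(p)
        if not ok.any():
            continue
        if not ok.all():
            used = [m for m, o in zip(used, ok) if o]
            R, used = ld_matrix(panel, used)
            p = tested.loc[used, "p_value"].to_numpy(float)
        x, observed = gene_statistic(p)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), gi]))
        emp = vegas_empirical_p(observed, R, n_reps=n_reps, seed=rng,
                                tail=tail, add_one=add_one)
        rows.append((gene, len(used), ",".join(used), observed, emp,
                     emp < threshold))
    df = pd.DataFrame(rows, columns=["gene_id", "n_snps", "snp_ids",
                                     "observed_statistic", "empirical_p",
                                     "candidate"])
    df.attrs.update({"n_replicates": n_reps, "seed": seed, "tail": tail})
    return df


@dataclass
class SetEnrichmentResult:
    set_name: str
    n_genes_tested: int
    observed_mean_min_p: float
    null_mean: float
    null_sd: float
    n_permutations: int
    empirical_p: float
    member_genes: list[str] = field(default_factory=list)


def gene_min_p(mlm_table: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    """Minimum tested marker p-value per gene (the enrichment summary)."""
    tested = mlm_table[(mlm_table["status"] == "ok")
                       & mlm_table["p_value"].notna()]
    gene_map = assign_snps_to_genes(annotation, list(tested["marker_id"]))
    pv = tested.set_index("marker_id")["p_value"]
    return pd.Series({g: float(pv.loc[mk].min()) for g, mk in gene_map.items()},
                     name="min_p").sort_index()


def set_enrichment(
    mlm_table: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_set: set[str] | list[str],
    set_name: str = "",
    universe: pd.Series | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> SetEnrichmentResult:
    """Permutation test for aggregate association of a gene set.

    The statistic is the mean per-gene minimum p over set members found
    in the universe (genes with tested markers).  The null resamples
    same-size gene sets from the universe; the one-sided empirical p is
    the proportion of null means <= the observed mean.
    """
    minp = universe if universe is not None else gene_min_p(mlm_table, annotation)
    members = sorted(set(gene_set) & set(minp.index))
    if not members:
        raise ValueError("gene set does not intersect the tested universe")
    observed = float(minp.loc[members].mean())
    vals = minp.to_numpy(float)
    m = len(members)
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_perm)
    for i in range(n_perm):
        null_means[i] = rng.choice(vals, size=m, replace=False).mean()
    emp = float(np.mean(null_means <= observed))
    return SetEnrichmentResult(
        set_name=set_name, n_genes_tested=m, observed_mean_min_p=observed,
        null_mean=float(null_means.mean()), null_sd=float(null_means.std(ddof=1)),
        n_permutations=n_perm, empirical_p=emp, member_genes=members)
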