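"""Synthetic isogenic-panel data with known planted marker effects.

Emulates a DGRP-style panel: fully homozygous lineages (calls coded 0 =
homozygous major, 2 = homozygous minor), block-structured LD, lineage
covariates (Wolbachia, inversions, relatedness PCs), and individual
log-body-size records generated under the hierarchical model used for
the interaction GWAS (fixed sex/diet/sex-by-diet structure, lineage
random intercept and sex/diet/sex-by-diet slopes, block intercepts,
residual noise) plus planted context-dependent marker effects.

Planted effect classes and their contrast conventions:

``G``       additive: minor-class lineages shift size by ``beta``.
``GxS``     the female-minus-male contrast differs by ``beta`` between
            minor- and major-allele lineages.
``GxD``     likewise for the fed-minus-starved contrast.
``GxSxD``   the double contrast (fed-starved difference of the
            female-male difference) differs by ``beta`` — the signature
            of sex-specific plasticity.

With sex coded +1/2 (female) / -1/2 (male) and diet +1/2 (fed) / -1/2
(starved), a class-``GxSxD`` effect contributes ``beta * s * d * g``
to a record, where ``g = dose/2`` is 0 or 1; the fixed-effect
coefficient of the three-way interaction in the association model then
equals ``beta`` exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

SEX_LEVELS = ("F", "M")
DIET_LEVELS = ("fed", "starved")
SEX_CONTRAST = {"F": 0.5, "M": -0.5}
DIET_CONTRAST = {"fed": 0.5, "starved": -0.5}

EFFECT_CLASSES = ("G", "GxS", "GxD", "GxSxD")

#: DGRP inversion catalogue (the five screen covariates first).
INVERSION_CATALOGUE = (
    "In(2L)t", "In(2R)NS", "In(3R)K", "In(3R)P", "In(3R)Mo",
    "In(2R)Y1", "In(2R)Y5", "In(3L)P", "In(3L)M", "In(3L)Y", "In(3R)C",
)

_CHROM_ARMS = ("2L", "2R", "3L", "3R", "X")


@dataclass
class PanelGenotypes:
    """Lineage x marker homozygous biallelic genotype matrix.

    ``calls`` holds 0 (homozygous major), 2 (homozygous minor) or NaN
    (missing), one row per lineage, one column per marker.
    """

    lineage_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    major_allele: np.ndarray
    minor_allele: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        ok = np.isnan(self.calls) | (self.calls == 0.0) | (self.calls == 2.0)
        if not ok.all():
            raise ValueError("calls must contain only 0, 2 or NaN")
        for arm in np.unique(self.chrom):
            p = self.pos[self.chrom == arm]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {arm}")

    @property
    def n_lineages(self) -> int:
        return len(self.lineage_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def maf(self) -> np.ndarray:
        """Minor-lineage frequency per marker, over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.calls == 2.0, axis=0)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in panel") from None

    def normalize_orientation(self) -> int:
        """Swap major/minor where the 'minor' class is the more frequent.

        Returns the number of markers flipped.
        """
        freq = self.maf
        flip = freq > 0.5
        if flip.any():
            cols = self.calls[:, flip]
            self.calls[:, flip] = np.where(np.isnan(cols), np.nan, 2.0 - cols)
            maj = self.major_allele[flip].copy()
            self.major_allele[flip] = self.minor_allele[flip]
            self.minor_allele[flip] = maj
        return int(flip.sum())

    def dose(self, marker_id: str, impute: bool = False) -> pd.Series:
        """Minor-allele dose per lineage; optionally NaN -> 0."""
        g = self.calls[:, self.marker_index(marker_id)]
        if impute:
            g = np.where(np.isnan(g), 0.0, g)
        return pd.Series(g, index=self.lineage_ids, name=marker_id)


@dataclass
class LineageCovariates:
    """Per-lineage Wolbachia status, inversion statuses and genotype PCs."""

    lineage_ids: list[str]
    wolbachia: np.ndarray
    inversions: pd.DataFrame        # lineage x inversion, 0/1
    pcs: np.ndarray                 # lineage x n_pcs scores

    def __post_init__(self) -> None:
        bad = [c for c in self.inversions.columns if c not in INVERSION_CATALOGUE]
        if bad:
            raise ValueError(f"unknown inversion names: {bad}")

    @property
    def n_pcs(self) -> int:
        return self.pcs.shape[1]

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"lineage_id": self.lineage_ids,
                           "wolbachia": self.wolbachia.astype(int)})
        for c in self.inversions.columns:
            df[c] = self.inversions[c].to_numpy()
        for j in range(self.n_pcs):
            df[f"pc{j + 1}"] = self.pcs[:, j]
        return df.set_index("lineage_id")


@dataclass
class VarianceComponents:
    """Variance components on the log-size scale (all >= 0)."""

    var_lineage_intercept: float = 0.010
    var_sex_slope: float = 0.002
    var_diet_slope: float = 0.004
    var_sexdiet_slope: float = 0.001
    var_block: float = 0.002
    var_residual: float = 0.010

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.as_dict().values()):
            raise ValueError("variance components must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "var_lineage_intercept": self.var_lineage_intercept,
            "var_sex_slope": self.var_sex_slope,
            "var_diet_slope": self.var_diet_slope,
            "var_sexdiet_slope": self.var_sexdiet_slope,
            "var_block": self.var_block,
            "var_residual": self.var_residual,
        }


@dataclass
class FixedEffects:
    """Population-level effects, on the contrast scale declared above."""

    intercept: float = 0.95       # log pupal-case area, ~ log mm^2
    sex: float = 0.18             # female - male
    diet: float = 0.25            # fed - starved
    sex_diet: float = 0.02        # diet contrast of the sex contrast


@dataclass
class PlantedEffect:
    marker_id: str
    effect_class: str
    size: float

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")


@dataclass
class SimTruth:
    """Everything needed to verify recovery of the generative model."""

    planted_effects: list[PlantedEffect] = field(default_factory=list)
    fixed_effects: FixedEffects = field(default_factory=FixedEffects)
    variance_components: VarianceComponents = field(default_factory=VarianceComponents)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [e.marker_id for e in self.planted_effects]
        if len(ids) != len(set(ids)):
            raise ValueError("effect_class must be unique per marker")


@dataclass
class SizeRecord:
    """One individual's phenotype observation (row schema of records frames)."""

    lineage_id: str
    sex: str
    diet: str
    block_id: str
    size: float


RECORD_COLUMNS = ["lineage_id", "sex", "diet", "block", "size_log"]


def _latent_rho_for_phi(phi: float, p: float) -> float:
    """Latent Gaussian correlation giving phi-correlation ``phi`` between
    two equal-frequency thresholded indicators with minor frequency ``p``."""
    if phi <= 0:
        return 0.0
    t = stats.norm.ppf(1.0 - p)  # minor class = upper tail
    target = p * p + phi * p * (1.0 - p)

    # P(Z1 > t, Z2 > t) = P(Z1 < -t, Z2 < -t) by symmetry; solve directly.
    def g(r: float) -> float:
        cov = np.array([[1.0, r], [r, 1.0]])
        return stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([-t, -t]) - target

    lo, hi = 0.0, 0.999999
    if g(lo) >= 0:
        return 0.0
    if g(hi) <= 0:
        return hi
    return float(optimize.brentq(g, lo, hi, xtol=1e-10))


def simulate_panel(
    n_lineages: int = 150,
    n_markers: int = 2000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 5,
    ld_rho: float = 0.8,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> PanelGenotypes:
    """Simulate a homozygous biallelic marker panel with block LD.

    Markers come in consecutive blocks of ``ld_block_size``; within a
    block all markers share a minor-lineage frequency and their allele
    assignments follow a Gaussian copula calibrated so the pairwise
    genotype (phi) correlation targets ``ld_rho``; blocks are mutually
    independent.  Realized per-marker MAF lies inside ``maf_range``
    before missingness is applied.
    """
    if n_lineages < 2:
        raise ValueError("n_lineages must be >= 2")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must lie in [0, 1)")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")
    if ld_block_size < 1:
        raise ValueError("ld_block_size must be >= 1")

    rng = np.random.default_rng(seed)
    # minor-count bounds implied by maf_range
    m_lo = max(1, int(np.ceil(lo * n_lineages - 1e-9)))
    m_hi = min(n_lineages // 2, int(np.floor(hi * n_lineages + 1e-9)))
    if m_lo > m_hi:
        m_lo = m_hi = max(1, min(n_lineages // 2, int(round(0.5 * (lo + hi) * n_lineages))))

    calls = np.empty((n_lineages, n_markers), dtype=float)
    n_blocks = int(np.ceil(n_markers / ld_block_size))
    latent_cache: dict[int, float] = {}
    for b in range(n_blocks):
        i0 = b * ld_block_size
        i1 = min(i0 + ld_block_size, n_markers)
        width = i1 - i0
        m = int(rng.integers(m_lo, m_hi + 1))
        p = m / n_lineages
        if m not in latent_cache:
            latent_cache[m] = _latent_rho_for_phi(ld_rho, p)
        r = latent_cache[m]
        shared = rng.standard_normal(n_lineages)[:, None]
        own = rng.standard_normal((n_lineages, width))
        z = np.sqrt(r) * shared + np.sqrt(1.0 - r) * own
        # rank-threshold: exactly m minor lineages per marker
        order = np.argsort(z, axis=0)
        block = np.zeros((n_lineages, width))
        for j in range(width):
            block[order[-m:, j], j] = 2.0
        calls[:, i0:i1] = block

    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = np.nan

    # map markers onto chromosome arms with increasing positions
    per_arm = int(np.ceil(n_markers / len(_CHROM_ARMS)))
    chrom = np.repeat(_CHROM_ARMS, per_arm)[:n_markers]
    pos = np.empty(n_markers, dtype=int)
    for arm in _CHROM_ARMS:
        idx = np.where(chrom == arm)[0]
        if idx.size:
            gaps = rng.integers(100, 5000, size=idx.size)
            pos[idx] = 10_000 + np.cumsum(gaps)
    nucs = np.array(list("ACGT"))
    major = nucs[rng.integers(0, 4, size=n_markers)]
    minor_off = rng.integers(1, 4, size=n_markers)
    minor = nucs[(np.searchsorted(nucs, major) + minor_off) % 4]

    lineage_ids = [f"line_{i + 1:03d}" for i in range(n_lineages)]
    marker_ids = [f"{c}_{p}_SNP" for c, p in zip(chrom, pos)]
    panel = PanelGenotypes(lineage_ids, marker_ids, chrom, pos, major, minor, calls)
    panel.normalize_orientation()
    return panel


def simulate_covariates(
    panel: PanelGenotypes,
    wolbachia_freq: float = 0.5,
    n_inversions: int = 5,
    n_pcs: int = 20,
    inversion_freq: float = 0.15,
    seed: int = 0,
) -> LineageCovariates:
    """Simulate Wolbachia/inversion statuses and compute genotype PCs.

    The PC scores are the leading principal components of the centered
    genotype matrix (missing calls imputed to the marker mean), i.e. the
    relatedness covariates the screen corrects for.
    """
    if panel.n_lineages == 0 or panel.n_markers == 0:
        raise ValueError("panel is empty")
    if n_pcs > panel.n_lineages - 1:
        raise ValueError("n_pcs must be <= n_lineages - 1")
    if n_inversions > len(INVERSION_CATALOGUE):
        raise ValueError("n_inversions exceeds the inversion catalogue")
    rng = np.random.default_rng(seed)
    n = panel.n_lineages
    wolb = (rng.random(n) < wolbachia_freq).astype(int)
    inv = pd.DataFrame(
        (rng.random((n, n_inversions)) < inversion_freq).astype(int),
        columns=list(INVERSION_CATALOGUE[:n_inversions]),
        index=panel.lineage_ids,
    )
    G = panel.calls.copy()
    col_mean = np.nanmean(G, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(G)
    G[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    G -= G.mean(axis=0)
    u, s, vt = np.linalg.svd(G, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    # deterministic sign: largest-|loading| entry of each PC positive
    for j in range(scores.shape[1]):
        v = vt[j]
        if v[np.argmax(np.abs(v))] < 0:
            scores[:, j] = -scores[:, j]
    return LineageCovariates(list(panel.lineage_ids), wolb, inv, scores)


def _class_multiplier(effect_class: str, s: np.ndarray, d: np.ndarray) -> np.ndarray:
    if effect_class == "G":
        return np.ones_like(s)
    if effect_class == "GxS":
        return s
    if effect_class == "GxD":
        return d
    return s * d  # GxSxD


def simulate_individuals(
    panel: PanelGenotypes,
    covariates: LineageCovariates | None,
    truth: SimTruth,
    design: dict[str, int] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate individual size records for every lineage x sex x diet cell.

    Returns a records frame with columns ``lineage_id, sex, diet, block,
    size_log``.  ``design`` keys: ``n_per_group`` (records per cell,
    default 10) and ``n_blocks`` (default 3); blocks are assigned to
    records uniformly at random, crossed with lineage.
    """
    design = {"n_per_group": 10, "n_blocks": 3, **(design or {})}
    n_per = int(design["n_per_group"])
    n_blocks = int(design["n_blocks"])
    if n_per < 1 or n_blocks < 1:
        raise ValueError("design counts must be >= 1")
    for eff in truth.planted_effects:
        panel.marker_index(eff.marker_id)  # raises KeyError if absent

    rng = np.random.default_rng(truth.seed if seed is None else seed)
    vc = truth.variance_components
    fx = truth.fixed_effects
    L = panel.n_lineages

    lam = rng.normal(0.0, np.sqrt(vc.var_lineage_intercept), L)
    sig = rng.normal(0.0, np.sqrt(vc.var_sex_slope), L)
    dlt = rng.normal(0.0, np.sqrt(vc.var_diet_slope), L)
    gam = rng.normal(0.0, np.sqrt(vc.var_sexdiet_slope), L)
    alpha = rng.normal(0.0, np.sqrt(vc.var_block), n_blocks)

    n_rows = L * 4 * n_per
    lin_idx = np.repeat(np.arange(L), 4 * n_per)
    cell = np.tile(np.repeat(np.arange(4), n_per), L)  # FF, FS, MF, MS
    sex = np.where(cell < 2, "F", "M")
    diet = np.where(cell % 2 == 0, "fed", "starved")
    s = np.where(sex == "F", SEX_CONTRAST["F"], SEX_CONTRAST["M"])
    d = np.where(diet == "fed", DIET_CONTRAST["fed"], DIET_CONTRAST["starved"])

    size = (fx.intercept + s * fx.sex + d * fx.diet + s * d * fx.sex_diet
            + lam[lin_idx] + s * sig[lin_idx] + d * dlt[lin_idx]
            + s * d * gam[lin_idx])
    for eff in truth.planted_effects:
        g = panel.dose(eff.marker_id, impute=True).to_numpy() / 2.0
        size = size + eff.size * g[lin_idx] * _class_multiplier(eff.effect_class, s, d)
    block = rng.integers(0, n_blocks, size=n_rows)
    size = size + alpha[block]
    size = size + rng.normal(0.0, np.sqrt(vc.var_residual), n_rows)

    return pd.DataFrame({
        "lineage_id": np.array(panel.lineage_ids)[lin_idx],
        "sex": sex,
        "diet": diet,
        "block": np.char.add("block_", (block + 1).astype(str)),
        "size_log": size,
    })


def simulate_annotation(
    panel: PanelGenotypes,
    markers_per_gene: int = 4,
    intergenic_every: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Tile synthetic genes along the panel and annotate each marker.

    Consecutive runs of ``markers_per_gene`` markers form a gene body;
    every ``intergenic_every``-th run is left intergenic, with markers
    near a gene end (within 2 kb) annotated as upstream/downstream of it.
    Returns a frame with columns marker_id, gene_id, site_class, distance.
    """
    rng = np.random.default_rng(seed)
    site_classes = np.array(["coding", "UTR", "intronic"])
    rows = []
    gene_counter = 0
    for arm in _CHROM_ARMS:
        idx = np.where(panel.chrom == arm)[0]
        if not idx.size:
            continue
        runs = [idx[i:i + markers_per_gene] for i in range(0, idx.size, markers_per_gene)]
        gene_spans = []  # (gene_id, start, end)
        for r_i, run in enumerate(runs):
            if (r_i + 1) % intergenic_every == 0:
                gene_spans.append(None)
                continue
            gene_counter += 1
            gid = f"gene_{gene_counter:04d}"
            gene_spans.append((gid, int(panel.pos[run[0]]), int(panel.pos[run[-1]])))
        for r_i, run in enumerate(runs):
            span = gene_spans[r_i]
            for k in run:
                mid, p = panel.marker_ids[k], int(panel.pos[k])
                if span is not None:
                    rows.append((mid, span[0], str(rng.choice(site_classes)), 0))
                    continue
                # intergenic run: annotate to a flanking gene if within 2 kb
                best = None
                for nb in (r_i - 1, r_i + 1):
                    if 0 <= nb < len(gene_spans) and gene_spans[nb] is not None:
                        gid, g0, g1 = gene_spans[nb]
                        dist = g0 - p if p < g0 else (p - g1 if p > g1 else 0)
                        if best is None or dist < best[1]:
                            cls = "upstream" if p < g0 else "downstream"
                            best = (gid, dist, cls)
                if best is not None and best[1] <= 2000:
                    rows.append((mid, best[0], best[2], int(best[1])))
                else:
                    rows.append((mid, "intergenic", "intergenic", -1))
    return pd.DataFrame(rows, columns=["marker_id", "gene_id", "site_class", "distance"])


def write_fixture(outdir, panel, covariates, records, truth) -> dict[str, str]:
    """Write the full fixture (genotypes, covariates, individuals, truth).

    Round-trips losslessly through :mod:`privateqtl.io` (floats kept to
    12 significant digits).  Returns the mapping of artifact name to path.
    """
    from . import io as pio
    return pio.write_fixture(outdir, panel, covariates, records, truth)
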