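"""Gaussian linear mixed models via cell-collapsed REML.

Every model in this package has categorical fixed and random designs, so
records sharing a (group, fixed-row, random-row) signature are
exchangeable.  The likelihood then factors exactly into (i) the pooled
within-cell sum of squares, which only informs the residual variance,
and (ii) a weighted model on the cell means.  Both paths below exploit
this: per-marker GWAS fits collapse ~thousands of records to at most a
handful of cells per lineage, and lineages with identical design and
replication collapse further into sufficient statistics, so one REML
objective evaluation costs microseconds regardless of record count.

Two solvers:

``fit_grouped_lmm``
    a single grouping factor (lineage) with a q-dimensional random
    design per group — the per-marker association models.

``fit_crossed_lmm``
    arbitrary crossed random terms (lineage intercept+slope crossed
    with block) via a Woodbury identity on the cell-mean covariance —
    the BLUP model.

Both profile out the residual variance, parametrize each random-effect
covariance (relative to the residual variance) by its log-Cholesky
factor, and maximize the restricted likelihood with L-BFGS-B.  Wald
inference on fixed effects uses the plug-in GLS covariance, referred to
the standard normal (no small-sample df correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

_LOGSD_LO, _LOGSD_HI = -10.0, 6.0
_OFF_LIM = 30.0


def _n_theta(r: int, structure: str) -> int:
    if structure == "un":
        return r * (r + 1) // 2
    if structure == "diag":
        return r
    raise ValueError(f"unknown structure {structure!r}")


def _chol_from_theta(theta: np.ndarray, r: int, structure: str) -> np.ndarray:
    """Lower-triangular Cholesky factor of Gamma from the parameter vector."""
    L = np.zeros((r, r))
    if structure == "diag":
        L[np.diag_indices(r)] = np.exp(theta)
        return L
    k = 0
    for i in range(r):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    return L


def _theta_bounds(r: int, structure: str) -> list[tuple[float, float]]:
    if structure == "diag":
        return [(_LOGSD_LO, _LOGSD_HI)] * r
    b = []
    for i in range(r):
        for j in range(i + 1):
            b.append((_LOGSD_LO, _LOGSD_HI) if i == j else (-_OFF_LIM, _OFF_LIM))
    return b


def _default_start(r: int, structure: str) -> np.ndarray:
    if structure == "diag":
        return np.full(r, -0.7)
    th = np.zeros(_n_theta(r, "un"))
    k = 0
    for i in range(r):
        for j in range(i + 1):
            if i == j:
                th[k] = -0.7
            k += 1
    return th


def _diag_to_un(theta_diag: np.ndarray, r: int) -> np.ndarray:
    th = np.zeros(_n_theta(r, "un"))
    k = 0
    for i in range(r):
        for j in range(i + 1):
            if i == j:
                th[k] = theta_diag[i]
            k += 1
    return th


@dataclass
class LmmResult:
    """Fitted mixed model on the cell-mean scale."""

    names: list[str]
    params: np.ndarray
    cov_params: np.ndarray
    sigma2: float
    converged: bool
    reml_criterion: float
    n_obs: int
    n_cells: int
    structure: str
    #: random-effect covariance matrices on the variance scale, by term
    vc: dict[str, np.ndarray] = field(default_factory=dict)
    #: BLUPs by term: {term: {level: vector}}
    blups: dict[str, dict] = field(default_factory=dict)
    theta: np.ndarray | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def wald(self, name: str) -> tuple[float, float, float]:
        """(estimate, se, two-sided p) for one fixed-effect coefficient."""
        i = self.names.index(name)
        est, se = float(self.params[i]), float(self.se[i])
        if se == 0.0 or not np.isfinite(se):
            return est, se, float("nan")
        z = est / se
        return est, se, float(2.0 * stats.norm.sf(abs(z)))


def _collapse(y, X, Zfull, groups):
    """Collapse records to cells keyed by (group, design row).

    Returns per-cell arrays plus the pooled within-cell SSE.
    """
    y = np.asarray(y, float)
    design = np.column_stack([np.asarray(groups, float), X, Zfull])
    cells, inverse = np.unique(design, axis=0, return_inverse=True)
    n_c = np.bincount(inverse).astype(float)
    ybar = np.bincount(inverse, weights=y) / n_c
    sse_w = float(np.sum(y * y) - np.sum(n_c * ybar * ybar))
    g_cell = cells[:, 0].astype(int)
    X_cell = cells[:, 1:1 + X.shape[1]]
    Z_cell = cells[:, 1 + X.shape[1]:]
    return g_cell, X_cell, Z_cell, n_c, ybar, max(sse_w, 0.0)


def fit_grouped_lmm(
    y,
    X,
    Z,
    groups,
    names: list[str] | None = None,
    structure: str = "un",
    reml: bool = True,
    start: np.ndarray | None = None,
    fix_gamma: np.ndarray | None = None,
    group_term: str = "group",
) -> LmmResult:
    """REML fit with one grouping factor and random design ``Z`` per group.

    ``groups`` are integer codes (0..G-1).  ``fix_gamma`` skips the
    variance optimization and computes GLS estimates and BLUPs at the
    given relative covariance ``Gamma = G_cov / sigma2`` — used for
    closed-form shrinkage checks and fixed-variance prediction.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.atleast_2d(np.asarray(Z, float))
    groups = np.asarray(groups)
    y = np.asarray(y, float)
    n, p = X.shape
    r = Z.shape[1]
    if names is None:
        names = [f"x{i}" for i in range(p)]

    g_cell, X_cell, Z_cell, n_c, ybar, sse_w = _collapse(y, X, Z, groups)
    n_cells = len(n_c)

    # pack cells per group, then group lineages into identical-design
    # classes; classes sharing a cell count are batched through LAPACK
    order = np.argsort(g_cell, kind="stable")
    g_sorted = g_cell[order]
    bounds_idx = np.searchsorted(g_sorted, np.unique(g_sorted))
    group_ids = np.unique(g_sorted)
    classes: dict[bytes, dict] = {}
    starts = list(bounds_idx) + [len(g_sorted)]
    for gi in range(len(group_ids)):
        sl = order[starts[gi]:starts[gi + 1]]
        key = np.ascontiguousarray(
            np.column_stack([n_c[sl], X_cell[sl], Z_cell[sl]])
        ).tobytes()
        cl = classes.setdefault(key, {
            "Xb": X_cell[sl], "Zb": Z_cell[sl], "n": n_c[sl],
            "members": [], "ybars": [],
        })
        cl["members"].append(int(group_ids[gi]))
        cl["ybars"].append(ybar[sl])
    # batch classes by their number of cells
    by_width: dict[int, dict] = {}
    for cl in classes.values():
        Y = np.array(cl["ybars"])                      # members x C
        C = Y.shape[1]
        bw = by_width.setdefault(C, {"Xb": [], "Zb": [], "ninv": [],
                                     "count": [], "S1": [], "S2": [],
                                     "members": [], "Y": []})
        bw["Xb"].append(cl["Xb"])
        bw["Zb"].append(cl["Zb"])
        bw["ninv"].append(1.0 / cl["n"])
        bw["count"].append(Y.shape[0])
        bw["S1"].append(Y.sum(axis=0))
        bw["S2"].append(Y.T @ Y)
        bw["members"].append(cl["members"])
        bw["Y"].append(Y)
    batches = []
    for C, bw in by_width.items():
        batches.append({
            "Xb": np.array(bw["Xb"]), "Zb": np.array(bw["Zb"]),
            "ninv": np.array(bw["ninv"]), "count": np.array(bw["count"], float),
            "S1": np.array(bw["S1"]), "S2": np.array(bw["S2"]),
            "members": bw["members"], "Y": bw["Y"], "C": C,
        })

    df = n - p if reml else n
    eye_p = np.eye(p)

    def core(Lmat: np.ndarray):
        logdet = 0.0
        A = np.zeros((p, p))
        b = np.zeros(p)
        qyy = 0.0
        per_batch = []
        for bt in batches:
            W = bt["Zb"] @ Lmat                         # K x C x r
            V = W @ W.transpose(0, 2, 1)
            idx = np.arange(bt["C"])
            V[:, idx, idx] += bt["ninv"]
            cf = np.linalg.cholesky(V)                  # K x C x C
            logdet += 2.0 * float(
                bt["count"] @ np.log(np.diagonal(cf, axis1=1, axis2=2)).sum(axis=1))
            Vi = np.linalg.solve(V, np.broadcast_to(
                np.eye(bt["C"]), V.shape).copy())       # K x C x C
            Vi_X = Vi @ bt["Xb"]
            A += np.einsum("kcp,kcq,k->pq", bt["Xb"], Vi_X, bt["count"])
            b += np.einsum("kcp,kc->p", Vi_X, bt["S1"])
            qyy += float(np.einsum("kij,kij->", Vi, bt["S2"]))
            per_batch.append((bt, Vi))
        Acf = linalg.cho_factor(A + 0.0 * eye_p, lower=True, check_finite=False)
        beta = linalg.cho_solve(Acf, b, check_finite=False)
        Q = max(qyy - float(b @ beta), 1e-12)
        sigma2 = (Q + sse_w) / df
        crit = df * np.log(sigma2) + logdet
        if reml:
            crit += 2.0 * np.sum(np.log(np.diag(Acf[0])))
        return crit, beta, sigma2, A, per_batch

    def objective(theta: np.ndarray) -> float:
        Lmat = _chol_from_theta(theta, r, structure)
        try:
            return core(Lmat)[0]
        except (linalg.LinAlgError, FloatingPointError, ValueError):
            return 1e12

    if fix_gamma is not None:
        gam = np.atleast_2d(np.asarray(fix_gamma, float))
        Lmat = np.linalg.cholesky(gam + 1e-12 * np.eye(r))
        theta_opt, converged = None, True
    else:
        if start is None:
            if structure == "un":
                # stabilize: diagonal pre-fit seeds the unstructured solve
                def objective_diag(theta):
                    Lm = _chol_from_theta(theta, r, "diag")
                    try:
                        return core(Lm)[0]
                    except (linalg.LinAlgError, FloatingPointError, ValueError):
                        return 1e12

                res_d = optimize.minimize(
                    objective_diag, _default_start(r, "diag"),
                    method="L-BFGS-B", bounds=_theta_bounds(r, "diag"),
                )
                start = _diag_to_un(res_d.x, r)
            else:
                start = _default_start(r, structure)
        res = optimize.minimize(
            objective, np.asarray(start, float), method="L-BFGS-B",
            bounds=_theta_bounds(r, structure),
        )
        theta_opt = res.x
        converged = bool(res.success)
        Lmat = _chol_from_theta(theta_opt, r, structure)

    crit, beta, sigma2, A, per_batch = core(Lmat)
    cov_beta = sigma2 * np.linalg.inv(A)
    gamma = Lmat @ Lmat.T

    blups: dict[int, np.ndarray] = {}
    for bt, Vi in per_batch:
        for ci in range(len(bt["members"])):
            resid = bt["Y"][ci] - (bt["Xb"][ci] @ beta)[None, :]
            U = resid @ Vi[ci].T @ bt["Zb"][ci] @ gamma.T   # members x r
            for m_i, gid in enumerate(bt["members"][ci]):
                blups[gid] = U[m_i]

    return LmmResult(
        names=list(names), params=beta, cov_params=cov_beta, sigma2=sigma2,
        converged=converged, reml_criterion=float(crit), n_obs=n,
        n_cells=n_cells, structure=structure if fix_gamma is None else "fixed",
        vc={group_term: sigma2 * gamma, "residual": np.array([[sigma2]])},
        blups={group_term: blups}, theta=theta_opt,
    )


@dataclass
class RandomTerm:
    """One crossed random term: per-level design columns with shared
    covariance (``structure`` 'un' or 'diag')."""

    name: str
    Z: np.ndarray          # n x r design
    levels: np.ndarray     # n integer codes
    structure: str = "un"

    @property
    def r(self) -> int:
        return self.Z.shape[1]


def fit_crossed_lmm(
    y,
    X,
    terms: list[RandomTerm],
    names: list[str] | None = None,
    reml: bool = True,
    start: np.ndarray | None = None,
    fix_gamma: dict[str, np.ndarray] | None = None,
) -> LmmResult:
    """REML fit with arbitrary crossed random terms (Woodbury path)."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]

    Zfull = np.column_stack([t.Z for t in terms] + [t.levels.astype(float) for t in terms])
    g_dummy = np.zeros(n)
    _, X_cell, ZL_cell, n_c, ybar, sse_w = _collapse(y, X, Zfull, g_dummy)
    C = len(n_c)
    rs = [t.r for t in terms]
    z_off = np.concatenate([[0], np.cumsum(rs)])
    lev_off = z_off[-1]
    tensors = []
    n_levels = []
    for ti, t in enumerate(terms):
        Zc = ZL_cell[:, z_off[ti]:z_off[ti + 1]]
        lev = ZL_cell[:, lev_off + ti].astype(int)
        K = int(lev.max()) + 1
        T = np.zeros((C, K, t.r))
        T[np.arange(C), lev] = Zc
        tensors.append(T.reshape(C, K * t.r))
        n_levels.append(K)

    n_th = [_n_theta(t.r, t.structure) for t in terms]
    th_off = np.concatenate([[0], np.cumsum(n_th)])
    df = n - p if reml else n

    def build_W(theta):
        parts = []
        for ti, t in enumerate(terms):
            Lmat = _chol_from_theta(theta[th_off[ti]:th_off[ti + 1]], t.r, t.structure)
            T = tensors[ti].reshape(C, n_levels[ti], t.r)
            parts.append((T @ Lmat).reshape(C, n_levels[ti] * t.r))
        return np.column_stack(parts)

    def core(theta):
        W = build_W(theta)
        q = W.shape[1]
        Wn = W * n_c[:, None]
        K = np.eye(q) + W.T @ Wn
        cf = linalg.cho_factor(K, lower=True, check_finite=False)
        logdetM = 2.0 * np.sum(np.log(np.diag(cf[0]))) - float(np.sum(np.log(n_c)))

        def Vi_mul(M):
            return n_c[:, None] * M - Wn @ linalg.cho_solve(cf, Wn.T @ M, check_finite=False)

        ViX = Vi_mul(X_cell)
        A = X_cell.T @ ViX
        b = ViX.T @ ybar
        Acf = linalg.cho_factor(A, lower=True, check_finite=False)
        beta = linalg.cho_solve(Acf, b, check_finite=False)
        Viy = Vi_mul(ybar[:, None])[:, 0]
        Q = max(float(ybar @ Viy) - float(b @ beta), 1e-12)
        sigma2 = (Q + sse_w) / df
        crit = df * np.log(sigma2) + logdetM
        if reml:
            crit += 2.0 * np.sum(np.log(np.diag(Acf[0])))
        return crit, beta, sigma2, A, Vi_mul

    def objective(theta):
        try:
            return core(theta)[0]
        except (linalg.LinAlgError, FloatingPointError, ValueError):
            return 1e12

    if fix_gamma is not None:
        theta = []
        for t in terms:
            gam = np.atleast_2d(np.asarray(fix_gamma[t.name], float))
            Lm = np.linalg.cholesky(gam + 1e-12 * np.eye(t.r))
            if t.structure == "diag":
                theta.extend(np.log(np.maximum(np.diag(Lm), 1e-12)))
            else:
                for i in range(t.r):
                    for j in range(i + 1):
                        theta.append(np.log(max(Lm[i, j], 1e-12)) if i == j else Lm[i, j])
        theta_opt = np.array(theta)
        converged = True
    else:
        if start is None:
            start = np.concatenate([_default_start(t.r, t.structure) for t in terms])
        bounds = sum((_theta_bounds(t.r, t.structure) for t in terms), [])
        res = optimize.minimize(objective, np.asarray(start, float),
                                method="L-BFGS-B", bounds=bounds)
        theta_opt = res.x
        converged = bool(res.success)

    crit, beta, sigma2, A, Vi_mul = core(theta_opt)
    cov_beta = sigma2 * np.linalg.inv(A)
    resid = ybar - X_cell @ beta
    m = Vi_mul(resid[:, None])[:, 0]

    vc = {"residual": np.array([[sigma2]])}
    blups: dict[str, dict] = {}
    for ti, t in enumerate(terms):
        Lmat = _chol_from_theta(theta_opt[th_off[ti]:th_off[ti + 1]], t.r, t.structure)
        gamma = Lmat @ Lmat.T
        vc[t.name] = sigma2 * gamma
        T = tensors[ti].reshape(C, n_levels[ti], t.r)
        U = np.einsum("clr,c->lr", T, m) @ gamma.T
        blups[t.name] = {lev: U[lev] for lev in range(n_levels[ti])}

    return LmmResult(
        names=list(names), params=beta, cov_params=cov_beta, sigma2=sigma2,
        converged=converged, reml_criterion=float(crit), n_obs=n, n_cells=C,
        structure="+".join(t.structure for t in terms), vc=vc, blups=blups,
        theta=theta_opt,
    )
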