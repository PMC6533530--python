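"""Gaussian penalized linear mixed models.

The engine behind the spatial analyses: a response is modeled as

    y = X beta + sum_j Z_j u_j + e,     u_j ~ N(0, sigma2_j I),  e ~ N(0, sigma2_e I)

where each ``Z_j`` is either a random-intercept indicator block or a
penalized smoother basis.  Smoothers (tensor-product splines, Markov random
fields) enter as quadratic penalties ``lambda_j u' P u``; each penalty is
eigen-reparametrized so that its range space becomes an i.i.d. random-effect
block and its null space joins the fixed effects.  Smoothing parameters are
then variance ratios ``lambda_j = sigma2_e / sigma2_j`` and the whole model
is fitted by REML: fixed effects and the residual variance are profiled out
analytically and the remaining log-ratios are optimized numerically (coarse
log-spaced grid per block, then Nelder--Mead refinement).

The restricted likelihood is evaluated through the penalized normal
equations: with ``C = [X, Z]`` and ``M = C'C + diag(0, Lambda)``,

    -2 l_R = (n - p) (log(2 pi s2) + 1) + log|M| - log|Lambda|,

``s2 = rss_pen / (n - p)`` — one Cholesky factorization per evaluation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize, stats

__all__ = [
    "SmoothTerm",
    "RandomTerm",
    "ModelSpec",
    "PenalizedBlock",
    "DesignBundle",
    "FitResult",
    "build_design",
    "fit_reml",
    "information_criteria",
    "bspline_basis",
    "tensor_spline",
    "mrf_penalty",
]

_RIDGE_GUARD = 1e-10


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomTerm:
    """A random intercept: ``factor`` may be "A" or an interaction "A:B".

    ``nested_in`` declares the parent grouping; child levels are coded as
    (parent, child) combinations and the parent's own intercept must be a
    separate :class:`RandomTerm`.
    """

    factor: str
    nested_in: Optional[str] = None

    @property
    def name(self) -> str:
        if self.nested_in:
            return f"{self.factor}%in%{self.nested_in}"
        return self.factor


@dataclass(frozen=True)
class SmoothTerm:
    """A penalized smooth.

    kind "tensor2d": tensor-product cubic B-spline over ``variables=(x, y)``
    with ``k`` basis functions per margin and second-order difference
    penalties on each margin.

    kind "mrf": Markov random field over the categorical cell variable
    ``variables=(cell,)``; ``adjacency`` maps each cell label to the set of
    its neighbors and the penalty is the graph Laplacian D - A.

    ``by`` replicates the field independently per level of a factor; all
    replicates share one smoothing parameter.
    """

    kind: str
    variables: tuple
    k: int = 8
    adjacency: Optional[dict] = None
    by: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("tensor2d", "mrf"):
            raise ValueError(f"unknown smooth kind {self.kind!r}")
        if self.kind == "mrf" and self.adjacency is None:
            raise ValueError("mrf smooth requires an adjacency mapping")

    @property
    def name(self) -> str:
        base = f"s({','.join(map(str, self.variables))},{self.kind})"
        if self.by:
            base += f":{self.by}"
        return base


@dataclass
class ModelSpec:
    """Declarative model description.

    ``fixed`` lists main effects ("A") and pairwise interactions ("A:B");
    an intercept is always included.  ``categorical`` forces columns with a
    numeric dtype (e.g. run numbers) to be treated as factors.
    """

    response: str
    log_transform: bool = False
    fixed: list = field(default_factory=list)
    random: list = field(default_factory=list)
    smooths: list = field(default_factory=list)
    categorical: set = field(default_factory=set)

    def __post_init__(self):
        names = list(self.fixed) + [r.name for r in self.random] + [s.name for s in self.smooths]
        if len(names) != len(set(names)):
            raise ValueError("duplicate terms in model specification")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "log_transform": self.log_transform,
            "fixed": list(self.fixed),
            "random": [dataclasses.asdict(r) for r in self.random],
            "smooths": [
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in dataclasses.asdict(s).items() if k != "adjacency"}
                for s in self.smooths
            ],
            "categorical": sorted(self.categorical),
        }

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, adjacency: Optional[dict] = None) -> "ModelSpec":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), adjacency)

    @classmethod
    def from_dict(cls, d: dict, adjacency: Optional[dict] = None) -> "ModelSpec":
        smooths = []
        for s in d.get("smooths", []):
            s = dict(s)
            s["variables"] = tuple(s["variables"])
            if s["kind"] == "mrf":
                s["adjacency"] = adjacency
            smooths.append(SmoothTerm(**s))
        return cls(
            response=d["response"],
            log_transform=d.get("log_transform", False),
            fixed=list(d.get("fixed", [])),
            random=[RandomTerm(**r) for r in d.get("random", [])],
            smooths=smooths,
            categorical=set(d.get("categorical", [])),
        )


# ---------------------------------------------------------------------------
# basis and penalty construction
# ---------------------------------------------------------------------------

def bspline_basis(x: np.ndarray, k: int, xlim: Optional[tuple] = None) -> np.ndarray:
    """Cubic B-spline design matrix with ``k`` basis functions."""
    from scipy.interpolate import BSpline

    if k < 4:
        raise ValueError("cubic B-spline basis needs k >= 4")
    x = np.asarray(x, float)
    lo, hi = xlim if xlim is not None else (x.min(), x.max())
    if hi <= lo:
        hi = lo + 1.0
    inner = np.linspace(lo, hi, k - 2)
    t = np.concatenate([[lo] * 3, inner, [hi] * 3])
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, t, 3).toarray()


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def tensor_spline(x: np.ndarray, y: np.ndarray, k: int = 8,
                  xlim: Optional[tuple] = None, ylim: Optional[tuple] = None):
    """Tensor-product basis and its double-penalty matrix.

    Returns ``(Z, P)`` with ``Z`` of shape (n, k*k) and
    ``P = Px (x) I + I (x) Py`` using second-order difference penalties.
    """
    Bx = bspline_basis(x, k, xlim)
    By = bspline_basis(y, k, ylim)
    n = Bx.shape[0]
    Z = (Bx[:, :, None] * By[:, None, :]).reshape(n, k * k)
    P1 = _difference_penalty(k)
    P = np.kron(P1, np.eye(k)) + np.kron(np.eye(k), P1)
    return Z, P


def mrf_penalty(nodes: Sequence, adjacency: dict) -> np.ndarray:
    """Graph Laplacian D - A over ``nodes`` (symmetrized)."""
    index = {v: i for i, v in enumerate(nodes)}
    P = np.zeros((len(nodes), len(nodes)))
    for v, nbrs in adjacency.items():
        if v not in index:
            continue
        i = index[v]
        for w in nbrs:
            if w in index and w != v:
                P[i, index[w]] = -1.0
    P = np.minimum(P, P.T)  # symmetrize: keep an edge if listed either way
    np.fill_diagonal(P, 0.0)
    np.fill_diagonal(P, -P.sum(axis=1))
    return P


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class PenalizedBlock:
    """One i.i.d. random-effect block after penalty reparametrization."""

    name: str
    Z: np.ndarray
    basis_dim: int          # original basis size (before null-space removal)
    n_null: int             # null-space columns moved to the fixed matrix
    col_names: list

    @property
    def q(self) -> int:
        return self.Z.shape[1]


@dataclass
class DesignBundle:
    X: np.ndarray
    x_names: list
    x_terms: list           # term label of each fixed column
    blocks: list
    dropped: list           # aliased fixed columns removed (first-come-kept)
    spec: ModelSpec
    n_obs: int

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _is_categorical(col: pd.Series, name: str, spec: ModelSpec) -> bool:
    if name in spec.categorical:
        return True
    return col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool


def _check_column(data: pd.DataFrame, name: str):
    if name not in data.columns:
        raise KeyError(f"model term references unknown column {name!r}")


def _coded_columns(data: pd.DataFrame, name: str, spec: ModelSpec, drop_first: bool):
    """Code one variable: list of (column values, label)."""
    _check_column(data, name)
    col = data[name]
    if _is_categorical(col, name, spec):
        levels = sorted(pd.unique(col.astype(str)))
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} has a single level")
        use = levels[1:] if drop_first else levels
        vals = col.astype(str).to_numpy()
        return [((vals == lev).astype(float), f"{name}[{lev}]") for lev in use]
    return [(col.to_numpy(float), name)]


def _indicator(data: pd.DataFrame, cols: Sequence[str]):
    """Full indicator coding of the interaction of ``cols`` (observed levels)."""
    key = data[list(cols)].astype(str).agg(":".join, axis=1)
    levels = sorted(pd.unique(key))
    Z = np.zeros((len(data), len(levels)))
    arr = key.to_numpy()
    for j, lev in enumerate(levels):
        Z[arr == lev, j] = 1.0
    return Z, levels


def _drop_aliased(X: np.ndarray, names: list, terms: list, tol: float = 1e-8):
    """Greedy first-come-kept removal of linearly dependent columns."""
    keep, basis = [], None
    dropped = []
    for j in range(X.shape[1]):
        cnorm = np.linalg.norm(X[:, j])
        if cnorm <= tol:
            dropped.append(names[j])
            continue
        if basis is None:
            keep.append(j)
            basis = X[:, [j]] / cnorm
            continue
        resid = X[:, j] - basis @ (basis.T @ X[:, j])
        if np.linalg.norm(resid) > tol * max(cnorm, 1.0):
            keep.append(j)
            basis = np.hstack([basis, (resid / np.linalg.norm(resid))[:, None]])
        else:
            dropped.append(names[j])
    return (X[:, keep], [names[j] for j in keep], [terms[j] for j in keep], dropped)


def build_design(spec: ModelSpec, data: pd.DataFrame) -> DesignBundle:
    """Realize a :class:`ModelSpec` against a data table.

    Fixed terms are dummy-coded (first level as reference); random intercepts
    become full-indicator blocks with identity penalties; smooth penalties are
    eigen-split into an identity-penalized range block and null-space columns
    appended to the fixed matrix.  Aliased fixed columns are dropped
    deterministically (first kept).
    """
    n = len(data)
    x_cols = [np.ones(n)]
    x_names = ["(Intercept)"]
    x_terms = ["(Intercept)"]

    for term in spec.fixed:
        parts = term.split(":")
        if len(parts) == 1:
            for vals, label in _coded_columns(data, parts[0], spec, drop_first=True):
                x_cols.append(vals)
                x_names.append(label)
                x_terms.append(term)
        elif len(parts) == 2:
            a = _coded_columns(data, parts[0], spec, drop_first=True)
            b = _coded_columns(data, parts[1], spec, drop_first=True)
            for va, la in a:
                for vb, lb in b:
                    x_cols.append(va * vb)
                    x_names.append(f"{la}:{lb}")
                    x_terms.append(term)
        else:
            raise ValueError(f"only pairwise interactions supported: {term!r}")

    blocks: list = []
    for rt in spec.random:
        cols = rt.factor.split(":")
        for c in cols:
            _check_column(data, c)
        if rt.nested_in:
            _check_column(data, rt.nested_in)
            cols = [rt.nested_in] + cols
        Z, levels = _indicator(data, cols)
        if Z.shape[1] < 2:
            raise ValueError(f"random factor {rt.name!r} has a single level")
        blocks.append(PenalizedBlock(
            name=rt.name, Z=Z, basis_dim=Z.shape[1], n_null=0,
            col_names=[f"{rt.name}[{lev}]" for lev in levels]))

    for st in spec.smooths:
        for v in st.variables:
            _check_column(data, v)
        if st.kind == "tensor2d":
            x = data[st.variables[0]].to_numpy(float)
            y = data[st.variables[1]].to_numpy(float)
            Z0, P = tensor_spline(x, y, st.k)
        else:
            cells = data[st.variables[0]]
            adj = {str(k): {str(w) for w in v} for k, v in st.adjacency.items()}
            nodes = sorted(adj)
            arr = cells.astype(str).to_numpy()
            unknown = set(arr) - set(nodes)
            if unknown:
                raise ValueError(f"mrf cells absent from adjacency: {sorted(unknown)[:5]}")
            Z0 = np.zeros((n, len(nodes)))
            node_ix = {v: j for j, v in enumerate(nodes)}
            Z0[np.arange(n), [node_ix[a] for a in arr]] = 1.0
            P = mrf_penalty(nodes, adj)

        # eigen-reparametrize: range -> identity-penalized block, null -> fixed
        evals, evecs = np.linalg.eigh(P)
        tol = max(evals.max(), 1.0) * 1e-9
        rng = evals > tol
        Ur = evecs[:, rng] / np.sqrt(evals[rng])
        U0 = evecs[:, ~rng]

        if st.by is None:
            reps = [(None, np.ones(n))]
        else:
            _check_column(data, st.by)
            byv = data[st.by].astype(str).to_numpy()
            reps = [(lev, (byv == lev).astype(float)) for lev in sorted(set(byv))]

        Zr_parts, zr_names = [], []
        for lev, w in reps:
            suff = f"[{lev}]" if lev is not None else ""
            Zr_parts.append((Z0 * w[:, None]) @ Ur)
            zr_names += [f"{st.name}{suff}.r{i}" for i in range(Ur.shape[1])]
            Znull = (Z0 * w[:, None]) @ U0
            for i in range(Znull.shape[1]):
                x_cols.append(Znull[:, i])
                x_names.append(f"{st.name}{suff}.null{i}")
                x_terms.append(st.name)
        blocks.append(PenalizedBlock(
            name=st.name, Z=np.hstack(Zr_parts),
            basis_dim=Z0.shape[1] * len(reps),
            n_null=U0.shape[1] * len(reps), col_names=zr_names))

    X = np.column_stack(x_cols)
    X, x_names, x_terms, dropped = _drop_aliased(X, x_names, x_terms)
    return DesignBundle(X=X, x_names=x_names, x_terms=x_terms, blocks=blocks,
                        dropped=dropped, spec=spec, n_obs=n)


def response_vector(spec: ModelSpec, data: pd.DataFrame) -> np.ndarray:
    """Response on the model (possibly log) scale."""
    _check_column(data, spec.response)
    y = data[spec.response].to_numpy(float)
    if spec.log_transform:
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive response")
        y = np.log(y)
    return y


# ---------------------------------------------------------------------------
# REML fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted penalized mixed model.

    ``components`` holds the per-observation contribution of every term (the
    columns sum to the fitted values; plus ``residual`` they reproduce the
    transformed response exactly).  ``variance_params`` maps each block to
    its variance on the response scale, plus ``"residual"``; smoothing
    parameters are the ratios ``residual / block variance``.
    """

    coefficients: pd.DataFrame
    components: pd.DataFrame
    variance_params: dict
    lambdas: dict
    edf: dict
    reml_loglik: float
    loglik: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    design: DesignBundle = dataclasses.field(repr=False)
    beta_full: np.ndarray = dataclasses.field(repr=False, default=None)
    y: np.ndarray = dataclasses.field(repr=False, default=None)
    cov_fixed: np.ndarray = dataclasses.field(repr=False, default=None)

    @property
    def fitted(self) -> np.ndarray:
        cols = [c for c in self.components.columns if c != "residual"]
        return self.components[cols].to_numpy().sum(axis=1)

    @property
    def residuals(self) -> np.ndarray:
        return self.components["residual"].to_numpy()

    def coefficients_tsv(self, path) -> None:
        self.coefficients.to_csv(path, sep="\t", index=False)

    def components_tsv(self, path) -> None:
        self.components.to_csv(path, sep="\t", index=False)


def _assemble(design: DesignBundle):
    C = np.hstack([design.X] + [b.Z for b in design.blocks]) if design.blocks else design.X
    slices, start = [], design.p
    for b in design.blocks:
        slices.append(slice(start, start + b.q))
        start += b.q
    return C, slices


class _REMLWork:
    """Cached cross-products for repeated restricted-likelihood evaluations."""

    def __init__(self, design: DesignBundle, y: np.ndarray):
        y = np.asarray(y, float)
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        if len(y) != design.n_obs:
            raise ValueError("response length does not match design")
        if len(y) <= design.p:
            raise ValueError("fewer observations than fixed-effect columns")
        self.design = design
        self.y = y
        self.C, self.slices = _assemble(design)
        self.G = self.C.T @ self.C
        self.cy = self.C.T @ y
        self.yty = float(y @ y)
        self.n = len(y)
        self.p = design.p
        self.qs = [b.q for b in design.blocks]

    def solve(self, loglams: np.ndarray):
        M = self.G.copy()
        d = M.shape[0]
        idx = np.arange(d)
        for s, ll in zip(self.slices, loglams):
            M[idx[s], idx[s]] += np.exp(min(ll, 690.0))
        M[idx, idx] += _RIDGE_GUARD * (1.0 + np.abs(M[idx, idx]))
        try:
            L = sla.cholesky(M, lower=True, check_finite=False)
        except sla.LinAlgError:
            return None
        b = sla.cho_solve((L, True), self.cy, check_finite=False)
        rss = max(self.yty - float(b @ self.cy), 1e-300)
        logdetM = 2.0 * float(np.log(np.diag(L)).sum())
        return L, b, rss, logdetM

    def neg2_reml(self, loglams: np.ndarray) -> float:
        out = self.solve(loglams)
        if out is None:
            return np.inf
        _, _, rss, logdetM = out
        npp = self.n - self.p
        s2 = rss / npp
        val = npp * (np.log(2 * np.pi * s2) + 1.0) + logdetM
        for q, ll in zip(self.qs, loglams):
            val -= q * ll
        return float(val)


def _default_optimizer(n_blocks: int, big: bool) -> dict:
    if big:
        return {"grid": np.logspace(-4, 4, 13), "sweeps": 1,
                "nm": {"maxfev": 40 * max(n_blocks, 1), "xatol": 5e-3, "fatol": 1e-3}}
    return {"grid": np.logspace(-4, 4, 25), "sweeps": 2,
            "nm": {"maxfev": 400 * max(n_blocks, 1), "xatol": 1e-9, "fatol": 1e-12}}


def fit_reml(design: DesignBundle, y: np.ndarray, *,
             fixed_lambdas: Optional[dict] = None,
             optimizer: Optional[dict] = None) -> FitResult:
    """Fit the model by REML.

    ``fixed_lambdas`` pins named blocks' smoothing parameters (ratio
    ``sigma2_e / sigma2_block``) instead of estimating them.  The optimizer
    is deterministic: a coordinate sweep over a log-spaced lambda grid
    followed by Nelder--Mead refinement of the free log-lambdas.
    """
    work = _REMLWork(design, y)
    k = len(design.blocks)
    fixed_lambdas = fixed_lambdas or {}
    names = [b.name for b in design.blocks]
    for nm in fixed_lambdas:
        if nm not in names:
            raise KeyError(f"fixed lambda for unknown block {nm!r}")
    free = [i for i, nm in enumerate(names) if nm not in fixed_lambdas]

    loglams = np.zeros(k)
    for i, nm in enumerate(names):
        if nm in fixed_lambdas:
            loglams[i] = np.log(fixed_lambdas[nm])

    converged = True
    if free:
        big = work.G.shape[0] > 600
        opts = _default_optimizer(len(free), big)
        if optimizer:
            opts = {**opts, **optimizer}
        grid = np.log(np.asarray(opts["grid"], float))
        for _ in range(int(opts["sweeps"])):
            for i in free:
                vals = []
                for g in grid:
                    trial = loglams.copy()
                    trial[i] = g
                    vals.append(work.neg2_reml(trial))
                loglams[i] = grid[int(np.argmin(vals))]

        def obj(z):
            trial = loglams.copy()
            trial[free] = z
            return work.neg2_reml(trial)

        res = optimize.minimize(obj, loglams[free], method="Nelder-Mead",
                                options={**opts["nm"], "maxiter": 10 * opts["nm"]["maxfev"]})
        loglams[free] = res.x
        converged = bool(np.isfinite(res.fun))

    out = work.solve(loglams)
    if out is None:
        raise FloatingPointError("restricted likelihood not evaluable at optimum")
    L, beta, rss, logdetM = out
    n, p = work.n, work.p
    s2 = rss / (n - p)
    neg2_reml = work.neg2_reml(loglams)

    # covariance of all coefficients (Bayesian): s2 * M^-1
    Minv = sla.cho_solve((L, True), np.eye(work.G.shape[0]), check_finite=False)
    se_all = np.sqrt(np.maximum(np.diag(Minv), 0.0) * s2)

    # effective degrees of freedom: diag of M^-1 C'C
    edf_col = np.einsum("ij,ji->i", Minv, work.G)
    edf = {}
    for t in dict.fromkeys(design.x_terms):
        cols = [j for j, tt in enumerate(design.x_terms) if tt == t]
        edf[t] = float(sum(edf_col[j] for j in cols))
    for b, s in zip(design.blocks, work.slices):
        edf[b.name] = edf.get(b.name, 0.0) + float(edf_col[s].sum())
    edf_total = float(edf_col.sum())

    zval = np.divide(beta[:p], se_all[:p], out=np.full(p, np.nan), where=se_all[:p] > 0)
    coefficients = pd.DataFrame({
        "term": design.x_terms,
        "name": design.x_names,
        "estimate": beta[:p],
        "se": se_all[:p],
        "z": zval,
        "p": 2 * stats.norm.sf(np.abs(zval)),
    })

    # per-term component predictions (exact decomposition of fitted values)
    comp = {}
    for t in dict.fromkeys(design.x_terms):
        cols = [j for j, tt in enumerate(design.x_terms) if tt == t]
        comp[t] = design.X[:, cols] @ beta[cols]
    for b, s in zip(design.blocks, work.slices):
        contrib = work.C[:, s] @ beta[s]
        comp[b.name] = comp.get(b.name, 0.0) + contrib
    components = pd.DataFrame(comp)
    components["residual"] = work.y - components.to_numpy().sum(axis=1)

    lambdas = {nm: float(np.exp(min(ll, 690.0))) for nm, ll in zip(names, loglams)}
    variance_params = {"residual": float(s2)}
    for nm in names:
        variance_params[nm] = float(s2 / lambdas[nm])

    # marginal (ML) log-likelihood for information criteria
    if k:
        q0 = design.p
        Mzz_logdet = None
        Mz = work.G[q0:, q0:].copy()
        idxz = np.arange(Mz.shape[0])
        off = 0
        for b, ll in zip(design.blocks, loglams):
            Mz[idxz[off:off + b.q], idxz[off:off + b.q]] += np.exp(min(ll, 690.0))
            off += b.q
        Lz = sla.cholesky(Mz, lower=True, check_finite=False)
        Mzz_logdet = 2.0 * float(np.log(np.diag(Lz)).sum())
        logdet_V0 = Mzz_logdet - float(sum(q * ll for q, ll in zip(work.qs, loglams)))
    else:
        logdet_V0 = 0.0
    s2_ml = rss / n
    neg2_ml = n * (np.log(2 * np.pi * s2_ml) + 1.0) + logdet_V0
    # marginal-likelihood complexity: random effects are integrated out, so
    # the parameter count is fixed coefficients + variance parameters (one
    # per block, plus the residual); edf is reported per term separately
    df = p + k + 1
    aic = neg2_ml + 2 * df
    bic = neg2_ml + np.log(n) * df

    beta_full = beta
    return FitResult(
        coefficients=coefficients, components=components,
        variance_params=variance_params, lambdas=lambdas, edf=edf,
        reml_loglik=-0.5 * neg2_reml, loglik=-0.5 * neg2_ml,
        aic=float(aic), bic=float(bic), n_obs=n, converged=converged,
        design=design, beta_full=beta_full, y=work.y,
        cov_fixed=s2 * Minv[:p, :p])


def information_criteria(fit: FitResult) -> tuple:
    """(AIC, BIC) of a fitted model, from the marginal Gaussian likelihood
    with effective-degrees-of-freedom complexity; BIC uses log(n_obs)."""
    return fit.aic, fit.bic
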