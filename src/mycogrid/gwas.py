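"""Kinship mixed-model association and windowed QTL cluster calling.

Single-SNP association uses the classical efficient mixed-model scheme: the
phenotype covariance is ``sigma2_g K + sigma2_e I`` with a genomic
relationship matrix ``K``; one eigendecomposition of ``K`` rotates the
problem so the restricted likelihood is a cheap one-dimensional function of
``delta = sigma2_e / sigma2_g``, optimized on a log grid with local
refinement.  Per-SNP tests then reuse the null-model ``delta`` (the
population-parameters-previously-determined approximation) in a
generalized-least-squares F test on 1 df; an exact per-SNP REML mode is
available for cross-checking at small scale.

QTLs are clusters of associated SNPs: single-linkage groups of supporting
SNPs (p < 1e-3) within 200 kb of each other on one chromosome that contain
at least one seed SNP (p < 1e-4 and MAF > 5%) and at least two SNPs in
total; singletons are never QTLs.  The candidate window extends 200 kb
either side of the cluster's most significant SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GenotypeMatrix", "QTL",
    "compute_maf", "compute_kinship", "emma_null", "snp_scan",
    "bh_adjust", "call_qtls", "read_genotype_tsv", "read_vcf",
]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic dosages for a panel of (largely inbred) accessions.

    ``dosages`` is (n_accessions, n_snps) with values 0/1/2 and NaN for
    missing calls.  Positions are 1-based bp, sorted within chromosome.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray
    samples: list

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, float)
        if self.dosages.shape != (len(self.samples), len(self.snp_ids)):
            raise ValueError("dosage matrix shape mismatch")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            self.snp_ids = self.snp_ids[order]
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.dosages = self.dosages[:, order]
        d = self.dosages
        bad = np.isfinite(d) & ~np.isin(d, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_samples(self, names) -> "GenotypeMatrix":
        """Restrict to the given accessions (order preserved as given)."""
        ix = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in ix]
        if missing:
            raise KeyError(f"unknown accessions: {missing[:5]}")
        rows = [ix[n] for n in names]
        return GenotypeMatrix(snp_ids=self.snp_ids, chrom=self.chrom, pos=self.pos,
                              dosages=self.dosages[rows], samples=list(names))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages.T, columns=self.samples)
        df.insert(0, "pos", self.pos)
        df.insert(0, "chrom", self.chrom)
        df.insert(0, "snp", self.snp_ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Plain matrix: columns snp, chrom, pos, then one column per accession."""
    df = pd.read_csv(path, sep="\t")
    for c in ("snp", "chrom", "pos"):
        if c not in df.columns:
            raise ValueError(f"genotype table missing column {c!r}")
    samples = [c for c in df.columns if c not in ("snp", "chrom", "pos")]
    return GenotypeMatrix(
        snp_ids=df["snp"].to_numpy(), chrom=df["chrom"].to_numpy().astype(str),
        pos=df["pos"].to_numpy(), dosages=df[samples].to_numpy(float).T,
        samples=samples)


def read_vcf(path) -> GenotypeMatrix:
    """Load biallelic records from a VCF; dosage = alt-allele count from GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            continue
        gt = np.array(v.gt_types, float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        chroms.append(str(v.CHROM))
        poss.append(v.POS)
        rows.append(dos)
    return GenotypeMatrix(snp_ids=np.array(ids), chrom=np.array(chroms),
                          pos=np.array(poss), dosages=np.array(rows).T,
                          samples=samples)


# ---------------------------------------------------------------------------
# per-SNP statistics
# ---------------------------------------------------------------------------

def compute_maf(dosages) -> float:
    """Minor allele frequency of one SNP: min(f, 1-f), f = mean(dosage)/2."""
    d = np.asarray(dosages, float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("all calls missing")
    f = d.mean() / 2.0
    return float(min(f, 1.0 - f))


def compute_kinship(G: GenotypeMatrix, method: str = "vanraden",
                    jitter: float = 1e-6) -> np.ndarray:
    """Genomic relationship matrix over accessions.

    ``vanraden``: centered/scaled GRM, W W' / (2 sum p(1-p)) with W the
    2p-centered dosages, then normalized so the diagonal averages 1.
    ``ibs``: mean allele-sharing proportion.  Monomorphic SNPs are excluded;
    missing dosages are mean-imputed per SNP.  A small diagonal jitter
    guarantees positive semi-definiteness.
    """
    D = G.dosages.copy()
    mu = np.nanmean(D, axis=0)
    inds = np.where(np.isnan(D))
    D[inds] = np.take(mu, inds[1])
    p = mu / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    D = D[:, poly]
    p = p[poly]
    if method == "vanraden":
        W = D - 2 * p
        K = W @ W.T / (2.0 * np.sum(p * (1 - p)))
    elif method == "ibs":
        # allele-sharing: 1 - |d_i - d_j| / 2 averaged over SNPs
        n = D.shape[0]
        K = np.empty((n, n))
        for i in range(n):
            K[i] = 1.0 - np.abs(D - D[i]).mean(axis=1) / 2.0
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    K = (K + K.T) / 2.0
    K += jitter * np.eye(K.shape[0])
    K /= np.mean(np.diag(K))
    return K


@dataclass
class EmmaNull:
    delta: float          # sigma2_e / sigma2_g
    sigma2_g: float
    sigma2_e: float
    reml_loglik: float
    eigvals: np.ndarray = field(repr=False)
    eigvecs: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)


def _reml_delta(log_delta, d, yt, Xt):
    """-2 restricted loglik for V = sigma2_g (K + delta I), profiled."""
    delta = np.exp(log_delta)
    w = d + delta
    if np.any(w <= 0):
        return np.inf
    n, p = Xt.shape
    Wi = 1.0 / w
    XtWX = Xt.T @ (Xt * Wi[:, None])
    try:
        c = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError:
        return np.inf
    beta = np.linalg.solve(XtWX, Xt.T @ (yt * Wi))
    r = yt - Xt @ beta
    quad = float(np.sum(r * r * Wi))
    s2g = quad / (n - p)
    val = ((n - p) * (np.log(2 * np.pi * s2g) + 1.0) + np.sum(np.log(w))
           + 2.0 * np.sum(np.log(np.diag(c))))
    return float(val)


def emma_null(y, X_cov, K) -> EmmaNull:
    """Null-model REML fit of the kinship mixed model.

    One eigendecomposition of ``K`` diagonalizes the covariance; the ratio
    ``delta`` is optimized on a log-spaced grid (1e-5..1e5) followed by
    bounded Brent refinement around the best grid point.  Deterministic.
    """
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values; "
                         "drop unphenotyped accessions first")
    K = np.asarray(K, float)
    X = np.atleast_2d(np.asarray(X_cov, float))
    if X.shape[0] != len(y):
        X = X.T
    if K.shape != (len(y), len(y)):
        raise ValueError("K must be n x n matching y")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    grid = np.log(np.logspace(-5, 5, 61))
    vals = [_reml_delta(g, d, yt, Xt) for g in grid]
    if not np.any(np.isfinite(vals)):
        raise FloatingPointError("restricted likelihood non-finite on entire grid")
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(_reml_delta, bounds=(lo, hi), method="bounded",
                                   args=(d, yt, Xt),
                                   options={"xatol": 1e-8})
    log_delta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    neg2 = _reml_delta(log_delta, d, yt, Xt)
    delta = float(np.exp(log_delta))
    n, p = Xt.shape
    Wi = 1.0 / (d + delta)
    XtWX = Xt.T @ (Xt * Wi[:, None])
    beta = np.linalg.solve(XtWX, Xt.T @ (yt * Wi))
    r = yt - Xt @ beta
    s2g = float(np.sum(r * r * Wi)) / (n - p)
    return EmmaNull(delta=delta, sigma2_g=s2g, sigma2_e=s2g * delta,
                    reml_loglik=-0.5 * neg2, eigvals=d, eigvecs=U, X=X, y=y)


def _scan_p3d(null: EmmaNull, G: GenotypeMatrix, usable):
    """Vectorized GLS F tests at the null-model delta."""
    d, U = null.eigvals, null.eigvecs
    w = np.sqrt(1.0 / (d + null.delta))
    yt = (U.T @ null.y) * w
    Xt = (U.T @ null.X) * w[:, None]
    D = G.dosages.copy()
    mu = np.nanmean(D, axis=0)
    ix = np.where(np.isnan(D))
    D[ix] = np.take(mu, ix[1])
    Gt = (U.T @ D) * w[:, None]
    # residualize on covariates
    Q, _ = np.linalg.qr(Xt)
    y_r = yt - Q @ (Q.T @ yt)
    G_r = Gt - Q @ (Q.T @ Gt)
    n, p = Xt.shape
    gg = np.einsum("ij,ij->j", G_r, G_r)
    gy = G_r.T @ y_r
    rss0 = float(y_r @ y_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss1 = rss0 - beta * gy
        df2 = n - p - 1
        F = (rss0 - rss1) / (rss1 / df2)
    pvals = stats.f.sf(F, 1, df2)
    pvals = np.where(gg > 1e-12, pvals, np.nan)
    beta = np.where(gg > 1e-12, beta, np.nan)
    return beta, pvals


def _scan_exact(y, X, K, G: GenotypeMatrix, usable):
    """Per-SNP REML re-optimization (slow; small-scale cross-check)."""
    betas = np.full(G.n_snps, np.nan)
    pvals = np.full(G.n_snps, np.nan)
    D = G.dosages
    for j in range(G.n_snps):
        if not usable[j]:
            continue
        g = D[:, j].copy()
        m = np.isnan(g)
        if m.any():
            g[m] = np.nanmean(g)
        if np.var(g) < 1e-12:
            continue
        Xa = np.column_stack([X, g])
        null = emma_null(y, Xa, K)
        d, U = null.eigvals, null.eigvecs
        w = 1.0 / (d + null.delta)
        Xt = (U.T @ Xa) * np.sqrt(w)[:, None]
        yt = (U.T @ y) * np.sqrt(w)
        XtX = Xt.T @ Xt
        beta = np.linalg.solve(XtX, Xt.T @ yt)
        cov = np.linalg.inv(XtX) * null.sigma2_g
        se = np.sqrt(cov[-1, -1])
        t = beta[-1] / se
        df = len(y) - Xa.shape[1]
        pvals[j] = 2 * stats.t.sf(abs(t), df)
        betas[j] = beta[-1]
    return betas, pvals


def snp_scan(y, X_cov, G: GenotypeMatrix, K=None, maf_min: float = 0.05,
             min_call_rate: float = 0.5, method: str = "p3d") -> pd.DataFrame:
    """Association scan over all SNPs.

    Returns a frame with snp, chrom, pos, maf, n_used, effect, p.  SNPs with
    MAF <= ``maf_min`` (strict filter) or call rate below ``min_call_rate``
    get NaN statistics.  ``method="exact"`` re-optimizes the variance ratio
    per SNP instead of reusing the null-model fit.
    """
    y = np.asarray(y, float)
    if K is None:
        K = compute_kinship(G)
    X = np.atleast_2d(np.asarray(X_cov, float))
    if X.shape[0] != len(y):
        X = X.T

    D = G.dosages
    n_called = np.sum(np.isfinite(D), axis=0)
    with np.errstate(invalid="ignore"):
        f = np.nanmean(D, axis=0) / 2.0
    maf = np.minimum(f, 1 - f)
    usable = (n_called >= min_call_rate * G.n_samples) & (maf > maf_min)

    null = emma_null(y, X, K)
    if method == "p3d":
        beta, pvals = _scan_p3d(null, G, usable)
    elif method == "exact":
        beta, pvals = _scan_exact(y, X, K, G, usable)
    else:
        raise ValueError(f"unknown scan method {method!r}")
    beta = np.where(usable, beta, np.nan)
    pvals = np.where(usable, pvals, np.nan)
    return pd.DataFrame({
        "snp": G.snp_ids, "chrom": G.chrom, "pos": G.pos,
        "maf": maf, "n_used": n_called, "effect": beta, "p": pvals})


# ---------------------------------------------------------------------------
# multiple testing and QTL calling
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvals, float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


@dataclass
class QTL:
    """A called SNP cluster with its candidate window."""

    qtl_id: str
    chrom: str
    members: pd.DataFrame
    top_snp: str
    top_pos: int
    top_p: float
    top_maf: float
    top_effect: float
    window: tuple  # (start, end), clipped at 1

    @property
    def n_members(self) -> int:
        return len(self.members)


def cluster_positions(pos: Sequence[int], window: int = 200_000) -> list:
    """Single-linkage clusters of sorted positions with gap <= window.

    Returns a list of index arrays into the *sorted* position order.
    """
    pos = np.asarray(pos, dtype=np.int64)
    order = np.argsort(pos, kind="mergesort")
    sp = pos[order]
    clusters, current = [], [0]
    for i in range(1, len(sp)):
        if sp[i] - sp[i - 1] <= window:
            current.append(i)
        else:
            clusters.append(order[current])
            current = [i]
    if len(sp):
        clusters.append(order[current])
    return clusters


def call_qtls(results: pd.DataFrame, seed_p: float = 1e-4, support_p: float = 1e-3,
              maf_min: float = 0.05, window: int = 200_000) -> list:
    """Call QTLs from a per-SNP association table.

    Support SNPs (p < ``support_p``) are single-linkage clustered per
    chromosome at gap <= ``window``; a cluster is a QTL iff it holds >= 2
    SNPs and >= 1 seed SNP (p < ``seed_p`` and MAF > ``maf_min``).  The top
    SNP minimizes p (ties broken toward the smallest bp) and defines the
    +/- ``window`` candidate interval, clipped at position 1.  Deterministic
    and invariant to input row order.
    """
    req = {"snp", "chrom", "pos", "p", "maf", "effect"}
    missing = req - set(results.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    df = results.dropna(subset=["p"])
    df = df[df["p"] < support_p]
    df = df.sort_values(["chrom", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    qtls = []
    for chrom in pd.unique(df["chrom"]):
        sub = df[df["chrom"] == chrom].reset_index(drop=True)
        idx_clusters = cluster_positions(sub["pos"].to_numpy(), window)
        count = 0
        for idx in idx_clusters:
            members = sub.iloc[np.sort(idx)].reset_index(drop=True)
            if len(members) < 2:
                continue
            is_seed = (members["p"] < seed_p) & (members["maf"] > maf_min)
            if not is_seed.any():
                continue
            count += 1
            top = members.sort_values(["p", "pos"], kind="mergesort").iloc[0]
            qtls.append(QTL(
                qtl_id=f"{chrom}.{count}", chrom=str(chrom), members=members,
                top_snp=str(top["snp"]), top_pos=int(top["pos"]),
                top_p=float(top["p"]), top_maf=float(top["maf"]),
                top_effect=float(top["effect"]),
                window=(max(int(top["pos"]) - window, 1), int(top["pos"]) + window)))
    return qtls


def qtls_to_frame(qtls: list) -> pd.DataFrame:
    rows = [{
        "qtl": q.qtl_id, "chrom": q.chrom, "top_snp": q.top_snp,
        "top_pos": q.top_pos, "top_p": q.top_p, "top_maf": q.top_maf,
        "top_effect": q.top_effect, "n_members": q.n_members,
        "window_start": q.window[0], "window_end": q.window[1],
    } for q in qtls]
    return pd.DataFrame(rows, columns=["qtl", "chrom", "top_snp", "top_pos", "top_p",
                                       "top_maf", "top_effect", "n_members",
                                       "window_start", "window_end"])
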