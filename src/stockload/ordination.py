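"""Constrained and unconstrained ordination: PCoA, PCA with broken-stick
retention, (partial) redundancy analysis with permutation inference, forward
model selection, collinearity diagnostics, per-population imputation, and a
DAPC-style cluster/membership analysis.

RDA here is multivariate least squares of a centered response on centered
predictors; R**2 is the fraction of total response variance captured by the
fitted values, adjusted with the Ezekiel correction, and significance comes
from permutation of response rows (or of reduced-model residuals for partial
models).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_io import MISSING, Genotypes

__all__ = [
    "PcoaResult", "PcaResult", "RdaResult", "QMatrix",
    "pcoa", "hellinger_stocking", "broken_stick", "pca_broken_stick",
    "rda", "partial_rda", "permutation_anova", "forward_select", "vif",
    "impute_by_population", "dapc",
]


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    scores: np.ndarray            # sites x positive axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray       # all eigenvalues, descending (negatives included)
    proportions: np.ndarray       # over positive eigenvalues only, sums to 1
    retained: np.ndarray          # boolean mask over positive axes

    def retained_scores(self) -> np.ndarray:
        return self.scores[:, self.retained]


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d: np.ndarray, min_axis_var: float = 0.05) -> PcoaResult:
    """Principal coordinates of a symmetric distance matrix.

    Negative eigenvalues are reported but excluded from the variance
    proportions; axes whose proportion is at least ``min_axis_var`` are
    flagged retained.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    g = _gower_center(d)
    w, v = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    tol = 1e-9 * max(abs(w).max(), 1e-30)
    pos = w > tol
    scores = v[:, pos] * np.sqrt(w[pos])
    total = w[pos].sum()
    props = w[pos] / total if total > 0 else np.zeros(pos.sum())
    return PcoaResult(scores, w, props, props >= min_axis_var)


# ---------------------------------------------------------------------------
# Stocking-matrix preparation
# ---------------------------------------------------------------------------

def hellinger_stocking(stocking: pd.DataFrame, lakes: pd.DataFrame) -> pd.DataFrame:
    """Area-normalize then Hellinger-transform the sink x source mass matrix.

    Each row is divided by the sink lake's surface (hectares) — stocking
    density, not raw mass, measures pressure — then mapped to
    sqrt(value / row sum).  All-zero rows (never-stocked lakes) stay zero.
    """
    if (stocking.values < 0).any():
        raise ValueError("stocking masses must be non-negative")
    areas = lakes.loc[stocking.index, "area_ha"].astype(float)
    dens = stocking.div(areas, axis=0)
    rs = dens.sum(axis=1)
    out = dens.div(rs.where(rs > 0, 1.0), axis=0)
    return np.sqrt(out)


# ---------------------------------------------------------------------------
# PCA with broken-stick retention
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray          # columns: component loadings (unit norm)
    proportions: np.ndarray
    broken_stick: np.ndarray
    retained: np.ndarray          # boolean prefix mask

    def retained_scores(self) -> np.ndarray:
        return self.scores[:, self.retained]


def broken_stick(p: int) -> np.ndarray:
    """Expected eigenvalue proportions from random division of a unit stick:
    b_k = (1/p) * sum_{i=k..p} 1/i."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def pca_broken_stick(x) -> PcaResult:
    """Covariance PCA (centered, unscaled) with broken-stick axis retention.

    The retained set is the longest prefix of components whose observed
    variance proportion exceeds the broken-stick expectation.
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= 0:
        p = x.shape[1]
        return PcaResult(np.zeros_like(xc), vt.T, np.zeros(p),
                         broken_stick(p), np.zeros(len(s), dtype=bool))
    props = var / total
    bs = broken_stick(len(s))
    retained = np.zeros(len(s), dtype=bool)
    for k in range(len(s)):
        if props[k] >= bs[k] and props[k] > 0:
            retained[k] = True
        else:
            break
    return PcaResult(u * s, vt.T, props, bs, retained)


# ---------------------------------------------------------------------------
# RDA / partial RDA
# ---------------------------------------------------------------------------

@dataclass
class RdaResult:
    r2: float
    adj_r2: float
    F: float
    p: Optional[float]
    axis_scores: np.ndarray
    axis_eigenvalues: np.ndarray
    rank: int
    conditioned_r2: float = 0.0   # fraction removed by the conditioning block
    max_vif: Optional[float] = None
    dropped_columns: list = field(default_factory=list)


def _center(m) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    return m - m.mean(axis=0)


def _drop_collinear(x: np.ndarray, tol: float = 1e-10):
    """Greedily drop columns that are linear combinations of earlier ones."""
    keep, dropped = [], []
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(x).max())) > len(keep):
            keep.append(j)
        else:
            dropped.append(j)
    return keep, dropped


def _fit_r2(y: np.ndarray, x: np.ndarray):
    """Least-squares fit of centered y on centered x; returns fitted values,
    SS_fit, SS_total and the design rank."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    return fitted, float((fitted ** 2).sum()), float((y ** 2).sum()), \
        int(np.linalg.matrix_rank(x))


def rda(y, x, n_perm: int = 0, seed: int = 0) -> RdaResult:
    """Redundancy analysis of response ``y`` on predictors ``x``.

    With a univariate response this is exactly ordinary least squares (the
    R**2 coincide).  ``n_perm`` > 0 adds a permutation test of the global
    pseudo-F (rows of the response permuted).
    """
    yc = _center(y)
    xc = _center(x)
    if yc.shape[0] != xc.shape[0]:
        raise ValueError("response and predictors must have aligned rows")
    keep, dropped = _drop_collinear(xc)
    xc = xc[:, keep]
    fitted, ss_fit, ss_tot, m = _fit_r2(yc, xc)
    n = yc.shape[0]
    if n <= m + 1:
        raise ValueError("too few rows for the number of predictors")
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    nz = s > 1e-12 * max(s.max(), 1e-30)
    F = _pseudo_f(ss_fit, ss_tot - ss_fit, m, n - m - 1)
    res = RdaResult(r2, adj, F, None, u[:, nz] * s[nz], (s[nz] ** 2) / max(n - 1, 1),
                    m, max_vif=(max(vif(xc)) if xc.shape[1] >= 2 else None),
                    dropped_columns=dropped)
    if n_perm:
        res.p = permutation_anova(yc, xc, None, n_perm=n_perm, seed=seed)[1]
    return res


def partial_rda(y, x, z, n_perm: int = 0, seed: int = 0) -> RdaResult:
    """RDA of ``y`` on ``x`` after removing the variance explained by the
    conditioning block ``z``.

    The reported R**2 is semipartial: the fraction of the ORIGINAL response
    variance attributable to x beyond z, so on orthogonal designs
    R2(x|z) + R2(z) equals R2 of the joint model.
    """
    if z is None or (hasattr(z, "shape") and np.size(z) == 0):
        return rda(y, x, n_perm=n_perm, seed=seed)
    yc, xc, zc = _center(y), _center(x), _center(z)
    keepz, _ = _drop_collinear(zc)
    zc = zc[:, keepz]
    bz, *_ = np.linalg.lstsq(zc, yc, rcond=None)
    y_res = yc - zc @ bz
    bxz, *_ = np.linalg.lstsq(zc, xc, rcond=None)
    x_res = xc - zc @ bxz
    keep, dropped = _drop_collinear(x_res)
    ss_tot0 = float((yc ** 2).sum())
    if not keep:
        # conditioning block spans the predictors: zero partial variance
        r2_z = 1.0 - float((y_res ** 2).sum()) / ss_tot0 if ss_tot0 > 0 else 0.0
        return RdaResult(0.0, 0.0, 0.0, None, np.zeros((yc.shape[0], 0)),
                         np.zeros(0), 0, conditioned_r2=r2_z,
                         dropped_columns=dropped)
    x_res = x_res[:, keep]
    fitted, ss_fit, _, m = _fit_r2(y_res, x_res)
    ss_tot = float((yc ** 2).sum())
    q = int(np.linalg.matrix_rank(zc))
    n = yc.shape[0]
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    r2_z = 1.0 - float((y_res ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - q - 1) if n > m + q + 1 else np.nan
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    nz = s > 1e-12 * max(s.max(), 1e-30)
    ss_res = float((y_res ** 2).sum()) - ss_fit
    F = _pseudo_f(ss_fit, ss_res, m, n - m - q - 1)
    res = RdaResult(r2, adj, F, None, u[:, nz] * s[nz], (s[nz] ** 2) / max(n - 1, 1),
                    m, conditioned_r2=r2_z,
                    max_vif=(max(vif(x_res)) if x_res.shape[1] >= 2 else None),
                    dropped_columns=dropped)
    if n_perm:
        res.p = permutation_anova(yc, xc, zc, n_perm=n_perm, seed=seed)[1]
    return res


def _pseudo_f(ss_fit, ss_res, m, df_res):
    if ss_res <= 0 or df_res <= 0:
        return np.inf if ss_fit > 0 else 0.0
    return float((ss_fit / m) / (ss_res / df_res))


def permutation_anova(y, x, z=None, n_perm: int = 999, seed: int = 0):
    """Global permutation test of an RDA (or partial RDA) model.

    Simple models permute response rows; partial models permute the
    residuals of the conditioning-only model (reduced-model permutation).
    Returns ``(pseudo_F, p)`` with p = (exceedances + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    yc, xc = _center(y), _center(x)
    n = yc.shape[0]
    # canonical joint row order: the permutation distribution then does not
    # depend on how the caller happened to order the rows
    zc0 = None if z is None or np.size(z) == 0 else _center(z)
    key = np.hstack([yc, xc] + ([zc0] if zc0 is not None else []))
    order = np.lexsort(key.T[::-1])
    yc, xc = yc[order], xc[order]
    if zc0 is not None:
        zc0 = zc0[order]
        z = zc0
    if z is None or (hasattr(z, "shape") and np.size(z) == 0):
        keep, _ = _drop_collinear(xc)
        xc = xc[:, keep]
        _, ss_fit, ss_tot, m = _fit_r2(yc, xc)
        df_res = n - m - 1
        F_obs = _pseudo_f(ss_fit, ss_tot - ss_fit, m, df_res)
        count = 0
        for _ in range(n_perm):
            yp = yc[rng.permutation(n)]
            _, sf, st, _ = _fit_r2(yp, xc)
            if _pseudo_f(sf, st - sf, m, df_res) >= F_obs:
                count += 1
        return F_obs, (count + 1) / (n_perm + 1)
    zc = _center(z)
    keepz, _ = _drop_collinear(zc)
    zc = zc[:, keepz]
    q = int(np.linalg.matrix_rank(zc))
    bz, *_ = np.linalg.lstsq(zc, yc, rcond=None)
    fit_z = zc @ bz
    res_z = yc - fit_z
    bxz, *_ = np.linalg.lstsq(zc, xc, rcond=None)
    x_res = xc - zc @ bxz
    keep, _ = _drop_collinear(x_res)
    if not keep:
        raise ValueError("conditioning block spans the predictors")
    x_res = x_res[:, keep]

    def partial_f(resid):
        _, sf, st, m = _fit_r2(resid, x_res)
        return _pseudo_f(sf, st - sf, m, n - m - q - 1), m

    F_obs, m = partial_f(res_z)
    count = 0
    for _ in range(n_perm):
        resid_p = res_z[rng.permutation(n)]
        # re-residualize the permuted residuals on z (freedman-lane style)
        bzp, *_ = np.linalg.lstsq(zc, resid_p, rcond=None)
        f, _m = partial_f(resid_p - zc @ bzp)
        if f >= F_obs:
            count += 1
    return F_obs, (count + 1) / (n_perm + 1)


def forward_select(y, candidates: dict, alpha: float = 0.05,
                   n_perm: int = 999, seed: int = 0):
    """Greedy forward selection of named predictor blocks for an RDA.

    At each step every remaining candidate's partial pseudo-F (given the
    already-selected blocks) is computed, and the best candidate is tested
    against the permutation null of the MAXIMUM F across candidates
    (max-statistic test): one set of permutations is shared by all
    candidates, the largest permuted F is recorded each time, and the best
    observed candidate enters while
    ``p = (#{max-F >= F_obs} + 1) / (n_perm + 1) <= alpha``.  Testing the
    maximum keeps the per-step false-selection rate at ``alpha`` no matter
    how many candidates compete, without sacrificing power to a correction
    on granular permutation p-values.

    Returns ``(selected_names, log)``; the log records each step's winning
    candidate with its F and max-statistic p.
    """
    if not candidates:
        raise ValueError("no candidate blocks")
    cand = {k: _center(v) for k, v in candidates.items()}
    yc = _center(y)
    n = yc.shape[0]
    selected: list[str] = []
    log = []
    rng = np.random.default_rng(seed)

    def partial_f(y_res, x_res, q):
        _, sf, st, m = _fit_r2(y_res, x_res)
        return _pseudo_f(sf, st - sf, m, n - m - q - 1)

    while True:
        remaining = [k for k in cand if k not in selected]
        if not remaining:
            break
        if selected:
            zc = np.hstack([cand[s] for s in selected])
            keepz, _ = _drop_collinear(zc)
            zc = zc[:, keepz]
            q = int(np.linalg.matrix_rank(zc))
            bz, *_ = np.linalg.lstsq(zc, yc, rcond=None)
            y_res = yc - zc @ bz
        else:
            zc, q, y_res = None, 0, yc

        x_res = {}
        for name in remaining:
            xr = cand[name]
            if zc is not None:
                bx, *_ = np.linalg.lstsq(zc, xr, rcond=None)
                xr = xr - zc @ bx
            keep, _ = _drop_collinear(xr)
            if keep:
                x_res[name] = xr[:, keep]
        if not x_res:
            break
        f_obs = {name: partial_f(y_res, xr, q) for name, xr in x_res.items()}
        best = max(f_obs, key=lambda k: f_obs[k])

        exceed = 0
        for _ in range(n_perm):
            yp = y_res[rng.permutation(n)]
            if zc is not None:       # re-residualize (Freedman-Lane)
                bp, *_ = np.linalg.lstsq(zc, yp, rcond=None)
                yp = yp - zc @ bp
            max_f = max(partial_f(yp, xr, q) for xr in x_res.values())
            if max_f >= f_obs[best]:
                exceed += 1
        p_best = (exceed + 1) / (n_perm + 1)
        log.append({"step": len(selected) + 1, "candidate": best,
                    "F": f_obs[best], "p": p_best,
                    "competing": len(x_res)})
        if p_best > alpha:
            break
        selected.append(best)
    return selected, pd.DataFrame(log)


def vif(x) -> np.ndarray:
    """Variance inflation factor of each column regressed on the others."""
    x = _center(x)
    n, p = x.shape
    if p < 2:
        raise ValueError("VIF needs at least two columns")
    if n <= p:
        raise ValueError("VIF needs more rows than columns")
    out = np.empty(p)
    for j in range(p):
        yj = x[:, j]
        others = np.delete(x, j, axis=1)
        ssy = float((yj ** 2).sum())
        if ssy == 0:
            out[j] = np.nan
            continue
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        r2 = 1.0 - float(((yj - others @ beta) ** 2).sum()) / ssy
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# Imputation and DAPC
# ---------------------------------------------------------------------------

def impute_by_population(g: Genotypes, popmap) -> Genotypes:
    """Replace missing dosages by the within-lake modal dosage (ties go to
    the lower dosage); lake-locus cells with no calls fall back to the global
    mode."""
    pops = pd.Series(popmap).reindex(g.individual_ids)
    d = g.dosage.copy()

    def mode(col):
        vals = col[col != MISSING]
        if vals.size == 0:
            return None
        counts = np.bincount(vals, minlength=3)
        return int(np.argmax(counts))  # argmax takes the lowest on ties

    global_modes = np.array([
        (m if (m := mode(d[:, j])) is not None else 0) for j in range(d.shape[1])
    ], dtype=np.int8)
    for code in pops.unique():
        rows = np.flatnonzero((pops == code).values)
        block = d[rows, :]
        miss = block == MISSING
        if not miss.any():
            continue
        for j in np.flatnonzero(miss.any(axis=0)):
            m = mode(block[:, j])
            fill = global_modes[j] if m is None else m
            block[miss[:, j], j] = fill
        d[rows, :] = block
    from dataclasses import replace
    return replace(g, dosage=d)


@dataclass
class QMatrix:
    q: pd.DataFrame               # individuals x clusters, rows sum to 1
    k: int
    bic: pd.Series                # BIC per candidate K
    cluster_labels: np.ndarray
    n_pcs: int

    def by_population(self, popmap) -> pd.DataFrame:
        pops = pd.Series(popmap).reindex(self.q.index)
        return self.q.groupby(pops).mean()


def dapc(g: Genotypes, k_max: int = 30, n_pc: Optional[int] = None,
         seed: int = 0, pc_var: float = 0.90) -> QMatrix:
    """Cluster individuals on genotype principal components and return
    posterior group memberships (a DAPC-style Q matrix).

    K-means is run for K = 1..k_max on the retained PCs (20 restarts each);
    the number of clusters minimizes BIC(K) = n*ln(WSS_K/n) + K*ln(n).
    Posteriors come from linear discriminant analysis on the same PCs.
    """
    from sklearn.cluster import KMeans
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if (g.dosage == MISSING).any():
        raise ValueError("DAPC requires complete (imputed) genotypes")
    x = _center(g.dosage.astype(float))
    n = x.shape[0]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s ** 2
    if n_pc is None:
        cum = np.cumsum(var) / var.sum()
        n_pc = int(np.searchsorted(cum, pc_var) + 1)
        n_pc = max(1, min(n_pc, n // 3))
    pcs = (u * s)[:, :n_pc]
    k_max = min(k_max, n)
    bic = {}
    labels = {}
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((pcs - pcs.mean(axis=0)) ** 2).sum())
            lab = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(pcs)
            wss = float(km.inertia_)
            lab = km.labels_
        bic[k] = n * np.log(max(wss, 1e-12) / n) + k * np.log(n)
        labels[k] = lab
    bic = pd.Series(bic)
    # smallest K within 2 BIC units of the minimum (parsimony on the
    # near-flat tail of the BIC curve)
    k_best = int(bic.index[bic <= bic.min() + 2.0][0])
    lab = labels[k_best]
    if k_best == 1:
        q = pd.DataFrame(np.ones((n, 1)), index=g.individual_ids, columns=[0])
    else:
        lda = LinearDiscriminantAnalysis()
        lda.fit(pcs, lab)
        q = pd.DataFrame(lda.predict_proba(pcs), index=g.individual_ids,
                         columns=lda.classes_)
    return QMatrix(q, k_best, bic, lab, n_pc)
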