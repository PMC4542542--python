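"""Ordination and permutation inference.

Implements the analysis chain used to relate lineage relatedness to
environmental affinity:

* Bray–Curtis dissimilarity (equals Sørensen on presence/absence data),
* non-metric multidimensional scaling (NMDS) minimizing Kruskal stress-1
  by iterative majorization with a monotone-regression (isotonic) step,
* principal coordinates analysis (PCoA, Gower double-centering) with
  drop / Lingoes / Cailliez handling of negative eigenvalues,
* redundancy analysis (RDA) with permutation pseudo-F tests,
* distance-based RDA (dbRDA): RDA on the PCoA coordinates of an arbitrary
  dissimilarity matrix,
* greedy forward selection of explanatory variables with conditional
  permutation tests and a p < alpha stopping rule.

Permutation p-values use the add-one estimator
p = (1 + #{permuted statistic >= observed}) / (1 + n_perm) under row
permutation of the explanatory matrix, which is exact for exchangeable
nulls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import DegenerateInputError, InvalidArgumentError

_RANK_TOL = 1e-9


# ---------------------------------------------------------------------------
# Dissimilarities


def bray_curtis(matrix: pd.DataFrame, presence_absence: bool = True) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between the rows (samples) of a matrix.

    BC(s, t) = 1 − 2·Σ min(x_s, x_t) / Σ (x_s + x_t); on 0/1 data this is
    the Sørensen dissimilarity.  With ``presence_absence`` (default) the
    input is binarized first, matching an analysis convention of ignoring
    clone frequencies.  A pair of all-zero rows is defined as distance 0
    (with a warning).
    """
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise InvalidArgumentError("Bray-Curtis requires nonnegative entries")
    if presence_absence:
        x = (x > 0).astype(float)
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    empty = den == 0
    if empty.sum() > len(x):  # off-diagonal all-zero pairs
        warnings.warn("pairs of empty samples assigned distance 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.where(empty, 0.0, num / np.where(empty, 1.0, den))
    np.fill_diagonal(bc, 0.0)
    ids = list(matrix.index) if isinstance(matrix, pd.DataFrame) else None
    return DistanceMatrix(bc, ids=ids)


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    """Principal-coordinates decomposition of a dissimilarity matrix."""

    coordinates: np.ndarray  # n × k, axes scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    ids: list[str]
    negative_policy: str
    correction: float = 0.0  # Lingoes/Cailliez constant applied (0 if none)

    @property
    def positive_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues > 0]

    @property
    def total_inertia(self) -> float:
        return float(self.positive_eigenvalues.sum())


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(d: DistanceMatrix, negative_policy: str = "drop") -> PcoaResult:
    """Classical scaling (Gower centering + eigendecomposition).

    Non-Euclidean input (e.g. Bray–Curtis, patristic) can produce negative
    eigenvalues; ``negative_policy`` is one of ``drop`` (keep positive axes
    only), ``lingoes`` (add a constant to squared off-diagonal distances) or
    ``cailliez`` (add a constant to off-diagonal distances).
    """
    if negative_policy not in ("drop", "lingoes", "cailliez"):
        raise InvalidArgumentError(f"unknown negative_policy {negative_policy!r}")
    dmat = d.data.astype(float)
    n = dmat.shape[0]
    correction = 0.0
    g = _gower_center(dmat**2)
    vals = np.linalg.eigvalsh(g)
    if negative_policy == "lingoes" and vals[0] < -_RANK_TOL * max(1.0, abs(vals[-1])):
        correction = -vals[0]
        d2 = dmat**2 + 2 * correction
        np.fill_diagonal(d2, 0.0)
        g = _gower_center(d2)
    elif negative_policy == "cailliez" and vals[0] < -_RANK_TOL * max(1.0, abs(vals[-1])):
        delta1 = _gower_center(dmat**2)
        delta2 = _gower_center(dmat)
        block = np.block(
            [[np.zeros((n, n)), 2 * delta1], [-np.eye(n), -4 * delta2]]
        )
        correction = float(np.max(np.linalg.eigvals(block).real))
        dc = dmat + correction
        np.fill_diagonal(dc, 0.0)
        g = _gower_center(dc**2)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * _RANK_TOL
    pos = eigval > tol
    if not pos.any():
        raise DegenerateInputError("no positive eigenvalues: degenerate distance matrix")
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    return PcoaResult(coords, eigval, list(d.ids), negative_policy, correction)


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class NmdsResult:
    """Best-of-starts NMDS configuration with Kruskal stress-1."""

    coordinates: np.ndarray
    stress: float
    n_starts: int
    best_start: int
    converged: bool
    ids: list[str] | None = None


def _stress_and_disparities(dissim: np.ndarray, conf_d: np.ndarray) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and the monotone (primary-ties) disparities."""
    order = np.lexsort((conf_d, dissim))
    iso = IsotonicRegression(increasing=True)
    dhat = np.empty_like(conf_d)
    dhat[order] = iso.fit_transform(np.arange(len(order)), conf_d[order])
    denom = float((conf_d**2).sum())
    if denom <= 0:
        return 1.0, dhat
    stress = float(np.sqrt(((conf_d - dhat) ** 2).sum() / denom))
    return stress, dhat


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> NmdsResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    One start is the PCoA configuration; the remainder are random.  Each
    start alternates isotonic (monotone) regression of configuration
    distances on the dissimilarity ranks with a Guttman-transform update,
    until the stress change falls below ``tol``.  The lowest-stress
    configuration is returned, centered and rotated to principal axes.
    """
    n = d.shape[0]
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if n < k + 1:
        raise InvalidArgumentError(f"need at least k+1={k + 1} objects, got {n}")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    dissim = d.data[iu]
    best = None
    for start in range(n_starts):
        if start == 0:
            try:
                pc = pcoa(d, "lingoes").coordinates
            except DegenerateInputError:
                pc = rng.standard_normal((n, k))
            x = np.zeros((n, k))
            m = min(k, pc.shape[1])
            x[:, :m] = pc[:, :m]
            if m < k:
                x[:, m:] = rng.standard_normal((n, k - m)) * 1e-3
        else:
            x = rng.standard_normal((n, k))
        converged = False
        prev_stress = np.inf
        stress = 1.0
        for _ in range(max_iter):
            conf = squareform(pdist(x))
            conf_d = conf[iu]
            stress, dhat = _stress_and_disparities(dissim, conf_d)
            if prev_stress - stress < tol:
                converged = prev_stress - stress > -tol
                break
            prev_stress = stress
            # Guttman transform with disparities dhat
            dh = np.zeros((n, n))
            dh[iu] = dhat
            dh = dh + dh.T
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(conf > 0, dh / np.where(conf > 0, conf, 1.0), 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = (b @ x) / n
        if best is None or stress < best[0]:
            best = (stress, x, start, converged)
    stress, x, start, converged = best
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    if not converged:
        warnings.warn("NMDS did not converge in any start", stacklevel=2)
    return NmdsResult(x, stress, n_starts, start, converged, list(d.ids))


# ---------------------------------------------------------------------------
# Design matrices


def dummy_code(
    sample_table: pd.DataFrame,
    column: str,
    drop_reference: bool = True,
    reference=None,
) -> pd.DataFrame:
    """0/1 indicator columns for a categorical variable.

    With ``drop_reference`` (default) the reference level (first level in
    order of appearance, or ``reference``) is dropped for a full-rank model
    matrix.  Constrained-model fits are invariant to which level is dropped.
    """
    if column not in sample_table.columns:
        raise InvalidArgumentError(f"no column {column!r}")
    values = sample_table[column]
    levels = list(pd.unique(values))
    if len(levels) < 2:
        raise InvalidArgumentError(f"column {column!r} has a single level")
    if drop_reference:
        ref = levels[0] if reference is None else reference
        if ref not in levels:
            raise InvalidArgumentError(f"reference {ref!r} not a level of {column!r}")
        levels = [l for l in levels if l != ref]
    out = pd.DataFrame(
        {f"{column}[{l}]": (values == l).astype(int).to_numpy() for l in levels},
        index=sample_table.index,
    )
    return out


# ---------------------------------------------------------------------------
# RDA / dbRDA


@dataclass
class ConstrainedOrdinationResult:
    """Fit statistics of a (distance-based) redundancy analysis."""

    r2: float
    adj_r2: float
    pseudo_f: float
    p_value: float
    n_perm: int
    rank: int
    n: int
    eigenvalues_constrained: np.ndarray
    eigenvalues_residual: np.ndarray
    explanatory: list[str] = field(default_factory=list)
    total_inertia: float = float("nan")
    dropped_axes: int = 0

    def row(self, data: str = "", explanatory_set: str = "") -> dict:
        """One report row: R2/adjR2/P as percentages and a p-value."""
        return {
            "data": data,
            "explanatory_set": explanatory_set,
            "selected": ", ".join(self.explanatory),
            "R2": round(100 * self.r2, 1),
            "adjR2": round(100 * self.adj_r2, 1),
            "P": self.p_value,
        }


def _as_matrix(x, name: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), [str(c) for c in x.columns]
    if isinstance(x, pd.Series):
        return x.to_numpy(dtype=float)[:, None], [str(x.name or name)]
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"{name}{i}" for i in range(arr.shape[1])]


def _orthonormal_basis(xc: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (SVD, rank-revealing)."""
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        return u[:, :0]
    keep = s > s[0] * _RANK_TOL
    return u[:, keep]


def rda(
    y,
    x,
    n_perm: int = 999,
    seed: int | None = None,
) -> ConstrainedOrdinationResult:
    """Redundancy analysis of a response matrix on explanatory variables.

    The response is column-centered; R² is the fraction of its total sum of
    squares captured by the projection onto the explanatory space (with
    intercept).  The permutation test permutes the rows of the explanatory
    matrix and compares R² (equivalently pseudo-F at fixed rank).
    """
    ymat, _ = _as_matrix(y, "y")
    xmat, xlabels = _as_matrix(x, "x")
    n = ymat.shape[0]
    if xmat.shape[0] != n:
        raise InvalidArgumentError("response and explanatory row counts differ")
    yc = ymat - ymat.mean(axis=0)
    total = float((yc**2).sum())
    if total <= 0:
        raise DegenerateInputError("response has zero variance")
    xc = xmat - xmat.mean(axis=0)
    if np.allclose(xc, 0.0):
        raise DegenerateInputError("explanatory matrix has zero variance")
    q = _orthonormal_basis(xc)
    m = q.shape[1]
    if m < xmat.shape[1]:
        warnings.warn(
            f"rank-deficient explanatory matrix: rank {m} < {xmat.shape[1]} columns",
            stacklevel=2,
        )
    if n <= m + 1:
        raise InvalidArgumentError(f"need n > rank+1 (n={n}, rank={m})")
    r2 = float(((q.T @ yc) ** 2).sum() / total)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    pseudo_f = (r2 / m) / ((1.0 - r2) / (n - m - 1))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r2p = float(((q[perm].T @ yc) ** 2).sum() / total)
        if r2p >= r2 - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    yhat = q @ (q.T @ yc)
    resid = yc - yhat
    sc = np.linalg.svd(yhat, compute_uv=False)
    sr = np.linalg.svd(resid, compute_uv=False)
    sc = sc[sc > (sc[0] * _RANK_TOL if sc.size else 0.0)]
    sr = sr[sr > (sr[0] * _RANK_TOL if sr.size else 0.0)]
    return ConstrainedOrdinationResult(
        r2=r2,
        adj_r2=adj_r2,
        pseudo_f=pseudo_f,
        p_value=p,
        n_perm=n_perm,
        rank=m,
        n=n,
        eigenvalues_constrained=sc**2,
        eigenvalues_residual=sr**2,
        explanatory=xlabels,
        total_inertia=total,
    )


def dbrda(
    d: DistanceMatrix,
    x,
    n_perm: int = 999,
    seed: int | None = None,
    negative_policy: str = "drop",
) -> ConstrainedOrdinationResult:
    """Distance-based RDA: RDA on the principal coordinates of ``d``.

    All retained (positive-eigenvalue) PCoA axes form the response; total
    inertia is the sum of positive eigenvalues, so R² is the fraction of
    the (representable) distance structure explained.
    """
    xmat = x
    if isinstance(x, (pd.DataFrame, pd.Series)):
        xdf = x.to_frame() if isinstance(x, pd.Series) else x
        missing = set(d.ids) - set(xdf.index)
        if missing:
            raise InvalidArgumentError(f"explanatory rows missing for: {sorted(missing)}")
        xmat = xdf.loc[list(d.ids)]
    pc = pcoa(d, negative_policy)
    result = rda(pc.coordinates, xmat, n_perm=n_perm, seed=seed)
    neg = int((pc.eigenvalues < 0).sum())
    result.dropped_axes = neg if negative_policy == "drop" else 0
    return result


# ---------------------------------------------------------------------------
# Forward selection


@dataclass
class ForwardSelectionResult:
    """Outcome of greedy forward selection of explanatory variables."""

    selected: list[str]
    steps: pd.DataFrame  # per-step: label, r2 (cumulative), adj_r2, p
    final: ConstrainedOrdinationResult | None
    best_single: ConstrainedOrdinationResult | None = None


def forward_select(
    response,
    candidates: pd.DataFrame,
    alpha: float = 0.1,
    n_perm: int = 999,
    seed: int | None = None,
    negative_policy: str = "drop",
) -> ForwardSelectionResult:
    """Greedy forward selection with conditional permutation tests.

    ``response`` is a raw response matrix or a distance matrix (then its
    positive PCoA axes are used, i.e. the dbRDA response).  At each step
    the candidate adding the most R² is tested by permuting its residuals
    off the current model; it enters if p < alpha.  The final model's R²,
    adjusted R² and global permutation p-value are reported.  If nothing is
    ever selected, diagnostics of the best single candidate are returned.
    """
    if not (0 < alpha < 1):
        raise InvalidArgumentError("alpha must be in (0, 1)")
    if candidates.shape[1] < 1:
        raise InvalidArgumentError("need at least one candidate")
    if isinstance(response, DistanceMatrix):
        pc = pcoa(response, negative_policy)
        ymat = pc.coordinates
        cand = candidates.loc[list(response.ids)]
    else:
        ymat, _ = _as_matrix(response, "y")
        cand = candidates
    n = ymat.shape[0]
    yc = ymat - ymat.mean(axis=0)
    total = float((yc**2).sum())
    if total <= 0:
        raise DegenerateInputError("response has zero variance")
    xall = cand.to_numpy(dtype=float)
    labels = [str(c) for c in cand.columns]
    rng = np.random.default_rng(seed)

    def fit_r2(cols: list[int]) -> float:
        xc = xall[:, cols] - xall[:, cols].mean(axis=0)
        q = _orthonormal_basis(xc)
        return float(((q.T @ yc) ** 2).sum() / total)

    selected: list[int] = []
    rows = []
    current_r2 = 0.0
    while len(selected) < len(labels):
        remaining = [j for j in range(len(labels)) if j not in selected]
        gains = []
        for j in remaining:
            r2j = fit_r2(selected + [j])
            gains.append((r2j - current_r2, labels[j], j, r2j))
        gains.sort(key=lambda g: (-g[0], g[1]))
        gain, label, j, r2j = gains[0]
        # conditional permutation test: permute candidate residuals off the
        # current model, refit, compare added R2
        if selected:
            xc_cur = xall[:, selected] - xall[:, selected].mean(axis=0)
            qcur = _orthonormal_basis(xc_cur)
        else:
            qcur = np.zeros((n, 0))
        cj = xall[:, j] - xall[:, j].mean()
        resid_j = cj - qcur @ (qcur.T @ cj)
        if float((resid_j**2).sum()) <= _RANK_TOL * max(1.0, float((cj**2).sum())):
            break  # candidate collinear with current model: nothing testable
        count = 0
        for _ in range(n_perm):
            perm_resid = resid_j[rng.permutation(n)]
            xperm = np.column_stack([xall[:, selected], perm_resid]) if selected else perm_resid[:, None]
            xpc = xperm - xperm.mean(axis=0)
            qp = _orthonormal_basis(xpc)
            r2p = float(((qp.T @ yc) ** 2).sum() / total)
            if r2p - current_r2 >= gain - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        m_after = len(selected) + 1
        adj = 1.0 - (1.0 - r2j) * (n - 1) / (n - m_after - 1)
        rows.append({"label": label, "r2": r2j, "adj_r2": adj, "p": p})
        if p < alpha:
            selected.append(j)
            current_r2 = r2j
        else:
            break
    steps = pd.DataFrame(rows, columns=["label", "r2", "adj_r2", "p"])
    final = None
    best_single = None
    perm_seed = int(rng.integers(2**31 - 1))
    if selected:
        final = rda(
            ymat, cand.iloc[:, selected], n_perm=n_perm, seed=perm_seed
        )
        if isinstance(response, DistanceMatrix):
            final.total_inertia = total
    else:
        # report the most promising single candidate for diagnostics
        singles = [(fit_r2([j]), labels[j], j) for j in range(len(labels))]
        singles.sort(key=lambda g: (-g[0], g[1]))
        best_single = rda(ymat, cand.iloc[:, [singles[0][2]]], n_perm=n_perm, seed=perm_seed)
    return ForwardSelectionResult(
        selected=[labels[j] for j in selected],
        steps=steps,
        final=final,
        best_single=best_single,
    )
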