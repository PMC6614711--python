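"""Core community-ecology numerics.

Relative abundance, the Hellinger transform, Bray-Curtis dissimilarity,
Shannon diversity, principal coordinates analysis (classical metric MDS) and
the Mantel permutation test.  All matrix routines accept either a
:class:`~agsflow.containers.CommunityTable` or a plain samples x taxa
DataFrame / array.

Conventions
-----------
* Bray-Curtis is computed on relative abundances:
  ``d(x, y) = 1 - 2 * sum(min(x_i, y_i)) / (sum x + sum y)``, in [0, 1].
* Shannon diversity uses the natural logarithm (ecology convention).
* PCoA reports negative eigenvalues but excludes them from coordinates and
  from the explained-variance denominator; no Lingoes/Cailliez correction.
* The Mantel statistic is the Pearson correlation of the strictly-lower
  triangles; the p-value is one-sided (upper tail) with the +1 correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import CommunityTable, ValidationError

__all__ = [
    "relative_abundance",
    "hellinger",
    "bray_curtis",
    "bray_curtis_matrix",
    "shannon",
    "pcoa",
    "mantel",
    "OrdinationResult",
]


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, CommunityTable):
        return table.values
    if isinstance(table, pd.DataFrame):
        return table
    return pd.DataFrame(np.asarray(table, dtype=float))


def relative_abundance(table):
    """Convert counts to per-sample proportions (rows sum to 1).

    Idempotent on proportion input.  Raises on an all-zero sample, naming it.
    """
    frame = _as_frame(table)
    arr = frame.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative abundances")
    totals = arr.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(f"all-zero sample(s): {list(frame.index[zero])}")
    out = frame.astype(float).div(totals, axis=0)
    if isinstance(table, CommunityTable):
        return CommunityTable(out, table.meta.copy())
    return out


def hellinger(table):
    """Hellinger transform: element-wise square root of relative abundance.

    Each output row has unit sum of squares.
    """
    frame = _as_frame(table)
    if (frame.to_numpy() < 0).any():
        raise ValidationError("negative abundances")
    rel = relative_abundance(frame)
    out = np.sqrt(rel)
    if isinstance(table, CommunityTable):
        return CommunityTable(out, table.meta.copy())
    return out


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity between two non-negative abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("negative abundances")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValidationError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def bray_curtis_matrix(table) -> pd.DataFrame:
    """Pairwise Bray-Curtis distance matrix over the samples of a table."""
    frame = _as_frame(table)
    arr = frame.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative abundances")
    if (arr.sum(axis=1) == 0).any():
        bad = frame.index[arr.sum(axis=1) == 0]
        raise ValidationError(f"all-zero sample(s): {list(bad)}")
    dm = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(dm, index=frame.index, columns=frame.index)


def shannon(proportions):
    """Shannon diversity H = -sum p_i ln p_i (natural log).

    Accepts a single proportion vector (returns a float) or a samples x taxa
    table (returns a per-sample Series).
    """
    arr = np.asarray(proportions if not isinstance(proportions, CommunityTable)
                     else proportions.values, dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative proportions")
    if arr.ndim == 1:
        p = arr / arr.sum()
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())
    frame = _as_frame(proportions)
    rel = relative_abundance(frame).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rel > 0, rel * np.log(rel), 0.0)
    return pd.Series(-terms.sum(axis=1), index=frame.index, name="shannon")


@dataclass
class OrdinationResult:
    """Principal-coordinates output.

    Attributes
    ----------
    coordinates : DataFrame, samples x axes (PCo1, PCo2, ...).
    eigenvalues : all eigenvalues of the double-centred matrix, descending
        (negative ones included for diagnostics).
    explained_fraction : eigenvalue / sum of positive eigenvalues, for each
        retained (positive) axis.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray


def pcoa(distance_matrix, n_axes: int = 2) -> OrdinationResult:
    """Classical scaling of a distance matrix (Gower's PCoA).

    Double-centres ``-0.5 * D**2``, eigendecomposes, and scales the
    eigenvectors of positive eigenvalues by the square root of their
    eigenvalue.  Requests for more axes than there are positive eigenvalues
    return fewer axes with a warning.
    """
    dm = distance_matrix
    labels = list(dm.index) if isinstance(dm, pd.DataFrame) else None
    d = np.asarray(dm, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    n = d.shape[0]
    if labels is None:
        labels = list(range(n))
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12 if n else 0.0
    pos = evals > tol
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; "
            f"returning {n_pos}",
            stacklevel=2,
        )
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes]) if n_axes else np.zeros((n, 0))
    pos_sum = evals[pos].sum()
    explained = evals[:n_axes] / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"PCo{i + 1}" for i in range(n_axes)]
    )
    return OrdinationResult(frame, evals, explained)


def _lower_triangle(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(d.shape[0], k=-1)
    return d[i, j]


def mantel(a, b, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Mantel test between two distance matrices over the same samples.

    Returns ``(r, p)`` where ``r`` is the Pearson correlation of the
    strictly-lower-triangle entries and ``p`` the one-sided upper-tail
    permutation p-value ``(1 + #{r_perm >= r}) / (n_perm + 1)``; rows and
    columns of ``b`` are permuted jointly.
    """
    la = list(a.index) if isinstance(a, pd.DataFrame) else None
    lb = list(b.index) if isinstance(b, pd.DataFrame) else None
    if la is not None and lb is not None and la != lb:
        raise ValidationError("distance matrices have mismatched labels")
    da = np.asarray(a, dtype=float)
    db = np.asarray(b, dtype=float)
    if da.shape != db.shape or da.shape[0] != da.shape[1]:
        raise ValidationError("distance matrices must be square and same shape")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    n = da.shape[0]
    va = _lower_triangle(da)
    va = (va - va.mean())
    sa = np.sqrt((va ** 2).sum())
    if sa == 0:
        raise ValidationError("matrix `a` has zero variance in its lower triangle")
    va /= sa

    def _stat(mat: np.ndarray) -> float:
        vb = _lower_triangle(mat)
        vb = vb - vb.mean()
        sb = np.sqrt((vb ** 2).sum())
        if sb == 0:
            return 0.0
        return float(va @ (vb / sb))

    r_obs = _stat(db)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if _stat(db[np.ix_(p, p)]) >= r_obs:
            count += 1
    p_val = (1 + count) / (n_perm + 1)
    return r_obs, p_val
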