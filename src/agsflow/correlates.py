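"""Taxa-parameter correlation analysis, correlation-profile clustering and
multiple factor analysis (MFA).

The correlation stage matches stable-state community samples to the nearest
sludge-parameter measurement of the same reactor (within a day window),
computes Pearson correlations of Hellinger-transformed taxon abundances
against each parameter, and attaches p-values from the t distribution with
n - 2 degrees of freedom.  Parameters flagged as inverse-transformed (the
settling-time-like quantities where *small* is good) are inverted before
correlating.  Taxa are then clustered by their correlation profiles
(hierarchical, average linkage, Euclidean) and the clusters renumbered so
cluster 1 is the one most positively associated with the large+medium
granule fractions.

MFA: each variable is centred and scaled, each variable block is divided by
its first singular value (so every block's leading axis carries unit
inertia), the weighted blocks are concatenated and decomposed by SVD.  Group
contributions per axis are the shares of squared loadings and sum to one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .containers import CommunityTable, ValidationError
from .metrics import hellinger

logger = logging.getLogger(__name__)

__all__ = [
    "match_samples",
    "taxa_parameter_correlations",
    "CorrelationClusterResult",
    "cluster_taxa",
    "MfaResult",
    "mfa",
]

GRANULE_SIZE_COLUMNS = ("frac_large", "frac_medium")


def match_samples(
    taxa_meta: pd.DataFrame, params: pd.DataFrame, day_window: float = 7.0
) -> pd.DataFrame:
    """Match each community sample to the nearest parameter row of the same
    reactor within ``day_window`` days.

    ``params`` must carry ``reactor`` and ``day`` columns.  Returns the
    parameter rows reindexed onto the community sample ids; unmatched samples
    are dropped.
    """
    for col in ("reactor", "day"):
        if col not in params.columns:
            raise ValidationError(f"parameter table lacks a {col!r} column")
        if col not in taxa_meta.columns:
            raise ValidationError(f"community metadata lacks a {col!r} column")
    matched = {}
    for sample, row in taxa_meta.iterrows():
        cand = params[params["reactor"] == row["reactor"]]
        if cand.empty:
            continue
        gaps = (cand["day"] - row["day"]).abs()
        best = gaps.idxmin()
        if gaps.loc[best] <= day_window:
            matched[sample] = cand.loc[best]
    if not matched:
        raise ValidationError("no community sample matched a parameter row")
    return pd.DataFrame(matched).T


@dataclass
class CorrelationClusterResult:
    """Taxa x parameters correlation matrix with p-values and, once
    :func:`cluster_taxa` has run, cluster labels and the dendrogram."""

    correlations: pd.DataFrame
    p_values: pd.DataFrame
    n_samples: pd.DataFrame
    clusters: pd.Series = None  # type: ignore[assignment]
    linkage: np.ndarray = None  # type: ignore[assignment]

    def stars(self, alpha: float = 0.01) -> pd.DataFrame:
        """Boolean mask of correlations significant at ``alpha``."""
        return self.p_values < alpha

    def to_dict(self) -> dict:
        out = {
            "correlations": self.correlations.round(6).to_dict(),
            "p_values": self.p_values.to_dict(),
        }
        if self.clusters is not None:
            out["clusters"] = {str(k): int(v) for k, v in self.clusters.items()}
        return out


def taxa_parameter_correlations(
    taxa: CommunityTable,
    params: pd.DataFrame,
    inverse_cols: tuple = (),
    day_window: float = 7.0,
    transform: bool = True,
    method: str = "pearson",
    min_n: int = 3,
) -> CorrelationClusterResult:
    """Correlate (Hellinger-transformed) taxon abundances with sludge
    parameters over day-matched stable-state samples.

    Parameters named in ``inverse_cols`` are replaced by their reciprocal
    before correlating (they must be strictly positive).  Pairs with fewer
    than ``min_n`` complete observations are reported as missing.
    """
    values = hellinger(taxa).values if transform else taxa.values
    matched = match_samples(taxa.meta, params, day_window=day_window)
    values = values.loc[matched.index]
    param_cols = [c for c in matched.columns if c not in ("reactor", "day")]
    pframe = matched[param_cols].astype(float)
    for col in inverse_cols:
        if col not in pframe.columns:
            raise ValidationError(f"inverse-flagged parameter {col!r} not present")
        if (pframe[col] <= 0).any():
            raise ValidationError(
                f"inverse-flagged parameter {col!r} must be strictly positive"
            )
        pframe[col] = 1.0 / pframe[col]
    corr = pd.DataFrame(index=values.columns, columns=param_cols, dtype=float)
    pval = pd.DataFrame(index=values.columns, columns=param_cols, dtype=float)
    nobs = pd.DataFrame(index=values.columns, columns=param_cols, dtype=int)
    for col in param_cols:
        y = pframe[col].to_numpy()
        ok = ~np.isnan(y)
        n = int(ok.sum())
        nobs[col] = n
        if n < min_n:
            logger.warning("parameter %s: only %d matched samples", col, n)
            continue
        yv = y[ok]
        x = values.to_numpy()[ok]
        if method == "spearman":
            x = stats.rankdata(x, axis=0)
            yv = stats.rankdata(yv)
        xc = x - x.mean(axis=0)
        yc = yv - yv.mean()
        sx = np.sqrt((xc ** 2).sum(axis=0))
        sy = np.sqrt((yc ** 2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc.T @ yc) / (sx * sy)
        r = np.clip(r, -1.0, 1.0)
        df = n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(df / (1.0 - r ** 2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
        corr[col] = r
        pval[col] = p
    return CorrelationClusterResult(correlations=corr, p_values=pval, n_samples=nobs)


def cluster_taxa(
    result,
    k: int = 3,
    granule_cols: tuple = GRANULE_SIZE_COLUMNS,
    method: str = "average",
) -> pd.Series:
    """Cluster taxa by their correlation profiles and number the clusters.

    Hierarchical agglomerative clustering (Euclidean distance between rows of
    the correlation matrix, average linkage by default), cut at ``k``
    clusters.  Missing correlations are imputed as 0 with a warning.  Clusters
    are renumbered by descending mean correlation with the ``granule_cols``
    columns (falling back to the first parameter column when absent), so
    cluster 1 is the granule-associated one.  Taxon input order does not
    matter: rows are sorted by label before linkage.
    """
    corr = result.correlations if isinstance(result, CorrelationClusterResult) else result
    corr = corr.sort_index(key=lambda ix: ix.map(str))
    if k > len(corr):
        raise ValidationError(f"k={k} exceeds the {len(corr)} taxa")
    if corr.isna().any().any():
        warnings.warn("missing correlations imputed as 0 for clustering",
                      stacklevel=2)
        corr = corr.fillna(0.0)
    link = hierarchy.linkage(corr.to_numpy(), method=method, metric="euclidean")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=corr.index, name="cluster")
    anchor = [c for c in granule_cols if c in corr.columns]
    if not anchor:
        anchor = [corr.columns[0]]
    score = corr[anchor].mean(axis=1).groupby(labels).mean().sort_values(ascending=False)
    remap = {old: new + 1 for new, old in enumerate(score.index)}
    labels = labels.map(remap).rename("cluster")
    if isinstance(result, CorrelationClusterResult):
        result.clusters = labels
        result.linkage = link
    return labels


@dataclass
class MfaResult:
    """Multiple-factor-analysis output.

    ``group_contributions`` rows are variable groups, columns axes; each
    column sums to 1.  ``group_weights`` are the inverse first singular
    values applied to each block.
    """

    eigenvalues: np.ndarray
    coordinates: pd.DataFrame            # samples x axes
    loadings: pd.DataFrame               # variables x axes (weighted loadings)
    group_contributions: pd.DataFrame    # groups x axes
    group_weights: dict
    explained_fraction: np.ndarray

    def to_dict(self) -> dict:
        return {
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "explained_fraction": [float(v) for v in self.explained_fraction],
            "group_weights": {k: float(v) for k, v in self.group_weights.items()},
            "group_contributions": self.group_contributions.round(6).to_dict(),
            "coordinates": self.coordinates.round(6).to_dict(),
        }


def mfa(groups: dict, n_axes: int = 2) -> MfaResult:
    """Multiple factor analysis over named blocks of variables.

    Every block is a samples x variables DataFrame on a shared sample index.
    Variables are centred and scaled to unit variance (population sd); each
    block is divided by its first singular value so no single block dominates;
    the concatenated matrix is decomposed by SVD.  The total inertia equals
    ``sum_g n_vars(g) / s1(g)**2`` where ``s1(g)`` is the block's first
    singular value on the correlation scale.
    """
    if not groups:
        raise ValidationError("at least one variable group is required")
    frames = {}
    index = None
    for name, block in groups.items():
        f = _dataframe(block)
        if f.shape[1] == 0 or f.shape[0] == 0:
            raise ValidationError(f"group {name!r} is empty")
        if index is None:
            index = f.index
        elif not f.index.equals(index):
            raise ValidationError(f"group {name!r} has a different sample set")
        frames[name] = f.astype(float)
    n = len(index)
    if n < 2:
        raise ValidationError("MFA needs at least 2 samples")
    weighted = {}
    weights = {}
    for name, f in frames.items():
        sd = f.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            dropped = list(f.columns[~keep])
            warnings.warn(f"group {name!r}: zero-variance variables dropped: "
                          f"{dropped}", stacklevel=2)
            f = f.loc[:, keep]
            sd = sd[keep]
            if f.shape[1] == 0:
                raise ValidationError(f"group {name!r} has no varying variables")
        z = (f - f.mean(axis=0)) / sd
        s1 = np.linalg.svd(z.to_numpy() / np.sqrt(n), compute_uv=False)[0]
        weights[name] = 1.0 / s1
        weighted[name] = z / (np.sqrt(n) * s1)
    concat = pd.concat(
        {name: w for name, w in weighted.items()}, axis=1
    )
    u, s, vt = np.linalg.svd(concat.to_numpy(), full_matrices=False)
    evals = s ** 2
    n_axes = min(n_axes, int((evals > evals[0] * 1e-12).sum()) if evals.size else 0)
    axes = [f"axis{i + 1}" for i in range(n_axes)]
    coords = pd.DataFrame(u[:, :n_axes] * s[:n_axes], index=index, columns=axes)
    load = pd.DataFrame(vt[:n_axes].T, index=concat.columns, columns=axes)
    group_of = concat.columns.get_level_values(0)
    contrib = (load ** 2).groupby(group_of).sum()
    contrib = contrib / contrib.sum(axis=0)
    total = evals.sum()
    return MfaResult(
        eigenvalues=evals,
        coordinates=coords,
        loadings=load,
        group_contributions=contrib,
        group_weights=weights,
        explained_fraction=evals[:n_axes] / total if total > 0 else evals[:n_axes],
    )


def _dataframe(block) -> pd.DataFrame:
    if isinstance(block, CommunityTable):
        return block.values
    if isinstance(block, pd.DataFrame):
        return block
    return pd.DataFrame(np.asarray(block, dtype=float))
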