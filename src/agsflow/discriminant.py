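"""Abundant / divergent / discriminant taxa selection across stable-state
datasets, and the floc-vs-granule enrichment comparison.

Definitions
-----------
abundant
    Mean relative abundance strictly above a threshold (default 1%) in at
    least one stable dataset.
divergent
    At least one pairwise two-sample t-test on the Hellinger-transformed
    abundances between two stable datasets with ``p < alpha / n_tests``
    (Bonferroni over the taxon count; with 422 genus-level taxa and
    alpha = 0.01 the per-test threshold is 0.01/422 = 2.37e-5).
discriminant
    Both abundant and divergent.

The floc/granule comparison takes the top-``n_top`` genera by grand mean
abundance, tests floc against granule means per reactor (paired on shared
sampling days when complete, Welch otherwise), applies Bonferroni over
``n_top`` (0.01/20 = 5e-4 at defaults), and reports a display ratio computed
with a pseudo-count (default 0.5%) added to both means.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CommunityTable, ValidationError
from .metrics import hellinger, relative_abundance

logger = logging.getLogger(__name__)

__all__ = [
    "bonferroni_threshold",
    "two_sample_t",
    "select_abundant",
    "select_divergent",
    "select_discriminant",
    "DiscriminantReport",
    "discriminant_report",
    "FlocGranuleReport",
    "floc_granule_compare",
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    return alpha / n_tests


def two_sample_t(x, y, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test with a zero-variance guard.

    Welch by default.  When both groups are constant: equal constants give
    p = 1, unequal constants give p = 0 (the limits of the t statistic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def _dataset_values(dataset) -> pd.DataFrame:
    if isinstance(dataset, CommunityTable):
        return dataset.values
    return pd.DataFrame(dataset)


def _align_datasets(datasets: dict) -> dict:
    """Align all datasets onto the union of taxa, absent taxa at 0."""
    if not datasets:
        raise ValidationError("no datasets supplied")
    frames = {name: _dataset_values(d).astype(float) for name, d in datasets.items()}
    taxa = sorted(set(itertools.chain.from_iterable(f.columns for f in frames.values())),
                  key=str)
    return {name: f.reindex(columns=taxa, fill_value=0.0) for name, f in frames.items()}


def select_abundant(datasets: dict, threshold: float = 0.01) -> set:
    """Taxa whose mean relative abundance exceeds ``threshold`` (strictly)
    in at least one dataset."""
    frames = _align_datasets(datasets)
    for name, f in frames.items():
        if len(f) == 0:
            raise ValidationError(f"dataset {name!r} is empty")
    means = pd.DataFrame({name: relative_abundance(f).mean(axis=0)
                          for name, f in frames.items()})
    return set(means.index[(means > threshold).any(axis=1)])


def select_divergent(
    datasets: dict,
    alpha: float = 0.01,
    n_tests: int | None = None,
    equal_var: bool = False,
    transform: bool = True,
) -> tuple[set, pd.DataFrame]:
    """Taxa with a Bonferroni-significant pairwise difference in mean
    Hellinger-transformed abundance between at least two datasets.

    Returns the divergent taxon set and the full p-value table
    (rows = dataset pairs, columns = taxa).  ``n_tests`` defaults to the
    taxon count.  Dataset pairs involving a single-sample dataset are
    skipped with a warning.
    """
    frames = _align_datasets(datasets)
    taxa = next(iter(frames.values())).columns
    if n_tests is None:
        n_tests = len(taxa)
    cutoff = bonferroni_threshold(alpha, n_tests)
    if transform:
        frames = {name: hellinger(f) for name, f in frames.items()}
    pairs = list(itertools.combinations(frames, 2))
    rows = {}
    for a, b in pairs:
        fa, fb = frames[a], frames[b]
        if len(fa) < 2 or len(fb) < 2:
            logger.warning("pair (%s, %s) skipped: a dataset has < 2 samples", a, b)
            continue
        xa, xb = fa.to_numpy(), fb.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(xa, xb, axis=0, equal_var=equal_var)
        # zero-variance columns: p = 1 if equal constants else 0
        degenerate = (np.ptp(xa, axis=0) == 0) & (np.ptp(xb, axis=0) == 0)
        if degenerate.any():
            equal = np.isclose(xa[0], xb[0])
            p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
        rows[(a, b)] = p
    if not rows:
        raise ValidationError("no testable dataset pairs (all have < 2 samples)")
    ptable = pd.DataFrame(rows, index=taxa).T
    ptable.index = pd.MultiIndex.from_tuples(ptable.index, names=["dataset_a", "dataset_b"])
    divergent = set(ptable.columns[(ptable < cutoff).any(axis=0)])
    return divergent, ptable


def select_discriminant(abundant: set, divergent: set) -> set:
    """Taxa that are both abundant and divergent."""
    return set(abundant) & set(divergent)


@dataclass
class DiscriminantReport:
    """Per-taxon abundant/divergent/discriminant flags with the evidence
    behind them."""

    means: pd.DataFrame            # taxa x datasets mean relative abundance
    p_values: pd.DataFrame         # dataset pairs x taxa
    abundant: set
    divergent: set
    discriminant: set
    abundance_threshold: float
    alpha: float
    n_tests: int

    @property
    def counts(self) -> dict:
        return {
            "n_abundant": len(self.abundant),
            "n_divergent": len(self.divergent),
            "n_discriminant": len(self.discriminant),
            "n_total": self.means.shape[0],
        }

    def to_frame(self) -> pd.DataFrame:
        frame = self.means.copy()
        frame["abundant"] = frame.index.isin(self.abundant)
        frame["divergent"] = frame.index.isin(self.divergent)
        frame["discriminant"] = frame.index.isin(self.discriminant)
        frame["min_pairwise_p"] = self.p_values.min(axis=0)
        return frame

    def to_dict(self) -> dict:
        return {
            "thresholds": {
                "abundance": self.abundance_threshold,
                "alpha": self.alpha,
                "n_tests": self.n_tests,
                "per_test_p": bonferroni_threshold(self.alpha, self.n_tests),
            },
            "counts": self.counts,
            "abundant": sorted(map(str, self.abundant)),
            "divergent": sorted(map(str, self.divergent)),
            "discriminant": sorted(map(str, self.discriminant)),
        }


def discriminant_report(
    datasets: dict,
    abundance_threshold: float = 0.01,
    alpha: float = 0.01,
    n_tests: int | None = None,
    equal_var: bool = False,
) -> DiscriminantReport:
    """Run the full abundant/divergent/discriminant selection over the stable
    datasets (typically the four reactors plus the inoculum)."""
    frames = _align_datasets(datasets)
    means = pd.DataFrame({name: relative_abundance(f).mean(axis=0)
                          for name, f in frames.items()})
    abundant = select_abundant(datasets, abundance_threshold)
    divergent, ptable = select_divergent(
        datasets, alpha=alpha, n_tests=n_tests, equal_var=equal_var
    )
    return DiscriminantReport(
        means=means,
        p_values=ptable,
        abundant=abundant,
        divergent=divergent,
        discriminant=select_discriminant(abundant, divergent),
        abundance_threshold=abundance_threshold,
        alpha=alpha,
        n_tests=n_tests if n_tests is not None else means.shape[0],
    )


@dataclass
class FlocGranuleReport:
    """Per-reactor, per-genus floc vs granule comparison.

    ``table`` columns: reactor, taxon, mean_floc, mean_granule, ratio
    (pseudo-counted), log2_ratio, t, p, significant, paired.
    """

    table: pd.DataFrame
    n_top: int
    pseudo: float
    alpha: float

    @property
    def per_test_threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.n_top)

    def enriched(self, where: str = "floc") -> pd.DataFrame:
        sig = self.table[self.table["significant"]]
        if where == "floc":
            return sig[sig["log2_ratio"] > 0]
        return sig[sig["log2_ratio"] < 0]

    def to_dict(self) -> dict:
        return {
            "n_top": self.n_top,
            "pseudo": self.pseudo,
            "alpha": self.alpha,
            "per_test_p": self.per_test_threshold,
            "comparisons": self.table.to_dict(orient="records"),
        }


def floc_granule_compare(
    table: CommunityTable,
    n_top: int = 20,
    pseudo: float = 0.005,
    alpha: float = 0.01,
    equal_var: bool = False,
) -> FlocGranuleReport:
    """Compare genus proportions between paired floc and granule samples.

    Uses the ``fraction`` metadata column (``floc`` / ``granule``).  Genera are
    ranked by grand mean relative abundance over all floc+granule samples and
    the top ``n_top`` tested per reactor.  Same-day pairs get a paired t-test;
    incomplete pairing falls back to an unpaired test (logged).  The displayed
    ratio is ``(mean_floc + pseudo) / (mean_granule + pseudo)``; the t-tests
    run on the raw (un-pseudo-counted) proportions.
    """
    if "fraction" not in table.meta.columns:
        raise ValidationError("metadata lacks a 'fraction' column")
    rel = relative_abundance(table)
    mask = rel.meta["fraction"].isin(["floc", "granule"])
    rel = rel.subset(mask)
    if rel.n_samples == 0:
        raise ValidationError("no floc/granule samples in table")
    grand = rel.values.mean(axis=0).sort_values(ascending=False)
    top = list(grand.index[:n_top])
    n_top_used = len(top)
    cutoff = bonferroni_threshold(alpha, n_top_used)
    rows = []
    for reactor in pd.unique(rel.meta["reactor"]):
        sub = rel.subset(rel.meta["reactor"] == reactor)
        floc = sub.values[sub.meta["fraction"] == "floc"]
        gran = sub.values[sub.meta["fraction"] == "granule"]
        floc_days = sub.meta.loc[sub.meta["fraction"] == "floc", "day"]
        gran_days = sub.meta.loc[sub.meta["fraction"] == "granule", "day"]
        paired = (
            len(floc_days) == len(gran_days)
            and len(floc_days) > 0
            and sorted(floc_days) == sorted(gran_days)
        )
        if min(len(floc), len(gran)) < 2:
            logger.warning("reactor %s skipped: fewer than 2 floc/granule pairs",
                           reactor)
            continue
        if paired:
            floc = floc.set_index(floc_days.to_numpy()).sort_index()
            gran = gran.set_index(gran_days.to_numpy()).sort_index()
        else:
            logger.info("reactor %s: incomplete day pairing, unpaired t-test",
                        reactor)
        for taxon in top:
            x = floc[taxon].to_numpy()
            y = gran[taxon].to_numpy()
            if paired:
                d = x - y
                if np.ptp(d) == 0:
                    t, p = (0.0, 1.0) if d[0] == 0 else (np.inf, 0.0)
                else:
                    t, p = stats.ttest_rel(x, y)
            else:
                t, p = two_sample_t(x, y, equal_var=equal_var)
            mf, mg = float(x.mean()), float(y.mean())
            ratio = (mf + pseudo) / (mg + pseudo)
            rows.append(
                {
                    "reactor": reactor,
                    "taxon": taxon,
                    "mean_floc": mf,
                    "mean_granule": mg,
                    "ratio": ratio,
                    "log2_ratio": float(np.log2(ratio)),
                    "t": float(t),
                    "p": float(p),
                    "significant": bool(p < cutoff),
                    "paired": paired,
                }
            )
    return FlocGranuleReport(
        table=pd.DataFrame(rows), n_top=n_top_used, pseudo=pseudo, alpha=alpha
    )
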