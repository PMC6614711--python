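"""Seeded synthetic-data generator for a four-reactor granular-sludge study.

The generator emulates the *post-clustering* data products of a multi-reactor
16S amplicon experiment plus the accompanying sludge measurements, with known
ground truth, so every downstream stage of the pipeline can be tested without
external data:

* per-reactor community time series that drift from a shared inoculum
  composition to a reactor-specific stable composition (log-space
  interpolation, renormalised), with Dirichlet-multinomial count noise;
* planted between-reactor differences: a set of *divergent* taxa whose
  stable-state means differ between reactors by a configured effect, a set of
  *abundant* taxa (> 1% mean), and their intersection as the planted
  discriminant set;
* paired floc/granule samples with planted log2 enrichments;
* sludge trajectories: exponentially decaying SVI curves with ordered
  SVI5 >= SVI10 >= SVI30, sieve size fractions drifting from floc- to
  granule-dominated on the simplex, and truncated-normal removal
  efficiencies;
* OTU-level tables with taxonomy records, for the rank-aggregation stage.

Effect sizes are balanced across reactors so that the residual "other"
pseudo-taxon (which absorbs the remaining mass) has identical stable means in
every reactor and never leaves the simplex.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import CommunityTable, ValidationError
from .metrics import bray_curtis
from .taxonomy import TaxonomyRecord

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SludgeCurveParams",
    "PerformanceParams",
    "SludgeSim",
    "generate_community_series",
    "generate_floc_granule",
    "generate_sludge_series",
    "generate_otu_tables",
]


class ConfigurationError(ValidationError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SludgeCurveParams:
    """Exponential settling-curve parameters for one reactor.

    ``svi30(t) = svi_inf + (svi0 - svi_inf) * exp(-t / tau) + noise`` with all
    SVI values in mL/g and ``tau`` in days.
    """

    svi0: float = 150.0
    svi_inf: float = 45.0
    tau: float = 40.0
    noise_sd: float = 4.0

    def __post_init__(self) -> None:
        if min(self.svi0, self.svi_inf, self.tau) <= 0 or self.noise_sd < 0:
            raise ConfigurationError("SVI curve parameters must be positive")


@dataclass(frozen=True)
class PerformanceParams:
    """Mean removal efficiencies (%) and their noise sd for one reactor."""

    means: dict = field(default_factory=lambda: {
        "removal_cod": 91.0, "removal_tn": 77.0, "removal_nh4": 95.0,
        "removal_tp": 89.0, "removal_po4": 92.0,
    })
    noise_sd: float = 5.0


# Stable-state targets loosely shaped on a four-reactor design: a VFA-fed
# reactor granulating fast and fully, and increasingly complex feeds keeping
# more flocs and settling worse.
_DEFAULT_SVI = (
    SludgeCurveParams(150.0, 40.0, 25.0, 4.0),
    SludgeCurveParams(150.0, 45.0, 30.0, 5.0),
    SludgeCurveParams(150.0, 80.0, 90.0, 8.0),
    SludgeCurveParams(150.0, 60.0, 45.0, 6.0),
)
_DEFAULT_PERF = (
    PerformanceParams({"removal_cod": 91.0, "removal_tn": 77.0,
                       "removal_nh4": 95.0, "removal_tp": 89.0,
                       "removal_po4": 92.0}, 5.0),
    PerformanceParams({"removal_cod": 93.0, "removal_tn": 60.0,
                       "removal_nh4": 97.0, "removal_tp": 89.0,
                       "removal_po4": 96.0}, 5.0),
    PerformanceParams({"removal_cod": 83.0, "removal_tn": 45.0,
                       "removal_nh4": 96.0, "removal_tp": 49.0,
                       "removal_po4": 64.0}, 8.0),
    PerformanceParams({"removal_cod": 92.0, "removal_tn": 47.0,
                       "removal_nh4": 94.0, "removal_tp": 64.0,
                       "removal_po4": 63.0}, 6.0),
)
_DEFAULT_ONSETS = (231, 178, 231, 120)

_SIZE_START = (0.80, 0.15, 0.04, 0.01)  # flocs, small, medium, large at day 0
_DEFAULT_SIZE_END = (
    (0.05, 0.15, 0.35, 0.45),
    (0.25, 0.55, 0.15, 0.05),
    (0.35, 0.50, 0.10, 0.05),
    (0.30, 0.55, 0.10, 0.05),
)


@dataclass
class SimConfig:
    """Full specification of one synthetic study.

    The defaults describe the emulated study design: 4 reactors sampled
    weekly for 400 days at a read depth of 50,000, 50 genus-level taxa (the
    last being a residual "other" pool), planted stable-state onsets of
    231/178/231/120 days, 12 planted abundant and 8 planted divergent taxa
    whose intersection (4 taxa) is the planted discriminant set.
    ``overdispersion`` is the Dirichlet concentration scale: per-taxon
    proportion variance is roughly p(1-p)/(overdispersion+1).
    """

    seed: int = 0
    n_reactors: int = 4
    n_taxa: int = 50
    n_otus_per_taxon: int = 3
    sampling_days: tuple = None  # type: ignore[assignment]
    read_depth: float = 50_000
    overdispersion: float = 500.0
    transition_day: tuple = None  # type: ignore[assignment]
    n_planted_divergent: int = 8
    n_planted_abundant: int = 12
    divergent_effect: float = 0.012
    floc_enrichment_log2: dict = None  # type: ignore[assignment]
    n_floc_granule_pairs: int = 10
    sludge_curve_params: tuple = None  # type: ignore[assignment]
    performance_params: tuple = None  # type: ignore[assignment]
    knee_distance: float = 0.66  # latent distance-to-stable held until onset

    def __post_init__(self) -> None:
        if self.n_reactors < 1:
            raise ConfigurationError("need at least one reactor")
        if self.n_taxa < self.n_planted_abundant + self.n_planted_divergent + 5:
            raise ConfigurationError(
                "n_taxa too small for the planted abundant/divergent sets"
            )
        if self.read_depth <= 0 or self.overdispersion <= 0:
            raise ConfigurationError("read_depth and overdispersion must be positive")
        if self.sampling_days is None:
            weekly = tuple(range(0, 400, 7))
            self.sampling_days = tuple(weekly for _ in range(self.n_reactors))
        self.sampling_days = tuple(tuple(d) for d in self.sampling_days)
        if len(self.sampling_days) != self.n_reactors:
            raise ConfigurationError(
                f"sampling_days has {len(self.sampling_days)} reactors, "
                f"expected {self.n_reactors}"
            )
        for days in self.sampling_days:
            arr = np.asarray(days)
            if (arr < 0).any() or (np.diff(arr) <= 0).any():
                raise ConfigurationError(
                    "sampling days must be non-negative and strictly increasing"
                )
        if self.transition_day is None:
            self.transition_day = tuple(
                _DEFAULT_ONSETS[i % 4] for i in range(self.n_reactors)
            )
        self.transition_day = tuple(self.transition_day)
        if len(self.transition_day) != self.n_reactors:
            raise ConfigurationError("one transition_day per reactor required")
        if any(t <= 0 for t in self.transition_day):
            raise ConfigurationError("transition days must be positive")
        if not 0 < self.divergent_effect < 0.2:
            raise ConfigurationError("divergent_effect must lie in (0, 0.2)")
        if self.sludge_curve_params is None:
            self.sludge_curve_params = tuple(
                _DEFAULT_SVI[i % 4] for i in range(self.n_reactors)
            )
        if self.performance_params is None:
            self.performance_params = tuple(
                _DEFAULT_PERF[i % 4] for i in range(self.n_reactors)
            )
        if len(self.sludge_curve_params) != self.n_reactors:
            raise ConfigurationError("one SludgeCurveParams per reactor required")
        if len(self.performance_params) != self.n_reactors:
            raise ConfigurationError("one PerformanceParams per reactor required")

    # -- derived layout ----------------------------------------------------
    @property
    def reactors(self) -> list:
        return [f"R{i + 1}" for i in range(self.n_reactors)]

    @property
    def taxa(self) -> list:
        named = [f"taxon_{i + 1:02d}" for i in range(self.n_taxa - 1)]
        return named + ["other"]

    @property
    def n_discriminant(self) -> int:
        return self.n_planted_divergent // 2

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for one output stream."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Planted structure of one synthetic study."""

    planted_onset: dict                 # reactor -> day
    planted_divergent: set
    planted_abundant: set
    planted_discriminant: set
    floc_enriched: set
    granule_enriched: set
    stable_compositions: pd.DataFrame   # reactors x taxa latent stable means
    inoculum_composition: pd.Series

    def __post_init__(self) -> None:
        assert self.planted_discriminant == (
            self.planted_divergent & self.planted_abundant
        )

    def to_dict(self) -> dict:
        return {
            "planted_onset": {k: float(v) for k, v in self.planted_onset.items()},
            "planted_divergent": sorted(self.planted_divergent),
            "planted_abundant": sorted(self.planted_abundant),
            "planted_discriminant": sorted(self.planted_discriminant),
            "floc_enriched": sorted(self.floc_enriched),
            "granule_enriched": sorted(self.granule_enriched),
        }


# ---------------------------------------------------------------------------
# latent compositions
# ---------------------------------------------------------------------------

def _planted_layout(config: SimConfig):
    """Index layout: abundant block, rare-divergent block, base block, 'other'."""
    n_ab = config.n_planted_abundant
    n_disc = config.n_discriminant
    n_rare = config.n_planted_divergent - n_disc
    abundant = list(range(n_ab))
    discriminant = abundant[:n_disc]
    rare_divergent = list(range(n_ab, n_ab + n_rare))
    base = list(range(n_ab + n_rare, config.n_taxa - 1))
    return abundant, discriminant, rare_divergent, base


def _stable_compositions(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Deterministic latent stable composition per reactor + inoculum.

    Planted effects are applied round-robin over reactors with compensating
    decreases elsewhere, so per-reactor totals stay balanced and "other"
    (which absorbs the residual mass) is identical across reactors.
    """
    taxa = config.taxa
    n_r = config.n_reactors
    abundant, discriminant, rare_divergent, base = _planted_layout(config)
    means = np.zeros((n_r, config.n_taxa))

    # abundant taxa: 1.2% .. 3.0%, identical across reactors
    ab_levels = np.linspace(0.030, 0.012, num=len(abundant))
    means[:, abundant] = ab_levels

    # discriminant taxa: the "hot" reactor sits divergent_effect above the
    # others; raises and compensating dips cancel within each reactor when the
    # taxon count divides n_reactors, keeping "other" balanced across reactors
    eff = config.divergent_effect
    for j, idx in enumerate(discriminant):
        r_hot = j % n_r
        means[:, idx] -= eff / n_r
        means[r_hot, idx] += eff

    # rare divergent taxa: low baseline, capped effect keeps them below 1%
    eff_rare = min(eff, 0.005)
    for j, idx in enumerate(rare_divergent):
        means[:, idx] = 0.004 - eff_rare / n_r
        means[j % n_r, idx] = 0.004 + eff_rare * (n_r - 1) / n_r

    # base taxa: geometric tail, identical across reactors, ~35% of mass
    if base:
        tail = 0.35 * np.geomspace(1.0, 0.05, num=len(base))
        tail /= tail.sum() / 0.35
        means[:, base] = tail

    if (means < 0).any():
        raise ConfigurationError(
            "divergent_effect pushes a planted taxon below zero abundance"
        )
    named_total = means.sum(axis=1)
    if (named_total >= 0.95).any():
        raise ConfigurationError(
            "planted abundances leave less than 5% mass for 'other'"
        )
    means[:, -1] = 1.0 - named_total  # "other" absorbs the residual

    stable = pd.DataFrame(means, index=config.reactors, columns=taxa)

    # inoculum: dominated by the tail of the base block, which is rare in
    # every stable state; floor keeps log-space interpolation finite
    inoc = np.full(config.n_taxa, 1e-4)
    pool = base[-10:] if len(base) >= 10 else base or abundant
    profile = np.geomspace(1.0, 0.2, num=len(pool))
    inoc[pool] = 0.72 * profile / profile.sum()
    inoc[-1] = 0.20
    inoc[abundant] = 0.0008
    inoc = inoc / inoc.sum()
    inoculum = pd.Series(inoc, index=taxa, name="inoculum")

    for r in config.reactors:
        d0 = bray_curtis(inoculum.to_numpy(), stable.loc[r].to_numpy())
        if d0 <= 0.6:
            raise ConfigurationError(
                f"inoculum-to-stable distance {d0:.3f} for {r} does not exceed 0.6"
            )
        if d0 <= config.knee_distance + 0.02:
            raise ConfigurationError(
                f"inoculum-to-stable distance {d0:.3f} for {r} leaves no "
                f"margin above the knee distance {config.knee_distance}"
            )
    return stable, inoculum


def _expected_within_stable_distance(config: SimConfig, comp: np.ndarray) -> float:
    """Analytic estimate of E[Bray-Curtis] between two noisy draws of ``comp``."""
    var = comp * (1 - comp) * (1.0 / (config.overdispersion + 1.0)
                               + 1.0 / min(config.read_depth, 1e12))
    return float(0.5 * np.sum(np.sqrt(2.0 * var) * np.sqrt(2.0 / np.pi)))


def _validate_detectability(config: SimConfig, stable: pd.DataFrame) -> None:
    """Planted divergent taxa must differ by > 5 pooled standard errors of the
    Hellinger-transformed abundance at the configured sample counts."""
    sd_h = 1.0 / (2.0 * np.sqrt(config.overdispersion + 1.0))
    n_stable = []
    for days, onset in zip(config.sampling_days, config.transition_day):
        n_stable.append(int(np.sum(np.asarray(days) >= onset)))
    n_min = max(min(n_stable), 2)
    pooled_se = sd_h * np.sqrt(2.0 / n_min)
    h = np.sqrt(stable.to_numpy())
    _, discriminant, rare_divergent, _ = _planted_layout(config)
    for idx in discriminant + rare_divergent:
        gap = h[:, idx].max() - h[:, idx].min()
        if gap <= 5.0 * pooled_se:
            raise ConfigurationError(
                f"planted divergent taxon {config.taxa[idx]} separates by "
                f"{gap / pooled_se:.1f} pooled SEs (< 5); increase "
                f"divergent_effect, overdispersion or the stable sample count"
            )


def _latent_series(config: SimConfig, reactor_index: int,
                   stable: pd.DataFrame, inoculum: pd.Series) -> np.ndarray:
    """Latent composition at each sampling day of one reactor.

    Log-space interpolation from the inoculum towards the stable composition:
    the mixing weight decays linearly until the planted onset while the
    community stays at least ``knee_distance`` away from the stable state,
    then drops to 0, so the community is within Bray-Curtis ~0 (< 0.05) of
    its stable composition from the onset onwards.
    """
    days = np.asarray(config.sampling_days[reactor_index], dtype=float)
    onset = float(config.transition_day[reactor_index])
    target = stable.iloc[reactor_index].to_numpy()
    start = inoculum.to_numpy()
    log_t, log_s = np.log(target), np.log(np.maximum(start, 1e-12))

    def mix(w: float) -> np.ndarray:
        x = np.exp(w * log_s + (1.0 - w) * log_t)
        return x / x.sum()

    def dist(w: float) -> float:
        return bray_curtis(mix(w), target)

    # knee weight: latent distance-to-stable held at the knee just before onset
    w_knee = optimize.brentq(lambda w: dist(w) - config.knee_distance, 0.0, 1.0,
                             xtol=1e-6)
    out = np.empty((len(days), config.n_taxa))
    for i, t in enumerate(days):
        if t >= onset:
            out[i] = target
        else:
            w = 1.0 - (1.0 - w_knee) * (t / onset)
            out[i] = mix(w)
    return out


def _observe(latent: np.ndarray, config: SimConfig,
             rng: np.random.Generator) -> np.ndarray:
    """Dirichlet-multinomial observation of latent compositions."""
    n, k = latent.shape
    if np.isinf(config.overdispersion):
        probs = latent.copy()
    else:
        probs = np.empty_like(latent)
        for i in range(n):
            probs[i] = rng.dirichlet(config.overdispersion * latent[i])
    if np.isinf(config.read_depth):
        return probs
    counts = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(int(config.read_depth), probs[i])
    return counts


def generate_community_series(config: SimConfig):
    """Generate per-reactor community count time series with ground truth.

    Returns ``(tables, truth)`` where ``tables`` maps reactor id to a
    :class:`CommunityTable` of counts (or proportions when ``read_depth`` is
    infinite) and ``truth`` is the :class:`GroundTruth`.
    """
    stable, inoculum = _stable_compositions(config)
    _validate_detectability(config, stable)
    for r in config.reactors:
        ewd = _expected_within_stable_distance(
            config, stable.loc[r].to_numpy())
        if ewd >= 0.3:
            raise ConfigurationError(
                f"expected within-stable distance {ewd:.2f} for {r} is not "
                f"below 0.3; increase overdispersion or read depth"
            )
    rng = config.rng(1)
    tables = {}
    for ri, reactor in enumerate(config.reactors):
        latent = _latent_series(config, ri, stable, inoculum)
        obs = _observe(latent, config, rng)
        days = config.sampling_days[ri]
        ids = [f"{reactor}_d{d:03d}" for d in days]
        values = pd.DataFrame(obs, index=ids, columns=config.taxa)
        meta = pd.DataFrame(
            {
                "reactor": reactor,
                "day": list(days),
                "fraction": "whole",
                "phase": ["stable" if d >= config.transition_day[ri]
                          else "transition" for d in days],
            },
            index=ids,
        )
        tables[reactor] = CommunityTable(values, meta)

    abundant, discriminant, rare_divergent, _ = _planted_layout(config)
    taxa = config.taxa
    enrich = _default_enrichment(config)
    truth = GroundTruth(
        planted_onset={r: float(t) for r, t in
                       zip(config.reactors, config.transition_day)},
        planted_divergent={taxa[i] for i in discriminant + rare_divergent},
        planted_abundant={taxa[i] for i in abundant},
        planted_discriminant={taxa[i] for i in discriminant},
        floc_enriched={t for t, e in enrich.items() if e > 0},
        granule_enriched={t for t, e in enrich.items() if e < 0},
        stable_compositions=stable,
        inoculum_composition=inoculum,
    )
    return tables, truth


def _default_enrichment(config: SimConfig) -> dict:
    if config.floc_enrichment_log2 is not None:
        return dict(config.floc_enrichment_log2)
    abundant, discriminant, _, _ = _planted_layout(config)
    free = [i for i in abundant if i not in discriminant]
    taxa = config.taxa
    # granule enrichment on the two most abundant free taxa so the halved
    # floc proportion still ranks inside the top-genera comparison
    enrich = {}
    for i in free[:2]:
        enrich[taxa[i]] = -1.0
    for i in free[2:4]:
        enrich[taxa[i]] = 1.0
    return enrich


def apply_enrichment(composition: np.ndarray, taxa: list, enrich: dict) -> np.ndarray:
    """Multiply taxa by 2**log2-enrichment and renormalise to the simplex."""
    factors = np.ones(len(taxa))
    for taxon, e in enrich.items():
        if taxon in taxa:
            factors[taxa.index(taxon)] = 2.0 ** e
    out = composition * factors
    return out / out.sum()


def generate_floc_granule(config: SimConfig, stable: pd.DataFrame | None = None
                          ) -> CommunityTable:
    """Paired floc/granule stable-state samples for every reactor.

    Granule samples are noisy draws around the stable composition; the paired
    floc sample multiplies the planted taxa by ``2**floc_enrichment_log2`` and
    renormalises.  Pairs share a sampling day.  An empty enrichment map yields
    exchangeable pairs.
    """
    if stable is None:
        stable, _ = _stable_compositions(config)
    enrich = _default_enrichment(config)
    rng = config.rng(2)
    taxa = list(stable.columns)
    frames, metas = [], []
    for ri, reactor in enumerate(config.reactors):
        days = [d for d in config.sampling_days[ri]
                if d >= config.transition_day[ri]]
        days = days[-config.n_floc_granule_pairs:]
        if len(days) < 2:
            raise ConfigurationError(
                f"{reactor}: fewer than 2 stable sampling days for pairing"
            )
        comp = stable.loc[reactor].to_numpy() if reactor in stable.index else \
            stable.iloc[ri].to_numpy()
        for d in days:
            if np.isinf(config.overdispersion):
                gran = comp.copy()
            else:
                gran = rng.dirichlet(config.overdispersion * comp)
            floc = apply_enrichment(gran, taxa, enrich)
            for frac, latent in (("granule", gran), ("floc", floc)):
                if np.isinf(config.read_depth):
                    obs = latent
                else:
                    obs = rng.multinomial(int(config.read_depth), latent)
                frames.append(pd.Series(obs, index=taxa,
                                        name=f"{reactor}_d{d:03d}_{frac}"))
                metas.append({"reactor": reactor, "day": d, "fraction": frac,
                              "phase": "stable"})
    values = pd.DataFrame(frames)
    meta = pd.DataFrame(metas, index=values.index)
    return CommunityTable(values, meta)


# ---------------------------------------------------------------------------
# sludge trajectories
# ---------------------------------------------------------------------------

@dataclass
class SludgeSim:
    """Per-reactor sludge trajectories plus the planted (noise-free) day on
    which the start-up criteria are first met."""

    frames: dict                   # reactor -> DataFrame
    planted_startup_day: dict      # reactor -> day or None


def _logit(p):
    return np.log(p / (1 - p))


def _size_fractions_path(days: np.ndarray, end: tuple, tau: float,
                         rng: np.random.Generator | None,
                         noise_sd: float) -> np.ndarray:
    """Simplex path from floc-dominated to the reactor's end profile.

    Linear interpolation of log-proportions with an exponential time constant,
    optional Gaussian jitter on the logits, softmax back to the simplex.
    """
    start = np.asarray(_SIZE_START)
    end = np.asarray(end)
    logs = np.log(start), np.log(end)
    w = np.exp(-days / tau)[:, None]
    path = w * logs[0] + (1 - w) * logs[1]
    if rng is not None and noise_sd > 0:
        path = path + rng.normal(0.0, noise_sd, size=path.shape)
    out = np.exp(path)
    return out / out.sum(axis=1, keepdims=True)


def _sludge_frame(config: SimConfig, ri: int,
                  rng: np.random.Generator | None) -> pd.DataFrame:
    """One reactor's sludge trajectory; ``rng=None`` gives the noise-free
    latent curves (used for the planted start-up day)."""
    days = np.asarray(config.sampling_days[ri], dtype=float)
    cp = config.sludge_curve_params[ri]
    pp = config.performance_params[ri]
    decay = np.exp(-days / cp.tau)
    svi30 = cp.svi_inf + (cp.svi0 - cp.svi_inf) * decay
    # SVI5 >= SVI10 >= SVI30 by construction: multiplicative gaps that close
    # as granulation proceeds (ratios approach ~0.95 of each other)
    gap10 = 0.60 * decay + 0.05
    gap5 = 0.40 * decay + 0.04
    if rng is not None:
        svi30 = svi30 + rng.normal(0.0, cp.noise_sd, size=len(days))
        gap10 = np.maximum(gap10 + rng.normal(0.0, 0.02, size=len(days)), 0.0)
        gap5 = np.maximum(gap5 + rng.normal(0.0, 0.02, size=len(days)), 0.0)
    svi30 = np.maximum(svi30, 10.0)
    svi10 = svi30 * (1.0 + gap10)
    svi5 = svi10 * (1.0 + gap5)
    fracs = _size_fractions_path(
        days, _DEFAULT_SIZE_END[ri % 4], max(cp.tau, 20.0),
        rng, 0.08 if rng is not None else 0.0,
    )
    tss = 3.0 + 5.0 * (1 - decay)
    if rng is not None:
        tss = np.maximum(tss + rng.normal(0.0, 0.3, size=len(days)), 0.5)
    frame = pd.DataFrame(
        {
            "day": days,
            "tss": tss,
            "svi5": svi5,
            "svi10": svi10,
            "svi30": svi30,
            "svi_30_10": svi30 / svi10,
            "svi_30_5": svi30 / svi5,
            "frac_floc": fracs[:, 0],
            "frac_small": fracs[:, 1],
            "frac_medium": fracs[:, 2],
            "frac_large": fracs[:, 3],
        }
    )
    for name, mean in pp.means.items():
        if rng is not None and pp.noise_sd > 0:
            a = (0.0 - mean) / pp.noise_sd
            b = (100.0 - mean) / pp.noise_sd
            vals = stats.truncnorm.rvs(a, b, loc=mean, scale=pp.noise_sd,
                                       size=len(days), random_state=rng)
        else:
            vals = np.full(len(days), float(np.clip(mean, 0, 100)))
        frame[name] = vals
    frame["reactor"] = config.reactors[ri]
    return frame


def generate_sludge_series(config: SimConfig) -> SludgeSim:
    """Sludge trajectories (SVI curves, size fractions, removal efficiencies)
    per reactor, plus the noise-free planted start-up day."""
    from .reactor import first_startup_day  # local import: avoids cycle

    rng = config.rng(3)
    frames, planted = {}, {}
    for ri, reactor in enumerate(config.reactors):
        frames[reactor] = _sludge_frame(config, ri, rng)
        latent = _sludge_frame(config, ri, None)
        latent["removal_stable"] = True
        planted[reactor] = first_startup_day(latent, persistence=1)
    return SludgeSim(frames=frames, planted_startup_day=planted)


# ---------------------------------------------------------------------------
# OTU-level tables
# ---------------------------------------------------------------------------

_PHYLA = ("Proteobacteria", "Actinobacteria", "Bacteroidetes", "Chloroflexi",
          "Nitrospirae")


def generate_otu_tables(config: SimConfig, table: CommunityTable):
    """Split a taxon-level count table into OTU clusters with taxonomy records.

    Each taxon becomes ``n_otus_per_taxon`` clusters with Dirichlet-drawn
    within-taxon weights; cluster identities are drawn so most clusters are
    genus-precise (>= 94.5%) and a minority truncate to family or above.
    Returns ``(otu_table, records)``; summing clusters of a taxon recovers the
    taxon's counts exactly.
    """
    rng = config.rng(4)
    n_per = max(int(config.n_otus_per_taxon), 1)
    columns, records = [], {}
    data = []
    counts = table.values.to_numpy()
    for j, taxon in enumerate(table.taxa):
        w = rng.dirichlet(np.full(n_per, 2.0))
        split = np.empty((len(table.values), n_per), dtype=counts.dtype)
        for i in range(len(table.values)):
            total = counts[i, j]
            if float(total).is_integer():
                split[i] = rng.multinomial(int(total), w)
            else:  # proportion tables: deterministic split
                split[i] = total * w
        phylum = _PHYLA[j % len(_PHYLA)]
        lineage_full = (
            "Bacteria", phylum, f"class_{phylum[:4]}", f"order_{j % 7 + 1}",
            f"family_{j // 3 + 1}", str(taxon), "",
        )
        for k in range(n_per):
            otu = f"otu_{j:03d}_{k}"
            columns.append(otu)
            u = rng.uniform()
            if u < 0.75:
                identity = rng.uniform(95.0, 100.0)
            elif u < 0.90:
                identity = rng.uniform(87.0, 94.0)
            elif u < 0.97:
                identity = rng.uniform(79.0, 86.0)
            else:
                identity = rng.uniform(60.0, 74.0)
            records[otu] = TaxonomyRecord(otu, lineage_full, round(identity, 1))
        data.append(split)
    values = pd.DataFrame(np.hstack(data), index=table.values.index,
                          columns=columns)
    return CommunityTable(values, table.meta.copy()), records
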