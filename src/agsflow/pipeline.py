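"""Pipeline driver: chains simulation, taxonomy aggregation, stable-state
detection, discriminant selection, floc/granule comparison, correlation
clustering, MFA and the reactor report into one seeded, reproducible run.

Every JSON artifact carries the configuration hash and the seed; rerunning
with an identical configuration reproduces identical bytes (no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as agsio
from .containers import ValidationError
from .correlates import cluster_taxa, mfa, taxa_parameter_correlations
from .discriminant import discriminant_report, floc_granule_compare
from .metrics import bray_curtis_matrix, mantel, pcoa, relative_abundance, shannon
from .reactor import first_startup_day, removal_stability
from .simulate import (SimConfig, generate_community_series,
                       generate_floc_granule, generate_sludge_series)
from .stability import flag_stable_samples

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate", "stable_state", "discriminant", "flocs_granules",
           "correlate", "mfa", "reactor_report")


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run.

    Thresholds default to the analysis constants: Bray-Curtis stability
    threshold 0.6, abundance 1%, alpha 0.01, pseudo-count 0.5%, top-20
    floc/granule genera, 3 correlation clusters.
    """

    seed: int = 0
    out_dir: str = "agsflow_out"
    stages: tuple = _STAGES
    stable_threshold: float = 0.6
    abundance_threshold: float = 0.01
    alpha: float = 0.01
    pseudo: float = 0.005
    n_top: int = 20
    k_clusters: int = 3
    day_window: float = 7.0
    log_level: str = "INFO"
    sim: dict = field(default_factory=dict)  # forwarded to SimConfig

    def __post_init__(self) -> None:
        if not 0 < self.stable_threshold <= 1:
            raise ValidationError("stable_threshold must lie in (0, 1]")
        if not 0 <= self.abundance_threshold < 1:
            raise ValidationError("abundance_threshold must lie in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.pseudo < 0:
            raise ValidationError("pseudo-count must be non-negative")
        if self.n_top < 1 or self.k_clusters < 1:
            raise ValidationError("n_top and k_clusters must be >= 1")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown configuration keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths and logging excluded, so
        the same analysis in a different directory hashes identically)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        payload.pop("log_level")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _dump(obj: dict, path: Path, config: PipelineConfig) -> None:
    obj = {"config_hash": config.config_hash(), "seed": config.seed, **obj}
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; returns the artifact
    manifest (stage name -> file path)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    stages = set(config.stages)

    simcfg = SimConfig(seed=config.seed, **config.sim)
    if "simulate" not in stages:
        raise ValidationError(
            "the pipeline driver is simulation-based: the 'simulate' stage "
            "is required upstream of all others"
        )
    tables, truth = generate_community_series(simcfg)
    for reactor, table in tables.items():
        agsio.write_community_tsv(table, out / f"counts_{reactor}.tsv",
                                  out / f"meta_{reactor}.tsv")
    (out / "ground_truth.json").write_text(
        json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    manifest["simulate"] = str(out / "ground_truth.json")

    results = {}
    if "stable_state" in stages:
        logger.info("stable-state threshold: %.2f", config.stable_threshold)
        for reactor, table in tables.items():
            results[reactor] = flag_stable_samples(
                table, threshold=config.stable_threshold, reactor=reactor)
        _dump({"reactors": {r: res.to_dict() for r, res in results.items()}},
              out / "stable_state.json", config)
        manifest["stable_state"] = str(out / "stable_state.json")

    stable_sets = {}
    if results:
        for reactor, table in tables.items():
            res = results[reactor]
            stable_sets[reactor] = relative_abundance(
                table.subset(table.meta["day"] >= res.onset_day))

    if "discriminant" in stages:
        if not stable_sets:
            raise ValidationError("discriminant stage requires stable_state")
        logger.info("abundance threshold %.3f, alpha %.3f",
                    config.abundance_threshold, config.alpha)
        report = discriminant_report(
            stable_sets, abundance_threshold=config.abundance_threshold,
            alpha=config.alpha)
        _dump(report.to_dict(), out / "discriminant.json", config)
        manifest["discriminant"] = str(out / "discriminant.json")

    if "flocs_granules" in stages:
        logger.info("floc/granule: top %d genera, pseudo-count %.3f",
                    config.n_top, config.pseudo)
        fg_table = generate_floc_granule(simcfg, truth.stable_compositions)
        fg = floc_granule_compare(fg_table, n_top=config.n_top,
                                  pseudo=config.pseudo, alpha=config.alpha)
        _dump(fg.to_dict(), out / "flocs_granules.json", config)
        manifest["flocs_granules"] = str(out / "flocs_granules.json")

    sludge = None
    if {"correlate", "mfa", "reactor_report"} & stages:
        sludge = generate_sludge_series(simcfg)
        params = pd.concat(sludge.frames.values(), ignore_index=True)

    if "correlate" in stages:
        if not stable_sets:
            raise ValidationError("correlate stage requires stable_state")
        taxa_table = _concat_tables(stable_sets)
        corr = taxa_parameter_correlations(taxa_table, params,
                                           day_window=config.day_window)
        cluster_taxa(corr, k=min(config.k_clusters, corr.correlations.shape[0]))
        _dump(corr.to_dict(), out / "correlations.json", config)
        manifest["correlate"] = str(out / "correlations.json")

    if "mfa" in stages:
        if not stable_sets:
            raise ValidationError("mfa stage requires stable_state")
        taxa_table = _concat_tables(stable_sets)
        from .correlates import match_samples
        matched = match_samples(taxa_table.meta, params,
                                day_window=config.day_window)
        settling_cols = ["svi5", "svi10", "svi30", "svi_30_10", "svi_30_5",
                         "frac_floc", "frac_small", "frac_medium", "frac_large"]
        removal_cols = [c for c in matched.columns if c.startswith("removal_")]
        community = taxa_table.values.loc[matched.index]
        community = community.loc[:, community.std(axis=0) > 0]
        groups = {
            "settling": matched[settling_cols].astype(float),
            "removal": matched[removal_cols].astype(float),
            "community": community,
        }
        res = mfa(groups, n_axes=2)
        _dump(res.to_dict(), out / "mfa.json", config)
        manifest["mfa"] = str(out / "mfa.json")

    if "reactor_report" in stages:
        report = {}
        for reactor, frame in sludge.frames.items():
            frame = frame.copy()
            frame["removal_stable"] = removal_stability(
                frame["removal_cod"]).to_numpy()
            day = first_startup_day(frame)
            report[reactor] = {
                "first_startup_day": day,
                "final_svi30": float(frame["svi30"].iloc[-1]),
                "final_granule_fraction": float(1 - frame["frac_floc"].iloc[-1]),
                "mean_removals": {
                    c: float(frame[c].mean())
                    for c in frame.columns if c.startswith("removal_")
                    and frame[c].dtype != bool
                },
            }
        _dump({"reactors": report}, out / "reactor_report.json", config)
        manifest["reactor_report"] = str(out / "reactor_report.json")

    (out / "manifest.json").write_text(
        json.dumps({"config_hash": config.config_hash(), "seed": config.seed,
                    "artifacts": manifest}, indent=1, sort_keys=True))
    return manifest


def _concat_tables(tables: dict):
    from .containers import CommunityTable
    values = pd.concat([t.values for t in tables.values()])
    meta = pd.concat([t.meta for t in tables.values()])
    return CommunityTable(values, meta)
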