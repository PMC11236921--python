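"""End-to-end orchestration: features -> VIF screen -> four model fits ->
DIC comparison -> exceedance hotspot tables, with a reproducibility manifest.

The pipeline is a thin, logged composition of the library modules.  Given
an area table (store counts, population, racial composition, SES
covariates) and a contiguity source (GeoJSON polygons or an edge list) it
emits, under the output directory:

* ``segregation_features.csv`` and ``vif.csv``
* ``model<k>_summary.csv`` (rate ratios, 95% CIs, significance flags)
* ``comparison.csv`` (DIC / pD / delta-DIC ranking)
* ``model<k>_exceedance.csv`` (per-area probabilities and classes)
* ``model<k>_draws.npz`` (columnar draws archive)
* ``manifest.json`` — inputs, seed, sampler settings, versions, wall time

Identical config + seed reproduce byte-identical summary tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import classify_exceedance, compare_models, dic, exceedance_probability
from .model import AreaTable, ModelSpec, Priors, summarize_posterior
from .sampler import fit_mcmc
from .segregation import compute_vif, segregation_features
from .spatial import adjacency_from_edge_list, adjacency_from_polygons, read_geojson_polygons

logger = logging.getLogger("fooddesert")

__all__ = ["RunConfig", "run_pipeline"]

_COMPOSITION_COLS = ("white", "black", "asian", "hispanic")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serialisable to YAML."""

    area_table: str
    adjacency: str  # GeoJSON (.geojson/.json) or edge-list text
    output_dir: str = "run"
    seed: int = 0
    models: tuple = (1, 2, 3, 4)
    n_iter: int = 20_000
    n_burn: int = 10_000
    n_chains: int = 4
    offset_rule: str = "population"
    exceedance_threshold: float = 1.0
    exceedance_cuts: tuple = (0.2, 0.8)
    priors: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        d["exceedance_cuts"] = list(self.exceedance_cuts)
        return d


def _load_graph(path: str, area_ids=None):
    p = Path(path)
    if p.suffix.lower() in {".geojson", ".json"}:
        return adjacency_from_polygons(read_geojson_polygons(p))
    return adjacency_from_edge_list(p, area_ids=area_ids)


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    priors = Priors(**config.priors)

    df = pd.read_csv(config.area_table)
    if "area_id" not in df.columns:
        raise ValueError("area table must have an 'area_id' column")
    df = df.set_index("area_id").sort_index()
    graph = _load_graph(config.adjacency, area_ids=tuple(df.index))
    if tuple(df.index) != tuple(graph.area_ids):
        raise ValueError("area ids in table and adjacency source disagree")
    logger.info("graph: %s", graph.summary())

    # --- segregation features -------------------------------------------
    missing = [c for c in _COMPOSITION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"area table lacks composition columns: {missing}")
    feats = segregation_features(df[list(_COMPOSITION_COLS)], graph)
    feats.to_csv(outdir / "segregation_features.csv")
    covs = feats[["entropy_score", "black_cluster_high", "white_cluster_high",
                  "pct_asian", "pct_hispanic"]].copy()
    for c in ModelSpec.for_model(3).covariates:
        if c not in df.columns:
            raise ValueError(f"area table lacks SES covariate column: {c}")
        covs[c] = df[c].to_numpy(dtype=float)

    table_df = pd.concat(
        [df[["store_count", "population"]], covs], axis=1
    ).reset_index()
    data = AreaTable.from_frame(table_df, offset_rule=config.offset_rule)

    # --- VIF screen on the full-model design ----------------------------
    vif = compute_vif(covs[list(ModelSpec.for_model(4).covariates)])
    vif.to_csv(outdir / "vif.csv")
    if vif["flagged"].any():
        logger.warning("VIF >= 6 for: %s (screen-and-proceed)",
                       vif.index[vif["flagged"]].tolist())

    # --- fit the nested models ------------------------------------------
    dics, pds = {}, {}
    for m in config.models:
        spec = ModelSpec.for_model(
            m,
            offset_rule=config.offset_rule,
            exceedance_threshold=config.exceedance_threshold,
        )
        t = time.time()
        samples = fit_mcmc(
            data, graph, spec, priors,
            n_iter=config.n_iter, n_burn=config.n_burn,
            n_chains=config.n_chains,
            seed=int(np.random.SeedSequence([config.seed, m]).generate_state(1)[0] % (2**31)),
        )
        summary = summarize_posterior(samples, spec)
        d, pd_ = dic(samples, data, spec)
        summary.to_csv(outdir / f"model{m}_summary.csv", float_format="%.6g")
        samples.save(outdir / f"model{m}_draws.npz")
        if samples.diagnostics is not None:
            samples.diagnostics.to_csv(outdir / f"model{m}_diagnostics.csv",
                                       float_format="%.4g")
        p = exceedance_probability(samples, config.exceedance_threshold)
        exc = pd.DataFrame(
            {
                "exceedance_prob": p,
                "class": classify_exceedance(p, tuple(config.exceedance_cuts)),
            },
            index=pd.Index(data.area_ids, name="area_id"),
        )
        exc.to_csv(outdir / f"model{m}_exceedance.csv", float_format="%.6g")
        dics[f"model{m}"], pds[f"model{m}"] = d, pd_
        logger.info("model %d: DIC=%.2f pD=%.2f (%.1fs)", m, d, pd_, time.time() - t)

    if len(dics) >= 2:
        report = compare_models(dics, pds)
    else:  # single-model run: report without a ranking
        report = pd.DataFrame(
            {"dic": list(dics.values()), "pd": list(pds.values()),
             "delta_dic": 0.0, "preferred": True, "evidence": ""},
            index=pd.Index(list(dics), name="model"),
        )
    report.to_csv(outdir / "comparison.csv", float_format="%.6g")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "inputs": {
            "area_table_sha256": _file_sha256(config.area_table),
            "adjacency_sha256": _file_sha256(config.adjacency),
        },
        "graph": graph.summary(),
        "dic": dics,
        "pd": pds,
        "preferred_model": report.index[report["preferred"]].tolist(),
        "wall_time_s": round(time.time() - t0, 2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("pipeline done in %.1fs -> %s", time.time() - t0, outdir)
    return outdir
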