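"""Gender-stratified pipeline orchestration and machine-readable report.

``run_pipeline`` drives the whole analysis for each requested gender
stratum — cohort input (file or synthetic), optional multimorbidity
selection, descriptives, pairwise associations, edge filter, network
and metrics — and writes every intermediate artifact plus a single
``report.json`` referencing all files with SHA-256 checksums.  The two
strata are processed independently; no pooled model is ever fitted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import descriptives as desc_mod
from . import graph as graph_mod
from .codebook import Cohort, read_cohort, split_by_gender, write_cohort
from .model import DiseaseNetworkModel
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "summarize_network",
           "load_config"]

logger = logging.getLogger("morbnet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs; mirrors the YAML config file."""

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    genders: tuple[str, ...] = ("women", "men")
    or_min: float = 1.2
    alpha: float = 0.05
    orientation: str = "both-geomean"
    distance_transform: str = "reciprocal"
    use_weights: bool = True
    robust_se: bool = False
    bh: bool = False
    multimorbid_only: bool = True
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.or_min <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")


def load_config(path) -> PipelineConfig:
    """Read a flat YAML/JSON pipeline config; synthetic keys nest under
    ``synthetic:``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = raw.pop("synthetic", None)
    cfg = PipelineConfig(**raw)
    if syn is not None:
        if "latent_corr" in syn:
            syn["latent_corr"] = np.asarray(syn["latent_corr"], dtype=float)
        cfg.synthetic = SyntheticConfig(**syn)
    if cfg.genders is not None:
        cfg.genders = tuple(cfg.genders)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("input")
def _load_input(config: PipelineConfig) -> Cohort:
    if config.input_path is not None:
        return read_cohort(config.input_path)
    if config.synthetic is not None:
        syn = config.synthetic
        if config.seed is not None:
            syn = SyntheticConfig(**{**syn.__dict__, "seed": config.seed})
        return generate_cohort(syn)
    raise ValueError("config needs either input_path or a synthetic block")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full stratified analysis and write all artifacts.

    Per stratum: ``cohort.csv`` (analysed records), ``prevalence.csv``,
    ``dyads.csv`` (long format, 120 rows), ``edges_all.csv``,
    ``edges_included.csv``, ``nodes.csv``, ``network.graphml`` and
    ``network_attributes.json``; globally a ``report.json`` with
    settings, per-stratum headline numbers, and the checksummed file
    manifest.  Deterministic given input and seed.  Returns the report
    dict (also written to disk).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run: or_min=%s alpha=%s orientation=%s transform=%s weights=%s "
                "robust=%s bh=%s multimorbid_only=%s seed=%s",
                config.or_min, config.alpha, config.orientation,
                config.distance_transform, config.use_weights, config.robust_se,
                config.bh, config.multimorbid_only, config.seed)

    cohort = _load_input(config)
    strata = dict(zip(("women", "men"), split_by_gender(cohort)))

    report: dict = {
        "settings": {
            "or_min": config.or_min, "alpha": config.alpha,
            "orientation": config.orientation,
            "distance_transform": config.distance_transform,
            "use_weights": config.use_weights, "robust_se": config.robust_se,
            "bh": config.bh, "multimorbid_only": config.multimorbid_only,
            "seed": config.seed,
            "n_dyads_tested": desc_mod.n_dyads(cohort),
            "multiple_testing": "BH" if config.bh else
                                f"none ({desc_mod.n_dyads(cohort)} raw tests)",
        },
        "strata": {},
        "files": {},
    }

    for gender in config.genders:
        stratum = strata[gender]
        if stratum.n == 0:
            raise PipelineError(f"stage 'input' failed: stratum {gender!r} is empty")
        model = DiseaseNetworkModel(
            stratum, or_min=config.or_min, alpha=config.alpha,
            orientation=config.orientation,
            distance_transform=config.distance_transform,
            use_weights=config.use_weights, robust_se=config.robust_se,
            bh=config.bh, multimorbid_only=config.multimorbid_only)
        res = _fit_stage(model)
        gdir = out / gender
        gdir.mkdir(exist_ok=True)
        files = _write_stage(res, gdir)
        attrs = res.attributes
        report["strata"][gender] = {
            "n_input": stratum.n,
            "n_analysed": res.cohort.n,
            "n_nodes": attrs.n_nodes,
            "n_edges": attrs.n_edges,
            "diameter": attrs.diameter,
            "density": attrs.density,
            "degree_sum": int(res.centrality["degree"].sum()),
            "top_dyads": [{"pair": list(p), "prevalence": v}
                          for p, v in res.ranked_dyads(5)],
        }
        for name, path in files.items():
            report["files"][f"{gender}/{name}"] = _sha256(path)

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("report written to %s", report_path)
    return report


@_stage("fit")
def _fit_stage(model: DiseaseNetworkModel):
    return model.fit()


@_stage("write")
def _write_stage(res, gdir: Path) -> dict[str, Path]:
    files: dict[str, Path] = {}

    def save(name: str, writer) -> None:
        path = gdir / name
        writer(path)
        files[name] = path

    save("cohort.csv", lambda p: write_cohort(res.cohort, p))
    save("prevalence.csv", lambda p: res.prevalence.to_csv(p, index=False))
    save("dyads.csv",
         lambda p: desc_mod.dyad_long_format(res.dyads).to_csv(p, index=False))
    frame = res.associations_frame()
    save("edges_all.csv", lambda p: frame.to_csv(p, index=False))
    save("edges_included.csv",
         lambda p: frame[frame["included"]].to_csv(p, index=False))
    save("nodes.csv", lambda p: res.centrality.to_csv(p, index=False))
    save("network.graphml", lambda p: graph_mod.write_graphml(res.network, p))
    attrs = res.attributes
    save("network_attributes.json", lambda p: Path(p).write_text(json.dumps({
        "n_nodes": attrs.n_nodes, "n_edges": attrs.n_edges,
        "diameter": attrs.diameter, "density": attrs.density,
        "distance_transform": attrs.distance_transform}, indent=2)))
    return files


def summarize_network(report: dict) -> str:
    """Text table of network attributes and headline numbers per stratum,
    mirroring the usual two-column (women, men) layout."""
    genders = list(report["strata"])
    lines = []
    header = f"{'Attribute':<28s}" + "".join(f"{g:>12s}" for g in genders)
    lines.append(header)
    lines.append("-" * len(header))
    rows = [
        ("Records analysed", "n_analysed", "{:d}"),
        ("Number of nodes", "n_nodes", "{:d}"),
        ("Number of edges", "n_edges", "{:d}"),
        ("Diameter", "diameter", "{:.4f}"),
        ("Density", "density", "{:.4f}"),
        ("Degree sum (2E)", "degree_sum", "{:d}"),
    ]
    for label, key, fmt in rows:
        vals = "".join(f"{fmt.format(report['strata'][g][key]):>12s}"
                       for g in genders)
        lines.append(f"{label:<28s}{vals}")
    return "\n".join(lines) + "\n"
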