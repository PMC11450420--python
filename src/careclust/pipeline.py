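"""End-to-end pipeline: simulate -> map -> filter -> impute -> cluster ->
network -> model -> report, from a single configuration.

Every stage writes plain-text artefacts into the run directory and the
manifest records settings, seeds and stage timings.  Re-running with the
same configuration reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .consensus import consensus_kmeans, select_k
from .errors import ConfigurationError, StageError
from .impute import impute
from .indicators import default_indicator_set, derive_indicators, exclusion_filter
from .multinomial import ModelSpec, fit_pooled
from .report import (
    centre_distribution,
    characteristics_by_cluster,
    cohort_accounting,
)
from .simulate import Cohort, GeneratorConfig, generate_cohort, apply_missingness
from .tetrachoric import kruskal_stress, pooled_matrix

log = logging.getLogger(__name__)

STAGES = ("simulate", "map", "filter", "impute", "cluster", "network", "model", "report")


def _stage_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """One configuration object driving the whole run."""

    outdir: str = "careclust_run"
    input_cohort: Optional[str] = None          # read instead of simulating
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    m: int = 20
    n_sweeps: int = 10
    k: int = 4                                  # chosen cluster number
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    run_k_diagnostics: bool = False
    consensus_R: int = 100
    subsample_p: float = 0.8
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    write_consensus_matrix: bool = True
    report_only: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ConfigurationError("pipeline needs m >= 2 imputations")
        if self.run_k_diagnostics and self.k not in self.k_range:
            log.warning("chosen k=%d outside diagnostic range %s (clinical override)",
                        self.k, self.k_range)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig.from_dict(raw.pop("generator", {}) or {})
        spec_raw = raw.pop("model_spec", None)
        spec = ModelSpec(**spec_raw) if spec_raw else ModelSpec()
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(generator=gen, model_spec=spec, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "settings": {"seed": config.seed, "m": config.m,
                                                 "k": config.k, "R": config.consensus_R,
                                                 "p": config.subsample_p},
                      "artefacts": {}, "timings_s": {}}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # annotate with the failing stage
            raise StageError(name, str(exc)) from exc
        manifest["stages"].append(name)
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
        return out

    if config.report_only:
        return _report_only(config, outdir, manifest)

    # ---- simulate (or load) ------------------------------------------------
    def stage_simulate() -> Cohort:
        if config.input_cohort:
            return cio.read_cohort(config.input_cohort)
        gen = replace(config.generator, seed=_stage_seed(config.seed, 0))
        cohort = apply_missingness(generate_cohort(gen))
        manifest["artefacts"].update(cio.write_cohort(cohort, outdir / "cohort"))
        return cohort

    cohort = run_stage("simulate", stage_simulate)

    # ---- map ---------------------------------------------------------------
    def stage_map():
        defs = default_indicator_set(mlt_cut=cohort.config.mlt_cut)
        mat = derive_indicators(cohort, defs)
        path = outdir / "indicators.csv"
        cio.write_indicator_matrix(mat, path)
        manifest["artefacts"]["indicators"] = str(path)
        return mat

    matrix = run_stage("map", stage_map)

    # ---- filter ------------------------------------------------------------
    def stage_filter():
        mat, report = exclusion_filter(matrix)
        cio.write_json(report, outdir / "exclusion_report.json")
        manifest["artefacts"]["exclusion_report"] = str(outdir / "exclusion_report.json")
        return mat, report

    filtered, excl_report = run_stage("filter", stage_filter)

    # ---- impute ------------------------------------------------------------
    def stage_impute():
        imps = impute(
            filtered,
            m_count=config.m,
            seed=_stage_seed(config.seed, 1),
            n_sweeps=config.n_sweeps,
        )
        cio.write_imputations(imps, outdir / "imputations")
        manifest["artefacts"]["imputations"] = str(outdir / "imputations")
        return imps

    imps = run_stage("impute", stage_impute)

    # ---- cluster -----------------------------------------------------------
    def stage_cluster():
        diag_payload = {}
        if config.run_k_diagnostics:
            diag, recommended, no_structure = select_k(
                imps, config.k_range, R=config.consensus_R, p=config.subsample_p,
                seed=_stage_seed(config.seed, 2),
            )
            diag_payload = {
                "per_k": diag.to_dict(orient="records"),
                "recommended_k": recommended,
                "no_structure": no_structure,
            }
        res = consensus_kmeans(
            imps, config.k, R=config.consensus_R, p=config.subsample_p,
            seed=_stage_seed(config.seed, 3),
        )
        labels = pd.DataFrame({"episode_id": imps.episode_ids, "cluster": res.labels})
        labels.to_csv(outdir / "labels.csv", index=False)
        manifest["artefacts"]["labels"] = str(outdir / "labels.csv")
        if config.write_consensus_matrix and imps.n <= 10_000:
            np.savetxt(outdir / "consensus_matrix.csv", res.consensus,
                       delimiter=",", fmt="%.6f")
            manifest["artefacts"]["consensus_matrix"] = str(outdir / "consensus_matrix.csv")
        cio.write_json(
            {
                "k": res.k,
                "chosen_k": config.k,
                "pac": res.pac,
                "settings": res.settings,
                "diagnostics": diag_payload,
                "cdf_points": res.cdf_points.to_dict(orient="list"),
            },
            outdir / "cluster_diagnostics.json",
        )
        manifest["artefacts"]["cluster_diagnostics"] = str(outdir / "cluster_diagnostics.json")
        return res

    result = run_stage("cluster", stage_cluster)

    # ---- network -----------------------------------------------------------
    def stage_network():
        net = pooled_matrix(imps)
        net.edge_list.to_csv(outdir / "network_edges.csv", index=False)
        pd.DataFrame(net.layout, columns=["x", "y"]).assign(
            indicator=list(net.indicator_names)
        ).to_csv(outdir / "network_layout.csv", index=False)
        pd.DataFrame(net.rho, columns=list(net.indicator_names)).to_csv(
            outdir / "network_rho.csv", index=False
        )
        manifest["artefacts"]["network_edges"] = str(outdir / "network_edges.csv")
        manifest["artefacts"]["network_layout"] = str(outdir / "network_layout.csv")
        manifest["artefacts"]["network_rho"] = str(outdir / "network_rho.csv")
        manifest["settings"]["layout_stress"] = kruskal_stress(
            np.nan_to_num(net.rho, nan=0.0), net.layout
        )
        return net

    run_stage("network", stage_network)

    # ---- model -------------------------------------------------------------
    def stage_model():
        episodes = cohort.episodes.set_index("episode_id").loc[
            list(imps.episode_ids)
        ].reset_index()
        pooled = fit_pooled(episodes, result.labels, config.model_spec, imps=imps)
        pooled.to_frame().to_csv(outdir / "model_rrr.csv", index=False)
        cio.write_json(
            {
                f"{cat}|{term}": {
                    "rrr": float(np.exp(s.estimate)),
                    "ci_low": float(np.exp(s.ci_low)),
                    "ci_high": float(np.exp(s.ci_high)),
                    "log_rrr": s.estimate,
                    "total_variance": s.total_variance,
                }
                for (cat, term), s in pooled.entries.items()
            },
            outdir / "model_rrr.json",
        )
        manifest["artefacts"]["model_rrr"] = str(outdir / "model_rrr.csv")
        manifest["artefacts"]["model_rrr_json"] = str(outdir / "model_rrr.json")
        return pooled

    run_stage("model", stage_model)

    # ---- report ------------------------------------------------------------
    def stage_report():
        _write_reports(cohort, filtered, excl_report, result.labels,
                       imps.episode_ids, outdir, manifest)

    run_stage("report", stage_report)

    cio.write_json(manifest, outdir / "manifest.json")
    return manifest


def _write_reports(cohort, filtered, excl_report, labels, episode_ids, outdir, manifest):
    accounting = cohort_accounting(excl_report, labels)
    cio.write_json(accounting.to_dict(), outdir / "cohort_accounting.json")
    chars = characteristics_by_cluster(cohort, labels, matrix=filtered)
    chars.to_csv(outdir / "characteristics_by_cluster.csv", index=False)
    episodes = cohort.episodes.set_index("episode_id").loc[list(episode_ids)]
    prevalence, density = centre_distribution(labels, episodes["centre_id"].to_numpy())
    prevalence.to_csv(outdir / "centre_prevalence.csv", index=False)
    density.to_csv(outdir / "centre_density.csv", index=False)
    manifest["artefacts"].update(
        {
            "cohort_accounting": str(outdir / "cohort_accounting.json"),
            "characteristics": str(outdir / "characteristics_by_cluster.csv"),
            "centre_prevalence": str(outdir / "centre_prevalence.csv"),
            "centre_density": str(outdir / "centre_density.csv"),
        }
    )


def _report_only(config: PipelineConfig, outdir: Path, manifest: dict) -> dict:
    """Re-derive report tables from cached cohort, filter and labels."""
    cohort = cio.read_cohort(outdir / "cohort")
    filtered = cio.read_indicator_matrix(outdir / "indicators.csv")
    filtered, excl_report = exclusion_filter(filtered)
    labels_df = pd.read_csv(outdir / "labels.csv")
    labels = labels_df["cluster"].to_numpy()
    manifest["stages"].append("report")
    _write_reports(cohort, filtered, excl_report, labels,
                   labels_df["episode_id"].to_numpy(object), outdir, manifest)
    cio.write_json(manifest, outdir / "manifest.json")
    return manifest
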