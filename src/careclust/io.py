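"""Delimited-text and JSON serialisation for every pipeline artefact.

All artefacts are plain text (CSV with header row, JSON manifests, YAML
configs) so runs are diffable and byte-reproducible given the same
configuration and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .impute import ImputationSet
from .indicators import IndicatorMatrix
from .simulate import Cohort, FLAG_FIELDS, GeneratorConfig


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, str]:
    """Write episode/visit tables plus the generator config (YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "episodes": str(outdir / "episodes.csv"),
        "visits": str(outdir / "visits.csv"),
        "config": str(outdir / "generator_config.yaml"),
    }
    cohort.episodes.to_csv(paths["episodes"], index=False)
    visits = cohort.visits.copy()
    for fld in FLAG_FIELDS:
        if fld in visits.columns:
            visits[fld] = visits[fld].astype("Int8")
    visits.to_csv(paths["visits"], index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=False)
    return paths


def read_cohort(indir: str | Path) -> Cohort:
    indir = Path(indir)
    episodes = pd.read_csv(indir / "episodes.csv")
    visits = pd.read_csv(indir / "visits.csv")
    for fld in FLAG_FIELDS:
        if fld in visits.columns:
            visits[fld] = visits[fld].astype("Float64").astype("Int8").astype("boolean")
    with open(indir / "generator_config.yaml") as fh:
        config = GeneratorConfig.from_dict(yaml.safe_load(fh))
    return Cohort(episodes=episodes, visits=visits, config=config)


def write_indicator_matrix(m: IndicatorMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, index=False)


def read_indicator_matrix(path: str | Path) -> IndicatorMatrix:
    return IndicatorMatrix.from_frame(pd.read_csv(path))


def write_imputations(imps: ImputationSet, outdir: str | Path) -> dict:
    """One CSV per completed dataset plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, c in enumerate(imps.completed, start=1):
        df = pd.DataFrame(c, columns=list(imps.indicator_names))
        df.insert(0, "episode_id", imps.episode_ids)
        path = outdir / f"imputed_{i:02d}.csv"
        df.to_csv(path, index=False)
        files.append(path.name)
    manifest = {
        "m": imps.m,
        "files": files,
        "indicator_names": list(imps.indicator_names),
        "rng_state": imps.rng_state,
    }
    with open(outdir / "imputation_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_imputations(indir: str | Path) -> ImputationSet:
    indir = Path(indir)
    with open(indir / "imputation_manifest.json") as fh:
        manifest = json.load(fh)
    completed, episode_ids = [], None
    for name in manifest["files"]:
        df = pd.read_csv(indir / name)
        episode_ids = df["episode_id"].to_numpy(object)
        completed.append(df[manifest["indicator_names"]].to_numpy(np.int8))
    return ImputationSet(
        completed=completed,
        episode_ids=episode_ids,
        indicator_names=tuple(manifest["indicator_names"]),
        m=manifest["m"],
        rng_state=manifest["rng_state"],
    )


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
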