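"""End-to-end study runners with single-seed determinism and provenance.

Each runner takes a :class:`RunConfig`, derives independent per-stage RNG
substreams from the run seed, writes its artifacts under the configured
output directory, and drops a ``provenance.json`` sidecar recording the
config hash and folding-engine version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io
from .classification import knn_cv, plsda_cv
from .folding import get_engine
from .motif_trends import (
    DEFAULT_LENGTH_GRID,
    build_length_grid_dataset,
    fit_all_motifs,
    structures_to_motif_points,
)
from .sampling import (
    CompositionSpec,
    filter_by_length,
    random_sequences,
    read_fasta,
    scramble,
    spawn_rngs,
)
from .shape_stats import (
    coverage_fraction,
    log_log_correlation,
    shape_frequency_table,
)
from .shapes import abstract_shape
from .synthetic import PseudoNaturalSpec, generate_pseudo_natural, make_feature_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """A single file/record that fully determines a pipeline run."""

    engine: str = "vienna"
    engine_params: dict = field(default_factory=dict)
    lengths: Sequence[int] = (100,)
    n_random: int = 1000
    trend_grid: Sequence[int] = DEFAULT_LENGTH_GRID
    n_per_length: int = 25
    gc: Optional[float] = None  # None = uniform composition
    seed: int = 0
    natural_fasta: Optional[str] = None
    synthetic: dict = field(default_factory=dict)  # PseudoNaturalSpec kwargs
    knn_k: int = 5
    pls_components: int = 2
    bootstrap: int = 1000
    outdir: str = "rnamotifs_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _prepare(config: RunConfig):
    engine = get_engine(config.engine, **config.engine_params)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_json(
        {"config": dataclasses.asdict(config), "config_hash": config.digest(),
         "engine_version": engine.version},
        outdir / "provenance.json",
    )
    return engine, outdir


def _composition(config: RunConfig) -> CompositionSpec:
    return (CompositionSpec.uniform() if config.gc is None
            else CompositionSpec.from_gc(config.gc))


def _natural_structures(config: RunConfig, engine, L: int):
    if config.natural_fasta is None:
        return None
    path = Path(config.natural_fasta)
    if not path.exists():
        raise FileNotFoundError(
            f"natural FASTA not found: {path}"
        )
    seqs = filter_by_length(read_fasta(path), L)
    return [engine.fold(s) for s in seqs]


def run_shape_study(config: RunConfig) -> dict:
    """Shape frequency tables, rank data, coverage and log-log correlation
    for random sampling (and a natural ensemble when a FASTA is supplied)."""
    engine, outdir = _prepare(config)
    comp = _composition(config)
    rngs = spawn_rngs(config.seed, len(config.lengths))
    summary: dict = {"lengths": {}}
    for L, rng in zip(config.lengths, rngs):
        logger.info("shape study: L=%d, n=%d", L, config.n_random)
        seqs = random_sequences(config.n_random, L, comp, rng,
                                id_prefix=f"rand_L{L}")
        folded = [engine.fold(s) for s in seqs]
        shapes = [abstract_shape(ss.structure) for ss in folded]
        table = shape_frequency_table(shapes)
        io.write_tsv(table, outdir / f"shapes_random_L{L}.tsv")
        entry = {"n_random": config.n_random,
                 "unique_shapes_random": len(table)}
        natural = _natural_structures(config, engine, L)
        if natural is not None:
            nat_table = shape_frequency_table(
                [abstract_shape(ss.structure) for ss in natural]
            )
            io.write_tsv(nat_table, outdir / f"shapes_natural_L{L}.tsv")
            entry["n_natural"] = int(nat_table["count"].sum())
            entry["unique_shapes_natural"] = len(nat_table)
            entry["coverage"] = coverage_fraction(nat_table, table)
            try:
                r, p, n_common = log_log_correlation(table, nat_table)
                entry["log_log_r"] = r
                entry["p_value"] = p
                entry["n_common"] = n_common
            except Exception as exc:  # InsufficientOverlap on tiny runs
                logger.warning("correlation skipped at L=%d: %s", L, exc)
        summary["lengths"][str(L)] = entry
    io.write_json(summary, outdir / "shape_summary.json")
    return summary


def run_trend_study(config: RunConfig) -> dict:
    """Per-structure motif points over the length grid and linear fits,
    for random sequences and (optionally) natural + scrambled ensembles."""
    engine, outdir = _prepare(config)
    rng_random, rng_scramble, rng_fit = spawn_rngs(config.seed, 3)
    points = build_length_grid_dataset(
        engine, config.trend_grid, config.n_per_length,
        _composition(config), rng_random,
    )
    frames = [points]
    if config.natural_fasta is not None:
        nat_seqs = read_fasta(config.natural_fasta)
        nat_seqs = [s for s in nat_seqs
                    if min(config.trend_grid) <= len(s) <= max(config.trend_grid)]
        nat_structures = [engine.fold(s) for s in nat_seqs]
        frames.append(structures_to_motif_points(nat_structures, "natural"))
        scr = [engine.fold(scramble(s, rng_scramble)) for s in nat_seqs]
        frames.append(structures_to_motif_points(scr, "scrambled"))
    import pandas as pd

    all_points = pd.concat(frames, ignore_index=True)
    io.write_tsv(all_points, outdir / "motif_points.tsv")
    fits = fit_all_motifs(all_points, B=config.bootstrap, seed=rng_fit)
    io.write_json([f.as_dict() for f in fits], outdir / "motif_fits.json")
    return {"fits": [f.as_dict() for f in fits],
            "n_points": len(all_points)}


def run_classification_study(config: RunConfig) -> dict:
    """Pseudo-natural vs random feature dataset, kNN and PLSDA results."""
    engine, outdir = _prepare(config)
    rng_sim, rng_cls = spawn_rngs(config.seed, 2)
    spec = PseudoNaturalSpec(**config.synthetic) if config.synthetic \
        else PseudoNaturalSpec(L=config.lengths[0])
    structures, labels = generate_pseudo_natural(spec, engine, rng_sim)
    io.write_fold_records(structures, outdir / "simulated.fold")
    features = make_feature_dataset(structures, labels)
    io.write_tsv(features, outdir / "features.tsv")
    X = features.drop(columns="label").to_numpy(float)
    y = features["label"].to_numpy(int)
    seed_int = int(np.asarray(rng_cls.integers(0, 2**31)))
    results = {
        "knn": knn_cv(X, y, k=config.knn_k, seed=seed_int,
                      B=config.bootstrap).as_dict(),
        "plsda": plsda_cv(X, y, n_components=config.pls_components,
                          seed=seed_int, B=config.bootstrap).as_dict(),
    }
    io.write_json(results, outdir / "classification.json")
    return results


def run_all(config: RunConfig) -> dict:
    return {
        "shapes": run_shape_study(config),
        "trends": run_trend_study(config),
        "classification": run_classification_study(config),
    }
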