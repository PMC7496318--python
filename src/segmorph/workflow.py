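"""End-to-end pipeline orchestration.

A :class:`RunConfig` names the inputs, the stages to run and the method
choices; :func:`run_pipeline` executes the stages in dependency order
(simulate -> measure -> morpho -> stats -> phylo), writes every stage's
outputs under the configured directory, and emits a JSON run report with
seeds, input digests and headline numbers so any run can be reproduced
exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import DataError, InvalidArgumentError
from . import io as sio
from . import morpho, stats
from .ratemodel import BranchRateModel
from .simulate import (
    SEGMENTS,
    default_species_profiles,
    simulate_study,
    simulate_tree,
)
from .trees import Phylogeny
from .phylo import SegmentEvolutionModel

log = logging.getLogger("segmorph")

STAGES = ("simulate", "morpho", "stats", "phylo")


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run."""

    out_dir: str = "segmorph_run"
    stages: tuple = STAGES
    measurements: str | None = None     # CSV path; None => use simulate output
    tree: str | None = None             # Newick path; None => simulated tree
    seed: int = 0
    n_species: int = 12
    n_range: tuple = (105, 145)
    method: str = "tukey"               # or "ttest"
    alpha: float = 0.05
    remove_end: str = "none"            # none | a8tail | ht
    rate_model: str = "ucln"
    mcmc_iters: int = 20_000
    mcmc_thin: int = 10

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise InvalidArgumentError(f"unknown config keys: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "n_range" in raw:
            raw["n_range"] = tuple(raw["n_range"])
        return cls(**raw)


def _digest(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config):
    """Execute the configured stages and return the run report (dict)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in config.stages]
    report = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": stages,
        "inputs": {},
        "warnings": [],
        "headline": {},
    }
    # -- resolve inputs up front so a bad config fails before any work
    need_measure = {"morpho", "stats", "phylo"} & set(stages)
    if need_measure and "simulate" not in stages and not config.measurements:
        raise DataError("stages morpho/stats/phylo need a measurements CSV or the simulate stage")
    if config.measurements and not Path(config.measurements).exists():
        raise DataError(f"measurements file not found: {config.measurements}")
    if config.tree and not Path(config.tree).exists():
        raise DataError(f"tree file not found: {config.tree}")

    measurements = None
    tree = None
    if "simulate" in stages:
        profiles = default_species_profiles()[: config.n_species]
        measurements = simulate_study(profiles, n_range=config.n_range, seed=config.seed)
        sio.write_measurements(measurements, out / "measurements.csv")
        tree = simulate_tree(len(profiles), seed=config.seed, labels=[p.species_id for p in profiles])
        tree.write_newick(out / "tree.nwk")
        report["inputs"]["measurements"] = {"path": "simulated", "n_larvae": int(measurements["larva_id"].nunique())}
        log.info("simulate: %d species, %d larvae", len(profiles), measurements["larva_id"].nunique())
    if config.measurements:
        measurements = sio.load_measurements(config.measurements)
        report["inputs"]["measurements"] = {"path": config.measurements, "sha256": _digest(config.measurements)}
    if config.tree:
        tree = Phylogeny.from_newick(config.tree)
        report["inputs"]["tree"] = {"path": config.tree, "sha256": _digest(config.tree)}

    rel = summary = None
    if "morpho" in stages:
        rel = morpho.relative_positions(measurements)
        if config.remove_end != "none":
            rel = morpho.remove_end(measurements, config.remove_end)
        rel.to_csv(out / "relative_positions.csv", index=False)
        summary = morpho.species_summary(rel)
        summary.per_segment.to_csv(out / "species_summary.csv", index=False)
        summary.per_species.to_csv(out / "species_lengths.csv")
        cv, mean_cv = morpho.coefficient_of_variation(rel)
        cv.to_csv(out / "cv.csv", index=False)
        try:
            pca = morpho.pca_segments(rel)
            report["headline"]["pc1_variance_pct"] = float(100 * pca.variance_explained[0])
        except InvalidArgumentError:
            pca = None
        report["headline"]["mean_cv"] = float(mean_cv.mean())
        log.info("morpho: mean CV %.4f", mean_cv.mean())

    if "stats" in stages:
        if rel is None:
            rel = morpho.relative_positions(measurements)
            summary = morpho.species_summary(rel)
        fn = stats.tukey_pairwise if config.method == "tukey" else stats.ttest_bonferroni
        matrix = fn(rel, alpha=config.alpha)
        counts = stats.count_and_correct(matrix)
        sio.write_json({k: v for k, v in counts.items() if k != "pair_counts"}, out / "difference_counts.json")
        counts["pair_counts"].to_csv(out / "pair_counts.csv", index=False)
        for seg, mat in matrix.indicators.items():
            mat.to_csv(out / f"significant_{seg}.tsv", sep="\t")
        profile = stats.within_species_correlations(rel)
        profile.to_csv(out / "within_species_correlations.csv", index=False)
        report["headline"]["total_differences"] = counts["total"]
        report["headline"]["corrected_total"] = counts["corrected_total"]
        log.info("stats: %d total differences (corrected %.2f)", counts["total"], counts["corrected_total"])

    if "phylo" in stages:
        if tree is None:
            raise DataError("phylo stage needs a tree (Newick input or the simulate stage)")
        if rel is None:
            rel = morpho.relative_positions(measurements)
        tips = rel.pivot_table(index="species", columns="segment", values="p")
        segs = [s for s in SEGMENTS if s in tips.columns]
        tips = tips[segs]
        model = SegmentEvolutionModel(tree, tips, rate_model=BranchRateModel(config.rate_model))
        res = model.fit(n_iter=config.mcmc_iters, thin=config.mcmc_thin, seed=config.seed)
        res.summary().to_csv(out / "posterior_summary.csv")
        res.ancestral_states().to_csv(out / "ancestral_states.csv", index=False)
        bc = res.branch_changes()
        bc.per_branch.to_csv(out / "branch_changes.csv", index=False)
        report["warnings"].extend(res.warnings)
        rates = res.rate_frame().mean()
        report["headline"]["max_branch_rate_posterior_mean"] = float(rates.max())
        report["headline"]["sigma2_posterior_mean"] = res.sigma2_frame().mean().to_dict()
        log.info("phylo: done (%d samples)", res.n_samples)

    with open(out / "run_report.json", "w") as fh:
        json.dump(sio._jsonable(report), fh, indent=1)
    return report
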