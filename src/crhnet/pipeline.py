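"""End-to-end orchestration and cross-method overlap accounting.

:func:`run_pipeline` wires the stages together — synthetic (or loaded)
intensities -> normalization -> ANOVA prefilter -> the four selectors ->
GA consensus -> PCA / GGM on the candidate genes — writing every artifact
plus a manifest of seeds and parameters to the run directory.
:func:`overlap_report` reproduces the method-comparison accounting
(intersections of ranked lists at a stated cut).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annealing, anova, baselines, ga, io, network, preprocess
from .containers import RatioMatrix
from .synthetic import SyntheticConfig, generate_intensity_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage toggles and parameters of one pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    out_dir: str = "crhnet_run"
    seed: int = 0
    background_fraction: float = 0.10
    loess_span: float = 0.75
    interaction_alpha: float = 0.01
    time_alpha: float = 0.01
    ga_params: ga.GaParams = field(default_factory=ga.GaParams)
    sa_params: annealing.SaParams = field(default_factory=annealing.SaParams)
    greedy_alpha: float = 0.001
    rf_params: baselines.RfParams = field(default_factory=baselines.RfParams)
    n_repetitions: int = 4
    consensus_top: int = 50
    consensus_min_runs: int = 3
    pcor_min: float = 0.35
    p_max: float = 0.05
    run_ga: bool = True
    run_insel: bool = True
    run_greedy: bool = True
    run_rf: bool = True
    run_network: bool = True


def load_pipeline_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Top-level keys mirror the dataclass fields; the nested ``synthetic``,
    ``ga_params``, ``sa_params`` and ``rf_params`` mappings mirror their
    respective parameter dataclasses.  Unknown keys raise.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    nested = {
        "synthetic": SyntheticConfig,
        "ga_params": ga.GaParams,
        "sa_params": annealing.SaParams,
        "rf_params": baselines.RfParams,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in nested:
            kwargs[key] = nested[key](**value)
        elif key in PipelineConfig.__dataclass_fields__:
            kwargs[key] = value
        else:
            raise ValueError(f"unknown pipeline config key: {key!r}")
    return PipelineConfig(**kwargs)


def overlap_report(lists: dict) -> pd.DataFrame:
    """Pairwise intersection accounting between named gene lists.

    Each row reports |A intersect B|, the two list sizes, and the overlap
    fraction relative to the smaller list ("x of y candidates").  Empty
    lists yield fraction 0 with a flag.
    """
    names = list(lists)
    if len(names) < 2:
        raise ValueError("need at least two lists to compare")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = set(lists[a]), set(lists[b])
            inter = len(sa & sb)
            denom = min(len(sa), len(sb))
            rows.append({
                "list_a": a, "list_b": b,
                "intersection": inter,
                "size_a": len(sa), "size_b": len(sb),
                "fraction": inter / denom if denom else 0.0,
                "empty": denom == 0,
            })
    return pd.DataFrame(rows)


def _stage(manifest: dict, name: str):
    manifest["stages"].append(name)
    logger.info("pipeline stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the in-memory results.

    A failing stage aborts with its name in the exception while artifacts
    of completed stages remain on disk.  Every stage seed derives
    deterministically from the master seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % 2**31
    manifest: dict = {
        "seed": config.seed,
        "stages": [],
        "parameters": {
            "background_fraction": config.background_fraction,
            "loess_span": config.loess_span,
            "interaction_alpha": config.interaction_alpha,
            "time_alpha": config.time_alpha,
            "ga": vars(config.ga_params),
            "sa": vars(config.sa_params),
            "greedy_alpha": config.greedy_alpha,
            "rf": vars(config.rf_params),
            "n_repetitions": config.n_repetitions,
            "consensus_top": config.consensus_top,
            "consensus_min_runs": config.consensus_min_runs,
            "pcor_min": config.pcor_min,
            "p_max": config.p_max,
            "synthetic": {
                k: v for k, v in vars(config.synthetic).items()
                if not isinstance(v, dict)
            },
        },
    }
    results: dict = {"manifest": manifest}

    def _run(name, fn):
        _stage(manifest, name)
        try:
            return fn()
        except Exception as exc:
            io.write_json(manifest, out / "manifest.json")
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    def _synthetic():
        cfg = SyntheticConfig(
            **{**vars(config.synthetic), "seed": int(seeds[0])}
        )
        arrays, truth = generate_intensity_dataset(cfg)
        io.write_truth(truth, out / "truth.json")
        return arrays, truth

    arrays, truth = _run("synthetic_data", _synthetic)
    results["truth"] = truth

    def _preprocess():
        matrix = preprocess.normalize_pipeline(
            arrays, config.background_fraction, config.loess_span
        )
        io.write_ratio_matrix(
            matrix, out / "ratios.tsv", out / "samples.tsv"
        )
        return matrix

    matrix: RatioMatrix = _run("preprocess", _preprocess)
    results["matrix"] = matrix

    def _prefilter():
        res = anova.prefilter(
            matrix, config.interaction_alpha, config.time_alpha
        )
        res.preselected.to_csv(out / "preselected.tsv", sep="\t")
        res.excluded.to_csv(out / "excluded_interaction.tsv", sep="\t")
        res.anova_interaction.to_csv(out / "anova_interaction.tsv", sep="\t")
        res.anova_time.to_csv(out / "anova_time.tsv", sep="\t")
        return res

    pre = _run("prefilter", _prefilter)
    results["prefilter"] = pre
    pool = matrix.subset(pre.preselected_ids) if len(pre.preselected) else matrix
    results["pool"] = pool

    top_lists: dict = {}

    if config.run_ga:
        def _ga():
            params = ga.GaParams(
                **{**vars(config.ga_params), "seed": int(seeds[1])}
            )
            runs = ga.repeated_runs(pool, params, config.n_repetitions)
            for i, r in enumerate(runs, 1):
                io.write_ranked_list(r.ranking, out / f"ga_run{i}.tsv")
            cons = ga.consensus(
                runs, config.consensus_top, config.consensus_min_runs
            )
            pd.Series(cons, name="gene").to_csv(
                out / "ga_consensus.tsv", sep="\t", index=False
            )
            return runs, cons

        ga_runs, ga_cons = _run("ga_select", _ga)
        results["ga_runs"], results["ga_consensus"] = ga_runs, ga_cons
        top_lists["ga_top"] = ga_runs[0].top(config.consensus_top)
        top_lists["ga_consensus"] = ga_cons

    if config.run_insel:
        def _insel():
            params = annealing.SaParams(
                **{**vars(config.sa_params), "seed": int(seeds[2])}
            )
            run = annealing.run_insel(pool, params)
            io.write_ranked_list(run.ranking, out / "insel.tsv")
            return run

        insel_run = _run("sa_select", _insel)
        results["insel"] = insel_run
        top_lists["insel_top"] = insel_run.top(config.consensus_top)

    if config.run_greedy:
        def _greedy():
            run = baselines.greedy_loocv(pool, config.greedy_alpha)
            io.write_ranked_list(run.ranking, out / "greedy.tsv")
            return run

        greedy_run = _run("baseline_greedy", _greedy)
        results["greedy"] = greedy_run
        top_lists["greedy"] = list(greedy_run.ranking.index)

    if config.run_rf:
        def _rf():
            params = baselines.RfParams(
                **{**vars(config.rf_params), "seed": int(seeds[3])}
            )
            run = baselines.rf_rank(pool, params)
            io.write_ranked_list(run.ranking, out / "rf.tsv")
            return run

        rf_run = _run("baseline_rf", _rf)
        results["rf"] = rf_run
        top_lists["rf_top"] = rf_run.top(config.consensus_top)

    if len(top_lists) >= 2:
        def _overlap():
            rep = overlap_report(top_lists)
            rep.to_csv(out / "overlap.tsv", sep="\t", index=False)
            return rep

        results["overlap"] = _run("overlap_report", _overlap)

    if config.run_network:
        def _network():
            candidates = results.get("ga_consensus") or list(
                pool.gene_ids[: min(11, pool.n_genes)]
            )
            candidates = [g for g in candidates if g in pool.values.index]
            if len(candidates) < 3:
                candidates = pool.gene_ids[: min(11, pool.n_genes)]
            sub = pool.values.loc[candidates]
            pca = network.pca_biplot(sub)
            pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
            pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
            net = network.infer_network(
                sub, time_points=pool.time,
                pcor_min=config.pcor_min, p_max=config.p_max,
            )
            io.write_network(net, out / "edges.tsv", out / "network.graphml")
            return pca, net

        results["pca"], results["network"] = _run("network", _network)

    io.write_json(manifest, out / "manifest.json")
    return results
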