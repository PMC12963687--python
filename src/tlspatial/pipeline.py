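"""End-to-end report pipeline: simulate (or load) -> score -> classify ->
co-occurrence + permutation tests -> hotspots -> TLS regions + maturity ->
cohort LOO, with provenance.

All randomness flows from one root seed, split deterministically per stage;
identical config + seed gives byte-identical JSON results.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, loo_influence, rank_influence
from .cooccurrence import (
    CLASS_NAMES,
    RadialBins,
    binarize_scores,
    cooccurrence_curve,
    cooccurrence_permutation_test,
    pair_classes,
)
from .data import GeneSignature, SpatialDataset, read_visium_like, write_visium_like
from .hotspot import call_hotspots, knn_neighbors, local_gi_star
from .scoring import mean_z_scores, ssgsea_scores
from .simulate import (
    METABOLIC_SIGNATURE,
    TLS_SIGNATURE,
    SyntheticSpatialConfig,
    config_record,
    simulate_cohort,
    simulate_spatial,
)
from .tls import call_tls_regions, classify_maturity, panel_reference, region_features

__all__ = ["RunConfig", "PipelineStageError", "run_report"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one report run.

    Defaults follow the analysis conventions: co-occurrence evaluated over
    0-6000 um in 30 cumulative bins, 1000 label permutations, binarization at
    the 0.90 score quantile, KNN with k = 6 (hex adjacency), hotspot and
    permutation alpha 0.05.
    """

    out_dir: str = "tlspatial_report"
    bundle: str | None = None  # load instead of simulate when set
    sim: SyntheticSpatialConfig = field(default_factory=SyntheticSpatialConfig)
    scoring_method: str = "mean_z"  # or "ssgsea"
    ssgsea_alpha: float = 0.25
    binarize_rule: str = "quantile"
    binarize_q: float = 0.90
    max_distance_um: float = 6000.0
    n_bins: int = 30
    n_perm: int = 1000
    alternative: str = "greater"
    k: int = 6
    hotspot_alpha: float = 0.05
    tls_quantile: float = 0.75
    cohort_n_samples: int = 26
    cohort_n_high: int = 13
    cohort_effect_delta: float = -0.08
    seed: int = 0


def _stage_seeds(root_seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _score(dataset: SpatialDataset, signature, config: RunConfig):
    if config.scoring_method == "mean_z":
        return mean_z_scores(dataset, signature)
    if config.scoring_method == "ssgsea":
        return ssgsea_scores(dataset, signature, weight_exponent=config.ssgsea_alpha)
    raise ValueError(f"unknown scoring method {config.scoring_method!r}")


def run_report(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict of the in-memory results; all tables, curves, JSON
    records and a provenance file are written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    results: dict = {}
    seeds = dict(zip(["sim", "perm", "cohort"], _stage_seeds(config.seed, 3)))

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                value = fn()
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise PipelineStageError(name, exc) from exc
            log_lines.append(
                f"{name}: ok ({time.perf_counter() - t0:.2f}s, seed={seeds.get(name)})"
            )
            return value

        return wrap

    truth = None
    if config.bundle is not None:
        dataset = stage("load")(lambda: read_visium_like(config.bundle))
    else:
        def _simulate():
            sim_cfg = SyntheticSpatialConfig(**{**asdict(config.sim), "seed": seeds["sim"]})
            return simulate_spatial(sim_cfg), sim_cfg

        (dataset, truth), sim_cfg = stage("sim")(_simulate)
        write_visium_like(dataset, out / "bundle")
        pd.DataFrame(
            {
                "spot_id": dataset.spot_ids,
                "tls_mask": truth.tls_mask.astype(int),
                "met_mask": truth.met_mask.astype(int),
            }
        ).to_csv(out / "truth.csv", index=False)
    results["dataset"] = dataset
    results["truth"] = truth

    tls_scores = stage("score_tls")(lambda: _score(dataset, TLS_SIGNATURE, config))
    met_scores = stage("score_met")(lambda: _score(dataset, METABOLIC_SIGNATURE, config))
    pd.DataFrame(
        {
            "spot_id": dataset.spot_ids,
            "tls_score": tls_scores.scores,
            "met_score": met_scores.scores,
        }
    ).to_csv(out / "scores.csv", index=False)

    def _classify():
        q = config.binarize_q if config.binarize_rule == "quantile" else None
        a = binarize_scores(tls_scores, rule=config.binarize_rule, q=q)
        b = binarize_scores(met_scores, rule=config.binarize_rule, q=q)
        return pair_classes(
            a, b, spot_ids=dataset.spot_ids,
            marker_a=TLS_SIGNATURE.name, marker_b=METABOLIC_SIGNATURE.name,
        )

    labels = stage("classify")(_classify)
    results["labels"] = labels
    pd.DataFrame({"spot_id": dataset.spot_ids, "label": labels.labels}).to_csv(
        out / "labels.csv", index=False
    )

    bins = RadialBins.regular(config.max_distance_um, config.n_bins)
    present = [c for c in CLASS_NAMES if labels.counts()[c] > 0]

    def _curves():
        rows = []
        for c in present:
            curve = cooccurrence_curve(dataset.coords, labels, c, c, bins)
            for edge, ratio, count in zip(curve.edges[1:], curve.ratio, curve.pair_counts):
                rows.append((c, c, float(edge), float(ratio), int(count)))
        return pd.DataFrame(
            rows, columns=["condition", "target", "radius_um", "ratio", "pairs"]
        )

    curves = stage("cooccur")(_curves)
    curves.to_csv(out / "curves.csv", index=False)
    results["curves"] = curves

    def _permtests():
        out_tests = {}
        for i, c in enumerate(present):
            res = cooccurrence_permutation_test(
                dataset.coords,
                labels,
                c,
                c,
                bins,
                n_perm=config.n_perm,
                alternative=config.alternative,
                max_eval_radius=config.max_distance_um,
                seed=seeds["perm"] + i,
            )
            out_tests[c] = res
        return out_tests

    permtests = stage("permtest")(_permtests)
    results["permtests"] = permtests
    perm_json = {
        c: {
            "observed": r.observed,
            "pvalue": r.pvalue,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "alternative": r.alternative,
            "n_perm": r.n_perm,
            "seed": r.seed,
            "statistic": r.statistic,
        }
        for c, r in permtests.items()
    }
    with open(out / "permtests.json", "w") as fh:
        json.dump(perm_json, fh, indent=2, sort_keys=True)

    def _hotspots():
        graph = knn_neighbors(dataset.coords, k=config.k)
        z = local_gi_star(tls_scores.scores, graph)
        return graph, call_hotspots(z, alpha=config.hotspot_alpha)

    graph, hotspots = stage("hotspot")(_hotspots)
    results["hotspots"] = hotspots
    pd.DataFrame(
        {
            "spot_id": dataset.spot_ids,
            "gi_star_z": hotspots.z,
            "pvalue": hotspots.pvalue,
            "qvalue": hotspots.qvalue,
            "hotspot": hotspots.flag.astype(int),
        }
    ).to_csv(out / "hotspots.csv", index=False)

    def _tls_regions():
        regions = call_tls_regions(tls_scores, hotspots, graph, quantile=config.tls_quantile)
        feats = []
        if (regions >= 0).any():
            # GC-like presence proxy: proportion of region spots whose
            # germinal-center panel score clears the global 0.75 quantile.
            gc_sig = mean_z_scores(
                dataset,
                GeneSignature(name="GC_panel", genes=("AICDA", "CD38", "IGHG1")),
            )
            gc_thr = float(np.quantile(gc_sig.scores, 0.75))
            presence = {
                int(rid): float(np.mean(gc_sig.scores[regions == rid] > gc_thr))
                for rid in sorted(set(regions[regions >= 0]))
            }
            feats = region_features(dataset, regions, gc_like_presence=presence)
        return regions, feats

    regions, feats = stage("tls")(_tls_regions)
    results["regions"] = regions
    pd.DataFrame({"spot_id": dataset.spot_ids, "region": regions}).to_csv(
        out / "regions.csv", index=False
    )

    def _maturity():
        if not feats:
            return []
        ref = panel_reference(feats)
        return [classify_maturity(f, ref) for f in feats]

    calls = stage("maturity")(_maturity)
    results["maturity"] = calls
    pd.DataFrame(
        [
            {
                "region": m.region_id,
                "call": m.call,
                "criterion_molecular": m.criterion_molecular,
                "criterion_gc_cells": m.criterion_gc_cells,
            }
            for m in calls
        ]
    ).to_csv(out / "maturity.csv", index=False)

    def _loo():
        cohort = simulate_cohort(
            n_samples=config.cohort_n_samples,
            n_high=config.cohort_n_high,
            effect_delta=config.cohort_effect_delta,
            seed=seeds["cohort"],
        )
        return cohort, loo_influence(cohort)

    cohort, loo = stage("loo")(_loo)
    results["cohort"] = cohort
    results["loo"] = loo
    cohort.to_frame().to_csv(out / "cohort.csv", index=False)
    rank_influence(loo).to_csv(out / "loo.csv", index=False)

    provenance = {
        "package": "tlspatial",
        "version": __version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "sim"},
            "sim": config_record(config.sim),
        },
        "stage_seeds": seeds,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    results["out_dir"] = out
    return results
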