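"""End-to-end orchestration of the six analysis stages.

``run_pipeline`` executes build/simulate → layer statistics → reducibility →
word scores → normative-ordering sampling → evaluation → weight
optimization, writing each stage's outputs plus a manifest (seeds, stage
timers, output paths) that makes a run exactly reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import defaults, io
from .aoa import sample_aoa_ensemble, spawn_seeds, rank_by_score
from .build import (
    build_association_layer,
    build_cooccurrence_layer,
    build_feature_layer,
    build_phonological_layer,
    intersect_vocabulary,
)
from .centrality import attribute_score, layer_centrality, multiplex_centrality
from .core import Vocabulary, aggregate, is_connected_multiplex
from .evaluate import StageWindows, gain_curve, random_baseline, significance, stage_report
from .optimize import DEParams, OptimizationConfig, optimize_weights, randomized_multiplex_control
from .synth import SyntheticSpec, generate_dataset
from .topology import (
    configuration_model_ensemble,
    cross_layer_degree_correlation,
    edge_overlap,
    layer_summary,
    reducibility_analysis,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full run; loadable from YAML via :meth:`from_yaml`."""

    mode: str = "synthetic"  # synthetic | real
    # real-data inputs
    assoc_path: Optional[str] = None
    feat_path: Optional[str] = None
    cooc_path: Optional[str] = None
    phon_path: Optional[str] = None
    cdi_list_path: Optional[str] = None
    norms_path: Optional[str] = None
    # synthetic-spec overrides (N, aoa_noise_sd, ...)
    synthetic: dict = field(default_factory=dict)
    # analysis parameters
    cooc_threshold: int = defaults.COOCCURRENCE_THRESHOLD
    cdi_threshold: float = defaults.CDI_KNOWN_THRESHOLD
    n_null_samples: int = defaults.N_NULL_SAMPLES
    n_aoa_orderings: int = defaults.N_AOA_ORDERINGS
    n_holdout_configs: int = defaults.N_HOLDOUT_CONFIGS
    holdout_fraction: float = defaults.HOLDOUT_FRACTION
    n_direct_samples: int = defaults.N_DIRECT_SAMPLES
    optimize_metric: str = "degree"
    run_control: bool = True
    de_maxiter: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "real":
            paths = {
                "assoc_path": self.assoc_path,
                "feat_path": self.feat_path,
                "cooc_path": self.cooc_path,
                "phon_path": self.phon_path,
                "cdi_list_path": self.cdi_list_path,
                "norms_path": self.norms_path,
            }
            for key, p in paths.items():
                if p is None:
                    raise ValueError(f"real-data mode requires {key}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{key}: no such file {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _build_real(cfg: PipelineConfig):
    cdi_words = io.read_cdi_list(cfg.cdi_list_path)
    superset = Vocabulary(sorted(set(cdi_words)))
    layers = [
        build_association_layer(io.read_association_tsv(cfg.assoc_path), superset),
        build_feature_layer(io.read_feature_tsv(cfg.feat_path), superset),
        build_cooccurrence_layer(
            io.read_cooccurrence_tsv(cfg.cooc_path), superset, cfg.cooc_threshold
        ),
        build_phonological_layer(io.read_phonological_tsv(cfg.phon_path), superset),
    ]
    mln = intersect_vocabulary(cdi_words, layers)
    norms = io.read_cdi_norms_csv(cfg.norms_path)
    norms.production = norms.production.loc[list(mln.vocabulary.ids)]
    return mln, norms, None


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Run every stage, write outputs under ``out_dir``, return the manifest."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "status": "running"}
    seeds = spawn_seeds(cfg.seed, 6)

    def stage(name):
        manifest["stages"][name] = {"t_start": time.time(), "outputs": []}
        return manifest["stages"][name]

    def done(rec, *paths):
        rec["outputs"] = [str(p) for p in paths]
        rec["seconds"] = round(time.time() - rec.pop("t_start"), 3)

    try:
        # stage 1: build or simulate
        rec = stage("build")
        if cfg.mode == "synthetic":
            spec = SyntheticSpec(**{**cfg.synthetic, "seed": seeds[0]})
            ds = generate_dataset(spec)
            mln, norms = ds.mln, ds.norms
            ds.attributes.to_csv(out / "attributes.csv", index=False)
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(ds.ground_truth, fh, indent=1)
        else:
            mln, norms, _ = _build_real(cfg)
        io.write_multiplex_edges(mln, out / "mln.edges")
        io.write_vocabulary_csv(mln.vocabulary, out / "vocab.csv")
        io.write_cdi_norms_csv(norms, out / "cdi.csv")
        done(rec, out / "mln.edges", out / "vocab.csv", out / "cdi.csv")
        n = len(mln.vocabulary)

        # stage 2: topology vs configuration models
        rec = stage("stats")
        nulls = {
            l.name: configuration_model_ensemble(
                l, cfg.n_null_samples, defaults.N_SWAPS_PER_EDGE, s, vocab=mln.vocabulary
            )
            for l, s in zip(mln.layers, spawn_seeds(seeds[1], mln.n_layers))
        }
        stats = {
            l.name: {
                "observed": layer_summary(l, vocab=mln.vocabulary).as_dict(),
                "cm_mean": nulls[l.name].stat_means,
                "cm_sd": nulls[l.name].stat_sds,
            }
            for l in mln.layers
        }
        agg = aggregate(mln, weighted=False)
        from .core import Layer as _Layer

        stats["aggregate"] = {
            "observed": layer_summary(
                _Layer("aggregate", agg.edges), vocab=mln.vocabulary
            ).as_dict(),
            "connected": is_connected_multiplex(mln),
        }
        tau = cross_layer_degree_correlation(mln)
        ov = edge_overlap(mln, nulls)
        import pandas as pd

        names = list(mln.layer_names)
        pd.DataFrame(tau.tau, index=names, columns=names).to_csv(out / "kendall_tau.csv")
        pd.DataFrame(ov.observed, index=names, columns=names).to_csv(out / "overlap.csv")
        pd.DataFrame(ov.zscore, index=names, columns=names).to_csv(out / "overlap_z.csv")
        with open(out / "stats.json", "w") as fh:
            json.dump(stats, fh, indent=1)
        done(rec, out / "stats.json", out / "kendall_tau.csv", out / "overlap.csv")

        # stage 3: reducibility
        rec = stage("reduce")
        red = reducibility_analysis(mln)
        with open(out / "reducibility.json", "w") as fh:
            json.dump(
                {
                    "verdict": red.verdict,
                    "quality": red.quality,
                    "jsd": red.jsd.tolist(),
                    "layers": names,
                },
                fh,
                indent=1,
            )
        (out / "dendrogram.nwk").write_text(red.to_newick() + "\n")
        done(rec, out / "reducibility.json", out / "dendrogram.nwk")

        # stage 4: word scores
        rec = stage("score")
        tables = [multiplex_centrality(mln, "closeness"), multiplex_centrality(mln, "pagerank")]
        for l in mln.layers:
            tables.append(layer_centrality(l, "degree", mln.vocabulary))
        if all(w.frequency is not None for w in mln.vocabulary):
            tables.append(attribute_score(mln.vocabulary, "frequency"))
        if all(w.length is not None for w in mln.vocabulary):
            tables.append(attribute_score(mln.vocabulary, "neg_length"))
        io.write_scores_csv(tables, out / "scores.csv")
        done(rec, out / "scores.csv")

        # stage 5: normative orderings
        rec = stage("sample_aoa")
        refs = sample_aoa_ensemble(norms, cfg.n_aoa_orderings, seeds[2], cfg.cdi_threshold)
        io.write_trajectories_csv(refs, out / "aoa.csv")
        done(rec, out / "aoa.csv")

        # stage 6: evaluation
        rec = stage("evaluate")
        base = random_baseline(n)
        curves = []
        sig_seeds = spawn_seeds(seeds[3], len(tables))
        for tbl, s in zip(tables, sig_seeds):
            pred = rank_by_score(tbl, tie_policy="expected")
            c = gain_curve(pred, refs, base)
            c = significance(c, base, refs, n_direct=max(1000, cfg.n_direct_samples), seed=s)
            curves.append(c)
        io.write_gain_curves_csv(curves, out / "gains.csv")
        month_to_t = norms.inventory_size_by_month(cfg.cdi_threshold)
        report = stage_report(curves, StageWindows(), month_to_t)
        report.to_csv(out / "stage_report.csv", index=False)
        done(rec, out / "gains.csv", out / "stage_report.csv")

        # stage 7: layer-influence optimization
        rec = stage("optimize")
        opt_cfg = OptimizationConfig(
            metric=cfg.optimize_metric,
            holdout_fraction=cfg.holdout_fraction,
            n_holdout_configs=cfg.n_holdout_configs,
            n_aoa_orderings=cfg.n_aoa_orderings,
            de=DEParams(maxiter=cfg.de_maxiter),
            seed=seeds[4],
        )
        res = optimize_weights(opt_cfg, mln, refs)
        payload = {
            "mean_weights": dict(res.mean_weights.weights),
            "sd_weights": res.sd_weights,
            "per_run_weights": res.per_run_weights,
            "mean_objective": res.mean_objective,
        }
        if cfg.run_control:
            ctl = randomized_multiplex_control(opt_cfg, mln, refs)
            payload["control_mean_weights"] = dict(ctl.mean_weights.weights)
            payload["control_mean_objective"] = ctl.mean_objective
        with open(out / "opt.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        done(rec, out / "opt.json")
        manifest["status"] = "complete"
    except Exception as exc:  # record partial completion, then re-raise
        manifest["status"] = f"failed: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
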