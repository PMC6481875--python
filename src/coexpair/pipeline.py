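"""End-to-end orchestration: config, staged execution, reproducible artifacts.

The pipeline sequences the analysis stages in their natural order:
filter -> align -> cross-correlation (per tissue pair) -> permutation null
and eFDR -> edge extraction -> connectivity -> clustering -> module
summaries -> signature selection -> dendrogram equivalence -> enrichment
(+ bootstrap).  All outputs are plain TSV/JSON/Newick/SIF; every artifact
directory carries a ``run_meta.json`` with the config hash and the master
seed, and identical config + seed reproduce every file byte for byte.

Randomness: one master seed; each randomized stage derives a sub-seed
deterministically via ``numpy.random.SeedSequence.spawn`` ordering, so
rerunning a single stage reproduces the full-run output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import connectivity as conn
from . import core, correlation, dendro, efdr, enrichment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "load_config"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    study_manifest: Optional[str] = None
    simulate: Optional[dict] = None
    pairs: list = field(default_factory=list)
    permuted_tissue: Optional[str] = None
    min_level: float = 1.0
    min_units: int = 4
    B: int = 100
    seed: int = 0
    thresholds: Optional[list] = None
    r_threshold: float = 0.95
    efdr_target: Optional[float] = 0.01
    signature_r_threshold: float = 0.9999
    cluster_k: Optional[int] = None
    cluster_height: Optional[float] = None
    cluster_method: str = "complete"
    cluster_metric: str = "euclidean"
    gmt: dict = field(default_factory=dict)  # tissue -> GMT path
    enrichment_fdr_max: float = 0.2
    bootstrap_rounds: int = 2000
    out_dir: str = "coexpair_out"

    def __post_init__(self) -> None:
        if (self.study_manifest is None) == (self.simulate is None):
            raise ValueError("give exactly one of study_manifest or simulate")
        if not self.pairs:
            raise ValueError("no tissue pairs configured")
        for pair in self.pairs:
            if len(pair) != 2:
                raise ValueError(f"pair must have 2 tissues: {pair}")
        if self.study_manifest is not None and not Path(self.study_manifest).exists():
            raise ValueError(f"study manifest not found: {self.study_manifest}")
        for tissue, path in self.gmt.items():
            if not Path(path).exists():
                raise ValueError(f"GMT for {tissue!r} not found: {path}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    def config_hash(self) -> str:
        fields = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = PipelineConfig(**raw)
    # resolve relative paths against the config file
    base = Path(path).parent
    if cfg.study_manifest and not Path(cfg.study_manifest).is_absolute():
        cfg.study_manifest = str(base / cfg.study_manifest)
    cfg.gmt = {
        t: str(p if Path(p).is_absolute() else base / p) for t, p in cfg.gmt.items()
    }
    return cfg


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


@_stage("load")
def _load_study(cfg: PipelineConfig) -> core.PairedStudy:
    if cfg.study_manifest is not None:
        return core.load_study_manifest(cfg.study_manifest)
    from .simulate import SimulationConfig, generate_paired_study

    sim = SimulationConfig(**{"seed": cfg.seed, **cfg.simulate})
    study, _ = generate_paired_study(sim)
    return study


def _validate_tissues(cfg: PipelineConfig, study: core.PairedStudy) -> None:
    named = {t for pair in cfg.pairs for t in pair}
    if cfg.permuted_tissue:
        named.add(cfg.permuted_tissue)
    missing = sorted(named - set(study.tissues))
    if missing:
        raise PipelineStageError(
            "validate", ValueError(f"tissues named in config but absent: {missing}")
        )


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and return the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict[str, Any] = {
        "config_hash": cfg.config_hash(),
        "seed": int(cfg.seed),
        "stages": [],
    }
    study = _load_study(cfg)
    _validate_tissues(cfg, study)

    # expression filter (per tissue, FPKM scale only)
    @_stage("filter")
    def do_filter():
        mats = []
        for t in study.tissues:
            m = study[t]
            mats.append(
                core.filter_expressed(m, cfg.min_level, cfg.min_units)
                if m.scale == "fpkm"
                else m
            )
        return core.align_paired_study(mats)

    filtered = do_filter()
    for t in filtered.tissues:
        core.write_expression_table(filtered[t], out / f"expressed_{t}.tsv")
    meta["stages"].append("filter")

    seed_seq = np.random.SeedSequence(cfg.seed)
    pair_seeds = seed_seq.spawn(len(cfg.pairs))
    summary: dict[str, Any] = {}

    for pair_idx, (t_a, t_b) in enumerate(cfg.pairs):
        tag = f"{t_a}-{t_b}"
        sub_seed = int(pair_seeds[pair_idx].generate_state(1)[0] % (2**31))

        @_stage(f"corr[{tag}]")
        def do_corr():
            return correlation.cross_correlation_matrix(filtered[t_a], filtered[t_b])

        R = do_corr()

        @_stage(f"efdr[{tag}]")
        def do_efdr():
            permuted = cfg.permuted_tissue or t_a
            null = efdr.scramble_pairing(filtered, permuted, cfg.B, seed=sub_seed)
            other = t_b if permuted == t_a else t_a
            grid = (
                np.asarray(cfg.thresholds, dtype=float)
                if cfg.thresholds
                else efdr.default_threshold_grid()
            )
            counts, total = efdr.null_tail_counts(filtered, permuted, other, null, grid)
            curve = efdr.efdr_curve_from_counts(counts, R.n_defined, cfg.B, grid)
            return null, curve

        null, curve = do_efdr()
        curve.to_frame().to_csv(out / f"efdr_{tag}.tsv", sep="\t", index=False)
        with open(out / f"permutations_{tag}.json", "w") as fh:
            json.dump(null.as_unit_sequences(), fh)

        @_stage(f"edges[{tag}]")
        def do_edges():
            t = cfg.r_threshold
            if cfg.efdr_target is not None:
                t_for_target = efdr.threshold_for_efdr(curve, cfg.efdr_target)
                if t_for_target is not None:
                    t = max(t, t_for_target)
            return correlation.significant_edges(R, t, efdr.efdr_at(curve, t)), t

        edges, used_threshold = do_edges()
        correlation.write_edges_tsv(edges, out / f"edges_{tag}.tsv")
        correlation.write_edges_sif(edges, out / f"edges_{tag}.sif")

        @_stage(f"connectivity[{tag}]")
        def do_connectivity():
            d_a = conn.degree_summary(edges, t_a, filtered[t_a].gene_ids)
            d_b = conn.degree_summary(edges, t_b, filtered[t_b].gene_ids)
            return d_a, d_b

        d_a, d_b = do_connectivity()
        deg = d_a.degrees.rename("degree").to_frame()
        deg.insert(0, "tissue", t_a)
        deg_b = d_b.degrees.rename("degree").to_frame()
        deg_b.insert(0, "tissue", t_b)
        deg.index.name = deg_b.index.name = "gene_id"
        import pandas as pd

        pd.concat([deg, deg_b]).to_csv(out / f"degrees_{tag}.tsv", sep="\t")

        @_stage(f"cluster[{tag}]")
        def do_cluster():
            if cfg.cluster_k is None and cfg.cluster_height is None:
                return None, None
            kw = dict(
                method=cfg.cluster_method,
                metric=cfg.cluster_metric,
                k=cfg.cluster_k,
                height=cfg.cluster_height,
            )
            from .clustering import cluster_correlation_profiles

            return (
                cluster_correlation_profiles(R, axis="a", **kw),
                cluster_correlation_profiles(R, axis="b", **kw),
            )

        assign_a, assign_b = do_cluster()
        if assign_a is not None:
            pd.concat([assign_a.to_frame(), assign_b.to_frame()]).to_csv(
                out / f"clusters_{tag}.tsv", sep="\t", index=False
            )

        @_stage(f"signature[{tag}]")
        def do_signature():
            return dendro.high_coexpression_gene_sets(R, cfg.signature_r_threshold)

        set_a, set_b, sig_report = do_signature()
        with open(out / f"signature_{tag}.json", "w") as fh:
            json.dump(sig_report, fh, indent=1, default=str)

        @_stage(f"mantel[{tag}]")
        def do_mantel():
            if len(set_a) < 2 or len(set_b) < 2:
                return None
            return dendro.dendrogram_equivalence(
                filtered, t_a, t_b, set_a, set_b, seed=sub_seed
            )

        equiv = do_mantel()
        if equiv is not None:
            (out / f"dendrogram_{t_a}_{tag}.nwk").write_text(
                equiv.tree_a.to_newick() + "\n"
            )
            (out / f"dendrogram_{t_b}_{tag}.nwk").write_text(
                equiv.tree_b.to_newick() + "\n"
            )
            with open(out / f"mantel_{tag}.json", "w") as fh:
                json.dump(
                    {
                        "statistic": equiv.mantel.statistic,
                        "p": equiv.mantel.p,
                        "n_permutations": equiv.mantel.n_permutations,
                        "exhaustive": equiv.mantel.exhaustive,
                        "cophenetic_r": equiv.cophenetic_r,
                    },
                    fh,
                    indent=1,
                )

        @_stage(f"enrich[{tag}]")
        def do_enrich():
            results = {}
            for tissue, gene_set in ((t_a, set_a), (t_b, set_b)):
                if tissue not in cfg.gmt or not gene_set:
                    continue
                collection = enrichment.read_gmt(cfg.gmt[tissue])
                background = set(map(str, filtered[tissue].gene_ids))
                res = enrichment.enrichment_test(gene_set, background, collection)
                if res and cfg.bootstrap_rounds:
                    probs = enrichment.bootstrap_enrichment_validation(
                        res, len(gene_set), background, collection,
                        rounds=cfg.bootstrap_rounds, seed=sub_seed,
                    )
                    for r in res:
                        r.bootstrap_probability = probs.get(r.set_id)
                results[tissue] = res
            return results

        enrich_results = do_enrich()
        for tissue, res in enrich_results.items():
            enrichment.results_to_frame(res).to_csv(
                out / f"enrichment_{tissue}_{tag}.tsv", sep="\t", index=False
            )

        ks_stat = ks_p = None
        summary[tag] = {
            "n_genes_a": int(filtered[t_a].n_genes),
            "n_genes_b": int(filtered[t_b].n_genes),
            "pair_count": int(R.n_defined),
            "n_undefined_pairs": int(R.n_undefined),
            "edge_threshold": float(used_threshold),
            "n_edges": int(edges.n_edges),
            "efdr_at_threshold": efdr.efdr_at(curve, used_threshold),
            "connectivity_a": d_a.to_dict(),
            "connectivity_b": d_b.to_dict(),
            "signature": {k: v for k, v in sig_report.items() if k != "shared"},
            "mantel_p": None if equiv is None else equiv.mantel.p,
        }
        meta["stages"].append(tag)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return out
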