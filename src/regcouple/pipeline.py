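"""End-to-end orchestration: inputs -> pairs -> labels -> features -> model.

``run_pipeline`` sequences the stages and records a manifest with the
input/output counts of every filtering step, so a run is fully accountable
and reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import expression as expr_mod
from . import features as feat_mod
from . import io as io_mod
from . import rfmodel, stats, synthdata
from .config import PipelineConfig
from .pairs import build_pairs

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: synthdata.SyntheticData | None
    pairs: pd.DataFrame
    hits: pd.DataFrame
    active: pd.DataFrame
    labeled: pd.DataFrame
    features: feat_mod.FeatureMatrix | None
    clusters: list | None
    clustered: pd.DataFrame | None
    screen: pd.DataFrame | None
    cv: rfmodel.CVResult | None
    manifest: dict = field(default_factory=dict)


def _checksum(frame: pd.DataFrame) -> int:
    return int(pd.util.hash_pandas_object(frame, index=True).sum() % (2**63))


def run_pipeline(
    config: PipelineConfig,
    until: str = "rfmodel",
    compute_interactions: bool = False,
) -> PipelineResult:
    """Run the pipeline through ``until`` (pairs|expression|features|stats|rfmodel).

    Synthetic mode generates all inputs from ``config.sim``; real mode reads
    them from the configured paths.
    """
    stages = ["pairs", "expression", "features", "stats", "rfmodel"]
    if until not in stages:
        raise ValueError(f"until must be one of {stages}")
    manifest: dict = {"mode": config.mode, "seed": config.seed, "stages": {}}

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        log.info("stage %s: %s", stage, counts)

    dataset = None
    if config.mode == "synthetic":
        dataset = synthdata.generate_all(config.sim)
        annotations, promoters = dataset.annotations, dataset.promoters
        pwms, expression, aux = dataset.pwms, dataset.expression, dataset.aux
        record(
            "synthdata",
            n_genes=len(annotations),
            n_tfs=sum(a.is_tf for a in annotations),
            n_planted_pairs=len(dataset.ground_truth.planted_hit_positions),
            n_coupled_pairs=len(dataset.ground_truth.coupled_pairs),
        )
    else:
        annotations = io_mod.read_gff3(config.gff3_path)
        promoters = io_mod.read_promoters(config.fasta_path)
        pwms = io_mod.read_pwms(config.pwm_path)
        expression = io_mod.read_matrix(config.expression_path)
        aux = None
        record("inputs", n_genes=len(annotations), n_pwms=len(pwms))

    pairs, hits = build_pairs(
        annotations,
        promoters,
        pwms,
        promoter_window=config.promoter_window,
        rel_threshold=config.scan_threshold,
    )
    retained = sum(1 for a in annotations if a.max_utr5_len() > 0)
    record(
        "pairs",
        n_genes_in=len(annotations),
        n_genes_retained=retained,
        n_genes_dropped=len(annotations) - retained,
        n_hits=len(hits),
        n_pairs=len(pairs),
        checksum=_checksum(pairs),
    )
    result = PipelineResult(
        config=config, dataset=dataset, pairs=pairs, hits=hits,
        active=pd.DataFrame(), labeled=pd.DataFrame(), features=None,
        clusters=None, clustered=None, screen=None, cv=None, manifest=manifest,
    )
    if until == "pairs":
        return result

    norm = expr_mod.quantile_normalize(expression)
    pairs = expr_mod.pair_correlation(norm, pairs)
    active = expr_mod.select_active_tfs(
        norm,
        pairs,
        percentile=config.active_percentile,
        tg_cap=config.tg_cap,
        seed=config.seed + 11,
    )
    labeled = expr_mod.label_pairs(
        pairs, active, hi=config.label_hi, band=config.label_band
    )
    n_active = int(active["is_active"].sum())
    counts = labeled["label"].value_counts()
    record(
        "expression",
        n_pairs_in=len(result.pairs),
        n_pairs_correlated_r=len(pairs),
        n_pairs_dropped=len(result.pairs) - len(pairs),
        n_tfs_tested=len(active),
        n_active_tfs=n_active,
        n_active_pairs=len(labeled),
        n_correlated=int(counts.get("correlated", 0)),
        n_uncorrelated=int(counts.get("uncorrelated", 0)),
        n_excluded=int(counts.get("excluded", 0)),
    )
    result.pairs, result.active, result.labeled = pairs, active, labeled
    if until == "expression":
        return result

    if aux is None:
        raise ValueError("feature assembly requires auxiliary tables (synthetic mode)")
    fm = feat_mod.assemble_features(
        labeled,
        annotations,
        promoters,
        hits,
        pwms,
        norm,
        aux,
        promoter_window=config.promoter_window,
        stats_window=config.stats_window,
    )
    record(
        "features",
        n_pairs=len(fm.X),
        n_features=fm.X.shape[1],
        n_imputed_cells=int(fm.mask.to_numpy().sum()),
        checksum=_checksum(fm.X),
    )
    result.features = fm
    if until == "features":
        return result

    clusters, clustered = stats.cluster_features(fm.X, config.cluster_r_threshold)
    usable = fm.labels.isin(["correlated", "uncorrelated"])
    screen = None
    if usable.sum() >= 4 and fm.labels[usable].nunique() == 2:
        screen = stats.univariate_screen(clustered.loc[usable], fm.labels[usable])
    record(
        "stats",
        n_features_in=fm.X.shape[1],
        n_clusters=len(clusters),
        n_screened=0 if screen is None else len(screen),
        n_significant_fdr05=0 if screen is None else int((screen["p_fdr"] < 0.05).sum()),
    )
    result.clusters, result.clustered, result.screen = clusters, clustered, screen
    if until == "stats":
        return result

    cv = rfmodel.cross_validate(
        clustered,
        fm.labels,
        repeats=config.cv_repeats,
        train_frac=config.train_frac,
        n_trees=config.n_trees,
        vars_per_split=config.vars_per_split,
        min_node=config.min_node,
        seed=config.seed + 23,
        compute_interactions=compute_interactions,
    )
    record("rfmodel", **cv.summary())
    result.cv = cv
    return result
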