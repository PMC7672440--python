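"""The feature panel: TF-, TG- and pair-level molecular characteristics.

Four categories are computed per regulatory pair:

* ``tfbs_info`` — motif entropy and composition, TFBS-TSS distance
  statistics, target/regulator counts, regulatory-network position;
* ``post_tx_ptm_ppi`` — PPI distance to the polymerase-II subunit, node
  degree, self-interaction, phosphosites, mRNA half-lives, miRNA targeting,
  DNA-binding domains;
* ``genomic_annotation`` — isoform length aggregates, 5'UTR introns,
  upstream distances, promoter nucleotide composition, TATA-box, gene ages,
  adjacent-gene context;
* ``epigenetics`` — DMR counts by context/source/region, stable and dynamic
  DHS counts, TFBS-in-DHS flags, epigenetic-mark-type percentage.

``assemble_features`` joins everything onto pair rows and imputes missing
values with per-column medians, separately within the TF-entity and
gene-entity tables.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import intervals
from .annotation import GeneAnnotation
from .pairs import BASES, MotifPWM, closest_promoter_hits, tfbs_distance_stats
from .synthdata import AuxTables, promoter_region, tss_region

log = logging.getLogger(__name__)

RATIO_EPS = 1e-9
TATA_RE = re.compile("TATA[AT]A")
ADJ_THRESHOLDS = (500, 1000, 2000, 5000)


# ---------------------------------------------------------------- motif


def motif_entropy(pwm: MotifPWM, base: str = "nat") -> tuple[float, float]:
    """Mean positional Shannon entropy (SE) and core-motif entropy.

    Per position ``S_i = -sum_j p_ij log p_ij`` (0 log 0 := 0); SE is the
    mean over positions and the core value averages the five positions of
    lowest ``S_i`` (all positions when the motif is shorter than five).
    ``base='bit'`` reports both in bits instead of nats.
    """
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    s = -terms.sum(axis=1)
    core = np.sort(s)[: min(5, len(s))]
    se, core_se = float(s.mean()), float(core.mean())
    if base == "bit":
        se, core_se = se / math.log(2), core_se / math.log(2)
    return se, core_se


def motif_composition(pwm: MotifPWM) -> dict[str, float]:
    """Motif length, per-base percentages and AT/GC, AG/TC frequency ratios."""
    sums = pwm.probs.sum(axis=0)
    n = pwm.length
    pct = sums / n * 100.0
    a, c, g, t = sums
    at_gc = (a + t) / max(g + c, RATIO_EPS)
    ag_tc = (a + g) / max(t + c, RATIO_EPS)
    if g + c < RATIO_EPS or t + c < RATIO_EPS:
        log.warning("%s: degenerate base composition, ratio guarded", pwm.tf_id)
    return {
        "motif_length": float(n),
        "motif_pct_a": pct[0],
        "motif_pct_c": pct[1],
        "motif_pct_g": pct[2],
        "motif_pct_t": pct[3],
        "motif_at_gc_ratio": float(at_gc),
        "motif_ag_tc_ratio": float(ag_tc),
    }


# ---------------------------------------------------------------- networks


def regulatory_network_features(pairs: pd.DataFrame) -> pd.DataFrame:
    """Position of each TF in the TF-TF regulatory network.

    In-degree counts distinct TFs that have this TF as a target; out-degree
    counts distinct TF targets.  The ratio in/(in+out) is near 0 for
    top-level regulators and near 1 for bottom-level ones; TFs with no
    TF-TF edges at all get ratio 0.
    """
    tfs = pd.unique(pairs["tf_id"])
    tf_set = set(tfs)
    tt = pairs[pairs["tg_id"].isin(tf_set)]
    out_deg = tt.groupby("tf_id")["tg_id"].nunique()
    in_deg = tt.groupby("tg_id")["tf_id"].nunique()
    frame = pd.DataFrame(index=pd.Index(sorted(tf_set), name="tf_id"))
    frame["tf_in_degree"] = in_deg.reindex(frame.index).fillna(0).astype(int)
    frame["tf_out_degree"] = out_deg.reindex(frame.index).fillna(0).astype(int)
    total = frame["tf_in_degree"] + frame["tf_out_degree"]
    frame["tf_in_out_ratio"] = np.where(total > 0, frame["tf_in_degree"] / total.where(total > 0, 1), 0.0)
    return frame


PPI_ABSENT = 2000
PPI_DISCONNECTED = 1000


def ppi_features(edges: pd.DataFrame, polII_id: str, tf_ids: list[str]) -> pd.DataFrame:
    """Per TF: BFS hop distance to the Pol-II node, degree, self-interaction.

    TFs absent from the interaction data get the sentinel distance 2000 with
    degree 0; TFs present but in a component without Pol-II get 1000.
    Degree counts distinct interaction partners (a self-loop adds one).
    """
    graph = nx.Graph()
    graph.add_edges_from(edges.itertuples(index=False, name=None))
    if polII_id not in graph:
        raise ValueError(f"Pol-II node {polII_id!r} missing from PPI graph")
    dist = nx.single_source_shortest_path_length(graph, polII_id)
    rows = []
    for tf in tf_ids:
        if tf not in graph:
            rows.append((tf, PPI_ABSENT, 0, 0))
            continue
        d = dist.get(tf, PPI_DISCONNECTED)
        loop = int(graph.has_edge(tf, tf))
        rows.append((tf, d, graph.degree(tf) - loop, loop))
    return pd.DataFrame(
        rows, columns=["tf_id", "ppi_distance_to_polII", "ppi_degree", "ppi_self_interaction"]
    ).set_index("tf_id")


# ---------------------------------------------------------------- sequence


DINUCS = ["".join(p) for p in itertools.product(BASES, repeat=2)]


def promoter_composition(seq: str) -> dict[str, float]:
    """Mononucleotide percentages and 16 dinucleotide sliding-window counts.

    Ambiguity codes are counted in neither numerator nor denominator.
    """
    counts = {b: 0 for b in BASES}
    for ch in seq:
        if ch in counts:
            counts[ch] += 1
    total = sum(counts.values())
    out = {f"prom_pct_{b.lower()}": (100.0 * counts[b] / total if total else np.nan) for b in BASES}
    dic = dict.fromkeys(DINUCS, 0)
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        if d in dic:
            dic[d] += 1
    out.update({f"prom_dinuc_{d.lower()}": float(v) for d, v in dic.items()})
    return out


def tata_box(seq: str, tss_offset: int, window: int = 60) -> int:
    """1 iff the TATAWA consensus occurs forward-strand within 60 bp upstream."""
    start = tss_offset - window
    if start < 0:
        log.debug("fewer than %d bp upstream available; scanning %d", window, tss_offset)
        start = 0
    return int(bool(TATA_RE.search(seq[start:tss_offset].upper())))


# ---------------------------------------------------------------- annotation


def annotation_features(gene: GeneAnnotation) -> dict[str, float]:
    """Isoform aggregates plus upstream distance for one gene."""
    if not gene.isoforms:
        raise ValueError(f"{gene.gene_id}: no isoforms")
    out: dict[str, float] = {}
    for name, attr in (
        ("mrna_len", "mrna_len"),
        ("protein_len", "protein_len"),
        ("utr5_len", "utr5_len"),
        ("utr3_len", "utr3_len"),
    ):
        vals = [getattr(iso, attr) for iso in gene.isoforms]
        out[f"{name}_min"] = float(min(vals))
        out[f"{name}_mean"] = float(np.mean(vals))
        out[f"{name}_max"] = float(max(vals))
    proteins = [iso.protein_len for iso in gene.isoforms]
    out["isoform_count"] = float(len(gene.isoforms))
    out["protein_len_diff"] = float(max(proteins) - min(proteins))
    out["utr5_has_intron"] = float(any(iso.utr5_has_intron for iso in gene.isoforms))
    out["upstream_gene_distance"] = (
        float(gene.upstream_gene_distance) if gene.upstream_gene_distance >= 0 else np.nan
    )
    return out


def age_features(ages: pd.Series, pairs: pd.DataFrame) -> pd.DataFrame:
    """Per pair: phylostratum of TG and TF, and age_TG - age_TF."""
    out = pd.DataFrame(index=pairs.index)
    out["age_tf"] = pairs["tf_id"].map(ages).to_numpy()
    out["age_tg"] = pairs["tg_id"].map(ages).to_numpy()
    out["age_diff"] = out["age_tg"] - out["age_tf"]
    return out


# ---------------------------------------------------------------- epigenetics


def stable_dynamic_dhs(
    dhs_tracks: dict[str, pd.DataFrame]
) -> tuple[intervals.Track, intervals.Track]:
    """Stable DHS = intersection of all condition tracks; dynamic = union minus stable."""
    if not dhs_tracks:
        raise ValueError("at least one DHS condition track is required")
    tracks = [intervals.from_frame(df) for df in dhs_tracks.values()]
    stable = intervals.intersect_all(tracks)
    dynamic = intervals.subtract(intervals.union_all(tracks), stable)
    return stable, dynamic


def epigenetic_gene_features(
    annotations: list[GeneAnnotation],
    dmr_tracks: dict[str, pd.DataFrame],
    stable: intervals.Track,
    dynamic: intervals.Track,
    promoter_len: int = 500,
    mark_type_denominator: int | None = None,
) -> pd.DataFrame:
    """Per gene: DMR counts by layer/region, DHS counts, mark-type percentage.

    An interval counts once per region it overlaps by at least 1 bp.  The
    mark-type percentage is the fraction of configured mark types (DMR
    layers plus the two DHS classes) with at least one feature in the gene's
    promoter.
    """
    dmr = {name: intervals.from_frame(df) for name, df in dmr_tracks.items()}
    if mark_type_denominator is None:
        mark_type_denominator = len(dmr) + 2
    rows = []
    for a in annotations:
        prom = promoter_region(a, promoter_len)
        tssr = tss_region(a)
        body = (a.chrom, a.gene_start, a.gene_end)
        row: dict[str, float] = {}
        present = 0
        for name, track in dmr.items():
            row[f"{name}_promoter"] = intervals.count_overlaps(track, *prom)
            row[f"{name}_tss"] = intervals.count_overlaps(track, *tssr)
            row[f"{name}_body"] = intervals.count_overlaps(track, *body)
            present += int(row[f"{name}_promoter"] > 0)
        row["dhs_stable_promoter"] = intervals.count_overlaps(stable, *prom)
        row["dhs_stable_body"] = intervals.count_overlaps(stable, *body)
        row["dhs_dynamic_promoter"] = intervals.count_overlaps(dynamic, *prom)
        row["dhs_dynamic_body"] = intervals.count_overlaps(dynamic, *body)
        present += int(row["dhs_stable_promoter"] > 0) + int(row["dhs_dynamic_promoter"] > 0)
        row["epi_mark_type_pct"] = present / mark_type_denominator
        rows.append(row)
    return pd.DataFrame(rows, index=[a.gene_id for a in annotations])


def pair_dhs_flags(
    hits: pd.DataFrame,
    annotations: list[GeneAnnotation],
    stable: intervals.Track,
    dynamic: intervals.Track,
    tss_offset: int,
    promoter_window: tuple[int, int] = (-500, -1),
) -> pd.DataFrame:
    """Per pair: does the closest TFBS fall in a stable / dynamic DHS?"""
    ann = {a.gene_id: a for a in annotations}
    best = closest_promoter_hits(hits, tss_offset, promoter_window)
    rows = []
    for rec in best.itertuples(index=False):
        a = ann[rec.gene_id]
        o_start, o_end = rec.start - tss_offset, rec.end - tss_offset
        if a.strand == "+":
            g_start, g_end = a.tss + o_start, a.tss + o_end
        else:
            g_start, g_end = a.tss - o_end + 1, a.tss - o_start + 1
        rows.append(
            (
                rec.tf_id,
                rec.gene_id,
                int(intervals.any_overlap(stable, a.chrom, g_start, g_end)),
                int(intervals.any_overlap(dynamic, a.chrom, g_start, g_end)),
            )
        )
    return pd.DataFrame(
        rows, columns=["tf_id", "tg_id", "tfbs_in_stable_dhs", "tfbs_in_dynamic_dhs"]
    )


# ---------------------------------------------------------------- neighbors


def adjacent_gene_features(
    annotations: list[GeneAnnotation],
    expr: pd.DataFrame,
    pairs: pd.DataFrame,
    thresholds: tuple[int, ...] = ADJ_THRESHOLDS,
) -> pd.DataFrame:
    """Per gene and distance threshold: neighbor expression / TFBS context.

    Neighbors are genes whose boundary-to-boundary gap is <= the threshold.
    Reported: mean neighbor expression (NaN when no neighbor), mean neighbor
    regulator (promoter TFBS) count, and the number of distinct TFs shared
    between the gene's promoter and any neighbor promoter.
    """
    mean_expr = expr.mean(axis=1)
    reg_count = pairs.groupby("tg_id")["tf_id"].nunique()
    reg_sets = pairs.groupby("tg_id")["tf_id"].agg(set)
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for a in annotations:
        by_chrom.setdefault(a.chrom, []).append(a)
    for lst in by_chrom.values():
        lst.sort(key=lambda a: a.gene_start)

    max_thr = max(thresholds)
    rows = {}
    for chrom, genes in by_chrom.items():
        starts = np.array([g.gene_start for g in genes])
        ends = np.array([g.gene_end for g in genes])
        for i, a in enumerate(genes):
            gaps = np.maximum(starts - a.gene_end, a.gene_start - ends)
            gaps[i] = max_thr + 1  # not its own neighbor
            row: dict[str, float] = {}
            own_regs = reg_sets.get(a.gene_id, set())
            for thr in thresholds:
                nb = np.nonzero(gaps <= thr)[0]
                ids = [genes[j].gene_id for j in nb]
                if ids:
                    ex = mean_expr.reindex(ids)
                    row[f"adj{thr}_mean_expr"] = float(ex.mean()) if ex.notna().any() else np.nan
                    row[f"adj{thr}_mean_tfbs"] = float(
                        np.mean([reg_count.get(g, 0) for g in ids])
                    )
                    shared = set().union(*(reg_sets.get(g, set()) for g in ids)) & own_regs
                    row[f"adj{thr}_shared_tfbs"] = float(len(shared))
                else:
                    row[f"adj{thr}_mean_expr"] = np.nan
                    row[f"adj{thr}_mean_tfbs"] = 0.0
                    row[f"adj{thr}_shared_tfbs"] = 0.0
            rows[a.gene_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------- assembly


@dataclass
class FeatureMatrix:
    """Pairs x features with provenance metadata and imputation mask."""

    X: pd.DataFrame  # index: "tf|tg" pair ids
    meta: pd.DataFrame  # index: feature name; columns: source, category, imputed_fraction
    mask: pd.DataFrame  # True where the cell was imputed
    labels: pd.Series  # pair label, aligned with X.index

    def __post_init__(self) -> None:
        assert list(self.meta.index) == list(self.X.columns)

    def subset(self, source: str) -> "FeatureMatrix":
        """Restrict to columns of one provenance (``TF``, ``TG`` or ``pair``).

        Supports ablations such as a TF-features-only classifier.
        """
        cols = self.meta.index[self.meta["source"] == source]
        if len(cols) == 0:
            raise ValueError(f"no features with source {source!r}")
        return FeatureMatrix(
            X=self.X[list(cols)],
            meta=self.meta.loc[cols],
            mask=self.mask[list(cols)],
            labels=self.labels,
        )


def _impute_median(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    mask = frame.isna()
    med = frame.median(numeric_only=True)
    return frame.fillna(med).fillna(0.0), mask


CATEGORY = {}  # filled below by _register


def _register(category: str, names: list[str]) -> None:
    for n in names:
        CATEGORY[n] = category


def assemble_features(
    pairs: pd.DataFrame,
    annotations: list[GeneAnnotation],
    promoters,
    hits: pd.DataFrame,
    pwms: list[MotifPWM],
    expr: pd.DataFrame,
    aux: AuxTables,
    promoter_window: tuple[int, int] = (-500, -1),
    stats_window: tuple[int, int] = (-1000, 500),
    mark_type_denominator: int | None = None,
) -> FeatureMatrix:
    """Join all feature families onto labeled pair rows and impute.

    Imputation uses per-column medians computed separately within the
    TF-entity table and the gene-entity table, then within the assembled
    pair-level columns; every imputed cell is flagged in the mask.
    """
    ann = {a.gene_id: a for a in annotations}
    missing_genes = (~pairs["tf_id"].isin(ann)) | (~pairs["tg_id"].isin(ann))
    if missing_genes.any():
        log.info("dropping %d pairs with unannotated genes", int(missing_genes.sum()))
        pairs = pairs.loc[~missing_genes]
    pairs = pairs.reset_index(drop=True)

    # --- TF-entity table
    tf_stats, tg_stats = tfbs_distance_stats(hits, pairs, stats_window)
    tf_rows = {}
    for pwm in pwms:
        se, core = motif_entropy(pwm)
        row = {"motif_entropy": se, "motif_core5_entropy": core}
        row.update(motif_composition(pwm))
        tf_rows[pwm.tf_id] = row
    tf_frame = pd.DataFrame.from_dict(tf_rows, orient="index")
    tf_frame = tf_frame.join(tf_stats.rename(columns={"mean": "tf_tfbs_tss_mean", "sd": "tf_tfbs_tss_sd", "n_targets": "tf_target_count"}))
    tf_frame = tf_frame.join(regulatory_network_features(pairs))
    tf_frame = tf_frame.join(ppi_features(aux.ppi_edges, aux.polII_id, list(tf_frame.index)))
    tf_frame = tf_frame.join(aux.tf_table)
    tf_frame, tf_mask = _impute_median(tf_frame)

    # --- gene-entity table (used for both pair roles)
    used = sorted(set(pairs["tf_id"]) | set(pairs["tg_id"]))
    g_rows = {g: annotation_features(ann[g]) for g in used}
    gene_frame = pd.DataFrame.from_dict(g_rows, orient="index")
    gene_frame["tata_box"] = [
        tata_box(promoters[g], promoters.tss_offset) if g in promoters else np.nan for g in gene_frame.index
    ]
    gene_frame["age"] = aux.gene_table["phylostratum"].reindex(gene_frame.index)
    gene_frame["halflife"] = aux.gene_table["halflife"].reindex(gene_frame.index)
    mirna = aux.mirna_table.reindex(gene_frame.index)
    gene_frame["mirna_target_sites"] = mirna["target_sites"]
    gene_frame["mirna_intron_target_sites"] = mirna["intron_target_sites"]
    gene_frame["mirna_max_energy_ratio"] = mirna["max_energy_ratio"]
    gene_frame["mirna_mimicry_sites"] = mirna["mimicry_sites"]
    gene_frame["mirna_mimicry_max_energy_ratio"] = mirna["mimicry_max_energy_ratio"]

    # TG-only families
    comp = pd.DataFrame.from_dict(
        {g: promoter_composition(_promoter_slice(promoters, g, promoter_window)) for g in used if g in promoters},
        orient="index",
    )
    stable, dynamic = stable_dynamic_dhs(aux.dhs_tracks)
    epi = epigenetic_gene_features(
        [ann[g] for g in used],
        aux.dmr_tracks,
        stable,
        dynamic,
        promoter_len=-promoter_window[0],
        mark_type_denominator=mark_type_denominator,
    )
    adj = adjacent_gene_features(annotations, expr, pairs).reindex(used)
    tg_extra = comp.join(epi).join(adj)
    tg_extra = tg_extra.join(
        tg_stats.rename(
            columns={"mean": "tg_tfbs_tss_mean", "sd": "tg_tfbs_tss_sd", "n_regulators": "tg_regulator_count"}
        )
    )
    gene_all = gene_frame.join(tg_extra, how="left")
    gene_all, gene_mask = _impute_median(gene_all)

    # --- assemble pair rows
    pair_ids = pairs["tf_id"] + "|" + pairs["tg_id"]
    role_cols = [
        "mrna_len_min", "mrna_len_mean", "mrna_len_max",
        "protein_len_min", "protein_len_mean", "protein_len_max",
        "utr5_len_min", "utr5_len_mean", "utr5_len_max",
        "utr3_len_min", "utr3_len_mean", "utr3_len_max",
        "isoform_count", "protein_len_diff", "utr5_has_intron",
        "upstream_gene_distance", "tata_box", "age", "halflife",
        "mirna_target_sites", "mirna_intron_target_sites", "mirna_max_energy_ratio",
        "mirna_mimicry_sites", "mirna_mimicry_max_energy_ratio",
    ]
    tg_only_cols = [c for c in tg_extra.columns]

    x_cols: dict[str, np.ndarray] = {}
    m_cols: dict[str, np.ndarray] = {}
    tfv = pairs["tf_id"].to_numpy()
    tgv = pairs["tg_id"].to_numpy()
    n_pairs = len(pairs)

    def add(colname, values, imputed=None, source="pair"):
        x_cols[colname] = np.asarray(values, dtype=float)
        m_cols[colname] = (
            np.asarray(imputed, dtype=bool)
            if imputed is not None
            else np.zeros(n_pairs, dtype=bool)
        )
        _SOURCE[colname] = source

    _SOURCE: dict[str, str] = {}
    for col in tf_frame.columns:
        add(col, tf_frame[col].reindex(tfv).to_numpy(), tf_mask[col].reindex(tfv).to_numpy(), "TF")
    for col in role_cols:
        add(f"{col}_tf", gene_all[col].reindex(tfv).to_numpy(), gene_mask[col].reindex(tfv).to_numpy(), "TF")
        add(f"{col}_tg", gene_all[col].reindex(tgv).to_numpy(), gene_mask[col].reindex(tgv).to_numpy(), "TG")
    for col in tg_only_cols:
        add(col, gene_all[col].reindex(tgv).to_numpy(), gene_mask[col].reindex(tgv).to_numpy(), "TG")

    add("pair_tfbs_tss_distance", pairs["closest_tfbs_distance"].to_numpy())
    add("halflife_product", x_cols["halflife_tf"] * x_cols["halflife_tg"],
        m_cols["halflife_tf"] | m_cols["halflife_tg"])
    add("age_diff", x_cols["age_tg"] - x_cols["age_tf"],
        m_cols["age_tf"] | m_cols["age_tg"])
    flags = pair_dhs_flags(hits, annotations, stable, dynamic, promoters.tss_offset, promoter_window)
    flags.index = flags["tf_id"] + "|" + flags["tg_id"]
    add("tfbs_in_stable_dhs", flags["tfbs_in_stable_dhs"].reindex(pair_ids).fillna(0).to_numpy())
    add("tfbs_in_dynamic_dhs", flags["tfbs_in_dynamic_dhs"].reindex(pair_ids).fillna(0).to_numpy())

    X = pd.DataFrame(x_cols, index=pair_ids)
    M = pd.DataFrame(m_cols, index=pair_ids)
    # final pass: anything still missing (e.g. pair-level) -> pair-table median
    X, late_mask = _impute_median(X)
    M = M | late_mask

    meta = pd.DataFrame(index=X.columns)
    meta["source"] = [_SOURCE[c] for c in X.columns]
    meta["category"] = [_categorize(c) for c in X.columns]
    meta["imputed_fraction"] = M.mean(axis=0).reindex(X.columns).to_numpy()
    labels = pairs.set_index(pair_ids)["label"] if "label" in pairs else pd.Series("unlabeled", index=pair_ids)
    return FeatureMatrix(X=X, meta=meta, mask=M, labels=labels)


def _promoter_slice(promoters, gene_id: str, window: tuple[int, int]) -> str:
    lo, hi = window
    t = promoters.tss_offset
    return promoters[gene_id][t + lo : t + hi + 1]


def _categorize(name: str) -> str:
    if name.startswith(("motif_", "tf_", "tg_")) or name in ("pair_tfbs_tss_distance",):
        return "tfbs_info"
    if name.startswith(("ppi_", "phospho", "halflife", "mirna_", "dbd_", "dbd1", "dbd2")):
        return "post_tx_ptm_ppi"
    if name.startswith(("dmr_", "dhs_", "tfbs_in_", "epi_")):
        return "epigenetics"
    return "genomic_annotation"
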