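"""Synthetic inputs with planted, parameterized structure.

The generator emulates the statistical structure of the study's inputs:

* promoters carrying planted PWM consensus sites at controlled TSS distances,
* a latent-activity expression model in which each TF has a per-sample
  activity ``x ~ N(0, 1)``; the TF's own (log-scale) expression equals ``x``
  and every coupled target gene is ``beta * x + N(0, sigma)``, so a coupled
  pair's expected Pearson correlation is ``beta / sqrt(beta**2 + sigma**2)``
  and coupled targets of the same TF are mutually correlated (the signal the
  resampling-based active-TF selection detects),
* a protein-protein interaction graph with controlled hop distances to a
  designated polymerase-II node,
* auxiliary per-gene/per-TF tables (half-lives, phosphosites, miRNA targets,
  evolutionary ages, DNA-binding domains) in which named features can be
  shifted between coupled and uncoupled pair populations at a configured
  Cohen's-D scale,
* DMR and DNase-hypersensitive-site interval tracks with configurable
  stable/dynamic overlap structure.

Everything is a pure function of ``SimConfig`` (including its seed); a
ground-truth manifest records what was planted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation, Isoform, PromoterSet
from .config import LN4, SimConfig
from .pairs import BASES, MotifPWM

POLII_ID = "PolII"
DMR_LAYERS = [
    ("s1", "CpG"),
    ("s1", "CHG"),
    ("s1", "CHH"),
    ("s2", "CpG"),
    ("s2", "CHH"),
]
DHS_CONDITIONS = ["cond1", "cond2", "cond3", "cond4"]


@dataclass
class GroundTruth:
    """Manifest of planted structure.

    ``planted_hit_positions`` maps every planted pair to the signed distance
    of its consensus site from the TSS; ``coupled_pairs`` is the subset whose
    expression is coupled through the TF's latent activity.
    """

    coupled_pairs: set[tuple[str, str]]
    planted_hit_positions: dict[tuple[str, str], int]
    expected_pair_r: dict[tuple[str, str], float]
    informative_features: list[str]
    active_tfs: list[str]
    noise_model: str = "gaussian latent activity (assumed, not fit to real data)"

    def planted_pairs(self) -> set[tuple[str, str]]:
        return set(self.planted_hit_positions)

    def to_json(self) -> str:
        return json.dumps(
            {
                "coupled_pairs": sorted(map(list, self.coupled_pairs)),
                "planted_hit_positions": {
                    f"{tf}|{tg}": int(d) for (tf, tg), d in sorted(self.planted_hit_positions.items())
                },
                "expected_pair_r": {
                    f"{tf}|{tg}": r for (tf, tg), r in sorted(self.expected_pair_r.items())
                },
                "informative_features": self.informative_features,
                "active_tfs": self.active_tfs,
                "noise_model": self.noise_model,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            coupled_pairs={tuple(p) for p in d["coupled_pairs"]},
            planted_hit_positions={
                tuple(k.split("|")): v for k, v in d["planted_hit_positions"].items()
            },
            expected_pair_r={tuple(k.split("|")): v for k, v in d["expected_pair_r"].items()},
            informative_features=d["informative_features"],
            active_tfs=d["active_tfs"],
            noise_model=d.get("noise_model", ""),
        )


@dataclass
class AuxTables:
    """Auxiliary inputs consumed verbatim by the feature assembly."""

    ppi_edges: pd.DataFrame  # columns a, b (undirected; loops allowed)
    polII_id: str
    gene_table: pd.DataFrame  # index gene_id: phylostratum, halflife
    tf_table: pd.DataFrame  # index tf_id: phospho_sites, dbd_count, dbd1/2_rel_start
    mirna_table: pd.DataFrame  # index gene_id: target/mimicry site counts, energy ratios
    dmr_tracks: dict[str, pd.DataFrame] = field(default_factory=dict)
    dhs_tracks: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class SyntheticData:
    config: SimConfig
    annotations: list[GeneAnnotation]
    promoters: PromoterSet
    pwms: list[MotifPWM]
    expression: pd.DataFrame
    aux: AuxTables
    ground_truth: GroundTruth


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stage])


# ---------------------------------------------------------------- genome


def generate_genome(config: SimConfig) -> tuple[list[GeneAnnotation], PromoterSet]:
    """Gene annotations plus TSS-anchored background promoter sequences."""
    rng = _rng(config, 1)
    ids = config.gene_ids()
    if not ids:
        return [], PromoterSet({}, config.upstream_len)
    order = list(ids)
    rng.shuffle(order)
    n_chrom = 5
    no_utr5 = set(
        rng.choice(ids, size=int(round(config.frac_no_utr5 * len(ids))), replace=False)
    )

    placed: dict[str, list[tuple[str, int, int]]] = {}
    coords: dict[str, tuple[str, int, int, str]] = {}
    cursors = {f"chr{c + 1}": 10_000 for c in range(n_chrom)}
    for k, gid in enumerate(order):
        chrom = f"chr{(k % n_chrom) + 1}"
        gap = int(np.clip(rng.lognormal(7.2, 1.0), 50, 30_000))
        start = cursors[chrom] + gap
        length = int(rng.integers(800, 4001))
        cursors[chrom] = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        coords[gid] = (chrom, start, start + length, strand)
        placed.setdefault(chrom, []).append((gid, start, start + length))

    annotations = []
    for gid in ids:
        chrom, start, end, strand = coords[gid]
        neighbors = placed[chrom]
        idx = next(i for i, (g, _, _) in enumerate(neighbors) if g == gid)
        if strand == "+":
            up = start - neighbors[idx - 1][2] if idx > 0 else -1
        else:
            up = neighbors[idx + 1][1] - end if idx + 1 < len(neighbors) else -1
        n_iso = int(rng.integers(1, 4))
        isoforms = []
        for _ in range(n_iso):
            utr5 = 0 if gid in no_utr5 else int(rng.integers(20, 300))
            utr3 = int(rng.integers(50, 400))
            protein = int(rng.integers(100, 600))
            isoforms.append(
                Isoform(
                    mrna_len=utr5 + utr3 + 3 * protein + 3,
                    protein_len=protein,
                    utr5_len=utr5,
                    utr3_len=utr3,
                    utr5_has_intron=bool(rng.random() < 0.15),
                )
            )
        annotations.append(
            GeneAnnotation(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                tss=start if strand == "+" else end - 1,
                gene_start=start,
                gene_end=end,
                isoforms=isoforms,
                upstream_gene_distance=up,
                is_tf=gid.startswith("TF"),
            )
        )

    base_probs = np.full(4, 0.25)
    seqs = {}
    for gid in ids:
        draw = rng.choice(4, size=config.record_len, p=base_probs)
        seqs[gid] = "".join(BASES[j] for j in draw)
    return annotations, PromoterSet(seqs, config.upstream_len)


# ---------------------------------------------------------------- PWMs


def _entropy_pmax(target: float) -> float:
    """Consensus-base probability giving per-position entropy ``target`` nats.

    Columns have one consensus base at probability p and the other three at
    (1 - p) / 3; the entropy decreases monotonically from ln 4 (p = 1/4)
    to 0 (p = 1), so p is found by bisection.
    """
    if target <= 0:
        return 1.0
    if target >= LN4:
        return 0.25

    def ent(p: float) -> float:
        q = (1.0 - p) / 3.0
        s = -p * math.log(p)
        if q > 0:
            s -= 3 * q * math.log(q)
        return s

    lo, hi = 0.25, 1.0 - 1e-12
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if ent(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_pwms(config: SimConfig) -> list[MotifPWM]:
    """One PWM per TF, with per-position entropy exactly at its target level."""
    rng = _rng(config, 2)
    lo, hi = config.motif_len_range
    pwms = []
    for i, tf in enumerate(config.tf_ids()):
        L = int(rng.integers(lo, hi + 1))
        level = config.entropy_levels[i % len(config.entropy_levels)]
        p = _entropy_pmax(level)
        probs = np.full((L, 4), (1.0 - p) / 3.0)
        consensus = rng.integers(0, 4, size=L)
        probs[np.arange(L), consensus] = p
        probs /= probs.sum(axis=1, keepdims=True)
        pwms.append(MotifPWM(tf_id=tf, probs=probs))
    return pwms


# ---------------------------------------------------------------- pair plan


def plan_pairs(
    config: SimConfig, annotations: list[GeneAnnotation], pwms: list[MotifPWM]
) -> GroundTruth:
    """Choose planted pairs, coupling assignments and TFBS offsets."""
    rng = _rng(config, 3)
    by_len = {p.tf_id: p.length for p in pwms}
    eligible = [a.gene_id for a in annotations if a.max_utr5_len() > 0]
    eligible_set = set(eligible)
    non_tf_eligible = [g for g in eligible if not g.startswith("TF")]
    tfs = [t for t in config.tf_ids() if t in eligible_set]
    actives = [t for t in config.resolved_active_tfs() if t in eligible_set]
    n_coupled = int(round(config.frac_coupled_pairs * config.targets_per_tf))

    need = n_coupled * len(actives)
    if need > len(non_tf_eligible):
        raise ValueError(
            f"need {need} coupled target genes but only {len(non_tf_eligible)} eligible"
        )
    coupled_pool = (
        [str(g) for g in rng.choice(non_tf_eligible, size=need, replace=False)] if need else []
    )

    planted: dict[tuple[str, str], int] = {}
    coupled: set[tuple[str, str]] = set()
    expected_r: dict[tuple[str, str], float] = {}
    occupied: dict[str, list[tuple[int, int]]] = {}
    r_coupled = config.expected_coupled_r()

    def draw_offset(tg: str, L: int) -> int:
        # avoid overlapping another planted site in the same promoter,
        # which would clobber it
        taken = occupied.setdefault(tg, [])
        for _ in range(200):
            offset = int(rng.integers(L - config.promoter_len, 0))
            s, e = offset - L, offset
            if all(e <= ts or s >= te for ts, te in taken):
                taken.append((s, e))
                return offset
        raise RuntimeError(f"could not place a non-overlapping motif in {tg}")

    pool_idx = 0
    for tf in tfs:
        L = by_len[tf]
        targets: list[str] = []
        if tf in actives and n_coupled:
            targets = coupled_pool[pool_idx : pool_idx + n_coupled]
            pool_idx += n_coupled
            for tg in targets:
                coupled.add((tf, tg))
                expected_r[(tf, tg)] = r_coupled
        n_rest = config.targets_per_tf - len(targets)
        candidates = [g for g in eligible if g != tf and g not in targets]
        rest = [
            str(g)
            for g in rng.choice(candidates, size=min(n_rest, len(candidates)), replace=False)
        ]
        for tg in targets + rest:
            planted[(tf, tg)] = draw_offset(tg, L)
            expected_r.setdefault((tf, tg), 0.0)
    return GroundTruth(
        coupled_pairs=coupled,
        planted_hit_positions=planted,
        expected_pair_r=expected_r,
        informative_features=sorted(
            k for k, v in config.planted_feature_shifts.items() if v != 0
        ),
        active_tfs=list(actives),
    )


def plant_motifs(
    pwms: list[MotifPWM],
    promoters: PromoterSet,
    planting: dict[tuple[str, str], int],
) -> PromoterSet:
    """Write each TF's consensus into its target's promoter at the planned offset.

    The offset is the signed distance the scanner will report (the hit's
    downstream boundary relative to the TSS); the consensus is written on the
    forward (coding) strand.
    """
    by_tf = {p.tf_id: p for p in pwms}
    seqs = dict(promoters.seqs)
    for (tf, tg), offset in sorted(planting.items()):
        pwm = by_tf[tf]
        motif = pwm.consensus()
        end = promoters.tss_offset + offset
        start = end - pwm.length
        if tg not in seqs:
            raise ValueError(f"pair ({tf}, {tg}): unknown gene {tg}")
        if start < 0 or end > len(seqs[tg]):
            raise ValueError(
                f"pair ({tf}, {tg}): planted offset {offset} outside promoter window"
            )
        s = seqs[tg]
        seqs[tg] = s[:start] + motif + s[end:]
    return PromoterSet(seqs, promoters.tss_offset)


# ---------------------------------------------------------------- expression


def generate_expression(config: SimConfig, ground_truth: GroundTruth) -> pd.DataFrame:
    """Log-scale expression matrix (genes x samples) under the latent model."""
    rng = _rng(config, 4)
    ids = config.gene_ids()
    n = len(ids)
    samples = [f"S{j + 1:04d}" for j in range(config.n_sample)]
    latent = {tf: rng.normal(size=config.n_sample) for tf in config.tf_ids()}
    coupling: dict[str, str] = {}
    for tf, tg in ground_truth.coupled_pairs:
        coupling[tg] = tf

    values = np.empty((n, config.n_sample))
    baseline = rng.normal(6.0, 1.0, size=n)
    for i, gid in enumerate(ids):
        if gid in latent:
            row = latent[gid]
        elif gid in coupling:
            x = latent[coupling[gid]]
            row = config.coupling_beta * x + rng.normal(0.0, config.noise_sd, config.n_sample)
        else:
            row = rng.normal(size=config.n_sample)
        values[i] = row + baseline[i]
    return pd.DataFrame(values, index=ids, columns=samples)


# ---------------------------------------------------------------- aux tables


def _count_like(rng, n, mean, sd, shift_sd=None):
    """Rounded, non-negative draws; ``shift_sd`` displaces per-element means in SD units."""
    x = rng.normal(mean, sd, size=n)
    if shift_sd is not None:
        x = x + sd * shift_sd
    return np.round(np.clip(x, 0, None)).astype(float)


def _cont_like(rng, n, mean, sd, lo=None, hi=None, shift_sd=None):
    x = rng.normal(mean, sd, size=n)
    if shift_sd is not None:
        x = x + sd * shift_sd
    return np.clip(x, lo, hi)


def generate_aux_tables(
    config: SimConfig, ground_truth: GroundTruth, annotations: list[GeneAnnotation]
) -> AuxTables:
    """PPI edge list, regulatory auxiliaries, and DMR/DHS interval tracks.

    Planted feature shifts are applied post hoc: the underlying per-gene or
    per-TF values of a shifted feature are drawn from a distribution displaced
    by ``shift x SD`` for genes on the coupled side (TFs owning coupled pairs,
    or target genes of coupled pairs).
    """
    rng = _rng(config, 5)
    shifts = config.planted_feature_shifts
    gene_ids = config.gene_ids()
    tf_ids = config.tf_ids()
    coupled_tfs = {tf for tf, _ in ground_truth.coupled_pairs}
    coupled_tgs = {tg for _, tg in ground_truth.coupled_pairs}
    g_mask_tg = np.array([g in coupled_tgs for g in gene_ids], dtype=float)
    g_mask_tf = np.array([g in coupled_tfs for g in gene_ids], dtype=float)
    t_mask = np.array([t in coupled_tfs for t in tf_ids], dtype=float)
    ng, nt = len(gene_ids), len(tf_ids)

    def gene_shift(stem: str) -> np.ndarray:
        return (
            shifts.get(f"{stem}_tg", 0.0) * g_mask_tg
            + shifts.get(f"{stem}_tf", 0.0) * g_mask_tf
        )

    # per-gene table: phylostratum (1..13) and mRNA half-life (hours)
    age = np.clip(_count_like(rng, ng, 7.0, 2.5, gene_shift("age")), 1, 13)
    halflife = _cont_like(rng, ng, 5.0, 1.5, lo=0.2, shift_sd=gene_shift("halflife"))
    gene_table = pd.DataFrame({"phylostratum": age, "halflife": halflife}, index=gene_ids)

    # per-TF table: phosphosites and DNA-binding domains
    phospho = _count_like(rng, nt, 5.0, 2.0, shifts.get("phospho_sites", 0.0) * t_mask)
    dbd_count = np.where(rng.random(nt) < 0.3, 2, 1).astype(float)
    dbd1 = rng.uniform(0.05, 0.6, size=nt)
    dbd2 = np.where(dbd_count == 2, rng.uniform(0.3, 0.9, size=nt), np.nan)
    tf_table = pd.DataFrame(
        {
            "phospho_sites": phospho,
            "dbd_count": dbd_count,
            "dbd1_rel_start": dbd1,
            "dbd2_rel_start": dbd2,
        },
        index=tf_ids,
    )

    # per-gene miRNA targeting table
    m_sites = _count_like(rng, ng, 4.0, 2.0, gene_shift("mirna_target_sites"))
    m_ratio = _cont_like(
        rng, ng, 0.45, 0.12, 0.0, 1.0, shift_sd=gene_shift("mirna_max_energy_ratio")
    )
    mirna_table = pd.DataFrame(
        {
            "target_sites": m_sites,
            "intron_target_sites": _count_like(rng, ng, 1.5, 1.0),
            "max_energy_ratio": m_ratio,
            "mimicry_sites": _count_like(rng, ng, 1.0, 1.0),
            "mimicry_max_energy_ratio": _cont_like(rng, ng, 0.4, 0.12, 0.0, 1.0),
        },
        index=gene_ids,
    )

    # inject missingness into columns that tolerate it (exercises imputation)
    for table, cols in ((gene_table, ["halflife"]), (tf_table, ["phospho_sites"]),
                        (mirna_table, ["max_energy_ratio", "mimicry_max_energy_ratio"])):
        for col in cols:
            mask = rng.random(len(table)) < config.missing_rate
            table.loc[mask, col] = np.nan

    # PPI graph: chains of dummy nodes to the polymerase-II subunit so the
    # hop distance is controlled; extra leaf edges vary degree without
    # creating shortcuts.
    edges: list[tuple[str, str]] = []
    ppi_shift = shifts.get("ppi_distance_to_polII", 0.0)
    for k, tf in enumerate(tf_ids):
        u = rng.random()
        if u < 0.1:  # absent from the PPI data entirely
            continue
        if u < 0.2:  # present but in a component without PolII
            edges.append((tf, f"{tf}_iso"))
            continue
        mean = 4.0 + (ppi_shift * 1.0 if tf in coupled_tfs else 0.0)
        hops = max(1, int(round(rng.normal(mean, 1.0))))
        prev = tf
        for h in range(hops - 1):
            nxt = f"{tf}_p{h}"
            edges.append((prev, nxt))
            prev = nxt
        edges.append((prev, POLII_ID))
        for d in range(rng.integers(0, 4)):
            edges.append((tf, f"{tf}_leaf{d}"))
        if rng.random() < 0.1:
            edges.append((tf, tf))  # homo-multimer
    ppi_edges = pd.DataFrame(edges, columns=["a", "b"])

    dmr_tracks = _dmr_tracks(config, annotations, rng)
    dhs_tracks = _dhs_tracks(config, annotations, rng)
    return AuxTables(
        ppi_edges=ppi_edges,
        polII_id=POLII_ID,
        gene_table=gene_table,
        tf_table=tf_table,
        mirna_table=mirna_table,
        dmr_tracks=dmr_tracks,
        dhs_tracks=dhs_tracks,
    )


def promoter_region(a: GeneAnnotation, length: int = 500) -> tuple[str, int, int]:
    """Genomic interval of the [-length, -1] upstream promoter."""
    if a.strand == "+":
        return a.chrom, a.tss - length, a.tss
    return a.chrom, a.tss + 1, a.tss + 1 + length


def tss_region(a: GeneAnnotation, flank: int = 100) -> tuple[str, int, int]:
    return a.chrom, a.tss - flank, a.tss + flank + 1


def _random_intervals(rng, chrom, lo, hi, count, min_len=50, max_len=150):
    rows = []
    for _ in range(count):
        length = int(rng.integers(min_len, max_len + 1))
        length = min(length, hi - lo)
        start = int(rng.integers(lo, max(hi - length, lo) + 1))
        rows.append((chrom, start, start + length))
    return rows


def _dmr_tracks(config, annotations, rng) -> dict[str, pd.DataFrame]:
    lam = {"promoter": 0.3, "tss": 0.15, "body": 0.5}
    tracks = {}
    for source, context in DMR_LAYERS:
        rows = []
        for a in annotations:
            for region, (chrom, lo, hi) in (
                ("promoter", promoter_region(a, config.promoter_len)),
                ("tss", tss_region(a)),
                ("body", (a.chrom, a.gene_start, a.gene_end)),
            ):
                count = rng.poisson(lam[region])
                rows.extend(_random_intervals(rng, chrom, lo, hi, count))
        tracks[f"dmr_{source}_{context}"] = pd.DataFrame(
            rows, columns=["chrom", "start", "end"]
        )
    return tracks


def _dhs_tracks(config, annotations, rng) -> dict[str, pd.DataFrame]:
    per_cond: dict[str, list[tuple[str, int, int]]] = {c: [] for c in DHS_CONDITIONS}
    for a in annotations:
        for chrom, lo, hi in (
            promoter_region(a, config.promoter_len),
            (a.chrom, a.gene_start, a.gene_end),
        ):
            if rng.random() < config.dhs_stable_prob:
                iv = _random_intervals(rng, chrom, lo, hi, 1, 100, 300)
                for c in DHS_CONDITIONS:
                    per_cond[c].extend(iv)
            if rng.random() < config.dhs_dynamic_prob:
                iv = _random_intervals(rng, chrom, lo, hi, 1, 100, 300)
                k = int(rng.integers(1, len(DHS_CONDITIONS)))
                for c in rng.choice(DHS_CONDITIONS, size=k, replace=False):
                    per_cond[c].extend(iv)
    return {
        c: pd.DataFrame(rows, columns=["chrom", "start", "end"])
        for c, rows in per_cond.items()
    }


# ---------------------------------------------------------------- bundle


def generate_all(config: SimConfig) -> SyntheticData:
    """Run every generator stage and return the full input bundle."""
    annotations, promoters = generate_genome(config)
    pwms = generate_pwms(config)
    ground_truth = plan_pairs(config, annotations, pwms)
    promoters = plant_motifs(pwms, promoters, ground_truth.planted_hit_positions)
    expression = generate_expression(config, ground_truth)
    aux = generate_aux_tables(config, ground_truth, annotations)
    return SyntheticData(
        config=config,
        annotations=annotations,
        promoters=promoters,
        pwms=pwms,
        expression=expression,
        aux=aux,
        ground_truth=ground_truth,
    )
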