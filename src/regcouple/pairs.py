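"""PWM promoter scanning and TF-target-gene pair construction.

A regulatory pair is a TF whose position weight matrix (PWM) matches a window
of a gene's upstream promoter (``[-500, -1]`` bp from the TSS by default) with
a relative log-odds score of at least 80% of the span between the minimal and
maximal attainable score.  Both strands are scanned; the per-pair binding-site
distance is the signed offset of the hit boundary nearest the TSS, negative
upstream in the gene's coding orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PSEUDOCOUNT = 1e-4
BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    table = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(table)[::-1]


@dataclass
class MotifPWM:
    """Position weight matrix: per-position base probabilities plus background.

    ``probs`` is an (L, 4) matrix in A, C, G, T column order; each row sums
    to 1.  ``background`` holds the genome base frequencies used in the
    log-odds score.
    """

    tf_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or len(self.probs) < 1:
            raise ValueError("probs must be an (L, 4) matrix with L >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM rows of {self.tf_id} must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return len(self.probs)

    def log_odds(self) -> np.ndarray:
        """(L, 4) matrix of log2((p + eps) / background)."""
        return np.log2((self.probs + PSEUDOCOUNT) / self.background)

    def score_range(self) -> tuple[float, float]:
        lo = self.log_odds()
        return float(lo.min(axis=1).sum()), float(lo.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.probs.argmax(axis=1))


def pwm_log_odds_score(pwm: MotifPWM, window: str) -> float:
    """Log-odds score of one window: sum_i log2((p[i, base] + eps) / bg[base])."""
    codes = encode_seq(window)
    if len(codes) != pwm.length:
        raise ValueError(f"window length {len(codes)} != motif length {pwm.length}")
    if (codes > 3).any():
        raise ValueError("window contains non-ACGT characters")
    lo = pwm.log_odds()
    return float(lo[np.arange(pwm.length), codes].sum())


def _strand_scores(lut: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores of all windows of len(lut) over an encoded sequence.

    Windows containing an ambiguity code score -inf.
    """
    L = len(lut)
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    # pad the lookup with a -inf column for code 4 (ambiguous base)
    lut_pad = np.hstack([lut, np.full((L, 1), -np.inf)])
    scores = np.zeros(n_win)
    for i in range(L):
        scores += lut_pad[i, codes[i : i + n_win]]
    return scores


def _rc_lut(lut: np.ndarray) -> np.ndarray:
    # reverse positions, complement base columns
    return lut[::-1, [3, 2, 1, 0]]


def scan_sequence(
    pwm: MotifPWM,
    seq: str,
    rel_threshold: float = 0.8,
    both_strands: bool = True,
) -> pd.DataFrame:
    """All windows with relative score >= ``rel_threshold``.

    Returns a frame with columns start, end (0-based half-open, forward
    coordinates of the sequence), strand, rel_score.  The relative score is
    ``(score - min_possible) / (max_possible - min_possible)``.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")
    L = pwm.length
    if len(seq) < L:
        log.warning("sequence shorter than motif (%d < %d): no hits", len(seq), L)
        return _empty_hits()
    codes = encode_seq(seq)
    if (codes > 3).any():
        log.debug("sequence contains %d ambiguous bases; windows skipped", int((codes > 3).sum()))
    lut = pwm.log_odds()
    smin, smax = pwm.score_range()
    span = smax - smin
    rows = []
    luts = [("+", lut)] + ([("-", _rc_lut(lut))] if both_strands else [])
    for strand, use_lut in luts:
        scores = _strand_scores(use_lut, codes)
        rel = (scores - smin) / span if span > 0 else np.where(np.isfinite(scores), 1.0, -np.inf)
        keep = np.nonzero(rel >= rel_threshold)[0]
        for p in keep:
            rows.append((int(p), int(p) + L, strand, float(rel[p])))
    if not rows:
        return _empty_hits()
    out = pd.DataFrame(rows, columns=["start", "end", "strand", "rel_score"])
    return out.sort_values(["start", "strand"]).reset_index(drop=True)


def _empty_hits() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": pd.Series(dtype=int),
            "end": pd.Series(dtype=int),
            "strand": pd.Series(dtype=object),
            "rel_score": pd.Series(dtype=float),
        }
    )


def signed_offset_distance(o_start: int, o_end: int) -> int:
    """Signed distance of an interval given TSS-relative offsets.

    ``o_start``/``o_end`` are 0-based half-open offsets relative to the TSS
    (offset 0 = first transcribed base).  0 if the interval covers the TSS,
    negative for upstream intervals (nearest-boundary convention), positive
    downstream.
    """
    if o_start <= 0 < o_end:
        return 0
    if o_end <= 0:
        return o_end
    return o_start


def tfbs_distance(hit_start: int, hit_end: int, tss: int, strand: str) -> int:
    """Signed TFBS-TSS distance from genomic coordinates, strand-aware.

    For a ``-`` strand gene the axis is mirrored so that upstream (larger
    genomic coordinates) is negative, matching the ``+`` strand convention.
    """
    if strand == "+":
        return signed_offset_distance(hit_start - tss, hit_end - tss)
    return signed_offset_distance(tss - hit_end + 1, tss - hit_start + 1)


def scan_promoter(
    pwm: MotifPWM,
    promoter_seq: str,
    tss_offset: int,
    rel_threshold: float = 0.8,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Scan one TSS-anchored promoter record and attach signed distances.

    ``tss_offset`` is the index of the TSS base within the record; the record
    is given in the gene's coding orientation, so hit strands are relative to
    the coding strand.
    """
    hits = scan_sequence(pwm, promoter_seq, rel_threshold, both_strands)
    hits["distance"] = [
        signed_offset_distance(s - tss_offset, e - tss_offset)
        for s, e in zip(hits["start"], hits["end"])
    ]
    return hits


def scan_promoters(
    pwms: list[MotifPWM],
    seqs: dict[str, str],
    tss_offset: int,
    rel_threshold: float = 0.8,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Scan many equal-length promoter records with many PWMs (fast path).

    Returns one frame with columns tf_id, gene_id, start, end, strand,
    rel_score, distance.  Equivalent to calling :func:`scan_promoter` per
    (PWM, gene); variable-length inputs fall back to that path.
    """
    gene_ids = list(seqs)
    if not gene_ids or not pwms:
        return _empty_batch()
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        frames = []
        for pwm in pwms:
            for g in gene_ids:
                h = scan_promoter(pwm, seqs[g], tss_offset, rel_threshold, both_strands)
                h.insert(0, "gene_id", g)
                h.insert(0, "tf_id", pwm.tf_id)
                frames.append(h)
        return pd.concat(frames, ignore_index=True) if frames else _empty_batch()

    mat = np.vstack([encode_seq(seqs[g]) for g in gene_ids])  # (n_gene, P)
    n_gene, P = mat.shape
    gene_arr = np.array(gene_ids)
    frames = []
    for pwm in pwms:
        L = pwm.length
        if P < L:
            continue
        lut = pwm.log_odds()
        smin, smax = pwm.score_range()
        span = smax - smin if smax > smin else 1.0
        n_win = P - L + 1
        for strand, use_lut in (("+", lut), ("-", _rc_lut(lut))) if both_strands else (("+", lut),):
            lut_pad = np.hstack([use_lut, np.full((L, 1), -np.inf)])
            scores = np.zeros((n_gene, n_win))
            for i in range(L):
                scores += lut_pad[i][mat[:, i : i + n_win]]
            rel = (scores - smin) / span
            gi, pi = np.nonzero(rel >= rel_threshold)
            if len(gi) == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "tf_id": pwm.tf_id,
                        "gene_id": gene_arr[gi],
                        "start": pi,
                        "end": pi + L,
                        "strand": strand,
                        "rel_score": rel[gi, pi],
                    }
                )
            )
    if not frames:
        return _empty_batch()
    hits = pd.concat(frames, ignore_index=True)
    o_start = hits["start"].to_numpy() - tss_offset
    o_end = hits["end"].to_numpy() - tss_offset
    dist = np.where(o_end <= 0, o_end, np.where(o_start <= 0, 0, o_start))
    hits["distance"] = dist
    return hits.sort_values(["tf_id", "gene_id", "start"]).reset_index(drop=True)


def _empty_batch() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["tf_id", "gene_id", "start", "end", "strand", "rel_score", "distance"]
    )


def build_pairs(
    annotations,
    promoters,
    pwms: list[MotifPWM],
    promoter_window: tuple[int, int] = (-500, -1),
    rel_threshold: float = 0.8,
    both_strands: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Construct the TF-TG pair set from promoter scans.

    A pair (tf, g) exists iff at least one of tf's hits overlaps g's promoter
    window; its ``closest_tfbs_distance`` is the in-window hit distance
    nearest 0, ties broken toward upstream.  Genes (and TFs) without an
    annotated 5'UTR are removed before pairing.

    Parameters
    ----------
    annotations : list[GeneAnnotation]
    promoters : PromoterSet
    """
    ann = {a.gene_id: a for a in annotations}
    tf_ids = {a.gene_id for a in annotations if a.is_tf}
    missing = sorted(t for t in tf_ids if t not in {p.tf_id for p in pwms})
    if missing:
        raise ValueError(f"TFs with no PWM: {', '.join(missing)}")

    retained = {g for g, a in ann.items() if a.max_utr5_len() > 0}
    dropped = len(ann) - len(retained)
    if dropped:
        log.info("removed %d genes without annotated 5'UTR", dropped)
    scan_pwms = [p for p in pwms if p.tf_id in retained]
    seqs = {g: promoters.seqs[g] for g in promoters.seqs if g in retained}

    hits = scan_promoters(scan_pwms, seqs, promoters.tss_offset, rel_threshold, both_strands)

    best = closest_promoter_hits(hits, promoters.tss_offset, promoter_window)
    if len(best) == 0:
        pairs = pd.DataFrame(columns=["tf_id", "tg_id", "closest_tfbs_distance"])
    else:
        pairs = best[["tf_id", "gene_id", "distance"]].rename(
            columns={"gene_id": "tg_id", "distance": "closest_tfbs_distance"}
        )
    pairs["pearson_r"] = np.nan
    pairs["label"] = "unlabeled"
    return pairs.reset_index(drop=True), hits


def closest_promoter_hits(
    hits: pd.DataFrame,
    tss_offset: int,
    promoter_window: tuple[int, int] = (-500, -1),
) -> pd.DataFrame:
    """Per (tf, gene): the promoter-window hit whose distance is nearest 0.

    A hit qualifies when its interval overlaps the promoter bases
    ``[window_lo, window_hi]``; ties in |distance| break toward upstream.
    """
    if len(hits) == 0:
        return hits.copy()
    lo, hi = promoter_window
    o_start = hits["start"].to_numpy() - tss_offset
    o_end = hits["end"].to_numpy() - tss_offset
    in_prom = (o_start <= hi) & (o_end > lo)
    prom_hits = hits.loc[in_prom]
    if len(prom_hits) == 0:
        return prom_hits.copy()
    key = prom_hits.assign(absd=prom_hits["distance"].abs()).sort_values(
        ["tf_id", "gene_id", "absd", "distance"]
    )
    best = key.groupby(["tf_id", "gene_id"], sort=True).first().reset_index()
    return best.drop(columns="absd")


def tfbs_distance_stats(
    hits: pd.DataFrame,
    pairs: pd.DataFrame | None = None,
    window: tuple[int, int] = (-1000, 500),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-TF and per-gene distance statistics over a wide TSS window.

    Mean and SD (ddof=1; 0 for a single hit) of signed TFBS-TSS distances of
    hits inside ``window``, plus pair-based target / regulator counts when a
    pair table is supplied.  TFs or genes without an in-window hit are absent
    (missing values are imputed downstream).
    """
    lo, hi = window
    inw = hits[(hits["distance"] >= lo) & (hits["distance"] <= hi)]

    def _agg(group_col: str) -> pd.DataFrame:
        g = inw.groupby(group_col)["distance"]
        out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1).fillna(0.0)})
        out.index.name = group_col
        return out

    tf_stats = _agg("tf_id")
    tg_stats = _agg("gene_id")
    if pairs is not None and len(pairs):
        tf_stats = tf_stats.join(pairs.groupby("tf_id").size().rename("n_targets"), how="outer")
        tg_stats = tg_stats.join(
            pairs.groupby("tg_id").size().rename("n_regulators"), how="outer"
        )
        tf_stats["n_targets"] = tf_stats["n_targets"].fillna(0).astype(int)
        tg_stats["n_regulators"] = tg_stats["n_regulators"].fillna(0).astype(int)
    return tf_stats, tg_stats
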