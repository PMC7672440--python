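"""Configuration objects for the synthetic study and the end-to-end pipeline.

``SimConfig`` fixes the conditions of the synthetic study: how many TFs and
genes are simulated, the latent-activity expression model (effect size ``beta``
and noise ``sigma``), motif geometry, and which auxiliary features are planted
with a class-dependent shift.  All randomness downstream flows from its single
``seed``; per-table sub-seeds are derived deterministically.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

LN4 = math.log(4.0)

#: Auxiliary feature columns that accept a planted Cohen's-D-scale shift
#: between coupled and uncoupled pair populations.  The suffix names the role
#: (``_tf`` shifts the value of TFs owning coupled pairs, ``_tg`` shifts the
#: value of target genes of coupled pairs).
VALID_SHIFT_FEATURES = (
    "ppi_distance_to_polII",
    "phospho_sites",
    "halflife_tf",
    "halflife_tg",
    "mirna_target_sites_tf",
    "mirna_target_sites_tg",
    "mirna_max_energy_ratio_tf",
    "mirna_max_energy_ratio_tg",
    "age_tf",
    "age_tg",
)


def _default_shifts() -> dict[str, float]:
    # Three informative target-gene-side features at a moderate effect size,
    # on a background of ~130 unshifted columns.
    return {
        "halflife_tg": 0.8,
        "mirna_target_sites_tg": 0.8,
        "mirna_max_energy_ratio_tg": 0.8,
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic data generator.

    Parameters
    ----------
    n_tf, n_gene
        Number of transcription factors and of non-TF genes.  TFs are genes
        too (they carry promoters and may be targets of other TFs).
    n_sample
        Number of expression samples (conditions).
    promoter_len
        Length in bp of the upstream promoter used for pairing
        (the ``[-promoter_len, -1]`` window).
    upstream_len, downstream_len
        Extent of the simulated sequence around each TSS.  The scanned record
        covers ``[-upstream_len, +downstream_len)`` so that binding sites
        outside the pairing promoter (used by the wide distance-statistics
        window) exist as well.
    motif_len_range
        Inclusive (min, max) motif length in bp.
    entropy_levels
        Target mean per-position entropies (nats) cycled across TFs.
    coupling_beta, noise_sd
        Latent model: a coupled target gene's expression is
        ``beta * x + Normal(0, noise_sd)`` where ``x`` is the regulating TF's
        per-sample latent activity; the expected TF-TG Pearson correlation is
        ``beta / sqrt(beta**2 + noise_sd**2)``.
    frac_coupled_pairs
        Fraction of each active TF's planted pairs that are expression
        coupled; the remainder (and all pairs of inactive TFs) are uncoupled.
    active_tf_ids
        TFs whose pairs may be coupled; default: the first half of all TFs.
    targets_per_tf
        Planted target genes per TF.
    planted_feature_shifts
        Map feature name -> Cohen's-D-scale shift applied between
        to-be-correlated and to-be-uncorrelated pair populations.
    missing_rate
        Fraction of cells blanked (NaN) in auxiliary tables that allow
        missingness, to exercise imputation.
    frac_no_utr5
        Fraction of genes generated without an annotated 5'UTR; these are
        filtered out before pairing and never receive planted motifs.
    """

    n_tf: int = 50
    n_gene: int = 2500
    n_sample: int = 200
    promoter_len: int = 500
    upstream_len: int = 1000
    downstream_len: int = 500
    motif_len_range: tuple[int, int] = (12, 18)
    entropy_levels: tuple[float, ...] = (0.05, 0.15, 0.3)
    coupling_beta: float = 1.0
    noise_sd: float = 1.0
    frac_coupled_pairs: float = 0.15
    active_tf_ids: Optional[tuple[str, ...]] = None
    targets_per_tf: int = 100
    planted_feature_shifts: dict[str, float] = field(default_factory=_default_shifts)
    missing_rate: float = 0.05
    frac_no_utr5: float = 0.02
    dhs_stable_prob: float = 0.5
    dhs_dynamic_prob: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sample < 3:
            raise ValueError("n_sample must be >= 3")
        if not 0.0 <= self.frac_coupled_pairs <= 1.0:
            raise ValueError("frac_coupled_pairs must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.motif_len_range
        if not 1 <= lo <= hi:
            raise ValueError("motif_len_range must satisfy 1 <= min <= max")
        if self.promoter_len < hi:
            raise ValueError(
                f"promoter_len ({self.promoter_len}) is shorter than the longest "
                f"configured motif ({hi})"
            )
        for level in self.entropy_levels:
            if not 0.0 <= level <= LN4 + 1e-12:
                raise ValueError(f"entropy level {level} outside [0, ln 4]")
        for name in self.planted_feature_shifts:
            if name not in VALID_SHIFT_FEATURES:
                raise ValueError(
                    f"unknown feature {name!r} in planted_feature_shifts; "
                    f"valid names: {', '.join(VALID_SHIFT_FEATURES)}"
                )

    @property
    def record_len(self) -> int:
        return self.upstream_len + self.downstream_len

    def tf_ids(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(self.n_tf)]

    def gene_ids(self) -> list[str]:
        return self.tf_ids() + [f"G{i:05d}" for i in range(self.n_gene)]

    def resolved_active_tfs(self) -> list[str]:
        if self.active_tf_ids is not None:
            return list(self.active_tf_ids)
        return self.tf_ids()[: self.n_tf // 2]

    def expected_coupled_r(self) -> float:
        b, s = self.coupling_beta, self.noise_sd
        return b / math.sqrt(b * b + s * s)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """End-to-end run configuration (synthetic or real-data mode).

    Every numeric knob defaults to the published analysis choice: promoter
    ``[-500, -1]``, 80% relative scan threshold, activity percentile 97.5 with
    a 3000-target cap, labels ``r > 0.4`` vs ``-0.1 < r < 0.1``, feature
    clustering at ``r > 0.85``, and a forest of 3000 trees with 5 candidate
    variables per split and terminal nodes of at least 150 observations,
    evaluated over 20 component-disjoint 80/20 repeats.
    """

    mode: str = "synthetic"
    sim: SimConfig = field(default_factory=SimConfig)
    # real-data input paths (required when mode == "real")
    gff3_path: Optional[str] = None
    fasta_path: Optional[str] = None
    pwm_path: Optional[str] = None
    expression_path: Optional[str] = None

    promoter_window: tuple[int, int] = (-500, -1)
    scan_threshold: float = 0.8
    stats_window: tuple[int, int] = (-1000, 500)
    active_percentile: float = 97.5
    tg_cap: int = 3000
    label_hi: float = 0.4
    label_band: tuple[float, float] = (-0.1, 0.1)
    cluster_r_threshold: float = 0.85
    n_trees: int = 3000
    vars_per_split: Optional[int] = 5
    min_node: int = 150
    train_frac: float = 0.8
    cv_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if self.mode == "real":
            missing = [
                name
                for name in ("gff3_path", "fasta_path", "pwm_path", "expression_path")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(f"mode='real' requires paths: {', '.join(missing)}")
        if not 0 < self.scan_threshold <= 1:
            raise ValueError("scan_threshold must be in (0, 1]")
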