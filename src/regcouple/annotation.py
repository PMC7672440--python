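"""Gene annotation containers: coordinates, isoform metrics, promoters."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Isoform:
    mrna_len: int
    protein_len: int
    utr5_len: int
    utr3_len: int
    utr5_has_intron: bool = False


@dataclass
class GeneAnnotation:
    """One gene: coordinates (0-based half-open), strand, TSS and isoforms.

    ``tss`` is the 0-based position of the first transcribed base; for a
    ``-`` strand gene that is ``gene_end - 1``.  ``upstream_gene_distance``
    is the boundary-to-boundary gap to the nearest gene on the coding-upstream
    side (-1 when there is none).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_start: int
    gene_end: int
    isoforms: list[Isoform] = field(default_factory=list)
    upstream_gene_distance: int = -1
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.gene_start >= self.gene_end:
            raise ValueError(f"{self.gene_id}: gene_start must be < gene_end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    def max_utr5_len(self) -> int:
        return max((iso.utr5_len for iso in self.isoforms), default=0)


@dataclass
class PromoterSet:
    """TSS-anchored sequence records, one per gene, in coding orientation.

    Each record covers ``[-tss_offset, +len - tss_offset)`` relative to the
    TSS; index ``tss_offset`` is the TSS base itself.
    """

    seqs: dict[str, str]
    tss_offset: int

    def __getitem__(self, gene_id: str) -> str:
        return self.seqs[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.seqs

    def __len__(self) -> int:
        return len(self.seqs)
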