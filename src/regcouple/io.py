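"""Readers and writers for the pipeline's on-disk formats.

Conventions: FASTA promoter records carry ``tss_offset=<int>`` in their
description; GFF3 is 1-based closed (converted at the boundary to the
0-based half-open coordinates used internally); BED is 0-based half-open;
PWM files are JASPAR-like probability matrices with rows A/C/G/T and an
optional ``#background`` comment line.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneAnnotation, Isoform, PromoterSet
from .config import PipelineConfig, SimConfig
from .pairs import MotifPWM

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- FASTA


def write_promoters(promoters: PromoterSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gid, description=f"tss_offset={promoters.tss_offset}")
        for gid, seq in sorted(promoters.seqs.items())
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_promoters(path: str | Path, tss_offset: int | None = None) -> PromoterSet:
    seqs = {}
    offsets = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        for token in rec.description.split():
            if token.startswith("tss_offset="):
                offsets.add(int(token.split("=", 1)[1]))
    if tss_offset is None:
        if len(offsets) != 1:
            raise ValueError("FASTA records lack a consistent tss_offset annotation")
        tss_offset = offsets.pop()
    return PromoterSet(seqs, tss_offset)


# ---------------------------------------------------------------- GFF3


def write_gff3(annotations: list[GeneAnnotation], path: str | Path) -> None:
    """Genes, mRNAs and UTR features; isoform metrics ride along as attributes."""
    lines = ["##gff-version 3"]
    for a in sorted(annotations, key=lambda x: (x.chrom, x.gene_start, x.gene_id)):
        start1, end1 = a.gene_start + 1, a.gene_end  # 1-based closed
        attrs = f"ID={a.gene_id};is_tf={int(a.is_tf)};upstream_gene_distance={a.upstream_gene_distance}"
        lines.append(
            "\t".join(
                [a.chrom, "regcouple", "gene", str(start1), str(end1), ".", a.strand, ".", attrs]
            )
        )
        for k, iso in enumerate(a.isoforms, start=1):
            mid = f"{a.gene_id}.{k}"
            mattrs = (
                f"ID={mid};Parent={a.gene_id};mrna_length={iso.mrna_len};"
                f"protein_length={iso.protein_len};utr5_length={iso.utr5_len};"
                f"utr3_length={iso.utr3_len};utr5_has_intron={int(iso.utr5_has_intron)}"
            )
            lines.append(
                "\t".join(
                    [a.chrom, "regcouple", "mRNA", str(start1), str(end1), ".", a.strand, ".", mattrs]
                )
            )
            if iso.utr5_len > 0:
                if a.strand == "+":
                    u5 = (start1, min(start1 + iso.utr5_len - 1, end1))
                else:
                    u5 = (max(end1 - iso.utr5_len + 1, start1), end1)
                lines.append(
                    "\t".join(
                        [a.chrom, "regcouple", "five_prime_UTR", str(u5[0]), str(u5[1]), ".",
                         a.strand, ".", f"ID={mid}.utr5;Parent={mid}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    annotations = []
    for gene in db.features_of_type("gene"):
        start0, end0 = gene.start - 1, gene.end  # to 0-based half-open
        isoforms = []
        for mrna in db.children(gene, featuretype="mRNA"):
            isoforms.append(
                Isoform(
                    mrna_len=int(mrna.attributes["mrna_length"][0]),
                    protein_len=int(mrna.attributes["protein_length"][0]),
                    utr5_len=int(mrna.attributes["utr5_length"][0]),
                    utr3_len=int(mrna.attributes["utr3_length"][0]),
                    utr5_has_intron=bool(int(mrna.attributes["utr5_has_intron"][0])),
                )
            )
        annotations.append(
            GeneAnnotation(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tss=start0 if gene.strand == "+" else end0 - 1,
                gene_start=start0,
                gene_end=end0,
                isoforms=isoforms,
                upstream_gene_distance=int(gene.attributes.get("upstream_gene_distance", ["-1"])[0]),
                is_tf=bool(int(gene.attributes.get("is_tf", ["0"])[0])),
            )
        )
    return annotations


# ---------------------------------------------------------------- BED / TSV


def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    frame = frame.sort_values(["chrom", "start", "end"])
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame = frame.iloc[:, :3]
    frame.columns = ["chrom", "start", "end"]
    if (frame["start"] >= frame["end"]).any():
        bad = (frame["start"] >= frame["end"]).idxmax()
        raise ValueError(f"{path}: malformed interval at line {bad + 1}")
    if not frame.equals(frame.sort_values(["chrom", "start", "end"]).reset_index(drop=True)):
        log.warning("%s: unsorted BED, sorting internally", path)
        frame = frame.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return frame


def write_matrix(frame: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    frame.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------- PWMs


def write_pwms(pwms: list[MotifPWM], path: str | Path) -> None:
    """JASPAR-like probability matrices, rows A/C/G/T, background as comment."""
    chunks = []
    for pwm in pwms:
        bg = " ".join(f"{v:.6f}" for v in pwm.background)
        rows = [f">{pwm.tf_id}", f"#background {bg}"]
        for j, base in enumerate("ACGT"):
            vals = " ".join(f"{v:.6f}" for v in pwm.probs[:, j])
            rows.append(f"{base} [ {vals} ]")
        chunks.append("\n".join(rows))
    Path(path).write_text("\n".join(chunks) + "\n")


def read_pwms(path: str | Path) -> list[MotifPWM]:
    text = Path(path).read_text()
    backgrounds: dict[str, np.ndarray] = {}
    current = None
    clean_lines = []
    for line in text.splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            clean_lines.append(line)
        elif line.startswith("#background"):
            backgrounds[current] = np.array([float(v) for v in line.split()[1:]])
        elif line.strip():
            clean_lines.append(line)
    parsed = bio_motifs.parse(StringIO("\n".join(clean_lines)), "jaspar")
    out = []
    for m in parsed:
        mat = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float).T  # (L, 4)
        mat = mat / mat.sum(axis=1, keepdims=True)
        tf_id = m.matrix_id if m.matrix_id else m.name
        out.append(
            MotifPWM(
                tf_id=tf_id,
                probs=mat,
                background=backgrounds.get(tf_id, np.full(4, 0.25)),
            )
        )
    return out


# ---------------------------------------------------------------- JSON / config


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


_TUPLE_FIELDS = {
    "motif_len_range", "entropy_levels", "active_tf_ids",
    "promoter_window", "label_band", "stats_window",
}


def config_to_json(config: SimConfig | PipelineConfig, path: str | Path) -> None:
    write_json(dataclasses.asdict(config), path)


def _detuple(d: dict) -> dict:
    return {
        k: tuple(v) if k in _TUPLE_FIELDS and v is not None else v for k, v in d.items()
    }


def sim_config_from_json(path: str | Path) -> SimConfig:
    return SimConfig(**_detuple(read_json(path)))


def pipeline_config_from_json(path: str | Path) -> PipelineConfig:
    d = _detuple(read_json(path))
    d["sim"] = SimConfig(**_detuple(d["sim"]))
    return PipelineConfig(**d)


# ---------------------------------------------------------------- bundles


def write_synthetic_inputs(dataset, outdir: str | Path) -> None:
    """Write every generated input in its external format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gff3(dataset.annotations, outdir / "genes.gff3")
    write_promoters(dataset.promoters, outdir / "promoters.fasta")
    write_pwms(dataset.pwms, outdir / "pwms.jaspar.txt")
    write_matrix(dataset.expression, outdir / "expression.tsv")
    aux = dataset.aux
    aux.ppi_edges.to_csv(outdir / "ppi_edges.tsv", sep="\t", index=False)
    write_matrix(aux.gene_table, outdir / "gene_table.tsv")
    write_matrix(aux.tf_table, outdir / "tf_table.tsv", index_label="tf_id")
    write_matrix(aux.mirna_table, outdir / "mirna_table.tsv")
    for name, frame in {**aux.dmr_tracks, **aux.dhs_tracks}.items():
        write_bed(frame, outdir / f"{name}.bed")
    (outdir / "ground_truth.json").write_text(dataset.ground_truth.to_json() + "\n")
    config_to_json(dataset.config, outdir / "sim_config.json")
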