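"""Generate the synthetic study inputs and write them in external formats.

Writes GFF3 annotation, promoter FASTA, JASPAR-like PWMs, the expression
matrix, auxiliary tables, DMR/DHS BED tracks and the ground-truth manifest
under scratch/pipeline/inputs/.
"""

from common import STUDY, outdirs

from regcouple import io as rcio
from regcouple import synthdata


def main() -> None:
    _, scratch = outdirs()
    ds = synthdata.generate_all(STUDY.sim)
    rcio.write_synthetic_inputs(ds, scratch / "inputs")
    gt = ds.ground_truth
    print(f"genes: {len(ds.annotations)} ({STUDY.sim.n_tf} TFs), "
          f"samples: {STUDY.sim.n_sample}")
    print(f"planted pairs: {len(gt.planted_hit_positions)} "
          f"({len(gt.coupled_pairs)} expression-coupled, "
          f"expected r = {STUDY.sim.expected_coupled_r():.4f})")
    print(f"active TFs by construction: {len(gt.active_tfs)}")
    print(f"shifted features: {', '.join(gt.informative_features)}")
    print(f"inputs written to {scratch / 'inputs'}")


if __name__ == "__main__":
    main()
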