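"""Shared configuration for the numbered analysis drivers.

Every driver reruns the deterministic pipeline from this one configuration,
so the scripts can be run independently and in any order.  The study is the
planted-signal recovery problem: 60 TFs (half active) against a pool of
9000 genes, ~5000 labeled pairs, three auxiliary features shifted between
the to-be-correlated and to-be-uncorrelated populations.  The problem needs
this many pairs because terminal nodes of >= 150 observations leave smaller
training sets without any splits.  The forest is reduced to 600 trees over
10 repeats for a desk-scale run; mtry 5 and the node size are unchanged.
"""

from pathlib import Path

from regcouple.studies import planted_recovery_config

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "pipeline"

STUDY = planted_recovery_config(seed=1)
STUDY.n_trees = 600
STUDY.cv_repeats = 10


def outdirs() -> tuple[Path, Path]:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    return RESULTS, SCRATCH
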