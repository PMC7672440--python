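"""Scan promoters with PWMs and build the TF-target pair set.

Reports how many planted pairs the 80%-threshold scan recovers and how many
extra (background) pairs arise, and writes the pair table to results/.
"""

from common import STUDY, outdirs

from regcouple import pipeline


def main() -> None:
    results, _ = outdirs()
    res = pipeline.run_pipeline(STUDY, until="pairs")
    gt = res.dataset.ground_truth
    got = set(zip(res.pairs.tf_id, res.pairs.tg_id))
    planted = gt.planted_pairs()
    recovered = len(planted & got)
    print(f"hits: {len(res.hits)}; pairs: {len(res.pairs)}")
    print(f"planted-pair recall: {recovered}/{len(planted)} "
          f"({100 * recovered / len(planted):.1f}%)")
    print(f"background (unplanted) pairs: {len(got - planted)} "
          f"({100 * len(got - planted) / len(got):.1f}% of the pair set)")
    res.pairs.to_csv(results / "pairs.tsv", sep="\t", index=False)
    print(f"wrote {results / 'pairs.tsv'}")


if __name__ == "__main__":
    main()
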