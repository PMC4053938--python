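#!/usr/bin/env python
"""Control vs Suz12-knockdown 5hmC differential metaprofile at
H3K27me3-positive promoters: per-bin difference with paired label-swap
permutation p-values and BH correction. The knockdown removes 5hmC from the
downstream (PRC2-coincident) component only.
"""

import pandas as pd

from _common import RESULTS, run_analyses


def main() -> None:
    run_analyses(["fig6_differential"])
    diff = pd.read_csv(RESULTS / "fig6_differential.tsv", sep="\t")
    sig = diff[diff["qvalue_bh"] < 0.05]
    print(f"{len(sig)}/{len(diff)} bins lose 5hmC significantly (BH q < 0.05)")
    if len(sig):
        print(f"significant span: {sig['position'].min():+.0f} .. "
              f"{sig['position'].max():+.0f} bp from TSS")
        top = diff.loc[diff["diff"].idxmax()]
        print(f"largest loss {top['diff']:.3f} at {top['position']:+.0f} bp")


if __name__ == "__main__":
    main()
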