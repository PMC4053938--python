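#!/usr/bin/env python
"""5hmC density across genomic element classes (promoters, exons, introns,
CpG classes, chromatin classes, enhancer states) with permutation enrichment
tests and BH correction, plus the mark-by-mark promoter correlation matrix.
"""

import pandas as pd

from _common import RESULTS, run_analyses


def main() -> None:
    run_analyses(["fig2_densities", "fig2_cormat"])
    dens = pd.read_csv(RESULTS / "fig2_densities.tsv", sep="\t")
    print("5hmC covered fraction per element class:")
    print(dens.set_index("class")["density"].round(3))
    tests = pd.read_csv(RESULTS / "fig2_enrichment_tests.tsv", sep="\t")
    print("\nenrichment tests (BH-adjusted):")
    print(tests[["class_a", "class_b", "delta_density", "pvalue", "qvalue_bh"]]
          .round(4).to_string(index=False))
    cor = pd.read_csv(RESULTS / "fig2_mark_correlation.tsv", sep="\t", index_col=0)
    print("\npromoter-level correlation of 5hmC with other marks:")
    print(cor["5hmC"].round(3))


if __name__ == "__main__":
    main()
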