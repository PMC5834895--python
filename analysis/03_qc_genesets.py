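#!/usr/bin/env python
"""Apply exclusion rules and build the core / hard-core gene sets.

Site validity (depth > 5x, qualities > 20), individual floors (10x mean
coverage, 80% alignment, covered-ORF and covered-core minima) and species
floors (70% alignment, ORF and core-gene minima, haplodiploids out), then
core = predicted ORFs found in the essential-gene list and hard-core = core
minus every gene homozygous-LoF anywhere in the panel.  Floors are scaled
to the demonstration panel's 1000 genes per species.
"""

from pathlib import Path

import pandas as pd

from lofprev.pipeline import RunConfig, stage_filter
from lofprev.qc import IndividualThresholds, SpeciesThresholds

OUT = Path("results/run")

# the published floors assume >= 5000 predicted ORFs; scale them to the
# demonstration panel (1000 genes, 200 core) keeping the same proportions
RUN = RunConfig(
    out_dir=OUT,
    input_dir=OUT / "panel",
    individual_thresholds=IndividualThresholds(min_covered_orfs=700, min_covered_core=20),
    species_thresholds=SpeciesThresholds(min_orfs=700, min_core=20),
)


def main() -> None:
    stage_filter(OUT, "default", RUN)
    sets = pd.read_csv(OUT / "gene_sets.tsv", sep="\t")
    excl = pd.read_csv(OUT / "exclusions.tsv", sep="\t")
    print(f"genes: {len(sets)}, core: {sets.core.sum()}, hardcore: {sets.hardcore.sum()}")
    print(f"{len(excl)} exclusions" + ("" if excl.empty else ":"))
    if not excl.empty:
        print(excl.to_string(index=False))


if __name__ == "__main__":
    main()
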