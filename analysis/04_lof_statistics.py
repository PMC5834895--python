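#!/usr/bin/env python
"""Compute LoF allele proportions and the cross-species summary.

Per individual, p = (N_het + 2 N_hom) / (2N) over its fully sequenced ORFs,
stratified by gene set (all/core/hardcore), variant type (all/nonsense/
frameshift/stoploss) and region (full CDS vs last 100 nt); species values
are unweighted means over individuals.
"""

from pathlib import Path

import pandas as pd

from lofprev.pipeline import stage_stats

import importlib.util as _iu

_spec = _iu.spec_from_file_location("qc_step", Path(__file__).parent / "03_qc_genesets.py")
_qc_step = _iu.module_from_spec(_spec)
_spec.loader.exec_module(_qc_step)

OUT = Path("results/run")


def main() -> None:
    stage_stats(OUT, "default", _qc_step.RUN)
    print("Species-level summary, all genes (percent of alleles):")
    print(pd.read_csv(OUT / "summary.tsv", sep="\t").to_string(index=False))
    means = pd.read_csv(OUT / "per_species.tsv", sep="\t")
    primary = means[
        (means.variant_type == "all_lof") & (means.region == "full_cds")
    ].pivot(index="species", columns="gene_set", values="mean_p")
    print("\nPer-species mean proportions (fraction):")
    print((primary).round(5).to_string())


if __name__ == "__main__":
    main()
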