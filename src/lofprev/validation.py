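"""Parameter-recovery diagnostics for synthetic panels.

Compares the pipeline's species-mean LoF proportions against the generating
panel's expectations (mean q per gene set; the no-homozygote conditional
form for the hardcore set) on the Monte-Carlo standard-error scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SyntheticPanel


@dataclass(frozen=True)
class RecoveryResult:
    gene_set: str
    expected: float
    observed: float  # grand mean of species-mean p-hat
    se_grand: float
    z_grand: float
    max_abs_z_species: float


def _gene_mask(panel: SyntheticPanel, gene_set: str, hardcore: frozenset[str] | None) -> np.ndarray:
    if gene_set == "all":
        return np.ones(len(panel.gene_ids), dtype=bool)
    if gene_set == "core":
        return np.array([g in panel.core_genes for g in panel.gene_ids])
    if gene_set == "hardcore":
        if hardcore is None:
            raise ValueError("hardcore recovery needs the realized hardcore set")
        return np.array([g in hardcore for g in panel.gene_ids])
    raise KeyError(gene_set)


def recovery_report(
    panel: SyntheticPanel,
    per_species: pd.DataFrame,
    hardcore: frozenset[str] | None = None,
) -> dict[str, RecoveryResult]:
    """Recovery z-scores per gene set from the pipeline's per-species table.

    The per-gene sampling variance of the allele-level statistic is
    2q(1-q) unconditionally and, for hardcore genes (conditioned on never
    observing a homozygote), that of a Bernoulli(2q/(1+q)) allele count.
    """
    cfg = panel.config
    out: dict[str, RecoveryResult] = {}
    sub = per_species[
        (per_species.variant_type == "all_lof") & (per_species.region == "full_cds")
    ]
    for gs in ("all", "core", "hardcore"):
        mask = _gene_mask(panel, gs, hardcore)
        exp_by_sp, var_by_sp, obs = [], [], []
        for sp in panel.species:
            q = sp.q[mask]
            if q.size == 0:
                continue
            if gs == "hardcore":
                pc = 2 * q / (1 + q)  # conditional per-gene allele-count mean
                mu = float(np.mean(pc / 2))
                var_gene = pc * (1 - pc)
            else:
                mu = float(np.mean(q))
                var_gene = 2 * q * (1 - q)
            n_eff = q.size * (1 - cfg.coverage_dropout)
            var_ind = float(np.mean(var_gene)) / (4 * n_eff)
            row = sub[(sub.species == sp.species_id) & (sub.gene_set == gs)]
            if row.empty or pd.isna(row["mean_p"].iloc[0]):
                continue
            exp_by_sp.append(mu)
            var_by_sp.append(var_ind / cfg.individuals_per_species)
            obs.append(float(row["mean_p"].iloc[0]))
        exp_arr, var_arr, obs_arr = map(np.asarray, (exp_by_sp, var_by_sp, obs))
        n = len(obs_arr)
        expected = float(exp_arr.mean())
        observed = float(obs_arr.mean())
        se_grand = float(np.sqrt(var_arr.sum()) / n)
        z_species = (obs_arr - exp_arr) / np.sqrt(var_arr)
        out[gs] = RecoveryResult(
            gene_set=gs,
            expected=expected,
            observed=observed,
            se_grand=se_grand,
            z_grand=(observed - expected) / se_grand,
            max_abs_z_species=float(np.max(np.abs(z_species))),
        )
    return out
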