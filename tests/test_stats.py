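"""The LoF proportion statistic, species means and the summary table."""

import numpy as np
import pandas as pd
import pytest

from lofprev.consequence import GeneLoF
from lofprev.qc import GeneSetPartition, IndividualProfile
from lofprev.stats import (
    all_individual_statistics,
    format_percent,
    individual_statistics,
    individual_table,
    lof_proportion,
    parse_percent,
    species_means,
    summary_table,
)


class TestProportionFormula:
    def test_worked_example(self):
        assert lof_proportion(100, 4, 1) == pytest.approx(0.03)

    def test_zero_lof(self):
        for n in (1, 10, 5000):
            assert lof_proportion(n, 0, 0) == 0.0

    def test_all_alleles_lof(self):
        assert lof_proportion(50, 0, 50) == 1.0

    def test_missing_when_no_genes(self):
        assert lof_proportion(0, 0, 0) is None

    def test_counts_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            lof_proportion(10, 8, 3)

    def test_monotone_in_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 100))
            het = int(rng.integers(0, n // 2))
            hom = int(rng.integers(0, n // 2 - het + 1)) if n // 2 - het > 0 else 0
            p = lof_proportion(n, het, hom)
            assert lof_proportion(n, het + 1, hom) > p
            assert lof_proportion(n + 1, het, hom) <= p or p == 0


def _gl(gene, triples):
    return GeneLoF(gene, tuple(triples))


def _profile(gene_lof, covered, iid="i1", sid="sp1"):
    return IndividualProfile(
        individual_id=iid,
        species_id=sid,
        mean_coverage=30,
        alignment_rate=0.95,
        covered_orfs=frozenset(covered),
        n_partial_orfs=len(covered),
        n_partial_core=10,
        gene_lof=gene_lof,
    )


@pytest.fixture
def partition():
    allg = frozenset(f"g{i}" for i in range(10))
    core = frozenset({"g0", "g1", "g2", "g3"})
    hard = frozenset({"g0", "g1"})
    return GeneSetPartition(allg, core, hard)


class TestIndividualStatistics:
    def test_matches_brute_force_recount(self, partition):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(10)]
        gene_lof = {}
        for g in genes:
            if rng.random() < 0.5:
                trips = []
                for _ in range(rng.integers(1, 3)):
                    trips.append(
                        (
                            ("nonsense", "frameshift", "stoploss")[rng.integers(0, 3)],
                            ("het", "hom")[rng.integers(0, 2)],
                            bool(rng.random() < 0.5),
                        )
                    )
                gene_lof[g] = _gl(g, trips)
        covered = [g for g in genes if rng.random() < 0.9]
        prof = _profile(gene_lof, covered)
        for gs in ("all", "core", "hardcore"):
            for vt in ("all_lof", "nonsense", "frameshift", "stoploss"):
                for rg in ("full_cds", "last100nt"):
                    got = individual_statistics(prof, partition, gs, vt, rg)
                    # independent recount over the gene map
                    sel = set(covered) & partition.get(gs)
                    het = hom = 0
                    for g in sel:
                        states = [
                            z
                            for t, z, w in (gene_lof[g].variants if g in gene_lof else [])
                            if (vt == "all_lof" or t == vt) and (rg == "full_cds" or w)
                        ]
                        if "hom" in states:
                            hom += 1
                        elif states:
                            het += 1
                    assert (got.n_total, got.n_het, got.n_hom) == (len(sel), het, hom)
                    if sel:
                        assert got.p == pytest.approx((het + 2 * hom) / (2 * len(sel)))
                    else:
                        assert got.p is None

    def test_empty_gene_set_is_missing_not_zero(self):
        part = GeneSetPartition(frozenset({"g0"}), frozenset(), frozenset())
        prof = _profile({}, ["g0"])
        res = individual_statistics(prof, part, "hardcore")
        assert res.p is None and res.n_total == 0

    def test_lof_outside_window_scores_zero_in_window_region(self, partition):
        gene_lof = {"g5": _gl("g5", [("nonsense", "het", False)])}
        prof = _profile(gene_lof, [f"g{i}" for i in range(10)])
        full = individual_statistics(prof, partition, "all", region="full_cds")
        win = individual_statistics(prof, partition, "all", region="last100nt")
        assert full.p > 0
        assert win.p == 0.0 and win.n_total == full.n_total

    def test_all_lof_dominates_single_types(self, partition):
        gene_lof = {
            "g0": _gl("g0", [("nonsense", "het", True)]),
            "g4": _gl("g4", [("frameshift", "hom", True), ("nonsense", "het", False)]),
        }
        prof = _profile(gene_lof, [f"g{i}" for i in range(10)])
        p_all = individual_statistics(prof, partition, "all", "all_lof").p
        for vt in ("nonsense", "frameshift", "stoploss"):
            assert p_all >= individual_statistics(prof, partition, "all", vt).p


class TestSpeciesMeans:
    def _stats(self, pairs):
        profs = []
        for iid, (sid, p_genes) in enumerate(pairs):
            gene_lof = {g: _gl(g, [("nonsense", "het", True)]) for g in p_genes}
            profs.append(
                _profile(gene_lof, [f"g{i}" for i in range(10)], iid=f"i{iid}", sid=sid)
            )
        part = GeneSetPartition(frozenset(f"g{i}" for i in range(10)), frozenset(), frozenset())
        return all_individual_statistics(profs, part, gene_sets=("all",))

    def test_unweighted_mean(self):
        # p = 0.02 -> 0.4 het genes... use integer counts: 0/10 and 2/10 het
        stats = self._stats([("sp", []), ("sp", ["g0", "g1"])])
        m = species_means(stats)
        row = m[(m.gene_set == "all") & (m.variant_type == "all_lof") & (m.region == "full_cds")]
        assert row["mean_p"].iloc[0] == pytest.approx((0.0 + 0.1) / 2)

    def test_single_individual_identity(self):
        stats = self._stats([("sp", ["g0"])])
        m = species_means(stats)
        row = m[(m.variant_type == "all_lof") & (m.region == "full_cds")]
        assert row["mean_p"].iloc[0] == pytest.approx(0.05)

    def test_hand_computed_mean_nine_individuals(self):
        rng = np.random.default_rng(4)
        pairs = [("sp", [f"g{i}" for i in range(rng.integers(0, 5))]) for _ in range(9)]
        stats = self._stats(pairs)
        m = species_means(stats)
        row = m[(m.variant_type == "all_lof") & (m.region == "full_cds")]
        expected = np.mean([len(genes) / 20 for _, genes in pairs])
        assert row["mean_p"].iloc[0] == pytest.approx(expected)

    def test_missing_propagates_not_zero(self):
        prof = _profile({}, [])  # nothing covered -> missing
        part = GeneSetPartition(frozenset({"g0"}), frozenset(), frozenset())
        stats = all_individual_statistics([prof], part, gene_sets=("all",))
        m = species_means(stats)
        assert m["mean_p"].isna().all()


class TestSummary:
    def _means(self, values, vt="all_lof"):
        return pd.DataFrame(
            {
                "species": [f"sp{i}" for i in range(len(values))],
                "gene_set": "all",
                "variant_type": vt,
                "region": "full_cds",
                "mean_p": values,
            }
        )

    def test_min_max_mean_in_percent(self):
        rows = summary_table(self._means([0.01, 0.02, 0.03]))
        row = [r for r in rows if r.variant_type == "all_lof"][0]
        assert (row.min, row.max, row.mean) == (1.00, 3.00, 2.00)

    def test_single_species_degenerate(self):
        rows = summary_table(self._means([0.0221]))
        row = rows[0]
        assert row.min == row.max == row.mean == 2.21


def test_percent_formatting_round_trips():
    for p in (0.0, 0.0034, 0.0221, 0.0533, 1.0):
        assert abs(parse_percent(format_percent(p)) - p) < 5e-5
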