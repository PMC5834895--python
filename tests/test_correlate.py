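"""Spearman tests, BH correction and the correlation grid."""

import itertools

import numpy as np
import pytest

from lofprev.correlate import (
    SpeciesRecord,
    bh_adjust,
    correlation_matrix,
    fecundity_correlations,
    grand_means_from_species_table,
    read_trait_table,
    spearman,
    write_trait_table,
)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = [1, 2, 3, 5, 8, 13]
        rho, p, n, _ = spearman(x, [v**2 for v in x])
        assert rho == 1.0 and p == 0.0 and n == 6

    def test_reversed_ranks_give_minus_one(self):
        x = [1, 2, 3, 4, 5]
        rho, p, _, _ = spearman(x, x[::-1])
        assert rho == -1.0 and p == 0.0

    def test_rank_difference_formula(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        rho, p, n, _ = spearman(x, y)
        d2 = sum((xr - yr) ** 2 for xr, yr in zip(x, y))  # ranks equal values here
        assert rho == pytest.approx(1 - 6 * d2 / (n * (n**2 - 1)))
        assert rho == pytest.approx(0.8)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho0, p0, _, _ = spearman(x, y)
        rho1, p1, _, _ = spearman(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho0)
        assert p1 == pytest.approx(p0)

    def test_too_few_pairs_missing_with_reason(self):
        rho, p, n, reason = spearman([1, 2], [3, 4])
        assert rho is None and "3" in reason

    def test_zero_variance_missing(self):
        rho, p, _, reason = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert rho is None and reason == "zero variance"

    def test_pairwise_deletion_of_missing(self):
        x = [1, None, 3, 4, 5, None]
        y = [2, 9, 6, 8, 10, None]
        rho, _, n, _ = spearman(x, y)
        rho2, _, _, _ = spearman([1, 3, 4, 5], [2, 6, 8, 10])
        assert n == 4 and rho == pytest.approx(rho2)

    def test_exact_permutation_p_perfect_monotone(self):
        # among 4! pairings only identity and full reversal reach |rho| = 1
        rho, p, _, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40], exact=True)
        assert rho == 1.0 and p == 0.0  # |rho| = 1 short-circuits to p = 0

    def test_exact_permutation_p_small_n(self):
        rho, p, _, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], exact=True)
        # enumerate independently
        xr = np.array([1, 2, 3, 4, 5], dtype=float)
        yr = np.array([2, 1, 4, 3, 5], dtype=float)
        obs = 1 - 6 * ((xr - yr) ** 2).sum() / (5 * 24)
        count = 0
        for perm in itertools.permutations(yr):
            r = 1 - 6 * ((xr - np.array(perm)) ** 2).sum() / (5 * 24)
            if abs(r) >= abs(obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 120)


class TestBH:
    def test_two_value_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.037]) == pytest.approx([0.037])

    def test_equal_entries_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_missing_passthrough(self):
        out = bh_adjust([0.01, None, 0.04])
        assert out[1] is None
        assert out[0] == pytest.approx(0.02) and out[2] == pytest.approx(0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def _oracle(self, ps):
        m = len(ps)
        order = np.argsort(ps)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, m * ps[i] / (rank + 1))
            adj[i] = running
        return adj

    def test_matches_manual_step_up_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            ps = rng.uniform(0, 1, rng.integers(2, 20)).tolist()
            assert bh_adjust(ps) == pytest.approx(self._oracle(ps))

    def test_adjusted_values_monotone_in_sorted_order(self):
        rng = np.random.default_rng(18)
        for _ in range(20):
            ps = rng.uniform(0, 1, 12)
            adj = np.asarray(bh_adjust(ps.tolist()))
            order = np.argsort(ps)
            assert np.all(np.diff(adj[order]) >= -1e-12)
            assert np.all(adj >= ps) and np.all(adj <= 1.0)


def _records(n=6, seed=2):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        f = float(10 ** rng.uniform(1, 6))
        recs.append(
            SpeciesRecord(
                species_id=f"sp{i}",
                phylum="Chordata",
                adult_size=float(rng.uniform(1, 100)),
                body_mass=float(rng.uniform(1, 1000)),
                longevity=float(rng.uniform(1, 50)),
                lifetime_fecundity=f,
                propagule_size=float(rng.uniform(0.01, 10)),
                genome_size=None if i == 0 else float(rng.uniform(300, 3000)),
                pi_s=float(rng.uniform(0.001, 0.05)),
                mean_p={("all", "all_lof", "full_cds"): float(rng.uniform(0.001, 0.05))},
            )
        )
    return recs


class TestCorrelationMatrix:
    def test_cells_equal_independent_pairwise_calls(self):
        recs = _records(6)
        measures = [("all", "all_lof", "full_cds")]
        traits = ["lifetime_fecundity", "longevity", "pi_s"]
        grid = correlation_matrix(recs, measures, traits)
        frame_cols = {
            "p_all": [r.mean_p[measures[0]] for r in recs],
            "lifetime_fecundity": [r.lifetime_fecundity for r in recs],
            "longevity": [r.longevity for r in recs],
            "pi_s": [r.pi_s for r in recs],
        }
        assert len(grid) == 6  # C(4, 2) pairs
        for _, row in grid.iterrows():
            rho, p, n, _ = spearman(frame_cols[row.x], frame_cols[row.y])
            assert row.rho == pytest.approx(rho)
            assert row.p_raw == pytest.approx(p)
        assert bh_adjust(list(grid.p_raw)) == pytest.approx(list(grid.p_bh))

    def test_requires_three_species(self):
        with pytest.raises(ValueError):
            correlation_matrix(_records(2), [("all", "all_lof", "full_cds")], ["pi_s"])

    def test_significance_framed_at_bh_alpha(self):
        recs = _records(10, seed=9)
        # make one measure a perfect monotone function of fecundity
        for r in recs:
            r.mean_p[("all", "all_lof", "full_cds")] = 1e-3 * r.lifetime_fecundity ** 0.5
        grid = correlation_matrix(
            recs, [("all", "all_lof", "full_cds")], ["lifetime_fecundity"]
        )
        row = grid.iloc[0]
        assert row.rho == 1.0 and bool(row.significant)


def test_trait_table_round_trip(tmp_path):
    recs = _records(5)
    path = tmp_path / "traits.tsv"
    write_trait_table(recs, path)
    back = read_trait_table(path)
    assert [r.species_id for r in back] == [r.species_id for r in recs]
    assert back[0].genome_size is None
    assert back[2].lifetime_fecundity == pytest.approx(recs[2].lifetime_fecundity)
    assert back[1].haplodiploid is False


def test_grand_means_and_fecundity_tests_from_species_table():
    import pandas as pd

    recs = _records(8, seed=31)
    rows = []
    for gs, base in (("all", 0.02), ("hardcore", 0.002)):
        for r in recs:
            rows.append(
                {
                    "species": r.species_id,
                    "gene_set": gs,
                    "variant_type": "all_lof",
                    "region": "full_cds",
                    "mean_p": base * (1 + 0.1 * recs.index(r)),
                }
            )
    tbl = pd.DataFrame(rows)
    gm = grand_means_from_species_table(tbl)
    assert gm["all"] == pytest.approx(np.mean([0.02 * (1 + 0.1 * i) for i in range(8)]))
    fec = fecundity_correlations(tbl, recs)
    x = [r.lifetime_fecundity for r in recs]
    y = [0.002 * (1 + 0.1 * i) for i in range(8)]
    rho, p, _, _ = spearman(x, y)
    assert fec["hardcore"].rho == pytest.approx(rho)
    assert fec["hardcore"].p_raw == pytest.approx(p)
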