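"""Stringency filtering, protein roll-up, and the filter-sweep diagnostic."""

import numpy as np
import pytest

from turnoverkit.filtering import (
    ProteinTurnover,
    StringencyFilter,
    apply_filter,
    filter_sweep,
    intra_protein_variability,
    protein_rollup,
)
from turnoverkit.kinetics import KineticFit


def make_fit(dp=7, r2=0.95, se=0.01, k=0.1, protein="P1", pid="pep"):
    return KineticFit(
        k=k, dk=0.0, ss=se**2 * max(dp - 1, 1), r2=r2, se=se, dp=dp,
        converged=True, peptide_id=pid, protein=protein,
    )


TOY_FITS = [
    make_fit(dp=3, r2=0.99, se=0.01, pid="p1"),   # too few time points
    make_fit(dp=4, r2=0.85, se=0.2, pid="p2"),    # R2 branch
    make_fit(dp=4, r2=0.5, se=0.04, pid="p3"),    # se branch
    make_fit(dp=4, r2=0.5, se=0.2, pid="p4"),     # fails both
    make_fit(dp=7, r2=0.8, se=0.05, pid="p5"),    # boundary: both inclusive
    make_fit(dp=5, r2=0.79, se=0.051, pid="p6"),  # just misses both
]


class TestApplyFilter:
    def test_r2_branch(self):
        accepted, _ = apply_filter([make_fit(dp=7, r2=0.95, se=0.2)])
        assert len(accepted) == 1

    def test_se_branch_rescues_slow_turnover(self):
        accepted, _ = apply_filter([make_fit(dp=7, r2=0.3, se=0.03)])
        assert len(accepted) == 1

    def test_toy_table_three_accepted(self):
        accepted, rejected = apply_filter(TOY_FITS)
        assert [f.peptide_id for f in accepted] == ["p2", "p3", "p5"]
        assert len(rejected) == 3
        reasons = dict((f.peptide_id, why) for f, why in rejected)
        assert "DP" in reasons["p1"]
        assert "R2" in reasons["p4"] and "se" in reasons["p4"]

    def test_pure_predicate_under_permutation(self):
        rng = np.random.default_rng(0)
        order = rng.permutation(len(TOY_FITS))
        shuffled = [TOY_FITS[i] for i in order]
        accepted, _ = apply_filter(shuffled)
        assert {f.peptide_id for f in accepted} == {"p2", "p3", "p5"}

    def test_invalid_filter_params_rejected(self):
        with pytest.raises(ValueError):
            StringencyFilter(min_dp=1)
        with pytest.raises(ValueError):
            StringencyFilter(se_max=0.0)
        # r2_min above 1 is legal: it just disables the R2 branch
        assert StringencyFilter(r2_min=1.01).r2_min == 1.01


class TestRollup:
    def test_median_and_mad(self):
        fits = [make_fit(k=k, pid=f"p{k}") for k in (1.0, 2.0, 3.0)]
        (roll,) = protein_rollup(fits)
        assert roll.median_k == 2.0
        assert roll.mad_k == 1.0
        assert roll.n_peptides == 3

    def test_single_peptide(self):
        (roll,) = protein_rollup([make_fit(k=0.5)])
        assert roll.median_k == 0.5
        assert roll.mad_k == 0.0

    def test_matches_sort_based_oracle_random_instances(self):
        """Median/MAD agree with an independent sort-based implementation."""

        def median_sorted(values):
            s = sorted(values)
            n = len(s)
            return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2

        rng = np.random.default_rng(21)
        for _ in range(1000):
            ks = rng.lognormal(-2.4, 0.8, size=int(rng.integers(1, 15)))
            fits = [make_fit(k=float(k), pid=str(i)) for i, k in enumerate(ks)]
            (roll,) = protein_rollup(fits)
            med = median_sorted(ks)
            mad = median_sorted([abs(k - med) for k in ks])
            assert roll.median_k == pytest.approx(med, rel=1e-12)
            assert roll.mad_k == pytest.approx(mad, rel=1e-12)

    def test_groups_by_protein(self):
        fits = [make_fit(k=0.1, protein="A", pid="1"),
                make_fit(k=0.3, protein="A", pid="2"),
                make_fit(k=0.5, protein="B", pid="3")]
        rolls = {r.protein: r for r in protein_rollup(fits)}
        assert rolls["A"].n_peptides == 2
        assert rolls["B"].median_k == 0.5


class TestVariability:
    def test_identical_rates_zero(self):
        rolls = [ProteinTurnover("A", 0.1, 0.0, 3), ProteinTurnover("B", 0.2, 0.0, 5)]
        assert intra_protein_variability(rolls) == 0.0

    def test_mad_of_near_tie(self):
        (roll,) = protein_rollup(
            [make_fit(k=k, pid=str(i)) for i, k in enumerate((1.0, 1.0, 2.0))]
        )
        assert roll.mad_k == 0.0  # MAD of {0,0,1} is 0
        assert intra_protein_variability([roll]) == 0.0

    def test_singletons_excluded(self):
        rolls = [ProteinTurnover("A", 0.1, 0.05, 1)]
        with pytest.raises(ValueError, match=">= 2"):
            intra_protein_variability(rolls)

    def test_matches_two_loop_reference(self):
        """Statistic equals a direct per-protein double-loop recomputation."""
        rng = np.random.default_rng(13)
        fits = []
        for ip in range(12):
            k_true = rng.lognormal(-2.4, 0.8)
            for j in range(int(rng.integers(2, 8))):
                fits.append(
                    make_fit(k=float(k_true * rng.lognormal(0, 0.05)),
                             protein=f"P{ip}", pid=f"{ip}-{j}")
                )
        rolls = protein_rollup(fits)
        stat = intra_protein_variability(rolls)

        by_protein: dict[str, list[float]] = {}
        for f in fits:
            by_protein.setdefault(f.protein, []).append(f.k)
        ratios = []
        for ks in by_protein.values():
            if len(ks) < 2:
                continue
            med = float(np.median(ks))
            mad = float(np.median([abs(k - med) for k in ks]))
            ratios.append(mad / med)
        assert stat == pytest.approx(float(np.median(ratios)) * 100, rel=1e-12)


@pytest.fixture(scope="module")
def noisy_fits():
    rng = np.random.default_rng(8)
    fits = []
    for ip in range(15):
        k_true = rng.lognormal(-2.4, 0.8)
        for j in range(5):
            # heteroscedastic quality: some peptides fit much worse
            quality = rng.uniform(0, 1)
            fits.append(
                make_fit(
                    k=float(k_true * rng.lognormal(0, 0.03 + 0.5 * quality)),
                    r2=float(1 - quality),
                    se=float(0.01 + 0.3 * quality * rng.uniform(0, 1)),
                    dp=int(rng.choice([4, 5, 6, 7])),
                    protein=f"P{ip}",
                    pid=f"{ip}-{j}",
                )
            )
    return fits


class TestFilterSweep:
    def test_single_point_consistent_with_direct_application(self, noisy_fits):
        sweep = filter_sweep(noisy_fits, [0.8], [0.05])
        accepted, _ = apply_filter(noisy_fits, StringencyFilter())
        row = sweep.iloc[0]
        assert row["n_accepted"] == len(accepted)
        expected = intra_protein_variability(protein_rollup(accepted))
        assert row["variability_pct"] == pytest.approx(expected)

    def test_count_monotone_along_both_axes(self, noisy_fits):
        r2_grid = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        se_grid = [0.01, 0.05, 0.1, 0.2]
        sweep = filter_sweep(noisy_fits, r2_grid, se_grid)
        pivot = sweep.pivot(index="r2_min", columns="se_max", values="n_accepted")
        # non-increasing in r2_min at fixed se_max
        assert (pivot.diff(axis=0).dropna() <= 0).all().all()
        # non-decreasing in se_max at fixed r2_min
        assert (pivot.diff(axis=1).T.dropna() >= 0).all().all()

    def test_relaxing_r2_does_not_reduce_variability(self, noisy_fits):
        sweep = filter_sweep(noisy_fits, [0.8, 0.0], [0.01])
        strict = sweep[sweep.r2_min == 0.8]["variability_pct"].iloc[0]
        relaxed = sweep[sweep.r2_min == 0.0]["variability_pct"].iloc[0]
        assert relaxed >= strict

    def test_empty_acceptance_reported_missing(self, noisy_fits):
        sweep = filter_sweep(noisy_fits, [1.01], [1e-9])
        row = sweep.iloc[0]
        assert row["n_accepted"] == 0
        assert np.isnan(row["variability_pct"])

    def test_empty_grid_rejected(self, noisy_fits):
        with pytest.raises(ValueError):
            filter_sweep(noisy_fits, [], [0.05])
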