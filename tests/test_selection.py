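"""Selection scans: EHH combinatorics, iHH integration vs brute force,
standardization, gene-level candidate calling and cross-population overlap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from isopop.selection import (
    ehh_curve,
    gene_selection_candidates,
    ihs_scan,
    selection_overlap,
    standardize_ihs,
)
from conftest import make_panel
from oracles import ehh_oracle, ihh_oracle


class TestEhhCurve:
    def test_identical_carriers_stay_at_one(self):
        haps = np.tile([1, 0, 1, 1, 0, 1], (4, 1)).astype(np.int8)
        left, right = ehh_curve(haps, np.arange(1, 7) * 100, core_index=2, core_allele=1)
        assert (left.ehh == 1.0).all() and (right.ehh == 1.0).all()

    def test_two_identical_pairs(self):
        """4 carriers splitting into two identical pairs: EHH = 2/C(4,2) = 1/3."""
        haps = np.array(
            [[1, 0, 0], [1, 0, 0], [1, 1, 1], [1, 1, 1]], dtype=np.int8
        )
        _, right = ehh_curve(haps, np.array([10, 20, 30]), core_index=0, core_allele=1)
        assert right.ehh.iloc[1] == pytest.approx(1 / 3)
        assert right.ehh.iloc[2] == pytest.approx(1 / 3)

    def test_fewer_than_two_carriers_rejected(self):
        haps = np.array([[1, 0], [0, 0], [0, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="carriers"):
            ehh_curve(haps, np.array([1, 2]), core_index=0, core_allele=1)

    @given(
        arrays(np.int8, (10, 12), elements=st.integers(0, 1)),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_non_increasing(self, haps):
        if haps[:, 5].sum() < 2:
            haps[:3, 5] = 1
        left, right = ehh_curve(haps, np.arange(1, 13) * 50, core_index=5, core_allele=1)
        for df in (left, right):
            assert (np.diff(df.ehh.to_numpy()) <= 1e-12).all()

    def test_matches_enumeration_oracle(self, toy_panel):
        left, right = ehh_curve(
            toy_panel.haplotypes, toy_panel.positions, core_index=3, core_allele=1
        )
        for df, direction in ((right, 1), (left, -1)):
            for _, row in df.iloc[1:].iterrows():
                expected = ehh_oracle(
                    toy_panel.haplotypes.tolist(), 3, 1, int(row.site_index)
                )
                assert row.ehh == pytest.approx(expected, abs=1e-12)


class TestIhsScan:
    def test_ihh_matches_bruteforce_oracle(self):
        """Random 12-haplotype panel: every valid site's iHH pair equals the
        brute-force EHH-integration oracle to 1e-9."""
        rng = np.random.default_rng(9)
        haps = rng.integers(0, 2, size=(12, 30)).astype(np.int8)
        positions = np.sort(rng.choice(100_000, 30, replace=False) + 1)
        panel = make_panel(haps, positions)
        results = ihs_scan(panel, maf_min=0.05, ehh_cutoff=0.05,
                           max_extend_bp=10**9, max_gap_bp=10**9)
        checked = 0
        for r in results:
            if not r.valid:
                continue
            ihh_a = ihh_oracle(haps.tolist(), positions.tolist(), r.site_index, 0)
            ihh_d = ihh_oracle(haps.tolist(), positions.tolist(), r.site_index, 1)
            assert r.ihh_ancestral == pytest.approx(ihh_a, abs=1e-9)
            assert r.ihh_derived == pytest.approx(ihh_d, abs=1e-9)
            checked += 1
        assert checked >= 5

    def test_mirror_symmetry_gives_zero(self):
        """Derived and ancestral carriers with mirror-image haplotype
        structure: iHS_unstd = 0."""
        block = np.array(
            [[0, 0, 0, 0], [0, 1, 1, 0], [1, 0, 0, 1], [1, 1, 1, 1]],
            dtype=np.int8,
        )
        hap = np.vstack([
            np.column_stack([block[:, :2], np.ones(4, np.int8), block[:, 2:]]),
            np.column_stack([block[:, :2], np.zeros(4, np.int8), block[:, 2:]]),
        ])
        panel = make_panel(hap)
        res = ihs_scan(panel, maf_min=0.05, max_extend_bp=10**9, max_gap_bp=10**9)
        focal = [r for r in res if r.site_index == 2][0]
        assert focal.valid
        assert focal.ihs_unstd == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_under_label_swap(self, toy_panel):
        a = ihs_scan(toy_panel, ancestral_is_ref=True,
                     max_extend_bp=10**9, max_gap_bp=10**9)
        b = ihs_scan(toy_panel, ancestral_is_ref=False,
                     max_extend_bp=10**9, max_gap_bp=10**9)
        for ra, rb in zip(a, b):
            if ra.valid and rb.valid:
                assert ra.ihs_unstd == pytest.approx(-rb.ihs_unstd, abs=1e-12)

    def test_low_maf_flagged(self, toy_panel):
        res = ihs_scan(toy_panel, maf_min=0.4)
        flagged = [r for r in res if r.reason == "low_maf"]
        assert all(min(r.derived_freq, 1 - r.derived_freq) <= 0.4 for r in flagged)


class TestStandardize:
    def _random_results(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        from isopop.core import VariantKey
        from isopop.selection import IhsResult

        out = []
        for i in range(n):
            f = rng.uniform(0.05, 0.95)
            out.append(IhsResult(
                key=VariantKey("1", i + 1, "A", "G"), derived_freq=f,
                ihh_ancestral=1.0, ihh_derived=1.0,
                ihs_unstd=rng.normal(f, 1.0),  # frequency-dependent mean
                valid=True, site_index=i, pos=i + 1,
            ))
        return out

    def test_bins_have_zero_mean_unit_sd(self):
        results = standardize_ihs(self._random_results(), n_freq_bins=10)
        edges = np.linspace(0, 1, 11)
        for b in range(10):
            vals = [r.ihs_std for r in results
                    if edges[b] < r.derived_freq <= edges[b + 1]
                    and np.isfinite(r.ihs_std)]
            if len(vals) >= 2:
                assert np.mean(vals) == pytest.approx(0.0, abs=1e-9)
                assert np.std(vals) == pytest.approx(1.0, abs=1e-9)

    def test_order_invariance(self):
        a = standardize_ihs(self._random_results(seed=1))
        b = standardize_ihs(self._random_results(seed=1)[::-1])
        mapped = {r.key: r.ihs_std for r in b}
        for r in a:
            assert r.ihs_std == pytest.approx(mapped[r.key], abs=1e-12)

    def test_overall_mean_zero_after_merging_shifted_bins(self):
        results = standardize_ihs(self._random_results(seed=2), n_freq_bins=2)
        vals = [r.ihs_std for r in results if np.isfinite(r.ihs_std)]
        assert np.mean(vals) == pytest.approx(0.0, abs=1e-9)

    def test_tiny_bins_flagged(self):
        results = self._random_results(n=1)
        out = standardize_ihs(results, n_freq_bins=50)
        assert not np.isfinite(out[0].ihs_std)
        assert out[0].reason == "unstandardizable_bin"


class TestGeneCalls:
    def _results_at(self, positions, score):
        from isopop.core import VariantKey
        from isopop.selection import IhsResult

        return [
            IhsResult(key=VariantKey("1", p, "A", "G"), derived_freq=0.5,
                      ihs_unstd=score, ihs_std=score, valid=True,
                      site_index=i, pos=p)
            for i, p in enumerate(positions)
        ]

    def test_threshold_counting(self):
        genes = [("G1", "1", 1, 10_000)]
        yes = gene_selection_candidates(
            self._results_at(range(100, 2600, 100), 2.5), genes, "P")
        assert yes[0].candidate and yes[0].n_markers_over_threshold == 25
        no = gene_selection_candidates(
            self._results_at(range(100, 2000, 100), 2.5), genes, "P")
        assert not no[0].candidate and no[0].n_markers_over_threshold == 19

    def test_stricter_threshold_nested(self):
        rng = np.random.default_rng(0)
        from isopop.core import VariantKey
        from isopop.selection import IhsResult

        results = [
            IhsResult(key=VariantKey("1", i + 1, "A", "G"), derived_freq=0.5,
                      ihs_unstd=0.0, ihs_std=float(rng.normal(0, 2)), valid=True,
                      site_index=i, pos=(i + 1) * 10)
            for i in range(2000)
        ]
        genes = [(f"G{k}", "1", k * 2000 + 1, (k + 1) * 2000) for k in range(10)]
        loose = {c.gene for c in gene_selection_candidates(results, genes, "P", 2.0, 5)
                 if c.candidate}
        strict = {c.gene for c in gene_selection_candidates(results, genes, "P", 2.5, 5)
                  if c.candidate}
        assert strict <= loose


class TestOverlap:
    def test_identical_sets(self):
        out = selection_overlap({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
        assert (out.private_fraction == 0).all()
        assert (out.n_all_population_shared == 2).all()

    def test_disjoint_sets(self):
        out = selection_overlap({"A": {"g1"}, "B": {"g2"}})
        assert (out.private_fraction == 1).all()
        assert (out.n_all_population_shared == 0).all()

    def test_three_set_toy(self):
        out = selection_overlap(
            {"P1": {"A", "B", "C"}, "P2": {"B", "C"}, "P3": {"C"}}
        ).set_index("population")
        assert out.loc["P1", "private_fraction"] == pytest.approx(1 / 3)
        assert out.loc["P1", "n_all_population_shared"] == 1
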