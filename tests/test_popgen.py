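import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrmarkers.genotypes import MISSING, Accession, GenotypeMatrix, PeakTable
from ssrmarkers.popgen import (
    TransferabilityMatrix,
    UndefinedLocusError,
    allele_frequencies,
    allele_mismatch,
    column_summary,
    error_rates,
    expected_heterozygosity,
    group_report,
    identity_analysis,
    locus_summary,
    marker_qc,
    p_identity,
    pic_from_freqs,
    transferability_summary,
)
from ssrmarkers.simulate import SimulationConfig, simulate_genotypes, simulate_panel

from oracles import pic_double_loop, pid_enumeration, tally_frequencies


def single_locus_matrix(calls, locus="L"):
    accs = [Accession(f"a{i}") for i in range(len(calls))]
    return GenotypeMatrix(
        accs, [locus], {(f"a{i}", locus): c for i, c in enumerate(calls)}
    )


class TestAlleleFrequencies:
    def test_direct_count(self):
        m = single_locus_matrix([("A", "A"), ("A", "B")])
        table = allele_frequencies(m, "L")
        assert table.freqs == {"A": 0.75, "B": 0.25}
        assert table.n_typed == 2

    def test_monomorphic(self):
        m = single_locus_matrix([("A", "A")] * 5)
        table = allele_frequencies(m, "L")
        assert table.freqs == {"A": 1.0}
        assert table.k == 1

    def test_missing_excluded_from_denominator(self):
        m = single_locus_matrix([("A", "A"), MISSING, ("A", "B"), MISSING])
        table = allele_frequencies(m, "L")
        assert table.n_typed == 2
        assert table.freqs["A"] == 0.75

    def test_all_missing_raises(self):
        m = single_locus_matrix([MISSING, MISSING])
        with pytest.raises(UndefinedLocusError):
            allele_frequencies(m, "L")

    def test_random_calls_match_tally_oracle(self, rng):
        alleles = [str(a) for a in range(6)]
        calls = [
            (alleles[rng.integers(6)], alleles[rng.integers(6)]) for _ in range(1000)
        ]
        m = single_locus_matrix(calls)
        table = allele_frequencies(m, "L")
        expected, n = tally_frequencies(m, "L", m.accession_ids)
        assert table.freqs == expected
        assert table.n_typed == n


class TestLocusSummary:
    def test_biallelic_closed_form(self):
        m = single_locus_matrix([("A", "A"), ("A", "B"), ("B", "B"), ("A", "B")])
        s = locus_summary(m, "L")
        assert s.He == pytest.approx(0.5)
        assert s.PIC == pytest.approx(0.375)
        assert s.Ho == pytest.approx(0.5)

    def test_monomorphic_zeroes(self):
        m = single_locus_matrix([("A", "A")] * 4)
        s = locus_summary(m, "L")
        assert (s.k, s.PIC, s.He, s.Ho) == (1, 0.0, 0.0, 0.0)

    def test_three_allele_pic(self):
        assert pic_from_freqs([0.5, 0.25, 0.25]) == pytest.approx(0.5546875)

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=8)
    )
    @settings(max_examples=120, deadline=None)
    def test_pic_bounded_by_he(self, weights):
        p = np.array(weights) / sum(weights)
        pic = pic_from_freqs(p)
        he = expected_heterozygosity(p)
        assert pic <= he + 1e-12
        assert pic == pytest.approx(pic_double_loop(p), abs=1e-12)
        if len(p) == 1:
            assert pic == pytest.approx(0.0) and he == pytest.approx(0.0)


class TestGroupReport:
    def test_rows_and_summary(self, small_matrix):
        groups = {
            "all": small_matrix.accession_ids,
            "culinary": small_matrix.group_members("culinary"),
        }
        report = group_report(small_matrix, groups)
        assert len(report) == 2 * (3 + 2)  # loci + mean/median rows per group
        all_k = report[(report.group == "all") & ~report.locus.isin(["mean", "median"])]["k"]
        mean_row = report[(report.group == "all") & (report.locus == "mean")].iloc[0]
        assert mean_row["k"] == pytest.approx(all_k.mean())

    def test_empty_group_raises(self, small_matrix):
        with pytest.raises(ValueError, match="ghost"):
            group_report(small_matrix, {"ghost": []})

    def test_column_summary_median_is_order_statistic(self):
        stats = column_summary([3, 9, 5])
        assert stats["median"] == 5
        assert stats["sum"] == 17
        assert (stats["min"], stats["max"]) == (3, 9)


@pytest.mark.parametrize(
    "c1, c2, expected",
    [
        (("A", "A"), ("A", "A"), 0),
        (("A", "B"), ("A", "B"), 0),
        (("A", "A"), ("A", "B"), 1),
        (("A", "B"), ("A", "C"), 1),
        (("A", "A"), ("B", "B"), 2),
        (("A", "B"), ("C", "D"), 2),
    ],
)
def test_allele_mismatch(c1, c2, expected):
    assert allele_mismatch(c1, c2) == expected
    assert allele_mismatch(c2, c1) == expected


class TestIdentityAnalysis:
    def test_identical_profiles_match_at_zero(self):
        config = SimulationConfig(n_isoline_pairs=1)
        panel = simulate_panel(config, seed=5)
        m = simulate_genotypes(panel, config, 10, seed=6)
        report = identity_analysis(m, min_shared_loci=10)
        iso = ("ACC0001", "ACC0001_iso")
        assert iso in report.matching_pairs[0]

    def test_single_allele_difference_matches_first_at_one(self):
        loci = [f"L{i}" for i in range(17)]
        calls = {}
        for locus in loci:
            calls[("x", locus)] = ("100", "100")
            calls[("y", locus)] = ("100", "100")
        calls[("y", "L0")] = ("100", "103")  # het vs homo: one mismatch
        m = GenotypeMatrix([Accession("x"), Accession("y")], loci, calls)
        report = identity_analysis(m)
        assert report.matching_pairs[0] == []
        assert report.matching_pairs[1] == [("x", "y")]
        assert report.n_unique_profiles == 2

    def test_low_overlap_pairs_are_incomparable(self):
        loci = [f"L{i}" for i in range(4)]
        calls = {("x", l): ("1", "1") for l in loci}
        calls.update({("y", l): MISSING for l in loci})
        calls[("y", "L0")] = ("1", "1")
        m = GenotypeMatrix([Accession("x"), Accession("y")], loci, calls)
        report = identity_analysis(m, min_shared_loci=2)
        assert report.incomparable_pairs == [("x", "y")]
        assert all(not pairs for pairs in report.matching_pairs.values())


class TestPIdentity:
    def test_one_locus_closed_form(self):
        m = single_locus_matrix([("A", "B"), ("A", "B")])
        pid = p_identity([allele_frequencies(m, "L")])
        assert pid.overall == pytest.approx(0.375)

    def test_product_over_independent_loci(self):
        m = single_locus_matrix([("A", "B"), ("A", "B")])
        t = allele_frequencies(m, "L")
        t2 = type(t)(locus="L2", freqs=dict(t.freqs), n_typed=t.n_typed)
        pid = p_identity([t, t2])
        assert pid.overall == pytest.approx(0.375**2)
        assert pid.overall == pytest.approx(0.140625)

    def test_adding_polymorphic_loci_strictly_decreases_pid(self, rng):
        tables = []
        last = 1.0
        for i in range(8):
            k = int(rng.integers(2, 7))
            p = rng.dirichlet(np.ones(k))
            from ssrmarkers.popgen import AlleleFrequencyTable

            tables.append(
                AlleleFrequencyTable(
                    locus=f"L{i}",
                    freqs={str(j): float(x) for j, x in enumerate(p)},
                    n_typed=50,
                )
            )
            pid = p_identity(tables)
            assert pid.overall < last
            last = pid.overall

    def test_sib_variant_exceeds_naive(self, rng):
        from ssrmarkers.popgen import AlleleFrequencyTable

        p = rng.dirichlet(np.ones(5))
        table = AlleleFrequencyTable(
            locus="L", freqs={str(j): float(x) for j, x in enumerate(p)}, n_typed=30
        )
        pid = p_identity([table])
        assert pid.overall_sib > pid.overall


class TestErrorRates:
    def make_pair(self, n, diff_alleles=0, fail=0):
        """n accessions, one locus; diff_alleles in {0,1,2} applied to a0;
        fail>0 drops the replicate call of the last `fail` accessions."""
        accs = [Accession(f"a{i}") for i in range(n)]
        ref_calls = {(f"a{i}", "L"): ("100", "100") for i in range(n)}
        rep_calls = dict(ref_calls)
        if diff_alleles == 1:
            rep_calls[("a0", "L")] = ("100", "103")
        elif diff_alleles == 2:
            rep_calls[("a0", "L")] = ("103", "103")
        for i in range(n - fail, n):
            rep_calls[(f"a{i}", "L")] = MISSING
        ref = GenotypeMatrix(accs, ["L"], ref_calls)
        rep = GenotypeMatrix(accs, ["L"], rep_calls)
        return ref, rep

    def test_identical_matrices_zero(self):
        ref, rep = self.make_pair(10)
        report = error_rates(ref, rep)
        assert report.mean_e_a == 0.0 and report.mean_e_l == 0.0

    def test_single_allele_difference(self):
        ref, rep = self.make_pair(10, diff_alleles=1)
        report = error_rates(ref, rep)
        row = report.per_locus.iloc[0]
        assert row["e_a"] == pytest.approx(1 / 20)
        assert row["e_l"] == pytest.approx(1 / 10)

    def test_failure_counts_as_full_locus_error(self):
        ref, rep = self.make_pair(10, fail=1)
        row = error_rates(ref, rep).per_locus.iloc[0]
        assert row["m_a"] == 2 and row["m_l"] == 1
        assert row["e_a"] == pytest.approx(row["e_l"])

    def test_error_bounds_invariant(self, rng):
        config = SimulationConfig(substitution_rate=0.05, failure_rate=0.05)
        panel = simulate_panel(config, seed=11)
        ref = simulate_genotypes(panel, config, 40, seed=12)
        from ssrmarkers.simulate import inject_errors

        rep = inject_errors(ref, config, seed=13, panel=panel)
        report = error_rates(ref, rep)
        usable = report.per_locus[report.per_locus["n"] > 0]
        assert ((usable["e_l"] / 2 - 1e-12 <= usable["e_a"]).all())
        assert ((usable["e_a"] <= usable["e_l"] + 1e-12).all())

    def test_disjoint_accessions_raise(self):
        ref, _ = self.make_pair(3)
        other = GenotypeMatrix(
            [Accession("zz")], ["L"], {("zz", "L"): ("100", "100")}
        )
        with pytest.raises(ValueError):
            error_rates(ref, other)


class TestTransferability:
    def test_consensus_is_and_over_labs(self):
        data = pd.DataFrame(
            [
                {"marker": "M1", "species": "P. rhoeas", "lab": "A", "amplified": True},
                {"marker": "M1", "species": "P. rhoeas", "lab": "B", "amplified": False},
                {"marker": "M2", "species": "P. rhoeas", "lab": "A", "amplified": True},
                {"marker": "M2", "species": "P. rhoeas", "lab": "B", "amplified": True},
            ]
        )
        consensus = TransferabilityMatrix(data=data).consensus()
        assert not consensus.loc["M1", "P. rhoeas"]
        assert consensus.loc["M2", "P. rhoeas"]

    def test_summary_percentages(self):
        rows = []
        presence = {"M1": ["s1", "s2"], "M2": ["s1"], "M3": []}
        for marker, species_list in presence.items():
            for sp in ("s1", "s2"):
                for lab in ("A", "B"):
                    rows.append(
                        {
                            "marker": marker,
                            "species": f"Genus {sp}",
                            "lab": lab,
                            "amplified": sp in species_list,
                        }
                    )
        tm = TransferabilityMatrix(data=pd.DataFrame(rows))
        summary = transferability_summary(tm, ["Genus s1", "Genus s2"])
        assert summary["pct_all_focal"] == pytest.approx(33.33)
        assert summary["pct_at_least_one_focal"] == pytest.approx(66.67)


class TestMarkerQC:
    def build(self, het_calls, k=5, n=20):
        """Matrix with one locus: k alleles, het_calls heterozygous accessions."""
        accs = [Accession(f"a{i}") for i in range(n)]
        calls = {}
        for i in range(n):
            if i < het_calls:
                calls[(f"a{i}", "L")] = ("100", "103")
            else:
                calls[(f"a{i}", "L")] = (str(100 + 3 * (i % k)), str(100 + 3 * (i % k)))
        return GenotypeMatrix(accs, ["L"], calls)

    def test_low_polymorphism(self):
        m = single_locus_matrix([("A", "A"), ("A", "B"), ("B", "B")])
        qc = marker_qc(m, min_alleles=3)
        assert qc.iloc[0]["reasons"] == "LOW_POLYMORPHISM"

    def test_implausible_heterozygosity(self):
        m = self.build(het_calls=19, n=20)
        qc = marker_qc(m)
        assert "IMPLAUSIBLE_HET" in qc.iloc[0]["reasons"]

    def test_multipeak_from_peak_table(self):
        m = self.build(het_calls=0)
        peaks = PeakTable(
            rows=pd.DataFrame(
                [{"accession": "a0", "locus": "L", "lab": "A", "sizes": [1.0, 2.0, 3.0]}]
            )
        )
        qc = marker_qc(m, peak_table=peaks)
        assert "MULTIPEAK" in qc.iloc[0]["reasons"]

    def test_clean_marker_passes(self):
        m = self.build(het_calls=1)
        qc = marker_qc(m)
        assert qc.iloc[0]["passed"]
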