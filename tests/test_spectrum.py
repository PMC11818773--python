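"""Allele-spectrum statistics tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

import lamaspectrum as ls
from lamaspectrum.hgvs import Consequence
from lamaspectrum.spectrum import (
    SpectrumConsistencyWarning,
    SpectrumError,
    round_half_up,
    spectrum_from_cohort,
)


class TestBuildSpectrum:
    def test_fixture_totals(self, fixture_spectrum):
        assert fixture_spectrum.total_alleles == 180
        assert fixture_spectrum.n_distinct == 75
        assert fixture_spectrum.n_patients == 90

    def test_two_n_check_passes_for_90_patients(self, fixture_rows):
        with warnings.catch_warnings():
            warnings.simplefilter("error", SpectrumConsistencyWarning)
            ls.build_spectrum(fixture_rows, n_patients=90)

    def test_two_n_mismatch_warns_or_raises(self, fixture_rows):
        with pytest.warns(SpectrumConsistencyWarning):
            ls.build_spectrum(fixture_rows, n_patients=80)
        with pytest.raises(SpectrumError):
            ls.build_spectrum(fixture_rows, n_patients=80, strict_2n=True)

    def test_empty_table_rejected(self):
        with pytest.raises(SpectrumError):
            ls.build_spectrum(pd.DataFrame(columns=["cdna", "protein", "allele_count"]))

    def test_duplicates_merged_but_conflicts_rejected(self):
        dup = pd.DataFrame(
            {
                "cdna": ["c.5116C>T", "c.5116C>T"],
                "protein": ["p.(Arg1706Ter)", "p.(Arg1706Ter)"],
                "allele_count": [2, 3],
            }
        )
        s = ls.build_spectrum(dup)
        assert s.n_distinct == 1 and s.total_alleles == 5
        conflict = dup.assign(protein=["p.(Arg1706Ter)", "p.(Arg1706Gln)"])
        with pytest.raises(SpectrumError, match="already seen"):
            ls.build_spectrum(conflict)


class TestTypeDistribution:
    def test_fixture_class_counts(self, fixture_spectrum):
        counts, fractions = ls.type_distribution(fixture_spectrum)
        assert counts == {
            Consequence.NONSENSE: 30,
            Consequence.FRAMESHIFT: 22,
            Consequence.SPLICE: 16,
            Consequence.GROSS_DEL_DUP: 4,
            Consequence.MISSENSE: 3,
        }
        assert fractions[Consequence.NONSENSE] == pytest.approx(0.40)
        # 16/75 recomputes to 21.33%, not the commonly printed 21.4%
        assert round_half_up(100 * fractions[Consequence.SPLICE], 1) == 21.3
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_variant_spectrum(self):
        rows = pd.DataFrame(
            {"cdna": ["c.5116C>T"], "protein": ["p.(Arg1706Ter)"], "allele_count": [4]}
        )
        counts, fractions = ls.type_distribution(ls.build_spectrum(rows))
        assert counts == {Consequence.NONSENSE: 1}
        assert fractions == {Consequence.NONSENSE: 1.0}


class TestTopVariants:
    def test_fixture_recurrent_list(self, fixture_spectrum):
        top, cumulative = ls.top_variants(fixture_spectrum, min_count=9)
        assert [(v.key, c) for v, c, _ in top] == [
            ("c.7536del", 27),
            ("c.4692_4695dup", 16),
            ("c.8245-2A>G", 12),
            ("c.5116C>T", 10),
            ("c.2049_2050del", 9),
        ]
        assert cumulative == pytest.approx(74 / 180)
        assert round_half_up(100 * cumulative, 1) == 41.1

    def test_min_count_one_covers_everything(self, fixture_spectrum):
        top, cumulative = ls.top_variants(fixture_spectrum, min_count=1)
        assert len(top) == 75
        assert cumulative == pytest.approx(1.0)

    def test_threshold_above_max_empty(self, fixture_spectrum):
        top, cumulative = ls.top_variants(fixture_spectrum, min_count=28)
        assert top == () and cumulative == 0

    def test_order_invariance(self, fixture_rows):
        shuffled = fixture_rows.sample(frac=1.0, random_state=3)
        s1 = ls.build_spectrum(fixture_rows, n_patients=90)
        s2 = ls.build_spectrum(shuffled, n_patients=90)
        t1, c1 = ls.top_variants(s1, 2)
        t2, c2 = ls.top_variants(s2, 2)
        assert [(v.key, c) for v, c, _ in t1] == [(v.key, c) for v, c, _ in t2]
        assert c1 == c2


class TestVariantShare:
    @pytest.mark.parametrize(
        "cdna,count,pct",
        [("c.7536del", 27, 15.0), ("c.4692_4695dup", 16, 8.9)],
    )
    def test_published_shares(self, fixture_spectrum, cdna, count, pct):
        got_count, share = ls.variant_share(fixture_spectrum, cdna)
        assert got_count == count
        assert round_half_up(100 * share, 1) == pct

    def test_absent_variant(self, fixture_spectrum):
        with pytest.raises(KeyError):
            ls.variant_share(fixture_spectrum, "c.9999A>T")


class TestCohortSummary:
    def _cohort(self, n_f=43, n_m=47):
        rows = []
        for i in range(n_f + n_m):
            rows.append(
                {
                    "patient_id": f"P{i}",
                    "sex": "F" if i < n_f else "M",
                    "phenotype": "MDC1A",
                    "allele1_cdna": "c.7536del",
                    "allele2_cdna": "c.5116C>T",
                    "zygosity": "het",
                }
            )
        return pd.DataFrame(rows)

    def test_sex_fractions(self):
        out = ls.summarize_cohort(self._cohort())
        assert out["sex"]["counts"] == {"F": 43, "M": 47}
        assert round_half_up(100 * out["sex"]["fractions"]["F"], 1) == 47.8
        assert round_half_up(100 * out["sex"]["fractions"]["M"], 1) == 52.2

    def test_all_missing_sex(self):
        df = self._cohort()
        df["sex"] = ""
        out = ls.summarize_cohort(df)
        assert out["sex"]["counts"] == {} and out["sex"]["fractions"] == {}

    def test_homozygote_counts(self):
        df = self._cohort()
        df.loc[:3, "allele2_cdna"] = "c.7536del"
        df.loc[:3, "zygosity"] = "hom"
        out = ls.summarize_cohort(df)
        assert out["homozygotes"] == {"c.7536del": 4}

    def test_unknown_zygosity_single_variant_assumed_homozygous(self):
        df = pd.DataFrame(
            [
                {
                    "patient_id": "P90",
                    "sex": "F",
                    "phenotype": "LGMD",
                    "allele1_cdna": "c.8245-2A>G",
                    "allele2_cdna": "",
                    "zygosity": "unknown",
                }
            ]
        )
        with pytest.warns(SpectrumConsistencyWarning, match="unknown"):
            out = ls.summarize_cohort(df)
        assert out["homozygotes"] == {"c.8245-2A>G": 1}
        assert out["homozygotes_assumed_from_unknown_zygosity"] == 1


class TestCohortToSpectrum:
    def test_allele_conservation(self):
        cfg = ls.SimulationConfig(n_patients=40, seed=11)
        cohort, _ = ls.generate_cohort(cfg)
        rows = spectrum_from_cohort(cohort)
        s = ls.build_spectrum(rows, n_patients=40)
        assert s.total_alleles == 80

    def test_unknown_zygosity_counts_two_alleles(self):
        df = pd.DataFrame(
            [
                {
                    "patient_id": "P1",
                    "allele1_cdna": "c.7536del",
                    "allele2_cdna": "",
                    "zygosity": "unknown",
                }
            ]
        )
        rows = spectrum_from_cohort(df)
        assert rows.loc[0, "allele_count"] == 2


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(41.15, 1) == 41.2
    assert round_half_up(8.885, 2) == 8.89
    assert round_half_up(2.5, 0) == 3.0
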