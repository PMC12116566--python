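"""Drug-name matching, SOC restriction, case building, characteristics."""

import numpy as np
import pandas as pd
import pytest

import pvfaers as pv
from pvfaers.cohort import (
    DrugLexicon,
    MeddraStub,
    build_cases,
    characteristics,
    convert_age_years,
    convert_weight_kg,
    filter_soc,
    match_drug,
    normalize_name,
    percentage,
)
from pvfaers.synthetic_data import DERM_SOC


@pytest.fixture
def small_lexicon():
    return DrugLexicon({"anastrozole": {"Arimidex"}, "letrozole": {"Femara"}})


@pytest.fixture
def small_meddra():
    return MeddraStub({
        "Alopecia": (DERM_SOC, "Skin"),
        "Rash": (DERM_SOC, "Skin"),
        "Nausea": (10017947, "GI"),
    })


def drug_frame(rows):
    return pd.DataFrame(
        {
            "primaryid": pd.array([r[0] for r in rows], dtype="Int64"),
            "caseid": pd.array([r[0] for r in rows], dtype="Int64"),
            "drug_seq": pd.array([r[1] for r in rows], dtype="Int64"),
            "role_cod": [r[2] for r in rows],
            "drugname": [r[3] for r in rows],
            "prod_ai": pd.array([r[4] for r in rows], dtype="string"),
        }
    )


class TestMatchDrug:
    def test_brand_name_upper_case_matches(self, small_lexicon):
        df = drug_frame([(1, 1, "PS", "ARIMIDEX", None)])
        assert match_drug(df, small_lexicon, "anastrozole") == {1}

    def test_trailing_punctuation_trimmed(self, small_lexicon):
        df = drug_frame([(2, 1, "PS", "anastrozole.", None)])
        assert match_drug(df, small_lexicon, "anastrozole") == {2}

    def test_concomitant_role_filtered(self, small_lexicon):
        df = drug_frame([(3, 1, "C", "Arimidex", None)])
        assert match_drug(df, small_lexicon, "anastrozole", roles={"PS", "SS"}) == set()
        assert match_drug(df, small_lexicon, "anastrozole", roles={"C"}) == {3}

    def test_match_via_active_ingredient(self, small_lexicon):
        df = drug_frame([(4, 1, "SS", "SOME TRADE NAME", "ANASTROZOLE")])
        assert match_drug(df, small_lexicon, "anastrozole") == {4}

    def test_no_substring_matching(self, small_lexicon):
        df = drug_frame([(5, 1, "PS", "anastrozole combination pack", None)])
        assert match_drug(df, small_lexicon, "anastrozole") == set()

    def test_unknown_target_rejected(self, small_lexicon):
        with pytest.raises(KeyError):
            match_drug(drug_frame([]), small_lexicon, "tamoxifen")


class TestFilterSoc:
    def reac(self, rows):
        return pd.DataFrame(
            {
                "primaryid": pd.array([r[0] for r in rows], dtype="Int64"),
                "caseid": pd.array([r[0] for r in rows], dtype="Int64"),
                "pt": [r[1] for r in rows],
            }
        )

    def test_any_match_semantics(self, small_meddra):
        df = self.reac([(1, "Alopecia"), (2, "Nausea"), (3, "Nausea"), (3, "Rash")])
        assert filter_soc(df, small_meddra, DERM_SOC) == {1, 3}

    def test_unknown_pt_ignored(self, small_meddra, caplog):
        df = self.reac([(1, "Completely novel PT")])
        with caplog.at_level("WARNING"):
            assert filter_soc(df, small_meddra, DERM_SOC) == set()
        assert "absent" in caplog.text

    def test_unknown_soc_rejected(self, small_meddra):
        with pytest.raises(ValueError):
            filter_soc(self.reac([]), small_meddra, 99999)


class TestUnitConversion:
    def test_age_months_to_years(self):
        assert convert_age_years(792, "MON") == pytest.approx(66.0)

    def test_weight_lbs_to_kg(self):
        assert convert_weight_kg(150, "LBS") == pytest.approx(68.04, abs=0.005)

    def test_unknown_unit_is_missing(self):
        assert convert_age_years(10, "DECADES") is None
        assert convert_weight_kg(10, "STONE") is None

    def test_missing_value(self):
        assert convert_age_years(None, "YR") is None


class TestBuildCases:
    def test_intersection_and_conversion(self, dedup_bundle, lexicon, meddra):
        matched = match_drug(dedup_bundle.drug, lexicon, "anastrozole")
        derm = filter_soc(dedup_bundle.reac, meddra, DERM_SOC)
        cases = build_cases(
            dedup_bundle, matched, derm, "anastrozole", lexicon, meddra, soc_code=DERM_SOC
        )
        assert set(cases["primaryid"]) == matched & derm
        assert (cases["pts"].map(len) >= 1).all()
        ages = cases["age_years"].dropna().astype(float)
        assert (ages >= 0).all() and ages.max() < 120  # MON/DY rows converted

    def test_not_in_derm_excluded(self, dedup_bundle, lexicon, meddra):
        matched = match_drug(dedup_bundle.drug, lexicon, "anastrozole")
        cases = build_cases(
            dedup_bundle, matched, set(), "anastrozole", lexicon, meddra, soc_code=DERM_SOC
        )
        assert cases.empty


class TestPercentage:
    @pytest.mark.parametrize(
        "count,total,expect",
        [
            (2164, 2237, 96.74),
            (555, 725, 76.55),
            (0, 100, 0.00),
            (1, 3, 33.33),
            (1, 8, 12.50),  # 12.5 rounds half-up at 2 dp (exact)
        ],
    )
    def test_half_up_two_decimals(self, count, total, expect):
        assert percentage(count, total) == expect

    def test_half_up_boundary(self):
        # 0.125% must round up to 0.13, not bankers-round to 0.12
        assert percentage(1, 800) == 0.13


@pytest.fixture(scope="module")
def cases(dedup_bundle, lexicon, meddra):
    matched = match_drug(dedup_bundle.drug, lexicon, "anastrozole")
    derm = filter_soc(dedup_bundle.reac, meddra, DERM_SOC)
    return build_cases(
        dedup_bundle, matched, derm, "anastrozole", lexicon, meddra, soc_code=DERM_SOC
    )


class TestCharacteristics:
    def test_categorical_blocks_sum_to_100(self, cases):
        table = characteristics(cases)
        partitioning = ("sex", "weight_kg", "age_years", "occupation", "country")
        for block in partitioning:
            sub = table[(table["block"] == block) & (table["stratum"] == "all")]
            assert sub["n"].sum() == len(cases)
            assert sub["pct"].sum() == pytest.approx(100.0, abs=0.02)

    def test_permutation_invariance(self, cases):
        shuffled = cases.sample(frac=1.0, random_state=4).reset_index(drop=True)
        t1 = characteristics(cases).reset_index(drop=True)
        t2 = characteristics(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(t1, t2)

    def test_counts_match_bruteforce_recount(self, cases):
        """Independent recount of the female row and the >65 age band."""
        table = characteristics(cases)
        sex = table[(table["block"] == "sex") & (table["stratum"] == "all")]
        n_female = sum(1 for s in cases["sex"] if s == "F")
        assert int(sex.loc[sex["label"] == "Female", "n"].iloc[0]) == n_female
        age = table[(table["block"] == "age_years") & (table["stratum"] == "all")]
        n_old = sum(1 for a in cases["age_years"] if pd.notna(a) and a > 65)
        assert int(age.loc[age["label"] == ">65", "n"].iloc[0]) == n_old

    def test_empty_stratum_all_zero(self, cases):
        table = characteristics(cases, strata={"empty": cases.iloc[0:0]})
        sub = table[(table["stratum"] == "empty") & (table["block"] == "sex")]
        assert (sub["n"] == 0).all() and (sub["pct"] == 0.0).all()

    def test_median_with_min_max(self, cases):
        table = characteristics(cases)
        row = table[(table["block"] == "median_age_years") & (table["stratum"] == "all")].iloc[0]
        vals = cases["age_years"].dropna().astype(float)
        assert row["median"] == pytest.approx(float(np.median(vals)))
        assert row["min"] == pytest.approx(float(vals.min()))
        assert row["max"] == pytest.approx(float(vals.max()))


def test_lexicon_and_meddra_file_roundtrip(tmp_path, lexicon, meddra):
    lp, mp = tmp_path / "lex.tsv", tmp_path / "meddra.tsv"
    lexicon.to_file(lp)
    meddra.to_file(mp)
    assert DrugLexicon.from_file(lp).aliases == lexicon.aliases
    assert MeddraStub.from_file(mp).mapping == meddra.mapping


def test_normalize_name():
    assert normalize_name("  ARIMIDEX. ") == "arimidex"
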