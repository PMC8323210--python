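"""Data model, I/O round-trips, binarization, CART imputation, and the
numeric representation."""

import math

import numpy as np
import pytest

from emrsim import (CohortConfig, NormalRange, TextSchema, assemble_numeric,
                    binarize_labs, exclude_outcome_codes, generate_cohort,
                    impute_missing, normalize_icd, read_cohort,
                    select_popular_comorbidities, write_cohort)


class TestNormalizeIcd:
    @pytest.mark.parametrize("raw,expected", [
        ("C78.7", "C787"),
        ("K76.0", "K760"),
        ("K269", "K269"),
        ("i10", "I10"),
        ("D18.0", "D180"),
    ])
    def test_normalization(self, raw, expected):
        assert normalize_icd(raw) == expected

    def test_idempotent(self):
        assert normalize_icd(normalize_icd("C78.7")) == "C787"

    @pytest.mark.parametrize("bad", ["", "123", ".C787", "K"])
    def test_invalid_codes_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_icd(bad)


class TestCohortIO:
    @pytest.mark.parametrize("fmt", ["jsonl", "csv"])
    def test_round_trip(self, tmp_path, fmt):
        patients, _ = generate_cohort(CohortConfig(n_patients=30, seed=5))
        path = tmp_path / f"cohort.{fmt}"
        write_cohort(patients, path, format=fmt)
        back = read_cohort(path, format=fmt)
        assert len(back) == 30
        for p, q in zip(patients, back):
            assert p.id == q.id and p.age == q.age
            assert p.comorbidities == q.comorbidities
            assert p.labs == q.labs
            assert p.report_tokens == q.report_tokens

    def test_missing_field_names_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"id": "x", "sex": 1}\n')
        with pytest.raises(ValueError, match="line 1.*age"):
            read_cohort(path)

    def test_malformed_json_names_line(self, tmp_path):
        patients, _ = generate_cohort(CohortConfig(n_patients=4, seed=1))
        path = tmp_path / "bad.jsonl"
        write_cohort(patients, path)
        lines = path.read_text().splitlines()
        lines[2] = "{not json"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="line 3"):
            read_cohort(path)

    def test_duplicate_id_rejected(self, tmp_path, make_patient):
        cohort = [make_patient("dup", 30), make_patient("dup", 40)]
        path = tmp_path / "dup.jsonl"
        write_cohort(cohort, path)
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort(path)


class TestBinarizeLabs:
    @pytest.mark.parametrize("value,expected", [
        (5.0, 0),      # inside
        (7.0, 1),      # above
        (3.0, 1),      # below
        (4.0, 0),      # closed lower boundary counts as normal
        (6.0, 0),      # closed upper boundary counts as normal
    ])
    def test_range_binarization(self, make_patient, value, expected):
        cohort = [make_patient("x", 30, labs={"alt": value})]
        out = binarize_labs(cohort, [NormalRange("alt", 4.0, 6.0)])
        assert out[0].labs["alt"] == expected

    def test_already_binary_passes_through_and_idempotent(self, make_patient):
        cohort = [make_patient("x", 30, labs={"flag": 1, "alt": 5.0})]
        ranges = [NormalRange("alt", 4, 6)]
        once = binarize_labs(cohort, ranges)
        twice = binarize_labs(once, ranges)
        assert once[0].labs == {"flag": 1, "alt": 0}
        # alt = 0 is outside [4, 6]: idempotence requires dropping the range
        assert binarize_labs(once, [])[0].labs == once[0].labs
        assert twice[0].labs["flag"] == 1

    def test_missing_value_instructs_imputation(self, make_patient):
        cohort = [make_patient("x", 30, labs={"alt": math.nan})]
        with pytest.raises(ValueError, match="impute"):
            binarize_labs(cohort, [NormalRange("alt", 4, 6)])

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            NormalRange("alt", 6, 4)


class TestImputeMissing:
    def test_no_missing_is_identity(self, make_patient):
        cohort = [make_patient(f"p{i}", 30 + i, labs={"a": i % 2, "b": 1})
                  for i in range(6)]
        out = impute_missing(cohort)
        assert all(p.labs == q.labs for p, q in zip(cohort, out))

    def test_constant_feature_imputed_to_constant(self, make_patient):
        cohort = [make_patient(f"p{i}", 30, labs={"a": 1.0, "b": float(i % 2)})
                  for i in range(10)]
        cohort[0].labs["a"] = math.nan
        out = impute_missing(cohort)
        assert out[0].labs["a"] == 1.0

    def test_deterministic_rule_recovered(self, make_patient):
        """b == a on all complete cases; the tree must impute the masked b
        from its a (oracle: the rule itself)."""
        cohort = []
        for i in range(12):
            a = float(i % 2)
            cohort.append(make_patient(f"p{i:02d}", 40, labs={"a": a, "b": a}))
        cohort[3].labs["b"] = math.nan          # patient with a = 1
        cohort[4].labs["b"] = math.nan          # patient with a = 0
        out = impute_missing(cohort)
        assert out[3].labs["b"] == cohort[3].labs["a"]
        assert out[4].labs["b"] == cohort[4].labs["a"]
        assert not any(math.isnan(v) for p in out for v in p.labs.values())

    def test_all_missing_feature_rejected(self, make_patient):
        cohort = [make_patient(f"p{i}", 30, labs={"a": math.nan, "b": 1.0})
                  for i in range(5)]
        with pytest.raises(ValueError, match="cannot impute"):
            impute_missing(cohort)


class TestPopularComorbidities:
    def test_strictly_greater_than_threshold(self, make_patient):
        cohort = [make_patient(f"p{i:03d}", 30,
                               codes=({"A01"} if i < 6 else set()) |
                                     ({"B02"} if i < 5 else set()))
                  for i in range(100)]
        popular = select_popular_comorbidities(cohort, 0.05)
        assert "A01" in popular        # 6 % > 5 %
        assert "B02" not in popular    # exactly 5 % is dropped
        assert select_popular_comorbidities(cohort, 0.0) == ["A01", "B02"]

    def test_sorted_by_frequency_then_code(self, make_patient):
        cohort = [make_patient("p0", 30, codes={"Z99", "A01"}),
                  make_patient("p1", 30, codes={"Z99", "A01"}),
                  make_patient("p2", 30, codes={"B05"})]
        assert select_popular_comorbidities(cohort, 0.0) == ["A01", "Z99", "B05"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            select_popular_comorbidities([], 0.05)


class TestExcludeOutcomeCodes:
    def test_outcome_codes_and_extensions_removed(self, make_patient):
        cohort = [make_patient("p0", 30,
                               codes={"C220", "C787", "D180", "K760", "K761", "I10"})]
        out = exclude_outcome_codes(cohort)
        assert out[0].labs == cohort[0].labs
        assert out[0].comorbidities == {"K761", "I10"}


class TestAssembleNumeric:
    def _cohort(self, make_patient, schema):
        tokens_all = set(schema.independent) | set(schema.set_features)
        return [
            make_patient("p0", 40, labs={"alt": 1, "ast": 0}, codes={"I10"},
                         tokens=tokens_all),
            make_patient("p1", 60, labs={"alt": 0, "ast": 0}, codes={"K590"},
                         tokens=set()),
            make_patient("p2", 50, labs={"alt": 1, "ast": 1}, codes={"I10", "K590"},
                         tokens={"cyst"}),
        ]

    def test_column_groups_and_order(self, make_patient, schema5):
        cohort = self._cohort(make_patient, schema5)
        frame, groups = assemble_numeric(cohort, ["I10", "K590"], schema5)
        assert list(frame.columns) == (groups["text"] + groups["lab"] +
                                       groups["comorbidity"] + groups["demographic"])
        assert frame.shape == (3, 9 + 2 + 2 + 4)
        assert frame.loc["p1", "icd:I10"] == 0.0
        assert frame.loc["p0", "age"] == 0.0 and frame.loc["p1", "age"] == 1.0

    def test_default_widths_give_131_features(self):
        patients, _ = generate_cohort(CohortConfig(n_patients=150, seed=1))
        from emrsim import prepare_cohort
        cohort, corpus, schema, popular = prepare_cohort(patients, max_popular=26)
        assert schema.size == 44 and len(popular) == 26
        frame, groups = assemble_numeric(cohort, popular, schema)
        assert frame.shape[1] == 131
        assert [len(groups[g]) for g in ("text", "lab", "comorbidity", "demographic")] \
            == [44, 57, 26, 4]

    def test_identical_patients_identical_rows(self, make_patient, schema5):
        cohort = self._cohort(make_patient, schema5)
        twin = self._cohort(make_patient, schema5)[0]
        twin.id = "p9"
        frame, _ = assemble_numeric(cohort + [twin], ["I10", "K590"], schema5)
        assert np.allclose(frame.loc["p0"], frame.loc["p9"])

    def test_permutation_stability(self, make_patient, schema5):
        cohort = self._cohort(make_patient, schema5)
        f1, _ = assemble_numeric(cohort, ["I10"], schema5)
        f2, _ = assemble_numeric(cohort[::-1], ["I10"], schema5)
        assert np.allclose(f1.sort_index(), f2.sort_index())

    def test_unknown_popular_code_rejected(self, make_patient, schema5):
        cohort = self._cohort(make_patient, schema5)
        with pytest.raises(ValueError, match="does not occur"):
            assemble_numeric(cohort, ["Z999"], schema5)

    def test_unbinarized_labs_rejected(self, make_patient, schema5):
        cohort = self._cohort(make_patient, schema5)
        cohort[0].labs["alt"] = 3.7
        with pytest.raises(ValueError, match="not binarized"):
            assemble_numeric(cohort, ["I10"], schema5)
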