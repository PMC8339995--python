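"""I/O, validation, instrument selection, clumping and harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate.simulate import SimConfig, simulate_two_sample
from mrmediate.summarystats import (
    LDMatrix,
    harmonize,
    harmonize_multi,
    ld_clump,
    mean_f_statistic,
    read_ld_matrix,
    read_summary_stats,
    select_instruments,
    validate_summary_stats,
    write_ld_matrix,
    write_summary_stats,
)

from .conftest import make_assoc_frame, make_harmonized


class TestReadValidate:
    def test_well_formed_roundtrip(self, tmp_path):
        df = make_assoc_frame([{"beta": 0.1}, {"beta": -0.2}, {"beta": 0.3}])
        path = tmp_path / "stats.tsv"
        write_summary_stats(df, path)
        out, report = read_summary_stats(path)
        assert len(out) == 3 and report.n_dropped == 0

    @pytest.mark.parametrize(
        "bad, reason",
        [
            ({"se": 0.0}, "nonpositive_se"),
            ({"se": -1.0}, "nonpositive_se"),
            ({"pvalue": 0.0}, "bad_pvalue"),
            ({"pvalue": 1.5}, "bad_pvalue"),
            ({"eaf": 1.2}, "bad_eaf"),
            ({"effect_allele": "AT"}, "bad_effect_allele"),
            ({"effect_allele": "G", "other_allele": "G"}, "identical_alleles"),
        ],
    )
    def test_invalid_rows_dropped_with_reason(self, bad, reason):
        df = make_assoc_frame([{}, bad])
        out, report = validate_summary_stats(df)
        assert len(out) == 1
        assert report.n_dropped == 1
        assert report.drop_reasons[reason] == 1

    def test_missing_mandatory_column_raises(self, tmp_path):
        path = tmp_path / "stats.tsv"
        write_summary_stats(make_assoc_frame([{}]), path)
        broken = pd.read_csv(path, sep="\t").drop(columns=["se"])
        broken.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="se"):
            read_summary_stats(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("variant_id\tchr\tpos\tea\toa\teaf\tbeta\tse\tpval\tn\n")
        with pytest.raises(ValueError, match="empty"):
            read_summary_stats(path)

    def test_simulated_roundtrip_full_precision(self, tmp_path):
        exposure, _, _ = simulate_two_sample(SimConfig(n_snps=100, seed=3))
        path = tmp_path / "sim.tsv"
        write_summary_stats(exposure, path)
        back, report = read_summary_stats(path)
        assert report.n_dropped == 0
        np.testing.assert_array_equal(back["beta"].to_numpy(), exposure["beta"].to_numpy())
        np.testing.assert_array_equal(back["se"].to_numpy(), exposure["se"].to_numpy())

    def test_column_map_remaps_source_columns(self, tmp_path):
        df = make_assoc_frame([{}])
        path = tmp_path / "renamed.tsv"
        write_summary_stats(df, path, column_map={"pvalue": "p_value", "beta": "b"})
        out, _ = read_summary_stats(path, column_map={"pvalue": "p_value", "beta": "b"})
        assert out.loc[0, "beta"] == df.loc[0, "beta"]


class TestSelectInstruments:
    def test_threshold_is_strict(self):
        df = make_assoc_frame(
            [{"pvalue": 4.9e-8}, {"pvalue": 5e-8}, {"pvalue": 1e-9}]
        )
        out = select_instruments(df, 5e-8)
        assert list(out["variant_id"]) == ["rs0", "rs2"]

    def test_threshold_one_keeps_everything_but_p_equal_one(self):
        df = make_assoc_frame([{"pvalue": 0.99}, {"pvalue": 0.5}])
        assert len(select_instruments(df, p_threshold=1.0)) == 2

    def test_matches_brute_force_on_simulated(self):
        exposure, _, _ = simulate_two_sample(SimConfig(n_snps=500, gamma_mean=0.01, seed=9))
        out = select_instruments(exposure)
        expected = [
            vid
            for vid, p in zip(exposure["variant_id"], exposure["pvalue"])
            if p < 5e-8
        ]
        assert list(out["variant_id"]) == expected

    def test_zero_survivors_returns_empty(self):
        df = make_assoc_frame([{"pvalue": 0.5}])
        assert len(select_instruments(df)) == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_idempotent(self, seed):
        exposure, _, _ = simulate_two_sample(
            SimConfig(n_snps=50, gamma_mean=0.02, seed=seed)
        )
        once = select_instruments(exposure)
        if len(once):
            twice = select_instruments(once)
            pd.testing.assert_frame_equal(once, twice)


def _clump_oracle(df, ld, r2_threshold, window_kb):
    """Exhaustive greedy re-implementation used as the independent check."""
    recs = df.to_dict("records")
    kept = []
    while recs:
        best = sorted(
            recs, key=lambda r: (r["pvalue"], r["position_bp"], r["variant_id"])
        )[0]
        kept.append(best["variant_id"])
        nxt = []
        for r in recs:
            if r["variant_id"] == best["variant_id"]:
                continue
            if (
                str(r["chromosome"]) == str(best["chromosome"])
                and abs(r["position_bp"] - best["position_bp"]) <= window_kb * 1000
                and ld.r2_between(r["variant_id"], best["variant_id"]) > r2_threshold
            ):
                continue
            nxt.append(r)
        recs = nxt
    return sorted(kept)


class TestLDClump:
    def _ld(self, ids, r2_pairs=None):
        n = len(ids)
        m = np.eye(n)
        idx = {v: i for i, v in enumerate(ids)}
        for (a, b), r2 in (r2_pairs or {}).items():
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = r2
        return LDMatrix(variant_ids=ids, r2=m)

    def test_independent_snps_all_retained(self):
        df = make_assoc_frame([{"position_bp": p} for p in (100, 200, 300)])
        ld = self._ld(list(df["variant_id"]))
        assert len(ld_clump(df, ld)) == 3

    def test_linked_pair_keeps_smaller_p(self):
        df = make_assoc_frame(
            [
                {"pvalue": 1e-10, "position_bp": 1000},
                {"pvalue": 1e-9, "position_bp": 2000},
            ]
        )
        ld = self._ld(["rs0", "rs1"], {("rs0", "rs1"): 0.5})
        out = ld_clump(df, ld)
        assert list(out["variant_id"]) == ["rs0"]

    def test_cross_chromosome_never_clumps(self):
        df = make_assoc_frame(
            [
                {"chromosome": "1", "position_bp": 1000},
                {"chromosome": "2", "position_bp": 1000},
            ]
        )
        ld = self._ld(["rs0", "rs1"], {("rs0", "rs1"): 0.99})
        assert len(ld_clump(df, ld)) == 2

    def test_outside_window_not_clumped(self):
        df = make_assoc_frame(
            [{"position_bp": 1}, {"position_bp": 5_000_003}]
        )
        ld = self._ld(["rs0", "rs1"], {("rs0", "rs1"): 0.99})
        assert len(ld_clump(df, ld)) == 2

    def test_six_snp_fixture_matches_exhaustive_oracle(self):
        df = make_assoc_frame(
            [
                {"chromosome": "1", "position_bp": 1_000, "pvalue": 1e-12},
                {"chromosome": "1", "position_bp": 500_000, "pvalue": 1e-10},
                {"chromosome": "1", "position_bp": 6_200_000, "pvalue": 1e-11},
                {"chromosome": "1", "position_bp": 6_300_000, "pvalue": 1e-9},
                {"chromosome": "2", "position_bp": 1_000, "pvalue": 1e-8},
                {"chromosome": "2", "position_bp": 2_000, "pvalue": 1e-8},
            ]
        )
        ids = list(df["variant_id"])
        ld = self._ld(
            ids,
            {
                ("rs0", "rs1"): 0.8,
                ("rs2", "rs3"): 0.3,
                ("rs0", "rs2"): 0.9,  # > window apart: must not clump
                ("rs4", "rs5"): 0.009,  # below r2 threshold: must not clump
            },
        )
        out = ld_clump(df, ld)
        assert sorted(out["variant_id"]) == _clump_oracle(df, ld, 0.01, 5000)
        # sorted by chromosome then position
        assert list(out["variant_id"]) == ["rs0", "rs2", "rs4", "rs5"]

    def test_equal_p_tiebreak_smaller_position(self):
        df = make_assoc_frame(
            [
                {"position_bp": 2000, "pvalue": 1e-9},
                {"position_bp": 1000, "pvalue": 1e-9},
            ]
        )
        ld = self._ld(["rs0", "rs1"], {("rs0", "rs1"): 0.9})
        assert list(ld_clump(df, ld)["variant_id"]) == ["rs1"]

    def test_missing_id_raises(self):
        df = make_assoc_frame([{}])
        ld = self._ld(["other"])
        with pytest.raises(ValueError, match="rs0"):
            ld_clump(df, ld)

    def test_contains_global_minimum_p_and_is_subset(self):
        exposure, _, _ = simulate_two_sample(SimConfig(n_snps=30, seed=4))
        ids = list(exposure["variant_id"])
        rng = np.random.default_rng(0)
        m = np.eye(30)
        # random symmetric r2 structure
        for i in range(30):
            for k in range(i + 1, 30):
                m[i, k] = m[k, i] = rng.uniform(0, 1) if rng.uniform() < 0.3 else 0.0
        ld = LDMatrix(variant_ids=ids, r2=m)
        out = ld_clump(exposure, ld)
        assert set(out["variant_id"]) <= set(ids)
        best = exposure.loc[exposure["pvalue"].idxmin(), "variant_id"]
        assert best in set(out["variant_id"])

    def test_ld_matrix_tsv_roundtrip(self, tmp_path):
        ld = self._ld(["a", "b"], {("a", "b"): 0.25})
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ld, path)
        back = read_ld_matrix(path)
        assert back.variant_ids == ["a", "b"]
        assert back.r2_between("a", "b") == 0.25


class TestHarmonize:
    def _pair(self, exp_row, out_row):
        exp = make_assoc_frame([exp_row])
        out = make_assoc_frame([out_row])
        return exp, out

    def test_identical_alleles_unchanged(self):
        exp, out = self._pair({"beta": 0.2}, {"beta": 0.1})
        h = harmonize(exp, out)
        assert h.table.loc[0, "beta_outcome"] == 0.1
        assert (h.log["action"] != "flip").all()

    def test_swapped_alleles_flip_sign(self):
        exp, out = self._pair(
            {"effect_allele": "A", "other_allele": "G"},
            {"effect_allele": "G", "other_allele": "A", "beta": 0.1},
        )
        h = harmonize(exp, out)
        assert h.table.loc[0, "beta_outcome"] == -0.1
        assert (h.log["action"] == "flip").any()

    def test_strand_complement_swapped_flips(self):
        exp, out = self._pair(
            {"effect_allele": "A", "other_allele": "G"},
            {"effect_allele": "C", "other_allele": "T", "beta": 0.1},
        )
        h = harmonize(exp, out)
        assert h.table.loc[0, "beta_outcome"] == -0.1

    def test_ambiguous_palindrome_dropped(self):
        exp, out = self._pair(
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.50},
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.50},
        )
        h = harmonize(exp, out)
        assert len(h) == 0
        assert list(h.log["reason"]) == ["ambiguous_palindrome"]

    def test_palindrome_policies(self):
        exp, out = self._pair(
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.1},
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.9, "beta": 0.1},
        )
        h = harmonize(exp, out, palindrome_policy="infer_by_eaf")
        # frequencies on opposite sides: the outcome effect is for the other allele
        assert h.table.loc[0, "beta_outcome"] == -0.1
        h2 = harmonize(exp, out, palindrome_policy="drop_all")
        assert len(h2) == 0 and list(h2.log["reason"]) == ["palindromic"]

    def test_irreconcilable_alleles_dropped(self):
        exp, out = self._pair(
            {"effect_allele": "A", "other_allele": "G"},
            {"effect_allele": "A", "other_allele": "C"},
        )
        h = harmonize(exp, out)
        assert len(h) == 0
        assert list(h.log["reason"]) == ["allele_mismatch"]

    def test_empty_intersection_raises(self):
        exp = make_assoc_frame([{}])
        out = make_assoc_frame([{}])
        out["variant_id"] = ["other"]
        with pytest.raises(ValueError, match="share no variant"):
            harmonize(exp, out)

    def test_outcome_allele_swap_roundtrip_identical(self):
        """Swapping ea/oa (and negating beta, reflecting eaf) in the outcome
        file must harmonize back to the identical dataset."""
        exposure, outcome, _ = simulate_two_sample(SimConfig(n_snps=20, seed=5))
        h1 = harmonize(exposure, outcome)
        swapped = outcome.copy()
        swapped[["effect_allele", "other_allele"]] = outcome[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        swapped["beta"] = -outcome["beta"]
        swapped["eaf"] = 1 - outcome["eaf"]
        h2 = harmonize(exposure, swapped)
        pd.testing.assert_frame_equal(h1.table, h2.table)

    def test_strand_relabel_invariance(self):
        """Relabeling both studies to the complementary strand leaves the
        harmonized betas unchanged."""
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        exposure, outcome, _ = simulate_two_sample(SimConfig(n_snps=20, seed=6))
        h1 = harmonize(exposure, outcome)
        relabeled = []
        for df in (exposure, outcome):
            d = df.copy()
            d["effect_allele"] = d["effect_allele"].map(comp)
            d["other_allele"] = d["other_allele"].map(comp)
            relabeled.append(d)
        h2 = harmonize(*relabeled)
        np.testing.assert_array_equal(
            h1.table["beta_outcome"].to_numpy(), h2.table["beta_outcome"].to_numpy()
        )

    def test_duplicate_ids_deduplicated(self):
        exp = make_assoc_frame([{}, {}])
        exp["variant_id"] = ["rs0", "rs0"]
        out = make_assoc_frame([{}])
        h = harmonize(exp, out)
        assert list(h.table["variant_id"]) == ["rs0"]


class TestHarmonizeMulti:
    def test_three_study_alignment_with_flip(self):
        e1 = make_assoc_frame([{"beta": 0.1}, {"beta": 0.2}])
        e2 = make_assoc_frame([{"beta": 0.3}, {"beta": 0.4}])
        # swap alleles of the second study's first variant
        e2.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
        e2.loc[0, "beta"] = -0.3
        out = make_assoc_frame([{"beta": 0.5}, {"beta": 0.6}])
        mv = harmonize_multi({"x1": e1, "x2": e2}, out)
        assert mv.exposure_names == ["x1", "x2"]
        np.testing.assert_allclose(mv.beta_exposures[:, 1], [0.3, 0.4])

    def test_requires_two_exposures(self):
        e1 = make_assoc_frame([{}])
        with pytest.raises(ValueError, match=">= 2"):
            harmonize_multi({"x1": e1}, e1.copy())


class TestMeanF:
    def test_single_variant_arithmetic(self):
        data = make_harmonized([0.1], [0.05], [0.0], [1.0])
        f, weak = mean_f_statistic(data)
        assert f == pytest.approx(4.0)
        assert weak is True

    def test_strong_instruments_not_flagged(self):
        data = make_harmonized([1.0, 2.0], [0.1, 0.2], [0, 0], [1, 1])
        f, weak = mean_f_statistic(data)
        assert f == pytest.approx(100.0)
        assert weak is False

    def test_matches_per_variant_loop(self):
        exposure, outcome, _ = simulate_two_sample(SimConfig(n_snps=50, seed=8))
        data = make_harmonized(
            exposure["beta"], exposure["se"], outcome["beta"], outcome["se"]
        )
        f, _ = mean_f_statistic(data)
        expected = np.mean(
            [(b / s) ** 2 for b, s in zip(exposure["beta"], exposure["se"])]
        )
        assert f == pytest.approx(expected, rel=1e-12)

    def test_empty_raises(self):
        data = make_harmonized([], [], [], [])
        with pytest.raises(ValueError):
            mean_f_statistic(data)
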