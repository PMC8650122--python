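"""Signature definitions and per-sample score computations."""

import numpy as np
import pandas as pd
import pytest

from msisig.expression import ExpressionMatrix
from msisig.signatures import (
    AdditiveSignature,
    DanaherSignature,
    MissingGenesError,
    SignatureError,
    builtin_signatures,
    load_hps_coefficients,
    score_additive,
    score_danaher_hps,
    score_danaher_mls,
    score_danaher_msi,
    signature_overlap,
)
from conftest import signature_matrix

MLS_OF_ZERO_Z = 1.03 / 0.69  # Zmin = 0 pushed through the affine transform


class TestDefinitions:
    def test_gene_counts_match_publications(self, signatures):
        li, pac, dan = signatures
        assert len(li.genes) == 15
        assert len(pac.genes) == 25
        assert len(dan.genes) == 14

    def test_overlap_structure(self, signatures):
        ov = signature_overlap(signatures)
        assert ov["li&pacinkova&danaher"] == {"MLH1"}
        assert ov["li&danaher"] - {"MLH1"} == {"EPM2AIP1", "RNLS", "SMAP1", "TTC30A"}
        assert ov["li&pacinkova"] - {"MLH1"} == {"RPL22L1", "SHROOM4"}
        assert ov["pacinkova&danaher"] - {"MLH1"} == set()

    def test_plus_minus_disjointness_enforced(self):
        with pytest.raises(SignatureError, match="both sets"):
            AdditiveSignature("bad", frozenset({"A"}), frozenset({"A", "B"}))

    def test_danaher_requires_all_coefficients(self):
        li, pac, dan = builtin_signatures()
        with pytest.raises(SignatureError, match="coefficient"):
            DanaherSignature(
                "bad", dan.mls_genes, dan.hps_genes, {"EPM2AIP1": 1.0}
            )

    def test_packaged_coefficients_cover_hps_genes(self, signatures):
        coeffs = load_hps_coefficients()
        assert set(coeffs) == set(signatures[2].hps_genes)


class TestScoreAdditive:
    def test_unit_expression_scores_zero(self, uniform_signature_matrix, signatures):
        for sig in signatures[:2]:
            sv = score_additive(uniform_signature_matrix, sig, pseudocount=0.0)
            np.testing.assert_allclose(sv.scores, 0.0)

    def test_li_tenfold_plus_genes(self, signatures):
        li = signatures[0]
        m = signature_matrix(lambda g: 10.0 if g in li.plus_genes else 1.0)
        sv = score_additive(m, li, pseudocount=0.0)
        np.testing.assert_allclose(sv.scores, 3.0)  # 3·log10(10) − 12·log10(1)

    def test_pacinkova_tenfold_minus_genes(self, signatures):
        pac = signatures[1]
        m = signature_matrix(lambda g: 10.0 if g in pac.minus_genes else 1.0)
        sv = score_additive(m, pac, pseudocount=0.0)
        np.testing.assert_allclose(sv.scores, -19.0)  # 0 − 19·log10(10)

    def test_monotone_in_plus_and_minus_genes(self, signatures):
        li = signatures[0]
        base = signature_matrix(lambda g: 5.0)
        s0 = score_additive(base, li).scores["S1"]
        bumped = base.data.copy()
        bumped.loc["LYG1", "S1"] += 1.0  # plus-gene up
        s_plus = score_additive(ExpressionMatrix(bumped), li).scores["S1"]
        assert s_plus > s0
        bumped2 = base.data.copy()
        bumped2.loc["MLH1", "S1"] += 1.0  # minus-gene up
        s_minus = score_additive(ExpressionMatrix(bumped2), li).scores["S1"]
        assert s_minus < s0

    def test_invariant_under_gene_and_sample_permutation(self, signatures):
        li = signatures[0]
        rng = np.random.default_rng(5)
        m = signature_matrix(lambda g: rng.uniform(1, 100, 3), samples=("a", "b", "c"))
        base = score_additive(m, li).scores
        shuffled = m.data.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2
        )
        perm = score_additive(ExpressionMatrix(shuffled), li).scores
        pd.testing.assert_series_equal(
            base.sort_index(), perm.sort_index(), check_names=False
        )

    def test_missing_gene_error_lists_symbols(self, signatures):
        li = signatures[0]
        df = pd.DataFrame({"S1": [1.0], "S2": [2.0]}, index=["MLH1"])
        with pytest.raises(MissingGenesError, match="LYG1"):
            score_additive(ExpressionMatrix(df), li)

    def test_skip_policy_drops_missing_terms(self, signatures, caplog):
        li = signatures[0]
        m = signature_matrix(lambda g: 10.0 if g in li.plus_genes else 1.0)
        dropped = ExpressionMatrix(m.data.drop(index=["LYG1"]))
        with caplog.at_level("WARNING"):
            sv = score_additive(dropped, li, pseudocount=0.0, missing_policy="skip")
        np.testing.assert_allclose(sv.scores, 2.0)
        assert "LYG1" in caplog.text

    def test_zero_expression_with_zero_pseudocount_rejected(self, signatures):
        m = signature_matrix(lambda g: 0.0)
        with pytest.raises(SignatureError, match="pseudocount"):
            score_additive(m, signatures[0], pseudocount=0.0)


class TestDanaherScores:
    def test_identical_samples_hit_degenerate_mls(self, uniform_signature_matrix,
                                                  signatures, caplog):
        # constant cohort → per-gene Z-scores 0 → MLS = 1.03/0.69 everywhere
        with caplog.at_level("WARNING"):
            mls = score_danaher_mls(uniform_signature_matrix, signatures[2])
        np.testing.assert_allclose(mls, MLS_OF_ZERO_Z)
        assert "zero variance" in caplog.text

    def test_mls_zero_at_zmin_minus_mu(self, signatures):
        dan = signatures[2]
        # two samples: MMR genes split so Z = ±1/sqrt(2)·sqrt(2) = ±0.707...;
        # engineer Zmin = −1.03 via custom constants instead
        custom = DanaherSignature(
            "custom", dan.mls_genes, dan.hps_genes, dan.hps_coefficients,
            mu_min=np.sqrt(0.5), sigma_min=0.69,
        )
        m = signature_matrix(
            lambda g: (2.0, 8.0) if g in dan.mls_genes else (4.0, 4.0),
            samples=("S1", "S2"),
        )
        mls = score_danaher_mls(m, custom, pseudocount=0.0)
        # S1 has Zmin = −1/√2 = −mu_min → MLS exactly 0
        assert mls["S1"] == pytest.approx(0.0, abs=1e-12)

    def test_mls_affine_in_zmin_with_positive_slope(self, signatures):
        dan = signatures[2]
        rng = np.random.default_rng(2)
        m = signature_matrix(lambda g: rng.uniform(1, 64, 6),
                             samples=[f"S{i}" for i in range(6)])
        logx = np.log2(m.data.loc[list(dan.mls_genes)] + 1.0)
        z = logx.sub(logx.mean(axis=1), axis=0).div(logx.std(axis=1, ddof=1), axis=0)
        zmin = z.min(axis=0)
        mls = score_danaher_mls(m, dan)
        np.testing.assert_allclose(mls, (zmin + 1.03) / 0.69, atol=1e-12)
        # per-gene Z-scores are standardized with the n−1 denominator
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_hps_of_arithmetic_raw_sequence(self, signatures):
        dan = signatures[2]
        # single unit coefficient on WNT11, rest 0 → raw = log2(x_WNT11)
        coeffs = {g: 0.0 for g in dan.hps_genes}
        coeffs["WNT11"] = 1.0
        sig = DanaherSignature("c", dan.mls_genes, dan.hps_genes, coeffs)
        m = signature_matrix(
            lambda g: (2.0, 4.0, 8.0) if g == "WNT11" else (1.0, 1.0, 1.0),
            samples=("a", "b", "c"),
        )
        hps = score_danaher_hps(m, sig, pseudocount=0.0)
        # raw = {1, 2, 3}: mean 2, sample SD 1 → Z = {−1, 0, 1}
        np.testing.assert_allclose(hps, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_hps_two_sample_n_minus_one_sd(self, signatures):
        dan = signatures[2]
        coeffs = {g: 0.0 for g in dan.hps_genes}
        coeffs["WNT11"] = 1.0
        sig = DanaherSignature("c", dan.mls_genes, dan.hps_genes, coeffs)
        m = signature_matrix(
            lambda g: (2.0, 8.0) if g == "WNT11" else (1.0, 1.0),
            samples=("a", "b"),
        )
        hps = score_danaher_hps(m, sig, pseudocount=0.0)
        np.testing.assert_allclose(
            hps, [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
        )

    def test_all_zero_coefficients_degenerate_to_zero(self, signatures, caplog):
        dan = signatures[2]
        sig = DanaherSignature(
            "z", dan.mls_genes, dan.hps_genes, {g: 0.0 for g in dan.hps_genes}
        )
        m = signature_matrix(lambda g: np.random.default_rng(0).uniform(1, 10, 2))
        with caplog.at_level("WARNING"):
            hps = score_danaher_hps(m, sig)
        np.testing.assert_allclose(hps, 0.0)

    def test_hps_standardization_invariant(self, signatures):
        dan = signatures[2]
        rng = np.random.default_rng(9)
        m = signature_matrix(lambda g: rng.uniform(1, 100, 8),
                             samples=[f"S{i}" for i in range(8)])
        hps = score_danaher_hps(m, dan)
        assert hps.mean() == pytest.approx(0.0, abs=1e-9)
        assert hps.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_fewer_than_two_samples_rejected(self, signatures):
        df = pd.DataFrame({"S1": np.ones(14)}, index=sorted(builtin_signatures()[2].genes))
        with pytest.raises(SignatureError, match="2 samples"):
            score_danaher_mls(ExpressionMatrix(df), signatures[2])


class TestDanaherMSIPredictor:
    @pytest.mark.parametrize(
        "mls, hps, expected",
        [
            (0.5, -1.0, 0.0),   # both clamps vanish
            (-3.0, 4.0, 5.0),   # sqrt(9 + 16)
            (0.0, 2.0, 2.0),    # single active term
            (-1.0, -5.0, 1.0),  # only the MLS clamp active
        ],
    )
    def test_hand_values(self, mls, hps, expected):
        sv = score_danaher_msi(
            pd.Series({"s": mls}), pd.Series({"s": hps})
        )
        assert sv.scores["s"] == pytest.approx(expected)

    def test_nonnegative_and_zero_set(self):
        rng = np.random.default_rng(4)
        mls = pd.Series(rng.normal(size=100), index=[f"s{i}" for i in range(100)])
        hps = pd.Series(rng.normal(size=100), index=mls.index)
        sv = score_danaher_msi(mls, hps)
        assert (sv.scores >= 0).all()
        zero = sv.scores == 0
        np.testing.assert_array_equal(zero, (mls >= 0) & (hps <= 0))

    def test_sample_mismatch_rejected(self):
        with pytest.raises(SignatureError, match="different samples"):
            score_danaher_msi(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))

    def test_orientation_statement(self, uniform_signature_matrix, signatures):
        sv = score_danaher_msi(
            pd.Series({"S1": 0.0, "S2": 0.0}), pd.Series({"S1": 0.0, "S2": 0.0})
        )
        assert "MSI-high" in sv.orientation
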