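"""Unit and property tests for the uncertainty scores and their fusion."""

import math

import numpy as np
import pytest

from conftest import make_bank, make_embeddings, make_logits, make_text
from plantood import (
    AlignmentError,
    EnsembleSpec,
    InputError,
    ParameterError,
    ProtocolError,
    ScoreVector,
    auroc,
    decide,
    energy_score,
    ensemble_score,
    knn_dissimilarity,
    max_logit_score,
    mcm_score,
    minmax_normalize,
)
from plantood.exceptions import DegenerateInputError
from plantood.scoring import MinMaxNormalizer, cpd_score, dsk_score, gk_score

E = math.e


class TestMaxLogit:
    @pytest.mark.parametrize(
        "logits, dialect, expected",
        [
            # symmetry forces a uniform softmax over four classes
            ([[0, 0, 0, 0]], "msp", [-0.25]),
            # raw max-logit is the identity on the row maximum
            ([[1, 1]], "raw_maxlogit", [-1.0]),
            # direct softmax evaluation: e^3 / (e^3 + e^1 + e^0.5)
            (
                [[3, 1, 0.5]],
                "msp",
                [-(E**3) / (E**3 + E**1 + E**0.5)],
            ),
            # the printed linear normalization: 3 / (3 + 1 + 0.5)
            ([[3, 1, 0.5]], "literal", [-3 / 4.5]),
        ],
    )
    def test_closed_form(self, logits, dialect, expected):
        sv = max_logit_score(make_logits(logits), dialect=dialect)
        np.testing.assert_allclose(sv.values, expected, atol=1e-12)
        assert sv.score_kind == "max_logit"
        assert not sv.normalized

    def test_temperature_sharpens_msp(self):
        lm = make_logits([[3, 1, 0.5]])
        cold = max_logit_score(lm, temperature=0.5).values[0]
        hot = max_logit_score(lm, temperature=10.0).values[0]
        assert cold < hot  # colder softmax is more confident, score lower

    def test_literal_zero_sum_rejected(self):
        lm = make_logits([[1.0, -1.0]])
        with pytest.raises(DegenerateInputError, match="s0"):
            max_logit_score(lm, dialect="literal")

    @pytest.mark.parametrize("temperature", [0.0, -1.0, float("nan")])
    def test_bad_temperature(self, temperature):
        with pytest.raises(ParameterError):
            max_logit_score(make_logits([[1, 2]]), temperature=temperature)

    def test_unknown_dialect(self):
        with pytest.raises(ParameterError):
            max_logit_score(make_logits([[1, 2]]), dialect="bogus")


class TestEnergy:
    @pytest.mark.parametrize(
        "logits, T, expected",
        [
            ([[0, 0]], 1.0, [-math.log(2)]),
            ([[5.0]], 1.0, [-5.0]),  # single class: -z/T exactly
            ([[5.0]], 2.0, [-2.5]),
            ([[1, 2, 3]], 1.0, [-math.log(E + E**2 + E**3)]),
        ],
    )
    def test_closed_form(self, logits, T, expected):
        sv = energy_score(make_logits(logits), temperature=T)
        np.testing.assert_allclose(sv.values, expected, atol=1e-12)

    def test_logsumexp_matches_naive(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(-20, 20, size=(50, 7))
        sv = energy_score(make_logits(z))
        naive = -np.log(np.exp(z).sum(axis=1))
        np.testing.assert_allclose(sv.values, naive, atol=1e-9)

    def test_overflow_safe(self):
        sv = energy_score(make_logits([[1000.0, 999.0]]))
        assert np.isfinite(sv.values).all()

    def test_bad_temperature(self):
        with pytest.raises(ParameterError):
            energy_score(make_logits([[1, 2]]), temperature=-1)


class TestMCM:
    def test_one_hot_similarity(self):
        # image equal to one text vector, orthogonal to the other two:
        # sims (1, 0, 0) -> -e / (e + 2)
        text = make_text(np.eye(3))
        img = make_embeddings([[1, 0, 0]])
        sv = mcm_score(img, text)
        np.testing.assert_allclose(sv.values, [-E / (E + 2)], atol=1e-12)

    def test_equidistant_gives_uniform(self):
        text = make_text(np.eye(4, 8))
        img = make_embeddings([np.ones(8)])
        sv = mcm_score(img, text)
        np.testing.assert_allclose(sv.values, [-0.25], atol=1e-12)

    def test_single_class_is_minus_one(self):
        text = make_text([[0.3, 0.4]])
        img = make_embeddings([[5, 1]])
        np.testing.assert_allclose(mcm_score(img, text).values, [-1.0])

    def test_dimension_mismatch(self):
        with pytest.raises(InputError, match="dimension"):
            mcm_score(make_embeddings([[1, 0, 0]]), make_text([[1, 0]]))

    def test_internal_normalization(self):
        # scaling the image vector must not change the cosine scores
        text = make_text(np.eye(3))
        a = mcm_score(make_embeddings([[2, 1, 0]]), text).values
        b = mcm_score(make_embeddings([[20, 10, 0]]), text).values
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestKnnDissimilarity:
    def test_duplicate_of_bank_row(self):
        bank = make_bank([[1, 0], [0, 1]])
        q = make_embeddings([[1, 0]])
        np.testing.assert_allclose(knn_dissimilarity(q, bank).values, [-1.0])

    def test_orthogonal_query(self):
        bank = make_bank([[1, 0, 0]])
        q = make_embeddings([[0, 1, 0]])
        np.testing.assert_allclose(knn_dissimilarity(q, bank).values, [0.0])

    def test_exhaustive_cosine(self):
        # hand oracle: cos with (1,0) = .6, with (0,1) = .8, max = .8
        bank = make_bank([[1, 0], [0, 1]])
        q = make_embeddings([[0.6, 0.8]])
        np.testing.assert_allclose(
            knn_dissimilarity(q, bank).values, [-0.8], atol=1e-12
        )

    def test_range_bounds(self):
        rng = np.random.default_rng(3)
        bank = make_bank(rng.normal(size=(20, 5)))
        q = make_embeddings(rng.normal(size=(30, 5)))
        vals = knn_dissimilarity(q, bank).values
        assert vals.min() >= -1.0 and vals.max() <= 1.0

    def test_space_mismatch_is_protocol_error(self):
        bank = make_bank([[1, 0]], tag="pretrained")
        q = make_embeddings([[1, 0]], tag="finetuned")
        with pytest.raises(ProtocolError, match="space tag"):
            knn_dissimilarity(q, bank)

    def test_empty_bank_rejected_at_construction(self):
        with pytest.raises(InputError):
            make_bank(np.empty((0, 3)))

    def test_zero_row_rejected(self):
        with pytest.raises(InputError, match="zero-norm"):
            make_embeddings([[0.0, 0.0]])


class TestMinMaxNormalize:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3], [0, 0.5, 1]),
            ([5, 5], [0.5, 0.5]),
            ([-1, 1], [0, 1]),
        ],
    )
    def test_examples(self, values, expected):
        sv = ScoreVector([f"s{i}" for i in range(len(values))], values, "energy")
        out = minmax_normalize(sv)
        np.testing.assert_allclose(out.values, expected)
        assert out.normalized

    def test_rank_invariance_preserves_auroc(self):
        rng = np.random.default_rng(11)
        known = rng.normal(size=40)
        unknown = rng.normal(loc=1.0, size=30)
        sv = ScoreVector(
            [f"s{i}" for i in range(70)],
            np.concatenate([known, unknown]),
            "energy",
        )
        norm = minmax_normalize(sv).values
        assert auroc(known, unknown) == pytest.approx(
            auroc(norm[:40], norm[40:]), abs=1e-12
        )

    def test_frozen_normalizer_clips(self):
        fit_on = ScoreVector(["a", "b"], [0.0, 1.0], "energy")
        nm = MinMaxNormalizer.fit(fit_on)
        out = nm.transform(ScoreVector(["c", "d"], [-0.5, 2.0], "energy"))
        np.testing.assert_allclose(out.values, [0.0, 1.0])


class TestCpdDskGk:
    def test_cpd_normalizes_base_scores(self):
        base = ScoreVector(["a", "b", "c"], [-0.9, -0.5, -0.1], "energy")
        out = cpd_score(base)
        np.testing.assert_allclose(out.values, [0, 0.5, 1])
        assert out.score_kind == "cpd" and out.normalized

    def test_cpd_constant_base_degenerates_to_half(self):
        base = ScoreVector(["a", "b"], [2.0, 2.0], "energy")
        np.testing.assert_allclose(cpd_score(base).values, [0.5, 0.5])

    def test_cpd_symmetric_logits(self):
        # mirrored two-class logits produce equal msp base scores
        lm = make_logits([[2, 0], [0, 2]])
        np.testing.assert_allclose(cpd_score(lm, "msp").values, [0.5, 0.5])

    def test_cpd_mcm_requires_text(self):
        from plantood import ConfigurationError

        with pytest.raises(ConfigurationError, match="text"):
            cpd_score(make_embeddings([[1, 0]]), "mcm")

    @pytest.mark.parametrize("fn, tag, kind", [
        (dsk_score, "finetuned", "dsk"),
        (gk_score, "pretrained", "gk"),
    ])
    def test_dsk_gk_normalized_knn(self, fn, tag, kind):
        bank = make_bank([[1, 0], [0, 1]], tag=tag)
        # one duplicate of a bank row, one orthogonal sample
        q = make_embeddings([[1, 0], [-1, 0]], tag=tag)
        out = fn(q, bank)
        assert out.score_kind == kind and out.normalized
        np.testing.assert_allclose(out.values, [0.0, 1.0])

    @pytest.mark.parametrize("fn, wrong_tag", [
        (dsk_score, "pretrained"),
        (gk_score, "finetuned"),
    ])
    def test_dsk_gk_space_guard(self, fn, wrong_tag):
        bank = make_bank([[1, 0]], tag=wrong_tag)
        q = make_embeddings([[1, 0]], tag=wrong_tag)
        with pytest.raises(ProtocolError):
            fn(q, bank)


def _norm_sv(values, kind, ids=None):
    ids = ids or [f"s{i}" for i in range(len(values))]
    return ScoreVector(ids, values, kind, normalized=True)


class TestEnsemble:
    def test_visual_three_way_mean(self):
        out = ensemble_score(
            [_norm_sv([0.2], "cpd"), _norm_sv([0.4], "dsk"),
             _norm_sv([0.6], "gk")],
            EnsembleSpec.visual_three_way(),
        )
        np.testing.assert_allclose(out.values, [0.4])

    def test_vlm_two_way_mean(self):
        out = ensemble_score(
            [_norm_sv([0.3], "dsk"), _norm_sv([0.5], "gk")],
            EnsembleSpec.vlm_two_way(),
        )
        np.testing.assert_allclose(out.values, [0.4])

    def test_idempotent_on_identical_components(self):
        v = [0.1, 0.7, 0.3]
        out = ensemble_score(
            [_norm_sv(v, "cpd"), _norm_sv(v, "dsk"), _norm_sv(v, "gk")],
            EnsembleSpec.visual_three_way(),
        )
        np.testing.assert_allclose(out.values, v)

    def test_component_order_invariance(self):
        comps = [_norm_sv([0.2, 0.9], "cpd"), _norm_sv([0.4, 0.1], "dsk"),
                 _norm_sv([0.6, 0.5], "gk")]
        spec = EnsembleSpec.visual_three_way()
        a = ensemble_score(comps, spec).values
        b = ensemble_score(comps[::-1], spec).values
        np.testing.assert_allclose(a, b)

    def test_permutation_equivariance_in_samples(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(size=(3, 6))
        ids = [f"s{i}" for i in range(6)]
        kinds = ["cpd", "dsk", "gk"]
        spec = EnsembleSpec.visual_three_way()
        base = ensemble_score(
            [ScoreVector(ids, v, k, normalized=True)
             for v, k in zip(vals, kinds)], spec
        )
        perm = rng.permutation(6)
        permuted = ensemble_score(
            [ScoreVector([ids[i] for i in perm], v[perm], k, normalized=True)
             for v, k in zip(vals, kinds)], spec
        )
        np.testing.assert_allclose(base.values[perm], permuted.values)

    def test_unnormalized_component_rejected(self):
        raw = ScoreVector(["s0"], [0.3], "dsk", normalized=False)
        with pytest.raises(ProtocolError, match="not normalized"):
            ensemble_score(
                [raw, _norm_sv([0.5], "gk", ids=["s0"])],
                EnsembleSpec.vlm_two_way(),
            )

    def test_sample_order_mismatch_rejected(self):
        a = ScoreVector(["s0", "s1"], [0.1, 0.2], "dsk", normalized=True)
        b = ScoreVector(["s1", "s0"], [0.3, 0.4], "gk", normalized=True)
        with pytest.raises(AlignmentError):
            ensemble_score([a, b], EnsembleSpec.vlm_two_way())

    def test_wrong_component_set_rejected(self):
        with pytest.raises(ProtocolError):
            ensemble_score(
                [_norm_sv([0.1], "dsk")], EnsembleSpec.vlm_two_way()
            )


class TestDecide:
    def test_threshold_rule(self):
        sv = _norm_sv([0.2, 0.9], "ensemble")
        assert list(decide(sv, 0.5)) == ["known", "unknown"]

    def test_boundary_is_known(self):
        sv = _norm_sv([0.5], "ensemble")
        assert list(decide(sv, 0.5)) == ["known"]

    def test_max_score_threshold_accepts_all(self):
        sv = _norm_sv([0.2, 0.9, 1.0], "ensemble")
        assert list(decide(sv, float(sv.values.max()))) == ["known"] * 3

    def test_nonfinite_lambda(self):
        with pytest.raises(ParameterError):
            decide(_norm_sv([0.5], "ensemble"), float("inf"))


class TestDirectionConvention:
    """A sample identical to a training row never scores above one
    orthogonal to the entire bank, for every feature-matching score."""

    def test_bank_duplicate_scores_lower(self):
        rng = np.random.default_rng(9)
        bank_rows = rng.normal(size=(4, 8))
        bank = make_bank(bank_rows)
        # build an orthogonal direction by Gram-Schmidt against the bank
        q, _ = np.linalg.qr(np.vstack([bank_rows, rng.normal(size=(1, 8))]).T)
        ortho = None
        for i in range(q.shape[1]):
            if np.abs(bank_rows @ q[:, i]).max() < 1e-8:
                ortho = q[:, i]
                break
        assert ortho is not None
        queries = make_embeddings([bank_rows[0], ortho])
        vals = knn_dissimilarity(queries, bank).values
        assert vals[0] < vals[1]
        assert vals[0] == pytest.approx(-1.0)
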