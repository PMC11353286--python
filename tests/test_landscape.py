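import numpy as np
import pytest

from affcom import (
    AffordanceLandscape,
    EncoderMap,
    build_decoder,
    column_expectations,
    estimates,
    induced_joint,
    marginalize,
    metrics_report,
    mse,
    mutual_information,
    row_expectations,
    toy_landscape,
)
from affcom.landscape import render_table_row


class TestLandscapeType:
    def test_rejects_tiny_matrix(self):
        with pytest.raises(ValueError):
            AffordanceLandscape(np.array([[1.0, 2.0]]))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            AffordanceLandscape(np.array([[1.0, np.nan], [0.0, 1.0]]))

    def test_default_axes_are_one_based(self, toy):
        assert toy.row_states.tolist() == [1, 2, 3, 4]
        assert toy.col_states.tolist() == [1, 2, 3, 4]

    def test_csv_round_trip(self, toy, tmp_path):
        path = tmp_path / "A.csv"
        toy.to_csv(path)
        again = AffordanceLandscape.from_csv(path)
        np.testing.assert_allclose(again.matrix, toy.matrix)


class TestEncoderMap:
    def test_total_assignment_required(self):
        with pytest.raises(ValueError, match="cover"):
            EncoderMap.from_blocks([[1, 2]], 4)

    def test_signals_within_range(self):
        with pytest.raises(ValueError):
            EncoderMap(np.array([0, 2]), 2)

    def test_json_round_trip(self, direct_encoders):
        enc = direct_encoders[0]
        again = EncoderMap.from_json_dict(enc.to_json_dict())
        assert again.L == enc.L
        np.testing.assert_array_equal(again.assignment, enc.assignment)


class TestRowExpectations:
    def test_toy_row_means(self, toy):
        np.testing.assert_allclose(row_expectations(toy), [0.5, 0.75, 0.75, 0.5])

    def test_toy_column_means_match_by_symmetry(self, toy):
        np.testing.assert_allclose(column_expectations(toy), [0.5, 0.75, 0.75, 0.5])

    def test_constant_matrix(self):
        land = AffordanceLandscape(np.full((3, 5), 7.0))
        np.testing.assert_allclose(row_expectations(land), 7.0)


class TestDecoder:
    def test_toy_direct_decoded_cell(self, toy_direct_pair):
        assert toy_direct_pair.decoder_table[0, 1] == pytest.approx(0.5)

    def test_toy_indirect_decoded_cell(self, toy_indirect_pair):
        assert toy_indirect_pair.decoder_table[0, 1] == pytest.approx(1.25)

    def test_identity_encoders_recover_matrix(self, toy):
        ident = EncoderMap(np.arange(4), 4)
        pair = build_decoder(toy, ident, ident)
        np.testing.assert_allclose(pair.decoder_table, toy.matrix)
        assert pair.used.all()

    def test_empty_preimage_cells_are_flagged_unused(self, toy):
        # signal 2 of a 3-signal encoder receives no observation
        enc = EncoderMap(np.array([0, 0, 1, 1]), 3)
        pair = build_decoder(toy, enc, enc)
        assert not pair.used[2, :].any()
        assert np.isnan(pair.decoder_table[2, 0])
        # actual cells never address unused entries
        est = estimates(pair, toy)
        assert np.isfinite(est.affordance_estimate).all()

    def test_length_mismatch_rejected(self, toy):
        with pytest.raises(ValueError, match="match"):
            build_decoder(toy, EncoderMap(np.zeros(3, int), 2), EncoderMap(np.zeros(4, int), 2))

    def test_conditional_mean_is_local_mse_minimum(self, toy, toy_direct_pair, toy_indirect_pair):
        # perturbing any used decoder entry by ±ε never decreases the MSE
        for pair in (toy_direct_pair, toy_indirect_pair):
            base = mse(toy.matrix, estimates(pair, toy).affordance_estimate)
            zb = pair.encoder_B.assignment
            zc = pair.encoder_C.assignment
            for i, j in np.argwhere(pair.used):
                for eps in (-1e-3, 1e-3):
                    table = pair.decoder_table.copy()
                    table[i, j] += eps
                    perturbed = table[zb[:, None], zc[None, :]]
                    assert mse(toy.matrix, perturbed) >= base


class TestEstimates:
    def test_direct_sensory_collapse(self, toy, toy_direct_pair):
        np.testing.assert_allclose(estimates(toy_direct_pair, toy).sensory_B, 2.5)

    def test_indirect_sensory_halves(self, toy, toy_indirect_pair):
        np.testing.assert_allclose(
            estimates(toy_indirect_pair, toy).sensory_B, [1.5, 1.5, 3.5, 3.5]
        )

    def test_direct_unidim_estimate_is_exact(self, toy, toy_direct_pair):
        est = estimates(toy_direct_pair, toy)
        np.testing.assert_allclose(est.unidim_B, row_expectations(toy))

    def test_estimate_constant_on_preimage_blocks(self, toy, toy_indirect_pair):
        ahat = estimates(toy_indirect_pair, toy).affordance_estimate
        zb = toy_indirect_pair.encoder_B.assignment
        zc = toy_indirect_pair.encoder_C.assignment
        for i in range(2):
            for j in range(2):
                block = ahat[np.ix_(zb == i, zc == j)]
                assert np.ptp(block) == 0.0


class TestMSE:
    def test_toy_direct(self, toy, toy_direct_pair):
        ahat = estimates(toy_direct_pair, toy).affordance_estimate
        assert mse(toy.matrix, ahat) == pytest.approx(0.4375)

    def test_toy_indirect(self, toy, toy_indirect_pair):
        ahat = estimates(toy_indirect_pair, toy).affordance_estimate
        assert mse(toy.matrix, ahat) == pytest.approx(0.09375)

    def test_perfect_estimate(self, toy):
        assert mse(toy.matrix, toy.matrix) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mse(np.zeros(3), np.zeros(4))


class TestInducedJoint:
    def test_affordance_marginal_frequencies(self, toy, toy_direct_pair):
        joint = induced_joint(toy, toy_direct_pair)
        marg = marginalize(joint, ("A",))
        assert marg.mass[(0.0,)] == pytest.approx(0.5)
        assert marg.mass[(1.0,)] == pytest.approx(0.375)
        assert marg.mass[(2.0,)] == pytest.approx(0.125)

    def test_direct_destroys_sensory_information(self, toy, toy_direct_pair):
        joint = induced_joint(toy, toy_direct_pair)
        assert mutual_information(joint, ("OB",), ("Ahat",)) >= 0  # well-formed
        # Ô^B is a deterministic constant, so I(O^B; Ô^B) = 0 via Z^B
        assert mutual_information(joint, ("OB",), ("ZB",)) == pytest.approx(1.0)

    def test_data_processing_along_markov_chain(self, toy, toy_direct_pair, toy_indirect_pair):
        for pair in (toy_direct_pair, toy_indirect_pair):
            joint = induced_joint(toy, pair)
            i_est = mutual_information(joint, ("A",), ("Ahat",))
            i_obs = mutual_information(joint, ("OB", "OC"), ("A",))
            assert i_est <= i_obs + 1e-9
            i_sig = mutual_information(joint, ("ZB", "ZC"), ("A",))
            assert i_est <= i_sig + 1e-9


class TestMetricsReport:
    def test_toy_direct_row(self, toy, toy_direct_pair):
        report = metrics_report(toy, toy_direct_pair)
        assert render_table_row(report) == (0.44, 0.25, 0.0, 0.0, 1.0, 1.0)
        assert report["mse_affordance"] == pytest.approx(0.4375)
        assert report["spatial_entropy_B"] == pytest.approx(0.0)

    def test_toy_indirect_row(self, toy, toy_indirect_pair):
        report = metrics_report(toy, toy_indirect_pair)
        assert render_table_row(report) == (0.09, 1.0, 1.0, 1.0, 0.0, 0.0)
        assert report["mse_affordance"] == pytest.approx(0.09375)
        # two estimate values 1.5/3.5 at distance 2, equiprobable
        assert report["spatial_entropy_B"] == pytest.approx(2.0)

    def test_lossless_regime(self, toy):
        ident = EncoderMap(np.arange(4), 4)
        report = metrics_report(toy, build_decoder(toy, ident, ident))
        assert report["mse_affordance"] == pytest.approx(0.0)
        assert report["mi_sensory_B"] == pytest.approx(2.0)

    def test_information_tradeoff_between_strategies(self, toy, toy_direct_pair, toy_indirect_pair):
        direct = metrics_report(toy, toy_direct_pair)
        indirect = metrics_report(toy, toy_indirect_pair)
        assert (direct["mi_unidim_B"], direct["mi_sensory_B"]) == (1.0, 0.0)
        assert (indirect["mi_unidim_B"], indirect["mi_sensory_B"]) == (0.0, 1.0)


class TestRefinementMonotonicity:
    def test_splitting_a_preimage_never_hurts(self, toy):
        rng = np.random.default_rng(11)
        for _ in range(10):
            zb = rng.integers(0, 2, size=4)
            zc = rng.integers(0, 2, size=4)
            enc_b = EncoderMap(zb, 2)
            enc_c = EncoderMap(zc, 2)
            pair = build_decoder(toy, enc_b, enc_c)
            base = mse(toy.matrix, estimates(pair, toy).affordance_estimate)
            # split one multi-member preimage of encoder B into two signals
            for sig in range(2):
                members = np.flatnonzero(zb == sig)
                if members.size < 2:
                    continue
                refined = zb.copy()
                refined[members[0]] = 2
                pair2 = build_decoder(toy, EncoderMap(refined, 3), enc_c)
                refined_mse = mse(
                    toy.matrix, estimates(pair2, toy).affordance_estimate
                )
                assert refined_mse <= base + 1e-12
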