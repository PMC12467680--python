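"""Decoders: LDA closed form and calibration, cumulative game scoring,
peak baselines, and leave-one-game-out cross-validation."""

import numpy as np
import pandas as pd
import pytest

from p300select import (CumulativeTargetDecoder, TaskType, extract_features,
                        generate_task_schedule, leave_one_game_out,
                        peak_amplitude_decode, peak_latency_decode,
                        reference_peak_latency, score_game, train_lda)
from p300select.decode import (DEFAULT_TIMEPOINT_INDICES, DecodeError,
                               DecoderModel, TaskResult)

from conftest import make_epochset


# --------------------------------------------------------------------- tools

def toy_model(weights, bias=0.0, gain=1.0, offset=0.0,
              timepoints=(0, 1)):
    w = np.asarray(weights, dtype=float)
    d = len(w)
    return DecoderModel(
        weights=w, bias=bias, mu_target=np.zeros(d), mu_nontarget=np.zeros(d),
        pooled_covariance=np.eye(d), scale_gain=gain, scale_offset=offset,
        timepoint_indices=timepoints,
    )


def game_meta(n_blocks, labels_per_block, target_label=0, game=0):
    rows = []
    for b, labels in enumerate(labels_per_block):
        for s, lab in enumerate(labels):
            rows.append({
                "game_index": game, "block_index": b, "slot_index": s,
                "stimulus_id": lab, "candidate_label": lab,
                "is_target": lab == target_label,
                "game_target_label": target_label,
            })
    return rows


# ------------------------------------------------------------------ features

def test_feature_vector_dimension_and_order(ts_subject):
    _, _, ep = ts_subject
    X = extract_features(ep)
    assert X.shape == (384, 120)
    # single nonzero sample maps to the predicted channel-major position
    data = np.zeros((1, 8, 64))
    ch, tp = 2, 5
    data[0, ch, DEFAULT_TIMEPOINT_INDICES[tp]] = 7.0
    ep1 = make_epochset(data, game_meta(1, [[0, 1, 2, 3, 4, 5, 6, 7]])[:1])
    v = extract_features(ep1)[0]
    assert v.sum() == 7.0 and v[ch * 15 + tp] == 7.0


def test_feature_index_validation(ts_subject):
    _, _, ep = ts_subject
    with pytest.raises(DecodeError):
        extract_features(ep, [0, 64])
    assert extract_features(ep.select(np.zeros(384, bool).__invert__()),
                            [0, 1]).shape[1] == 16


# ----------------------------------------------------------------------- LDA

def test_lda_weights_match_closed_form_oracle():
    """Hand-built 6-point dataset: weights equal explicit mean/covariance
    arithmetic (independently coded below) to 1e-10."""
    X = np.array([[1.0, 2.0], [2.0, 1.0], [1.5, 1.8],
                  [-1.0, -0.5], [-2.0, -1.5], [-1.2, -2.0]])
    y = np.array([True, True, True, False, False, False])

    # oracle: explicit arithmetic, no shared code with the implementation
    mt = X[:3].sum(axis=0) / 3.0
    mn = X[3:].sum(axis=0) / 3.0
    S = np.zeros((2, 2))
    for i in range(3):
        d = X[i] - mt
        S += np.outer(d, d)
    for i in range(3, 6):
        d = X[i] - mn
        S += np.outer(d, d)
    S /= 6 - 2
    w_oracle = np.linalg.solve(S, mt - mn)

    model = train_lda(X, y)
    np.testing.assert_allclose(model.weights, w_oracle, atol=1e-10)
    np.testing.assert_allclose(model.raw_score((mt + mn) / 2.0), 0.0,
                               atol=1e-10)


def test_lda_direction_matches_sklearn():
    """Independent cross-check against scikit-learn's LDA coefficients."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1, (60, 5)) + [2, 0, 1, 0, 0],
                   rng.normal(0, 1, (120, 5))])
    y = np.repeat([True, False], [60, 120])
    model = train_lda(X, y)
    sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
    cos = (model.weights @ sk.coef_[0]) / (
        np.linalg.norm(model.weights) * np.linalg.norm(sk.coef_[0]))
    assert cos > 0.999


def test_lda_weight_direction_isotropic_gaussians():
    rng = np.random.default_rng(1)
    mu = np.array([3.0, -1.0])
    X = np.vstack([rng.normal(0, 1, (500, 2)) + mu,
                   rng.normal(0, 1, (500, 2))])
    y = np.repeat([True, False], 500)
    w = train_lda(X, y).weights
    cos = w @ mu / (np.linalg.norm(w) * np.linalg.norm(mu))
    assert cos > 0.98


def test_scaled_score_calibration_is_exact():
    rng = np.random.default_rng(2)
    X = rng.normal(0, 1, (64, 7))
    y = rng.random(64) < 0.3
    model = train_lda(X, y)
    s = model.score(X)
    assert s[y].mean() == pytest.approx(1.0, abs=1e-12)
    assert s[~y].mean() == pytest.approx(-1.0, abs=1e-12)


def test_lda_degenerate_and_error_paths():
    X = np.ones((6, 3))
    y = np.repeat([True, False], 3)
    with pytest.warns(RuntimeWarning, match="degenerate"):
        model = train_lda(X, y)
    assert np.all(model.weights == 0) and model.degenerate
    with pytest.raises(DecodeError):
        train_lda(np.ones((3, 2)), np.array([True, True, True]))


def test_decoder_model_json_round_trip(tmp_path):
    model = train_lda(np.random.default_rng(3).normal(size=(40, 6)),
                      np.arange(40) % 4 == 0, timepoint_indices=(1, 2, 3))
    p = tmp_path / "model.json"
    model.to_json(p)
    back = DecoderModel.from_json(p)
    np.testing.assert_allclose(back.weights, model.weights)
    assert back.scale_gain == model.scale_gain
    assert back.timepoint_indices == (1, 2, 3)


# ---------------------------------------------------------------- score_game

def test_perfect_scorer_correct_at_every_block():
    """Features equal to ±1 on the first feature: targets score +1."""
    labels = [[3, 0, 1, 2], [1, 2, 3, 0]]
    data = np.zeros((8, 1, 4))
    meta = game_meta(2, labels, target_label=3)
    for i, m in enumerate(meta):
        data[i, 0, 0] = 1.0 if m["is_target"] else -1.0
    ep = make_epochset(data, meta)
    res = score_game(toy_model([1.0, 0.0]), ep)
    assert res.correct_per_block.all()
    assert res.true_label == 3


def test_zero_weights_tie_breaks_to_label_zero():
    labels = [[3, 0, 1, 2]]
    ep = make_epochset(np.zeros((4, 1, 4)), game_meta(1, labels, 2))
    res = score_game(toy_model([0.0, 0.0]), ep)
    assert res.predicted_per_block.tolist() == [0]


def test_cumulative_scores_match_hand_sums():
    """2-block, 3-candidate game with listed scaled scores."""
    labels = [[2, 0, 1], [1, 2, 0]]
    scores = {(0, 2): 0.5, (0, 0): -1.0, (0, 1): 0.25,
              (1, 1): -0.5, (1, 2): 2.0, (1, 0): -0.25}
    data = np.zeros((6, 1, 4))
    meta = game_meta(2, labels, target_label=2)
    for i, m in enumerate(meta):
        data[i, 0, 0] = scores[(m["block_index"], m["candidate_label"])]
    ep = make_epochset(data, meta)
    res = score_game(toy_model([1.0, 0.0]), ep)
    expected = np.array([[-1.0, 0.25, 0.5],
                         [-1.25, -0.25, 2.5]])
    np.testing.assert_allclose(res.cumulative_scores, expected, atol=1e-12)
    assert res.predicted_per_block.tolist() == [2, 2]


def test_cumulative_additivity(ts_subject):
    """Block k+1 evidence equals block k plus that block's contribution."""
    _, _, ep = ts_subject
    game = ep.game(0)
    train = ep.select(ep.trial_meta["game_index"].to_numpy() != 0)
    model = train_lda(extract_features(train),
                      train.trial_meta["is_target"].to_numpy().astype(bool))
    res = score_game(model, game)
    scores = model.score(extract_features(game))
    meta = game.trial_meta
    for k in range(1, res.n_blocks):
        contrib = np.zeros(8)
        rows = meta.index[meta["block_index"] == k]
        for r in rows:
            contrib[meta.at[r, "candidate_label"]] += scores[r]
        np.testing.assert_allclose(
            res.cumulative_scores[k],
            res.cumulative_scores[k - 1] + contrib, atol=1e-9)


# -------------------------------------------------------------- peak methods

def bump(center_idx, amp, n=64, width=4):
    x = np.zeros(n)
    lo = max(center_idx - width, 0)
    hi = min(center_idx + width + 1, n)
    x[lo:hi] = amp * np.cos(
        np.linspace(-np.pi / 2, np.pi / 2, hi - lo)) ** 2
    return x


def test_peak_amplitude_selects_injected_bump():
    labels = [[0, 1, 2], [2, 0, 1]]
    meta = game_meta(2, labels, target_label=1)
    data = np.zeros((6, 2, 64))
    for i, m in enumerate(meta):
        if m["candidate_label"] == 1:
            data[i, :, :] = bump(35, 10.0)  # ~344 ms
    ep = make_epochset(data, meta)
    res = peak_amplitude_decode(ep)
    assert res.correct_per_block.all()


def test_peak_amplitude_tie_and_ranking():
    labels = [[0, 1, 2]]
    meta = game_meta(1, labels, target_label=0)
    ep = make_epochset(np.zeros((3, 1, 64)), meta)
    assert peak_amplitude_decode(ep).predicted_per_block.tolist() == [0]
    # listed maxima 2 < 5 < 9 -> candidate 2 wins
    data = np.zeros((3, 1, 64))
    for i, amp in enumerate([2.0, 5.0, 9.0]):
        data[i, 0] = bump(30 + 3 * i, amp)
    res = peak_amplitude_decode(make_epochset(data, meta))
    assert res.predicted_per_block.tolist() == [2]
    assert res.cumulative_scores[0] == pytest.approx([2.0, 5.0, 9.0])


def test_peak_latency_prefers_reference_aligned_candidate():
    labels = [[0, 1, 2]]
    meta = game_meta(1, labels, target_label=1)
    data = np.zeros((3, 1, 64))
    data[0, 0] = bump(45, 5.0)   # ~500 ms
    data[1, 0] = bump(33, 5.0)   # ~312 ms  <- at reference
    data[2, 0] = bump(40, 5.0)
    ep = make_epochset(data, meta)
    res = peak_latency_decode(ep, model_latency_ref_ms=312.5)
    assert res.predicted_per_block.tolist() == [1]
    # tabulated latencies: |500-312.5|, |312.5-312.5|, |421.9-312.5|
    lat = (np.array([45, 33, 40]) - 13) / 64 * 1000
    np.testing.assert_allclose(res.cumulative_scores[0],
                               -np.abs(lat - 312.5), atol=1e-9)


def test_peak_latency_equidistant_tie_breaks_low():
    labels = [[0, 1, 2]]
    meta = game_meta(1, labels, target_label=2)
    data = np.zeros((3, 1, 64))
    data[0, 0] = bump(30, 5.0)
    data[1, 0] = bump(40, 5.0)  # both 5 samples from ref 35
    data[2, 0] = bump(50, 5.0)
    res = peak_latency_decode(make_epochset(data, meta),
                              model_latency_ref_ms=(35 - 13) / 64 * 1000)
    assert res.predicted_per_block.tolist() == [0]


def test_reference_latency_from_training_targets(separable_subject):
    _, prof, ep = separable_subject
    ref = reference_peak_latency(ep)
    assert abs(ref - prof.late_latency_ms[TaskType.TARGET_SELECTION]) < 40.0


def test_empty_window_rejected(ts_subject):
    _, _, ep = ts_subject
    with pytest.raises(DecodeError):
        peak_amplitude_decode(ep.game(0), search_window_ms=(700, 200))


# ------------------------------------------------------- cross-validation

def test_logo_fold_structure(ts_subject):
    _, _, ep = ts_subject
    res = leave_one_game_out(ep, "pattern_matching")
    assert res.n_games == 8
    assert sorted(g.game_index for g in res.game_results) == list(range(8))
    assert len(res.accuracy_by_block) == 6


def test_logo_perfect_on_separable_subject(separable_subject):
    _, _, ep = separable_subject
    res = CumulativeTargetDecoder(ep, "pattern_matching").fit()
    assert res.success_rate_final == 1.0


def test_logo_requires_two_games():
    from conftest import simulate_epochs
    _, _, ep = simulate_epochs(n_games=2, n_blocks=2)
    one = ep.game(0)
    with pytest.raises(DecodeError):
        leave_one_game_out(one)


def test_task_result_json_and_frame(ts_subject):
    _, _, ep = ts_subject
    res = leave_one_game_out(ep, "peak_amplitude", subject=7)
    back = TaskResult.from_json(res.to_json())
    assert back.success_rate_final == res.success_rate_final
    np.testing.assert_allclose(back.accuracy_by_block, res.accuracy_by_block)
    frame = res.to_frame()
    assert len(frame) == 8 * 6
    assert set(frame["method"]) == {"peak_amplitude"}
    assert "final success rate" in res.summary()
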