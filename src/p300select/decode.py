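"""Single-trial decoders with cumulative 8-candidate evidence.

Three decoding strategies are implemented:

``pattern_matching``
    A binary linear discriminant (target vs non-target) over spatiotemporal
    features — the epoch voltages at 15 time points on all 8 channels
    (120 features).  Weights are the classical closed form
    ``w = S_pooled^+ (mu_t - mu_n)`` without shrinkage (pseudo-inverse for
    rank-deficient pooled covariance), and raw discriminant scores are
    affinely rescaled so the training-set means map to +1 (targets) and
    -1 (non-targets).
``peak_amplitude``
    The maximum voltage of each candidate's channel-averaged, cumulatively
    averaged waveform inside a 200–700 ms search window.
``peak_latency``
    Proximity of each candidate's positive-peak latency to a reference
    latency estimated from training-set target averages.

For every game, per-candidate evidence is accumulated over blocks 1..k and
the candidate with the highest cumulative score at block k is the
prediction (ties break to the lowest label).  Evaluation uses
leave-one-game-out cross-validation: 8 folds, each trained on 7 games.

The user-facing surface follows the model/results idiom:
``CumulativeTargetDecoder(epochs, method=...).fit()`` returns a
:class:`TaskResult` carrying per-game predictions, the block-wise accuracy
curve and a ``summary()`` table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paradigm import TaskType
from .preprocess import EpochSet

__all__ = [
    "DEFAULT_TIMEPOINT_INDICES",
    "PEAK_WINDOW_MS",
    "DecoderModel",
    "GameResult",
    "TaskResult",
    "CumulativeTargetDecoder",
    "extract_features",
    "train_lda",
    "score_game",
    "peak_amplitude_decode",
    "peak_latency_decode",
    "reference_peak_latency",
    "leave_one_game_out",
    "shuffle_candidate_labels",
]

#: 15 equally spaced samples of the 64 Hz epoch grid, 31.25–687.5 ms
#: post-stimulus (every 3rd sample after onset index 13 + 2).
DEFAULT_TIMEPOINT_INDICES = tuple(range(15, 58, 3))

#: Search window of the peak-based decoders, ms post-stimulus.
PEAK_WINDOW_MS = (200.0, 700.0)

METHODS = ("pattern_matching", "peak_amplitude", "peak_latency")


class DecodeError(ValueError):
    pass


# --------------------------------------------------------------------------
# features and the linear discriminant
# --------------------------------------------------------------------------

def extract_features(
    epoch_set: EpochSet,
    timepoint_indices=DEFAULT_TIMEPOINT_INDICES,
) -> np.ndarray:
    """Per-trial feature vectors: voltages at the given sample indices on
    every channel, channel-major order (trials x (channels*timepoints))."""
    idx = np.asarray(timepoint_indices, dtype=int)
    if idx.ndim != 1 or len(idx) == 0:
        raise DecodeError("timepoint_indices must be a non-empty 1-D sequence")
    if idx.min() < 0 or idx.max() >= epoch_set.n_samples:
        raise DecodeError("timepoint index out of epoch sample range")
    # (trials, channels, timepoints) -> channel-major flat vectors
    return epoch_set.data[:, :, idx].reshape(epoch_set.n_trials, -1)


@dataclass
class DecoderModel:
    """A trained discriminant with its ±1 score calibration."""

    weights: np.ndarray
    bias: float
    mu_target: np.ndarray
    mu_nontarget: np.ndarray
    pooled_covariance: np.ndarray
    scale_gain: float
    scale_offset: float
    timepoint_indices: tuple[int, ...] = DEFAULT_TIMEPOINT_INDICES
    channel_names: tuple[str, ...] = ()
    degenerate: bool = False

    def raw_score(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    def score(self, X: np.ndarray) -> np.ndarray:
        """Scaled discriminant scores (training class means at ±1)."""
        return self.scale_gain * self.raw_score(X) + self.scale_offset

    def to_json(self, path=None) -> str:
        payload = {
            "format_version": "1.0",
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "scale_gain": self.scale_gain,
            "scale_offset": self.scale_offset,
            "timepoint_indices": list(self.timepoint_indices),
            "channel_names": list(self.channel_names),
            "degenerate": self.degenerate,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DecoderModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        w = np.asarray(payload["weights"])
        d = len(w)
        return cls(
            weights=w, bias=payload["bias"],
            mu_target=np.full(d, np.nan), mu_nontarget=np.full(d, np.nan),
            pooled_covariance=np.full((d, d), np.nan),
            scale_gain=payload["scale_gain"],
            scale_offset=payload["scale_offset"],
            timepoint_indices=tuple(payload["timepoint_indices"]),
            channel_names=tuple(payload["channel_names"]),
            degenerate=payload.get("degenerate", False),
        )


def train_lda(
    X: np.ndarray,
    y: np.ndarray,
    timepoint_indices=DEFAULT_TIMEPOINT_INDICES,
    channel_names: tuple[str, ...] = (),
) -> DecoderModel:
    """Fit the binary discriminant and its ±1 score scaling.

    ``y`` is boolean (True = target).  Pooled within-class covariance with
    the unbiased ``n - 2`` denominator; a Moore–Penrose pseudo-inverse
    handles rank deficiency without shrinkage.  After fitting, an affine
    map is calibrated so the mean raw score of the training targets goes to
    +1 and of the non-targets to -1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if X.ndim != 2 or len(X) != len(y):
        raise DecodeError("X must be 2-D with one label per row")
    nt, nn = int(y.sum()), int((~y).sum())
    if nt == 0 or nn == 0:
        raise DecodeError("both target and non-target trials are required")

    mu_t = X[y].mean(axis=0)
    mu_n = X[~y].mean(axis=0)
    Xt = X[y] - mu_t
    Xn = X[~y] - mu_n
    pooled = (Xt.T @ Xt + Xn.T @ Xn) / max(nt + nn - 2, 1)

    diff = mu_t - mu_n
    if np.allclose(diff, 0.0):
        warnings.warn("identical class means: degenerate discriminant "
                      "(zero weights)", RuntimeWarning, stacklevel=2)
        d = X.shape[1]
        return DecoderModel(
            weights=np.zeros(d), bias=0.0, mu_target=mu_t, mu_nontarget=mu_n,
            pooled_covariance=pooled, scale_gain=1.0, scale_offset=0.0,
            timepoint_indices=tuple(timepoint_indices),
            channel_names=tuple(channel_names), degenerate=True,
        )

    w = np.linalg.pinv(pooled, rcond=1e-10) @ diff
    bias = -float(w @ (mu_t + mu_n) / 2.0)

    raw = X @ w + bias
    s_t, s_n = float(raw[y].mean()), float(raw[~y].mean())
    gain = 2.0 / (s_t - s_n)
    offset = -gain * (s_t + s_n) / 2.0
    return DecoderModel(
        weights=w, bias=bias, mu_target=mu_t, mu_nontarget=mu_n,
        pooled_covariance=pooled, scale_gain=gain, scale_offset=offset,
        timepoint_indices=tuple(timepoint_indices),
        channel_names=tuple(channel_names),
    )


# --------------------------------------------------------------------------
# per-game cumulative selection
# --------------------------------------------------------------------------

@dataclass
class GameResult:
    """Cumulative candidate evidence and predictions for one game."""

    game_index: int
    cumulative_scores: np.ndarray      # n_blocks x n_candidates
    predicted_per_block: np.ndarray    # argmax per cumulative block count
    true_label: int
    correct_per_block: np.ndarray      # booleans

    @property
    def n_blocks(self) -> int:
        return self.cumulative_scores.shape[0]

    @property
    def final_correct(self) -> bool:
        return bool(self.correct_per_block[-1])


def _game_arrays(epochs: EpochSet):
    """Validate and index one game's epochs by (block, candidate label)."""
    meta = epochs.trial_meta
    games = meta["game_index"].unique()
    if len(games) != 1:
        raise DecodeError("expected epochs restricted to a single game")
    blocks = np.sort(meta["block_index"].unique())
    labels = np.sort(meta["candidate_label"].unique())
    n_labels = len(labels)
    if meta["candidate_label"].isna().any():
        raise DecodeError("missing candidate labels")
    if not np.array_equal(labels, np.arange(n_labels)):
        raise DecodeError("candidate labels must be 0..n-1")
    if "game_target_label" in meta.columns:
        true = meta["game_target_label"].unique()
    else:
        true = meta.loc[meta["is_target"], "candidate_label"].unique()
    if len(true) != 1:
        raise DecodeError("game must have a single target label")
    return int(games[0]), blocks, n_labels, int(true[0])


def _results_from_scores(game, cum, true_label) -> GameResult:
    pred = cum.argmax(axis=1)  # ties -> lowest label
    return GameResult(
        game_index=game, cumulative_scores=cum,
        predicted_per_block=pred, true_label=true_label,
        correct_per_block=pred == true_label,
    )


def score_game(model: DecoderModel, epochs: EpochSet) -> GameResult:
    """Pattern-matching selection: accumulate scaled discriminant scores.

    ``cumulative_scores[k, c]`` sums the scaled scores of all trials with
    candidate label ``c`` in blocks 1..k+1; the block-k prediction is the
    argmax with lowest-label tie-break.
    """
    game, blocks, n_labels, true_label = _game_arrays(epochs)
    scores = model.score(extract_features(epochs, model.timepoint_indices))
    meta = epochs.trial_meta
    per_block = np.zeros((len(blocks), n_labels))
    for i, b in enumerate(blocks):
        rows = meta.index[meta["block_index"] == b]
        for r in rows:
            per_block[i, meta.at[r, "candidate_label"]] += scores[r]
    return _results_from_scores(game, per_block.cumsum(axis=0), true_label)


def _cumulative_waveforms(epochs: EpochSet, blocks, n_labels):
    """Channel-averaged candidate waveforms cumulatively averaged over
    blocks 1..k; returns array (n_blocks, n_labels, n_samples)."""
    meta = epochs.trial_meta
    chan_avg = epochs.data.mean(axis=1)  # trials x samples
    out = np.zeros((len(blocks), n_labels, epochs.n_samples))
    running = np.zeros((n_labels, epochs.n_samples))
    for i, b in enumerate(blocks):
        rows = meta.index[meta["block_index"] == b]
        for r in rows:
            running[meta.at[r, "candidate_label"]] += chan_avg[r]
        out[i] = running / (i + 1)
    return out


def _window_mask(epochs: EpochSet, window_ms) -> np.ndarray:
    lo, hi = window_ms
    if hi <= lo:
        raise DecodeError("empty search window")
    mask = (epochs.times_ms >= lo) & (epochs.times_ms <= hi)
    if not mask.any():
        raise DecodeError("search window contains no samples")
    return mask


def peak_amplitude_decode(
    epochs: EpochSet, search_window_ms=PEAK_WINDOW_MS,
) -> GameResult:
    """Select the candidate with the largest cumulative-average peak voltage."""
    game, blocks, n_labels, true_label = _game_arrays(epochs)
    waves = _cumulative_waveforms(epochs, blocks, n_labels)
    mask = _window_mask(epochs, search_window_ms)
    cum = waves[:, :, mask].max(axis=2)
    return _results_from_scores(game, cum, true_label)


def reference_peak_latency(
    epochs: EpochSet, search_window_ms=PEAK_WINDOW_MS,
) -> float:
    """Positive-peak latency (ms) of the channel-averaged mean target
    waveform — the training-set latency template for peak-latency decoding."""
    tmask = epochs.trial_meta["is_target"].to_numpy().astype(bool)
    if not tmask.any():
        raise DecodeError("no target trials to estimate the reference latency")
    wave = epochs.data[tmask].mean(axis=(0, 1))
    wmask = _window_mask(epochs, search_window_ms)
    times = epochs.times_ms[wmask]
    return float(times[np.argmax(wave[wmask])])


def peak_latency_decode(
    epochs: EpochSet,
    model_latency_ref_ms: float,
    search_window_ms=PEAK_WINDOW_MS,
) -> GameResult:
    """Select the candidate whose peak latency is nearest the reference."""
    game, blocks, n_labels, true_label = _game_arrays(epochs)
    waves = _cumulative_waveforms(epochs, blocks, n_labels)
    mask = _window_mask(epochs, search_window_ms)
    times = epochs.times_ms[mask]
    lat = times[waves[:, :, mask].argmax(axis=2)]
    cum = -np.abs(lat - model_latency_ref_ms)
    return _results_from_scores(game, cum, true_label)


# --------------------------------------------------------------------------
# cross-validation and the model/results surface
# --------------------------------------------------------------------------

@dataclass
class TaskResult:
    """Decoding results of one subject x task x method.

    ``accuracy_by_block[k]`` is the fraction of games decoded correctly from
    cumulative evidence over blocks 1..k+1; ``success_rate_final`` is the
    final-block value (correct games / total games).
    """

    subject: str | int
    task_type: TaskType | None
    method: str
    game_results: list[GameResult]
    accuracy_by_block: np.ndarray = field(init=False)
    success_rate_final: float = field(init=False)

    def __post_init__(self):
        correct = np.stack([g.correct_per_block for g in self.game_results])
        self.accuracy_by_block = correct.mean(axis=0)
        self.success_rate_final = float(self.accuracy_by_block[-1])

    @property
    def n_games(self) -> int:
        return len(self.game_results)

    def to_frame(self) -> pd.DataFrame:
        """Flat per-(game, block) table: subject, task, method, predictions."""
        rows = []
        for g in self.game_results:
            for k in range(g.n_blocks):
                rows.append({
                    "subject": self.subject,
                    "task": self.task_type.value if self.task_type else None,
                    "method": self.method,
                    "game": g.game_index,
                    "block": k + 1,
                    "predicted": int(g.predicted_per_block[k]),
                    "true": g.true_label,
                    "correct": bool(g.correct_per_block[k]),
                })
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {
            "subject": self.subject,
            "task_type": self.task_type.value if self.task_type else None,
            "method": self.method,
            "success_rate_final": self.success_rate_final,
            "accuracy_by_block": self.accuracy_by_block.tolist(),
            "games": [{
                "game_index": g.game_index,
                "true_label": g.true_label,
                "predicted_per_block": g.predicted_per_block.tolist(),
                "correct_per_block": g.correct_per_block.tolist(),
                "cumulative_scores": g.cumulative_scores.tolist(),
            } for g in self.game_results],
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TaskResult":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        games = [GameResult(
            game_index=g["game_index"],
            cumulative_scores=np.asarray(g["cumulative_scores"]),
            predicted_per_block=np.asarray(g["predicted_per_block"]),
            true_label=g["true_label"],
            correct_per_block=np.asarray(g["correct_per_block"], dtype=bool),
        ) for g in payload["games"]]
        task = payload["task_type"]
        return cls(
            subject=payload["subject"],
            task_type=TaskType(task) if task else None,
            method=payload["method"],
            game_results=games,
        )

    def summary(self) -> str:
        lines = [
            "Cumulative target decoding",
            "==========================",
            f"subject:            {self.subject}",
            f"task:               {self.task_type.value if self.task_type else '?'}",
            f"method:             {self.method}",
            f"games:              {self.n_games}",
            f"final success rate: {self.success_rate_final:.3f}",
            "accuracy by block:  " + "  ".join(
                f"{k + 1}:{a:.3f}" for k, a in enumerate(self.accuracy_by_block)),
        ]
        return "\n".join(lines)


def leave_one_game_out(
    epoch_set: EpochSet,
    method: str = "pattern_matching",
    subject: str | int = 0,
    timepoint_indices=DEFAULT_TIMEPOINT_INDICES,
    search_window_ms=PEAK_WINDOW_MS,
) -> TaskResult:
    """Leave-one-game-out cross-validated decoding of one subject's task.

    Per fold, the held-out game is decoded by a decoder whose trainable
    parts (discriminant weights and ±1 calibration, or the reference peak
    latency) come from the remaining games only.  The peak-amplitude rule
    has no trainable part but is evaluated through the same folds.
    """
    if method not in METHODS:
        raise DecodeError(f"unknown method {method!r}; pick one of {METHODS}")
    games = epoch_set.games
    if len(games) < 2:
        raise DecodeError("leave-one-game-out needs at least 2 games")

    game_results = []
    for g in games:
        test = epoch_set.game(int(g))
        train_mask = epoch_set.trial_meta["game_index"].to_numpy() != g
        if method == "pattern_matching":
            train = epoch_set.select(train_mask)
            model = train_lda(
                extract_features(train, timepoint_indices),
                train.trial_meta["is_target"].to_numpy().astype(bool),
                timepoint_indices=timepoint_indices,
                channel_names=epoch_set.channel_names,
            )
            game_results.append(score_game(model, test))
        elif method == "peak_amplitude":
            game_results.append(peak_amplitude_decode(test, search_window_ms))
        else:
            ref = reference_peak_latency(
                epoch_set.select(train_mask), search_window_ms)
            game_results.append(peak_latency_decode(test, ref, search_window_ms))
    return TaskResult(
        subject=subject, task_type=epoch_set.task_type,
        method=method, game_results=game_results,
    )


class CumulativeTargetDecoder:
    """Model object: an 8-alternative ERP target decoder for one subject.

    Parameters
    ----------
    epoch_set : EpochSet
        Preprocessed single-trial epochs of one subject and task, carrying
        game/block/candidate metadata.
    method : str
        ``pattern_matching`` (LDA), ``peak_amplitude`` or ``peak_latency``.
    timepoint_indices : sequence of int
        Epoch sample indices used as LDA features (default: 15 points,
        31.25–687.5 ms).
    search_window_ms : (float, float)
        Peak search window of the peak-based decoders.

    ``fit()`` runs leave-one-game-out cross-validation and returns a
    :class:`TaskResult`.
    """

    def __init__(self, epoch_set: EpochSet, method: str = "pattern_matching",
                 subject: str | int = 0,
                 timepoint_indices=DEFAULT_TIMEPOINT_INDICES,
                 search_window_ms=PEAK_WINDOW_MS):
        if method not in METHODS:
            raise DecodeError(f"unknown method {method!r}")
        self.epoch_set = epoch_set
        self.method = method
        self.subject = subject
        self.timepoint_indices = tuple(timepoint_indices)
        self.search_window_ms = tuple(search_window_ms)

    def fit(self) -> TaskResult:
        return leave_one_game_out(
            self.epoch_set, method=self.method, subject=self.subject,
            timepoint_indices=self.timepoint_indices,
            search_window_ms=self.search_window_ms,
        )

    def train_full(self) -> DecoderModel:
        """Train the discriminant on *all* games (no held-out game); only
        meaningful for ``pattern_matching``."""
        if self.method != "pattern_matching":
            raise DecodeError("train_full applies to pattern_matching only")
        X = extract_features(self.epoch_set, self.timepoint_indices)
        y = self.epoch_set.trial_meta["is_target"].to_numpy().astype(bool)
        return train_lda(X, y, timepoint_indices=self.timepoint_indices,
                         channel_names=self.epoch_set.channel_names)


def shuffle_candidate_labels(
    epoch_set: EpochSet, rng: np.random.Generator,
) -> EpochSet:
    """Permute candidate labels independently within each block (null model).

    Target/non-target flags and the games' true labels stay untouched, so
    decoded evidence no longer points at the true label and accuracy drops
    to chance (1 / n_candidates).
    """
    meta = epoch_set.trial_meta.copy()
    for (_, _), rows in meta.groupby(["game_index", "block_index"]).groups.items():
        labels = meta.loc[rows, "candidate_label"].to_numpy()
        meta.loc[rows, "candidate_label"] = rng.permutation(labels)
    return EpochSet(
        data=epoch_set.data, sample_rate_hz=epoch_set.sample_rate_hz,
        times_ms=epoch_set.times_ms, trial_meta=meta,
        channel_names=epoch_set.channel_names, task_type=epoch_set.task_type,
    )
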