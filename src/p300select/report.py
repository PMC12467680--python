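"""Cohort-level summaries: grand-average ERPs, mean amplitudes,
success-rate statistics and accuracy-by-block curves.

Grand averages weight subjects equally (subject-level averages first, then
the mean across subjects).  Mean ERP amplitude is the time-mean of the
channel-averaged waveform over 100–700 ms post-stimulus.  Accuracy tables
test each (task, method) cell against the theoretical chance level of the
8-alternative problem with a one-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decode import TaskResult
from .paradigm import TaskType
from .preprocess import EpochSet

__all__ = [
    "ERPSummary",
    "grand_average",
    "mean_amplitude",
    "accuracy_summary",
    "accuracy_by_block_curve",
    "plot_accuracy_by_block",
    "plot_grand_average",
]

AMPLITUDE_WINDOW_MS = (100.0, 700.0)


class ReportError(ValueError):
    pass


@dataclass
class ERPSummary:
    """Grand-average ERP of one condition (task x target/non-target)."""

    task_type: TaskType | None
    is_target: bool
    waveform: np.ndarray          # channels x samples, µV
    times_ms: np.ndarray
    channel_names: tuple[str, ...]
    n_trials: int
    n_subjects: int
    mean_amplitude_100_700: float


def mean_amplitude(
    waveform: np.ndarray, times_ms: np.ndarray,
    window_ms=AMPLITUDE_WINDOW_MS,
) -> float:
    """Time-mean of the channel-averaged waveform over the window (µV)."""
    mask = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not mask.any():
        raise ReportError("amplitude window contains no samples")
    return float(waveform.mean(axis=0)[mask].mean())


def grand_average(
    epoch_sets: list[EpochSet],
    is_target: bool = True,
) -> ERPSummary:
    """Equal-subject-weight grand average over a list of per-subject epochs.

    Each EpochSet is reduced to its subject-level mean over the selected
    condition first; the grand average is the mean of those.
    """
    if not epoch_sets:
        raise ReportError("no epoch sets given")
    ref = epoch_sets[0]
    subj_means = []
    n_trials = 0
    for es in epoch_sets:
        if es.data.shape[1:] != ref.data.shape[1:] or not np.allclose(
                es.times_ms, ref.times_ms):
            raise ReportError("incompatible channel/sample grids")
        mask = es.trial_meta["is_target"].to_numpy().astype(bool)
        if not is_target:
            mask = ~mask
        if not mask.any():
            raise ReportError("a subject has no trials in the condition")
        subj_means.append(es.data[mask].mean(axis=0))
        n_trials += int(mask.sum())
    wave = np.mean(subj_means, axis=0)
    return ERPSummary(
        task_type=ref.task_type, is_target=is_target,
        waveform=wave, times_ms=ref.times_ms,
        channel_names=ref.channel_names,
        n_trials=n_trials, n_subjects=len(epoch_sets),
        mean_amplitude_100_700=mean_amplitude(wave, ref.times_ms),
    )


def _one_sample_t(values: np.ndarray, popmean: float):
    """One-sample two-sided t-test, explicit formula.

    Returns (t, df, p); a zero-variance sample off the population mean
    gives an infinite t (with p = 0) rather than an error.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    df = n - 1
    sd = values.std(ddof=1)
    mean = values.mean()
    if sd == 0.0:
        if mean == popmean:
            return 0.0, df, 1.0
        return float(np.sign(mean - popmean) * np.inf), df, 0.0
    t = (mean - popmean) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def accuracy_summary(
    results: list[TaskResult],
    chance: float = 0.125,
) -> pd.DataFrame:
    """Per (task, method): mean/SD of final success rates + t-test vs chance.

    Columns: task, method, n, mean_accuracy, sd, t, df, p, note.  The note
    flags degenerate (zero-variance) cells where t is infinite.
    """
    if len(results) < 2:
        raise ReportError("need results from at least 2 subjects")
    df = pd.DataFrame([{
        "task": r.task_type.value if r.task_type else None,
        "method": r.method,
        "subject": r.subject,
        "accuracy": r.success_rate_final,
    } for r in results])
    rows = []
    for (task, method), grp in df.groupby(["task", "method"], sort=True):
        acc = grp["accuracy"].to_numpy()
        t, dof, p = _one_sample_t(acc, chance)
        rows.append({
            "task": task, "method": method, "n": len(acc),
            "mean_accuracy": acc.mean(), "sd": acc.std(ddof=1),
            "t": t, "df": dof, "p": p,
            "note": "zero variance" if np.isinf(t) else "",
        })
    return pd.DataFrame(rows)


def accuracy_by_block_curve(results: list[TaskResult]) -> pd.DataFrame:
    """Mean ± SD of per-subject accuracy at each cumulative block count.

    Grouped by (task, method); all results must share a block count.
    """
    if not results:
        raise ReportError("no results given")
    n_blocks = {len(r.accuracy_by_block) for r in results}
    if len(n_blocks) != 1:
        raise ReportError("ragged block counts across results")
    rows = []
    df = pd.DataFrame([{
        "task": r.task_type.value if r.task_type else None,
        "method": r.method,
        "curve": r.accuracy_by_block,
    } for r in results])
    for (task, method), grp in df.groupby(["task", "method"], sort=True):
        curves = np.stack(grp["curve"].to_list())
        for k in range(curves.shape[1]):
            rows.append({
                "task": task, "method": method, "block": k + 1,
                "mean_accuracy": curves[:, k].mean(),
                "sd": curves[:, k].std(ddof=1) if len(curves) > 1 else 0.0,
                "n": len(curves),
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# plotting
# --------------------------------------------------------------------------

def plot_accuracy_by_block(curve_table: pd.DataFrame, chance: float = 0.125,
                           ax=None):
    """Accuracy-vs-cumulative-block curves with SD error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (task, method), grp in curve_table.groupby(["task", "method"]):
        ax.errorbar(grp["block"], grp["mean_accuracy"], yerr=grp["sd"],
                    marker="o", capsize=3, label=f"{task} / {method}")
    ax.axhline(chance, ls="--", color="grey", label="chance")
    ax.set_xlabel("cumulative blocks")
    ax.set_ylabel("decoding accuracy")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize="small")
    return ax


def plot_grand_average(summaries: list[ERPSummary], ax=None):
    """Channel-averaged grand-average waveforms per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for s in summaries:
        label = (f"{s.task_type.value if s.task_type else '?'} / "
                 f"{'target' if s.is_target else 'non-target'}")
        ax.plot(s.times_ms, s.waveform.mean(axis=0), label=label)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time from stimulus onset (ms)")
    ax.set_ylabel("voltage (µV)")
    ax.legend(fontsize="small")
    return ax
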