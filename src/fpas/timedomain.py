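"""Target-locked ERP analysis.

The time-domain branch runs at the 512 Hz acquisition rate: the
band-pass/notch-filtered continuous data get an extra notch at the base
presentation rate and its harmonics (2.5, 5, 7.5 Hz) so that activity
merely tracking sound presentation is removed, then 800 ms epochs are
cut around each target onset (one base cycle of pre-target baseline),
artifactual epochs are rejected, epoch counts are equalized across
cells, per-participant averages are baseline-corrected, and the
intact-vs-scrambled difference is tested point by point with FDR across
channels and a consecutive-significance duration criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .freqtag import bh_fdr, round_samples
from .io import EEGRecording
from .sequences import SequenceSpec, StimulusSequence

#: epoch window relative to target onset (s): one base cycle before the
#: target to the end of the 400 ms target slot
EPOCH_WINDOW_S = (-0.4, 0.4)
#: amplitude-rejection threshold (uV); epochs with any |sample| strictly
#: above it are deleted (a sample exactly at the threshold is kept)
REJECT_UV = 100.0
#: minimum duration of a significant intact-vs-scrambled difference (ms)
MIN_SIG_DURATION_MS = 25.0


@dataclass
class EpochSet:
    """Target-locked epochs of one condition/type cell."""

    epochs: np.ndarray                  # trials x channels x samples, uV
    rate: int
    channel_names: list[str]
    window_s: tuple[float, float] = EPOCH_WINDOW_S
    condition: str = ""
    ctype: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x samples")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_pre(self) -> int:
        return round_samples(-self.window_s[0], self.rate)

    def times(self) -> np.ndarray:
        return np.arange(self.epochs.shape[2]) / self.rate + self.window_s[0]

    def average(self) -> np.ndarray:
        return self.epochs.mean(axis=0)


def notch_base(rec: EEGRecording,
               freqs: tuple[float, ...] = (2.5, 5.0, 7.5),
               width_hz: float = 0.5) -> EEGRecording:
    """Zero-phase notches at the base presentation rate and harmonics."""
    if rec.rate <= 2 * max(freqs):
        raise ValueError("sampling rate too low for the requested notches")
    out = rec.copy()
    sos = np.vstack([signal.butter(2, [f - width_hz / 2, f + width_hz / 2],
                                   btype="bandstop", fs=rec.rate,
                                   output="sos") for f in freqs])
    out.data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return out


def extract_target_epochs(trial: EEGRecording, seq,
                          drop_edge: int = 2,
                          reject_uv: float = REJECT_UV,
                          condition: str = "", ctype: str = "") -> EpochSet:
    """Cut one 800 ms epoch per target slot of a segmented trial.

    The trial must carry its sequence-onset event.  The first and last
    ``drop_edge`` target epochs are deleted (fade-in/out), then epochs
    with any |amplitude| exceeding ``reject_uv`` are rejected.
    """
    spec = seq.spec if isinstance(seq, StimulusSequence) else seq
    if not isinstance(spec, SequenceSpec):
        raise TypeError("seq must be a StimulusSequence or SequenceSpec")
    if not trial.events:
        raise ValueError("trial carries no sequence-onset event")
    onset_sample = trial.events[0][0]
    slot = spec.stim_dur + spec.isi
    n_samp = round_samples(EPOCH_WINDOW_S[1] - EPOCH_WINDOW_S[0], trial.rate)
    epochs = []
    for pos in range(3, spec.n_slots + 1, 3):
        t_onset = (pos - 1) * slot
        start = onset_sample + round_samples(t_onset + EPOCH_WINDOW_S[0],
                                             trial.rate)
        if start < 0 or start + n_samp > trial.n_samples:
            raise ValueError(f"epoch for target slot {pos} exceeds trial")
        epochs.append(trial.data[:, start:start + n_samp])
    epochs = np.array(epochs)
    if drop_edge:
        epochs = epochs[drop_edge:-drop_edge]
    keep = np.max(np.abs(epochs), axis=(1, 2)) <= reject_uv
    epochs = epochs[keep]
    if len(epochs) == 0:
        raise ValueError("no epochs survive amplitude rejection")
    return EpochSet(epochs, trial.rate, list(trial.channel_names),
                    condition=condition, ctype=ctype)


def concatenate_epochs(sets: list[EpochSet]) -> EpochSet:
    """Pool the epochs of several trials of one cell."""
    if not sets:
        raise ValueError("no epoch sets to concatenate")
    first = sets[0]
    return EpochSet(np.concatenate([s.epochs for s in sets], axis=0),
                    first.rate, list(first.channel_names),
                    first.window_s, first.condition, first.ctype)


def equalize_epoch_counts(cells: dict, seed: int = 0) -> dict:
    """Subsample every cell (without replacement, seeded) to the minimum
    epoch count across cells."""
    n_min = min(s.n_epochs for s in cells.values())
    rng = np.random.default_rng(seed)
    out = {}
    for key in sorted(cells, key=str):
        s = cells[key]
        idx = np.sort(rng.choice(s.n_epochs, n_min, replace=False))
        out[key] = EpochSet(s.epochs[idx], s.rate, list(s.channel_names),
                            s.window_s, s.condition, s.ctype)
    return out


def baseline_correct(epochs: np.ndarray, n_pre: int) -> np.ndarray:
    """Subtract the mean of the pre-target window (first ``n_pre``
    samples) per epoch and channel; idempotent."""
    epochs = np.asarray(epochs, dtype=float)
    baseline = epochs[..., :n_pre].mean(axis=-1, keepdims=True)
    return epochs - baseline


def pointwise_test(intact_by_participant: np.ndarray,
                   scrambled_by_participant: np.ndarray,
                   rate: int,
                   channel_names: list[str] | None = None,
                   min_dur_ms: float = MIN_SIG_DURATION_MS,
                   q: float = 0.05,
                   window_start_s: float = EPOCH_WINDOW_S[0]
                   ) -> pd.DataFrame:
    """Point-by-point paired one-tailed test (intact > scrambled).

    Inputs are per-participant averaged epochs, participants x channels
    x samples, paired across types.  At each time point a paired t-test
    runs per channel with Benjamini-Hochberg FDR across channels; runs
    of significant points strictly longer than ``min_dur_ms`` (25 ms =
    13 points at 512 Hz, so >= 14 consecutive points) are reported as
    significant windows with their peak t and latency.
    """
    intact = np.asarray(intact_by_participant, dtype=float)
    scram = np.asarray(scrambled_by_participant, dtype=float)
    if intact.shape != scram.shape:
        raise ValueError("paired arrays must share shape")
    n_part, n_ch, n_samp = intact.shape
    if n_part < 2:
        raise ValueError("need at least two participants")
    diff = intact - scram
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = mean / (sd / np.sqrt(n_part))
    tval = np.nan_to_num(tval, nan=0.0, posinf=np.inf, neginf=-np.inf)
    pval = stats.t.sf(tval, df=n_part - 1)
    sig = np.zeros_like(pval, dtype=bool)
    for j in range(n_samp):                    # FDR across channels per point
        sig[:, j] = bh_fdr(pval[:, j], q)

    min_run = round_samples(min_dur_ms / 1000.0, rate)   # strictly more than
    rows = []
    times = np.arange(n_samp) / rate + window_start_s
    for ch in range(n_ch):
        mask = sig[ch]
        j = 0
        while j < n_samp:
            if mask[j]:
                k = j
                while k < n_samp and mask[k]:
                    k += 1
                if k - j > min_run:
                    peak = j + int(np.argmax(tval[ch, j:k]))
                    rows.append({
                        "channel": channel_names[ch] if channel_names
                        else ch,
                        "start_s": times[j], "end_s": times[k - 1],
                        "n_points": k - j,
                        "peak_t": tval[ch, peak],
                        "peak_time_s": times[peak],
                        "peak_mean_uv": mean[ch, peak],
                    })
                j = k
            else:
                j += 1
    return pd.DataFrame(rows, columns=["channel", "start_s", "end_s",
                                       "n_points", "peak_t", "peak_time_s",
                                       "peak_mean_uv"])
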