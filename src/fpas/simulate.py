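"""Synthetic EEG and behavior with the structure the analysis assumes.

The response model is the one a frequency-tagging analysis presumes:
steady-state sinusoids at the base rate (2.5 Hz) and its harmonics, a
weaker steady-state response at the target rate (0.833 Hz) and its
non-base-coincident harmonics with smooth scalp topographies, transient
ERP components locked to target onsets, and spatially correlated 1/f^a
Gaussian noise.  The scrambled sequence type carries the same signal
scaled by a gain in [0, 1]; per-participant multiplicative gains add
realistic between-subject variability.

All randomness is seeded and reproducible: the recording for a given
(spec seed, participant, type, trial) is bit-identical across calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .freqtag import BASE_RATE_HZ, TARGET_RATE_HZ, round_samples
from .io import EEGRecording, biosemi128_layout, save_recording, \
    save_manifest
from .sequences import SequenceSpec, StimulusSequence

#: harmonic multiples of the target rate that do not coincide with the
#: base rate (multiples of 3 are excluded): 0.833, 1.666, 3.333, ... Hz
TARGET_HARMONIC_MULTIPLES = (1, 2, 4, 5, 7)


@dataclass(frozen=True)
class ERPComponent:
    """A Gaussian transient locked to target onsets.

    latency_s : peak latency after target onset
    width_s   : full width at half maximum
    amp_uv    : peak amplitude at the topography maximum
    """

    latency_s: float
    width_s: float
    amp_uv: float


@dataclass
class SimulationSpec:
    """Parameters of the synthetic EEG generator.

    Amplitudes are in microvolts at the topography maximum.  The default
    response amplitudes are set so that a single participant's averaged
    trials carry a clearly detectable tagged response (per-harmonic
    spectral SNR of roughly 5-20), with 1/f noise of realistic broadband
    RMS.  ``scrambled_gain`` scales every stimulus-driven component in
    the scrambled sequence type.
    """

    base_amp: tuple[float, ...] = (2.5, 1.2, 0.6)
    target_amp: tuple[float, ...] = (2.0, 1.5, 1.0, 0.7, 0.4)
    erp_components: tuple[ERPComponent, ...] = (
        ERPComponent(0.152, 0.050, 0.7),
        ERPComponent(0.339, 0.090, 0.8),
    )
    noise_sigma: float = 6.0            # uV broadband per channel
    noise_exponent: float = 1.0         # power ~ 1/f^alpha
    scrambled_gain: float = 0.6
    n_participants: int = 24
    participant_gain_sd: float = 0.2    # lognormal sigma
    phase_jitter_sd: float = 0.25       # rad, across participants
    rate: int = 512
    seed: int = 0
    base_topo: np.ndarray | None = None
    target_topo: np.ndarray | None = None
    erp_topo: np.ndarray | None = None
    spatial_scale_m: float = 0.06       # noise correlation length

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.base_amp + self.target_amp):
            raise ValueError("amplitudes must be non-negative")
        if not 0.0 <= self.scrambled_gain <= 1.0:
            raise ValueError("scrambled_gain must lie in [0, 1]")
        if self.rate not in (512, 256):
            raise ValueError("rate must be 512 or 256 Hz")


# ---------------------------------------------------------------------------
# Layout, topographies, noise
# ---------------------------------------------------------------------------

_LAYOUT_CACHE: dict = {}


def _layout() -> tuple[list[str], np.ndarray]:
    if "layout" not in _LAYOUT_CACHE:
        _LAYOUT_CACHE["layout"] = biosemi128_layout()
    return _LAYOUT_CACHE["layout"]


def _gaussian_map(positions: np.ndarray, center: np.ndarray,
                  scale: float) -> np.ndarray:
    d2 = np.sum((positions - center) ** 2, axis=1)
    w = np.exp(-d2 / (2 * scale**2))
    return w / w.max()


def _center_scalp_map(w: np.ndarray, n_scalp: int = 128) -> np.ndarray:
    """Mean-center a map over the scalp channels and renormalize to peak 1.

    EEG fields integrate to approximately zero over the scalp, and the
    frequency-domain pipeline works on average-referenced data, which
    removes any common mode; a zero-mean topography makes the injected
    peak amplitude invariant under average referencing.  Mastoid rows
    (beyond ``n_scalp``) are set to zero (far-field reference sites).
    """
    out = w.copy()
    out[:n_scalp] -= out[:n_scalp].mean()
    out[n_scalp:] = 0.0
    return out / out.max()


def default_topographies(positions: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth default scalp maps (base: vertex; target: right temporal
    plus a weaker left temporal lobe; ERP: fronto-central), each
    mean-centered over the 128 scalp channels with peak weight 1."""
    base = _gaussian_map(positions, np.array([0.0, 0.0, 0.11]), 0.07)
    target = np.maximum(
        _gaussian_map(positions, np.array([0.075, -0.02, 0.02]), 0.05),
        0.6 * _gaussian_map(positions, np.array([-0.075, -0.02, 0.02]), 0.05))
    erp = _gaussian_map(positions, np.array([0.0, 0.03, 0.10]), 0.06)
    return (_center_scalp_map(base), _center_scalp_map(target),
            _center_scalp_map(erp))


def _mixing_matrix(positions: np.ndarray, scale: float) -> np.ndarray:
    """Cholesky factor of a smooth distance-based spatial covariance, row
    -normalized so mixed channels keep unit variance."""
    key = ("mix", positions.shape[0], round(scale, 6))
    if key not in _LAYOUT_CACHE:
        d2 = np.sum((positions[:, None] - positions[None]) ** 2, axis=-1)
        cov = np.exp(-d2 / (2 * scale**2)) + 1e-6 * np.eye(len(positions))
        chol = np.linalg.cholesky(cov)
        chol /= np.linalg.norm(chol, axis=1, keepdims=True)
        _LAYOUT_CACHE[key] = chol
    return _LAYOUT_CACHE[key]


def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               rate: float, sigma: float, exponent: float,
               mixing: np.ndarray | None = None,
               f_floor: float = 0.1) -> np.ndarray:
    """Spatially correlated 1/f^a Gaussian noise, unit-SD rows * sigma.

    White Gaussian noise is spectrally shaped with amplitude weights
    f^(-a/2) (flattened below ``f_floor`` to keep finite power), then
    mixed across channels and rescaled to per-channel SD ``sigma``.
    """
    from scipy.fft import irfft, next_fast_len, rfft
    n_fft = next_fast_len(n_samples)       # pad: raw lengths can be near-prime
    white = rng.standard_normal((n_channels, n_fft))
    if exponent != 0.0:
        freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
        w = np.empty_like(freqs)
        w[0] = 0.0
        w[1:] = np.maximum(freqs[1:], f_floor) ** (-exponent / 2.0)
        shaped = irfft(rfft(white, axis=1) * w, n=n_fft,
                       axis=1)[:, :n_samples]
    else:
        shaped = white[:, :n_samples]
    if mixing is not None:
        shaped = mixing @ shaped
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd * sigma


# ---------------------------------------------------------------------------
# Recording simulation
# ---------------------------------------------------------------------------

def _sequence_spec(seq) -> SequenceSpec:
    if isinstance(seq, StimulusSequence):
        return seq.spec
    if isinstance(seq, SequenceSpec):
        return seq
    raise TypeError("seq must be a StimulusSequence or SequenceSpec")


def participant_params(spec: SimulationSpec, participant: int) -> dict:
    """Per-participant gain and response phases.

    Phases are common across the group up to a small jitter (evoked
    responses share latency across people), and fixed across that
    participant's trials so time-domain averaging is coherent.
    """
    rng_common = np.random.default_rng([spec.seed, 101])
    common_base = rng_common.uniform(0, 2 * np.pi, len(spec.base_amp))
    common_target = rng_common.uniform(0, 2 * np.pi, len(spec.target_amp))
    rng = np.random.default_rng([spec.seed, 211, participant])
    return {
        "gain": float(np.exp(rng.normal(0.0, spec.participant_gain_sd))),
        "base_phase": common_base + rng.normal(0, spec.phase_jitter_sd,
                                               len(spec.base_amp)),
        "target_phase": common_target + rng.normal(0, spec.phase_jitter_sd,
                                                   len(spec.target_amp)),
    }


def simulate_recording(seq, spec: SimulationSpec,
                       condition: str = "intact", participant: int = 0,
                       trial: int = 0) -> EEGRecording:
    """Simulate one continuous recording containing one sequence.

    The recording spans 2 s + sequence duration + 2 s (61.6 s with the
    default design) with an event marker at sequence onset.  Steady-state
    components follow the stimulus volume (including the 2 s fades); ERP
    components are locked to target onsets.  ``condition`` is the
    sequence type: ``intact`` (gain 1) or ``scrambled``
    (gain ``scrambled_gain``).
    """
    if condition not in ("intact", "scrambled"):
        raise ValueError("condition must be 'intact' or 'scrambled'")
    seq_spec = _sequence_spec(seq)
    rate = spec.rate
    pre_s = post_s = 2.0
    n = round_samples(pre_s + seq_spec.duration + post_s, rate)
    names, positions = _layout()
    n_ch = len(names)

    base_topo, target_topo, erp_topo = default_topographies(positions)
    if spec.base_topo is not None:
        base_topo = np.asarray(spec.base_topo, dtype=float)
    if spec.target_topo is not None:
        target_topo = np.asarray(spec.target_topo, dtype=float)
    if spec.erp_topo is not None:
        erp_topo = np.asarray(spec.erp_topo, dtype=float)

    pp = participant_params(spec, participant)
    g = 1.0 if condition == "intact" else spec.scrambled_gain
    gain = pp["gain"]

    t = np.arange(n) / rate
    ts = t - pre_s                       # time relative to sequence onset
    # stimulation volume envelope: fades mirror the audio fades
    vol = np.clip(ts / seq_spec.fade, 0, 1) \
        * np.clip((seq_spec.duration - ts) / seq_spec.fade, 0, 1)
    vol[(ts < 0) | (ts > seq_spec.duration)] = 0.0

    drive = np.zeros(n)
    for k, amp in enumerate(spec.base_amp):
        drive_k = amp * np.cos(2 * np.pi * (k + 1) * seq_spec.base_rate * ts
                               + pp["base_phase"][k])
        drive += drive_k
    signal = gain * np.outer(base_topo, drive * vol)

    tdrive = np.zeros(n)
    for j, amp in enumerate(spec.target_amp):
        m = TARGET_HARMONIC_MULTIPLES[j] if j < len(TARGET_HARMONIC_MULTIPLES) \
            else j + 1
        tdrive += amp * np.cos(2 * np.pi * m * seq_spec.target_rate * ts
                               + pp["target_phase"][j])
    signal += gain * g * np.outer(target_topo, tdrive * vol)

    # transient components at each target onset
    if spec.erp_components:
        onsets = [(p - 1) * (seq_spec.stim_dur + seq_spec.isi)
                  for p in range(3, seq_spec.n_slots + 1, 3)]
        erp_drive = np.zeros(n)
        for comp in spec.erp_components:
            sd = comp.width_s / 2.355          # FWHM -> Gaussian SD
            for onset in onsets:
                center = pre_s + onset + comp.latency_s
                i0 = max(0, int((center - 4 * sd) * rate))
                i1 = min(n, int((center + 4 * sd) * rate) + 1)
                erp_drive[i0:i1] += comp.amp_uv * np.exp(
                    -0.5 * ((t[i0:i1] - center) / sd) ** 2)
        signal += gain * g * np.outer(erp_topo, erp_drive)

    cond_code = 0 if condition == "intact" else 1
    rng = np.random.default_rng([spec.seed, 307, participant, trial,
                                 cond_code])
    if spec.noise_sigma > 0:
        mixing = _mixing_matrix(positions, spec.spatial_scale_m)
        signal += pink_noise(rng, n_ch, n, rate, spec.noise_sigma,
                             spec.noise_exponent, mixing)
    return EEGRecording(signal, rate, list(names), positions,
                        [(round_samples(pre_s, rate), 1)])


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def dataset_manifest(spec: SimulationSpec,
                     n_trials_per_condition: int = 10,
                     conditions: tuple[str, ...] = ("Fear", "Happiness"),
                     types: tuple[str, ...] = ("intact", "scrambled")
                     ) -> pd.DataFrame:
    """Enumerate every recording of a dataset (one row per trial)."""
    rows = []
    for p in range(spec.n_participants):
        for cond in conditions:
            for ctype in types:
                for tr in range(n_trials_per_condition):
                    rows.append({
                        "path": f"sub{p:02d}_{cond}_{ctype}_t{tr:02d}.raw",
                        "participant": p, "condition": cond, "type": ctype,
                        "trial": tr, "seed": spec.seed})
    return pd.DataFrame(rows)


def iter_dataset(spec: SimulationSpec, n_trials_per_condition: int = 10,
                 conditions: tuple[str, ...] = ("Fear", "Happiness"),
                 types: tuple[str, ...] = ("intact", "scrambled"),
                 seq_spec: SequenceSpec | None = None):
    """Lazily yield (participant, condition, type, trial, recording).

    Emotion conditions share the response model but use sequences with
    the matching target category; trial noise differs across all cells.
    """
    for p in range(spec.n_participants):
        for ci, cond in enumerate(conditions):
            seq = seq_spec or SequenceSpec(target_category=cond.lower())
            for ctype in types:
                for tr in range(n_trials_per_condition):
                    rec = simulate_recording(
                        seq, spec, condition=ctype, participant=p,
                        trial=1000 * ci + tr)
                    yield p, cond, ctype, tr, rec


def simulate_dataset(spec: SimulationSpec, out_dir: str | Path,
                     n_trials_per_condition: int = 10,
                     conditions: tuple[str, ...] = ("Fear", "Happiness"),
                     types: tuple[str, ...] = ("intact", "scrambled"),
                     fmt: str = "raw") -> pd.DataFrame:
    """Write a full dataset to disk and return its manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dataset_manifest(spec, n_trials_per_condition, conditions,
                                types)
    if fmt == "edf":
        manifest["path"] = manifest["path"].str.replace(
            ".raw", ".edf", regex=False)
    for (_, row), (_, _, _, _, rec) in zip(
            manifest.iterrows(),
            iter_dataset(spec, n_trials_per_condition, conditions, types)):
        save_recording(rec, out_dir / row["path"])
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest


# ---------------------------------------------------------------------------
# Behavior simulation
# ---------------------------------------------------------------------------

def simulate_behavior(d_prime_true: float, n_trials: int,
                      seed: int | np.random.Generator = 0,
                      criterion: float = 0.0, participant: int = 0,
                      task: str = "sequence",
                      target_category: str = "fear") -> pd.DataFrame:
    """Yes/no detection trials from the equal-variance Gaussian model.

    Half the trials contain the target.  The decision variable is
    N(d' * present, 1) compared against d'/2 + criterion, so an unbiased
    observer (criterion 0) has hit rate Phi(d'/2) and false-alarm rate
    Phi(-d'/2).
    """
    if n_trials % 2:
        raise ValueError("n_trials must be even (half target-present)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    present = np.zeros(n_trials, dtype=bool)
    present[: n_trials // 2] = True
    present = rng.permutation(present)
    evidence = rng.standard_normal(n_trials) + d_prime_true * present
    responded_yes = evidence > d_prime_true / 2.0 + criterion
    return pd.DataFrame({
        "participant": participant,
        "task": task,
        "block": 1,
        "stimulus_id": [f"trial_{i:04d}" for i in range(n_trials)],
        "true_category": np.where(present, target_category, "none"),
        "target_present": present,
        "response": np.where(responded_yes, "yes", "no"),
        "valence": np.nan,
        "arousal": np.nan,
    })
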