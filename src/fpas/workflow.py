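"""End-to-end drivers: dataset-level frequency and time-domain analyses
and the config-driven pipeline runner.

These bind the per-recording operations into the full procedure: per
participant and sequence type, trials are preprocessed, segmented,
re-referenced, averaged and Fourier-transformed; group-level harmonic
selection runs on the grand averages; channel statistics and the
participant-level group test follow.  The time-domain driver mirrors
the ERP branch.  ``run_pipeline`` executes the stages named in a
plain-text configuration and writes a machine-readable summary.
"""

from __future__ import annotations

import configparser
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import freqtag as ft
from . import simulate as sim
from . import timedomain as td
from .io import EEGRecording, load_manifest, load_recording
from .sequences import SequenceSpec

logger = logging.getLogger("fpas")

#: spectra kept up to this frequency when storing per-participant results
SPECTRUM_STORE_FMAX_HZ = 30.0


# ---------------------------------------------------------------------------
# Frequency-domain dataset analysis
# ---------------------------------------------------------------------------

def _truncate_spectrum(spec: ft.AmplitudeSpectrumSet,
                       fmax: float) -> ft.AmplitudeSpectrumSet:
    n = int(np.floor(fmax / spec.df)) + 1
    return ft.AmplitudeSpectrumSet(spec.amps[:, :n], spec.df,
                                   min(fmax, spec.fmax),
                                   spec.channel_names)


def _scalp_spectrum(avg: EEGRecording) -> ft.AmplitudeSpectrumSet:
    picks = avg.scalp_picks()
    scalp = EEGRecording(avg.data[picks], avg.rate,
                         [avg.channel_names[i] for i in picks])
    return _truncate_spectrum(ft.amplitude_spectrum(scalp),
                              SPECTRUM_STORE_FMAX_HZ)


def participant_average(trial_recs: list[EEGRecording],
                        reference: str = "average",
                        crop_start_s: float = 2.0,
                        crop_length_s: float = 52.8) -> EEGRecording:
    """Preprocess, segment, re-reference, crop and average one
    participant/type cell given its raw continuous recordings."""
    trials = []
    for rec in trial_recs:
        pre = ft.preprocess(rec)
        for trial in ft.segment_trials(pre):
            trials.append(ft.rereference(trial, reference))
    return ft.crop_and_average(trials, crop_start_s, crop_length_s)


def frequency_analysis(averages_by_cell: dict,
                       f0: float = ft.TARGET_RATE_HZ,
                       base: float = ft.BASE_RATE_HZ,
                       policy: ft.NoisePolicy = ft.NoisePolicy(),
                       q: float = 0.05,
                       candidate_fmax: float = 8.0) -> dict:
    """Group-level frequency-domain analysis.

    ``averages_by_cell`` maps (participant, type) -> averaged cropped
    trial, with type in {"intact", "scrambled"}.  Returns grand spectra,
    pooled harmonic z-scores, the selected harmonics, per-channel
    reports, the intact-scrambled contrast and the participant group
    test.
    """
    participants = sorted({p for p, _ in averages_by_cell})
    types = ("intact", "scrambled")
    spectra = {t: [] for t in types}
    grand = {}
    for ctype in types:
        cells = [averages_by_cell[(p, ctype)] for p in participants]
        for avg in cells:
            spectra[ctype].append(_scalp_spectrum(avg))
        grand_data = np.mean([c.data for c in cells], axis=0)
        first = cells[0]
        grand[ctype] = _scalp_spectrum(
            EEGRecording(grand_data, first.rate, list(first.channel_names),
                         first.positions, []))

    candidate_bins, z_pooled = {}, {}
    for ctype in types:
        candidate_bins[ctype], z_pooled[ctype] = ft.harmonic_z(
            grand[ctype], f0, policy, exclude_base=base, fmax=candidate_fmax)
    selected = ft.select_harmonics(candidate_bins["intact"],
                                   z_pooled["intact"], z_pooled["scrambled"])

    result = {
        "participants": participants,
        "grand_spectra": grand,
        "participant_spectra": spectra,
        "candidate_bins": candidate_bins["intact"],
        "z_pooled": z_pooled,
        "selected_bins": selected,
        "df": grand["intact"].df,
        "channel_names": grand["intact"].channel_names,
    }
    base_bins, base_z = {}, {}
    for ctype in types:
        base_bins[ctype], base_z[ctype] = ft.harmonic_z(
            grand[ctype], base, policy, exclude_base=None,
            fmax=candidate_fmax)
    result["base_bins"] = base_bins["intact"]
    result["base_z_pooled"] = base_z

    if len(selected) == 0:
        result["no_significant_response"] = True
        return result
    result["no_significant_response"] = False
    result["reports"] = {
        t: ft.harmonic_response_report(grand[t], f0, selected, policy, q)
        for t in types}
    result["contrast"] = ft.contrast_intact_scrambled(
        grand["intact"], grand["scrambled"], selected, policy, q)
    sig = np.nonzero(result["contrast"].sig_mask)[0]
    if len(sig) == 0:
        sig = np.arange(grand["intact"].amps.shape[0])
    result["sig_channels"] = sig
    result["group"] = ft.per_participant_response(
        spectra["intact"], spectra["scrambled"], selected, sig, policy)
    return result


def synthetic_frequency_analysis(sim_spec: sim.SimulationSpec,
                                 seq_spec: SequenceSpec | None = None,
                                 n_trials: int = 10,
                                 condition: str = "Fear",
                                 **kwargs) -> dict:
    """Frequency analysis of a freshly simulated dataset (one emotion
    condition, both sequence types), without touching disk."""
    seq_spec = seq_spec or SequenceSpec(target_category=condition.lower())
    averages = {}
    for p in range(sim_spec.n_participants):
        for ctype in ("intact", "scrambled"):
            recs = [sim.simulate_recording(seq_spec, sim_spec, ctype, p, tr)
                    for tr in range(n_trials)]
            averages[(p, ctype)] = participant_average(recs)
        logger.debug("frequency analysis: participant %d averaged", p)
    out = frequency_analysis(averages, **kwargs)
    out["recovery"] = _recovery_metrics(out, sim_spec)
    return out


def _recovery_metrics(result: dict, sim_spec: sim.SimulationSpec) -> dict:
    """Injected-vs-recovered summed amplitude at the topography peak."""
    injected = float(np.sum(sim_spec.target_amp))
    names, positions = sim._layout()
    _, target_topo, _ = sim.default_topographies(positions)
    if sim_spec.target_topo is not None:
        target_topo = np.asarray(sim_spec.target_topo, dtype=float)
    peak_name = names[int(np.argmax(target_topo))]
    peak = result["channel_names"].index(peak_name)
    # recover exactly the injected harmonics, whatever the selection found
    bins = result["candidate_bins"][:len(sim_spec.target_amp)]
    per_part = []
    for spec_p in result["participant_spectra"]["intact"]:
        _, _, summed = ft.quantify(spec_p, bins)
        per_part.append(summed[peak])
    recovered = float(np.mean(per_part))
    return {"injected_sum_uv": injected, "recovered_sum_uv": recovered,
            "peak_channel": peak_name,
            "relative_error": (recovered - injected) / injected
            if injected > 0 else np.nan}


# ---------------------------------------------------------------------------
# Time-domain dataset analysis
# ---------------------------------------------------------------------------

def _epochs_for_cell(recs: list[EEGRecording], seq_spec: SequenceSpec,
                     condition: str, ctype: str) -> td.EpochSet:
    sets = []
    for rec in recs:
        filt = ft.preprocess(rec, target_rate=rec.rate)   # keep 512 Hz
        filt = td.notch_base(filt)
        for trial in ft.segment_trials(filt):
            trial = ft.rereference(trial, "linked_mastoids")
            sets.append(td.extract_target_epochs(trial, seq_spec,
                                                 condition=condition,
                                                 ctype=ctype))
    return td.concatenate_epochs(sets)


def synthetic_time_analysis(sim_spec: sim.SimulationSpec,
                            seq_spec: SequenceSpec | None = None,
                            n_trials: int = 4,
                            condition: str = "Fear",
                            q: float = 0.05,
                            equalize_seed: int = 0) -> dict:
    """Time-domain ERP analysis of a freshly simulated dataset."""
    seq_spec = seq_spec or SequenceSpec(target_category=condition.lower())
    per_participant = {"intact": [], "scrambled": []}
    channel_names = None
    for p in range(sim_spec.n_participants):
        cells = {}
        for ctype in ("intact", "scrambled"):
            recs = [sim.simulate_recording(seq_spec, sim_spec, ctype, p, tr)
                    for tr in range(n_trials)]
            cells[ctype] = _epochs_for_cell(recs, seq_spec, condition, ctype)
        cells = td.equalize_epoch_counts(cells, seed=equalize_seed + p)
        for ctype, eset in cells.items():
            avg = td.baseline_correct(eset.average(), eset.n_pre)
            scalp = [i for i, nm in enumerate(eset.channel_names)
                     if nm not in ("M1", "M2")]
            per_participant[ctype].append(avg[scalp])
            if channel_names is None:
                channel_names = [eset.channel_names[i] for i in scalp]
        logger.debug("time analysis: participant %d done", p)
    intact = np.array(per_participant["intact"])
    scram = np.array(per_participant["scrambled"])
    windows = td.pointwise_test(intact, scram, sim_spec.rate,
                                channel_names=channel_names, q=q)
    return {
        "windows": windows,
        "grand_intact": intact.mean(axis=0),
        "grand_scrambled": scram.mean(axis=0),
        "rate": sim_spec.rate,
        "channel_names": channel_names,
    }


# ---------------------------------------------------------------------------
# Manifest-driven analysis (CLI entry)
# ---------------------------------------------------------------------------

def frequency_analysis_from_manifest(manifest_path: str | Path,
                                     condition: str = "Fear",
                                     **kwargs) -> dict:
    """Run the frequency analysis on recordings listed in a manifest."""
    manifest = load_manifest(manifest_path)
    rows = manifest[manifest["condition"] == condition]
    if rows.empty:
        raise ValueError(f"manifest has no rows for condition {condition!r}")
    averages = {}
    for (p, ctype), grp in rows.groupby(["participant", "type"]):
        recs = [load_recording(path) for path in grp["path"]]
        averages[(int(p), str(ctype))] = participant_average(recs)
    return frequency_analysis(averages, **kwargs)


# ---------------------------------------------------------------------------
# Config-driven pipeline
# ---------------------------------------------------------------------------

_ALLOWED_KEYS = {
    "run": {"stages", "out_dir"},
    "simulate": {"seed", "n_participants", "n_trials", "noise_sigma",
                 "noise_exponent", "scrambled_gain", "participant_gain_sd",
                 "target_category"},
    "freqtag": {"q", "candidate_fmax"},
    "timedomain": {"q", "n_trials"},
    "behavior": {"d_prime_true", "n_trials"},
}


def _validate_config(cfg: configparser.ConfigParser) -> None:
    for section in cfg.sections():
        if section not in _ALLOWED_KEYS:
            raise ValueError(f"unknown config section [{section}]")
        unknown = set(cfg[section]) - _ALLOWED_KEYS[section]
        if unknown:
            raise ValueError(
                f"unknown key(s) in [{section}]: {sorted(unknown)}")


def run_pipeline(config_path: str | Path,
                 out_dir: str | Path | None = None) -> dict:
    """Execute the stages named in a key = value configuration.

    Stages: ``simulate-freq`` (simulate + frequency analysis),
    ``simulate-time`` (simulate + time-domain analysis), ``behavior``.
    All randomness flows from the master ``seed`` in [simulate].  A
    machine-readable summary (JSON) and a parameter log are written to
    the output directory.
    """
    cfg = configparser.ConfigParser()
    read = cfg.read(config_path)
    if not read:
        raise FileNotFoundError(config_path)
    _validate_config(cfg)

    run = cfg["run"] if cfg.has_section("run") else {}
    out_dir = Path(out_dir or run.get("out_dir", "fpas_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = [s.strip() for s in
              run.get("stages", "simulate-freq,behavior").split(",")]

    simc = cfg["simulate"] if cfg.has_section("simulate") else {}
    seed = int(simc.get("seed", 0))
    sim_spec = sim.SimulationSpec(
        seed=seed,
        n_participants=int(simc.get("n_participants", 8)),
        noise_sigma=float(simc.get("noise_sigma", 6.0)),
        noise_exponent=float(simc.get("noise_exponent", 1.0)),
        scrambled_gain=float(simc.get("scrambled_gain", 0.6)),
        participant_gain_sd=float(simc.get("participant_gain_sd", 0.2)),
    )
    n_trials = int(simc.get("n_trials", 2))
    condition = simc.get("target_category", "fear").capitalize()

    summary: dict = {"config": {s: dict(cfg[s]) for s in cfg.sections()},
                     "seed": seed, "stages": stages}
    if "simulate-freq" in stages:
        fq = cfg["freqtag"] if cfg.has_section("freqtag") else {}
        res = synthetic_frequency_analysis(
            sim_spec, n_trials=n_trials, condition=condition,
            q=float(fq.get("q", 0.05)),
            candidate_fmax=float(fq.get("candidate_fmax", 8.0)))
        summary["frequency"] = {
            "selected_harmonic_bins": [int(b) for b in res["selected_bins"]],
            "z_pooled_intact": list(np.round(res["z_pooled"]["intact"], 3)),
            "z_pooled_scrambled":
                list(np.round(res["z_pooled"]["scrambled"], 3)),
            "n_significant_channels":
                int(res["contrast"].sig_mask.sum())
                if not res["no_significant_response"] else 0,
            "group_t": res.get("group", {}).get("t"),
            "group_p": res.get("group", {}).get("p"),
            "recovery": {k: (float(v) if isinstance(v, (int, float))
                             else v)
                         for k, v in res.get("recovery", {}).items()},
        }
    if "simulate-time" in stages:
        tdc = cfg["timedomain"] if cfg.has_section("timedomain") else {}
        res = synthetic_time_analysis(
            sim_spec, n_trials=int(tdc.get("n_trials", n_trials)),
            condition=condition, q=float(tdc.get("q", 0.05)))
        summary["time"] = {
            "n_windows": int(len(res["windows"])),
            "windows": res["windows"].to_dict("records"),
        }
    if "behavior" in stages:
        bc = cfg["behavior"] if cfg.has_section("behavior") else {}
        d_true = float(bc.get("d_prime_true", 1.4))
        n_b = int(bc.get("n_trials", 96))
        dps = []
        for p in range(sim_spec.n_participants):
            table = sim.simulate_behavior(
                d_true, n_b, seed=np.random.default_rng([seed, 401, p]),
                participant=p)
            dps.append(beh.dprime_from_table(table))
        t, pval, d = beh.group_test(np.array(dps))
        summary["behavior"] = {"d_prime_true": d_true,
                               "d_prime_mean": float(np.mean(dps)),
                               "t": t, "p": pval, "cohen_d": d}

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     default=str))
    logger.info("pipeline summary written to %s", out_dir / "summary.json")
    return summary
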