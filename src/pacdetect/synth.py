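"""Annotated synthetic 2-lead ECG records with controllable ectopy.

Beats are sum-of-Gaussians P-QRS-T kernels: transparent ground truth for
the P/QRS morphology knobs that the pipeline must pick up.  Premature
atrial beats (S) keep a near-normal QRS but perturb the P wave
(inverted/attenuated/shifted per config) and arrive early with a
non-compensatory pause; ventricular beats (V) drop the P wave, widen the
QRS, invert the T and take a full compensatory pause.  Bigeminy,
trigeminy and atrial-run patterns, Gaussian noise and sinusoidal
baseline wander are available.  Everything is deterministic given the
config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import BeatAnnotation, ECGRecord

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "beat_waveform",
    "rhythm_plan",
    "generate_record",
    "write_fixture",
    "demo_patient_configs",
]

SYMBOL_FOR_LABEL = {"N": "N", "S": "A", "V": "V"}

#: (center s, width s, amplitude mV) of each normal-beat component, lead 1.
BASE_COMPONENTS: Dict[str, Tuple[float, float, float]] = {
    "p": (-0.170, 0.022, 0.25),
    "q": (-0.026, 0.008, -0.08),
    "r": (0.0, 0.010, 1.00),
    "s": (0.026, 0.009, -0.15),
    "t": (0.210, 0.045, 0.30),
}
KERNEL_SPAN_S = (-0.35, 0.40)


@dataclass(frozen=True)
class SynthConfig:
    patient_id: str = "synth"
    fs: float = 250.0
    n_beats: int = 200
    mean_rr_ms: float = 800.0
    rr_sd_ms: float = 30.0
    resp_amp_ms: float = 20.0
    resp_freq_hz: float = 0.25
    pac_rate: float = 0.0
    pvc_rate: float = 0.0
    pac_prematurity: float = 0.25  # fraction of the mean RR
    pac_p_amp_factor: float = -1.0  # inverted P by default
    pac_p_shift_ms: float = 0.0
    pac_p_width_factor: float = 1.0
    pvc_qrs_width_factor: float = 2.5
    pvc_qrs_amp_factor: float = 1.3
    pattern: str = "isolated"  # isolated | bigeminy | trigeminy | atrial_run
    pattern_run_len: int = 3
    noise_sd_mv: float = 0.01
    wander_amp_mv: float = 0.10
    wander_freq_hz: float = 0.30
    kernel_jitter: float = 0.10  # per-patient component randomization
    beat_amp_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pac_rate <= 1 and 0 <= self.pvc_rate <= 1):
            raise ValueError("event rates must lie in [0, 1]")
        if self.pac_rate + self.pvc_rate >= 1:
            raise ValueError("pac_rate + pvc_rate must be < 1")
        if not self.fs > 0:
            raise ValueError("fs must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Per-beat truth plus the event-pattern log of a generated record."""

    beats: pd.DataFrame  # columns: sample, label
    events: Tuple[str, ...]


def _patient_params(cfg: SynthConfig, rng: np.random.Generator) -> Dict[str, Dict[str, float]]:
    """Per-patient multiplicative jitter on component amplitudes/widths."""
    params = {}
    for name in BASE_COMPONENTS:
        params[name] = {
            "amp": float(1.0 + cfg.kernel_jitter * rng.standard_normal()),
            "width": float(np.clip(1.0 + cfg.kernel_jitter * rng.standard_normal(), 0.7, 1.3)),
        }
    params["lead2_gain"] = float(np.clip(0.6 + 0.1 * rng.standard_normal(), 0.35, 0.9))
    return params


def _components_for(kind: str, cfg: SynthConfig, lead: int, params=None) -> List[Tuple[float, float, float]]:
    comps = []
    for name, (mu, sigma, amp) in BASE_COMPONENTS.items():
        if params is not None and name in params:
            amp = amp * params[name]["amp"]
            sigma = sigma * params[name]["width"]
        if kind == "S" and name == "p":
            amp *= cfg.pac_p_amp_factor
            mu += cfg.pac_p_shift_ms / 1000.0
            sigma *= cfg.pac_p_width_factor
        elif kind == "V":
            if name == "p":
                continue  # no preceding P wave
            if name == "r":
                sigma *= cfg.pvc_qrs_width_factor
                amp *= cfg.pvc_qrs_amp_factor
            elif name in ("q", "s"):
                sigma *= 2.0
                amp *= 0.5
            elif name == "t":
                amp *= -0.9
                sigma *= 1.2
        if lead == 1:
            gain = params["lead2_gain"] if params is not None else 0.6
            amp *= gain if name != "p" else min(1.0, gain + 0.2)
            sigma *= 1.05
        comps.append((mu, sigma, amp))
    return comps


def beat_waveform(
    kind: str,
    cfg: SynthConfig | None = None,
    lead: int = 0,
    params: Optional[Dict] = None,
) -> Tuple[np.ndarray, int]:
    """Sampled beat kernel and the index of its R reference (t = 0).

    ``kind`` is one of N/S/V.  The R peak of N and S kernels is the
    dominant positive deflection exactly at t = 0.
    """
    cfg = cfg or SynthConfig()
    if kind not in ("N", "S", "V"):
        raise ValueError(f"unknown beat kind {kind!r}")
    lo = int(round(KERNEL_SPAN_S[0] * cfg.fs))
    hi = int(round(KERNEL_SPAN_S[1] * cfg.fs))
    t = np.arange(lo, hi + 1) / cfg.fs
    wave = np.zeros_like(t)
    for mu, sigma, amp in _components_for(kind, cfg, lead, params):
        wave += amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return wave, -lo


def _event_labels(cfg: SynthConfig, rng: np.random.Generator) -> Tuple[List[str], List[str]]:
    n = cfg.n_beats
    labels = ["N"] * n
    events: List[str] = []
    lo, hi = 2, n - 3  # keep record ends normal
    if cfg.pattern == "isolated":
        for i in range(lo, hi + 1):
            if labels[i - 1] != "N":
                continue  # no adjacent events
            u = rng.random()
            if u < cfg.pac_rate:
                labels[i] = "S"
                events.append(f"S@{i}")
            elif u < cfg.pac_rate + cfg.pvc_rate:
                labels[i] = "V"
                events.append(f"V@{i}")
    elif cfg.pattern == "bigeminy":
        for i in range(lo, hi + 1):
            if i % 2 == 1:
                labels[i] = "S"
        events.append("bigeminy")
    elif cfg.pattern == "trigeminy":
        for i in range(lo, hi + 1):
            if i % 3 == 2:
                labels[i] = "S"
        events.append("trigeminy")
    elif cfg.pattern == "atrial_run":
        i = lo
        while i <= hi - cfg.pattern_run_len:
            if rng.random() < cfg.pac_rate:
                for j in range(i, i + cfg.pattern_run_len):
                    labels[j] = "S"
                events.append(f"run@{i}x{cfg.pattern_run_len}")
                i += cfg.pattern_run_len + 2
            else:
                i += 1
    else:
        raise ValueError(f"unknown pattern {cfg.pattern!r}")
    return labels, events


def rhythm_plan(
    cfg: SynthConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[np.ndarray, List[str], List[str]]:
    """Beat times (seconds), labels and the event log.

    PACs arrive ``pac_prematurity`` early with a non-compensatory pause
    (pre+post RR sums to ``(2 - prematurity/2)`` mean RRs); PVCs take a
    full compensatory pause (sum exactly two mean RRs).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    labels, events = _event_labels(cfg, rng)
    n = cfg.n_beats
    mean_s = cfg.mean_rr_ms / 1000.0
    prem = cfg.pac_prematurity

    rr = mean_s + (cfg.rr_sd_ms / 1000.0) * rng.standard_normal(n - 1)
    # respiratory modulation of the baseline rhythm
    t_approx = np.cumsum(np.r_[0.0, rr[:-1]])
    rr = rr + (cfg.resp_amp_ms / 1000.0) * np.sin(
        2 * np.pi * cfg.resp_freq_hz * t_approx
    )
    for i, label in enumerate(labels):
        if label == "N":
            continue
        rr[i - 1] = (1.0 - prem) * mean_s
        if i <= n - 2 and labels[i + 1] == "N":
            if label == "S":
                rr[i] = (2.0 - prem / 2.0) * mean_s - rr[i - 1]
            else:  # V: full compensatory pause
                rr[i] = 2.0 * mean_s - rr[i - 1]
    if np.any(rr < 0.25):
        raise ValueError(
            "planned RR below 250 ms: beat kernels would overlap "
            "(mean_rr_ms too small for the configured prematurity/noise)"
        )
    times = 0.6 + np.cumsum(np.r_[0.0, rr])
    return times, labels, events


def generate_record(cfg: SynthConfig) -> Tuple[ECGRecord, GroundTruth]:
    """Deterministic synthetic record + ground truth for one config."""
    rng = np.random.default_rng(cfg.seed)
    params = _patient_params(cfg, rng)
    times, labels, events = rhythm_plan(cfg, rng)
    fs = cfg.fs
    n_samples = int(round((times[-1] + 0.6) * fs))
    kernels = {
        (kind, lead): beat_waveform(kind, cfg, lead, params)
        for kind in ("N", "S", "V")
        for lead in (0, 1)
    }
    signal = np.zeros((n_samples, 2))
    r_samples = np.floor(times * fs + 0.5).astype(int)
    beat_gains = 1.0 + cfg.beat_amp_jitter * rng.standard_normal(len(times))
    for t_idx, (r, label) in enumerate(zip(r_samples, labels)):
        for lead in (0, 1):
            wave, center = kernels[(label, lead)]
            start = r - center
            stop = start + wave.size
            if start < 0 or stop > n_samples:
                raise ValueError("beat kernel extends beyond the record")
            signal[start:stop, lead] += beat_gains[t_idx] * wave
    if cfg.wander_amp_mv > 0:
        t = np.arange(n_samples) / fs
        for lead in (0, 1):
            phase = rng.uniform(0, 2 * np.pi)
            signal[:, lead] += cfg.wander_amp_mv * np.sin(
                2 * np.pi * cfg.wander_freq_hz * t + phase
            )
    if cfg.noise_sd_mv > 0:
        signal += rng.normal(0.0, cfg.noise_sd_mv, size=signal.shape)

    record = ECGRecord(cfg.patient_id, fs, signal)
    beats = pd.DataFrame({"sample": r_samples, "label": labels})
    return record, GroundTruth(beats=beats, events=tuple(events))


def annotations_from_truth(truth: GroundTruth) -> List[BeatAnnotation]:
    return [
        BeatAnnotation(int(s), SYMBOL_FOR_LABEL[label], label)
        for s, label in zip(truth.beats["sample"], truth.beats["label"])
    ]


def write_fixture(record: ECGRecord, truth: GroundTruth, out_dir) -> Dict[str, Path]:
    """Write a record as CSV fixtures (plus a WFDB pair when available).

    Produces ``<id>_signal.csv``, ``<id>_meta.json``, ``<id>_ann.csv``
    and ``<id>_truth.csv``; signal samples are quantized to 1e-6 mV by
    the text format.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = out_dir / record.patient_id
    paths = {
        "signal": stem.with_name(stem.name + "_signal.csv"),
        "meta": stem.with_name(stem.name + "_meta.json"),
        "ann": stem.with_name(stem.name + "_ann.csv"),
        "truth": stem.with_name(stem.name + "_truth.csv"),
    }
    np.savetxt(paths["signal"], record.signal, delimiter=",", fmt="%.6f")
    paths["meta"].write_text(
        json.dumps({"fs": record.fs, "patient_id": record.patient_id})
    )
    ann = pd.DataFrame(
        {
            "sample": truth.beats["sample"].astype(int),
            "symbol": [SYMBOL_FOR_LABEL[l] for l in truth.beats["label"]],
        }
    )
    ann.to_csv(paths["ann"], index=False)
    truth.beats.to_csv(paths["truth"], index=False)
    try:  # optional binary sibling for interoperability
        import wfdb

        wfdb.wrsamp(
            record.patient_id,
            fs=record.fs,
            units=["mV"] * record.n_leads,
            sig_name=[f"lead{j + 1}" for j in range(record.n_leads)],
            p_signal=record.signal,
            write_dir=str(out_dir),
        )
        wfdb.wrann(
            record.patient_id,
            "atr",
            np.asarray(ann["sample"], dtype=int),
            symbol=list(ann["symbol"]),
            write_dir=str(out_dir),
        )
        paths["wfdb_header"] = stem.with_suffix(".hea")
    except ImportError:
        pass
    return paths


def replace_config(cfg: SynthConfig, overrides: Dict) -> SynthConfig:
    """New config with recognized keys overridden (YAML config support)."""
    known = {k: v for k, v in overrides.items() if k in SynthConfig.__dataclass_fields__}
    unknown = set(overrides) - set(known)
    if unknown:
        raise ValueError(f"unknown synth config keys: {sorted(unknown)}")
    return replace(cfg, **known)


def demo_patient_configs(
    n_patients: int = 20,
    seed: int = 0,
    n_beats: int = 150,
) -> List[SynthConfig]:
    """Heterogeneous per-patient configs for the end-to-end recovery demo.

    Most patients carry isolated PACs and PVCs; a few exhibit bigeminy,
    trigeminy or atrial runs so templates see structured ectopy too.
    """
    rng = np.random.default_rng(seed)
    patterns = ["isolated"] * (n_patients - 6) + [
        "bigeminy",
        "trigeminy",
        "atrial_run",
        "isolated",
        "bigeminy",
        "atrial_run",
    ]
    configs = []
    for j in range(n_patients):
        pattern = patterns[j % len(patterns)]
        configs.append(
            SynthConfig(
                patient_id=f"p{j:02d}",
                n_beats=n_beats,
                mean_rr_ms=float(rng.uniform(700, 950)),
                rr_sd_ms=float(rng.uniform(20, 40)),
                pac_rate=float(rng.uniform(0.08, 0.15)),
                pvc_rate=float(rng.uniform(0.05, 0.09)) if pattern == "isolated" else 0.0,
                pattern=pattern,
                pattern_run_len=int(rng.integers(3, 6)),
                noise_sd_mv=float(rng.uniform(0.005, 0.02)),
                wander_amp_mv=float(rng.uniform(0.05, 0.15)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return configs
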