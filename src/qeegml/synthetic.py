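"""Synthetic EEG cohort generator.

Generates labeled 19-channel recordings (normal / TBI / stroke) whose
class-conditional structure realizes the quantities the downstream feature
extractor measures:

* per-channel relative band power, shaped by FIR band-limited Gaussian noise
  mixed to per-class targets;
* inter-channel coherence, controlled by shared latent band-limited sources
  mixed into channel groups (a channel that carries shared-power fraction
  ``a`` in a band has pairwise magnitude-squared coherence ~ ``a**2`` with
  another such channel in that band);
* phase-amplitude coupling, injected by sinusoidally modulating the
  gamma-band component with the channel's alpha-band phase at a configurable
  depth;
* ocular / muscle artifacts as Poisson event trains with fixed spatial
  patterns (frontal-dominant slow transients, temporal-dominant broadband
  bursts).

Demographics (sex ratios with an explicit unknown category, age, unique
medication counts) default to the observed training-cohort composition of
the clinical dataset the pipeline emulates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .bands import DEFAULT_BANDS, BandScheme
from .filters import bandlimited_noise, design_bandpass, spectral_noise
from .montage import CHANNELS_1020, CHANNEL_GROUPS
from .recording import EEGRecording

CLASS_LABELS = ("normal", "TBI", "stroke")

#: fraction of a band's power carried by the shared source at
#: ``coherence_scale == 1`` (pairwise MSC ~ 0.25 at this setting)
BASE_SHARED_FRAC = 0.5

#: overall per-channel signal scale in microvolts (standard deviation)
AMPLITUDE_UV = 20.0


@dataclass
class ClassProfile:
    """Generative parameters for one subject class."""

    label: str
    #: band name -> target relative power fraction; fractions sum to <= 1,
    #: the remainder is broadband 1-100 Hz background
    rel_band_power: dict[str, float]
    #: channel-group name -> multiplier on the shared-source power fraction
    coherence_scale: dict[str, float]
    #: alpha-phase -> gamma-amplitude modulation depth in [0, 1]
    pac_depth: float
    #: artifact type ("eye" / "muscle") -> events per minute
    artifact_rates: dict[str, float]
    #: probabilities of (M, F, unknown)
    sex_probs: tuple[float, float, float]
    age_mean_sd: tuple[float, float]
    medication_mean: float
    #: per-subject lognormal jitter (sigma) on band-power targets
    subject_jitter: float = 0.05

    def validate(self) -> None:
        fracs = np.array(list(self.rel_band_power.values()))
        if np.any(fracs < 0) or np.any(fracs > 1) or fracs.sum() > 1 + 1e-9:
            raise ValueError(
                f"{self.label}: rel_band_power fractions must be in [0,1] and sum <= 1"
            )
        if any(r < 0 for r in self.artifact_rates.values()):
            raise ValueError("artifact rates must be >= 0")
        if not np.isclose(sum(self.sex_probs), 1.0):
            raise ValueError("sex_probs must sum to 1")
        if not 0 <= self.pac_depth <= 1:
            raise ValueError("pac_depth must be in [0, 1]")


@dataclass
class CohortSpec:
    """Full cohort description: per-class profiles, split sizes and seed."""

    profiles: dict[str, ClassProfile]
    n_train: dict[str, int]
    n_iv: dict[str, int]
    seed: int = 0
    duration_s: float = 300.0
    fs: float = 250.0

    def validate(self) -> None:
        for prof in self.profiles.values():
            prof.validate()
        for counts in (self.n_train, self.n_iv):
            if any(n < 0 for n in counts.values()):
                raise ValueError("class counts must be >= 0")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        profiles = {}
        for label, p in d["profiles"].items():
            p["sex_probs"] = tuple(p["sex_probs"])
            p["age_mean_sd"] = tuple(p["age_mean_sd"])
            profiles[label] = ClassProfile(**p)
        return cls(
            profiles=profiles,
            n_train={k: int(v) for k, v in d["n_train"].items()},
            n_iv={k: int(v) for k, v in d["n_iv"].items()},
            seed=int(d["seed"]),
            duration_s=float(d["duration_s"]),
            fs=float(d["fs"]),
        )


# --- default class profiles -------------------------------------------------
# Effect directions vs normal: TBI = raised relative delta, lowered alpha/mu,
# reduced global coherence. Stroke = same directions at twice the magnitude,
# plus a theta shift (default +, config-exposed because the literature on its
# sign is mixed).

_NORMAL_BANDS = {
    "delta": 0.24, "theta": 0.16, "alpha": 0.30,
    "mu": 0.10, "beta": 0.08, "gamma": 0.05,
}
_TBI_BANDS = {
    "delta": 0.30, "theta": 0.16, "alpha": 0.25,
    "mu": 0.08, "beta": 0.08, "gamma": 0.05,
}
_STROKE_BANDS = {
    "delta": 0.36, "theta": 0.20, "alpha": 0.20,
    "mu": 0.06, "beta": 0.08, "gamma": 0.05,
}


def default_profiles() -> dict[str, ClassProfile]:
    return {
        "normal": ClassProfile(
            label="normal",
            rel_band_power=dict(_NORMAL_BANDS),
            coherence_scale={"global": 1.0},
            pac_depth=0.30,
            artifact_rates={"eye": 2.0, "muscle": 1.0},
            sex_probs=(29 / 79, 47 / 79, 3 / 79),
            age_mean_sd=(47.6, 18.7),
            medication_mean=1.4,
        ),
        "TBI": ClassProfile(
            label="TBI",
            rel_band_power=dict(_TBI_BANDS),
            coherence_scale={"global": 0.75},
            pac_depth=0.22,
            artifact_rates={"eye": 4.0, "muscle": 2.0},
            sex_probs=(74 / 98, 20 / 98, 4 / 98),
            age_mean_sd=(42.7, 16.7),
            medication_mean=1.4,
        ),
        "stroke": ClassProfile(
            label="stroke",
            rel_band_power=dict(_STROKE_BANDS),
            coherence_scale={"global": 0.5},
            pac_depth=0.15,
            artifact_rates={"eye": 5.0, "muscle": 3.0},
            sex_probs=(62 / 115, 47 / 115, 6 / 115),
            age_mean_sd=(59.7, 9.7),
            medication_mean=1.5,
        ),
    }


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Cohort spec mirroring the clinical study composition (train 79/98/115,
    independent validation 26/44/50)."""
    return CohortSpec(
        profiles=default_profiles(),
        n_train={"normal": 79, "TBI": 98, "stroke": 115},
        n_iv={"normal": 26, "TBI": 44, "stroke": 50},
        seed=seed,
    )


# --- subject-level generation -----------------------------------------------

def generate_subject(
    profile: ClassProfile,
    duration_s: float = 300.0,
    fs: float = 250.0,
    seed: int | np.random.SeedSequence = 0,
    bands: BandScheme = DEFAULT_BANDS,
    subject_id: str = "",
) -> EEGRecording:
    """Generate one 19-channel recording realizing the profile's structure.

    Deterministic given ``seed``. ``duration_s`` must be >= 240 s so the
    post-first-minute 3-minute analysis segment exists; ``fs`` >= 200 Hz.
    """
    profile.validate()
    if duration_s < 240:
        raise ValueError("duration_s must be >= 240 s")
    if fs < 200:
        raise ValueError("fs must be >= 200 Hz")
    rng = np.random.default_rng(seed)
    n_ch = len(CHANNELS_1020)
    n = int(round(duration_s * fs))

    # per-subject jittered band-power targets
    targets = {}
    for name, frac in profile.rel_band_power.items():
        targets[name] = frac * float(np.exp(rng.normal(0.0, profile.subject_jitter)))
    total = sum(targets.values())
    if total > 0.98:  # keep head-room for the broadband background
        targets = {k: v * 0.98 / total for k, v in targets.items()}
    residual = max(1.0 - sum(targets.values()), 0.02)

    # shared-power fraction per channel and band, from group memberships
    shared_frac = np.zeros((n_ch, 1))
    group_sources: list[tuple[np.ndarray, np.ndarray]] = []  # (mask, frac col)
    for group, mult in profile.coherence_scale.items():
        members = CHANNEL_GROUPS[group]
        mask = np.array([ch in members for ch in CHANNELS_1020])
        frac = BASE_SHARED_FRAC * mult
        group_sources.append((mask, frac))
        shared_frac[mask, 0] += frac
    if np.any(shared_frac > 0.9):
        shared_frac = np.minimum(shared_frac, 0.9)

    data = np.zeros((n_ch, n))
    alpha_analytic: np.ndarray | None = None
    gamma_component: np.ndarray | None = None
    for name, lo, hi in bands.bands:
        p = targets.get(name, 0.0)
        if p <= 0:
            continue
        analytic = name == "alpha"
        indep = spectral_noise(rng, n_ch, n, fs, lo, hi, analytic=analytic)
        comp = np.zeros((n_ch, n), dtype=complex if analytic else float)
        used = np.zeros((n_ch, 1))
        for mask, frac in group_sources:
            if frac <= 0:
                continue
            shared = spectral_noise(rng, 1, n, fs, lo, hi, analytic=analytic)
            # balanced +/-1 channel gains: pairwise coherence is sign-invariant,
            # but a sign-balanced source survives average re-referencing where
            # a common-mode one would cancel
            m = int(mask.sum())
            signs = np.array([1.0, -1.0] * (m // 2) + [1.0] * (m % 2))
            rng.shuffle(signs)
            f = np.minimum(frac, 0.9 - used[:, 0])[mask]
            comp[mask] += (signs * np.sqrt(np.maximum(f, 0.0)))[:, None] * shared
            used[mask, 0] += frac
        used = np.minimum(used, 0.9)
        comp += np.sqrt(1.0 - used) * indep
        comp *= np.sqrt(p)
        if name == "alpha":
            alpha_analytic = comp
            comp = comp.real
        elif name == "gamma":
            gamma_component = comp
            continue  # added after PAC modulation below
        data += comp

    # PAC: modulate the gamma component with the alpha-band phase
    if gamma_component is not None:
        d = profile.pac_depth
        if d > 0 and alpha_analytic is not None:
            phase = np.angle(alpha_analytic)
            gamma_component = (
                gamma_component * (1.0 + d * np.cos(phase)) / np.sqrt(1.0 + d * d / 2.0)
            )
        data += gamma_component

    # broadband 1-100 Hz background filling the residual power
    data += np.sqrt(residual) * spectral_noise(
        rng, n_ch, n, fs, 1.0, min(100.0, fs / 2 * 0.95), trans=2.0
    )

    data *= AMPLITUDE_UV

    sex = rng.choice(["M", "F", "U"], p=np.asarray(profile.sex_probs) / sum(profile.sex_probs))
    age = float(np.clip(rng.normal(*profile.age_mean_sd), 1.0, 85.0))
    medication = int(rng.poisson(profile.medication_mean))
    return EEGRecording(
        channel_labels=list(CHANNELS_1020),
        fs=fs,
        data=data,
        subject_id=subject_id,
        class_label=profile.label,
        demographics={"sex": str(sex), "age": age, "medication": medication},
    )


# --- artifact injection -----------------------------------------------------

#: spatial gain patterns (channel -> gain); channels not listed get 0
EYE_PATTERN = {"FP1": 1.0, "FP2": 1.0, "F7": 0.5, "F8": 0.5, "F3": 0.4, "F4": 0.4, "FZ": 0.3}
MUSCLE_PATTERN = {"T7": 1.0, "T8": 1.0, "F7": 0.5, "F8": 0.5, "P7": 0.3, "P8": 0.3}

EYE_AMPLITUDE_UV = 120.0
EYE_WIDTH_S = 0.18       # Gaussian sigma of the slow transient (< 4 Hz energy)
MUSCLE_SD_UV = 35.0
MUSCLE_DURATION_S = 0.3  # 20-100 Hz burst length


def _pattern_vector(pattern: dict[str, float]) -> np.ndarray:
    return np.array([pattern.get(ch, 0.0) for ch in CHANNELS_1020])


def _render_event(event: dict, n_samples: int, fs: float) -> np.ndarray:
    """Pure artifact signal (channels x samples) for one logged event."""
    out = np.zeros((len(CHANNELS_1020), n_samples))
    t0 = event["time"]
    if event["type"] == "eye":
        i0 = int(round((t0 - 4 * EYE_WIDTH_S) * fs))
        i1 = int(round((t0 + 4 * EYE_WIDTH_S) * fs))
        idx = np.arange(max(i0, 0), min(i1, n_samples))
        t = idx / fs
        wave = event["amplitude"] * np.exp(-0.5 * ((t - t0) / EYE_WIDTH_S) ** 2)
        out[:, idx] = _pattern_vector(EYE_PATTERN)[:, None] * wave
    elif event["type"] == "muscle":
        i0 = int(round(t0 * fs))
        i1 = min(i0 + int(round(MUSCLE_DURATION_S * fs)), n_samples)
        m = i1 - i0
        if m > 8:
            rng = np.random.default_rng(event["event_seed"])
            burst = bandlimited_noise(rng, (1, m), fs, 20.0, min(100.0, fs / 2 * 0.95))[0]
            burst *= event["amplitude"] * np.hanning(m)
            out[:, i0:i1] = _pattern_vector(MUSCLE_PATTERN)[:, None] * burst
    else:
        raise ValueError(f"unknown artifact type {event['type']!r}")
    return out


def artifact_signal_from_log(
    events: list[dict], n_samples: int, fs: float, types: tuple[str, ...] | None = None
) -> np.ndarray:
    """Reconstruct the pure injected-artifact signal from an event log."""
    out = np.zeros((len(CHANNELS_1020), n_samples))
    for ev in events:
        if types is None or ev["type"] in types:
            out += _render_event(ev, n_samples, fs)
    return out


def inject_artifacts(
    rec: EEGRecording, rates: dict[str, float], seed: int | np.random.SeedSequence = 0
) -> tuple[EEGRecording, list[dict]]:
    """Add Poisson trains of eye / muscle artifact events to a recording.

    Returns a new recording and the event log; the input is unmodified.
    Event counts are Poisson with mean ``rate * duration_minutes``.
    """
    if any(r < 0 for r in rates.values()):
        raise ValueError("artifact rates must be >= 0")
    rng = np.random.default_rng(seed)
    events: list[dict] = []
    duration_min = rec.duration / 60.0
    for kind in ("eye", "muscle"):
        rate = rates.get(kind, 0.0)
        if rate <= 0:
            continue
        count = rng.poisson(rate * duration_min)
        for _ in range(count):
            t = float(rng.uniform(1.0, rec.duration - 1.0))
            if kind == "eye":
                amp = float(EYE_AMPLITUDE_UV * rng.uniform(0.7, 1.3))
                events.append({"type": "eye", "time": t, "amplitude": amp})
            else:
                amp = float(MUSCLE_SD_UV * rng.uniform(0.7, 1.3))
                events.append(
                    {"type": "muscle", "time": t, "amplitude": amp,
                     "event_seed": int(rng.integers(0, 2**31 - 1))}
                )
    events.sort(key=lambda e: e["time"])
    if not events:
        return rec.copy(), []
    out = rec.with_data(rec.data + artifact_signal_from_log(events, rec.n_samples, rec.fs))
    return out, events


# --- cohort generation ------------------------------------------------------

def _subject_seeds(spec: CohortSpec) -> dict[tuple[str, str, int], np.random.SeedSequence]:
    """Deterministic per-subject seed fan-out from the master seed."""
    seeds = {}
    root = np.random.SeedSequence(spec.seed)
    splits = [("train", spec.n_train), ("iv", spec.n_iv)]
    order = []
    for split, counts in splits:
        for label in CLASS_LABELS:
            for i in range(counts.get(label, 0)):
                order.append((split, label, i))
    children = root.spawn(len(order))
    for key, child in zip(order, children):
        seeds[key] = child
    return seeds


def iter_subjects(
    spec: CohortSpec, split: str, inject: bool = True
) -> Iterator[tuple[EEGRecording, list[dict]]]:
    """Yield ``(recording, artifact_event_log)`` for one split, lazily.

    Subject IDs encode split/class/index and are disjoint between splits by
    construction.
    """
    spec.validate()
    counts = {"train": spec.n_train, "iv": spec.n_iv}[split]
    seeds = _subject_seeds(spec)
    for label in CLASS_LABELS:
        profile = spec.profiles[label]
        for i in range(counts.get(label, 0)):
            ss = seeds[(split, label, i)]
            gen_seed, art_seed = ss.spawn(2)
            rec = generate_subject(
                profile,
                duration_s=spec.duration_s,
                fs=spec.fs,
                seed=gen_seed,
                subject_id=f"sub-{split}-{label}-{i:03d}",
            )
            events: list[dict] = []
            if inject and profile.artifact_rates:
                rec, events = inject_artifacts(rec, profile.artifact_rates, seed=art_seed)
            yield rec, events


def generate_dataset(
    spec: CohortSpec, out_dir: str | Path | None = None, inject: bool = True
) -> pd.DataFrame:
    """Generate the full cohort; optionally write EDF files and a manifest.

    Returns the subjects manifest (subject_id, split, class, sex, age,
    medication, file). With ``out_dir`` set, writes one EDF per subject,
    ``manifest.csv`` and ``spec.json``; repeated runs with the same spec are
    byte-identical.
    """
    from .edf import write_edf  # local import to avoid cycle at module load

    spec.validate()
    rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for split in ("train", "iv"):
        for rec, _events in iter_subjects(spec, split, inject=inject):
            fname = f"{rec.subject_id}.edf"
            if out_path is not None:
                write_edf(rec, out_path / fname)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "split": split,
                    "class": rec.class_label,
                    "sex": rec.demographics["sex"],
                    "age": round(rec.demographics["age"], 2),
                    "medication": rec.demographics["medication"],
                    "file": fname,
                }
            )
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        (out_path / "spec.json").write_text(spec.to_json())
    return manifest
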