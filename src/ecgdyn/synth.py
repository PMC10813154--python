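"""Seeded generator of PTB-like multi-lead ECG cohorts.

Records emulate the reference cohort layout: 15 named leads (12
conventional + 3 Frank), 10 s at 1000 Hz, one of 8 diagnostic classes.
Each record is built from a sum-of-Gaussians beat template (P, Q, R,
S, T waves on a normalised beat phase) repeated at RR intervals drawn
from a class heart-rate distribution, with class-specific morphology
deformations — widened QRS for the bundle-branch-block-like class, ST
elevation with reduced R for the infarction-like class, strong RR
irregularity for the dysrhythmia-like class, and so on.  The 15 leads
are fixed linear projections of the single beat-train source plus
per-lead Gaussian noise.

The generator is fully parametric and seeded: the same
:class:`SyntheticSpec` always yields the same cohort, which is what
makes every pipeline stage testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import CANONICAL_LEADS, ECGRecord, GroupLabel, \
    write_csv_record, write_wfdb_record

__all__ = ["BeatMorphology", "SyntheticSpec", "default_morphologies",
           "generate_beat_train", "generate_cohort", "table3_spec",
           "write_cohort"]

#: Fixed projection gains of the beat-train source onto the 15 leads.
LEAD_GAINS: dict[str, float] = {
    "I": 0.6, "II": 1.0, "III": 0.5, "aVr": -0.8, "aVl": 0.4, "aVf": 0.7,
    "V1": -0.4, "V2": 0.9, "V3": 1.1, "V4": 1.2, "V5": 1.0, "V6": 0.8,
    "Vx": 0.7, "Vy": 0.5, "Vz": -0.3,
}


@dataclass(frozen=True)
class BeatMorphology:
    """Gaussian wave parameters of one beat, on phase in [0, 1).

    Amplitudes in mV, widths and centres as phase fractions.  ``st_amp``
    adds a broad ST-segment bump between S and T; ``rr_jitter`` is the
    relative SD of the RR interval within a record.
    """

    p_amp: float = 0.12
    p_width: float = 0.025
    q_amp: float = -0.10
    r_amp: float = 1.00
    r_width: float = 0.012
    s_amp: float = -0.15
    t_amp: float = 0.30
    t_width: float = 0.040
    st_amp: float = 0.0
    amp_scale: float = 1.0
    rr_jitter: float = 0.03

    def waveform(self, phase: np.ndarray) -> np.ndarray:
        centres = {"p": 0.18, "q": 0.37, "r": 0.40, "s": 0.43, "t": 0.62,
                   "st": 0.52}
        widths = {"p": self.p_width, "q": 0.010, "r": self.r_width,
                  "s": 0.010, "t": self.t_width, "st": 0.060}
        amps = {"p": self.p_amp, "q": self.q_amp, "r": self.r_amp,
                "s": self.s_amp, "t": self.t_amp, "st": self.st_amp}
        y = np.zeros_like(phase)
        for w in centres:
            y += amps[w] * np.exp(-0.5 * ((phase - centres[w]) / widths[w]) ** 2)
        return self.amp_scale * y


def default_morphologies() -> dict[GroupLabel, BeatMorphology]:
    """Per-class beat morphologies (deformations of the healthy template)."""
    hc = BeatMorphology()
    return {
        GroupLabel.HC: hc,
        GroupLabel.MI: replace(hc, st_amp=0.20, r_amp=0.70),
        GroupLabel.BBB: replace(hc, r_width=hc.r_width * 2.8, s_amp=-0.25),
        GroupLabel.CardMyo: replace(hc, amp_scale=0.6,
                                    r_width=hc.r_width * 1.5),
        GroupLabel.M: replace(hc, t_amp=-0.15, st_amp=0.08),
        GroupLabel.MH: replace(hc, r_amp=1.6),
        GroupLabel.VHD: replace(hc, p_amp=0.26, t_amp=0.24),
        GroupLabel.Dis: replace(hc, rr_jitter=0.25),
    }


@dataclass
class SyntheticSpec:
    """Cohort recipe: class sizes, signal geometry, morphology, noise.

    Defaults give a balanced cohort (``n_per_class`` applied to every
    class in ``classes``) of 10-s, 1000-Hz, 15-lead records with a
    70 +/- 5 bpm heart rate and 0.02 mV per-lead noise.
    """

    n_per_class: dict[GroupLabel, int] = field(
        default_factory=lambda: {g: 4 for g in GroupLabel})
    fs: float = 1000.0
    duration_s: float = 10.0
    heart_rate_bpm: tuple[float, float] = (70.0, 5.0)
    morphology: dict[GroupLabel, BeatMorphology] = field(
        default_factory=default_morphologies)
    noise_sd: float = 0.02
    leads: tuple[str, ...] = CANONICAL_LEADS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be non-negative")
        unknown = [l for l in self.leads if l not in CANONICAL_LEADS]
        if unknown:
            raise ValueError(f"unknown lead names {unknown}")


def table3_spec(scale: float = 12.0, seed: int = 0, **kwargs) -> SyntheticSpec:
    """Imbalanced preset with class counts 9:15:75:3:4:362:4:11 scaled down.

    Counts are divided by ``scale`` and floored at 2 so every class
    remains usable under leave-one-out evaluation.  This preset exists
    to exercise the minority-swamping pathology (0% recall next to
    high accuracy) that strong imbalance produces.
    """
    base = {
        GroupLabel.BBB: 9, GroupLabel.CardMyo: 15, GroupLabel.HC: 75,
        GroupLabel.M: 3, GroupLabel.MH: 4, GroupLabel.MI: 362,
        GroupLabel.VHD: 4, GroupLabel.Dis: 11,
    }
    counts = {g: max(2, round(n / scale)) for g, n in base.items()}
    return SyntheticSpec(n_per_class=counts, seed=seed, **kwargs)


def generate_beat_train(
    spec: SyntheticSpec,
    group: GroupLabel,
    rng: np.random.Generator,
    heart_rate_bpm: float | None = None,
) -> np.ndarray:
    """One single-lead beat-train source signal for a record of ``group``.

    Beats of the class morphology are placed back to back at RR
    intervals ``60/HR * (1 + jitter)``; the signal is trimmed to
    ``fs * duration_s`` samples.  No noise is added here — noise is
    per-lead and added during cohort assembly.
    """
    morph = spec.morphology[GroupLabel(group)]
    n_total = int(round(spec.fs * spec.duration_s))
    if heart_rate_bpm is None:
        mean_hr, sd_hr = spec.heart_rate_bpm
        heart_rate_bpm = float(np.clip(rng.normal(mean_hr, sd_hr), 40.0, 180.0))
    pieces: list[np.ndarray] = []
    n_done = 0
    while n_done < n_total:
        rr = 60.0 / heart_rate_bpm * float(
            np.clip(1.0 + morph.rr_jitter * rng.standard_normal(), 0.5, 2.0))
        n_beat = max(int(round(rr * spec.fs)), 8)
        phase = np.arange(n_beat) / n_beat
        pieces.append(morph.waveform(phase))
        n_done += n_beat
    return np.concatenate(pieces)[:n_total]


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[list[ECGRecord], dict]:
    """Generate the full cohort plus a manifest of what was generated.

    Records are ordered class by class (canonical enum order) and named
    ``SYN-<class>-<k>``.  Reproducible: the manifest records the seed
    and geometry, and the same spec always yields identical signals.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ECGRecord] = []
    for group in GroupLabel:
        n = spec.n_per_class.get(group, 0)
        for k in range(n):
            source = generate_beat_train(spec, group, rng)
            leads = {}
            for lead in spec.leads:
                noise = spec.noise_sd * rng.standard_normal(len(source))
                leads[lead] = LEAD_GAINS[lead] * source + noise
            records.append(ECGRecord(
                record_id=f"SYN-{group.value}-{k:03d}",
                group=group, fs=spec.fs, leads=leads,
            ))
    manifest = {
        "seed": spec.seed, "fs": spec.fs, "duration_s": spec.duration_s,
        "n_records": len(records),
        "n_per_class": {g.value: spec.n_per_class.get(g, 0) for g in GroupLabel},
        "leads": list(spec.leads), "noise_sd": spec.noise_sd,
    }
    return records, manifest


def write_cohort(records: list[ECGRecord], directory, fmt: str = "wfdb") -> list:
    """Write cohort fixtures as WFDB pairs or per-record CSV files."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in records:
        if fmt == "wfdb":
            paths.append(write_wfdb_record(rec, directory))
        elif fmt == "csv":
            paths.append(write_csv_record(rec, directory / f"{rec.record_id}.csv"))
        else:
            raise ValueError(f"unknown fixture format {fmt!r}")
    return paths
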