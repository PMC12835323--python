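"""Synthetic anesthesia EEG and synthetic patient cohorts.

Two generators make the whole pipeline testable without any recorded data:

``generate_eeg`` builds multichannel recordings of agent-specific
anesthesia background — propofol: coherent alpha (8-12 Hz) plus slow-delta
(0.5-4 Hz) oscillations; sevoflurane: coherent theta (4-8 Hz) — over
broadband noise, and injects burst-suppression episodes with exact
ground-truth interval labels: each episode alternates low-amplitude
suppression segments with polyphasic bursts that satisfy the ACNS burst
criteria used by the detector (>= 0.5 s, >= 4 phases).

``generate_cohort`` builds patient tables with the conditional
postoperative-delirium (POD) risk structure of a two-agent cohort: POD is
Bernoulli with

    logit p = logit(p0) + log(OR_sevo)*sevo + log(OR_bs)*bs
              + log(OR_int)*sevo*bs            [+ log(OR_h)*surgery_hours]

so the four agent x BS cells carry conditional odds ratios
(1, OR_bs, OR_sevo, OR_sevo*OR_bs*OR_int) relative to propofol without BS.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning; the same seed reproduces signals and tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import LabeledRecording
from .io import AnnotationTrack, EEGRecording, Interval, ValidationError

__all__ = [
    "EEGSimSpec",
    "CohortSimSpec",
    "Episode",
    "generate_eeg",
    "generate_corpus",
    "generate_cohort",
    "DEFAULT_CHANNELS",
]

DEFAULT_CHANNELS = ("Fp1", "Fp2", "F7", "F8")

#: Fraction of recordings with zero BS per agent at "low" episode intensity;
#: propofol recordings receive stochastically longer BS than sevoflurane ones,
#: mirroring cohorts where propofol shows the longer suppression tail.
_INTENSITY = {
    "none": {"propofol": (1.0, None), "sevoflurane": (1.0, None)},
    "low": {
        "propofol": (0.45, (np.log(45.0), 1.1)),
        "sevoflurane": (0.65, (np.log(6.0), 1.0)),
    },
    "high": {
        "propofol": (0.10, (np.log(90.0), 0.9)),
        "sevoflurane": (0.30, (np.log(30.0), 0.9)),
    },
}


@dataclass(frozen=True)
class Episode:
    """Plan for one injected BS episode.

    ``n_alternations`` bursts are interleaved between ``n_alternations + 1``
    suppression segments, so the episode is delimited by suppressions on
    both sides (matching the epoch definition used downstream).
    """

    onset: float
    supp_duration: float
    burst_duration: float
    n_alternations: int = 1

    @property
    def span(self) -> float:
        return (self.n_alternations + 1) * self.supp_duration + (
            self.n_alternations * self.burst_duration
        )

    @property
    def total_suppression(self) -> float:
        return (self.n_alternations + 1) * self.supp_duration


@dataclass
class EEGSimSpec:
    """Specification of one simulated anesthesia-EEG recording."""

    agent: str = "propofol"
    duration: float = 300.0
    fs: float = 178.0
    n_channels: int = 4
    background_rms: float = 15.0
    episode_plan: list[Episode] = field(default_factory=list)
    suppression_rms: float = 1.5
    burst_amp: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.agent not in ("propofol", "sevoflurane"):
            raise ValidationError(f"unknown agent {self.agent!r}")
        if self.duration <= 0 or self.fs <= 0 or self.n_channels < 1:
            raise ValidationError("duration, fs and n_channels must be positive")
        eps = sorted(self.episode_plan, key=lambda e: e.onset)
        end = 0.0
        for e in eps:
            if e.onset < end:
                raise ValidationError(
                    f"episode at {e.onset:.3f} s overlaps the previous one"
                )
            if e.onset + e.span > self.duration + 1e-9:
                raise ValidationError(
                    f"episode at {e.onset:.3f} s extends past the recording end"
                )
            end = e.onset + e.span
        self.episode_plan = eps


def _channel_labels(n: int) -> list[str]:
    labels = list(DEFAULT_CHANNELS[:n])
    labels += [f"EEG{i + 1}" for i in range(len(labels), n)]
    return labels


def _background(rng: np.random.Generator, n: int, fs: float, agent: str, rms: float) -> np.ndarray:
    """Agent-specific background: band oscillations over broadband noise."""
    t = np.arange(n) / fs
    if agent == "propofol":
        # coherent alpha + slow-delta; alpha dominates the spectral peak
        comps = [(10.0, 0.55 * rms), (1.5, 0.40 * rms)]
    else:
        comps = [(6.0, 0.60 * rms)]
    osc = np.zeros(n)
    for f0, comp_rms in comps:
        phase = rng.uniform(0, 2 * np.pi)
        osc += comp_rms * np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + phase)
    noise_var = rms**2 - sum(c[1] ** 2 for c in comps)
    noise = rng.standard_normal(n) * np.sqrt(max(noise_var, 0.0))
    return osc + noise


def _episode_segments(ep: Episode) -> list[tuple[float, float, str]]:
    """(onset, duration, kind) pieces of one episode, kind in {supp, burst}."""
    out = []
    t = ep.onset
    for i in range(ep.n_alternations):
        out.append((t, ep.supp_duration, "supp"))
        t += ep.supp_duration
        out.append((t, ep.burst_duration, "burst"))
        t += ep.burst_duration
    out.append((t, ep.supp_duration, "supp"))
    return out


def generate_eeg(spec: EEGSimSpec) -> tuple[EEGRecording, AnnotationTrack]:
    """Simulate one recording and its ground-truth annotation track.

    Episode timing is identical across channels (suppression is a global
    cortical state); channel noise realizations differ.  The truth track
    holds every suppression interval (channel ``"all"``), every burst, and
    each episode as a ``bs_epoch``.  Bit-identical for identical specs.
    """
    n = int(round(spec.duration * spec.fs))
    ss = np.random.SeedSequence(spec.seed)
    ch_seeds = ss.spawn(spec.n_channels)
    signal = np.empty((spec.n_channels, n))

    segments = [seg for ep in spec.episode_plan for seg in _episode_segments(ep)]
    burst_freq = 10.0  # polyphasic burst carrier; 2*f*d phases per segment

    for c in range(spec.n_channels):
        rng = np.random.default_rng(ch_seeds[c])
        x = _background(rng, n, spec.fs, spec.agent, spec.background_rms)
        for onset, dur, kind in segments:
            s = int(round(onset * spec.fs))
            e = min(int(round((onset + dur) * spec.fs)), n)
            if kind == "supp":
                x[s:e] = rng.standard_normal(e - s) * spec.suppression_rms
            else:
                tt = np.arange(e - s) / spec.fs
                x[s:e] = spec.burst_amp * np.sin(2 * np.pi * burst_freq * tt)
        signal[c] = x

    intervals = []
    for onset, dur, kind in segments:
        label = "suppression" if kind == "supp" else "burst"
        intervals.append(Interval(onset=onset, duration=dur, label=label, channel="all"))
    for ep in spec.episode_plan:
        intervals.append(Interval(onset=ep.onset, duration=ep.span, label="bs_epoch"))

    rec = EEGRecording(
        signal=signal, fs=spec.fs, channel_labels=_channel_labels(spec.n_channels)
    )
    track = AnnotationTrack(intervals=intervals)
    return rec, track


def _plan_episodes(
    rng: np.random.Generator, total_supp: float, duration: float
) -> list[Episode]:
    """Turn a total suppression budget into non-overlapping episodes.

    Suppression is split into segments of a few seconds, grouped into
    episodes of 1-3 alternations with ~1 s bursts between, and the episodes
    are placed at random non-overlapping onsets with a margin at both ends.
    """
    total_supp = min(total_supp, 0.5 * duration)
    if total_supp <= 0:
        return []
    episodes: list[tuple[float, float, int]] = []  # (supp_dur, burst_dur, n_alt)
    remaining = total_supp
    while remaining > 1e-9:
        n_alt = int(rng.integers(1, 4))
        seg = float(np.clip(rng.lognormal(np.log(4.0), 0.5), 1.0, 12.0))
        need = (n_alt + 1) * seg
        if need > remaining:
            n_alt = 1
            seg = max(remaining / 2.0, 0.75)
        burst = float(rng.uniform(0.6, 1.5))
        episodes.append((seg, burst, n_alt))
        remaining -= (n_alt + 1) * seg
    spans = [(n + 1) * s + n * b for s, b, n in episodes]
    margin = 5.0
    slack = duration - 2 * margin - sum(spans)
    while slack < 0 and len(episodes) > 1:
        episodes.pop()
        spans.pop()
        slack = duration - 2 * margin - sum(spans)
    gaps = rng.dirichlet(np.ones(len(episodes) + 1)) * max(slack, 0.0)
    out = []
    t = margin + gaps[0]
    for (s, b, n_alt), span, g in zip(episodes, spans, gaps[1:]):
        out.append(Episode(onset=round(t, 3), supp_duration=round(s, 3),
                           burst_duration=round(b, 3), n_alternations=n_alt))
        t += span + g
    return out


def generate_corpus(
    n_per_group: int,
    episode_intensity: str = "low",
    seed: int = 0,
    duration: float = 600.0,
    fs: float = 178.0,
) -> list[LabeledRecording]:
    """Simulate an annotated two-agent corpus for calibration experiments.

    ``episode_intensity`` controls the per-recording total true suppression:
    ``"none"`` gives BS-free recordings; ``"low"`` draws from a
    zero-inflated log-normal with many zeros (propofol 45% zeros,
    sevoflurane 65%) and a longer propofol tail; ``"high"`` has few zeros
    and longer suppression.  Reproducible from ``seed``.
    """
    if episode_intensity not in _INTENSITY:
        raise ValidationError(
            f"episode_intensity must be one of {sorted(_INTENSITY)}"
        )
    ss = np.random.SeedSequence(seed)
    corpus: list[LabeledRecording] = []
    for agent in ("propofol", "sevoflurane"):
        p_zero, lognorm = _INTENSITY[episode_intensity][agent]
        for i, child in enumerate(ss.spawn(n_per_group)):
            rng = np.random.default_rng(child)
            plan_seed = int(rng.integers(0, 2**31 - 1))
            if rng.uniform() < p_zero or lognorm is None:
                plan = []
            else:
                mu, sigma = lognorm
                total = float(rng.lognormal(mu, sigma))
                plan = _plan_episodes(rng, total, duration)
            spec = EEGSimSpec(
                agent=agent,
                duration=duration,
                fs=fs,
                episode_plan=plan,
                seed=plan_seed,
            )
            rec, truth = generate_eeg(spec)
            rid = f"{agent[:4]}-{i:03d}"
            truth.recording_id = rid
            corpus.append(
                LabeledRecording(recording=rec, truth=truth, group=agent, recording_id=rid)
            )
    return corpus


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSimSpec:
    """Specification of a synthetic patient cohort.

    The default odds ratios (1.50 for BS under propofol, 1.63 for
    sevoflurane without BS, 3.80 multiplicative interaction, hence
    1.50*1.63*3.80 = 9.30 for sevoflurane with BS) and the BS-presence
    probabilities reproduce the conditional risk structure of an elderly
    two-agent surgical cohort; ``baseline_pod`` is the POD probability in
    the propofol/no-BS reference cell.
    """

    n: int = 265
    p_sevo: float = 126 / 265
    p_bs_given_propofol: float = 0.55
    p_bs_given_sevo: float = 0.35
    baseline_pod: float = 0.25
    or_bs: float = 1.50
    or_sevo: float = 1.63
    or_interaction: float = 3.80
    age_mean: float = 77.0
    age_sd: float = 5.0
    asa_probs: tuple[float, float, float, float] = (0.03, 0.44, 0.51, 0.02)
    surgery_mean_h: float = 2.7
    surgery_sd_h: float = 1.0
    or_surgery_per_h: float = 1.0  # set to e.g. 1.27 for a duration effect
    p_pacu_icu: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_sevo", "p_bs_given_propofol", "p_bs_given_sevo", "baseline_pod"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        for name in ("or_bs", "or_sevo", "or_interaction", "or_surgery_per_h"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if abs(sum(self.asa_probs) - 1.0) > 1e-9:
            raise ValidationError("asa_probs must sum to 1")


def generate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a patient cohort table.

    Columns: ``id, agent, pod, age, asa, surgery_duration, bs_duration,
    bsr, any_bs, care_location``; surgery duration in hours, BS duration in
    seconds, BSR in percent of surgery time.  Covariates are independent of
    the outcome unless ``or_surgery_per_h != 1``.  Deterministic per seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n
    sevo = rng.uniform(size=n) < spec.p_sevo
    p_bs = np.where(sevo, spec.p_bs_given_sevo, spec.p_bs_given_propofol)
    any_bs = rng.uniform(size=n) < p_bs

    surgery_h = np.clip(rng.normal(spec.surgery_mean_h, spec.surgery_sd_h, n), 0.5, None)
    logit = (
        np.log(spec.baseline_pod / (1 - spec.baseline_pod))
        + np.log(spec.or_sevo) * sevo
        + np.log(spec.or_bs) * any_bs
        + np.log(spec.or_interaction) * (sevo & any_bs)
        + np.log(spec.or_surgery_per_h) * surgery_h
    )
    p_pod = 1.0 / (1.0 + np.exp(-logit))
    pod = rng.uniform(size=n) < p_pod

    # BS duration: zero when no BS, log-normal tail otherwise (longer under
    # propofol, mirroring the observed skew)
    mu = np.where(sevo, np.log(6.0), np.log(45.0))
    draw = np.clip(rng.lognormal(mu, 1.0), 0.5, 0.5 * surgery_h * 3600.0)
    bs_dur = np.where(any_bs, draw, 0.0)
    bsr = 100.0 * bs_dur / (surgery_h * 3600.0)

    table = pd.DataFrame(
        {
            "id": [f"p{i:06d}" for i in range(n)],
            "agent": np.where(sevo, "sevoflurane", "propofol"),
            "pod": pod.astype(int),
            "age": np.round(rng.normal(spec.age_mean, spec.age_sd, n), 1),
            "asa": rng.choice([1, 2, 3, 4], size=n, p=spec.asa_probs),
            "surgery_duration": np.round(surgery_h, 3),
            "bs_duration": np.round(bs_dur, 3),
            "bsr": bsr,
            "any_bs": any_bs.astype(int),
            "care_location": np.where(
                rng.uniform(size=n) < spec.p_pacu_icu, "pacu_icu", "recovery"
            ),
        }
    )
    return table
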