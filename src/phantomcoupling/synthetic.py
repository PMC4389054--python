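"""Synthetic EEG cohorts with planted theta-gamma coupling and behavior.

Everything the analysis pipeline consumes is emulated here with known
ground truth: dipole source currents in which one source carries a theta
oscillation and another carries a gamma oscillation whose amplitude is
modulated by the theta phase; instantaneous (volume-conducted) mixing to
19 scalp sensors through a leadfield; additive sensor noise at a
controlled SNR; and per-subject behavioral scores (subjective loudness on
a 0-10 numeric rating scale, passively matched loudness in dB SL) whose
statistical link to the planted coupling strength is configurable.

The matching staircase is simulated too: a deterministic responder
compares the presented pure tone to the true percept, pitch converges by
octave then half-octave steps (1 kHz start, 12 kHz cap) and level by 2 dB
steps (10 dB SL start, 80 dB HL cap); sensation level is hearing level
minus the individual threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import MONTAGE_10_20, EEGRecording
from .inverse import LeadField


@dataclass(frozen=True)
class CouplingConfig:
    """Generator settings for one subject's source activity.

    ``theta_hz`` must lie in the theta band (4-7.5 Hz) and ``gamma_hz`` in
    the gamma band (30.5-44 Hz). ``mod_depth`` is the fraction of the gamma
    amplitude that follows the theta waveform; 0 = constant envelope,
    1 = fully nested. ``snr_db`` is the sensor-level signal-to-noise ratio.
    Defaults mirror a resting-state acquisition: 500 Hz sampling, 5 min.
    """

    theta_hz: float = 6.0
    gamma_hz: float = 40.0
    mod_depth: float = 0.5
    snr_db: float = 10.0
    duration_s: float = 300.0
    rate_hz: float = 500.0
    n_sources: int = 16
    background_amp: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mod_depth <= 1.0):
            raise ValueError("mod_depth must be in [0, 1]")
        if not (4.0 <= self.theta_hz <= 7.5):
            raise ValueError("theta_hz must lie in the 4-7.5 Hz theta band")
        if not (30.5 <= self.gamma_hz <= 44.0):
            raise ValueError("gamma_hz must lie in the 30.5-44 Hz gamma band")
        if self.gamma_hz >= self.rate_hz / 2:
            raise ValueError("gamma_hz must be below the Nyquist frequency")
        n = self.duration_s * self.rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * rate_hz must be an integer")
        if self.n_sources < 3:
            raise ValueError("need at least 3 sources (theta, gamma, noise)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))


@dataclass
class SourceSimulation:
    """Planted dipole currents: ``source_currents`` is sources x 3 x samples.

    ``truth`` labels each source as ``theta-carrier``, ``gamma-modulated``
    or ``noise``.
    """

    source_currents: np.ndarray
    truth: tuple[str, ...]
    mod_depth: float
    rate_hz: float

    def __post_init__(self) -> None:
        if self.source_currents.ndim != 3 or self.source_currents.shape[1] != 3:
            raise ValueError("source_currents must be sources x 3 x samples")
        if len(self.truth) != self.source_currents.shape[0]:
            raise ValueError("truth labels must cover all sources")

    @property
    def theta_index(self) -> int:
        return self.truth.index("theta-carrier")

    @property
    def gamma_index(self) -> int:
        return self.truth.index("gamma-modulated")


@dataclass(frozen=True)
class StaircaseConfig:
    """Tinnitus-matching staircase settings (steps in octaves / dB)."""

    start_offset_db: float = 10.0
    coarse_step: float = 1.0     # octaves
    fine_step: float = 0.5       # octaves
    level_step_db: float = 2.0
    max_hz: float = 12000.0
    max_level_db_hl: float = 80.0
    start_hz: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("coarse_step", "fine_step", "level_step_db", "start_hz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class BehavioralRecord:
    """One subject's loudness measures.

    ``matched_db_sl = matched_db_hl - threshold_db_hl`` by construction
    (sensation level compensates the individual hearing threshold at the
    matched frequency).
    """

    subject_id: str
    nrs_loudness: float
    matched_db_hl: float
    threshold_db_hl: float
    matched_hz: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.nrs_loudness <= 10.0):
            raise ValueError("nrs_loudness must be in [0, 10]")
        if self.matched_hz > 12000.0:
            raise ValueError("matched_hz above the 12 kHz staircase cap")
        if self.matched_db_hl > 80.0:
            raise ValueError("matched_db_hl above the 80 dB HL staircase cap")

    @property
    def matched_db_sl(self) -> float:
        return self.matched_db_hl - self.threshold_db_hl

    def as_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "nrs": self.nrs_loudness,
            "db_sl": self.matched_db_sl,
            "db_hl": self.matched_db_hl,
            "threshold_db": self.threshold_db_hl,
            "hz": self.matched_hz,
        }


# ---------------------------------------------------------------------------
# source simulation


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f power-spectral-slope noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    with np.errstate(divide="ignore"):
        shaping = np.where(freqs > 0, freqs ** -0.5, 0.0)
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_subject_sources(cfg: CouplingConfig) -> SourceSimulation:
    """Plant a theta carrier, a theta-phase-modulated gamma source, and
    1/f background sources.

    The gamma waveform is ``[1 - d + d*m(t)] * sin(2*pi*f_gamma*t)`` where
    ``d`` is ``mod_depth`` and ``m(t)`` is the theta carrier min-max
    normalized to [0, 1], so at d=1 the envelope is an affine image of the
    theta waveform and at d=0 it is constant. Every source's current
    points along the fixed +z orientation: the sign of the nesting
    statistic's theta component is pinned by a (deterministic but
    arbitrary) sign convention, so a random dipole orientation would
    randomize the sign of the planted theta-envelope correlation; a fixed
    orientation makes the planted coupling consistently positive across
    subjects, as consistent cortical dipole geometry would in real data.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    t = np.arange(n) / cfg.rate_hz

    theta = np.sin(2 * np.pi * cfg.theta_hz * t + rng.uniform(0, 2 * np.pi))
    m = (theta - theta.min()) / (theta.max() - theta.min())
    envelope = 1.0 - cfg.mod_depth + cfg.mod_depth * m
    gamma = envelope * np.sin(2 * np.pi * cfg.gamma_hz * t + rng.uniform(0, 2 * np.pi))

    waves = np.empty((cfg.n_sources, n))
    labels = []
    for j in range(cfg.n_sources):
        if j == 0:
            waves[j], lab = theta, "theta-carrier"
        elif j == 1:
            waves[j], lab = gamma, "gamma-modulated"
        else:
            waves[j], lab = cfg.background_amp * _pink_noise(n, rng), "noise"
        labels.append(lab)

    orients = np.tile(np.array([0.0, 0.0, 1.0]), (cfg.n_sources, 1))
    currents = orients[:, :, None] * waves[:, None, :]
    return SourceSimulation(
        source_currents=currents,
        truth=tuple(labels),
        mod_depth=cfg.mod_depth,
        rate_hz=cfg.rate_hz,
    )


def project_to_sensors(
    sim: SourceSimulation,
    lf: LeadField,
    snr_db: float,
    seed: int,
) -> EEGRecording:
    """Forward-project source currents through the leadfield and add white
    Gaussian sensor noise at the requested SNR.

    The noise variance per channel is (mean clean sensor power) / 10^(snr/10).
    A recording with zero source currents gets unit-variance noise (the SNR
    is undefined there; the convention keeps the output well defined).
    """
    n_src = lf.n_sources
    if sim.source_currents.shape[0] != n_src:
        raise ValueError(
            f"leadfield has {n_src} sources, simulation has {sim.source_currents.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    n = sim.source_currents.shape[2]
    clean = lf.gain @ sim.source_currents.reshape(n_src * 3, n)
    sig_power = float(np.mean(clean**2))
    if sig_power > 0:
        noise_var = sig_power / 10 ** (snr_db / 10.0)
    else:
        noise_var = 1.0
    noisy = clean + math.sqrt(noise_var) * rng.standard_normal(clean.shape)
    labels = tuple(lf.sensor_labels) if lf.sensor_labels else MONTAGE_10_20[: clean.shape[0]]
    return EEGRecording(data=noisy, rate_hz=sim.rate_hz, channel_labels=labels)


# ---------------------------------------------------------------------------
# matching staircase


def _pitch_response(presented_hz: float, true_hz: float, tol_oct: float) -> int:
    """Deterministic responder: +1 tinnitus higher, -1 lower, 0 match."""
    diff = math.log2(true_hz / presented_hz)
    if abs(diff) <= tol_oct:
        return 0
    return 1 if diff > 0 else -1


def simulate_matching_staircase(
    true_hz: float,
    true_db_hl: float,
    threshold_db_hl: float,
    cfg: StaircaseConfig | None = None,
    subject_id: str = "s0",
    nrs_loudness: float = 5.0,
) -> BehavioralRecord:
    """Run the pitch-then-level matching staircase against a deterministic
    responder whose percept is (``true_hz``, ``true_db_hl``).

    Pitch starts at 1 kHz and moves in octave steps until the responder's
    direction reverses (or matches), then refines in half-octave steps;
    level starts 10 dB above threshold and moves in 2 dB steps. The match
    is guaranteed within half the final step of the truth on each axis.
    """
    cfg = cfg or StaircaseConfig()
    if not (0 < true_hz <= cfg.max_hz):
        raise ValueError("true_hz outside (0, max_hz]")
    if true_db_hl > cfg.max_level_db_hl:
        raise ValueError("true_db_hl above max_level_db_hl")

    # --- pitch phase: octave steps, then half-octave refinement
    hz = cfg.start_hz
    for step_oct in (cfg.coarse_step, cfg.fine_step):
        tol = cfg.fine_step / 2.0
        direction = _pitch_response(hz, true_hz, tol)
        while direction != 0:
            nxt = hz * 2.0 ** (direction * step_oct)
            nxt = min(nxt, cfg.max_hz)
            if nxt == hz:  # pinned at the cap
                break
            new_dir = _pitch_response(nxt, true_hz, tol)
            hz = nxt
            if new_dir != direction:
                direction = new_dir if step_oct == cfg.coarse_step else 0
                break
            direction = new_dir
    matched_hz = hz

    # --- level phase: 2 dB steps from 10 dB SL toward the percept
    level = min(threshold_db_hl + cfg.start_offset_db, cfg.max_level_db_hl)
    tol_db = cfg.level_step_db / 2.0
    while abs(true_db_hl - level) > tol_db:
        step = math.copysign(cfg.level_step_db, true_db_hl - level)
        nxt = min(level + step, cfg.max_level_db_hl)
        if nxt == level:
            break
        # stop at the closer of the two grid points when about to overshoot
        if abs(true_db_hl - nxt) >= abs(true_db_hl - level):
            break
        level = nxt
    matched_db_hl = level

    return BehavioralRecord(
        subject_id=subject_id,
        nrs_loudness=nrs_loudness,
        matched_db_hl=matched_db_hl,
        threshold_db_hl=threshold_db_hl,
        matched_hz=matched_hz,
    )


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(
    n_subjects: int,
    mod_depth_range: tuple[float, float] = (0.0, 1.0),
    behavior_link_r: float = 0.45,
    seed: int = 0,
    coupling: CouplingConfig | None = None,
    leadfield: LeadField | None = None,
    make_recordings: bool = True,
) -> tuple[list[EEGRecording] | None, pd.DataFrame, pd.DataFrame]:
    """Generate a cohort with a controlled coupling-behavior link.

    Per subject, ``mod_depth`` is drawn uniformly from ``mod_depth_range``;
    the subjective loudness (NRS, 0-10) is built so that
    corr(mod_depth, nrs) targets ``behavior_link_r`` in expectation, while
    the passively matched level (dB SL) is generated independently of
    mod_depth — the cohort's two loudness measures are therefore
    dissociated by construction. Returns (recordings, behavior table,
    truth table); with ``make_recordings=False`` the EEG is skipped (the
    behavioral/truth tables are identical either way).
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    if not (-1.0 <= behavior_link_r <= 1.0):
        raise ValueError("behavior_link_r must be in [-1, 1]")
    lo, hi = mod_depth_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("mod_depth_range must be within [0, 1] with lo <= hi")

    rng = np.random.default_rng(seed)
    depths = rng.uniform(lo, hi, n_subjects)
    if hi > lo:
        z = (depths - depths.mean()) / depths.std()
    else:
        z = np.zeros(n_subjects)
    r = behavior_link_r
    noise = rng.standard_normal(n_subjects)
    latent = r * z + math.sqrt(max(0.0, 1.0 - r * r)) * noise
    nrs = np.clip(5.0 + 2.0 * latent, 0.0, 10.0)

    # percept loudness independent of coupling strength (the dissociation)
    thresholds = np.round(rng.uniform(0.0, 40.0, n_subjects) / 5.0) * 5.0
    true_sl = rng.uniform(2.0, 30.0, n_subjects)
    true_hz = 2.0 ** rng.uniform(math.log2(250.0), math.log2(8000.0), n_subjects)

    base = coupling or CouplingConfig()
    recs: list[EEGRecording] | None = [] if make_recordings else None
    if make_recordings and leadfield is None:
        from .inverse import toy_leadfield

        leadfield = toy_leadfield(n_sources=base.n_sources)

    behav_rows, truth_rows = [], []
    for i in range(n_subjects):
        sid = f"subj{i:03d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        true_db_hl = min(thresholds[i] + true_sl[i], 80.0)
        rec_b = simulate_matching_staircase(
            true_hz=float(true_hz[i]),
            true_db_hl=float(true_db_hl),
            threshold_db_hl=float(thresholds[i]),
            subject_id=sid,
            nrs_loudness=float(nrs[i]),
        )
        behav_rows.append(rec_b.as_row())
        truth_rows.append(
            {
                "subject_id": sid,
                "mod_depth": float(depths[i]),
                "true_hz": float(true_hz[i]),
                "true_db_hl": float(true_db_hl),
                "seed": sub_seed,
            }
        )
        if make_recordings:
            cfg_i = CouplingConfig(
                theta_hz=base.theta_hz,
                gamma_hz=base.gamma_hz,
                mod_depth=float(depths[i]),
                snr_db=base.snr_db,
                duration_s=base.duration_s,
                rate_hz=base.rate_hz,
                n_sources=base.n_sources,
                seed=sub_seed,
            )
            sim = simulate_subject_sources(cfg_i)
            recs.append(project_to_sensors(sim, leadfield, base.snr_db, sub_seed + 1))

    behavior = pd.DataFrame(behav_rows)
    truth = pd.DataFrame(truth_rows)
    return recs, behavior, truth


# ---------------------------------------------------------------------------
# text output


def write_recording_text(rec: EEGRecording, path) -> None:
    """Write a recording as tab-delimited samples x channels text with a
    ``# rate_hz=... channels=...`` header line."""
    header = f"# rate_hz={rec.rate_hz} channels={','.join(rec.channel_labels)}"
    np.savetxt(path, rec.data.T, delimiter="\t", header=header, comments="")


def write_cohort(
    out_dir,
    recordings: list[EEGRecording],
    behavior: pd.DataFrame,
    truth: pd.DataFrame,
) -> None:
    """Write one delimited text file per subject plus behavior/truth tables."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec, sid in zip(recordings, behavior["subject_id"]):
        write_recording_text(rec, out / f"{sid}.tsv")
    behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
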