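"""Seeded synthetic fNIRS cohorts with a calibrated group structure.

The generator emulates the study conditions end to end: an 8-channel
760/850 nm prefrontal montage at 10 Hz, a 3 min eyes-closed rest followed
by 15 digit-span blocks (encoding / verbal recall / 10 s rest), and two
groups (84 healthy, 52 amnestic-MCI) whose regional mean-HbO features,
demographics, and MoCA-K association reproduce the reported group moments
in expectation *after* the default preprocessing pipeline.

Forward model per subject
-------------------------
True HbO per channel is a regional amplitude times a unit response
(boxcar over each encoding period convolved with a canonical double-gamma
HRF).  The amplitude is pre-compensated for the two deterministic gains of
the default pipeline: the band-pass/epoch/window gain ``c`` of the unit
response, and the linear mixing ``M`` that removal of the systemic spatial
component applies to the two regional means.  Physiological interference
(Mayer waves, respiration, cardiac pulsation) is added as sinusoids
sharing one fixed spatial profile across channels — the pattern the
eigenvector spatial filter is meant to remove — plus per-channel white
noise, slow drift, and sparse spike artifacts.  HbR is tied to HbO by a
fixed negative ratio, and the pair is pushed through the forward
Beer-Lambert model to yield strictly positive two-wavelength intensities
around a unit baseline.

MoCA-K is drawn jointly with the left-PFC amplitude from a bivariate
normal whose latent within-group correlation is numerically calibrated so
the pooled correlation across both groups, after rounding MoCA-K to
integer points, hits the target.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataio import AcquisitionSpec, EventTable, EVENT_COLUMNS, RawRecording
from .features import FeatureConfig
from .preprocess import MBLLParams, PreprocConfig, bandpass, mbll_forward

# Fixed spatial profile of the systemic interference across the 8-channel
# montage (arbitrary units).  Deliberately heterogeneous within each
# hemisphere so that projecting it out leaves the regional means
# identifiable (the mixing matrix M below stays well conditioned).
SYSTEMIC_PROFILE = np.array([1.5, 0.3, 0.9, 0.7, 0.2, 1.1, 0.5, 0.8])


def systemic_profile(n_channels: int) -> np.ndarray:
    return np.resize(SYSTEMIC_PROFILE, n_channels)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HrfSpec:
    """Canonical double-gamma hemodynamic response, seconds."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    def __post_init__(self) -> None:
        if min(self.peak_delay, self.undershoot_delay,
               self.peak_dispersion, self.undershoot_dispersion) <= 0:
            raise ValueError("HRF delays and dispersions must be positive")
        if not 0 <= self.undershoot_ratio < 1:
            raise ValueError("undershoot_ratio must be in [0, 1)")

    def kernel(self, sampling_rate: float) -> np.ndarray:
        t = np.arange(0, self.duration, 1.0 / sampling_rate)
        peak = stats.gamma.pdf(t, self.peak_delay / self.peak_dispersion,
                               scale=self.peak_dispersion)
        under = stats.gamma.pdf(t, self.undershoot_delay / self.undershoot_dispersion,
                                scale=self.undershoot_dispersion)
        h = peak - self.undershoot_ratio * under
        if h.sum() <= 0:
            raise ValueError("HRF must integrate to a positive value")
        return h


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model, concentration units (uM*mm) and Hz.

    Cardiac/respiration/Mayer components are global sinusoids sharing the
    fixed systemic spatial profile; white noise, drift, and spikes are
    independent per channel.
    """

    cardiac_freq: float = 1.1
    cardiac_amplitude: float = 0.4
    resp_freq: float = 0.25
    resp_amplitude: float = 0.6
    mayer_freq: float = 0.095
    mayer_amplitude: float = 2.0
    white_noise_sd: float = 0.5
    drift_slope: float = 0.005  # per second
    spike_rate: float = 0.3  # per minute per channel
    spike_amplitude: float = 5.0
    spike_width_s: float = 0.3

    def __post_init__(self) -> None:
        amps = (self.cardiac_amplitude, self.resp_amplitude, self.mayer_amplitude,
                self.white_noise_sd, self.spike_rate, self.spike_amplitude)
        if any(a < 0 for a in amps):
            raise ValueError("noise amplitudes must be non-negative")

    def validate_frequencies(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        for f in (self.cardiac_freq, self.resp_freq, self.mayer_freq):
            if not 0 < f < nyq:
                raise ValueError(f"noise frequency {f} Hz outside (0, Nyquist={nyq})")

    @property
    def has_global_component(self) -> bool:
        return (self.cardiac_amplitude + self.resp_amplitude + self.mayer_amplitude) > 0

    def inband_global_dominates(
        self,
        sampling_rate: float,
        band: tuple[float, float],
        filter_order: int,
        margin: float = 5.0,
    ) -> bool:
        """Whether the systemic component is estimable from filtered rest data.

        Compares the post-band-pass RMS of the global sinusoids against the
        in-band white-noise RMS; only when the global component dominates
        does the rest-period leading eigenvector recover its spatial
        profile (and only then does the generator pre-compensate for its
        removal).
        """
        from .preprocess import butter_bandpass_gain

        rms_global = 0.0
        for freq, amp in ((self.cardiac_freq, self.cardiac_amplitude),
                          (self.resp_freq, self.resp_amplitude),
                          (self.mayer_freq, self.mayer_amplitude)):
            if amp > 0:
                gain = float(butter_bandpass_gain(freq, sampling_rate, band, filter_order)[0])
                rms_global += (amp * gain) ** 2 / 2.0
        rms_global = np.sqrt(rms_global)
        if rms_global == 0:
            return False
        if self.white_noise_sd == 0:
            return True
        freqs = np.linspace(1e-3, sampling_rate / 2 * 0.999, 512)
        gains = butter_bandpass_gain(freqs, sampling_rate, band, filter_order)
        enbw_frac = float(np.trapezoid(gains**2, freqs)) / (sampling_rate / 2.0)
        rms_white = self.white_noise_sd * np.sqrt(enbw_frac)
        return rms_global > margin * rms_white

    def quiet(self) -> "NoiseSpec":
        """Copy with every noise source off (for oracle checks)."""
        return NoiseSpec(cardiac_amplitude=0.0, resp_amplitude=0.0,
                         mayer_amplitude=0.0, white_noise_sd=0.0,
                         drift_slope=0.0, spike_rate=0.0, spike_amplitude=0.0)


@dataclass(frozen=True)
class BlockTimingSpec:
    """Task schedule: 3 min rest then 15 encoding/recall/rest blocks."""

    initial_rest: float = 180.0
    n_blocks: int = 15
    encoding_duration: float = 6.0
    recall_duration: float = 6.0
    inter_block_rest: float = 10.0

    def __post_init__(self) -> None:
        if min(self.initial_rest, self.encoding_duration,
               self.recall_duration, self.inter_block_rest) <= 0:
            raise ValueError("all durations must be positive")
        if self.n_blocks < 1:
            raise ValueError("need at least one block")

    @property
    def block_length(self) -> float:
        return self.encoding_duration + self.recall_duration + self.inter_block_rest

    @property
    def total_duration(self) -> float:
        return self.initial_rest + self.n_blocks * self.block_length

    def encoding_onsets(self) -> np.ndarray:
        return self.initial_rest + np.arange(self.n_blocks) * self.block_length


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes and the published group moments the generator targets.

    Regional amplitude moments are (mean, sd) of mHbO in uM*mm; MoCA-K
    and digit-span (VDST) scores in points; demographics for cohort
    completeness only (they do not enter the signal model).
    ``moca_mhbo_correlation`` is the pooled Pearson correlation between
    MoCA-K and left-PFC mHbO across both groups.
    """

    n_healthy: int = 84
    n_mci: int = 52
    healthy_left: tuple[float, float] = (0.977, 0.244)
    mci_left: tuple[float, float] = (0.591, 0.163)
    healthy_right: tuple[float, float] = (0.895, 0.222)
    mci_right: tuple[float, float] = (0.655, 0.138)
    healthy_total_sd: float = 0.220
    mci_total_sd: float = 0.148
    healthy_moca: tuple[float, float] = (25.86, 1.74)
    mci_moca: tuple[float, float] = (22.44, 1.95)
    healthy_vdst: tuple[float, float] = (14.45, 0.75)
    mci_vdst: tuple[float, float] = (13.35, 1.10)
    healthy_age: tuple[float, float] = (73.61, 6.38)
    mci_age: tuple[float, float] = (75.35, 5.98)
    healthy_education: tuple[float, float] = (6.88, 4.23)
    mci_education: tuple[float, float] = (6.00, 4.32)
    healthy_males: int = 37
    mci_males: int = 21
    moca_mhbo_correlation: float = 0.500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy <= 0 or self.n_mci <= 0:
            raise ValueError("group sizes must be positive")
        if not abs(self.moca_mhbo_correlation) < 1:
            raise ValueError("|correlation| must be < 1")
        for name in ("healthy_left", "mci_left", "healthy_right", "mci_right",
                     "healthy_moca", "mci_moca", "healthy_vdst", "mci_vdst"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name} sd must be positive")

    def group_moments(self, group: str) -> dict:
        g = "healthy" if group == "healthy" else "mci"
        return {
            "left": getattr(self, f"{g}_left"),
            "right": getattr(self, f"{g}_right"),
            "total_sd": getattr(self, f"{g}_total_sd"),
            "moca": getattr(self, f"{g}_moca"),
            "vdst": getattr(self, f"{g}_vdst"),
            "age": getattr(self, f"{g}_age"),
            "education": getattr(self, f"{g}_education"),
        }

    def interhemi_correlation(self, group: str) -> float:
        """Left/right amplitude correlation implied by the total-PFC sd.

        With equal channel counts per hemisphere the total feature is the
        mean of the two regional features, so
        4*var_total = var_L + var_R + 2*rho*sd_L*sd_R.
        """
        m = self.group_moments(group)
        s_l, s_r, s_t = m["left"][1], m["right"][1], m["total_sd"]
        rho = (4 * s_t**2 - s_l**2 - s_r**2) / (2 * s_l * s_r)
        return float(np.clip(rho, -0.999, 0.999))


# ---------------------------------------------------------------------------
# Calibration of the MoCA / mHbO joint distribution
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=32)
def calibrate_latent_correlation(
    cohort: CohortSpec, n_draws: int = 200_000, seed: int = 1_234_567
) -> float:
    """Within-group latent correlation hitting the pooled target after rounding.

    The pooled (both groups) Pearson correlation between MoCA-K and the
    left-PFC amplitude has a between-group component from the shared group
    mean differences plus a within-group component; integer rounding of
    MoCA-K slightly attenuates it.  This solves for the latent within-group
    correlation by root finding on a large fixed Monte-Carlo population
    (common random numbers, so the objective is smooth and deterministic).
    """
    w_h = cohort.n_healthy / (cohort.n_healthy + cohort.n_mci)
    n_h = int(round(n_draws * w_h))
    n_m = n_draws - n_h
    rng = np.random.default_rng(seed)
    draws = {}
    for group, n in (("healthy", n_h), ("mci", n_m)):
        m = cohort.group_moments(group)
        z_l = rng.standard_normal(n)
        eps = rng.standard_normal(n)
        draws[group] = (m, z_l, eps)

    def pooled_r(rho: float) -> float:
        amps, mocas = [], []
        for m, z_l, eps in draws.values():
            amps.append(m["left"][0] + m["left"][1] * z_l)
            z_m = rho * z_l + np.sqrt(1 - rho**2) * eps
            moca = np.clip(np.round(m["moca"][0] + m["moca"][1] * z_m), 0, 30)
            mocas.append(moca)
        a = np.concatenate(amps)
        mo = np.concatenate(mocas)
        return float(np.corrcoef(a, mo)[0, 1])

    target = cohort.moca_mhbo_correlation
    return float(optimize.brentq(lambda r: pooled_r(r) - target, -0.995, 0.995, xtol=1e-4))


def draw_latent_features(
    cohort: CohortSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Latent (noise-free) per-subject feature table for one cohort.

    Columns mirror the extracted feature table (subject_id, group,
    mhbo_left/right/total, moca_k, vdst_score) plus demographics.  This is
    the ground truth the signal-level generator embeds and the fast path
    for statistical calibration studies.
    """
    if rng is None:
        rng = np.random.default_rng(cohort.rng_seed if seed is None else seed)
    rho_w = calibrate_latent_correlation(cohort)
    rows = []
    for group, n, males in (
        ("healthy", cohort.n_healthy, cohort.healthy_males),
        ("mci", cohort.n_mci, cohort.mci_males),
    ):
        m = cohort.group_moments(group)
        rho_lr = cohort.interhemi_correlation(group)
        z_l = rng.standard_normal(n)
        z_r = rho_lr * z_l + np.sqrt(1 - rho_lr**2) * rng.standard_normal(n)
        f_l = m["left"][0] + m["left"][1] * z_l
        f_r = m["right"][0] + m["right"][1] * z_r
        z_m = rho_w * z_l + np.sqrt(1 - rho_w**2) * rng.standard_normal(n)
        moca = np.clip(np.round(m["moca"][0] + m["moca"][1] * z_m), 0, 30)
        vdst = np.maximum(m["vdst"][0] + m["vdst"][1] * rng.standard_normal(n), 0.0)
        age = np.round(m["age"][0] + m["age"][1] * rng.standard_normal(n), 1)
        edu = np.round(np.maximum(m["education"][0]
                                  + m["education"][1] * rng.standard_normal(n), 0.0), 1)
        sex = np.array(["male"] * males + ["female"] * (n - males))
        rng.shuffle(sex)
        prefix = "h" if group == "healthy" else "m"
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{prefix}{i + 1:03d}",
                    "group": group,
                    "mhbo_left": f_l[i],
                    "mhbo_right": f_r[i],
                    "mhbo_total": 0.5 * (f_l[i] + f_r[i]),
                    "moca_k": float(moca[i]),
                    "vdst_score": float(np.round(vdst[i], 2)),
                    "age": float(age[i]),
                    "sex": sex[i],
                    "education": float(edu[i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Deterministic pipeline gains
# ---------------------------------------------------------------------------


def task_regressor(
    timing: BlockTimingSpec, hrf: HrfSpec, sampling_rate: float
) -> np.ndarray:
    """Unit response: boxcar over each encoding period convolved with the HRF."""
    n = int(round(timing.total_duration * sampling_rate))
    box = np.zeros(n)
    for onset in timing.encoding_onsets():
        i0 = int(round(onset * sampling_rate))
        i1 = min(n, i0 + int(round(timing.encoding_duration * sampling_rate)))
        box[i0:i1] = 1.0
    kern = hrf.kernel(sampling_rate)
    return np.convolve(box, kern)[:n] / sampling_rate


@functools.lru_cache(maxsize=32)
def _chain_gain(
    timing: BlockTimingSpec,
    hrf: HrfSpec,
    sampling_rate: float,
    band: tuple[float, float] | None,
    filter_order: int,
    feat: FeatureConfig,
) -> float:
    """Windowed mean of the band-passed, epoch-averaged unit response.

    The generator divides drawn amplitudes by this gain so the analysis
    window mean of the trial-averaged, preprocessed response equals the
    drawn amplitude.
    """
    g = task_regressor(timing, hrf, sampling_rate)
    if band is not None:
        g = bandpass(g, sampling_rate, band, filter_order)
    span = feat.epoch_span
    rel0 = int(round(span[0] * sampling_rate))
    rel1 = int(round(span[1] * sampling_rate))
    times = np.arange(rel0, rel1) / sampling_rate
    segs = []
    for onset in timing.encoding_onsets():
        i_on = int(round(onset * sampling_rate))
        i0, i1 = i_on + rel0, i_on + rel1
        if i0 < 0 or i1 > len(g):
            continue
        seg = g[i0:i1]
        if feat.baseline_window is not None:
            b0 = i_on + int(round(feat.baseline_window[0] * sampling_rate))
            b1 = i_on + int(round(feat.baseline_window[1] * sampling_rate))
            seg = seg - g[b0:b1].mean()
        segs.append(seg)
    avg = np.mean(segs, axis=0)
    lo, hi = feat.analysis_window
    mask = (times >= lo) & (times < hi)
    gain = float(avg[mask].mean())
    if gain <= 0:
        raise ValueError("degenerate timing/HRF: non-positive window gain")
    return gain


def regional_mixing_matrix(acquisition: AcquisitionSpec) -> np.ndarray:
    """Linear map that rank-1 removal of the systemic profile applies to
    the (left, right) regional mean amplitudes.

    For uniform channel gains within each region, projecting out the unit
    systemic profile p maps region means by M = I - outer(mean_r(p),
    sum_r(p)).
    """
    p = systemic_profile(acquisition.n_channels)
    p_hat = p / np.linalg.norm(p)
    regions = ("left_pfc", "right_pfc")
    mean_p = np.array(
        [np.mean([p_hat[ch - 1] for ch in acquisition.region_channels(r)]) for r in regions]
    )
    sum_p = np.array(
        [np.sum([p_hat[ch - 1] for ch in acquisition.region_channels(r)]) for r in regions]
    )
    return np.eye(2) - np.outer(mean_p, sum_p)


# ---------------------------------------------------------------------------
# Signal-level generation
# ---------------------------------------------------------------------------


def build_events(timing: BlockTimingSpec) -> EventTable:
    onsets = timing.encoding_onsets()
    frame = pd.DataFrame(
        {
            "block": np.arange(1, timing.n_blocks + 1),
            "encoding_onset_s": onsets,
            "encoding_duration_s": timing.encoding_duration,
            "recall_onset_s": onsets + timing.encoding_duration,
            "rest_onset_s": onsets + timing.encoding_duration + timing.recall_duration,
        }
    )[EVENT_COLUMNS]
    return EventTable(frame)


def generate_subject(
    group: str,
    cohort: CohortSpec | None = None,
    timing: BlockTimingSpec | None = None,
    hrf: HrfSpec | None = None,
    noise: NoiseSpec | None = None,
    acquisition: AcquisitionSpec | None = None,
    seed: int = 0,
    latent: dict | None = None,
    mbll: MBLLParams | None = None,
    preproc: PreprocConfig | None = None,
    feat: FeatureConfig | None = None,
    hbr_ratio: float = 1.0 / 3.0,
    baseline_intensity: float = 1.0,
) -> RawRecording:
    """Forward-model one subject's raw two-wavelength recording.

    If ``latent`` (a row from :func:`draw_latent_features`) is omitted, a
    single-subject latent draw is made from ``cohort``.  The returned
    intensities, pushed through the default preprocessing and feature
    chain, recover the latent regional mHbO values in expectation.
    """
    cohort = cohort if cohort is not None else CohortSpec()
    timing = timing if timing is not None else BlockTimingSpec()
    hrf = hrf if hrf is not None else HrfSpec()
    noise = noise if noise is not None else NoiseSpec()
    acquisition = acquisition if acquisition is not None else AcquisitionSpec()
    mbll = mbll if mbll is not None else MBLLParams(wavelengths=acquisition.wavelengths)
    preproc = preproc if preproc is not None else PreprocConfig()
    feat = feat if feat is not None else FeatureConfig()
    if group not in ("healthy", "mci"):
        raise ValueError(f"unknown group {group!r}")
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError("seed must be a non-negative integer")
    noise.validate_frequencies(acquisition.sampling_rate)

    rng = np.random.default_rng(int(seed))
    if latent is None:
        one = replace(cohort, n_healthy=1, n_mci=1,
                      healthy_males=min(cohort.healthy_males, 1),
                      mci_males=min(cohort.mci_males, 1))
        table = draw_latent_features(one, rng=rng)
        latent = table[table["group"] == group].iloc[0].to_dict()

    fs = acquisition.sampling_rate
    n = int(round(timing.total_duration * fs))
    t = np.arange(n) / fs

    # deterministic pipeline gains to pre-compensate
    gain = _chain_gain(timing, hrf, fs, tuple(preproc.band), preproc.filter_order, feat)
    f_target = np.array([latent["mhbo_left"], latent["mhbo_right"]], float)
    spatial_active = (
        preproc.n_spatial_components_removed > 0
        and noise.inband_global_dominates(fs, tuple(preproc.band), preproc.filter_order)
    )
    if spatial_active:
        m_mix = regional_mixing_matrix(acquisition)
        amps_region = np.linalg.solve(m_mix, f_target) / gain
    else:
        amps_region = f_target / gain

    g = task_regressor(timing, hrf, fs)
    region_idx = np.array(
        [0 if acquisition.channel_region_map[ch] == "left_pfc" else 1
         for ch in acquisition.channels]
    )
    hbo = amps_region[region_idx][:, None] * g[None, :]

    # --- noise ---
    p = systemic_profile(acquisition.n_channels)
    for freq, amp in (
        (noise.cardiac_freq, noise.cardiac_amplitude),
        (noise.resp_freq, noise.resp_amplitude),
        (noise.mayer_freq, noise.mayer_amplitude),
    ):
        if amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            hbo += amp * np.outer(p, np.sin(2 * np.pi * freq * t + phase))
    if noise.white_noise_sd > 0:
        hbo += noise.white_noise_sd * rng.standard_normal(hbo.shape)
    if noise.drift_slope != 0:
        slopes = noise.drift_slope * rng.uniform(-1, 1, acquisition.n_channels)
        hbo += np.outer(slopes, t - t.mean())
    if noise.spike_rate > 0 and noise.spike_amplitude > 0:
        minutes = timing.total_duration / 60.0
        width = noise.spike_width_s
        for ch in range(acquisition.n_channels):
            for _ in range(rng.poisson(noise.spike_rate * minutes)):
                t0 = rng.uniform(0, timing.total_duration)
                sign = rng.choice([-1.0, 1.0])
                hbo[ch] += (sign * noise.spike_amplitude
                            * np.exp(-0.5 * ((t - t0) / width) ** 2))

    hbr = -hbr_ratio * hbo
    od = mbll_forward(hbo, hbr, mbll)  # (wl, ch, t)
    intensity = baseline_intensity * np.power(10.0, -od)
    if not np.all(np.isfinite(intensity)) or np.any(intensity <= 0):
        raise ValueError("forward model produced non-positive or non-finite intensity")
    intensity = np.moveaxis(intensity, 0, 1)  # ch x wl x t

    return RawRecording(
        subject_id=str(latent.get("subject_id", f"{group[0]}000")),
        group=group,
        acquisition=acquisition,
        events=build_events(timing),
        intensity=intensity,
        moca_k=float(latent["moca_k"]),
        vdst_score=float(latent["vdst_score"]),
        demographics={
            k: latent[k] for k in ("age", "sex", "education") if k in latent
        },
    )


def generate_cohort(
    cohort: CohortSpec | None = None,
    timing: BlockTimingSpec | None = None,
    hrf: HrfSpec | None = None,
    noise: NoiseSpec | None = None,
    acquisition: AcquisitionSpec | None = None,
    seed: int | None = None,
    **subject_kwargs,
) -> tuple[list[RawRecording], pd.DataFrame]:
    """All subjects' raw recordings plus the latent truth table.

    Per-subject seeds are derived deterministically from the cohort seed,
    so identical (spec, seed) pairs produce identical cohorts.
    """
    cohort = cohort if cohort is not None else CohortSpec()
    root = cohort.rng_seed if seed is None else seed
    truth = draw_latent_features(cohort, seed=root)
    child_seeds = np.random.SeedSequence(root).generate_state(len(truth))
    recordings = []
    for (_, row), sub_seed in zip(truth.iterrows(), child_seeds):
        recordings.append(
            generate_subject(
                group=row["group"],
                cohort=cohort,
                timing=timing,
                hrf=hrf,
                noise=noise,
                acquisition=acquisition,
                seed=int(sub_seed),
                latent=row.to_dict(),
                **subject_kwargs,
            )
        )
    return recordings, truth
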