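"""Windowed mean-HbO (mHbO) features from cleaned recordings.

Each task block contributes one epoch time-locked to the digit-encoding
onset.  Epochs are baseline-corrected, averaged across trials, and the
mean of the averaged HbO over a 3-12 s post-onset window is taken per
channel, then averaged within each hemisphere (left/right PFC) and over
all kept channels (total PFC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import FEATURE_COLUMNS, HemoRecording


@dataclass(frozen=True)
class FeatureConfig:
    """Epoching and windowing parameters, seconds relative to encoding onset.

    The analysis window is half-open [start, end) in sample indices; the
    baseline window precedes the onset and its mean is subtracted per
    epoch (set ``baseline_window=None`` for no correction).
    """

    analysis_window: tuple[float, float] = (3.0, 12.0)
    baseline_window: tuple[float, float] | None = (-2.0, 0.0)
    min_trials: int = 12

    def __post_init__(self) -> None:
        lo, hi = self.analysis_window
        if not lo < hi:
            raise ValueError("analysis window start must precede end")
        if self.baseline_window is not None:
            blo, bhi = self.baseline_window
            if not blo < bhi:
                raise ValueError("baseline window start must precede end")
            if bhi > 0:
                raise ValueError("baseline window must precede the encoding onset")
        if self.min_trials < 1:
            raise ValueError("min_trials must be >= 1")

    @property
    def epoch_span(self) -> tuple[float, float]:
        start = 0.0 if self.baseline_window is None else min(self.baseline_window[0], 0.0)
        return (start, self.analysis_window[1])


@dataclass
class TrialTensor:
    """Baseline-corrected epochs: channel x trial x time, onset-aligned.

    ``times`` is the onset-relative axis; ``channels`` the 1-based kept
    channel ids in row order.
    """

    data: np.ndarray
    times: np.ndarray
    channels: list[int]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("trial tensor must be channel x trial x time")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis mismatch")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel axis mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]


class TooFewTrialsError(ValueError):
    """Fewer usable trials than ``FeatureConfig.min_trials``."""


def epoch(hemo: HemoRecording, config: FeatureConfig | None = None) -> TrialTensor:
    """Segment kept-channel HbO into onset-locked, baseline-corrected epochs.

    Epochs extending past the recording end are dropped with a warning;
    fewer than ``min_trials`` surviving epochs raises
    :class:`TooFewTrialsError`.
    """
    config = config if config is not None else FeatureConfig()
    fs = hemo.acquisition.sampling_rate
    kept = hemo.kept_channels
    if not kept:
        raise ValueError("no kept channels to epoch")
    span = config.epoch_span
    rel0 = int(round(span[0] * fs))
    rel1 = int(round(span[1] * fs))  # exclusive
    times = np.arange(rel0, rel1) / fs
    n_t = hemo.hbo.shape[1]

    rows = [ch - 1 for ch in kept]
    epochs = []
    dropped = []
    for b, onset in enumerate(hemo.events.encoding_onsets, start=1):
        i_on = int(round(onset * fs))
        i0, i1 = i_on + rel0, i_on + rel1
        if i0 < 0 or i1 > n_t:
            dropped.append(b)
            continue
        seg = hemo.hbo[rows, i0:i1]
        if config.baseline_window is not None:
            b0 = i_on + int(round(config.baseline_window[0] * fs))
            b1 = i_on + int(round(config.baseline_window[1] * fs))
            seg = seg - hemo.hbo[rows, b0:b1].mean(axis=1, keepdims=True)
        epochs.append(seg)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} trial(s) extending past the recording: blocks {dropped}"
        )
    if len(epochs) < config.min_trials:
        raise TooFewTrialsError(
            f"only {len(epochs)} usable trials; at least {config.min_trials} required"
        )
    data = np.stack(epochs, axis=1)  # ch x trial x time
    return TrialTensor(data=data, times=times, channels=kept)


def trial_average(tensor: TrialTensor) -> np.ndarray:
    """Pointwise mean across trials -> channel x time."""
    return tensor.data.mean(axis=1)


def mhbo(
    avg: np.ndarray,
    times: np.ndarray,
    channels: list[int],
    region_map: dict[int, str],
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """Windowed mean-HbO per region from a trial-averaged response.

    Per channel, the mean of ``avg`` over the half-open analysis window;
    region value = mean over that region's kept channels; total = mean
    over all kept channels.  A region with no kept channels yields NaN.
    """
    config = config if config is not None else FeatureConfig()
    lo, hi = config.analysis_window
    mask = (times >= lo) & (times < hi)
    if not mask.any():
        raise ValueError("analysis window contains no samples")
    per_channel = np.asarray(avg)[:, mask].mean(axis=1)

    out: dict[str, float] = {}
    for region, key in (("left_pfc", "mhbo_left"), ("right_pfc", "mhbo_right")):
        idx = [i for i, ch in enumerate(channels) if region_map[ch] == region]
        if not idx:
            warnings.warn(f"region {region} has no kept channels; mHbO missing")
            out[key] = float("nan")
        else:
            out[key] = float(per_channel[idx].mean())
    out["mhbo_total"] = float(per_channel.mean())
    return out


def extract_subject_features(
    hemo: HemoRecording, config: FeatureConfig | None = None
) -> dict:
    """One feature-table row (dict) for a preprocessed subject."""
    config = config if config is not None else FeatureConfig()
    tensor = epoch(hemo, config)
    avg = trial_average(tensor)
    region_map = dict(hemo.acquisition.channel_region_map)
    feats = mhbo(avg, tensor.times, tensor.channels, region_map, config)
    return {
        "subject_id": hemo.subject_id,
        "group": hemo.group,
        **feats,
        "moca_k": hemo.moca_k,
        "vdst_score": hemo.vdst_score,
        "n_trials": tensor.n_trials,
    }


def extract_features(
    hemos: list[HemoRecording], config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Feature table (one row per subject) from preprocessed recordings."""
    rows = [extract_subject_features(h, config) for h in hemos]
    df = pd.DataFrame(rows)
    order = FEATURE_COLUMNS + [c for c in df.columns if c not in FEATURE_COLUMNS]
    return df[order]
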