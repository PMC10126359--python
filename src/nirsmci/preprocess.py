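"""Raw-intensity to clean HbO/HbR conversion.

The chain is: intensity -> optical-density change (log10, referenced to
the initial rest) -> modified Beer-Lambert inversion (two wavelengths, two
chromophores) -> spike-based channel rejection -> zero-phase 4th-order
Butterworth band-pass (0.01-0.2 Hz) -> eigenvector-based spatial filtering
(removal of the leading spatial component, estimated from the rest
segment).

All steps except the data-driven spatial filter are linear in the signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .dataio import HemoRecording, RawRecording

# Molar base-10 extinction coefficients, 1/(cm*M), for HbO2 and Hb at the
# two laser lines; values from the Prahl/Oregon Medical Laser Center
# compiled tabulation of hemoglobin spectra (as used by HOMER and most
# continuous-wave fNIRS toolchains).
EXTINCTION_1_PER_CM_M = {
    760.0: (586.0, 1548.52),  # (HbO, HbR)
    850.0: (1058.0, 691.32),
}


@dataclass(frozen=True)
class MBLLParams:
    """Modified Beer-Lambert inversion parameters.

    ``extinction`` rows are wavelengths (760, 850 nm), columns are
    chromophores (HbO, HbR), in 1/(uM*mm) so concentrations come out in
    uM (after pathlength division) or uM*mm (pathlength-scaled, the
    default).  The differential pathlength factor (DPF) corrects the
    geometric optode distance for scattering-lengthened photon paths.
    """

    wavelengths: tuple[float, float] = (760.0, 850.0)
    extinction: np.ndarray | None = None
    dpf: tuple[float, float] = (6.0, 6.0)
    distance: float = 3.0  # cm
    unit_mode: str = "uM*mm"

    def __post_init__(self) -> None:
        if self.extinction is None:
            try:
                e = np.array([EXTINCTION_1_PER_CM_M[w] for w in self.wavelengths])
            except KeyError as err:
                raise ValueError(
                    f"no tabulated extinction for wavelength {err}; pass `extinction`"
                ) from err
            # 1/(cm*M) -> 1/(mm*uM): /10 for cm->mm, /1e6 for M->uM
            object.__setattr__(self, "extinction", e * 1e-7)
        else:
            object.__setattr__(self, "extinction", np.asarray(self.extinction, float))
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction must be 2x2 (wavelength x chromophore)")
        cond = np.linalg.cond(self.extinction)
        if not np.isfinite(cond) or cond >= 100:
            raise ValueError(f"extinction matrix ill-conditioned (cond={cond:.3g})")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("dpf must be positive")
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.unit_mode not in ("uM*mm", "uM"):
            raise ValueError("unit_mode must be 'uM*mm' or 'uM'")

    @property
    def pathlength_scale(self) -> np.ndarray:
        """Per-wavelength divisor applied to dOD before inversion.

        DPF only in uM*mm mode (pathlength-scaled concentration); DPF times
        distance in mm for absolute uM.
        """
        dpf = np.asarray(self.dpf, float)
        if self.unit_mode == "uM":
            return dpf * (self.distance * 10.0)
        return dpf


@dataclass(frozen=True)
class PreprocConfig:
    """Denoising configuration.

    ``spike_threshold`` is in the active concentration unit; a channel
    whose HbO trace strays beyond it from the channel mean is rejected as
    noisy.  ``band`` is the Butterworth pass band in Hz,
    ``n_spatial_components_removed`` the number of leading spatial
    eigenvectors projected out.
    """

    band: tuple[float, float] = (0.01, 0.2)
    filter_order: int = 4
    spike_threshold: float = 300.0
    spike_rule: str = "peak"  # "peak" (any excursion) or "sd" (channel SD)
    n_spatial_components_removed: int = 1
    baseline_window_for_od: tuple[float, float] = (0.0, 180.0)
    qc_edge_exclusion_s: float = 10.0
    spatial_basis: str = "rest"  # "rest" (Zhang-style baseline basis) or "full"

    def validate(self, sampling_rate: float, n_channels: int | None = None) -> None:
        nyq = sampling_rate / 2.0
        lo, hi = self.band
        if not (0 < lo < hi < nyq):
            raise ValueError(f"band {self.band} must satisfy 0 < low < high < Nyquist ({nyq})")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.spike_threshold <= 0:
            raise ValueError("spike_threshold must be positive")
        if self.spike_rule not in ("peak", "sd"):
            raise ValueError("spike_rule must be 'peak' or 'sd'")
        if n_channels is not None and self.n_spatial_components_removed >= n_channels:
            raise ValueError("cannot remove as many spatial components as channels")
        if self.spatial_basis not in ("rest", "full"):
            raise ValueError("spatial_basis must be 'rest' or 'full'")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def intensity_to_od(
    intensity: np.ndarray,
    sampling_rate: float,
    reference_window: tuple[float, float],
) -> np.ndarray:
    """Optical-density change relative to the mean over a reference window.

    dOD(t) = -log10(I(t) / mean(I over reference window)), computed
    independently per channel and wavelength.  Input shape is
    (..., time); any leading axes are preserved.
    """
    intensity = np.asarray(intensity, float)
    if np.any(intensity <= 0):
        idx = tuple(int(i) for i in np.argwhere(intensity <= 0)[0])
        raise ValueError(
            f"non-positive intensity at index {idx} "
            "(channel/wavelength/sample); cannot take log"
        )
    n_t = intensity.shape[-1]
    i0 = int(round(reference_window[0] * sampling_rate))
    i1 = int(round(reference_window[1] * sampling_rate))
    if not (0 <= i0 < i1 <= n_t):
        raise ValueError(f"reference window {reference_window} outside recording")
    ref = intensity[..., i0:i1].mean(axis=-1, keepdims=True)
    return -np.log10(intensity / ref)


def mbll_forward(hbo: np.ndarray, hbr: np.ndarray, params: MBLLParams) -> np.ndarray:
    """Forward Beer-Lambert model: concentrations -> dOD per wavelength.

    Returns an array of shape (2, ...) stacked over wavelengths.  Exact
    inverse of :func:`mbll_invert`; used by the synthetic generator.
    """
    conc = np.stack([np.asarray(hbo, float), np.asarray(hbr, float)])
    od = np.tensordot(params.extinction, conc, axes=(1, 0))
    return od * params.pathlength_scale.reshape((2,) + (1,) * (od.ndim - 1))


def mbll_invert(od: np.ndarray, params: MBLLParams) -> tuple[np.ndarray, np.ndarray]:
    """Invert the modified Beer-Lambert law at every time point.

    ``od`` has shape (2, ...) over the two wavelengths.  Solves
    E [HbO; HbR] = dOD / (DPF * s) with s the pathlength scale implied by
    ``params.unit_mode``.  Linear in dOD.
    """
    od = np.asarray(od, float)
    if od.shape[0] != 2:
        raise ValueError("od must be stacked over exactly two wavelengths")
    scale = params.pathlength_scale.reshape((2,) + (1,) * (od.ndim - 1))
    rhs = od / scale
    inv = np.linalg.inv(params.extinction)
    conc = np.tensordot(inv, rhs, axes=(1, 0))
    return conc[0], conc[1]


def reject_noisy_channels(
    hbo: np.ndarray,
    threshold: float = 300.0,
    rule: str = "peak",
    edge_exclude: int = 0,
) -> dict[int, str]:
    """Flag channels with large spikes as rejected.

    Under the default ``peak`` rule a channel is rejected iff any sample
    deviates more than ``threshold`` (concentration units) from the
    channel mean; under ``sd`` iff the channel standard deviation exceeds
    the threshold.  ``edge_exclude`` samples at each end are ignored
    (filter-transient guard).  Flags are keyed by 1-based channel id.
    """
    hbo = np.asarray(hbo, float)
    if hbo.ndim != 2:
        raise ValueError("hbo must be channel x time")
    sl = slice(edge_exclude, hbo.shape[1] - edge_exclude if edge_exclude else None)
    core = hbo[:, sl]
    mean = core.mean(axis=1, keepdims=True)
    if rule == "peak":
        stat = np.abs(core - mean).max(axis=1)
    elif rule == "sd":
        stat = core.std(axis=1, ddof=0)
    else:
        raise ValueError("rule must be 'peak' or 'sd'")
    flags = {
        ch + 1: ("rejected" if stat[ch] > threshold else "kept")
        for ch in range(hbo.shape[0])
    }
    if all(v == "rejected" for v in flags.values()):
        raise ValueError("all channels rejected; subject unusable")
    return flags


def bandpass(
    series: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = (0.01, 0.2),
    order: int = 4,
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis.

    Applied forward-backward (filtfilt) so event-locked averages incur no
    phase delay; the effective magnitude response is squared.
    """
    series = np.asarray(series, float)
    nyq = sampling_rate / 2.0
    lo, hi = band
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} outside (0, Nyquist={nyq})")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")
    padlen = 3 * (2 * order + 1)
    if series.shape[-1] <= 3 * padlen:
        raise ValueError(
            f"series length {series.shape[-1]} too short for order-{order} band-pass"
        )
    return signal.sosfiltfilt(sos, series, axis=-1)


def butter_bandpass_gain(
    freq_hz: float | np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = (0.01, 0.2),
    order: int = 4,
) -> np.ndarray:
    """Magnitude response of the zero-phase band-pass at given frequencies.

    Squares the single-pass Butterworth magnitude (forward-backward
    application).  Serves as the analytic oracle for attenuation tests.
    """
    sos = signal.butter(order, list(band), btype="bandpass", fs=sampling_rate, output="sos")
    w, h = signal.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freq_hz, float)), fs=sampling_rate)
    return np.abs(h) ** 2


def spatial_filter_eigen(
    matrix: np.ndarray,
    k: int = 1,
    basis: np.ndarray | None = None,
    min_basis_ratio: float = 0.1,
) -> np.ndarray:
    """Remove the leading spatial components of a channel x time matrix.

    Channels are mean-centered over time; the leading ``k`` spatial
    eigenvectors (left singular vectors) are estimated from ``basis``
    (defaults to the matrix itself) and their projection is subtracted from
    the centered matrix, so the output has zero channel means and is
    orthogonal over time to the removed spatial components.

    Passing a rest-period segment as ``basis`` removes the spatial pattern
    of systemic interference (scalp blood flow, Mayer waves) without
    subtracting the task-evoked response.  If the basis segment carries
    less than ``min_basis_ratio`` of the full-matrix RMS the input is
    returned unchanged (nothing to estimate the interference from).
    """
    matrix = np.asarray(matrix, float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be channel x time")
    n_ch = matrix.shape[0]
    if k < 0 or (k >= n_ch and k > 0):
        raise ValueError(f"k={k} must satisfy 0 <= k < n_channels={n_ch}")
    if k == 0:
        return matrix.copy()
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    if basis is None:
        basis_c = centered
    else:
        basis = np.asarray(basis, float)
        basis_c = basis - basis.mean(axis=1, keepdims=True)
        full_rms = np.sqrt(np.mean(centered**2))
        basis_rms = np.sqrt(np.mean(basis_c**2))
        if full_rms == 0 or basis_rms < min_basis_ratio * full_rms:
            return matrix.copy()
    if not np.any(basis_c):
        return matrix.copy()
    u, _, _ = np.linalg.svd(basis_c, full_matrices=False)
    uk = u[:, :k]
    return centered - uk @ (uk.T @ centered)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def preprocess_recording(
    rec: RawRecording,
    mbll: MBLLParams | None = None,
    config: PreprocConfig | None = None,
) -> HemoRecording:
    """Raw intensities to denoised HbO/HbR with channel QC.

    Order: OD conversion (referenced to the initial rest), Beer-Lambert
    inversion, spike-based channel rejection on the unfiltered
    concentrations, band-pass, spatial filtering of kept channels.
    """
    mbll = mbll if mbll is not None else MBLLParams(wavelengths=rec.acquisition.wavelengths)
    config = config if config is not None else PreprocConfig()
    fs = rec.acquisition.sampling_rate
    config.validate(fs, rec.acquisition.n_channels)

    ref = (
        config.baseline_window_for_od
        if config.baseline_window_for_od[1] <= rec.duration
        else (0.0, rec.duration)
    )
    od = intensity_to_od(rec.intensity, fs, ref)  # ch x wl x t
    hbo, hbr = mbll_invert(np.moveaxis(od, 1, 0), mbll)  # each ch x t

    edge = int(round(config.qc_edge_exclusion_s * fs))
    qc = reject_noisy_channels(
        hbo, threshold=config.spike_threshold, rule=config.spike_rule, edge_exclude=edge
    )

    hbo = bandpass(hbo, fs, config.band, config.filter_order)
    hbr = bandpass(hbr, fs, config.band, config.filter_order)

    kept = [ch - 1 for ch, flag in qc.items() if flag == "kept"]
    k = config.n_spatial_components_removed
    if k > 0 and len(kept) > k:
        if config.spatial_basis == "rest":
            i0 = int(round(ref[0] * fs)) + edge
            i1 = max(i0 + 1, int(round(ref[1] * fs)) - edge)
            basis = hbo[kept, i0:i1]
        else:
            basis = None
        hbo[kept] = spatial_filter_eigen(hbo[kept], k=k, basis=basis)
        hbr[kept] = spatial_filter_eigen(hbr[kept], k=k, basis=basis)
    elif k > 0:
        warnings.warn("too few kept channels for spatial filtering; skipped")

    return HemoRecording(
        subject_id=rec.subject_id,
        group=rec.group,
        acquisition=rec.acquisition,
        events=rec.events,
        hbo=hbo,
        hbr=hbr,
        channel_qc=qc,
        unit=mbll.unit_mode,
        moca_k=rec.moca_k,
        vdst_score=rec.vdst_score,
    )
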