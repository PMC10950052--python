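"""Band-limited power envelopes of ROI time-series.

Processing chain per ROI and trial: zero-phase Butterworth band-pass in the
beta (13-30 Hz) or gamma (31-90 Hz) range, reduction of the ROI's vertices
to their first principal component, Hilbert-transform amplitude envelope,
anti-aliased downsampling to 100 Hz, and per-trial percent-change
normalisation against the pre-stimulus baseline (-0.4 to -0.1 s relative
to coherence onset). The resulting trial x time arrays (one per ROI and
band) are what the latency-mapping and group-statistics stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, resample_poly, sosfiltfilt

__all__ = [
    "BANDS", "EnvelopeArray", "ROISpec",
    "bandpass", "roi_first_pc", "hilbert_envelope", "preprocess_envelopes",
    "save_envelopes", "load_envelopes", "read_roi_table",
]

#: frequency bands in Hz
BANDS = {"beta": (13.0, 30.0), "gamma": (31.0, 90.0)}


@dataclass(frozen=True)
class ROISpec:
    """Metadata for one cortical region of interest."""

    roi: str
    name: str
    hemisphere: str            # "L" | "R"
    dorsal_path: bool
    caudo_rostral_position: float


@dataclass
class EnvelopeArray:
    """Baseline-normalised band-power envelopes for one subject and band.

    ``data`` is roi x trial x time (percent change vs the baseline mean);
    the time axis runs over ``epoch`` at sampling rate ``fs``.
    """

    subject: str
    band: str
    roi_ids: list
    data: np.ndarray
    fs: float = 100.0
    epoch: tuple = (-0.5, 1.5)
    baseline_window: tuple = (-0.4, -0.1)
    truth: dict = field(default_factory=dict)   # generator ground truth

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be roi x trial x time")
        if len(self.roi_ids) != self.data.shape[0]:
            raise ValueError("roi_ids does not match data")
        n_expect = int(round((self.epoch[1] - self.epoch[0]) * self.fs))
        if self.data.shape[2] != n_expect:
            raise ValueError(
                f"time axis has {self.data.shape[2]} samples, epoch/fs "
                f"imply {n_expect}")
        if np.any(~np.isfinite(self.data)):
            raise ValueError("NaNs/inf in envelope data")

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.epoch[0] + np.arange(n) / self.fs

    def roi(self, roi_id) -> np.ndarray:
        """trial x time array for one ROI."""
        return self.data[self.roi_ids.index(roi_id)]


def bandpass(x, band, fs: float, order: int = 4):
    """Zero-phase (forward-backward) Butterworth band-pass.

    ``band`` is ``(lo, hi)`` in Hz or a named band from :data:`BANDS`.
    Applied along the last axis.
    """
    if isinstance(band, str):
        band = BANDS[band]
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band {band} exceeds the Nyquist rate {fs / 2}")
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def roi_first_pc(vertices: np.ndarray) -> np.ndarray:
    """First principal-component time-course of a vertices x time matrix.

    The loading vector is unit norm and the sign is aligned so the
    component correlates positively with the vertex mean.
    """
    m = np.asarray(vertices, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValueError("need a vertices x time matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite values")
    if not np.any(m):
        raise ValueError("all-zero matrix has no principal component")
    centred = m - m.mean(axis=1, keepdims=True)
    # SVD of time x vertex: right singular vector = vertex loadings
    u, s, vt = np.linalg.svd(centred.T, full_matrices=False)
    loadings = vt[0]
    comp = centred.T @ loadings
    mean_tc = centred.mean(axis=0)
    if np.dot(comp, mean_tc) < 0:
        comp = -comp
    return comp


def hilbert_envelope(x) -> np.ndarray:
    """Instantaneous amplitude: modulus of the analytic signal.

    Operates along the last axis; input must have at least 16 samples.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 16:
        raise ValueError("need at least 16 samples")
    return np.abs(hilbert(x, axis=-1))


def _resample_to(x, fs_in: float, fs_out: float):
    """Anti-aliased rational-rate resampling along the last axis."""
    from fractions import Fraction
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def preprocess_envelopes(raw, band, fs_in: float, subject: str = "s0",
                         roi_ids=None, fs_out: float = 100.0,
                         epoch=(-0.5, 1.5), baseline_window=(-0.4, -0.1),
                         square: bool = False) -> EnvelopeArray:
    """Full envelope pipeline on raw ROI series.

    Parameters
    ----------
    raw : array, roi x trial x time
        ROI time-courses at the native rate, spanning ``epoch``.
    band : str or (lo, hi)
        Frequency band.
    fs_in : float
        Native sampling rate (Hz).
    square : bool
        If True use squared amplitude ("power" convention); default is the
        Hilbert amplitude itself.

    Returns
    -------
    EnvelopeArray with per-trial percent-change baseline normalisation:
    ``100 * (env - mean_baseline) / mean_baseline``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3:
        raise ValueError("raw must be roi x trial x time")
    band_name = band if isinstance(band, str) else "custom"
    if baseline_window[0] < epoch[0] or baseline_window[1] > epoch[1]:
        raise ValueError("epoch must cover the baseline window")

    filtered = bandpass(raw, band, fs_in)
    env = hilbert_envelope(filtered)
    if square:
        env = env ** 2
    env = _resample_to(env, fs_in, fs_out)
    n_out = int(round((epoch[1] - epoch[0]) * fs_out))
    env = env[..., :n_out]
    times = epoch[0] + np.arange(env.shape[-1]) / fs_out
    base = (times >= baseline_window[0]) & (times < baseline_window[1])
    mu = env[..., base].mean(axis=-1, keepdims=True)
    if np.any(mu <= 0):
        raise ValueError("baseline mean power must be positive")
    data = 100.0 * (env - mu) / mu
    if roi_ids is None:
        roi_ids = [f"roi{i}" for i in range(raw.shape[0])]
    return EnvelopeArray(subject=subject, band=band_name,
                         roi_ids=list(roi_ids), data=data, fs=fs_out,
                         epoch=tuple(epoch),
                         baseline_window=tuple(baseline_window))


# ---------------------------------------------------------------------------
# HDF5 container: /<subject>/<band>/<roi> datasets (trial x time)
# ---------------------------------------------------------------------------

def save_envelopes(path, arrays) -> None:
    """Write one or more :class:`EnvelopeArray` to an HDF5 file."""
    if isinstance(arrays, EnvelopeArray):
        arrays = [arrays]
    with h5py.File(path, "w") as f:
        for arr in arrays:
            grp = f.require_group(f"{arr.subject}/{arr.band}")
            grp.attrs["fs"] = arr.fs
            grp.attrs["epoch"] = arr.epoch
            grp.attrs["baseline_window"] = arr.baseline_window
            for i, roi in enumerate(arr.roi_ids):
                grp.create_dataset(str(roi), data=arr.data[i])
            if arr.truth:
                for k, v in arr.truth.items():
                    grp.attrs[f"truth_{k}"] = v


def load_envelopes(path, subject: str, band: str) -> EnvelopeArray:
    """Read one subject/band group back from HDF5."""
    with h5py.File(path, "r") as f:
        grp = f[f"{subject}/{band}"]
        roi_ids = sorted(grp.keys())
        data = np.stack([grp[r][()] for r in roi_ids])
        truth = {k[len("truth_"):]: np.asarray(v).tolist()
                 for k, v in grp.attrs.items() if k.startswith("truth_")}
        return EnvelopeArray(subject=subject, band=band, roi_ids=roi_ids,
                             data=data, fs=float(grp.attrs["fs"]),
                             epoch=tuple(grp.attrs["epoch"]),
                             baseline_window=tuple(
                                 grp.attrs["baseline_window"]),
                             truth=truth)


def read_roi_table(path) -> list[ROISpec]:
    """ROI metadata CSV -> list of :class:`ROISpec`."""
    df = pd.read_csv(path)
    return [ROISpec(roi=str(r.roi), name=str(r.name),
                    hemisphere=str(r.hemisphere),
                    dorsal_path=bool(r.dorsal_path),
                    caudo_rostral_position=float(r.caudo_rostral_position))
            for r in df.itertuples()]
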