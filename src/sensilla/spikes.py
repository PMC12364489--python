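"""Spike detection, amplitude-based unit sorting, and stimulus quantification.

Single-sensillum recordings (SSR) pick up extracellular action potentials from
the small number of olfactory sensory neurons (OSNs) housed in one sensillum.
Different neurons in the same sensillum produce spikes of different extracellular
amplitude, so a one-dimensional clustering of spike amplitudes is the standard
way to attribute spikes to units.  Responses are quantified as
``delta spikes/s``: the spike count in a window after stimulus onset minus the
count in an equally long window before onset, divided by the window length, and
optionally corrected by subtracting the response elicited by the solvent alone.
"""

from __future__ import annotations

import json
import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VoltageTrace",
    "SpikeTrain",
    "StimulusResponse",
    "detect_spikes",
    "sort_units_by_amplitude",
    "delta_response",
    "solvent_correct",
]

#: Default refractory period (s); also used by the simulator.
DEFAULT_REFRACTORY = 0.002

#: Default robust threshold multiplier: threshold = MAD_K * sigma_hat, with
#: sigma_hat = MAD / 0.6745 the standard robust noise-SD estimate.
MAD_K = 5.0

#: MAD of a unit-variance Gaussian; divides MAD into a noise-SD estimate.
_MAD_TO_SD = 0.6745


@dataclass(frozen=True)
class VoltageTrace:
    """A sampled extracellular recording with stimulus timing.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in mV.
    sampling_rate : float
        Sampling rate in Hz (> 0).
    stim_onset : float
        Stimulus onset time in seconds from the start of the trace.
    stim_duration : float
        Stimulus pulse duration in seconds (0.3 s pulses are typical for
        olfactometer stimulation).
    """

    samples: np.ndarray
    sampling_rate: float
    stim_onset: float
    stim_duration: float = 0.3

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if samples.ndim != 1:
            raise ValueError("samples must be a 1-D series")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trace contains non-finite samples")
        if not (0 <= self.stim_onset and
                self.stim_onset + self.stim_duration <= self.duration + 1e-12):
            raise ValueError("stimulus window must lie within the trace")

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(len(self.samples)) / self.sampling_rate

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> None:
        """Write as two-column CSV (time_s, mV)."""
        pd.DataFrame({"time_s": self.times, "mV": self.samples}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, stim_onset: float,
                 stim_duration: float = 0.3) -> "VoltageTrace":
        df = pd.read_csv(path)
        dt = np.diff(df["time_s"].to_numpy())
        rate = 1.0 / np.median(dt)
        return cls(df["mV"].to_numpy(), rate, stim_onset, stim_duration)

    def to_raw(self, path: str | Path) -> None:
        """Write raw float32 binary with a JSON sidecar (``<path>.json``)."""
        path = Path(path)
        self.samples.astype("<f4").tofile(path)
        meta = {"sampling_rate": self.sampling_rate,
                "stim_onset": self.stim_onset,
                "stim_duration": self.stim_duration,
                "dtype": "<f4", "unit": "mV"}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2))

    @classmethod
    def from_raw(cls, path: str | Path) -> "VoltageTrace":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        samples = np.fromfile(path, dtype=meta.get("dtype", "<f4"))
        return cls(samples.astype(float), meta["sampling_rate"],
                   meta["stim_onset"], meta["stim_duration"])


@dataclass
class SpikeTrain:
    """Detected (or simulated ground-truth) spikes.

    ``times`` are seconds, sorted ascending; ``amplitudes`` are positive mV
    (peak-to-trough for detected spikes); ``unit_labels`` are categorical
    letters ``a, b, c, ...`` assigned in order of decreasing mean amplitude,
    or ``None`` before sorting.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    unit_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted ascending")
        if self.unit_labels is not None:
            self.unit_labels = np.asarray(self.unit_labels, dtype=object)
            if self.unit_labels.shape != self.times.shape:
                raise ValueError("unit_labels length mismatch")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def units(self) -> list[str]:
        """Sorted distinct unit labels (empty if unlabeled)."""
        if self.unit_labels is None:
            return []
        return sorted(set(self.unit_labels))

    def for_unit(self, unit: str) -> "SpikeTrain":
        if self.unit_labels is None:
            raise ValueError("spike train is unlabeled; sort units first")
        mask = self.unit_labels == unit
        return SpikeTrain(self.times[mask], self.amplitudes[mask],
                          self.unit_labels[mask])

    def count_between(self, start: float, stop: float) -> int:
        """Number of spikes with start <= t < stop."""
        return int(np.sum((self.times >= start) & (self.times < stop)))

    def to_csv(self, path: str | Path) -> None:
        labels = (self.unit_labels if self.unit_labels is not None
                  else np.full(len(self), "", dtype=object))
        pd.DataFrame({"time_s": self.times, "amplitude_mV": self.amplitudes,
                      "unit": labels}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpikeTrain":
        df = pd.read_csv(path)
        labels = df["unit"].astype(str).to_numpy(dtype=object)
        if np.all(labels == "") or df["unit"].isna().all():
            labels = None
        return cls(df["time_s"].to_numpy(), df["amplitude_mV"].to_numpy(),
                   labels)


@dataclass(frozen=True)
class StimulusResponse:
    """Pre/post spike counts and the derived delta spikes/s for one stimulus."""

    pre_count: int
    post_count: int
    window: float
    delta_spikes_per_s: float
    solvent_corrected: bool = False

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------

def detect_spikes(trace: VoltageTrace, threshold: float | str = "auto",
                  refractory: float = DEFAULT_REFRACTORY,
                  mad_k: float = MAD_K) -> SpikeTrain:
    """Detect spikes by robust threshold crossing.

    The trace is median-centred (detection is therefore invariant to a DC
    offset).  Contiguous runs of samples whose absolute deviation exceeds the
    threshold form candidate events; each event is timed at its absolute
    extremum and its amplitude is the local peak-to-trough depth.  Events
    closer than ``refractory`` are merged into the larger one.

    Parameters
    ----------
    trace : VoltageTrace
    threshold : float or "auto"
        Absolute threshold in mV, or ``"auto"`` for ``mad_k`` times the robust
        noise SD estimated as MAD/0.6745 — the standard robust noise floor
        (the median absolute deviation is insensitive to the spikes
        themselves; the 0.6745 factor calibrates it to the SD of the Gaussian
        noise background).
    refractory : float
        Minimum spacing between distinct events, seconds.

    Returns
    -------
    SpikeTrain
        Unlabeled spike train (run :func:`sort_units_by_amplitude` next).
    """
    x = trace.samples - np.median(trace.samples)
    if threshold == "auto":
        mad = np.median(np.abs(x))
        thr = mad_k * mad / _MAD_TO_SD
        if thr <= 0:
            # constant trace
            return SpikeTrain(np.array([]), np.array([]))
    else:
        thr = float(threshold)
        if thr <= 0:
            raise ValueError("threshold must be > 0")

    above = np.abs(x) > thr
    if not above.any():
        return SpikeTrain(np.array([]), np.array([]))

    # contiguous supra-threshold runs
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)  # exclusive

    half_win = max(1, int(round(0.0005 * trace.sampling_rate)))  # +/-0.5 ms
    times, amps = [], []
    for s, e in zip(starts, stops):
        seg = x[s:e]
        peak_rel = int(np.argmax(np.abs(seg)))
        idx = s + peak_rel
        lo, hi = max(0, idx - half_win), min(len(x), idx + half_win + 1)
        amp = float(x[lo:hi].max() - x[lo:hi].min())
        times.append(idx / trace.sampling_rate)
        amps.append(amp)

    times = np.asarray(times)
    amps = np.asarray(amps)

    # merge events within the refractory period, keeping the larger
    keep_t, keep_a = [], []
    for t, a in zip(times, amps):
        if keep_t and t - keep_t[-1] < refractory:
            if a > keep_a[-1]:
                keep_t[-1], keep_a[-1] = t, a
        else:
            keep_t.append(t)
            keep_a.append(a)

    return SpikeTrain(np.asarray(keep_t), np.asarray(keep_a))


# --------------------------------------------------------------------------
# Amplitude sorting
# --------------------------------------------------------------------------

def _lloyd_1d(values: np.ndarray, centers: np.ndarray,
              n_iter: int = 300) -> tuple[np.ndarray, float]:
    """Lloyd iterations from given centers; returns (assignment, SSE).

    Ties in assignment break toward the lower center index.
    """
    centers = centers.astype(float).copy()
    assign = np.full(len(values), -1)
    for _ in range(n_iter):
        dist = np.abs(values[:, None] - centers[None, :])
        new_assign = np.argmin(dist, axis=1)  # argmin -> lowest index on ties
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(len(centers)):
            sel = values[assign == j]
            if len(sel):
                centers[j] = sel.mean()
    sse = float(np.sum((values - centers[assign]) ** 2))
    return assign, sse


def _farthest_first_centers(values: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-first center seeding (ties -> smaller value)."""
    centers = [float(np.median(values))]
    for _ in range(k - 1):
        dist = np.min(np.abs(values[:, None] - np.asarray(centers)[None, :]),
                      axis=1)
        centers.append(float(values[np.argmax(dist)]))
    return np.sort(np.asarray(centers))


def _kmeans_1d(values: np.ndarray, k: int) -> np.ndarray:
    """Deterministic 1-D k-means.

    Two deterministic seedings are tried — centers at the (i+0.5)/k amplitude
    quantiles, and farthest-first seeding (robust when cluster sizes are very
    unequal, where quantile seeding can place two centers in one dense
    cluster) — and the Lloyd solution with the lower within-cluster SSE is
    kept.  Fully reproducible: no random state is involved.
    """
    quantile_init = np.quantile(values, (np.arange(k) + 0.5) / k)
    candidates = [_lloyd_1d(values, quantile_init)]
    if k > 1:
        candidates.append(_lloyd_1d(values, _farthest_first_centers(values, k)))
    assign, _ = min(candidates, key=lambda c: c[1])
    return assign


def _gmm_bic(values: np.ndarray, assign: np.ndarray, k: int) -> float:
    """BIC of an equal-variance 1-D Gaussian mixture at the k-means solution."""
    n = len(values)
    resid2 = 0.0
    weights = []
    means = []
    for j in range(k):
        sel = values[assign == j]
        weights.append(len(sel) / n)
        means.append(sel.mean() if len(sel) else 0.0)
        resid2 += float(np.sum((sel - sel.mean()) ** 2)) if len(sel) else 0.0
    sigma2 = max(resid2 / n, 1e-12)
    ll = 0.0
    for v, a in zip(values, assign):
        w = max(weights[a], 1e-12)
        ll += (np.log(w)
               - 0.5 * np.log(2 * np.pi * sigma2)
               - 0.5 * (v - means[a]) ** 2 / sigma2)
    n_params = 2 * k  # k means + (k-1) weights + shared variance
    return -2.0 * ll + n_params * np.log(n)


def sort_units_by_amplitude(spikes: SpikeTrain, k: int | str = "auto",
                            max_auto_k: int = 3) -> SpikeTrain:
    """Cluster spike amplitudes into units and label them ``a, b, c, ...``.

    Labels are assigned in order of decreasing mean cluster amplitude (the
    largest-amplitude neuron is ``a``).  With ``k="auto"`` the number of units
    is chosen in ``1..max_auto_k`` by the BIC of an equal-variance Gaussian
    mixture evaluated at the deterministic k-means solution; sensilla of this
    kind house at most a handful of OSNs, so the default search stops at 3.
    """
    if len(spikes) == 0:
        raise ValueError("cannot sort an empty spike train")
    amps = spikes.amplitudes
    n_distinct = len(np.unique(amps))

    if k == "auto":
        best_k, best_bic = 1, np.inf
        for kk in range(1, min(max_auto_k, n_distinct, len(amps)) + 1):
            assign = _kmeans_1d(amps, kk)
            if len(np.unique(assign)) < kk:
                continue
            bic = _gmm_bic(amps, assign, kk)
            if bic < best_bic - 1e-9:
                best_k, best_bic = kk, bic
        k = best_k
    else:
        k = int(k)
        if k < 1:
            raise ValueError("k must be >= 1")
        if len(spikes) < k:
            raise ValueError(f"need at least k={k} spikes, have {len(spikes)}")
        if n_distinct < k:
            warnings.warn(
                f"only {n_distinct} distinct amplitudes; returning "
                f"{n_distinct} clusters instead of {k}", stacklevel=2)
            k = n_distinct

    assign = _kmeans_1d(amps, k)
    # relabel clusters by decreasing mean amplitude -> a, b, c ...
    order = np.argsort([-amps[assign == j].mean() if np.any(assign == j)
                        else np.inf for j in range(k)], kind="stable")
    letter = {int(j): string.ascii_lowercase[rank]
              for rank, j in enumerate(order)}
    labels = np.array([letter[int(j)] for j in assign], dtype=object)
    return SpikeTrain(spikes.times, spikes.amplitudes, labels)


# --------------------------------------------------------------------------
# Response quantification
# --------------------------------------------------------------------------

def delta_response(spikes: SpikeTrain, unit: str | None, stim_onset: float,
                   window: float = 1.0,
                   recording_duration: float | None = None) -> StimulusResponse:
    """Delta spikes/s of one unit around stimulus onset.

    Counts spikes of ``unit`` in ``[stim_onset - window, stim_onset)`` and
    ``[stim_onset, stim_onset + window)`` and returns
    ``(post - pre) / window``.  Counting windows of 1 s are used for screening
    and 0.5 s for dose–response work; the division renormalizes both to per
    second.

    ``unit=None`` counts all spikes regardless of label.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if stim_onset - window < 0:
        raise ValueError("pre-stimulus window extends before the recording")
    if recording_duration is not None and stim_onset + window > recording_duration:
        raise ValueError("post-stimulus window extends past the recording")
    train = spikes if unit is None else spikes.for_unit(unit)
    pre = train.count_between(stim_onset - window, stim_onset)
    post = train.count_between(stim_onset, stim_onset + window)
    return StimulusResponse(pre_count=pre, post_count=post, window=window,
                            delta_spikes_per_s=(post - pre) / window)


def solvent_correct(response: float, solvent_response: float) -> float:
    """Subtract the solvent-only response (both in delta spikes/s, same window)."""
    return response - solvent_response
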