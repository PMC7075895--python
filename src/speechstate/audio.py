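"""Acoustic feature extraction: the 88-feature voice profile of a recording.

The extractor mirrors a standard clinical voice-analysis stack (autocorrelation
pitch tracking, cycle-based jitter/shimmer, periodicity-based HNR/NHR,
intensity-based pause segmentation, long-term average spectrum, MFCCs, and
LPC formants with vowel-space geometry), implemented on numpy/scipy.  Feature
names and their distributional descriptors follow the convention
``<category>_<d>`` with d one of: a=median, b=IQR, c=kurtosis, d=skewness,
e=5th percentile, f=50th percentile, g=95th percentile, h=local, i=frames.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile
from scipy.spatial import ConvexHull, QhullError

log = logging.getLogger(__name__)

TRIM_S = 30.0

#: Reference (F1, F2) corner targets for the /a/-/i/-/u/ vowel triangle.
AIU_REFERENCE = {"a": (800.0, 1200.0), "i": (300.0, 2300.0),
                 "u": (350.0, 800.0)}


def load_inventory() -> list[str]:
    """The canonical, versioned list of the 88 acoustic feature names."""
    with resources.files("speechstate.data").joinpath(
            "acoustic_inventory.json").open() as fh:
        payload = json.load(fh)
    names = payload["features"]
    if len(names) != payload["n_features"]:
        raise ValueError("corrupt acoustic inventory file")
    return list(names)


@dataclass
class AcousticConfig:
    f0_band: tuple[float, float] = (75.0, 500.0)
    frame_s: float = 0.040
    hop_s: float = 0.010
    voicing_threshold: float = 0.45      # normalized autocorrelation peak
    silence_rel_db: float = 30.0         # voicing energy gate below max RMS
    pause_rel_db: float = 25.0           # pause threshold below max intensity
    min_pause_s: float = 0.30
    min_utterance_s: float = 0.10
    nucleus_prominence_db: float = 2.0
    mfcc_frame_s: float = 0.025
    mfcc_hop_s: float = 0.010
    n_mel_filters: int = 26
    n_mfcc: int = 16
    formant_rate: float = 10000.0        # analysis band for LPC
    preemphasis: float = 0.97

    def __post_init__(self) -> None:
        lo, hi = self.f0_band
        if not (50.0 <= lo < hi <= 600.0):
            raise ValueError("f0_band must lie within (50, 600) Hz")


@dataclass
class VoicingTrack:
    times: np.ndarray                    # frame centers, s
    f0: np.ndarray                       # Hz, NaN where unvoiced
    voiced: np.ndarray                   # bool per frame
    r_at_lag: np.ndarray                 # normalized autocorr at pitch lag
    periods: np.ndarray                  # glottal periods T_i, s
    amplitudes: np.ndarray               # cycle peak amplitudes A_i
    hop_s: float

    @property
    def voiced_fraction(self) -> float:
        return float(np.mean(self.voiced)) if len(self.voiced) else 0.0


@dataclass
class SegmentationResult:
    pauses: list[tuple[float, float]]
    utterances: list[tuple[float, float]]
    n_nuclei: int
    total_s: float

    @property
    def pause_durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.pauses])

    @property
    def utterance_durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.utterances])

    @property
    def phonation_s(self) -> float:
        return self.total_s - float(self.pause_durations.sum())

    @property
    def speech_rate(self) -> float:
        return self.n_nuclei / self.total_s if self.total_s > 0 else np.nan

    @property
    def articulation_rate(self) -> float:
        return self.n_nuclei / self.phonation_s if self.phonation_s > 0 else np.nan


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------

def preprocess(waveform: np.ndarray, sample_rate: int,
               annotations: list[tuple[float, float]] | None = None
               ) -> np.ndarray:
    """Trim the first/last 30 s and excise interviewer intervals.

    Annotation intervals are given in the time base of the *original*
    recording; excised spans are removed (not zero-filled) so duration
    statistics reflect participant speech only.
    """
    n = len(waveform)
    duration = n / sample_rate
    if duration <= 2 * TRIM_S:
        raise ValueError(
            f"recording of {duration:.1f} s is too short: must exceed "
            f"{2 * TRIM_S:.0f} s (30 s is trimmed from each end)")
    i0, i1 = int(TRIM_S * sample_rate), n - int(TRIM_S * sample_rate)
    x = np.asarray(waveform, dtype=float)[i0:i1]
    if annotations:
        keep = np.ones(len(x), dtype=bool)
        for a, b in annotations:
            j0 = int(round((a - TRIM_S) * sample_rate))
            j1 = int(round((b - TRIM_S) * sample_rate))
            j0, j1 = max(j0, 0), min(j1, len(x))
            if j1 > j0:
                keep[j0:j1] = False
        x = x[keep]
    return x


def _frame(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    if len(x) < frame_len:
        return np.empty((0, frame_len))
    n_frames = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


# ---------------------------------------------------------------------------
# voicing / pitch
# ---------------------------------------------------------------------------

def track_voicing(waveform: np.ndarray, sample_rate: int,
                  config: AcousticConfig | None = None) -> VoicingTrack:
    """Frame-wise autocorrelation pitch tracking plus glottal cycle marks."""
    cfg = config or AcousticConfig()
    sr = sample_rate
    flen = int(round(cfg.frame_s * sr))
    hop = int(round(cfg.hop_s * sr))
    frames = _frame(np.asarray(waveform, dtype=float), flen, hop)
    n_frames = len(frames)
    empty = VoicingTrack(times=np.empty(0), f0=np.empty(0),
                         voiced=np.empty(0, bool), r_at_lag=np.empty(0),
                         periods=np.empty(0), amplitudes=np.empty(0),
                         hop_s=cfg.hop_s)
    if n_frames == 0:
        return empty

    frames = frames - frames.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(frames ** 2, axis=1))
    max_rms = rms.max()
    if max_rms <= 0:
        log.warning("all-silent input: empty voicing track")
        return empty
    energy_ok = rms > max_rms * 10 ** (-cfg.silence_rel_db / 20)

    lag_min = max(2, int(np.floor(sr / cfg.f0_band[1])))
    lag_max = min(flen - 2, int(np.ceil(sr / cfg.f0_band[0])))
    nfft = int(2 ** np.ceil(np.log2(flen + lag_max + 2)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, axis=1)[:, :lag_max + 2]
    ac0 = ac[:, 0].copy()
    ac0[ac0 <= 0] = 1.0
    # unbiased normalization: the boxcar overlap shrinks raw autocorrelation
    # by (1 - lag/flen), which would deflate r at low f0
    lags = np.arange(lag_max + 2)
    acn = ac / ac0[:, None] / np.maximum(1.0 - lags / flen, 1e-3)[None, :]

    band = acn[:, lag_min:lag_max + 1]
    peak_idx = band.argmax(axis=1) + lag_min
    # parabolic refinement of the lag
    i = peak_idx
    y0 = acn[np.arange(n_frames), i - 1]
    y1 = acn[np.arange(n_frames), i]
    y2 = acn[np.arange(n_frames), i + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    lag = i + shift
    r_peak = np.clip(y1 - 0.25 * (y0 - y2) * shift, -1.0, 1.0)

    voiced = (r_peak > cfg.voicing_threshold) & energy_ok
    f0 = np.where(voiced, sr / lag, np.nan)
    times = (np.arange(n_frames) * hop + flen / 2) / sr
    r_at_lag = np.where(voiced, np.clip(r_peak, 1e-6, 1 - 1e-6), np.nan)

    periods, amplitudes = _cycle_marks(np.asarray(waveform, float), sr, times,
                                       f0, voiced, hop)
    return VoicingTrack(times=times, f0=f0, voiced=voiced, r_at_lag=r_at_lag,
                        periods=periods, amplitudes=amplitudes, hop_s=cfg.hop_s)


def _cycle_marks(x: np.ndarray, sr: int, times: np.ndarray, f0: np.ndarray,
                 voiced: np.ndarray, hop: int) -> tuple[np.ndarray, np.ndarray]:
    """Peak-picked glottal cycle marks inside each voiced run.

    Returns period and amplitude sequences; cycles in distinct voiced runs
    are never differenced together (a NaN separator is *not* stored — the
    sequences are concatenated per run by the caller convention that
    jitter/shimmer use within-run differences; we keep runs apart by
    inserting the boundary via period = NaN).
    """
    periods: list[float] = []
    amps: list[float] = []
    absx = np.abs(x)
    runs = _bool_runs(voiced)
    for r0, r1 in runs:
        t_start = int(times[r0] * sr) - hop
        t_end = min(int(times[r1 - 1] * sr) + hop, len(x) - 1)
        t_start = max(t_start, 0)
        med_f0 = np.nanmedian(f0[r0:r1])
        if not np.isfinite(med_f0) or med_f0 <= 0:
            continue
        period = sr / med_f0
        # first mark: strongest peak within one period of the run start
        w1 = absx[t_start:min(t_start + int(period) + 1, t_end)]
        if len(w1) == 0:
            continue
        mark = t_start + int(np.argmax(w1))
        run_marks = [_refine_peak(absx, mark)]
        pos = mark
        while True:
            lo = pos + int(period * 0.7)
            hi = pos + int(period * 1.3) + 1
            if hi >= t_end:
                break
            nxt = lo + int(np.argmax(absx[lo:hi]))
            run_marks.append(_refine_peak(absx, nxt))
            pos = nxt
        if len(run_marks) >= 2:
            m = np.asarray(run_marks)
            periods.extend(np.diff(m) / sr)
            amps.extend(np.interp(m, np.arange(len(absx)), absx))
            periods.append(np.nan)  # run separator
            amps.append(np.nan)
    return np.asarray(periods), np.asarray(amps)


def _refine_peak(absx: np.ndarray, i: int) -> float:
    if 1 <= i < len(absx) - 1:
        y0, y1, y2 = absx[i - 1], absx[i], absx[i + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-12:
            return i + float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    return float(i)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of True runs."""
    if len(mask) == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


# ---------------------------------------------------------------------------
# perturbation / noise measures
# ---------------------------------------------------------------------------

def _within_run_sequences(values: np.ndarray) -> list[np.ndarray]:
    """Split a NaN-separated sequence into per-run arrays."""
    out, cur = [], []
    for v in values:
        if np.isnan(v):
            if cur:
                out.append(np.asarray(cur))
            cur = []
        else:
            cur.append(v)
    if cur:
        out.append(np.asarray(cur))
    return out


def _local_perturbation(seqs: list[np.ndarray]) -> float:
    num = sum(float(np.sum(np.abs(np.diff(s)))) for s in seqs if len(s) > 1)
    cnt = sum(len(s) - 1 for s in seqs if len(s) > 1)
    allv = np.concatenate(seqs) if seqs else np.empty(0)
    if cnt == 0 or len(allv) == 0 or np.mean(allv) == 0:
        return np.nan
    return 100.0 * (num / cnt) / float(np.mean(allv))


def _ppq5(seqs: list[np.ndarray]) -> float:
    devs, vals = [], []
    for s in seqs:
        if len(s) < 5:
            continue
        ma = np.convolve(s, np.ones(5) / 5, mode="valid")
        devs.append(np.abs(s[2:-2] - ma))
        vals.append(s)
    if not devs:
        return np.nan
    allv = np.concatenate(vals)
    return 100.0 * float(np.mean(np.concatenate(devs))) / float(np.mean(allv))


def jitter_shimmer(track: VoicingTrack) -> dict[str, float]:
    """Cycle-based perturbation and voice-break measures (percent)."""
    p_seqs = _within_run_sequences(track.periods)
    a_seqs = _within_run_sequences(track.amplitudes)
    out = {
        "jitter_local": _local_perturbation(p_seqs),
        "jitter_ppq5": _ppq5(p_seqs),
        "shimmer_local": _local_perturbation(a_seqs),
        "shimmer_apq5": _ppq5(a_seqs),
    }
    voiced = track.voiced
    if voiced.any():
        first, last = np.flatnonzero(voiced)[[0, -1]]
        span = voiced[first:last + 1]
        unvoiced_runs = _bool_runs(~span)
        out["voice_breaks_n"] = float(len(unvoiced_runs))
        out["voice_breaks_degree"] = 100.0 * float(np.sum(~span)) / len(span)
    else:
        out["voice_breaks_n"] = np.nan
        out["voice_breaks_degree"] = np.nan
        log.info("no voiced frames: voice-break measures missing")
    return out


def noise_measures(track: VoicingTrack) -> dict[str, float]:
    """HNR (dB), NHR, and mean autocorrelation from voiced-frame periodicity."""
    r = track.r_at_lag[np.isfinite(track.r_at_lag)]
    if len(r) == 0:
        log.info("no voiced frames: noise measures missing")
        return {"hnr_db": np.nan, "nhr": np.nan, "mean_autocorr": np.nan}
    return {
        "hnr_db": float(np.mean(10.0 * np.log10(r / (1.0 - r)))),
        "nhr": float(np.mean((1.0 - r) / r)),
        "mean_autocorr": float(np.mean(r)),
    }


# ---------------------------------------------------------------------------
# temporal segmentation
# ---------------------------------------------------------------------------

def segment_pauses(waveform: np.ndarray, sample_rate: int,
                   config: AcousticConfig | None = None) -> SegmentationResult:
    """Intensity-threshold pause/utterance segmentation and syllable nuclei."""
    cfg = config or AcousticConfig()
    sr = sample_rate
    flen = int(round(0.030 * sr))
    hop = int(round(cfg.hop_s * sr))
    x = np.asarray(waveform, dtype=float)
    total_s = len(x) / sr
    frames = _frame(x, flen, hop)
    if len(frames) == 0:
        return SegmentationResult([(0.0, total_s)], [], 0, total_s)
    rms = np.sqrt(np.mean(frames ** 2, axis=1))
    db = 20.0 * np.log10(rms + 1e-12)
    threshold = db.max() - cfg.pause_rel_db
    speechy = (db >= threshold) & (rms > 1e-9)
    if not speechy.any():
        return SegmentationResult([(0.0, total_s)], [], 0, total_s)

    # silent runs shorter than min_pause are folded into speech ...
    for a, b in _bool_runs(~speechy):
        if (b - a) * cfg.hop_s < cfg.min_pause_s:
            speechy[a:b] = True
    # ... then speech runs shorter than min_utterance are folded into silence
    for a, b in _bool_runs(speechy):
        if (b - a) * cfg.hop_s < cfg.min_utterance_s:
            speechy[a:b] = False

    def to_time(i: int) -> float:
        return min(i * cfg.hop_s, total_s)

    pauses = [(to_time(a), to_time(b)) for a, b in _bool_runs(~speechy)]
    utterances = [(to_time(a), to_time(b)) for a, b in _bool_runs(speechy)]

    peaks, _ = sps.find_peaks(db, prominence=cfg.nucleus_prominence_db)
    n_nuclei = int(np.sum(speechy[peaks]))
    return SegmentationResult(pauses, utterances, n_nuclei, total_s)


# ---------------------------------------------------------------------------
# spectral block
# ---------------------------------------------------------------------------

def _mel(f: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_inv(m: np.ndarray) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, nfft: int, sr: float) -> np.ndarray:
    edges = _mel_inv(np.linspace(_mel(0.0), _mel(sr / 2), n_filters + 2))
    bins = np.floor((nfft + 1) * edges / sr).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for m in range(1, n_filters + 1):
        lo, c, hi = bins[m - 1], bins[m], bins[m + 1]
        if c == lo:
            c += 1
        if hi == c:
            hi += 1
        fb[m - 1, lo:c] = (np.arange(lo, c) - lo) / (c - lo)
        fb[m - 1, c:hi] = (hi - np.arange(c, hi)) / (hi - c)
    return fb


def mfcc(waveform: np.ndarray, sample_rate: int,
         config: AcousticConfig | None = None) -> np.ndarray:
    """MFCC matrix (n_mfcc, n_frames): coefficients 1..16, 25/10 ms framing."""
    from scipy.fft import dct

    cfg = config or AcousticConfig()
    sr = sample_rate
    flen = int(round(cfg.mfcc_frame_s * sr))
    hop = int(round(cfg.mfcc_hop_s * sr))
    frames = _frame(np.asarray(waveform, float), flen, hop)
    if len(frames) == 0:
        return np.empty((cfg.n_mfcc, 0))
    window = np.hanning(flen)
    nfft = int(2 ** np.ceil(np.log2(flen)))
    power = np.abs(np.fft.rfft(frames * window, n=nfft, axis=1)) ** 2
    fb = _mel_filterbank(cfg.n_mel_filters, nfft, sr)
    logmel = np.log(power @ fb.T + 1e-10)
    coeffs = dct(logmel, type=2, norm="ortho", axis=1)
    return coeffs[:, 1:cfg.n_mfcc + 1].T


def spectral_block(waveform: np.ndarray, sample_rate: int,
                   config: AcousticConfig | None = None) -> dict[str, float]:
    """Long-term average spectrum statistics."""
    x = np.asarray(waveform, dtype=float)
    nperseg = min(4096, len(x))
    freqs, psd = sps.welch(x, fs=sample_rate, nperseg=nperseg)
    psd_db = 10.0 * np.log10(psd + 1e-20)
    imax = int(np.argmax(psd))
    band = (freqs >= 50.0) & (freqs <= min(8000.0, sample_rate / 2))
    if band.sum() >= 2:
        slope = float(np.polyfit(np.log2(freqs[band]), psd_db[band], 1)[0])
    else:
        slope = np.nan
    return {
        "max_db": float(psd_db[imax]),
        "freq_at_max": float(freqs[imax]),
        "energy": float(np.sum(x ** 2)),
        "spectral_slope": slope,
    }


# ---------------------------------------------------------------------------
# formants / vowel space
# ---------------------------------------------------------------------------

def _batch_levinson(r: np.ndarray, order: int) -> np.ndarray:
    """Levinson-Durbin recursion vectorized over frames.

    r: (n_frames, order+1) autocorrelation rows (r[:,0] > 0).
    Returns predictor coefficients a of shape (n_frames, order) such that the
    inverse filter is A(z) = 1 - sum_k a_k z^-k.
    """
    n = len(r)
    a = np.zeros((n, order))
    err = r[:, 0].astype(float).copy()
    for m in range(order):
        acc = r[:, m + 1].copy()
        if m > 0:
            acc -= np.einsum("ij,ij->i", a[:, :m], r[:, m:0:-1])
        k = np.where(err > 1e-20, acc / np.maximum(err, 1e-20), 0.0)
        if m > 0:
            a[:, :m] -= k[:, None] * a[:, m - 1::-1]
        a[:, m] = k
        err *= (1.0 - k * k)
    return a


def _batch_formants(frames: np.ndarray, sr: float, order: int) -> np.ndarray:
    """First three formants per frame via LPC root-solving (batched).

    Returns (n_frames, 3); rows with fewer than three admissible resonances
    are NaN.
    """
    n, flen = frames.shape
    out = np.full((n, 3), np.nan)
    if n == 0:
        return out
    nfft = int(2 ** np.ceil(np.log2(2 * flen)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    r = np.fft.irfft(np.abs(spec) ** 2, axis=1)[:, :order + 1]
    good = r[:, 0] > 1e-20
    a = _batch_levinson(r[good], order)
    # companion matrices of A(z) = 1 - a1 z^-1 - ... - a_p z^-p
    p = order
    comp = np.zeros((len(a), p, p))
    comp[:, 0, :] = a
    idx = np.arange(p - 1)
    comp[:, idx + 1, idx] = 1.0
    roots = np.linalg.eigvals(comp)
    freqs = np.angle(roots) * sr / (2 * np.pi)
    bw = -np.log(np.maximum(np.abs(roots), 1e-12)) * sr / np.pi
    admissible = (np.imag(roots) > 0.01) & (freqs > 90.0) \
        & (freqs < sr / 2 - 100.0) & (bw < 700.0)
    freqs = np.where(admissible, freqs, np.inf)
    freqs.sort(axis=1)
    rows = np.flatnonzero(good)
    first3 = freqs[:, :3]
    ok = np.isfinite(first3).all(axis=1)
    out[rows[ok]] = first3[ok]
    return out


def shoelace_area(points: np.ndarray) -> float:
    """Polygon area by the shoelace formula; vertices in order."""
    x, y = np.asarray(points, float).T
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def aiu_metrics(f1f2: np.ndarray) -> dict[str, float]:
    """Corner-centroid /a/-/i/-/u/ triangle area (Hz^2) and apex angle at /i/.

    Each (F1, F2) point is assigned to the nearest of the three reference
    corner targets; the triangle is formed by the per-corner centroids.
    """
    refs = np.array(list(AIU_REFERENCE.values()))
    names = list(AIU_REFERENCE)
    pts = np.asarray(f1f2, dtype=float)
    d = np.linalg.norm(pts[:, None, :] - refs[None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    centroids = {}
    for k, name in enumerate(names):
        sel = pts[nearest == k]
        if len(sel) == 0:
            return {"aiu_area": np.nan, "angle_deg": np.nan}
        centroids[name] = sel.mean(axis=0)
    tri = np.array([centroids["a"], centroids["i"], centroids["u"]])
    area = shoelace_area(tri)
    va = centroids["a"] - centroids["i"]
    vu = centroids["u"] - centroids["i"]
    cosang = np.dot(va, vu) / (np.linalg.norm(va) * np.linalg.norm(vu) + 1e-12)
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return {"aiu_area": area, "angle_deg": angle}


def formant_block(waveform: np.ndarray, sample_rate: int, track: VoicingTrack,
                  config: AcousticConfig | None = None
                  ) -> tuple[np.ndarray, dict[str, float]]:
    """LPC formants on voiced frames plus vowel-space geometry.

    Returns (formant matrix of shape (n_voiced_frames, 3) with NaN rows where
    fewer than three formants resolved, summary dict).
    """
    cfg = config or AcousticConfig()
    sr_a = cfg.formant_rate
    x = np.asarray(waveform, dtype=float)
    from math import gcd
    g = gcd(int(sr_a), int(sample_rate))
    y = sps.resample_poly(x, int(sr_a) // g, int(sample_rate) // g)
    y = np.append(y[0], y[1:] - cfg.preemphasis * y[:-1])
    order = int(2 + sr_a / 1000)
    flen = int(round(0.025 * sr_a))
    window = np.hamming(flen)

    # every second voiced frame (20 ms effective hop) is ample for the
    # distributional summaries and halves the LPC cost
    voiced_times = track.times[track.voiced][::2]
    starts = (voiced_times * sr_a).astype(int) - flen // 2
    starts = starts[(starts >= 0) & (starts + flen <= len(y))]
    if len(starts):
        idx = starts[:, None] + np.arange(flen)[None, :]
        formants = _batch_formants(y[idx] * window, sr_a, order)
    else:
        formants = np.empty((0, 3))

    valid = formants[~np.isnan(formants).any(axis=1)] if len(formants) else formants
    summary: dict[str, float]
    if len(valid) < 10:
        log.info("fewer than 10 voiced formant frames: vowel-space missing")
        summary = {"total_area": np.nan, "aiu_area": np.nan, "angle_deg": np.nan}
    else:
        f1f2 = valid[:, :2]
        try:
            total = float(ConvexHull(f1f2).volume)  # 2-D volume == area
        except QhullError:
            total = 0.0
        summary = {"total_area": total, **aiu_metrics(f1f2)}
    return formants, summary


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

_DESCRIPTORS = {"a": "median", "b": "IQR", "c": "kurtosis", "d": "skewness",
                "e": "p5", "f": "p50", "g": "p95"}


def summarize(series: np.ndarray, descriptors: str = "abcdeg"
              ) -> dict[str, float]:
    """Distributional descriptors of a series (NaNs ignored).

    a=median, b=IQR, c=excess kurtosis, d=skewness, e/f/g=5th/50th/95th
    percentiles; order statistics use linear interpolation between closest
    ranks.  Constant series have skewness and kurtosis 0 by convention.
    """
    unknown = set(descriptors) - set(_DESCRIPTORS)
    if unknown:
        raise ValueError(f"unknown descriptors: {sorted(unknown)}")
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    out: dict[str, float] = {}
    for d in descriptors:
        if len(x) == 0:
            out[d] = np.nan
            continue
        if d == "a" or d == "f":
            out[d] = float(np.median(x))
        elif d == "b":
            q75, q25 = np.percentile(x, [75, 25])
            out[d] = float(q75 - q25)
        elif d in ("c", "d"):
            sd = x.std()
            if sd == 0:
                out[d] = 0.0
            else:
                z = (x - x.mean()) / sd
                out[d] = float(np.mean(z ** 4) - 3.0) if d == "c" \
                    else float(np.mean(z ** 3))
        elif d == "e":
            out[d] = float(np.percentile(x, 5))
        elif d == "g":
            out[d] = float(np.percentile(x, 95))
    return out


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a mono PCM WAV as float in [-1, 1]."""
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio")
    if data.dtype == np.int16:
        data = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(float) / 2147483648.0
    else:
        data = data.astype(float)
    return data, int(sr)


def read_annotations(path: str | Path) -> list[tuple[float, float]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != "start_s,end_s":
            raise ValueError(f"{path}: expected 'start_s,end_s' header")
        for line in fh:
            a, b = line.strip().split(",")
            out.append((float(a), float(b)))
    return out


def extract_acoustic_from_signal(waveform: np.ndarray, sample_rate: int,
                                 annotations=None,
                                 config: AcousticConfig | None = None
                                 ) -> dict[str, float]:
    """Compute the 88 canonical acoustic features from a raw recording."""
    cfg = config or AcousticConfig()
    x = preprocess(waveform, sample_rate, annotations)

    track = track_voicing(x, sample_rate, cfg)
    js = jitter_shimmer(track)
    nm = noise_measures(track)
    seg = segment_pauses(x, sample_rate, cfg)
    spec = spectral_block(x, sample_rate, cfg)
    mf = mfcc(x, sample_rate, cfg)
    formants, vowel = formant_block(x, sample_rate, track, cfg)

    feats: dict[str, float] = {}
    f0 = track.f0[np.isfinite(track.f0)]
    for d, v in summarize(f0, "abcdeg").items():
        feats[f"Pitch_{d}"] = v
    feats["Jitter_h"] = js["jitter_local"]
    feats["Jitter_ppq5"] = js["jitter_ppq5"]
    feats["Shimmer_h"] = js["shimmer_local"]
    feats["Shimmer_apq5"] = js["shimmer_apq5"]
    feats["VoiceBreaks_n"] = js["voice_breaks_n"]
    feats["VoiceBreaks_degree"] = js["voice_breaks_degree"]
    feats["HNR"] = nm["hnr_db"]
    feats["NHR"] = nm["nhr"]
    feats["MeanAutocorr"] = nm["mean_autocorr"]
    feats["Spectral_maxdB"] = spec["max_db"]
    feats["Spectral_maxfreq"] = spec["freq_at_max"]
    feats["Spectral_energy"] = spec["energy"]
    feats["Spectral_slope"] = spec["spectral_slope"]
    for i in range(cfg.n_mfcc):
        s = summarize(mf[i], "ab") if mf.shape[1] else {"a": np.nan, "b": np.nan}
        feats[f"MFCC #{i + 1}_a"] = s["a"]
        feats[f"MFCC #{i + 1}_b"] = s["b"]
    for k in range(3):
        series = formants[:, k] if len(formants) else np.empty(0)
        for d, v in summarize(series, "abcdeg").items():
            feats[f"F{k + 1}_{d}"] = v
    feats["VowelSpace_total"] = vowel["total_area"]
    feats["VowelSpace_aiu"] = vowel["aiu_area"]
    feats["Angle"] = vowel["angle_deg"]
    for d, v in summarize(seg.pause_durations, "abcdeg").items():
        feats[f"PauseDist_{d}"] = v
    feats["PauseDist_max"] = (float(seg.pause_durations.max())
                              if len(seg.pauses) else np.nan)
    for d, v in summarize(seg.utterance_durations, "abeg").items():
        feats[f"UttDist_{d}"] = v
    feats["PauseCount"] = float(len(seg.pauses))
    feats["Unvoiced_i"] = (100.0 * (1.0 - track.voiced_fraction)
                           if len(track.voiced) else np.nan)
    feats["SpeechRate"] = seg.speech_rate
    feats["ArticRate"] = seg.articulation_rate
    feats["PhonationRatio"] = (seg.phonation_s / seg.total_s
                               if seg.total_s > 0 else np.nan)

    inventory = load_inventory()
    missing = set(inventory) - set(feats)
    extra = set(feats) - set(inventory)
    if missing or extra:
        raise RuntimeError(f"inventory mismatch: missing={sorted(missing)} "
                           f"extra={sorted(extra)}")
    return {name: float(feats[name]) for name in inventory}


def extract_acoustic(audio_path: str | Path, annotation_path: str | Path | None = None,
                     config: AcousticConfig | None = None) -> dict[str, float]:
    """Extract the 88 acoustic features from a WAV file on disk."""
    wave, sr = read_wav(audio_path)
    ann = None
    if annotation_path:
        ann = read_annotations(annotation_path)
    return extract_acoustic_from_signal(wave, sr, ann, config)
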