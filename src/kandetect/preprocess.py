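"""Scalp-EEG preprocessing: segmentation, ICA eye-artifact removal, STFT features.

The pipeline turns an annotated multichannel recording into labeled
time-frequency tensors:

1. the recording is cut into non-overlapping 12 s windows, each labeled
   seizure or background from the annotated ictal intervals;
2. each window is decomposed into 19 independent components (``T = M A``,
   with ``M`` the component time courses and ``A`` the topographies);
   components whose time course correlates strongly with the fronto-polar
   channels FP1/FP2 — the signature of eye blinks — are removed and the
   window is rebuilt from the remainder;
3. a short-time Fourier transform (250-sample window, 50% overlap, DC bin
   dropped) turns each cleaned window into a channels x frames x frequencies
   tensor: ``19 x 23 x 125`` at the pipeline's 250 Hz rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA

__all__ = [
    "CHANNELS_1020",
    "EEGRecording",
    "ICADecomposition",
    "STFTConfig",
    "FeatureSet",
    "load_edf",
    "count_windows",
    "segment_recording",
    "run_ica",
    "pearson_r",
    "score_eye_components",
    "remove_components",
    "clean_recording",
    "stft_features",
    "stft_shape",
    "standardize_features",
    "flatten_features",
]

#: The fixed 19-electrode 10-20 montage used throughout the pipeline.
CHANNELS_1020 = [
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "FZ", "CZ", "PZ",
]

PIPELINE_FS = 250.0  # Hz; recordings at other rates are resampled
_STD_EPS = 1e-8  # variance floor for standardization


@dataclass
class EEGRecording:
    """Multichannel scalp EEG in microvolts plus seizure annotations."""

    signals: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_names: list[str]
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    record_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a (n_channels, n_samples) matrix")
        if self.signals.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.signals.shape[0]} signal rows but {len(self.channel_names)} channel names"
            )
        dur = self.duration_s
        for onset, offset, _label in self.annotations:
            if not (0.0 <= onset < offset <= dur + 1e-9):
                raise ValueError(f"annotation ({onset}, {offset}) outside [0, {dur:.3f}]")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.signals.shape[1] / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.signals[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None


def load_edf(path, sidecar_csv=None, resample_to: float = PIPELINE_FS) -> EEGRecording:
    """Read an EDF/EDF+ file into the standard 19-channel montage.

    Channels are mapped by 10-20 label (case-insensitive; common prefixes
    like ``EEG FP1-REF`` are stripped); surplus channels are dropped and a
    missing montage channel is an error.  Seizure annotations come from the
    EDF+ annotation records or, if given, a sidecar CSV with columns
    ``onset_s, offset_s, label``.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads volts; the pipeline uses microvolts
    fs = float(raw.info["sfreq"])

    def norm(name: str) -> str:
        n = name.upper().replace("EEG ", "").strip()
        for sep in ("-REF", "-LE", "-AVG"):
            n = n.replace(sep, "")
        return n.strip()

    lookup = {norm(n): i for i, n in enumerate(raw.ch_names)}
    rows = []
    for ch in CHANNELS_1020:
        if ch not in lookup:
            raise ValueError(f"EDF file {path} is missing montage channel {ch}")
        rows.append(data[lookup[ch]])
    signals = np.vstack(rows)

    annotations: list[tuple[float, float, str]] = []
    if sidecar_csv is not None:
        import pandas as pd

        tab = pd.read_csv(sidecar_csv)
        for _, row in tab.iterrows():
            annotations.append((float(row["onset_s"]), float(row["offset_s"]), str(row["label"])))
    else:
        for ann in raw.annotations:
            desc = str(ann["description"]).lower()
            if "seiz" in desc:
                annotations.append(
                    (float(ann["onset"]), float(ann["onset"]) + float(ann["duration"]), "seizure")
                )

    if resample_to and abs(fs - resample_to) > 1e-6:
        from fractions import Fraction

        frac = Fraction(int(round(resample_to)), int(round(fs)))
        signals = sps.resample_poly(signals, frac.numerator, frac.denominator, axis=1)
        fs = float(resample_to)

    return EEGRecording(signals, fs, list(CHANNELS_1020), annotations, record_id=Path(path).stem)


# -- segmentation -----------------------------------------------------------


def count_windows(n_samples: int, fs: float, window_s: float = 12.0) -> int:
    """Number of full non-overlapping windows in a recording of ``n_samples``."""
    wlen = int(round(fs * window_s))
    if wlen <= 0:
        raise ValueError("window length must be positive")
    return int(n_samples // wlen)


def segment_recording(
    rec: EEGRecording,
    window_s: float = 12.0,
    label_rule: float = 0.0,
) -> list[tuple[np.ndarray, int, float]]:
    """Cut a recording into non-overlapping windows with binary labels.

    Returns ``(segment, label, onset_s)`` triples; the trailing partial
    window is discarded.  A window is labeled seizure (1) when its overlap
    with any annotated seizure interval exceeds ``label_rule`` as a fraction
    of the window (the default 0.0 means *any* overlap marks it seizure).
    """
    wlen = int(round(rec.fs * window_s))
    if abs(rec.fs * window_s - wlen) > 1e-6:
        raise ValueError(f"fs * window_s must be integral, got {rec.fs * window_s}")
    if not 0.0 <= label_rule < 1.0:
        raise ValueError(f"label_rule must be in [0, 1), got {label_rule}")
    n_win = count_windows(rec.n_samples, rec.fs, window_s)
    out = []
    for w in range(n_win):
        t0 = w * window_s
        t1 = t0 + window_s
        overlap = 0.0
        for onset, offset, label in rec.annotations:
            if label != "seizure":
                continue
            overlap += max(0.0, min(t1, offset) - max(t0, onset))
        is_seizure = overlap > label_rule * window_s if label_rule > 0 else overlap > 0
        out.append((rec.signals[:, w * wlen : (w + 1) * wlen], int(is_seizure), t0))
    return out


# -- ICA eye-artifact removal ----------------------------------------------


@dataclass
class ICADecomposition:
    """``T = M A`` factorization of a (centered) recording.

    ``mixing_time_courses`` M: (n_samples, n_components) unit-variance
    component time courses; ``topographies`` A: (n_components, n_channels);
    the centered data is recovered as ``M @ A``.
    """

    mixing_time_courses: np.ndarray
    topographies: np.ndarray
    channel_mean: np.ndarray
    channel_names: list[str]
    fs: float
    residual: float
    eye_scores: np.ndarray | None = None
    rejected: set[int] = field(default_factory=set)

    @property
    def n_components(self) -> int:
        return self.topographies.shape[0]

    def reconstruct(self, drop: set[int] | None = None) -> np.ndarray:
        """Rebuild channel-space signals, optionally zeroing some components."""
        m = self.mixing_time_courses
        if drop:
            keep = [i for i in range(self.n_components) if i not in drop]
            data = m[:, keep] @ self.topographies[keep]
        else:
            data = m @ self.topographies
        return data.T + self.channel_mean[:, None]


def run_ica(
    rec: EEGRecording,
    n_components: int = 19,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-3,
) -> ICADecomposition:
    """Blind source separation of the recording into independent components.

    FastICA with a fixed seed; components are ordered by descending explained
    variance and each topography's sign is fixed so its largest-magnitude
    channel weight is positive, making the factorization reproducible.
    """
    if n_components > rec.n_channels:
        raise ValueError(
            f"n_components={n_components} exceeds the {rec.n_channels} available channels"
        )
    x = rec.signals.T  # (n_samples, n_channels)
    mean = x.mean(axis=0)
    xc = x - mean
    stds = xc.std(axis=0)
    if np.any(stds < 1e-12):
        flat = [rec.channel_names[i] for i in np.where(stds < 1e-12)[0]]
        raise ValueError(f"rank-deficient data: constant channel(s) {flat}")
    ica = FastICA(
        n_components=n_components,
        random_state=seed,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-convergence on odd segments is tolerable
        m = ica.fit_transform(xc)  # (n_samples, n_components), unit variance
    a = ica.mixing_.T  # (n_components, n_channels)

    # canonical ordering: descending variance contributed to channel space
    contrib = m.var(axis=0) * np.sum(a**2, axis=1)
    order = np.argsort(contrib)[::-1]
    m, a = m[:, order], a[order]
    # canonical signs: largest-|weight| entry of each topography positive
    signs = np.sign(a[np.arange(a.shape[0]), np.argmax(np.abs(a), axis=1)])
    signs[signs == 0] = 1.0
    m, a = m * signs, a * signs[:, None]

    recon = m @ a
    denom = np.linalg.norm(xc)
    residual = float(np.linalg.norm(xc - recon) / denom) if denom > 0 else 0.0
    return ICADecomposition(m, a, mean, list(rec.channel_names), rec.fs, residual)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; defined as 0 when either vector has no variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt(np.sum(ac**2) * np.sum(bc**2))
    if denom == 0:
        import warnings

        warnings.warn("zero-variance input to Pearson correlation; score set to 0", stacklevel=2)
        return 0.0
    return float(np.dot(ac, bc) / denom)


def score_eye_components(dec: ICADecomposition, rec: EEGRecording) -> np.ndarray:
    """Per-component eye score: max |r| of its time course vs FP1 and FP2."""
    fp1 = rec.channel("FP1")
    fp2 = rec.channel("FP2")
    scores = np.array(
        [
            max(
                abs(pearson_r(dec.mixing_time_courses[:, c], fp1)),
                abs(pearson_r(dec.mixing_time_courses[:, c], fp2)),
            )
            for c in range(dec.n_components)
        ]
    )
    dec.eye_scores = scores
    return scores


def remove_components(
    dec: ICADecomposition,
    rec: EEGRecording,
    threshold: float = 0.6,
    top_k: int | None = None,
) -> EEGRecording:
    """Rebuild the recording with eye-related components removed.

    Components with eye score >= ``threshold`` (or, in top-k mode, the ``k``
    highest-scoring ones) are zeroed before reconstruction.  Refuses to
    remove everything.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    scores = dec.eye_scores if dec.eye_scores is not None else score_eye_components(dec, rec)
    if top_k is not None:
        drop = set(np.argsort(scores)[::-1][:top_k].tolist())
    else:
        drop = set(np.where(scores >= threshold)[0].tolist())
    if len(drop) >= dec.n_components:
        raise ValueError("refusing to remove every component (would output all-zero EEG)")
    dec.rejected = drop
    cleaned = dec.reconstruct(drop=drop)
    return EEGRecording(
        cleaned, rec.fs, list(rec.channel_names), list(rec.annotations), rec.record_id
    )


def clean_recording(
    rec: EEGRecording,
    threshold: float = 0.6,
    seed: int = 0,
    per_segment_s: float | None = 12.0,
) -> EEGRecording:
    """Eye-artifact removal over a whole recording.

    By default ICA runs independently on each 12 s segment (matching the
    segment-wise pipeline); ``per_segment_s=None`` runs a single whole-record
    decomposition, which is faster on long files.
    """
    if per_segment_s is None:
        dec = run_ica(rec, n_components=rec.n_channels, seed=seed)
        score_eye_components(dec, rec)
        return remove_components(dec, rec, threshold=threshold)
    wlen = int(round(rec.fs * per_segment_s))
    n_win = rec.n_samples // wlen
    cleaned = rec.signals.copy()
    for w in range(n_win):
        sl = slice(w * wlen, (w + 1) * wlen)
        seg = EEGRecording(rec.signals[:, sl], rec.fs, list(rec.channel_names))
        dec = run_ica(seg, n_components=rec.n_channels, seed=seed)
        score_eye_components(dec, seg)
        cleaned[:, sl] = remove_components(dec, seg, threshold=threshold).signals
    return EEGRecording(cleaned, rec.fs, list(rec.channel_names), list(rec.annotations),
                        rec.record_id)


# -- STFT featurization -----------------------------------------------------


@dataclass(frozen=True)
class STFTConfig:
    """Short-time Fourier transform settings.

    Defaults give the pipeline's shape contract: a 250-sample (1 s) window
    with 50% overlap and the DC bin dropped turns a 12 s, 250 Hz segment into
    23 frames x 125 frequency bins per channel.
    """

    window_samples: int = 250
    overlap_fraction: float = 0.5
    drop_dc: bool = True
    window_function: str = "hann"
    magnitude_mode: str = "log_magnitude"

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError(f"overlap_fraction must be in [0, 1), got {self.overlap_fraction}")
        if self.window_function not in ("hann", "rectangular"):
            raise ValueError(f"unknown window_function {self.window_function!r}")
        if self.magnitude_mode not in ("magnitude", "log_magnitude", "power"):
            raise ValueError(f"unknown magnitude_mode {self.magnitude_mode!r}")

    @property
    def hop(self) -> int:
        return int(round(self.window_samples * (1.0 - self.overlap_fraction)))


def stft_shape(segment_len: int, cfg: STFTConfig | None = None) -> tuple[int, int]:
    """(n_frames, n_freqs) the transform will produce for a segment length."""
    cfg = cfg or STFTConfig()
    if segment_len < cfg.window_samples:
        raise ValueError(
            f"segment of {segment_len} samples is shorter than the "
            f"{cfg.window_samples}-sample analysis window"
        )
    n_frames = (segment_len - cfg.window_samples) // cfg.hop + 1
    n_freqs = cfg.window_samples // 2 + 1 - (1 if cfg.drop_dc else 0)
    return n_frames, n_freqs


def stft_features(segment: np.ndarray, cfg: STFTConfig | None = None) -> np.ndarray:
    """Time-frequency features of one multichannel segment.

    ``segment``: (n_channels, n_samples).  Returns (n_channels, n_frames,
    n_freqs) with magnitudes per ``cfg.magnitude_mode``.
    """
    cfg = cfg or STFTConfig()
    segment = np.atleast_2d(np.asarray(segment, dtype=np.float64))
    n_frames, n_freqs = stft_shape(segment.shape[1], cfg)
    win = "hann" if cfg.window_function == "hann" else ("boxcar", 0)
    _, _, z = sps.stft(
        segment,
        window=win if cfg.window_function == "hann" else "boxcar",
        nperseg=cfg.window_samples,
        noverlap=cfg.window_samples - cfg.hop,
        boundary=None,
        padded=False,
        axis=-1,
        scaling="spectrum",
    )
    # z: (n_channels, n_freq_bins, n_frames)
    mag = np.abs(z)
    if cfg.drop_dc:
        mag = mag[:, 1:, :]
    if cfg.magnitude_mode == "power":
        mag = mag**2
    elif cfg.magnitude_mode == "log_magnitude":
        mag = np.log1p(mag)
    feats = mag.transpose(0, 2, 1)  # -> (channels, frames, freqs)
    if feats.shape[1:] != (n_frames, n_freqs):
        raise AssertionError(f"STFT produced {feats.shape[1:]}, expected {(n_frames, n_freqs)}")
    return feats


def flatten_features(x: np.ndarray) -> np.ndarray:
    """Flatten (n, channels, frames, freqs) channel-major into (n, d)."""
    x = np.asarray(x)
    return x.reshape(x.shape[0], -1)


def standardize_features(
    x: np.ndarray, stats: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-feature affine transform to zero mean / unit variance.

    ``stats=None`` computes (mean, std) on ``x`` — do this on the training
    split only — otherwise the provided training stats are applied unchanged.
    Note the transform is not idempotent when re-applied with saved stats.
    Zero-variance features have their std floored so constants map to 0.
    """
    flat = flatten_features(x)
    if stats is None:
        mean = flat.mean(axis=0)
        std = flat.std(axis=0)
        std = np.maximum(std, _STD_EPS)
        stats = (mean, std)
    mean, std = stats
    out = (flat - mean) / std
    return out.reshape(x.shape), stats


# -- feature-set container ---------------------------------------------------


@dataclass
class FeatureSet:
    """Labeled feature tensors plus the provenance needed to reuse them."""

    x: np.ndarray  # (n, channels, frames, freqs)
    y: np.ndarray  # (n,) 1 = seizure
    sources: list[str]
    stft_config: STFTConfig = field(default_factory=STFTConfig)
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("features and labels disagree in length")

    def __len__(self) -> int:
        return self.x.shape[0]

    @property
    def feature_dim(self) -> int:
        return int(np.prod(self.x.shape[1:]))

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = dict(self.manifest)
        manifest.update(
            {
                "n_windows": len(self),
                "n_seizure": int(self.y.sum()),
                "shape": list(self.x.shape),
                "flatten_order": "channel-major, then frame, then frequency (C order)",
                "stft_config": dict(self.stft_config.__dict__),
            }
        )
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        np.savez_compressed(
            d / "features.npz",
            x=self.x.astype(np.float32),
            y=self.y,
            sources=np.array(self.sources, dtype=object),
        )

    @classmethod
    def load(cls, directory) -> "FeatureSet":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        with np.load(d / "features.npz", allow_pickle=True) as data:
            x = data["x"].astype(np.float64)
            y = data["y"]
            sources = [str(s) for s in data["sources"]]
        sc = manifest.get("stft_config", {})
        cfg = STFTConfig(**sc) if sc else STFTConfig()
        return cls(x, y, sources, stft_config=cfg, manifest=manifest)
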