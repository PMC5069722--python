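"""The 25 per-channel time- and frequency-domain EMG features.

Catalog (per channel):

========  =====================================================
family    features
========  =====================================================
TD        MAV, ZC, SSC, WL           (classic Hudgins set)
amplitude WAMP, RMS, VAR, Vord, LogDet
AR        AR1..AR6                   (sixth-order Burg fit)
spectral  MnF, MdF, PF, MP           (Hamming periodogram)
PSD       PSD1..PSD6                 (time-domain power-spectrum
                                      descriptors via Parseval)
========  =====================================================

All kernels are implemented twice over: a batch path operating on a
(windows, samples) matrix per channel (used by :func:`extract_feature_matrix`)
and thin single-window wrappers exposing each feature family on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .dataset import Window

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_FAMILIES",
    "NAMED_FEATURE_SETS",
    "FeatureMatrix",
    "FeatureWarning",
    "named_feature_set",
    "td_features",
    "amplitude_features",
    "ar_features",
    "spectral_features",
    "psd_descriptors",
    "extract_feature_matrix",
]


class FeatureWarning(UserWarning):
    """Signals a defined fallback on a degenerate window (e.g. all-zero)."""


FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "TD": ("MAV", "ZC", "SSC", "WL"),
    "amplitude": ("WAMP", "RMS", "VAR", "Vord", "LogDet"),
    "AR": tuple(f"AR{i}" for i in range(1, 7)),
    "spectral": ("MnF", "MdF", "PF", "MP"),
    "PSD": tuple(f"PSD{i}" for i in range(1, 7)),
}

#: Full 25-feature catalog in canonical order.
FEATURE_NAMES: tuple[str, ...] = sum(FEATURE_FAMILIES.values(), ())

#: Resolvable named feature sets (per-channel feature name lists).
NAMED_FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "TD": FEATURE_FAMILIES["TD"],
    "TDAR": FEATURE_FAMILIES["TD"] + FEATURE_FAMILIES["AR"],
    "ALL": FEATURE_NAMES,
}

_LOGDET_GUARD = 1e-10
_PSD_LOG_GUARD = 1e-12
_PSD_LAMBDA = 0.1
_AR_ORDER = 6


def named_feature_set(name: str) -> tuple[str, ...]:
    """Per-channel feature names of a named set (``TD``, ``TDAR``, ``ALL``)."""
    try:
        return NAMED_FEATURE_SETS[name]
    except KeyError:
        raise ValueError(
            f"unknown feature set {name!r}; choose from {sorted(NAMED_FEATURE_SETS)}"
        ) from None


# ---------------------------------------------------------------------------
# batch kernels: X is (n_windows, n_samples) for one channel
# ---------------------------------------------------------------------------


def _td_batch(X: np.ndarray, eps_zc: float, eps_ssc: float) -> np.ndarray:
    mav = np.mean(np.abs(X), axis=1)
    d = np.diff(X, axis=1)
    wl = np.sum(np.abs(d), axis=1)
    zc = np.sum(
        (X[:, :-1] * X[:, 1:] < 0) & (np.abs(d) >= eps_zc), axis=1
    ).astype(float)
    mid, prev, nxt = X[:, 1:-1], X[:, :-2], X[:, 2:]
    dl, dr = mid - prev, mid - nxt
    ssc = np.sum(
        (dl * dr > 0) & (np.maximum(np.abs(dl), np.abs(dr)) >= eps_ssc), axis=1
    ).astype(float)
    return np.column_stack([mav, zc, ssc, wl])


def _amplitude_batch(X: np.ndarray, eps_wamp: float) -> np.ndarray:
    d = np.abs(np.diff(X, axis=1))
    # strict inequality so a constant signal scores 0 even at zero threshold
    wamp = np.sum(d > eps_wamp, axis=1).astype(float)
    rms = np.sqrt(np.mean(X**2, axis=1))
    var = np.var(X, axis=1, ddof=1)
    vord = np.mean(np.abs(X) ** 3, axis=1) ** (1.0 / 3.0)
    logdet = np.exp(np.mean(np.log(np.abs(X) + _LOGDET_GUARD), axis=1))
    return np.column_stack([wamp, rms, var, vord, logdet])


def _burg_batch(X: np.ndarray, order: int = _AR_ORDER) -> np.ndarray:
    """Burg AR coefficients, vectorised across rows.

    Returns coefficients ``a1..a_p`` in the regression convention
    ``x_t = a1 x_{t-1} + ... + a_p x_{t-p} + e_t`` for the mean-removed
    rows.  Rows with (numerically) zero variance get all-zero coefficients
    and raise a :class:`FeatureWarning`.
    """
    X = np.asarray(X, dtype=float)
    M, n = X.shape
    if n <= order:
        raise ValueError(f"need more than {order} samples, got {n}")
    X = X - X.mean(axis=1, keepdims=True)
    power = np.mean(X**2, axis=1)
    degenerate = power <= 1e-30
    if np.any(degenerate):
        warnings.warn(
            "zero-variance window(s): AR coefficients set to 0", FeatureWarning
        )
    f = X[:, 1:].copy()
    b = X[:, :-1].copy()
    a = np.zeros((M, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        for m in range(order):
            den = np.sum(f * f, axis=1) + np.sum(b * b, axis=1)
            k = 2.0 * np.sum(f * b, axis=1) / den
            k[~np.isfinite(k)] = 0.0
            a = np.column_stack([a - k[:, None] * a[:, ::-1], k])
            f, b = (f - k[:, None] * b)[:, 1:], (b - k[:, None] * f)[:, :-1]
    a[degenerate] = 0.0
    return a


def _next_pow2(n: int) -> int:
    return 1 << max(int(n) - 1, 1).bit_length()


def _spectral_batch(X: np.ndarray, fs: float) -> np.ndarray:
    n = X.shape[1]
    nfft = max(256, _next_pow2(n))
    freqs, P = sps.periodogram(
        X, fs=fs, window="hamming", nfft=nfft, detrend=False, axis=-1
    )
    total = P.sum(axis=1)
    zero = total <= 0
    if np.any(zero):
        warnings.warn(
            "all-zero window(s): spectral features set to 0", FeatureWarning
        )
    safe_total = np.where(zero, 1.0, total)
    mnf = (P @ freqs) / safe_total
    half = np.cumsum(P, axis=1) >= (safe_total / 2.0)[:, None]
    mdf = freqs[np.argmax(half, axis=1)]
    pf = freqs[1:][np.argmax(P[:, 1:], axis=1)]  # DC excluded from the peak
    mp = P.mean(axis=1)
    out = np.column_stack([mnf, mdf, pf, mp])
    out[zero] = 0.0
    return out


def _psd_moment_logs(Y: np.ndarray) -> np.ndarray:
    """Six log-domain spectral-moment descriptors of each row of Y.

    Spectral moments are computed in the time domain via Parseval's theorem
    from the record and its first/second differences, power-compressed by
    ``m -> m**lambda / lambda`` (lambda = 0.1); logs are guarded against
    non-positive arguments.
    """
    n = Y.shape[1]
    d1 = np.diff(Y, axis=1)
    d2 = np.diff(Y, n=2, axis=1)
    m0 = np.sqrt(np.sum(Y**2, axis=1))
    m2 = np.sqrt(np.sum(d1**2, axis=1)) / (n - 1)
    m4 = np.sqrt(np.sum(d2**2, axis=1)) / (n - 1)
    lam = _PSD_LAMBDA
    m0, m2, m4 = (np.power(m, lam) / lam for m in (m0, m2, m4))

    def glog(v: np.ndarray) -> np.ndarray:
        clipped = v <= _PSD_LOG_GUARD
        if np.any(clipped):
            warnings.warn(
                "non-positive log argument in PSD descriptors: guarded",
                FeatureWarning,
            )
        return np.log(np.maximum(v, _PSD_LOG_GUARD))

    g02 = np.maximum(m0 - m2, _PSD_LOG_GUARD)
    g04 = np.maximum(m0 - m4, _PSD_LOG_GUARD)
    wl1 = np.sum(np.abs(d1), axis=1)
    wl2 = np.sum(np.abs(d2), axis=1)
    return np.column_stack(
        [
            glog(m0),
            glog(m0 - m2),
            glog(m0 - m4),
            glog(m0 / np.sqrt(g02 * g04)),  # sparseness
            glog(m2 / np.sqrt(np.maximum(m0 * m4, _PSD_LOG_GUARD))),  # IRF
            glog(wl1 / np.maximum(wl2, _PSD_LOG_GUARD)),  # WL ratio
        ]
    )


def _psd_batch(X: np.ndarray) -> np.ndarray:
    """Orientation descriptors between a record and its squared mapping.

    ``PSDk = -2 a_k b_k / (a_k^2 + b_k^2)`` where ``a`` are the moment logs
    of the record and ``b`` those of the element-wise squared record; the
    cosine-type ratio is bounded in [-1, 1].
    """
    a = _psd_moment_logs(X)
    b = _psd_moment_logs(X**2)
    den = a**2 + b**2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -2.0 * a * b / den
    out[den == 0] = 0.0
    return np.clip(out, -1.0, 1.0)  # guard rounding at the +-1 bound


# ---------------------------------------------------------------------------
# single-window API
# ---------------------------------------------------------------------------


def _as_row(x, min_len: int, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_len:
        raise ValueError(f"{what} needs at least {min_len} samples, got {x.size}")
    return x[None, :]


def td_features(
    x, eps_zc: float = 0.0, eps_ssc: float = 0.0
) -> tuple[float, float, float, float]:
    """Hudgins time-domain features (MAV, ZC, SSC, WL) of one channel window.

    Zero crossings and slope-sign changes count only excursions at least
    ``eps_zc`` / ``eps_ssc`` in amplitude, suppressing noise-level jitter.
    """
    row = _as_row(x, 3, "td_features")
    return tuple(_td_batch(row, eps_zc, eps_ssc)[0])


def amplitude_features(
    x, eps_wamp: float = 0.0
) -> tuple[float, float, float, float, float]:
    """Amplitude statistics: WAMP, RMS, unbiased VAR, v-order (3), log-detector."""
    row = _as_row(x, 2, "amplitude_features")
    return tuple(_amplitude_batch(row, eps_wamp)[0])


def ar_features(x, order: int = _AR_ORDER) -> np.ndarray:
    """Burg autoregressive coefficients a1..a_order of a mean-removed window."""
    row = _as_row(x, order + 1, "ar_features")
    return _burg_batch(row, order)[0]


def spectral_features(x, fs: float) -> tuple[float, float, float, float]:
    """Mean/median/peak frequency and mean power of the Hamming periodogram.

    The FFT length is the next power of two of the window length (minimum
    256); the peak frequency excludes the DC bin.
    """
    row = _as_row(x, 8, "spectral_features")
    return tuple(_spectral_batch(row, fs)[0])


def psd_descriptors(x) -> np.ndarray:
    """Six time-domain power-spectrum descriptors (PSD1..PSD6) in [-1, 1]."""
    row = _as_row(x, 3, "psd_descriptors")
    return _psd_batch(row)[0]


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

LABEL_COLUMNS = (
    "subject",
    "motion_class",
    "wrist_position",
    "repetition",
    "start_offset",
)


@dataclass
class FeatureMatrix:
    """Windows-by-features matrix with per-window labels.

    ``columns`` are (channel_id, feature_name) pairs; ``labels`` is a
    DataFrame aligned row-wise with ``values`` carrying subject, class,
    position, repetition and window offset.  ``thresholds`` records the
    per-channel amplitude threshold used for ZC/SSC/WAMP so any stored
    matrix is self-describing.
    """

    values: np.ndarray
    columns: list[tuple[str, str]]
    labels: pd.DataFrame
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column count mismatch")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("label rows must match value rows")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column ids")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def channel_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ch, _ in self.columns:
            seen.setdefault(ch, None)
        return tuple(seen)

    def column_positions(self, columns: Sequence[tuple[str, str]]) -> list[int]:
        index = {col: i for i, col in enumerate(self.columns)}
        return [index[c] for c in columns]

    def subset_columns(self, columns: Sequence[tuple[str, str]]) -> "FeatureMatrix":
        pos = self.column_positions(columns)
        return FeatureMatrix(
            values=self.values[:, pos],
            columns=[self.columns[i] for i in pos],
            labels=self.labels.copy(),
            thresholds=dict(self.thresholds),
        )

    def subset_feature_names(self, names: Sequence[str]) -> "FeatureMatrix":
        keep = set(names)
        cols = [c for c in self.columns if c[1] in keep]
        return self.subset_columns(cols)

    def subset_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return FeatureMatrix(
            values=self.values[mask],
            columns=list(self.columns),
            labels=self.labels.iloc[mask].reset_index(drop=True)
            if mask.dtype == bool
            else self.labels.iloc[mask].reset_index(drop=True),
            thresholds=dict(self.thresholds),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"{ch}:{feat}" for ch, feat in self.columns]
        )
        return pd.concat([self.labels.reset_index(drop=True), df], axis=1)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ch, eps in self.thresholds.items():
                fh.write(f"# threshold {ch}: {eps:.17g}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        thresholds: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("# threshold "):
                    body = line[len("# threshold ") :]
                    ch, val = body.split(":")
                    thresholds[ch.strip()] = float(val)
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            df = pd.read_csv(fh)
        label_cols = [c for c in LABEL_COLUMNS if c in df.columns]
        feat_cols = [c for c in df.columns if c not in label_cols]
        columns = [tuple(c.split(":", 1)) for c in feat_cols]
        return cls(
            values=df[feat_cols].to_numpy(dtype=float),
            columns=columns,  # type: ignore[arg-type]
            labels=df[label_cols],
            thresholds=thresholds,
        )


def default_thresholds(
    stacked: np.ndarray, channel_ids: Sequence[str], scale: float = 0.01
) -> dict[str, float]:
    """Per-channel eps for ZC/SSC/WAMP: ``scale`` x pooled channel std.

    The pooled standard deviation is taken over every sample of every
    window in the extraction run, making the threshold scale-aware yet
    frozen and reproducible for the run.
    """
    stds = stacked.std(axis=(0, 2))
    return {ch: float(scale * s) for ch, s in zip(channel_ids, stds)}


def extract_feature_matrix(
    windows: Sequence[Window],
    catalog: Sequence[str] | None = None,
    thresholds: dict[str, float] | None = None,
) -> FeatureMatrix:
    """Extract a (windows x (channel, feature)) matrix.

    Columns are ordered channel-major: all catalog features of channel 1,
    then of channel 2, and so on.  Raises if any resulting value is
    non-finite, naming the offending window and column.
    """
    if not windows:
        raise ValueError("no windows to extract")
    catalog = tuple(catalog) if catalog is not None else FEATURE_NAMES
    unknown = set(catalog) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature name(s): {sorted(unknown)}")
    layout = windows[0].layout
    L = windows[0].n_samples
    for w in windows:
        if w.layout != layout or w.n_samples != L:
            raise ValueError("all windows must share one layout and length")
    stacked = np.stack([w.data for w in windows])  # (n, C, L)
    if thresholds is None:
        thresholds = default_thresholds(stacked, layout.channel_ids)

    want = set(catalog)
    per_channel: list[np.ndarray] = []
    names_per_channel: list[str] = []
    for c, ch in enumerate(layout.channel_ids):
        X = stacked[:, c, :]
        eps = thresholds.get(ch, 0.0)
        blocks: dict[str, np.ndarray] = {}
        if want & set(FEATURE_FAMILIES["TD"]):
            td = _td_batch(X, eps, eps)
            blocks.update(zip(FEATURE_FAMILIES["TD"], td.T))
        if want & set(FEATURE_FAMILIES["amplitude"]):
            amp = _amplitude_batch(X, eps)
            blocks.update(zip(FEATURE_FAMILIES["amplitude"], amp.T))
        if want & set(FEATURE_FAMILIES["AR"]):
            ar = _burg_batch(X, _AR_ORDER)
            blocks.update(zip(FEATURE_FAMILIES["AR"], ar.T))
        if want & set(FEATURE_FAMILIES["spectral"]):
            spec = _spectral_batch(X, layout.sampling_rate)
            blocks.update(zip(FEATURE_FAMILIES["spectral"], spec.T))
        if want & set(FEATURE_FAMILIES["PSD"]):
            psd = _psd_batch(X)
            blocks.update(zip(FEATURE_FAMILIES["PSD"], psd.T))
        per_channel.append(np.column_stack([blocks[f] for f in catalog]))
        names_per_channel = list(catalog)

    values = np.concatenate(per_channel, axis=1)
    columns = [
        (ch, feat)
        for ch in layout.channel_ids
        for feat in names_per_channel
    ]
    bad = ~np.isfinite(values)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        w = windows[i]
        raise ValueError(
            f"non-finite value for column {columns[j]} in window of trial "
            f"({w.subject_id}, {w.motion_class}, {w.wrist_position}, "
            f"rep {w.repetition}) at offset {w.start_offset}"
        )
    labels = pd.DataFrame(
        {
            "subject": [w.subject_id for w in windows],
            "motion_class": [w.motion_class for w in windows],
            "wrist_position": [w.wrist_position for w in windows],
            "repetition": [w.repetition for w in windows],
            "start_offset": [w.start_offset for w in windows],
        }
    )
    return FeatureMatrix(
        values=values,
        columns=columns,
        labels=labels,
        thresholds=dict(thresholds),
    )
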