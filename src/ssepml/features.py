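"""Waveform feature extraction: the five metric categories and their bookkeeping.

Each recording channel contributes exactly 11 features per trial:

===================  =========================================================
category             features
===================  =========================================================
phase space curve    ``psc_area`` — area of the delay-embedded trajectory
evoked latency       ``lat_peak``, ``lat_valley`` (ms)
evoked amplitude     ``amp_peak``, ``amp_valley`` (uV)
time-frequency       ``tfa_peak_freq`` (Hz), ``tfa_peak_power``,
                     ``tfa_peak_time`` (ms)
PCA                  ``pc1``, ``pc2``, ``pc3`` — scores on the first three
                     principal components of the channel's trial matrix
===================  =========================================================

Three channels per nerve give 33 features per nerve; four monitored nerves
give 132 per patient. Qualified column names are ``<nerve>.<montage>.<feature>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.decomposition import PCA

from .session import (
    NERVE_MONTAGES,
    PatientSession,
    SSEPTrial,
    SyncedTrial,
    channel_class,
    synchronize,
)

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = (
    "psc_area",
    "lat_peak",
    "lat_valley",
    "amp_peak",
    "amp_valley",
    "tfa_peak_freq",
    "tfa_peak_power",
    "tfa_peak_time",
    "pc1",
    "pc2",
    "pc3",
)

#: Non-feature columns of an assembled feature table.
META_COLUMNS: tuple[str, ...] = ("patient_id", "nerve", "timestamp_s")
TARGET_COLUMN = "et_sevo_pct"


@dataclass(frozen=True)
class ComponentWindow:
    start_ms: float
    end_ms: float
    polarity: int

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError("window start must precede end")


@dataclass(frozen=True)
class EvokedWindows:
    """Search windows (ms post-stimulus) for each named evoked component.

    Nominal component latencies are fixed by the field's nomenclature; the
    window half-widths of roughly 5-10 ms around them are a configurable
    analysis choice.
    """

    windows: dict[str, ComponentWindow] = field(
        default_factory=lambda: {
            "N20": ComponentWindow(15.0, 25.0, -1),
            "P30": ComponentWindow(25.0, 40.0, +1),
            "N13": ComponentWindow(10.0, 16.0, -1),
            "P14": ComponentWindow(11.0, 18.0, +1),
            "P37": ComponentWindow(30.0, 45.0, +1),
            "N45": ComponentWindow(40.0, 55.0, -1),
        }
    )

    def for_channel(self, nerve: str, montage: str) -> tuple[ComponentWindow, ComponentWindow]:
        """(positive-component window, negative-component window) for a channel."""
        cls = channel_class(nerve, montage)
        pos_name, neg_name = {
            "cortical_ulnar": ("P30", "N20"),
            "subcortical_ulnar": ("P14", "N13"),
            "tibial": ("P37", "N45"),
        }[cls]
        return self.windows[pos_name], self.windows[neg_name]


def detect_evoked_response(
    trial: SSEPTrial, windows: EvokedWindows | None = None
) -> tuple[float, float, float, float]:
    """Detect the channel's positive and negative evoked components.

    Returns ``(lat_peak, amp_peak, lat_valley, amp_valley)``: the latency (ms)
    and waveform value (uV) of the maximum within the positive component's
    search window and of the minimum within the negative component's window.
    Ties break toward the earlier sample.
    """
    windows = windows or EvokedWindows()
    pos_w, neg_w = windows.for_channel(trial.nerve, trial.montage)
    t = trial.times_ms
    for w in (pos_w, neg_w):
        if w.start_ms < t[0] or w.end_ms > t[-1]:
            raise ValueError(
                f"search window [{w.start_ms}, {w.end_ms}] ms outside the sampled "
                f"range [0, {t[-1]:.1f}] ms"
            )
    pos_mask = (t >= pos_w.start_ms) & (t <= pos_w.end_ms)
    neg_mask = (t >= neg_w.start_ms) & (t <= neg_w.end_ms)
    x = trial.samples
    i_peak = np.flatnonzero(pos_mask)[np.argmax(x[pos_mask])]
    i_valley = np.flatnonzero(neg_mask)[np.argmin(x[neg_mask])]
    return float(t[i_peak]), float(x[i_peak]), float(t[i_valley]), float(x[i_valley])


def psc_area(trial: SSEPTrial, delay_ms: float = 2.0, dim: int = 3) -> float:
    """Area of the phase-space curve of one trial (uV^2).

    The waveform is delay-embedded into ``dim`` dimensions with lag
    ``delay_ms`` — points ``(x(t), x(t+tau), ..., x(t+(dim-1)tau))`` — and the
    trajectory is projected onto its first two embedding coordinates. The
    returned value is the absolute shoelace (signed polygon) area of the
    closed projected curve; a trajectory that winds the same loop k times
    reports k times the loop area.
    """
    if delay_ms <= 0:
        raise ValueError("delay_ms must be positive")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    lag = int(round(delay_ms * trial.sample_rate / 1000.0))
    if lag < 1 or (dim - 1) * lag >= trial.samples.size:
        raise ValueError(
            f"delay {delay_ms} ms with dim {dim} exceeds the trial duration"
        )
    n_pts = trial.samples.size - (dim - 1) * lag
    u = trial.samples[:n_pts]
    v = trial.samples[lag : lag + n_pts]
    # shoelace sum over the closed polygon (last vertex joined to the first)
    cross = u * np.roll(v, -1) - np.roll(u, -1) * v
    return float(abs(0.5 * np.sum(cross)))


def tfa_features(
    trial: SSEPTrial,
    band_hz: tuple[float, float] = (10.0, 500.0),
    window_ms: float = 20.0,
    overlap: float = 0.5,
) -> tuple[float, float, float]:
    """Spectrogram peak of one trial: ``(peak_freq_hz, peak_power, peak_time_ms)``.

    A Hann-windowed magnitude-squared short-time spectrogram is computed and
    the global maximum inside ``band_hz`` located. An all-zero waveform is a
    documented degenerate case returning ``(band minimum, 0, 0)``.
    """
    lo, hi = band_hz
    if not 0 < lo < hi < trial.sample_rate / 2:
        raise ValueError("band must lie inside (0, sample_rate/2)")
    if not np.any(trial.samples):
        logger.warning("tfa_features: all-zero waveform for %s", trial.trial_id)
        return float(lo), 0.0, 0.0
    nperseg = max(8, int(round(window_ms * trial.sample_rate / 1000.0)))
    nperseg = min(nperseg, trial.samples.size)
    noverlap = int(nperseg * overlap)
    freqs, times, spec = sps.spectrogram(
        trial.samples,
        fs=trial.sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        mode="psd",
    )
    in_band = (freqs >= lo) & (freqs <= hi)
    sub = spec[in_band]
    fi, ti = np.unravel_index(np.argmax(sub), sub.shape)
    return (
        float(freqs[in_band][fi]),
        float(sub[fi, ti]),
        float(times[ti] * 1000.0),
    )


def pca_scores(
    trial_matrix: np.ndarray, n_components: int = 3
) -> tuple[np.ndarray, float]:
    """Scores of one channel's trials on the channel's principal components.

    ``trial_matrix`` is trials x samples for one channel of one patient. The
    matrix is mean-centered across trials and projected onto its top
    ``n_components`` components. Component signs are fixed so each
    component's largest-magnitude loading is positive. Returns
    ``(scores, cumulative_variance_fraction)``; a zero-variance matrix is a
    degenerate case returning all-zero scores and variance fraction ``nan``.
    """
    X = np.asarray(trial_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("trial_matrix must be 2-D (trials x samples)")
    if X.shape[0] <= n_components:
        raise ValueError(
            f"need more than {n_components} trials for {n_components} components, "
            f"got {X.shape[0]}"
        )
    if np.allclose(X, X[0]):
        logger.warning("pca_scores: zero-variance trial matrix (all trials identical)")
        return np.zeros((X.shape[0], n_components)), float("nan")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores, float(np.sum(pca.explained_variance_ratio_))


# ---------------------------------------------------------------------------
# Feature-table assembly
# ---------------------------------------------------------------------------

def channel_columns(nerve: str, montage: str) -> list[str]:
    """The 11 qualified feature names of one channel."""
    channel_class(nerve, montage)
    return [f"{nerve}.{montage}.{f}" for f in FEATURE_NAMES]


def nerve_columns(nerve: str) -> list[str]:
    """The 33 qualified feature names of one nerve (three channels)."""
    return [c for m in NERVE_MONTAGES[nerve] for c in channel_columns(nerve, m)]


def all_feature_columns() -> list[str]:
    """The 132 qualified feature names of a full patient."""
    return [c for n in NERVE_MONTAGES for c in nerve_columns(n)]


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters of the extraction stage."""

    windows: EvokedWindows = field(default_factory=EvokedWindows)
    psc_delay_ms: float = 2.0
    psc_dim: int = 3
    tfa_band_hz: tuple[float, float] = (10.0, 500.0)
    tfa_window_ms: float = 20.0
    tfa_overlap: float = 0.5
    sync_tolerance_s: float = 60.0


def assemble_feature_table(
    sessions: PatientSession | list[PatientSession],
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Synchronized trials x qualified features, target column last.

    One row per synchronized stimulation event of one nerve (the nerve's
    three montages share the stimulation timestamp, so each row carries that
    nerve's 33 features; the other nerves' columns are left missing). The
    full column universe is the 132 qualified names plus metadata
    (``patient_id``, ``nerve``, ``timestamp_s``) and the regression target
    ``et_sevo_pct``.

    PCA scores are computed per patient x channel across that patient's
    synchronized trials, so no patient's features depend on any other
    patient's data.
    """
    cfg = config or FeatureConfig()
    if isinstance(sessions, PatientSession):
        sessions = [sessions]
    rows: list[dict] = []
    for session in sessions:
        synced = synchronize(session, tolerance=cfg.sync_tolerance_s)
        by_channel: dict[tuple[str, str], list[SyncedTrial]] = {}
        for st in synced:
            by_channel.setdefault((st.trial.nerve, st.trial.montage), []).append(st)
        # events: rows keyed by (nerve, timestamp); montages of a nerve share one row
        events: dict[tuple[str, float], dict] = {}
        for (nerve, montage), stlist in sorted(by_channel.items()):
            if len(stlist) <= 3:
                raise ValueError(
                    f"{session.patient_id} {nerve}/{montage}: need > 3 synchronized "
                    "trials per channel for PCA"
                )
            matrix = np.vstack([st.trial.samples for st in stlist])
            scores, _ = pca_scores(matrix, n_components=3)
            for i, st in enumerate(stlist):
                key = (nerve, st.trial.timestamp)
                row = events.setdefault(
                    key,
                    {
                        "patient_id": session.patient_id,
                        "nerve": nerve,
                        "timestamp_s": st.trial.timestamp,
                        TARGET_COLUMN: st.concentration,
                    },
                )
                lat_p, amp_p, lat_v, amp_v = detect_evoked_response(st.trial, cfg.windows)
                f_freq, f_pow, f_time = tfa_features(
                    st.trial, cfg.tfa_band_hz, cfg.tfa_window_ms, cfg.tfa_overlap
                )
                values = {
                    "psc_area": psc_area(st.trial, cfg.psc_delay_ms, cfg.psc_dim),
                    "lat_peak": lat_p,
                    "lat_valley": lat_v,
                    "amp_peak": amp_p,
                    "amp_valley": amp_v,
                    "tfa_peak_freq": f_freq,
                    "tfa_peak_power": f_pow,
                    "tfa_peak_time": f_time,
                    "pc1": scores[i, 0],
                    "pc2": scores[i, 1],
                    "pc3": scores[i, 2],
                }
                for name, val in values.items():
                    row[f"{nerve}.{montage}.{name}"] = val
        for nerve in NERVE_MONTAGES:
            present = {m for (n, m) in by_channel if n == nerve}
            missing = set(NERVE_MONTAGES[nerve]) - present
            if missing:
                raise ValueError(
                    f"{session.patient_id}: nerve {nerve!r} missing channel(s) "
                    f"{sorted(missing)} in the synchronized data"
                )
        rows.extend(events[k] for k in sorted(events))
    columns = list(META_COLUMNS) + all_feature_columns() + [TARGET_COLUMN]
    table = pd.DataFrame(rows).reindex(columns=columns)
    return table.sort_values(["patient_id", "nerve", "timestamp_s"]).reset_index(drop=True)
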