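"""Session data model, JSON/CSV persistence, and anesthesia-to-trial synchronization.

A *session* is one patient's intraoperative recording: a collection of
stimulation-locked SSEP trial waveforms (one per nerve x montage x stimulation
event) together with the per-minute end-tidal sevoflurane concentration series
charted by the anesthesia information system.

Conventions
-----------
* Session time is measured in seconds since session start (0-based).
* Waveform time is milliseconds post-stimulus (0-based).
* Waveform samples are microvolts.
* Concentrations are end-tidal sevoflurane volume percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

#: Recording montages (active-reference electrode pairs) per monitored nerve.
#: Three channels per nerve; CS5-Fpz is the subcortical ulnar channel.
NERVE_MONTAGES: dict[str, tuple[str, str, str]] = {
    "left_ulnar": ("CP4-Fpz", "CP4-CP3", "CS5-Fpz"),
    "right_ulnar": ("CP3-Fpz", "CP3-CP4", "CS5-Fpz"),
    "left_post_tibial": ("CPz-Fpz", "CP3-CP4", "CP3-Fpz"),
    "right_post_tibial": ("CPz-Fpz", "CP4-CP3", "CP4-Fpz"),
}

NERVES: tuple[str, ...] = tuple(NERVE_MONTAGES)

ULNAR_NERVES = ("left_ulnar", "right_ulnar")
TIBIAL_NERVES = ("left_post_tibial", "right_post_tibial")


class SchemaError(ValueError):
    """A session file or in-memory session violates the data model."""


def channel_class(nerve: str, montage: str) -> str:
    """Classify a channel as ``cortical_ulnar``, ``subcortical_ulnar`` or ``tibial``.

    The class determines which evoked components the channel carries:
    cortical ulnar channels carry N20/P30, the subcortical (CS5-Fpz) ulnar
    channel carries N13/P14, and every tibial channel carries P37/N45.
    """
    if nerve not in NERVE_MONTAGES:
        raise SchemaError(f"unknown nerve {nerve!r}")
    if montage not in NERVE_MONTAGES[nerve]:
        raise SchemaError(
            f"montage {montage!r} is not a recording channel of {nerve!r}; "
            f"expected one of {NERVE_MONTAGES[nerve]}"
        )
    if nerve in ULNAR_NERVES:
        return "subcortical_ulnar" if montage == "CS5-Fpz" else "cortical_ulnar"
    return "tibial"


@dataclass
class SSEPTrial:
    """One stimulation-locked SSEP waveform from a single recording channel."""

    trial_id: str
    nerve: str
    montage: str
    timestamp: float  # seconds since session start
    samples: np.ndarray  # microvolts, uniform sampling
    sample_rate: float  # Hz

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        channel_class(self.nerve, self.montage)  # validates the pairing
        if self.sample_rate <= 0:
            raise SchemaError(f"trial {self.trial_id}: sample_rate must be positive")
        if self.timestamp < 0:
            raise SchemaError(f"trial {self.trial_id}: negative timestamp")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise SchemaError(f"trial {self.trial_id}: samples must be a 1-D array")

    @property
    def window_ms(self) -> float:
        """Length of the post-stimulus analysis window in milliseconds."""
        return 1000.0 * self.samples.size / self.sample_rate

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in milliseconds post-stimulus."""
        return np.arange(self.samples.size) * 1000.0 / self.sample_rate


@dataclass
class AnesthesiaSeries:
    """Per-minute end-tidal sevoflurane concentration series."""

    timestamps: np.ndarray  # seconds since session start, strictly increasing
    et_sevo: np.ndarray  # percent, >= 0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.et_sevo = np.asarray(self.et_sevo, dtype=float)
        if self.timestamps.shape != self.et_sevo.shape or self.timestamps.ndim != 1:
            raise SchemaError("anesthesia: timestamps and et_sevo must be 1-D and equal length")
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            raise SchemaError("anesthesia: timestamps must be strictly increasing")
        if np.any(self.et_sevo < 0):
            raise SchemaError("anesthesia: negative concentration")

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass
class PatientSession:
    """All trials and the anesthesia series of one patient."""

    patient_id: str
    age: float
    sex: str
    trials: list[SSEPTrial]
    anesthesia: AnesthesiaSeries

    def validate(self) -> None:
        """Enforce the four-nerves / three-montages-per-nerve invariant."""
        present: dict[str, set[str]] = {}
        for t in self.trials:
            present.setdefault(t.nerve, set()).add(t.montage)
        for nerve, montages in NERVE_MONTAGES.items():
            if nerve not in present:
                raise SchemaError(f"session {self.patient_id}: nerve {nerve!r} has no trials")
            missing = set(montages) - present[nerve]
            if missing:
                raise SchemaError(
                    f"session {self.patient_id}: nerve {nerve!r} missing channel(s) "
                    f"{sorted(missing)}"
                )

    def channel_trials(self, nerve: str, montage: str) -> list[SSEPTrial]:
        """Trials of one channel, sorted by timestamp."""
        sel = [t for t in self.trials if t.nerve == nerve and t.montage == montage]
        return sorted(sel, key=lambda t: t.timestamp)


@dataclass(frozen=True)
class SyncedTrial:
    """A trial matched to the nearest-in-time end-tidal sevoflurane reading."""

    trial: SSEPTrial
    concentration: float


@dataclass
class SyncReport:
    """Bookkeeping from :func:`synchronize`."""

    n_input: int = 0
    n_matched: int = 0
    n_excluded: int = 0
    excluded_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# JSON session dialect
# ---------------------------------------------------------------------------

def session_to_dict(session: PatientSession) -> dict:
    channels: dict[tuple[str, str], list[SSEPTrial]] = {}
    for t in session.trials:
        channels.setdefault((t.nerve, t.montage), []).append(t)
    return {
        "schema_version": SCHEMA_VERSION,
        "patient": {
            "patient_id": session.patient_id,
            "age": session.age,
            "sex": session.sex,
        },
        "anesthesia": {
            "timestamps_s": session.anesthesia.timestamps.tolist(),
            "et_sevo_pct": session.anesthesia.et_sevo.tolist(),
        },
        "channels": [
            {
                "nerve": nerve,
                "montage": montage,
                "sample_rate_hz": trials[0].sample_rate,
                "trials": [
                    {
                        "trial_id": t.trial_id,
                        "timestamp_s": t.timestamp,
                        "samples_uv": t.samples.tolist(),
                    }
                    for t in sorted(trials, key=lambda t: t.timestamp)
                ],
            }
            for (nerve, montage), trials in sorted(channels.items())
        ],
    }


def session_from_dict(data: dict) -> PatientSession:
    try:
        version = data["schema_version"]
    except (TypeError, KeyError):
        raise SchemaError("missing field: schema_version") from None
    if version != SCHEMA_VERSION:
        raise SchemaError(f"schema_version: expected {SCHEMA_VERSION}, got {version!r}")
    try:
        patient = data["patient"]
        anes = data["anesthesia"]
        channels = data["channels"]
    except KeyError as exc:
        raise SchemaError(f"missing field: {exc.args[0]}") from None
    try:
        anesthesia = AnesthesiaSeries(
            timestamps=np.asarray(anes["timestamps_s"], dtype=float),
            et_sevo=np.asarray(anes["et_sevo_pct"], dtype=float),
        )
    except KeyError as exc:
        raise SchemaError(f"anesthesia: missing field {exc.args[0]}") from None
    trials: list[SSEPTrial] = []
    for ci, ch in enumerate(channels):
        try:
            nerve, montage, rate = ch["nerve"], ch["montage"], ch["sample_rate_hz"]
            raw_trials = ch["trials"]
        except KeyError as exc:
            raise SchemaError(f"channels[{ci}]: missing field {exc.args[0]}") from None
        for ti, tr in enumerate(raw_trials):
            try:
                samples = np.asarray(tr["samples_uv"], dtype=float)
            except (KeyError, ValueError) as exc:
                raise SchemaError(f"channels[{ci}].trials[{ti}]: malformed samples ({exc})") from None
            try:
                trials.append(
                    SSEPTrial(
                        trial_id=tr["trial_id"],
                        nerve=nerve,
                        montage=montage,
                        timestamp=float(tr["timestamp_s"]),
                        samples=samples,
                        sample_rate=float(rate),
                    )
                )
            except KeyError as exc:
                raise SchemaError(f"channels[{ci}].trials[{ti}]: missing field {exc.args[0]}") from None
    try:
        session = PatientSession(
            patient_id=patient["patient_id"],
            age=float(patient["age"]),
            sex=patient["sex"],
            trials=trials,
            anesthesia=anesthesia,
        )
    except KeyError as exc:
        raise SchemaError(f"patient: missing field {exc.args[0]}") from None
    session.validate()
    return session


def write_session(session: PatientSession, path: str | Path) -> None:
    """Serialize a session to the JSON session dialect."""
    session.validate()
    Path(path).write_text(json.dumps(session_to_dict(session)))


def read_session(path: str | Path) -> PatientSession:
    """Load and validate a session from the JSON session dialect."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from None
    return session_from_dict(data)


def write_anesthesia_csv(series: AnesthesiaSeries, path: str | Path) -> None:
    """Write the concentration series as a two-column CSV (timestamp_s, et_sevo_pct)."""
    pd.DataFrame(
        {"timestamp_s": series.timestamps, "et_sevo_pct": series.et_sevo}
    ).to_csv(path, index=False)


def read_anesthesia_csv(path: str | Path) -> AnesthesiaSeries:
    df = pd.read_csv(path)
    for col in ("timestamp_s", "et_sevo_pct"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return AnesthesiaSeries(
        timestamps=df["timestamp_s"].to_numpy(float),
        et_sevo=df["et_sevo_pct"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# Timepoint synchronization
# ---------------------------------------------------------------------------

def synchronize(
    session: PatientSession,
    tolerance: float = 60.0,
    report: SyncReport | None = None,
) -> list[SyncedTrial]:
    """Match each trial to the nearest-in-time concentration reading.

    Trials farther than ``tolerance`` seconds from every reading are excluded
    (and counted in ``report``). Ties between two equidistant readings go to
    the earlier reading. The output is sorted by trial timestamp; every
    returned concentration is a value that appears verbatim in the series.
    """
    if len(session.anesthesia) == 0:
        raise ValueError("synchronize: anesthesia series is empty")
    ts = session.anesthesia.timestamps
    cs = session.anesthesia.et_sevo
    out: list[SyncedTrial] = []
    rep = report if report is not None else SyncReport()
    for trial in sorted(session.trials, key=lambda t: t.timestamp):
        rep.n_input += 1
        # nearest reading; on an exact midpoint prefer the earlier reading
        idx = int(np.searchsorted(ts, trial.timestamp))
        candidates = [i for i in (idx - 1, idx) if 0 <= i < ts.size]
        best = min(candidates, key=lambda i: (abs(ts[i] - trial.timestamp), ts[i]))
        if abs(ts[best] - trial.timestamp) <= tolerance:
            out.append(SyncedTrial(trial=trial, concentration=float(cs[best])))
            rep.n_matched += 1
        else:
            rep.n_excluded += 1
            rep.excluded_ids.append(trial.trial_id)
    return out
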