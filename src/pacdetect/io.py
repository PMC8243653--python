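"""Reading ECG records and R-peak beat annotations.

Two storage layouts are supported:

* a plain-text layout that needs no binary codec:
  ``<stem>_signal.csv`` (one column per lead, millivolts),
  ``<stem>_meta.json`` (``fs`` in Hz and ``patient_id``) and
  ``<stem>_ann.csv`` (columns ``sample,symbol``);
* WFDB header/signal/annotation triplets (``.hea``/``.dat``/``.atr``),
  available only when the optional :mod:`wfdb` package is installed.

Beat symbols follow the PhysioNet convention and are simplified to the
three classifier classes N / S / V (junctional and unclassifiable beats
are excluded).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LABEL_N",
    "LABEL_S",
    "LABEL_V",
    "LABEL_EXCLUDED",
    "SYMBOL_TO_LABEL",
    "BEAT_SYMBOLS",
    "ECGRecord",
    "BeatAnnotation",
    "simplify_label",
    "read_record",
    "read_annotations",
]

LABEL_N = "N"
LABEL_S = "S"
LABEL_V = "V"
LABEL_EXCLUDED = "EXCLUDED"

#: Simplified class for each of the twelve beat symbols handled natively.
SYMBOL_TO_LABEL = {
    "N": LABEL_N,
    "B": LABEL_N,
    "e": LABEL_N,
    "A": LABEL_S,
    "a": LABEL_S,
    "S": LABEL_S,
    "V": LABEL_V,
    "F": LABEL_V,
    "E": LABEL_V,
    "J": LABEL_EXCLUDED,
    "j": LABEL_EXCLUDED,
    "Q": LABEL_EXCLUDED,
}

#: WFDB annotation codes that mark a heartbeat.  Everything else on an
#: annotation stream (rhythm changes '+', noise '~', signal quality ...)
#: is not a beat and is silently dropped by :func:`read_annotations`.
BEAT_SYMBOLS = set("NLRBAaJSVrFejnE/fQ?")


@dataclass(frozen=True)
class ECGRecord:
    """A multi-lead sampled ECG.

    Parameters
    ----------
    patient_id:
        Opaque identifier, carried through the pipeline.
    fs:
        Sampling rate in Hz (positive).
    signal:
        2-D float array of shape ``(n_samples, n_leads)`` in millivolts.
    """

    patient_id: str
    fs: float
    signal: np.ndarray

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2 or sig.shape[1] < 1 or sig.shape[0] < 1:
            raise ValueError(
                "signal must be a (n_samples, n_leads) array with at least "
                f"one lead and one sample, got shape {sig.shape}"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "signal", sig)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    def lead(self, index: int) -> np.ndarray:
        return self.signal[:, index]


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated R peak: 0-based sample index, raw symbol, class label."""

    sample: int
    symbol_raw: str
    label: str


def simplify_label(symbol_raw: str) -> str:
    """Map a PhysioNet beat symbol to one of N / S / V / EXCLUDED.

    The mapping is total: known beat symbols outside the twelve handled
    classes map to ``EXCLUDED`` with a warning so foreign databases
    degrade gracefully.
    """
    try:
        return SYMBOL_TO_LABEL[symbol_raw]
    except KeyError:
        warnings.warn(
            f"unknown beat symbol {symbol_raw!r}: excluded from classification",
            stacklevel=2,
        )
        return LABEL_EXCLUDED


def _csv_stem(path: Path) -> Path:
    name = path.name
    for suffix in ("_signal.csv", "_meta.json", "_ann.csv", ".hea", ".dat"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)])
    return path


def read_record(path) -> ECGRecord:
    """Read an ECG record from either the CSV layout or a WFDB pair.

    ``path`` may be the record stem, the ``.hea`` file or the
    ``_signal.csv`` file.  Signals are returned in physical units with
    the stored lead order.
    """
    stem = _csv_stem(Path(path))
    sig_csv = stem.with_name(stem.name + "_signal.csv")
    if sig_csv.exists():
        return _read_csv_record(stem)
    hea = stem.with_suffix(".hea")
    if hea.exists():
        return _read_wfdb_record(stem)
    raise FileNotFoundError(
        f"no record found at {path!s}: expected {sig_csv.name} or {hea.name}"
    )


def _read_csv_record(stem: Path) -> ECGRecord:
    sig_csv = stem.with_name(stem.name + "_signal.csv")
    meta_json = stem.with_name(stem.name + "_meta.json")
    try:
        signal = np.loadtxt(sig_csv, delimiter=",", ndmin=2)
    except Exception as exc:  # noqa: BLE001 - re-raise with file name
        raise IOError(f"cannot read signal file {sig_csv}: {exc}") from exc
    try:
        meta = json.loads(meta_json.read_text())
    except FileNotFoundError as exc:
        raise IOError(f"missing sidecar {meta_json}") from exc
    return ECGRecord(
        patient_id=str(meta.get("patient_id", stem.name)),
        fs=float(meta["fs"]),
        signal=signal,
    )


def _read_wfdb_record(stem: Path) -> ECGRecord:
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install wfdb); alternatively provide the CSV layout"
        ) from exc
    try:
        rec = wfdb.rdrecord(str(stem))
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read WFDB record {stem}: {exc}") from exc
    signal = np.asarray(rec.p_signal, dtype=float)
    if signal.ndim != 2 or signal.shape[1] < 1:
        raise ValueError(f"WFDB record {stem} contains no leads")
    return ECGRecord(patient_id=str(rec.record_name), fs=float(rec.fs), signal=signal)


def read_annotations(path, record: ECGRecord) -> List[BeatAnnotation]:
    """Read beat annotations referring to ``record``.

    Non-beat annotation symbols are dropped; samples outside the record
    are dropped with a warning; output is sorted by sample index and
    labels are filled via :func:`simplify_label`.
    """
    p = Path(path)
    if p.suffix == ".csv" or p.with_name(p.name + "_ann.csv").exists():
        csv_path = p if p.suffix == ".csv" else p.with_name(p.name + "_ann.csv")
        entries = _read_csv_annotations(csv_path)
    else:
        entries = _read_wfdb_annotations(p)
    return _build_annotations(entries, record)


def _read_csv_annotations(path: Path):
    try:
        df = pd.read_csv(path, dtype={"symbol": str})
    except pd.errors.EmptyDataError:
        return []
    except FileNotFoundError as exc:
        raise IOError(f"missing annotation file {path}") from exc
    return list(zip(df["sample"].astype(int), df["symbol"].astype(str)))


def _read_wfdb_annotations(path: Path):
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB annotations requires the optional 'wfdb' package"
        ) from exc
    ext = path.suffix.lstrip(".") or "atr"
    stem = path.with_suffix("")
    ann = wfdb.rdann(str(stem), ext)
    return list(zip(np.asarray(ann.sample, dtype=int), ann.symbol))


def _build_annotations(entries: Sequence, record: ECGRecord) -> List[BeatAnnotation]:
    beats = []
    n_dropped = 0
    for sample, symbol in entries:
        if symbol not in BEAT_SYMBOLS:
            continue  # rhythm/noise/quality markers are not beats
        if not 0 <= sample < record.n_samples:
            n_dropped += 1
            continue
        beats.append(BeatAnnotation(int(sample), symbol, simplify_label(symbol)))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} annotation(s) outside record "
            f"{record.patient_id} ({record.n_samples} samples)",
            stacklevel=2,
        )
    beats.sort(key=lambda b: b.sample)
    return beats
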