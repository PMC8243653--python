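"""Per-beat feature matrix assembly and conditioning.

Assembly trims the first and last 40 beats of each record, then emits
one row per remaining N/S/V beat: 42 HRV features plus 72 raw-signal and
72 wavelet-scale-4 morphology features (186 columns).

Conditioning order is part of the contract: physiological clipping of
RR/dRR-bearing features -> missing-value imputation with training-fold
column means -> variance pruning (< 0.05, computed before z-scoring) ->
Pearson-correlation pruning (|r| > 0.95, later column in canonical order
dropped) -> z-score with training-fold parameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from . import dwt, hrv, morphology
from .io import LABEL_EXCLUDED, BeatAnnotation, ECGRecord

__all__ = [
    "RR_MIN_MS",
    "RR_MAX_MS",
    "ClipBounds",
    "META_COLUMNS",
    "TRIM_BEATS",
    "feature_names",
    "assemble_matrix",
    "clip_features",
    "prune_features",
    "zscore_fit",
    "zscore_apply",
    "FeatureTransform",
    "save_features",
    "load_features",
]

RR_MIN_MS = 250.0
#: Twice the RR interval of a 35 bpm extreme bradycardia (maximum
#: post-ectopic pause), rounded to one decimal: 2 * (60/35) * 1000 ms.
RR_MAX_MS = round(2.0 * 60_000.0 / 35.0, 1)

META_COLUMNS = ("patient_id", "beat_sample", "label")
TRIM_BEATS = morphology.TRIM_BEATS


@dataclass(frozen=True)
class ClipBounds:
    """Physiological bounds for RR/dRR-bearing features (milliseconds).

    dRR bounds are derived symmetrically from the RR bounds:
    ``[-(rr_max - rr_min), +(rr_max - rr_min)]``.
    """

    rr_min: float = RR_MIN_MS
    rr_max: float = RR_MAX_MS

    def __post_init__(self) -> None:
        if not self.rr_min < self.rr_max:
            raise ValueError("rr_min must be < rr_max")

    @property
    def drr_min(self) -> float:
        return -(self.rr_max - self.rr_min)

    @property
    def drr_max(self) -> float:
        return self.rr_max - self.rr_min


#: Columns clipped to RR bounds: beat-local RRs and window means.
RR_CLIP_FEATURES = ("hrv_rr_i", "hrv_rr_im1", "hrv_rr_ip1") + tuple(
    f"hrv_win{spec.tag}_meanrr" for spec in hrv.WINDOW_SPECS
)
#: Columns clipped to dRR bounds: the beat-local dRRs.
DRR_CLIP_FEATURES = ("hrv_drr_i", "hrv_drr_im1", "hrv_drr_ip1")


def feature_names() -> List[str]:
    """Canonical column order: HRV block, raw morphology, W4 morphology."""
    return (
        list(hrv.HRV_FEATURE_NAMES)
        + morphology.morph_feature_names("raw")
        + morphology.morph_feature_names("w4")
    )


def assemble_matrix(
    record: ECGRecord,
    annotations: Sequence[BeatAnnotation],
    hrv_drop: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-beat feature matrix for one preprocessed record.

    Emits rows for beat indices in ``[40, n_beats - 41]`` whose label is
    one of N/S/V; EXCLUDED beats contribute context (RR timing, template
    neighbors) but get no row.  Records of 80 or fewer beats yield an
    empty frame with a warning.
    """
    cols = list(META_COLUMNS) + [n for n in feature_names() if n not in set(hrv_drop)]
    n_beats = len(annotations)
    if n_beats <= 2 * TRIM_BEATS:
        warnings.warn(
            f"record {record.patient_id}: {n_beats} beats <= {2 * TRIM_BEATS}; "
            "trim consumes all beats",
            stacklevel=2,
        )
        return pd.DataFrame(columns=cols)
    if record.n_leads < 2:
        raise ValueError("feature extraction requires a 2-lead record")

    series = hrv.compute_rr_series(annotations, record.fs)
    samples = [a.sample for a in annotations]
    raw_leads = [record.lead(0), record.lead(1)]
    w4_leads = [dwt.w4_transform(lead, record.fs) for lead in raw_leads]
    extractors = {
        "raw": morphology.MorphologyExtractor(raw_leads, samples, record.fs, "raw"),
        "w4": morphology.MorphologyExtractor(w4_leads, samples, record.fs, "w4"),
    }

    rows = []
    for i in range(TRIM_BEATS, n_beats - TRIM_BEATS):
        ann = annotations[i]
        if ann.label == LABEL_EXCLUDED:
            continue
        row: Dict[str, object] = {
            "patient_id": record.patient_id,
            "beat_sample": ann.sample,
            "label": ann.label,
        }
        row.update(hrv.beat_hrv_vector(series, i, drop=hrv_drop))
        row.update(extractors["raw"].beat_features(i))
        row.update(extractors["w4"].beat_features(i))
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def clip_features(matrix: pd.DataFrame, bounds: ClipBounds | None = None) -> pd.DataFrame:
    """Clip RR/dRR-bearing columns to physiological bounds (copy).

    Only the beat-local RR/dRR values and window mean RRs are affected;
    spreads, pNNx, RMSSD and all morphology columns pass through.
    """
    bounds = bounds or ClipBounds()
    out = matrix.copy()
    for col in RR_CLIP_FEATURES:
        if col in out.columns:
            out[col] = out[col].clip(bounds.rr_min, bounds.rr_max)
    for col in DRR_CLIP_FEATURES:
        if col in out.columns:
            out[col] = out[col].clip(bounds.drr_min, bounds.drr_max)
    return out


def prune_features(
    train_matrix: pd.DataFrame,
    corr_max: float = 0.95,
    var_min: float = 0.05,
) -> List[str]:
    """Kept-feature list after variance then correlation pruning.

    Fitted on training beats only.  Columns with sample variance below
    ``var_min`` go first; then, scanning pairs in canonical order, the
    later member of any pair with |Pearson r| > ``corr_max`` is dropped.
    Deterministic.
    """
    X = train_matrix.to_numpy(dtype=float)
    names = list(train_matrix.columns)
    variances = np.var(X, axis=0, ddof=1)
    candidates = [j for j, v in enumerate(variances) if v >= var_min]
    if not candidates:
        raise ValueError("variance pruning dropped every feature")
    corr = np.corrcoef(X[:, candidates], rowvar=False)
    kept: List[int] = []  # positions within `candidates`
    dropped_pairs: List[tuple] = []
    for pj, j in enumerate(candidates):
        correlated = False
        for pk in kept:
            r = corr[pk, pj]
            if abs(r) > corr_max:
                correlated = True
                dropped_pairs.append((names[candidates[pk]], names[j], float(r)))
                break
        if not correlated:
            kept.append(pj)
    kept = [candidates[p] for p in kept]
    if dropped_pairs:
        warnings.warn(
            f"correlation pruning dropped {len(dropped_pairs)} feature(s): "
            + ", ".join(f"{b}~{a} (r={r:.3f})" for a, b, r in dropped_pairs[:10]),
            stacklevel=2,
        )
    if not kept:
        raise ValueError("correlation pruning dropped every feature")
    return [names[j] for j in kept]


def zscore_fit(train_matrix: pd.DataFrame):
    """Column means and sample SDs; errors on constant columns."""
    mu = train_matrix.mean(axis=0)
    sd = train_matrix.std(axis=0, ddof=1)
    if (sd <= 0).any() or sd.isna().any():
        bad = list(sd.index[(sd <= 0) | sd.isna()])
        raise ValueError(f"constant column(s) reached z-scoring: {bad}")
    return mu, sd


def zscore_apply(params, matrix: pd.DataFrame) -> pd.DataFrame:
    mu, sd = params
    return (matrix - mu) / sd


@dataclass
class FeatureTransform:
    """Conditioning fitted on training-fold beats, applied to any fold.

    Captures clip bounds, imputation means, the kept-feature list and
    z-score parameters; application never looks at the target fold's
    content beyond the rows it transforms.
    """

    bounds: ClipBounds = field(default_factory=ClipBounds)
    corr_max: float = 0.95
    var_min: float = 0.05
    impute_means: pd.Series | None = None
    kept: List[str] | None = None
    mu: pd.Series | None = None
    sd: pd.Series | None = None

    def fit(self, train_matrix: pd.DataFrame) -> "FeatureTransform":
        X = self._feature_block(train_matrix)
        X = clip_features(X, self.bounds)
        self.impute_means = X.mean(axis=0, skipna=True)
        X = X.fillna(self.impute_means)
        self.kept = prune_features(X, self.corr_max, self.var_min)
        self.mu, self.sd = zscore_fit(X[self.kept])
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if self.kept is None:
            raise RuntimeError("FeatureTransform.transform called before fit")
        X = self._feature_block(matrix)
        X = clip_features(X, self.bounds)
        X = X.fillna(self.impute_means)
        return zscore_apply((self.mu, self.sd), X[self.kept])

    @staticmethod
    def _feature_block(matrix: pd.DataFrame) -> pd.DataFrame:
        drop = [c for c in META_COLUMNS if c in matrix.columns]
        return matrix.drop(columns=drop)

    def to_json(self, path) -> None:
        payload = {
            "bounds": {"rr_min": self.bounds.rr_min, "rr_max": self.bounds.rr_max},
            "corr_max": self.corr_max,
            "var_min": self.var_min,
            "impute_means": {k: float(v) for k, v in self.impute_means.items()},
            "kept": self.kept,
            "mu": {k: float(v) for k, v in self.mu.items()},
            "sd": {k: float(v) for k, v in self.sd.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "FeatureTransform":
        payload = json.loads(Path(path).read_text())
        obj = cls(
            bounds=ClipBounds(**payload["bounds"]),
            corr_max=payload["corr_max"],
            var_min=payload["var_min"],
        )
        obj.impute_means = pd.Series(payload["impute_means"])
        obj.kept = list(payload["kept"])
        obj.mu = pd.Series(payload["mu"])
        obj.sd = pd.Series(payload["sd"])
        return obj


def save_features(matrix: pd.DataFrame, path) -> None:
    """CSV serialization; floats use shortest round-trip representation."""
    matrix.to_csv(path, index=False)


def load_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "label": str})
    return df
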