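"""Intra-patient template morphology features.

Fixed windows are cut around each annotated R peak (whole beat, P wave,
PR interval, QRS complex — approximate regions, no delineation).  For a
given beat, templates are built from symmetric neighborhoods of 80, 20
and 4 surrounding beats: neighbor segments are aligned to a robust
(element-wise median) reference by maximum-|NCC| cross-correlation,
outliers excluded, and the survivors averaged.  The beat is then scored
against each template, yielding per (segment, neighborhood, lead):
maximum normalized cross-correlation, its lag, and the template's median
per-sample standard deviation — 72 values per signal version (raw or
wavelet scale 4).

Lag convention: the returned lag is the shift applied to the segment to
align it with the reference (``aligned[k] = x[k - lag]``); a segment
delayed by m samples relative to the reference yields lag ``-m``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SEGMENT_WINDOWS_MS",
    "SEGMENT_KINDS",
    "NEIGHBORHOOD_SIZES",
    "MAX_LAG_SAMPLES",
    "OUTLIER_NCC_MIN",
    "TemplateModel",
    "segment_offsets",
    "extract_segment",
    "align_lag",
    "build_template",
    "neighborhoods",
    "morph_feature_names",
    "MorphologyExtractor",
    "beat_morph_features",
]

#: Closed windows in ms relative to the R peak (t = 0).
SEGMENT_WINDOWS_MS = {
    "beat": (-300.0, 250.0),
    "p": (-300.0, 40.0),
    "pr": (-288.0, 0.0),
    "qrs": (-70.0, 60.0),
}
SEGMENT_KINDS: Tuple[str, ...] = ("beat", "p", "pr", "qrs")
NEIGHBORHOOD_SIZES: Tuple[int, ...] = (80, 20, 4)
TRIM_BEATS = 40

#: +-40 ms at 250 Hz: larger than plausible fiducial jitter, smaller than
#: inter-beat spacing.
MAX_LAG_SAMPLES = 10
OUTLIER_NCC_MIN = 0.8


@dataclass(frozen=True)
class TemplateModel:
    """Averaged aligned segment plus per-sample spread for one combination."""

    mean_wave: np.ndarray
    per_sample_sd: np.ndarray
    n_used: int
    median_sd: float
    segment: Optional[str] = None
    neighborhood: Optional[int] = None
    lead: Optional[int] = None
    signal_version: Optional[str] = None


def _round_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def segment_offsets(kind: str, fs: float = 250.0) -> Tuple[int, int]:
    """Sample offsets (inclusive) of a segment window; ties round away from 0."""
    lo_ms, hi_ms = SEGMENT_WINDOWS_MS[kind]
    return _round_away(lo_ms * fs / 1000.0), _round_away(hi_ms * fs / 1000.0)


def extract_segment(lead, r_sample: int, kind: str, fs: float = 250.0) -> np.ndarray:
    """Contiguous samples ``[r+off_lo, r+off_hi]``; errors if out of range."""
    x = np.asarray(lead)
    lo, hi = segment_offsets(kind, fs)
    start, stop = r_sample + lo, r_sample + hi
    if start < 0 or stop >= x.size:
        raise ValueError(
            f"{kind} window [{start}, {stop}] outside record of {x.size} samples"
        )
    return x[start : stop + 1]


def _lag_order(max_lag: int) -> List[int]:
    # smallest |lag| first, negative before positive -> tie preference
    order = [0]
    for m in range(1, max_lag + 1):
        order.extend((-m, m))
    return order


def _ncc_many(beats: np.ndarray, ref: np.ndarray, max_lag: int) -> Tuple[np.ndarray, np.ndarray]:
    """Best (lag, ncc) per row of ``beats``, maximizing |NCC| over lags.

    NCC uses zero-mean, unit-energy normalization over the overlapping
    parts so self-correlation at lag 0 equals 1.  Zero-variance overlap
    yields ncc 0.  Ties prefer the smallest |lag|, then the negative one
    (guaranteed by strict-improvement scanning in that order).
    """
    m, L = beats.shape
    lags = np.array(_lag_order(max_lag))
    n_lags = lags.size

    # Dot products for every lag in one matmul: column j of R holds the
    # reference shifted to its overlap position, zero elsewhere, so
    # beats @ R[:, j] equals the overlap dot product at lag lags[j].
    R = np.zeros((L, n_lags))
    x_lo = np.empty(n_lags, dtype=int)  # overlap slice of x: [x_lo, x_hi)
    x_hi = np.empty(n_lags, dtype=int)
    for j, lag in enumerate(lags):
        if lag >= 0:
            R[:, j][: L - lag] = ref[lag:] if lag else ref
            x_lo[j], x_hi[j] = 0, L - lag
        else:
            R[:, j][-lag:] = ref[: L + lag]
            x_lo[j], x_hi[j] = -lag, L
    dots = beats @ R  # (m, n_lags)

    # Overlap sums from prefix sums (zero-mean, unit-energy normalization).
    csum = np.concatenate([np.zeros((m, 1)), np.cumsum(beats, axis=1)], axis=1)
    csum2 = np.concatenate([np.zeros((m, 1)), np.cumsum(beats**2, axis=1)], axis=1)
    n_ov = (x_hi - x_lo).astype(float)
    sx = csum[:, x_hi] - csum[:, x_lo]
    sx2 = csum2[:, x_hi] - csum2[:, x_lo]
    rsum = np.concatenate([[0.0], np.cumsum(ref)])
    rsum2 = np.concatenate([[0.0], np.cumsum(ref**2)])
    r_lo = np.where(lags >= 0, lags, 0)
    r_hi = np.where(lags >= 0, L, L + lags)
    sr = rsum[r_hi] - rsum[r_lo]
    sr2 = rsum2[r_hi] - rsum2[r_lo]

    num = dots - sx * (sr / n_ov)
    var_x = np.maximum(sx2 - sx**2 / n_ov, 0.0)
    var_r = np.maximum(sr2 - sr**2 / n_ov, 0.0)
    den = np.sqrt(var_x * var_r)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(den > 0, num / den, 0.0)
    ncc = np.clip(ncc, -1.0, 1.0)

    # columns are ordered smallest |lag| first, negative before positive,
    # and argmax returns the first maximum -> the tie preference.
    pick = np.argmax(np.abs(ncc), axis=1)
    rows = np.arange(m)
    return lags[pick], ncc[rows, pick]


def align_lag(x, ref, max_lag: int = MAX_LAG_SAMPLES) -> Tuple[int, float]:
    """Alignment of one waveform against a reference of equal length."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {ref.shape}")
    lags, nccs = _ncc_many(x[None, :], ref, max_lag)
    return int(lags[0]), float(nccs[0])


def _apply_lags(beats: np.ndarray, lags: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Shift rows by their lag; samples beyond overlap filled from ``ref``."""
    m, L = beats.shape
    idx = np.arange(L)[None, :] - lags[:, None]
    valid = (idx >= 0) & (idx < L)
    gathered = beats[np.arange(m)[:, None], np.clip(idx, 0, L - 1)]
    return np.where(valid, gathered, ref[None, :])


def build_template(
    beats: Sequence[np.ndarray],
    outlier_ncc_min: float = OUTLIER_NCC_MIN,
    max_lag: int = MAX_LAG_SAMPLES,
) -> TemplateModel:
    """Robust template from >= 2 equal-length waveforms.

    Steps: element-wise median reference; align each waveform to it;
    exclude waveforms with ncc < ``outlier_ncc_min``; if fewer than 2
    survive, keep the 2 highest-ncc waveforms; average the aligned
    survivors and take per-sample SD and its median.
    """
    B = np.asarray(beats, dtype=float)
    if B.ndim != 2 or B.shape[0] < 2:
        raise ValueError("build_template needs at least 2 equal-length waveforms")
    ref = np.median(B, axis=0)
    lags, nccs = _ncc_many(B, ref, max_lag)
    keep = nccs >= outlier_ncc_min
    if keep.sum() < 2:
        keep = np.zeros(B.shape[0], dtype=bool)
        keep[np.argsort(-nccs, kind="stable")[:2]] = True
    aligned = _apply_lags(B[keep], lags[keep], ref)
    mean_wave = aligned.mean(axis=0)
    per_sample_sd = aligned.std(axis=0, ddof=1)
    return TemplateModel(
        mean_wave=mean_wave,
        per_sample_sd=per_sample_sd,
        n_used=int(keep.sum()),
        median_sd=float(np.median(per_sample_sd)),
    )


def neighborhoods(i: int, n_beats: int) -> Dict[int, np.ndarray]:
    """Symmetric neighbor index sets (excluding ``i``) for each template size."""
    if not TRIM_BEATS <= i <= n_beats - TRIM_BEATS - 1:
        raise IndexError(
            f"beat {i} lies in the trim zone of a {n_beats}-beat record"
        )
    out = {}
    for size in NEIGHBORHOOD_SIZES:
        half = size // 2
        idx = np.r_[i - half : i, i + 1 : i + half + 1]
        out[size] = idx
    return out


def morph_feature_names(version: str) -> List[str]:
    """Canonical 72-name ordering for one signal version ('raw' or 'w4')."""
    return [
        f"morph_{version}_{seg}_t{size}_L{lead + 1}_{stat}"
        for seg in SEGMENT_KINDS
        for size in NEIGHBORHOOD_SIZES
        for lead in (0, 1)
        for stat in ("xcorr", "lag", "medsd")
    ]


class MorphologyExtractor:
    """Batch extractor for one signal version of one record.

    Segments for every annotated beat are pre-cut once; templates are
    rebuilt per beat from its neighbors (the beat itself never enters its
    own template).  Neighbors whose window falls outside the record are
    skipped when gathering template inputs.
    """

    def __init__(
        self,
        leads: Sequence[np.ndarray],
        ann_samples: Sequence[int],
        fs: float = 250.0,
        version: str = "raw",
        max_lag: int = MAX_LAG_SAMPLES,
        outlier_ncc_min: float = OUTLIER_NCC_MIN,
    ) -> None:
        if len(leads) < 2:
            raise ValueError("the feature extractor requires 2 leads")
        self.version = version
        self.max_lag = max_lag
        self.outlier_ncc_min = outlier_ncc_min
        self._names = morph_feature_names(version)
        self.n_beats = len(ann_samples)
        r = np.asarray(ann_samples, dtype=int)
        self._segments: Dict[Tuple[str, int], np.ndarray] = {}
        self._valid: Dict[str, np.ndarray] = {}
        for kind in SEGMENT_KINDS:
            lo, hi = segment_offsets(kind, fs)
            length = hi - lo + 1
            for li, lead in enumerate(leads[:2]):
                x = np.asarray(lead, dtype=float)
                valid = (r + lo >= 0) & (r + hi < x.size)
                mat = np.zeros((r.size, length))
                if valid.any():
                    idx = r[valid, None] + np.arange(lo, hi + 1)[None, :]
                    mat[valid] = x[idx]
                self._segments[(kind, li)] = mat
            self._valid[kind] = valid  # same annotation geometry on both leads

    def beat_features(
        self, i: int, collect: Optional[List[TemplateModel]] = None
    ) -> Dict[str, float]:
        """The 72 morphology features of beat ``i`` (one signal version)."""
        neigh = neighborhoods(i, self.n_beats)
        features: Dict[str, float] = {}
        for kind in SEGMENT_KINDS:
            valid = self._valid[kind]
            if not valid[i]:
                raise ValueError(f"beat {i}: {kind} window outside record")
            for size in NEIGHBORHOOD_SIZES:
                idx = neigh[size]
                idx = idx[valid[idx]]
                for li in (0, 1):
                    seg = self._segments[(kind, li)]
                    tpl = build_template(
                        seg[idx], self.outlier_ncc_min, self.max_lag
                    )
                    if collect is not None:
                        collect.append(
                            TemplateModel(
                                tpl.mean_wave,
                                tpl.per_sample_sd,
                                tpl.n_used,
                                tpl.median_sd,
                                segment=kind,
                                neighborhood=size,
                                lead=li,
                                signal_version=self.version,
                            )
                        )
                    lag, ncc = align_lag(seg[i], tpl.mean_wave, self.max_lag)
                    prefix = f"morph_{self.version}_{kind}_t{size}_L{li + 1}"
                    features[f"{prefix}_xcorr"] = ncc
                    features[f"{prefix}_lag"] = float(lag)
                    features[f"{prefix}_medsd"] = tpl.median_sd
        return {name: features[name] for name in self._names}


def beat_morph_features(
    leads: Sequence[np.ndarray],
    ann_samples: Sequence[int],
    i: int,
    fs: float = 250.0,
    version: str = "raw",
    collect: Optional[List[TemplateModel]] = None,
) -> Dict[str, float]:
    """One-shot morphology features for a single beat (one signal version)."""
    extractor = MorphologyExtractor(leads, ann_samples, fs=fs, version=version)
    return extractor.beat_features(i, collect=collect)
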