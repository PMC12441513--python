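"""MZmine-style feature extraction from centroided MS1 scans.

The chain mirrors the usual LC-MS preprocessing sequence: trace
chromatograms by greedy m/z binning, resolve traces into features at
local intensity minima, drop 13C isotope satellites, align features
across samples with a weighted-score join aligner, and keep only rows
that carry an MS2 scan (the molecular-networking input filter).

Defaults are the processing settings this pipeline is validated with
(noise floors 1000/100, five consecutive scans, 7000 minimum height,
3000 minimum consecutive-scan intensity, 0.005 Da / 10 ppm trace
tolerance, 90% chromatographic threshold, 0-1 min peak duration, 13C
filter at 0.001 Da / 5 ppm and 0.01 min, join alignment at 0.001 Da /
5 ppm and 0.1 min with m/z weight 3 and RT weight 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .spectra_io import MS1Scan, Spectrum

__all__ = [
    "FeatureFinderParams",
    "ChromatogramTrace",
    "Feature",
    "build_chromatograms",
    "resolve_local_minimum",
    "isotope_filter",
    "assign_ms2",
    "join_align",
    "find_features",
]

#: mass difference between 13C and 12C
C13_DELTA = 1.003355


@dataclass(frozen=True)
class FeatureFinderParams:
    noise_ms1: float = 1000.0
    noise_ms2: float = 100.0
    min_consecutive_scans: int = 5
    min_height: float = 7000.0
    min_intensity_consecutive: float = 3000.0
    mz_tol_da: float = 0.005
    mz_tol_ppm: float = 10.0
    chrom_threshold: float = 0.90
    peak_duration_max: float = 1.0  # minutes; duration must be in (0, max]
    min_scans_resolve: int = 5
    isotope_mz_tol_da: float = 0.001
    isotope_mz_tol_ppm: float = 5.0
    isotope_rt_tol: float = 0.01
    max_charge: int = 1
    align_mz_tol_da: float = 0.001
    align_mz_tol_ppm: float = 5.0
    align_rt_tol: float = 0.1
    weight_mz: float = 3.0
    weight_rt: float = 1.0

    def mz_tol(self, mz: float) -> float:
        """Trace-building tolerance: the more permissive of Da and ppm."""
        return max(self.mz_tol_da, self.mz_tol_ppm * 1e-6 * mz)

    def isotope_tol(self, mz: float) -> float:
        return max(self.isotope_mz_tol_da, self.isotope_mz_tol_ppm * 1e-6 * mz)

    def align_tol(self, mz: float) -> float:
        return max(self.align_mz_tol_da, self.align_mz_tol_ppm * 1e-6 * mz)


@dataclass
class ChromatogramTrace:
    """An extracted-ion trace: m/z center plus (rt, intensity) points."""

    mz_center: float
    points: list[tuple[float, float]]  # (rt minutes, intensity), rt increasing

    @property
    def rts(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass
class Feature:
    """A resolved chromatographic peak, optionally with an MS2 spectrum."""

    id: str
    mz: float
    rt_apex: float
    height: float
    rt_start: float = 0.0
    rt_end: float = 0.0
    sample_intensities: dict[str, float] = field(default_factory=dict)
    ms2: Spectrum | None = None


# ---------------------------------------------------------------------------
# chromatogram building
# ---------------------------------------------------------------------------


class _OpenTrace:
    __slots__ = ("mz_sum", "weight", "points", "last_scan")

    def __init__(self, mz: float, rt: float, intensity: float, scan_idx: int):
        self.mz_sum = mz * intensity
        self.weight = intensity
        self.points = [(rt, intensity)]
        self.last_scan = scan_idx

    @property
    def mz(self) -> float:
        return self.mz_sum / self.weight

    def add(self, mz: float, rt: float, intensity: float, scan_idx: int):
        self.mz_sum += mz * intensity
        self.weight += intensity
        self.points.append((rt, intensity))
        self.last_scan = scan_idx


def build_chromatograms(
    ms1_scans: Sequence[MS1Scan], params: FeatureFinderParams | None = None
) -> list[ChromatogramTrace]:
    """Greedy m/z-bin chromatogram tracing.

    A peak above the MS1 noise floor joins the open trace whose running
    intensity-weighted mean m/z is nearest and within tolerance; a trace
    not extended on a scan is closed (consecutive-scan semantics).
    Traces shorter than ``min_consecutive_scans`` or never reaching
    ``min_intensity_consecutive`` are discarded.
    """
    params = params or FeatureFinderParams()
    scans = sorted(ms1_scans, key=lambda s: s.rt)
    open_traces: list[_OpenTrace] = []
    closed: list[_OpenTrace] = []

    for idx, scan in enumerate(scans):
        # close traces that missed the previous scan
        still_open = []
        for tr in open_traces:
            (still_open if tr.last_scan >= idx - 1 else closed).append(tr)
        open_traces = still_open

        if scan.peaks.size == 0:
            continue
        peaks = scan.peaks[scan.peaks[:, 1] >= params.noise_ms1]
        # assign strongest peaks first so they claim the nearest trace
        for mz, inten in sorted(peaks.tolist(), key=lambda p: -p[1]):
            best, best_d = None, None
            for tr in open_traces:
                if tr.last_scan == idx:  # already extended this scan
                    continue
                d = abs(tr.mz - mz)
                if d <= params.mz_tol(mz) and (best is None or d < best_d):
                    best, best_d = tr, d
            if best is None:
                open_traces.append(_OpenTrace(mz, scan.rt, inten, idx))
            else:
                best.add(mz, scan.rt, inten, idx)

    closed.extend(open_traces)
    out = []
    for tr in closed:
        if len(tr.points) < params.min_consecutive_scans:
            continue
        if max(i for _, i in tr.points) < params.min_intensity_consecutive:
            continue
        out.append(ChromatogramTrace(mz_center=tr.mz, points=tr.points))
    out.sort(key=lambda t: t.mz_center)
    return out


# ---------------------------------------------------------------------------
# local-minimum resolving
# ---------------------------------------------------------------------------


def resolve_local_minimum(
    trace: ChromatogramTrace,
    params: FeatureFinderParams | None = None,
    feature_prefix: str = "F",
) -> list[Feature]:
    """Split a trace into features at deep local minima.

    A local minimum splits two sub-peaks when its intensity falls to at
    most ``(1 - chrom_threshold)`` of the smaller adjacent apex (with the
    default 90% threshold: the valley must drop below 10% of the lower
    apex).  Segments must reach ``min_height`` at the apex, span at least
    ``min_scans_resolve`` scans, and elute within the peak-duration
    bound.
    """
    params = params or FeatureFinderParams()
    rts = trace.rts
    ints = trace.intensities
    n = len(ints)
    if n == 0:
        return []

    minima = [
        i
        for i in range(1, n - 1)
        if ints[i] < ints[i - 1] and ints[i] <= ints[i + 1]
    ]
    # candidate split points, deepest first, validated against both apexes
    cut_points: list[int] = []
    bounds = [0, n - 1]
    for i in sorted(minima, key=lambda i: ints[i]):
        segment_bounds = sorted(set(bounds + cut_points))
        left = max(b for b in segment_bounds if b <= i)
        right = min(b for b in segment_bounds if b >= i)
        if right <= left:
            continue
        left_apex = ints[left : i + 1].max()
        right_apex = ints[i : right + 1].max()
        if ints[i] <= (1.0 - params.chrom_threshold) * min(left_apex, right_apex):
            cut_points.append(i)

    edges = sorted(set([0, *cut_points, n - 1]))
    features = []
    for a, b in itertools.pairwise(edges):
        seg = slice(a, b + 1)
        seg_ints = ints[seg]
        seg_rts = rts[seg]
        apex = int(np.argmax(seg_ints))
        height = float(seg_ints[apex])
        duration = float(seg_rts[-1] - seg_rts[0])
        if height < params.min_height:
            continue
        if len(seg_ints) < params.min_scans_resolve:
            continue
        if not (0.0 < duration <= params.peak_duration_max):
            continue
        features.append(
            Feature(
                id=f"{feature_prefix}{len(features)}_{trace.mz_center:.4f}",
                mz=trace.mz_center,
                rt_apex=float(seg_rts[apex]),
                height=height,
                rt_start=float(seg_rts[0]),
                rt_end=float(seg_rts[-1]),
            )
        )
    return features


# ---------------------------------------------------------------------------
# 13C isotope filter
# ---------------------------------------------------------------------------


def isotope_filter(
    features: Sequence[Feature], params: FeatureFinderParams | None = None
) -> list[Feature]:
    """Drop features that look like the 13C satellite of a stronger one.

    B is removed as the satellite of A when mz(B) - mz(A) matches the
    13C spacing within tolerance, the apexes co-elute within the RT
    tolerance, and B is the smaller of the two (the monotonic-shape
    check at charge one).
    """
    params = params or FeatureFinderParams()
    feats = sorted(features, key=lambda f: f.mz)
    drop: set[int] = set()
    for i, a in enumerate(feats):
        for j, b in enumerate(feats):
            if i == j or j in drop:
                continue
            dm = b.mz - a.mz
            if abs(dm - C13_DELTA) > params.isotope_tol(a.mz):
                continue
            if abs(b.rt_apex - a.rt_apex) > params.isotope_rt_tol:
                continue
            if b.height < a.height:
                drop.add(j)
    return [f for j, f in enumerate(feats) if j not in drop]


# ---------------------------------------------------------------------------
# MS2 pairing
# ---------------------------------------------------------------------------


def assign_ms2(
    features: Sequence[Feature],
    ms2_spectra: Sequence[Spectrum],
    params: FeatureFinderParams | None = None,
) -> list[Feature]:
    """Attach to each feature the best-matching MS2 scan.

    A scan qualifies when its precursor m/z is within the alignment
    tolerance of the feature m/z and its RT lies inside the feature's
    elution window; among qualifiers the most intense (by base peak)
    wins.  Features keep ``ms2=None`` when nothing qualifies.
    """
    params = params or FeatureFinderParams()
    out = []
    for f in features:
        best: Spectrum | None = None
        best_int = -1.0
        for s in ms2_spectra:
            if abs(s.precursor_mz - f.mz) > params.align_tol(f.mz):
                continue
            if not (f.rt_start - 1e-9 <= s.rt <= f.rt_end + 1e-9):
                continue
            base = float(s.intensity.max()) if len(s) else 0.0
            if base > best_int:
                best, best_int = s, base
        out.append(replace(f, ms2=best))
    return out


# ---------------------------------------------------------------------------
# join alignment
# ---------------------------------------------------------------------------


def _align_score(a: Feature, b: Feature, params: FeatureFinderParams) -> float | None:
    mz_tol = params.align_tol(min(a.mz, b.mz))
    dmz = abs(a.mz - b.mz)
    drt = abs(a.rt_apex - b.rt_apex)
    if dmz > mz_tol or drt > params.align_rt_tol:
        return None
    return params.weight_mz * (1.0 - dmz / mz_tol) + params.weight_rt * (
        1.0 - drt / params.align_rt_tol
    )


def join_align(
    feature_lists: dict[str, Sequence[Feature]],
    params: FeatureFinderParams | None = None,
    require_ms2: bool = True,
) -> list[Feature]:
    """Align per-sample feature lists into one table by greedy best score.

    score(a, b) = w_mz * (1 - |dmz|/mz_tol) + w_rt * (1 - |drt|/rt_tol)
    for candidate pairs within both tolerances; higher score wins, exact
    ties broken by smaller |dmz| then sample order.  Aligned rows carry
    per-sample intensities; rows without any MS2 scan are dropped when
    ``require_ms2`` (the feature-with-MS2 filter).
    """
    params = params or FeatureFinderParams()
    sample_ids = list(feature_lists)
    rows: list[Feature] = []
    for si, sample in enumerate(sample_ids):
        feats = list(feature_lists[sample])
        if si == 0 or not rows:
            for f in feats:
                row = replace(
                    f,
                    id=f"R{len(rows)}",
                    sample_intensities={sample: f.height},
                )
                rows.append(row)
            continue
        candidates = []
        for ri, row in enumerate(rows):
            for fi, f in enumerate(feats):
                score = _align_score(row, f, params)
                if score is not None:
                    candidates.append(
                        (-score, abs(row.mz - f.mz), ri, fi)
                    )
        candidates.sort()
        used_rows: set[int] = set()
        used_feats: set[int] = set()
        for _, _, ri, fi in candidates:
            if ri in used_rows or fi in used_feats:
                continue
            used_rows.add(ri)
            used_feats.add(fi)
            row, f = rows[ri], feats[fi]
            row.sample_intensities[sample] = f.height
            if row.ms2 is None and f.ms2 is not None:
                row.ms2 = f.ms2
            if f.height > row.height:
                row.mz, row.rt_apex, row.height = f.mz, f.rt_apex, f.height
        for fi, f in enumerate(feats):
            if fi not in used_feats:
                rows.append(
                    replace(
                        f,
                        id=f"R{len(rows)}",
                        sample_intensities={sample: f.height},
                    )
                )
    for row in rows:
        for sample in sample_ids:
            row.sample_intensities.setdefault(sample, 0.0)
    if require_ms2:
        rows = [r for r in rows if r.ms2 is not None]
    return rows


# ---------------------------------------------------------------------------
# one-call pipeline per run
# ---------------------------------------------------------------------------


def find_features(
    ms1_scans: Sequence[MS1Scan],
    ms2_spectra: Sequence[Spectrum] = (),
    params: FeatureFinderParams | None = None,
    sample_id: str = "sample",
) -> list[Feature]:
    """Trace, resolve, de-isotope and MS2-pair one sample's scans."""
    params = params or FeatureFinderParams()
    traces = build_chromatograms(ms1_scans, params)
    feats: list[Feature] = []
    for k, trace in enumerate(traces):
        feats.extend(
            resolve_local_minimum(trace, params, feature_prefix=f"{sample_id}_T{k}_")
        )
    feats = isotope_filter(feats, params)
    feats = assign_ms2(feats, ms2_spectra, params)
    return feats
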