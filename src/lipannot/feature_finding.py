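"""MS1 feature detection and DDA MS/MS association.

Extracted-ion chromatograms are built by linking MS1 peaks within a ppm
tolerance across scans; chromatographic peaks are detected as local maxima
with boundaries at the nearest local minimum or 10% of apex (whichever is
closer to the apex), integrated by the trapezoid rule.  MS2 scans whose
precursor falls on a feature within its retention window are averaged into a
composite spectrum — a single MS/MS scan suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from .chem import ISOTOPE_MZ_SPACING, IsotopePattern
from .spectra_io import Run, Scan


@dataclass
class EicTrace:
    """One extracted-ion chromatogram: intensity per MS1 scan for an m/z cluster."""

    mz: float  # intensity-weighted cluster mean
    rt: np.ndarray  # minutes, one per MS1 scan
    intensity: np.ndarray
    scan_indices: np.ndarray  # indices into run.ms1_scans()
    mz_per_scan: np.ndarray | None = None  # weighted mean m/z per scan (nan if absent)


@dataclass
class ChromatographicFeature:
    mz: float
    rt_apex: float
    rt_start: float
    rt_end: float
    height: float
    area: float
    quality: float  # Gaussian-fit correlation, clamped to [0, 1]
    observed_isotopes: IsotopePattern = field(default_factory=IsotopePattern)
    apex_scan_index: int = 0

    def __post_init__(self):
        if not (self.rt_start < self.rt_apex < self.rt_end):
            raise ValueError("feature bounds must bracket the apex")


@dataclass
class CompositeMS2:
    feature: ChromatographicFeature
    mz: np.ndarray
    intensity: np.ndarray
    n_scans_averaged: int
    precursor_mz: float


def extract_eics(run: Run, mz_tol_ppm: float = 20.0, min_intensity: float = 0.0) -> list[EicTrace]:
    """Cluster MS1 peaks into EIC traces.

    Peaks from all MS1 scans are pooled, sorted by m/z, and split into
    clusters wherever the gap between consecutive peaks exceeds twice the ppm
    tolerance; each cluster becomes one trace (intensities summed per scan).
    """
    ms1 = run.ms1_scans()
    if not ms1:
        return []
    rts = np.array([s.rt for s in ms1])
    mzs, intens, scan_idx = [], [], []
    for i, scan in enumerate(ms1):
        keep = scan.intensity > min_intensity
        mzs.append(scan.mz[keep])
        intens.append(scan.intensity[keep])
        scan_idx.append(np.full(keep.sum(), i))
    mz = np.concatenate(mzs)
    inten = np.concatenate(intens)
    sidx = np.concatenate(scan_idx)
    if len(mz) == 0:
        return []
    order = np.argsort(mz, kind="stable")
    mz, inten, sidx = mz[order], inten[order], sidx[order]

    gaps = np.diff(mz) > 2e-6 * mz_tol_ppm * mz[1:]
    boundaries = np.flatnonzero(gaps) + 1
    traces = []
    for chunk in np.split(np.arange(len(mz)), boundaries):
        c_mz, c_int, c_sidx = mz[chunk], inten[chunk], sidx[chunk]
        profile = np.zeros(len(ms1))
        weighted_mz = np.zeros(len(ms1))
        np.add.at(profile, c_sidx, c_int)
        np.add.at(weighted_mz, c_sidx, c_int * c_mz)
        with np.errstate(invalid="ignore"):
            per_scan = np.where(profile > 0, weighted_mz / profile, np.nan)
        traces.append(
            EicTrace(
                mz=float(np.average(c_mz, weights=c_int)),
                rt=rts,
                intensity=profile,
                scan_indices=np.arange(len(ms1)),
                mz_per_scan=per_scan,
            )
        )
    return traces


def _gaussian_quality(rt: np.ndarray, inten: np.ndarray) -> float:
    """Pearson correlation of a trace segment against a moment-fit Gaussian."""
    if len(rt) < 3 or inten.sum() <= 0:
        return 0.0
    mu = float(np.average(rt, weights=inten))
    var = float(np.average((rt - mu) ** 2, weights=inten))
    if var <= 0:
        return 0.0
    model = np.exp(-0.5 * (rt - mu) ** 2 / var)
    if np.ptp(model) == 0 or np.ptp(inten) == 0:
        return 0.0
    r = pearsonr(inten, model).statistic
    return float(np.clip(r, 0.0, 1.0))


def detect_features(
    traces: list[EicTrace],
    min_height: float,
    min_points: int = 3,
) -> list[ChromatographicFeature]:
    """Local-maximum peak picking on EIC traces.

    Apexes are strict local maxima above ``min_height`` supported by at least
    ``min_points`` nonzero points; each peak's boundaries sit at the nearest
    local minimum or at the 10%-of-apex crossing, whichever is closer to the
    apex.  Area is trapezoidal over retention time (intensity·minutes).
    """
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    features = []
    for trace in traces:
        y, rt = trace.intensity, trace.rt
        n = len(y)
        if n < min_points:
            continue
        apexes = [
            i
            for i in range(1, n - 1)
            if y[i] >= min_height and y[i] >= y[i - 1] and y[i] > y[i + 1]
        ]
        for apex in apexes:
            # walk left/right to the nearest local minimum
            left = apex
            while left > 0 and y[left - 1] < y[left]:
                left -= 1
            right = apex
            while right < n - 1 and y[right + 1] < y[right]:
                right += 1
            # tighten to the 10%-of-apex crossing if that is closer to apex
            cutoff = 0.1 * y[apex]
            lo = apex
            while lo > left and y[lo - 1] >= cutoff:
                lo -= 1
            hi = apex
            while hi < right and y[hi + 1] >= cutoff:
                hi += 1
            lo, hi = max(lo, left), min(hi, right)
            if hi - lo + 1 < min_points or not (lo < apex < hi):
                continue
            seg = slice(lo, hi + 1)
            if np.count_nonzero(y[seg]) < min_points:
                continue
            area = float(np.trapezoid(y[seg], rt[seg]))
            if area <= 0:
                continue
            # apex-local m/z: weighted over this peak's own scans, so a trace
            # shared with a temporally resolved near-isobar is not biased
            if trace.mz_per_scan is not None:
                mz_seg = trace.mz_per_scan[seg]
                ok = ~np.isnan(mz_seg) & (y[seg] > 0)
                feat_mz = (
                    float(np.average(mz_seg[ok], weights=y[seg][ok]))
                    if ok.any()
                    else trace.mz
                )
            else:
                feat_mz = trace.mz
            features.append(
                ChromatographicFeature(
                    mz=feat_mz,
                    rt_apex=float(rt[apex]),
                    rt_start=float(rt[lo]),
                    rt_end=float(rt[hi]),
                    height=float(y[apex]),
                    area=area,
                    quality=_gaussian_quality(rt[seg], y[seg]),
                    apex_scan_index=int(trace.scan_indices[apex]),
                )
            )
    features.sort(key=lambda f: (f.rt_apex, f.mz))
    return features


def attach_isotopes(
    feature: ChromatographicFeature,
    run: Run,
    mz_tol_ppm: float = 20.0,
    n_peaks: int = 3,
) -> ChromatographicFeature:
    """Read the observed A+k isotope envelope at the feature's apex scan.

    Ratios are relative to the monoisotopic (A) peak intensity at the apex;
    missing isotopologues read as 0.
    """
    scan = run.ms1_scans()[feature.apex_scan_index]
    ratios = np.zeros(n_peaks)
    tol = feature.mz * mz_tol_ppm * 1e-6
    base = _intensity_near(scan, feature.mz, tol)
    if base <= 0:
        base = feature.height
    ratios[0] = 1.0
    for k in range(1, n_peaks):
        obs = _intensity_near(scan, feature.mz + k * ISOTOPE_MZ_SPACING, tol)
        ratios[k] = obs / base if base > 0 else 0.0
    feature.observed_isotopes = IsotopePattern(ratios)
    return feature


def _intensity_near(scan: Scan, mz: float, tol: float) -> float:
    lo = np.searchsorted(scan.mz, mz - tol)
    hi = np.searchsorted(scan.mz, mz + tol)
    return float(scan.intensity[lo:hi].sum())


def average_ms2_peaks(
    scans: list[Scan], tol_ppm: float = 20.0, min_tol_da: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Bin and average fragment peaks across MS2 scans.

    Peaks within max(tol_ppm, ``min_tol_da``) merge into one bin; bin
    intensity is the summed intensity divided by the number of scans, so a
    fragment absent from a scan counts as zero there and the average of
    identical scans reproduces either one.
    """
    n = len(scans)
    mz = np.concatenate([s.mz for s in scans])
    inten = np.concatenate([s.intensity for s in scans])
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    if len(mz) == 0:
        return mz, inten
    out_mz, out_int = [], []
    start = 0
    for i in range(1, len(mz) + 1):
        if i == len(mz) or mz[i] - mz[i - 1] > max(mz[i] * tol_ppm * 1e-6, min_tol_da):
            seg = slice(start, i)
            out_mz.append(float(np.average(mz[seg], weights=inten[seg]))
                          if inten[seg].sum() > 0 else float(mz[seg].mean()))
            out_int.append(float(inten[seg].sum()) / n)
            start = i
    return np.array(out_mz), np.array(out_int)


def associate_and_average_ms2(
    feature: ChromatographicFeature,
    run: Run,
    precursor_tol_da: float = 0.7,
    frag_tol_ppm: float = 20.0,
) -> CompositeMS2 | None:
    """Average the MS2 scans acquired on this feature.

    Qualifying scans have rt within [rt_start, rt_end] and a precursor within
    ±``precursor_tol_da`` of the feature m/z.  Returns None when no scan
    qualifies; a single scan is sufficient.  The result is independent of
    scan order.
    """
    if precursor_tol_da <= 0:
        raise ValueError("precursor_tol_da must be > 0")
    hits = [
        s
        for s in run.ms2_scans()
        if feature.rt_start <= s.rt <= feature.rt_end
        and s.precursor_mz is not None
        and abs(s.precursor_mz - feature.mz) <= precursor_tol_da
    ]
    if not hits:
        return None
    hits.sort(key=lambda s: s.rt)
    mz, inten = average_ms2_peaks(hits, tol_ppm=frag_tol_ppm)
    return CompositeMS2(
        feature=feature,
        mz=mz,
        intensity=inten,
        n_scans_averaged=len(hits),
        precursor_mz=float(np.mean([s.precursor_mz for s in hits])),
    )
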