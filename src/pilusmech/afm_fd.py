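"""AFM retraction force-distance curve analysis.

Curves are classified into nanospring (approximately Hookean force rise
ending in a sharp rupture), constant-force plateau, both, or none, and the
spring constant, rupture force, and plateau force are extracted.

Conventions: distance in nm, strictly increasing during retraction; force in
pN with tension positive after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "FDCurve",
    "FDSignature",
    "baseline_correct",
    "classify_signature",
    "fit_nanospring",
    "measure_plateau",
    "read_fd_tsv",
    "write_fd_tsv",
]


@dataclass
class FDCurve:
    distance: np.ndarray          # nm, strictly increasing
    force: np.ndarray             # pN, tension positive
    retract_speed: float = 1.0    # µm/s
    label: str = ""
    flags: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.distance.shape != self.force.shape or self.distance.ndim != 1:
            raise ValueError("distance and force must be equal-length 1D arrays")
        if len(self.distance) < 50:
            raise ValueError("curve must have at least 50 samples")
        if np.any(np.diff(self.distance) <= 0):
            raise ValueError("distance must be strictly increasing")


@dataclass
class FDSignature:
    kind: str                            # nanospring | plateau | both | none
    k_pilus: float | None = None         # pN/nm
    f_adh: float | None = None           # pN
    plateau_force: float | None = None   # pN
    plateau_len: float | None = None     # nm
    rupture_distance: float | None = None  # nm
    fit_r2: float | None = None
    event_window: tuple[int, int] | None = None   # sample indices
    flags: list[str] = field(default_factory=list)


def baseline_correct(curve: FDCurve, tail_fraction: float = 0.10) -> FDCurve:
    """Remove force offset and linear drift estimated on the baseline region.

    The baseline is anchored at the median of the final `tail_fraction` of
    samples (always part of the post-rupture tail) and extended backward to
    everything after the last excursion above the tail noise level. A robust
    (Theil-Sen) line is fitted over that region and subtracted; if its slope
    is statistically indistinguishable from zero only the offset is removed,
    so a noise-fitted tilt is never extrapolated into the event region.
    """
    d, f = curve.distance, curve.force
    n = len(f)
    n_tail = max(int(n * tail_fraction), 5)
    f_tail = f[-n_tail:]
    flags = list(curve.flags)
    if np.ptp(f) == 0:
        return FDCurve(d.copy(), f.copy(), curve.retract_speed, curve.label,
                       flags + ["all-constant curve: baseline not adjusted"],
                       dict(curve.meta))
    tail_median = float(np.median(f_tail))
    noise = 1.4826 * float(np.median(np.abs(f_tail - tail_median)))
    # baseline region: everything after the last excursion above noise
    fs = _smooth(f, max(5, n // 200))
    above = fs > tail_median + max(5.0 * noise, 10.0)
    base_start = int(np.flatnonzero(above)[-1]) + 1 if above.any() else 0
    base_start = min(base_start, n - n_tail)
    d_base, f_base = d[base_start:], f[base_start:]
    if np.ptp(f_base) == 0:
        slope, intercept = 0.0, float(f_base[0])
    else:
        slope, intercept, lo, hi = stats.theilslopes(f_base, d_base)
        if lo <= 0.0 <= hi:
            slope, intercept = 0.0, float(np.median(f_base))
    corrected = f - (slope * d + intercept)
    return FDCurve(d.copy(), corrected, curve.retract_speed,
                   curve.label, flags, dict(curve.meta))


def _smooth(f: np.ndarray, width: int) -> np.ndarray:
    """Boxcar smoothing with edge padding; width forced odd."""
    width = max(width | 1, 3)
    kernel = np.ones(width) / width
    padded = np.concatenate([np.full(width // 2, f[0]), f,
                             np.full(width // 2, f[-1])])
    return np.convolve(padded, kernel, mode="valid")


def _event_runs(fs: np.ndarray, min_force: float, dx: float,
                merge_gap: float = 2.0, min_len: float = 1.0,
                ) -> list[tuple[int, int]]:
    """Contiguous runs with smoothed force >= min_force, nearby runs merged."""
    above = fs >= min_force
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = ([0] if above[0] else []) + [int(e) + 1 for e in edges if above[e + 1]]
    ends = [int(e) for e in edges if above[e]] + ([len(fs) - 1] if above[-1] else [])
    runs = list(zip(starts, ends))
    merged = [runs[0]]
    for s, e in runs[1:]:
        if (s - merged[-1][1]) * dx <= merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if (e - s) * dx >= min_len]


def _windowed_slopes(d: np.ndarray, f: np.ndarray, w: int) -> np.ndarray:
    """Least-squares slope in every length-w sample window (vectorized).

    Returns slopes for windows starting at 0..n-w (inclusive).
    """
    n = len(d)
    ones = np.ones(n)
    cs = lambda a: np.concatenate([[0.0], np.cumsum(a)])
    sx, sy, sxx, sxy, sn = cs(d), cs(f), cs(d * d), cs(d * f), cs(ones)
    i = np.arange(n - w + 1)
    j = i + w
    Sx = sx[j] - sx[i]
    Sy = sy[j] - sy[i]
    Sxx = sxx[j] - sxx[i]
    Sxy = sxy[j] - sxy[i]
    denom = w * Sxx - Sx * Sx
    return (w * Sxy - Sx * Sy) / denom


def classify_signature(curve: FDCurve, min_force: float = 40.0,
                       min_plateau_len: float = 50.0,
                       plateau_slope: float = 0.2,
                       spring_min_slope: float = 0.5,
                       spring_min_r2: float = 0.9,
                       spring_feed_len: float = 20.0,
                       spring_max_feed_slope: float = 10.0) -> FDSignature:
    """Classify the last above-threshold event before return to baseline.

    plateau: a regression slope <= `plateau_slope` pN/nm over windows of
    `min_plateau_len` nm persisting at force >= `min_force`. nanospring: a
    rising segment with linear r^2 >= `spring_min_r2` and slope >=
    `spring_min_slope` pN/nm ending in a sharp drop (>50% of peak within
    10 nm). both: a linear rise of >= `spring_feed_len` nm with slope
    between `spring_min_slope` and `spring_max_feed_slope` feeding a
    qualifying plateau. Multi-event curves are flagged, and only the final
    event is scored.
    """
    d, f = curve.distance, curve.force
    dx = float(np.median(np.diff(d)))
    fs = _smooth(f, int(round(2.0 / dx)))
    runs = _event_runs(fs, min_force, dx)
    if not runs:
        return FDSignature(kind="none", flags=["no event above threshold"])
    flags: list[str] = []
    if len(runs) > 1:
        flags.append(f"{len(runs)} events above threshold; scoring the last")
    start, end = runs[-1]

    # walk the event start backward to where the rise leaves the baseline
    rise_floor = 0.2 * min_force
    while start > 0 and fs[start - 1] > rise_floor:
        start -= 1
    rupture_distance = float(d[end])

    # ---- plateau test -------------------------------------------------
    plateau_window: tuple[int, int] | None = None
    w = max(int(round(min_plateau_len / dx)), 4)
    if end - start + 1 >= w:
        seg_d, seg_f = d[start:end + 1], f[start:end + 1]
        seg_fs = fs[start:end + 1]
        slopes = _windowed_slopes(seg_d, seg_f, w)
        # windowed min of the smoothed force, via a strided view
        from numpy.lib.stride_tricks import sliding_window_view
        win_min = sliding_window_view(seg_fs, w).min(axis=1)
        ok = (np.abs(slopes) <= plateau_slope) & (win_min >= min_force)
        if ok.any():
            # longest contiguous run of qualifying window starts
            idx = np.flatnonzero(ok)
            breaks = np.flatnonzero(np.diff(idx) > 1)
            run_starts = np.concatenate([[0], breaks + 1])
            run_ends = np.concatenate([breaks, [len(idx) - 1]])
            lengths = idx[run_ends] - idx[run_starts]
            best = int(np.argmax(lengths))
            lo = start + int(idx[run_starts[best]])
            hi = start + int(idx[run_ends[best]]) + w - 1
            if d[hi] - d[lo] >= min_plateau_len:
                plateau_window = (lo, hi)

    # ---- nanospring test ---------------------------------------------
    spring_found = False
    spring_r2 = None
    peak_idx = start + int(np.argmax(f[start:end + 1]))
    peak_force = f[peak_idx]
    after = (d > d[peak_idx]) & (d <= d[peak_idx] + 10.0)
    sharp_drop = (bool(np.min(f[after]) < 0.5 * peak_force) if after.any()
                  else peak_idx >= len(f) - 2)
    if peak_idx - start + 1 >= 10 and sharp_drop:
        res = stats.linregress(d[start:peak_idx + 1], f[start:peak_idx + 1])
        spring_r2 = float(res.rvalue ** 2)
        if spring_r2 >= spring_min_r2 and res.slope >= spring_min_slope:
            spring_found = True

    # ---- combine ------------------------------------------------------
    if plateau_window is not None:
        kind = "plateau"
        p_start = plateau_window[0]
        feed_d, feed_f = d[start:p_start + 1], f[start:p_start + 1]
        if (feed_d[-1] - feed_d[0]) >= spring_feed_len and len(feed_d) >= 10:
            res = stats.linregress(feed_d, feed_f)
            if (res.rvalue ** 2 >= spring_min_r2
                    and spring_min_slope <= res.slope <= spring_max_feed_slope):
                kind = "both"
        sig = FDSignature(kind=kind, rupture_distance=rupture_distance,
                          event_window=(start, end), flags=flags)
        sig = _attach_plateau(sig, curve, plateau_window)
        if kind == "both":
            sig = _attach_spring(sig, curve, (start, plateau_window[0]))
        return sig
    if spring_found:
        sig = FDSignature(kind="nanospring", rupture_distance=rupture_distance,
                          fit_r2=spring_r2, event_window=(start, end),
                          flags=flags)
        return _attach_spring(sig, curve, (start, peak_idx))
    return FDSignature(kind="none", rupture_distance=rupture_distance,
                       event_window=(start, end),
                       flags=flags + ["event matched no signature"])


def fit_nanospring(curve: FDCurve, window: tuple[int, int]) -> dict[str, float]:
    """Spring constant and rupture force from a rising segment.

    k_pilus is the least-squares slope between 20% and 95% of the peak
    force; f_adh is the baseline-referenced peak force just before rupture.
    """
    lo, hi = window
    d, f = curve.distance[lo:hi + 1], curve.force[lo:hi + 1]
    peak = float(f.max())
    mask = (f >= 0.20 * peak) & (f <= 0.95 * peak)
    # keep only the contiguous rise up to the first peak crossing
    if mask.sum() < 10:
        raise ValueError("rising segment has fewer than 10 usable samples")
    res = stats.linregress(d[mask], f[mask])
    return {"k_pilus": float(res.slope), "f_adh": peak,
            "r2": float(res.rvalue ** 2)}


def measure_plateau(curve: FDCurve, window: tuple[int, int],
                    min_plateau_len: float = 50.0) -> dict[str, float]:
    """Median force over the flat window plus rupture-edge force."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("degenerate plateau window")
    d, f = curve.distance[lo:hi + 1], curve.force[lo:hi + 1]
    length = float(d[-1] - d[0])
    if length < min_plateau_len:
        raise ValueError(
            f"plateau window {length:.1f} nm shorter than {min_plateau_len} nm")
    return {"plateau_force": float(np.median(f)), "plateau_len": length,
            "f_adh": float(f[-1])}


def _attach_spring(sig: FDSignature, curve: FDCurve,
                   window: tuple[int, int]) -> FDSignature:
    try:
        fit = fit_nanospring(curve, window)
    except ValueError as exc:
        sig.flags.append(f"spring fit skipped: {exc}")
        return sig
    sig.k_pilus = fit["k_pilus"]
    if sig.f_adh is None:
        sig.f_adh = fit["f_adh"]
    sig.fit_r2 = fit["r2"]
    return sig


def _attach_plateau(sig: FDSignature, curve: FDCurve,
                    window: tuple[int, int]) -> FDSignature:
    try:
        res = measure_plateau(curve, window)
    except ValueError as exc:
        sig.flags.append(f"plateau measurement skipped: {exc}")
        return sig
    sig.plateau_force = res["plateau_force"]
    sig.plateau_len = res["plateau_len"]
    sig.f_adh = res["f_adh"]
    return sig


# ---------------------------------------------------------------------------
# TSV I/O: two columns distance_nm, force_pN
# ---------------------------------------------------------------------------

def read_fd_tsv(path, retract_speed: float = 1.0,
                tension_negative: bool = False) -> FDCurve:
    """Read a two-column TSV curve; flip the force sign if the file stores
    tension as negative."""
    data = np.loadtxt(path, delimiter="\t", comments="#", skiprows=0, ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    force = -data[:, 1] if tension_negative else data[:, 1]
    return FDCurve(distance=data[:, 0], force=force,
                   retract_speed=retract_speed, label=Path(path).stem)


def write_fd_tsv(curve: FDCurve, path) -> None:
    with open(path, "w") as handle:
        handle.write("# distance_nm\tforce_pN\n")
        for d, f in zip(curve.distance, curve.force):
            handle.write(f"{d:.4f}\t{f:.4f}\n")
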