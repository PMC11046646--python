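"""Worm-like-chain persistence length from 2D-adsorbed filament contours.

Two estimators are provided: the tangent-correlation decay fit (primary) and
the mean-squared end-to-end distance fit. Both default to the 2D-equilibrium
convention, in which the tangent correlation decays as exp(-s / (2 Lp)); a
3D mode (decay exp(-s / Lp)) exists for projected, non-equilibrated data.

Units: trace coordinates and ds are in nm; persistence lengths in µm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Trace2D",
    "PLEstimate",
    "discretize_trace",
    "tangent_correlation",
    "estimate_pl_tancorr",
    "mean_square_distance",
    "estimate_pl_msd",
    "read_traces_tsv",
    "write_traces_tsv",
]

NM_PER_UM = 1000.0
#: Boltzmann constant times 298 K, in pN nm.
KT_298 = 4.1164


@dataclass
class Trace2D:
    """Ordered 2D filament contour, coordinates in nm."""

    points: np.ndarray
    pixel_size: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if len(self.points) < 3:
            raise ValueError("a trace needs at least 3 points")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive trace points must be distinct")

    @property
    def contour_length(self) -> float:
        """Total arc length in nm."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class PLEstimate:
    lp: float                       # µm; may be inf for straight data
    ci_low: float | None
    ci_high: float | None
    method: str
    s_max_fit: float                # µm
    n_traces: int
    flags: list[str] = field(default_factory=list)

    @property
    def bending_rigidity(self) -> float:
        """B = Lp * kT at 298 K, in pN nm * µm (annotation only)."""
        return self.lp * KT_298


def discretize_trace(raw: Trace2D, ds: float) -> Trace2D:
    """Re-parameterize a contour at uniform arc-length spacing ds (nm).

    Linear interpolation along the polyline; both endpoints are preserved.
    """
    if ds <= 0:
        raise ValueError("ds must be positive")
    contour = raw.contour_length
    if contour < 2 * ds:
        raise ValueError(f"contour {contour:.1f} nm shorter than 2*ds")
    steps = np.linalg.norm(np.diff(raw.points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    n_seg = int(np.floor(contour / ds + 1e-9))
    s_new = np.arange(n_seg + 1) * ds
    if contour - s_new[-1] > 1e-9 * contour:
        s_new = np.append(s_new, contour)
    x = np.interp(s_new, s, raw.points[:, 0])
    y = np.interp(s_new, s, raw.points[:, 1])
    return Trace2D(points=np.column_stack([x, y]),
                   pixel_size=raw.pixel_size, label=raw.label)


def _tangent_angles(trace: Trace2D) -> np.ndarray:
    d = np.diff(trace.points, axis=0)
    return np.arctan2(d[:, 1], d[:, 0])


def tangent_correlation(traces: list[Trace2D], ds: float, m_max: int,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled <cos theta(s)> for s = m*ds, m = 1..m_max.

    Returns (s values in nm, correlations, pair counts). All tangent pairs at
    each separation contribute, pooled across traces.
    """
    sums = np.zeros(m_max)
    counts = np.zeros(m_max)
    for trace in traces:
        theta = _tangent_angles(trace)
        n = len(theta)
        for m in range(1, min(m_max, n - 1) + 1):
            diff = theta[m:] - theta[:-m]
            sums[m - 1] += np.cos(diff).sum()
            counts[m - 1] += n - m
    valid = counts > 0
    s = np.arange(1, m_max + 1) * ds
    corr = np.full(m_max, np.nan)
    corr[valid] = sums[valid] / counts[valid]
    return s[valid], corr[valid], counts[valid]


def _default_s_max(traces: list[Trace2D]) -> float:
    contours = np.array([t.contour_length for t in traces])
    return float(min(contours.min() / 2.0, 2.0 * contours.mean()))


def _fit_log_decay(s: np.ndarray, corr: np.ndarray, weights: np.ndarray,
                   ) -> tuple[float, list[str]]:
    """Weighted least-squares fit of log corr = -s * slope through the origin.

    Returns the decay rate (1/nm, >= 0) and any warnings raised.
    """
    flags: list[str] = []
    nonpos = corr <= 0
    if np.any(nonpos):
        cut = int(np.argmax(nonpos))
        if cut == 0:
            return np.inf, ["all correlations non-positive"]
        s, corr, weights = s[:cut], corr[:cut], weights[:cut]
        flags.append(f"fit range truncated at s={s[-1]:.1f} nm "
                     "(non-positive correlation)")
        warnings.warn(flags[-1], stacklevel=3)
    log_c = np.log(corr)
    denom = np.sum(weights * s * s)
    rate = -np.sum(weights * s * log_c) / denom
    return max(rate, 0.0), flags


def estimate_pl_tancorr(traces: list[Trace2D], ds: float,
                        s_max: float | None = None, mode: str = "2d",
                        n_boot: int = 1000, seed: int = 0) -> PLEstimate:
    """Persistence length from the tangent-correlation decay.

    Fits <cos theta(s)> = exp(-s / (c Lp)) with c = 2 for 2D-equilibrated
    contours (default) or c = 1 for the 3D convention, by weighted
    least squares on the log correlations, weights proportional to pair
    counts. Bootstrap CIs resample whole traces.
    """
    if not traces:
        raise ValueError("no traces")
    factor = {"2d": 2.0, "3d": 1.0}[mode]
    if s_max is None:
        s_max = _default_s_max(traces)
    if s_max < 10 * ds:
        raise ValueError("s_max must be at least 10*ds")
    m_max = int(round(s_max / ds))

    # per-trace sufficient statistics so the bootstrap is cheap
    per_sums = np.zeros((len(traces), m_max))
    per_counts = np.zeros((len(traces), m_max))
    for t_idx, trace in enumerate(traces):
        theta = _tangent_angles(trace)
        n = len(theta)
        for m in range(1, min(m_max, n - 1) + 1):
            per_sums[t_idx, m - 1] = np.cos(theta[m:] - theta[:-m]).sum()
            per_counts[t_idx, m - 1] = n - m

    s = np.arange(1, m_max + 1) * ds

    def lp_from(subset: np.ndarray) -> tuple[float, list[str]]:
        counts = per_counts[subset].sum(axis=0)
        valid = counts > 0
        corr = per_sums[subset].sum(axis=0)[valid] / counts[valid]
        rate, fl = _fit_log_decay(s[valid], corr, counts[valid])
        if rate == 0.0:
            return np.inf, fl + ["zero decay rate: straight traces"]
        return 1.0 / (factor * rate) / NM_PER_UM, fl

    all_idx = np.arange(len(traces))
    lp, flags = lp_from(all_idx)
    ci_low = ci_high = None
    if len(traces) < 3:
        flags.append("fewer than 3 traces: no bootstrap CI")
    elif n_boot > 0 and np.isfinite(lp):
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for b in range(n_boot):
                boot[b] = lp_from(rng.integers(0, len(traces), len(traces)))[0]
        finite = boot[np.isfinite(boot)]
        if len(finite) >= max(10, n_boot // 2):
            ci_low, ci_high = (float(np.percentile(finite, 2.5)),
                               float(np.percentile(finite, 97.5)))
    if not np.isfinite(lp):
        flags.append("lp is +inf sentinel (no measurable decay)")
    return PLEstimate(lp=float(lp), ci_low=ci_low, ci_high=ci_high,
                      method="tancorr", s_max_fit=s_max / NM_PER_UM,
                      n_traces=len(traces), flags=flags)


def wlc_msd_2d(s: np.ndarray, lp: float) -> np.ndarray:
    """2D worm-like-chain mean-squared end-to-end distance (nm units)."""
    # expm1 keeps the rigid limit (s << lp, where the bracket cancels to
    # s^2/(4 lp)) numerically exact
    return 4.0 * lp * (s + 2.0 * lp * np.expm1(-s / (2.0 * lp)))


def mean_square_distance(traces: list[Trace2D], ds: float, m_max: int,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled <R^2(s)> over all point pairs separated by arc length s."""
    sums = np.zeros(m_max)
    counts = np.zeros(m_max)
    for trace in traces:
        pts = trace.points
        n = len(pts)
        for m in range(1, min(m_max, n - 1) + 1):
            d = pts[m:] - pts[:-m]
            sums[m - 1] += np.einsum("ij,ij->", d, d)
            counts[m - 1] += n - m
    valid = counts > 0
    s = np.arange(1, m_max + 1) * ds
    msd = np.full(m_max, np.nan)
    msd[valid] = sums[valid] / counts[valid]
    return s[valid], msd[valid], counts[valid]


def estimate_pl_msd(traces: list[Trace2D], ds: float,
                    s_max: float | None = None,
                    n_boot: int = 1000, seed: int = 0) -> PLEstimate:
    """Persistence length from <R^2(s)> fitted to the 2D worm-like-chain form.

    Nonlinear least squares of <R^2(s)> = 4 Lp [s - 2 Lp (1 - e^{-s/2Lp})].
    Straight traces (R^2 = s^2 exactly) yield the +inf sentinel.
    """
    if not traces:
        raise ValueError("no traces")
    if s_max is None:
        s_max = _default_s_max(traces)
    if s_max < 10 * ds:
        raise ValueError("s_max must be at least 10*ds")
    m_max = int(round(s_max / ds))

    def fit(subset: list[Trace2D]) -> float:
        s, msd, counts = mean_square_distance(subset, ds, m_max)
        if np.allclose(msd, s * s, rtol=1e-9):
            return np.inf
        sigma = 1.0 / np.sqrt(counts)
        try:
            popt, _ = curve_fit(wlc_msd_2d, s, msd, p0=[s[-1]],
                                sigma=sigma, maxfev=10000,
                                bounds=(1e-6, np.inf))
        except RuntimeError as exc:
            raise RuntimeError(f"MSD fit failed to converge: {exc}") from exc
        return float(popt[0]) / NM_PER_UM

    lp = fit(traces)
    flags: list[str] = []
    ci_low = ci_high = None
    if len(traces) < 3:
        flags.append("fewer than 3 traces: no bootstrap CI")
    elif n_boot > 0 and np.isfinite(lp):
        rng = np.random.default_rng(seed)
        boot = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(traces), len(traces))
            try:
                boot.append(fit([traces[i] for i in idx]))
            except RuntimeError:
                continue
        finite = np.array([b for b in boot if np.isfinite(b)])
        if len(finite) >= max(10, n_boot // 2):
            ci_low, ci_high = (float(np.percentile(finite, 2.5)),
                               float(np.percentile(finite, 97.5)))
    if not np.isfinite(lp):
        flags.append("lp is +inf sentinel (rigid-limit data)")
    return PLEstimate(lp=float(lp), ci_low=ci_low, ci_high=ci_high,
                      method="msd", s_max_fit=s_max / NM_PER_UM,
                      n_traces=len(traces), flags=flags)


# ---------------------------------------------------------------------------
# TSV I/O: one filament per block, "# id" header then x_nm<TAB>y_nm rows
# ---------------------------------------------------------------------------

def read_traces_tsv(path) -> list[Trace2D]:
    traces: list[Trace2D] = []
    label = ""
    points: list[list[float]] = []

    def flush() -> None:
        nonlocal points
        if points:
            traces.append(Trace2D(points=np.array(points), label=label))
            points = []

    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                flush()
                label = line.lstrip("#").strip()
                continue
            if line.lower().startswith(("x_nm", "x\t")):
                continue
            fields = line.split("\t")
            points.append([float(fields[0]), float(fields[1])])
    flush()
    if not traces:
        raise ValueError(f"no traces found in {path}")
    return traces


def write_traces_tsv(traces: list[Trace2D], path) -> None:
    with open(path, "w") as handle:
        for i, trace in enumerate(traces):
            handle.write(f"# {trace.label or f'trace_{i}'}\n")
            for x, y in trace.points:
                handle.write(f"{x:.6f}\t{y:.6f}\n")
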