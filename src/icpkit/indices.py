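"""Per-segment monitoring indices from uniformly sampled neuromonitoring trends.

The five quantities computed here are the standard multimodal-monitoring
summaries used in neurocritical care:

* mean ICP — arithmetic mean of the intracranial pressure trend (mmHg);
* CPP — cerebral perfusion pressure, the mean of MAP − ICP (mmHg);
* PRx — pressure reactivity index, a moving Pearson correlation between the
  MAP and ICP trends (negative/near-zero with intact cerebrovascular
  reactivity, positive when reactivity is impaired);
* RAP — compensatory-reserve index, the moving correlation between the ICP
  pulse amplitude (AMP) and mean ICP (≈0 good reserve, ≈1 on the steep part
  of the pressure–volume curve, <0 when compensation is exhausted);
* DICP — pressure-time dose, the area of the ICP trend above a treatment
  threshold (20 mmHg by default), in mmHg·h.

All indices are computed on non-overlapping 1-hour segments of the trend and
then aggregated to patient level. CPPopt (the CPP minimising PRx) is
estimated from a quadratic fit to PRx binned by CPP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TrendSeries",
    "Segment",
    "HourlyIndices",
    "PatientIndices",
    "IndexParams",
    "CPPOptResult",
    "ChannelMissingError",
    "AllSegmentsUndefinedError",
    "segment",
    "mean_icp",
    "cpp",
    "prx",
    "rap",
    "dicp",
    "sliding_correlations",
    "compute_hourly",
    "aggregate_patient",
    "cppopt",
]


class ChannelMissingError(ValueError):
    """A required channel (MAP or AMP) is absent from the series."""


class AllSegmentsUndefinedError(ValueError):
    """Every segment of a patient failed the validity requirements."""


@dataclass
class TrendSeries:
    """One patient's uniformly sampled trend channels.

    Channels are mmHg; ``valid`` flags samples usable for analysis (dropouts
    and artifacts are flagged invalid rather than deleted, so segmentation
    stays index-based). ``amp`` (ICP pulse amplitude) may be absent, in which
    case RAP is unavailable.
    """

    sample_interval_s: float
    icp: np.ndarray
    map: Optional[np.ndarray] = None
    amp: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be positive")
        self.icp = np.asarray(self.icp, dtype=float)
        n = self.icp.shape[0]
        for name in ("map", "amp"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if ch.shape[0] != n:
                    raise ValueError(
                        f"channel '{name}' has length {ch.shape[0]}, expected {n}"
                    )
                setattr(self, name, ch)
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape[0] != n:
                raise ValueError("valid flag length does not match channels")

    def __len__(self) -> int:
        return int(self.icp.shape[0])

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) * self.sample_interval_s

    @property
    def duration_hours(self) -> float:
        return len(self) * self.sample_interval_s / 3600.0

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if len(self) else 0.0

    def slice(self, start: int, stop: int) -> "TrendSeries":
        return TrendSeries(
            sample_interval_s=self.sample_interval_s,
            icp=self.icp[start:stop],
            map=None if self.map is None else self.map[start:stop],
            amp=None if self.amp is None else self.amp[start:stop],
            valid=self.valid[start:stop],
            t0=self.t0 + start * self.sample_interval_s,
        )


@dataclass
class Segment:
    """A windowed view of a TrendSeries (one analysis segment)."""

    series: TrendSeries
    index: int
    partial: bool = False

    @property
    def valid_fraction(self) -> float:
        return self.series.valid_fraction

    def __len__(self) -> int:
        return len(self.series)


@dataclass
class HourlyIndices:
    """Index values for one analysis segment; ``None`` marks undefined."""

    segment_index: int
    mean_icp: Optional[float]
    mean_cpp: Optional[float]
    prx: Optional[float]
    rap: Optional[float]
    dicp: Optional[float]
    valid_fraction: float
    partial: bool = False


@dataclass
class PatientIndices:
    """Patient-level aggregation: means over defined segments, DICP total."""

    mean_icp: Optional[float]
    mean_cpp: Optional[float]
    mean_prx: Optional[float]
    mean_rap: Optional[float]
    total_dicp: float
    n_segments: int


@dataclass
class IndexParams:
    """Tunable parameters of the index engine.

    Windowing defaults follow neuromonitoring convention (5-min sliding
    window stepped by 1 min for PRx; 4-min for RAP), applied directly to the
    3-s trend samples. ``window_s = 3600`` recovers a single correlation per
    hour. Validity minima gate segments (0.5) and correlation windows (0.75).
    """

    dicp_threshold: float = 20.0
    prx_window_s: float = 300.0
    prx_step_s: float = 60.0
    rap_window_s: float = 240.0
    rap_step_s: float = 60.0
    min_valid_fraction: float = 0.5
    window_min_valid: float = 0.75
    segment_hours: float = 1.0
    cppopt_bin_width: float = 5.0
    cppopt_min_bins: int = 4
    cppopt_min_per_bin: int = 2


def _as_series(seg) -> TrendSeries:
    return seg.series if isinstance(seg, Segment) else seg


def segment(series: TrendSeries, segment_hours: float = 1.0) -> list[Segment]:
    """Split a series into consecutive non-overlapping segments.

    A trailing partial segment is kept and flagged ``partial``.
    """
    if len(series) == 0:
        raise ValueError("cannot segment an empty series")
    if segment_hours <= 0:
        raise ValueError("segment_hours must be positive")
    n_per = int(math.floor(3600.0 * segment_hours / series.sample_interval_s))
    if n_per < 1:
        raise ValueError("segment shorter than one sample")
    out: list[Segment] = []
    n = len(series)
    for k, start in enumerate(range(0, n, n_per)):
        stop = min(start + n_per, n)
        out.append(Segment(series.slice(start, stop), index=k, partial=(stop - start) < n_per))
    return out


def mean_icp(seg, min_valid_fraction: float = 0.5) -> Optional[float]:
    """Mean ICP over valid samples; ``None`` below the validity threshold."""
    s = _as_series(seg)
    if s.valid_fraction < min_valid_fraction or not s.valid.any():
        return None
    return float(s.icp[s.valid].mean())


def cpp(seg, min_valid_fraction: float = 0.5) -> Optional[float]:
    """Mean cerebral perfusion pressure, MAP − ICP, over valid samples."""
    s = _as_series(seg)
    if s.map is None:
        raise ChannelMissingError("MAP channel is required to compute CPP")
    if s.valid_fraction < min_valid_fraction or not s.valid.any():
        return None
    return float((s.map[s.valid] - s.icp[s.valid]).mean())


def sliding_correlations(
    x: np.ndarray,
    y: np.ndarray,
    valid: np.ndarray,
    window_samples: int,
    step_samples: int,
    min_valid: float = 0.75,
) -> np.ndarray:
    """Pearson correlations of (x, y) over sliding windows of valid samples.

    Windows with fewer than ``min_valid`` of their samples valid (or fewer
    than 3 valid samples), or with zero variance in either channel, are
    skipped — zero variance carries no information about coupling, so no
    value is reported rather than 0. Returns the qualifying correlations.
    """
    n = len(x)
    if window_samples < 3:
        raise ValueError("correlation window must contain at least 3 samples")
    if step_samples < 1:
        raise ValueError("step must be at least one sample")
    if n < window_samples:
        return np.empty(0)
    starts = np.arange(0, n - window_samples + 1, step_samples)
    xw = sliding_window_view(np.asarray(x, float), window_samples)[starts]
    yw = sliding_window_view(np.asarray(y, float), window_samples)[starts]
    m = sliding_window_view(np.asarray(valid, bool), window_samples)[starts].astype(float)
    c = m.sum(axis=1)
    enough = c >= max(min_valid * window_samples, 3.0)
    c_safe = np.where(c > 0, c, 1.0)
    mx = (xw * m).sum(axis=1) / c_safe
    my = (yw * m).sum(axis=1) / c_safe
    dx = (xw - mx[:, None]) * m
    dy = (yw - my[:, None]) * m
    cov = (dx * dy).sum(axis=1)
    vx = (dx * dx).sum(axis=1)
    vy = (dy * dy).sum(axis=1)
    # Relative floor distinguishes true zero variance from rounding residue.
    tol_x = c_safe * (1e-9 * (1.0 + np.abs(mx))) ** 2
    tol_y = c_safe * (1e-9 * (1.0 + np.abs(my))) ** 2
    defined = enough & (vx > tol_x) & (vy > tol_y)
    if not defined.any():
        return np.empty(0)
    r = cov[defined] / np.sqrt(vx[defined] * vy[defined])
    return np.clip(r, -1.0, 1.0)


def _window_samples(window_s: float, step_s: float, dt: float) -> tuple[int, int]:
    w = int(round(window_s / dt))
    s = max(int(round(step_s / dt)), 1)
    return w, s


def prx(
    seg,
    window_s: float = 300.0,
    step_s: float = 60.0,
    window_min_valid: float = 0.75,
) -> Optional[float]:
    """Pressure reactivity index of a segment.

    Mean of the Pearson correlations between MAP and ICP over sliding
    windows (5 min stepped by 1 min by default); ``None`` if no window
    qualifies.
    """
    s = _as_series(seg)
    if s.map is None:
        raise ChannelMissingError("MAP channel is required to compute PRx")
    w, st = _window_samples(window_s, step_s, s.sample_interval_s)
    r = sliding_correlations(s.map, s.icp, s.valid, w, st, window_min_valid)
    return float(r.mean()) if r.size else None


def rap(
    seg,
    window_s: float = 240.0,
    step_s: float = 60.0,
    window_min_valid: float = 0.75,
) -> Optional[float]:
    """Compensatory-reserve index: sliding AMP–ICP correlation of a segment."""
    s = _as_series(seg)
    if s.amp is None:
        raise ChannelMissingError(
            "RAP unavailable: the series has no ICP pulse-amplitude (AMP) channel"
        )
    w, st = _window_samples(window_s, step_s, s.sample_interval_s)
    r = sliding_correlations(s.amp, s.icp, s.valid, w, st, window_min_valid)
    return float(r.mean()) if r.size else None


def dicp(seg, threshold: float = 20.0) -> float:
    """Pressure-time dose: area of ICP above ``threshold``, in mmHg·h.

    Each valid sample represents its own sampling interval, so the dose is
    dt·Σ max(0, ICP − threshold) over valid samples. Within a run of
    consecutive valid samples this equals trapezoidal integration of the
    supra-threshold excess plus a half-interval constant extension at the run
    ends; runs broken by invalid samples are integrated separately with no
    bridging across the gap. The rule is exactly additive over any partition
    of the samples and monotone non-increasing in the threshold.
    """
    s = _as_series(seg)
    if len(s) == 0:
        raise ValueError("cannot integrate an empty segment")
    excess = np.clip(s.icp[s.valid] - threshold, 0.0, None)
    return float(excess.sum() * s.sample_interval_s / 3600.0)


def compute_hourly(series: TrendSeries, params: Optional[IndexParams] = None) -> list[HourlyIndices]:
    """All five indices for every segment of a series."""
    p = params or IndexParams()
    out = []
    for seg in segment(series, p.segment_hours):
        vf = seg.valid_fraction
        out.append(
            HourlyIndices(
                segment_index=seg.index,
                mean_icp=mean_icp(seg, p.min_valid_fraction),
                mean_cpp=cpp(seg, p.min_valid_fraction),
                prx=prx(seg, p.prx_window_s, p.prx_step_s, p.window_min_valid),
                rap=rap(seg, p.rap_window_s, p.rap_step_s, p.window_min_valid),
                dicp=dicp(seg, p.dicp_threshold),
                valid_fraction=vf,
                partial=seg.partial,
            )
        )
    return out


def aggregate_patient(hourly: Sequence[HourlyIndices]) -> PatientIndices:
    """Aggregate segment indices to patient level.

    Means are taken over the segments where the given index is defined; DICP
    is the monitoring-period total (sum of segment integrals — a partial
    segment contributes exactly its own area, no reweighting). Raises
    :class:`AllSegmentsUndefinedError` if no segment defines any index, so
    the caller can exclude the patient with a logged reason.
    """
    if not hourly:
        raise ValueError("need at least one segment")

    def _mean(vals: list[float]) -> Optional[float]:
        return float(np.mean(vals)) if vals else None

    icps = [h.mean_icp for h in hourly if h.mean_icp is not None]
    cpps = [h.mean_cpp for h in hourly if h.mean_cpp is not None]
    prxs = [h.prx for h in hourly if h.prx is not None]
    raps = [h.rap for h in hourly if h.rap is not None]
    doses = [h.dicp for h in hourly if h.dicp is not None]
    contributing = [
        h
        for h in hourly
        if any(v is not None for v in (h.mean_icp, h.mean_cpp, h.prx, h.rap, h.dicp))
    ]
    if not icps and not cpps and not prxs and not raps:
        raise AllSegmentsUndefinedError(
            "all segments below the validity threshold; patient excluded"
        )
    return PatientIndices(
        mean_icp=_mean(icps),
        mean_cpp=_mean(cpps),
        mean_prx=_mean(prxs),
        mean_rap=_mean(raps),
        total_dicp=float(np.sum(doses)) if doses else 0.0,
        n_segments=len(contributing),
    )


@dataclass
class CPPOptResult:
    """Outcome of a CPPopt estimate; ``value`` is None when undefined."""

    value: Optional[float]
    reason: Optional[str] = None
    bin_centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    bin_prx: np.ndarray = field(default_factory=lambda: np.empty(0))
    coefficients: Optional[np.ndarray] = None


def cppopt(
    hourly: Sequence[HourlyIndices],
    bin_width: float = 5.0,
    min_bins: int = 4,
    min_per_bin: int = 2,
) -> CPPOptResult:
    """Optimal CPP from the PRx–CPP relation.

    Segments are binned by mean CPP; a quadratic is fitted to (bin centre,
    mean PRx). The vertex abscissa is returned when the parabola opens
    upward and the vertex lies inside the observed CPP range; otherwise the
    estimate is undefined with a reason code (``insufficient_bins``,
    ``non_convex`` or ``vertex_out_of_range``).
    """
    pts = [
        (h.mean_cpp, h.prx)
        for h in hourly
        if h.mean_cpp is not None and h.prx is not None
    ]
    if not pts:
        return CPPOptResult(None, "insufficient_bins")
    cpps = np.array([p[0] for p in pts])
    prxs = np.array([p[1] for p in pts])
    bins = np.floor(cpps / bin_width).astype(int)
    centers, means = [], []
    for b in np.unique(bins):
        mask = bins == b
        if mask.sum() >= min_per_bin:
            centers.append((b + 0.5) * bin_width)
            means.append(prxs[mask].mean())
    centers_a, means_a = np.array(centers), np.array(means)
    if len(centers_a) < min_bins:
        return CPPOptResult(None, "insufficient_bins", centers_a, means_a)
    coeffs = np.polyfit(centers_a, means_a, 2)
    if coeffs[0] <= 0:
        return CPPOptResult(None, "non_convex", centers_a, means_a, coeffs)
    vertex = -coeffs[1] / (2.0 * coeffs[0])
    lo, hi = float(cpps.min()), float(cpps.max())
    if not (lo <= vertex <= hi):
        return CPPOptResult(None, "vertex_out_of_range", centers_a, means_a, coeffs)
    return CPPOptResult(float(vertex), None, centers_a, means_a, coeffs)
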