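"""Sniffer-method processing of 1-Hz breath-gas traces.

During each visit to the automatic milking system (AMS), air sampled at
the feed bin carries a mixture of barn background and the cow's breath.
This module converts a raw 1-Hz CH4/CO2 concentration trace into the
quantities the prediction workflow consumes:

* a background estimate from a 5-min window before or after milking,
* background-corrected per-second concentrations with a head-position
  filter (a second is kept only if its CO2 excess over background
  reaches 500 ppm, the signature of breath actually hitting the inlet),
* the per-visit CH4/CO2 ratio, computed as ratio of the corrected
  means (not the mean of per-second ratios),
* an eructation rate — belch peaks per minute in the per-second ratio
  series — detected with :func:`scipy.signal.find_peaks`,
* the time elapsed since the cow's last eating bout, read from 10-min
  dominant-activity logs, and
* the model-based adjustment of a measured ratio back to 0 h after
  eating.

Concentrations are handled in ppm throughout (1 % = 10,000 ppm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

if TYPE_CHECKING:  # pragma: no cover
    from .models import MixedFit

__all__ = [
    "GasTrace",
    "Background",
    "CorrectedSeries",
    "VisitSummary",
    "ActivityLog",
    "InvalidBackgroundError",
    "InvalidVisitError",
    "MissingCovariateError",
    "estimate_background",
    "correct_and_filter",
    "visit_ratio",
    "eructation_rate",
    "time_after_eating",
    "adjust_ratio_to_zero",
    "summarize_visit",
    "read_trace_csv",
    "read_activity_csv",
]

PPM_PER_PERCENT = 10_000.0

#: Default CO2-excess threshold (ppm) below which a second is discarded
#: as "head away from the feed bin".
DEFAULT_CO2_THRESHOLD_PPM = 500.0

#: Default background-window length (s): 5 minutes.
DEFAULT_BACKGROUND_S = 300

#: Minimum usable background window (s).
MIN_BACKGROUND_S = 60

#: Minimum retained seconds for a visit ratio to be considered valid.
DEFAULT_MIN_RETAINED_S = 60

#: Minimum spacing between detected eructation peaks (s).
DEFAULT_PEAK_DISTANCE_S = 10


class InvalidBackgroundError(ValueError):
    """Background window too short to average."""


class InvalidVisitError(ValueError):
    """Visit has too few retained seconds (or is too short) to summarize."""


class MissingCovariateError(ValueError):
    """No eating bout precedes the visit, so time-after-eating is undefined."""


@dataclass
class GasTrace:
    """A gap-free 1-Hz CH4/CO2 concentration series.

    ``t`` is seconds since the start of the visit or measurement and
    must advance by exactly 1 s. ``flow`` (L/min at 0 degC, 1 atm) is
    present for head-box traces only.
    """

    source: str  # "AMS" | "headbox"
    t: np.ndarray
    ch4: np.ndarray  # ppm
    co2: np.ndarray  # ppm
    flow: np.ndarray | None = None  # L/min, headbox only

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ch4 = np.asarray(self.ch4, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        if self.source not in ("AMS", "headbox"):
            raise ValueError(f"unknown trace source {self.source!r}")
        n = len(self.t)
        if len(self.ch4) != n or len(self.co2) != n:
            raise ValueError("t, ch4 and co2 must have equal length")
        if n > 1 and not np.allclose(np.diff(self.t), 1.0):
            raise ValueError("trace must be 1-Hz and gap-free (t strictly +1 s)")
        if np.any(self.ch4 < 0) or np.any(self.co2 < 0):
            raise ValueError("concentrations must be non-negative")
        if self.flow is not None:
            self.flow = np.asarray(self.flow, dtype=float)
            if len(self.flow) != n:
                raise ValueError("flow must match trace length")
            if np.any(self.flow <= 0):
                raise ValueError("flow must be positive")
        elif self.source == "headbox":
            raise ValueError("head-box traces require a flow series")

    @property
    def duration_s(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class Background:
    """Background (barn air) concentrations, ppm."""

    ch4: float
    co2: float


@dataclass
class CorrectedSeries:
    """Background-corrected, head-position-filtered seconds of a visit."""

    t: np.ndarray
    ch4: np.ndarray  # ppm above background, clipped at 0
    co2: np.ndarray  # ppm above background (>= threshold by construction)

    @property
    def n_retained(self) -> int:
        return len(self.t)

    def ratio_series(self) -> np.ndarray:
        """Per-second CH4/CO2 ratio over retained seconds (gaps bridged)."""
        return self.ch4 / self.co2


@dataclass
class VisitSummary:
    """Per-visit sniffer outputs."""

    visit_id: str
    cow_id: str
    start_time: pd.Timestamp | None
    duration: int  # s
    bg_ch4: float
    bg_co2: float
    mean_ch4_corr: float | None
    mean_co2_corr: float | None
    ratio: float | None
    n_retained: int
    eructation_rate: float | None  # peaks/min
    time_after_eating: float | None  # h
    valid: bool
    diet: str = "other"


@dataclass
class ActivityLog:
    """10-min dominant-activity bins for one cow.

    ``bins`` has columns ``bin_start`` (Timestamp) and ``activity``
    (eating, ruminating, moving, standing, lying); bins are sorted and
    non-overlapping.
    """

    bins: pd.DataFrame
    bin_minutes: int = 10

    ACTIVITIES = ("eating", "ruminating", "moving", "standing", "lying")

    def __post_init__(self) -> None:
        df = self.bins
        if not {"bin_start", "activity"} <= set(df.columns):
            raise ValueError("activity log needs bin_start and activity columns")
        df = df.copy()
        df["bin_start"] = pd.to_datetime(df["bin_start"])
        df = df.sort_values("bin_start").reset_index(drop=True)
        starts = df["bin_start"].to_numpy()
        if len(starts) > 1:
            gaps = np.diff(starts).astype("timedelta64[s]").astype(float)
            if np.any(gaps < self.bin_minutes * 60):
                raise ValueError("activity bins overlap")
        bad = set(df["activity"]) - set(self.ACTIVITIES)
        if bad:
            raise ValueError(f"unknown activities {sorted(bad)}")
        self.bins = df


def dominant_activity(seconds_by_activity: Mapping[str, float]) -> str:
    """Pick the dominant activity of a 10-min bin.

    Ties are broken in favour of eating (conservative: it shortens the
    time-after-eating covariate), then by the fixed activity order.
    """
    best = max(
        seconds_by_activity.items(),
        key=lambda kv: (kv[1], kv[0] == "eating", -ActivityLog.ACTIVITIES.index(kv[0])),
    )
    return best[0]


def estimate_background(
    trace: GasTrace,
    window: str = "pre",
    length_s: int = DEFAULT_BACKGROUND_S,
) -> Background:
    """Average CH4 and CO2 over a 5-min window of cow-free air.

    ``window='pre'`` uses the first ``length_s`` seconds of the trace,
    ``'post'`` the last. The window is truncated to the trace but must
    contain at least 60 s.
    """
    if window not in ("pre", "post"):
        raise ValueError("window must be 'pre' or 'post'")
    n = min(length_s, trace.duration_s)
    if n < MIN_BACKGROUND_S:
        raise InvalidBackgroundError(
            f"background window of {n} s is shorter than {MIN_BACKGROUND_S} s"
        )
    sl = slice(0, n) if window == "pre" else slice(-n, None)
    return Background(ch4=float(trace.ch4[sl].mean()), co2=float(trace.co2[sl].mean()))


def combine_backgrounds(pre: Background | None, post: Background | None) -> Background:
    """Combine pre- and post-visit backgrounds: average both when
    available, otherwise use whichever exists."""
    if pre is not None and post is not None:
        return Background(ch4=(pre.ch4 + post.ch4) / 2.0, co2=(pre.co2 + post.co2) / 2.0)
    bg = pre if pre is not None else post
    if bg is None:
        raise InvalidBackgroundError("no background window available")
    return bg


def correct_and_filter(
    trace: GasTrace,
    bg: Background,
    co2_threshold: float = DEFAULT_CO2_THRESHOLD_PPM,
) -> CorrectedSeries:
    """Background-correct a trace and drop head-away seconds.

    Second *i* is retained iff ``co2[i] - bg.co2 >= co2_threshold``;
    retained values are the background-corrected excesses, with CH4
    clipped at zero (analyzer noise can dip below background).
    """
    if not (np.isfinite(bg.ch4) and np.isfinite(bg.co2)):
        raise ValueError("background must be finite")
    co2_excess = trace.co2 - bg.co2
    keep = co2_excess >= co2_threshold
    ch4_corr = np.clip(trace.ch4[keep] - bg.ch4, 0.0, None)
    return CorrectedSeries(t=trace.t[keep], ch4=ch4_corr, co2=co2_excess[keep])


def visit_ratio(
    corrected: CorrectedSeries,
    min_retained: int = DEFAULT_MIN_RETAINED_S,
    mean_of_ratios: bool = False,
) -> tuple[float, float, float]:
    """Per-visit corrected means and CH4/CO2 ratio.

    The default (and recommended) estimator averages CH4 and CO2 over
    the retained seconds and then takes the ratio of the means; the
    mean of per-second ratios is available for sensitivity analysis.
    """
    n = corrected.n_retained
    if n < min_retained:
        raise InvalidVisitError(f"only {n} retained seconds (< {min_retained})")
    mean_ch4 = float(corrected.ch4.mean())
    mean_co2 = float(corrected.co2.mean())
    if mean_of_ratios:
        ratio = float(corrected.ratio_series().mean())
    else:
        ratio = mean_ch4 / mean_co2
    return mean_ch4, mean_co2, ratio


def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD of a series from the median absolute successive
    difference (insensitive to sparse spikes)."""
    if len(x) < 3:
        return 0.0
    d = np.diff(x)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def eructation_rate(
    ratio_series: np.ndarray,
    duration_s: float,
    min_distance_s: int = DEFAULT_PEAK_DISTANCE_S,
    prominence: float | None = None,
) -> float:
    """Eructation (belch) peaks per minute in a per-second ratio series.

    A peak is a local maximum whose prominence reaches
    ``max(0.25 x median of the positive ratios, 3 x robust noise SD)``
    (both overridable via ``prominence``), with peaks at least
    ``min_distance_s`` apart — belches are brief CH4 bursts riding on
    the breath baseline, physiologically spaced by tens of seconds.
    The count is scaled by 60/duration to a per-minute rate.
    """
    ratio_series = np.asarray(ratio_series, dtype=float)
    if duration_s < 60:
        raise InvalidVisitError(f"visit of {duration_s} s too short for a rate (< 60 s)")
    if len(ratio_series) < 3:
        return 0.0
    if prominence is None:
        positive = ratio_series[ratio_series > 0]
        med = float(np.median(positive)) if len(positive) else 0.0
        prominence = max(0.25 * med, 3.0 * _robust_noise_sd(ratio_series))
        if prominence <= 0:
            return 0.0
    peaks, _ = find_peaks(ratio_series, prominence=prominence, distance=min_distance_s)
    return len(peaks) * 60.0 / float(duration_s)


def time_after_eating(log: ActivityLog, visit_start) -> float:
    """Hours from the end of the last eating bout to ``visit_start``.

    The eating bout ends when its last 10-min eating bin ends; only
    bins ending at or before the visit start count. Raises
    :class:`MissingCovariateError` when no eating precedes the visit.
    """
    visit_start = pd.Timestamp(visit_start)
    eat = log.bins[log.bins["activity"] == "eating"]
    if eat.empty:
        raise MissingCovariateError("no eating bout in activity log")
    bin_len = pd.Timedelta(minutes=log.bin_minutes)
    ends = eat["bin_start"] + bin_len
    prior = ends[ends <= visit_start]
    if prior.empty:
        raise MissingCovariateError("no eating bout before visit start")
    dt_h = (visit_start - prior.iloc[-1]).total_seconds() / 3600.0
    return max(dt_h, 0.0)


def adjust_ratio_to_zero(ratio: float, t: float, diet: str, fit: "MixedFit") -> float:
    """Adjust a measured CH4/CO2 ratio to 0 h after eating.

    Subtracts the fitted linear time trend (common slope plus the
    diet-specific interaction) times the observed interval, i.e. the
    model prediction at t = 0 holding everything else at its observed
    value. The measured ratio declines with time after eating, so the
    adjusted ratio is typically larger.
    """
    slope = fit.time_slope(diet)
    return ratio - slope * t


def summarize_visit(
    trace: GasTrace,
    bg: Background,
    visit_id: str = "",
    cow_id: str = "",
    start_time=None,
    diet: str = "other",
    activity_log: ActivityLog | None = None,
    co2_threshold: float = DEFAULT_CO2_THRESHOLD_PPM,
    min_retained: int = DEFAULT_MIN_RETAINED_S,
    peak_distance_s: int = DEFAULT_PEAK_DISTANCE_S,
    peak_prominence: float | None = None,
) -> VisitSummary:
    """Run the full per-visit chain: correct, filter, ratio, belch rate,
    time-after-eating. Invalid visits come back flagged, not raised."""
    corrected = correct_and_filter(trace, bg, co2_threshold)
    mean_ch4 = mean_co2 = ratio = rate = None
    valid = True
    try:
        mean_ch4, mean_co2, ratio = visit_ratio(corrected, min_retained)
        # the ratio series exists only on retained seconds, so the rate
        # denominator is retained time, not wall-clock visit length
        rate = eructation_rate(
            corrected.ratio_series(),
            corrected.n_retained,
            min_distance_s=peak_distance_s,
            prominence=peak_prominence,
        )
    except InvalidVisitError:
        valid = False
    tae = None
    if activity_log is not None and start_time is not None:
        try:
            tae = time_after_eating(activity_log, start_time)
        except MissingCovariateError:
            tae = None
    return VisitSummary(
        visit_id=visit_id,
        cow_id=cow_id,
        start_time=None if start_time is None else pd.Timestamp(start_time),
        duration=trace.duration_s,
        bg_ch4=bg.ch4,
        bg_co2=bg.co2,
        mean_ch4_corr=mean_ch4,
        mean_co2_corr=mean_co2,
        ratio=ratio,
        n_retained=corrected.n_retained,
        eructation_rate=rate,
        time_after_eating=tae,
        valid=valid,
        diet=diet,
    )


def visits_to_frame(visits: Iterable[VisitSummary]) -> pd.DataFrame:
    """Tabulate visit summaries (one row per visit)."""
    rows = [vars(v).copy() for v in visits]
    return pd.DataFrame(rows)


def read_trace_csv(path, source: str = "AMS") -> GasTrace:
    """Read one trace CSV with columns time_s, ch4_ppm, co2_ppm
    [, flow_lpm]. Percent columns (ch4_pct/co2_pct) are converted."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "ch4_ppm" in cols:
        ch4 = df[cols["ch4_ppm"]].to_numpy(float)
    elif "ch4_pct" in cols:
        ch4 = df[cols["ch4_pct"]].to_numpy(float) * PPM_PER_PERCENT
    else:
        raise ValueError("trace CSV needs a ch4_ppm (or ch4_pct) column")
    if "co2_ppm" in cols:
        co2 = df[cols["co2_ppm"]].to_numpy(float)
    elif "co2_pct" in cols:
        co2 = df[cols["co2_pct"]].to_numpy(float) * PPM_PER_PERCENT
    else:
        raise ValueError("trace CSV needs a co2_ppm (or co2_pct) column")
    if "time_s" not in cols:
        raise ValueError("trace CSV needs a time_s column")
    flow = df[cols["flow_lpm"]].to_numpy(float) if "flow_lpm" in cols else None
    return GasTrace(source=source, t=df[cols["time_s"]].to_numpy(float), ch4=ch4, co2=co2, flow=flow)


def read_activity_csv(path) -> ActivityLog:
    """Read an activity log CSV with columns bin_start (ISO-8601),
    activity."""
    return ActivityLog(bins=pd.read_csv(path))
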