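"""Automated molecule classification and gyrase burst analysis.

The pipeline turns raw tracks into annotated molecule records by
replaying the experiment protocol:

1. *Mobility / attachment* — during the flow-reversal phase the bead
   swings between two extreme positions; their midpoint is the DNA
   attachment site, and the swing amplitude separates tethered beads
   from beads stuck to the surface.
2. *Coilability and tether multiplicity* — magnet-rotation series at
   high force.  Single, intact tethers compact only when overwound
   (underwound DNA melts at high force); nicked tethers ignore turns;
   multiply-tethered beads compact for both rotation directions.
3. *Force* — variance of bead position orthogonal to flow in the
   high-frame-rate window, solved through the blur-corrected
   equipartition/WLC system.
4. *Turn-slope calibration* — nm of projected-length change per magnet
   turn during rotations at the reaction flow rate; this converts
   length slopes into enzymatic cycles/s (each gyrase cycle changes the
   linking number by -2).
5. *Burst detection* — sliding-window slope search in the reaction
   phase (12.5 s window before the trace maximum for positive-supercoil
   relaxation, 25 s after it for negative-supercoil introduction), with
   burst intervals delimited by change-point segmentation.
6. *alpha/chi tagging* — sign of the net length change across the
   reaction; *break detection* with burst/background rate contrast and
   bootstrap errors; *dose-response* (IC50) fitting; treadmilling cycle
   counting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy import stats

from .archive import MoleculeArchive, MoleculeRecord
from .calibration import BeadModel, CalibrationError, VarianceMeasurement, WLCParams, solve_force_length_blurred
from .changepoint import segment_trace, segments_to_table
from .protocol import ProtocolTimeline

__all__ = [
    "ClassifyConfig", "MoleculeClassification", "BurstRecord", "BreakEvent",
    "BreakStats", "DoseResponseFit", "assess_mobility", "projected_length",
    "classify_coilability", "measure_force", "calibrate_turn_slope",
    "detect_bursts", "classify_reaction_mode", "classify_molecule",
    "classify_archive", "detect_breaks", "pool_break_stats",
    "fit_dose_response", "count_treadmill_cycles",
]


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifyConfig:
    """Named thresholds of the classification pipeline."""

    min_amplitude_um: float = 0.5       # reversal swing for "mobile"
    min_msd_um2: float = 0.0025         # stuck-baseline mean-squared displacement
    compaction_frac: float = 0.25       # fractional loss for "coilable"
    multi_slope_frac: float = 0.25      # neg/pos slope ratio for "single tether"
    w_pos_s: float = 12.5               # positive-burst window
    w_neg_s: float = 25.0               # negative-burst window
    min_burst_slope_nm_s: float = 10.0  # absolute slope floor for a burst
    plateau_s: float = 30.0             # net-length plateau median window
    min_turn_slope_nm: float = 5.0      # below this: cannot calibrate
    wlc: WLCParams = field(default_factory=WLCParams)
    bead: BeadModel = field(default_factory=BeadModel)


@dataclass
class MoleculeClassification:
    uid: str = ""
    mobile: bool = False
    attachment: tuple[float, float] = (np.nan, np.nan)
    reversal_amplitude: float = np.nan
    coilable: bool = False
    single_tether: bool = False
    accepted: bool = False
    force_pn: float = np.nan
    extension_um: float = np.nan
    turn_slope_nm: float = np.nan
    mode: str | None = None  # "alpha", "chi" or None


@dataclass(frozen=True)
class BurstRecord:
    """One detected activity burst.

    ``velocity`` is in enzymatic cycles/s: |slope| / turn_slope / 2,
    two magnet turns per enzymatic cycle.
    """

    sign: str                 # "positive_relaxation" | "negative_introduction"
    t_start: float
    t_end: float
    slope_nm_s: float         # signed window slope
    velocity: float           # cycles/s
    start_time: float         # s relative to reaction start

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ClassificationError("burst requires t_start < t_end")


@dataclass(frozen=True)
class BreakEvent:
    uid: str
    t_break: float
    during_burst: bool


@dataclass
class BreakStats:
    events: list[BreakEvent]
    burst_rate: float        # breaks per second of burst time
    background_rate: float   # breaks per second outside bursts
    ratio: float             # burst_rate / background_rate (inf flagged)
    ratio_sd: float          # s.d. over bootstrap resamples of molecules
    infinite: bool = False


@dataclass(frozen=True)
class DoseResponseFit:
    ic50: float
    top: float
    bottom: float
    ci95: tuple[float, float]


# ----------------------------------------------------------------------
def _phase_slice(rec: MoleculeRecord, ph) -> pd.DataFrame:
    t = rec.trajectory["t_s"]
    return rec.trajectory[(t >= ph.t0) & (t <= ph.t1)]


def assess_mobility(rec: MoleculeRecord, tl: ProtocolTimeline,
                    config: ClassifyConfig | None = None):
    """Mobility flag, attachment site and reversal amplitude.

    The attachment site is the midpoint of the two extreme flow-axis
    positions during the reversal phase; a bead is mobile when the
    swing amplitude and the positional variance both exceed the stuck
    baseline.
    """
    cfg = config or ClassifyConfig()
    if not tl.has_phase("reversal"):
        raise ClassificationError("timeline has no reversal phase")
    seg = _phase_slice(rec, tl.phase("reversal"))
    if len(seg) < 4:
        raise ClassificationError("reversal phase has too few samples")
    x = seg["x_um"].to_numpy()
    y = seg["y_um"].to_numpy()
    amplitude = float(x.max() - x.min())
    attachment = (float((x.max() + x.min()) / 2.0), float(np.median(y)))
    msd = float(np.var(x))
    mobile = amplitude >= cfg.min_amplitude_um and msd >= cfg.min_msd_um2
    return mobile, attachment, amplitude


def projected_length(rec: MoleculeRecord, attachment) -> pd.Series:
    """Planar distance from the attachment site, l_xy(t), in um."""
    ax, ay = attachment
    dx = rec.trajectory["x_um"] - ax
    dy = rec.trajectory["y_um"] - ay
    return pd.Series(np.hypot(dx, dy).to_numpy(),
                     index=rec.trajectory["t_s"].to_numpy(), name="l_xy_um")


def _slope_vs_turns(seg_t, seg_l, ph) -> float:
    """OLS slope of l_xy versus cumulative turns over one coiling phase."""
    turns = ph.turns_at(seg_t)
    if np.ptp(turns) == 0:
        return 0.0
    return float(np.polyfit(turns, seg_l, 1)[0])


def classify_coilability(l_xy: pd.Series, tl: ProtocolTimeline,
                         config: ClassifyConfig | None = None):
    """(coilable, single_tether) from the high-force coiling series.

    Compaction is the fractional length loss across the positive
    coiling phase; a molecule is coilable when it exceeds
    ``compaction_frac``.  Single tethers show essentially no response
    to negative coiling at high force, so the magnitude ratio of the
    negative- to positive-phase slope separates them from
    multiply-tethered beads.
    """
    cfg = config or ClassifyConfig()
    for name in ("coil_neg", "coil_pos"):
        if not tl.has_phase(name):
            raise ClassificationError(f"timeline has no {name} phase")
    t = l_xy.index.to_numpy()
    vals = l_xy.to_numpy()

    def phase_data(name):
        ph = tl.phase(name)
        m = (t >= ph.t0) & (t <= ph.t1)
        if m.sum() < 6:
            raise ClassificationError(f"phase {name} has too few samples")
        return ph, t[m], vals[m]

    ph_pos, tp, lp = phase_data("coil_pos")
    ph_neg, tn, ln = phase_data("coil_neg")

    k = max(3, len(lp) // 10)
    start_len = float(np.median(lp[:k]))
    end_len = float(np.median(lp[-k:]))
    compaction = (start_len - end_len) / start_len if start_len > 0 else 0.0
    coilable = compaction >= cfg.compaction_frac

    slope_pos = abs(_slope_vs_turns(tp, lp, ph_pos))
    slope_neg = abs(_slope_vs_turns(tn, ln, ph_neg))
    single = coilable and slope_neg <= cfg.multi_slope_frac * slope_pos
    return coilable, single


def measure_force(rec: MoleculeRecord, tl: ProtocolTimeline,
                  config: ClassifyConfig | None = None):
    """Blur-corrected (force pN, extension um) from the force window.

    Uses the variance of motion orthogonal to flow at the high frame
    rate, with the camera integration time taken as one frame interval.
    """
    cfg = config or ClassifyConfig()
    if not tl.has_phase("force_window"):
        raise ClassificationError("timeline has no force_window phase")
    ph = tl.phase("force_window")
    seg = _phase_slice(rec, ph)
    if len(seg) < 100:
        raise ClassificationError(
            f"force window has {len(seg)} samples; need at least 100")
    var_y = float(np.var(seg["y_um"].to_numpy() * 1e-6))
    m = VarianceMeasurement(var_y=var_y, integration_time=1.0 / ph.frame_rate,
                            n_samples=len(seg))
    sol = solve_force_length_blurred(m, cfg.bead, cfg.wlc)
    return sol.force_pn, sol.extension_um


def calibrate_turn_slope(l_xy: pd.Series, tl: ProtocolTimeline,
                         phase_name: str = "partial_uncoil",
                         config: ClassifyConfig | None = None) -> float:
    """Compaction slope in nm per magnet turn at the reaction flow rate.

    Fits l_xy against cumulative turns over the responsive part of the
    rotation phase (samples pinned at the compaction floor or at full
    extension are excluded).  Raises if the molecule does not respond.
    """
    cfg = config or ClassifyConfig()
    if not tl.has_phase(phase_name):
        raise ClassificationError(f"timeline has no {phase_name} phase")
    ph = tl.phase(phase_name)
    t = l_xy.index.to_numpy()
    m = (t >= ph.t0) & (t <= ph.t1)
    tt, ll = t[m], l_xy.to_numpy()[m]
    if len(ll) < 10:
        raise ClassificationError("rotation phase has too few samples")
    if np.ptp(ll) < 0.3:
        raise ClassificationError("molecule does not compact: cannot calibrate")
    # the tether responds only beyond the buckling onset (and may sit at
    # the compaction floor for part of the phase): segment l_xy against
    # turns and read the slope off the steepest linear piece
    turns = ph.turns_at(tt)
    if turns[0] > turns[-1]:
        turns, ll = turns[::-1], ll[::-1]
    segs = segment_trace(turns, ll, confidence=0.99)
    segs = [s for s in segs if s.n_points >= 6] or segs
    best = max(segs, key=lambda s: abs(s.slope))
    slope_nm = abs(best.slope) * 1e3
    if slope_nm < cfg.min_turn_slope_nm:
        raise ClassificationError("turn slope below calibration floor")
    return slope_nm


# ----------------------------------------------------------------------
def _rolling_slopes(t: np.ndarray, y: np.ndarray, w: int):
    """OLS slope of every length-w window (vectorized); returns
    (slopes, slope standard errors) indexed by window start."""
    n = len(t)
    if w > n:
        return np.empty(0), np.empty(0)
    c = lambda a: np.concatenate(([0.0], np.cumsum(a)))
    st, sy, stt, sty, syy = c(t), c(y), c(t * t), c(t * y), c(y * y)
    i = np.arange(n - w + 1)
    j = i + w
    S_t = st[j] - st[i]
    S_y = sy[j] - sy[i]
    S_tt = stt[j] - stt[i]
    S_ty = sty[j] - sty[i]
    S_yy = syy[j] - syy[i]
    sxx = S_tt - S_t * S_t / w
    sxy = S_ty - S_t * S_y / w
    syy_c = S_yy - S_y * S_y / w
    slope = sxy / sxx
    sse = np.maximum(syy_c - slope * sxy, 0.0)
    dof = max(w - 2, 1)
    se = np.sqrt(sse / dof / sxx)
    return slope, se


def _burst_interval(t, y, i_best, w, sign, min_slope_um_s):
    """Burst extent from change-point segmentation around the best window."""
    segs = segment_trace(t, y, confidence=0.99)
    center = 0.5 * (t[i_best] + t[min(i_best + w - 1, len(t) - 1)])
    for s in segs:
        if s.t_start <= center <= s.t_end and np.sign(s.slope) == sign \
                and abs(s.slope) >= 0.5 * min_slope_um_s:
            return s.t_start, s.t_end
    return t[i_best], t[min(i_best + w - 1, len(t) - 1)]


def detect_bursts(l_xy: pd.Series, turn_slope_nm: float, tl: ProtocolTimeline,
                  config: ClassifyConfig | None = None) -> list[BurstRecord]:
    """Sliding-window burst detection in the reaction phase.

    The positive-relaxation burst is the maximum-slope window (width
    ``w_pos_s``) before the trace maximum; the negative-introduction
    burst is the minimum-slope window (width ``w_neg_s``) after it.  A
    window qualifies only if its slope exceeds both three standard
    errors and the absolute floor ``min_burst_slope_nm_s``.  Burst
    intervals are widened to the enclosing change-point segment.
    """
    cfg = config or ClassifyConfig()
    if turn_slope_nm <= 0:
        raise ClassificationError("turn_slope must be positive")
    if not tl.has_phase("reaction"):
        raise ClassificationError("timeline has no reaction phase")
    ph = tl.phase("reaction")
    t_all = l_xy.index.to_numpy()
    m = (t_all >= ph.t0) & (t_all <= ph.t1)
    t, y = t_all[m], l_xy.to_numpy()[m]
    if len(t) < 8:
        raise ClassificationError("reaction phase has too few samples")
    for w_s in (cfg.w_pos_s, cfg.w_neg_s):
        if t[-1] - t[0] < w_s:
            raise ClassificationError("reaction phase shorter than burst window")

    dt = np.median(np.diff(t))
    i_max = int(np.argmax(y))
    floor = cfg.min_burst_slope_nm_s * 1e-3  # um/s
    truncated = t[-1] < ph.t1 - 2 * dt  # tether lost mid-reaction
    bursts: list[BurstRecord] = []

    def scan(ti, yi, w_s, want_sign, label):
        w = max(4, int(round(w_s / dt)))
        if truncated:  # partial bursts are still bursts: shrink the window
            w = max(4, min(w, len(ti)))
        slopes, ses = _rolling_slopes(ti, yi, w)
        if len(slopes) == 0:
            return
        signed = slopes * want_sign
        k = int(np.argmax(signed))
        if signed[k] < max(3.0 * ses[k], floor):
            return
        t0, t1 = _burst_interval(ti, yi, k, w, want_sign, floor)
        slope_nm = slopes[k] * 1e3
        bursts.append(BurstRecord(
            sign=label, t_start=float(t0), t_end=float(t1),
            slope_nm_s=float(slope_nm),
            velocity=abs(slope_nm) / turn_slope_nm / 2.0,
            start_time=float(t0 - ph.t0)))

    scan(t[: i_max + 1], y[: i_max + 1], cfg.w_pos_s, +1.0, "positive_relaxation")
    scan(t[i_max:], y[i_max:], cfg.w_neg_s, -1.0, "negative_introduction")
    return bursts


def classify_reaction_mode(l_xy: pd.Series, tl: ProtocolTimeline,
                           config: ClassifyConfig | None = None) -> str | None:
    """alpha/chi tag from the net length change across the reaction.

    alpha: the tether ends shorter than before enzyme arrival (negative
    supercoils were introduced after relaxation).  chi: it ends longer
    (only positive supercoils were relaxed).  Levels are read off the
    change-point segmentation of the reaction trace: the first
    segment's value at the reaction start (pre-arrival) against the
    last segment's value at the end.  Returns None with a warning when
    the trace ends mid-reaction (no final plateau).
    """
    cfg = config or ClassifyConfig()
    ph = tl.phase("reaction")
    t = l_xy.index.to_numpy()
    vals = l_xy.to_numpy()
    m = (t >= ph.t0) & (t <= ph.t1)
    if m.sum() < 8:
        raise ClassificationError("not enough samples in the reaction phase")
    if t[m][-1] < ph.t1 - cfg.plateau_s:
        warnings.warn("trace ends mid-reaction; alpha/chi not assigned")
        return None
    segs = segment_trace(t[m], vals[m], confidence=0.99)
    first, last = segs[0], segs[-1]
    pre = first.intercept + first.slope * first.t_start
    final = last.intercept + last.slope * last.t_end
    return "alpha" if final - pre < 0 else "chi"


# ----------------------------------------------------------------------
def classify_molecule(rec: MoleculeRecord, tl: ProtocolTimeline,
                      config: ClassifyConfig | None = None,
                      ) -> tuple[MoleculeClassification, list[BurstRecord]]:
    """Run the full per-molecule pipeline; annotate the record in place."""
    cfg = config or ClassifyConfig()
    cls = MoleculeClassification(uid=rec.uid)
    bursts: list[BurstRecord] = []

    cls.mobile, cls.attachment, cls.reversal_amplitude = assess_mobility(rec, tl, cfg)
    rec.set_parameter("reversal_amplitude_um", cls.reversal_amplitude)
    if not cls.mobile:
        return cls, bursts
    rec.add_tag("mobile")

    l_xy = projected_length(rec, cls.attachment)
    # a projected length beyond the contour length is non-physical: the
    # bead has been released; analyze only the tethered part
    beyond = np.flatnonzero(l_xy.to_numpy() > cfg.wlc.contour * 1e6)
    if len(beyond):
        l_xy = l_xy.iloc[: beyond[0]]
    try:
        cls.coilable, cls.single_tether = classify_coilability(l_xy, tl, cfg)
    except ClassificationError:
        return cls, bursts
    if cls.coilable:
        rec.add_tag("coilable")
    if cls.single_tether:
        rec.add_tag("single_tether")
    cls.accepted = cls.mobile and cls.coilable and cls.single_tether
    if not cls.accepted:
        return cls, bursts
    rec.add_tag("accepted")

    try:
        cls.force_pn, cls.extension_um = measure_force(rec, tl, cfg)
        rec.set_parameter("force_pn", cls.force_pn)
        rec.set_parameter("length_um", cls.extension_um)
    except (ClassificationError, CalibrationError):
        pass

    try:
        cls.turn_slope_nm = calibrate_turn_slope(l_xy, tl, config=cfg)
        rec.set_parameter("turn_slope_nm_per_turn", cls.turn_slope_nm)
    except ClassificationError:
        return cls, bursts

    if tl.has_phase("reaction"):
        try:
            bursts = detect_bursts(l_xy, cls.turn_slope_nm, tl, cfg)
        except ClassificationError:
            bursts = []
        for b in bursts:
            rec.set_parameter(f"{b.sign}_cycles_per_s", b.velocity)
        # archive the reaction-phase segmentation: downstream break-rate
        # normalization reads activity intervals off this table
        ph = tl.phase("reaction")
        t = l_xy.index.to_numpy()
        m = (t >= ph.t0) & (t <= ph.t1)
        if m.sum() >= 8:
            segs = segment_trace(t[m], l_xy.to_numpy()[m], confidence=0.99)
            rec.add_segments(segments_to_table(segs), note="reaction l_xy")
        try:
            cls.mode = classify_reaction_mode(l_xy, tl, cfg)
        except ClassificationError:
            cls.mode = None
        if cls.mode:
            rec.add_tag(cls.mode)
    return cls, bursts


def classify_archive(arch: MoleculeArchive, tl: ProtocolTimeline,
                     config: ClassifyConfig | None = None):
    """Classify every record; returns (results table, bursts per uid)."""
    cfg = config or ClassifyConfig()
    rows = []
    bursts_by_uid: dict[str, list[BurstRecord]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rec in arch:
            cls, bursts = classify_molecule(rec, tl, cfg)
            bursts_by_uid[rec.uid] = bursts
            rows.append({
                "uid": cls.uid, "mobile": cls.mobile, "coilable": cls.coilable,
                "single": cls.single_tether, "accepted": cls.accepted,
                "force_pN": cls.force_pn, "length_um": cls.extension_um,
                "turn_slope_nm_per_turn": cls.turn_slope_nm,
                "mode": cls.mode or "",
                "v_pos": next((b.velocity for b in bursts
                               if b.sign == "positive_relaxation"), np.nan),
                "v_neg": next((b.velocity for b in bursts
                               if b.sign == "negative_introduction"), np.nan),
            })
    return pd.DataFrame(rows), bursts_by_uid


# ----------------------------------------------------------------------
def predicted_class(mobile: bool, coilable: bool, single: bool) -> str:
    """Molecule class implied by the pipeline flags.

    Immobile beads are stuck to the surface; mobile but non-coilable
    tethers are nicked; coilable tethers failing the single-tether
    slope test carry multiple DNAs; the rest are single tethers.
    """
    if not mobile:
        return "stuck"
    if not coilable:
        return "nicked"
    if not single:
        return "multi"
    return "single"


def activity_intervals(rec: MoleculeRecord, bursts: list[BurstRecord],
                       tl: ProtocolTimeline,
                       min_slope_um_s: float = 0.01) -> list[tuple[float, float]]:
    """Enzymatic-activity intervals for break-rate normalization.

    Preferred source is the record's stored reaction segment table
    (rows with |slope| above the floor); it covers partial ramps that
    are too short for the sliding-window burst gate, e.g. when the
    tether broke early in a burst.  Falls back to the burst records.
    """
    ph = tl.phase("reaction")
    for seg in reversed(rec.segments):
        rows = seg[(seg["t_start"] >= ph.t0 - 1e-6) & (seg["t_end"] <= ph.t1 + 1e-6)]
        if len(rows) == 0 or len(rows) != len(seg):
            continue
        return [(float(r.t_start), float(r.t_end)) for r in rows.itertuples()
                if abs(r.slope) >= min_slope_um_s]
    return [(b.t_start, b.t_end) for b in bursts]


def molecule_break_summary(rec: MoleculeRecord, bursts: list[BurstRecord],
                           tl: ProtocolTimeline, end_times: np.ndarray,
                           contour_um: float = 6.8,
                           persistence_frac: float = 0.9) -> dict:
    """Per-molecule break/exposure summary for rate pooling.

    A break is an irreversible tether loss: the track terminates before
    the end of the reaction while at least ``persistence_frac`` of
    concurrent tracks persist, or the projected length jumps beyond the
    contour length.  Exposure time is split between activity intervals
    (see :func:`activity_intervals`) and background.
    """
    ph = tl.phase("reaction")
    t = rec.trajectory["t_s"].to_numpy()
    x = rec.trajectory["x_um"].to_numpy()
    t_end = t[-1]
    dt = 1.0 / ph.frame_rate

    broke = False
    t_break = np.nan
    if x[-1] - np.median(x) > contour_um:  # bead released: beyond any tether state
        broke = True
        t_break = t_end
    elif t_end < ph.t1 - 2 * dt:
        persist = np.mean(end_times > t_end + dt)
        if persist >= persistence_frac:
            broke = True
            t_break = t_end

    obs_end = min(t_end, ph.t1)
    total = max(obs_end - ph.t0, 0.0)
    burst_time = 0.0
    in_burst = False
    for b_start, b_end in activity_intervals(rec, bursts, tl):
        s, e = max(b_start, ph.t0), min(b_end, obs_end)
        burst_time += max(e - s, 0.0)
        if broke and b_start - 2 * dt <= t_break <= b_end + 2 * dt:
            in_burst = True
    return {
        "uid": rec.uid, "broke": broke, "t_break": t_break,
        "in_burst": in_burst, "burst_time": burst_time,
        "background_time": max(total - burst_time, 0.0),
    }


def pool_break_stats(summaries: pd.DataFrame, n_boot: int = 30,
                     rng: np.random.Generator | None = None) -> BreakStats:
    """Break rates inside vs outside bursts, pooled over molecules.

    The ratio's standard deviation comes from ``n_boot`` bootstrap
    resamples of whole molecules.
    """
    rng = rng or np.random.default_rng(0)
    df = summaries

    def rates(d: pd.DataFrame):
        bt = d["burst_time"].sum()
        gt = d["background_time"].sum()
        nb = int((d["broke"] & d["in_burst"]).sum())
        ng = int((d["broke"] & ~d["in_burst"]).sum())
        rb = nb / bt if bt > 0 else 0.0
        rg = ng / gt if gt > 0 else 0.0
        return rb, rg

    rb, rg = rates(df)
    events = [BreakEvent(uid=r.uid, t_break=float(r.t_break),
                         during_burst=bool(r.in_burst))
              for r in df.itertuples() if r.broke]
    infinite = rg == 0.0 and rb > 0.0
    ratio = math.inf if infinite else (rb / rg if rg > 0 else math.nan)

    ratios = []
    n = len(df)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rbb, rgb = rates(df.iloc[idx])
        if rgb > 0:
            ratios.append(rbb / rgb)
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else math.nan
    return BreakStats(events=events, burst_rate=rb, background_rate=rg,
                      ratio=ratio, ratio_sd=sd, infinite=infinite)


def detect_breaks(arch: MoleculeArchive, bursts_by_uid: dict,
                  tl: ProtocolTimeline, contour_um: float = 6.8,
                  n_boot: int = 30,
                  rng: np.random.Generator | None = None) -> BreakStats:
    """Break events and burst/background break-rate contrast."""
    end_times = np.array([rec.trajectory["t_s"].iloc[-1] for rec in arch])
    rows = [molecule_break_summary(rec, bursts_by_uid.get(rec.uid, []),
                                   tl, end_times, contour_um)
            for rec in arch]
    return pool_break_stats(pd.DataFrame(rows), n_boot=n_boot, rng=rng)


# ----------------------------------------------------------------------
def fit_dose_response(conc: np.ndarray, response: np.ndarray) -> DoseResponseFit:
    """One-site inhibitor-vs-response fit: Y = Bottom + (Top-Bottom)/(1 + X/IC50).

    Zero concentration is the X -> 0 limit (Y = Top).  The 95% CI on
    IC50 comes from the parameter covariance.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(np.unique(conc)) < 4:
        raise ClassificationError("need at least 4 distinct concentrations")
    if np.ptp(response) < 1e-12 * max(1.0, abs(response).max()):
        raise ClassificationError("flat response: IC50 not identifiable")

    def model(x, top, bottom, ic50):
        return bottom + (top - bottom) / (1.0 + x / ic50)

    pos = conc[conc > 0]
    p0 = [float(response.max()), float(response.min()), float(np.median(pos))]
    try:
        popt, pcov = curve_fit(model, conc, response, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise ClassificationError(f"dose-response fit failed: {exc}") from exc
    top, bottom, ic50 = popt
    if ic50 <= 0 or not np.isfinite(pcov[2, 2]):
        raise ClassificationError("dose-response fit not identifiable")
    se = math.sqrt(pcov[2, 2])
    return DoseResponseFit(ic50=float(ic50), top=float(top), bottom=float(bottom),
                           ci95=(float(ic50 - 1.96 * se), float(ic50 + 1.96 * se)))


def count_treadmill_cycles(rotation_rate: float, active_time: float) -> float:
    """Enzymatic cycles resolved while treadmilling: rate/2 * time.

    Continuous magnet rotation introduces ``rotation_rate`` turns/s and
    the enzyme removes them as they form; each cycle accounts for two
    turns, so length stays stationary while cycles accumulate.
    """
    if rotation_rate < 0 or active_time < 0:
        raise ClassificationError("rotation rate and time must be non-negative")
    return rotation_rate / 2.0 * active_time
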