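"""Synthetic flow-magnetic-tweezers data with ground truth.

The generator produces everything the analysis chain consumes, at the
level of realism the pipeline is sensitive to:

* lateral bead fluctuations as an exact Ornstein-Uhlenbeck process with
  stationary variance k_B*T*l/F and relaxation time gamma*l/F, with
  camera motion blur modeled by within-exposure averaging;
* extension-versus-turns "hat" curves with the force-dependent
  asymmetry of supercoiled DNA (symmetric buckling at low force,
  positive-only compaction above the melting force);
* full protocol traces per molecule class (single, nicked,
  multi-tethered, stuck) over a :class:`~fmtkit.protocol.ProtocolTimeline`,
  including gyrase bursts (positive relaxation, pause, negative
  introduction at set cycles/s) and rare tether breaks with an elevated
  hazard during activity bursts;
* ground-truth-labeled cohorts for pipeline validation, deterministic
  under a single seed;
* rendered camera frames (integrated Gaussian spots, Poisson photon
  noise, Gaussian background) for the tracking chain.

Everything stochastic draws from explicitly passed numpy Generators;
cohorts derive one child stream per molecule from the cohort seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .archive import MoleculeArchive, MoleculeRecord, new_uid
from .calibration import K_B, BeadModel, WLCParams, wlc_extension
from .protocol import ProtocolTimeline, default_timeline

#: default ratio of projected to true extension (constant tether angle).
PROJECTION = 3.8 / 4.4

#: reference flow (ul/min) at which a molecule's nominal force applies.
FLOW_REF = 2.5


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SupercoilState:
    """Signed turn count and the supercoiling density it implies."""

    turns: float
    lk0: float = 2000.0

    @property
    def sigma(self) -> float:
        return self.turns / self.lk0


@dataclass(frozen=True)
class HatCurveModel:
    """Phenomenological extension-vs-turns response of a DNA tether.

    Beyond the buckling onset the tether compacts linearly at
    ``slope_per_turn``.  The onset grows linearly with force, anchored
    at ``anchor_turns`` turns for ``anchor_force_pn`` pN (overwound
    DNA); underwound DNA uses the same onset below ``melt_above_pn``
    and does not compact at all above it (helix melting).
    """

    slope_per_turn_nm: float = 50.0
    anchor_turns: float = 150.0
    anchor_force_pn: float = 6.5
    melt_above_pn: float = 1.0
    min_extension_um: float = 0.2

    def buckling_onset(self, force_pn: float, sign: int) -> float:
        """Turns at which buckling starts; inf if no compaction."""
        if sign < 0 and force_pn >= self.melt_above_pn:
            return math.inf
        return self.anchor_turns * force_pn / self.anchor_force_pn


@dataclass(frozen=True)
class GyraseKinetics:
    """Gyrase burst parameters; each enzymatic cycle changes Lk by -2."""

    v_pos: float = 1.26               # cycles/s, positive relaxation
    v_neg: float = 0.65               # cycles/s, negative introduction
    pause_s: float = 10.0             # pause between the two bursts
    arrival_s: float = 10.0           # mean enzyme arrival delay
    n_neg_turns: float = 60.0         # negative turns introduced (alpha mode)
    chi_force_pn: float = 0.5         # above this force: chi mode (no negatives)
    break_hazard_burst: float = 3e-4      # 1/s during activity bursts
    break_hazard_background: float = 1e-4  # 1/s otherwise in the reaction

    def __post_init__(self) -> None:
        if min(self.v_pos, self.v_neg, self.pause_s, self.arrival_s,
               self.break_hazard_burst, self.break_hazard_background) < 0:
            raise SimulationError("kinetic parameters must be non-negative")


CLASS_LABELS = ("stuck", "nicked", "multi", "single")


@dataclass
class CohortSpec:
    """Ground-truth-labeled synthetic population.

    Class fractions must sum to 1; assignment is stratified so counts
    are exact.  Per-molecule forces are lognormal (median
    ``force_median_pn``, log-sd ``force_sigma_log``), reflecting
    bead-to-bead variation in size and magnetic content.
    """

    n_molecules: int = 100
    fractions: dict = field(default_factory=lambda: {
        "stuck": 0.1, "nicked": 0.2, "multi": 0.2, "single": 0.5})
    force_median_pn: float = 0.2
    force_sigma_log: float = 0.25
    kinetics: GyraseKinetics = field(default_factory=GyraseKinetics)
    hat: HatCurveModel = field(default_factory=HatCurveModel)
    noise_sd_um: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise SimulationError("class fractions must sum to 1")
        if set(self.fractions) - set(CLASS_LABELS):
            raise SimulationError(f"unknown class in {self.fractions}")


# ----------------------------------------------------------------------
def simulate_ou_segment(
    force_pn: float,
    extension_um: float,
    n_steps: int,
    dt: float,
    exposure: int = 1,
    bead: BeadModel | None = None,
    temperature: float = 296.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Lateral OU fluctuations (meters), optionally motion-blurred.

    The trap stiffness is k = F/l, relaxation time tau = gamma/k, and
    stationary variance k_B*T*l/F.  The exact discrete OU update is
    used, so any dt is admissible for point samples (``exposure=1``).
    With ``exposure > 1`` each camera sample is the mean of that many
    equispaced substeps spanning the frame interval (integration time
    W = dt); substeps are refined automatically to at most tau/10.
    """
    if force_pn <= 0 or extension_um <= 0:
        raise SimulationError("force and extension must be positive")
    b = bead or BeadModel()
    rng = rng or np.random.default_rng()
    f = force_pn * 1e-12
    l = extension_um * 1e-6
    k = f / l
    tau = b.gamma / k
    var_inf = K_B * temperature * l / f

    from scipy.signal import lfilter

    def ar1(n: int, rho: float) -> np.ndarray:
        innov_sd = math.sqrt(var_inf * (1.0 - rho * rho))
        y0 = rng.standard_normal() * math.sqrt(var_inf)
        xi = innov_sd * rng.standard_normal(n)
        y, _ = lfilter([1.0], [1.0, -rho], xi, zi=np.array([rho * y0]))
        return y

    if exposure <= 1:
        return ar1(n_steps, math.exp(-dt / tau))

    m = max(int(exposure), int(math.ceil(10.0 * dt / tau)))
    path = ar1(n_steps * m, math.exp(-dt / (m * tau)))
    return path.reshape(n_steps, m).mean(axis=1)


def extension_vs_turns(
    turns: float | np.ndarray,
    force_pn: float,
    hat: HatCurveModel | None = None,
    wlc: WLCParams | None = None,
    projection: float = PROJECTION,
) -> np.ndarray:
    """Projected tether length (um) as a function of magnet turns.

    Below the melting force the hat is symmetric; above it underwound
    DNA melts locally and keeps its full length while overwound DNA
    still buckles and compacts at ``slope_per_turn`` per excess turn.
    """
    h = hat or HatCurveModel()
    p = wlc or WLCParams()
    n = np.asarray(turns, dtype=float)
    baseline = wlc_extension(force_pn * 1e-12, p) * 1e6 * projection
    onset_pos = h.buckling_onset(force_pn, +1)
    onset_neg = h.buckling_onset(force_pn, -1)
    excess = np.where(
        n >= 0,
        np.maximum(0.0, n - onset_pos),
        np.maximum(0.0, -n - onset_neg) if np.isfinite(onset_neg) else 0.0,
    )
    l_xy = baseline - excess * h.slope_per_turn_nm * 1e-3
    return np.maximum(l_xy, h.min_extension_um)


# ----------------------------------------------------------------------
def _gyrase_turns(t: np.ndarray, n0: float, kin: GyraseKinetics,
                  arrival: float, alpha_mode: bool) -> np.ndarray:
    """Internal linking-number deficit (turns) during the reaction phase.

    Hold at n0 until enzyme arrival, relax positives at 2*v_pos turns/s,
    pause, then (alpha mode only) introduce negatives at 2*v_neg turns/s
    down to -n_neg_turns.
    """
    relax_end = arrival + n0 / (2.0 * kin.v_pos) if kin.v_pos > 0 else math.inf
    neg_start = relax_end + kin.pause_s
    neg_end = neg_start + (kin.n_neg_turns / (2.0 * kin.v_neg)
                           if (alpha_mode and kin.v_neg > 0) else 0.0)
    n = np.full_like(t, n0)
    relax = (t >= arrival) & (t < relax_end)
    n[relax] = n0 - 2.0 * kin.v_pos * (t[relax] - arrival)
    n[(t >= relax_end) & (t < neg_start)] = 0.0
    if alpha_mode and kin.v_neg > 0:
        intro = (t >= neg_start) & (t < neg_end)
        n[intro] = -2.0 * kin.v_neg * (t[intro] - neg_start)
        n[t >= neg_end] = -kin.n_neg_turns
    else:
        n[t >= relax_end] = 0.0
        n[(t >= relax_end) & (t < neg_start)] = 0.0
    return n


def _burst_intervals(n0: float, kin: GyraseKinetics, arrival: float,
                     alpha_mode: bool) -> list[tuple[float, float]]:
    out = []
    if kin.v_pos > 0 and n0 > 0:
        relax_end = arrival + n0 / (2.0 * kin.v_pos)
        out.append((arrival, relax_end))
        if alpha_mode and kin.v_neg > 0:
            neg_start = relax_end + kin.pause_s
            out.append((neg_start, neg_start + kin.n_neg_turns / (2.0 * kin.v_neg)))
    return out


def _sample_break(t0: float, t1: float, bursts: list[tuple[float, float]],
                  kin: GyraseKinetics, rng: np.random.Generator) -> float | None:
    """First event of an inhomogeneous Poisson process on [t0, t1].

    Piecewise-constant hazard: burst hazard inside burst intervals,
    background hazard elsewhere.  Returns None when no break occurs.
    """
    edges = [t0]
    for a, b in bursts:
        edges += [max(t0, min(a, t1)), max(t0, min(b, t1))]
    edges.append(t1)
    edges = sorted(set(edges))
    t = t0
    for a, b in zip(edges, edges[1:]):
        mid = 0.5 * (a + b)
        in_burst = any(s <= mid < e for s, e in bursts)
        lam = kin.break_hazard_burst if in_burst else kin.break_hazard_background
        if lam > 0:
            wait = rng.exponential(1.0 / lam)
            if a + wait < b:
                return a + wait
    return None


def simulate_protocol_trace(
    class_label: str,
    tl: ProtocolTimeline | None = None,
    force_pn: float = 0.2,
    kinetics: GyraseKinetics | None = None,
    hat: HatCurveModel | None = None,
    wlc: WLCParams | None = None,
    bead: BeadModel | None = None,
    noise_sd_um: float = 0.05,
    attachment=(20.0, 20.0),
    rng: np.random.Generator | None = None,
    uid: str | None = None,
) -> MoleculeRecord:
    """One molecule's full trace over the protocol, with ground truth.

    The bead sits at ``attachment + l_xy`` along the flow axis (sign
    flipping mid-reversal), with Gaussian measurement noise; the
    force-window phase carries proper motion-blurred OU fluctuations on
    the orthogonal axis.  Ground truth (class, force, injected
    velocities, break time) is stored in the record's parameters/tags.
    """
    if class_label not in CLASS_LABELS:
        raise SimulationError(f"unknown class {class_label!r}")
    tl = tl or default_timeline()
    kin = kinetics or GyraseKinetics()
    h = hat or HatCurveModel()
    p = wlc or WLCParams()
    b = bead or BeadModel()
    rng = rng or np.random.default_rng()
    ax, ay = attachment
    alpha_mode = force_pn < kin.chi_force_pn

    reaction = tl.phase("reaction") if tl.has_phase("reaction") else None
    arrival = break_time = None
    bursts: list[tuple[float, float]] = []
    if reaction is not None and class_label == "single":
        arrival = rng.exponential(kin.arrival_s)
        bursts = [(reaction.t0 + s, reaction.t0 + e)
                  for s, e in _burst_intervals(reaction.turns_start, kin, arrival, alpha_mode)]
    if reaction is not None and class_label != "stuck":
        break_time = _sample_break(reaction.t0, reaction.t1, bursts, kin, rng)

    times, frames, xs, ys = [], [], [], []
    frame0 = 0
    for ph in tl.phases:
        n = int(round(ph.duration * ph.frame_rate))
        t = ph.t0 + (np.arange(n) + 0.5) / ph.frame_rate
        f_phase = force_pn * ph.flow / FLOW_REF

        if class_label == "stuck":
            l_xy = np.zeros(n)
            x = ax + rng.normal(0.0, 0.02, n)
            y = ay + rng.normal(0.0, 0.02, n)
        else:
            turns = ph.turns_at(t) if ph.name != "reaction" else None
            if ph.name == "reaction":
                if class_label == "single":
                    turns = _gyrase_turns(t - ph.t0, ph.turns_start, kin,
                                          arrival, alpha_mode)
                elif class_label == "nicked":
                    turns = np.zeros(n)
                else:  # multi: stays wrapped at the pre-reaction state
                    turns = np.full(n, ph.turns_start)
            if class_label == "nicked":
                turns = np.zeros_like(np.asarray(turns, dtype=float))
            if class_label == "multi":
                # both coiling directions wrap the two tethers: symmetric
                # compaction regardless of force, immediate onset
                base = wlc_extension(f_phase * 1e-12, p) * 1e6 * PROJECTION
                l_xy = np.maximum(base - np.abs(turns) * h.slope_per_turn_nm * 1e-3,
                                  h.min_extension_um)
            else:
                l_xy = extension_vs_turns(turns, f_phase, h, p)
            sign = np.ones(n)
            if ph.name == "reversal":
                sign[t < ph.t0 + ph.duration / 2.0] = -1.0
            x = ax + sign * l_xy + rng.normal(0.0, noise_sd_um, n)
            if ph.name == "force_window":
                ext_um = wlc_extension(f_phase * 1e-12, p) * 1e6
                y = ay + 1e6 * simulate_ou_segment(
                    f_phase, ext_um, n, 1.0 / ph.frame_rate, exposure=4,
                    bead=b, temperature=p.temperature, rng=rng)
            else:
                y = ay + rng.normal(0.0, noise_sd_um, n)

        if break_time is not None and ph.t1 > break_time:
            keep = t <= break_time
            n_keep = int(keep.sum())
            if n_keep < n:
                # bead released: one frame far beyond contour, then gone
                x = np.concatenate([x[:n_keep], [ax + p.contour * 1e6 * 1.5]])
                y = np.concatenate([y[:n_keep], [ay]])
                t = t[:n_keep + 1]
                n = n_keep + 1
                times.append(t); frames.append(frame0 + np.arange(n))
                xs.append(x); ys.append(y)
                break
        times.append(t)
        frames.append(frame0 + np.arange(n))
        xs.append(x)
        ys.append(y)
        frame0 += n

    traj = pd.DataFrame({
        "frame": np.concatenate(frames).astype(int),
        "t_s": np.concatenate(times),
        "x_um": np.concatenate(xs),
        "y_um": np.concatenate(ys),
    })
    rec = MoleculeRecord(uid=uid or new_uid(rng), trajectory=traj)
    rec.tags.add(f"truth:{class_label}")
    rec.parameters["truth_force_pn"] = float(force_pn)
    rec.parameters["truth_class"] = float(CLASS_LABELS.index(class_label))
    if class_label == "single":
        rec.parameters["truth_v_pos"] = kin.v_pos
        rec.parameters["truth_v_neg"] = kin.v_neg if alpha_mode else 0.0
        rec.parameters["truth_alpha"] = float(alpha_mode)
        rec.parameters["truth_turn_slope_nm"] = h.slope_per_turn_nm
    if break_time is not None:
        rec.parameters["truth_break_t"] = float(break_time)
        in_burst = any(s <= break_time < e for s, e in bursts)
        rec.parameters["truth_break_in_burst"] = float(in_burst)
    rec.log.append(f"simulated {class_label} trace")
    return rec


def _stratified_labels(spec: CohortSpec) -> list[str]:
    """Exact class counts by largest remainder, deterministic order."""
    n = spec.n_molecules
    raw = {c: spec.fractions.get(c, 0.0) * n for c in CLASS_LABELS}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    by_frac = sorted(CLASS_LABELS, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in by_frac[:short]:
        counts[c] += 1
    labels: list[str] = []
    for c in CLASS_LABELS:
        labels += [c] * counts[c]
    return labels


def simulate_cohort(
    spec: CohortSpec,
    tl: ProtocolTimeline | None = None,
) -> tuple[MoleculeArchive, pd.DataFrame]:
    """Seeded cohort: archive of records plus a ground-truth table.

    One child random stream per molecule is derived from the cohort
    seed, so cohorts are reproducible and insensitive to generation
    order.
    """
    tl = tl or default_timeline()
    labels = _stratified_labels(spec)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(labels) + 1)
    rng_global = np.random.default_rng(children[0])
    order = rng_global.permutation(len(labels))

    arch = MoleculeArchive(metadata={"cohort_seed": spec.seed,
                                     "n_molecules": spec.n_molecules,
                                     "timeline": tl.to_dict()})
    rows = []
    for i in order:
        label = labels[i]
        rng = np.random.default_rng(children[i + 1])
        force = spec.force_median_pn * math.exp(
            spec.force_sigma_log * rng.standard_normal())
        rec = simulate_protocol_trace(
            label, tl, force_pn=force, kinetics=spec.kinetics, hat=spec.hat,
            noise_sd_um=spec.noise_sd_um, rng=rng)
        arch.add_record(rec)
        rows.append({
            "uid": rec.uid, "class": label, "force_pn": force,
            "v_pos": rec.parameters.get("truth_v_pos", np.nan),
            "v_neg": rec.parameters.get("truth_v_neg", np.nan),
            "alpha": rec.parameters.get("truth_alpha", np.nan),
            "break_t": rec.parameters.get("truth_break_t", np.nan),
            "break_in_burst": rec.parameters.get("truth_break_in_burst", np.nan),
        })
    return arch, pd.DataFrame(rows)


# ----------------------------------------------------------------------
def render_frame(
    positions_px: np.ndarray,
    shape: tuple[int, int],
    psf_sigma_px: float = 1.3,
    photons: float = 50200.0,
    background_mean: float = 200.0,
    background_sd: float = 0.0,
    poisson: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one camera frame of Gaussian spots.

    Each bead contributes ``photons`` photons distributed as a 2-D
    Gaussian integrated over pixels (difference of error functions), to
    which Poisson shot noise and Gaussian background noise are applied.
    """
    rng = rng or np.random.default_rng()
    ny, nx = shape
    img = np.zeros(shape, dtype=float)
    s = psf_sigma_px
    root2s = math.sqrt(2.0) * s
    for x0, y0 in np.atleast_2d(positions_px):
        if not (-3 * s <= x0 <= nx - 1 + 3 * s and -3 * s <= y0 <= ny - 1 + 3 * s):
            import warnings

            warnings.warn(f"bead at ({x0:.1f}, {y0:.1f}) outside frame; clipped")
        r = int(math.ceil(5 * s)) + 1
        cx0, cx1 = max(0, int(x0) - r), min(nx, int(x0) + r + 1)
        cy0, cy1 = max(0, int(y0) - r), min(ny, int(y0) + r + 1)
        if cx0 >= cx1 or cy0 >= cy1:
            continue
        xe = np.arange(cx0, cx1 + 1) - 0.5
        ye = np.arange(cy0, cy1 + 1) - 0.5
        fx = 0.5 * (erf((xe[1:] - x0) / root2s) - erf((xe[:-1] - x0) / root2s))
        fy = 0.5 * (erf((ye[1:] - y0) / root2s) - erf((ye[:-1] - y0) / root2s))
        img[cy0:cy1, cx0:cx1] += photons * np.outer(fy, fx)
    if poisson:
        img = rng.poisson(img).astype(float)
    img += background_mean
    if background_sd > 0:
        img += rng.normal(0.0, background_sd, size=shape)
    return img


def render_video(
    positions_px: np.ndarray,
    shape: tuple[int, int],
    path=None,
    seed: int = 0,
    **kwargs,
) -> np.ndarray:
    """Render a stack of frames; positions_px is (n_frames, n_beads, 2).

    Optionally writes a multi-page TIFF (uint16) to ``path``.
    """
    rng = np.random.default_rng(seed)
    stack = np.stack([render_frame(p, shape, rng=rng, **kwargs)
                      for p in positions_px])
    if path is not None:
        import tifffile

        tifffile.imwrite(path, np.clip(stack, 0, 65535).astype(np.uint16),
                         photometric="minisblack")
    return stack
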