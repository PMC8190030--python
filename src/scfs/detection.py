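"""Rupture-event detection and classification in retract curves.

Per-curve procedure: fit and subtract a straight baseline from the force
trace (the far tail of the retract, assumed event-free, anchors the fit),
locate the contact point, place the data on a tip-sample separation axis,
find abrupt force-release steps, and classify each step by how the local
force-vs-separation slope changes across it: a bond-rupture *jump* releases
its loading stiffness (slope relaxes by ~k_eff), a membrane-tether
detachment ends a constant-force plateau and leaves the slope unchanged.

Step statistic.  For every interior sample ``i`` a straight line is fitted
by least squares to the ``window_w`` samples on each side and both lines are
extrapolated to the boundary between samples ``i-1`` and ``i``; the step
estimate is the difference of the two extrapolations.  Fitting lines rather
than plain window means makes the statistic exactly zero on any locally
linear stretch -- loaded ramps, drift, the contact-region kink -- so only
genuine discontinuities score.  The estimate is normalised by its standard
error under white baseline noise (baseline_sd times the known extrapolation
leverage of the two fits), giving a dimensionless statistic thresholded at
``threshold_theta``.  Candidates are screened as strict local maxima of the
statistic; candidates closer than a window to an accepted stronger neighbour
are re-tested with windows truncated at that neighbour, which suppresses
side-lobe ghosts of a single step while still resolving genuinely distinct
steps only a few samples apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import ForceCurve, RuptureEvent
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "DetectionParams",
    "ProcessedCurve",
    "StepCandidate",
    "BenchmarkResult",
    "correct_baseline",
    "find_contact_point",
    "detect_steps",
    "classify_event",
    "process_curve",
    "detection_benchmark",
]

_EPS_SD = 1e-12  # floor on the noise scale; keeps noise-free curves finite


@dataclass
class DetectionParams:
    """Tunable detector settings.

    ``window_w``: half-window (samples) of the step statistic.
    ``threshold_theta``: dimensionless detection threshold.
    ``min_force_factor``: reject steps below this multiple of baseline_sd.
    ``min_step_force_pN``: absolute floor on the step force; a few pN of
    force resolution is the practical discrimination limit of a soft
    cantilever regardless of the fitted noise level.
    ``min_separation_events``: hard floor (samples) between reported events.
    ``slope_min``: pN/nm; slope changes across the step below this mark a
    tether plateau release rather than a bond rupture.
    ``slope_window``: samples per side for the classification slope fits.
    ``baseline_fraction``: fraction of the retract tail used for the
    baseline fit.
    """

    window_w: int = 15
    threshold_theta: float = 6.0
    min_force_factor: float = 3.0
    min_step_force_pN: float = 5.0
    min_separation_events: int = 3
    slope_min: float = 0.05
    slope_window: int = 60
    baseline_fraction: float = 0.25

    def validate(self) -> None:
        if self.window_w < 3:
            raise ValidationError("window_w must be >= 3")
        for name in ("threshold_theta", "min_force_factor", "slope_min"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.min_separation_events < 1:
            raise ValidationError("min_separation_events must be >= 1")
        if self.slope_window < 4:
            raise ValidationError("slope_window must be >= 4")
        if not 0 < self.baseline_fraction <= 0.5:
            raise ValidationError("baseline_fraction must lie in (0, 0.5]")


@dataclass
class ProcessedCurve:
    """Baseline-corrected retract trace on a separation axis.

    Arrays are in retract time order (contact first).  ``force`` is in pN,
    ``baseline_sd`` is the robust per-sample noise (pN), ``separation`` is
    tip-sample separation in nm (0 at contact, increasing during retract;
    None until the contact point is located).
    """

    z: np.ndarray
    force: np.ndarray
    baseline_sd: float
    metadata: object
    contact_index: int | None = None
    contact_flagged: bool = False
    separation: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.force.size)


@dataclass(frozen=True)
class StepCandidate:
    """A detected force-release step before classification."""

    index: int
    step_force_pN: float
    statistic: float


@dataclass
class BenchmarkResult:
    recall: float
    precision: float
    force_rmse_pN: float
    n_truth: int
    n_detected: int
    n_matched: int


def correct_baseline(curve: ForceCurve, params: DetectionParams | None = None) -> ProcessedCurve:
    """Fit and subtract a straight baseline; convert deflection to force.

    The line is least-squares fitted to the final ``baseline_fraction`` of
    the retract (farthest from the surface, assumed event-free) as a
    function of piezo position, then subtracted from the whole retract.
    ``baseline_sd`` is 1.4826 times the median absolute deviation of the
    corrected baseline region, a robust estimate that tolerates occasional
    tether plateaus reaching into the tail.
    """
    params = params or DetectionParams()
    params.validate()
    curve.validate()
    ret = curve.retract_indices
    z = curve.z_position[ret]
    force = curve.metadata.spring_constant_k * curve.deflection[ret]
    n = force.size
    n_base = int(round(params.baseline_fraction * n))
    if n_base < 50:
        raise InsufficientDataError(
            f"baseline region has {n_base} samples (< 50); curve too short for baseline_fraction={params.baseline_fraction}"
        )
    zb, fb = z[-n_base:], force[-n_base:]
    slope, intercept = np.polyfit(zb, fb, 1)
    corrected = force - (slope * z + intercept)
    resid = corrected[-n_base:]
    sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    return ProcessedCurve(
        z=z,
        force=corrected,
        baseline_sd=sd,
        metadata=curve.metadata,
        provenance={"baseline_slope_pN_per_nm": float(-slope), "baseline_intercept_pN": float(intercept), "params": params},
    )


def find_contact_point(p: ProcessedCurve) -> int:
    """Locate the contact point and build the separation axis.

    The contact index is the last sample of the initial repulsive region
    (force above +3 baseline_sd while still on the surface side of the
    trace).  If the curve starts off-contact the index falls back to 0 and
    the curve is flagged.  Separation is s = (z_contact - z) - d with d the
    corrected deflection, clipped at 0.
    """
    thr = 3.0 * max(p.baseline_sd, _EPS_SD)
    repulsive = p.force > thr
    if repulsive.size and repulsive[0]:
        off = np.flatnonzero(~repulsive)
        contact = int(off[0]) - 1 if off.size else p.n - 1
        flagged = not off.size
    else:
        contact = 0
        flagged = True
    p.contact_index = contact
    p.contact_flagged = flagged
    k = p.metadata.spring_constant_k
    s = (p.z[contact] - p.z) - p.force / k
    p.separation = np.maximum(s, 0.0)
    return contact


def _window_fits(y: np.ndarray, w: int):
    """Moving least-squares line fits over windows of length w.

    Returns (mean, slope, resid_var) per window start index, x in samples."""
    ones = np.ones(w)
    ramp = np.arange(w, dtype=float)
    S = np.correlate(y, ones, mode="valid")
    C = np.correlate(y, ramp, mode="valid")
    S2 = np.correlate(y * y, ones, mode="valid")
    mbar = (w - 1) / 2.0
    sxx = w * (w * w - 1) / 12.0
    mean = S / w
    slope = (C - mbar * S) / sxx
    ssr = np.maximum(S2 - S * S / w - slope * slope * sxx, 0.0)
    resid_var = ssr / max(w - 2, 1)
    return mean, slope, resid_var


def step_statistic(p: ProcessedCurve, params: DetectionParams):
    """Per-boundary step estimates for every interior index.

    Returns (est, g, stat) arrays of length n (edges 0):

    * ``est``  -- difference of the two line extrapolations at the boundary,
      the step-height estimate;
    * ``g``    -- est plus the mean of the two fitted slopes, which equals
      the raw one-sample trace difference exactly on piecewise-linear data
      (the quantity an exact finite-difference scan thresholds);
    * ``stat`` -- est normalised by its standard error, using the larger of
      the local fit-residual scale and the global baseline noise, so that
      slope kinks (which break the local-linearity assumption) suppress
      themselves instead of scoring.
    """
    w = params.window_w
    y = p.force
    n = y.size
    est = np.zeros(n)
    g = np.zeros(n)
    stat = np.zeros(n)
    if n < 2 * w:
        return est, g, stat
    mean, slope, rvar = _window_fits(y, w)
    # boundary i: pre-window starts at i-w, post-window starts at i
    idx = np.arange(w, n - w + 1)
    pre = mean[idx - w] + slope[idx - w] * (w / 2.0)
    post = mean[idx] - slope[idx] * (w / 2.0)
    d = post - pre
    leverage = 2.0 * (1.0 / w + 3.0 * w / (w * w - 1.0))
    sd_local = np.sqrt(0.5 * (rvar[idx - w] + rvar[idx]))
    se = np.maximum.reduce([sd_local, np.full_like(sd_local, p.baseline_sd), np.full_like(sd_local, _EPS_SD)]) * np.sqrt(leverage)
    est[idx] = d
    g[idx] = d + 0.5 * (slope[idx - w] + slope[idx])
    stat[idx] = d / se
    return est, g, stat


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, intercept); a single point fits a constant."""
    if x.size == 1:
        return 0.0, float(y[0])
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _leverage(x: np.ndarray, xb: float) -> float:
    """Prediction-variance factor of a line fit evaluated at xb."""
    if x.size == 1:
        return 1.0
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    return 1.0 / x.size + (xb - xbar) ** 2 / sxx


def _refit_step(y: np.ndarray, i: int, lo: int, hi: int, w: int, sd: float):
    """Step estimate at boundary i with windows clipped to the exclusive
    bounds (lo, hi); returns (est, g, stat) or None if either window is
    empty.  Windows down to a single sample are allowed so that events
    bounded by accepted neighbours a couple of samples away stay
    resolvable in the noise-free limit (tiny windows carry large
    extrapolation leverage, so they cannot score under real noise)."""
    a = max(i - w, lo + 1)
    b = min(i + w, hi)
    if i - a < 1 or b - i < 1:
        return None
    xp = np.arange(a, i, dtype=float)
    xq = np.arange(i, b, dtype=float)
    mp, cp = _fit_line(xp, y[a:i])
    mq, cq = _fit_line(xq, y[i:b])
    xb = i - 0.5
    est = (mq * xb + cq) - (mp * xb + cp)
    g = est + 0.5 * (mp + mq)
    ssr = float(np.sum((y[a:i] - (mp * xp + cp)) ** 2) + np.sum((y[i:b] - (mq * xq + cq)) ** 2))
    n_par = (1 if xp.size == 1 else 2) + (1 if xq.size == 1 else 2)
    dof = max(xp.size + xq.size - n_par, 1)
    sd_local = np.sqrt(ssr / dof)
    se = max(sd_local, sd, _EPS_SD) * np.sqrt(_leverage(xp, xb) + _leverage(xq, xb))
    return float(est), float(g), float(est / se)


def detect_steps(p: ProcessedCurve, params: DetectionParams | None = None) -> list[StepCandidate]:
    """Find force-release steps in a corrected retract trace.

    Only steps in the release direction (force increasing toward the
    baseline) count.  A candidate must clear both the dimensionless
    statistic threshold and a force gate: the larger of
    ``min_force_factor * baseline_sd`` and the absolute
    ``min_step_force_pN`` floor, applied to the trace-difference quantity
    ``g``.  Candidates are strict local maxima of the statistic; each is
    verified with windows truncated at its accepted neighbours, which
    resolves genuinely distinct steps only a few samples apart while
    suppressing side-lobe ghosts of a single step.  Raises
    InsufficientDataError for curves shorter than four windows.
    """
    params = params or DetectionParams()
    params.validate()
    w = params.window_w
    if p.n < 4 * w:
        raise InsufficientDataError(f"curve has {p.n} samples, need >= {4 * w}")
    est, g, stat = step_statistic(p, params)
    theta = params.threshold_theta
    gate = max(params.min_force_factor * p.baseline_sd, params.min_step_force_pN)

    # Candidate pool: strict local maxima of the statistic in either
    # direction, plus every index whose raw one-sample difference clears
    # the force gate (the global statistic is blind next to a neighbouring
    # event, whose presence inflates the local residual scale).  Negative
    # candidates (tether engagements and the like) are tracked internally
    # so that accepted ones can truncate their neighbours' windows; only
    # positive (force-release) events are reported.
    left = np.empty_like(stat)
    right = np.empty_like(stat)
    left[0], right[-1] = 0.0, 0.0
    left[1:] = stat[:-1]
    right[:-1] = stat[1:]
    a_stat = np.abs(stat)
    peak_mask = (a_stat >= theta) & (a_stat > np.abs(left)) & (a_stat >= np.abs(right))
    signs: dict[int, int] = {}
    for i in np.flatnonzero(peak_mask):
        signs[int(i)] = 1 if stat[i] > 0 else -1
    diffs = np.diff(p.force)
    # pool membership is more permissive than acceptance: sub-gate steps
    # still deserve to truncate a neighbour's windows.  The noise term keeps
    # the pool sparse on noisy traces (raw differences scatter with
    # sd*sqrt(2)), where close-pair rescue is beyond resolution anyway.
    pool_gate = max(0.5 * gate, 4.0 * np.sqrt(2.0) * p.baseline_sd)
    for j in np.flatnonzero(np.abs(diffs) >= pool_gate):
        i = int(j) + 1
        if w <= i <= p.n - w and i not in signs:
            signs[i] = 1 if diffs[j] > 0 else -1
    if not signs:
        return []
    order = sorted(signs, key=lambda i: (-a_stat[i], i))

    def judge(i: int, sign: int, lo: int, hi: int):
        if lo >= i - w or hi <= i + w:
            refit = _refit_step(p.force, i, lo, hi, w, p.baseline_sd)
            if refit is None:
                return None
            est_i, g_i, stat_i = refit
        else:
            est_i, g_i, stat_i = float(est[i]), float(g[i]), float(stat[i])
        if sign * stat_i < theta or sign * g_i < gate or sign * est_i <= 0:
            return None
        return est_i

    def decide(i: int, sign: int, accepted: dict[int, tuple[int, float]]):
        same = [j for j, (s, _) in accepted.items() if s == sign and j != i]
        if any(abs(j - i) < params.min_separation_events for j in same):
            return None
        lo_n = [j for j in accepted if j < i]
        hi_n = [j for j in accepted if j > i]
        lo = max(lo_n) if lo_n else -10 * w
        hi = min(hi_n) if hi_n else p.n + 10 * w
        res = judge(i, sign, lo, hi)
        if res is not None:
            return res
        # second chance: a not-yet-accepted candidate inside the window may
        # be the contaminant; truncating at it costs nothing when it is
        # spurious and rescues both members of a genuine close pair
        lo2 = max([j for j in signs if lo < j < i] or [lo])
        hi2 = min([j for j in signs if i < j < hi] or [hi])
        if (lo2, hi2) != (lo, hi):
            return judge(i, sign, lo2, hi2)
        return None

    # Iterate to a fixed point: a candidate rejected while a weaker true
    # neighbour was still unverified gets a second chance once the neighbour
    # is in, and ghosts admitted early are evicted once their source step is.
    accepted: dict[int, tuple[int, float]] = {}
    for _ in range(6):
        changed = False
        for i in order:
            others = {j: v for j, v in accepted.items() if j != i}
            res = decide(i, signs[i], others)
            if res is None:
                if i in accepted:
                    del accepted[i]
                    changed = True
            elif i not in accepted or accepted[i] != (signs[i], res):
                accepted[i] = (signs[i], res)
                changed = True
        if not changed:
            break

    # internally accepted negative steps (tether engagements and similar)
    # are stashed so that classification windows can be truncated at them
    p.provenance["negative_steps"] = sorted(i for i, (s, _) in accepted.items() if s < 0)
    kept = sorted(i for i, (s, _) in accepted.items() if s > 0)

    def cluster_force(i: int) -> float:
        """Reported height: a spacing-rejected same-sign partner within the
        resolution limit is part of the same trace discontinuity, so the
        height is measured across the whole cluster (lines fitted before
        and after it), recovering the summed step."""
        left = right = i
        moved = True
        while moved:
            moved = False
            for j in signs:
                if j in accepted or signs[j] != 1:
                    continue
                if 0 < left - j < params.min_separation_events:
                    left, moved = j, True
                elif 0 < j - right < params.min_separation_events:
                    right, moved = j, True
        if left == i and right == i:
            return accepted[i][1]
        lo_n = [j for j in accepted if j < i and j != i]
        hi_n = [j for j in accepted if j > i]
        a = max(left - w, (max(lo_n) + 1) if lo_n else 0)
        b = min(right + 1 + w, min(hi_n) if hi_n else p.n)
        if left - a < 1 or b - (right + 1) < 1:
            return accepted[i][1]
        xp = np.arange(a, left, dtype=float)
        xq = np.arange(right + 1, b, dtype=float)
        if xp.size < 1 or xq.size < 1:
            return accepted[i][1]
        mp, cp = _fit_line(xp, p.force[a:left])
        mq, cq = _fit_line(xq, p.force[right + 1 : b])
        xb = left - 0.5
        return float((mq * xb + cq) - (mp * xb + cp))

    return [StepCandidate(index=i, step_force_pN=cluster_force(i), statistic=float(stat[i])) for i in kept]


def _segment_slope(p: ProcessedCurve, a: int, b: int) -> float:
    """LS slope of force vs separation over [a, b), 0 if degenerate."""
    s_win = p.separation[a:b]
    f_win = p.force[a:b]
    if s_win.size >= 2 and np.ptp(s_win) > 0:
        return float(np.polyfit(s_win, f_win, 1)[0])
    return 0.0


def _adaptive_slope(p: ProcessedCurve, i: int, bound: int, params: DetectionParams) -> float:
    """Slope of the locally linear stretch adjacent to sample i.

    Grows the window from the step outward (toward ``bound``, exclusive) in
    quarter-steps of ``slope_window`` and keeps the longest stretch whose
    line-fit residuals stay consistent with the baseline noise: an
    engagement kink of another bond inside the window inflates the
    residuals and stops the growth, so the fitted slope describes the
    segment the step actually sits on.  Longer windows win because the
    slope error shrinks ~ length^(-3/2).  Returns (slope, standard error).
    """
    direction = 1 if bound > i else -1
    max_len = abs(bound - i)
    if max_len < 2:
        return 0.0, np.inf
    base = max(params.window_w, params.slope_window // 4)
    lengths = sorted({min(max_len, L) for L in (base, *range(base * 2, params.slope_window + 1, base))})
    tol = 1.5 * max(p.baseline_sd, _EPS_SD)
    best = None
    for L in lengths:
        a, b = (i, i + L) if direction > 0 else (i - L, i)
        s_win, f_win = p.separation[a:b], p.force[a:b]
        if s_win.size < 2 or np.ptp(s_win) <= 0:
            continue
        coef = np.polyfit(s_win, f_win, 1)
        resid = f_win - np.polyval(coef, s_win)
        ok = np.sqrt(np.mean(resid**2)) <= tol
        if best is None or ok:
            sxx = float(((s_win - s_win.mean()) ** 2).sum())
            se = max(p.baseline_sd, _EPS_SD) / np.sqrt(sxx) if sxx > 0 else np.inf
            best = (float(coef[0]), float(se))
        if not ok:
            break
    return (0.0, np.inf) if best is None else best


def classify_event(
    p: ProcessedCurve,
    candidate: StepCandidate,
    params: DetectionParams | None = None,
    prev_index: int | None = None,
    next_index: int | None = None,
) -> RuptureEvent:
    """Classify a detected step as a bond-rupture jump or a tether release.

    Force-vs-separation slopes are fitted over ``slope_window`` samples on
    each side of the step (truncated at the neighbouring detected events
    when given).  A bond rupture removes the bond's loading stiffness, so
    the slope relaxes by ~k_eff across the step; a tether detach removes a
    constant-force plateau and leaves the slope unchanged.  The class is
    therefore decided by the slope *change*: jump if
    |pre_slope - post_slope| >= slope_min, tether otherwise -- a rule that
    stays correct when a tether lets go while other bonds are still being
    loaded.  The window is much longer than the detection window because a
    slope of a few hundredths of a pN/nm must be resolved against
    per-sample noise of a few pN.  The loading rate is |pre_slope| times
    the pulling velocity.
    """
    params = params or DetectionParams()
    if p.separation is None:
        raise ValidationError("run find_contact_point before classify_event")
    i = candidate.index
    neg = p.provenance.get("negative_steps", [])
    lo = max(i - params.slope_window, 0)
    if prev_index is not None:
        lo = max(lo, prev_index + 1)
    neg_left = [j for j in neg if lo <= j < i]
    if neg_left:
        lo = max(lo, max(neg_left) + 1)
    hi = min(i + params.slope_window, p.n)
    if next_index is not None:
        hi = min(hi, next_index)
    neg_right = [j for j in neg if i < j < hi]
    if neg_right:
        hi = min(hi, min(neg_right))
    pre_slope, pre_se = _adaptive_slope(p, i, lo, params)
    post_slope, post_se = _adaptive_slope(p, i, hi, params)
    # variance-aware discriminant: short usable segments cannot resolve a
    # small stiffness release, so the evidence bar rises with the slope
    # uncertainty -- but is capped so a clear k_eff-sized release stays
    # callable even from a cramped neighbourhood
    se_change = float(np.hypot(pre_se, post_se))
    threshold = max(params.slope_min, min(2.5 * se_change, 3.0 * params.slope_min))
    event_class = "jump" if abs(pre_slope - post_slope) >= threshold else "tether"
    k = p.metadata.spring_constant_k
    v_nm = p.metadata.velocity_v * 1000.0
    return RuptureEvent(
        curve_id=p.metadata.curve_id,
        index=i,
        separation_nm=float(p.separation[i]),
        step_height_d=candidate.step_force_pN / k,
        force_F=candidate.step_force_pN,
        event_class=event_class,
        loading_rate_r=abs(pre_slope) * v_nm,
        pre_slope=pre_slope,
    )


def process_curve(
    curve: ForceCurve, params: DetectionParams | None = None
) -> tuple[ProcessedCurve, list[RuptureEvent]]:
    """End-to-end per-curve pipeline: baseline, contact, steps, classes.

    Events inside the contact region (non-specific surface interactions)
    are excluded; the returned list is sorted by separation.
    """
    params = params or DetectionParams()
    try:
        p = correct_baseline(curve, params)
        contact = find_contact_point(p)
        candidates = detect_steps(p, params)
    except InsufficientDataError as exc:
        raise InsufficientDataError(f"curve {curve.metadata.curve_id!r}: {exc}") from exc
    events = []
    prev: int | None = None
    indices = [c.index for c in candidates]
    for pos, c in enumerate(candidates):
        nxt = indices[pos + 1] if pos + 1 < len(indices) else None
        if c.index <= contact + params.window_w:
            prev = c.index
            continue
        events.append(classify_event(p, c, params, prev_index=prev, next_index=nxt))
        prev = c.index
    events.sort(key=lambda e: e.separation_nm)
    return p, events


def _cluster_truth(truth: list[RuptureEvent], resolution: int) -> list[RuptureEvent]:
    if resolution <= 1:
        return truth
    out: list[RuptureEvent] = []
    by_curve: dict[str, list[RuptureEvent]] = {}
    for t in truth:
        by_curve.setdefault(t.curve_id, []).append(t)
    for cid in sorted(by_curve):
        group: list[RuptureEvent] = []
        for t in sorted(by_curve[cid], key=lambda e: e.index):
            if group and t.index - group[-1].index < resolution:
                group.append(t)
            else:
                if group:
                    out.append(_merge_events(group))
                group = [t]
        if group:
            out.append(_merge_events(group))
    return out


def _merge_events(group: list[RuptureEvent]) -> RuptureEvent:
    if len(group) == 1:
        return group[0]
    lead = max(group, key=lambda e: e.force_F)
    total = sum(e.force_F for e in group)
    k_ratio = lead.step_height_d / lead.force_F if lead.force_F else 0.0
    from dataclasses import replace as _replace

    return _replace(lead, force_F=total, step_height_d=total * k_ratio)


def detection_benchmark(
    truth: Sequence[RuptureEvent],
    detected: Sequence[RuptureEvent],
    match_window: int = 30,
    min_truth_force: float = 0.0,
    resolution: int = 3,
) -> BenchmarkResult:
    """Score detections against ground truth by nearest-index pairing.

    One-to-one greedy matching within ``match_window`` samples (pairs sorted
    by index distance).  ``min_truth_force`` restricts recall and the force
    RMSE to truth events at or above that force (e.g. the detectable range
    at a given noise level); unmatched detections always count against
    precision and unmatched truths above the floor against recall.

    Truth events of one curve closer than ``resolution`` samples are merged
    (summed force, index and class of the largest member) before matching:
    ruptures inside a step detector's resolution appear in the trace as one
    discontinuity whose height is the sum, so that is the recoverable
    ground truth.  Pass ``resolution=1`` to disable merging.
    """
    truth = _cluster_truth(list(truth), resolution)
    detected = list(detected)
    by_curve: dict[str, list[int]] = {}
    pairs: list[tuple[int, int, int]] = []
    det_by_curve: dict[str, list[int]] = {}
    for ti, t in enumerate(truth):
        by_curve.setdefault(t.curve_id, []).append(ti)
    for di, d in enumerate(detected):
        det_by_curve.setdefault(d.curve_id, []).append(di)
    for cid, dis in det_by_curve.items():
        for di in dis:
            for ti in by_curve.get(cid, []):
                dist = abs(detected[di].index - truth[ti].index)
                if dist <= match_window:
                    pairs.append((dist, ti, di))
    pairs.sort()
    matched_t: dict[int, int] = {}
    matched_d: set[int] = set()
    for dist, ti, di in pairs:
        if ti in matched_t or di in matched_d:
            continue
        matched_t[ti] = di
        matched_d.add(di)

    eligible = [ti for ti, t in enumerate(truth) if t.force_F >= min_truth_force]
    hits = [ti for ti in eligible if ti in matched_t]
    recall = len(hits) / len(eligible) if eligible else 1.0
    precision = len(matched_d) / len(detected) if detected else 1.0
    if hits:
        errs = np.array([detected[matched_t[ti]].force_F - truth[ti].force_F for ti in hits])
        rmse = float(np.sqrt(np.mean(errs**2)))
    else:
        rmse = float("nan") if eligible else 0.0
    return BenchmarkResult(
        recall=float(recall),
        precision=float(precision),
        force_rmse_pN=rmse,
        n_truth=len(eligible),
        n_detected=len(detected),
        n_matched=len(hits),
    )
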