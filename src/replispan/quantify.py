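"""Kymograph quantification: images -> length traces -> divisions -> lifespan.

Mirrors the two-stage image pipeline used with catch-channel devices:

Stage 1 (pre-processing): undo the fixed field rotation, then register
every frame to the first by cross-correlation to remove stage jitter.

Stage 2 (quantification): extract the centerline pixel row of each frame
from the notch toward the central trench and stack the rows into a 2-D
kymograph; annotate the old-pole and leftmost-septum positions; convert to
a length time series; call divisions at the local minima of the smoothed
trace; screen for catch-channel ejection events (abrupt, non-division
length changes) whose cells are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate

from .simulate import KymographStack

__all__ = [
    "RegistrationResult",
    "LengthTrace",
    "DivisionResult",
    "correct_rotation",
    "register_stack",
    "build_kymograph",
    "annotate_kymograph",
    "trace_lengths",
    "detect_divisions",
    "detect_ejection",
    "detect_neto",
    "quantify_stack",
]


class AnnotationError(ValueError):
    pass


@dataclass
class RegistrationResult:
    """Integer per-frame displacement relative to frame 0 (row, col)."""

    shifts: np.ndarray                  # (T, 2) int
    rotation_applied: float = 0.0
    registered: KymographStack | None = None

    def __post_init__(self) -> None:
        if tuple(self.shifts[0]) != (0, 0):
            raise ValueError("shift of frame 0 must be (0, 0)")


@dataclass
class LengthTrace:
    """Per-timepoint cell length with its annotation and quality flags."""

    times: np.ndarray       # hours
    lengths: np.ndarray     # um
    pole: np.ndarray        # old-pole column per timepoint (kymograph coords)
    septum: np.ndarray      # leftmost-septum / new-end column per timepoint
    pixel_size: float = 1.0
    ejection_suspected: bool = False
    ejection_time: float | None = None


@dataclass
class DivisionResult:
    """Division calls from a length trace."""

    division_times: np.ndarray      # hours
    division_indices: np.ndarray    # trace indices of the accepted minima
    division_lengths: np.ndarray    # um, pre-division peak length
    intervals: np.ndarray           # hours between consecutive divisions
    generation_count: int = 0

    def __post_init__(self) -> None:
        self.generation_count = len(self.division_times)


# --------------------------------------------------------------------------
# stage 1: rotation + drift correction
# --------------------------------------------------------------------------

def correct_rotation(stack: KymographStack, measured_angle: float) -> KymographStack:
    """Apply the corrective rotation -measured_angle to every frame.

    The angle is measured from the static device geometry (the channel-wall
    axis relative to the image axis); the same correction is applied to the
    whole sequence.  Linear interpolation; frame shape preserved.
    """
    if abs(measured_angle) >= 45:
        raise ValueError("|measured_angle| must be < 45 degrees")
    if measured_angle == 0.0:
        return stack
    frames = np.stack([
        rotate(f, -measured_angle, preserve_range=True, order=1,
               mode="edge").astype(np.float32)
        for f in stack.frames
    ])
    return KymographStack(frames=frames, timestamps=stack.timestamps,
                          truth=stack.truth)


def register_stack(stack: KymographStack) -> RegistrationResult:
    """Recover integer per-frame stage shifts by cross-correlation to frame 0.

    Returns the displacement of each frame relative to the first (equal to
    the applied stage jitter on synthetic stacks) and a registered copy
    with the displacements removed.
    """
    if stack.frames.shape[0] < 2:
        raise ValueError("registration needs at least 2 frames")
    ref = stack.frames[0]
    if np.ptp(ref) == 0:
        raise ValueError("degenerate correlation: reference frame is constant")
    shifts = np.zeros((stack.frames.shape[0], 2), dtype=int)
    registered = np.empty_like(stack.frames)
    registered[0] = ref
    for i in range(1, stack.frames.shape[0]):
        frame = stack.frames[i]
        if np.ptp(frame) == 0:
            raise ValueError(f"degenerate correlation: frame {i} is constant")
        # phase correlation returns the shift that maps `frame` onto `ref`,
        # i.e. minus the displacement of the frame
        shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=1,
                                              normalization=None)
        disp = -np.round(shift).astype(int)
        shifts[i] = disp
        registered[i] = np.roll(frame, (-disp[0], -disp[1]), axis=(0, 1))
    reg_stack = KymographStack(frames=registered, timestamps=stack.timestamps,
                               truth=stack.truth)
    return RegistrationResult(shifts=shifts, registered=reg_stack)


# --------------------------------------------------------------------------
# stage 2: kymograph, annotation, length tracing
# --------------------------------------------------------------------------

def build_kymograph(stack: KymographStack, notch_position: int,
                    centerline_row: int) -> np.ndarray:
    """Stack centerline pixel rows into a 2-D kymograph (time down rows).

    Row t of the output is the pixel line of frame t along the channel
    centerline, from the notch center toward the central trench.
    """
    rows = stack.frames.shape[1]
    if not 0 <= centerline_row < rows:
        raise ValueError("centerline_row outside frame")
    if not 0 <= notch_position < stack.frames.shape[2]:
        raise ValueError("notch_position outside frame")
    return np.asarray(stack.frames[:, centerline_row, notch_position:])


def annotate_kymograph(kymo: np.ndarray, threshold: float | None = None,
                       smooth: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Programmatic pole/septum annotation from a kymograph.

    The old pole is anchored at the notch (column 0); the far cell boundary
    is the last column of each (median-filtered) row darker than the
    threshold, defaulting to the midpoint between the dark cell body and
    the bright channel lumen.
    """
    kymo = np.asarray(kymo, dtype=float)
    if smooth > 1:
        kymo = ndimage.median_filter(kymo, size=(1, smooth))
    if threshold is None:
        threshold = 0.5 * (kymo.min() + kymo.max())
    dark = kymo < threshold
    n_t = kymo.shape[0]
    pole = np.zeros(n_t, dtype=int)
    septum = np.zeros(n_t, dtype=int)
    for t in range(n_t):
        cols = np.flatnonzero(dark[t])
        if cols.size == 0:
            raise AnnotationError(f"no cell found in kymograph row {t}")
        # restrict to the run of dark pixels containing the pole
        breaks = np.flatnonzero(np.diff(cols) > 2)
        end = cols[breaks[0]] if breaks.size else cols[-1]
        septum[t] = end
    return pole, septum


def trace_lengths(times: np.ndarray, annotations, pixel_size: float) -> LengthTrace:
    """Convert pole/septum annotations into a length time series (um).

    ``annotations`` is either dense — a ``(pole, septum)`` pair of
    per-timepoint column arrays — or sparse, a list of
    ``(time_index, pole_col, septum_col)`` marks (e.g. clicked at each
    division) that are linearly interpolated to the full grid.
    """
    times = np.asarray(times, dtype=float)
    if isinstance(annotations, tuple) and len(annotations) == 2:
        pole = np.asarray(annotations[0], dtype=float)
        septum = np.asarray(annotations[1], dtype=float)
    else:
        marks = sorted(annotations)
        idx = np.array([m[0] for m in marks], dtype=float)
        pole = np.interp(np.arange(len(times)), idx,
                         [m[1] for m in marks])
        septum = np.interp(np.arange(len(times)), idx,
                           [m[2] for m in marks])
    if np.any(septum <= pole):
        raise AnnotationError("septum position must lie right of the old pole")
    lengths = (septum - pole) * pixel_size
    return LengthTrace(times=times, lengths=lengths, pole=pole,
                       septum=septum, pixel_size=pixel_size)


# --------------------------------------------------------------------------
# division calling, ejection screening, NETO
# --------------------------------------------------------------------------

def _smoothed(lengths: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(lengths, dtype=float)
    return ndimage.median_filter(np.asarray(lengths, dtype=float),
                                 size=window, mode="nearest")


def detect_divisions(trace: LengthTrace, smoothing_window: int = 5,
                     min_generation_time: float = 0.5,
                     drop_fraction: float = 0.72) -> DivisionResult:
    """Call divisions at local minima of the smoothed length trace.

    Growth between divisions is monotone, so the trace is a rising sawtooth
    and every division is a sharp reset: after moving-median smoothing, a
    division is called where the trace falls below ``drop_fraction`` of its
    running maximum since the previous division, at the local minimum of
    the drop.  Minima closer together than ``min_generation_time`` are
    merged, keeping the deepest.  The replicative age is the number of
    accepted minima.
    """
    if len(trace.lengths) == 0:
        raise ValueError("empty trace")
    if len(trace.lengths) < 3:
        return DivisionResult(np.array([]), np.array([], dtype=int),
                              np.array([]), np.array([]))
    lengths = np.asarray(trace.lengths, dtype=float)
    sm = _smoothed(lengths, smoothing_window)
    n = len(sm)

    accepted: list[int] = []
    run_max = sm[0]
    i = 1
    while i < n:
        if sm[i] < drop_fraction * run_max:
            while i + 1 < n and sm[i + 1] < sm[i]:   # walk to the bottom
                i += 1
            if (accepted and trace.times[i] - trace.times[accepted[-1]]
                    < min_generation_time):
                if sm[i] < sm[accepted[-1]]:          # merge: keep deepest
                    accepted[-1] = i
            else:
                accepted.append(i)
            run_max = sm[i]
        else:
            run_max = max(run_max, sm[i])
        i += 1
    if not accepted:
        return DivisionResult(np.array([]), np.array([], dtype=int),
                              np.array([]), np.array([]))
    idx = np.asarray(accepted, dtype=int)

    div_lengths = np.empty(idx.size)
    prev = 0
    for k, i in enumerate(idx):
        div_lengths[k] = float(np.max(lengths[prev:i + 1]))
        prev = i
    div_times = trace.times[idx]
    intervals = np.diff(np.concatenate([[trace.times[0]], div_times]))
    return DivisionResult(division_times=div_times, division_indices=idx,
                          division_lengths=div_lengths, intervals=intervals)


def detect_ejection(trace: LengthTrace, drop_threshold: float = 0.35):
    """Flag abrupt non-division length changes (catch-channel re-loading).

    Any between-frame relative length change larger than ``drop_threshold``
    is suspect unless it is consistent with medial fission — a drop to
    42–58% of the pre-drop length (four sigma of the division-asymmetry
    spread) within one frame of an accepted division minimum.  Flagged
    cells are excluded from the final analysis downstream.
    """
    lengths = np.asarray(trace.lengths, dtype=float)
    if lengths.size < 2:
        return False, None
    ratio = lengths[1:] / lengths[:-1]
    change = np.abs(lengths[1:] - lengths[:-1]) / lengths[:-1]
    suspects = np.flatnonzero(change > drop_threshold)
    if suspects.size == 0:
        return False, None
    div = detect_divisions(trace)
    div_idx = set(div.division_indices.tolist())
    for i in suspects:
        near_division = any(abs((i + 1) - j) <= 1 for j in div_idx)
        halving = 0.42 < ratio[i] < 0.58
        if not (near_division and halving):
            return True, float(trace.times[i + 1])
    return False, None


def detect_neto(t_norm: np.ndarray, l_norm: np.ndarray,
                slope_tol: float = 0.05):
    """Fit a continuous two-segment line to one normalized generation.

    Input is a single complete generation with time and length normalized
    to [0, 1].  A continuous piecewise-linear least-squares fit over a grid
    of candidate breakpoints returns the NETO breakpoint (cycle fraction)
    and the two slopes.  If the slopes differ by less than ``slope_tol``
    (relative to the mean slope) the breakpoint is unidentifiable and
    ``None`` is returned in its place.
    """
    t = np.asarray(t_norm, dtype=float)
    y = np.asarray(l_norm, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 points in the generation")

    def sse_for(c: float):
        hinge = np.maximum(t - c, 0.0)
        X = np.column_stack([np.ones_like(t), t, hinge])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(res[0]) if res.size else float(np.sum((X @ coef - y) ** 2))
        return sse, coef

    grid = np.linspace(0.08, 0.92, 169)
    sses = np.array([sse_for(c)[0] for c in grid])
    c0 = grid[int(np.argmin(sses))]
    res = optimize.minimize_scalar(lambda c: sse_for(c)[0],
                                   bounds=(max(0.02, c0 - 0.02),
                                           min(0.98, c0 + 0.02)),
                                   method="bounded")
    c_best = float(res.x)
    _, coef = sse_for(c_best)
    s1 = float(coef[1])
    s2 = float(coef[1] + coef[2])
    mean_slope = 0.5 * (abs(s1) + abs(s2))
    if mean_slope == 0 or abs(s2 - s1) < slope_tol * mean_slope:
        return None, s1, s2
    return c_best, s1, s2


# --------------------------------------------------------------------------
# end-to-end quantification of one stack
# --------------------------------------------------------------------------

def quantify_stack(stack: KymographStack, pixel_size: float, notch_col: int,
                   centerline_row: int, rotation_deg: float = 0.0,
                   smoothing_window: int = 5, min_generation_time: float = 0.5):
    """Full Stage 1 + Stage 2 chain: stack -> (LengthTrace, DivisionResult).

    Rotation correction, drift registration, kymograph construction,
    programmatic annotation, length tracing and division calling with the
    ejection screen applied.
    """
    stack = correct_rotation(stack, rotation_deg)
    reg = register_stack(stack)
    kymo = build_kymograph(reg.registered, notch_col, centerline_row)
    annotations = annotate_kymograph(kymo)
    trace = trace_lengths(stack.timestamps, annotations, pixel_size)
    flagged, t_flag = detect_ejection(trace)
    trace.ejection_suspected = flagged
    trace.ejection_time = t_flag
    divisions = detect_divisions(trace, smoothing_window, min_generation_time)
    return trace, divisions
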