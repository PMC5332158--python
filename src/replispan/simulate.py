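"""Stochastic single-cell lineage simulator for fission-yeast lifespan studies.

Generates the three kinds of raw data the downstream pipeline consumes, with
full ground truth attached:

* lifespan tables — per-cell generation-at-death under exponential
  (constant-hazard) or Gompertz (age-dependent) mortality;
* growth trajectories — bilinear per-generation length traces with a NETO
  (new end take-off) rate change partway through each cycle, medial fission
  at division, and short/elongated terminal phenotypes;
* synthetic catch-channel image stacks — a dark rod in a microfluidic
  channel, with stage jitter, field rotation and shot noise, rendered as a
  multi-frame grayscale stack whose kymograph reproduces the sawtooth
  growth-and-division pattern of the real device.

Death is discrete in replicative age: a cell's lifespan is the number of
divisions it completes, and the survivor function is matched exactly at
integer generations by inverse-CDF sampling of the mass S(g-1) - S(g).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MortalityModel",
    "GrowthParams",
    "PhenotypeProbs",
    "ImagingParams",
    "CellTrajectory",
    "KymographStack",
    "LIFESPAN_COLUMNS",
    "SIBLING_FATES",
    "DEFECT_CLASSES",
    "DEFAULT_DEFECT_LETHALITY",
    "sample_lifespans",
    "simulate_trajectory",
    "simulate_cohort",
    "sample_cell_records",
    "assign_terminal_phenotypes",
    "sample_defect_events",
    "render_kymograph_stack",
    "cell_rng",
]


class InvalidModelError(ValueError):
    """Raised when mortality-model coefficients are outside their domain."""


SIBLING_FATES = ("never_divided", "divided_once", "divided_multiple")
DEFECT_CLASSES = ("normal", "multi", "unequal", "bridge")

LIFESPAN_COLUMNS = (
    "cell_id",
    "generations_at_death",
    "status",
    "terminal_phenotype",
    "sibling_fate",
    "defect_class",
)

#: Per-class probability that a division showing the defect kills the cell.
#: Multi-focal nucleolar loci are treated as nearly always lethal; unequal
#: partitioning and anaphase bridges are lethal in a minority of divisions.
DEFAULT_DEFECT_LETHALITY = {
    "normal": 0.02,
    "multi": 0.95,
    "unequal": 0.40,
    "bridge": 0.40,
}


# --------------------------------------------------------------------------
# mortality model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MortalityModel:
    """Per-generation mortality law.

    Parameters
    ----------
    kind:
        ``"exponential"`` for a constant hazard (non-aging) or
        ``"gompertz"`` for an exponentially increasing hazard (aging).
    alpha:
        Age-independent hazard scale, per generation, > 0.
    beta:
        Age-dependent rate, per generation, >= 0.  Ignored (treated as 0)
        for the exponential kind.

    The survivor function is ``S(g) = exp(-alpha * g)`` (exponential) or
    ``S(g) = exp((alpha / beta) * (1 - exp(beta * g)))`` (Gompertz); the
    hazard is ``alpha`` and ``alpha * exp(beta * g)`` respectively.
    """

    kind: str
    alpha: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "gompertz"):
            raise InvalidModelError(f"unknown mortality kind {self.kind!r}")
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise InvalidModelError("mortality.alpha must be finite and > 0")
        if not np.isfinite(self.beta) or self.beta < 0:
            raise InvalidModelError("mortality.beta must be finite and >= 0")

    @property
    def effective_beta(self) -> float:
        return 0.0 if self.kind == "exponential" else self.beta

    def survival(self, g):
        """S(g): probability of being alive after generation g."""
        g = np.asarray(g, dtype=float)
        b = self.effective_beta
        if b < 1e-12:   # exponential limit (also guards denormal beta)
            return np.exp(-self.alpha * g)
        # exp((alpha/beta) * (1 - e^{beta g})), via expm1 for small beta*g;
        # overflow in the deep tail maps cleanly to S = 0
        with np.errstate(over="ignore"):
            return np.exp(-self.alpha * np.expm1(b * g) / b)

    def hazard(self, g):
        """lambda(g): instantaneous per-generation risk of death."""
        g = np.asarray(g, dtype=float)
        return self.alpha * np.exp(self.effective_beta * g)

    def rls(self) -> float:
        """Median lifespan: the g at which S(g) crosses 1/2 (closed form)."""
        b = self.effective_beta
        if b < 1e-12:
            return float(np.log(2) / self.alpha)
        return float(np.log1p(b * np.log(2) / self.alpha) / b)

    def inverse_survival(self, u):
        """Continuous g such that S(g) = u, for u in (0, 1]."""
        u = np.asarray(u, dtype=float)
        b = self.effective_beta
        if b < 1e-12:
            return -np.log(u) / self.alpha
        return np.log1p(-b * np.log(u) / self.alpha) / b


# --------------------------------------------------------------------------
# growth / phenotype / imaging parameter sets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthParams:
    """Bilinear growth-law parameters (defaults: wild-type fission yeast).

    Cells are born at ~8.3 um, extend linearly at a slow monopolar rate
    until the NETO switch at ``neto_fraction`` of the cycle, then at a
    faster bipolar rate until dividing medially at ~16 um after ~2.05 h.
    ``monopolar_rate_share`` is the fraction of the generation's total
    extension accrued before NETO; values below ``neto_fraction`` give the
    slow-then-fast profile.
    """

    birth_length_mean: float = 8.3       # um
    birth_length_sd: float = 1.5         # um
    division_length_mean: float = 16.0   # um
    division_length_sd: float = 2.2      # um
    doubling_time_mean: float = 2.05     # hours
    doubling_time_sd: float = 0.45       # hours
    neto_fraction: float = 0.3
    monopolar_rate_share: float = 0.2
    division_asymmetry_sd: float = 0.02  # sd of the septum-position fraction
    sampling_interval: float = 2.0       # minutes

    def __post_init__(self) -> None:
        for name in ("birth_length_mean", "division_length_mean",
                     "doubling_time_mean", "sampling_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"growth.{name} must be > 0")
        for name in ("birth_length_sd", "division_length_sd",
                     "doubling_time_sd", "division_asymmetry_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"growth.{name} must be >= 0")
        if self.division_length_mean <= self.birth_length_mean:
            raise ValueError(
                "growth.division_length_mean must exceed birth_length_mean")
        if not 0 < self.neto_fraction < 1:
            raise ValueError("growth.neto_fraction must lie in (0, 1)")
        if not 0 < self.monopolar_rate_share < 1:
            raise ValueError("growth.monopolar_rate_share must lie in (0, 1)")

    @property
    def sampling_interval_h(self) -> float:
        return self.sampling_interval / 60.0


def _check_simplex(values: Sequence[float], name: str) -> None:
    if any(v < 0 for v in values):
        raise ValueError(f"phenotype.{name} entries must be >= 0")
    if abs(sum(values) - 1.0) > 1e-9:
        raise ValueError(f"phenotype.{name} must sum to 1 (got {sum(values)})")


@dataclass(frozen=True)
class PhenotypeProbs:
    """Terminal phenotype, last-sibling fate and division-defect frequencies.

    Defaults reproduce the wild-type tallies: 72% of dying cells die short
    of the normal division length and 28% hyper-elongate; last siblings
    never divide / divide once / keep dividing at 66/14/20%; nucleolar
    (rDNA) segregation defects occur in ~7% of all divisions but ~40% of
    terminal divisions.
    """

    p_short_death: float = 0.72
    p_elongated_death: float = 0.28
    sibling_fate_probs: tuple = (0.66, 0.14, 0.20)
    defect_class_probs: tuple = (0.9256, 0.0085, 0.0330, 0.0329)
    defect_class_probs_dying: tuple = (0.6028, 0.1134, 0.1419, 0.1419)

    def __post_init__(self) -> None:
        _check_simplex((self.p_short_death, self.p_elongated_death),
                       "p_short_death/p_elongated_death")
        _check_simplex(self.sibling_fate_probs, "sibling_fate_probs")
        _check_simplex(self.defect_class_probs, "defect_class_probs")
        _check_simplex(self.defect_class_probs_dying,
                       "defect_class_probs_dying")


@dataclass(frozen=True)
class ImagingParams:
    """Synthetic catch-channel rendering geometry and nuisance levels."""

    pixel_size: float = 0.2          # um per pixel
    frame_shape: tuple = (64, 384)   # (rows, cols)
    rotation_deg: float = 0.0        # field rotation applied to every frame
    max_jitter: int = 0              # max |stage shift| per frame, pixels
    noise_sd: float = 0.0            # additive Gaussian noise, intensity units
    psf_sigma: float = 1.0           # optical blur (Gaussian PSF), pixels
    channel_center_row: int = 32     # pixel row of the channel centerline
    notch_col: int = 24              # column of the notch (old-pole anchor)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("imaging.pixel_size must be > 0")
        if abs(self.rotation_deg) >= 15:
            raise ValueError("imaging.rotation_deg must satisfy |angle| < 15")
        if self.max_jitter < 0:
            raise ValueError("imaging.max_jitter must be >= 0")
        if not 0 <= self.channel_center_row < self.frame_shape[0]:
            raise ValueError("imaging.channel_center_row outside frame")


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class CellTrajectory:
    """One cell's sampled length time series with ground truth.

    ``times`` is a uniform grid (hours); ``lengths`` the cell length (um)
    at each time point.  ``division_times`` are the strictly increasing
    times of the completed divisions; ``generation_count`` equals
    ``len(division_times)`` and is the replicative age at death.  The
    per-generation ground truth (``division_lengths``, birth lengths and
    durations) is carried for death-aligned analyses.
    """

    cell_id: str
    times: np.ndarray
    lengths: np.ndarray
    division_times: np.ndarray
    generation_count: int
    fate: str = "died"
    terminal_phenotype: str = "none"
    division_lengths: np.ndarray = field(default_factory=lambda: np.array([]))
    birth_lengths: np.ndarray = field(default_factory=lambda: np.array([]))
    generation_durations: np.ndarray = field(default_factory=lambda: np.array([]))
    terminal_duration: float = 0.0
    ground_truth: bool = True

    def __post_init__(self) -> None:
        if len(self.times) != len(self.lengths):
            raise ValueError("times and lengths must have equal length")
        if np.any(np.asarray(self.lengths) <= 0):
            raise ValueError("lengths must be positive")
        if np.any(np.diff(self.division_times) <= 0):
            raise ValueError("division_times must be strictly increasing")
        if self.generation_count != len(self.division_times):
            raise ValueError("generation_count must equal len(division_times)")


@dataclass
class KymographStack:
    """Time-ordered stack of 2-D grayscale frames with rendering truth."""

    frames: np.ndarray          # (T, rows, cols) float32
    timestamps: np.ndarray      # hours, strictly increasing
    truth: dict | None = None   # trajectory, applied shifts, imaging params

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, rows, cols) array")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")


# --------------------------------------------------------------------------
# random-number plumbing
# --------------------------------------------------------------------------

def cell_rng(master_seed: int, cell_index: int) -> np.random.Generator:
    """Independent per-cell stream derived stably from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(cell_index)]))


def _truncated_normal(rng, mean, sd, low=0.0, high=np.inf, size=None):
    """Normal draw redrawn (via the truncated distribution) to (low, high)."""
    if sd == 0:
        return np.full(size, float(mean)) if size is not None else float(mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    draw = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)
    return draw


# --------------------------------------------------------------------------
# lifespan sampling
# --------------------------------------------------------------------------

def sample_lifespans(model: MortalityModel, n_cells: int, seed: int) -> pd.DataFrame:
    """Draw integer generations-at-death matching S(g) at every integer g.

    The death generation g* satisfies P(g* > g) = S(g) exactly: a uniform
    draw u is inverted through the continuous survivor function and rounded
    up to the next integer, which is equivalent to inverse-CDF sampling of
    the discrete mass S(g-1) - S(g).  Lifespans are floored at one
    generation (every observed cell completes at least one division).

    Returns a lifespan table (DataFrame) with the standard columns;
    phenotype columns are filled with ``"none"`` until assigned.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if model.kind == "gompertz" and model.beta == 0:
        warnings.warn(
            "Gompertz model with beta=0 falls back to exponential semantics",
            UserWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    u = rng.random(n_cells)
    g_cont = model.inverse_survival(u)
    g = np.maximum(1, np.ceil(g_cont)).astype(int)
    return pd.DataFrame({
        "cell_id": [f"cell_{i:06d}" for i in range(n_cells)],
        "generations_at_death": g,
        "status": "died",
        "terminal_phenotype": "none",
        "sibling_fate": "none",
        "defect_class": "none",
    })


def assign_terminal_phenotypes(table: pd.DataFrame, probs: PhenotypeProbs,
                               seed: int) -> pd.DataFrame:
    """Assign terminal phenotype, sibling fate and defect class to dying cells.

    Draws are multinomial from the configured frequencies and independent of
    replicative age (the age-independence null of the wild-type data).
    Non-died rows keep ``"none"`` in every phenotype column.
    """
    if len(table) == 0:
        raise ValueError("lifespan table is empty")
    rng = np.random.default_rng(seed)
    out = table.copy()
    died = (out["status"] == "died").to_numpy()
    n = int(died.sum())
    phen = rng.choice(["short", "elongated"], size=n,
                      p=[probs.p_short_death, probs.p_elongated_death])
    fate = rng.choice(list(SIBLING_FATES), size=n,
                      p=list(probs.sibling_fate_probs))
    defect = rng.choice(list(DEFECT_CLASSES), size=n,
                        p=list(probs.defect_class_probs_dying))
    out.loc[died, "terminal_phenotype"] = phen
    out.loc[died, "sibling_fate"] = fate
    out.loc[died, "defect_class"] = defect
    return out


# --------------------------------------------------------------------------
# growth trajectories
# --------------------------------------------------------------------------

def _bilinear_profile(x, share, neto):
    """Fraction of the generation's extension accrued at cycle fraction x."""
    x = np.asarray(x, dtype=float)
    pre = share * x / neto
    post = share + (1.0 - share) * (x - neto) / (1.0 - neto)
    return np.where(x < neto, pre, post)


def simulate_trajectory(growth: GrowthParams, lifespan: int, phenotype: str,
                        seed) -> CellTrajectory:
    """Simulate one cell's length trace over ``lifespan`` completed divisions.

    Each generation draws a division length and doubling time (truncated
    normals), grows bilinearly (monopolar rate before NETO, bipolar after),
    and divides medially: the retained old-pole cell restarts at a noisy
    fraction (~0.5) of the division length.  After the last division the
    terminal generation implements the death phenotype: ``short`` cells die
    partway through the cycle below the division length; ``elongated``
    cells blow through the division point and keep extending for more than
    three mean doubling times without dividing.
    """
    if lifespan < 1:
        raise ValueError("lifespan must be >= 1")
    if phenotype not in ("short", "elongated"):
        raise ValueError(f"unknown phenotype {phenotype!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = growth
    dt = g.sampling_interval_h

    birth = _truncated_normal(rng, g.birth_length_mean, g.birth_length_sd,
                              low=0.5)
    seg_times = [0.0]
    seg_lengths = [birth]
    division_times, division_lengths = [], []
    birth_lengths, durations = [], []
    t = 0.0
    length = birth
    for _ in range(lifespan):
        div_len = _truncated_normal(rng, g.division_length_mean,
                                    g.division_length_sd, low=length + 0.5)
        T = _truncated_normal(rng, g.doubling_time_mean, g.doubling_time_sd,
                              low=0.25)
        birth_lengths.append(length)
        durations.append(T)
        # bilinear knot at NETO, endpoint at division
        t_neto = t + g.neto_fraction * T
        l_neto = length + g.monopolar_rate_share * (div_len - length)
        seg_times.extend([t_neto, t + T])
        seg_lengths.extend([l_neto, div_len])
        division_times.append(t + T)
        division_lengths.append(div_len)
        t += T
        frac = _truncated_normal(rng, 0.5, g.division_asymmetry_sd,
                                 low=0.4, high=0.6)
        length = div_len * frac
        seg_times.append(t + 1e-9)  # post-division reset
        seg_lengths.append(length)

    # terminal (incomplete) generation
    div_len = _truncated_normal(rng, g.division_length_mean,
                                g.division_length_sd, low=length + 0.5)
    T = _truncated_normal(rng, g.doubling_time_mean, g.doubling_time_sd,
                          low=0.25)
    if phenotype == "short":
        t_death_rel = rng.uniform(0.3, 0.8) * T
        x = t_death_rel / T
        l_death = length + _bilinear_profile(x, g.monopolar_rate_share,
                                             g.neto_fraction) * (div_len - length)
        t_neto = t + g.neto_fraction * T
        if t_death_rel > g.neto_fraction * T:
            l_neto = length + g.monopolar_rate_share * (div_len - length)
            seg_times.extend([t_neto, t + t_death_rel])
            seg_lengths.extend([l_neto, float(l_death)])
        else:
            seg_times.append(t + t_death_rel)
            seg_lengths.append(float(l_death))
        terminal_duration = t_death_rel
    else:
        # full cycle, then continued bipolar extension without division
        extra = rng.uniform(3.2, 4.5) * g.doubling_time_mean - T
        extra = max(extra, 0.5)
        bipolar_rate = ((1.0 - g.monopolar_rate_share) * (div_len - length)
                        / ((1.0 - g.neto_fraction) * T))
        t_neto = t + g.neto_fraction * T
        l_neto = length + g.monopolar_rate_share * (div_len - length)
        seg_times.extend([t_neto, t + T, t + T + extra])
        seg_lengths.extend([l_neto, div_len, div_len + bipolar_rate * extra])
        terminal_duration = T + extra
    t_end = seg_times[-1]

    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    lengths = np.interp(times, seg_times, seg_lengths)
    return CellTrajectory(
        cell_id="cell",
        times=times,
        lengths=lengths,
        division_times=np.asarray(division_times),
        generation_count=lifespan,
        fate="died",
        terminal_phenotype=phenotype,
        division_lengths=np.asarray(division_lengths),
        birth_lengths=np.asarray(birth_lengths),
        generation_durations=np.asarray(durations),
        terminal_duration=float(terminal_duration),
    )


def simulate_cohort(model: MortalityModel, growth: GrowthParams,
                    probs: PhenotypeProbs, n_cells: int, seed: int):
    """Lifespan table plus one trajectory per cell (shared master seed)."""
    table = sample_lifespans(model, n_cells, seed)
    table = assign_terminal_phenotypes(table, probs, seed + 1)
    trajectories = []
    for i, row in enumerate(table.itertuples(index=False)):
        traj = simulate_trajectory(growth, int(row.generations_at_death),
                                   row.terminal_phenotype, cell_rng(seed, i))
        traj.cell_id = row.cell_id
        trajectories.append(traj)
    return table, trajectories


def sample_cell_records(model: MortalityModel, growth: GrowthParams,
                        n_cells: int, seed: int,
                        last_generation_time_inflation: float = 1.0):
    """Light-weight cohort: per-generation stats without time grids.

    Draws each cell's lifespan and its per-generation division lengths and
    doubling times directly, skipping the sampled length traces.  Useful
    for calibration studies that only need death-aligned generation
    statistics.  ``last_generation_time_inflation`` multiplies the doubling
    time of the final completed generation (1.0 = age-independent null).
    """
    table = sample_lifespans(model, n_cells, seed)
    records = []
    for i, g_star in enumerate(table["generations_at_death"]):
        rng = cell_rng(seed, i)
        div_len = _truncated_normal(rng, growth.division_length_mean,
                                    growth.division_length_sd, low=0.5,
                                    size=g_star)
        dur = _truncated_normal(rng, growth.doubling_time_mean,
                                growth.doubling_time_sd, low=0.25,
                                size=g_star)
        dur = np.asarray(dur, dtype=float)
        dur[-1] *= last_generation_time_inflation
        records.append(CellTrajectory(
            cell_id=f"cell_{i:06d}",
            times=np.array([0.0]),
            lengths=np.array([growth.birth_length_mean]),
            division_times=np.cumsum(dur),
            generation_count=int(g_star),
            fate="died",
            division_lengths=np.asarray(div_len, dtype=float),
            generation_durations=dur,
        ))
    return table, records


def sample_defect_events(n_events: int, class_probs: Sequence[float],
                         lethality: dict, seed: int) -> pd.DataFrame:
    """Division-level defect events with stochastic death outcomes."""
    rng = np.random.default_rng(seed)
    classes = rng.choice(list(DEFECT_CLASSES), size=n_events,
                         p=list(class_probs))
    p_death = np.array([lethality[c] for c in classes])
    died = rng.random(n_events) < p_death
    return pd.DataFrame({"defect_class": classes, "died": died})


# --------------------------------------------------------------------------
# image rendering
# --------------------------------------------------------------------------

_BACKGROUND = 200.0
_WALL = 50.0
_CELL = 80.0
_SEPTUM = 25.0


def render_kymograph_stack(traj: CellTrajectory, imaging: ImagingParams,
                           seed: int) -> KymographStack:
    """Render a trajectory as a synthetic catch-channel image stack.

    Each frame draws the cell as a dark rod anchored at the notch along the
    channel centerline, inside a static channel geometry (walls and notch
    ridge) that gives the registration step stationary features to lock
    onto.  A darker septum band is drawn at the nascent division plane in
    the frames straddling each division.  The scene is convolved with a
    Gaussian PSF (slightly defocused optics render septa and cell walls as
    soft, high-contrast features); then, per frame, an integer stage
    jitter (recorded in the truth sidecar) is applied, followed by the
    global field rotation and additive Gaussian noise.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.transform import rotate

    rng = np.random.default_rng(seed)
    rows, cols = imaging.frame_shape
    px = imaging.pixel_size
    c0 = imaging.channel_center_row
    notch = imaging.notch_col

    max_len_px = int(np.ceil(np.max(traj.lengths) / px))
    if notch + max_len_px >= cols - 2:
        raise ValueError(
            f"cell length {np.max(traj.lengths):.1f} um exceeds frame extent")

    n = len(traj.times)
    jitter = np.zeros((n, 2), dtype=int)
    if imaging.max_jitter > 0:
        jitter[1:] = rng.integers(-imaging.max_jitter, imaging.max_jitter + 1,
                                  size=(n - 1, 2))

    dt = float(np.median(np.diff(traj.times))) if n > 1 else 1.0
    div_frames = {int(round(t / dt)): l for t, l in
                  zip(traj.division_times, traj.division_lengths)}

    frames = np.empty((n, rows, cols), dtype=np.float32)
    for i, (t, length) in enumerate(zip(traj.times, traj.lengths)):
        frame = np.full((rows, cols), _BACKGROUND, dtype=np.float32)
        # static geometry: channel walls, notch ridge, and PDMS post marks
        # away from the channel (strong stationary features for drift
        # registration in both axes)
        frame[c0 - 10, :] = _WALL
        frame[c0 + 10, :] = _WALL
        frame[c0 - 10:c0 + 11, notch - 8:notch - 5] = _WALL
        for col in range(16, cols - 8, 48):
            frame[8:c0 - 14, col:col + 3] = _WALL
            frame[c0 + 15:rows - 8, col:col + 3] = _WALL
        # the cell: dark rod from the notch toward the central trench
        tip = notch + int(round(length / px))
        frame[c0 - 4:c0 + 5, notch:tip + 1] = _CELL
        # septum band in the frames straddling a division, clipped to the
        # cell extent (post-division it sits at the newborn cell's new end)
        for j in (i, i + 1):
            if j in div_frames:
                sep = notch + int(round(0.5 * div_frames[j] / px))
                sep = min(sep, tip - 1)
                frame[c0 - 4:c0 + 5, sep:sep + 2] = _SEPTUM
        if imaging.psf_sigma > 0:
            frame = gaussian_filter(frame, imaging.psf_sigma)
        dr, dc = jitter[i]
        if dr or dc:
            frame = np.roll(frame, (dr, dc), axis=(0, 1))
        if imaging.rotation_deg != 0.0:
            frame = rotate(frame, imaging.rotation_deg, preserve_range=True,
                           order=1, mode="edge").astype(np.float32)
        if imaging.noise_sd > 0:
            frame = frame + rng.normal(0.0, imaging.noise_sd,
                                       size=frame.shape).astype(np.float32)
        frames[i] = frame

    timestamps = np.asarray(traj.times, dtype=float)
    if n == 1:
        timestamps = timestamps.copy()
    return KymographStack(
        frames=frames,
        timestamps=timestamps,
        truth={"trajectory": traj, "shifts": jitter, "imaging": imaging},
    )
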