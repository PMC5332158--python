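"""Aging-vs-stochastic decomposition and death-phenotype analyses.

Given fitted survival models, growth trajectories and division-event
tables, this module answers the study's core questions: does the hazard
rate rise with replicative age (aging) or stay flat (stochastic death)?
Do cells deteriorate as death approaches?  Are last-sibling fates and
division defects age-dependent?

Components: RLS contour maps over the Gompertz coefficient plane; the
aging / non-aging verdict; post-synchronization of per-generation
statistics to the time of death with sequential Kolmogorov–Smirnov
comparisons; terminal-phenotype classification (short vs hyper-elongated);
last-sibling fate tables with bootstrap errors; nucleolar (rDNA)
segregation-defect tallies and per-class lethality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import DEFECT_CLASSES, SIBLING_FATES, CellTrajectory
from .survival import SurvivalFit, select_model

__all__ = [
    "ContourGrid",
    "DeathAlignedDistributions",
    "DefectTally",
    "rls_contour_grid",
    "classify_aging",
    "post_synchronize_to_death",
    "ks_generation_comparison",
    "classify_death_phenotype",
    "sibling_fate_by_age",
    "tally_segregation_defects",
    "defect_lethality",
]


@dataclass
class ContourGrid:
    """Median-RLS surface over the (alpha, beta) coefficient plane."""

    alpha_values: np.ndarray
    beta_values: np.ndarray
    rls_matrix: np.ndarray            # indexed [i_alpha, j_beta]
    strain_points: list | None = None  # (label, alpha, beta) markers


@dataclass
class DeathAlignedDistributions:
    """Per-generation samples indexed backwards from death (k = 1 is last).

    ``lengths[k]`` / ``doubling_times[k]`` hold the division lengths (um)
    and doubling times (hours) of the k-th generation before death, pooled
    over cells; cells with fewer than k completed generations skip bin k.
    """

    lengths: dict
    doubling_times: dict
    n_per_bin: dict

    @property
    def k_max(self) -> int:
        return max(self.lengths) if self.lengths else 0


@dataclass
class DefectTally:
    """Defect-class counts and proportions for one population."""

    population: str
    counts: dict
    proportions: dict

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def defect_rate(self) -> float:
        return 1.0 - self.proportions.get("normal", 0.0)


# --------------------------------------------------------------------------
# RLS contours and the aging verdict
# --------------------------------------------------------------------------

def rls_contour_grid(alpha_range, beta_range, resolution: int = 100,
                     strain_points=None) -> ContourGrid:
    """Median RLS evaluated densely over the Gompertz coefficient plane.

    ``RLS = ln(1 + beta ln2 / alpha) / beta``, with the ``beta = 0`` column
    taking the exponential limit ``ln 2 / alpha``.  RLS decreases in both
    coefficients: alpha scales the age-independent risk, beta the
    age-dependent acceleration.
    """
    alphas = np.linspace(*alpha_range, resolution)
    betas = np.linspace(*beta_range, resolution)
    if np.any(alphas <= 0):
        raise ValueError("alpha grid must be positive")
    if np.any(betas < 0):
        raise ValueError("beta grid must be non-negative")
    A, B = np.meshgrid(alphas, betas, indexing="ij")
    with np.errstate(divide="ignore", invalid="ignore"):
        rls = np.log1p(B * np.log(2) / A) / B
    exp_limit = np.log(2) / A
    rls = np.where(B == 0, exp_limit, rls)
    return ContourGrid(alpha_values=alphas, beta_values=betas,
                       rls_matrix=rls, strain_points=strain_points)


def classify_aging(fit_exp: SurvivalFit, fit_gom: SurvivalFit,
                   beta_ci=None) -> dict:
    """Aging / non-aging verdict from the paired survivor fits.

    The population is called ``non_aging`` when the exponential model wins
    the adjusted-r² comparison, or when the Gompertz age-dependent rate is
    statistically indistinguishable from zero (its bootstrap CI reaches 0).
    ``beta_ci`` may be passed precomputed; otherwise the CI attached to
    ``fit_gom`` is used if present.
    """
    exp_wins = fit_gom.adjusted_r2 - fit_exp.adjusted_r2 <= 1e-4
    if beta_ci is None and fit_gom.coef_cis is not None:
        beta_ci = fit_gom.coef_cis.get("beta")
    beta_ci_includes_zero = beta_ci is not None and beta_ci[0] <= 1e-6
    non_aging = exp_wins or beta_ci_includes_zero
    return {
        "verdict": "non_aging" if non_aging else "aging",
        "exponential_selected": bool(exp_wins),
        "beta": fit_gom.model.effective_beta,
        "beta_ci": beta_ci,
        "adjusted_r2_exponential": fit_exp.adjusted_r2,
        "adjusted_r2_gompertz": fit_gom.adjusted_r2,
    }


# --------------------------------------------------------------------------
# death-aligned (post-synchronized) generation statistics
# --------------------------------------------------------------------------

def post_synchronize_to_death(trajectories, k_max: int = 5) -> DeathAlignedDistributions:
    """Re-index per-generation statistics backwards from each cell's death.

    Generation ``g_death - k`` (k = 1 is the last completed generation)
    contributes its division length and doubling time to bin k.  Only died
    cells with at least one completed generation participate.
    """
    lengths = {k: [] for k in range(1, k_max + 1)}
    times = {k: [] for k in range(1, k_max + 1)}
    for traj in trajectories:
        if traj.fate != "died" or traj.generation_count < 1:
            continue
        div_len = np.asarray(traj.division_lengths, dtype=float)
        dur = np.asarray(traj.generation_durations, dtype=float)
        for k in range(1, min(k_max, traj.generation_count) + 1):
            lengths[k].append(div_len[-k])
            times[k].append(dur[-k])
    return DeathAlignedDistributions(
        lengths={k: np.asarray(v) for k, v in lengths.items()},
        doubling_times={k: np.asarray(v) for k, v in times.items()},
        n_per_bin={k: len(v) for k, v in lengths.items()},
    )


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def ks_generation_comparison(dists: DeathAlignedDistributions) -> pd.DataFrame:
    """Two-sample KS tests between sequential death-aligned generations.

    Bins (k+1, k) are compared for both division length and doubling time;
    stars mark p < 0.05 (*) and p < 0.01 (**) with no multiplicity
    correction, and a Holm-corrected column is reported alongside.  Pairs
    with an empty or singleton bin are skipped with a note.
    """
    rows = []
    for quantity, data in (("length", dists.lengths),
                           ("doubling_time", dists.doubling_times)):
        for k in range(1, dists.k_max):
            a, b = data.get(k + 1), data.get(k)
            if a is None or b is None or len(a) < 2 or len(b) < 2:
                rows.append({"quantity": quantity, "pair": f"{k+1}v{k}",
                             "p_value": np.nan, "stars": "",
                             "note": "insufficient samples"})
                continue
            p = float(stats.ks_2samp(a, b).pvalue)
            rows.append({"quantity": quantity, "pair": f"{k+1}v{k}",
                         "p_value": p, "stars": _stars(p), "note": ""})
    out = pd.DataFrame(rows)
    # Holm step-down over the valid comparisons, reported but not starred
    valid = out["p_value"].notna()
    holm = np.full(len(out), np.nan)
    if valid.any():
        p = out.loc[valid, "p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.minimum.accumulate((np.sort(p) * (m - np.arange(m)))[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        corrected = np.empty(m)
        corrected[order] = adj
        holm[np.flatnonzero(valid)] = corrected
    out["holm_p"] = holm
    return out


# --------------------------------------------------------------------------
# terminal phenotype
# --------------------------------------------------------------------------

def classify_death_phenotype(traj: CellTrajectory,
                             normal_division_length: float = 16.2,
                             mean_doubling_time: float = 2.05) -> str:
    """Classify a dying cell as ``short`` or ``elongated``.

    ``short``: the terminal length stays below the normal division length.
    ``elongated``: the terminal generation lasts more than three mean
    doubling times without dividing.  When both criteria hold the cell is
    called ``elongated`` (hyper-elongation is the marked phenotype); a cell
    meeting neither (died at normal length within a normal cycle time) is
    also called ``elongated``, as it reached the division point without
    dividing.
    """
    if traj.fate != "died":
        raise ValueError("phenotype classification applies to died cells only")
    if traj.terminal_duration > 0:
        duration = traj.terminal_duration
    elif len(traj.division_times):
        duration = float(traj.times[-1] - traj.division_times[-1])
    else:
        duration = float(traj.times[-1] - traj.times[0])
    terminal_length = float(traj.lengths[-1])
    if duration > 3.0 * mean_doubling_time:
        return "elongated"
    if terminal_length < normal_division_length:
        return "short"
    return "elongated"


# --------------------------------------------------------------------------
# last-sibling fates
# --------------------------------------------------------------------------

def sibling_fate_by_age(table: pd.DataFrame, age_bins=None, n_boot: int = 500,
                        seed: int = 0) -> dict:
    """Last-sibling fate proportions per old-pole age bin, with bootstrap SDs.

    Default bins are the quartiles of replicative age at death.  Fate
    proportions are multinomial per bin; their SDs come from cell-level
    resampling.  A global chi-square of fate x age-bin tests the
    age-independence of sibling fates.
    """
    died = table[(table["status"] == "died")
                 & (table["sibling_fate"] != "none")].copy()
    if len(died) == 0:
        raise ValueError("no died cells with sibling fates")
    ages = died["generations_at_death"].to_numpy()
    if age_bins is None:
        age_bins = np.unique(np.quantile(ages, [0, 0.25, 0.5, 0.75, 1.0]))
        age_bins[-1] += 1
    died["age_bin"] = pd.cut(ages, bins=age_bins, right=False,
                             include_lowest=True)

    def proportions(df):
        out = {}
        for bin_label, grp in df.groupby("age_bin", observed=True):
            counts = grp["sibling_fate"].value_counts()
            n = len(grp)
            out[bin_label] = {f: counts.get(f, 0) / n for f in SIBLING_FATES}
        return out

    props = proportions(died)
    rng = np.random.default_rng(seed)
    boot = {b: {f: [] for f in SIBLING_FATES} for b in props}
    for _ in range(n_boot):
        resampled = died.sample(n=len(died), replace=True,
                                random_state=rng.integers(2**31))
        bp = proportions(resampled)
        for b in boot:
            for f in SIBLING_FATES:
                boot[b][f].append(bp.get(b, {}).get(f, np.nan))
    sds = {b: {f: float(np.nanstd(v)) for f, v in fates.items()}
           for b, fates in boot.items()}

    contingency = pd.crosstab(died["age_bin"], died["sibling_fate"],
                              dropna=True)
    contingency = contingency.loc[(contingency.sum(axis=1) > 0)]
    if contingency.shape[0] >= 2 and contingency.shape[1] >= 2:
        chi2, chi2_p, *_ = stats.chi2_contingency(contingency)
    else:
        chi2, chi2_p = np.nan, np.nan
    return {"proportions": props, "bootstrap_sd": sds, "bins": age_bins,
            "chi2": float(chi2), "chi2_p": float(chi2_p),
            "n_per_bin": died.groupby("age_bin", observed=True).size().to_dict()}


# --------------------------------------------------------------------------
# segregation defects
# --------------------------------------------------------------------------

def _tally(events: pd.DataFrame, population: str) -> DefectTally:
    counts = {c: int((events["defect_class"] == c).sum())
              for c in DEFECT_CLASSES}
    n = sum(counts.values())
    props = {c: counts[c] / n if n else np.nan for c in DEFECT_CLASSES}
    return DefectTally(population=population, counts=counts, proportions=props)


def tally_segregation_defects(events: pd.DataFrame):
    """Defect-class tallies for all vs terminal divisions, with enrichment.

    ``events`` needs columns ``population`` (``"all"`` or ``"terminal"``)
    and ``defect_class``.  Returns the two tallies (the inner and outer
    rings of the ring chart) and the fold-enrichment of the terminal
    defect rate over the overall rate (NaN when the overall rate is zero).
    """
    unknown = set(events["defect_class"]) - set(DEFECT_CLASSES)
    if unknown:
        raise ValueError(f"unknown defect class labels: {sorted(unknown)}")
    unknown_pop = set(events["population"]) - {"all", "terminal"}
    if unknown_pop:
        raise ValueError(f"unknown population labels: {sorted(unknown_pop)}")
    overall = _tally(events[events["population"] == "all"], "all")
    terminal = _tally(events[events["population"] == "terminal"], "terminal")
    if overall.n_total and overall.defect_rate > 0 and terminal.n_total:
        fold = terminal.defect_rate / overall.defect_rate
    else:
        fold = np.nan
    return overall, terminal, fold


def defect_lethality(events: pd.DataFrame, ci_alpha: float = 0.05) -> pd.DataFrame:
    """P(death | defect class) with Clopper–Pearson binomial CIs.

    ``events`` needs columns ``defect_class`` and boolean ``died``; classes
    with zero events are omitted.
    """
    from statsmodels.stats.proportion import proportion_confint

    rows = []
    for c in DEFECT_CLASSES:
        sub = events[events["defect_class"] == c]
        n = len(sub)
        if n == 0:
            continue
        deaths = int(sub["died"].sum())
        lo, hi = proportion_confint(deaths, n, alpha=ci_alpha, method="beta")
        rows.append({"defect_class": c, "n": n, "deaths": deaths,
                     "p_death": deaths / n, "ci_low": float(lo),
                     "ci_high": float(hi)})
    return pd.DataFrame(rows)
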