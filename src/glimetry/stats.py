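"""Day-vs-night group statistics for per-cell volume and dry mass.

Two complementary analyses are always reported, mirroring common practice
for cells nested within animals:

* an exact (enumerated) two-sided Mann-Whitney U test on the pooled cells,
  chosen for the non-normality of single-cell morphometrics, and
* a one-way mixed-model ANOVA — time-of-day as the fixed two-level factor,
  animal as a random intercept — fitted by REML, which respects the
  cells-within-animal correlation structure.

The volume–mass relationship per group is summarised by an OLS fit of
volume (L) on dry mass (g); the reciprocal of the slope is the effective
cell density in g/L.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .units import density_from_slope, round_sig

log = logging.getLogger(__name__)

EXACT_ENUMERATION_LIMIT = 200_000  # max C(n1+n2, n1) for exact enumeration


@dataclass
class MannWhitneyResult:
    U: float
    p: float
    method: str  # "exact" | "asymptotic"


@dataclass
class MixedAnovaResult:
    F: float
    p: float
    df_num: int
    df_den: int
    sigma2_animal: float
    sigma2_resid: float
    group_effect: float  # fitted night − day contrast


@dataclass
class MassVolumeFit:
    group: str
    slope_L_per_g: float
    intercept_um3: float
    r: float
    density_g_per_L: float
    n_cells: int

    @property
    def density_display(self) -> float:
        """Density rounded to 2 significant figures, the reporting convention."""
        return round_sig(self.density_g_per_L, 2)


@dataclass
class GroupComparison:
    variable: str
    n_day: int
    n_night: int
    mean_day: float
    sem_day: float
    mean_night: float
    sem_night: float
    percent_change: float  # (night − day)/day × 100
    mw_U: float
    mw_p: float
    mixed_F: float
    mixed_p: float
    significant: bool


def _u_statistic(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney(day, night) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    The p-value is computed by exhaustive enumeration of all group
    assignments of the pooled (tied-rank) data when C(n1+n2, n1) is small
    enough; otherwise the tie-corrected normal approximation is used.
    """
    x = np.asarray(day, dtype=np.float64)
    y = np.asarray(night, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks[:n1], n1)
    mu = n1 * n2 / 2.0
    if np.ptp(pooled) == 0:
        log.info("all pooled values identical; p = 1")
        return MannWhitneyResult(U=u_obs, p=1.0, method="exact")
    if math.comb(n1 + n2, n1) <= EXACT_ENUMERATION_LIMIT or n1 * n2 <= 400:
        dev_obs = abs(u_obs - mu)
        count = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks[list(idx)], n1)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                count += 1
        return MannWhitneyResult(U=u_obs, p=count / total, method="exact")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue),
                             method="asymptotic")


def mixed_anova(
    records: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    animal_col: str = "animal_id",
) -> MixedAnovaResult:
    """One-way mixed-model ANOVA: ``variable ~ group`` with a random
    per-animal intercept, fitted by REML.

    The group F statistic is the squared Wald t of the two-level contrast
    (with two levels, a Tukey post-hoc comparison reduces to this same
    contrast); the denominator df is the between-animal df,
    n_animals − 2.  Reports the animal and residual variance components.
    """
    import statsmodels.formula.api as smf

    df = records[[variable, group_col, animal_col]].dropna().copy()
    df.columns = ["y", "g", "a"]
    # standardise the response for optimiser conditioning; the Wald F of the
    # contrast is invariant and variance components are rescaled afterwards
    y_loc = float(df["y"].mean())
    y_scale = float(df["y"].std(ddof=0)) or 1.0
    df["y"] = (df["y"] - y_loc) / y_scale
    animals_per_group = df.groupby("g")["a"].nunique()
    if len(animals_per_group) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(animals_per_group.index)}")
    if (animals_per_group < 2).any():
        bad = animals_per_group[animals_per_group < 2].index.tolist()
        raise ValueError(f"group(s) {bad} have a single animal; the random "
                         "animal effect is inestimable")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("y ~ C(g)", data=df, groups=df["a"])
        fit = None
        last_err: Exception | None = None
        # several optimisers; gradient-based ones can diverge near the
        # variance boundary, so keep the best finite-REML solution found
        for method in ("powell", "lbfgs", "cg"):
            try:
                cand = model.fit(reml=True, method=[method])
            except (np.linalg.LinAlgError, ValueError) as e:
                last_err = e
                continue
            # at the variance boundary the variance-parameter SE is NaN;
            # only the fixed-effect SE must be finite
            if not (np.isfinite(cand.llf) and np.isfinite(cand.bse.iloc[1])):
                continue
            if fit is None or cand.llf > fit.llf + 1e-10:
                fit = cand
        if fit is None:
            raise RuntimeError(f"mixed model failed to converge: {last_err}")
    coef = fit.params.iloc[1]
    se = fit.bse.iloc[1]
    F = float((coef / se) ** 2)
    n_animals = df["a"].nunique()
    df_den = n_animals - 2
    p = float(sps.f.sf(F, 1, df_den))
    return MixedAnovaResult(
        F=F, p=p, df_num=1, df_den=df_den,
        sigma2_animal=float(np.asarray(fit.cov_re).ravel()[0]) * y_scale**2,
        sigma2_resid=float(fit.scale) * y_scale**2,
        group_effect=float(coef) * y_scale,
    )


def fit_mass_volume(records: pd.DataFrame, group: str) -> MassVolumeFit:
    """OLS of volume (L) on dry mass (g) within one group; density = 1/slope."""
    sub = records[records["group"] == group]
    if len(sub) < 3:
        raise ValueError(f"group {group!r} has {len(sub)} cells; need >= 3")
    mass_g = sub["dry_mass_pg"].to_numpy() * 1e-12
    vol_L = sub["volume_um3"].to_numpy() * 1e-15
    if np.ptp(mass_g) == 0:
        raise ValueError("zero mass variance; slope undefined")
    res = sps.linregress(mass_g, vol_L)
    return MassVolumeFit(
        group=group,
        slope_L_per_g=float(res.slope),
        intercept_um3=float(res.intercept * 1e15),
        r=float(res.rvalue),
        density_g_per_L=density_from_slope(float(res.slope)),
        n_cells=len(sub),
    )


def summarize(
    records: pd.DataFrame,
    variables: tuple[str, ...] = ("volume_um3", "dry_mass_pg"),
    alpha_level: float = 0.05,
    significance_from: str = "mixed",
) -> dict[str, GroupComparison]:
    """Per-variable day-vs-night comparison: means ± SEM (over cells),
    percent change, both tests; ``significant`` is taken from the mixed
    model by default (it respects the animal nesting)."""
    for g in ("day", "night"):
        if g not in set(records["group"]):
            raise ValueError(f"group {g!r} missing from records")
    out: dict[str, GroupComparison] = {}
    for var in variables:
        day = records.loc[records["group"] == "day", var].to_numpy()
        night = records.loc[records["group"] == "night", var].to_numpy()
        mw = mann_whitney(day, night)
        mx = mixed_anova(records, var)
        p_used = mx.p if significance_from == "mixed" else mw.p
        out[var] = GroupComparison(
            variable=var,
            n_day=len(day), n_night=len(night),
            mean_day=float(day.mean()), sem_day=float(sps.sem(day)),
            mean_night=float(night.mean()), sem_night=float(sps.sem(night)),
            percent_change=float((night.mean() - day.mean()) / day.mean() * 100),
            mw_U=mw.U, mw_p=mw.p, mixed_F=mx.F, mixed_p=mx.p,
            significant=bool(p_used < alpha_level),
        )
    return out


def comparisons_frame(comparisons: dict[str, GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons.values()])


def report_markdown(
    comparisons: dict[str, GroupComparison],
    fits: list[MassVolumeFit] | None = None,
) -> str:
    """Markdown report of the group comparisons and volume-mass fits."""
    lines = ["# Day vs night comparison", ""]
    for c in comparisons.values():
        star = " *" if c.significant else ""
        lines += [
            f"## {c.variable}{star}",
            f"- day:   mean {c.mean_day:.4g} ± {c.sem_day:.3g} SEM (n={c.n_day} cells)",
            f"- night: mean {c.mean_night:.4g} ± {c.sem_night:.3g} SEM (n={c.n_night} cells)",
            f"- change (night vs day): {c.percent_change:+.1f}%",
            f"- Mann-Whitney: U = {c.mw_U:.1f}, p = {c.mw_p:.4g}",
            f"- mixed-model ANOVA (animal random): F = {c.mixed_F:.3f}, p = {c.mixed_p:.4g}",
            "",
        ]
    for f in fits or []:
        lines += [
            f"## volume-mass fit, {f.group}",
            f"- slope {f.slope_L_per_g:.3e} L/g, r = {f.r:.3f} (n={f.n_cells})",
            f"- density 1/slope = {f.density_display:.0f} g/L",
            "",
        ]
    return "\n".join(lines)
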