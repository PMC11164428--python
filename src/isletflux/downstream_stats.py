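"""Group statistics, power analysis, Wald-ratio Mendelian randomization,
CTCF image quantification, and fluorescence-trace processing.

These are the auxiliary computations around the tracing analysis: the
two-sample power calculation that sizes tracing cohorts, summary-statistic
harmonization and the single-instrument Wald ratio for cis-eQTL MR,
corrected total cell fluorescence with Hi/Lo thresholding, and baseline
normalization plus area-under-curve readouts for biosensor time series.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------

VALID_ALLELES = frozenset("ACGT")


@dataclass
class PowerSpec:
    """Two-sample two-tailed t test design.

    alpha and target power default to the conventional 0.05 / 0.80 pair
    (stated explicitly because power software defaults vary).
    """

    effect_size: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if self.effect_size <= 0:
            raise ValueError("effect size d must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")


def power_two_sample_t(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-tailed two-sample t test with n per group, from the
    noncentral t distribution (df = 2n-2, noncentrality d*sqrt(n/2))."""
    if n < 2:
        return 0.0
    df = 2 * n - 2
    nc = d * np.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    )


def sample_size_two_sample_t(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest per-group n whose power reaches the target."""
    for n in range(2, n_max + 1):
        if power_two_sample_t(n, spec.effect_size, spec.alpha) >= spec.power:
            return n
    raise ValueError(f"no n <= {n_max} reaches power {spec.power}")


# ---------------------------------------------------------------------------
# Mendelian randomization
# ---------------------------------------------------------------------------

def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizeResult:
    harmonized: pd.DataFrame
    dropped: pd.DataFrame  # snp + reason

    @property
    def n_used(self) -> int:
        return len(self.harmonized)


def _check_summary_stats(df: pd.DataFrame, role: str) -> None:
    required = {"snp", "ea", "oa", "beta", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{role} summary stats missing columns {sorted(missing)}")
    bad = set(df["ea"]) | set(df["oa"])
    if bad - VALID_ALLELES:
        raise ValueError(f"{role}: non-ACGT alleles {sorted(bad - VALID_ALLELES)}")
    if (df["se"] <= 0).any():
        raise ValueError(f"{role}: standard errors must be positive")


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    drop_palindromic: bool = True,
) -> HarmonizeResult:
    """Align outcome effect alleles (and effect signs) to the exposure coding.

    Where the outcome's effect allele equals the exposure's other allele the
    outcome beta is sign-flipped and its alleles swapped.  Strand-ambiguous
    (A/T, C/G) SNPs cannot be oriented without frequency information and are
    excluded by default; allele sets that neither match nor flip are dropped
    with a logged reason.
    """
    _check_summary_stats(exposure, "exposure")
    _check_summary_stats(outcome, "outcome")
    merged = exposure.merge(
        outcome, on="snp", suffixes=("_exp", "_out"), how="inner"
    )
    rows, dropped = [], []
    for _, row in merged.iterrows():
        if _is_palindromic(row["ea_exp"], row["oa_exp"]):
            if drop_palindromic:
                dropped.append({"snp": row["snp"], "reason": "palindromic"})
                continue
        if (row["ea_out"], row["oa_out"]) == (row["ea_exp"], row["oa_exp"]):
            beta_out = row["beta_out"]
        elif (row["ea_out"], row["oa_out"]) == (row["oa_exp"], row["ea_exp"]):
            beta_out = -row["beta_out"]
        else:
            dropped.append({"snp": row["snp"], "reason": "incompatible_alleles"})
            continue
        rows.append(
            {
                "snp": row["snp"],
                "ea": row["ea_exp"],
                "oa": row["oa_exp"],
                "beta_exp": row["beta_exp"],
                "se_exp": row["se_exp"],
                "beta_out": beta_out,
                "se_out": row["se_out"],
            }
        )
    return HarmonizeResult(
        harmonized=pd.DataFrame(
            rows,
            columns=["snp", "ea", "oa", "beta_exp", "se_exp", "beta_out",
                     "se_out"],
        ),
        dropped=pd.DataFrame(dropped, columns=["snp", "reason"]),
    )


@dataclass
class WaldRatio:
    estimate: float
    se: float
    p_value: float


def wald_ratio(
    exposure_beta: float,
    exposure_se: float,
    outcome_beta: float,
    outcome_se: float,
) -> WaldRatio:
    """Single-instrument MR estimate: outcome effect over exposure effect.

    The standard error is the first-order delta approximation
    outcome_se / |exposure_beta| (exposure uncertainty ignored, adequate
    when exposure_se << |exposure_beta|); the p value is the normal Wald
    test of a zero causal effect.
    """
    if exposure_beta == 0:
        raise ZeroDivisionError("exposure beta is zero; Wald ratio undefined")
    estimate = outcome_beta / exposure_beta
    se = outcome_se / abs(exposure_beta)
    z = estimate / se
    return WaldRatio(
        estimate=float(estimate),
        se=float(se),
        p_value=float(2 * stats.norm.sf(abs(z))),
    )


# ---------------------------------------------------------------------------
# imaging: corrected total cell fluorescence
# ---------------------------------------------------------------------------

CTCF_HI_THRESHOLD = 8e4  # CTCF units separating Hi from Lo expressors


def ctcf(integrated_density, area, background_mean):
    """Corrected total cell fluorescence: integrated density minus the
    product of cell area and mean background fluorescence."""
    return np.asarray(integrated_density, dtype=float) - (
        np.asarray(area, dtype=float) * np.asarray(background_mean, dtype=float)
    )


@dataclass
class HiLoResult:
    labels: np.ndarray  # "Hi"/"Lo" per cell
    hi_proportion: float
    n: int

    def proportion_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        """Exact (Clopper-Pearson) binomial CI on the Hi proportion."""
        from statsmodels.stats.proportion import proportion_confint

        k = int(round(self.hi_proportion * self.n))
        lo, hi = proportion_confint(k, self.n, alpha=alpha, method="beta")
        return float(lo), float(hi)


def classify_hi_lo(values, threshold: float = CTCF_HI_THRESHOLD) -> HiLoResult:
    """Hi iff CTCF strictly exceeds the threshold (ties go to Lo)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no CTCF values to classify")
    hi = values > threshold
    labels = np.where(hi, "Hi", "Lo")
    return HiLoResult(labels=labels, hi_proportion=float(hi.mean()),
                      n=int(values.size))


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def ratio_trace(numerator, denominator) -> np.ndarray:
    numerator = np.asarray(numerator, dtype=float)
    denominator = np.asarray(denominator, dtype=float)
    if np.any(denominator == 0):
        raise ValueError("zero denominator frame in ratio trace")
    return numerator / denominator


def normalize_trace(
    values,
    mode: str = "baseline",
    baseline_window: tuple[int, int] = (0, 20),
) -> np.ndarray:
    """Pointwise division by the baseline mean (R/R_a-b) or by the trace
    minimum (F/F_min).  Window bounds are inclusive frame indices."""
    values = np.asarray(values, dtype=float)
    if mode == "baseline":
        a, b = baseline_window
        if not 0 <= a <= b < values.size:
            raise ValueError(
                f"baseline window {baseline_window} outside trace of "
                f"{values.size} frames"
            )
        ref = values[a : b + 1].mean()
    elif mode == "min":
        ref = values.min()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if ref == 0:
        raise ValueError("zero baseline; cannot normalize")
    return values / ref


def auc(
    values,
    window: tuple[int, int],
    baseline: float = 1.0,
    frame_rate: float | None = None,
) -> float:
    """Trapezoidal area of (value - baseline) over an inclusive frame
    window, in frame units, or in time units when a frame rate (Hz) is
    supplied."""
    values = np.asarray(values, dtype=float)
    a, b = window
    if a > b:
        raise ValueError(f"inverted AUC window {window}")
    if not 0 <= a <= b < values.size:
        raise ValueError(f"window {window} outside trace of {values.size} frames")
    dx = 1.0 if frame_rate is None else 1.0 / frame_rate
    return float(np.trapezoid(values[a : b + 1] - baseline, dx=dx))


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

DESIGNS = (
    "welch_t",
    "mann_whitney",
    "one_way_anova_sidak",
    "two_way_anova_sidak",
    "kruskal_dunn",
)


def _sidak(p: np.ndarray, m: int) -> np.ndarray:
    return 1.0 - (1.0 - np.clip(p, 0, 1)) ** m


def _descriptives(df, value, group) -> pd.DataFrame:
    return (
        df.groupby(group)[value]
        .agg(n="count", mean="mean", sd="std", sem="sem", median="median")
        .reset_index()
    )


def _normality(df, value, group) -> pd.DataFrame:
    rows = []
    for name, sub in df.groupby(group):
        x = sub[value].to_numpy()
        if x.size >= 8:
            stat, p = stats.normaltest(x)
        else:
            stat, p = np.nan, np.nan
        rows.append({"group": name, "dagostino_k2": stat, "p_normal": p})
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    design: str
    omnibus: dict
    comparisons: pd.DataFrame
    descriptives: pd.DataFrame
    normality: pd.DataFrame


def _pairwise_welch(df, value, group, levels) -> pd.DataFrame:
    rows = []
    for a, b in itertools.combinations(levels, 2):
        xa = df.loc[df[group] == a, value].to_numpy()
        xb = df.loc[df[group] == b, value].to_numpy()
        stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"group_a": a, "group_b": b, "statistic": stat, "p_raw": p})
    return pd.DataFrame(rows)


def _dunn(df, value, group) -> pd.DataFrame:
    """Dunn's rank-based post hoc z tests with tie correction."""
    x = df[value].to_numpy()
    g = df[group].to_numpy()
    ranks = stats.rankdata(x)
    n = x.size
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    variance = n * (n + 1) / 12.0 - tie_term
    levels = pd.unique(g)
    mean_ranks = {lev: ranks[g == lev].mean() for lev in levels}
    sizes = {lev: int((g == lev).sum()) for lev in levels}
    rows = []
    for a, b in itertools.combinations(levels, 2):
        se = np.sqrt(variance * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append(
            {"group_a": a, "group_b": b, "statistic": z,
             "p_raw": 2 * stats.norm.sf(abs(z))}
        )
    return pd.DataFrame(rows)


def compare_groups(
    table: pd.DataFrame,
    design: str,
    value: str = "value",
    group: str = "group",
    factor: str | None = None,
) -> GroupComparison:
    """Run the named comparison exactly (no automatic test selection).

    ``factor`` is the second factor of the two-way design (e.g. mass shift
    when comparing species across isotopologue channels); post hoc
    comparisons are then between group levels within each factor level.
    A D'Agostino-Pearson normality screen is reported alongside, never used
    to switch tests.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    counts = table.groupby(group)[value].count()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("each design needs >=2 groups with >=2 values each")
    levels = list(counts.index)

    if design == "welch_t":
        if len(levels) != 2:
            raise ValueError("welch_t needs exactly two groups")
        xa = table.loc[table[group] == levels[0], value].to_numpy()
        xb = table.loc[table[group] == levels[1], value].to_numpy()
        stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        omnibus = {"test": "welch_t", "statistic": float(stat),
                   "p": float(p)}
        comparisons = pd.DataFrame(
            [{"group_a": levels[0], "group_b": levels[1],
              "statistic": float(stat), "p_raw": float(p),
              "p_adjusted": float(p)}]
        )
    elif design == "mann_whitney":
        if len(levels) != 2:
            raise ValueError("mann_whitney needs exactly two groups")
        xa = table.loc[table[group] == levels[0], value].to_numpy()
        xb = table.loc[table[group] == levels[1], value].to_numpy()
        stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        omnibus = {"test": "mann_whitney_u", "statistic": float(stat),
                   "p": float(p)}
        comparisons = pd.DataFrame(
            [{"group_a": levels[0], "group_b": levels[1],
              "statistic": float(stat), "p_raw": float(p),
              "p_adjusted": float(p)}]
        )
    elif design == "one_way_anova_sidak":
        samples = [table.loc[table[group] == lev, value].to_numpy()
                   for lev in levels]
        stat, p = stats.f_oneway(*samples)
        omnibus = {"test": "one_way_anova", "statistic": float(stat),
                   "p": float(p)}
        comparisons = _pairwise_welch(table, value, group, levels)
        comparisons["p_adjusted"] = _sidak(
            comparisons["p_raw"].to_numpy(), len(comparisons)
        )
    elif design == "two_way_anova_sidak":
        if factor is None:
            raise ValueError("two_way_anova_sidak needs a second factor column")
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        frame = table.rename(columns={value: "y", group: "g1", factor: "g2"})
        model = smf.ols("y ~ C(g1) * C(g2)", data=frame).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        omnibus = {
            "test": "two_way_anova",
            "p_group": float(anova.loc["C(g1)", "PR(>F)"]),
            "p_factor": float(anova.loc["C(g2)", "PR(>F)"]),
            "p_interaction": float(anova.loc["C(g1):C(g2)", "PR(>F)"]),
        }
        rows = []
        for f_level, sub in frame.groupby("g2"):
            pw = _pairwise_welch(sub, "y", "g1", list(pd.unique(sub["g1"])))
            pw.insert(0, "factor_level", f_level)
            rows.append(pw)
        comparisons = pd.concat(rows, ignore_index=True)
        comparisons["p_adjusted"] = _sidak(
            comparisons["p_raw"].to_numpy(), len(comparisons)
        )
    else:  # kruskal_dunn
        samples = [table.loc[table[group] == lev, value].to_numpy()
                   for lev in levels]
        stat, p = stats.kruskal(*samples)
        omnibus = {"test": "kruskal_wallis", "statistic": float(stat),
                   "p": float(p)}
        comparisons = _dunn(table, value, group)
        # Dunn's classical correction is Bonferroni-style over comparisons
        comparisons["p_adjusted"] = np.minimum(
            comparisons["p_raw"] * len(comparisons), 1.0
        )

    return GroupComparison(
        design=design,
        omnibus=omnibus,
        comparisons=comparisons,
        descriptives=_descriptives(table, value, group),
        normality=_normality(table, value, group),
    )


# ---------------------------------------------------------------------------
# fold change with bootstrap CI
# ---------------------------------------------------------------------------

@dataclass
class FoldChange:
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def fold_change(
    a,
    b,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 20240411,
) -> FoldChange:
    """mean(a)/mean(b) with a seeded percentile-bootstrap CI."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 samples per side for a fold change")
    if b.mean() == 0:
        raise ZeroDivisionError("denominator group has zero mean")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    boots = a[idx_a].mean(axis=1) / b[idx_b].mean(axis=1)
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return FoldChange(
        estimate=float(a.mean() / b.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
    )
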