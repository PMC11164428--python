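"""Headline quantities from processed tracing data.

Covers the lactate source partition (m+3 glycolytic vs m+2 TCA-derived
proxies), the m+3 G-3-P / m+3 lactate glycolytic ratio, cross-cohort fold
changes with bootstrap CIs, and the PC fraction of pyruvate entry into the
TCA cycle (f_PC = v_PC / (v_PC + v_PDH)) estimated by fitting the
steady-state isotopomer simulator to observed fractions over a grid of
f_PC with nuisance parameters profiled out.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .downstream_stats import FoldChange, fold_change  # noqa: F401 (re-export)
from .isotopomer_model import (
    FluxConfig,
    build_beta_cell_network,
    index_to_pattern,
    propagate_to_steady_state,
)
from .nmr_multiplet import COMPONENTS, component_of

_PATTERN_RE = re.compile(r"^[01]+$")
_MID_RE = re.compile(r"^m\+(\d)$")
_COMPONENT_RE = re.compile(r"^C(\d+):(\w+)$")

N_CARBONS = {
    "pyruvate": 3, "lactate": 3, "alanine": 3, "g3p": 3,
    "oaa": 4, "malate": 4, "aspartate": 4, "fumarate": 4, "succinate": 4,
    "akg": 5, "glutamate": 5,
}


# ---------------------------------------------------------------------------
# simple MID-level readouts
# ---------------------------------------------------------------------------

@dataclass
class LactatePartition:
    glycolytic: float  # m+3: direct pyruvate conversion
    tca: float         # m+2: TCA-cycle-derived
    ratio: float       # glycolytic / tca; nan when undefined

    @property
    def ratio_defined(self) -> bool:
        return np.isfinite(self.ratio)


def lactate_source_partition(mid: np.ndarray) -> LactatePartition:
    """Proxy split of labeled lactate into its two sources: the m+3
    isotopologue (pyruvate converted directly below glycolysis) and m+2
    (pyruvate regenerated from TCA intermediates).  These are labeling
    proxies, not flux estimates."""
    mid = np.asarray(mid, dtype=float)
    if mid.size < 4:
        raise ValueError("lactate MID must include channels up to m+3")
    m2, m3 = float(mid[2]), float(mid[3])
    ratio = m3 / m2 if m2 > 0 else (np.nan if m3 == 0 else np.inf)
    return LactatePartition(glycolytic=m3, tca=m2, ratio=ratio)


def glycolytic_ratio(g3p_mid: np.ndarray, lactate_mid: np.ndarray) -> float:
    """m+3(G-3-P) / m+3(lactate): how much fully labeled triose remains
    upstream relative to fully labeled lactate; higher values mean less
    direct pyruvate-to-lactate conversion.  Infinite when lactate m+3 = 0."""
    g3p_mid = np.asarray(g3p_mid, dtype=float)
    lactate_mid = np.asarray(lactate_mid, dtype=float)
    if g3p_mid.size < 4 or lactate_mid.size < 4:
        raise ValueError("both MIDs must include the m+3 channel")
    if lactate_mid[3] == 0:
        return np.inf
    return float(g3p_mid[3] / lactate_mid[3])


# ---------------------------------------------------------------------------
# PC-fraction estimation
# ---------------------------------------------------------------------------

@dataclass
class FluxEstimate:
    f_pc: float
    nuisances: dict[str, float]
    objective: float
    grid_f: np.ndarray
    grid_objective: np.ndarray
    ci_low: float
    ci_high: float
    ci_method: str
    identifiable: bool
    n_solves: int

    def __post_init__(self):
        if not self.ci_low <= self.f_pc <= self.ci_high:
            raise ValueError("confidence interval must contain the estimate")


DEFAULT_NUISANCES: dict[str, tuple[float, float]] = {
    # nuisance name -> (lower, upper) bound
    "tracer_enrichment": (0.01, 1.0),
    "v_glu_dilution": (0.0, 20.0),
}


def _aggregate(data: pd.DataFrame) -> pd.DataFrame:
    """Mean observation per (metabolite, key), with its standard error when
    per-sample replication is available (used as inverse-variance weights so
    the objective is a calibrated chi-square)."""
    required = {"metabolite", "key", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    grouped = data.groupby(["metabolite", "key"], sort=True)["value"]
    out = grouped.mean().reset_index()
    counts = grouped.count().to_numpy()
    if "sample_id" in data.columns and (counts >= 3).all():
        out["se"] = grouped.sem().to_numpy()
    else:
        out["se"] = 1.0  # unweighted fallback for unreplicated data
    # floor the SE so structurally constant channels cannot dominate
    positive = out["se"][out["se"] > 0]
    floor = max(1e-6, 0.05 * float(positive.median())) if len(positive) else 1.0
    out["se"] = out["se"].clip(lower=floor)
    return out


def _extraction_matrix(metabolite: str, keys: list[str]) -> np.ndarray:
    """Rows map a steady-state pattern vector to the observed quantities:
    pattern fractions, MID channels, or multiplet component intensities."""
    n = N_CARBONS[metabolite]
    size = 2 ** n
    rows = np.zeros((len(keys), size))
    for i, key in enumerate(keys):
        if _PATTERN_RE.match(key):
            if len(key) != n:
                raise ValueError(f"{metabolite}: pattern {key} has wrong length")
            rows[i, int(key, 2)] = 1.0
        elif m := _MID_RE.match(key):
            shift = int(m.group(1))
            if shift > n:
                raise ValueError(f"{metabolite}: no channel {key}")
            for j in range(size):
                if index_to_pattern(j, n).count("1") == shift:
                    rows[i, j] = 1.0
        elif m := _COMPONENT_RE.match(key):
            position, comp = int(m.group(1)), m.group(2)
            if comp not in COMPONENTS:
                raise ValueError(f"unknown multiplet component in key {key!r}")
            for j in range(size):
                if component_of(index_to_pattern(j, n), position) == comp:
                    rows[i, j] = 1.0
        else:
            raise ValueError(f"unparseable observation key {key!r}")
    return rows


class _SimObjective:
    """Sum of squared deviations between simulator predictions and observed
    values, as a function of (f_PC, nuisance vector)."""

    def __init__(self, observed: pd.DataFrame, template: FluxConfig,
                 nuisances: dict[str, tuple[float, float]], tol: float):
        self.template = template
        self.nuisance_names = list(nuisances)
        self.bounds = [nuisances[k] for k in self.nuisance_names]
        self.tol = tol
        self.n_solves = 0
        self.blocks: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
        self.n_obs = 0
        for met, sub in observed.groupby("metabolite", sort=True):
            if met not in N_CARBONS:
                raise ValueError(f"simulator does not model metabolite {met!r}")
            keys = sub["key"].tolist()
            matrix = _extraction_matrix(met, keys)
            values = sub["value"].to_numpy(dtype=float)
            weights = 1.0 / sub["se"].to_numpy(dtype=float) ** 2
            self.blocks.append((met, matrix, values, weights))
            self.n_obs += len(keys)

    def config(self, f_pc: float, theta: np.ndarray) -> FluxConfig:
        cfg = self.template.with_pc_fraction(f_pc)
        return replace(
            cfg,
            v_glycolysis=None,
            **{k: float(v) for k, v in zip(self.nuisance_names, theta)},
        )

    def __call__(self, f_pc: float, theta: np.ndarray) -> float:
        theta = np.clip(theta, [b[0] for b in self.bounds],
                        [b[1] for b in self.bounds])
        cfg = self.config(f_pc, theta)
        net = build_beta_cell_network(cfg)
        dists = propagate_to_steady_state(net, tol=self.tol)
        self.n_solves += 1
        total = 0.0
        for met, matrix, values, weights in self.blocks:
            pred = matrix @ dists[met].vector
            total += float(np.sum(weights * (pred - values) ** 2))
        return total

    def predict(self, f_pc: float, theta: np.ndarray) -> np.ndarray:
        """Concatenated predictions in the aggregated (metabolite, key)
        row order."""
        cfg = self.config(f_pc, np.clip(theta, [b[0] for b in self.bounds],
                                        [b[1] for b in self.bounds]))
        dists = propagate_to_steady_state(build_beta_cell_network(cfg),
                                          tol=self.tol)
        self.n_solves += 1
        return np.concatenate(
            [matrix @ dists[met].vector for met, matrix, _v, _w in self.blocks]
        )

    def profile(self, f_pc: float, theta0: np.ndarray,
                maxfev: int) -> tuple[float, np.ndarray]:
        """Minimize over nuisances at fixed f_PC (Nelder-Mead, warm start)."""
        if not self.nuisance_names:
            return self(f_pc, np.empty(0)), np.empty(0)
        res = optimize.minimize(
            lambda th: self(f_pc, th),
            np.asarray(theta0, dtype=float),
            method="Nelder-Mead",
            bounds=self.bounds,
            options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-12},
        )
        return float(res.fun), np.asarray(res.x)


def estimate_pc_fraction(
    data: pd.DataFrame,
    template: FluxConfig | None = None,
    grid_max: float = 0.5,
    grid_step: float = 0.005,
    coarse_step: float = 0.05,
    nuisances: dict[str, tuple[float, float]] | None = None,
    exhaustive: bool = False,
    ci_alpha: float = 0.05,
    solver_tol: float = 1e-8,
    n_boot: int = 200,
    boot_seed: int = 20240411,
) -> FluxEstimate:
    """Estimate f_PC by simulator fitting.

    ``data`` is a long cohort table (columns metabolite, key, value, plus
    optional sample/group columns averaged over); keys may be isotopomer
    patterns ('110'), MID channels ('m+2'), or multiplet components
    ('C2:doublet_low') in fraction units.  The squared inverse-variance-
    weighted deviation between simulator predictions and observed means is
    minimized over a grid of f_PC in [0, grid_max] at resolution
    ``grid_step`` -- exhaustively when ``exhaustive``, otherwise
    coarse-to-fine -- with nuisance parameters profiled out by nested
    optimization at every grid point.

    The CI is a bootstrap over samples when per-sample replication is
    available: cohort rows are resampled by sample, the objective is
    re-evaluated against the stored prediction path along the grid (no new
    simulator solves), and the argmin distribution gives percentile bounds.
    Without replication it falls back to an F-threshold profile interval
    on the objective curve.
    """
    template = template or FluxConfig()
    nuisances = DEFAULT_NUISANCES if nuisances is None else nuisances
    observed = _aggregate(data)
    if observed.empty:
        raise ValueError("no observations to fit")
    obj = _SimObjective(observed, template, nuisances, solver_tol)

    theta0 = np.array(
        [np.clip(getattr(template, k), *b)
         for k, b in zip(obj.nuisance_names, obj.bounds)]
    )

    n_decimals = max(0, int(np.ceil(-np.log10(grid_step))))
    fine = np.round(np.arange(0.0, grid_max + grid_step / 2, grid_step),
                    n_decimals)
    if exhaustive:
        candidates = fine
    else:
        candidates = np.round(
            np.arange(0.0, grid_max + coarse_step / 2, coarse_step), n_decimals
        )

    evaluated: dict[float, float] = {}
    thetas: dict[float, np.ndarray] = {}
    theta = theta0
    for i, f in enumerate(candidates):
        maxfev = 80 if i == 0 else 18
        val, theta = obj.profile(float(f), theta, maxfev)
        evaluated[float(f)] = val
        thetas[float(f)] = theta

    if not exhaustive:
        best_coarse = min(evaluated, key=evaluated.get)
        window = [
            float(f) for f in fine
            if abs(f - best_coarse) <= 0.7 * coarse_step + 1e-9
            and float(f) not in evaluated
        ]
        theta = thetas[best_coarse]
        for f in sorted(window, key=lambda x: abs(x - best_coarse)):
            val, theta = obj.profile(f, theta, 15)
            evaluated[f] = val
            thetas[f] = theta

    grid_f = np.array(sorted(evaluated))
    grid_obj = np.array([evaluated[f] for f in grid_f])
    best = float(grid_f[np.argmin(grid_obj)])
    best_obj = float(np.min(grid_obj))

    spread = float(np.max(grid_obj) - best_obj)
    identifiable = spread > 1e-10 * max(1.0, float(np.max(grid_obj)))

    ci_low = ci_high = best
    ci_method = "profile_f"
    samples = None
    if "sample_id" in data.columns and n_boot > 0:
        wide = data.pivot_table(
            index="sample_id", columns=["metabolite", "key"], values="value",
            aggfunc="mean",
        )
        target_cols = list(observed[["metabolite", "key"]].itertuples(
            index=False, name=None))
        if len(wide) >= 3 and all(c in wide.columns for c in target_cols):
            samples = wide[target_cols].to_numpy(dtype=float)
            col_means = np.nanmean(samples, axis=0)
            nan_rows, nan_cols = np.where(np.isnan(samples))
            samples[nan_rows, nan_cols] = col_means[nan_cols]

    if samples is not None:
        # bootstrap over samples against the stored prediction path; the
        # simulator predictions depend only on (f_PC, nuisances), so no new
        # solves are needed per replicate
        weights = np.concatenate([w for _m, _x, _v, w in obj.blocks])
        preds = np.vstack(
            [obj.predict(f, thetas[float(f)]) for f in grid_f]
        )
        rng = np.random.default_rng(boot_seed)
        n_samples = samples.shape[0]
        boot_f = np.empty(n_boot)
        for b in range(n_boot):
            means = samples[rng.integers(0, n_samples, n_samples)].mean(axis=0)
            boot_obj = np.sum(weights * (preds - means) ** 2, axis=1)
            boot_f[b] = grid_f[int(np.argmin(boot_obj))]
        lo, hi = np.quantile(boot_f, [ci_alpha / 2, 1 - ci_alpha / 2])
        ci_low, ci_high = min(float(lo), best), max(float(hi), best)
        ci_method = "grid_bootstrap"
    else:
        # F-threshold profile interval, interpolating the crossing between
        # evaluated grid points
        dof = max(obj.n_obs - (1 + len(obj.nuisance_names)), 1)
        threshold = best_obj * (1.0 + stats.f.ppf(1 - ci_alpha, 1, dof) / dof)
        i_best = int(np.argmin(grid_obj))
        below = grid_obj <= threshold + 1e-300

        def _bound(direction: int) -> float:
            i = i_best
            while 0 <= i + direction < grid_f.size and below[i + direction]:
                i += direction
            j = i + direction
            if not 0 <= j < grid_f.size:
                return float(grid_f[i])
            o_in, o_out = grid_obj[i], grid_obj[j]
            if o_out <= o_in:  # flat; no crossing to interpolate
                return float(grid_f[i])
            t = (threshold - o_in) / (o_out - o_in)
            return float(grid_f[i] + t * (grid_f[j] - grid_f[i]))

        ci_low, ci_high = _bound(-1), _bound(+1)

    return FluxEstimate(
        f_pc=best,
        nuisances={k: float(v) for k, v in zip(obj.nuisance_names, thetas[best])},
        objective=best_obj,
        grid_f=grid_f,
        grid_objective=grid_obj,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_method=ci_method,
        identifiable=identifiable,
        n_solves=obj.n_solves,
    )


# ---------------------------------------------------------------------------
# cohort assembly helper
# ---------------------------------------------------------------------------

def cohort_from_mids(mid_table: pd.DataFrame) -> pd.DataFrame:
    """Long cohort rows from a corrected-MID table
    (sample_id, metabolite, mass_shift, fraction)."""
    out = mid_table.rename(columns={"mass_shift": "key", "fraction": "value"})
    return out[[c for c in ("group", "sample_id", "metabolite", "key", "value")
                if c in out.columns]]


def cohort_from_multiplets(
    nmr_table: pd.DataFrame, scales: pd.DataFrame
) -> pd.DataFrame:
    """Long cohort rows from a multiplet table plus fitted per-(sample,
    metabolite) intensity scales: intensities are divided by the scale so
    they are on the fraction scale the simulator predicts."""
    merged = nmr_table.merge(scales, on=["sample_id", "metabolite"], how="inner")
    merged["key"] = "C" + merged["position"].astype(int).astype(str) + ":" + (
        merged["component"]
    )
    merged["value"] = merged["intensity"] / merged["scale"]
    return merged[[c for c in ("group", "sample_id", "metabolite", "key", "value")
                   if c in merged.columns]]
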