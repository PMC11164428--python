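"""2D 1H-13C HSQC multiplet analysis of 13C labeling patterns.

A protonated carbon is visible in the HSQC only when it is 13C; one-bond
13C-13C couplings to its backbone neighbors then split its peak into a
singlet (both neighbors 12C), a doublet (exactly one neighbor 13C -- split
by J(k-1,k) or J(k,k+1), named doublet_low / doublet_high relative to
carbon numbering), or a doublet of doublets (both neighbors 13C).  Multiplet
component intensities are therefore linear in the positional isotopomer
fractions, which is what lets NMR separate e.g. lactate 110 from 011 when
a mass spectrum alone cannot.

The inverse problem (multiplet intensities, optionally stacked with a GC-MS
MID, back to isotopomer fractions) is solved as nonnegative least squares
on the probability simplex, with a single per-table intensity scale factor
estimated jointly and per-pattern identifiability flags from the design
matrix rank structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .isotopomer_model import IsotopomerDistribution, index_to_pattern

COMPONENTS = ("singlet", "doublet_low", "doublet_high", "doublet_of_doublets")

#: carboxyl (and other unprotonated) carbons bear no proton and are
#: invisible in a 1H-detected HSQC; these are the observable positions.
DEFAULT_OBSERVABLE: dict[str, tuple[int, ...]] = {
    "lactate": (2, 3),
    "alanine": (2, 3),
    "glutamate": (2, 3, 4),
    "aspartate": (2, 3),
    "malate": (2, 3),
}


class NmrError(ValueError):
    pass


@dataclass
class ObservabilityMap:
    positions: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_OBSERVABLE)
    )

    def observable(self, metabolite: str) -> tuple[int, ...]:
        if metabolite not in self.positions:
            raise NmrError(f"no observability information for {metabolite!r}")
        return self.positions[metabolite]


def component_of(pattern: str, position: int) -> str | None:
    """Multiplet component contributed by `pattern` at carbon `position`
    (1-based), or None if that carbon is 12C and silent."""
    n = len(pattern)
    if not 1 <= position <= n:
        raise NmrError(f"position {position} outside 1..{n}")
    if pattern[position - 1] == "0":
        return None
    low = position > 1 and pattern[position - 2] == "1"
    high = position < n and pattern[position] == "1"
    if low and high:
        return "doublet_of_doublets"
    if low:
        return "doublet_low"
    if high:
        return "doublet_high"
    return "singlet"


def multiplet_forward(
    d: IsotopomerDistribution,
    obs: ObservabilityMap | None = None,
) -> pd.DataFrame:
    """Noise-free multiplet component intensities (fraction units) of a
    distribution at its observable positions.  Silent components are omitted,
    so a fully unlabeled pool yields an empty table."""
    obs = obs or ObservabilityMap()
    rows = []
    for position in obs.observable(d.metabolite):
        acc: dict[str, float] = {}
        for index, frac in enumerate(d.vector):
            if frac == 0.0:
                continue
            comp = component_of(index_to_pattern(index, d.n_carbons), position)
            if comp is not None:
                acc[comp] = acc.get(comp, 0.0) + float(frac)
        for comp in COMPONENTS:
            if acc.get(comp, 0.0) > 0.0:
                rows.append(
                    {
                        "metabolite": d.metabolite,
                        "position": position,
                        "component": comp,
                        "intensity": acc[comp],
                    }
                )
    return pd.DataFrame(rows, columns=["metabolite", "position", "component",
                                       "intensity"])


def design_matrix(
    n_carbons: int, positions: tuple[int, ...]
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Rows = (position, component) pairs, columns = the 2**n patterns."""
    size = 2 ** n_carbons
    row_keys = [(p, c) for p in positions for c in COMPONENTS]
    matrix = np.zeros((len(row_keys), size))
    for j in range(size):
        pattern = index_to_pattern(j, n_carbons)
        for i, (position, comp) in enumerate(row_keys):
            if component_of(pattern, position) == comp:
                matrix[i, j] = 1.0
    return matrix, row_keys


def _mid_matrix(n_carbons: int) -> np.ndarray:
    size = 2 ** n_carbons
    matrix = np.zeros((n_carbons + 1, size))
    for j in range(size):
        matrix[index_to_pattern(j, n_carbons).count("1"), j] = 1.0
    return matrix


def identifiable_patterns(design: np.ndarray) -> np.ndarray:
    """Boolean flag per pattern: its coefficient is estimable, i.e. the unit
    vector lies in the row space of the design (otherwise only equivalence-
    class sums are constrained)."""
    size = design.shape[1]
    flags = np.zeros(size, dtype=bool)
    pinv = np.linalg.pinv(design)
    for j in range(size):
        e = np.zeros(size)
        e[j] = 1.0
        w = pinv.T @ e
        flags[j] = np.linalg.norm(design.T @ w - e) < 1e-8
    return flags


@dataclass
class MultipletFit:
    distribution: IsotopomerDistribution
    residual: float
    scale: float
    identifiable: dict[str, bool]
    n_rows: int

    def as_frame(self, sample_id: str = "") -> pd.DataFrame:
        rows = [
            {
                "sample_id": sample_id,
                "metabolite": self.distribution.metabolite,
                "pattern": p,
                "fraction": f,
                "identifiable": self.identifiable[p],
                "residual": self.residual,
            }
            for p, f in self.distribution.fractions.items()
        ]
        return pd.DataFrame(rows)


SUM_ROW_WEIGHT = 10.0


def fit_isotopomers(
    table: pd.DataFrame,
    n_carbons: int,
    mid: np.ndarray | None = None,
    obs: ObservabilityMap | None = None,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> MultipletFit:
    """Invert a multiplet table (one metabolite) to isotopomer fractions.

    Solves ``scale * A_nmr @ x = intensities`` stacked with
    ``A_mid @ x = mid`` (when a corrected MID is supplied) under ``x >= 0``
    and ``sum(x) = 1``, by alternating nonnegative least squares on ``x``
    with a closed-form update of the scalar ``scale``.  Without a MID the
    intensities are taken to be on the fraction scale (scale fixed at 1),
    since the split between the unlabeled pool and an arbitrary intensity
    unit is otherwise unidentifiable.

    Observed positions are the positions present in the table; within an
    observed position, absent components are constrained to zero intensity.
    """
    if table.empty:
        raise NmrError("empty multiplet table")
    metabolites = table["metabolite"].unique()
    if len(metabolites) != 1:
        raise NmrError("fit_isotopomers expects a single-metabolite table")
    metabolite = metabolites[0]
    positions = tuple(sorted(int(p) for p in table["position"].unique()))
    for p in positions:
        if not 1 <= p <= n_carbons:
            raise NmrError(f"position {p} outside 1..{n_carbons}")
    bad = set(table["component"]) - set(COMPONENTS)
    if bad:
        raise NmrError(f"unknown multiplet components: {sorted(bad)}")

    a_nmr, row_keys = design_matrix(n_carbons, positions)
    b_nmr = np.zeros(len(row_keys))
    lookup = {key: i for i, key in enumerate(row_keys)}
    for _, row in table.iterrows():
        b_nmr[lookup[(int(row["position"]), row["component"])]] += float(
            row["intensity"]
        )

    blocks = [a_nmr]
    size = 2 ** n_carbons
    if mid is not None:
        mid = np.asarray(mid, dtype=float)
        if mid.shape != (n_carbons + 1,):
            raise NmrError(
                f"MID length {mid.size} does not match {n_carbons} carbons"
            )
        blocks.append(_mid_matrix(n_carbons))
    blocks.append(np.ones((1, size)))
    design_full = np.vstack(blocks)
    flags = identifiable_patterns(design_full)

    estimate_scale = mid is not None
    scale = 1.0
    x = np.full(size, 1.0 / size)
    for _ in range(max_iter):
        rhs = [b_nmr / scale]
        if mid is not None:
            rhs.append(mid)
        rhs.append(np.array([1.0]))
        stacked_a = np.vstack(blocks[:-1] + [SUM_ROW_WEIGHT * blocks[-1]])
        stacked_b = np.concatenate(rhs[:-1] + [SUM_ROW_WEIGHT * rhs[-1]])
        x, _ = nnls(stacked_a, stacked_b)
        if not estimate_scale:
            break
        model = a_nmr @ x
        denom = float(model @ model)
        if denom <= 0:
            break
        new_scale = float(b_nmr @ model) / denom
        if new_scale <= 0:
            new_scale = scale
        if abs(new_scale - scale) < tol * max(1.0, scale):
            scale = new_scale
            break
        scale = new_scale

    total = x.sum()
    if total <= 0:
        raise NmrError("inversion produced an all-zero distribution")
    x = x / total
    ss = np.sum((scale * (a_nmr @ x) - b_nmr) ** 2)
    if mid is not None:
        ss += np.sum((_mid_matrix(n_carbons) @ x - mid) ** 2)
    residual = float(np.sqrt(ss))
    dist = IsotopomerDistribution(metabolite, n_carbons, x)
    identifiable = {
        index_to_pattern(j, n_carbons): bool(flags[j]) for j in range(size)
    }
    return MultipletFit(
        distribution=dist,
        residual=residual,
        scale=scale,
        identifiable=identifiable,
        n_rows=len(table),
    )
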