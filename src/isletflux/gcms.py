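"""GC-MS ion-count processing: internal-standard normalization and
natural-abundance correction of mass isotopologue distributions (MIDs).

Raw ion counts per mass channel m+0..m+n mix the tracer-derived labeling
with naturally occurring heavy isotopes.  The correction builds the
theoretical channel distribution of each pure labeling state (a column of
the correction matrix) and deconvolves the measured channel vector by
nonnegative least squares, then renormalizes to a fractional MID.

CSV schema (input): sample_id, metabolite, n_carbons, m0..m6, is_counts,
formula (optional).  Output: sample_id, metabolite, mass_shift, fraction,
residual.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

#: natural abundance of 13C (configurable in every entry point)
P13C_DEFAULT = 0.0107

#: isotope mass-shift distributions of elements that can appear in
#: derivatized fragments; shift 0 abundance first, heavier shifts after.
_ELEMENT_ENVELOPES: dict[str, np.ndarray] = {
    "C": np.array([1 - 0.0107, 0.0107]),
    "H": np.array([1 - 0.000115, 0.000115]),
    "N": np.array([1 - 0.00364, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0, 0.0001]),
    "Si": np.array([0.92223, 0.04685, 0.03092]),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

MAX_CHANNELS = 7  # m0..m6 in the CSV schema


class GcmsError(ValueError):
    pass


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula such as 'C10H25NO2Si2' into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise GcmsError(f"cannot parse formula {formula!r}")
        pos = match.end()
        if not match.group(1):
            continue
        element = match.group(1)
        if element not in _ELEMENT_ENVELOPES:
            raise GcmsError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + int(match.group(2) or "1")
    if pos != len(formula):
        raise GcmsError(f"cannot parse formula {formula!r}")
    return counts


def _self_convolve(single: np.ndarray, count: int, length: int) -> np.ndarray:
    out = np.zeros(length)
    out[0] = 1.0
    for _ in range(count):
        out = np.convolve(out, single)[:length]
    return out


def isotope_envelope(counts: dict[str, int], length: int) -> np.ndarray:
    """Mass-shift distribution of a molecular formula at natural abundance,
    truncated to `length` channels (mass shifts beyond are dropped and the
    vector left unrenormalized)."""
    env = np.zeros(length)
    env[0] = 1.0
    for element, count in counts.items():
        env = np.convolve(env, _self_convolve(_ELEMENT_ENVELOPES[element],
                                              count, length))[:length]
    return env


def correction_matrix(
    n: int,
    p13: float = P13C_DEFAULT,
    formula: str | None = None,
) -> np.ndarray:
    """(n+1) x (n+1) matrix whose column j is the theoretical raw-channel
    distribution of a molecule with exactly j labeled backbone carbons.

    The n-j unlabeled backbone carbons contribute a Binomial(n-j, p13) mass
    shift; when a fragment formula is supplied, the envelope of the
    non-backbone atoms (everything in the formula except the n backbone
    carbons) is convolved in.  Shifts beyond m+n are truncated, so columns
    sum to <= 1.
    """
    if n < 1:
        raise GcmsError("need at least one backbone carbon")
    if not 0.0 <= p13 < 0.5:
        raise GcmsError(f"p13 must lie in [0, 0.5), got {p13}")
    extra = None
    if formula is not None:
        counts = dict(parse_formula(formula))
        backbone = counts.get("C", 0)
        if backbone < n:
            raise GcmsError(
                f"formula {formula!r} has fewer carbons than the {n}-carbon backbone"
            )
        counts["C"] = backbone - n
        extra = isotope_envelope(
            {el: c for el, c in counts.items() if c > 0}, n + 1
        )
    single = np.array([1 - p13, p13])
    matrix = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        column = _self_convolve(single, n - j, n + 1 - j)
        if extra is not None:
            column = np.convolve(column, extra)[: n + 1 - j]
        matrix[j:, j] = column
    return matrix


@dataclass
class CorrectionResult:
    mid: np.ndarray
    residual: float
    condition_number: float


def correct_natural_abundance(
    raw: np.ndarray,
    matrix: np.ndarray,
    cond_threshold: float = 1e6,
) -> CorrectionResult:
    """Deconvolve raw channel counts into a corrected MID.

    Solves matrix @ x = raw under x >= 0 (nonnegative least squares, robust
    to noise-driven negative fractions), renormalizes x to sum 1, and
    reports the relative residual of the unnormalized fit.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (matrix.shape[0],):
        raise GcmsError(
            f"raw vector length {raw.size} does not match matrix {matrix.shape}"
        )
    total = raw.sum()
    if total <= 0:
        raise GcmsError("all-zero raw channel vector")
    cond = float(np.linalg.cond(matrix))
    if cond > cond_threshold:
        warnings.warn(
            f"correction matrix condition number {cond:.3g} exceeds "
            f"{cond_threshold:.3g}; corrected MID may be unstable",
            stacklevel=2,
        )
    x, rnorm = nnls(matrix, raw / total)
    if x.sum() <= 0:
        raise GcmsError("correction produced an all-zero MID")
    return CorrectionResult(mid=x / x.sum(), residual=float(rnorm), condition_number=cond)


# ---------------------------------------------------------------------------
# table-level operations
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("sample_id", "metabolite", "n_carbons", "is_counts")


def _validate_table(table: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise GcmsError(f"ion-count table is missing column {col!r}")


def _channel_columns(n: int) -> list[str]:
    return [f"m{k}" for k in range(n + 1)]


def counts_vector(row: pd.Series, n: int) -> np.ndarray:
    return row[_channel_columns(n)].to_numpy(dtype=float)


def normalize_to_standard(table: pd.DataFrame) -> pd.DataFrame:
    """Total ion counts per (sample, metabolite) divided by the sample's
    internal-standard counts (D6-glutaric-acid channel), in arbitrary units."""
    _validate_table(table)
    records = []
    for _, row in table.iterrows():
        standard = row["is_counts"]
        if pd.isna(standard) or standard <= 0:
            raise GcmsError(
                f"sample {row['sample_id']!r}: missing or non-positive "
                "internal-standard counts"
            )
        n = int(row["n_carbons"])
        total = float(np.nansum(counts_vector(row, n)))
        records.append(
            {
                "sample_id": row["sample_id"],
                "metabolite": row["metabolite"],
                "normalized_total": total / float(standard),
            }
        )
    return pd.DataFrame.from_records(records)


def correct_table(
    table: pd.DataFrame,
    p13: float = P13C_DEFAULT,
    use_formula: bool = True,
) -> pd.DataFrame:
    """Natural-abundance-correct every row of an ion-count table.

    Correction is carbon-backbone-only unless a fragment formula column is
    present (then the non-backbone envelope is included).  Output is long
    format: sample_id, metabolite, mass_shift, fraction, residual.
    """
    _validate_table(table)
    records = []
    matrices: dict[tuple[int, str | None], np.ndarray] = {}
    for _, row in table.iterrows():
        n = int(row["n_carbons"])
        formula = None
        if use_formula and "formula" in table.columns and isinstance(row.get("formula"), str) and row["formula"]:
            formula = row["formula"]
        key = (n, formula)
        if key not in matrices:
            matrices[key] = correction_matrix(n, p13=p13, formula=formula)
        raw = counts_vector(row, n)
        result = correct_natural_abundance(raw, matrices[key])
        for k in range(n + 1):
            records.append(
                {
                    "sample_id": row["sample_id"],
                    "metabolite": row["metabolite"],
                    "mass_shift": f"m+{k}",
                    "fraction": result.mid[k],
                    "residual": result.residual,
                }
            )
    return pd.DataFrame.from_records(records)


def read_ion_counts(path) -> pd.DataFrame:
    table = pd.read_csv(path, comment="#")
    _validate_table(table)
    return table


def write_mids(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
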