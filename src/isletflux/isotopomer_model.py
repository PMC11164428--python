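"""Atom-transition model of beta-cell glucose metabolism.

Propagates a fully labeled glucose tracer (entering as glycolytic pyruvate)
through a fixed central-carbon network -- lactate dehydrogenase (LDH),
alanine transaminase (ALT), pyruvate dehydrogenase (PDH), pyruvate
carboxylase (PC), a condensed TCA turn, and a malic-enzyme/PEPCK return --
to an isotopic steady state, and predicts positional isotopomer
distributions and mass isotopologue distributions (MIDs) under a given
relative-flux configuration.

Labeling patterns are written as strings of 0/1 over carbons C1..Cn in
IUPAC numbering (leftmost character = C1), 1 marking a ``13C`` atom, so
``lactate 110`` is lactate labeled at C1 and C2.  Internally a distribution
over the 2**n patterns of an n-carbon metabolite is a dense vector indexed
by ``int(pattern, 2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np

UNLABELED_POOL = "UNLABELED_POOL"
CO2_POOL = "CO2_POOL"

# Carbon source of one product carbon: ("sub", substrate_index, carbon_1based)
# or one of the pool tokens above.
Source = tuple | str


class ConvergenceError(RuntimeError):
    """Fixed-point label propagation failed to reach tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# pattern helpers
# ---------------------------------------------------------------------------

def pattern_to_index(pattern: str) -> int:
    return int(pattern, 2)


def index_to_pattern(index: int, n_carbons: int) -> str:
    return format(index, f"0{n_carbons}b")


def _popcounts(n_carbons: int) -> np.ndarray:
    idx = np.arange(2 ** n_carbons, dtype=np.uint32)
    return np.array([int(i).bit_count() for i in idx], dtype=np.intp)


def _reversal_permutation(n_carbons: int) -> np.ndarray:
    """index of the carbon-reversed pattern, for rotationally symmetric pools."""
    size = 2 ** n_carbons
    perm = np.empty(size, dtype=np.intp)
    for i in range(size):
        p = index_to_pattern(i, n_carbons)
        perm[i] = pattern_to_index(p[::-1])
    return perm


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class IsotopomerDistribution:
    """Distribution over the 2**n 12C/13C labeling patterns of one metabolite."""

    metabolite: str
    n_carbons: int
    vector: np.ndarray

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (2 ** self.n_carbons,):
            raise ValueError(
                f"{self.metabolite}: vector length {self.vector.size} does not "
                f"match 2**{self.n_carbons}"
            )

    @classmethod
    def from_fractions(
        cls, metabolite: str, n_carbons: int, fractions: Mapping[str, float]
    ) -> "IsotopomerDistribution":
        vec = np.zeros(2 ** n_carbons)
        for pattern, frac in fractions.items():
            if len(pattern) != n_carbons or set(pattern) - {"0", "1"}:
                raise ValueError(f"bad pattern {pattern!r} for {n_carbons} carbons")
            vec[pattern_to_index(pattern)] = frac
        return cls(metabolite, n_carbons, vec)

    @classmethod
    def unlabeled(cls, metabolite: str, n_carbons: int) -> "IsotopomerDistribution":
        vec = np.zeros(2 ** n_carbons)
        vec[0] = 1.0
        return cls(metabolite, n_carbons, vec)

    @property
    def fractions(self) -> dict[str, float]:
        return {
            index_to_pattern(i, self.n_carbons): float(v)
            for i, v in enumerate(self.vector)
        }

    def fraction(self, pattern: str) -> float:
        return float(self.vector[pattern_to_index(pattern)])

    @property
    def labeled_fraction(self) -> float:
        return float(self.vector[1:].sum())

    def conditional_on_labeled(self) -> dict[str, float]:
        """Pattern fractions renormalized over labeled (non all-zero) patterns."""
        lab = self.vector[1:].sum()
        if lab <= 0:
            return {}
        return {
            index_to_pattern(i, self.n_carbons): float(v / lab)
            for i, v in enumerate(self.vector)
            if i > 0
        }

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.vector < -atol):
            raise ValueError(f"{self.metabolite}: negative fraction")
        if abs(self.vector.sum() - 1.0) > atol:
            raise ValueError(
                f"{self.metabolite}: fractions sum to {self.vector.sum()!r}, not 1"
            )


@dataclass
class AtomMap:
    """Carbon-level atom transitions of one reaction.

    ``carbon_sources[product]`` lists, for carbons C1..Cn of that product,
    where each carbon comes from: a substrate carbon, the unlabeled pool, or
    the CO2 pool.
    """

    reaction: str
    substrates: list[tuple[str, int]]
    products: list[tuple[str, int]]
    carbon_sources: dict[str, tuple[Source, ...]]

    def __post_init__(self):
        self._validate()
        self._precompute()

    def _validate(self) -> None:
        used: set[tuple[int, int]] = set()
        for product, n_prod in self.products:
            sources = self.carbon_sources.get(product)
            if sources is None or len(sources) != n_prod:
                raise ValueError(
                    f"{self.reaction}: product {product} needs exactly "
                    f"{n_prod} carbon sources"
                )
            for src in sources:
                if src in (UNLABELED_POOL, CO2_POOL):
                    continue
                tag, s_idx, carbon = src
                if tag != "sub":
                    raise ValueError(f"{self.reaction}: bad source {src!r}")
                n_sub = self.substrates[s_idx][1]
                if not 1 <= carbon <= n_sub:
                    raise ValueError(
                        f"{self.reaction}: substrate carbon C{carbon} out of "
                        f"range for {self.substrates[s_idx][0]}"
                    )
                if (s_idx, carbon) in used:
                    raise ValueError(
                        f"{self.reaction}: substrate carbon used twice: {src!r}"
                    )
                used.add((s_idx, carbon))

    def _precompute(self) -> None:
        """Transfer tables: product index as a function of the joint substrate
        index (row-major over substrates), with pool-sourced bits at zero, plus
        the bit masks of CO2-sourced product carbons."""
        sub_sizes = [2 ** n for _, n in self.substrates]
        joint = int(np.prod(sub_sizes)) if sub_sizes else 1
        self._joint_size = joint
        self._transfer: dict[str, np.ndarray] = {}
        self._co2_bits: dict[str, list[int]] = {}
        for product, n_prod in self.products:
            table = np.zeros(joint, dtype=np.intp)
            co2_bits: list[int] = []
            for k, src in enumerate(self.carbon_sources[product]):
                bit = 1 << (n_prod - 1 - k)  # carbon C(k+1)
                if src == UNLABELED_POOL:
                    continue
                if src == CO2_POOL:
                    co2_bits.append(bit)
                    continue
                _, s_idx, carbon = src
                n_sub = self.substrates[s_idx][1]
                sub_bit = 1 << (n_sub - 1 - (carbon - 1))
                for j in range(joint):
                    rem = j
                    for t in range(len(sub_sizes) - 1, s_idx, -1):
                        rem //= sub_sizes[t]
                    sub_index = rem % sub_sizes[s_idx]
                    if sub_index & sub_bit:
                        table[j] |= bit
            self._transfer[product] = table
            self._co2_bits[product] = co2_bits

    @property
    def is_identity(self) -> bool:
        """One substrate, one tracked carbon-preserving product, same order."""
        if len(self.substrates) != 1 or len(self.products) != 1:
            return False
        product, n_prod = self.products[0]
        if n_prod != self.substrates[0][1] or self._co2_bits[product]:
            return False
        return bool(np.array_equal(self._transfer[product],
                                   np.arange(self._joint_size)))

    def _joint(self, substrate_dists: Sequence[np.ndarray]) -> np.ndarray:
        if len(substrate_dists) != len(self.substrates):
            raise ValueError(f"{self.reaction}: wrong number of substrate pools")
        if not substrate_dists:
            return np.ones(1)
        joint = substrate_dists[0]
        for d in substrate_dists[1:]:
            joint = np.outer(joint, d).ravel()
        return joint

    def apply_one(
        self,
        product: str,
        substrate_dists: Sequence[np.ndarray],
        co2_enrichment: float = 0.0,
        _joint: np.ndarray | None = None,
    ) -> np.ndarray:
        """Pattern distribution of a single product."""
        joint = self._joint(substrate_dists) if _joint is None else _joint
        n_prod = dict(self.products)[product]
        size = 2 ** n_prod
        table = self._transfer[product]
        co2_bits = self._co2_bits[product]
        if co2_enrichment == 0.0 or not co2_bits:
            return np.bincount(table, weights=joint, minlength=size)
        vec = np.zeros(size)
        for assignment in range(2 ** len(co2_bits)):
            w = 1.0
            offset = 0
            for b, bit in enumerate(co2_bits):
                if assignment >> b & 1:
                    w *= co2_enrichment
                    offset |= bit
                else:
                    w *= 1.0 - co2_enrichment
            if w > 0.0:
                vec += w * np.bincount(table + offset, weights=joint,
                                       minlength=size)
        return vec

    def apply(
        self,
        substrate_dists: Sequence[np.ndarray],
        co2_enrichment: float = 0.0,
    ) -> dict[str, np.ndarray]:
        """Product pattern distributions given substrate pattern distributions,
        assuming statistically independent substrate pools."""
        joint = self._joint(substrate_dists)
        return {
            product: self.apply_one(product, substrate_dists, co2_enrichment,
                                    _joint=joint)
            for product, _ in self.products
        }


def identity_map(reaction: str, substrate: str, product: str, n: int) -> AtomMap:
    return AtomMap(
        reaction,
        substrates=[(substrate, n)],
        products=[(product, n)],
        carbon_sources={product: tuple(("sub", 0, k) for k in range(1, n + 1))},
    )


@dataclass
class FluxConfig:
    """Relative fluxes (arbitrary units) of the beta-cell network.

    ``v_glycolysis`` left as None is balanced so that pyruvate production
    equals consumption: v_glycolysis = v_PDH + v_PC + v_LDH + v_ALT - v_ME.
    ``tracer_enrichment`` is the fraction of glycolytic pyruvate that is
    fully labeled (111); the remainder is unlabeled, standing in for
    pre-existing pools and unlabeled carbon sources.
    """

    v_PDH: float = 0.8
    v_PC: float = 0.2
    v_LDH: float = 0.4
    v_ALT: float = 0.2
    v_TCA: float = 0.8
    v_ME: float = 0.2
    v_glu_exchange: float = 2.0
    v_glu_dilution: float = 0.5
    v_asp_exchange: float = 1.0
    v_fum_exchange: float = 0.5
    tracer_enrichment: float = 0.5
    co2_enrichment: float = 0.0
    v_glycolysis: float | None = None

    def __post_init__(self):
        if self.v_glycolysis is None:
            self.v_glycolysis = self.v_PDH + self.v_PC + self.v_LDH + self.v_ALT - self.v_ME
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value is not None and value < 0:
                raise ValueError(f"negative flux/parameter: {f.name}={value}")
        for name in ("tracer_enrichment", "co2_enrichment"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        production = self.v_glycolysis + self.v_ME
        consumption = self.v_PDH + self.v_PC + self.v_LDH + self.v_ALT
        if abs(production - consumption) > 1e-9:
            raise ValueError(
                f"pyruvate unbalanced: production {production} != consumption {consumption}"
            )
        if self.v_ME > self.v_TCA + 1e-12:
            raise ValueError("v_ME cannot exceed v_TCA (malate supply)")

    @property
    def f_PC(self) -> float:
        """PC fraction of pyruvate entry into the TCA cycle."""
        entry = self.v_PC + self.v_PDH
        if entry == 0:
            raise ValueError("no TCA entry flux")
        return self.v_PC / entry

    def with_pc_fraction(self, f_pc: float) -> "FluxConfig":
        """Same configuration with the PC/PDH split changed at fixed total entry."""
        if not 0.0 <= f_pc <= 1.0:
            raise ValueError(f"f_PC must lie in [0, 1], got {f_pc}")
        entry = self.v_PC + self.v_PDH
        return replace(
            self,
            v_PC=f_pc * entry,
            v_PDH=(1.0 - f_pc) * entry,
            v_glycolysis=None,
        )


METABOLITES: tuple[tuple[str, int], ...] = (
    ("pyruvate", 3),
    ("lactate", 3),
    ("alanine", 3),
    ("acetyl_coa", 2),
    ("oaa", 4),
    ("akg", 5),
    ("glutamate", 5),
    ("succinate", 4),
    ("fumarate", 4),
    ("malate", 4),
    ("aspartate", 4),
    ("g3p", 3),
    ("co2", 1),
)

SYMMETRIC_METABOLITES = frozenset({"succinate", "fumarate"})

#: fixed upstream pool feeding pyruvate (and G-3-P) from glycolysis
GLYCOLYTIC_SOURCE = "glycolytic_pyruvate"


@dataclass
class NetworkModel:
    """Reactions with atom maps and attached fluxes, plus fixed source pools."""

    metabolites: list[tuple[str, int]]
    reactions: list[tuple[AtomMap, float]]
    symmetric_metabolites: frozenset[str] = SYMMETRIC_METABOLITES
    fixed_distributions: dict[str, np.ndarray] = field(default_factory=dict)
    co2_enrichment: float = 0.0

    def __post_init__(self):
        n_by_name = dict(self.metabolites)
        for name in self.symmetric_metabolites:
            if n_by_name.get(name) != 4:
                raise ValueError(f"symmetric metabolite {name} must have 4 carbons")
        for amap, flux in self.reactions:
            if flux < 0:
                raise ValueError(f"negative flux on {amap.reaction}")
            for met, n in amap.substrates:
                if met not in n_by_name and met not in self.fixed_distributions:
                    raise ValueError(f"{amap.reaction}: undeclared substrate {met}")
        # producer index used by the fixed-point iteration
        self._producers: dict[str, list[tuple[AtomMap, float]]] = {
            name: [] for name, _ in self.metabolites
        }
        for amap, flux in self.reactions:
            if flux <= 0:
                continue
            for product, _ in amap.products:
                if product in self._producers:
                    self._producers[product].append((amap, flux))
        # flux-normalized update plans (identity maps short-circuited)
        self._plans: dict[str, list[tuple[float, AtomMap | None, tuple[str, ...]]]] = {}
        for name, entries in self._producers.items():
            total = sum(f for _, f in entries)
            plan = []
            for amap, f in entries:
                subs = tuple(m for m, _ in amap.substrates)
                plan.append((f / total, amap if not amap.is_identity else None, subs))
            self._plans[name] = plan

    def n_carbons(self, metabolite: str) -> int:
        for name, n in self.metabolites:
            if name == metabolite:
                return n
        raise KeyError(metabolite)


def _beta_cell_maps() -> dict[str, AtomMap]:
    """The flux-independent atom maps of the beta-cell network (built once;
    the precomputed transfer tables are shared across flux configurations)."""
    maps: dict[str, AtomMap] = {}

    def add(amap: AtomMap) -> None:
        maps[amap.reaction] = amap

    add(identity_map("glycolysis", GLYCOLYTIC_SOURCE, "pyruvate", 3))
    add(identity_map("glycolysis_g3p", GLYCOLYTIC_SOURCE, "g3p", 3))
    add(identity_map("LDH", "pyruvate", "lactate", 3))
    add(identity_map("ALT", "pyruvate", "alanine", 3))
    add(AtomMap(
        "PDH",
        substrates=[("pyruvate", 3)],
        products=[("acetyl_coa", 2), ("co2", 1)],
        carbon_sources={
            "acetyl_coa": (("sub", 0, 2), ("sub", 0, 3)),
            "co2": (("sub", 0, 1),),
        },
    ))
    add(AtomMap(
        "PC",
        substrates=[("pyruvate", 3)],
        products=[("oaa", 4)],
        carbon_sources={
            "oaa": (("sub", 0, 1), ("sub", 0, 2), ("sub", 0, 3), CO2_POOL),
        },
    ))
    add(AtomMap(
        "CS_ACO_IDH",
        substrates=[("oaa", 4), ("acetyl_coa", 2)],
        products=[("akg", 5), ("co2", 1)],
        carbon_sources={
            "akg": (
                ("sub", 0, 4),
                ("sub", 0, 3),
                ("sub", 0, 2),
                ("sub", 1, 2),
                ("sub", 1, 1),
            ),
            "co2": (("sub", 0, 1),),
        },
    ))
    add(AtomMap(
        "AKGDH_SCS",
        substrates=[("akg", 5)],
        products=[("succinate", 4), ("co2", 1)],
        carbon_sources={
            "succinate": (
                ("sub", 0, 2),
                ("sub", 0, 3),
                ("sub", 0, 4),
                ("sub", 0, 5),
            ),
            "co2": (("sub", 0, 1),),
        },
    ))
    add(identity_map("SDH", "succinate", "fumarate", 4))
    add(identity_map("fumarase", "fumarate", "malate", 4))
    add(identity_map("MDH", "malate", "oaa", 4))
    # Near-equilibrium MDH/fumarase backbone exchange: OAA-derived label
    # visits the rotationally symmetric fumarate pool and returns scrambled
    # (OAA 1110 <-> 0111), the route by which PC-derived carbon reaches
    # pyruvate 011 without passing the decarboxylating TCA steps.
    add(identity_map("MDH_rev", "oaa", "malate", 4))
    add(identity_map("fumarase_rev", "malate", "fumarate", 4))
    add(AtomMap(
        "ME_PEPCK",
        substrates=[("malate", 4)],
        products=[("pyruvate", 3), ("co2", 1)],
        carbon_sources={
            "pyruvate": (("sub", 0, 1), ("sub", 0, 2), ("sub", 0, 3)),
            "co2": (("sub", 0, 4),),
        },
    ))
    add(identity_map("GLUD_fwd", "akg", "glutamate", 5))
    add(identity_map("GLUD_rev", "glutamate", "akg", 5))
    add(AtomMap(
        "glutamate_dilution",
        substrates=[],
        products=[("glutamate", 5)],
        carbon_sources={"glutamate": (UNLABELED_POOL,) * 5},
    ))
    add(identity_map("AST_fwd", "oaa", "aspartate", 4))
    add(identity_map("AST_rev", "aspartate", "oaa", 4))
    return maps


_BETA_CELL_MAPS: dict[str, AtomMap] | None = None


def build_beta_cell_network(flux: FluxConfig) -> NetworkModel:
    """The fixed beta-cell network with the carbon maps of the PDH and PC
    routes into the TCA cycle.

    PDH releases pyruvate C1 as CO2 and passes C2/C3 to acetyl-CoA; PC keeps
    pyruvate C1-C3 as OAA C1-C3 and adds a CO2-pool carbon as OAA C4.  The
    condensed citrate-synthase..IDH step places acetyl-CoA carbons at aKG
    C4/C5 (so PDH-only flux labels glutamate as 00011), and the
    malic-enzyme/PEPCK return truncates malate C1-C3 back to pyruvate
    (malate 1100 -> pyruvate 110).
    """
    global _BETA_CELL_MAPS
    if _BETA_CELL_MAPS is None:
        _BETA_CELL_MAPS = _beta_cell_maps()
    flux.validate()
    m = _BETA_CELL_MAPS
    reactions = [
        (m["glycolysis"], flux.v_glycolysis),
        # G-3-P mirrors the glycolytic two-point mixture (reporting
        # convenience; the flux value is immaterial as glycolysis is its
        # only producer).
        (m["glycolysis_g3p"], 1.0),
        (m["LDH"], flux.v_LDH),
        (m["ALT"], flux.v_ALT),
        (m["PDH"], flux.v_PDH),
        (m["PC"], flux.v_PC),
        (m["CS_ACO_IDH"], flux.v_TCA),
        (m["AKGDH_SCS"], flux.v_TCA),
        (m["SDH"], flux.v_TCA),
        (m["fumarase"], flux.v_TCA),
        (m["MDH"], flux.v_TCA - flux.v_ME),
        (m["MDH_rev"], flux.v_fum_exchange),
        (m["fumarase_rev"], flux.v_fum_exchange),
        (m["ME_PEPCK"], flux.v_ME),
        (m["GLUD_fwd"], flux.v_glu_exchange),
        (m["GLUD_rev"], flux.v_glu_exchange),
        (m["glutamate_dilution"], flux.v_glu_dilution),
        (m["AST_fwd"], flux.v_asp_exchange),
        (m["AST_rev"], flux.v_asp_exchange),
    ]

    e = flux.tracer_enrichment
    source = np.zeros(8)
    source[0] = 1.0 - e
    source[-1] = e

    return NetworkModel(
        metabolites=list(METABOLITES),
        reactions=reactions,
        symmetric_metabolites=SYMMETRIC_METABOLITES,
        fixed_distributions={GLYCOLYTIC_SOURCE: source},
        co2_enrichment=flux.co2_enrichment,
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def condense(
    d1: IsotopomerDistribution,
    d2: IsotopomerDistribution,
    amap: AtomMap,
) -> IsotopomerDistribution:
    """Product distribution of a two-substrate reaction, assuming the
    substrate pools mix independently.  Returns the first listed product;
    use :meth:`AtomMap.apply` for co-products (e.g. released CO2)."""
    expected = [(d1.metabolite, d1.n_carbons), (d2.metabolite, d2.n_carbons)]
    if [tuple(s) for s in amap.substrates] != [tuple(x) for x in expected]:
        raise ValueError(
            f"{amap.reaction}: substrates {amap.substrates} do not match "
            f"distributions {expected}"
        )
    out = amap.apply([d1.vector, d2.vector])
    product, n_prod = amap.products[0]
    return IsotopomerDistribution(product, n_prod, out[product])


def transform(d: IsotopomerDistribution, amap: AtomMap) -> IsotopomerDistribution:
    """Single-substrate counterpart of :func:`condense`."""
    if list(amap.substrates) != [(d.metabolite, d.n_carbons)]:
        raise ValueError(f"{amap.reaction}: substrate does not match {d.metabolite}")
    out = amap.apply([d.vector])
    product, n_prod = amap.products[0]
    return IsotopomerDistribution(product, n_prod, out[product])


_REV4 = _reversal_permutation(4)


def symmetry_scramble(d: IsotopomerDistribution) -> IsotopomerDistribution:
    """50/50 mixture of a 4-carbon distribution with its carbon-reversed form
    (rotational symmetry of succinate and fumarate)."""
    if d.n_carbons != 4:
        raise ValueError("symmetry scrambling is defined for 4-carbon metabolites")
    vec = 0.5 * (d.vector + d.vector[_REV4])
    return IsotopomerDistribution(d.metabolite, 4, vec)


def mid_from_isotopomers(d: IsotopomerDistribution) -> np.ndarray:
    """MID m+0..m+n: mass-shift marginal of the positional distribution."""
    pop = _popcounts(d.n_carbons)
    return np.bincount(pop, weights=d.vector, minlength=d.n_carbons + 1)


def _init_pools(net: NetworkModel) -> tuple[dict[str, np.ndarray], list[tuple[str, int]]]:
    dists: dict[str, np.ndarray] = {}
    order: list[tuple[str, int]] = []
    for name, n in net.metabolites:
        if name == "co2":
            continue  # external pool, fixed at co2_enrichment
        if not net._producers[name]:
            raise ValueError(f"metabolite {name} has no production flux")
        vec = np.zeros(2 ** n)
        vec[0] = 1.0
        dists[name] = vec
        order.append((name, n))
    return dists, order


def _sweep(
    net: NetworkModel,
    pools: dict[str, np.ndarray],
    order: list[tuple[str, int]],
    damping: float = 0.0,
) -> float:
    """One Gauss-Seidel pass over all metabolites; returns the max change."""
    residual = 0.0
    co2 = net.co2_enrichment
    symmetric = net.symmetric_metabolites
    for name, n in order:
        new = None
        for weight, amap, subs in net._plans[name]:
            if amap is None:  # identity map
                term = weight * pools[subs[0]]
            else:
                term = weight * amap.apply_one(
                    name, [pools[m] for m in subs], co2
                )
            new = term if new is None else new + term
        if name in symmetric:
            new = 0.5 * (new + new[_REV4])
        if damping:
            new = (1.0 - damping) * new + damping * pools[name]
        delta = float(np.max(np.abs(new - pools[name])))
        if delta > residual:
            residual = delta
        pools[name] = new
    return residual


def propagate_sweeps(
    net: NetworkModel, n_sweeps: int
) -> dict[str, IsotopomerDistribution]:
    """Distributions after a fixed number of propagation passes starting from
    fully unlabeled pools (no convergence requirement).  One pass suffices to
    expose the first-turn signatures of the PDH and PC routes."""
    dists, order = _init_pools(net)
    pools = {**net.fixed_distributions, **dists}
    for _ in range(n_sweeps):
        _sweep(net, pools, order)
    return {name: IsotopomerDistribution(name, n, pools[name]) for name, n in order}


def propagate_to_steady_state(
    net: NetworkModel,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> dict[str, IsotopomerDistribution]:
    """Fixed-point label propagation.

    Each metabolite's distribution is replaced by the flux-weighted mixture
    of its production terms, sweeping metabolites in declared order
    (Gauss-Seidel).  Rotational scrambling is applied to symmetric
    metabolites within the sweep.  If the sweep residual ever increases, the
    remaining updates are damped to suppress oscillation.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    dists, order = _init_pools(net)
    pools = {**net.fixed_distributions, **dists}

    prev_residual = math.inf
    damp = 0.0
    cooldown = 0  # sweeps to wait before trusting residual trends again
    for it in range(max_iter):
        old = {name: pools[name] for name, _ in order}
        residual = _sweep(net, pools, order, damping=damp)
        if residual < tol:
            break
        if cooldown == 0 and residual > prev_residual and damp == 0.0:
            damp = damping
        # the iteration converges geometrically; extrapolate the remaining
        # geometric tail every few sweeps to cut the sweep count
        if (
            damp == 0.0
            and cooldown == 0
            and it >= 4
            and 0.0 < residual < prev_residual
        ):
            rho = residual / prev_residual
            if 0.3 < rho < 0.97:
                factor = rho / (1.0 - rho)
                for name, _n in order:
                    vec = pools[name] + factor * (pools[name] - old[name])
                    np.clip(vec, 0.0, None, out=vec)
                    vec /= vec.sum()
                    pools[name] = vec
                cooldown = 3
        elif cooldown:
            cooldown -= 1
        prev_residual = residual
    else:
        raise ConvergenceError(
            f"steady state not reached in {max_iter} iterations "
            f"(residual {residual:.3e})",
            residual,
        )

    out = {
        name: IsotopomerDistribution(name, n, pools[name]) for name, n in order
    }
    for d in out.values():
        d.validate(atol=max(1e-9, 10 * tol))
    return out


def steady_state_mids(
    net: NetworkModel, tol: float = 1e-10, max_iter: int = 10_000
) -> dict[str, np.ndarray]:
    """Convenience: steady-state MIDs for every simulated metabolite."""
    dists = propagate_to_steady_state(net, tol=tol, max_iter=max_iter)
    return {name: mid_from_isotopomers(d) for name, d in dists.items()}


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def load_flux_config(path) -> FluxConfig:
    """Read a FluxConfig from a YAML file whose keys are exactly the
    FluxConfig field names."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(FluxConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown flux-config keys: {sorted(unknown)}")
    return FluxConfig(**raw)


def distributions_to_frame(dists: Mapping[str, IsotopomerDistribution]):
    """Long table of predicted isotopomer fractions:
    metabolite, pattern, fraction."""
    import pandas as pd

    rows = [
        {"metabolite": name, "pattern": pattern, "fraction": frac}
        for name, d in dists.items()
        for pattern, frac in d.fractions.items()
    ]
    return pd.DataFrame(rows, columns=["metabolite", "pattern", "fraction"])


def mids_to_frame(dists: Mapping[str, IsotopomerDistribution]):
    """Long table of predicted MIDs: metabolite, mass_shift, fraction."""
    import pandas as pd

    rows = [
        {"metabolite": name, "mass_shift": f"m+{k}", "fraction": frac}
        for name, d in dists.items()
        for k, frac in enumerate(mid_from_isotopomers(d))
    ]
    return pd.DataFrame(rows, columns=["metabolite", "mass_shift", "fraction"])
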