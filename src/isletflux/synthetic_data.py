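"""Seeded generator of synthetic islet-tracing cohorts.

Produces every input the pipeline consumes -- GC-MS ion-count tables, HSQC
multiplet tables, per-cell imaging measurements, biosensor traces, and MR
summary statistics -- for a human-like and a mouse-like cohort whose
generative parameters encode the headline observations the analysis is
meant to recover: a PC fraction of 0.20 for TCA entry in both species,
6-fold higher labeled-lactate accumulation and 1.2-fold higher alanine_111
in the human-like cohort, a 3-fold larger (more diluted) glutamate pool in
the mouse-like cohort, Hi-LDHB subpopulations of 19% among alpha cells and
74% among beta cells, a 10-20% LDHB-inhibitor effect on stimulated lactate
traces, and a fixed causal effect behind the eQTL summary statistics.
Because those truths are built in, pipeline recovery of them is a
self-consistency check of the implementation, not an external validation.

Determinism: every output is a pure function of the master seed.  Child
streams are derived from ``numpy.random.SeedSequence(master_seed)`` spawned
in a fixed order (gcms, nmr, imaging, traces, mr), and the master seed is
recorded in each CSV header line and in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .gcms import correction_matrix
from .isotopomer_model import (
    FluxConfig,
    IsotopomerDistribution,
    build_beta_cell_network,
    mid_from_isotopomers,
    propagate_to_steady_state,
)
from .nmr_multiplet import DEFAULT_OBSERVABLE, multiplet_forward

#: metabolites reported by the GC-MS arm (with backbone carbon counts)
GCMS_METABOLITES: tuple[tuple[str, int], ...] = (
    ("lactate", 3),
    ("alanine", 3),
    ("glutamate", 5),
    ("aspartate", 4),
    ("malate", 4),
    ("fumarate", 4),
    ("g3p", 3),
)

NMR_METABOLITES = ("lactate", "alanine", "glutamate")

#: pool size per unit of production inflow (arbitrary units); sets the
#: normalized-total scale of flux-proportional pools
POOL_TURNOVER = 2.0
GLU_POOL_TURNOVER = 0.4

#: fixed pools for metabolites whose totals the cohorts share
FIXED_POOLS = {"aspartate": 0.8, "malate": 1.0, "fumarate": 0.6, "g3p": 0.5}

IS_COUNTS_MEAN = 5e5  # internal-standard (D6-glutaric acid) ion counts


@dataclass
class ImagingMixture:
    hi_weight: float
    hi_mean: float = 1.6e5
    hi_sd: float = 2.5e4
    lo_mean: float = 3.0e4
    lo_sd: float = 1.5e4


@dataclass
class SpeciesProfile:
    """Generative parameters of one cohort."""

    name: str
    flux: FluxConfig
    pool_sizes: dict[str, float]
    gcms_sigma: float = 0.05      # per-channel multiplicative lognormal
    bio_sigma: float = 0.10       # per-sample pool-size lognormal
    is_sigma: float = 0.03        # internal-standard lognormal
    nmr_sigma_frac: float = 0.02  # additive Gaussian, fraction of max peak
    nmr_scale_mean: float = 100.0
    nmr_scale_sigma: float = 0.2
    imaging: dict[str, ImagingMixture] = field(default_factory=dict)
    trace_baseline: float = 0.8
    trace_response: float = 0.25      # fractional plateau rise at 17 mM glucose
    inhibitor_multiplier: float = 1.15  # LDHB-inhibitor effect on the response
    trace_noise: float = 0.01
    mr_exposure_beta: float = -0.35
    mr_exposure_se: float = 0.04
    mr_causal_effect: float = -0.5
    mr_outcome_se: float = 0.015

    def __post_init__(self):
        for marker, mix in self.imaging.items():
            if not 0.0 <= mix.hi_weight <= 1.0:
                raise ValueError(f"{marker}: Hi weight outside [0, 1]")


@dataclass
class GeneratorConfig:
    n_per_group: int = 9          # the tracing cohort size from the power analysis
    master_seed: int = 20240411
    n_cells: int = 150            # imaged cells per marker
    n_islets_per_arm: int = 12
    n_frames: int = 100
    stimulus_frame: int = 25
    frame_rate: float = 0.33

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need at least two samples per group")


_STREAMS = ("gcms", "nmr", "imaging", "traces", "mr")


def child_rng(master_seed: int, stream: str) -> np.random.Generator:
    """Named child stream from the documented spawn order."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


@lru_cache(maxsize=64)
def _steady_state_cached(flux_key: tuple) -> dict[str, IsotopomerDistribution]:
    cfg = FluxConfig(**dict(flux_key))
    return propagate_to_steady_state(build_beta_cell_network(cfg))


def steady_state(flux: FluxConfig) -> dict[str, IsotopomerDistribution]:
    key = tuple(sorted(dataclasses.asdict(flux).items()))
    return _steady_state_cached(key)


def _labeled_lactate_output(flux: FluxConfig) -> float:
    """Labeled-lactate accumulation proxy: pool (prop. to v_LDH) times the
    labeled fraction of the steady-state lactate distribution."""
    dist = steady_state(flux)["lactate"]
    return flux.v_LDH * POOL_TURNOVER * dist.labeled_fraction


def _alanine_111_output(flux: FluxConfig) -> float:
    dist = steady_state(flux)["alanine"]
    return flux.v_ALT * POOL_TURNOVER * dist.fraction("111")


@lru_cache(maxsize=1)
def default_profiles() -> tuple[SpeciesProfile, SpeciesProfile]:
    """(human_like, mouse_like) profiles.

    Shared fluxes put the PC fraction of TCA entry at 0.20.  The mouse-like
    cohort has low LDH flux and a strongly diluted glutamate pool
    (v_glu_dilution chosen for a 3-fold total-pool ratio); the human-like
    v_LDH and v_ALT are then calibrated on the noiseless simulator so the
    labeled-lactate output ratio is exactly 6 and the alanine_111 output
    ratio exactly 1.2.
    """
    shared = dict(
        v_PDH=0.8,
        v_PC=0.2,
        v_TCA=0.8,
        v_glu_exchange=2.0,
        v_asp_exchange=1.0,
        v_fum_exchange=0.5,
        tracer_enrichment=0.5,
    )
    # the mouse-like cohort routes relatively more pyruvate through the
    # TCA return (higher v_ME, lower v_LDH), which is what pushes its
    # m+3 G-3-P / m+3 lactate labeling ratio above the human-like one
    mouse_flux = FluxConfig(
        v_LDH=0.1, v_ALT=0.2, v_ME=0.35, v_glu_dilution=5.5, **shared
    )
    mouse_lactate = _labeled_lactate_output(mouse_flux)
    mouse_ala = _alanine_111_output(mouse_flux)

    v_ldh_h, v_alt_h = 0.6, 0.24
    human_flux = None
    for _ in range(6):  # fixed-point calibration; converges in a few rounds
        human_flux = FluxConfig(
            v_LDH=v_ldh_h, v_ALT=v_alt_h, v_ME=0.15, v_glu_dilution=0.5,
            **shared,
        )
        v_ldh_h *= 6.0 * mouse_lactate / _labeled_lactate_output(human_flux)
        v_alt_h *= 1.2 * mouse_ala / _alanine_111_output(human_flux)
    human_flux = FluxConfig(
        v_LDH=v_ldh_h, v_ALT=v_alt_h, v_ME=0.15, v_glu_dilution=0.5, **shared
    )

    def pools(flux: FluxConfig) -> dict[str, float]:
        out = dict(FIXED_POOLS)
        out["lactate"] = flux.v_LDH * POOL_TURNOVER
        out["alanine"] = flux.v_ALT * POOL_TURNOVER
        out["glutamate"] = (
            flux.v_glu_exchange + flux.v_glu_dilution
        ) * GLU_POOL_TURNOVER
        return out

    imaging = {
        "GCG": ImagingMixture(hi_weight=0.19),  # small Hi-LDHB alpha subset
        "INS": ImagingMixture(hi_weight=0.74),  # 26% of beta cells are Lo
    }
    human = SpeciesProfile(
        name="human_like", flux=human_flux, pool_sizes=pools(human_flux),
        imaging=imaging,
    )
    mouse = SpeciesProfile(
        name="mouse_like", flux=mouse_flux, pool_sizes=pools(mouse_flux),
        imaging=imaging, inhibitor_multiplier=1.12,
    )
    return human, mouse


def _lognormal(rng: np.random.Generator, sigma: float, size=None) -> np.ndarray:
    """Mean-one multiplicative noise."""
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_gcms(
    config: GeneratorConfig,
    profiles: tuple[SpeciesProfile, ...] | None = None,
) -> pd.DataFrame:
    """Ion-count table: steady-state MIDs convolved with natural abundance,
    scaled by per-sample pools and internal standard, with per-channel
    lognormal noise."""
    profiles = profiles or default_profiles()
    rng = child_rng(config.master_seed, "gcms")
    rows = []
    for profile in profiles:
        dists = steady_state(profile.flux)
        for s in range(1, config.n_per_group + 1):
            sample = f"{profile.name}_{s:02d}"
            bio = _lognormal(rng, profile.bio_sigma)
            standard = IS_COUNTS_MEAN * _lognormal(rng, profile.is_sigma)
            for met, n in GCMS_METABOLITES:
                mid = mid_from_isotopomers(dists[met])
                raw = correction_matrix(n) @ mid
                pool = profile.pool_sizes[met] * bio
                counts = (
                    pool * raw * standard * _lognormal(rng, profile.gcms_sigma, n + 1)
                )
                row = {
                    "sample_id": sample,
                    "group": profile.name,
                    "metabolite": met,
                    "n_carbons": n,
                }
                row.update({f"m{k}": counts[k] for k in range(n + 1)})
                for k in range(n + 1, 7):
                    row[f"m{k}"] = np.nan
                row["is_counts"] = standard
                rows.append(row)
    columns = ["sample_id", "group", "metabolite", "n_carbons"] + [
        f"m{k}" for k in range(7)
    ] + ["is_counts"]
    return pd.DataFrame(rows, columns=columns)


def generate_nmr(
    config: GeneratorConfig,
    profiles: tuple[SpeciesProfile, ...] | None = None,
) -> pd.DataFrame:
    """Multiplet table: forward-modeled component intensities at an
    arbitrary per-sample spectrometer scale plus additive Gaussian noise."""
    profiles = profiles or default_profiles()
    rng = child_rng(config.master_seed, "nmr")
    rows = []
    for profile in profiles:
        dists = steady_state(profile.flux)
        for s in range(1, config.n_per_group + 1):
            sample = f"{profile.name}_{s:02d}"
            scale = profile.nmr_scale_mean * _lognormal(
                rng, profile.nmr_scale_sigma
            )
            for met in NMR_METABOLITES:
                table = multiplet_forward(dists[met])
                if table.empty:
                    continue
                sigma = profile.nmr_sigma_frac * table["intensity"].max() * scale
                for _, r in table.iterrows():
                    intensity = scale * r["intensity"] + rng.normal(0.0, sigma)
                    rows.append(
                        {
                            "sample_id": sample,
                            "group": profile.name,
                            "metabolite": met,
                            "position": int(r["position"]),
                            "component": r["component"],
                            "intensity": max(float(intensity), 0.0),
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "metabolite", "position", "component",
                 "intensity"],
    )


def generate_imaging(
    config: GeneratorConfig,
    profile: SpeciesProfile | None = None,
) -> pd.DataFrame:
    """Per-cell measurements drawn from the two-component CTCF mixture per
    marker; integrated density is reconstructed so CTCF recovers the drawn
    component value exactly."""
    profile = profile or default_profiles()[0]
    rng = child_rng(config.master_seed, "imaging")
    rows = []
    for marker, mix in profile.imaging.items():
        hi = rng.random(config.n_cells) < mix.hi_weight
        target = np.where(
            hi,
            rng.normal(mix.hi_mean, mix.hi_sd, config.n_cells),
            rng.normal(mix.lo_mean, mix.lo_sd, config.n_cells),
        )
        target = np.clip(target, 1.0, None)
        area = np.clip(rng.normal(200.0, 30.0, config.n_cells), 50.0, None)
        background = np.clip(rng.normal(100.0, 10.0, config.n_cells), 10.0, None)
        for i in range(config.n_cells):
            rows.append(
                {
                    "cell_id": f"{marker}_{i + 1:03d}",
                    "marker": marker,
                    "integrated_density": target[i] + area[i] * background[i],
                    "area": area[i],
                    "background_mean": background[i],
                }
            )
    return pd.DataFrame(rows)


def _response_shape(config: GeneratorConfig) -> np.ndarray:
    """Saturating rise after the stimulus frame, zero before."""
    frames = np.arange(config.n_frames)
    shape = 1.0 - np.exp(-(frames - config.stimulus_frame) / 8.0)
    shape[frames < config.stimulus_frame] = 0.0
    return shape


def generate_traces(
    config: GeneratorConfig,
    profile: SpeciesProfile | None = None,
) -> pd.DataFrame:
    """Lactate-biosensor ratio traces for vehicle and LDHB-inhibitor arms;
    the inhibitor multiplies the glucose response by a fixed factor."""
    profile = profile or default_profiles()[0]
    rng = child_rng(config.master_seed, "traces")
    shape = _response_shape(config)
    rows = []
    for arm, multiplier in (
        ("vehicle", 1.0),
        ("inhibitor", profile.inhibitor_multiplier),
    ):
        amplitude = profile.trace_response * multiplier
        for islet in range(1, config.n_islets_per_arm + 1):
            ratio = profile.trace_baseline * (1.0 + amplitude * shape)
            denominator = rng.normal(1000.0, 5.0, config.n_frames)
            numerator = ratio * denominator * (
                1.0 + rng.normal(0.0, profile.trace_noise, config.n_frames)
            )
            for frame in range(config.n_frames):
                rows.append(
                    {
                        "arm": arm,
                        "islet_id": f"{arm}_{islet:02d}",
                        "frame": frame,
                        "numerator": numerator[frame],
                        "denominator": denominator[frame],
                    }
                )
    return pd.DataFrame(rows)


def generate_mr(
    config: GeneratorConfig,
    profile: SpeciesProfile | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure/outcome summary statistics: one usable instrument plus
    secondary SNPs, a palindromic SNP (must be excluded downstream), and
    randomized outcome allele coding to exercise harmonization."""
    profile = profile or default_profiles()[0]
    rng = child_rng(config.master_seed, "mr")
    snps = [
        ("rs_ldhb_1", "A", "G"),
        ("rs_ldhb_2", "C", "T"),
        ("rs_ldhb_3", "G", "A"),
        ("rs_ldhb_pal", "A", "T"),  # strand-ambiguous; dropped by policy
    ]
    exp_rows, out_rows = [], []
    for snp, ea, oa in snps:
        beta_exp = profile.mr_exposure_beta * (0.8 + 0.4 * rng.random())
        beta_out = profile.mr_causal_effect * beta_exp + rng.normal(
            0.0, profile.mr_outcome_se
        )
        exp_rows.append(
            {"snp": snp, "ea": ea, "oa": oa, "beta": beta_exp,
             "se": profile.mr_exposure_se, "role": "exposure"}
        )
        if rng.random() < 0.5:  # re-code the outcome allele orientation
            out_rows.append(
                {"snp": snp, "ea": oa, "oa": ea, "beta": -beta_out,
                 "se": profile.mr_outcome_se, "role": "outcome"}
            )
        else:
            out_rows.append(
                {"snp": snp, "ea": ea, "oa": oa, "beta": beta_out,
                 "se": profile.mr_outcome_se, "role": "outcome"}
            )
    return pd.DataFrame(exp_rows), pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# bundle writing
# ---------------------------------------------------------------------------

def generative_truths(
    config: GeneratorConfig,
    profiles: tuple[SpeciesProfile, ...] | None = None,
) -> dict:
    """The noiseless quantities the pipeline is expected to recover."""
    human, mouse = profiles or default_profiles()
    truths = {
        "f_PC": {p.name: p.flux.f_PC for p in (human, mouse)},
        "labeled_lactate_ratio_human_over_mouse": _labeled_lactate_output(
            human.flux
        ) / _labeled_lactate_output(mouse.flux),
        "alanine_111_ratio_human_over_mouse": _alanine_111_output(human.flux)
        / _alanine_111_output(mouse.flux),
        "glutamate_pool_ratio_mouse_over_human": mouse.pool_sizes["glutamate"]
        / human.pool_sizes["glutamate"],
        "hi_proportion": {m: mix.hi_weight for m, mix in human.imaging.items()},
        "inhibitor_auc_multiplier": {
            p.name: p.inhibitor_multiplier for p in (human, mouse)
        },
        "mr_causal_effect": human.mr_causal_effect,
        "tracer_enrichment": {p.name: p.flux.tracer_enrichment
                              for p in (human, mouse)},
    }
    return truths


def _write_csv(df: pd.DataFrame, path: Path, master_seed: int, kind: str) -> None:
    header = f"# isletflux synthetic {kind}; master_seed={master_seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def generate_all(config: GeneratorConfig, outdir: str | Path) -> dict:
    """Write the full synthetic bundle and its manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = default_profiles()
    seed = config.master_seed

    _write_csv(generate_gcms(config, profiles), outdir / "gcms_ion_counts.csv",
               seed, "gcms ion counts")
    _write_csv(generate_nmr(config, profiles), outdir / "nmr_multiplets.csv",
               seed, "nmr multiplets")
    _write_csv(generate_imaging(config), outdir / "imaging_cells.csv",
               seed, "imaging cells")
    _write_csv(generate_traces(config), outdir / "traces.csv", seed, "traces")
    exposure, outcome = generate_mr(config)
    _write_csv(exposure, outdir / "mr_exposure.csv", seed, "mr exposure")
    _write_csv(outcome, outdir / "mr_outcome.csv", seed, "mr outcome")

    manifest = {
        "config": dataclasses.asdict(config),
        "seed_streams": {s: f"SeedSequence({seed}).spawn[{i}]"
                         for i, s in enumerate(_STREAMS)},
        "profiles": {
            p.name: {
                "flux": dataclasses.asdict(p.flux),
                "pool_sizes": p.pool_sizes,
                "noise": {
                    "gcms_sigma": p.gcms_sigma,
                    "bio_sigma": p.bio_sigma,
                    "nmr_sigma_frac": p.nmr_sigma_frac,
                },
            }
            for p in profiles
        },
        "generative_truths": generative_truths(config, profiles),
        "observable_positions": {m: list(v) for m, v in DEFAULT_OBSERVABLE.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
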