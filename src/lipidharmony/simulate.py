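"""Synthetic multi-method lipidomics datasets with known ground truth.

The generator emulates the study design the pipeline assumes: several
acquisition methods/sites measure aliquots of the same two plasma pools in
replicate, alongside replicate QC (long-term-reference) injections, blank
extractions, a seven-point dilution series of extract against internal
standard (10–200% of the standard sample volume, two replicates per point),
and replicates of a shared reference material measured with the same biases
as the study samples.

The observation model for analyte feature i in injection j of method m is

    I_ijm = c_true(i, sample(j)) × V / A_IS(i) × I_IS × b_im × (1 + ε_ijm)

with plasma volume V, spiked IS amount A, a per-lipid per-method
multiplicative response bias b_im ~ LogNormal(0, σ_log) — the systematic
method difference the shared-reference normalization cancels — and
proportional technical noise ε ~ N(0, τ) truncated at −0.9.  Optionally the
M+2 isotopic-overlap forward model is applied to the raw areas, and planted
QC-failure subsets receive blank contamination, inflated QC variability, or
a flat dilution response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .isotopes import m2_ratio
from .nomenclature import LipidSpecies, parse_shorthand
from .quantify import InternalStandardMap
from .tables import MeasurementTable, Role

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "lipid_panel",
    "build_is_map",
    "generate",
    "plant_qc_failures",
]

# class-typical total-carbon grids used to spell out the synthetic panel;
# the most common species come first so small panels stay plausible
_GP_CARBONS = (32, 34, 36, 38, 40, 30, 31, 33, 35, 37)
_LYSO_CARBONS = (16, 17, 18, 20, 22, 14, 15, 19, 21, 24)
_SPH_CARBONS = (34, 36, 38, 40, 42, 32, 33, 35, 37, 39)
_CLASS_CARBONS: dict[str, tuple[int, ...]] = {
    "PC": _GP_CARBONS, "PE": _GP_CARBONS, "PI": _GP_CARBONS,
    "PS": _GP_CARBONS, "PG": _GP_CARBONS, "PA": _GP_CARBONS,
    "LPC": _LYSO_CARBONS, "LPE": _LYSO_CARBONS, "CE": _LYSO_CARBONS,
    "SM": _SPH_CARBONS, "Cer": _SPH_CARBONS, "DG": _SPH_CARBONS,
    "TG": (48, 50, 52, 54, 56, 46, 47, 49, 51, 53),
}
_MAX_DB = 4


@dataclass(frozen=True)
class SimulationConfig:
    classes: tuple[str, ...] = ("PC", "LPC", "PE", "SM", "Cer", "TG", "CE")
    lipids_per_class: int = 12
    methods: tuple[str, ...] = ("RP", "HILIC", "DI")
    n_replicates: int = 5           # study replicates per pool per method
    n_qc: int = 10                  # replicate QC injections
    n_blank: int = 4                # replicate blank extractions
    n_reference: int = 5            # shared-reference replicates per method
    dilution_fractions: tuple[float, ...] = (0.10, 0.25, 0.50, 0.75, 1.0, 1.5, 2.0)
    dilution_replicates: int = 2
    # two study pools: log-normal mean profile across lipids
    conc_log_mean: float = np.log(5.0)   # ln µmol/L
    conc_log_sigma: float = 1.15         # panel spans ~3 orders of magnitude
    n_fold_changed: int = 10
    fold_change: float = 2.0
    # reference material is plasma like the study pools: its per-lipid levels
    # track the study profile within a modest log-normal factor
    ref_log_sigma: float = 0.3
    bias_sigma_log: float = 0.5     # per-lipid per-method bias, up to ~3-fold
    technical_cov: float = 0.08
    injection_scale_sigma: float = 0.0  # global per-injection intensity factor
    sample_dependent_bias_sigma: float = 0.0  # residual, non-cancelable bias
    species_specific_is: tuple[str, ...] = ()
    contamination_lipids: tuple[str, ...] = ()
    high_cov_lipids: tuple[str, ...] = ()
    nonlinear_lipids: tuple[str, ...] = ()
    reference_missing_lipids: tuple[str, ...] = ()
    isotope_overlap: bool = False
    plasma_volume_ul: float = 10.0
    is_amount_pmol: float = 100.0
    is_base_intensity: float = 1.0e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lipids_per_class < 1 or self.n_replicates < 1:
            raise ValueError("lipid and replicate counts must be positive")
        if self.technical_cov < 0 or self.bias_sigma_log < 0:
            raise ValueError("noise scales must be non-negative")
        for cls in self.classes:
            if cls not in _CLASS_CARBONS:
                raise ValueError(f"no panel grid for class {cls!r}")
            if self.lipids_per_class > len(_CLASS_CARBONS[cls]) * (_MAX_DB + 1):
                raise ValueError(f"panel grid for {cls!r} too small")
        planted = [set(self.contamination_lipids), set(self.high_cov_lipids),
                   set(self.nonlinear_lipids)]
        for i, a in enumerate(planted):
            for b in planted[i + 1:]:
                if a & b:
                    raise ValueError(f"planted failure sets overlap: {sorted(a & b)}")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    pool_concentrations: pd.DataFrame     # lipid × {A, B}, µmol/L
    qc_concentrations: pd.Series          # lipid, µmol/L
    reference_concentrations: pd.Series   # lipid, µmol/L
    bias: pd.DataFrame                    # lipid × method
    species_index: dict[str, LipidSpecies]
    fold_changed: tuple[str, ...]
    planted_fail: tuple[str, ...]
    planted_pass: tuple[str, ...]


def lipid_panel(config: SimulationConfig) -> dict[str, LipidSpecies]:
    """Deterministic panel of shorthand names → species for the config."""
    index: dict[str, LipidSpecies] = {}
    for cls in config.classes:
        names = []
        for carbons in _CLASS_CARBONS[cls]:
            for dbs in range(_MAX_DB + 1):
                prefix = "d" if cls in ("SM", "Cer") else ""
                names.append(f"{cls} {prefix}{carbons}:{dbs}")
        for name in names[: config.lipids_per_class]:
            index[name] = parse_shorthand(name)
    return index


def build_is_map(config: SimulationConfig) -> InternalStandardMap:
    """Internal-standard map matching the generator's feature naming."""
    return InternalStandardMap(
        class_map={cls: (f"IS {cls}", config.is_amount_pmol) for cls in config.classes},
        species_overrides={
            name: (f"IS {name}-d7", config.is_amount_pmol)
            for name in config.species_specific_is
        },
    )


def plant_qc_failures(
    config: SimulationConfig,
    n_contamination: int = 0,
    n_high_cov: int = 0,
    n_nonlinear: int = 0,
) -> SimulationConfig:
    """Mark disjoint lipid subsets to trip each QC filter.

    Subsets are drawn without replacement from the panel with the config's
    seed, so the same config always plants the same lipids.
    """
    panel = list(lipid_panel(config))
    total = n_contamination + n_high_cov + n_nonlinear
    if total > len(panel):
        raise ValueError(
            f"cannot plant {total} failures among {len(panel)} lipids"
        )
    rng = np.random.default_rng(config.seed)
    chosen = list(rng.choice(panel, size=total, replace=False))
    return replace(
        config,
        contamination_lipids=tuple(chosen[:n_contamination]),
        high_cov_lipids=tuple(chosen[n_contamination:n_contamination + n_high_cov]),
        nonlinear_lipids=tuple(chosen[n_contamination + n_high_cov:]),
    )


def _injection_layout(config: SimulationConfig, method: str) -> pd.DataFrame:
    rows = []
    for pool in ("A", "B"):
        for r in range(1, config.n_replicates + 1):
            rows.append((f"{method}:{pool}{r}", f"pool{pool}", Role.STUDY, r, np.nan))
    for r in range(1, config.n_qc + 1):
        rows.append((f"{method}:QC{r}", "LTR", Role.QC_LTR, r, np.nan))
    for r in range(1, config.n_blank + 1):
        rows.append((f"{method}:BL{r}", "blank", Role.BLANK, r, np.nan))
    for r in range(1, config.n_reference + 1):
        rows.append((f"{method}:REF{r}", "SRM", Role.REFERENCE, r, np.nan))
    for frac in config.dilution_fractions:
        for r in range(1, config.dilution_replicates + 1):
            rows.append(
                (f"{method}:DIL{int(round(frac * 100))}-{r}", "LTR-dil", Role.DILUTION, r, frac)
            )
    meta = pd.DataFrame(
        rows, columns=["injection", "sample", "role", "replicate", "dilution_fraction"]
    ).set_index("injection")
    meta["method"] = method
    meta["batch"] = 0
    return meta


def generate(
    config: SimulationConfig,
) -> tuple[dict[str, MeasurementTable], GroundTruth]:
    """Simulate one MeasurementTable per method plus the ground truth.

    Deterministic for a fixed config (the seed is part of the config): the
    same config yields bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    species_index = lipid_panel(config)
    lipids = list(species_index)
    n = len(lipids)

    # true concentration profiles (shared by every method)
    base = np.exp(rng.normal(config.conc_log_mean, config.conc_log_sigma, size=n))
    pool_a = pd.Series(base, index=lipids)
    # biological fold changes between two plasma pools sit in the minor
    # species; bulk structural lipids are homeostatically regulated
    low_abundance = [l for l in lipids if pool_a[l] <= pool_a.median()] or lipids
    fold_changed = tuple(
        str(x) for x in rng.choice(
            low_abundance, size=min(config.n_fold_changed, len(low_abundance)),
            replace=False,
        )
    )
    pool_b = pool_a.copy()
    pool_b.loc[list(fold_changed)] *= config.fold_change
    c_qc = (pool_a + pool_b) / 2.0
    # reference material: same matrix as the study pools, modest offsets
    c_ref = c_qc * np.exp(rng.normal(0.0, config.ref_log_sigma, size=n))
    c_ref.loc[[l for l in config.reference_missing_lipids if l in c_ref.index]] = 0.0

    bias = pd.DataFrame(
        np.exp(rng.normal(0.0, config.bias_sigma_log, size=(n, len(config.methods)))),
        index=lipids, columns=list(config.methods),
    )

    m2 = {
        name: m2_ratio(sp) for name, sp in species_index.items()
    } if config.isotope_overlap else {}

    planted_fail = tuple(
        sorted(set(config.contamination_lipids) | set(config.high_cov_lipids)
               | set(config.nonlinear_lipids))
    )
    truth = GroundTruth(
        pool_concentrations=pd.DataFrame({"A": pool_a, "B": pool_b}),
        qc_concentrations=c_qc,
        reference_concentrations=c_ref,
        bias=bias,
        species_index=species_index,
        fold_changed=fold_changed,
        planted_fail=planted_fail,
        planted_pass=tuple(l for l in lipids if l not in planted_fail),
    )

    scale = config.plasma_volume_ul / config.is_amount_pmol * config.is_base_intensity
    is_map = build_is_map(config)
    tables: dict[str, MeasurementTable] = {}
    for method in config.methods:
        meta = _injection_layout(config, method)
        cols = list(meta.index)
        matrix = pd.DataFrame(0.0, index=_feature_order(config, is_map), columns=cols)

        for j, inj in enumerate(cols):
            role = meta.loc[inj, "role"]
            # per-injection global factor (cancels in IS ratios)
            g = (
                np.exp(rng.normal(0.0, config.injection_scale_sigma))
                if config.injection_scale_sigma > 0 else 1.0
            )
            if role == Role.STUDY:
                conc = pool_a if meta.loc[inj, "sample"] == "poolA" else pool_b
            elif role in (Role.QC_LTR, Role.DILUTION):
                conc = c_qc
            elif role == Role.REFERENCE:
                conc = c_ref
            else:  # blank
                conc = pd.Series(0.0, index=lipids)

            analyte = conc.to_numpy() * scale * bias[method].to_numpy()
            if role == Role.BLANK and config.contamination_lipids:
                idx = [lipids.index(l) for l in config.contamination_lipids]
                contaminated = (
                    c_qc.iloc[idx].to_numpy() * scale * bias[method].iloc[idx].to_numpy()
                )
                analyte[idx] = 0.3 * contaminated
            if role == Role.DILUTION:
                analyte = analyte * float(meta.loc[inj, "dilution_fraction"])
                if config.nonlinear_lipids:
                    idx = [lipids.index(l) for l in config.nonlinear_lipids]
                    # flat response: ignore the dilution factor entirely
                    analyte[idx] = (
                        c_qc.iloc[idx].to_numpy() * scale * bias[method].iloc[idx].to_numpy()
                    )
            if role == Role.QC_LTR and config.high_cov_lipids:
                idx = [lipids.index(l) for l in config.high_cov_lipids]
                # deterministic ±50% alternation: guaranteed CoV ≈ 0.53
                analyte[idx] *= 1.0 + 0.5 * (-1.0) ** meta.loc[inj, "replicate"]
            if config.sample_dependent_bias_sigma > 0 and role == Role.STUDY:
                analyte = analyte * np.exp(
                    rng.normal(0.0, config.sample_dependent_bias_sigma, size=n)
                )

            noise = _noise(rng, config.technical_cov, n)
            analyte = analyte * noise * g

            if config.isotope_overlap:
                analyte = _apply_m2_overlap(analyte, lipids, species_index, m2)

            matrix.loc[lipids, inj] = analyte

            # internal-standard rows: constant spike, shared injection factor.
            # Technical noise is attached to the analyte response (the
            # IS-normalized ratio); the IS is the noiseless denominator.
            for cls in config.classes:
                matrix.loc[f"IS {cls}", inj] = config.is_base_intensity * g
            for name in config.species_specific_is:
                # labeled analog: co-ionizes with its target, same bias
                matrix.loc[f"IS {name}-d7", inj] = (
                    config.is_base_intensity * bias.loc[name, method] * g
                )

        tables[method] = MeasurementTable(matrix, meta)
    return tables, truth


def _feature_order(config: SimulationConfig, is_map: InternalStandardMap) -> list[str]:
    panel = list(lipid_panel(config))
    is_features = [f for f, _ in is_map.class_map.values()]
    is_features += [f for f, _ in is_map.species_overrides.values()]
    return panel + is_features


def _noise(rng: np.random.Generator, tau: float, size: int) -> np.ndarray:
    if tau == 0:
        return np.ones(size)
    return 1.0 + np.clip(rng.normal(0.0, tau, size=size), -0.9, None)


def _apply_m2_overlap(
    analyte: np.ndarray,
    lipids: list[str],
    species_index: Mapping[str, LipidSpecies],
    m2: Mapping[str, float],
) -> np.ndarray:
    """Forward model: measured(C:D) = true(C:D) + true(C:D+1) × a2(C:D+1)."""
    series: dict[tuple, dict[int, int]] = {}
    for pos, name in enumerate(lipids):
        sp = species_index[name]
        series.setdefault(sp.series_key(), {})[sp.total_double_bonds] = pos
    measured = analyte.copy()
    for group in series.values():
        for dbs, pos in group.items():
            donor = group.get(dbs + 1)
            if donor is not None:
                measured[pos] = analyte[pos] + analyte[donor] * m2[lipids[donor]]
    return measured
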