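"""Synthetic LiP, TPP and DSF data with the statistical structure the
analysis assumes.

Peptide thermal profiles are generated from the same two-state unfolding
sigmoid used by the DSF model (flat baselines, default unfolding enthalpy
300 kJ/mol so a transition spans roughly 3-4 gradient steps):

* ``unfolder`` proteins: fully tryptic peptides follow the decreasing folded
  fraction f(T; Tm);
* ``aggregator`` proteins: fully tryptic peptides follow 1 - f (new protease
  sites appear as the protein aggregates);
* ``nonmonotonous`` proteins: a bump profile, the product of a rising and a
  falling sigmoid bracketing Tm.

Half-tryptic peptides carry the mirrored profile (1 - FT profile) with an
independent amplitude.  The osmolyte condition shifts every transition
midpoint of a protein rightward by its ``delta_Tm``.  Observed intensity is
amplitude x profile x lognormal replicate noise, with optional missingness.
All generators are pure functions of (parameters, seed); the seed is
mandatory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    PeptideDataset,
    ProteinSolubilityDataset,
    TemperatureGrid,
    dataset_from_table,
)
from .dsf import DSFModelParams, KELVIN, two_state_model

ARCHETYPES = ("unfolder", "aggregator", "nonmonotonous")

#: default unfolding enthalpy of the generating sigmoid (J/mol)
DEFAULT_DHM = 3.0e5


@dataclass(frozen=True)
class SimProteinSpec:
    """Generating parameters of one simulated protein."""

    protein_id: str
    length: int = 160
    archetype: str = "unfolder"
    Tm_control: float = 55.0          # deg C
    delta_Tm: float = 0.0             # rightward osmolyte shift, deg C
    precipitator: bool = True
    n_peptides: int = 8
    overlap_fraction: float = 0.3     # fraction of peptide length shared with neighbour
    n_ht_peptides: int = 0
    tpp_plateau: float = 0.1          # soluble fraction remaining at the top temperature

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if not 40.0 < self.Tm_control < 72.0:
            raise ValueError("Tm_control must lie within (40, 72) deg C")


@dataclass(frozen=True)
class SimNoiseModel:
    """Replicate noise: multiplicative lognormal with log-scale s.d.
    ``sigma``; per-peptide amplitudes drawn log-uniformly between the given
    bounds; entries dropped at the missingness rate."""

    sigma: float = 0.05
    amplitude_range: tuple[float, float] = (1e4, 1e6)
    missingness: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not 0.0 <= self.missingness <= 0.2:
            raise ValueError("missingness rate must lie in [0, 0.2]")


def folded_fraction(t_celsius: np.ndarray, tm_celsius: float, dhm: float = DEFAULT_DHM) -> np.ndarray:
    """Decreasing two-state folded fraction (flat unit/zero baselines)."""
    params = DSFModelParams(Sf=1.0, Su=0.0, mf=0.0, mu=0.0,
                            Tm=tm_celsius + KELVIN, dHm=dhm)
    return two_state_model(params, np.asarray(t_celsius, dtype=float) + KELVIN)


def archetype_profile(
    archetype: str, t_celsius: np.ndarray, tm_celsius: float, dhm: float = DEFAULT_DHM
) -> np.ndarray:
    """Noise-free fully tryptic profile of an archetype at midpoint Tm."""
    t = np.asarray(t_celsius, dtype=float)
    if archetype == "unfolder":
        return folded_fraction(t, tm_celsius, dhm)
    if archetype == "aggregator":
        return 1.0 - folded_fraction(t, tm_celsius, dhm)
    # nonmonotonous: bump between a rise at Tm - 5 and a fall at Tm + 5
    rise = 1.0 - folded_fraction(t, tm_celsius - 5.0, dhm)
    fall = folded_fraction(t, tm_celsius + 5.0, dhm)
    return rise * fall


def _peptide_coords(spec: SimProteinSpec, peptide_length: int = 15) -> list[tuple[int, int]]:
    """Tile ``n_peptides`` peptides along the protein with the configured
    overlap fraction, clipped to the protein length."""
    stride = max(1, int(round(peptide_length * (1.0 - spec.overlap_fraction))))
    coords = []
    for i in range(spec.n_peptides):
        start = 1 + (i * stride) % max(1, spec.length - peptide_length + 1)
        coords.append((start, min(start + peptide_length - 1, spec.length)))
    return coords


def _expected_group(archetype: str, tryptic_type: str) -> str:
    """Shape group a peptide's generating profile belongs to (FT; HT
    mirrored)."""
    if archetype == "nonmonotonous":
        return "nonmonotonous"
    flip = tryptic_type == "HT"
    if archetype == "unfolder":
        return "increasing" if flip else "decreasing"
    return "decreasing" if flip else "increasing"


def simulate_lip_experiment(
    specs: list[SimProteinSpec],
    noise: SimNoiseModel,
    grid: TemperatureGrid | None = None,
    n_replicates: int = 2,
    seed: int | None = None,
    conditions: tuple[str, str] = ("control", "osmolyte"),
    dhm: float = DEFAULT_DHM,
) -> PeptideDataset:
    """Simulate a two-condition LiP thermal-gradient peptide dataset."""
    if seed is None:
        raise ValueError("a seed is mandatory: generators must be reproducible")
    if not specs:
        raise ValueError("at least one protein spec is required")
    grid = grid or TemperatureGrid()
    rng = np.random.default_rng(seed)
    t = grid.array

    rows = []
    lo, hi = noise.amplitude_range
    for spec in specs:
        coords = _peptide_coords(spec)
        peptides = [("FT", s, e) for s, e in coords]
        for j in range(spec.n_ht_peptides):
            s, e = coords[j % len(coords)]
            peptides.append(("HT", s + 2, max(s + 2, e - 3)))
        for idx, (ttype, start, end) in enumerate(peptides):
            amplitude = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            pep_id = f"{spec.protein_id}_{ttype}{idx:02d}"
            for cond_i, cond in enumerate(conditions):
                tm = spec.Tm_control + (spec.delta_Tm if cond_i == 1 else 0.0)
                prof = archetype_profile(spec.archetype, t, tm, dhm)
                if ttype == "HT":
                    prof = np.clip(1.0 - prof, 1e-4, None)
                for rep in range(1, n_replicates + 1):
                    eps = (
                        np.exp(rng.normal(0.0, noise.sigma, size=t.size))
                        if noise.sigma > 0
                        else np.ones(t.size)
                    )
                    inten = amplitude * prof * eps
                    keep = (
                        rng.random(t.size) >= noise.missingness
                        if noise.missingness > 0
                        else np.ones(t.size, dtype=bool)
                    )
                    for ti, temp in enumerate(t):
                        rows.append(
                            (spec.protein_id, pep_id, start, end, ttype, cond,
                             rep, float(temp),
                             float(inten[ti]) if keep[ti] else np.nan)
                        )
    df = pd.DataFrame(
        rows,
        columns=["protein_id", "peptide", "start", "end", "tryptic_type",
                 "condition", "replicate", "temperature_C", "intensity"],
    )
    return dataset_from_table(df, grid=grid)


def simulate_null_experiment(
    specs: list[SimProteinSpec],
    noise: SimNoiseModel,
    grid: TemperatureGrid | None = None,
    seed: int | None = None,
) -> PeptideDataset:
    """Four identically generated control replicates relabelled as two
    pseudo-conditions of two replicates each ({1,2} -> null_a, {3,4} ->
    null_b) — the replicate-split null used for FDR calibration.  Any
    ``delta_Tm`` in the specs is ignored (both pseudo-conditions share the
    control parameters)."""
    null_specs = [
        SimProteinSpec(
            protein_id=s.protein_id, length=s.length, archetype=s.archetype,
            Tm_control=s.Tm_control, delta_Tm=0.0, precipitator=s.precipitator,
            n_peptides=s.n_peptides, overlap_fraction=s.overlap_fraction,
            n_ht_peptides=s.n_ht_peptides, tpp_plateau=s.tpp_plateau,
        )
        for s in specs
    ]
    ds = simulate_lip_experiment(
        null_specs, noise, grid=grid, n_replicates=4, seed=seed,
        conditions=("control",),
    )
    table = ds.table.copy()
    table["condition"] = np.where(table["replicate"] <= 2, "null_a", "null_b")
    table["replicate"] = ((table["replicate"] - 1) % 2) + 1
    return dataset_from_table(table, grid=ds.grid)


def simulate_tpp_experiment(
    specs: list[SimProteinSpec],
    noise: SimNoiseModel,
    grid: TemperatureGrid | None = None,
    seed: int | None = None,
    n_replicates: int = 2,
    conditions: tuple[str, str] = ("control", "osmolyte"),
    dhm: float = DEFAULT_DHM,
) -> ProteinSolubilityDataset:
    """Simulate soluble-fraction protein abundance over the gradient.

    Precipitators decay sigmoidally to ``tpp_plateau`` (< 0.5); proteins
    flagged as nonprecipitators keep a plateau >= 0.5.  The osmolyte shifts
    the midpoint by ``delta_Tm``.  Each (protein, condition, replicate)
    profile is scaled so the 37 C value is exactly 1.
    """
    if seed is None:
        raise ValueError("a seed is mandatory: generators must be reproducible")
    grid = grid or TemperatureGrid()
    rng = np.random.default_rng(seed)
    t = grid.array

    rows = []
    for spec in specs:
        plateau = spec.tpp_plateau if spec.precipitator else max(spec.tpp_plateau, 0.6)
        for cond_i, cond in enumerate(conditions):
            tm = spec.Tm_control + (spec.delta_Tm if cond_i == 1 else 0.0)
            prof = plateau + (1.0 - plateau) * folded_fraction(t, tm, dhm)
            for rep in range(1, n_replicates + 1):
                eps = (
                    np.exp(rng.normal(0.0, noise.sigma, size=t.size))
                    if noise.sigma > 0
                    else np.ones(t.size)
                )
                y = prof * eps
                y = y / y[0]  # scale to the 37 C value
                for ti, temp in enumerate(t):
                    rows.append((spec.protein_id, cond, rep, float(temp), float(y[ti])))
    df = pd.DataFrame(
        rows,
        columns=["protein_id", "condition", "replicate", "temperature_C",
                 "rel_abundance"],
    )
    return ProteinSolubilityDataset(table=df, grid=grid)


def simulate_dsf_curve(
    params: DSFModelParams,
    sigma: float = 0.0,
    t_range: tuple[float, float, float] = (25.0, 95.0, 0.5),
    seed: int | None = None,
) -> pd.DataFrame:
    """Noisy two-state fluorescence curve: S(T) + additive Gaussian noise.

    Returns a DataFrame with columns temperature_C, signal, replicate.
    """
    if seed is None:
        raise ValueError("a seed is mandatory: generators must be reproducible")
    lo, hi, step = t_range
    tC = np.arange(lo, hi + step / 2, step)
    if not lo <= params.Tm_C <= hi:
        warnings.warn(
            f"Tm = {params.Tm_C:.1f} C lies outside the simulated range "
            f"[{lo}, {hi}] C; the fit will be unstable"
        )
    rng = np.random.default_rng(seed)
    s = two_state_model(params, tC + KELVIN)
    if sigma > 0:
        s = s + rng.normal(0.0, sigma, size=tC.size)
    return pd.DataFrame(
        {"temperature_C": tC, "signal": s, "replicate": 1}
    )


def make_protein_specs(
    n_proteins: int,
    seed: int,
    delta_Tm: float = 0.0,
    archetype_weights: tuple[float, float, float] = (0.6, 0.25, 0.15),
    n_peptides: int = 8,
    tm_range: tuple[float, float] = (48.0, 62.0),
    n_ht_peptides: int = 0,
    precipitator_fraction: float = 0.8,
) -> list[SimProteinSpec]:
    """Draw a reproducible population of protein specs.

    Archetype weights default to the mix observed in bacterial lysate
    profiles (decreasing-dominated); melting midpoints are uniform on
    ``tm_range`` so transitions fall well inside the gradient.
    """
    rng = np.random.default_rng(seed)
    archetypes = rng.choice(ARCHETYPES, size=n_proteins, p=np.asarray(archetype_weights) / sum(archetype_weights))
    tms = rng.uniform(*tm_range, size=n_proteins)
    precip = rng.random(n_proteins) < precipitator_fraction
    return [
        SimProteinSpec(
            protein_id=f"P{i:04d}",
            archetype=str(archetypes[i]),
            Tm_control=float(tms[i]),
            delta_Tm=delta_Tm,
            n_peptides=n_peptides,
            precipitator=bool(precip[i]),
            n_ht_peptides=n_ht_peptides,
        )
        for i in range(n_proteins)
    ]
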