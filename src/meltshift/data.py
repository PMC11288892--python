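"""Core data containers for thermal-gradient peptide quantification.

The central object is :class:`PeptideDataset`: replicate peptide intensities
measured over a temperature gradient in two or more conditions (control vs
osmolyte), with 1-based residue coordinates on the parent protein and the
tryptic type of each peptide.  Half-tryptic (HT) peptides carry a protease-K
cleavage site inside the sequence of some fully tryptic (FT) peptide and are
expected to mirror its thermal behaviour, which :func:`match_ht_to_ft` and
:func:`ht_ft_correlation` exploit.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the ten-point limited-proteolysis gradient, in deg C
DEFAULT_GRADIENT = (37.0, 40.5, 44.4, 49.3, 54.1, 58.9, 63.8, 68.6, 72.5, 76.0)

#: TSV columns of the long-format peptide table
PEPTIDE_COLUMNS = [
    "protein_id", "peptide", "start", "end", "tryptic_type",
    "condition", "replicate", "temperature_C", "intensity",
]


class SchemaError(ValueError):
    """Input table does not have the required columns / parseable values."""


class IntegrityError(ValueError):
    """Input table violates a uniqueness or consistency constraint."""


class TrypticType(str, enum.Enum):
    FT = "FT"
    HT = "HT"


@dataclass(frozen=True)
class TemperatureGrid:
    """Strictly increasing list of gradient temperatures in deg C."""

    temperatures: tuple[float, ...] = DEFAULT_GRADIENT

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        if t.size < 4:
            raise ValueError("a temperature grid needs at least 4 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", tuple(float(x) for x in t))

    def __len__(self) -> int:
        return len(self.temperatures)

    def __iter__(self):
        return iter(self.temperatures)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.temperatures, dtype=float)

    @property
    def min(self) -> float:
        return self.temperatures[0]

    @property
    def max(self) -> float:
        return self.temperatures[-1]


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide with 1-based inclusive residue coordinates on its protein."""

    protein_id: str
    peptide_id: str
    start: int
    end: int
    tryptic_type: TrypticType = TrypticType.FT
    proteotypic: bool = True

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid coordinates {self.start}-{self.end} for {self.peptide_id}"
            )
        object.__setattr__(self, "tryptic_type", TrypticType(self.tryptic_type))

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PeptideDataset:
    """Long-format replicate intensities keyed by (peptide, condition, replicate, T).

    ``table`` is the canonical store: a DataFrame with the columns of
    :data:`PEPTIDE_COLUMNS`.  Intensities are raw, nonnegative; zero is treated
    as missing downstream (DIA zero means not-quantified).
    """

    records: dict[str, PeptideRecord]
    table: pd.DataFrame
    grid: TemperatureGrid = field(default_factory=TemperatureGrid)

    def __post_init__(self):
        key = ["peptide", "condition", "replicate", "temperature_C"]
        if self.table.duplicated(subset=key).any():
            dup = self.table[self.table.duplicated(subset=key)].iloc[0]
            raise IntegrityError(
                f"duplicate observation for peptide {dup['peptide']!r} "
                f"({dup['condition']}, rep {dup['replicate']}, {dup['temperature_C']} C)"
            )

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.records)

    def intensity_matrix(
        self, peptide: str, condition: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (temperatures, intensities) observation pairs for one
        peptide in one condition, replicates stacked as independent points.
        Zero / non-finite intensities are dropped (treated as missing)."""
        sub = self.table[
            (self.table["peptide"] == peptide) & (self.table["condition"] == condition)
        ]
        t = sub["temperature_C"].to_numpy(float)
        y = sub["intensity"].to_numpy(float)
        ok = np.isfinite(y) & (y > 0)
        return t[ok], y[ok]

    def n_quantified_temperatures(self, peptide: str, condition: str) -> int:
        """Number of distinct gradient temperatures at which the peptide has at
        least one finite positive intensity in the condition."""
        t, _ = self.intensity_matrix(peptide, condition)
        return np.unique(t).size

    def eligible_peptides(self, min_temperatures: int = 8) -> list[str]:
        """Peptides quantified at >= ``min_temperatures`` gradient temperatures
        in every condition — the entry requirement for profile fitting."""
        out = []
        for pep in self.records:
            if all(
                self.n_quantified_temperatures(pep, c) >= min_temperatures
                for c in self.conditions
            ):
                out.append(pep)
        return out


@dataclass
class ProteinSolubilityDataset:
    """Soluble-fraction protein abundance over the gradient, scaled so the
    value at 37 C is exactly 1 for every (protein, condition, replicate)."""

    table: pd.DataFrame  # protein_id, condition, replicate, temperature_C, rel_abundance
    grid: TemperatureGrid = field(default_factory=TemperatureGrid)

    def __post_init__(self):
        t0 = self.grid.min
        base = self.table[np.isclose(self.table["temperature_C"], t0)]
        if not np.allclose(base["rel_abundance"], 1.0):
            raise IntegrityError(f"relative abundance at {t0} C must equal 1")
        if (self.table["rel_abundance"] < 0).any():
            raise IntegrityError("relative abundances must be nonnegative")

    @property
    def protein_ids(self) -> list[str]:
        return sorted(self.table["protein_id"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def profile(self, protein: str, condition: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.table[
            (self.table["protein_id"] == protein)
            & (self.table["condition"] == condition)
        ]
        t = sub["temperature_C"].to_numpy(float)
        y = sub["rel_abundance"].to_numpy(float)
        ok = np.isfinite(y)
        return t[ok], y[ok]


@dataclass(frozen=True)
class DomainAnnotation:
    """1-based inclusive residue range of a protein domain."""

    protein_id: str
    domain_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid domain range {self.start}-{self.end}")

    def overlaps(self, other: "DomainAnnotation") -> bool:
        return (
            self.protein_id == other.protein_id
            and self.start <= other.end
            and other.start <= self.end
        )


def read_domain_table(path) -> list[DomainAnnotation]:
    """Read TSV of protein_id, domain_id, start, end; reject overlapping
    domains within a protein."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "domain_id", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"domain table missing columns: {sorted(missing)}")
    domains = [
        DomainAnnotation(r.protein_id, r.domain_id, int(r.start), int(r.end))
        for r in df.itertuples()
    ]
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        for other in by_protein.setdefault(d.protein_id, []):
            if d.overlaps(other):
                raise IntegrityError(
                    f"domains {other.domain_id} and {d.domain_id} overlap "
                    f"on {d.protein_id}"
                )
        by_protein[d.protein_id].append(d)
    return domains


def read_peptide_table(path, schema_config: dict | None = None) -> PeptideDataset:
    """Read a long-format peptide quantification table (TSV or CSV).

    ``schema_config`` maps the canonical column names of
    :data:`PEPTIDE_COLUMNS` to the names used in the file, adapting arbitrary
    search-software exports.  Non-numeric intensities become missing (NaN);
    duplicate (peptide, condition, replicate, temperature) rows are an error.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if schema_config:
        df = df.rename(columns={v: k for k, v in schema_config.items()})
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"peptide table missing columns: {sorted(missing)}")
    df = df[PEPTIDE_COLUMNS].copy()
    df["temperature_C"] = pd.to_numeric(df["temperature_C"], errors="raise")
    df["intensity"] = pd.to_numeric(df["intensity"], errors="coerce")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return dataset_from_table(df)


def dataset_from_table(
    df: pd.DataFrame, grid: TemperatureGrid | None = None
) -> PeptideDataset:
    """Build a validated PeptideDataset from a canonical long table."""
    records: dict[str, PeptideRecord] = {}
    meta = df.drop_duplicates(subset="peptide")
    for r in meta.itertuples():
        proteo = bool(getattr(r, "proteotypic", True))
        records[r.peptide] = PeptideRecord(
            protein_id=r.protein_id,
            peptide_id=r.peptide,
            start=int(r.start),
            end=int(r.end),
            tryptic_type=TrypticType(r.tryptic_type),
            proteotypic=proteo,
        )
    if grid is None:
        temps = np.sort(df["temperature_C"].unique())
        grid = TemperatureGrid(tuple(temps)) if temps.size >= 4 else TemperatureGrid()
    return PeptideDataset(records=records, table=df.reset_index(drop=True), grid=grid)


def write_peptide_table(dataset: PeptideDataset, path) -> None:
    """Write the canonical TSV so that read_peptide_table round-trips."""
    dataset.table[PEPTIDE_COLUMNS].to_csv(path, sep="\t", index=False)


def match_ht_to_ft(dataset: PeptideDataset) -> list[tuple[str, str]]:
    """Pair each half-tryptic peptide with every fully tryptic peptide of the
    same protein whose borders contain it (f.start <= h.start and
    h.end <= f.end; coinciding borders allowed)."""
    recs = list(dataset.records.values())
    fts = [r for r in recs if r.tryptic_type is TrypticType.FT]
    hts = [r for r in recs if r.tryptic_type is TrypticType.HT]
    ft_by_protein: dict[str, list[PeptideRecord]] = {}
    for f in fts:
        ft_by_protein.setdefault(f.protein_id, []).append(f)
    pairs = []
    for h in hts:
        for f in ft_by_protein.get(h.protein_id, ()):
            if f.start <= h.start and h.end <= f.end:
                pairs.append((h.peptide_id, f.peptide_id))
    return pairs


def ht_ft_correlation(
    pairs: list[tuple[str, str]], dataset: PeptideDataset, min_shared: int = 3
) -> pd.DataFrame:
    """Pearson correlation of raw intensities over shared observations for
    each matched (HT, FT) pair.  Pairs with fewer than ``min_shared`` shared
    (condition, replicate, temperature) observations are skipped with a
    warning."""
    key = ["condition", "replicate", "temperature_C"]
    rows = []
    for ht, ft in pairs:
        a = dataset.table[dataset.table["peptide"] == ht].set_index(key)["intensity"]
        b = dataset.table[dataset.table["peptide"] == ft].set_index(key)["intensity"]
        joined = pd.concat([a, b], axis=1, join="inner", keys=["ht", "ft"]).dropna()
        joined = joined[(joined > 0).all(axis=1)]
        if len(joined) < min_shared:
            warnings.warn(
                f"pair ({ht}, {ft}): only {len(joined)} shared observations, skipped"
            )
            continue
        r = float(np.corrcoef(joined["ht"], joined["ft"])[0, 1])
        rows.append({"ht_peptide": ht, "ft_peptide": ft, "pearson_r": r,
                     "n_shared": len(joined)})
    return pd.DataFrame(rows, columns=["ht_peptide", "ft_peptide", "pearson_r", "n_shared"])
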