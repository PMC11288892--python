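"""Statistical machinery: empirical FDR calibration on replicate-split nulls,
differential-abundance testing (protease-activity, binding and aggregation
modes), moderated t-tests, TPP solubility analysis, LiP-TPP agreement,
Spearman randomization, and sequence-derived protein features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .data import PeptideDataset, ProteinSolubilityDataset
from .scoring import PeptideScore, weighted_quantile  # noqa: F401 (re-export)


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values
    (adj_i = min_{j >= rank(i)} p_(j) * m / j, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# moderated t-test (empirical-Bayes variance shrinkage)


@dataclass(frozen=True)
class VariancePrior:
    """Prior d0 (degrees of freedom) and s0^2 (variance) shared across
    units, estimated by method of moments on the log sample variances."""

    d0: float
    s0_sq: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x -= dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(variances, df: int) -> VariancePrior:
    """Method-of-moments fit of the scaled inverse-chi-square prior from the
    per-unit sample variances (each on ``df`` degrees of freedom), via the
    digamma/trigamma moments of log s^2."""
    s2 = np.asarray(variances, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return VariancePrior(d0=0.0, s0_sq=float(np.median(s2)) if s2.size else 1.0)
    z = np.log(s2)
    e_z = z.mean()
    v_z = z.var(ddof=1)
    resid = v_z - special.polygamma(1, df / 2.0)
    if resid <= 0:
        d0 = np.inf
        s0 = np.exp(e_z - special.polygamma(0, df / 2.0) + np.log(df / 2.0))
    else:
        half_d0 = _trigamma_inverse(resid)
        d0 = 2.0 * half_d0
        s0 = np.exp(
            e_z
            - special.polygamma(0, df / 2.0)
            + np.log(df / 2.0)
            + special.polygamma(0, half_d0)
            - np.log(half_d0)
        )
    return VariancePrior(d0=float(d0), s0_sq=float(s0))


def moderated_t(group_a, group_b, prior: VariancePrior | None = None):
    """Two-sample t-test with empirical-Bayes moderated pooled variance.

    With prior (d0, s0^2) the pooled variance s^2 on d degrees of freedom is
    shrunk to s~^2 = (d0 s0^2 + d s^2) / (d0 + d) and the statistic is
    referred to a t distribution on d0 + d degrees of freedom.  d0 = 0
    reproduces the ordinary pooled t-test; d0 = inf fixes every unit's
    variance at s0^2.  Without a prior, Welch's t-test is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two observations")
    if prior is None:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    d = na + nb - 2
    s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / d
    if np.isinf(prior.d0):
        s2_mod, df_mod = prior.s0_sq, np.inf
    elif prior.d0 <= 0:
        s2_mod, df_mod = s2, d
    else:
        s2_mod = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_mod = prior.d0 + d
    delta = a.mean() - b.mean()
    if s2_mod == 0:
        if delta == 0:
            return 0.0, 1.0
        return float(np.sign(delta) * np.inf), 0.0
    t = delta / np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    if np.isinf(df_mod):
        p = 2.0 * sps.norm.sf(abs(t))
    else:
        p = 2.0 * sps.t.sf(abs(t), df_mod)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# differential abundance


#: preset (temperatures, alpha, |log2FC| cutoff, level) per analysis mode;
#: temperature None means "resolved against the dataset grid"
DIFFERENTIAL_MODES = {
    "binding": {"temperatures": (37.0, 40.5), "alpha": 0.01, "lfc": 1.5},
    "aggregation": {"temperatures": (72.5, 76.0), "alpha": 0.05, "lfc": 1.0},
    "tpp-aggregation": {"temperatures": (68.6, 72.5, 76.0), "alpha": 0.05, "lfc": 1.0},
    "pk-activity": {"temperatures": None, "alpha": 0.05, "lfc": 1.0},
}


def differential_abundance(
    dataset: PeptideDataset,
    temperatures=None,
    mode: str | None = None,
    test: str = "t",
    lfc_cutoff: float | None = None,
    alpha: float | None = None,
    conditions: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-peptide differential abundance between two conditions on a
    temperature subset.

    Observations at the included temperatures are pooled (log2 intensities)
    into one two-sample test per peptide; p-values are BH-adjusted across all
    tested peptides.  A hit requires adj p < alpha AND |log2FC| > cutoff
    (strict), with log2FC computed on mean raw intensities.  ``mode`` applies
    the binding / aggregation / pk-activity presets; ``test`` is "t"
    (Welch) or "moderated".  The protein-level call flags a protein as soon
    as one of its proteotypic peptides is a hit.
    """
    cfg = DIFFERENTIAL_MODES.get(mode, {}) if mode else {}
    temperatures = temperatures if temperatures is not None else cfg.get("temperatures")
    alpha = alpha if alpha is not None else cfg.get("alpha", 0.05)
    lfc_cutoff = lfc_cutoff if lfc_cutoff is not None else cfg.get("lfc", 1.0)
    conds = list(conditions) if conditions else dataset.conditions
    if len(conds) != 2:
        raise ValueError("differential abundance needs exactly two conditions")

    tab = dataset.table
    tab = tab[np.isfinite(tab["intensity"]) & (tab["intensity"] > 0)]
    if temperatures is not None:
        mask = np.zeros(len(tab), dtype=bool)
        for t in temperatures:
            mask |= np.isclose(tab["temperature_C"], t)
        tab = tab[mask]

    groups = {
        (pep, cond): g["intensity"].to_numpy(float)
        for (pep, cond), g in tab.groupby(["peptide", "condition"])
    }
    units = []
    for pep in dataset.records:
        a = groups.get((pep, conds[0]), np.array([]))
        b = groups.get((pep, conds[1]), np.array([]))
        if a.size < 2 or b.size < 2:
            continue
        units.append((pep, a, b))

    prior = None
    if test == "moderated" and len(units) >= 10:
        variances, dfs = [], []
        for _, a, b in units:
            la, lb = np.log2(a), np.log2(b)
            d = la.size + lb.size - 2
            s2 = ((la.size - 1) * la.var(ddof=1) + (lb.size - 1) * lb.var(ddof=1)) / d
            variances.append(s2)
            dfs.append(d)
        prior = estimate_variance_prior(variances, int(np.median(dfs)))

    rows = []
    for pep, a, b in units:
        la, lb = np.log2(a), np.log2(b)
        if test == "moderated" and prior is not None:
            t, p = moderated_t(lb, la, prior)
        else:
            t, p = sps.ttest_ind(lb, la, equal_var=False)
        if not np.isfinite(p):  # zero variance in both groups, equal means
            t, p = 0.0, 1.0
        lfc = float(np.log2(b.mean() / a.mean()))
        rec = dataset.records[pep]
        rows.append({
            "peptide": pep, "protein_id": rec.protein_id,
            "proteotypic": rec.proteotypic, "log2_fc": lfc,
            "statistic": float(t), "pvalue": float(p),
        })
    df = pd.DataFrame(rows, columns=["peptide", "protein_id", "proteotypic",
                                     "log2_fc", "statistic", "pvalue"])
    if len(df):
        df["adj_pvalue"] = bh_adjust(df["pvalue"].to_numpy())
        df["hit"] = (df["adj_pvalue"] < alpha) & (df["log2_fc"].abs() > lfc_cutoff)
        df["protein_hit"] = df["protein_id"].isin(
            df.loc[df["hit"] & df["proteotypic"], "protein_id"].unique()
        )
    else:
        for col in ("adj_pvalue", "hit", "protein_hit"):
            df[col] = pd.Series(dtype=float if col == "adj_pvalue" else bool)
    return df


# ---------------------------------------------------------------------------
# FDR calibration on the replicate-split null


@dataclass
class FDREstimate:
    level: str                 # "peptide" | "protein"
    quantile_pair: tuple[float, float]
    fdr: float
    n_tested: int
    n_nonzero: int


def estimate_null_fdr(
    null_dataset: PeptideDataset,
    quantile_pair: tuple[float, float] = (0.75, 0.25),
    level: str = "peptide",
    seed: int = 0,
    config=None,
):
    """Empirical FDR of the fit-cluster-score pipeline on a replicate-split
    null dataset: the fraction of units (peptides or proteins) assigned a
    nonzero stabilization-class score when there is no true condition
    difference.  Returns (FDREstimate, ThermalShiftResults)."""
    from .model import ThermalShiftModel

    conds = null_dataset.conditions
    if len(conds) != 2:
        raise ValueError("the null dataset must carry exactly two pseudo-conditions")
    model = ThermalShiftModel(null_dataset, control=conds[0], treatment=conds[1],
                              config=config)
    results = model.fit(seed=seed, q_stab=quantile_pair[0], q_destab=quantile_pair[1])
    if results.failure_fraction > 0.2:
        raise RuntimeError(
            f"profile fitting failed for {results.failure_fraction:.0%} of peptides"
        )
    if level == "peptide":
        scores = results.peptide_scores["score"].to_numpy()
    elif level == "protein":
        scores = results.protein_scores["score"].to_numpy()
    else:
        raise ValueError("level must be 'peptide' or 'protein'")
    n = scores.size
    nz = int(np.sum(scores != 0.0))
    est = FDREstimate(level=level, quantile_pair=quantile_pair,
                      fdr=nz / n if n else 0.0, n_tested=n, n_nonzero=nz)
    return est, results


def sweep_quantile(
    null_dataset: PeptideDataset,
    target: float = 0.05,
    seed: int = 0,
    step: float = 0.05,
    config=None,
) -> tuple[float, pd.DataFrame]:
    """Sweep symmetric summarization quantile pairs (q, 1-q), q from 0.5 to
    1.0, on a null dataset and return the smallest q whose protein-level
    empirical FDR meets the target (plus the full sweep table).  If no pair
    reaches the target, 1.0 is returned with a warning.

    The expensive GP fits are shared: the pipeline runs once and only the
    rollup is repeated per quantile pair.
    """
    import warnings

    from .model import ThermalShiftModel

    conds = null_dataset.conditions
    model = ThermalShiftModel(null_dataset, control=conds[0], treatment=conds[1],
                              config=config)
    results = model.fit(seed=seed)
    qs = np.round(np.arange(0.5, 1.0 + step / 2, step), 10)
    rows = []
    chosen = None
    for q in qs:
        prot = results.rollup(q_stab=float(q), q_destab=float(1.0 - q))
        scores = prot["score"].to_numpy()
        fdr = float(np.mean(scores != 0.0)) if scores.size else 0.0
        rows.append({"q": float(q), "fdr": fdr, "n": scores.size})
        if chosen is None and fdr <= target:
            chosen = float(q)
    if chosen is None:
        warnings.warn(f"no quantile pair achieves the target FDR {target}; returning 1.0")
        chosen = 1.0
    return chosen, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TPP


def tpp_analysis(
    tpp: ProteinSolubilityDataset,
    seed: int = 0,
    config=None,
) -> pd.DataFrame:
    """Protein-level stabilization calls from soluble-fraction profiles.

    Scaled abundances are min-max rescaled, GP-fitted and scored with the
    same confidence-band machinery as peptide-level data, with no rollup
    (one unit per protein).  Adds the precipitator call per protein.
    """
    from .model import ThermalShiftModel

    tab = tpp.table.rename(columns={"rel_abundance": "intensity",
                                    "protein_id": "protein"})
    tab = tab.assign(
        protein_id=tab["protein"], peptide=tab["protein"], start=1, end=1,
        tryptic_type="FT",
    )[["protein_id", "peptide", "start", "end", "tryptic_type",
       "condition", "replicate", "temperature_C", "intensity"]]
    from .data import dataset_from_table

    ds = dataset_from_table(tab, grid=tpp.grid)
    conds = ds.conditions
    model = ThermalShiftModel(ds, control="control",
                              treatment=[c for c in conds if c != "control"][0],
                              config=config)
    results = model.fit(seed=seed)
    out = results.peptide_scores.drop(columns=["protein_id"]).rename(
        columns={"peptide": "protein_id"}
    )
    precip = {
        p: classify_precipitator(tpp, p)
        for p in tpp.protein_ids
    }
    out["nonprecipitator"] = out["protein_id"].map(lambda p: not precip.get(p, True))
    out["stabilized"] = out["score"] > 0
    return out


def classify_precipitator(
    tpp: ProteinSolubilityDataset, protein: str, condition: str = "control"
) -> bool:
    """Precipitator call: True unless more than 50% of the protein (relative
    to 37 C) remains soluble at the highest gradient temperature."""
    t, y = tpp.profile(protein, condition)
    top = tpp.grid.max
    at_top = y[np.isclose(t, top)]
    if at_top.size == 0:
        raise ValueError(f"protein {protein} has no observation at {top} C")
    return not (float(at_top.mean()) > 0.5)


def lip_tpp_agreement(
    lip_calls: dict[str, bool],
    tpp_calls: dict[str, bool],
    precipitators: set[str] | None = None,
) -> dict[str, float]:
    """Agreement fractions between LiP and TPP stabilization calls.

    Restricted to proteins present in both datasets (and, when given, to TPP
    precipitators — nonprecipitators have no meaningful TPP melting shift).
    Returns fractions {both, none, only_lip, only_tpp} summing to 1.
    """
    shared = set(lip_calls) & set(tpp_calls)
    if precipitators is not None:
        shared &= precipitators
    if not shared:
        raise ValueError("no proteins shared between the LiP and TPP call sets")
    n = len(shared)
    both = sum(1 for p in shared if lip_calls[p] and tpp_calls[p])
    none = sum(1 for p in shared if not lip_calls[p] and not tpp_calls[p])
    only_lip = sum(1 for p in shared if lip_calls[p] and not tpp_calls[p])
    return {
        "both": both / n,
        "none": none / n,
        "only_lip": only_lip / n,
        "only_tpp": (n - both - none - only_lip) / n,
        "n": n,
    }


# ---------------------------------------------------------------------------
# Spearman randomization


def spearman_randomization(
    score_matrix: pd.DataFrame, n_rep: int = 1000, seed: int = 0
) -> tuple[pd.Series, np.ndarray]:
    """Per-protein Spearman correlation with the proteome-mean trend.

    ``score_matrix`` is proteins x osmolyte conditions (>= 3 conditions).
    The observed statistic correlates each protein's score vector with the
    across-protein mean vector.  The null distribution correlates each
    protein's vector with the mean vector randomly shuffled across conditions
    (independently per protein and repetition), ``n_rep`` times.  Proteins
    with constant vectors are excluded (correlation undefined).
    """
    X = score_matrix.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("Spearman analysis needs at least 3 conditions")
    variable = np.array([np.unique(row).size > 1 for row in X])
    mean_vec = X.mean(axis=0)

    observed = pd.Series(
        [
            sps.spearmanr(X[i], mean_vec).statistic if variable[i] else np.nan
            for i in range(X.shape[0])
        ],
        index=score_matrix.index,
        name="spearman_r",
    )
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(variable)
    null = np.empty((n_rep, idx.size))
    for r in range(n_rep):
        for j, i in enumerate(idx):
            null[r, j] = sps.spearmanr(
                X[i], mean_vec[rng.permutation(X.shape[1])]
            ).statistic
    return observed, null.ravel()


# ---------------------------------------------------------------------------
# sequence-derived protein features

# EMBOSS pKa values for ionisable groups
_PKA = {"Nterm": 8.6, "Cterm": 3.6, "C": 8.5, "D": 3.9, "E": 4.1,
        "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1}
_POSITIVE = ("Nterm", "K", "R", "H")
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_AA_GROUPS = {
    "tiny": "ACGST", "small": "ACDGNPSTV", "aliphatic": "AILV",
    "aromatic": "FHWY", "nonpolar": "ACFGILMPVWY", "polar": "DEHKNQRSTZ",
    "charged": "DEHKR", "basic": "HKR", "acidic": "DE",
}


def net_charge(sequence: str, ph: float = 7.5) -> float:
    """Henderson-Hasselbalch net charge at the given pH (EMBOSS pKa set)."""
    seq = [a for a in sequence.upper() if a in _STANDARD_AA]
    counts = {a: seq.count(a) for a in _PKA if len(a) == 1}
    charge = 1.0 / (1.0 + 10 ** (ph - _PKA["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (_PKA["Cterm"] - ph))
    for aa, n in counts.items():
        if n == 0:
            continue
        if aa in _POSITIVE:
            charge += n / (1.0 + 10 ** (ph - _PKA[aa]))
        else:
            charge -= n / (1.0 + 10 ** (_PKA[aa] - ph))
    return float(charge)


def isoelectric_point(sequence: str) -> float:
    """pI by bisection on the net-charge curve."""
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydrophobic_moment(sequence: str, angle_deg: float = 100.0, window: int = 11) -> float:
    """Maximal Eisenberg hydrophobic moment over sliding windows (alpha-helix
    periodicity by default)."""
    from Bio.SeqUtils.ProtParamData import kd

    seq = [a for a in sequence.upper() if a in _STANDARD_AA]
    if len(seq) < window:
        window = len(seq)
    if window == 0:
        return 0.0
    angles = np.deg2rad(angle_deg) * np.arange(window)
    best = 0.0
    for i in range(len(seq) - window + 1):
        h = np.array([kd[a] for a in seq[i:i + window]])
        mu = np.hypot((h * np.sin(angles)).sum(), (h * np.cos(angles)).sum()) / window
        best = max(best, float(mu))
    return best


def sequence_features(sequence: str) -> pd.Series:
    """Physicochemical feature vector of a protein sequence: length,
    amino-acid and group percentages, Kyte-Doolittle GRAVY, aliphatic index,
    hydrophobic moment, net charge at pH 7.5 and pI."""
    import warnings

    from Bio.SeqUtils.ProtParam import ProteinAnalysis

    raw = sequence.upper()
    seq = "".join(a for a in raw if a in _STANDARD_AA)
    if len(seq) < len(raw):
        warnings.warn(
            f"{len(raw) - len(seq)} non-standard residues excluded from feature "
            "calculation"
        )
    if not seq:
        raise ValueError("no standard residues in sequence")
    pa = ProteinAnalysis(seq)
    pct = {a: 100.0 * seq.count(a) / len(seq) for a in sorted(_STANDARD_AA)}
    feats = {"length": float(len(seq))}
    feats.update({f"pct_{a}": v for a, v in pct.items()})
    for name, members in _AA_GROUPS.items():
        feats[f"pct_{name}"] = sum(pct.get(a, 0.0) for a in members)
    feats["gravy"] = pa.gravy()
    feats["aliphatic_index"] = (
        pct["A"] + 2.9 * pct["V"] + 3.9 * (pct["I"] + pct["L"])
    )
    feats["hydrophobic_moment"] = hydrophobic_moment(seq)
    feats["charge_ph7.5"] = net_charge(seq, 7.5)
    feats["pI"] = isoelectric_point(seq)
    return pd.Series(feats)


def compare_feature_groups(
    features: pd.DataFrame, labels, control_label=None, min_group: int = 3
) -> pd.DataFrame:
    """Per-feature two-sided t-test between two protein groups with BH
    correction across features; the difference of means subtracts the
    control group (sign convention: test - control)."""
    labels = pd.Series(labels, index=features.index)
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError("exactly two group labels are required")
    if control_label is None:
        control_label = sorted(groups)[0]
    test_label = [g for g in groups if g != control_label][0]
    rows = []
    for col in features.columns:
        a = features.loc[labels == test_label, col].dropna()
        b = features.loc[labels == control_label, col].dropna()
        if len(a) < min_group or len(b) < min_group:
            continue
        t, p = sps.ttest_ind(a, b, equal_var=False)
        if not np.isfinite(p):
            t, p = 0.0, 1.0
        rows.append({"feature": col, "delta_mean": float(a.mean() - b.mean()),
                     "statistic": float(t), "pvalue": float(p)})
    df = pd.DataFrame(rows, columns=["feature", "delta_mean", "statistic", "pvalue"])
    if len(df):
        df["adj_pvalue"] = bh_adjust(df["pvalue"].to_numpy())
        df["significant"] = df["adj_pvalue"] < 0.05
    return df
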