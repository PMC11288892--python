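"""Confidence-band non-overlap area scores and peptide→residue→protein rollup.

The stabilization score of a peptide is the signed area between its control
and osmolyte posterior mean profiles, summed only over temperature regions
where the two ±2 s.d. confidence bands do not overlap (the distance is set to
0 wherever the bands overlap).  Regions are classed by where they sit on the
gradient — binding at the start, stabilization in the middle, aggregation at
the end — and only stabilization-class regions contribute to the score.  The
sign is corrected by the peptide's profile shape group so that a rightward
melting shift is always positive: for decreasing (unfolding) profiles the
osmolyte-minus-control area is kept as is; for increasing (aggregation)
profiles it is flipped.

Peptide scores are rolled up to residue level (weighted 0.75/0.25 quantile of
covering peptides, weights = inverse summed fit RSS) and then to protein
level, correcting for overlapping peptides of different lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gp import ProfileCurve

#: gradient temperatures bounding the interval classes: a non-overlap region
#: whose midpoint is below the 3rd gradient temperature is "binding", above
#: the 8th is "aggregation", otherwise "stabilization"
BINDING_BOUNDARY = 44.4
AGGREGATION_BOUNDARY = 68.6

#: regulariser in the fit weight, w = eps + RSS_ctl + RSS_osm
FIT_WEIGHT_EPS = 1e-3


def fit_weight(rss_ctl: float, rss_osm: float, eps: float = FIT_WEIGHT_EPS,
               mode: str = "rss") -> float:
    """Quantile weight of a peptide in the rollup, from the goodness of fit
    (residual sum of squares) summed over both conditions.

    ``rss`` (default) weights by eps + RSS_ctl + RSS_osm.  A near-zero RSS
    on replicated noisy data signals a fit that interpolated the replicate
    noise (the fitted noise variance collapsed), which is precisely the
    failure mode that produces spurious band separations — such peptides
    carry little weight.  ``inverse_rss`` (1 / (eps + RSS)) is the opposite
    convention, kept as an option.
    """
    s = eps + rss_ctl + rss_osm
    if mode == "rss":
        return float(s)
    if mode == "inverse_rss":
        return float(1.0 / s)
    raise ValueError(f"unknown fit-weight mode {mode!r}")


@dataclass
class NonOverlapInterval:
    """Maximal run of grid points with disjoint confidence bands."""

    t_start: float
    t_end: float
    area: float                # sum over points of (m_osm - m_ctl) * dT
    interval_class: str        # binding | stabilization | aggregation
    index: slice = field(default=None, repr=False)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass
class PeptideScore:
    peptide_id: str
    score: float               # signed, deg C x scaled intensity
    interval: NonOverlapInterval | None
    fit_weight: float
    shape_group: str


def classify_interval(
    t_start: float,
    t_end: float,
    binding_boundary: float = BINDING_BOUNDARY,
    aggregation_boundary: float = AGGREGATION_BOUNDARY,
) -> str:
    mid = 0.5 * (t_start + t_end)
    if mid < binding_boundary:
        return "binding"
    if mid > aggregation_boundary:
        return "aggregation"
    return "stabilization"


def nonoverlap_intervals(
    curve_ctl: ProfileCurve,
    curve_osm: ProfileCurve,
    binding_boundary: float = BINDING_BOUNDARY,
    aggregation_boundary: float = AGGREGATION_BOUNDARY,
) -> list[NonOverlapInterval]:
    """Maximal runs of consecutive grid points where the two ±2 s.d. bands
    are disjoint.  The area of a run is the spacing-weighted Riemann sum of
    (m_osm - m_ctl) over its points."""
    if curve_ctl.grid.shape != curve_osm.grid.shape or not np.allclose(
        curve_ctl.grid, curve_osm.grid
    ):
        raise ValueError("control and osmolyte curves must share the same grid")
    grid = curve_ctl.grid
    dt = float(np.median(np.diff(grid))) if grid.size > 1 else 1.0
    disjoint = (curve_ctl.lower > curve_osm.upper) | (curve_osm.lower > curve_ctl.upper)
    intervals: list[NonOverlapInterval] = []
    i = 0
    n = grid.size
    while i < n:
        if not disjoint[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and disjoint[j + 1]:
            j += 1
        sl = slice(i, j + 1)
        area = float(np.sum(curve_osm.mean[sl] - curve_ctl.mean[sl]) * dt)
        intervals.append(
            NonOverlapInterval(
                t_start=float(grid[i]),
                t_end=float(grid[j]),
                area=area,
                interval_class=classify_interval(
                    grid[i], grid[j], binding_boundary, aggregation_boundary
                ),
                index=sl,
            )
        )
        i = j + 1
    return intervals


def peptide_score(
    peptide_id: str,
    curve_ctl: ProfileCurve,
    curve_osm: ProfileCurve,
    shape_group: str,
    rss_ctl: float,
    rss_osm: float,
    eps: float = FIT_WEIGHT_EPS,
    binding_boundary: float = BINDING_BOUNDARY,
    aggregation_boundary: float = AGGREGATION_BOUNDARY,
    weight_mode: str = "rss",
) -> PeptideScore:
    """Signed stabilization score of one peptide.

    Among stabilization-class non-overlap intervals, the one of maximal
    absolute area is taken; its area is multiplied by +1 for the decreasing
    shape group, -1 for the increasing group, and for nonmonotonous peptides
    by the sign of the local control-curve trend over the interval (falling
    trend behaves like a decreasing profile).  No stabilization-class interval
    means score 0.
    """
    intervals = nonoverlap_intervals(
        curve_ctl, curve_osm, binding_boundary, aggregation_boundary
    )
    stab = [iv for iv in intervals if iv.interval_class == "stabilization"]
    weight = fit_weight(rss_ctl, rss_osm, eps, weight_mode)
    if not stab:
        return PeptideScore(peptide_id, 0.0, None, weight, shape_group)
    best = max(stab, key=lambda iv: abs(iv.area))
    if shape_group == "decreasing":
        sign = 1.0
    elif shape_group == "increasing":
        sign = -1.0
    else:  # nonmonotonous: use the local slope of the control curve
        m = curve_ctl.mean[best.index]
        slope = m[-1] - m[0] if m.size > 1 else 0.0
        sign = 1.0 if slope <= 0 else -1.0
    return PeptideScore(peptide_id, float(best.area * sign), best, weight, shape_group)


def weighted_quantile(values, weights, q: float, method: str = "inverse_cdf") -> float:
    """Weighted quantile, exactly invariant under repetition expansion
    (replacing a weight-k point by k unit copies of the same value).

    ``inverse_cdf`` (default): the smallest value whose cumulative weight
    fraction reaches q — the step-function inverse of the weighted empirical
    CDF.  This is the definition used by the score rollup: a protein whose
    positive-score positions carry less than 1-q of the weight rolls up to
    exactly 0, which is what keeps the protein-level false-positive rate at
    the calibrated level.

    ``interpolated``: tied values are merged (weights summed), cumulative-
    weight midpoints p_i = (cum_i - w_i/2) / W define the CDF support, and
    the quantile is linearly interpolated between adjacent distinct values,
    clamped at the extremes.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted quantile of an empty set")
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    if not 0.0 <= q <= 1.0:
        raise ValueError("quantile must be in [0, 1]")
    uniq, inv = np.unique(v, return_inverse=True)
    wm = np.bincount(inv, weights=w)
    cum = np.cumsum(wm)
    W = cum[-1]
    if method == "inverse_cdf":
        idx = int(np.searchsorted(cum / W, q, side="left"))
        return float(uniq[min(idx, uniq.size - 1)])
    if method == "interpolated":
        p = (cum - wm / 2.0) / W
        return float(np.interp(q, p, uniq))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ResidueScore:
    protein_id: str
    position: int
    score: float
    mean_fit_weight: float


def residue_scores(
    peptide_scores: list[PeptideScore],
    coords: dict[str, tuple[str, int, int]],
    q_stab: float = 0.75,
    q_destab: float = 0.25,
) -> list[ResidueScore]:
    """Amino-acid-level rollup, correcting for overlapping peptides and
    peptides of different lengths.

    ``coords`` maps peptide_id -> (protein_id, start, end), 1-based inclusive.
    Per covered position: the mean of covering peptide scores decides the
    direction; the position score is the weighted ``q_stab`` quantile of the
    covering scores when the mean is positive, the weighted ``q_destab``
    quantile when negative (fit weights as quantile weights).
    """
    by_pos: dict[tuple[str, int], list[PeptideScore]] = {}
    for ps in peptide_scores:
        protein, start, end = coords[ps.peptide_id]
        for pos in range(start, end + 1):
            by_pos.setdefault((protein, pos), []).append(ps)
    out = []
    for (protein, pos), cover in sorted(by_pos.items()):
        scores = np.array([c.score for c in cover])
        weights = np.array([c.fit_weight for c in cover])
        mean = scores.mean()
        if mean > 0:
            s = weighted_quantile(scores, weights, q_stab)
        elif mean < 0:
            s = weighted_quantile(scores, weights, q_destab)
        else:
            s = 0.0
        out.append(ResidueScore(protein, pos, float(s), float(weights.mean())))
    return out


@dataclass
class ProteinScore:
    protein_id: str
    score: float
    direction: str  # stabilized | destabilized | none


def protein_score(
    residues: list[ResidueScore], q_stab: float = 0.75, q_destab: float = 0.25
) -> ProteinScore:
    """Protein-level rollup of residue scores: the mean decides the
    direction, the score is the weighted ``q_stab`` (mean > 0) or
    ``q_destab`` (mean < 0) quantile of residue scores weighted by the mean
    fit weight per position.  The quantile pair is the knob swept during FDR
    calibration."""
    if not residues:
        raise ValueError("protein score needs at least one residue score")
    protein = residues[0].protein_id
    scores = np.array([r.score for r in residues])
    weights = np.array([r.mean_fit_weight for r in residues])
    mean = scores.mean()
    if mean > 0:
        s = weighted_quantile(scores, weights, q_stab)
    elif mean < 0:
        s = weighted_quantile(scores, weights, q_destab)
    else:
        s = 0.0
    direction = "stabilized" if s > 0 else ("destabilized" if s < 0 else "none")
    return ProteinScore(protein, float(s), direction)


def scaled_binder_score(significant_scores: np.ndarray) -> np.ndarray:
    """Scale significant peptide stabilization scores within one osmolyte
    dataset for cross-osmolyte comparison of known binders:

        scaled = (score - median(scores)) / (Q0.7(scores) - Q0.25(scores))

    The asymmetric 0.7/0.25 quantile pair is applied exactly as stated.
    """
    s = np.asarray(significant_scores, dtype=float)
    if s.size < 4:
        raise ValueError("binder scaling needs at least 4 significant scores")
    denom = np.quantile(s, 0.7) - np.quantile(s, 0.25)
    if denom == 0:
        raise ZeroDivisionError("degenerate score distribution: zero IQR-like span")
    return (s - np.median(s)) / denom


def domain_differential(
    peptide_scores: list[PeptideScore],
    coords: dict[str, tuple[str, int, int]],
    domains,
    min_peptides: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test, per protein, whether its domains are differentially stabilized.

    A peptide belongs to a domain when at least one of its residues falls in
    the domain range.  Proteins with >= 2 domains each covered by >=
    ``min_peptides`` peptides are tested: a two-sample t-test for two
    domains, one-way ANOVA for more, Benjamini-Hochberg across proteins.
    """
    from .stats import bh_adjust

    dom_by_protein: dict[str, list] = {}
    for d in domains:
        dom_by_protein.setdefault(d.protein_id, []).append(d)

    rows = []
    for protein, doms in sorted(dom_by_protein.items()):
        groups = []
        for d in doms:
            member = [
                ps.score
                for ps in peptide_scores
                if coords[ps.peptide_id][0] == protein
                and coords[ps.peptide_id][1] <= d.end
                and d.start <= coords[ps.peptide_id][2]
            ]
            if len(member) >= min_peptides:
                groups.append(member)
        if len(groups) < 2:
            continue
        if len(groups) == 2:
            stat, p = sps.ttest_ind(groups[0], groups[1])
        else:
            stat, p = sps.f_oneway(*groups)
        rows.append({"protein_id": protein, "n_domains": len(groups),
                     "statistic": float(stat), "pvalue": float(p)})
    df = pd.DataFrame(rows, columns=["protein_id", "n_domains", "statistic", "pvalue"])
    if len(df):
        df["adj_pvalue"] = bh_adjust(df["pvalue"].to_numpy())
        df["significant"] = df["adj_pvalue"] < alpha
    else:
        df["adj_pvalue"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
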