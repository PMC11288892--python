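"""Model/Results interface to the LiP thermal-profiling pipeline.

:class:`ThermalShiftModel` wraps a :class:`~meltshift.data.PeptideDataset`
with a control and a treatment (osmolyte) condition; ``fit()`` runs the full
pipeline — per-peptide min-max scaling pooled across conditions, exact-GP
profile fits per condition, fuzzy-k-means shape clustering, confidence-band
non-overlap area scoring, and the weighted-quantile rollup to residue and
protein level — and returns a :class:`ThermalShiftResults` carrying the
scores, cluster assignments, fit diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import gp as _gp
from . import scoring as _scoring
from .data import PeptideDataset, dataset_from_table


@dataclass
class PipelineConfig:
    """Tunable parameters of the pipeline with the study defaults."""

    min_temperatures: int = 8          # quantified gradient temps required per condition
    scoring_step: float = 0.5          # deg C, area-scoring grid spacing
    n_clusters: int = 20
    fuzzifier: float = 2.0             # entropy degree p
    n_restarts: int = 5
    binding_boundary: float = _scoring.BINDING_BOUNDARY
    aggregation_boundary: float = _scoring.AGGREGATION_BOUNDARY
    fit_weight_eps: float = _scoring.FIT_WEIGHT_EPS
    q_stab: float = 0.75
    q_destab: float = 0.25
    cluster_representative: str = "centroid"   # or "median"
    band_includes_noise: bool = True
    weight_mode: str = "rss"                   # or "inverse_rss"
    share_hyperparameters: bool = True


@dataclass
class _PeptideFit:
    peptide: str
    fit_ctl: _gp.GPFit
    fit_osm: _gp.GPFit
    curve_ctl: _gp.ProfileCurve
    curve_osm: _gp.ProfileCurve
    cluster_ctl: np.ndarray    # control-condition profile on the clustering grid
    cluster_osm: np.ndarray
    flat: bool


class ThermalShiftModel:
    """Osmolyte-stabilization model for one (control, treatment) pair."""

    def __init__(
        self,
        dataset: PeptideDataset,
        control: str = "control",
        treatment: str = "osmolyte",
        config: PipelineConfig | None = None,
    ):
        if control not in dataset.conditions or treatment not in dataset.conditions:
            raise ValueError(
                f"conditions {control!r}/{treatment!r} not found in dataset "
                f"(available: {dataset.conditions})"
            )
        self.dataset = dataset
        self.control = control
        self.treatment = treatment
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, control: str = "control",
                       treatment: str = "osmolyte",
                       config: PipelineConfig | None = None) -> "ThermalShiftModel":
        return cls(dataset_from_table(df), control, treatment, config)

    # -- fitting ----------------------------------------------------------

    def _fit_peptide(self, pep: str, sgrid, cgrid) -> _PeptideFit | None:
        ds, cfg = self.dataset, self.config
        t_ctl, y_ctl = ds.intensity_matrix(pep, self.control)
        t_osm, y_osm = ds.intensity_matrix(pep, self.treatment)
        pooled = np.concatenate([y_ctl, y_osm])
        scaled, constant = _gp.scale_profile(pooled)
        if constant:
            return None
        s_ctl, s_osm = scaled[: y_ctl.size], scaled[y_ctl.size:]
        try:
            if cfg.share_hyperparameters:
                fit_ctl, fit_osm = _gp.fit_gp_pair(t_ctl, s_ctl, t_osm, s_osm)
            else:
                fit_ctl = _gp.fit_gp(t_ctl, s_ctl)
                fit_osm = _gp.fit_gp(t_osm, s_osm)
        except (ValueError, np.linalg.LinAlgError):
            return None
        if not (fit_ctl.converged and fit_osm.converged):
            return None
        inc = cfg.band_includes_noise
        # per-temperature replicate means of raw control intensities, for the
        # flat-profile (disorder) call
        means = pd.Series(y_ctl).groupby(pd.Series(t_ctl)).mean().to_numpy()
        flat = bool(_gp.flat_profile_flag(means)) if (means > 0).all() else False
        return _PeptideFit(
            peptide=pep,
            fit_ctl=fit_ctl,
            fit_osm=fit_osm,
            curve_ctl=_gp.predict_profile(fit_ctl, sgrid, include_noise=inc),
            curve_osm=_gp.predict_profile(fit_osm, sgrid, include_noise=inc),
            cluster_ctl=fit_ctl.predict(cgrid, include_noise=False)[0],
            cluster_osm=fit_osm.predict(cgrid, include_noise=False)[0],
            flat=flat,
        )

    def fit(self, seed: int = 0, q_stab: float | None = None,
            q_destab: float | None = None) -> "ThermalShiftResults":
        cfg = self.config
        ds = self.dataset
        sgrid = _gp.scoring_grid(ds.grid.min, ds.grid.max, cfg.scoring_step)
        cgrid = _gp.clustering_grid()
        cgrid = cgrid[(cgrid >= ds.grid.min) & (cgrid <= ds.grid.max)]

        eligible = ds.eligible_peptides(cfg.min_temperatures)
        fits: list[_PeptideFit] = []
        n_failed = 0
        for pep in eligible:
            pf = self._fit_peptide(pep, sgrid, cgrid)
            if pf is None:
                n_failed += 1
            else:
                fits.append(pf)
        if not fits:
            raise RuntimeError("no peptide could be fitted")

        # control-condition clustering defines each peptide's shape group
        ctl_profiles = np.vstack([pf.cluster_ctl for pf in fits])
        k = min(cfg.n_clusters, ctl_profiles.shape[0] - 1)
        ctl_model = _cluster.fuzzy_kmeans_entropy(
            ctl_profiles, k=k, p=cfg.fuzzifier, seed=seed,
            n_restarts=cfg.n_restarts,
        )
        ctl_groups = _cluster.group_clusters(ctl_model, cfg.cluster_representative)
        shape_groups, group_probs = [], []
        for row in ctl_model.membership:
            probs, label = _cluster.peptide_group(row, ctl_groups)
            shape_groups.append(label)
            group_probs.append(probs)

        # joint clustering (control + osmolyte profiles) for shape-change calls
        joint_profiles = np.vstack(
            [pf.cluster_ctl for pf in fits] + [pf.cluster_osm for pf in fits]
        )
        kj = min(cfg.n_clusters, joint_profiles.shape[0] - 1)
        joint_model = _cluster.fuzzy_kmeans_entropy(
            joint_profiles, k=kj, p=cfg.fuzzifier, seed=seed,
            n_restarts=cfg.n_restarts,
        )
        joint_groups = _cluster.group_clusters(joint_model, cfg.cluster_representative)
        n = len(fits)
        shape_changed = []
        for i in range(n):
            pc, _ = _cluster.peptide_group(joint_model.membership[i], joint_groups)
            po, _ = _cluster.peptide_group(joint_model.membership[n + i], joint_groups)
            shape_changed.append(_cluster.detect_shape_change(pc, po))

        # confidence-band non-overlap scores
        pep_scores: list[_scoring.PeptideScore] = []
        for pf, group in zip(fits, shape_groups):
            pep_scores.append(
                _scoring.peptide_score(
                    pf.peptide, pf.curve_ctl, pf.curve_osm, group,
                    pf.fit_ctl.rss, pf.fit_osm.rss,
                    eps=cfg.fit_weight_eps,
                    binding_boundary=cfg.binding_boundary,
                    aggregation_boundary=cfg.aggregation_boundary,
                    weight_mode=cfg.weight_mode,
                )
            )

        return ThermalShiftResults(
            model=self,
            fits=fits,
            peptide_score_objs=pep_scores,
            shape_groups=shape_groups,
            group_probs=group_probs,
            shape_changed=shape_changed,
            control_clusters=ctl_model,
            joint_clusters=joint_model,
            n_eligible=len(eligible),
            n_failed=n_failed,
            q_stab=cfg.q_stab if q_stab is None else q_stab,
            q_destab=cfg.q_destab if q_destab is None else q_destab,
        )


@dataclass
class ThermalShiftResults:
    """Fitted pipeline output: scores at peptide, residue and protein level
    plus clustering and fit diagnostics."""

    model: ThermalShiftModel
    fits: list[_PeptideFit]
    peptide_score_objs: list[_scoring.PeptideScore]
    shape_groups: list[str]
    group_probs: list[dict[str, float]]
    shape_changed: list[bool]
    control_clusters: _cluster.ClusterModel
    joint_clusters: _cluster.ClusterModel
    n_eligible: int
    n_failed: int
    q_stab: float = 0.75
    q_destab: float = 0.25
    _tables: dict = field(default_factory=dict, repr=False)

    # -- derived tables ---------------------------------------------------

    @property
    def coords(self) -> dict[str, tuple[str, int, int]]:
        recs = self.model.dataset.records
        return {
            pf.peptide: (recs[pf.peptide].protein_id, recs[pf.peptide].start,
                         recs[pf.peptide].end)
            for pf in self.fits
        }

    @property
    def failure_fraction(self) -> float:
        return self.n_failed / self.n_eligible if self.n_eligible else 0.0

    @property
    def peptide_scores(self) -> pd.DataFrame:
        if "peptide" not in self._tables:
            recs = self.model.dataset.records
            rows = []
            for pf, ps, group, probs, changed in zip(
                self.fits, self.peptide_score_objs, self.shape_groups,
                self.group_probs, self.shape_changed,
            ):
                r = recs[pf.peptide]
                iv = ps.interval
                rows.append({
                    "peptide": pf.peptide, "protein_id": r.protein_id,
                    "start": r.start, "end": r.end,
                    "tryptic_type": r.tryptic_type.value,
                    "score": ps.score, "fit_weight": ps.fit_weight,
                    "shape_group": group,
                    "p_decreasing": probs["decreasing"],
                    "p_increasing": probs["increasing"],
                    "p_nonmonotonous": probs["nonmonotonous"],
                    "shape_changed": changed,
                    "interval_start": iv.t_start if iv else np.nan,
                    "interval_end": iv.t_end if iv else np.nan,
                    "rss_control": pf.fit_ctl.rss, "rss_osmolyte": pf.fit_osm.rss,
                    "mll_control": pf.fit_ctl.log_marginal_likelihood,
                    "mll_osmolyte": pf.fit_osm.log_marginal_likelihood,
                    "flat_profile": pf.flat,
                })
            self._tables["peptide"] = pd.DataFrame(rows)
        return self._tables["peptide"]

    def _rollup(self, q_stab: float, q_destab: float):
        coords = self.coords
        by_protein: dict[str, list[_scoring.PeptideScore]] = {}
        for ps in self.peptide_score_objs:
            by_protein.setdefault(coords[ps.peptide_id][0], []).append(ps)
        res_rows, prot_rows = [], []
        for protein, plist in sorted(by_protein.items()):
            residues = _scoring.residue_scores(plist, coords, q_stab, q_destab)
            for r in residues:
                res_rows.append({
                    "protein_id": r.protein_id, "position": r.position,
                    "score": r.score, "mean_fit_weight": r.mean_fit_weight,
                })
            prot = _scoring.protein_score(residues, q_stab, q_destab)
            prot_rows.append({
                "protein_id": prot.protein_id, "score": prot.score,
                "direction": prot.direction, "n_peptides": len(plist),
            })
        return pd.DataFrame(res_rows), pd.DataFrame(prot_rows)

    @property
    def residue_scores(self) -> pd.DataFrame:
        key = ("rollup", self.q_stab, self.q_destab)
        if key not in self._tables:
            self._tables[key] = self._rollup(self.q_stab, self.q_destab)
        return self._tables[key][0]

    @property
    def protein_scores(self) -> pd.DataFrame:
        key = ("rollup", self.q_stab, self.q_destab)
        if key not in self._tables:
            self._tables[key] = self._rollup(self.q_stab, self.q_destab)
        return self._tables[key][1]

    def rollup(self, q_stab: float, q_destab: float) -> pd.DataFrame:
        """Protein-level scores under an alternative summarization quantile
        pair (used by the FDR sweep); GP fits and clustering are reused."""
        return self._rollup(q_stab, q_destab)[1]

    # -- diagnostics ------------------------------------------------------

    def joint_fit_diagnostic(self, peptide: str) -> dict[str, float]:
        """Delta marginal log likelihood of separate vs pooled-condition GP
        fits for one peptide (positive when the two conditions genuinely
        differ in profile)."""
        pf = next(f for f in self.fits if f.peptide == peptide)
        t = np.concatenate([pf.fit_ctl.train_t, pf.fit_osm.train_t])
        y = np.concatenate([pf.fit_ctl.train_y, pf.fit_osm.train_y])
        joint = _gp.fit_gp(t, y)
        separate = (pf.fit_ctl.log_marginal_likelihood
                    + pf.fit_osm.log_marginal_likelihood)
        return {
            "mll_separate": separate,
            "mll_joint": joint.log_marginal_likelihood,
            "delta_mll": separate - joint.log_marginal_likelihood,
        }

    def summary(self) -> str:
        pep = self.peptide_scores
        prot = self.protein_scores
        n_nz = int((pep["score"] != 0).sum())
        counts = prot["direction"].value_counts()
        lines = [
            "Thermal stabilization analysis",
            "==============================",
            f"conditions          {self.model.control} vs {self.model.treatment}",
            f"peptides fitted     {len(pep)} of {self.n_eligible} eligible "
            f"({self.n_failed} failed)",
            f"shape groups        "
            + ", ".join(f"{g}: {self.shape_groups.count(g)}"
                        for g in _cluster.GROUPS),
            f"nonzero peptide scores  {n_nz} ({n_nz / len(pep):.1%})",
            f"summarization       weighted {self.q_stab:.2f}/{self.q_destab:.2f} "
            "quantiles",
            f"proteins            {len(prot)} "
            f"(stabilized: {counts.get('stabilized', 0)}, "
            f"destabilized: {counts.get('destabilized', 0)}, "
            f"none: {counts.get('none', 0)})",
        ]
        return "\n".join(lines)

    # -- output -----------------------------------------------------------

    def to_tsv(self, directory) -> None:
        """Write peptide / residue / protein score tables as TSV."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.peptide_scores.to_csv(d / "peptide_scores.tsv", sep="\t", index=False)
        self.residue_scores.to_csv(d / "residue_scores.tsv", sep="\t", index=False)
        self.protein_scores.to_csv(d / "protein_scores.tsv", sep="\t", index=False)

    def plot_profile(self, peptide: str, ax=None):
        """Plot the scaled observations, posterior mean profiles and +-2 s.d.
        bands for one peptide in both conditions."""
        import matplotlib.pyplot as plt

        pf = next(f for f in self.fits if f.peptide == peptide)
        if ax is None:
            _, ax = plt.subplots()
        for fit, curve, color, label in (
            (pf.fit_ctl, pf.curve_ctl, "tab:gray", self.model.control),
            (pf.fit_osm, pf.curve_osm, "tab:blue", self.model.treatment),
        ):
            ax.scatter(fit.train_t, fit.train_y, s=12, color=color)
            ax.plot(curve.grid, curve.mean, color=color, label=label)
            ax.fill_between(curve.grid, curve.lower, curve.upper,
                            color=color, alpha=0.2, linewidth=0)
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel("scaled intensity")
        ax.set_title(peptide)
        ax.legend()
        return ax
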