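"""End-to-end orchestration: configuration, seed ladder, and the full
population-aware analysis — thin, buffer, collinearity screen, population
grouping, per-suite model tuning and bootstrap ensembles, scenario
projection, range summaries, change maps, population-map combination, and
niche-overlap series.

Defaults follow the study design this pipeline reproduces: 20-km thinning,
500-km study buffer, VIF threshold 10, 10,000 background points, RM grid
0-4 in 0.5 steps with six feature-class combinations, 10 bootstrap
replicates filtered at test AUC 0.85, strict >60% consensus voting, and a
0.2 response-curve cutoff. Every random stage derives its own seed from the
master seed by hashing (stage name, replicate tag), so reruns are
bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .collinearity import vif_eliminate
from .ensemble import (EnsembleResult, build_ensemble, change_map,
                       combine_union, project_ensemble)
from .grouping import hca, lda_misjudgment, pca
from .maxent import (FC_COMBOS, DEFAULT_RM_GRID, model_select,
                     permutation_importance, predict, response_curve,
                     threshold_range)
from .overlap import overlap
from .raster import (OccurrenceSet, RasterGrid, RasterStack, RangeSummary,
                     buffer_region, extract_values, sample_background,
                     spatial_filter, write_ascii_grid)

logger = logging.getLogger("popsdm")


def derive_seed(master: int, *tags) -> int:
    """Deterministic child seed from the master seed and stage tags."""
    text = repr((int(master),) + tuple(str(t) for t in tags))
    digest = hashlib.blake2b(text.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """All tunables of the analysis, with the study's defaults."""

    cell_km: float = 20.0
    radius_km: float = 500.0
    vif_threshold: float = 10.0
    background_n: int = 10_000
    rm_grid: tuple = DEFAULT_RM_GRID
    fc_combos: tuple = FC_COMBOS
    eval_splits: int = 10
    bootstrap_reps: int = 10
    auc_cutoff: float = 0.85
    vote_frac: float = 0.6
    response_cutoff: float = 0.2
    lda_reps: int = 1000
    k_groups: int = 2
    n_knots: int = 20
    output_transform: str = "cloglog"
    combination_mode: str = "union"
    pca_vars: str = "all"          # "all" (19 variables) or "retained"
    max_iter: int = 500
    tol: float = 1e-7
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rm_grid"] = list(self.rm_grid)
        d["fc_combos"] = list(self.fc_combos)
        return d


@dataclass
class SuiteResult:
    """Everything the pipeline computed for one presence-data suite."""

    name: str
    rm: float
    fc: str
    selection_scores: pd.DataFrame
    ensemble: EnsembleResult
    mean_suitability: RasterGrid                 # mean continuous surface
    consensus_by_scenario: dict[str, RasterGrid]
    suitability_by_scenario: dict[str, RasterGrid]
    summaries: list[RangeSummary]
    importance: pd.Series
    response_thresholds: dict[str, tuple[float, float] | None]
    change_counts: dict[str, pd.Series] = field(default_factory=dict)


@dataclass
class PipelineReport:
    config: PipelineConfig
    n_raw: int
    n_thinned: int
    region_mask: RasterGrid
    vif_retained: list[str]
    vif_trace: pd.DataFrame
    pca_table: pd.DataFrame
    pca_cumulative: np.ndarray
    hca_method: str
    hca_coefficients: dict[str, float]
    hca_label_counts: dict
    lda_mean: float
    lda_sd: float
    suites: dict[str, SuiteResult]
    combination_by_scenario: dict[str, RasterGrid]
    combination_summaries: list[RangeSummary]
    overlap_series: pd.DataFrame

    def summary(self) -> dict:
        """JSON-able digest of the headline quantities."""
        out = {
            "version": __version__,
            "config": self.config.to_dict(),
            "thinning": {"n_in": self.n_raw, "n_out": self.n_thinned},
            "vif": {"retained": self.vif_retained},
            "pca": {
                "cumulative_percent": [round(float(v), 4) for v in self.pca_cumulative],
                "cumulative_percent_pc2": float(self.pca_cumulative[1])
                if len(self.pca_cumulative) > 1 else None,
                "cumulative_percent_pc3": float(self.pca_cumulative[2])
                if len(self.pca_cumulative) > 2 else None,
            },
            "hca": {"method": self.hca_method,
                    "coefficients": {k: float(v) for k, v in self.hca_coefficients.items()},
                    "label_counts": {str(k): int(v) for k, v in self.hca_label_counts.items()}},
            "lda": {"mean_misjudgment": self.lda_mean, "sd": self.lda_sd},
            "suites": {},
            "overlap": self.overlap_series.to_dict(orient="records"),
        }
        for name, s in self.suites.items():
            out["suites"][name] = {
                "rm": s.rm, "fc": s.fc,
                "mean_test_auc": float(np.mean([r.test_auc for r in s.ensemble.retained])),
                "n_replicates_retained": len(s.ensemble.retained),
                "permutation_importance": {k: float(v) for k, v in s.importance.items()},
                "areas_km2": {r.scenario: r.area_km2 for r in s.summaries},
                "centroids": {r.scenario: [r.centroid_lon, r.centroid_lat]
                              for r in s.summaries},
                "response_thresholds": {k: list(v) if v else None
                                        for k, v in s.response_thresholds.items()},
                "change_counts": {k: v.to_dict() for k, v in s.change_counts.items()},
            }
        out["combination"] = {
            "areas_km2": {r.scenario: r.area_km2 for r in self.combination_summaries}}
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.summary(), fh, indent=1, default=float)
        self.pca_table.to_csv(outdir / "pca_table.csv")
        self.vif_trace.to_csv(outdir / "vif_trace.csv")
        self.overlap_series.to_csv(outdir / "overlap_series.csv", index=False)
        write_ascii_grid(self.region_mask, outdir / "region_mask.asc")
        for name, s in self.suites.items():
            s.selection_scores.to_csv(outdir / f"{name}_selection.csv", index=False)
            for scen, grid in s.consensus_by_scenario.items():
                write_ascii_grid(grid, outdir / f"{name}_{scen}_consensus.asc", precision=1)
        for scen, grid in self.combination_by_scenario.items():
            write_ascii_grid(grid, outdir / f"Combination_{scen}_consensus.asc", precision=1)


# ---------------------------------------------------------------------------
# Stack utilities
# ---------------------------------------------------------------------------

def average_stacks(stacks: list[RasterStack]) -> RasterStack:
    """Equally weighted cellwise mean of stacks with identical geometry and
    layer names; a cell is nodata if any input is nodata there."""
    if not stacks:
        raise ValueError("no stacks to average")
    first = stacks[0]
    names = first.layer_names
    for s in stacks[1:]:
        if s.layer_names != names:
            raise ValueError("average_stacks: layer-name mismatch")
        if not s.template.same_geometry(first.template):
            raise ValueError("average_stacks: geometry mismatch")
    layers = {}
    for name in names:
        vals = np.mean([s[name].values for s in stacks], axis=0)  # NaN propagates
        layers[name] = first[name].copy_with(vals)
    return RasterStack(layers)


def _mean_suitability(result: EnsembleResult, stack: RasterStack,
                      output: str) -> RasterGrid:
    grids = [predict(rep.model, stack, output=output) for rep in result.retained]
    vals = np.mean([g.values for g in grids], axis=0)
    return grids[0].copy_with(vals)


def _scenario_rcps(scenario_labels: list[str]) -> dict[str, list[str]]:
    """Group 'PERIOD_RCP' labels by RCP, periods in sorted order."""
    by_rcp: dict[str, list[str]] = {}
    for label in scenario_labels:
        if "_" in label:
            period, rcp = label.split("_", 1)
            by_rcp.setdefault(rcp, []).append(label)
    return {rcp: sorted(labels) for rcp, labels in by_rcp.items()}


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def run_pipeline(occurrences: OccurrenceSet, current_stack: RasterStack,
                 scenario_stacks: dict[str, RasterStack] | None = None,
                 config: PipelineConfig | None = None) -> PipelineReport:
    """Run the whole analysis on in-memory inputs.

    ``scenario_stacks`` maps labels like '2050s_RCP2.6' to future climate
    stacks (already GCM-averaged — see :func:`average_stacks`). Occurrence
    population labels are used when present; otherwise the clustering cut
    assigns them.
    """
    cfg = config or PipelineConfig()
    scenario_stacks = scenario_stacks or {}
    master = cfg.seed

    # 1. thinning ---------------------------------------------------------
    n_raw = len(occurrences)
    occ = spatial_filter(occurrences, cell_km=cfg.cell_km)
    logger.info("pipeline: thinning %d -> %d", n_raw, len(occ))

    # 2. study region + background ---------------------------------------
    mask = buffer_region(occ, cfg.radius_km, current_stack.template)
    bg = sample_background(mask, n=cfg.background_n,
                           seed=derive_seed(master, "background"))
    bg_clim_all = extract_values(current_stack, bg.as_occurrences())

    # 3. collinearity screen ---------------------------------------------
    _, vif_report = vif_eliminate(bg_clim_all, threshold=cfg.vif_threshold)
    retained_vars = vif_report.retained
    bg_clim = bg_clim_all[retained_vars]

    # 4. population grouping ----------------------------------------------
    occ_clim_all = extract_values(current_stack, occ)
    occ = occ.subset(occ_clim_all.index.to_numpy())  # drop nodata hits
    occ_clim_all = occ_clim_all.reset_index(drop=True)
    pca_input = occ_clim_all if cfg.pca_vars == "all" else occ_clim_all[retained_vars]
    pca_res = pca(pca_input)

    occ_retained = occ_clim_all[retained_vars]
    zscored = (occ_retained - occ_retained.mean()) / occ_retained.std(ddof=1)
    cluster = hca(zscored, k=cfg.k_groups)

    pops = occ.population
    if pops is None:
        pops = np.where(cluster.labels == 1, "West", "East")
        logger.info("pipeline: no population labels supplied; using the "
                    "k=%d clustering cut", cfg.k_groups)
    lda_res = lda_misjudgment(occ_retained, pops, n_reps=cfg.lda_reps,
                              seed=derive_seed(master, "lda"))

    # 5. per-suite modeling ------------------------------------------------
    pop_names = [str(p) for p in pd.unique(pd.Series(pops))]
    suite_presences = {name: occ_retained[np.asarray(pops) == name] for name in pop_names}
    suite_presences["Whole"] = occ_retained
    suites: dict[str, SuiteResult] = {}
    for name, pres in suite_presences.items():
        sel = model_select(pres, bg_clim, rm_grid=cfg.rm_grid,
                           fc_combos=cfg.fc_combos, n_eval_splits=cfg.eval_splits,
                           seed=derive_seed(master, "select", name),
                           n_knots=cfg.n_knots, max_iter=cfg.max_iter, tol=cfg.tol)
        ens = build_ensemble(pres, bg_clim, sel.rm, sel.fc, current_stack,
                             n_reps=cfg.bootstrap_reps,
                             seed=derive_seed(master, "bootstrap", name),
                             auc_cutoff=cfg.auc_cutoff, vote_frac=cfg.vote_frac,
                             output=cfg.output_transform, n_knots=cfg.n_knots,
                             max_iter=cfg.max_iter, tol=cfg.tol, label=name)
        consensus = {"current": ens.consensus}
        suit = {"current": _mean_suitability(ens, current_stack, cfg.output_transform)}
        for label, stack in scenario_stacks.items():
            cons, _frac = project_ensemble(ens, stack, output=cfg.output_transform)
            consensus[label] = cons
            suit[label] = _mean_suitability(ens, stack, cfg.output_transform)
        summaries = [RangeSummary.of(g, scen) for scen, g in consensus.items()]

        importance = permutation_importance(
            sel.model, pres, bg_clim, seed=derive_seed(master, "perm", name))
        thresholds = {}
        for v in retained_vars:
            grid, curve = response_curve(sel.model, v, output=cfg.output_transform)
            thresholds[v] = threshold_range(grid, curve, cutoff=cfg.response_cutoff)

        changes = {}
        for rcp, labels in _scenario_rcps(list(scenario_stacks)).items():
            if len(labels) == 2:
                cm = change_map(consensus["current"], consensus[labels[0]],
                                consensus[labels[1]])
                changes[rcp] = cm.counts()

        suites[name] = SuiteResult(name, sel.rm, sel.fc, sel.scores, ens,
                                   suit["current"], consensus, suit, summaries,
                                   importance, thresholds, changes)

    # 6. combination + overlap series -------------------------------------
    combo_sources = [n for n in pop_names if n in suites]
    combination: dict[str, RasterGrid] = {}
    if len(combo_sources) == 2:
        a, b = combo_sources
        for scen in suites[a].consensus_by_scenario:
            combination[scen] = combine_union(
                suites[a].consensus_by_scenario[scen],
                suites[b].consensus_by_scenario[scen], mode=cfg.combination_mode)
    combo_summaries = [RangeSummary.of(g, scen) for scen, g in combination.items()]

    overlap_rows = []
    scenarios = ["current"] + list(scenario_stacks)
    if len(combo_sources) == 2:
        a, b = combo_sources
        for scen in scenarios:
            r = overlap(suites[a].suitability_by_scenario[scen],
                        suites[b].suitability_by_scenario[scen],
                        region=mask, pair=f"{a}-{b}", scenario=scen)
            overlap_rows.append({"pair": r.pair, "scenario": scen,
                                 "Sch_D": r.D, "Cor_I": r.I})
        if "Whole" in suites:
            for scen in scenarios:
                r = overlap(combination[scen],
                            suites["Whole"].consensus_by_scenario[scen],
                            pair="Combination-Whole", scenario=scen)
                overlap_rows.append({"pair": r.pair, "scenario": scen,
                                     "Sch_D": r.D, "Cor_I": r.I})
    overlap_series = pd.DataFrame(overlap_rows,
                                  columns=["pair", "scenario", "Sch_D", "Cor_I"])

    labels_unique, labels_counts = np.unique(cluster.labels, return_counts=True)
    return PipelineReport(
        config=cfg, n_raw=n_raw, n_thinned=len(occ), region_mask=mask,
        vif_retained=retained_vars, vif_trace=vif_report.to_frame(),
        pca_table=pca_res.table(), pca_cumulative=pca_res.cumulative_percent,
        hca_method=cluster.method, hca_coefficients=cluster.coefficients,
        hca_label_counts=dict(zip(labels_unique.tolist(), labels_counts.tolist())),
        lda_mean=lda_res.mean, lda_sd=lda_res.sd, suites=suites,
        combination_by_scenario=combination, combination_summaries=combo_summaries,
        overlap_series=overlap_series,
    )
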