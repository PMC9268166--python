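"""One-command reproduction of the full lipophilicity analysis.

Stages, on the packaged 27-compound tables (or user-supplied CSVs of the
same layout):

1. audit of the CHI-to-logk_IAM / CHI-to-CHI_logD transforms and of the
   consensus logP against the printed columns;
2. correlation matrix of the 12-measure lipophilicity panel;
3. PCA and Ward/Euclidean cluster analysis of the standardized measures
   (potency pIC50 included alongside, as in the clustered heat map);
4. SRD with row-average reference, Monte-Carlo CRRN null, 7-fold
   cross-validation and pairwise Wilcoxon grouping;
5. a GA-PLS demonstration on a seeded synthetic descriptor set with
   known ground truth (the study's own descriptor matrix is commercial
   and not redistributable), including y-randomization and the leverage
   applicability domain.

All outputs are plain CSV/JSON; the summary JSON carries the seed and a
hash of the configuration, so a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, chemometrics, dataset, transforms
from .gapls import GAConfig, GAPLS, split_minmax
from .srd import srd_analysis
from .synthetic import make_descriptor_dataset

__all__ = ["PipelineConfig", "run_study_pipeline"]

log = logging.getLogger("lipochemo.pipeline")


@dataclass
class PipelineConfig:
    out_dir: str = "lipochemo_out"
    table1: str | None = None     # None -> packaged fixture
    table2: str | None = None
    seed: int = 0
    crrn_draws: int = 1_000_000
    cv_folds: int = 7
    ga_generations: int = 30
    ga_population: int = 500
    y_permutations: int = 200
    pca_components: int = 2
    cluster_k: int = 2
    log_level: str = "INFO"

    def hash(self) -> str:
        """Hash of the analysis-relevant settings (paths/logging excluded),
        so identical analyses produce identical summaries wherever written."""
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("out_dir", "log_level")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def run_study_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; write the report bundle; return the summary dict."""
    logging.basicConfig(level=config.log_level, stream=None)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "provenance": {
            "package": "lipochemo",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.hash(),
        }
    }

    def stage(name):
        log.info("stage: %s", name)
        return time.perf_counter()

    try:
        t0 = stage("load")
        t1 = dataset.read_table(config.table1) if config.table1 \
            else dataset.load_table1()
        t2 = dataset.read_table(config.table2) if config.table2 \
            else dataset.load_table2()
        panel = t1.join(
            t2[["logk_IAM", "CHI_logD", "logkw_C8", "logkw_CN", "logkw_Ph"]]
        )[list(dataset.PANEL_MEASURES)]

        stage("transform audit")
        audit = pd.DataFrame(index=t2.index)
        audit["logk_IAM_printed"] = t2["logk_IAM"]
        audit["logk_IAM_computed"] = transforms.round_half_away(
            transforms.chi_to_logk_iam(t2["CHI_IAM"].to_numpy()), 2)
        audit["CHI_logD_printed"] = t2["CHI_logD"]
        audit["CHI_logD_computed"] = transforms.round_half_away(
            transforms.chi_to_chi_logd(t2["CHI_C18"].to_numpy()), 2)
        audit["consensus_printed"] = t1["Consensus LogP"]
        audit["consensus_computed"] = transforms.round_half_away(
            transforms.consensus_logp(*(t1[c].to_numpy() for c in
                                        ("iLogP", "XLogP3", "WLogP", "MLogP",
                                         "Silicos-IT LogP"))), 2)
        audit.to_csv(out / "transform_audit.csv")
        summary["transform_audit"] = {
            "max_gap_logk_iam": float(
                (audit["logk_IAM_computed"] - audit["logk_IAM_printed"]).abs().max()),
            "max_gap_chi_logd": float(
                (audit["CHI_logD_computed"] - audit["CHI_logD_printed"]).abs().max()),
            "max_gap_consensus": float(
                (audit["consensus_computed"] - audit["consensus_printed"]).abs().max()),
        }

        stage("correlation")
        corr = chemometrics.correlation_matrix(panel)
        corr.to_csv(out / "correlation_matrix.csv")

        stage("pca + clustering")
        with_pot = panel.copy()
        with_pot["pIC50"] = t2["pIC50"]
        std = transforms.standardize_columns(with_pot)
        pca_res = chemometrics.pca(std, n_components=config.pca_components)
        pca_res.scores.to_csv(out / "pca_scores.csv")
        pca_res.loadings.to_csv(out / "pca_loadings.csv")
        dend = chemometrics.hierarchical_cluster(std.T)
        np.savetxt(out / "linkage_measures.csv", dend.linkage, delimiter=",",
                   header="left,right,height,size", comments="")
        membership = chemometrics.cluster_membership(dend, config.cluster_k)
        membership.to_csv(out / "cluster_membership.csv")
        summary["pca_explained_variance_ratio"] = [
            round(float(r), 6) for r in pca_res.explained_variance_ratio]
        summary["measure_clusters"] = {m: int(c) for m, c in membership.items()}

        stage("srd")
        res = srd_analysis(panel, crrn_method="monte_carlo",
                           n_draws=config.crrn_draws, seed=config.seed)
        ranking = pd.DataFrame({"srd": res.srd_raw, "srd_pct": res.srd_pct})
        ranking = ranking.loc[res.ordering]
        ranking.to_csv(out / "srd_ranking.csv")
        _write_json(out / "crrn_quantiles.json",
                    {"n_objects": res.crrn.n_objects,
                     "mean": round(res.crrn.mean, 4),
                     "quantiles": {str(k): round(v, 4)
                                   for k, v in res.crrn.quantiles.items()}})
        cv = res.crossvalidate(k=config.cv_folds, seed=config.seed)
        cv.to_csv(out / "srd_cv.csv")
        cv.describe().to_csv(out / "srd_cv_boxstats.csv")
        res.wilcoxon_matrix(cv).to_csv(out / "wilcoxon_pvalues.csv")
        summary["srd"] = {
            "ordering": res.ordering,
            "best_measure": res.ordering[0],
            "worst_three": sorted(res.ordering[-3:]),
            "cv_median_best": cv.median().idxmin(),
            "crrn_quantiles": {str(k): round(v, 4)
                               for k, v in res.crrn.quantiles.items()},
        }

        stage("ga-pls demo (synthetic descriptors)")
        data = make_descriptor_dataset(seed=config.seed)
        split = split_minmax(data.y.to_numpy(), 18, 9, seed=config.seed)
        cfg = GAConfig(population_size=config.ga_population,
                       n_generations=config.ga_generations, seed=config.seed)
        fit = GAPLS(data.X, data.y.to_numpy(), config=cfg, split=split).fit()
        yrand = fit.y_randomization(n_permutations=config.y_permutations,
                                    seed=config.seed)
        fit.ad.frame(ids=list(data.X.index[split[0]]) +
                     list(data.X.index[split[1]])).to_csv(
            out / "williams_plot.csv")
        pd.DataFrame({"r2": yrand.r2_permuted,
                      "q2": yrand.q2_permuted}).to_csv(
            out / "y_randomization.csv", index_label="permutation")
        summary["gapls_demo"] = {
            "true_support": list(data.support_names),
            "selected": list(fit.selected),
            "recovered_exactly": sorted(fit.selected) == sorted(data.support_names),
            "r2": round(fit.stats.r2, 4),
            "q2_loo": round(fit.stats.q2_loo, 4),
            "q2_f1": round(fit.stats.q2_f1, 4),
            "q2_f2": round(fit.stats.q2_f2, 4),
            "q2_f3": round(fit.stats.q2_f3, 4),
            "rmse_p": round(fit.stats.rmse_p, 4),
            "ccc": round(fit.stats.ccc, 4),
            "h_star": round(fit.ad.h_star, 4),
            "y_randomization": {
                "n_permutations": yrand.n_permutations,
                "r2_original": round(yrand.r2_original, 4),
                "max_r2_permuted": round(float(yrand.r2_permuted.max()), 4),
                "r2_exceedance": yrand.r2_exceedance,
            },
        }
    except Exception as exc:  # annotate which stage died, then re-raise
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    _write_json(out / "summary.json", summary)
    log.info("done in %.1fs", time.perf_counter() - t0)
    return summary
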