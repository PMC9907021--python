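"""End-to-end benchmark over a cohort: the CohortBenchmark model.

``CohortBenchmark(cohort, ...).fit()`` runs, per (case, ROI):

1. surface-Dice tolerance tau from expert pairwise mean surface distance;
2. pairwise interobserver variability for each group and metric;
3. expert acceptability thresholds (median expert pairwise value);
4. Mann-Whitney U comparison of expert vs nonexpert pairwise values;
5. expert and nonexpert STAPLE consensus masks, consensus volumes, and
   evaluation of the nonexpert consensus against the expert thresholds;
6. a bootstrap curve of consensus quality vs number of nonexperts, the
   minimum observer count crossing the expert bar, and a nonsaturation
   flag;
7. optionally, per-case observer skill scores, tertile stratification with
   per-class consensus evaluation, and cross-case score correlation.

One ROI's degenerate data never aborts the run: failures are recorded per
(case, ROI, stage) and the remaining ROIs proceed.  All results are pure
functions of (cohort, config, seed), so reruns are bitwise identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmark import (
    AcceptabilityThreshold,
    InsufficientGroupError,
    compare_groups_mwu,
    determine_sdsc_tolerance,
    expert_acceptability_threshold,
    evaluate_consensus_vs_threshold,
    pairwise_matrix_to_frame,
    pairwise_metric_values,
)
from .bootstrap import (
    DEFAULT_N_ITER,
    DEFAULT_SIZES,
    bootstrap_consensus_curve,
    minimum_observers,
)
from .io import Cohort, Expertise
from .metrics import Metric, volume_cc
from .staple import STAPLE, StapleConfig
from .stratify import (
    case_level_performance,
    class_consensus_evaluation,
    correlate_case_performance,
    tertile_stratify,
)

logger = logging.getLogger("contourbench")

__all__ = ["BenchmarkConfig", "CohortBenchmark", "BenchmarkResults", "run_full_analysis"]


@dataclass(frozen=True)
class BenchmarkConfig:
    metrics: tuple[str, ...] = ("DSC", "SDSC")
    staple: StapleConfig = field(default_factory=StapleConfig)
    bootstrap_sizes: tuple[int, ...] = DEFAULT_SIZES
    bootstrap_iters: int = DEFAULT_N_ITER
    bootstrap_metric: str = "DSC"
    seed: int = 0
    run_bootstrap: bool = True
    run_stratification: bool = False


class CohortBenchmark:
    """Benchmark model over a loaded or simulated observer cohort."""

    def __init__(self, cohort: Cohort, config: BenchmarkConfig | None = None):
        self.cohort = cohort
        self.config = config or BenchmarkConfig()

    def fit(self) -> "BenchmarkResults":
        cfg = self.config
        iov_rows: list[pd.DataFrame] = []
        thr_rows, tol_rows, mwu_rows, eval_rows = [], [], [], []
        boot_frames, minobs_rows, failures = [], [], []
        curves = {}
        consensus_masks = {}
        thresholds: dict[tuple[str, str, str], AcceptabilityThreshold] = {}
        taus: dict[tuple[str, str], float] = {}

        for case_id, roi in self.cohort.groups():
            t0 = time.perf_counter()
            try:
                self._run_roi(
                    case_id, roi, cfg,
                    iov_rows, thr_rows, tol_rows, mwu_rows, eval_rows,
                    boot_frames, minobs_rows, curves, consensus_masks,
                    thresholds, taus,
                )
            except Exception as exc:  # per-ROI isolation
                logger.warning("ROI %s/%s failed: %s", case_id, roi, exc)
                failures.append(
                    {"case_id": case_id, "roi_name": roi, "error": str(exc)}
                )
            logger.info(
                "%s/%s done in %.1fs", case_id, roi, time.perf_counter() - t0
            )

        strat = None
        if cfg.run_stratification:
            strat = self._run_stratification(cfg, consensus_masks, thresholds, taus)

        return BenchmarkResults(
            config=cfg,
            iov_pairs=pd.concat(iov_rows, ignore_index=True)
            if iov_rows
            else pd.DataFrame(),
            thresholds=pd.DataFrame(thr_rows),
            tolerances=pd.DataFrame(tol_rows),
            mwu=pd.DataFrame(mwu_rows),
            consensus_eval=pd.DataFrame(eval_rows),
            bootstrap_curves=pd.concat(boot_frames, ignore_index=True)
            if boot_frames
            else pd.DataFrame(),
            min_observers=pd.DataFrame(minobs_rows),
            stratification=strat,
            failures=pd.DataFrame(failures),
            curves=curves,
            consensus_masks=consensus_masks,
        )

    # -- per-ROI pipeline -------------------------------------------------

    def _run_roi(
        self, case_id, roi, cfg,
        iov_rows, thr_rows, tol_rows, mwu_rows, eval_rows,
        boot_frames, minobs_rows, curves, consensus_masks, thresholds, taus,
    ):
        experts = self.cohort.by_expertise(case_id, roi, Expertise.EXPERT)
        nonexperts = self.cohort.by_expertise(case_id, roi, Expertise.NONEXPERT)

        tau = None
        if len(experts) >= 2:
            try:
                tau = determine_sdsc_tolerance(experts)
                taus[(case_id, roi)] = tau
                tol_rows.append(
                    {"case_id": case_id, "roi_name": roi, "tolerance_mm": tau}
                )
            except InsufficientGroupError as exc:
                logger.info("%s/%s: tolerance undefined (%s)", case_id, roi, exc)

        matrices = {}
        for metric_name in cfg.metrics:
            metric = Metric(metric_name)
            mtau = tau if metric in (Metric.SDSC, Metric.APL) else None
            if metric == Metric.SDSC and tau is None:
                continue
            for group, contours in (("expert", experts), ("nonexpert", nonexperts)):
                if len(contours) < 2:
                    continue
                matrix = pairwise_metric_values(contours, metric, mtau)
                matrices[(metric, group)] = matrix
                iov_rows.append(pairwise_matrix_to_frame(matrix))
            if (metric, "expert") in matrices:
                thr = expert_acceptability_threshold(matrices[(metric, "expert")])
                thresholds[(case_id, roi, metric.value)] = thr
                thr_rows.append(
                    {
                        "case_id": case_id,
                        "roi_name": roi,
                        "metric": metric.value,
                        "value": thr.value,
                    }
                )
            if (metric, "expert") in matrices and (metric, "nonexpert") in matrices:
                u, p, band = compare_groups_mwu(
                    matrices[(metric, "expert")].defined_values(),
                    matrices[(metric, "nonexpert")].defined_values(),
                )
                mwu_rows.append(
                    {
                        "case_id": case_id,
                        "roi_name": roi,
                        "metric": metric.value,
                        "U": u,
                        "p": p,
                        "band": band,
                    }
                )

        expert_consensus = nonexpert_consensus = None
        if len(experts) >= 2:
            expert_consensus = (
                STAPLE([c.mask for c in experts], config=cfg.staple).fit().consensus_mask
            )
            consensus_masks[(case_id, roi, "expert")] = expert_consensus
        if len(nonexperts) >= 2:
            nonexpert_consensus = (
                STAPLE([c.mask for c in nonexperts], config=cfg.staple)
                .fit()
                .consensus_mask
            )
            consensus_masks[(case_id, roi, "nonexpert")] = nonexpert_consensus

        if expert_consensus is not None and nonexpert_consensus is not None:
            for metric_name in cfg.metrics:
                key = (case_id, roi, metric_name)
                if key not in thresholds:
                    continue
                mtau = tau if Metric(metric_name) in (Metric.SDSC, Metric.APL) else None
                value, crossed, reason = evaluate_consensus_vs_threshold(
                    nonexpert_consensus, expert_consensus, thresholds[key], mtau
                )
                eval_rows.append(
                    {
                        "case_id": case_id,
                        "roi_name": roi,
                        "metric": metric_name,
                        "value": value,
                        "threshold": thresholds[key].value,
                        "crossed": crossed,
                        "expert_consensus_cc": float(volume_cc(expert_consensus)),
                        "nonexpert_consensus_cc": float(volume_cc(nonexpert_consensus)),
                        "reason": reason,
                    }
                )

        if (
            cfg.run_bootstrap
            and expert_consensus is not None
            and len(nonexperts) >= 2
        ):
            key = (case_id, roi, cfg.bootstrap_metric)
            thr = thresholds.get(key)
            mtau = tau if Metric(cfg.bootstrap_metric) == Metric.SDSC else None
            curve = bootstrap_consensus_curve(
                nonexperts,
                expert_consensus,
                threshold=thr,
                sizes=cfg.bootstrap_sizes,
                n_iter=cfg.bootstrap_iters,
                seed=cfg.seed,
                metric=cfg.bootstrap_metric,
                tau_mm=mtau,
                staple_config=cfg.staple,
            )
            curves[(case_id, roi)] = curve
            boot_frames.append(curve.to_frame())
            if thr is not None:
                mo = minimum_observers(curve)
                minobs_rows.append(
                    {
                        "case_id": case_id,
                        "roi_name": roi,
                        "metric": mo.metric.value,
                        "k_min": mo.k_min,
                        "nonsaturating": mo.nonsaturating,
                        "description": mo.description,
                    }
                )

    # -- optional stratification ------------------------------------------

    def _run_stratification(self, cfg, consensus_masks, thresholds, taus):
        frames = {}
        scores_by_case = {}
        for case_id in sorted({c for c, _ in self.cohort.groups()}):
            rois = [r for c, r in self.cohort.groups() if c == case_id]
            consensus_by_roi = {
                r: consensus_masks[(case_id, r, "expert")]
                for r in rois
                if (case_id, r, "expert") in consensus_masks
            }
            if not consensus_by_roi:
                continue
            by_obs: dict[str, list] = {}
            for r in consensus_by_roi:
                for c in self.cohort.by_expertise(case_id, r, Expertise.NONEXPERT):
                    by_obs.setdefault(c.observer_id, []).append(c)
            tau_by_roi = {r: taus[(case_id, r)] for r in rois if (case_id, r) in taus}
            scores = []
            for obs, contours in sorted(by_obs.items()):
                try:
                    scores.append(
                        case_level_performance(
                            contours, consensus_by_roi, Metric.DSC, tau_by_roi
                        )
                    )
                except Exception as exc:
                    logger.info("no case score for %s/%s: %s", case_id, obs, exc)
            scores_by_case[case_id] = scores
            if len(scores) < 3:
                continue
            try:
                assignment = tertile_stratify(scores)
            except Exception as exc:
                logger.info("stratification skipped for %s: %s", case_id, exc)
                continue
            contours_by_roi = {
                r: self.cohort.by_expertise(case_id, r, Expertise.NONEXPERT)
                for r in consensus_by_roi
            }
            thr_map = {
                (r, m): t
                for (c, r, m), t in thresholds.items()
                if c == case_id
            }
            table = class_consensus_evaluation(
                assignment, contours_by_roi, consensus_by_roi, thr_map,
                tau_by_roi, cfg.staple,
            )
            table.insert(0, "case_id", case_id)
            frames[case_id] = {
                "assignment": assignment,
                "scores": scores,
                "table": table,
            }

        correlations = []
        case_ids = sorted(scores_by_case)
        for i, ca in enumerate(case_ids):
            for cb in case_ids[i + 1 :]:
                try:
                    r, p, n = correlate_case_performance(
                        scores_by_case[ca], scores_by_case[cb]
                    )
                    correlations.append(
                        {"case_a": ca, "case_b": cb, "metric": "DSC",
                         "r": r, "p": p, "n": n}
                    )
                except Exception as exc:
                    logger.info("correlation %s-%s skipped: %s", ca, cb, exc)
        return {
            "per_case": frames,
            "correlations": pd.DataFrame(correlations),
            "scores_by_case": scores_by_case,
        }


@dataclass
class BenchmarkResults:
    """Result tables of a full benchmark run (one row granularity each)."""

    config: BenchmarkConfig
    iov_pairs: pd.DataFrame
    thresholds: pd.DataFrame
    tolerances: pd.DataFrame
    mwu: pd.DataFrame
    consensus_eval: pd.DataFrame
    bootstrap_curves: pd.DataFrame
    min_observers: pd.DataFrame
    stratification: dict | None
    failures: pd.DataFrame
    curves: dict = field(repr=False, default_factory=dict)
    consensus_masks: dict = field(repr=False, default_factory=dict)

    def summary(self) -> str:
        lines = ["Cohort benchmark summary", "========================"]
        if not self.thresholds.empty:
            lines.append("\nExpert acceptability thresholds:")
            lines.append(self.thresholds.to_string(index=False))
        if not self.consensus_eval.empty:
            lines.append("\nNonexpert consensus vs expert consensus:")
            lines.append(
                self.consensus_eval[
                    ["case_id", "roi_name", "metric", "value", "threshold", "crossed"]
                ].to_string(index=False)
            )
        if not self.min_observers.empty:
            lines.append("\nMinimum nonexperts to cross the expert bar:")
            lines.append(
                self.min_observers[
                    ["case_id", "roi_name", "metric", "k_min", "nonsaturating"]
                ].to_string(index=False)
            )
        if not self.failures.empty:
            lines.append("\nFailed ROIs:")
            lines.append(self.failures.to_string(index=False))
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        per_roi: dict[str, dict] = {}
        for _, row in self.consensus_eval.iterrows():
            key = f"{row.case_id}/{row.roi_name}"
            per_roi.setdefault(key, {})[f"crossed_{row.metric}"] = bool(row.crossed)
        for _, row in self.min_observers.iterrows():
            key = f"{row.case_id}/{row.roi_name}"
            per_roi.setdefault(key, {})["k_min"] = (
                None if pd.isna(row.k_min) else int(row.k_min)
            )
            per_roi.setdefault(key, {})["nonsaturating"] = bool(row.nonsaturating)
        return {
            "rois": per_roi,
            "n_failures": int(len(self.failures)),
        }

    def write_outputs(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        tables = {
            "iov_pairs.csv": self.iov_pairs,
            "thresholds.csv": self.thresholds,
            "tolerances.csv": self.tolerances,
            "mwu.csv": self.mwu,
            "consensus_eval.csv": self.consensus_eval,
            "bootstrap_curve.csv": self.bootstrap_curves,
            "min_observers.csv": self.min_observers,
            "failures.csv": self.failures,
        }
        if self.stratification is not None:
            tables["correlations.csv"] = self.stratification["correlations"]
            strat_tables, tert_rows, score_rows = [], [], []
            for case_id, bundle in self.stratification["per_case"].items():
                strat_tables.append(bundle["table"])
                a = bundle["assignment"]
                for obs, cls in sorted(a.classes.items()):
                    tert_rows.append(
                        {"case_id": case_id, "observer_id": obs, "class": cls,
                         "edges": json.dumps(a.bin_edges)}
                    )
            for case_id, scores in self.stratification["scores_by_case"].items():
                for s in scores:
                    score_rows.append(
                        {"case_id": case_id, "observer_id": s.observer_id,
                         "metric": s.metric.value, "value": s.value,
                         "n_rois_used": s.n_rois_used}
                    )
            tables["class_consensus_eval.csv"] = (
                pd.concat(strat_tables, ignore_index=True)
                if strat_tables
                else pd.DataFrame()
            )
            tables["tertiles.csv"] = pd.DataFrame(tert_rows)
            tables["case_scores.csv"] = pd.DataFrame(score_rows)
        for name, df in tables.items():
            path = out_dir / name
            df.to_csv(path, index=False)
            written.append(path)
        summary_path = out_dir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)
        written.append(summary_path)
        config_path = out_dir / "run_config.json"
        with open(config_path, "w") as fh:
            json.dump(asdict(self.config), fh, indent=2, default=str)
        written.append(config_path)
        return written


def run_full_analysis(
    cohort: Cohort,
    config: BenchmarkConfig | None = None,
    out_dir: str | Path | None = None,
) -> BenchmarkResults:
    """Fit the benchmark and optionally write the CSV bundle."""
    results = CohortBenchmark(cohort, config).fit()
    if out_dir is not None:
        results.write_outputs(out_dir)
    return results
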