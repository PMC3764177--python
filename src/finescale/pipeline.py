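"""End-to-end orchestration: per-plot SGS, clustering, differentiation and
complexity, plus the scenario-based marker-power study.

Every stochastic stage receives a seed derived deterministically from the
global seed, so a run is reproducible byte-for-byte from its config.
Per-stage wall-times are logged but never written into report files, to
keep reports byte-identical across repeated runs.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .clustering import select_k
from .complexity import standardized_cluster_count
from .fstats import hier_f, theta_ena
from .genotypes import GeoGenotypes, read_genotypes
from .sgs import DistanceClassSpec, correlogram, sp_statistic
from .simulate import SimScenario, named_scenarios, run_scenario, twenty_locus_scenario

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run (fully serializable)."""

    input_path: str | None = None
    output_dir: str = "finescale_out"
    seed: int = 0
    class_width_m: float = 20.0
    n_even_classes: int = 7
    n_perm: int = 1000
    n_boot: int = 1000
    k_max: int = 10
    cluster_reps: int = 10
    spatial_clustering: bool = False
    null_allele_model: bool = False
    window_area_ha: float = 0.21
    margin_m: float = 23.0
    power_reps: int = 20
    power_scenarios: list[str] = field(default_factory=lambda: list(
        ["HIGH-SGS", "Fl-like", "Fh-like", "LOW-SGS"]))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    tag = zlib.crc32(stage.encode()) % (2 ** 31)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2 ** 31))


def run_plot_analysis(cfg: RunConfig, g: GeoGenotypes | None = None) -> dict:
    """Per-plot SGS -> clustering -> theta among clusters -> complexity,
    plus hierarchical F across plots when two or more plots are present.

    Returns the report dict (also written to ``output_dir``); a failing
    stage is recorded as failed and later independent stages still run.
    """
    if g is None:
        g = read_genotypes(cfg.input_path)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": cfg.to_dict(), "plots": {}}
    summary_rows = []
    all_cluster_labels = np.zeros(g.n_ind, dtype=np.int64)

    for plot in g.plots():
        rows = np.flatnonzero(g.plot == plot)
        sub = g.subset(rows)
        entry: dict = {}
        t0 = time.perf_counter()
        try:
            summ = sp_statistic(sub, spec=DistanceClassSpec(width_m=cfg.class_width_m),
                                n_perm=cfg.n_perm, seed=_stage_seed(cfg.seed, f"sgs:{plot}"))
            for mode in ("even_width", "even_count"):
                spec = DistanceClassSpec(mode=mode, width_m=cfg.class_width_m,
                                         n_classes=cfg.n_even_classes)
                cg = correlogram(sub, spec=spec, n_perm=cfg.n_perm, n_boot=cfg.n_boot,
                                 seed=_stage_seed(cfg.seed, f"corr:{plot}:{mode}"))
                pd.DataFrame({
                    "edge_hi": cg.edges[1:], "mean_dist": cg.mean_dist,
                    "n_pairs": cg.n_pairs, "r": cg.estimate,
                    "perm_lo": cg.perm_lo, "perm_hi": cg.perm_hi,
                    "boot_lo": cg.boot_lo, "boot_hi": cg.boot_hi,
                }).to_csv(out / f"correlogram_{plot}_{mode}.csv", index=False)
            entry["sgs"] = {"F1": summ.F1, "bF": summ.bF, "Sp": summ.Sp,
                            "F1_se": summ.F1_se, "bF_se": summ.bF_se,
                            "Sp_se": summ.Sp_se, "p_F1": summ.p_F1, "p_bF": summ.p_bF}
        except Exception as e:  # stage isolation
            logger.exception("SGS stage failed for plot %s", plot)
            entry["sgs"] = {"failed": str(e)}
            summ = None
        logger.info("plot %s sgs stage: %.2fs", plot, time.perf_counter() - t0)

        t0 = time.perf_counter()
        try:
            ca = select_k(sub, K_max=cfg.k_max, reps=cfg.cluster_reps,
                          seed=_stage_seed(cfg.seed, f"cluster:{plot}"),
                          spatial=cfg.spatial_clustering,
                          null_allele_model=cfg.null_allele_model)
            all_cluster_labels[rows] = ca.labels
            entry["clustering"] = {"K": ca.K, "rep_Ks": ca.rep_Ks}
            pd.DataFrame({"id": sub.ids, "label": ca.labels}).to_csv(
                out / f"clusters_{plot}.csv", index=False)
        except Exception as e:
            logger.exception("clustering stage failed for plot %s", plot)
            entry["clustering"] = {"failed": str(e)}
            ca = None
        logger.info("plot %s clustering stage: %.2fs", plot, time.perf_counter() - t0)

        theta = theta_e = None
        if ca is not None and ca.K >= 2:
            try:
                tr = theta_ena(sub, ca.labels, n_perm=cfg.n_perm,
                               seed=_stage_seed(cfg.seed, f"theta:{plot}"))
                theta, theta_e = tr.theta, tr.theta_ena
                entry["theta"] = {"theta": tr.theta, "theta_ena": tr.theta_ena,
                                  "p": tr.p_value}
            except Exception as e:
                logger.exception("theta stage failed for plot %s", plot)
                entry["theta"] = {"failed": str(e)}
        else:
            entry["theta"] = {"skipped": "single cluster"}
            logger.info("plot %s: single cluster, theta stage skipped", plot)

        nbar = None
        if ca is not None:
            try:
                cx = standardized_cluster_count(
                    sub, ca.labels, window_area_ha=cfg.window_area_ha,
                    margin_m=cfg.margin_m, n_boot=cfg.n_boot,
                    seed=_stage_seed(cfg.seed, f"nc:{plot}"))
                nbar = cx.nbar_c
                entry["complexity"] = {"nbar_c": cx.nbar_c, "ci": list(cx.ci),
                                       "n_focal": cx.n_focal}
            except Exception as e:
                logger.exception("complexity stage failed for plot %s", plot)
                entry["complexity"] = {"failed": str(e)}

        report["plots"][plot] = entry
        summary_rows.append({
            "plot": plot, "n": sub.n_ind,
            "F1": None if summ is None else summ.F1,
            "bF": None if summ is None else summ.bF,
            "bF_se": None if summ is None else summ.bF_se,
            "Sp": None if summ is None else summ.Sp,
            "Sp_se": None if summ is None else summ.Sp_se,
            "K": None if ca is None else ca.K,
            "theta_ST": theta, "theta_ST_ena": theta_e, "Nbar_c": nbar,
        })

    if len(g.plots()) >= 2 and all_cluster_labels.max() > 0:
        try:
            # cluster labels made globally unique by prefixing the plot
            glob = np.array([f"{p}:{c}" for p, c in zip(g.plot, all_cluster_labels)])
            hf = hier_f(g, g.plot, glob, n_perm=cfg.n_perm,
                        seed=_stage_seed(cfg.seed, "hierf"))
            report["hier_f"] = {
                "F_PlotTotal": hf.f_plot_total, "F_CluPlot": hf.f_clu_plot,
                "F_IndClu": hf.f_ind_clu, "F_IndTotal": hf.f_ind_total,
                "p_PlotTotal": hf.p_plot_total, "p_CluPlot": hf.p_clu_plot,
                "p_IndClu": hf.p_ind_clu}
        except Exception as e:
            logger.exception("hierarchical F stage failed")
            report["hier_f"] = {"failed": str(e)}
    else:
        report["hier_f"] = {"skipped": "fewer than two plots"}

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                default=float))
    return report


def run_power_study(cfg: RunConfig, n_perm_envelope: int = 0) -> dict:
    """Marker-power study: the named dispersal/density scenarios at 4 and
    20 loci, with per-checkpoint SGS trajectories and a Welch comparison of
    the generation-64 F_1 means between the two locus counts."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scen4 = {name: s for name, s in named_scenarios().items()
             if name in cfg.power_scenarios}
    rows = []
    report: dict = {"version": __version__, "config": cfg.to_dict(), "scenarios": {}}
    for name, base in scen4.items():
        entry: dict = {}
        for n_loci, scen in (("4", base), ("20", twenty_locus_scenario(base))):
            scen.seed = _stage_seed(cfg.seed, f"power:{name}:{n_loci}")
            t0 = time.perf_counter()
            res = run_scenario(scen, n_reps=cfg.power_reps, n_perm=n_perm_envelope,
                               keep_snapshots=False)
            logger.info("scenario %s (%s loci): %.1fs", name, n_loci,
                        time.perf_counter() - t0)
            rec = res.records.assign(scenario=name, n_loci=int(n_loci))
            rows.append(rec)
            final = rec[rec.generation == scen.generations]
            entry[f"F1_gen{scen.generations}_{n_loci}loci"] = {
                "median": float(final.F1.median()), "mean": float(final.F1.mean()),
                "sd": float(final.F1.std(ddof=1)),
            }
        f4 = rows[-2].query("generation == @base.generations").F1
        f20 = rows[-1].query("generation == @base.generations").F1
        t, p = sps.ttest_ind(f4, f20, equal_var=False)
        entry["welch_4_vs_20"] = {"t": float(t), "p": float(p)}
        report["scenarios"][name] = entry
    records = pd.concat(rows, ignore_index=True)
    records.to_csv(out / "power_trajectories.csv", index=False)
    (out / "power_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float))
    return report


def welch_test(a, b) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances); t = 0, p = 1 for
    identical samples."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if np.array_equal(a, b) and a.std(ddof=1) == 0:
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
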