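"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes, for one dataset (loaded from TSV or generated
synthetically): per-probe ME/CD/SE metrics with criterion correlations,
power/critical-value summaries, correlation-bin networks with graph
summaries and specific (non-shared-node) networks, differential
(Fisher r-to-z) edge networks, the changed-correlation/stable-mean pair
count, and the differential multiple-regression screen.  Every output file
is a TSV/GEXF listed in a JSON manifest; a fixed seed makes the run
byte-reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io, metrics, mra, networks, power
from .dataset import ExpressionDataset
from .simulate import SyntheticConfig, generate_dataset


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``expression_path`` + ``sample_sheet_path``) or
    ``synthetic`` must be provided.
    """

    output_dir: str | Path = "results"
    expression_path: str | Path | None = None
    sample_sheet_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    alpha: float = 0.05
    entropy_bins: int = 10
    bootstrap_reps: int = 1000
    se_method: str = "collection"
    diffnet_alphas: tuple[float, ...] = (0.05, 0.001)
    subsample_fraction: float = 0.9
    subsample_reps: int = 100
    stable_pair_subsample: int = 3000
    mra_config: mra.ScreenConfig | None = None
    max_probes: int = networks.DEFAULT_MAX_PROBES
    seed: int = 0

    def validate(self) -> None:
        has_files = self.expression_path is not None or self.sample_sheet_path is not None
        if has_files and self.synthetic is not None:
            raise ValueError("provide either input files or a synthetic config, not both")
        if not has_files and self.synthetic is None:
            raise ValueError("provide input files or a synthetic config")
        if has_files and (self.expression_path is None or self.sample_sheet_path is None):
            raise ValueError("both expression_path and sample_sheet_path are required")


@dataclass
class RunResult:
    manifest: dict
    metrics: pd.DataFrame
    bin_tables: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)


def _stage_seed(root: int, k: int) -> int:
    # independent per-stage seeds below 2**31, derived from the root
    import numpy as np

    return int(np.random.default_rng([root, 1000 + k]).integers(0, 2**31 - 1))


def run_pipeline(config: RunConfig) -> RunResult:
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    files: list[str] = []
    manifest: dict = {
        "seed": config.seed,
        "alpha": config.alpha,
        "paritynet_version": __version__,
        "stages": {},
    }

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        files.append(name)

    stage = "load"
    try:
        if config.synthetic is not None:
            ds, truth = generate_dataset(config.synthetic)
            emit("expression.tsv", lambda p: io.write_dataset(ds, p, outdir / "samples.tsv"))
            files.append("samples.tsv")
            emit("ground_truth.tsv", lambda p: io.write_ground_truth(truth, p))
        else:
            ds = io.read_expression_matrix(config.expression_path, config.sample_sheet_path)
        manifest["stages"]["load"] = {
            "n_probes": ds.n_probes,
            "n_group1": ds.group_size(ds.group1),
            "n_group2": ds.group_size(ds.group2),
        }

        stage = "gene_metrics"
        me = metrics.me_differential(ds, config.alpha)
        cd = metrics.cd_differential(ds, config.alpha)
        se = metrics.se_bootstrap_differential(
            ds,
            n_bins=config.entropy_bins,
            n_boot=config.bootstrap_reps,
            alpha=config.alpha,
            seed=_stage_seed(config.seed, 1),
            method=config.se_method,
        )
        combined = metrics.combine_metrics(me, cd, se)
        emit("probe_metrics.tsv", lambda p: io.write_table(combined, p))
        crit_corr = metrics.criteria_correlations(combined)
        manifest["stages"]["gene_metrics"] = {
            "me_significant": int(me["me_significant"].sum()),
            "me_up": int((me["me_significant"] & (me["me_delta"] > 0)).sum()),
            "me_down": int((me["me_significant"] & (me["me_delta"] < 0)).sum()),
            "cd_significant_raw": int(cd["cd_significant_raw"].sum()),
            "cd_significant_adj": int(cd["cd_significant_adj"].sum()),
            "se_significant": int(se["se_significant"].sum()),
            "se_gain": int((se["se_significant"] & (se["se_delta"] > 0)).sum()),
            "criteria_correlations": crit_corr,
        }

        stage = "power_calibration"
        spec = power.PowerSpec(
            alpha=config.alpha,
            n1=ds.group_size(ds.group1),
            n2=ds.group_size(ds.group2),
        )
        coverage = power.detectable_difference_coverage(ds, 0.10, spec)
        screen = power.normality_screen(ds, config.alpha)
        power_summary = pd.DataFrame(
            [
                {
                    "critical_rho_group1": power.correlation_critical_value(spec.n1),
                    "critical_rho_group2": power.correlation_critical_value(spec.n2),
                    "power_coverage_10pct": float(coverage["covered"].mean()),
                    "fraction_normal": screen["fraction_normal"],
                }
            ]
        )
        emit("power_summary.tsv", lambda p: io.write_table(power_summary, p, index=False))
        manifest["stages"]["power_calibration"] = power_summary.iloc[0].to_dict()

        stage = "coexpression_networks"
        corr1 = networks.group_correlation_matrix(ds, ds.group1, max_probes=config.max_probes)
        corr2 = networks.group_correlation_matrix(ds, ds.group2, max_probes=config.max_probes)
        nets1, table1 = networks.bin_networks(corr1, build="high")
        nets2, table2 = networks.bin_networks(corr2, build="high")
        emit("bin_counts_group1.tsv", lambda p: io.write_table(table1, p, index=False))
        emit("bin_counts_group2.tsv", lambda p: io.write_table(table2, p, index=False))
        summaries = []
        net_seed = _stage_seed(config.seed, 2)
        for label in ("(0.8,1]", "[-1,-0.8)"):
            for group, nets in ((ds.group1, nets1), (ds.group2, nets2)):
                g = nets[label]
                if g.number_of_nodes() == 0:
                    continue
                row = networks.graph_summary(g, seed=net_seed).to_dict()
                row.update(bin=label, group=group, specific=False)
                summaries.append(row)
                fname = f"network_{group}_{'pos' if label == '(0.8,1]' else 'neg'}.gexf"
                emit(fname, lambda p, g=g: networks.export_network(g, p, "gexf", seed=net_seed))
            sp1, sp2 = networks.specific_networks(nets1[label], nets2[label])
            for group, g in ((ds.group1, sp1), (ds.group2, sp2)):
                if g.number_of_nodes() == 0:
                    continue
                row = networks.graph_summary(g, seed=net_seed).to_dict()
                row.update(bin=label, group=group, specific=True)
                summaries.append(row)
        emit(
            "graph_summaries.tsv",
            lambda p: io.write_table(pd.DataFrame(summaries), p, index=False),
        )
        manifest["stages"]["coexpression_networks"] = {
            "total_pairs": int(table1["n_pairs"].sum()),
            "n_bins": len(table1),
        }

        stage = "differential_networks"
        diff_table, diff_graphs = networks.differential_edges(
            corr1, corr2, alphas=config.diffnet_alphas,
            significant_only=True, seed=_stage_seed(config.seed, 3),
        )
        emit("differential_edges.tsv", lambda p: io.write_table(diff_table, p, index=False))
        for alpha, g in diff_graphs.items():
            emit(
                f"differential_network_alpha{alpha:g}.gexf",
                lambda p, g=g: networks.export_network(g, p, "gexf"),
            )
        pdf = networks.correlation_difference_pdf(corr1, corr2)
        stable = networks.changed_corr_stable_mean_pairs(
            ds,
            subsample_size=config.stable_pair_subsample,
            alpha=config.alpha,
            seed=_stage_seed(config.seed, 4),
            max_probes=config.max_probes,
        )
        manifest["stages"]["differential_networks"] = {
            "significant_edges": {
                f"{a:g}": int(g.number_of_edges()) for a, g in diff_graphs.items()
            },
            "sd_group1": pdf.sd_group1,
            "sd_group2": pdf.sd_group2,
            "sd_diff": pdf.sd_diff,
            "covariance": pdf.covariance,
            "changed_corr_stable_mean": stable,
        }

        stage = "differential_mra"
        seeds = mra.classify_seed_pairs(corr1, corr2)
        mra_cfg = config.mra_config or mra.ScreenConfig(seed=_stage_seed(config.seed, 5))
        selected, counts = mra.screen_relations(ds, seeds, me, corr1, corr2, mra_cfg)
        emit("mra_selected.tsv", lambda p: io.write_table(selected, p, index=False))
        extrap = (
            mra.extrapolate_relation_counts(
                counts["selected_total"],
                counts["examined_total"],
                networks.pair_count(ds.n_probes) * max(ds.n_probes - 2, 1),
            )
            if counts["examined_total"]
            else None
        )
        manifest["stages"]["differential_mra"] = {
            "seed_pairs_per_class": seeds["class"].value_counts().to_dict(),
            **counts,
            "extrapolation": extrap,
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest["files"] = files
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["wall_time_s"] = round(time.time() - t0, 2)
    manifest["files"] = files + ["manifest.json"]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return RunResult(manifest=manifest, metrics=combined, bin_tables={"group1": table1, "group2": table2})
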