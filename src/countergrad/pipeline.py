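"""End-to-end orchestration: ingest -> filter -> aggregate -> model selection
-> contrasts -> Cov_GE, with reproducible outputs under a run directory."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from countergrad._version import __version__
from countergrad.core_data import (
    read_survival_csv,
    write_survival_csv,
    filter_by_weight,
    aggregate_to_replicates,
    write_summary_csv,
)
from countergrad.synth import preset_scenarios, simulate_dataset, config_to_dict
from countergrad.brglm import backward_select, estimate_dispersion
from countergrad.contrasts import run_contrast_battery
from countergrad.covge import run_covge_per_species, DEFAULT_PAIRING

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible run: exactly one of ``input_csv`` / ``scenario`` set."""

    input_csv: str | None = None
    scenario: str | None = None
    endpoint: str = "48h"
    max_weight_g: float = 1.0
    select_interactions: bool = True
    bh_m: int | None = None
    n_boot: int = 999
    n_perm: int = 999
    pairing: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PAIRING))
    sd_convention: str = "population"
    bootstrap_unit: str = "individual"
    seed: int = 0
    output_dir: str = "run_output"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.scenario is None):
            raise ValueError("set exactly one of input_csv / scenario")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and write all artifacts.

    Outputs under ``config.output_dir``: the individual records (synthetic
    runs), the replicate summary CSV, the model-selection trace, the fitted
    model summary, the contrast table, per-species Cov_GE JSON, and a run
    manifest (seed, version, config hash).  Reruns with the same config are
    deterministic.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "config_hash": config.config_hash()}
    t0 = time.time()

    stage = "ingest"
    try:
        ss = np.random.SeedSequence(config.seed)
        synth_seed, covge_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
        if config.scenario is not None:
            sim_cfg = preset_scenarios(config.scenario, seed=synth_seed)
            records = simulate_dataset(sim_cfg)
            report["simulation"] = config_to_dict(sim_cfg)
            write_survival_csv(records, out / "records.csv")
        else:
            records = read_survival_csv(config.input_csv)
        report["n_records"] = len(records)

        stage = "filter"
        records = filter_by_weight(records, config.max_weight_g)
        report["n_after_weight_filter"] = len(records)

        stage = "aggregate"
        summaries = aggregate_to_replicates(records, endpoint=config.endpoint)
        write_summary_csv(summaries, out / "replicate_summary.csv")
        report["n_replicates"] = len(summaries)

        stage = "model_selection"
        if config.select_interactions:
            best_spec, fit, trace = backward_select(summaries)
        else:
            from countergrad.brglm import full_factorial_spec, fit_brglm

            best_spec = full_factorial_spec(config.endpoint)
            fit = fit_brglm(best_spec, summaries)
            trace = []
        pd.DataFrame(trace).to_csv(out / "selection_trace.csv", index=False)
        fit.summary_frame().to_csv(out / "model_summary.csv", index=False)
        report["best_model"] = best_spec.formula_rhs
        report["aic"] = fit.aic
        report["phi"] = estimate_dispersion(fit) if fit.df_resid > 0 else None

        stage = "contrasts"
        table = run_contrast_battery(fit, m=config.bh_m)
        table.to_csv(out / "contrasts.csv", index=False)
        report["n_contrasts"] = len(table)
        report["contrast_directions"] = list(table["direction"])

        stage = "covge"
        results = run_covge_per_species(
            summaries,
            pairing=config.pairing,
            n_boot=config.n_boot,
            n_perm=config.n_perm,
            seed=covge_seed,
            sd_convention=config.sd_convention,
            bootstrap_unit=config.bootstrap_unit,
        )
        covge_dicts = [r.to_dict() for r in results]
        (out / "covge.json").write_text(json.dumps(covge_dicts, indent=2))
        pd.DataFrame(
            [{k: v for k, v in d.items() if k != "pairing"} for d in covge_dicts]
        ).to_csv(out / "covge.csv", index=False)
        report["covge"] = covge_dicts
    except Exception as exc:
        logger.error("pipeline aborted in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["elapsed_s"] = round(time.time() - t0, 3)
    report["version"] = __version__
    manifest = {
        "config": asdict(config),
        "config_hash": report["config_hash"],
        "seed": config.seed,
        "version": __version__,
        "best_model": report["best_model"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def summarize_figures(report: dict, output_dir: str | None = None) -> list[str]:
    """Survival-by-group panels (mean +/- SE per treatment, one per species)
    and per-species reaction norms across the two extreme environments.

    Plotting failures warn rather than abort.  Returns paths written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir or report["config"]["output_dir"])
    summary_path = out / "replicate_summary.csv"
    if not summary_path.exists():
        logger.warning("summarize_figures: no replicate summary at %s", summary_path)
        return []
    df = pd.read_csv(summary_path)
    written: list[str] = []
    species_list = sorted(df["species"].unique())
    try:
        fig, axes = plt.subplots(1, len(species_list), figsize=(4 * len(species_list), 3.2),
                                 sharey=True, squeeze=False)
        for ax, sp in zip(axes[0], species_list):
            sub = df[df["species"] == sp]
            for pop, marker in (("N", "o"), ("S", "s")):
                g = sub[sub["population"] == pop].groupby("treatment")["prop_surviving"]
                stats_ = g.agg(["mean", "sem", "count"]).reindex(["control", "heat", "cold"]).dropna()
                if stats_.empty:
                    logger.warning("summarize_figures: no data for %s/%s", sp, pop)
                    continue
                x = np.arange(len(stats_))
                ax.errorbar(x, stats_["mean"], yerr=stats_["sem"].fillna(0), marker=marker,
                            capsize=3, label=f"{pop}")
                ax.set_xticks(x, stats_.index)
            ax.set_title(sp)
            ax.set_ylim(-0.05, 1.05)
        axes[0][0].set_ylabel("proportion surviving")
        axes[0][-1].legend(title="population")
        fig.tight_layout()
        p = out / "survival_by_group.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(str(p))
    except Exception as exc:  # pragma: no cover - plotting is best-effort
        logger.warning("summarize_figures: survival panel failed: %s", exc)

    try:
        extremes = df[df["treatment"].isin(["heat", "cold"])]
        fig, axes = plt.subplots(1, len(species_list), figsize=(4 * len(species_list), 3.2),
                                 sharey=True, squeeze=False)
        for ax, sp in zip(axes[0], species_list):
            sub = extremes[extremes["species"] == sp]
            for pop in ("N", "S"):
                g = sub[sub["population"] == pop].groupby("treatment")["prop_surviving"].mean()
                g = g.reindex(["cold", "heat"]).dropna()
                ax.plot(np.arange(len(g)), g.values, marker="o", label=pop)
                ax.set_xticks(np.arange(len(g)), g.index)
            ax.set_title(sp)
            ax.set_ylim(-0.05, 1.05)
        axes[0][0].set_ylabel("proportion surviving")
        axes[0][-1].legend(title="population")
        fig.tight_layout()
        p = out / "reaction_norms.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(str(p))
    except Exception as exc:  # pragma: no cover
        logger.warning("summarize_figures: reaction-norm panel failed: %s", exc)
    return written
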