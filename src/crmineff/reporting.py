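"""Experiment driver and report rendering (tables and plots).

``run_experiment`` simulates every (design, scenario) cell of a run
configuration and writes, per scenario, an operating-characteristics
table (one row block per design: mean participants per dose, then the
selection distribution under each criterion), a summary-measure table,
and adaptive-vs-benchmark difference tables.  Plots mirror the two
standard views: per-measure differences against the fixed benchmark and
stacked allocation at the target and higher doses.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .config import RunConfig
from .engine import OperatingCharacteristics, simulate_design
from .metrics import design_difference, summary_measures
from .scenarios import Scenario, default_bank

__all__ = ["run_experiment", "render_tables", "render_plots", "table_frame"]

log = logging.getLogger("crmineff")


def run_experiment(config: RunConfig) -> dict[tuple[str, str], OperatingCharacteristics]:
    """Simulate the full design x scenario grid and write all reports.

    Per-cell failures are logged and skipped so one bad cell does not
    abort the run.
    """
    bank = default_bank()
    model = config.model_spec()
    designs = config.design_specs()
    results: dict[tuple[str, str], OperatingCharacteristics] = {}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s_name in config.scenarios:
        scenario = bank[s_name]
        for token, design in designs.items():
            log.info("simulating %s under %s (n=%d)", token, s_name, config.n_realisations)
            try:
                results[(token, s_name)] = simulate_design(
                    design, scenario, model, config.n_realisations, config.seed
                )
            except Exception:
                log.exception("cell (%s, %s) failed; continuing", token, s_name)
    config.to_yaml(out / "config.yaml")
    with open(out / "operating_characteristics.json", "w") as fh:
        json.dump(
            {f"{tok}|{sc}": oc.to_dict() for (tok, sc), oc in results.items()}, fh, indent=1
        )
    render_tables(results, bank, out)
    if config.make_plots:
        render_plots(results, bank, out)
    return results


def load_results(out_dir) -> dict[tuple[str, str], OperatingCharacteristics]:
    path = Path(out_dir) / "operating_characteristics.json"
    if not path.exists():
        raise FileNotFoundError(f"no saved results at {path}")
    with open(path) as fh:
        raw = json.load(fh)
    return {tuple(key.split("|")): OperatingCharacteristics.from_dict(d) for key, d in raw.items()}


def table_frame(
    ocs: list[OperatingCharacteristics], scenario: Scenario
) -> pd.DataFrame:
    """Operating-characteristics table for one scenario, one row block per design."""
    doses = sorted(scenario.probs)
    columns = ["none"] + [f"{d} mg" for d in doses] + ["N ineffective", "N below target"]
    rows, index = [], []
    truth = [""] + [f"{scenario.probs[d]:.2f}" for d in doses] + ["", ""]
    rows.append(truth)
    index.append(("True inefficacy", ""))
    for oc in ocs:
        alloc = [""] + [f"{oc.n_per_dose.get(d, 0.0):.2f}" for d in doses]
        below = "" if oc.n_below_target is None else f"{oc.n_below_target:.2f}"
        rows.append(alloc + [f"{oc.n_ineffective:.2f}", below])
        index.append((oc.design, "N per dose"))
        for crit, sel in oc.p_select.items():
            row = [f"{sel.get(None, 0.0):.2f}"] + [f"{sel.get(d, 0.0):.2f}" for d in doses]
            rows.append(row + ["", ""])
            index.append((oc.design, f"P(selection) - {crit}"))
    return pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index), columns=columns)


def render_tables(results, bank, out_dir) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not results:
        return []
    written = []
    scenarios = sorted({sc for _, sc in results})
    summary_rows = []
    for sc in scenarios:
        scenario = bank[sc]
        ocs = [results[(tok, s)] for (tok, s) in results if s == sc]
        frame = table_frame(ocs, scenario)
        path = out / f"operating_characteristics_{sc}.csv"
        frame.to_csv(path)
        written.append(path)
        for oc in ocs:
            for crit in oc.p_select:
                sm = summary_measures(oc, scenario, crit)
                summary_rows.append(
                    {"scenario": sc, "design": oc.design, "criterion": crit, **sm.as_dict()}
                )
    summary = pd.DataFrame(summary_rows)
    path = out / "summary_measures.csv"
    summary.to_csv(path, index=False)
    written.append(path)

    # adaptive-vs-benchmark differences (benchmark is rule-based)
    diff_rows = []
    for sc in scenarios:
        scenario = bank[sc]
        bench_oc = next(
            (results[(tok, s)] for (tok, s) in results if s == sc and tok == "fixed"), None
        )
        if bench_oc is None:
            continue
        bench = summary_measures(bench_oc, scenario, "rule")
        for (tok, s), oc in results.items():
            if s != sc or tok == "fixed":
                continue
            for crit in oc.p_select:
                diff = design_difference(summary_measures(oc, scenario, crit), bench)
                diff_rows.append({"scenario": sc, "design": oc.design, "criterion": crit, **diff})
    if diff_rows:
        path = out / "design_differences.csv"
        pd.DataFrame(diff_rows).to_csv(path, index=False)
        written.append(path)
    return written


def render_plots(results, bank, out_dir) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not results:
        return []
    written = []
    scenarios = sorted({sc for _, sc in results})

    # differences vs the fixed benchmark, one panel per summary measure
    diff_rows = []
    for sc in scenarios:
        scenario = bank[sc]
        bench_oc = next(
            (results[(tok, s)] for (tok, s) in results if s == sc and tok == "fixed"), None
        )
        if bench_oc is None:
            continue
        bench = summary_measures(bench_oc, scenario, "rule")
        for (tok, s), oc in results.items():
            if s != sc or tok == "fixed":
                continue
            for crit in oc.p_select:
                diff = design_difference(summary_measures(oc, scenario, crit), bench)
                diff_rows.append({"scenario": sc, "design": oc.design, "criterion": crit, **diff})
    if diff_rows:
        frame = pd.DataFrame(diff_rows)
        measures = ["sm1", "sm2", "sm3", "sm4", "wsm"]
        fig, axes = plt.subplots(1, len(measures), figsize=(4 * len(measures), 4), sharey=True)
        markers = {"rule": "o", "model": "^"}
        for ax, m in zip(axes, measures):
            for (design, crit), sub in frame.groupby(["design", "criterion"]):
                ax.plot(
                    sub["scenario"], sub[m], markers[crit], label=f"{design} ({crit})", alpha=0.7
                )
            ax.axhline(0.0, color="grey", lw=0.8)
            ax.set_title(m.upper())
            ax.tick_params(axis="x", rotation=60)
        axes[0].set_ylabel("adaptive minus benchmark")
        axes[-1].legend(fontsize=7)
        fig.tight_layout()
        path = out / "design_differences.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    # stacked allocation at the target and higher doses
    targeted = [sc for sc in scenarios if bank[sc].target_mg is not None]
    if targeted:
        fig, axes = plt.subplots(1, len(targeted), figsize=(3.2 * len(targeted), 4), sharey=True)
        if len(targeted) == 1:
            axes = [axes]
        for ax, sc in zip(axes, targeted):
            scenario = bank[sc]
            target = scenario.target_mg
            ocs = [(tok, results[(tok, s)]) for (tok, s) in results if s == sc]
            labels = [oc.design for _, oc in ocs]
            bottoms = [0.0] * len(ocs)
            for dose in sorted(d for d in scenario.probs if d >= target):
                heights = [oc.n_per_dose.get(dose, 0.0) for _, oc in ocs]
                ax.bar(labels, heights, bottom=bottoms, label=f"{dose} mg")
                bottoms = [b + h for b, h in zip(bottoms, heights)]
            ax.set_title(sc)
            ax.tick_params(axis="x", rotation=45)
        axes[0].set_ylabel("mean participants at target and higher doses")
        axes[-1].legend(fontsize=7)
        fig.tight_layout()
        path = out / "allocation_target_and_higher.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
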