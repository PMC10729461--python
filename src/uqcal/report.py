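"""Report assembly: run every metric on a dataset, render JSON/markdown/plots.

A :class:`MetricReport` is a pure function of (input data, config): one
top-level seed is streamed deterministically to every randomised
sub-computation, so the same input and config always reproduce the same
report bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import calibration, metrics
from .binning import BinnedCalibration, error_based_calibration
from .calibration import CalibrationCurve, IntervalTestResult
from .dataset import UQDataset
from .metrics import SimulatedReference

__all__ = [
    "ReportConfig",
    "MetricReport",
    "evaluate_all",
    "render_report",
    "load_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ReportConfig:
    """All knobs a report depends on; echoed verbatim into the report."""

    bin_size: int = 250
    reps: int = 1000
    level: float = 0.95
    curve_grid: int = 100
    seed: int = 0

    def child_seeds(self) -> dict[str, int]:
        """Deterministic per-subcomputation seeds streamed from the top seed."""
        names = ["rho_sim", "nll_sim", "var_z", "mean_z", "bin_ci"]
        state = np.random.SeedSequence(self.seed).generate_state(len(names))
        return {name: int(s % (2**31)) for name, s in zip(names, state)}


@dataclass(frozen=True)
class MetricReport:
    """Every validation metric for one dataset, plus the config that made it."""

    rho_rank: float
    rho_rank_sim: SimulatedReference
    nll: float
    nll_sim: SimulatedReference
    a_mis: float
    curve: CalibrationCurve
    var_z: IntervalTestResult
    mean_z: IntervalTestResult
    error_calibration: BinnedCalibration
    config: ReportConfig


def evaluate_all(data: UQDataset, config: ReportConfig = ReportConfig()) -> MetricReport:
    """Compute the full metric tuple for one dataset.

    Emits a warning (but proceeds) when the dataset holds fewer than two
    bins' worth of samples, since a one-bin error-based fit is impossible.
    """
    if data.n < 2 * config.bin_size:
        warnings.warn(
            f"dataset has {data.n} samples; at least {2 * config.bin_size} "
            "recommended for the error-based calibration fit",
            stacklevel=2,
        )
    seeds = config.child_seeds()
    z = data.z_scores()
    curve = calibration.calibration_curve(z, grid_size=config.curve_grid)
    bin_size = min(config.bin_size, data.n)
    return MetricReport(
        rho_rank=metrics.spearman_rank(data.absolute_errors(), data.uncertainties),
        rho_rank_sim=metrics.simulate_reference(
            data.uncertainties, "spearman", reps=config.reps, seed=seeds["rho_sim"]
        ),
        nll=metrics.nll(data),
        nll_sim=metrics.simulate_reference(
            data.uncertainties, "nll", reps=config.reps, seed=seeds["nll_sim"]
        ),
        a_mis=calibration.miscalibration_area(curve),
        curve=curve,
        var_z=calibration.z_variance_test(
            z, level=config.level, reps=config.reps, seed=seeds["var_z"]
        ),
        mean_z=calibration.z_mean_test(
            z, level=config.level, reps=config.reps, seed=seeds["mean_z"]
        ),
        error_calibration=error_based_calibration(
            data,
            bin_size=bin_size,
            with_ci=True,
            level=config.level,
            reps=config.reps,
            seed=seeds["bin_ci"],
        ),
        config=config,
    )


def _report_to_dict(report: MetricReport) -> dict:
    ec = report.error_calibration
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "rho_rank": report.rho_rank,
        "rho_rank_sim": dataclasses.asdict(report.rho_rank_sim),
        "nll": report.nll,
        "nll_sim": dataclasses.asdict(report.nll_sim),
        "a_mis": report.a_mis,
        "calibration_curve": {
            "expected": report.curve.expected_fractions.tolist(),
            "observed": report.curve.observed_fractions.tolist(),
        },
        "var_z": dataclasses.asdict(report.var_z),
        "mean_z": dataclasses.asdict(report.mean_z),
        "error_calibration": {
            "fit": dataclasses.asdict(ec.fit) if ec.fit is not None else None,
            "bins": [
                {
                    "n": b.n,
                    "rmv": b.rmv,
                    "rmse": b.rmse,
                    "rmse_ci": list(b.rmse_ci) if b.rmse_ci is not None else None,
                }
                for b in ec.bins
            ],
        },
        "config": dataclasses.asdict(report.config),
    }


def _markdown_table(report: MetricReport) -> str:
    fit = report.error_calibration.fit
    r2, a, b = (
        (f"{fit.r_squared:.2f}", f"{fit.slope:.2f}", f"{fit.intercept:.2f}")
        if fit is not None
        else ("-", "-", "-")
    )
    rows = [
        "| R^2 | a | b | rho_rank | rho_rank_sim | A_mis | NLL | NLL_sim |",
        "|---|---|---|---|---|---|---|---|",
        f"| {r2} | {a} | {b} | {report.rho_rank:.2f} | {report.rho_rank_sim} "
        f"| {report.a_mis:.2f} | {report.nll:.2f} | {report.nll_sim} |",
    ]
    lines = ["# Uncertainty validation report", "", *rows, ""]
    for name, test in (("Var(Z) =? 1", report.var_z), ("mu(Z) =? 0", report.mean_z)):
        verdict = "pass" if test.passed else "FAIL"
        lines.append(
            f"- {name}: {test.estimate:.3f}, {test.level:.0%} CI "
            f"[{test.ci_low:.3f}, {test.ci_high:.3f}] -> {verdict}"
        )
    lines.append(
        f"- rho_rank z-distance from simulated: "
        f"{report.rho_rank_sim.z_distance(report.rho_rank):+.1f} sd"
    )
    lines.append(
        f"- NLL z-distance from simulated: "
        f"{report.nll_sim.z_distance(report.nll):+.1f} sd"
    )
    return "\n".join(lines) + "\n"


def _plot_error_calibration(report: MetricReport, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ec = report.error_calibration
    rmv, rmse = ec.rmv, ec.rmse
    fig, ax = plt.subplots(figsize=(5, 5))
    has_ci = all(b.rmse_ci is not None for b in ec.bins)
    if has_ci:
        yerr = np.array(
            [[b.rmse - b.rmse_ci[0] for b in ec.bins],
             [b.rmse_ci[1] - b.rmse for b in ec.bins]]
        )
        ax.errorbar(rmv, rmse, yerr=yerr, fmt="o", capsize=3, label="bins (95% CI)")
    else:
        ax.plot(rmv, rmse, "o", label="bins")
    lims = [0.0, float(max(rmv.max(), rmse.max()) * 1.05)]
    ax.plot(lims, lims, "k--", label="identity")
    if ec.fit is not None:
        xs = np.array(lims)
        ax.plot(
            xs,
            ec.fit.slope * xs + ec.fit.intercept,
            "-",
            label=(
                f"fit: a={ec.fit.slope:.2f}, b={ec.fit.intercept:.2f}, "
                f"R$^2$={ec.fit.r_squared:.2f}"
            ),
        )
    ax.set_xlabel("RMV")
    ax.set_ylabel("RMSE")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_calibration_curve(report: MetricReport, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(report.curve.expected_fractions, report.curve.observed_fractions,
            label=f"calibration curve (A_mis={report.a_mis:.3f})")
    ax.plot([0, 1], [0, 1], "k--", label="perfect calibration")
    ax.set_xlabel("expected fraction of |Z|")
    ax.set_ylabel("observed fraction of |Z|")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_report(
    report: MetricReport, out_dir, formats=("json", "markdown", "plots")
) -> list[Path]:
    """Write the report as JSON / markdown / plot files; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(formats) - {"json", "markdown", "plots"}
    if unknown:
        raise ValueError(f"unknown formats: {sorted(unknown)}")
    written: list[Path] = []
    if "json" in formats:
        p = out / "report.json"
        p.write_text(json.dumps(_report_to_dict(report), indent=2) + "\n")
        written.append(p)
    if "markdown" in formats:
        p = out / "report.md"
        p.write_text(_markdown_table(report))
        written.append(p)
    if "plots" in formats:
        p1 = out / "error_calibration.png"
        _plot_error_calibration(report, p1)
        p2 = out / "calibration_curve.png"
        _plot_calibration_curve(report, p2)
        written.extend([p1, p2])
    return written


def load_report(path) -> dict:
    """Read a JSON report back; rejects unknown schema versions loudly."""
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != REPORT_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema version {version!r}; "
            f"this build reads version {REPORT_SCHEMA_VERSION}"
        )
    return payload
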