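"""End-to-end runner: data (read or simulated) -> exclusions -> all seven
analyses per group -> report bundle on disk.

Stage failures are caught and recorded so one degenerate group cannot
abort the rest of the run; the resulting bundle is marked partial.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from udsamp import __version__, analyses as an
from udsamp.glmm import FitResult
from udsamp.io import fingerprint, read_control_table, read_trial_table
from udsamp.simulate import SimulationConfig, simulate_experiment, substream

__all__ = ["PipelineConfig", "ReportBundle", "run_full_pipeline",
           "write_report", "ANALYSIS_NAMES"]

ANALYSIS_NAMES = (
    "overall_accuracy",
    "confidence_accuracy",
    "preferential_sampling",
    "chance_corrected_beta",
    "sampling_accuracy_preregistered",
    "sampling_accuracy_posthoc",
    "sampling_interaction",
)


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible pipeline run.

    Exactly one of (``records_path`` + ``controls_path``) or
    ``simulation`` must be supplied.
    """

    records_path: str | None = None
    controls_path: str | None = None
    simulation: SimulationConfig | None = None
    groups: tuple[str, ...] | None = None
    n_perm: int = 1000
    n_boot: int = 1000
    seed: int | None = None
    exclusion_threshold: int = 5
    out_dir: str = "udsamp_reports"
    verbose: bool = False

    def validate(self) -> None:
        has_paths = self.records_path is not None
        if has_paths != (self.controls_path is not None):
            raise ValueError(
                "records_path and controls_path must be supplied together")
        if has_paths == (self.simulation is not None):
            raise ValueError(
                "supply either input paths or a simulation config, not both")
        if self.seed is None:
            raise ValueError("a master seed is required (permutations, "
                             "bootstrap and simulation are stochastic)")

    def payload(self) -> dict:
        d = {
            "records_path": self.records_path,
            "controls_path": self.controls_path,
            "simulation": (self.simulation.to_dict()
                           if self.simulation else None),
            "groups": self.groups,
            "n_perm": self.n_perm,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "exclusion_threshold": self.exclusion_threshold,
            "version": __version__,
        }
        return d


@dataclass
class ReportBundle:
    reports: dict[str, dict[str, an.AnalysisReport]]
    errors: dict[str, dict[str, str]]
    exclusion_log: pd.DataFrame
    fingerprint: str
    seed: int
    partial: bool

    def report(self, group: str, analysis: str) -> an.AnalysisReport:
        return self.reports[group][analysis]


def _stage_seed(master: int, group: str, analysis: str) -> int:
    return int(substream(master, "analysis", group, analysis)
               .integers(0, 2**31 - 1))


def run_full_pipeline(config: PipelineConfig) -> ReportBundle:
    """Apply exclusions, then run every analysis for every group."""
    config.validate()
    if config.simulation is not None:
        records, controls = simulate_experiment(config.simulation)
    else:
        records = read_trial_table(config.records_path)
        controls = read_control_table(config.controls_path)

    scores, included = an.score_controls_and_exclude(
        controls, threshold=config.exclusion_threshold)
    exclusion_log = pd.DataFrame(
        [{"participant_id": s.participant_id, "score": s.score,
          "excluded": s.excluded} for s in scores])
    kept = an.apply_exclusions(records, included)

    groups = (tuple(config.groups) if config.groups
              else tuple(pd.unique(records["age_group"])))
    reports: dict[str, dict[str, an.AnalysisReport]] = {}
    errors: dict[str, dict[str, str]] = {}
    for group in groups:
        reports[group] = {}
        errors[group] = {}
        present = (kept["age_group"] == group).any()
        n_excluded_in_group = int(
            records.loc[~records["participant_id"].isin(included)
                        & (records["age_group"] == group),
                        "participant_id"].nunique())

        def run(name, fn):
            try:
                if not present:
                    raise ValueError(f"no data for group {group!r}")
                rep = fn()
                rep.n_removed += n_excluded_in_group
                reports[group][name] = rep
            except Exception as exc:  # recorded, never fatal
                errors[group][name] = f"{type(exc).__name__}: {exc}"
                if config.verbose:
                    traceback.print_exc()

        seed = config.seed
        run("overall_accuracy",
            lambda: an.run_overall_accuracy(
                kept, group, n_boot=config.n_boot,
                seed=_stage_seed(seed, group, "overall_boot")))
        run("confidence_accuracy",
            lambda: an.run_confidence_accuracy(
                kept, group,
                include_random_slopes=not group.lower().startswith("adult"),
                n_boot=config.n_boot,
                seed=_stage_seed(seed, group, "confidence_boot")))
        run("preferential_sampling",
            lambda: an.run_preferential_sampling(
                kept, group, n_perm=config.n_perm,
                seed=_stage_seed(seed, group, "permutation")))
        run("chance_corrected_beta",
            lambda: an.run_chance_corrected_beta(kept, group))
        run("sampling_accuracy_preregistered",
            lambda: an.run_sampling_accuracy(kept, group, "preregistered"))
        run("sampling_accuracy_posthoc",
            lambda: an.run_sampling_accuracy(kept, group, "posthoc"))
        run("sampling_interaction",
            lambda: an.run_sampling_interaction(kept, group))

    partial = any(errors[g] for g in errors)
    return ReportBundle(
        reports=reports,
        errors=errors,
        exclusion_log=exclusion_log,
        fingerprint=fingerprint(config.payload()),
        seed=config.seed,
        partial=partial,
    )


# ---------------------------------------------------------------------------
# serialization


def _fit_rows(name: str, fit: FitResult):
    for term, est in fit.estimates.items():
        yield {"fit": name, "kind": "fixed", "term": term, "estimate": est,
               "se": fit.standard_errors.get(term)}
    for factor, cov in fit.varcomps.items():
        cov = np.atleast_2d(cov)
        for i in range(cov.shape[0]):
            yield {"fit": name, "kind": "varcomp",
                   "term": f"{factor}[{i},{i}]", "estimate": cov[i, i],
                   "se": None}
    yield {"fit": name, "kind": "loglik", "term": "loglik",
           "estimate": fit.loglik, "se": None}
    yield {"fit": name, "kind": "flag", "term": "converged",
           "estimate": float(fit.converged), "se": None}
    yield {"fit": name, "kind": "flag", "term": "singular",
           "estimate": float(fit.singular), "se": None}


def report_frame(rep: an.AnalysisReport) -> pd.DataFrame:
    """Flatten one analysis report into a machine-readable table."""
    rows = []
    for name, fit in rep.fits.items():
        rows.extend(_fit_rows(name, fit))
    for name, test in rep.tests.items():
        rows.append({"fit": name, "kind": f"test:{test.method}",
                     "term": name, "estimate": test.statistic,
                     "se": None, "p": test.p_value, "df": test.df})
    for name, value in rep.fitted_values.items():
        rows.append({"fit": "fitted", "kind": "fitted", "term": name,
                     "estimate": value, "se": None})
    if rep.intervals is not None:
        for term, (lo, hi) in rep.intervals.intervals.items():
            rows.append({"fit": "bootstrap", "kind": "interval",
                         "term": term, "estimate": None, "se": None,
                         "lower": lo, "upper": hi})
    if rep.permutation is not None:
        rows.append({"fit": "permutation", "kind": "permutation",
                     "term": "abs_estimate",
                     "estimate": rep.permutation.observed_statistic,
                     "p": rep.permutation.p_value, "se": None})
    df = pd.DataFrame(rows)
    df.insert(0, "analysis", rep.analysis)
    df.insert(1, "group", rep.group)
    df["n_included"] = rep.n_included
    df["n_removed"] = rep.n_removed
    return df


def write_report(bundle: ReportBundle, path) -> list[Path]:
    """Write one CSV per analysis per group plus a combined summary.

    Returns the list of files written.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    lines = [
        "# Analysis report",
        "",
        f"- config fingerprint: `{bundle.fingerprint}`",
        f"- master seed: {bundle.seed}",
        f"- partial: {bundle.partial}",
        "",
        "## Exclusions",
        "",
        f"{int(bundle.exclusion_log['excluded'].sum())} of "
        f"{len(bundle.exclusion_log)} participants excluded "
        "(control score below threshold).",
        "",
    ]
    for group, reps in bundle.reports.items():
        lines.append(f"## Group {group}")
        lines.append("")
        for name in ANALYSIS_NAMES:
            if name in reps:
                rep = reps[name]
                fname = f"{group}__{name}.csv".replace("/", "-")
                fpath = out / fname
                report_frame(rep).to_csv(fpath, index=False)
                written.append(fpath)
                lines.append(f"### {name}")
                lines.append("")
                lines.append(f"- n_included={rep.n_included}, "
                             f"n_removed={rep.n_removed}")
                for tname, t in rep.tests.items():
                    lines.append(
                        f"- {tname}: statistic={t.statistic:.3f} "
                        f"p={t.p_value:.4g} ({t.method})")
                for vname, v in rep.fitted_values.items():
                    lines.append(f"- {vname}: {v:.3f}")
                for note in rep.notes:
                    lines.append(f"- note: {note}")
                lines.append(f"- table: `{fname}`")
                lines.append("")
            elif name in bundle.errors.get(group, {}):
                lines.append(f"### {name}: FAILED")
                lines.append("")
                lines.append(f"- {bundle.errors[group][name]}")
                lines.append("")
    if bundle.partial:
        lines.append("## Failed stages")
        lines.append("")
        for group, errs in bundle.errors.items():
            for name, msg in errs.items():
                lines.append(f"- {group}/{name}: {msg}")
        lines.append("")
    summary = out / "summary.md"
    summary.write_text("\n".join(lines), encoding="utf-8")
    written.append(summary)
    (out / "bundle.json").write_text(json.dumps({
        "fingerprint": bundle.fingerprint,
        "seed": bundle.seed,
        "partial": bundle.partial,
        "errors": bundle.errors,
        "files": [p.name for p in written],
    }, indent=2), encoding="utf-8")
    bundle.exclusion_log.to_csv(out / "exclusions.csv", index=False)
    return written
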