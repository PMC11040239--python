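"""Analysis stages for the sampling experiment.

Covers the control-trial exclusion filter, the two-column sampling-matrix
construction, the four planned mixed-model analyses (overall accuracy,
confidence-accuracy, preferential sampling with a within-participant
permutation test, sampling-proportion effect on accuracy) and the post-hoc
analyses (chance-corrected beta regression, unknown-denominator accuracy
model, sampling x judgement interaction).

All analyses operate on one age group at a time; groups are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from udsamp import glmm
from udsamp.beta import fit_beta_glm
from udsamp.bootstrap import IntervalSet, parametric_bootstrap_ci
from udsamp.glmm import (
    FitResult,
    ModelSpec,
    NonEstimableError,
    TestResult,
    fit_logistic_mixed,
    likelihood_ratio_test,
    logit,
    refit,
    wald_test,
    z_standardize,
)

__all__ = [
    "ControlScore",
    "PermutationResult",
    "AnalysisReport",
    "ExclusionSignal",
    "score_controls_and_exclude",
    "build_sampling_matrix",
    "chance_corrected_response",
    "run_overall_accuracy",
    "run_confidence_accuracy",
    "permutation_test_sampling",
    "run_preferential_sampling",
    "run_chance_corrected_beta",
    "run_sampling_accuracy",
    "run_sampling_interaction",
    "CHANCE_LOGIT",
]

#: chance level for one target among six alternatives, in link space
CHANCE_LOGIT = logit(1.0 / 6.0)

N_SAMPLING_CHOICES = 3
N_OBJECTS = 6

_PERM_FAILURE_FRACTION = 0.10


class ExclusionSignal(ValueError):
    """A participant cannot contribute to this analysis by construction."""


@dataclass(frozen=True)
class ControlScore:
    participant_id: str
    score: int
    excluded: bool


@dataclass
class PermutationResult:
    """Within-participant permutation distribution of |fixed effect|."""

    observed_statistic: float
    permuted_statistics: np.ndarray
    p_value: float
    n_perm: int
    n_failed: int
    seed: int | None
    observed_fit: FitResult | None = None


@dataclass
class AnalysisReport:
    """Fits, tests and bookkeeping for one analysis on one group."""

    analysis: str
    group: str
    fits: dict[str, FitResult] = field(default_factory=dict)
    tests: dict[str, TestResult] = field(default_factory=dict)
    n_included: int = 0
    n_removed: int = 0
    notes: list[str] = field(default_factory=list)
    fitted_values: dict[str, float] = field(default_factory=dict)
    intervals: IntervalSet | None = None
    permutation: PermutationResult | None = None

    @property
    def n_total(self) -> int:
        return self.n_included + self.n_removed


# ---------------------------------------------------------------------------
# exclusion filter


def score_controls_and_exclude(controls: pd.DataFrame, threshold: int = 5
                               ) -> tuple[list[ControlScore], set[str]]:
    """Score the familiar/unfamiliar control judgements per participant.

    Score = familiar items judged known + unfamiliar items judged unknown
    (0-9); a participant scoring below ``threshold`` is excluded.
    """
    scores: list[ControlScore] = []
    included: set[str] = set()
    for pid, sub in controls.groupby("participant_id", sort=True):
        fam = sub[sub["item_class"] == "familiar"]
        unf = sub[sub["item_class"] == "unfamiliar"]
        if len(sub) != 9 or len(fam) != 5 or len(unf) != 4:
            raise ValueError(
                f"participant {pid!r} has {len(fam)} familiar and "
                f"{len(unf)} unfamiliar control rows (need 5 + 4)"
            )
        score = int((fam["judged_known"] == 1).sum()
                    + (unf["judged_known"] == 0).sum())
        excluded = score < threshold
        scores.append(ControlScore(str(pid), score, excluded))
        if not excluded:
            included.add(str(pid))
    return scores, included


def apply_exclusions(records: pd.DataFrame, included: set[str]
                     ) -> pd.DataFrame:
    return records[records["participant_id"].isin(included)].copy()


# ---------------------------------------------------------------------------
# response construction


def build_sampling_matrix(records: pd.DataFrame,
                          n_choices: int = N_SAMPLING_CHOICES
                          ) -> pd.DataFrame:
    """Two-column response: (times sampled, ``n_choices`` - times sampled).

    One row per participant x object, carrying that object's knowledge
    judgement as the predictor.
    """
    sums = records.groupby("participant_id")["times_sampled"].sum()
    bad = sums[sums != n_choices]
    if len(bad):
        raise ValueError(
            "sampling counts must sum to "
            f"{n_choices} per participant; violated by: "
            + ", ".join(repr(p) for p in bad.index.tolist())
        )
    out = records[["participant_id", "object_id", "times_sampled",
                   "knowledge_judgement"]].copy()
    out["times_not_sampled"] = n_choices - out["times_sampled"]
    return out[["participant_id", "object_id", "times_sampled",
                "times_not_sampled", "knowledge_judgement"]]


def chance_corrected_response(judgements: Sequence[int],
                              sampled_objects: Iterable[int],
                              n_choices: int = N_SAMPLING_CHOICES) -> float:
    """Chance-corrected uncertainty-sampling score in (0, 1).

    ``judgements`` is the per-object knowledge judgement (1 = known) and
    ``sampled_objects`` the distinct indices of sampled objects.  The score
    is::

        (u_sampled / min(u_avail, n_choices) - u_avail / n_objects) / 2 + 0.5

    with u_sampled the number of distinct judged-unknown objects sampled
    and u_avail the number of judged-unknown objects.  It equals 0.5 when
    unknown objects are sampled exactly at chance.  Participants who judged
    every object known, or every object unknown, carry no information and
    raise :class:`ExclusionSignal`.
    """
    j = np.asarray(judgements, dtype=int)
    n_objects = j.size
    sampled = set(int(s) for s in sampled_objects)
    if not sampled <= set(range(n_objects)):
        raise ValueError("sampled_objects must be valid object indices")
    u_avail = int((j == 0).sum())
    if u_avail == 0 or u_avail == n_objects:
        raise ExclusionSignal(
            "participant judged all objects known or all unknown"
        )
    u_sampled = sum(1 for s in sampled if j[s] == 0)
    prop_sampled = u_sampled / min(u_avail, n_choices)
    prop_avail = u_avail / n_objects
    return (prop_sampled - prop_avail) / 2.0 + 0.5


# ---------------------------------------------------------------------------
# planned analyses


def _group_records(records: pd.DataFrame, group: str) -> pd.DataFrame:
    sub = records[records["age_group"] == group]
    if len(sub) == 0:
        raise ValueError(f"no records for group {group!r}")
    return sub.copy()


def _drop_singular_slopes(spec: ModelSpec, table: pd.DataFrame,
                          notes: list[str], fast: bool = False) -> FitResult:
    """Fit, dropping random slopes one at a time while the fit is singular
    or non-convergent; every drop is recorded in ``notes``.
    """
    fit = fit_logistic_mixed(spec, table, fast=fast)
    while (fit.singular or not fit.converged) and not fit.separation:
        sloped = [(g, s) for g, s in spec.random_terms if s]
        if not sloped:
            break
        g_drop, _ = sloped[-1]
        new_terms = tuple(
            (g, () if g == g_drop else s) for g, s in spec.random_terms
        )
        notes.append(
            f"random slope within {g_drop!r} dropped "
            "(singular or non-convergent fit)"
        )
        spec = ModelSpec(response=spec.response, fixed_terms=spec.fixed_terms,
                         random_terms=new_terms, family=spec.family)
        fit = fit_logistic_mixed(spec, table, fast=fast)
    return fit


def run_overall_accuracy(records: pd.DataFrame, group: str,
                         n_boot: int = 0, seed: int | None = None,
                         fast: bool = False) -> AnalysisReport:
    """Intercept-only accuracy model with a Wald comparison against the
    one-in-six chance level in link space.
    """
    sub = _group_records(records, group)
    n_part = sub["participant_id"].nunique()
    if n_part < 2:
        raise ValueError("overall accuracy needs at least 2 participants")
    report = AnalysisReport(analysis="overall_accuracy", group=group,
                            n_included=n_part)
    spec = ModelSpec(response="test_correct",
                     random_terms=(("participant_id", ()), ("object_id", ())))
    fit = fit_logistic_mixed(spec, sub, fast=fast)
    report.fits["accuracy"] = fit
    if fit.separation or not fit.converged:
        report.notes.append("model non-estimable (separation or no "
                            "convergence); no chance comparison performed")
        return report
    report.tests["intercept_vs_chance"] = wald_test(
        fit, "intercept", reference_value=CHANCE_LOGIT)
    report.fitted_values["p_correct"] = glmm.inv_logit(
        fit.estimates["intercept"])
    if n_boot > 0:
        report.intervals = parametric_bootstrap_ci(
            fit, n_boot=n_boot, seed=seed,
            fitted_points={"p_correct": {}})
    return report


def run_confidence_accuracy(records: pd.DataFrame, group: str,
                            include_random_slopes: bool = True,
                            n_boot: int = 0, seed: int | None = None
                            ) -> AnalysisReport:
    """Confidence-rating model with an LRT for the accuracy fixed effect.

    ``include_random_slopes`` follows the per-group convention (slopes of
    accuracy within participant and object for children; the adult model
    omits the participant slope).  Singular slope terms are dropped and
    recorded.
    """
    sub = _group_records(records, group)
    report = AnalysisReport(analysis="confidence_accuracy", group=group,
                            n_included=sub["participant_id"].nunique())
    if sub["confidence_rating"].nunique() < 2:
        report.notes.append("constant confidence rating: non-estimable")
        return report
    p_slopes = ("test_correct",) if include_random_slopes else ()
    spec = ModelSpec(
        response="confidence_rating", fixed_terms=("test_correct",),
        random_terms=(("participant_id", p_slopes),
                      ("object_id", ("test_correct",))),
    )
    fit = _drop_singular_slopes(spec, sub, report.notes)
    report.fits["confidence"] = fit
    if fit.separation:
        report.notes.append("separation: no finite estimate for the "
                            "accuracy effect")
        return report
    # the reduced model must not carry a slope of the dropped fixed effect
    reduced_spec = ModelSpec(
        response="confidence_rating",
        random_terms=tuple((g, ()) for g, _ in fit.spec.random_terms),
    )
    fit_reduced = fit_logistic_mixed(reduced_spec, sub)
    report.fits["confidence_reduced"] = fit_reduced
    report.tests["accuracy_lrt"] = likelihood_ratio_test(fit, fit_reduced)
    b0, b1 = fit.estimates["intercept"], fit.estimates["test_correct"]
    report.fitted_values["p_sure_given_correct"] = glmm.inv_logit(b0 + b1)
    report.fitted_values["p_sure_given_incorrect"] = glmm.inv_logit(b0)
    if n_boot > 0:
        report.intervals = parametric_bootstrap_ci(
            fit, n_boot=n_boot, seed=seed,
            fitted_points={
                "p_sure_given_correct": {"test_correct": 1.0},
                "p_sure_given_incorrect": {"test_correct": 0.0},
            })
    return report


def _sampling_spec(participant_slope: bool) -> ModelSpec:
    p_slopes = ("knowledge_judgement",) if participant_slope else ()
    return ModelSpec(
        response=("times_sampled", "times_not_sampled"),
        fixed_terms=("knowledge_judgement",),
        random_terms=(("participant_id", p_slopes),
                      ("object_id", ("knowledge_judgement",))),
    )


def permutation_test_sampling(sampling_rows: pd.DataFrame,
                              n_perm: int = 1000,
                              seed: int | None = None,
                              participant_slope: bool = False,
                              n_choices: int = N_SAMPLING_CHOICES
                              ) -> PermutationResult:
    """Within-participant permutation test of the judgement effect.

    The (sampled, not-sampled) response pairs are shuffled across each
    participant's objects while the judgement column stays fixed, the
    two-column mixed model is refitted, and |judgement estimate| serves as
    the statistic.  The observed arrangement counts as one of ``n_perm``
    permutations, so the p-value can never drop below ``1 / n_perm``.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be at least 2")
    pids = sampling_rows["participant_id"].to_numpy()
    if len(set(pids)) < 2:
        raise ValueError("permutation test needs at least 2 participants")
    per_part = sampling_rows.groupby("participant_id")["knowledge_judgement"]
    if not (per_part.nunique() > 1).any():
        raise ValueError(
            "knowledge judgement is constant within every participant"
        )

    spec = _sampling_spec(participant_slope)
    model = glmm.MixedLogitModel(spec, sampling_rows)
    fit = model.fit(fast=True)
    if not fit.converged:
        raise RuntimeError("observed-data sampling model did not converge")
    observed = abs(fit.estimates["knowledge_judgement"])

    # per-participant row index blocks, shuffled as units
    order = {}
    for pid in pids:
        order.setdefault(pid, [])
    positions = {pid: np.flatnonzero(pids == pid) for pid in order}
    totals = {pid: sampling_rows["times_sampled"].to_numpy()[idx].sum()
              for pid, idx in positions.items()}

    rng = np.random.default_rng(seed)
    y0 = sampling_rows["times_sampled"].to_numpy(dtype=float)
    stats = [observed]
    n_failed = 0
    y_orig = model.y.copy()
    try:
        for _ in range(n_perm - 1):
            y_perm = y0.copy()
            for pid, idx in positions.items():
                y_perm[idx] = y_perm[rng.permutation(idx)]
                assert y_perm[idx].sum() == totals[pid]
            f = refit(fit, y_perm, fast=True)
            if not f.converged:
                n_failed += 1
                continue
            stats.append(abs(f.estimates["knowledge_judgement"]))
    finally:
        model.set_response(y_orig)

    if n_failed > _PERM_FAILURE_FRACTION * n_perm:
        raise RuntimeError(
            f"{n_failed}/{n_perm - 1} permutation refits failed to converge"
        )
    arr = np.asarray(stats, dtype=float)
    p = float(np.sum(arr >= observed - 1e-12) / arr.size)
    return PermutationResult(observed_statistic=float(observed),
                             permuted_statistics=arr, p_value=p,
                             n_perm=n_perm, n_failed=n_failed, seed=seed,
                             observed_fit=fit)


def run_preferential_sampling(records: pd.DataFrame, group: str,
                              n_perm: int = 1000, seed: int | None = None,
                              participant_slope: bool | None = None,
                              fast: bool = False) -> AnalysisReport:
    """Two-column sampling model: naive Wald p next to the permutation p.

    ``participant_slope`` adds the judgement random slope within
    participant (the adult-group convention); when None it is inferred
    from the group label.
    """
    sub = _group_records(records, group)
    if participant_slope is None:
        participant_slope = group.lower().startswith("adult")
    report = AnalysisReport(analysis="preferential_sampling", group=group,
                            n_included=sub["participant_id"].nunique())
    rows = build_sampling_matrix(sub)
    if rows["knowledge_judgement"].nunique() < 2:
        report.notes.append("knowledge judgement constant: non-estimable")
        return report

    spec = _sampling_spec(participant_slope)
    fit = _drop_singular_slopes(spec, rows, report.notes, fast=fast)
    report.fits["sampling"] = fit
    if fit.separation or "knowledge_judgement" in fit.non_estimable:
        report.notes.append("judgement effect non-estimable")
        return report
    report.tests["judgement_wald_naive"] = wald_test(fit,
                                                     "knowledge_judgement")
    perm = permutation_test_sampling(
        rows, n_perm=n_perm, seed=seed,
        participant_slope=any(
            g == "participant_id" and len(s) > 0
            for g, s in fit.spec.random_terms),
    )
    report.permutation = perm
    report.tests["judgement_permutation"] = TestResult(
        statistic=perm.observed_statistic, df=None,
        p_value=perm.p_value, method="permutation")
    est = fit.estimates["knowledge_judgement"]
    report.notes.append(
        "judgement coded 0 = 'don't know', 1 = 'know'; estimate "
        f"{est:+.3f} means judged-known objects were "
        f"{'more' if est > 0 else 'less'} likely to be sampled"
    )
    report.fitted_values["p_sample_known"] = glmm.inv_logit(
        fit.estimates["intercept"] + est)
    report.fitted_values["p_sample_unknown"] = glmm.inv_logit(
        fit.estimates["intercept"])
    return report


# ---------------------------------------------------------------------------
# post-hoc analyses


def _per_participant(records: pd.DataFrame):
    for pid, sub in records.groupby("participant_id", sort=True):
        sub = sub.sort_values("object_id")
        yield pid, sub


def run_chance_corrected_beta(records: pd.DataFrame, group: str
                              ) -> AnalysisReport:
    """Intercept-only beta regression of the chance-corrected sampling
    score, tested against 0 in link space (= chance).
    """
    sub = _group_records(records, group)
    report = AnalysisReport(analysis="chance_corrected_beta", group=group)
    responses = []
    for pid, part in _per_participant(sub):
        j = part["knowledge_judgement"].to_numpy()
        sampled = np.flatnonzero(part["times_sampled"].to_numpy() > 0)
        try:
            responses.append(chance_corrected_response(j, sampled))
            report.n_included += 1
        except ExclusionSignal:
            report.n_removed += 1
    if report.n_included < 5:
        raise ValueError(
            f"only {report.n_included} participants have an informative "
            "chance-corrected response (need at least 5)"
        )
    table = pd.DataFrame({"score": responses})
    fit = fit_beta_glm(table, "score")
    report.fits["beta"] = fit
    report.tests["intercept_vs_chance"] = wald_test(fit, "intercept",
                                                    reference_value=0.0)
    report.fitted_values["mean_score"] = glmm.inv_logit(
        fit.estimates["intercept"])
    report.notes.append(
        f"{report.n_removed} participant(s) removed (all labels judged "
        "known or all judged unknown)"
    )
    return report


def run_sampling_accuracy(records: pd.DataFrame, group: str,
                          mode: str = "preregistered",
                          fast: bool = False) -> AnalysisReport:
    """Effect of the (z-scored) proportion of unknown objects sampled on
    test accuracy.

    preregistered mode: predictor = unknown objects sampled / 3.
    posthoc mode: predictor = unique unknown objects sampled / unknown
    objects available, dropping participants with no unknown objects.
    """
    if mode not in ("preregistered", "posthoc"):
        raise ValueError("mode must be 'preregistered' or 'posthoc'")
    sub = _group_records(records, group)
    report = AnalysisReport(analysis=f"sampling_accuracy_{mode}", group=group)

    per_part: dict[str, float] = {}
    for pid, part in _per_participant(sub):
        j = part["knowledge_judgement"].to_numpy()
        ts = part["times_sampled"].to_numpy()
        if mode == "preregistered":
            per_part[pid] = float(ts[j == 0].sum()) / N_SAMPLING_CHOICES
            report.n_included += 1
        else:
            u_avail = int((j == 0).sum())
            if u_avail == 0:
                report.n_removed += 1
                continue
            u_sampled = int(((ts > 0) & (j == 0)).sum())
            per_part[pid] = u_sampled / u_avail
            report.n_included += 1

    kept = sub[sub["participant_id"].isin(per_part)].copy()
    raw = kept["participant_id"].map(per_part).to_numpy(dtype=float)
    try:
        z_by_pid = dict(zip(sorted(per_part),
                            z_standardize([per_part[p]
                                           for p in sorted(per_part)])))
    except NonEstimableError:
        report.notes.append("proportion-sampled predictor is constant "
                            "after exclusions: non-estimable")
        return report
    kept["prop_unknown_sampled_z"] = kept["participant_id"].map(z_by_pid)

    spec = ModelSpec(
        response="test_correct", fixed_terms=("prop_unknown_sampled_z",),
        random_terms=(("participant_id", ()),
                      ("object_id", ("prop_unknown_sampled_z",))),
    )
    fit = _drop_singular_slopes(spec, kept, report.notes, fast=fast)
    report.fits["accuracy"] = fit
    if fit.separation:
        report.notes.append("separation: slope non-estimable")
        return report
    report.tests["slope_wald"] = wald_test(fit, "prop_unknown_sampled_z")
    if mode == "posthoc":
        report.notes.append(
            f"{report.n_removed} participant(s) removed (no objects judged "
            "unknown)"
        )
    return report


def run_sampling_interaction(records: pd.DataFrame, group: str
                             ) -> AnalysisReport:
    """Accuracy ~ sampling count x knowledge judgement with null and
    reduced model comparisons.
    """
    sub = _group_records(records, group)
    report = AnalysisReport(analysis="sampling_interaction", group=group,
                            n_included=sub["participant_id"].nunique())
    random_terms = (("participant_id", ()), ("object_id", ()))

    if sub["times_sampled"].nunique() < 2:
        report.notes.append("sampling count constant: sampling terms "
                            "non-estimable")
        return report
    if sub["knowledge_judgement"].nunique() < 2:
        report.notes.append("knowledge judgement constant: judgement and "
                            "interaction terms non-estimable")
        return report

    full_spec = ModelSpec(
        response="test_correct",
        fixed_terms=("times_sampled", "knowledge_judgement",
                     "times_sampled:knowledge_judgement"),
        random_terms=random_terms)
    null_spec = ModelSpec(response="test_correct",
                          fixed_terms=("knowledge_judgement",),
                          random_terms=random_terms)
    reduced_spec = ModelSpec(
        response="test_correct",
        fixed_terms=("times_sampled", "knowledge_judgement"),
        random_terms=random_terms)

    fit_full = fit_logistic_mixed(full_spec, sub)
    fit_null = fit_logistic_mixed(null_spec, sub)
    fit_reduced = fit_logistic_mixed(reduced_spec, sub)
    report.fits.update(full=fit_full, null=fit_null, reduced=fit_reduced)

    inter = "times_sampled:knowledge_judgement"
    if inter in fit_full.non_estimable or fit_full.separation:
        report.notes.append("interaction term non-estimable")
    else:
        report.tests["interaction_wald"] = wald_test(fit_full, inter)
        report.tests["interaction_lrt"] = likelihood_ratio_test(
            fit_full, fit_reduced)
    if not (fit_full.separation or fit_null.separation):
        report.tests["sampling_lrt_full_vs_null"] = likelihood_ratio_test(
            fit_full, fit_null)
    if not fit_reduced.separation:
        report.tests["sampling_wald_reduced"] = wald_test(
            fit_reduced, "times_sampled")

    if not fit_full.separation:
        b = fit_full.estimates
        for know in (0, 1):
            for samp in (0, 1):
                eta = (b["intercept"] + b["times_sampled"] * samp
                       + b["knowledge_judgement"] * know + b[inter]
                       * samp * know)
                label = (f"p_correct_{'known' if know else 'unknown'}_"
                         f"{'sampled' if samp else 'unsampled'}")
                cell = sub[(sub["knowledge_judgement"] == know)
                           & ((sub["times_sampled"] > 0) == bool(samp))]
                if len(cell) == 0:
                    report.notes.append(f"no data in cell {label}: fitted "
                                        "value extrapolated")
                report.fitted_values[label] = glmm.inv_logit(eta)
    return report
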