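"""Longitudinal phenotype stability.

Subjects classified at each follow-up visit (with the 7-variable Model B,
since blood eosinophils and PC20 are unavailable longitudinally) are
compared with their original baseline phenotype assignment: per-visit
discordance fractions, transition tables, and a per-baseline-phenotype
Pearson contingency coefficient ``C = sqrt(chi2 / (chi2 + n))`` summarizing
within-subject consistency of the classified phenotype across visits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from phenoclust.classify import ClassifierModel, classify_cohort
from phenoclust.preprocess import transform_variables


def longitudinal_classify(
    model: ClassifierModel,
    records: pd.DataFrame,
    visits: list[str] | None = None,
) -> pd.DataFrame:
    """Classify each subject at each visit; returns a tidy calls frame.

    A subject missing any model variable at a visit is excluded at that
    visit only.  Columns: subject_id, visit, call, max_probability.
    """
    if visits is None:
        visits = list(dict.fromkeys(records["visit"]))
    if not visits:
        raise ValueError("no visits to classify")
    frames = []
    for visit in visits:
        sub = records[records["visit"] == visit]
        if sub.empty:
            continue
        fm = transform_variables(sub, model.var_names)
        res = classify_cohort(model, fm)
        frames.append(pd.DataFrame({
            "subject_id": list(res.subject_ids),
            "visit": visit,
            "call": res.calls,
            "max_probability": res.max_probability,
        }))
    if not frames:
        raise ValueError("no classifiable subject-visits")
    return pd.concat(frames, ignore_index=True)


def discordance(calls: pd.DataFrame, reference: pd.Series) -> pd.Series:
    """Per-visit fraction of subjects whose call differs from baseline.

    ``reference`` maps subject_id -> baseline phenotype.  Only subjects
    classified at the visit and present in the reference contribute.
    """
    out = {}
    for visit, grp in calls.groupby("visit", sort=False):
        shared = grp[grp["subject_id"].isin(reference.index)]
        if shared.empty:
            raise ValueError(f"no shared subjects at visit {visit!r}")
        ref = reference.loc[shared["subject_id"]].to_numpy().astype(str)
        out[visit] = float((shared["call"].to_numpy().astype(str) != ref).mean())
    return pd.Series(out, name="discordance")


def contingency_coefficient(table: np.ndarray) -> float:
    """Pearson contingency coefficient ``sqrt(chi2/(chi2+n))`` of a table.

    Zero-margin rows/columns are dropped (with a warning) before the
    chi-square statistic is computed without continuity correction.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("need a nonnegative 2-d count table")
    n = t.sum()
    if n <= 0:
        raise ValueError("all-zero table")
    rows = t.sum(axis=1) > 0
    cols = t.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        t = t[np.ix_(rows, cols)]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0
    chi2 = stats.chi2_contingency(t, correction=False).statistic
    return float(np.sqrt(chi2 / (chi2 + n)))


@dataclass
class StabilityReport:
    """Longitudinal stability summary relative to baseline phenotypes."""

    per_visit_discordance: pd.Series
    per_phenotype_coefficient: dict[str, float]
    transition_tables: dict[str, pd.DataFrame]   # visit -> baseline x call counts
    n_no_followup: int

    def to_dict(self) -> dict:
        return {
            "per_visit_discordance": {k: float(v) for k, v in
                                      self.per_visit_discordance.items()},
            "per_phenotype_coefficient": self.per_phenotype_coefficient,
            "transition_tables": {v: t.to_dict() for v, t in
                                  self.transition_tables.items()},
            "n_no_followup": self.n_no_followup,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_markdown(self) -> str:
        lines = ["# Longitudinal stability", "", "## Per-visit discordance", ""]
        for visit, frac in self.per_visit_discordance.items():
            lines.append(f"- {visit}: {100 * frac:.1f}% discordant")
        lines += ["", "## Within-subject consistency (Pearson contingency coefficient)", ""]
        for pheno, c in self.per_phenotype_coefficient.items():
            lines.append(f"- baseline {pheno}: C = {c:.2f}")
        lines += ["", "## Transition counts (baseline phenotype x classified phenotype)", ""]
        for visit, table in self.transition_tables.items():
            lines += [f"### {visit}", "", table.to_markdown(), ""]
        if self.n_no_followup:
            lines.append(f"\n{self.n_no_followup} subject(s) had no classifiable follow-up visit.")
        return "\n".join(lines)


def stability_report(
    calls: pd.DataFrame,
    baseline_assignments: pd.Series,
    baseline_visit: str = "baseline",
) -> StabilityReport:
    """Assemble discordance, transitions and per-phenotype coefficients.

    The per-baseline-phenotype coefficient is computed from that stratum's
    (visit x classified phenotype) count table over follow-up visits.
    """
    followup = calls[calls["visit"] != baseline_visit]
    disc = discordance(calls, baseline_assignments)

    phenos = sorted(baseline_assignments.astype(str).unique())
    coeffs: dict[str, float] = {}
    for pheno in phenos:
        members = baseline_assignments.index[baseline_assignments.astype(str) == pheno]
        sub = followup[followup["subject_id"].isin(members)]
        if sub.empty:
            coeffs[pheno] = float("nan")
            continue
        table = pd.crosstab(sub["visit"], sub["call"]).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coeffs[pheno] = contingency_coefficient(table)

    transitions: dict[str, pd.DataFrame] = {}
    for visit, grp in followup.groupby("visit", sort=False):
        shared = grp[grp["subject_id"].isin(baseline_assignments.index)]
        ref = baseline_assignments.loc[shared["subject_id"]].astype(str).to_numpy()
        transitions[visit] = pd.crosstab(
            pd.Series(ref, name="baseline"),
            pd.Series(shared["call"].to_numpy(), name="classified"),
        )

    with_followup = set(followup["subject_id"])
    n_missing = int(sum(1 for s in baseline_assignments.index if s not in with_followup))
    return StabilityReport(
        per_visit_discordance=disc,
        per_phenotype_coefficient=coeffs,
        transition_tables=transitions,
        n_no_followup=n_missing,
    )
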