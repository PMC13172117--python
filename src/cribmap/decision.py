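"""Active-surveillance decision scenarios and outcome accounting.

Patients are stratified by Cambridge Prognostic Group (CPG), computed from
PSA, biopsy grade group (GG) and clinical T-stage.  Three allocation
scenarios are simulated:

* ``reference``  — guideline benchmark: CPG-1 to active surveillance (AS),
  everyone else to active treatment (AT); the model is never consulted.
* ``cpg12``      — CPG-1 to AS automatically; CPG-2 routed by the model
  (AT iff patient score strictly exceeds the threshold, else AS).
* ``cpg123gg2``  — as above, with CPG-3 patients whose biopsy GG is 2 also
  routed by the model.

Against prostatectomy ground truth, every allocation lands in one of six
mutually exclusive outcome categories.  An AS allocation is appropriate only
for cribriform-negative patients with prostatectomy GG < 3; an AT allocation
is appropriate for any patient with adverse histology (cribriform growth or
GG >= 3).  Undertreatment is the sum of the three false-AS categories, with
cribriform misses split at a focus-diameter cutoff (default 1.5 mm, the
approximate MRI detectability limit); overtreatment is false AT.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .types import PatientRecord

__all__ = [
    "OutcomeCategory",
    "Allocation",
    "ScenarioResult",
    "SCENARIOS",
    "assign_cpg",
    "select_cohort",
    "allocate",
    "categorize",
    "run_scenario",
    "plot_scenario",
]

SCENARIOS = ("reference", "cpg12", "cpg123gg2")


class OutcomeCategory(Enum):
    """The six allocation-outcome categories (exhaustive, exclusive)."""

    correct_AS = "correct_AS"
    correct_AT = "correct_AT"
    false_AS_crib_small = "false_AS_crib_small"  # missed cribriform < cutoff
    false_AS_crib_large = "false_AS_crib_large"  # missed cribriform >= cutoff
    false_AS_gg3 = "false_AS_gg3"  # cribriform-negative but GG >= 3 in AS
    false_AT = "false_AT"  # no adverse histology, still treated


#: Categories counted as undertreatment (inappropriately in AS).
UNDERTREATMENT = (
    OutcomeCategory.false_AS_crib_small,
    OutcomeCategory.false_AS_crib_large,
    OutcomeCategory.false_AS_gg3,
)


@dataclass
class Allocation:
    patient_id: str
    arm: str  # "AS" | "AT"
    source: str  # "rule_cpg1" | "model" | "rule_reference"


def assign_cpg(psa: float, biopsy_gg: int, clinical_t_stage: int) -> int:
    """Five-tier Cambridge Prognostic Group from PSA, biopsy GG and T-stage.

    CPG-1: GG1, PSA < 10, T1-2.  CPG-2: T1-2, GG <= 2 and exactly one of
    {GG2, PSA 10-20}.  CPG-3: T1-2 and (GG2 with PSA 10-20, or GG3 with
    PSA <= 20).  CPG-4: exactly one of {GG4, PSA > 20, T3}.  CPG-5: two or
    more of those, or GG5, or T4.
    """
    if psa <= 0:
        raise ValueError("PSA must be positive")
    if biopsy_gg not in (1, 2, 3, 4, 5):
        raise ValueError("biopsy GG must be 1-5")
    if clinical_t_stage not in (1, 2, 3, 4):
        raise ValueError("clinical T-stage must be 1-4")

    gg, t = biopsy_gg, clinical_t_stage
    psa_mid = 10 <= psa <= 20
    n_adverse = int(gg == 4) + int(psa > 20) + int(t == 3)
    if gg == 5 or t == 4 or n_adverse >= 2:
        return 5
    if n_adverse == 1:
        return 4
    # from here: gg <= 3, psa <= 20, t <= 2
    if gg == 3:
        return 3
    if gg == 2 and psa_mid:
        return 3
    if (gg == 2) != psa_mid:  # exactly one intermediate factor
        return 2
    return 1


def select_cohort(records, which: str):
    """Filter records to a scenario cohort.

    ``"cpg12"`` keeps CPG-1 and CPG-2; ``"cpg123gg2"`` additionally keeps
    CPG-3 patients whose biopsy GG is 2.
    """
    if which not in ("cpg12", "cpg123gg2"):
        raise ValueError("cohort must be 'cpg12' or 'cpg123gg2'")
    out = []
    for r in records:
        cpg = r.cpg or assign_cpg(r.psa, r.biopsy_gg, r.clinical_t_stage)
        if cpg in (1, 2):
            out.append(r)
        elif which == "cpg123gg2" and cpg == 3 and r.biopsy_gg == 2:
            out.append(r)
    return out


def allocate(
    records,
    scores: dict[str, float] | None,
    scenario: str,
    threshold: float = 0.5,
) -> list[Allocation]:
    """Assign each patient to AS or AT under one scenario.

    ``scores`` maps patient_id to the patient-level probability score; it may
    be None for the reference scenario (which ignores the model entirely).
    Model-routed patients go to AT iff their score strictly exceeds the
    threshold.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    out = []
    for r in records:
        cpg = r.cpg or assign_cpg(r.psa, r.biopsy_gg, r.clinical_t_stage)
        if cpg == 1:
            out.append(Allocation(r.patient_id, "AS", "rule_cpg1"))
        elif scenario == "reference":
            out.append(Allocation(r.patient_id, "AT", "rule_reference"))
        else:
            if scores is None or r.patient_id not in scores:
                raise ValueError(
                    f"patient {r.patient_id} is model-routed but has no score"
                )
            arm = "AT" if scores[r.patient_id] > threshold else "AS"
            out.append(Allocation(r.patient_id, arm, "model"))
    return out


def categorize(
    record: PatientRecord,
    allocation: Allocation,
    size_cutoff_mm: float = 1.5,
) -> OutcomeCategory:
    """Outcome category of one allocation against prostatectomy ground truth."""
    adverse_gg = record.prostatectomy_gg >= 3
    if allocation.arm == "AS":
        if record.crib_positive:
            if record.max_crib_diameter_mm < size_cutoff_mm:
                return OutcomeCategory.false_AS_crib_small
            return OutcomeCategory.false_AS_crib_large
        return OutcomeCategory.false_AS_gg3 if adverse_gg else OutcomeCategory.correct_AS
    # AT arm
    if record.crib_positive or adverse_gg:
        return OutcomeCategory.correct_AT
    return OutcomeCategory.false_AT


@dataclass
class ScenarioResult:
    """Outcome accounting of one scenario at one threshold."""

    scenario: str
    threshold: float | None
    n: int
    counts: dict[OutcomeCategory, int]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n:
            raise ValueError("category counts must partition the cohort")

    def pct(self, category: OutcomeCategory) -> float:
        return 100.0 * self.counts[category] / self.n

    @property
    def undertreatment_n(self) -> int:
        return sum(self.counts[c] for c in UNDERTREATMENT)

    @property
    def undertreatment_pct(self) -> float:
        return 100.0 * self.undertreatment_n / self.n

    @property
    def overtreatment_pct(self) -> float:
        return self.pct(OutcomeCategory.false_AT)

    @property
    def appropriate_pct(self) -> float:
        return self.pct(OutcomeCategory.correct_AS) + self.pct(OutcomeCategory.correct_AT)

    @property
    def as_eligible_pct(self) -> float:
        n_as = (
            self.counts[OutcomeCategory.correct_AS]
            + sum(self.counts[c] for c in UNDERTREATMENT)
        )
        return 100.0 * n_as / self.n

    def to_row(self) -> dict:
        row = {
            "scenario": self.scenario,
            "threshold": self.threshold,
            "n": self.n,
        }
        for cat in OutcomeCategory:
            row[cat.value] = self.counts[cat]
            row[cat.value + "_pct"] = round(self.pct(cat), 1)
        row["appropriate_pct"] = round(self.appropriate_pct, 1)
        row["undertreatment_pct"] = round(self.undertreatment_pct, 1)
        row["overtreatment_pct"] = round(self.overtreatment_pct, 1)
        row["as_eligible_pct"] = round(self.as_eligible_pct, 1)
        return row


def run_scenario(
    records,
    scores: dict[str, float] | None,
    scenario: str,
    thresholds=None,
    size_cutoff_mm: float = 1.5,
) -> list[ScenarioResult]:
    """Allocate and categorise a cohort over a threshold grid.

    ``records`` must already be the scenario cohort (see
    :func:`select_cohort`).  The reference scenario is threshold-independent
    and always yields a single result.
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    by_id = {r.patient_id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate patient ids in cohort")

    if scenario == "reference":
        grid = [None]
    else:
        if thresholds is None:
            raise ValueError("model scenarios need a threshold grid")
        grid = sorted(float(t) for t in np.atleast_1d(thresholds))

    results = []
    for thr in grid:
        allocs = allocate(records, scores, scenario, threshold=0.0 if thr is None else thr)
        counts = {cat: 0 for cat in OutcomeCategory}
        for a in allocs:
            counts[categorize(by_id[a.patient_id], a, size_cutoff_mm)] += 1
        results.append(ScenarioResult(scenario, thr, len(records), counts))
    return results


# colour palette mirroring the clinical stacked-bar convention
_PALETTE = {
    OutcomeCategory.correct_AS: "#4daf4a",  # green
    OutcomeCategory.correct_AT: "#984ea3",  # purple
    OutcomeCategory.false_AS_crib_small: "#ffffb3",  # light yellow
    OutcomeCategory.false_AS_crib_large: "#ffd92f",  # dark yellow
    OutcomeCategory.false_AS_gg3: "#c9a227",  # mustard
    OutcomeCategory.false_AT: "#ff7f00",  # orange
}


def plot_scenario(results: list[ScenarioResult], ax=None):
    """Stacked-bar chart of outcome-category percentages per threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * len(results), 4))
    xs = range(len(results))
    bottom = np.zeros(len(results))
    for cat in OutcomeCategory:
        vals = np.array([r.pct(cat) for r in results])
        ax.bar(xs, vals, bottom=bottom, color=_PALETTE[cat], label=cat.value, width=0.8)
        bottom += vals
    ax.set_xticks(list(xs))
    ax.set_xticklabels(
        ["ref" if r.threshold is None else f"{r.threshold:.2f}" for r in results],
        rotation=90,
    )
    ax.set_ylabel("% of cohort")
    ax.set_xlabel("probability threshold")
    ax.set_title(results[0].scenario if results else "")
    ax.legend(fontsize=7, loc="center left", bbox_to_anchor=(1.0, 0.5))
    return ax
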