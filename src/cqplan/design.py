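"""Replicate-allocation planning under a monetary budget.

Given pilot estimates of the step noise, a balanced sampling plan —
``n_subjects`` biological subjects per condition, ``n_sampling`` RNA
extractions per subject, ``n_rt`` RTs per extraction, ``n_qpcr`` qPCRs
per RT — has an expected variance of the group-mean Cq of

    sigma_Cqg^2 = [ v_i / n_i  +  v_j / (n_i n_j)  +  v_k / (n_i n_j n_k) ]
                  / n_subjects  (+ v_subject / n_subjects)

where v_i, v_j, v_k are the variance-scale step components: replicating
a step averages out its own noise and the noise of everything
downstream of it.  The optimizer enumerates all balanced integer plans
whose total cost fits a budget and returns the one minimizing this
variance.

Step-noise inputs must declare their scale.  Published step summaries
are sometimes tabulated as SDs but used in the planning arithmetic
directly as variance-scale values; ``StepNoise.from_values(...,
scale=...)`` squares SD inputs on ingest and records the declaration so
every report can echo it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .anova import VarianceComponents


class InfeasibleError(ValueError):
    """No plan satisfies the constraints within the budget."""


@dataclass(frozen=True, order=True)
class SamplingPlan:
    """Balanced replicate counts: subjects x extractions x RTs x qPCRs."""

    n_subjects: int
    n_sampling: int
    n_rt: int
    n_qpcr: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")

    @property
    def total_replicates(self) -> int:
        """Total qPCR reactions per condition."""
        return self.n_subjects * self.n_sampling * self.n_rt * self.n_qpcr


@dataclass(frozen=True)
class StepNoise:
    """Variance-scale step components used by the planning calculus.

    ``scale_declared`` records whether the caller supplied SDs (squared
    on ingest) or variance-scale values (used directly); ``subject`` is
    an optional between-subject component, default 0.
    """

    sampling: float
    rt: float
    qpcr: float
    subject: float = 0.0
    scale_declared: str = "variance"

    def __post_init__(self) -> None:
        for name in ("sampling", "rt", "qpcr", "subject"):
            if getattr(self, name) < 0:
                raise ValueError(f"step component {name!r} must be >= 0")

    @classmethod
    def from_values(
        cls,
        sampling: float,
        rt: float,
        qpcr: float,
        scale: str,
        subject: float = 0.0,
    ) -> "StepNoise":
        """Build from values declared as ``'sd'`` or ``'variance'``."""
        if scale == "sd":
            return cls(sampling**2, rt**2, qpcr**2, subject**2, "sd")
        if scale == "variance":
            return cls(sampling, rt, qpcr, subject, "variance")
        raise ValueError(f"scale must be 'sd' or 'variance', got {scale!r}")

    @classmethod
    def from_components(cls, vc: VarianceComponents, subject_sd: float = 0.0) -> "StepNoise":
        """Adopt estimated variance components (already variance scale)."""
        return cls(vc.var_sampling, vc.var_rt, vc.var_qpcr, subject_sd**2, "variance")


@dataclass(frozen=True)
class CostModel:
    """Per-unit monetary costs of each workflow level."""

    subject: float
    sampling: float
    rt: float
    qpcr: float

    def __post_init__(self) -> None:
        if any(c < 0 for c in (self.subject, self.sampling, self.rt, self.qpcr)):
            raise ValueError("costs must be >= 0")


@dataclass
class OptimizationConstraints:
    """Search-space constraints for :func:`optimize_plan`.

    ``budget`` is the total across all conditions.  ``min_subjects``
    defaults to 3 — fewer than three biological replicates per
    condition is below accepted practice for drawing biological
    conclusions, and a plan optimizer should not recommend it.  Upper
    bounds default to whatever the budget allows; a level with zero
    marginal cost needs an explicit bound.
    """

    budget: float
    n_conditions: int = 1
    min_subjects: int = 3
    max_subjects: int | None = None
    max_sampling: int | None = None
    max_rt: int | None = None
    max_qpcr: int | None = None

    def __post_init__(self) -> None:
        if self.budget <= 0:
            raise ValueError("budget must be > 0")
        if self.n_conditions < 1 or self.min_subjects < 1:
            raise ValueError("n_conditions and min_subjects must be >= 1")


@dataclass
class PlanEvaluation:
    """A plan together with its predicted variance and cost."""

    plan: SamplingPlan
    group_variance: float
    total_cost: float | None = None
    reactions_per_condition: int = 0

    def as_dict(self) -> dict:
        return {
            "n_subjects": self.plan.n_subjects,
            "n_sampling": self.plan.n_sampling,
            "n_rt": self.plan.n_rt,
            "n_qpcr": self.plan.n_qpcr,
            "total_replicates": self.plan.total_replicates,
            "group_variance": self.group_variance,
            "total_cost": self.total_cost,
            "reactions_per_condition": self.reactions_per_condition,
        }


def plan_variance(noise: StepNoise, plan: SamplingPlan) -> float:
    """Expected variance of the group-mean Cq under a balanced plan.

    Each step's variance is divided by the number of independent
    realizations of that step contributing to the group mean, and the
    whole technical part again by the subject count.
    """
    ni, nj, nk = plan.n_sampling, plan.n_rt, plan.n_qpcr
    step_part = (
        noise.sampling / ni
        + noise.rt / (ni * nj)
        + noise.qpcr / (ni * nj * nk)
    )
    return (step_part + noise.subject) / plan.n_subjects


def plan_cost(plan: SamplingPlan, costs: CostModel, n_conditions: int = 1) -> float:
    """Total monetary cost of running a plan across all conditions."""
    per_subject = costs.subject + plan.n_sampling * (
        costs.sampling + plan.n_rt * (costs.rt + plan.n_qpcr * costs.qpcr)
    )
    return n_conditions * plan.n_subjects * per_subject


def evaluate_plan(
    noise: StepNoise,
    plan: SamplingPlan,
    costs: CostModel | None = None,
    n_conditions: int = 1,
) -> PlanEvaluation:
    return PlanEvaluation(
        plan=plan,
        group_variance=plan_variance(noise, plan),
        total_cost=plan_cost(plan, costs, n_conditions) if costs else None,
        reactions_per_condition=plan.total_replicates,
    )


def rank_plans(
    noise: StepNoise,
    plans: list[SamplingPlan],
    costs: CostModel | None = None,
    n_conditions: int = 1,
) -> list[PlanEvaluation]:
    """Evaluate plans and sort by predicted group variance, ascending."""
    evals = [evaluate_plan(noise, p, costs, n_conditions) for p in plans]
    evals.sort(key=lambda e: (e.group_variance,
                              e.total_cost if e.total_cost is not None else 0.0,
                              e.reactions_per_condition,
                              e.plan))
    return evals


def frontier_frame(evals: list[PlanEvaluation]) -> pd.DataFrame:
    """Tabulate evaluations in the conventional planning-table layout."""
    rows = [e.as_dict() for e in evals]
    df = pd.DataFrame(rows)
    cols = ["total_replicates", "n_subjects", "n_sampling", "n_rt", "n_qpcr",
            "group_variance", "total_cost"]
    return df[cols]


def _marginal_cost_bounds(
    costs: CostModel, constraints: OptimizationConstraints
) -> tuple[int, int, int, int]:
    """Per-level upper bounds implied by the budget, or explicit caps."""
    per_condition = constraints.budget / constraints.n_conditions

    def bound(explicit: int | None, marginal: float, floor_cost: float) -> int:
        if explicit is not None:
            return explicit
        if marginal <= 0:
            raise ValueError(
                "a level with zero marginal cost needs an explicit upper "
                "bound (otherwise its replicate count is unbounded)"
            )
        return max(1, int((per_condition - floor_cost) // marginal) + 1)

    # cheapest possible surroundings: one replicate everywhere else
    min_plan_wo_subject = costs.sampling + costs.rt + costs.qpcr
    b_subj = bound(
        constraints.max_subjects,
        costs.subject + min_plan_wo_subject,
        0.0,
    )
    floor = constraints.min_subjects * costs.subject
    b_samp = bound(constraints.max_sampling,
                   constraints.min_subjects * (costs.sampling + costs.rt + costs.qpcr),
                   floor)
    b_rt = bound(constraints.max_rt,
                 constraints.min_subjects * (costs.rt + costs.qpcr),
                 floor)
    b_q = bound(constraints.max_qpcr,
                constraints.min_subjects * costs.qpcr,
                floor)
    return b_subj, b_samp, b_rt, b_q


def optimize_plan(
    noise: StepNoise,
    costs: CostModel,
    constraints: OptimizationConstraints,
    variance_tol: float = 0.005,
    return_frontier: bool = False,
) -> PlanEvaluation | tuple[PlanEvaluation, list[PlanEvaluation]]:
    """Exhaustively find the best affordable balanced plan.

    All integer plans with total cost within the budget and at least
    ``min_subjects`` biological replicates per condition are evaluated.
    Plans whose predicted variances differ by less than ``variance_tol``
    (cycles^2) are treated as equivalent — pilot components are far too
    uncertain to distinguish them — and among equivalent plans the
    cheaper one wins, then the one with fewer qPCR reactions per
    condition, then the lexicographically smallest.  Set
    ``variance_tol=0`` for strict variance minimization.

    The default tolerance of 0.005 is half a unit in the second decimal
    place, i.e. plans are compared at the precision at which planning
    tables are conventionally printed.

    Returns the winning :class:`PlanEvaluation`; with
    ``return_frontier=True`` also the full feasible list sorted as by
    :func:`rank_plans`.

    Raises
    ------
    InfeasibleError
        If no plan fits the budget; the message reports the cheapest
        admissible plan's cost.
    """
    if variance_tol < 0:
        raise ValueError("variance_tol must be >= 0")
    b_subj, b_samp, b_rt, b_q = _marginal_cost_bounds(costs, constraints)

    feasible: list[PlanEvaluation] = []
    for ns in range(constraints.min_subjects, b_subj + 1):
        if plan_cost(SamplingPlan(ns, 1, 1, 1), costs,
                     constraints.n_conditions) > constraints.budget:
            break
        for ni in range(1, b_samp + 1):
            if plan_cost(SamplingPlan(ns, ni, 1, 1), costs,
                         constraints.n_conditions) > constraints.budget:
                break
            for nj in range(1, b_rt + 1):
                if plan_cost(SamplingPlan(ns, ni, nj, 1), costs,
                             constraints.n_conditions) > constraints.budget:
                    break
                for nk in range(1, b_q + 1):
                    plan = SamplingPlan(ns, ni, nj, nk)
                    cost = plan_cost(plan, costs, constraints.n_conditions)
                    if cost > constraints.budget:
                        break
                    feasible.append(PlanEvaluation(
                        plan=plan,
                        group_variance=plan_variance(noise, plan),
                        total_cost=cost,
                        reactions_per_condition=plan.total_replicates,
                    ))

    if not feasible:
        cheapest = plan_cost(
            SamplingPlan(constraints.min_subjects, 1, 1, 1),
            costs, constraints.n_conditions,
        )
        raise InfeasibleError(
            f"no feasible plan: budget {constraints.budget} is below the "
            f"cheapest admissible plan's cost {cheapest}"
        )

    v_star = min(e.group_variance for e in feasible)
    tied = [e for e in feasible if e.group_variance <= v_star + variance_tol]
    best = min(tied, key=lambda e: (e.total_cost, e.reactions_per_condition, e.plan))

    if return_frontier:
        frontier = sorted(
            feasible,
            key=lambda e: (e.group_variance, e.total_cost,
                           e.reactions_per_condition, e.plan),
        )
        return best, frontier
    return best
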