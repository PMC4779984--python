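"""Model/Results interface for nested Cq variance decomposition.

:class:`NestedCqModel` wraps a hierarchically replicated Cq table and
``fit()`` runs the method-of-moments nested ANOVA independently in each
subject/tissue/gene stratum, returning a :class:`NestedCqResults` that
carries per-stratum variance components, noise summaries, ANOVA
diagnostics and a text ``summary()``.  Downstream planning hangs off
the results: ``recommend_plan`` feeds the estimated components of a
chosen stratum into the budget optimizer.

Example
-------
>>> from cqplan import NestedCqModel, simulate, SimulationSpec
>>> ds = simulate.simulate_stratum(
...     SimulationSpec(mu=24, sd_sampling=.5, sd_rt=.4, sd_qpcr=.3, seed=7))
>>> res = NestedCqModel(ds).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design as _design
from .anova import (EstimabilityError, NestedAnovaTable, VarianceComponents,
                    estimate_components, nested_anova)
from .dataset import STRATUM_KEYS, CqDataset
from .noise import NoiseSummary, total_noise

GroupKey = tuple[str, ...]


@dataclass
class StratumFit:
    """Everything estimated for one group."""

    key: GroupKey
    components: VarianceComponents | None
    anova: NestedAnovaTable | None
    noise: NoiseSummary | None
    pooled_sd: float | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


class NestedCqModel:
    """Nested random-effects noise model for replicated Cq data.

    Parameters
    ----------
    data : CqDataset or DataFrame
        Long-format Cq table (see :mod:`cqplan.dataset`).
    groupby : sequence of str
        Coordinates defining independent estimation groups; defaults to
        ``('subject', 'tissue', 'gene')`` — the model is fitted within
        a single treatment group, so subjects are never pooled into one
        stratum (that would add a fourth nesting level the model does
        not have).
    """

    def __init__(
        self,
        data: CqDataset | pd.DataFrame,
        groupby: tuple[str, ...] = tuple(STRATUM_KEYS),
    ):
        if isinstance(data, pd.DataFrame):
            data = CqDataset(data)
        self.dataset = data
        unknown = [g for g in groupby if g not in STRATUM_KEYS]
        if unknown:
            raise ValueError(f"cannot group on {unknown}; "
                             f"choose from {STRATUM_KEYS}")
        self.groupby = tuple(groupby)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "NestedCqModel":
        from .dataset import read_long_csv

        return cls(read_long_csv(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "NestedCqModel":
        return cls(CqDataset(df), **kwargs)

    def fit(self, truncate: bool = True) -> "NestedCqResults":
        """Estimate variance components in every group.

        Groups where a level is not estimable (zero degrees of
        freedom) are kept in the results with an error message rather
        than silently dropped.  ``truncate=False`` preserves negative
        raw moment estimates for diagnostics.
        """
        fits: list[StratumFit] = []
        obs = self.dataset.observed()
        for key, grp in obs.groupby(list(self.groupby), sort=True):
            key = key if isinstance(key, tuple) else (key,)
            # a grouping coarser than the full stratum key still
            # estimates per full stratum and would mix strata; refuse
            sub = grp
            try:
                for c in STRATUM_KEYS:
                    if c not in self.groupby and sub[c].nunique() > 1:
                        raise EstimabilityError(
                            f"group {key} mixes several {c} values; include "
                            f"{c!r} in groupby"
                        )
                table = nested_anova(sub)
                vc = estimate_components(sub, truncate=truncate)
                estimable = not vc.non_estimable
                nonneg = min(vc.var_sampling, vc.var_rt, vc.var_qpcr) >= 0
                noise = total_noise(vc) if estimable and nonneg else None
                pooled = float(np.std(sub["cq"].to_numpy(), ddof=1)) \
                    if len(sub) > 1 else None
                err = None
                if vc.non_estimable:
                    err = ("variance not estimable (zero df) at level(s): "
                           + ", ".join(vc.non_estimable))
                fits.append(StratumFit(key, vc, table, noise, pooled, err))
            except (EstimabilityError, ValueError) as exc:
                fits.append(StratumFit(key, None, None, None, None, str(exc)))
        return NestedCqResults(self, fits, truncate=truncate)


class NestedCqResults:
    """Fitted per-group variance components with diagnostics."""

    def __init__(self, model: NestedCqModel, fits: list[StratumFit],
                 truncate: bool = True):
        self.model = model
        self.fits = fits
        self.truncate = truncate

    # -- access -------------------------------------------------------------
    def __getitem__(self, key: GroupKey) -> StratumFit:
        key = key if isinstance(key, tuple) else (key,)
        for f in self.fits:
            if f.key == key:
                return f
        raise KeyError(key)

    @property
    def groups(self) -> list[GroupKey]:
        return [f.key for f in self.fits]

    @property
    def errors(self) -> dict[GroupKey, str]:
        return {f.key: f.error for f in self.fits if not f.ok}

    # -- tabular views ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """One row per group: mean Cq, step SDs, totals, diagnostics."""
        rows = []
        for f in self.fits:
            row = dict(zip(self.model.groupby, f.key))
            if f.components is not None:
                vc, nz = f.components, f.noise
                row.update(
                    mean_cq=vc.mu,
                    sd_sampling=vc.sd_sampling,
                    sd_rt=vc.sd_rt,
                    sd_qpcr=vc.sd_qpcr,
                    total_sd_combined=nz.total_sd if nz else None,
                    pooled_sd=f.pooled_sd,
                    n_obs=vc.n_obs,
                    truncated=",".join(vc.truncated),
                )
            row["error"] = f.error
            rows.append(row)
        return pd.DataFrame(rows)

    def mean_over_subjects(self) -> pd.DataFrame:
        """Average SD estimates across subjects per tissue/gene.

        Averaging the per-subject SD estimates halves (with two
        subjects) the sampling variance of the reported noise figures;
        it is the default reporting mode when several subjects were
        processed with the same design.
        """
        df = self.to_frame()
        df = df[df["error"].isna()]
        keys = [k for k in ("tissue", "gene") if k in df.columns]
        cols = ["mean_cq", "sd_sampling", "sd_rt", "sd_qpcr",
                "total_sd_combined", "pooled_sd"]
        return df.groupby(keys, sort=True)[cols].mean().reset_index()

    def to_json(self, indent: int = 2) -> str:
        """Full-precision machine-readable serialization."""
        out = []
        for f in self.fits:
            entry = dict(zip(self.model.groupby, f.key))
            if f.components is not None:
                entry.update(f.components.as_dict())
                entry["total_noise"] = f.noise.as_dict() if f.noise else None
                entry["pooled_sd"] = f.pooled_sd
            if f.error is not None:
                entry["error"] = f.error
            out.append(entry)
        return json.dumps(out, indent=indent)

    def summary(self) -> str:
        """Human-readable per-group table, 2-decimal precision."""
        df = self.to_frame()
        lines = ["Nested Cq variance decomposition",
                 "=" * 72,
                 f"groups: {len(self.fits)}   "
                 f"estimation: method-of-moments nested ANOVA"
                 f"{' (truncated at 0)' if self.truncate else ' (raw)'}",
                 ""]
        num = df.select_dtypes("number").columns
        show = df.copy()
        show[num] = show[num].round(2)
        lines.append(show.to_string(index=False))
        if self.errors:
            lines.append("")
            lines.append("groups with estimability problems:")
            for k, msg in self.errors.items():
                lines.append(f"  {k}: {msg}")
        return "\n".join(lines)

    # -- planning -----------------------------------------------------------
    def step_noise(self, key: GroupKey, subject_sd: float = 0.0) -> "_design.StepNoise":
        """Estimated components of one group as planning inputs."""
        fit = self[key]
        if not fit.ok:
            raise EstimabilityError(f"group {key} was not estimable: {fit.error}")
        return _design.StepNoise.from_components(fit.components, subject_sd)

    def recommend_plan(
        self,
        key: GroupKey,
        costs: "_design.CostModel",
        constraints: "_design.OptimizationConstraints",
        **kwargs,
    ) -> "_design.PlanEvaluation":
        """Budget-optimal replicate allocation for one group's noise."""
        return _design.optimize_plan(
            self.step_noise(key), costs, constraints, **kwargs
        )
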