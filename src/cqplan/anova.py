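"""Method-of-moments nested ANOVA for the three-level Cq noise model.

Within one stratum (one subject, tissue and gene) every Cq reading is
modelled as

    Cq_ijk = mu + a_i + b_j(i) + c_k(ij)

with independent zero-mean Gaussian effects: a_i for the i-th RNA
extraction (sampling noise, variance sigma_i^2), b_j(i) for the j-th RT
reaction within extraction i (sigma_j^2), and c_k(ij) for the k-th qPCR
well within that RT (sigma_k^2).

Estimation is the classical unbalanced fully-nested random-model ANOVA
(the SAS PROC NESTED computation): Type-I nested sums of squares are
formed from group means, expected-mean-square (EMS) coefficients are
computed from the realized group sizes, and the triangular EMS system is
solved bottom-up.  Missing records are excluded (complete-case) and the
EMS coefficients automatically account for the resulting imbalance.

With n_ij observations in RT j of extraction i, n_i. = sum_j n_ij and
N = sum n_i., the expected mean squares are

    E[MS_qpcr]     = sigma_k^2
    E[MS_rt]       = sigma_k^2 + c1 sigma_j^2
    E[MS_sampling] = sigma_k^2 + c2 sigma_j^2 + c3 sigma_i^2

    c1 = (N - sum_i (sum_j n_ij^2) / n_i.) / (sum_i b_i - a)
    c2 = (sum_i (sum_j n_ij^2) / n_i. - sum_ij n_ij^2 / N) / (a - 1)
    c3 = (N - sum_i n_i.^2 / N) / (a - 1)

where a is the number of extractions and b_i the number of RTs within
extraction i.  For a balanced design with n_j RTs of n_k wells each,
these reduce to c1 = c2 = n_k and c3 = n_j * n_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CqDataset

LEVELS = ("sampling", "rt", "qpcr")

#: Sums of squares below this (cycles^2) are treated as exactly zero, to
#: avoid spurious tiny negatives from floating-point cancellation.
SS_TOL = 1e-12


class EstimabilityError(ValueError):
    """A requested variance level has zero degrees of freedom."""


@dataclass
class NestedAnovaTable:
    """ANOVA bookkeeping for one stratum of the fully nested model.

    ``df``, ``ss`` and ``ms`` are keyed by level name; ``c1``, ``c2``,
    ``c3`` are the EMS coefficients on the replicate-count scale.  A
    level with zero df has NaN mean square and appears in
    ``non_estimable``.
    """

    df: dict[str, int]
    ss: dict[str, float]
    ms: dict[str, float]
    c1: float
    c2: float
    c3: float
    grand_mean: float
    n_obs: int
    non_estimable: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df[lv] for lv in LEVELS],
                "ss": [self.ss[lv] for lv in LEVELS],
                "ms": [self.ms[lv] for lv in LEVELS],
            },
            index=list(LEVELS),
        )


def _stratum_frame(stratum: CqDataset | pd.DataFrame) -> pd.DataFrame:
    if isinstance(stratum, CqDataset):
        df = stratum.observed()
        for key in ("subject", "tissue", "gene"):
            if df[key].nunique() > 1:
                raise ValueError(
                    f"stratum spans several {key} values; analyse one "
                    "subject/tissue/gene combination at a time"
                )
    else:
        df = stratum[stratum["cq"].notna()]
    return df


def nested_anova(stratum: CqDataset | pd.DataFrame) -> NestedAnovaTable:
    """Type-I nested ANOVA table with unbalanced EMS coefficients.

    Parameters
    ----------
    stratum : CqDataset or DataFrame
        Records of a single subject/tissue/gene combination.  Missing
        Cq values are dropped (complete-case).

    Returns
    -------
    NestedAnovaTable
        Degrees of freedom, sums of squares, mean squares per level and
        the EMS coefficients computed from the realized group sizes.
    """
    df = _stratum_frame(stratum)
    if df.empty:
        raise EstimabilityError("stratum has no non-missing Cq records")

    y = df["cq"].to_numpy(float)
    n_total = len(y)
    grand = y.mean()

    # realized group sizes and means
    rt_groups = df.groupby(["rna_rep", "rt_rep"])["cq"]
    rt_n = rt_groups.size()                    # n_ij
    rt_mean = rt_groups.mean()
    ext_groups = df.groupby("rna_rep")["cq"]
    ext_n = ext_groups.size()                  # n_i.
    ext_mean = ext_groups.mean()

    a = len(ext_n)
    b_i = rt_n.groupby(level="rna_rep").size()  # RTs within extraction i
    b_total = int(b_i.sum())

    df_sampling = a - 1
    df_rt = b_total - a
    df_qpcr = n_total - b_total

    ss_sampling = float((ext_n * (ext_mean - grand) ** 2).sum())
    parent_mean = ext_mean.reindex(rt_n.index.get_level_values("rna_rep"))
    ss_rt = float((rt_n.to_numpy() * (rt_mean.to_numpy() - parent_mean.to_numpy()) ** 2).sum())
    well_parent = rt_mean.reindex(
        pd.MultiIndex.from_frame(df[["rna_rep", "rt_rep"]])
    )
    ss_qpcr = float(((y - well_parent.to_numpy()) ** 2).sum())

    ss = {
        lv: (0.0 if s < SS_TOL else s)
        for lv, s in zip(LEVELS, (ss_sampling, ss_rt, ss_qpcr))
    }
    dfs = {"sampling": df_sampling, "rt": df_rt, "qpcr": df_qpcr}
    ms = {lv: (ss[lv] / dfs[lv] if dfs[lv] > 0 else float("nan")) for lv in LEVELS}
    non_estimable = tuple(lv for lv in LEVELS if dfs[lv] == 0)

    # EMS coefficients from the realized sizes
    sum_nij2_over_ni = float((rt_n**2).groupby(level="rna_rep").sum().div(ext_n).sum())
    sum_nij2 = float((rt_n**2).sum())
    sum_ni2 = float((ext_n**2).sum())
    c1 = (n_total - sum_nij2_over_ni) / df_rt if df_rt > 0 else float("nan")
    if df_sampling > 0:
        c2 = (sum_nij2_over_ni - sum_nij2 / n_total) / df_sampling
        c3 = (n_total - sum_ni2 / n_total) / df_sampling
    else:
        c2 = c3 = float("nan")

    return NestedAnovaTable(
        df=dfs, ss=ss, ms=ms, c1=c1, c2=c2, c3=c3,
        grand_mean=float(grand), n_obs=n_total, non_estimable=non_estimable,
    )


@dataclass
class VarianceComponents:
    """Estimated variance components of the nested Cq noise model.

    All variances are in cycles^2 and the SD properties in cycles.
    ``truncated`` lists the levels whose raw moment estimate was
    negative and was set to zero; ``raw`` keeps the untruncated
    solutions for diagnostics.  Levels with zero degrees of freedom
    carry NaN and are listed in ``non_estimable``.
    """

    mu: float
    var_sampling: float
    var_rt: float
    var_qpcr: float
    truncated: tuple[str, ...] = ()
    non_estimable: tuple[str, ...] = ()
    raw: dict[str, float] = field(default_factory=dict)
    n_obs: int = 0

    @property
    def sd_sampling(self) -> float:
        return float(np.sqrt(self.var_sampling))

    @property
    def sd_rt(self) -> float:
        return float(np.sqrt(self.var_rt))

    @property
    def sd_qpcr(self) -> float:
        return float(np.sqrt(self.var_qpcr))

    def as_dict(self) -> dict:
        return {
            "mu": self.mu,
            "var_sampling": self.var_sampling,
            "var_rt": self.var_rt,
            "var_qpcr": self.var_qpcr,
            "sd_sampling": self.sd_sampling,
            "sd_rt": self.sd_rt,
            "sd_qpcr": self.sd_qpcr,
            "truncated": list(self.truncated),
        }


def estimate_components(
    stratum: CqDataset | pd.DataFrame,
    truncate: bool = True,
) -> VarianceComponents:
    """Estimate (mu, sigma_i^2, sigma_j^2, sigma_k^2) for one stratum.

    Solves the triangular EMS system bottom-up:

        sigma_k^2 = MS_qpcr
        sigma_j^2 = (MS_rt - MS_qpcr) / c1
        sigma_i^2 = (MS_sampling - MS_qpcr - c2 sigma_j^2) / c3

    The raw (possibly negative) moment solutions enter the equations; by
    default negative final estimates are truncated to zero and recorded
    in ``truncated``.  Pass ``truncate=False`` to keep raw values.
    """
    table = nested_anova(stratum)
    raw_qpcr = table.ms["qpcr"]
    raw_rt = (
        (table.ms["rt"] - raw_qpcr) / table.c1
        if "rt" not in table.non_estimable and "qpcr" not in table.non_estimable
        else float("nan")
    )
    raw_sampling = (
        (table.ms["sampling"] - raw_qpcr - table.c2 * raw_rt) / table.c3
        if table.non_estimable == ()
        else float("nan")
    )
    raw = {"sampling": raw_sampling, "rt": raw_rt, "qpcr": raw_qpcr}

    truncated: list[str] = []
    final = {}
    for lv in LEVELS:
        v = raw[lv]
        if truncate and np.isfinite(v) and v < 0:
            truncated.append(lv)
            v = 0.0
        final[lv] = float(v)

    return VarianceComponents(
        mu=table.grand_mean,
        var_sampling=final["sampling"],
        var_rt=final["rt"],
        var_qpcr=final["qpcr"],
        truncated=tuple(truncated),
        non_estimable=table.non_estimable,
        raw=raw,
        n_obs=table.n_obs,
    )
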