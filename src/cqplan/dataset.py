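"""Data model and I/O for hierarchically replicated Cq measurements.

A dataset holds quantification-cycle (Cq) readings from a fully nested
RT-qPCR workflow: each biological subject yields tissue samples, each
tissue is split into RNA extractions (``rna_rep``), each extraction into
reverse-transcription reactions (``rt_rep``), and each RT reaction into
qPCR wells (``qpcr_rep``).  The replicate indices are nominal labels —
nothing downstream may depend on their numbering, only on the grouping
they induce.

The on-disk format is a long CSV with the exact header
``subject,tissue,gene,rna_rep,rt_rep,qpcr_rep,cq``; an empty ``cq``
field marks a missing (failed or discarded) reaction.  Missing reactions
may equivalently be represented by absent rows.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

#: Canonical column order of the long CSV format.
COLUMNS = ["subject", "tissue", "gene", "rna_rep", "rt_rep", "qpcr_rep", "cq"]

#: Columns that identify a stratum (one subject/tissue/gene combination).
STRATUM_KEYS = ["subject", "tissue", "gene"]

#: Columns holding nested replicate indices, outermost first.
REPLICATE_KEYS = ["rna_rep", "rt_rep", "qpcr_rep"]


class CqRecord(NamedTuple):
    """One Cq measurement with its full hierarchical coordinates."""

    subject: str
    tissue: str
    gene: str
    rna_rep: int
    rt_rep: int
    qpcr_rep: int
    cq: float  # NaN marks a missing reaction

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.cq)


class CqValidationError(ValueError):
    """Raised when a table of Cq records violates the data contract."""


def _coerce_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a raw table onto the canonical dtypes, validating as we go."""
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise CqValidationError(
            f"missing required column(s): {', '.join(missing_cols)}"
        )
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        raise CqValidationError(f"unexpected column(s): {', '.join(extra)}")

    out = df.loc[:, COLUMNS].copy()
    for c in STRATUM_KEYS:
        out[c] = out[c].astype(str)
    for c in REPLICATE_KEYS:
        vals = pd.to_numeric(out[c], errors="coerce")
        if vals.isna().any() or not np.allclose(vals, np.round(vals)):
            raise CqValidationError(f"column {c!r} must hold integer indices")
        if (vals < 1).any():
            raise CqValidationError(f"replicate indices in {c!r} must be >= 1")
        out[c] = vals.astype(int)
    cq = pd.to_numeric(out["cq"], errors="coerce")
    # distinguish "blank cell" (missing datum, fine) from junk text (error)
    junk = cq.isna() & out["cq"].notna() & (out["cq"].astype(str).str.strip() != "")
    if junk.any():
        bad = out.loc[junk, "cq"].iloc[0]
        raise CqValidationError(f"non-numeric cq value: {bad!r}")
    present = cq.notna()
    if (~np.isfinite(cq[present])).any() or (cq[present] <= 0).any():
        raise CqValidationError("cq values must be finite and > 0")
    out["cq"] = cq.astype(float)

    dup = out.duplicated(subset=STRATUM_KEYS + REPLICATE_KEYS)
    if dup.any():
        row = out.loc[dup.idxmax(), STRATUM_KEYS + REPLICATE_KEYS]
        raise CqValidationError(
            "duplicate coordinate tuple: " + ", ".join(map(str, row.tolist()))
        )

    all_missing = out.groupby(STRATUM_KEYS, sort=False)["cq"].apply(
        lambda s: s.isna().all()
    )
    if all_missing.any():
        key = all_missing[all_missing].index[0]
        raise CqValidationError(
            f"stratum {key} contains no non-missing Cq record"
        )
    return out.reset_index(drop=True)


@dataclass
class CqDataset:
    """Validated, ordered collection of Cq records.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format table with columns :data:`COLUMNS`.
    provenance : str
        Free-text note on where the data came from (file path, simulation
        seed, ...).  Carried through I/O round trips where possible.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = _coerce_frame(self.data)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[CqRecord]:
        for row in self.data.itertuples(index=False):
            yield CqRecord(*row)

    @property
    def records(self) -> list[CqRecord]:
        return list(self)

    @property
    def n_observed(self) -> int:
        """Number of non-missing Cq values."""
        return int(self.data["cq"].notna().sum())

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[CqRecord | tuple], provenance: str = ""
    ) -> "CqDataset":
        df = pd.DataFrame(list(records), columns=COLUMNS)
        return cls(df, provenance=provenance)

    # -- views --------------------------------------------------------------
    def observed(self) -> pd.DataFrame:
        """Complete-case view: rows with a non-missing Cq."""
        return self.data[self.data["cq"].notna()].reset_index(drop=True)

    def strata(self) -> Iterator[tuple[tuple[str, str, str], "CqDataset"]]:
        """Iterate (key, sub-dataset) over subject/tissue/gene strata."""
        for key, grp in self.data.groupby(STRATUM_KEYS, sort=False):
            yield key, CqDataset(grp, provenance=self.provenance)

    def write_csv(self, path: str | Path | io.TextIOBase) -> None:
        """Write the long CSV; missing Cq becomes an empty field."""
        self.data.to_csv(path, index=False)


def read_long_csv(path: str | Path | io.TextIOBase) -> CqDataset:
    """Read a long-format Cq CSV into a validated :class:`CqDataset`.

    Rows with an empty ``cq`` field become missing-marked records.
    Duplicate coordinate tuples, unknown or absent columns and
    non-numeric Cq entries raise :class:`CqValidationError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"cq": {"": None}}) if "cq" in df.columns else df
    name = path if isinstance(path, (str, Path)) else "<stream>"
    return CqDataset(df, provenance=str(name))


def summarize_counts(
    ds: CqDataset,
    design: tuple[int, int, int] | None = None,
) -> pd.DataFrame:
    """Per-stratum record counts.

    Parameters
    ----------
    ds : CqDataset
    design : (n_sampling, n_rt, n_qpcr), optional
        Declared design dimensions.  When given, the expected record
        count per stratum is their product and ``missing`` counts both
        empty-cell records and absent rows; otherwise only explicit
        missing-marked rows are counted.

    Returns
    -------
    DataFrame with columns subject, tissue, gene, expected, observed,
    missing — one row per stratum.
    """
    rows = []
    expected = int(np.prod(design)) if design is not None else None
    for key, grp in ds.data.groupby(STRATUM_KEYS, sort=False):
        observed = int(grp["cq"].notna().sum())
        exp = expected if expected is not None else len(grp)
        rows.append((*key, exp, observed, exp - observed))
    return pd.DataFrame(
        rows, columns=STRATUM_KEYS + ["expected", "observed", "missing"]
    )


@dataclass
class HierarchyFinding:
    """One estimability problem in one stratum."""

    subject: str
    tissue: str
    gene: str
    level: str  # 'sampling' | 'rt' | 'qpcr'
    message: str


@dataclass
class HierarchyReport:
    """Report-only validation of per-stratum estimability.

    A variance component is estimable only with positive degrees of
    freedom at its level: at least 2 extractions for the sampling
    component, at least one extraction with 2+ RTs for the RT component,
    and at least one RT with 2+ qPCR replicates for the qPCR component.
    """

    findings: list[HierarchyFinding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings


def validate_hierarchy(ds: CqDataset) -> HierarchyReport:
    """List strata where one or more variance components are not estimable."""
    report = HierarchyReport()
    obs = ds.observed()
    for key, grp in obs.groupby(STRATUM_KEYS, sort=False):
        a = grp["rna_rep"].nunique()
        rts = grp.groupby("rna_rep")["rt_rep"].nunique()
        b_total = int(rts.sum())
        n = len(grp)
        if a < 2:
            report.findings.append(
                HierarchyFinding(*key, "sampling",
                                 "fewer than 2 RNA extractions: sampling-level "
                                 "variance not estimable (df = 0)")
            )
        if b_total - a < 1:
            report.findings.append(
                HierarchyFinding(*key, "rt",
                                 "no extraction has 2 or more RTs: RT-level "
                                 "variance not estimable (df = 0)")
            )
        if n - b_total < 1:
            report.findings.append(
                HierarchyFinding(*key, "qpcr",
                                 "every RT has exactly 1 qPCR: qPCR-level "
                                 "variance not estimable (df = 0)")
            )
    return report
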