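"""Seeded simulation of hierarchically replicated Cq datasets.

Data are generated exactly under the nested Gaussian noise model: a
stratum mean mu, plus independent zero-mean Gaussian effects per RNA
extraction, per RT reaction within extraction, and per qPCR well within
RT (and optionally per subject).  Missingness, when requested, is
completely at random (MCAR) — each record is independently dropped-out
with probability ``missing_rate``, its Cq recorded as an empty field.

The generator is the workhorse for parameter-recovery tests: feed a
simulated stratum to the nested ANOVA estimator and the estimates
should recover the generating SDs in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import COLUMNS, CqDataset
from .presets import BLUEBERRY_PILOT, PILOT_DESIGN


@dataclass(frozen=True)
class SimulationSpec:
    """Generating parameters for one stratum (all SDs in cycles).

    ``sd_subject`` adds a between-subject effect and defaults to 0, in
    which case the three-level technical model holds exactly within
    every subject.
    """

    mu: float
    sd_sampling: float
    sd_rt: float
    sd_qpcr: float
    sd_subject: float = 0.0
    n_subjects: int = 1
    n_sampling: int = 4
    n_rt: int = 4
    n_qpcr: int = 3
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.sd_sampling, self.sd_rt, self.sd_qpcr, self.sd_subject) < 0:
            raise ValueError("SDs must be >= 0")
        if min(self.n_subjects, self.n_sampling, self.n_rt, self.n_qpcr) < 1:
            raise ValueError("design dimensions must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_records(self) -> int:
        return self.n_subjects * self.n_sampling * self.n_rt * self.n_qpcr


def _simulate_into(
    spec: SimulationSpec,
    rng: np.random.Generator,
    tissue: str,
    gene: str,
    subject_prefix: str = "S",
) -> pd.DataFrame:
    ns, ni, nj, nk = spec.n_subjects, spec.n_sampling, spec.n_rt, spec.n_qpcr
    subj_eff = rng.normal(0.0, spec.sd_subject, size=ns)
    samp_eff = rng.normal(0.0, spec.sd_sampling, size=(ns, ni))
    rt_eff = rng.normal(0.0, spec.sd_rt, size=(ns, ni, nj))
    q_eff = rng.normal(0.0, spec.sd_qpcr, size=(ns, ni, nj, nk))
    cq = (
        spec.mu
        + subj_eff[:, None, None, None]
        + samp_eff[:, :, None, None]
        + rt_eff[:, :, :, None]
        + q_eff
    ).ravel()
    if spec.missing_rate > 0.0:
        drop = rng.random(cq.size) < spec.missing_rate
        cq = np.where(drop, np.nan, cq)

    s_idx, i_idx, j_idx, k_idx = np.unravel_index(
        np.arange(cq.size), (ns, ni, nj, nk)
    )
    return pd.DataFrame(
        {
            "subject": [f"{subject_prefix}{s + 1}" for s in s_idx],
            "tissue": tissue,
            "gene": gene,
            "rna_rep": i_idx + 1,
            "rt_rep": j_idx + 1,
            "qpcr_rep": k_idx + 1,
            "cq": cq,
        },
        columns=COLUMNS,
    )


def simulate_stratum(
    spec: SimulationSpec,
    tissue: str = "tissue1",
    gene: str = "gene1",
) -> CqDataset:
    """Simulate one (or, with n_subjects > 1, several parallel) strata.

    Identical spec (including seed) gives a byte-identical dataset.  If
    MCAR drop-out happens to empty a stratum entirely the affected
    records are regenerated deterministically from the same stream
    until valid (relevant only at extreme missing rates).
    """
    rng = np.random.default_rng(spec.seed)
    df = _simulate_into(spec, rng, tissue, gene)
    # a stratum must keep at least one observed record to stay valid
    while df.groupby("subject")["cq"].apply(lambda s: s.isna().all()).any():
        df = _simulate_into(spec, rng, tissue, gene)
    return CqDataset(df, provenance=f"simulated (seed={spec.seed})")


def simulate_study(
    specs: dict[tuple[str, str], SimulationSpec],
    seed: int | None = None,
) -> CqDataset:
    """Concatenate simulated strata over (tissue, gene) combinations.

    Each stratum spec keeps its own dimensions and parameters; a single
    ``seed`` drives one generator across all strata so the whole study
    is reproducible from one integer.  Duplicate (tissue, gene) keys
    are impossible by construction of the dict argument.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for (tissue, gene), spec in specs.items():
        df = _simulate_into(spec, rng, tissue, gene)
        while df.groupby("subject")["cq"].apply(lambda s: s.isna().all()).any():
            df = _simulate_into(spec, rng, tissue, gene)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    return CqDataset(data, provenance=f"simulated study (seed={seed})")


def pilot_study_specs(
    n_subjects: int = 2,
    missing_rate: float = 0.0,
) -> dict[tuple[str, str], SimulationSpec]:
    """Simulation specs emulating the bundled blueberry pilot.

    Returns one spec per (tissue, gene) stratum with the pilot's mean
    Cq and step SDs at the pilot design dimensions (4 extractions x
    4 RTs x 3 qPCRs); two subjects reproduce the full pilot layout of
    864 reactions.
    """
    ni, nj, nk = PILOT_DESIGN
    return {
        key: SimulationSpec(
            mu=s.mean_cq,
            sd_sampling=s.sd_sampling,
            sd_rt=s.sd_rt,
            sd_qpcr=s.sd_qpcr,
            n_subjects=n_subjects,
            n_sampling=ni,
            n_rt=nj,
            n_qpcr=nk,
            missing_rate=missing_rate,
        )
        for key, s in BLUEBERRY_PILOT.items()
    }


def with_seed(spec: SimulationSpec, seed: int | None) -> SimulationSpec:
    """Copy of ``spec`` with its seed replaced."""
    return replace(spec, seed=seed)
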