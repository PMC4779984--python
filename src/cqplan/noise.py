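"""Scalar noise calculus on Cq variance components.

The three technical levels contribute independently, so the variance of
a single Cq reading is the sum of the step variances,

    sigma_Cq^2 = sigma_i^2 + sigma_j^2 + sigma_k^2,

and averaging N replicates of an isolated step shrinks that step's SD
to sigma / sqrt(N).  Because one PCR cycle is (ideally) one doubling, a
Cq spread of d cycles corresponds to a (1 + E)^d fold-range in template
amount, with E the amplification efficiency (E = 1 for perfect
doubling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .anova import VarianceComponents


@dataclass
class NoiseSummary:
    """Total technical noise of a single Cq measurement.

    ``total_sd`` is the combined SD in cycles; ``contributions`` gives
    each step's share of the total variance in percent (None when all
    components are zero, where shares are undefined); ``fold_equiv`` is
    the fold-change magnitude equivalent to one total-SD of Cq spread.
    """

    total_sd: float
    contributions: dict[str, float] | None
    fold_equiv: float

    def as_dict(self) -> dict:
        return {
            "total_sd": self.total_sd,
            "contributions_pct": self.contributions,
            "fold_equiv": self.fold_equiv,
        }


def total_noise(vc: VarianceComponents) -> NoiseSummary:
    """Combine step variances into the total noise of one Cq reading.

    Parameters
    ----------
    vc : VarianceComponents
        Non-negative step variances (truncated estimates).

    Returns
    -------
    NoiseSummary
        total_sd = sqrt(var_sampling + var_rt + var_qpcr), per-step
        variance shares in percent, and the 2**total_sd fold
        equivalent.
    """
    parts = {
        "sampling": vc.var_sampling,
        "rt": vc.var_rt,
        "qpcr": vc.var_qpcr,
    }
    if any(v < 0 for v in parts.values()):
        raise ValueError("variance components must be non-negative")
    total_var = sum(parts.values())
    total_sd = math.sqrt(total_var)
    if total_var > 0:
        contributions = {k: 100.0 * v / total_var for k, v in parts.items()}
    else:
        contributions = None
    return NoiseSummary(
        total_sd=total_sd,
        contributions=contributions,
        fold_equiv=2.0**total_sd,
    )


def se_of_mean(sd: float, n: int) -> float:
    """SD of the mean of ``n`` replicates of one processing step.

    Averaging n independent replicates divides the step's SD by
    sqrt(n); this is the standard error of the replicate mean.
    """
    if n < 1:
        raise ValueError("replicate count must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return sd / math.sqrt(n)


def cq_to_fold(delta_cq: float, efficiency: float = 1.0) -> float:
    """Fold-change implied by a Cq difference.

    Parameters
    ----------
    delta_cq : float
        Cq difference in cycles.
    efficiency : float
        Per-cycle amplification efficiency in [0, 1]; 1 means perfect
        doubling, giving the usual 2**delta_cq.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    return (1.0 + efficiency) ** delta_cq


def three_five_ratio(
    cq_5prime: float, cq_3prime: float, threshold: float = 4.5
) -> tuple[float, bool]:
    """Comparative-Cq 3':5' amplification ratio for RNA-integrity QC.

    Amplicons near a transcript's 3' and 5' ends should amplify
    comparably from intact, fully reverse-transcribed RNA; a large
    ratio 2**(Cq_5' - Cq_3') flags degradation or poor RT processivity.

    Returns
    -------
    (ratio, passed) : ratio on the fold scale and True when the ratio
    does not exceed ``threshold`` (RNA quality adequate).
    """
    ratio = 2.0 ** (cq_5prime - cq_3prime)
    return ratio, ratio <= threshold
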