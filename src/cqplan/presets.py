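"""Bundled step-noise presets.

``BLUEBERRY_PILOT`` holds the per-stratum summaries of a nested
RT-qPCR pilot experiment in rabbiteye blueberry (*Vaccinium
virgatum*): three tissues (leaves, stems, fruits) by three genes (the
B3-domain transcription factor *VRN*, 3-ketoacyl-CoA thiolase *KAT*,
and flavonoid 3',5'-hydroxylase *F3'5'H*), each measured per plant with
4 RNA extractions x 4 RTs x 3 qPCR wells.  For each stratum the preset
records the mean Cq, the estimated step SDs (cycles), and the observed
total noise — the empirical SD of measured Cq values across plants,
which includes between-plant spread and therefore exceeds the
combination of the three step SDs alone.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class StratumSummary:
    """Pilot summary of one tissue/gene stratum (all values in cycles)."""

    tissue: str
    gene: str
    mean_cq: float
    sd_sampling: float
    sd_rt: float
    sd_qpcr: float
    total_sd_observed: float


#: Pilot design dimensions per plant: extractions x RTs x qPCR wells.
PILOT_DESIGN = (4, 4, 3)

BLUEBERRY_PILOT: dict[tuple[str, str], StratumSummary] = {
    (s.tissue, s.gene): s
    for s in [
        StratumSummary("leaves", "VRN", 25.19, 0.45, 0.73, 0.32, 0.91),
        StratumSummary("leaves", "KAT", 22.78, 0.02, 0.28, 0.18, 0.55),
        StratumSummary("leaves", "F35H", 30.82, 0.64, 0.53, 0.49, 0.97),
        StratumSummary("stems", "VRN", 23.69, 0.87, 0.59, 0.35, 1.15),
        StratumSummary("stems", "KAT", 22.29, 0.53, 0.32, 0.21, 0.67),
        StratumSummary("stems", "F35H", 30.76, 0.19, 0.50, 0.44, 0.74),
        StratumSummary("fruits", "VRN", 25.12, 0.41, 0.34, 0.30, 0.65),
        StratumSummary("fruits", "KAT", 20.77, 0.42, 0.31, 0.27, 0.60),
        StratumSummary("fruits", "F35H", 18.29, 0.43, 0.29, 0.35, 0.64),
    ]
}
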