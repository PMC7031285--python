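"""Outcome labels derived from exposure metadata.

Data set A (homogeneous gamma vs. 1:1 blood mixtures): ``MixIndex`` marks
heterogeneous exposure and ``MeanDose`` is the average dose to the sample —
half of the dose received by the irradiated fraction when mixed 1:1 with
unirradiated blood.

Data set B (x rays vs. neutron + photon mixtures): ``MixIndex`` marks a
neutron contribution of at least 10% of the total dose and ``NeutronIndex``
marks a neutron dose of at least 0.5 Gy; both comparisons are inclusive.
The photon dose is expected to already include the neutron beam's ~18%
concomitant gamma component.

These are metadata-only functions: labels never depend on histogram content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .data import SampleRecord

logger = logging.getLogger(__name__)

GAMMA_COMPANION_FRACTION = 0.18  # gamma dose accompanying the neutron beam
NEUTRON_FRACTION_CUTOFF = 0.1
NEUTRON_DOSE_CUTOFF_GY = 0.5


@dataclass(frozen=True)
class OutcomeVector:
    mix_index: int
    neutron_index: int | None  # dataset B only
    mean_dose: float | None  # dataset A only
    photon_dose: float
    neutron_dose: float


def label_outcomes_A(rec: SampleRecord) -> OutcomeVector:
    """MixIndex and MeanDose for a homogeneous-vs-mixed gamma sample.

    ``photon_dose`` is the dose delivered to the irradiated fraction; a 1:1
    mixture with unirradiated blood therefore received half of it on average.
    """
    if rec.dataset != "A":
        raise ValueError(f"expected dataset A record, got {rec.dataset}")
    mix = int(rec.mixed_flag)
    return OutcomeVector(
        mix_index=mix,
        neutron_index=None,
        mean_dose=rec.photon_dose / (1 + mix),
        photon_dose=rec.photon_dose,
        neutron_dose=0.0,
    )


def label_outcomes_B(
    rec: SampleRecord,
    fraction_cutoff: float = NEUTRON_FRACTION_CUTOFF,
    dose_cutoff: float = NEUTRON_DOSE_CUTOFF_GY,
) -> OutcomeVector:
    """MixIndex (neutron fraction >= cutoff) and NeutronIndex (neutron dose >= cutoff)."""
    if rec.dataset != "B":
        raise ValueError(f"expected dataset B record, got {rec.dataset}")
    total = rec.photon_dose + rec.neutron_dose
    if total == 0:
        logger.debug("sample %s: zero total dose, labeling as control", rec.sample_id)
        mix = 0
    else:
        mix = int(rec.neutron_dose / total >= fraction_cutoff)
    return OutcomeVector(
        mix_index=mix,
        neutron_index=int(rec.neutron_dose >= dose_cutoff),
        mean_dose=None,
        photon_dose=rec.photon_dose,
        neutron_dose=rec.neutron_dose,
    )


def outcomes_frame(records: list[SampleRecord], dataset: str) -> pd.DataFrame:
    """Outcome table (one row per record) for the given dataset tag."""
    rows = []
    for r in records:
        o = label_outcomes_A(r) if dataset == "A" else label_outcomes_B(r)
        rows.append(
            {
                "mix_index": o.mix_index,
                "neutron_index": o.neutron_index,
                "mean_dose_gy": o.mean_dose,
                "photon_dose_gy": o.photon_dose,
                "neutron_dose_gy": o.neutron_dose,
            }
        )
    df = pd.DataFrame(rows, index=[r.sample_id for r in records])
    return df.dropna(axis=1, how="all")
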