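"""Canonical per-sample micronuclei histogram tables: types, I/O, pooling.

A sample is a histogram of binucleated cells by micronucleus count k = 0..5,
where the top bin holds cells with >= 5 micronuclei (the scorer truncates
there), plus exposure metadata. The canonical on-disk form is a CSV with
header::

    sample_id,dataset,photon_dose_gy,neutron_dose_gy,mixed_flag,mn0,mn1,mn2,mn3,mn4,mn5plus

Doses are decimals in Gy; counts are non-negative integers; ``mixed_flag`` is
``1``/``true`` for 1:1 irradiated/unirradiated blood mixtures (data set A) and
empty otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_BINS = 6  # k = 0..4 plus the >=5 bin

CSV_COLUMNS = [
    "sample_id",
    "dataset",
    "photon_dose_gy",
    "neutron_dose_gy",
    "mixed_flag",
    "mn0",
    "mn1",
    "mn2",
    "mn3",
    "mn4",
    "mn5plus",
]

COUNT_COLUMNS = CSV_COLUMNS[5:]


class ValidationError(ValueError):
    """Raised when a sample table or record violates the schema invariants."""


@dataclass(frozen=True)
class MNHistogram:
    """Counts of binucleated cells per micronucleus number for one sample.

    ``counts[k]`` is the number of cells with exactly k micronuclei for
    k = 0..4; ``counts[5]`` is the number of cells with >= 5.
    """

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != N_BINS:
            raise ValidationError(f"histogram needs {N_BINS} bins, got {len(self.counts)}")
        for k, c in enumerate(self.counts):
            if int(c) != c or c < 0:
                raise ValidationError(f"bin {k} has invalid count {c!r}")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def n(self) -> int:
        """Total scored binucleated cells."""
        return int(sum(self.counts))

    def values(self) -> np.ndarray:
        """Per-cell micronucleus counts expanded from the histogram.

        Cells in the >=5 bin are scored as exactly 5; counts above 5 are rare
        enough that this truncation does not move the shape statistics
        appreciably.
        """
        return np.repeat(np.arange(N_BINS), self.counts)

    def pooled_with(self, other: "MNHistogram") -> "MNHistogram":
        return MNHistogram(tuple(a + b for a, b in zip(self.counts, other.counts)))


@dataclass(frozen=True)
class SampleRecord:
    """One blood sample: MN histogram plus exposure metadata."""

    sample_id: str
    dataset: str  # "A" or "B"
    photon_dose: float
    neutron_dose: float
    mixed_flag: bool
    histogram: MNHistogram

    def __post_init__(self) -> None:
        if self.dataset not in ("A", "B"):
            raise ValidationError(f"unknown dataset tag {self.dataset!r}")
        for name in ("photon_dose", "neutron_dose"):
            d = getattr(self, name)
            if not np.isfinite(d) or d < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {d!r}")
        if self.dataset == "A" and self.neutron_dose != 0:
            raise ValidationError("dataset A records must have neutron_dose = 0")
        if self.dataset == "B" and self.mixed_flag:
            raise ValidationError("dataset B records must not carry mixed_flag")


def _parse_flag(raw) -> bool:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return False
    s = str(raw).strip().lower()
    return s in ("1", "true", "t", "yes")


def read_samples(path, dataset: str | None = None) -> list[SampleRecord]:
    """Read the canonical sample CSV into validated records, preserving row order.

    Parameters
    ----------
    path : str or file-like
        Canonical CSV (see module docstring).
    dataset : "A", "B", or None
        If given, require every row to carry this dataset tag.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "dataset": str, "mixed_flag": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")

    records: list[SampleRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        counts = [getattr(row, c) for c in COUNT_COLUMNS]
        try:
            hist = MNHistogram(tuple(int(c) for c in counts))
            rec = SampleRecord(
                sample_id=str(row.sample_id),
                dataset=str(row.dataset).strip(),
                photon_dose=float(row.photon_dose_gy),
                neutron_dose=float(row.neutron_dose_gy),
                mixed_flag=_parse_flag(row.mixed_flag),
                histogram=hist,
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"row {i} ({row.sample_id!r}): {exc}") from exc
        if dataset is not None and rec.dataset != dataset:
            raise ValidationError(
                f"row {i}: dataset tag {rec.dataset!r} does not match requested {dataset!r}"
            )
        records.append(rec)
    return records


def to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Canonical DataFrame view of a record list (column order fixed)."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "dataset": r.dataset,
                "photon_dose_gy": r.photon_dose,
                "neutron_dose_gy": r.neutron_dose,
                "mixed_flag": int(r.mixed_flag) if r.mixed_flag else "",
                **{c: r.histogram.counts[k] for k, c in enumerate(COUNT_COLUMNS)},
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_samples(records: list[SampleRecord], path) -> None:
    """Write records to the canonical CSV (round-trips bit-identically)."""
    to_frame(records).to_csv(path, index=False)


def drop_empty(records: list[SampleRecord]) -> list[SampleRecord]:
    """Drop records with zero scored cells (warned), ahead of feature computation."""
    kept = []
    for r in records:
        if r.histogram.n == 0:
            logger.warning("dropping sample %s: no scored cells", r.sample_id)
        else:
            kept.append(r)
    return kept


def pool_samples(records: list[SampleRecord], ndigits: int = 3) -> list[SampleRecord]:
    """Pool (sum) all samples sharing a (photon, neutron) dose combination.

    Dose combinations in the underlying experiments are discrete design
    points, so the pooling key rounds doses to ``ndigits`` decimals to absorb
    floating-point formatting. Histograms are summed elementwise, conserving
    cells and micronuclei; output is ordered by (photon, neutron) dose.
    """
    if not records:
        return []
    datasets = {r.dataset for r in records}
    if len(datasets) > 1:
        raise ValidationError(f"cannot pool across datasets: {sorted(datasets)}")
    groups: dict[tuple, SampleRecord] = {}
    for r in records:
        key = (round(r.photon_dose, ndigits), round(r.neutron_dose, ndigits), r.mixed_flag)
        if key not in groups:
            groups[key] = replace(r, sample_id=f"pool_p{key[0]:g}_n{key[1]:g}" + ("_mix" if r.mixed_flag else ""))
        else:
            prev = groups[key]
            groups[key] = replace(prev, histogram=prev.histogram.pooled_with(r.histogram))
    return [groups[k] for k in sorted(groups)]
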