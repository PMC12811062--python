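"""Sample metadata: what was grown, when it was sampled, how much it grew.

Each sequenced sample carries its culture condition (carbon source and
nitrogen status), replicate number, time point (t1 = inoculation, t2 =
harvest after ~7 generations), the OD600 pair, and the mapped-read total.
The expansion factor d = OD600_t2 / OD600_t1 is the population fold-growth
the fitness estimator needs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import IO, Sequence

import pandas as pd

from .io import ParseError, ValidationError

_OD_REL_TOL = 0.005  # d must match the OD ratio to 0.5% when ODs are given


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced library sample."""

    sample_id: str
    condition: str
    nitrogen: str  # "diazotrophic" (N2 fixation) or "urea"
    replicate: int
    timepoint: str  # "t1" or "t2"
    d: float  # expansion factor over the growth interval
    od_t1: float | None = None
    od_t2: float | None = None
    mapped_reads: int = 0

    def __post_init__(self) -> None:
        if self.timepoint not in ("t1", "t2"):
            raise ValidationError(f"{self.sample_id}: timepoint must be t1 or t2")
        if self.replicate < 1:
            raise ValidationError(f"{self.sample_id}: replicate must be >= 1")
        if not self.d > 0:
            raise ValidationError(f"{self.sample_id}: expansion factor d must be > 0")
        if self.mapped_reads < 0:
            raise ValidationError(f"{self.sample_id}: mapped_reads must be >= 0")
        if self.od_t1 is not None and self.od_t2 is not None:
            ratio = self.od_t2 / self.od_t1
            if abs(ratio - self.d) > _OD_REL_TOL * self.d:
                raise ValidationError(
                    f"{self.sample_id}: d={self.d} disagrees with "
                    f"OD ratio {ratio:.4f} beyond 0.5%"
                )


_META_COLUMNS = [
    "sample_id", "condition", "nitrogen", "replicate", "timepoint",
    "od_t1", "od_t2", "d", "mapped_reads",
]


def write_sample_meta(meta: Sequence[SampleMeta], stream: IO[str] | str | os.PathLike) -> None:
    frame = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id, "condition": m.condition,
                "nitrogen": m.nitrogen, "replicate": m.replicate,
                "timepoint": m.timepoint, "od_t1": m.od_t1, "od_t2": m.od_t2,
                "d": m.d, "mapped_reads": m.mapped_reads,
            }
            for m in meta
        ],
        columns=_META_COLUMNS,
    )
    frame.to_csv(stream, sep="\t", index=False, lineterminator="\n")


def read_sample_meta(stream: IO[str] | str | os.PathLike) -> list[SampleMeta]:
    try:
        frame = pd.read_csv(stream, sep="\t")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"malformed sample metadata: {exc}") from exc
    missing = set(_META_COLUMNS) - {"od_t1", "od_t2"} - set(frame.columns)
    if missing:
        raise ParseError(f"sample metadata missing columns: {sorted(missing)}")
    out = []
    for row in frame.itertuples():
        od1 = getattr(row, "od_t1", None)
        od2 = getattr(row, "od_t2", None)
        out.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                condition=str(row.condition),
                nitrogen=str(row.nitrogen),
                replicate=int(row.replicate),
                timepoint=str(row.timepoint),
                d=float(row.d),
                od_t1=None if od1 is None or pd.isna(od1) else float(od1),
                od_t2=None if od2 is None or pd.isna(od2) else float(od2),
                mapped_reads=int(row.mapped_reads),
            )
        )
    return out
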