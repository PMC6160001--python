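"""Spike-in normalization of ChIP-ddPCR copy-number tables.

Exogenous spike-in chromatin (e.g. Drosophila, immunoprecipitated with an
anti-H2Av antibody alongside the target) provides a per-sample recovery
control. One sample's spike-in value (copies per microliter of the PCR
reaction) is chosen as the reference; every sample's normalization factor
is reference spike-in divided by that sample's spike-in, and target values
are multiplied by the factor. The reference sample's factor is 1, and
ratios between samples do not depend on which sample is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["DdpcrSample", "spikein_normalize", "read_ddpcr_table",
           "normalized_frame"]


@dataclass
class DdpcrSample:
    sample_id: str
    spikein_copies: float
    target_copies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spikein_copies <= 0:
            raise ValueError(f"sample {self.sample_id}: spike-in copies "
                             "must be > 0")
        for target, value in self.target_copies.items():
            if value < 0:
                raise ValueError(f"sample {self.sample_id}: negative copy "
                                 f"number for {target}")


def spikein_normalize(samples: list[DdpcrSample],
                      reference_id: str | None = None
                      ) -> dict[str, dict[str, float]]:
    """Normalize target copy numbers to one sample's spike-in value.

    factor_s = spikein_ref / spikein_s; normalized target = raw * factor_s.
    Defaults to the first sample as reference.
    """
    if not samples:
        raise ValueError("no samples to normalize")
    if reference_id is None:
        reference_id = samples[0].sample_id
    by_id = {s.sample_id: s for s in samples}
    if reference_id not in by_id:
        raise ValueError(f"reference sample {reference_id!r} not present")
    ref_spike = by_id[reference_id].spikein_copies
    out: dict[str, dict[str, float]] = {}
    for s in samples:
        factor = ref_spike / s.spikein_copies
        out[s.sample_id] = {t: v * factor for t, v in s.target_copies.items()}
    return out


def read_ddpcr_table(path: str | Path) -> list[DdpcrSample]:
    """Read a TSV with columns sample_id, spikein, then one per target."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "spikein"}
    if not required.issubset(df.columns):
        raise ValueError(f"ddPCR table needs columns {sorted(required)}")
    targets = [c for c in df.columns if c not in required]
    return [
        DdpcrSample(sample_id=str(row["sample_id"]),
                    spikein_copies=float(row["spikein"]),
                    target_copies={t: float(row[t]) for t in targets})
        for _, row in df.iterrows()
    ]


def normalized_frame(samples: list[DdpcrSample],
                     reference_id: str | None = None) -> pd.DataFrame:
    """Raw and normalized values side by side, one row per sample."""
    norm = spikein_normalize(samples, reference_id)
    rows = []
    for s in samples:
        row: dict[str, object] = {"sample_id": s.sample_id,
                                  "spikein": s.spikein_copies}
        row.update(s.target_copies)
        row.update({f"{t}_normalized": v for t, v in norm[s.sample_id].items()})
        rows.append(row)
    return pd.DataFrame(rows)
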