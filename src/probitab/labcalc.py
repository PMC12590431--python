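"""Plate-count arithmetic for laboratory survival-rate determination.

Viable counts per tablet follow the standard serial-dilution convention

    S = NP * VI / (r * VF)

with NP the colony count on the plate, VI the initial suspension volume (ml),
r the cumulative dilution fraction (e.g. 1e-3) and VF the plated volume (ml).
The survival rate is the count relative to the as-received formulation's
baseline of 3.9e7 CFU per tablet, expressed as a percentage; values above
100 % can occur experimentally (cell activation / membrane repair on
rehydration).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["PlateRecord", "cfu_per_tablet", "survival_rate",
           "process_plate_table", "DEFAULT_BASELINE_CFU"]

DEFAULT_BASELINE_CFU = 3.9e7  # CFU per tablet in the as-received formulation


@dataclass(frozen=True)
class PlateRecord:
    """One plated dilution: colony count and dilution bookkeeping."""

    NP: int       # colonies on the plate, CFU
    VI: float     # initial suspension volume, ml
    r: float      # cumulative dilution fraction (0 < r <= 1)
    VF: float     # plated volume, ml

    def __post_init__(self):
        if self.NP < 0 or int(self.NP) != self.NP:
            raise ValueError("NP must be a non-negative integer colony count")
        if self.VI <= 0 or self.VF <= 0:
            raise ValueError("VI and VF must be positive volumes")
        if not 0.0 < self.r <= 1.0:
            raise ValueError("dilution fraction r must lie in (0, 1]")


def cfu_per_tablet(rec: PlateRecord) -> float:
    """Viable count per tablet from one plate record."""
    return rec.NP * rec.VI / (rec.r * rec.VF)


def survival_rate(S: float, Sb: float = DEFAULT_BASELINE_CFU) -> float:
    """Survival rate in percent: 100 * S / Sb (may exceed 100)."""
    if Sb <= 0:
        raise ValueError("baseline viability Sb must be positive")
    if S < 0:
        raise ValueError("viable count S must be non-negative")
    return 100.0 * S / Sb


def process_plate_table(df: pd.DataFrame,
                        Sb: float = DEFAULT_BASELINE_CFU) -> pd.DataFrame:
    """Survival rates from a plate-count table.

    Expects columns ``sample_id, NP, VI_ml, r, VF_ml``. Duplicate plates
    sharing a ``sample_id`` (aliquots of the same dilution series) are
    averaged on the colony-count level before conversion.
    """
    required = {"sample_id", "NP", "VI_ml", "r", "VF_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    rows = []
    for sid, grp in df.groupby("sample_id", sort=False):
        np_mean = grp["NP"].mean()
        vi, r, vf = (grp["VI_ml"].iloc[0], grp["r"].iloc[0], grp["VF_ml"].iloc[0])
        if (grp["VI_ml"].nunique() > 1 or grp["r"].nunique() > 1
                or grp["VF_ml"].nunique() > 1):
            raise ValueError(
                f"sample {sid!r}: replicate plates must share VI, r and VF"
            )
        S = np_mean * vi / (r * vf)
        rows.append({"sample_id": sid, "S_cfu_per_tablet": S,
                     "survival_rate_pct": survival_rate(S, Sb)})
    return pd.DataFrame(rows)
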