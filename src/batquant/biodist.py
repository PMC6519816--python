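"""Ex-vivo biodistribution: gamma-counter measurements to %ID/g.

Dissected organs are weighed and counted; each measurement is decay-corrected
back to injection time and expressed as percent of the injected dose per gram
of tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "OrganCount",
    "HALF_LIFE_S",
    "decay_correct",
    "percent_id_per_gram",
    "biodistribution_table",
]

#: Physical half-lives in seconds.
HALF_LIFE_S: dict[str, float] = {
    "F18": 6586.0,
    "Tc99m": 21636.0,
    "I123": 47592.0,
}


@dataclass(frozen=True)
class OrganCount:
    """One dissected-organ measurement.

    ``activity_Bq`` is the counter reading converted to Bq (apply a counter
    efficiency factor upstream if the counter reports raw counts);
    ``count_time_s`` is the elapsed time since injection when counted.
    """

    organ: str
    weight_g: float
    activity_Bq: float
    count_time_s: float
    isotope: str

    def __post_init__(self):
        if self.weight_g < 0 or self.activity_Bq < 0 or self.count_time_s < 0:
            raise ValueError("weight, activity and count time must be non-negative")
        if self.isotope not in HALF_LIFE_S:
            raise ValueError(f"unknown isotope {self.isotope!r}")


def decay_correct(
    activity_Bq: float,
    isotope: str,
    elapsed_s: float,
    half_life_s: float | None = None,
) -> float:
    """Correct a measured activity back to injection time.

    Returns activity * 2**(elapsed_s / half_life); a negative ``elapsed_s``
    inverts the correction.
    """
    if half_life_s is None:
        try:
            half_life_s = HALF_LIFE_S[isotope]
        except KeyError:
            raise ValueError(f"unknown isotope {isotope!r}") from None
    return activity_Bq * 2.0 ** (elapsed_s / half_life_s)


def percent_id_per_gram(
    sample: OrganCount,
    injected_dose_Bq: float,
    decay_correction: bool = True,
) -> float:
    """Percent injected dose per gram for one organ.

    100 * (decay-corrected activity) / injected dose / organ weight.
    """
    if injected_dose_Bq <= 0:
        raise ValueError("injected_dose_Bq must be positive")
    if sample.weight_g <= 0:
        raise ValueError(f"organ {sample.organ!r} has zero weight")
    act = sample.activity_Bq
    if decay_correction:
        act = decay_correct(act, sample.isotope, sample.count_time_s)
    return 100.0 * act / injected_dose_Bq / sample.weight_g


def biodistribution_table(
    samples: Iterable[OrganCount],
    injected_dose_Bq: float,
    decay_correction: bool = True,
) -> pd.DataFrame:
    """Tabulate %ID/g for a full dissection (one row per organ)."""
    rows = []
    for s in samples:
        rows.append({
            "organ": s.organ,
            "weight_g": s.weight_g,
            "pid_per_g": percent_id_per_gram(
                s, injected_dose_Bq, decay_correction=decay_correction
            ),
        })
    return pd.DataFrame(rows)
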