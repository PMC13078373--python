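"""Strain rearing profiles and the intake/gain scaling step.

Commercial layer-strain management guides publish, for the rearing period
(weeks 1-18), the body weight a pullet should reach at the end of each week
and the metabolizable-energy (ME) intake for that week.  Before any growth
model can be fitted, both series are put on a common per-unit-body-weight,
per-day scale:

    y_w = (BW_w - BW_{w-1}) / (BW̄_w * days)      gain, g per g BW per day
    x_w =  ME_w              / (BW̄_w * days)      intake, kcal per g BW per day

where BW̄_w is an average body weight for week ``w``.  Two conventions for
BW̄ are supported (see :func:`average_bw`); ``interval_mean`` — the mean of
the interval's start and end weight — is the default.  When a guide does not
record the hatch weight, 38 g is assumed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

DEFAULT_HATCH_WEIGHT_G = 38.0
DAYS_PER_WEEK = 7

ScalingMode = Literal["hatch_anchored", "interval_mean"]

PROFILE_CSV_COLUMNS = ["strain", "week", "body_weight_g", "me_intake_kcal_week"]
SCALED_CSV_COLUMNS = [
    "strain",
    "week",
    "x_kcal_per_g_day",
    "y_g_per_g_day",
    "bw_mean_g",
    "days",
]


@dataclass(frozen=True)
class WeekRecord:
    """One strain-guide row: end-of-week body weight and weekly ME intake."""

    week: int
    body_weight_g: float
    me_intake_kcal: float
    days: int = DAYS_PER_WEEK

    def __post_init__(self) -> None:
        if self.week < 1:
            raise ValueError(f"week index must be >= 1, got {self.week}")
        if self.body_weight_g <= 0:
            raise ValueError(f"body weight must be positive, got {self.body_weight_g}")
        if self.me_intake_kcal <= 0:
            raise ValueError(f"ME intake must be positive, got {self.me_intake_kcal}")
        if self.days <= 0:
            raise ValueError(f"days must be positive, got {self.days}")


@dataclass(frozen=True)
class StrainProfile:
    """Raw weekly body-weight / ME-intake records for one strain.

    Week indices must be strictly increasing and start at 1.  The hatch
    weight is optional; :func:`default_hatch_weight` fills in 38 g.
    """

    strain_name: str
    records: tuple[WeekRecord, ...]
    hatch_weight_g: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValueError("profile needs at least one weekly record")
        weeks = [r.week for r in self.records]
        if weeks[0] != 1:
            raise ValueError(f"week indices must start at 1, got {weeks[0]}")
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError("week indices must be strictly increasing")
        if self.hatch_weight_g is not None and self.hatch_weight_g <= 0:
            raise ValueError("hatch weight must be positive")

    def record_for_week(self, week: int) -> WeekRecord:
        for r in self.records:
            if r.week == week:
                return r
        raise KeyError(f"no record for week {week} in strain {self.strain_name!r}")


@dataclass(frozen=True)
class ScaledObservation:
    """One scaled (x, y) point.

    ``x`` is ME intake in kcal per g of average BW per day, ``y`` is BW gain
    in g per g of average BW per day.  ``y`` may be negative (weight loss);
    ``x`` cannot.
    """

    week: int
    x: float
    y: float
    bw_mean_g: float
    days: int

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError(f"scaled intake must be positive, got {self.x}")
        if self.bw_mean_g <= 0:
            raise ValueError(f"mean body weight must be positive, got {self.bw_mean_g}")
        if self.days <= 0:
            raise ValueError(f"days must be positive, got {self.days}")


def default_hatch_weight(profile: StrainProfile) -> StrainProfile:
    """Return the profile with a 38 g hatch weight filled in if absent."""
    if profile.hatch_weight_g is not None:
        return profile
    return replace(profile, hatch_weight_g=DEFAULT_HATCH_WEIGHT_G)


def average_bw(
    profile: StrainProfile, week: int, mode: ScalingMode = "interval_mean"
) -> float:
    """Average body weight BW̄ for one week under either convention.

    ``hatch_anchored`` averages the hatch weight with the week's end weight
    for every week; ``interval_mean`` averages the interval's start weight
    (previous week's end, or hatch for week 1) with its end weight.  The two
    coincide at week 1.
    """
    profile = default_hatch_weight(profile)
    rec = profile.record_for_week(week)
    assert profile.hatch_weight_g is not None
    if mode == "hatch_anchored":
        start = profile.hatch_weight_g
    elif mode == "interval_mean":
        start = _interval_start(profile, week)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return (start + rec.body_weight_g) / 2.0


def _interval_start(profile: StrainProfile, week: int) -> float:
    assert profile.hatch_weight_g is not None
    prev = [r for r in profile.records if r.week < week]
    return prev[-1].body_weight_g if prev else profile.hatch_weight_g


def scale_observations(
    profile: StrainProfile, mode: ScalingMode = "interval_mean"
) -> list[ScaledObservation]:
    """Scale one profile to (x, y) observations, one per recorded week."""
    profile = default_hatch_weight(profile)
    out: list[ScaledObservation] = []
    for rec in profile.records:
        bw_mean = average_bw(profile, rec.week, mode=mode)
        if bw_mean <= 0:
            raise ValueError(f"non-positive mean BW in week {rec.week}")
        start = _interval_start(profile, rec.week)
        denom = bw_mean * rec.days
        out.append(
            ScaledObservation(
                week=rec.week,
                x=rec.me_intake_kcal / denom,
                y=(rec.body_weight_g - start) / denom,
                bw_mean_g=bw_mean,
                days=rec.days,
            )
        )
    return out


def observations_to_arrays(observations: Sequence[ScaledObservation]):
    """(x, y) numpy arrays from a list of scaled observations."""
    import numpy as np

    x = np.array([o.x for o in observations], dtype=float)
    y = np.array([o.y for o in observations], dtype=float)
    return x, y


# ---------------------------------------------------------------------------
# CSV I/O.  One row per strain-week; optional hatch_weight_g column (repeated
# per row).  UTF-8, dot decimal.  Floats are round-tripped via repr so that a
# write/read cycle is bit-exact.
# ---------------------------------------------------------------------------


def write_profiles_csv(profiles: Iterable[StrainProfile], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PROFILE_CSV_COLUMNS + ["hatch_weight_g", "days"])
        for p in profiles:
            hatch = "" if p.hatch_weight_g is None else repr(p.hatch_weight_g)
            for r in p.records:
                writer.writerow(
                    [p.strain_name, r.week, repr(r.body_weight_g),
                     repr(r.me_intake_kcal), hatch, r.days]
                )


def read_profiles_csv(path: str | Path) -> list[StrainProfile]:
    path = Path(path)
    by_strain: dict[str, list[WeekRecord]] = {}
    hatch: dict[str, float | None] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(PROFILE_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
        for row in reader:
            strain = row["strain"]
            rec = WeekRecord(
                week=int(row["week"]),
                body_weight_g=float(row["body_weight_g"]),
                me_intake_kcal=float(row["me_intake_kcal_week"]),
                days=int(row.get("days") or DAYS_PER_WEEK),
            )
            by_strain.setdefault(strain, []).append(rec)
            hw = row.get("hatch_weight_g") or ""
            hatch[strain] = float(hw) if hw else hatch.get(strain)
    return [
        StrainProfile(strain_name=s, records=tuple(recs), hatch_weight_g=hatch.get(s))
        for s, recs in by_strain.items()
    ]


def write_scaled_csv(
    scaled_by_strain: dict[str, Sequence[ScaledObservation]], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCALED_CSV_COLUMNS)
        for strain, obs in scaled_by_strain.items():
            for o in obs:
                writer.writerow(
                    [strain, o.week, repr(o.x), repr(o.y), repr(o.bw_mean_g), o.days]
                )
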