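"""Core domain types shared by the simulator and the population-PK baseline.

The package works with sparsely sampled therapeutic-drug-monitoring data:
each subject contributes a handful of plasma concentrations drawn during
chronic oral therapy, together with a fixed set of eleven demographic and
co-medication covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ParameterError

#: Covariate column names in the canonical CSV schema, in model input order.
COVARIATE_COLUMNS = (
    "AGE",
    "COUNT",
    "INDUCER",
    "INHIB",
    "RACE_B",
    "RACE_W",
    "RACE_O",
    "SEX",
    "SMOK",
    "SUBSTR",
    "WT",
)

#: Full dataset schema. INTERVAL (dosing interval, h) is written by the
#: generator and consumed by the PK baseline; readers default it to 24 when
#: a file omits it.
DATASET_COLUMNS = (
    "ID",
    "CALENDAR",
    "TSFD",
    "DOSE",
    "INTERVAL",
    "AGE",
    "WT",
    "SEX",
    "SMOK",
    "RACE_B",
    "RACE_W",
    "RACE_O",
    "COUNT",
    "INDUCER",
    "INHIB",
    "SUBSTR",
    "CONC",
)

#: Columns that must be present in any file read back as a PK dataset.
REQUIRED_COLUMNS = tuple(c for c in DATASET_COLUMNS if c != "INTERVAL")


@dataclass
class CovariateProfile:
    """One subject's covariate vector.

    Counts are numbers of concomitant medications overall (``count``) and in
    three CYP-interaction classes (enzyme inducers, inhibitors, and shared
    substrates).  Race is one-hot across black / white / other.
    """

    age: float  # years
    weight: float  # kg
    sex: int  # 0 female, 1 male
    smoking: int  # 1 active smoker
    race_black: int
    race_white: int
    race_other: int
    count: int
    inducers: int
    inhibitors: int
    substrate: int

    def validate(self) -> None:
        if self.age <= 0:
            raise ParameterError(f"age must be positive, got {self.age}")
        if self.weight <= 0:
            raise ParameterError(f"weight must be positive, got {self.weight}")
        if self.race_black + self.race_white + self.race_other != 1:
            raise ParameterError("exactly one race indicator must equal 1")
        for name in ("count", "inducers", "inhibitors", "substrate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        for name in ("sex", "smoking"):
            if getattr(self, name) not in (0, 1):
                raise ParameterError(f"{name} must be 0 or 1")

    def as_row(self) -> dict[str, float]:
        """Map to the CSV column names."""
        return {
            "AGE": self.age,
            "WT": self.weight,
            "SEX": self.sex,
            "SMOK": self.smoking,
            "RACE_B": self.race_black,
            "RACE_W": self.race_white,
            "RACE_O": self.race_other,
            "COUNT": self.count,
            "INDUCER": self.inducers,
            "INHIB": self.inhibitors,
            "SUBSTR": self.substrate,
        }

    @classmethod
    def from_row(cls, row) -> "CovariateProfile":
        return cls(
            age=float(row["AGE"]),
            weight=float(row["WT"]),
            sex=int(row["SEX"]),
            smoking=int(row["SMOK"]),
            race_black=int(row["RACE_B"]),
            race_white=int(row["RACE_W"]),
            race_other=int(row["RACE_O"]),
            count=int(row["COUNT"]),
            inducers=int(row["INDUCER"]),
            inhibitors=int(row["INHIB"]),
            substrate=int(row["SUBSTR"]),
        )


@dataclass
class DosingRegimen:
    """Repeated equal-interval oral dosing up to the sampling time."""

    dose_amount: float  # mg per administration
    interval: float  # hours, 12 (twice daily) or 24 (once daily)
    n_doses_before_sample: int = 1

    def validate(self) -> None:
        if not (2.5 <= self.dose_amount <= 30.0):
            raise ParameterError(
                f"dose_amount must be within 2.5-30 mg, got {self.dose_amount}"
            )
        if self.interval not in (12.0, 24.0, 12, 24):
            raise ParameterError(f"interval must be 12 or 24 h, got {self.interval}")
        if self.n_doses_before_sample < 1:
            raise ParameterError("n_doses_before_sample must be >= 1")
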