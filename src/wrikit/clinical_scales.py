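"""Clinical developmental and autism-severity scale scoring.

Three instruments accompany the motor task for the autistic participants:

* **Gesell Developmental Schedules (3rd ed., GDS-3)** — per domain (gross
  motor, fine motor, adaptability, language, personal-social behaviour), the
  examiner records how many items the child passes at each of 24 standard
  developmental milestones.  Developmental age is the pass-weighted mean of
  the milestone ages, DA = sum(W_i * N_i) / sum(N_i), and the developmental
  quotient DQ = 100 * DA / CA with CA the chronological age.  DQ < 76
  indicates developmental delay, 76-85 is borderline, >= 86 normal.
* **Childhood Autism Rating Scale (CARS)** — 15 items each scored 1-4 (half
  points admitted, as in standard practice); the total classifies severity:
  < 30 not autistic, 30-36 mild/moderate, > 36 severe.
* **PEP-3 Performance Test** — six subscale scores (CVP, EL, RL, FM, GM,
  VMI) stored as-is; they enter only correlation analyses.

Milestones quoted in weeks are converted to months (4.345 weeks/month)
before the DA formula, since the standard milestone list mixes the units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "GESELL_DOMAINS",
    "GESELL_MILESTONES_MONTHS",
    "WEEKS_PER_MONTH",
    "GesellDomainRecord",
    "CarsRecord",
    "Pep3Record",
    "compute_developmental_age",
    "compute_dq",
    "classify_dq",
    "score_cars",
    "weeks_to_months",
    "read_gesell_csv",
    "read_cars_csv",
    "read_pep3_csv",
]

GESELL_DOMAINS = ("GM", "FM", "AD", "LA", "PSB")

WEEKS_PER_MONTH = 4.345

#: The 24 standard milestone ages, normalised to months.  The first 13 are
#: defined in weeks (4 through 56), the rest in months (15 through 72).
_MILESTONES_WEEKS = (4, 8, 12, 16, 20, 24, 28, 32, 40, 44, 48, 52, 56)
_MILESTONES_MONTHS = (15, 18, 21, 24, 30, 36, 42, 48, 54, 60, 72)


def weeks_to_months(weeks: float) -> float:
    return weeks / WEEKS_PER_MONTH


GESELL_MILESTONES_MONTHS = tuple(
    [round(weeks_to_months(w), 3) for w in _MILESTONES_WEEKS]
    + [float(m) for m in _MILESTONES_MONTHS]
)

CARS_VALID_SCORES = {1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0}


@dataclass
class GesellDomainRecord:
    """One participant x one GDS-3 domain: milestone passes and age.

    ``milestone_passes`` maps milestone age in **months** to the number of
    items passed at that milestone.
    """

    domain: str
    milestone_passes: Mapping[float, int]
    ca_months: float

    def __post_init__(self) -> None:
        if self.domain not in GESELL_DOMAINS:
            raise ValueError(f"domain must be one of {GESELL_DOMAINS}, got {self.domain!r}")
        if self.ca_months <= 0:
            raise ValueError("chronological age must be > 0 months")
        for w, n in self.milestone_passes.items():
            if w <= 0:
                raise ValueError(f"milestone age must be > 0 months, got {w}")
            if int(n) != n or n < 0:
                raise ValueError(f"pass count at milestone {w} must be a non-negative integer")


@dataclass
class CarsRecord:
    """The 15 CARS item scores of one participant."""

    item_scores: tuple[float, ...]

    def __post_init__(self) -> None:
        scores = tuple(float(s) for s in self.item_scores)
        if len(scores) != 15:
            raise ValueError(f"CARS has exactly 15 items, got {len(scores)}")
        bad = [s for s in scores if s not in CARS_VALID_SCORES]
        if bad:
            raise ValueError(f"item scores must be in 1..4 half-point steps, got {bad}")
        self.item_scores = scores


@dataclass
class Pep3Record:
    """PEP-3 Performance Test subscale scores (container only)."""

    cvp: float
    el: float
    rl: float
    fm: float
    gm: float
    vmi: float

    def __post_init__(self) -> None:
        for name in ("cvp", "el", "rl", "fm", "gm", "vmi"):
            if getattr(self, name) < 0:
                raise ValueError(f"PEP-3 {name.upper()} must be non-negative")


def compute_developmental_age(rec: GesellDomainRecord) -> float:
    """Developmental age in months: DA = sum(W_i N_i) / sum(N_i)."""
    total = sum(rec.milestone_passes.values())
    if total <= 0:
        raise ValueError("no items passed at any milestone; DA undefined")
    weighted = sum(w * n for w, n in rec.milestone_passes.items())
    return weighted / total


def compute_dq(da_months: float, ca_months: float) -> float:
    """Developmental quotient: DQ = 100 * DA / CA."""
    if ca_months <= 0:
        raise ValueError("chronological age must be > 0")
    return 100.0 * da_months / ca_months


def classify_dq(dq: float) -> str:
    """Band a DQ score: < 76 delay, 76-85 borderline, >= 86 normal."""
    if dq < 0:
        raise ValueError("DQ must be >= 0")
    if dq < 76:
        return "delay"
    if dq <= 85:
        return "borderline"
    return "normal"


def score_cars(rec: CarsRecord) -> tuple[float, str]:
    """Total CARS score and severity band.

    < 30 not autistic; 30-36 (inclusive) mild or moderately autistic;
    > 36 severely autistic.
    """
    total = float(sum(rec.item_scores))
    if total < 30:
        severity = "not_autistic"
    elif total <= 36:
        severity = "mild_moderate"
    else:
        severity = "severe"
    return total, severity


# ---------------------------------------------------------------------------
# CSV readers (documented headers; see package docs)
# ---------------------------------------------------------------------------

def read_gesell_csv(path: str | Path) -> pd.DataFrame:
    """Long-format Gesell table -> per-participant, per-domain DA/DQ/band.

    Expected columns: ``id, domain, milestone_months, n_passed, ca_months``.
    """
    df = pd.read_csv(path)
    required = {"id", "domain", "milestone_months", "n_passed", "ca_months"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for (pid, domain), sub in df.groupby(["id", "domain"], sort=False):
        rec = GesellDomainRecord(
            domain=str(domain),
            milestone_passes={
                float(w): int(n)
                for w, n in zip(sub["milestone_months"], sub["n_passed"])
            },
            ca_months=float(sub["ca_months"].iloc[0]),
        )
        da = compute_developmental_age(rec)
        dq = compute_dq(da, rec.ca_months)
        rows.append(
            {
                "id": pid,
                "domain": domain,
                "da_months": da,
                "dq": dq,
                "dq_band": classify_dq(dq),
            }
        )
    return pd.DataFrame(rows)


def read_cars_csv(path: str | Path) -> pd.DataFrame:
    """CARS table (``id, item1..item15``) -> id, total, severity."""
    df = pd.read_csv(path)
    item_cols = [f"item{i}" for i in range(1, 16)]
    missing = [c for c in ["id", *item_cols] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    rows = []
    for _, row in df.iterrows():
        total, severity = score_cars(CarsRecord(tuple(row[c] for c in item_cols)))
        rows.append({"id": row["id"], "cars_total": total, "cars_severity": severity})
    return pd.DataFrame(rows)


def read_pep3_csv(path: str | Path) -> pd.DataFrame:
    """PEP-3 table (``id, cvp, el, rl, fm, gm, vmi``), validated and returned."""
    df = pd.read_csv(path)
    required = ["id", "cvp", "el", "rl", "fm", "gm", "vmi"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for _, row in df.iterrows():
        Pep3Record(**{k: float(row[k]) for k in required[1:]})
    return df[required]
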