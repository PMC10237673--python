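"""Fecundity ratios and two-sire paternity attribution via the sepia marker.

Females mated to naive or experienced males lay eggs that are counted after
24 h and reared to eclosion; the naive/experienced ratio of arm means is the
reported effect.  In the sperm-competition design, an se/se female mates
with two sires differing at the sepia locus; because sepia is recessive, a
progeny's eye colour identifies its father (se-eyed iff the sire is se/se),
so per-female eye-colour counts convert directly into paternity shares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .stats import TTestResult, students_t

__all__ = [
    "CrossRecord",
    "PaternityResult",
    "assign_sire",
    "paternity_share",
    "relative_ratio",
    "records_from_table",
]

SEPIA = "se/se"
WILDTYPE = "+/+"


@dataclass(frozen=True)
class CrossRecord:
    """One two-sire cross: genotypes at the sepia locus and progeny eye-colour counts."""

    female_id: str
    mother_genotype: str
    first_sire_genotype: str
    second_sire_genotype: str
    count_sepia_eyed: int
    count_wildtype_eyed: int

    def __post_init__(self) -> None:
        if self.count_sepia_eyed < 0 or self.count_wildtype_eyed < 0:
            raise ValueError("progeny counts must be non-negative")
        for name in ("mother_genotype", "first_sire_genotype", "second_sire_genotype"):
            if getattr(self, name) not in (SEPIA, WILDTYPE):
                raise ValueError(f"{name} must be {SEPIA!r} or {WILDTYPE!r}")
        if self.first_sire_genotype == self.second_sire_genotype:
            raise ValueError("sires share a genotype; paternity is unattributable")

    @property
    def total_progeny(self) -> int:
        return self.count_sepia_eyed + self.count_wildtype_eyed


@dataclass(frozen=True)
class PaternityResult:
    """Progeny-pooled and per-female paternity shares, in percent."""

    first_sire_share: float
    second_sire_share: float
    n_females: int
    total_progeny: int
    per_female_shares: tuple[float, ...]


def assign_sire(
    eye_phenotype: Literal["sepia", "wildtype"],
    mother_genotype: str,
    first_sire_genotype: str,
    second_sire_genotype: str,
) -> Literal["first", "second"]:
    """Attribute one progeny to a sire from its eye colour.

    Requires an se/se mother and sires differing at the locus: she transmits
    se to every offspring, so a sepia-eyed fly inherited se from its father
    (the se/se sire) and a wild-type-eyed fly carries the +/+ sire's + allele.
    """
    if mother_genotype != SEPIA:
        raise ValueError("attribution requires an se/se mother")
    genotypes = {first_sire_genotype, second_sire_genotype}
    if genotypes != {SEPIA, WILDTYPE}:
        raise ValueError("exactly one sire must be se/se and the other +/+")
    if eye_phenotype not in ("sepia", "wildtype"):
        raise ValueError(f"unknown eye phenotype {eye_phenotype!r}")
    sepia_sire = "first" if first_sire_genotype == SEPIA else "second"
    if eye_phenotype == "sepia":
        return sepia_sire
    return "second" if sepia_sire == "first" else "first"


def paternity_share(records: Sequence[CrossRecord]) -> PaternityResult:
    """Pooled and per-female percentages of progeny per sire.

    The headline share pools progeny across females (weighting by brood
    size); per-female shares are reported for females with progeny, while
    females with empty broods still count toward n_females.
    """
    if not records:
        raise ValueError("no cross records to analyse")
    first_total = 0
    total = 0
    per_female = []
    for rec in records:
        first_is_sepia = (
            assign_sire("sepia", rec.mother_genotype, rec.first_sire_genotype, rec.second_sire_genotype)
            == "first"
        )
        n_first = rec.count_sepia_eyed if first_is_sepia else rec.count_wildtype_eyed
        first_total += n_first
        total += rec.total_progeny
        if rec.total_progeny > 0:
            per_female.append(100.0 * n_first / rec.total_progeny)
    share = 100.0 * first_total / total if total > 0 else float("nan")
    return PaternityResult(
        first_sire_share=share,
        second_sire_share=100.0 - share if total > 0 else float("nan"),
        n_females=len(records),
        total_progeny=total,
        per_female_shares=tuple(per_female),
    )


def records_from_table(table: pd.DataFrame) -> list[CrossRecord]:
    """Build CrossRecords from a crosses CSV (female_id, mother_gt, sire1_gt, sire2_gt, n_sepia, n_wildtype)."""
    required = ["female_id", "mother_gt", "sire1_gt", "sire2_gt", "n_sepia", "n_wildtype"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise KeyError(f"crosses table lacks required columns: {missing}")
    return [
        CrossRecord(
            female_id=str(r.female_id),
            mother_genotype=str(r.mother_gt),
            first_sire_genotype=str(r.sire1_gt),
            second_sire_genotype=str(r.sire2_gt),
            count_sepia_eyed=int(r.n_sepia),
            count_wildtype_eyed=int(r.n_wildtype),
        )
        for r in table.itertuples(index=False)
    ]


def relative_ratio(
    counts_naive_arm: Iterable[float],
    counts_experienced_arm: Iterable[float],
    n_resamples: int = 5000,
    seed: int = 0,
) -> dict:
    """Naive/experienced ratio of arm means with the naive bar fixed at 1.

    Returns the ratio of means (naive over experienced), a Student's t
    comparison of the raw counts, and a bootstrap CI for the ratio obtained
    by resampling females within each arm.
    """
    a = np.asarray(list(counts_naive_arm), dtype=float)
    b = np.asarray(list(counts_experienced_arm), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both arms must be non-empty")
    if b.mean() <= 0:
        raise ValueError("experienced-arm mean must be > 0")
    ratio = a.mean() / b.mean()
    tt: TTestResult = students_t(a, b)
    rng = np.random.default_rng(seed)
    ra = rng.choice(a, size=(n_resamples, a.size), replace=True).mean(axis=1)
    rb = rng.choice(b, size=(n_resamples, b.size), replace=True).mean(axis=1)
    valid = rb > 0
    boot = ra[valid] / rb[valid]
    lo, hi = np.quantile(boot, [0.025, 0.975])
    return {
        "control_bar": 1.0,
        "ratio": float(ratio),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "t": tt.t,
        "df": tt.df,
        "p": tt.p,
        "n_naive": int(a.size),
        "n_experienced": int(b.size),
    }
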