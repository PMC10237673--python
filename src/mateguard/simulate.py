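"""Seeded generators for synthetic behavioral-assay datasets.

The study's raw measurements are per-fly mating durations, courtship and
locomotion metrics, egg/progeny counts, two-sire cross progeny classified by
eye colour, and fluorescence ROI intensities.  These generators emit tidy
tables with the statistical structure those analyses assume: normally
distributed mating durations recorded at 10-s accuracy, a configurable
percent reduction in the experienced condition, lognormal latencies with the
one-hour inclusion window, Poisson eggs with binomial survival to eclosion,
binomial sperm use in two-sire crosses with a recessive sepia eye marker,
and lognormal fluorescence with separate autofluorescence.

Every generator is a pure function of (design, seed): identical inputs give
identical tables.  Substreams are derived deterministically from the design
seed so partial runs stay reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayDesign",
    "FecundityDesign",
    "CrossDesign",
    "FluorescenceDesign",
    "generate_md_assay",
    "generate_fecundity",
    "generate_paternity",
    "generate_calexa",
    "MD_FLOOR_S",
    "MD_RECORDING_ACCURACY_S",
]

#: Mating durations are truncated at this floor (s) and rounded to the
#: recording accuracy below.
MD_FLOOR_S = 60.0
MD_RECORDING_ACCURACY_S = 10.0

SEPIA = "se/se"
WILDTYPE = "+/+"


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-generator substream of the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())])
    )


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Lognormal draws moment-matched to the given mean and sd."""
    if mean <= 0:
        raise ValueError(f"lognormal mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if sd == 0:
        return np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


@dataclass(frozen=True)
class AssayDesign:
    """Design of a mating-duration assay.

    ``groups`` lists (genotype, condition, n) with condition in
    {naive, experienced}; the default emulates the paper-style two-group
    comparison at the study's minimum sample size of 36 males per group.
    ``percent_reduction`` is the configured shortening of the experienced
    group mean relative to the naive mean, in percent.
    """

    groups: tuple[tuple[str, str, int], ...] = (
        ("CS", "naive", 36),
        ("CS", "experienced", 36),
    )
    md_mean_naive: float = 1260.0
    md_sd: float = 240.0
    percent_reduction: float = 15.0
    copulation_latency_mean: float = 900.0
    copulation_latency_sd: float = 700.0
    courtship_latency_mean: float = 60.0
    courtship_latency_sd: float = 45.0
    mating_window: float = 3600.0
    courtship_index_mean: float = 0.6
    courtship_index_sd: float = 0.15
    locomotion_velocity_mean: float = 8.0
    locomotion_velocity_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design needs at least one group")
        for g, cond, n in self.groups:
            if cond not in ("naive", "experienced"):
                raise ValueError(f"condition must be naive/experienced, got {cond!r}")
            if n < 1:
                raise ValueError(f"group ({g}, {cond}) needs n >= 1, got {n}")
        if self.md_mean_naive <= 0:
            raise ValueError("md_mean_naive must be > 0")
        if self.md_sd < 0:
            raise ValueError("md_sd must be >= 0")
        if not (0 <= self.percent_reduction < 100):
            raise ValueError("percent_reduction must be in [0, 100)")
        if self.mating_window <= 0:
            raise ValueError("mating_window must be > 0")
        if not (0 <= self.courtship_index_mean <= 1):
            raise ValueError("courtship_index_mean must be on [0, 1]")


ASSAY_COLUMNS = [
    "fly_id",
    "genotype",
    "condition",
    "mating_duration_s",
    "copulation_latency_s",
    "courtship_latency_s",
    "courtship_index",
    "velocity_mm_s",
    "included",
]


def generate_md_assay(design: AssayDesign) -> pd.DataFrame:
    """Tidy per-fly assay table (one row = one male).

    Mating durations are normal per group (experienced mean = naive mean
    scaled by 1 - percent_reduction/100), truncated at 60 s and rounded to
    the 10-s recording accuracy.  ``included`` is False exactly when the
    copulation latency exceeds the mating window.
    """
    rng = _rng(design.seed, "md_assay")
    frames = []
    fly = 0
    for genotype, condition, n in design.groups:
        mean = design.md_mean_naive
        if condition == "experienced":
            mean *= 1.0 - design.percent_reduction / 100.0
        md = rng.normal(mean, design.md_sd, n)
        md = np.maximum(md, MD_FLOOR_S)
        md = np.round(md / MD_RECORDING_ACCURACY_S) * MD_RECORDING_ACCURACY_S
        cop_lat = _lognormal(
            rng, design.copulation_latency_mean, design.copulation_latency_sd, n
        )
        court_lat = _lognormal(
            rng, design.courtship_latency_mean, design.courtship_latency_sd, n
        )
        ci = np.clip(
            rng.normal(design.courtship_index_mean, design.courtship_index_sd, n), 0.0, 1.0
        )
        vel = np.maximum(
            rng.normal(design.locomotion_velocity_mean, design.locomotion_velocity_sd, n),
            0.0,
        )
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": [f"fly{fly + i:05d}" for i in range(n)],
                    "genotype": genotype,
                    "condition": condition,
                    "mating_duration_s": md.astype(int),
                    "copulation_latency_s": cop_lat,
                    "courtship_latency_s": court_lat,
                    "courtship_index": ci,
                    "velocity_mm_s": vel,
                    "included": cop_lat <= design.mating_window,
                }
            )
        )
        fly += n
    return pd.concat(frames, ignore_index=True)[ASSAY_COLUMNS]


@dataclass(frozen=True)
class FecundityDesign:
    """Egg-laying and progeny design: females mated to naive vs experienced males.

    Eggs over 24 h are Poisson at the arm's mean (optionally negative
    binomial when ``overdispersion`` > 0, parametrised so the variance is
    mean * (1 + overdispersion)); each egg eclosed with the arm's survival
    probability.  ``arm_effects`` maps arm -> (egg multiplier, survival
    multiplier); the default reproduces the study's pattern of comparable
    eggs but reduced progeny from experienced males.
    """

    n_females: int = 24
    egg_mean: float = 50.0
    progeny_survival: float = 0.85
    arm_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "mated_to_naive": (1.0, 1.0),
            "mated_to_experienced": (1.0, 0.7),
        }
    )
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")
        if self.egg_mean < 0:
            raise ValueError("egg_mean must be >= 0")
        if not (0 <= self.progeny_survival <= 1):
            raise ValueError("progeny_survival must be on [0, 1]")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        for arm, (em, sm) in self.arm_effects.items():
            if em < 0 or sm < 0 or self.progeny_survival * sm > 1:
                raise ValueError(f"invalid effect multipliers for arm {arm!r}")


def generate_fecundity(design: FecundityDesign) -> pd.DataFrame:
    """Per-female (female_id, arm, eggs_24h, progeny) table; progeny <= eggs."""
    rng = _rng(design.seed, "fecundity")
    rows = []
    for arm, (egg_mult, surv_mult) in design.arm_effects.items():
        mean = design.egg_mean * egg_mult
        if design.overdispersion > 0:
            # NB as Poisson-gamma mixture: var = mean * (1 + overdispersion)
            shape = mean / design.overdispersion if mean > 0 else 1.0
            lam = rng.gamma(shape, design.overdispersion, design.n_females) if mean > 0 else np.zeros(design.n_females)
            eggs = rng.poisson(lam)
        else:
            eggs = rng.poisson(mean, design.n_females)
        progeny = rng.binomial(eggs, design.progeny_survival * surv_mult)
        for i, (e, p) in enumerate(zip(eggs, progeny)):
            rows.append(
                {
                    "female_id": f"{arm}_f{i:04d}",
                    "arm": arm,
                    "eggs_24h": int(e),
                    "progeny": int(p),
                }
            )
    return pd.DataFrame(rows, columns=["female_id", "arm", "eggs_24h", "progeny"])


@dataclass(frozen=True)
class CrossDesign:
    """Two-sire cross with a recessive sepia eye marker.

    The mother and the two sires carry se/se or +/+ at the sepia locus; the
    sires must differ for eye colour to attribute paternity.  Each progeny is
    sired by the first male with probability ``first_sire_share``; brood size
    per female is Poisson(``progeny_mean``).
    """

    n_females: int = 20
    mother_genotype: str = SEPIA
    first_sire_genotype: str = SEPIA
    second_sire_genotype: str = WILDTYPE
    first_sire_share: float = 0.2
    progeny_mean: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mother_genotype", "first_sire_genotype", "second_sire_genotype"):
            if getattr(self, name) not in (SEPIA, WILDTYPE):
                raise ValueError(f"{name} must be {SEPIA!r} or {WILDTYPE!r}")
        if self.first_sire_genotype == self.second_sire_genotype:
            raise ValueError("sires must differ at the sepia locus for attribution")
        if not (0 <= self.first_sire_share <= 1):
            raise ValueError("first_sire_share must be on [0, 1]")
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")
        if self.progeny_mean < 0:
            raise ValueError("progeny_mean must be >= 0")


def _eye_phenotype(mother_gt: str, sire_gt: str, rng: np.random.Generator, n: int) -> np.ndarray:
    """Progeny phenotypes: sepia iff both inherited alleles are se.

    A se/se parent always transmits se; a +/+ parent always transmits +, so
    with an se/se mother the sire's genotype fixes the phenotype and with a
    +/+ parent anywhere all progeny are wild-type eyed.
    """
    maternal_se = mother_gt == SEPIA
    paternal_se = sire_gt == SEPIA
    sepia = np.full(n, maternal_se & paternal_se)
    return np.where(sepia, "sepia", "wildtype")


def generate_paternity(design: CrossDesign) -> pd.DataFrame:
    """Per-female two-sire cross records with per-eye-colour progeny counts.

    Columns: female_id, mother_gt, sire1_gt, sire2_gt, n_sepia, n_wildtype,
    n_first_sire (ground truth for tests).
    """
    rng = _rng(design.seed, "paternity")
    rows = []
    for i in range(design.n_females):
        total = int(rng.poisson(design.progeny_mean))
        from_first = int(rng.binomial(total, design.first_sire_share))
        pheno_first = _eye_phenotype(design.mother_genotype, design.first_sire_genotype, rng, from_first)
        pheno_second = _eye_phenotype(design.mother_genotype, design.second_sire_genotype, rng, total - from_first)
        n_sepia = int((pheno_first == "sepia").sum() + (pheno_second == "sepia").sum())
        rows.append(
            {
                "female_id": f"f{i:04d}",
                "mother_gt": design.mother_genotype,
                "sire1_gt": design.first_sire_genotype,
                "sire2_gt": design.second_sire_genotype,
                "n_sepia": n_sepia,
                "n_wildtype": total - n_sepia,
                "n_first_sire": from_first,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["female_id", "mother_gt", "sire1_gt", "sire2_gt", "n_sepia", "n_wildtype", "n_first_sire"],
    )


@dataclass(frozen=True)
class FluorescenceDesign:
    """CaLexA GFP readout per tarsal segment (T4, T5) and condition.

    ``gfp`` maps segment -> condition -> (mean, sd) in arbitrary fluorescence
    units; intensities are lognormal so they stay strictly positive.  The
    default encodes the study's contrast structure: an experienced-condition
    increase confined to the 5th tarsal segment.
    """

    n_flies: int = 12
    gfp: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "T4": {"naive": (100.0, 25.0), "experienced": (100.0, 25.0)},
            "T5": {"naive": (100.0, 25.0), "experienced": (250.0, 60.0)},
        }
    )
    autofluorescence_mean: float = 50.0
    autofluorescence_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if self.autofluorescence_mean <= 0:
            raise ValueError("autofluorescence_mean must be > 0")
        if self.autofluorescence_sd < 0:
            raise ValueError("autofluorescence_sd must be >= 0")
        for seg, conds in self.gfp.items():
            for cond, (m, s) in conds.items():
                if m <= 0 or s < 0:
                    raise ValueError(f"invalid gfp mean/sd for {seg}/{cond}")


def generate_calexa(design: FluorescenceDesign) -> pd.DataFrame:
    """Per-fly GFP and autofluorescence intensities (fly_id, condition, segment, gfp, autofluorescence)."""
    rng = _rng(design.seed, "calexa")
    rows = []
    for segment, conds in design.gfp.items():
        for condition, (mean, sd) in conds.items():
            gfp = _lognormal(rng, mean, sd, design.n_flies)
            auto = _lognormal(
                rng, design.autofluorescence_mean, design.autofluorescence_sd, design.n_flies
            )
            for i in range(design.n_flies):
                rows.append(
                    {
                        "fly_id": f"{segment}_{condition}_{i:03d}",
                        "condition": condition,
                        "segment": segment,
                        "gfp": float(gfp[i]),
                        "autofluorescence": float(auto[i]),
                    }
                )
    return pd.DataFrame(rows, columns=["fly_id", "condition", "segment", "gfp", "autofluorescence"])


def exposure_time_reduction(hours: float, full_effect: float = 15.0) -> float:
    """Percent reduction induced by a given exposure time to females.

    Emulates the study's threshold: no effect for exposures of 6 h or less,
    the full effect at 12 h or longer, linear in between.
    """
    if hours < 0:
        raise ValueError("exposure hours must be >= 0")
    if hours <= 6.0:
        return 0.0
    if hours >= 12.0:
        return full_effect
    return full_effect * (hours - 6.0) / 6.0
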