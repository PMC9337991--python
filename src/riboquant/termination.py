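"""Radiolabel-corrected quantification of transcription-termination gels.

Single-round transcription reactions incorporate [alpha-32P]-UTP at a high
fraction during initiation and a much lower fraction during elongation, so
a longer product is "hotter" than a shorter one in proportion to its U
content, not its molar amount. Band volumes must therefore be corrected by
each species' relative radioactivity

    R = u_init * f_init + u_elong * f_elong

before molar fractions can be compared. For a single terminator the percent
termination is 100 * T / (T + FL * X) with X = R_T / R_FL; for a tandem
construct the same logic uses pairwise factors X_T2 = R_T1 / R_T2 and
X_FL = R_T1 / R_FL. Both forms are algebraically identical to normalizing
the corrected counts I_s / R_s, and `tandem_fractions` asserts the two
routes agree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constructs import AptamerConstruct, TranscriptSpecies

logger = logging.getLogger(__name__)

__all__ = [
    "LabelingScheme",
    "LABELING_PRESETS",
    "TerminationLane",
    "TerminationResult",
    "relative_radioactivity",
    "correction_factor",
    "percent_termination_single",
    "tandem_fractions",
    "quantify_lane",
    "readthrough_series",
]


@dataclass(frozen=True)
class LabelingScheme:
    """Fractions of UTP that are radiolabelled in each transcription phase.

    Initiation mixes are hotter than elongation mixes in both presets, so
    0 < f_elong <= f_init <= 1 is enforced.
    """

    f_init: float
    f_elong: float

    def __post_init__(self) -> None:
        if not (0 < self.f_elong <= self.f_init <= 1):
            raise ValueError(
                f"labelling fractions must satisfy 0 < f_elong <= f_init <= 1,"
                f" got f_init={self.f_init}, f_elong={self.f_elong}"
            )

    @classmethod
    def preset(cls, name: str) -> "LabelingScheme":
        try:
            return LABELING_PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown labelling preset {name!r}; "
                f"available: {sorted(LABELING_PRESETS)}"
            ) from None


#: Single-riboswitch assays used 7% labelled UTP during initiation and 0.2%
#: during elongation; tandem assays used 3% and 0.4%.
LABELING_PRESETS = {
    "single-2022": LabelingScheme(0.07, 0.002),
    "tandem-2022": LabelingScheme(0.03, 0.004),
}


@dataclass(frozen=True)
class TerminationLane:
    """Band volumes per transcript species for one transcription reaction."""

    lane_id: str
    intensities: dict[str, float]
    condition: str = ""
    concentration_mM: float | None = None
    construct: str | None = None

    def __post_init__(self) -> None:
        if "FL" not in self.intensities:
            raise ValueError(f"lane {self.lane_id}: FL band missing")
        vals = list(self.intensities.values())
        if any(v < 0 for v in vals):
            raise ValueError(f"lane {self.lane_id}: negative band volume")
        if not any(v > 0 for v in vals):
            raise ValueError(f"lane {self.lane_id}: all band volumes zero")


@dataclass
class TerminationResult:
    """Molar fractions of transcript species after radiolabel correction.

    ``fractions`` sum to 1; ``readthrough`` maps each terminator to the
    fraction of polymerases arriving at it that read through it;
    ``correction_factors`` are the X factors relative to the shortest
    species.
    """

    fractions: dict[str, float]
    readthrough: dict[str, float]
    correction_factors: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"fractions sum to {total}, not 1")
        for t, p in self.readthrough.items():
            if not -1e-12 <= p <= 1 + 1e-12:
                raise ValueError(f"readthrough past {t} = {p} outside [0,1]")


def relative_radioactivity(
    species: TranscriptSpecies, labeling: LabelingScheme
) -> float:
    """Relative radioactivity R of one species under a labelling scheme."""
    r = species.u_init * labeling.f_init + species.u_elong * labeling.f_elong
    if r == 0:
        logger.warning(
            "species %s has no U residues: unlabelable (R = 0)", species.label
        )
    return r


def correction_factor(r_short: float, r_long: float) -> float:
    """X = R_short / R_long, the band-volume correction for the longer species."""
    if r_long <= 0 or r_short <= 0:
        raise ValueError("relative radioactivities must be positive")
    x = r_short / r_long
    if x > 1:
        logger.warning(
            "correction factor %.3g > 1: the shorter species carries more "
            "label than the longer one (unusual construct)",
            x,
        )
    return x


def percent_termination_single(i_t: float, i_fl: float, x: float) -> float:
    """Percent termination for a single-terminator construct.

    100 * T / (T + FL * X) with X = R_T / R_FL; fraction FL is
    1 - percent/100.
    """
    if i_t < 0 or i_fl < 0:
        raise ValueError("band volumes must be non-negative")
    if i_t == 0 and i_fl == 0:
        raise ValueError("both band volumes are zero")
    if x <= 0:
        raise ValueError("correction factor must be positive")
    return 100.0 * i_t / (i_t + i_fl * x)


def tandem_fractions(
    i_t1: float,
    i_t2: float,
    i_fl: float,
    r_t1: float,
    r_t2: float,
    r_fl: float,
) -> TerminationResult:
    """Molar fractions of T1/T2/FL products for a tandem construct.

    Sequential route: with X_T2 = R_T1/R_T2 and X_FL = R_T1/R_FL,
    f_T1 = T1 / (T1 + T2*X_T2 + FL*X_FL); of the pool that read through T1,
    the split between T2 and FL uses T2*X_T2 against FL*X_FL. This is
    algebraically the corrected-count normalization (I_s / R_s,
    renormalized); both routes are computed and must agree.
    """
    for name, v in (("T1", i_t1), ("T2", i_t2), ("FL", i_fl)):
        if v < 0:
            raise ValueError(f"band volume {name} is negative")
    if i_t1 + i_t2 + i_fl == 0:
        raise ValueError("all band volumes are zero")
    if min(r_t1, r_t2, r_fl) <= 0:
        raise ValueError("relative radioactivities must be positive")

    x_t2 = correction_factor(r_t1, r_t2)
    x_fl = correction_factor(r_t1, r_fl)
    denom = i_t1 + i_t2 * x_t2 + i_fl * x_fl
    f_t1 = i_t1 / denom
    past_t1 = 1.0 - f_t1
    pool = i_t2 * x_t2 + i_fl * x_fl
    frac_t2_of_pool = (i_t2 * x_t2 / pool) if pool > 0 else 0.0
    f_t2 = past_t1 * frac_t2_of_pool
    f_fl = past_t1 - f_t2

    # independent route: corrected counts renormalized
    corrected = np.array([i_t1 / r_t1, i_t2 / r_t2, i_fl / r_fl])
    alt = corrected / corrected.sum()
    if not np.allclose([f_t1, f_t2, f_fl], alt, atol=1e-12, rtol=1e-9):
        raise AssertionError(
            "sequential-formula and corrected-count routes disagree: "
            f"{(f_t1, f_t2, f_fl)} vs {tuple(alt)}"
        )

    # force exact conservation
    f_fl = 1.0 - f_t1 - f_t2
    readthrough_t2 = (f_fl / (f_t2 + f_fl)) if (f_t2 + f_fl) > 0 else 0.0
    return TerminationResult(
        fractions={"T1": f_t1, "T2": f_t2, "FL": f_fl},
        readthrough={"T1": past_t1, "T2": readthrough_t2},
        correction_factors={"T1": 1.0, "T2": x_t2, "FL": x_fl},
    )


def quantify_lane(
    lane: TerminationLane,
    species: list[TranscriptSpecies],
    labeling: LabelingScheme,
    background: float = 0.0,
) -> TerminationResult:
    """Quantify one lane given its construct's species and labelling scheme.

    Dispatches to the single-terminator or tandem formulas according to the
    species labels. ``background`` is an optional constant band-volume
    background subtracted from every band (default 0: no subtraction).
    """
    labels = [s.label for s in species]
    missing = [l for l in labels if l not in lane.intensities]
    if missing:
        raise ValueError(
            f"lane {lane.lane_id}: missing band(s) for species {missing}"
        )
    ints = {s.label: max(lane.intensities[s.label] - background, 0.0)
            for s in species}
    r = {s.label: relative_radioactivity(s, labeling) for s in species}

    if labels == ["FL"]:
        return TerminationResult(
            fractions={"FL": 1.0}, readthrough={}, correction_factors={"FL": 1.0}
        )
    if set(labels) == {"T", "FL"}:
        x = correction_factor(r["T"], r["FL"])
        pct = percent_termination_single(ints["T"], ints["FL"], x)
        f_t = pct / 100.0
        return TerminationResult(
            fractions={"T": f_t, "FL": 1.0 - f_t},
            readthrough={"T": 1.0 - f_t},
            correction_factors={"T": 1.0, "FL": x},
        )
    if set(labels) == {"T1", "T2", "FL"}:
        return tandem_fractions(
            ints["T1"], ints["T2"], ints["FL"], r["T1"], r["T2"], r["FL"]
        )
    raise ValueError(f"unsupported species set {labels}")


def readthrough_series(
    lanes: list[TerminationLane],
    species: list[TranscriptSpecies],
    labeling: LabelingScheme,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a set of lanes and summarize per condition.

    Returns ``(per_lane, per_condition)``: one row per lane with species
    fractions and read-through values, and the per-condition means across
    replicate lanes (assays are typically run in triplicate, and plots show
    the replicates alongside the condition mean).
    """
    constructs = {l.construct for l in lanes if l.construct is not None}
    if len(constructs) > 1:
        raise ValueError(f"lanes mix constructs: {sorted(constructs)}")
    rows = []
    for lane in lanes:
        res = quantify_lane(lane, species, labeling)
        row: dict = {
            "lane_id": lane.lane_id,
            "condition": lane.condition,
            "concentration_mM": lane.concentration_mM,
        }
        row.update({f"fraction_{k}": v for k, v in res.fractions.items()})
        row.update({f"readthrough_{k}": v for k, v in res.readthrough.items()})
        rows.append(row)
    per_lane = pd.DataFrame(rows)
    value_cols = [c for c in per_lane.columns
                  if c.startswith(("fraction_", "readthrough_"))]
    per_condition = (
        per_lane.groupby(["condition"], dropna=False)[value_cols]
        .mean()
        .reset_index()
    )
    return per_lane, per_condition
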