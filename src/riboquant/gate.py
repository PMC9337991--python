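"""Two-input Boolean logic-gate model for tandem riboswitches.

A tandem arrangement of a Na+ riboswitch (genetic ON switch: ligand binding
precludes terminator formation at T1) followed by a c-di-AMP riboswitch
(genetic OFF switch: ligand binding triggers termination at T2) is modelled
as two independent stochastic gates acting in series on each transcribing
polymerase. Each switch maps its ligand concentration to a read-through
probability through a Hill dose-response bounded by a floor and a ceiling;
the polymerase population then partitions into transcripts ending at T1,
T2, or full length (FL).

With independent switches the expected behaviour is an "A and Not B"
(material nonimplication) gate: appreciable FL output only when Na+ is high
and c-di-AMP is low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .probing import isotherm

__all__ = [
    "SwitchParams",
    "GateParams",
    "TruthTable",
    "default_gate",
    "readthrough_prob",
    "partition",
    "evaluate_truth_table",
    "gate_fidelity",
]


@dataclass(frozen=True)
class SwitchParams:
    """Dose-response read-through parameters for one riboswitch.

    ``polarity`` "ON" means ligand binding increases read-through (the
    terminator cannot form when the aptamer is occupied); "OFF" means
    ligand binding increases termination. ``k_half`` is the ligand
    concentration at the response midpoint, in the units named by
    ``unit`` (mM for Na+, μM for c-di-AMP). ``p_floor``/``p_ceil`` bound
    the read-through probability: real switches leak (some termination
    escapes even at full activation, some read-through persists at full
    repression).
    """

    polarity: str
    k_half: float
    hill: float = 1.0
    p_floor: float = 0.02
    p_ceil: float = 0.8
    ligand: str = "ligand"
    unit: str = "mM"

    def __post_init__(self) -> None:
        if self.polarity not in ("ON", "OFF"):
            raise ValueError(f"polarity must be ON or OFF, got {self.polarity!r}")
        if self.k_half <= 0:
            raise ValueError("k_half must be positive")
        if not 0 <= self.p_floor < self.p_ceil <= 1:
            raise ValueError(
                f"need 0 <= p_floor < p_ceil <= 1, got "
                f"({self.p_floor}, {self.p_ceil})"
            )


@dataclass(frozen=True)
class GateParams:
    """Parameters of the tandem gate: switch1 acts at T1, switch2 at T2.

    The switches are assumed independent (each aptamer has its own
    terminator and they do not interact); switch order is fixed with T1
    upstream of T2.
    """

    switch1: SwitchParams
    switch2: SwitchParams


def default_gate() -> GateParams:
    """Calibrated defaults for the tandem Na+ / c-di-AMP gate.

    Switch 1 (Na+, ON): ceiling 0.80 read-through at saturating Na+, hill 1
    (one-to-one ion binding). Switch 2 (c-di-AMP, OFF): floor 0.05
    read-through at saturating c-di-AMP (so at most ~5% of the T1
    read-through pool reaches FL), hill 2 (these riboswitches bind two
    c-di-AMP molecules). Midpoints are user parameters; defaults are
    order-of-magnitude placeholders (2.2 mM Na+, 1 μM c-di-AMP).
    """
    return GateParams(
        switch1=SwitchParams(
            "ON", k_half=2.2, hill=1.0, p_floor=0.02, p_ceil=0.80,
            ligand="Na+", unit="mM",
        ),
        switch2=SwitchParams(
            "OFF", k_half=1.0, hill=2.0, p_floor=0.05, p_ceil=0.95,
            ligand="c-di-AMP", unit="uM",
        ),
    )


def readthrough_prob(L: float, sw: SwitchParams) -> float:
    """Read-through probability of one switch at ligand concentration L.

    theta = L^h / (L^h + k_half^h); ON: p = p_floor + (p_ceil - p_floor) *
    theta; OFF: p = p_ceil - (p_ceil - p_floor) * theta.
    """
    if L < 0:
        raise ValueError("concentration must be non-negative")
    theta = isotherm(L, sw.k_half, sw.hill) if L > 0 else 0.0
    span = sw.p_ceil - sw.p_floor
    if sw.polarity == "ON":
        return sw.p_floor + span * theta
    return sw.p_ceil - span * theta


def partition(p1: float, p2: float) -> tuple[float, float, float]:
    """Analytic transcript partition for read-through probabilities (p1, p2).

    Each polymerase independently terminates at T1 with probability 1 - p1;
    survivors terminate at T2 with probability 1 - p2:
    f_T1 = 1 - p1, f_T2 = p1 * (1 - p2), f_FL = p1 * p2. Sums to 1.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} = {p} outside [0, 1]")
    f_t1 = 1.0 - p1
    f_t2 = p1 * (1.0 - p2)
    f_fl = p1 * p2
    return f_t1, f_t2, f_fl


@dataclass
class TruthTable:
    """FL-fraction predictions at the four ligand-level corners.

    ``rows`` maps (a_level, b_level) in {"low","high"}^2 to a dict with the
    concentrations, read-through probabilities, transcript fractions,
    Boolean output, and the output expected of a perfect A-and-Not-B gate.
    ``matches_a_and_not_b`` is True when the thresholded outputs reproduce
    material nonimplication: ON only at (A high, B low).
    """

    rows: dict[tuple[str, str], dict]
    on_threshold: float
    matches_a_and_not_b: bool


_EXPECTED_A_NOT_B = {
    ("low", "low"): False,
    ("low", "high"): False,
    ("high", "low"): True,
    ("high", "high"): False,
}


def evaluate_truth_table(
    gate: GateParams,
    a_levels: tuple[float, float] | None = None,
    b_levels: tuple[float, float] | None = None,
    on_threshold: float = 0.3,
) -> TruthTable:
    """Evaluate the gate at the four (A low/high, B low/high) corners.

    ``a_levels``/``b_levels`` are (low, high) concentrations per ligand;
    defaults are 0 and 1000 * k_half (saturating). Boolean output is
    FL fraction >= on_threshold.
    """
    if not 0 < on_threshold < 1:
        if on_threshold <= 0:
            warnings.warn(
                "on_threshold <= 0 is degenerate: every corner reads ON",
                stacklevel=2,
            )
        else:
            raise ValueError("on_threshold must be below 1")
    if a_levels is None:
        a_levels = (0.0, 1000.0 * gate.switch1.k_half)
    if b_levels is None:
        b_levels = (0.0, 1000.0 * gate.switch2.k_half)
    for name, (lo, hi) in (("A", a_levels), ("B", b_levels)):
        if not lo < hi:
            raise ValueError(f"{name} levels must satisfy low < high")

    rows: dict[tuple[str, str], dict] = {}
    for a_name, a in zip(("low", "high"), a_levels):
        for b_name, b in zip(("low", "high"), b_levels):
            p1 = readthrough_prob(a, gate.switch1)
            p2 = readthrough_prob(b, gate.switch2)
            f_t1, f_t2, f_fl = partition(p1, p2)
            rows[(a_name, b_name)] = {
                "conc_a": a,
                "conc_b": b,
                "p1": p1,
                "p2": p2,
                "fraction_T1": f_t1,
                "fraction_T2": f_t2,
                "fraction_FL": f_fl,
                "output": f_fl >= on_threshold,
                "expected": _EXPECTED_A_NOT_B[(a_name, b_name)],
            }
    matches = all(r["output"] == r["expected"] for r in rows.values())
    return TruthTable(rows=rows, on_threshold=on_threshold,
                      matches_a_and_not_b=matches)


def gate_fidelity(table: TruthTable) -> float:
    """Separation score of a truth table, in [-1, 1].

    min FL fraction over corners where a perfect A-and-Not-B gate is ON,
    minus max FL fraction over corners where it is OFF. Positive means the
    gate's outputs are separable by some threshold; 1 is a perfect gate.
    """
    on = [r["fraction_FL"] for r in table.rows.values() if r["expected"]]
    off = [r["fraction_FL"] for r in table.rows.values() if not r["expected"]]
    if not on or not off:
        raise ValueError("truth table incomplete")
    return min(on) - max(off)
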