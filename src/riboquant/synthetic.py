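"""Seeded generators for synthetic probing titrations and transcription gels.

The wet-lab assays these analyses were designed for produce autoradiogram
band volumes that are not deposited in any archive, so every downstream
stage here is exercised on synthetic data with the statistical structure
the analyses assume:

* in-line probing titrations — per-site scission intensities whose
  ligand-modulated sites follow a one-site binding isotherm, with
  multiplicative lognormal noise per band (densitometry noise scales with
  band volume);
* single-round transcription gels — per-molecule termination outcomes drawn
  binomially at each terminator, converted to band volumes by weighting
  each species with its relative radioactivity.

All generators are pure functions of their parameters and a seed, and store
the generating truth in a side-car that analyses never read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constructs import AptamerConstruct, TranscriptSpecies, define_species
from .probing import ProbingLane, TitrationSeries, isotherm
from .termination import LabelingScheme, TerminationLane, relative_radioactivity

__all__ = [
    "ProbingSiteSpec",
    "NoiseModel",
    "default_probing_sites",
    "simulate_titration",
    "simulate_transcription",
    "simulate_ion_panel",
    "random_construct",
    "titration_concentrations",
    "NA_BACKGROUND_MM",
    "effective_na_mM",
]

#: Transcription buffer contributes roughly 4 mM Na+ (from the polymerase
#: storage buffer) on top of any nominal supplementation.
NA_BACKGROUND_MM = 4.0


def effective_na_mM(nominal_mM: float, include_background: bool = True) -> float:
    """Effective Na+ concentration in a transcription reaction.

    The nominal supplementation plus the ~4 mM contributed by the reaction
    buffer itself (switchable off for buffers without the carry-over).
    """
    if nominal_mM < 0:
        raise ValueError("concentration must be non-negative")
    return nominal_mM + (NA_BACKGROUND_MM if include_background else 0.0)


@dataclass(frozen=True)
class ProbingSiteSpec:
    """Generating parameters for one scission site on a probing gel.

    ``role`` is "reference" (constant band used for normalization),
    "modulated" (intensity follows the binding isotherm) or "inert"
    (constant, not used for normalization). ``baseline`` is the intensity
    at zero ligand; ``amplitude`` the signed change at full saturation —
    negative for sites whose cleavage is suppressed by ligand binding,
    positive for sites that become more exposed.
    """

    site_id: str
    role: str
    baseline: float
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("reference", "modulated", "inert"):
            raise ValueError(f"unknown site role {self.role!r}")
        if self.baseline <= 0:
            raise ValueError("baseline intensity must be positive")
        if self.role != "modulated" and self.amplitude != 0:
            raise ValueError(f"{self.role} site must have amplitude 0")
        if self.role == "modulated" and self.amplitude == 0:
            raise ValueError("modulated site needs a nonzero amplitude")
        if self.baseline + self.amplitude <= 0:
            raise ValueError("saturated intensity must stay positive")

    @property
    def direction(self) -> str:
        return "suppressed" if self.amplitude < 0 else "enhanced"


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal band noise with unit mean.

    ``cv`` is the coefficient of variation of the noise factor; cv = 0
    yields exactly 1. The same (cv, seed) always produces the same stream.
    """

    cv: float = 0.10
    seed: int = 0
    family: str = "multiplicative-lognormal"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.family != "multiplicative-lognormal":
            raise ValueError(f"unknown noise family {self.family!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def factors(self, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
        """n unit-mean lognormal factors; sigma^2 = ln(1 + cv^2)."""
        if self.cv == 0:
            return np.ones(n)
        if rng is None:
            rng = self.rng()
        sigma2 = np.log1p(self.cv**2)
        return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


def default_probing_sites() -> list[ProbingSiteSpec]:
    """A realistic probing site panel: one enhanced site, one suppressed
    site (the two quantified sites), a constant reference band and one
    inert band."""
    return [
        ProbingSiteSpec("site1", "modulated", baseline=100.0, amplitude=150.0),
        ProbingSiteSpec("site2", "modulated", baseline=250.0, amplitude=-180.0),
        ProbingSiteSpec("refG", "reference", baseline=150.0),
        ProbingSiteSpec("inert1", "inert", baseline=80.0),
    ]


def titration_concentrations(
    lo_mM: float = 0.01,
    hi_mM: float = 100.0,
    n: int = 12,
    include_zero: bool = True,
) -> np.ndarray:
    """Log-spaced titration grid, optionally with a zero-ligand lane
    prepended. Defaults give 12 points spanning 10 uM to 100 mM (about
    three lanes per decade)."""
    grid = np.geomspace(lo_mM, hi_mM, n)
    if include_zero:
        grid = np.concatenate([[0.0], grid])
    return grid


def simulate_titration(
    true_kd: float,
    sites: list[ProbingSiteSpec],
    concentrations,
    noise: NoiseModel,
    hill: float = 1.0,
    saturation: float = 1.0,
    ligand: str = "Na+",
) -> TitrationSeries:
    """Generate one probing titration series.

    Modulated sites' expected intensity at ligand concentration L is
    ``baseline + amplitude * saturation * theta(L)`` with theta the Hill
    isotherm at ``true_kd``; reference and inert sites are constant in
    expectation. ``saturation`` < 1 models a titration whose top lane does
    not reach full saturation of the site response. Noise is applied per
    band independently. The zero-concentration lane is required (it anchors
    fraction bound downstream); the saturating anchor is the
    highest-concentration lane.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if not np.any(conc == 0):
        raise ValueError(
            "a zero-concentration lane is required (fraction-bound anchor)"
        )
    if true_kd <= 0:
        raise ValueError("true_kd must be positive")
    if not 0 < saturation <= 1:
        raise ValueError("saturation must be in (0, 1]")
    refs = [s for s in sites if s.role == "reference"]
    if len(refs) != 1:
        raise ValueError("exactly one reference site is required")

    rng = noise.rng()
    lanes = []
    for i, L in enumerate(conc):
        theta = isotherm(L, true_kd, hill) if L > 0 else 0.0
        expected = {
            s.site_id: s.baseline + s.amplitude * saturation * theta
            for s in sites
        }
        factors = noise.factors(len(sites), rng)
        lanes.append(
            ProbingLane(
                lane_id=f"L{i:02d}",
                ligand=ligand,
                concentration_mM=float(L),
                intensities={
                    sid: float(v * f)
                    for (sid, v), f in zip(expected.items(), factors)
                },
            )
        )
    zero_lane = lanes[int(np.argmin(conc))].lane_id
    sat_lane = lanes[int(np.argmax(conc))].lane_id
    return TitrationSeries(
        lanes=lanes,
        reference_site=refs[0].site_id,
        modulated_sites={
            s.site_id: s.direction for s in sites if s.role == "modulated"
        },
        zero_lane=zero_lane,
        sat_lane=sat_lane,
        truth={
            "true_kd_mM": true_kd,
            "hill": hill,
            "saturation": saturation,
            "cv": noise.cv,
            "seed": noise.seed,
        },
    )


def simulate_transcription(
    species: list[TranscriptSpecies],
    readthrough,
    n_molecules: int,
    labeling: LabelingScheme,
    lane_scale: float = 1.0,
    noise: NoiseModel | None = None,
    condition: str = "",
    lane_id: str = "sim",
) -> tuple[TerminationLane, dict[str, int]]:
    """Simulate one single-round transcription lane.

    Each of ``n_molecules`` polymerases passes each terminator in order
    with its read-through probability (binomial sampling); the band volume
    of species s is count(s) * R(s) * lane_scale * noise, with R(s) the
    relative radioactivity under ``labeling``. Returns the lane and the
    true molecule counts (the oracle side-car).
    """
    labels = [s.label for s in species]
    if "FL" not in labels:
        raise ValueError("species list must include FL")
    terminators = [l for l in labels if l != "FL"]
    probs = list(np.atleast_1d(np.asarray(readthrough, dtype=float)))
    if len(probs) != len(terminators):
        raise ValueError(
            f"{len(terminators)} terminator(s) but {len(probs)} read-through "
            "probabilities"
        )
    if any(not 0 <= p <= 1 for p in probs):
        raise ValueError("read-through probabilities must lie in [0, 1]")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    noise = noise or NoiseModel(cv=0.0, seed=0)
    if lane_scale <= 0:
        raise ValueError("lane_scale must be positive")

    rng = noise.rng()
    counts: dict[str, int] = {}
    remaining = int(n_molecules)
    for label, p in zip(terminators, probs):
        passed = int(rng.binomial(remaining, p)) if remaining else 0
        counts[label] = remaining - passed
        remaining = passed
    counts["FL"] = remaining

    factors = noise.factors(len(species), rng)
    intensities = {}
    for s, f in zip(species, factors):
        r = relative_radioactivity(s, labeling)
        intensities[s.label] = float(counts[s.label] * r * lane_scale * f)
    lane = TerminationLane(
        lane_id=lane_id, intensities=intensities, condition=condition
    )
    return lane, counts


def simulate_ion_panel(
    selective_ion: str,
    panel: list[str],
    true_kd: float,
    sites: list[ProbingSiteSpec],
    concentration: float,
    noise: NoiseModel,
    hill: float = 1.0,
) -> list[tuple[str, ProbingLane]]:
    """Generate a selectivity panel: one lane per candidate ion.

    Only the selective ion's lane deviates from baseline (its modulated
    sites at fraction bound L/(L + K_D)); every other ion's lane is
    generated at fraction bound 0, modelling an aptamer that rejects it.
    """
    if selective_ion not in panel:
        raise ValueError(f"selective ion {selective_ion!r} not in panel")
    rng = noise.rng()
    out = []
    for ion in panel:
        theta = (
            isotherm(concentration, true_kd, hill)
            if (ion == selective_ion and concentration > 0)
            else 0.0
        )
        factors = noise.factors(len(sites), rng)
        intensities = {
            s.site_id: float((s.baseline + s.amplitude * theta) * f)
            for s, f in zip(sites, factors)
        }
        out.append(
            (
                ion,
                ProbingLane(
                    lane_id=ion,
                    ligand=ion,
                    concentration_mM=float(concentration),
                    intensities=intensities,
                ),
            )
        )
    return out


def random_construct(
    seed: int,
    init_len: int = 13,
    elong_len: int = 157,
    u_run: int = 6,
    n_terminators: int = 1,
    name: str | None = None,
) -> AptamerConstruct:
    """Generate a random construct with the layout the assays assume.

    The initiation region (``init_len`` nt) contains exactly one C, at its
    last position — the halt site under the first-C rule. The elongation
    region (``elong_len`` nt) carries ``n_terminators`` intrinsic
    terminators, each marked by a run of ``u_run`` contiguous U residues
    whose last U is the terminated product's 3' end; terminator ends are
    evenly spaced and the full-length product ends at the last nucleotide.
    Remaining positions are drawn uniformly. Defaults give the 170-nt
    single-terminator geometry (13-nt initiation, halt at position 13).
    """
    if u_run < 1:
        raise ValueError("u_run must be >= 1")
    if init_len < 1 or elong_len < 1:
        raise ValueError("region lengths must be positive")
    if n_terminators < 0 or n_terminators > 2:
        raise ValueError("0, 1 or 2 terminators supported")

    total = init_len + elong_len
    term_ends = [
        init_len + round(elong_len * (i + 1) / (n_terminators + 1))
        for i in range(n_terminators)
    ]
    for prev, e in zip([init_len] + term_ends, term_ends):
        if e - prev < u_run or e >= total:
            raise ValueError(
                "elong_len too small to place the requested terminators "
                f"with u_run={u_run}"
            )

    rng = np.random.default_rng(seed)
    # initiation: no C before the final (halt) position
    seq = list(rng.choice(list("AGU"), size=init_len)) + list(
        rng.choice(list("ACGU"), size=elong_len)
    )
    seq[init_len - 1] = "C"
    for e in term_ends:
        for i in range(e - u_run, e):
            seq[i] = "U"

    labels = _terminator_labels(n_terminators)
    construct = AptamerConstruct(
        name=name or f"synthetic-{seed}",
        sequence="".join(seq),
        halt_index=init_len,
        species_ends=tuple(zip(labels, term_ends)) + (("FL", total),),
    )
    return construct


def _terminator_labels(n: int) -> list[str]:
    return {0: [], 1: ["T"], 2: ["T1", "T2"]}[n]
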