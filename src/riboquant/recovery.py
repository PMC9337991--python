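"""Parameter-recovery experiments: generator -> quantification round trips.

These drive the synthetic generators through the quantification code and
compare the recovered quantities with the generating truth. They are the
package's substitute for re-analysing the original autoradiograms (whose
raw densitometry is not deposited): if the quantification equations are
implemented correctly, they must recover the parameters the generator used.
"""

from __future__ import annotations

import numpy as np

from . import synthetic
from .gate import GateParams, default_gate, partition, readthrough_prob
from .probing import BindingFit, fit_kd
from .synthetic import NoiseModel, default_probing_sites
from .termination import LabelingScheme, TerminationResult, quantify_lane

__all__ = ["kd_recovery", "tandem_recovery", "gate_corner_recovery"]


def kd_recovery(
    true_kd: float,
    seeds,
    cv: float = 0.10,
    concentrations=None,
    sites=None,
    hill_mode: str = "fixed-1",
) -> np.ndarray:
    """Fitted K_D values from replicate synthetic titrations.

    One titration is generated per seed at ``true_kd`` (one-to-one
    isotherm, multiplicative noise of the given cv, default 12 half-log
    concentrations from 0.01 to 100 mM plus the zero anchor) and fitted
    with :func:`riboquant.probing.fit_kd`. Returns the array of fitted
    K_D values, typically summarized by its median.
    """
    if concentrations is None:
        concentrations = synthetic.titration_concentrations()
    if sites is None:
        sites = default_probing_sites()
    out = []
    for seed in seeds:
        series = synthetic.simulate_titration(
            true_kd=true_kd,
            sites=sites,
            concentrations=concentrations,
            noise=NoiseModel(cv=cv, seed=int(seed)),
        )
        out.append(fit_kd(series, hill_mode=hill_mode).kd_mM)
    return np.asarray(out)


def tandem_recovery(
    p1: float,
    p2: float,
    n_molecules: int = 100_000,
    labeling: LabelingScheme | None = None,
    cv: float = 0.0,
    seed: int = 0,
    construct_seed: int = 20_220_725,
) -> tuple[TerminationResult, dict[str, int]]:
    """Round trip through the tandem termination quantification.

    Simulates ``n_molecules`` polymerases through a synthetic tandem
    construct at read-through probabilities (p1, p2), converts counts to
    radiolabel-weighted band volumes, then recovers the species fractions
    with the correction-factor equations. Returns the recovered
    :class:`TerminationResult` and the true counts.
    """
    labeling = labeling or LabelingScheme.preset("tandem-2022")
    construct = synthetic.random_construct(
        seed=construct_seed, init_len=14, elong_len=300, u_run=6,
        n_terminators=2,
    )
    species = construct.species()
    lane, counts = synthetic.simulate_transcription(
        species=species,
        readthrough=(p1, p2),
        n_molecules=n_molecules,
        labeling=labeling,
        noise=NoiseModel(cv=cv, seed=seed),
    )
    return quantify_lane(lane, species, labeling), counts


def gate_corner_recovery(
    gate: GateParams | None = None,
    na_mM: float = 0.0,
    cdiamp: float = 0.0,
    n_molecules: int = 100_000,
    seed: int = 0,
    cv: float = 0.0,
) -> tuple[TerminationResult, tuple[float, float, float]]:
    """Simulate one gate operating point and recover its partition.

    Maps the two ligand concentrations to read-through probabilities with
    the gate's dose-response parameters, simulates and quantifies a lane,
    and returns the recovered fractions alongside the analytic partition.
    """
    gate = gate or default_gate()
    p1 = readthrough_prob(na_mM, gate.switch1)
    p2 = readthrough_prob(cdiamp, gate.switch2)
    result, _ = tandem_recovery(
        p1, p2, n_molecules=n_molecules, cv=cv, seed=seed
    )
    return result, partition(p1, p2)
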