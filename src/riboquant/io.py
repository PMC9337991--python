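"""File formats, run configuration and the reproducible pipeline runner.

Band tables travel as UTF-8 TSV with a mandatory header (condition labels
may contain commas, so TSV over CSV); results are written as JSON with
units embedded in key names (``kd_mM``) and every result file embeds the
hash of the run configuration that produced it, so re-running with the
stored configuration reproduces outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constructs import read_constructs_fasta
from .gate import SwitchParams, GateParams, default_gate, evaluate_truth_table, gate_fidelity
from .probing import BindingFit, ProbingLane, TitrationSeries, fit_kd, isotherm
from .recovery import gate_corner_recovery, kd_recovery, tandem_recovery
from .synthetic import (
    NoiseModel,
    default_probing_sites,
    titration_concentrations,
    simulate_titration,
    simulate_transcription,
    random_construct,
)
from .termination import LabelingScheme, TerminationLane, readthrough_series

logger = logging.getLogger(__name__)

PROBING_COLUMNS = ["lane_id", "ligand", "concentration_mM", "site", "intensity"]
TERMINATION_COLUMNS = ["lane_id", "condition", "species", "intensity"]


# ---------------------------------------------------------------- TSV I/O


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    num = pd.to_numeric(df["intensity"], errors="coerce")
    bad = df.index[num.isna()]
    if len(bad):
        raise ValueError(
            f"{path}: non-numeric intensity at data row {int(bad[0]) + 1} "
            f"(value {df.loc[bad[0], 'intensity']!r})"
        )
    df["intensity"] = num.astype(float)
    return df


def read_lanes(
    path,
    schema: str,
    reference_site: str | None = None,
    modulated_sites: dict[str, str] | None = None,
):
    """Read a lane TSV as a :class:`TitrationSeries` (schema="probing") or a
    list of :class:`TerminationLane` (schema="termination").

    Probing series need the reference site and modulated-site metadata,
    which are assay knowledge rather than gel data and therefore travel in
    configuration, not in the TSV. Anchor lanes are chosen as the zero- and
    highest-concentration lanes. Unknown columns are preserved as lane
    metadata where the container supports it.
    """
    if schema == "probing":
        df = _read_tsv(path, PROBING_COLUMNS)
        if reference_site is None or not modulated_sites:
            raise ValueError(
                "probing schema requires reference_site and modulated_sites"
            )
        df["concentration_mM"] = df["concentration_mM"].astype(float)
        lanes = []
        for (lane_id, ligand, conc), grp in sorted(
            df.groupby(["lane_id", "ligand", "concentration_mM"]),
            key=lambda kv: (kv[0][2], kv[0][0]),
        ):
            lanes.append(
                ProbingLane(
                    lane_id=str(lane_id),
                    ligand=str(ligand),
                    concentration_mM=float(conc),
                    intensities=dict(zip(grp["site"], grp["intensity"])),
                )
            )
        conc = [l.concentration_mM for l in lanes]
        zero_lane = lanes[int(np.argmin(conc))].lane_id
        sat_lane = lanes[int(np.argmax(conc))].lane_id
        logger.info(
            "probing series: anchors zero=%s sat=%s (by concentration)",
            zero_lane,
            sat_lane,
        )
        return TitrationSeries(
            lanes=lanes,
            reference_site=reference_site,
            modulated_sites=dict(modulated_sites),
            zero_lane=zero_lane,
            sat_lane=sat_lane,
        )
    if schema == "termination":
        df = _read_tsv(path, TERMINATION_COLUMNS)
        extra = [c for c in df.columns if c not in TERMINATION_COLUMNS]
        lanes = []
        for (lane_id, condition), grp in df.groupby(
            ["lane_id", "condition"], sort=False
        ):
            conc = None
            if "concentration_mM" in extra:
                conc = float(grp["concentration_mM"].iloc[0])
            lanes.append(
                TerminationLane(
                    lane_id=str(lane_id),
                    condition=str(condition),
                    concentration_mM=conc,
                    intensities=dict(zip(grp["species"], grp["intensity"])),
                )
            )
        return lanes
    raise ValueError(f"unknown schema {schema!r}")


def write_titration_tsv(series: TitrationSeries, path) -> None:
    rows = [
        {
            "lane_id": lane.lane_id,
            "ligand": lane.ligand,
            "concentration_mM": lane.concentration_mM,
            "site": site,
            "intensity": v,
        }
        for lane in series.lanes
        for site, v in lane.intensities.items()
    ]
    pd.DataFrame(rows, columns=PROBING_COLUMNS).to_csv(path, sep="\t", index=False)
    if series.truth is not None:
        Path(path).with_suffix(".truth.json").write_text(
            json.dumps(series.truth, indent=2)
        )


def write_termination_tsv(lanes: list[TerminationLane], path) -> None:
    rows = []
    for lane in lanes:
        for species, v in lane.intensities.items():
            row = {
                "lane_id": lane.lane_id,
                "condition": lane.condition,
                "species": species,
                "intensity": v,
            }
            if lane.concentration_mM is not None:
                row["concentration_mM"] = lane.concentration_mM
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fit_json(fit: BindingFit, series: TitrationSeries, path, config_hash=""):
    payload = {
        "kd_mM": fit.kd_mM,
        "hill": fit.hill,
        "top": fit.top,
        "bottom": fit.bottom,
        "residual_norm": fit.residual_norm,
        "n_sites_used": fit.n_sites_used,
        "anchor_ok": fit.anchor_ok,
        "fraction_bound": {
            lane.lane_id: fb
            for lane, fb in zip(series.lanes, fit.fraction_bound.tolist())
        },
        "config_hash": config_hash,
        "riboquant_version": __version__,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
    return payload


def write_fit_curve_tsv(fit: BindingFit, path, lo_mM=1e-3, hi_mM=1e3, n=121):
    """Smooth fitted curve for plotting the dose-response."""
    L = np.logspace(np.log10(lo_mM), np.log10(hi_mM), n)
    f = fit.bottom + fit.top * isotherm(L, fit.kd_mM, fit.hill)
    pd.DataFrame(
        {"concentration_mM": L, "fraction_bound_fit": f}
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- run config


@dataclass
class RunConfig:
    """Everything that determines a pipeline run's outputs.

    ``command`` selects the pipeline stage; ``seed`` feeds every source of
    randomness; ``params`` carries stage parameters; ``inputs``/``outputs``
    are paths. The serialized config plus input files fully determine the
    outputs.
    """

    command: str
    seed: int = 0
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            command=raw["command"],
            seed=int(raw.get("seed", 0)),
            params=raw.get("params", {}) or {},
            inputs=raw.get("inputs", {}) or {},
            outputs=raw.get("outputs", {}) or {},
        )

    def hash(self) -> str:
        canon = json.dumps(
            {
                "command": self.command,
                "seed": self.seed,
                "params": self.params,
                "inputs": {k: str(v) for k, v in self.inputs.items()},
            },
            sort_keys=True,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _result_json(path, config: RunConfig, payload: dict) -> dict:
    payload = dict(payload)
    payload["config_hash"] = config.hash()
    payload["riboquant_version"] = __version__
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload


def _gate_from_params(params: dict) -> GateParams:
    gate = default_gate()
    if "switch1" in params or "switch2" in params:
        from dataclasses import replace

        s1 = replace(gate.switch1, **params.get("switch1", {}))
        s2 = replace(gate.switch2, **params.get("switch2", {}))
        gate = GateParams(switch1=s1, switch2=s2)
    return gate


def run_pipeline(config: RunConfig) -> dict:
    """Execute one pipeline stage and write its result files.

    Returns the result payload (also written as JSON where an output path
    is configured). Every applied default is narrated at INFO level since
    those choices change numbers.
    """
    for key, path in config.inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {key!r}: {path} does not exist")
    cmd = config.command
    p = config.params
    logger.info("run %s (seed %d, config %s)", cmd, config.seed, config.hash())

    if cmd == "simulate-probing":
        series = simulate_titration(
            true_kd=float(p.get("true_kd_mM", 2.2)),
            sites=default_probing_sites(),
            concentrations=titration_concentrations(),
            noise=NoiseModel(cv=float(p.get("cv", 0.10)), seed=config.seed),
            hill=float(p.get("hill", 1.0)),
            saturation=float(p.get("saturation", 1.0)),
        )
        write_titration_tsv(series, config.outputs["lanes"])
        return {"lanes": len(series.lanes)}

    if cmd == "fit-kd":
        sites_meta = p.get(
            "modulated_sites", {"site1": "enhanced", "site2": "suppressed"}
        )
        series = read_lanes(
            config.inputs["lanes"],
            "probing",
            reference_site=p.get("reference_site", "refG"),
            modulated_sites=sites_meta,
        )
        fit = fit_kd(
            series,
            sites=p.get("sites"),
            hill_mode=p.get("hill_mode", "fixed-1"),
            top_mode=p.get("top_mode", "free"),
        )
        payload = write_fit_json(
            fit, series, config.outputs["fit"], config.hash()
        )
        if "curve" in config.outputs:
            write_fit_curve_tsv(fit, config.outputs["curve"])
        return payload

    if cmd == "simulate-transcription":
        construct = random_construct(
            seed=int(p.get("construct_seed", config.seed)),
            init_len=int(p.get("init_len", 14)),
            elong_len=int(p.get("elong_len", 300)),
            u_run=int(p.get("u_run", 6)),
            n_terminators=int(p.get("n_terminators", 2)),
        )
        species = construct.species()
        lane, counts = simulate_transcription(
            species=species,
            readthrough=p.get("readthrough", [0.8, 0.95]),
            n_molecules=int(p.get("n_molecules", 100_000)),
            labeling=LabelingScheme.preset(p.get("labeling", "tandem-2022")),
            noise=NoiseModel(cv=float(p.get("cv", 0.0)), seed=config.seed),
            condition=str(p.get("condition", "")),
        )
        write_termination_tsv([lane], config.outputs["lanes"])
        return {"counts": counts, "construct": construct.name}

    if cmd == "quantify-termination":
        if "construct" in config.inputs:
            construct = read_constructs_fasta(
                config.inputs["construct"],
                halt_rule=p.get("halt_rule", "first-C"),
                terminator_ends=p.get("terminator_ends", ()),
            )[0]
        else:
            construct = random_construct(
                seed=int(p.get("construct_seed", config.seed)),
                init_len=int(p.get("init_len", 14)),
                elong_len=int(p.get("elong_len", 300)),
                u_run=int(p.get("u_run", 6)),
                n_terminators=int(p.get("n_terminators", 2)),
            )
        species = construct.species()
        lanes = read_lanes(config.inputs["lanes"], "termination")
        labeling = LabelingScheme.preset(p.get("labeling", "tandem-2022"))
        per_lane, per_condition = readthrough_series(lanes, species, labeling)
        per_lane.to_csv(config.outputs["fractions"], sep="\t", index=False)
        payload = {
            "per_condition": per_condition.to_dict(orient="records"),
            "n_lanes": len(per_lane),
        }
        if "summary" in config.outputs:
            _result_json(config.outputs["summary"], config, payload)
        return payload

    if cmd == "simulate-gate":
        gate = _gate_from_params(p)
        corners = {}
        for i, (a_name, b_name) in enumerate(
            [("low", "low"), ("low", "high"), ("high", "low"), ("high", "high")]
        ):
            na = 0.0 if a_name == "low" else 1000.0 * gate.switch1.k_half
            cda = 0.0 if b_name == "low" else 1000.0 * gate.switch2.k_half
            result, analytic = gate_corner_recovery(
                gate,
                na_mM=na,
                cdiamp=cda,
                n_molecules=int(p.get("n_molecules", 100_000)),
                seed=config.seed + i,
                cv=float(p.get("cv", 0.0)),
            )
            corners[f"Na_{a_name}__cdiAMP_{b_name}"] = {
                "recovered": result.fractions,
                "analytic": dict(zip(("T1", "T2", "FL"), analytic)),
            }
        payload = {"corners": corners}
        if "result" in config.outputs:
            _result_json(config.outputs["result"], config, payload)
        return payload

    if cmd == "gate-evaluate":
        gate = _gate_from_params(p)
        table = evaluate_truth_table(
            gate, on_threshold=float(p.get("on_threshold", 0.3))
        )
        payload = {
            "on_threshold": table.on_threshold,
            "matches_a_and_not_b": table.matches_a_and_not_b,
            "fidelity": gate_fidelity(table),
            "rows": {
                f"Na_{a}__cdiAMP_{b}": row
                for (a, b), row in table.rows.items()
            },
        }
        if "result" in config.outputs:
            _result_json(config.outputs["result"], config, payload)
        return payload

    if cmd == "demo":
        n_seeds = int(p.get("n_seeds", 20))
        kds = kd_recovery(
            true_kd=float(p.get("true_kd_mM", 2.2)),
            seeds=range(config.seed, config.seed + n_seeds),
            cv=float(p.get("cv", 0.10)),
        )
        result, _ = tandem_recovery(0.8, 0.95, seed=config.seed)
        table = evaluate_truth_table(default_gate())
        payload = {
            "median_kd_mM": float(np.median(kds)),
            "percent_past_T1": 100.0 * result.readthrough["T1"],
            "gate_matches_a_and_not_b": table.matches_a_and_not_b,
            "gate_fidelity": gate_fidelity(table),
        }
        if "result" in config.outputs:
            _result_json(config.outputs["result"], config, payload)
        return payload

    raise ValueError(f"unknown command {config.command!r}")
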