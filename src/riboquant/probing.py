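"""In-line probing quantification: fraction bound and K_D estimation.

In-line probing reads out ligand-induced RNA structure change through the
rate of spontaneous strand scission: internucleotide linkages in
unstructured regions cleave faster, so band intensities at specific sites
rise or fall as ligand is titrated. Quantification proceeds in three steps:

1. each lane's band intensities are normalized to a constant-intensity
   reference band in the same lane (removing loading differences);
2. each ligand-modulated site's normalized intensities are rescaled to a
   fraction bound between 0 and 1, anchored to the no-ligand lane (0) and a
   saturating-ligand lane (1);
3. the pooled fraction-bound curve is fitted with a sigmoidal dose-response
   (Hill) equation against log10 ligand concentration, and the midpoint is
   reported as the apparent dissociation constant K_D.

The default fit pins the Hill slope at 1 (one-to-one binding) and lets the
top amplitude float, because the highest-concentration lane used as the
"fraction bound = 1" anchor need not be truly saturating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ProbingLane",
    "TitrationSeries",
    "BindingFit",
    "normalize_lane",
    "fraction_bound_series",
    "isotherm",
    "fit_kd",
    "classify_ion_response",
]


@dataclass(frozen=True)
class ProbingLane:
    """One gel lane: ligand identity, concentration and per-site band volumes."""

    lane_id: str
    ligand: str
    concentration_mM: float
    intensities: dict[str, float]


@dataclass
class TitrationSeries:
    """An ordered series of probing lanes for one ligand titration.

    ``reference_site`` is the constant-intensity band used for per-lane
    normalization; ``modulated_sites`` maps each quantified site to its
    direction of change ("suppressed" or "enhanced"); ``zero_lane`` and
    ``sat_lane`` are the lane ids anchoring fraction bound 0 and 1.

    ``truth`` is an optional side-car written by the synthetic generator
    recording the generating parameters; analyses never read it.
    """

    lanes: list[ProbingLane]
    reference_site: str
    modulated_sites: dict[str, str]
    zero_lane: str
    sat_lane: str
    truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.lanes:
            raise ValueError("titration series has no lanes")
        sites = set(self.lanes[0].intensities)
        for lane in self.lanes:
            if set(lane.intensities) != sites:
                raise ValueError(
                    f"lane {lane.lane_id}: site set differs from first lane"
                )
            for site, v in lane.intensities.items():
                if not v > 0:
                    raise ValueError(
                        f"lane {lane.lane_id}, site {site}: intensity {v} "
                        "must be positive"
                    )
        ids = [lane.lane_id for lane in self.lanes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate lane ids")
        for anchor in (self.zero_lane, self.sat_lane):
            if anchor not in ids:
                raise ValueError(f"anchor lane {anchor!r} not in series")
        if self.lane(self.zero_lane).concentration_mM != 0:
            raise ValueError("zero anchor lane must have concentration 0")
        if self.reference_site not in sites:
            raise ValueError(f"reference site {self.reference_site!r} absent")
        missing = set(self.modulated_sites) - sites
        if missing:
            raise ValueError(f"modulated sites absent from lanes: {missing}")

    def lane(self, lane_id: str) -> ProbingLane:
        for lane in self.lanes:
            if lane.lane_id == lane_id:
                return lane
        raise KeyError(lane_id)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([l.concentration_mM for l in self.lanes], dtype=float)

    @property
    def sites(self) -> list[str]:
        return sorted(self.lanes[0].intensities)


@dataclass
class BindingFit:
    """Result of a sigmoidal dose-response fit.

    ``kd_mM`` is the midpoint concentration; ``hill`` the (fitted or pinned)
    slope; ``top`` and ``bottom`` the fitted plateaus of the fraction-bound
    scale; ``fraction_bound`` the per-lane site-averaged values in series
    order. ``anchor_ok`` is False when any fraction-bound value falls
    outside [-0.2, 1.2], signalling anchor failure.
    """

    kd_mM: float
    hill: float
    top: float
    bottom: float
    fraction_bound: np.ndarray
    residual_norm: float
    n_sites_used: int
    anchor_ok: bool = True


def normalize_lane(lane: ProbingLane, reference_site: str) -> dict[str, float]:
    """Divide every band by the lane's reference band (reference maps to 1)."""
    ref = lane.intensities.get(reference_site)
    if ref is None:
        raise ValueError(
            f"lane {lane.lane_id}: reference site {reference_site!r} absent"
        )
    if ref <= 0:
        raise ValueError(
            f"lane {lane.lane_id}: reference intensity {ref} is not positive"
        )
    return {site: v / ref for site, v in lane.intensities.items()}


def fraction_bound_series(
    series: TitrationSeries,
    site: str,
    rel_tol: float = 1e-6,
) -> np.ndarray:
    """Fraction-bound values for one modulated site, in lane order.

    f = (I_norm - I_norm(zero anchor)) / (I_norm(sat anchor) - I_norm(zero
    anchor)). The anchor difference carries the direction of modulation, so
    the same formula serves suppressed and enhanced sites.
    """
    if site not in series.modulated_sites:
        raise ValueError(f"site {site!r} is not declared as modulated")
    norm = [normalize_lane(l, series.reference_site)[site] for l in series.lanes]
    ids = [l.lane_id for l in series.lanes]
    i0 = norm[ids.index(series.zero_lane)]
    i1 = norm[ids.index(series.sat_lane)]
    span = i1 - i0
    if abs(span) <= rel_tol * max(abs(i0), abs(i1)):
        raise ValueError(
            f"site {site!r} not modulated: anchor intensities differ by "
            f"{span:.3g} only"
        )
    return (np.asarray(norm) - i0) / span


def isotherm(L, kd: float, hill: float = 1.0):
    """One-site binding isotherm: fraction bound = L^h / (L^h + K_D^h).

    ``hill = 1`` is the one-to-one binding model; L may be scalar or array,
    in the same concentration units as ``kd``.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if hill <= 0:
        raise ValueError("hill slope must be positive")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("concentrations must be non-negative")
    with np.errstate(divide="ignore"):
        lh = np.power(L, hill)
    out = lh / (lh + kd**hill)
    return out if out.ndim else float(out)


def fit_kd(
    series: TitrationSeries,
    sites: list[str] | None = None,
    hill_mode: str = "fixed-1",
    top_mode: str = "free",
    bottom_mode: str = "free",
) -> BindingFit:
    """Fit the sigmoidal dose-response to a titration and estimate K_D.

    Fraction-bound curves of the requested sites (default: all modulated
    sites) are averaged into one curve, and the model ``bottom + top *
    L^h / (L^h + K_D^h)`` is least-squares fitted on log10 concentration.
    The zero-concentration lane anchors the fraction-bound scale but is
    excluded from the regression (log undefined at L = 0).

    The regression is variance-weighted: with multiplicative band noise,
    the fraction-bound error of a lane scales with its normalized band
    intensity divided by the anchor span, so weights are propagated from
    the measured bands (only relative weights matter).

    ``hill_mode``: "fixed-1" pins h = 1 (one-to-one binding); "free" fits
    it (the stoichiometry check). ``top_mode``/``bottom_mode``: "free"
    (default) fits the plateau, as the saturating anchor need not sit at
    full saturation and anchor-lane noise offsets the whole curve;
    "fixed-1"/"fixed-0" pin the plateaus to the anchor values.
    """
    if hill_mode not in ("fixed-1", "free"):
        raise ValueError(f"unknown hill_mode {hill_mode!r}")
    if top_mode not in ("fixed-1", "free"):
        raise ValueError(f"unknown top_mode {top_mode!r}")
    if bottom_mode not in ("fixed-0", "free"):
        raise ValueError(f"unknown bottom_mode {bottom_mode!r}")
    if sites is None:
        sites = sorted(series.modulated_sites)
    if not sites:
        raise ValueError("no sites to fit")

    fb = np.mean([fraction_bound_series(series, s) for s in sites], axis=0)
    conc = series.concentrations
    pos = conc > 0
    if len(np.unique(conc[pos])) < 4:
        raise ValueError(
            "need at least 4 distinct nonzero concentrations for the fit"
        )
    anchor_ok = bool(np.all((fb > -0.2) & (fb < 1.2)))
    if not anchor_ok:
        warnings.warn(
            "fraction-bound values outside [-0.2, 1.2]: anchor lanes may not "
            "bracket the transition",
            stacklevel=2,
        )
    # modulation strength: relative change of the normalized band between
    # the two anchor lanes (the fraction-bound scale itself is anchored to
    # [0, 1] by construction, so it cannot carry this diagnostic)
    n0 = normalize_lane(series.lane(series.zero_lane), series.reference_site)
    n1 = normalize_lane(series.lane(series.sat_lane), series.reference_site)
    rel_span = float(np.mean([abs(n1[s] - n0[s]) / n0[s] for s in sites]))
    if rel_span < 0.5:
        warnings.warn(
            f"weak modulation: mean relative anchor-band change {rel_span:.2f}"
            " < 0.5",
            stacklevel=2,
        )

    # propagated noise scale per lane: sd(fraction bound) is proportional
    # to the normalized band level over the anchor span for each site
    all_norm = [normalize_lane(l, series.reference_site) for l in series.lanes]
    sigma = np.sqrt(
        np.array(
            [
                np.mean([(n[s] / abs(n1[s] - n0[s])) ** 2 for s in sites])
                for n in all_norm
            ]
        )
        / len(sites)
    )

    x = np.log10(conc[pos])
    y = fb[pos]
    w = sigma[pos]
    free_hill = hill_mode == "free"
    free_top = top_mode == "free"
    free_bottom = bottom_mode == "free"

    def unpack(theta):
        log_kd = theta[0]
        i = 1
        hill = theta[i] if free_hill else 1.0
        i += free_hill
        top = theta[i] if free_top else 1.0
        i += free_top
        bottom = theta[i] if free_bottom else 0.0
        return log_kd, hill, top, bottom

    def resid(theta):
        log_kd, hill, top, bottom = unpack(theta)
        return (bottom + top * isotherm(10.0**x, 10.0**log_kd, hill) - y) / w

    p0 = [float(np.median(x))]
    lo = [x.min() - 3.0]
    hi = [x.max() + 3.0]
    if free_hill:
        p0.append(1.0), lo.append(0.1), hi.append(10.0)
    if free_top:
        p0.append(1.0), lo.append(0.05), hi.append(5.0)
    if free_bottom:
        p0.append(0.0), lo.append(-0.5), hi.append(0.5)

    sol = least_squares(resid, p0, bounds=(lo, hi), max_nfev=5000)
    if not sol.success:
        raise RuntimeError(
            f"dose-response fit did not converge (status {sol.status}); "
            f"best iterate: {sol.x}"
        )
    log_kd, hill, top, bottom = unpack(sol.x)
    return BindingFit(
        kd_mM=float(10.0**log_kd),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        fraction_bound=fb,
        residual_norm=float(np.linalg.norm(sol.fun)),
        n_sites_used=len(sites),
        anchor_ok=anchor_ok,
    )


def classify_ion_response(
    panel: list[tuple[str, ProbingLane]],
    baseline: "ProbingLane | list[ProbingLane]",
    modulated_sites: dict[str, str],
    reference_site: str,
    effect_threshold: float = 0.2,
) -> dict[str, dict]:
    """Classify each ion of a selectivity panel as modulating or not.

    ``modulated_sites`` maps each quantified site to its known direction of
    change ("enhanced" or "suppressed"). The effect size of an ion is the
    direction-aligned mean relative change of reference-normalized
    intensity at those sites versus the no-ligand baseline — signing each
    site's change by its expected direction lets incoherent band noise
    cancel while a genuine structural response accumulates. Replicate
    lanes (repeated ion entries in ``panel``, or a list of baseline lanes)
    are averaged on the normalized scale before the comparison. An ion is
    modulating when its effect exceeds ``effect_threshold`` times the
    largest effect in the panel (default 0.2, i.e. a fifth of the
    strongest responder's effect).
    """
    if not panel:
        raise ValueError("empty ion panel")
    if effect_threshold <= 0:
        warnings.warn(
            "effect_threshold <= 0 is degenerate: every ion with any "
            "nonzero change will be called modulating",
            stacklevel=2,
        )
    signs = {}
    for site, direction in modulated_sites.items():
        if direction not in ("enhanced", "suppressed"):
            raise ValueError(f"site {site}: unknown direction {direction!r}")
        signs[site] = 1.0 if direction == "enhanced" else -1.0

    baselines = [baseline] if isinstance(baseline, ProbingLane) else list(baseline)
    base_norms = [normalize_lane(l, reference_site) for l in baselines]
    base = {
        s: float(np.mean([n[s] for n in base_norms])) for s in base_norms[0]
    }

    by_ion: dict[str, list[dict[str, float]]] = {}
    for ion, lane in panel:
        by_ion.setdefault(ion, []).append(normalize_lane(lane, reference_site))
    effects: dict[str, float] = {}
    for ion, norms in by_ion.items():
        mean_norm = {s: float(np.mean([n[s] for n in norms])) for s in norms[0]}
        effects[ion] = abs(
            float(
                np.mean(
                    [
                        signs[s] * (mean_norm[s] - base[s]) / base[s]
                        for s in modulated_sites
                    ]
                )
            )
        )
    # effects at rounding level are indistinguishable from "no change"
    effects = {k: (0.0 if v < 1e-9 else v) for k, v in effects.items()}
    max_effect = max(effects.values())
    out = {}
    for ion, eff in effects.items():
        rel = eff / max_effect if max_effect > 0 else 0.0
        out[ion] = {
            "effect": eff,
            "relative_effect": rel,
            "modulating": max_effect > 0 and eff > effect_threshold * max_effect,
        }
    return out
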