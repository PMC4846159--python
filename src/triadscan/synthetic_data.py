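"""Synthetic stand-ins for the pipeline's two experimental inputs.

The original conformational ensembles (hundreds of nanoseconds of explicit-
solvent MD) and the raw absorbance curves are not distributable, so every
analysis stage is exercised against generated data with known ground truth:

* **Ensembles** — frames of an idealized structure model with i.i.d. Gaussian
  positional jitter, optionally with a *planted* catalytic triad that is made
  geometrically competent in a Bernoulli(p)-chosen subset of frames.  Planted
  competent geometry places the three designated atoms on an equilateral
  triangle of side 0.8 x cutoff; incompetent frames force them beyond
  1.4 x cutoff.  The guard band around the cutoff, together with the planted
  atoms being placed exactly (not jittered), makes the frame labels provably
  noise-proof, so the occupancy analysis must recover the realized Bernoulli
  fraction exactly.  Planted atoms sit on a staging site offset from the
  model's bounding box so they cannot collide with the rest of the structure.

* **Kinetics traces** — absorbance at 400 nm following a burst-plus-linear
  product model P(t) = A0 (1 - e^(-kb t)) + (v_ss + v_bg) t (the burst shape
  of acyl-intermediate hydrolases), plus an optional linear turbidity ramp
  shared with an independently-noised reference channel.  Panel fixtures are
  calibrated: the steady rate is solved so that the documented analysis
  (OLS initial rate over the default window, or the 1200 s endpoint,
  normalized by the no-peptide control) recovers each construct's designed
  fold exactly on a noiseless trace.

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .peptide_models import StructureModel
from .trajectory_io import Trajectory, DEFAULT_FRAME_SPACING_PS, atom_records
from .triad_analysis import Triad, DEFAULT_CUTOFF
from .kinetics_analysis import (
    KineticsTrace,
    EPSILON_PNP,
    METHOD_INITIAL_RATE,
    METHOD_ENDPOINT,
)

__all__ = [
    "JitterSpec",
    "PlantSpec",
    "KineticFixture",
    "PanelDefaults",
    "jitter_trajectory",
    "plant_triad",
    "simulate_trace",
    "make_panel_fixtures",
    "product_concentration",
    "expected_initial_rate",
    "load_fixture_config",
]

DEFAULT_JITTER_SIGMA = 0.3  # Angstrom per coordinate; sub-bond-length thermal wiggle


@dataclass(frozen=True)
class JitterSpec:
    """Gaussian positional noise applied per coordinate, per frame."""

    sigma: float = DEFAULT_JITTER_SIGMA
    n_frames: int = 100
    seed: int = 0
    frame_spacing_ps: float = DEFAULT_FRAME_SPACING_PS

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass(frozen=True)
class PlantSpec:
    """A triad identity to make competent in a controlled fraction of frames."""

    triad: Triad
    occupancy: float
    cutoff: float = DEFAULT_CUTOFF
    competent_scale: float = 0.8
    incompetent_scale: float = 1.4
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if not 0 < self.competent_scale < 1.0 <= self.incompetent_scale:
            raise ValueError(
                "need competent_scale < 1 <= incompetent_scale around the cutoff"
            )


def jitter_trajectory(model: StructureModel, spec: JitterSpec) -> Trajectory:
    """n_frames copies of the model with i.i.d. Gaussian coordinate noise."""
    rng = np.random.default_rng(spec.seed)
    base = model.coords()
    noise = (rng.normal(0.0, spec.sigma, size=(spec.n_frames,) + base.shape)
             if spec.sigma > 0 else np.zeros((spec.n_frames,) + base.shape))
    return Trajectory(model.copy(), base[None, :, :] + noise,
                      frame_spacing_ps=spec.frame_spacing_ps)


_PLANT_ATOM_PREFERENCE = {
    "hydroxyl": ("OG", "OG1"),
    "his": ("NE2", "ND1"),
    "acid": ("OE1", "OD1"),
    "cterm": ("OXT", "O"),
}


def _resolve_designated_atoms(model: StructureModel, triad: Triad) -> list:
    """Topology indices of one designated atom per triad member."""
    records = atom_records(model)
    indices = []
    for ref in (triad.hydroxyl, triad.his, triad.acid):
        wanted = _PLANT_ATOM_PREFERENCE[ref.role]
        found = None
        for name in wanted:
            for i, cid, rid, rname, aname in records:
                if (cid, rid, rname, aname) == (ref.chain_id, ref.res_id,
                                                ref.res_name, name):
                    found = i
                    break
            if found is not None:
                break
        if found is None:
            raise ValueError(
                f"triad member {ref.label} ({ref.role}) not resolvable in topology"
            )
        indices.append(found)
    return indices


def plant_triad(model: StructureModel, plant: PlantSpec,
                jitter: JitterSpec) -> Trajectory:
    """Jittered ensemble with one triad competent in ~occupancy of frames.

    The designated atoms are placed exactly (no jitter): competent frames set
    all three pairwise distances to ``competent_scale * cutoff``, incompetent
    frames to at least ``incompetent_scale * cutoff``, on a staging site
    offset +X from the model bounding box so no other atom interferes.
    """
    designated = _resolve_designated_atoms(model, plant.triad)
    traj = jitter_trajectory(model, jitter)
    frames = traj.frames
    base = model.coords()
    margin = max(15.0, 2 * plant.incompetent_scale * plant.cutoff)
    site = np.array([base[:, 0].max() + margin, 0.0, 0.0])
    side = plant.competent_scale * plant.cutoff
    competent_xyz = site + np.array([
        [0.0, 0.0, 0.0],
        [side, 0.0, 0.0],
        [side / 2.0, side * np.sqrt(3.0) / 2.0, 0.0],
    ])
    gap = plant.incompetent_scale * plant.cutoff
    incompetent_xyz = site + np.array([
        [0.0, 0.0, 0.0],
        [gap, 0.0, 0.0],
        [2.0 * gap, 0.0, 0.0],
    ])
    rng = np.random.default_rng(plant.seed)
    competent = rng.random(jitter.n_frames) < plant.occupancy
    for f in range(jitter.n_frames):
        xyz = competent_xyz if competent[f] else incompetent_xyz
        frames[f, designated, :] = xyz
    return Trajectory(traj.topology, frames,
                      frame_spacing_ps=jitter.frame_spacing_ps)


# ---------------------------------------------------------------------------
# Kinetics fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelDefaults:
    """Shared assay parameters of the fixture panel."""

    background_rate_M_s: float
    noise_sigma_AU: float
    duration_s: float
    dt_s: float
    rate_window_s: float
    endpoint_s: float
    epsilon_M_cm: float = EPSILON_PNP
    pathlength_cm: float = 1.0


@dataclass(frozen=True)
class KineticFixture:
    """Ground-truth parameters of one synthetic absorbance trace."""

    panel_id: int
    label: str
    designed_fold: float
    burst_amplitude_M: float
    burst_rate_per_s: float
    steady_rate_M_s: float
    background_rate_M_s: float
    turbidity_ramp_AU_s: float
    noise_sigma_AU: float
    seed: int
    method: str = METHOD_INITIAL_RATE

    def __post_init__(self):
        for name in ("burst_amplitude_M", "burst_rate_per_s", "steady_rate_M_s",
                     "background_rate_M_s", "turbidity_ramp_AU_s",
                     "noise_sigma_AU"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def product_concentration(fixture: KineticFixture, time_s) -> np.ndarray:
    """Closed-form product concentration P(t) of the burst-plus-linear model
    (catalyzed + uncatalyzed background), in molar."""
    t = np.asarray(time_s, dtype=float)
    burst = (fixture.burst_amplitude_M
             * -np.expm1(-fixture.burst_rate_per_s * t)
             if fixture.burst_amplitude_M > 0 else 0.0)
    return burst + (fixture.steady_rate_M_s + fixture.background_rate_M_s) * t


def expected_initial_rate(fixture: KineticFixture, time_s,
                          window_s: float) -> float:
    """Closed-form OLS slope of P(t) over the sampled window: the value the
    initial-rate analysis must recover on a noiseless trace."""
    t = np.asarray(time_s, dtype=float)
    mask = t <= t[0] + window_s
    tw = t[mask]
    p = product_concentration(fixture, tw)
    tc = tw - tw.mean()
    return float(np.dot(tc, p - p.mean()) / np.dot(tc, tc))


def simulate_trace(fixture: KineticFixture,
                   duration_s: float = 1800.0,
                   dt_s: float = 5.0,
                   epsilon: float = EPSILON_PNP,
                   pathlength_cm: float = 1.0) -> KineticsTrace:
    """Reaction + reference absorbance channels for a fixture.

    Reaction channel: epsilon * l * P(t) + turbidity ramp + noise.
    Reference channel (separately prepared, no substrate): ramp + independent
    noise.  Reproducible per fixture seed.
    """
    if duration_s <= 0 or dt_s <= 0:
        raise ValueError("duration and dt must be > 0")
    rng = np.random.default_rng(fixture.seed)
    t = np.arange(0.0, duration_s + dt_s / 2.0, dt_s)
    signal = epsilon * pathlength_cm * product_concentration(fixture, t)
    ramp = fixture.turbidity_ramp_AU_s * t
    if fixture.noise_sigma_AU > 0:
        noise_rxn = rng.normal(0.0, fixture.noise_sigma_AU, t.shape)
        noise_ref = rng.normal(0.0, fixture.noise_sigma_AU, t.shape)
    else:
        noise_rxn = noise_ref = np.zeros_like(t)
    return KineticsTrace(
        time_s=t,
        absorbance=signal + ramp + noise_rxn,
        reference=ramp + noise_ref,
        label=fixture.label,
        pathlength_cm=pathlength_cm,
    )


def load_fixture_config() -> dict:
    text = resources.files("triadscan.data").joinpath(
        "kinetics_fixtures.yaml").read_text()
    return yaml.safe_load(text)


def _solve_steady_rate(entry: dict, defaults: PanelDefaults) -> float:
    """Steady catalytic rate that makes the documented analysis recover the
    designed fold exactly on a noiseless trace."""
    fold = float(entry["designed_fold"])
    v_bg = defaults.background_rate_M_s
    a0 = float(entry["burst_amplitude_M"])
    kb = float(entry["burst_rate_per_s"])
    method = entry.get("method", METHOD_INITIAL_RATE)
    if method == METHOD_INITIAL_RATE:
        # OLS slope of the burst term over the sampled analysis window
        t = np.arange(0.0, defaults.duration_s + defaults.dt_s / 2.0,
                      defaults.dt_s)
        tw = t[t <= defaults.rate_window_s]
        burst = a0 * -np.expm1(-kb * tw) if a0 > 0 else np.zeros_like(tw)
        tc = tw - tw.mean()
        s_burst = float(np.dot(tc, burst - burst.mean()) / np.dot(tc, tc))
        v_ss = fold * v_bg - v_bg - s_burst
    elif method == METHOD_ENDPOINT:
        te = defaults.endpoint_s
        burst_at_end = a0 * -np.expm1(-kb * te) if a0 > 0 else 0.0
        v_ss = fold * v_bg - v_bg - burst_at_end / te
    else:
        raise ValueError(f"unknown method {method!r} in fixture config")
    if v_ss < 0:
        raise ValueError(
            f"fixture {entry.get('label')}: burst term alone exceeds the "
            f"designed fold; reduce burst_amplitude_M"
        )
    return v_ss


def make_panel_fixtures(seed: int, noise_sigma_AU: float | None = None):
    """Build the 12-entry fixture panel plus the no-peptide control.

    Returns ``(fixtures, control, defaults)`` where ``fixtures`` maps
    panel_id (1..12) to :class:`KineticFixture`; panel entry 1 is the
    standard itself (designed fold 1.0) and ``control`` is an independently
    seeded replicate of it used as the normalization denominator (the
    physically separate control cuvette).  Set ``noise_sigma_AU=0`` for the
    noiseless calibration fixtures.
    """
    raw = load_fixture_config()
    d = raw["defaults"]
    defaults = PanelDefaults(
        background_rate_M_s=float(d["background_rate_M_s"]),
        noise_sigma_AU=float(d["noise_sigma_AU"]),
        duration_s=float(d["duration_s"]),
        dt_s=float(d["dt_s"]),
        rate_window_s=float(d["rate_window_s"]),
        endpoint_s=float(d["endpoint_s"]),
        epsilon_M_cm=float(d["epsilon_M_cm"]),
        pathlength_cm=float(d["pathlength_cm"]),
    )
    sigma = defaults.noise_sigma_AU if noise_sigma_AU is None else float(noise_sigma_AU)

    def build(entry: dict, sub_seed: int) -> KineticFixture:
        return KineticFixture(
            panel_id=int(entry["panel_id"]),
            label=str(entry["label"]),
            designed_fold=float(entry["designed_fold"]),
            burst_amplitude_M=float(entry["burst_amplitude_M"]),
            burst_rate_per_s=float(entry["burst_rate_per_s"]),
            steady_rate_M_s=_solve_steady_rate(entry, defaults),
            background_rate_M_s=defaults.background_rate_M_s,
            turbidity_ramp_AU_s=float(entry["turbidity_ramp_AU_s"]),
            noise_sigma_AU=sigma,
            seed=sub_seed,
            method=entry.get("method", METHOD_INITIAL_RATE),
        )

    fixtures = {}
    entry1 = dict(raw["control"])
    fixtures[1] = build(entry1, _sub_seed(seed, 1))
    for entry in raw["fixtures"]:
        fx = build(entry, _sub_seed(seed, int(entry["panel_id"])))
        fixtures[fx.panel_id] = fx
    control = build(entry1, _sub_seed(seed, 0))
    return fixtures, control, defaults


def _sub_seed(seed: int, stream: int) -> int:
    """Derived per-stream seed, kept below 2**31."""
    return (int(seed) * 101 + stream) % (2**31 - 1)
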