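"""Seeded generators for every input the assessment chain consumes.

The generators emulate the statistical structure of a mid-sized lowland
sand-bed river: a seasonal lognormal hydrograph ensemble, channelized
depth/velocity rasters hydraulically consistent with a given discharge, a
dendritic reach network fragmented by barriers, and simplex-valued
substrate compositions. Default parameters mirror a typical lowland study
reach (mean discharge 3.0 m³/s, bankfull ≈ 6 m³/s, bankfull width ≈ 11 m,
depth 1.4 m, slope 0.045‰, raster cell 0.25 m², 0.16 barriers/km), so
fixture magnitudes are realistic without reproducing any particular river.

Everything is a pure function of (config, seed): a single global seed fans
out to fixed per-generator substreams, so adding a generator never perturbs
existing fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channel import CrossSection, invert_stage
from .dispersal import Barrier, RiverNetworkGraph
from .flow import Hydrograph
from .fuzzy import FuzzySystem, HydraulicGrid, MembershipFunction, Rule
from .het import DoseResponse, ReferenceRange, SubstrateComposition, SubstratePreference

__all__ = [
    "SynthConfig", "synth_hydrographs", "synth_hydraulic_grid",
    "synth_network", "synth_substrate", "example_fish_species",
    "example_invert_species", "example_reference_ranges",
]

# fixed substream keys: new generators get new keys, existing ones never move
_STREAMS = {"hydrographs": 0, "grid": 1, "network": 2, "substrate": 3, "regime": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic riverscape.

    Units: discharge m³/s, lengths m, slope dimensionless, barrier density
    per km; ``amplitude`` is the fractional seasonal modulation of the mean
    discharge and ``noise_sd`` the standard deviation of the lognormal
    day-to-day multiplier on the log scale.
    """

    seed: int = 0
    years: int = 5
    mean_q: float = 3.0
    amplitude: float = 0.6
    noise_sd: float = 0.35
    peak_doy: int = 15          # midwinter discharge peak, as in Atlantic lowlands
    channel_width: float = 11.0
    channel_depth: float = 1.4
    # energy slope of the synthetic channel; chosen so normal-depth
    # conveyance at bankfull stage matches a ~6-7 m³/s bankfull discharge
    # (a backwater-dominated field slope would starve the Manning stand-in)
    slope: float = 0.0007
    n_manning: float = 0.03
    cell_size: float = 0.5
    reach_rows: int = 40        # along-channel rows of the hydraulic raster
    n_reaches: int = 30
    mean_reach_length: float = 1000.0
    branching: float = 0.5
    barrier_density: float = 0.16
    # Bernoulli cell-occupancy of source populations; sparse, as expected
    # for species recolonizing from scattered refugia
    source_rate: float = 0.02
    dx: float = 50.0
    substrate_concentration: dict = field(default_factory=lambda: {
        "sand": 10.0, "silt": 2.0, "fine_gravel": 1.0, "macrophytes": 1.5,
        "wood": 0.8, "cpom": 1.2,
    })

    def __post_init__(self):
        if self.years < 1 or self.n_reaches < 1:
            raise ValueError("years and n_reaches must be >= 1")
        if not 0 <= self.amplitude < 1:
            raise ValueError("seasonal amplitude must lie in [0, 1)")
        for name in ("mean_q", "channel_width", "channel_depth", "slope",
                     "n_manning", "cell_size", "mean_reach_length", "dx"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def synth_hydrographs(cfg: SynthConfig, n_runs: int = 1) -> list[Hydrograph]:
    """Ensemble of seasonal lognormal daily hydrographs.

    q(d) = mean · (1 + A·cos(2π(doy − peak)/365)) · exp(N(0, sd²)), with
    independent noise across days and runs.
    """
    if n_runs < 1:
        raise ValueError("need at least one run")
    rng = _rng(cfg.seed, "hydrographs")
    dates = pd.date_range("2021-01-01", periods=cfg.years * 365, freq="D")
    doy = dates.dayofyear.to_numpy()
    seasonal = cfg.mean_q * (1 + cfg.amplitude * np.cos(
        2 * np.pi * (doy - cfg.peak_doy) / 365.0))
    runs = []
    for _ in range(n_runs):
        noise = np.exp(rng.normal(0.0, cfg.noise_sd, size=len(dates)))
        runs.append(Hydrograph(dates, seasonal * noise))
    return runs


def _parabolic_section(cfg: SynthConfig, n_pts: int = 41) -> CrossSection:
    """Parabolic cross-section of the configured width and thalweg depth."""
    half = cfg.channel_width / 2
    y = np.linspace(-half, half, n_pts)
    z = cfg.channel_depth * (y / half) ** 2   # thalweg at z=0, banks at channel_depth
    return CrossSection(stations=y + half, elevations=z,
                        n_manning=cfg.n_manning, slope=cfg.slope)


def synth_hydraulic_grid(cfg: SynthConfig, q: float) -> HydraulicGrid:
    """Depth/velocity raster of a straight channel carrying discharge ``q``.

    The cross-channel depth profile is parabolic, with the water level set
    by inverting Manning's equation on the parabolic section (normal
    depth), so the section geometry is hydraulically consistent with ``q``.
    Velocity follows the local depth^(2/3) profile (Manning's vertical),
    rescaled exactly so the section flux Σ v·h·Δw equals ``q``. Rows repeat
    the section along the channel; cells with zero depth are dry.
    """
    if q <= 0:
        raise ValueError("discharge must be positive")
    xs = _parabolic_section(cfg)
    stage = invert_stage(xs, q, tol=1e-4)
    half = cfg.channel_width / 2
    ncols = int(round(cfg.channel_width / cfg.cell_size))
    y = (np.arange(ncols) + 0.5) * cfg.cell_size - half
    bed = cfg.channel_depth * (y / half) ** 2
    depth = np.clip(stage - bed, 0.0, None)
    v = depth ** (2.0 / 3.0)
    flux = float(np.sum(v * depth * cfg.cell_size))
    if flux <= 0:
        raise ValueError("discharge too small for the grid resolution")
    v *= q / flux
    depth2d = np.tile(depth, (cfg.reach_rows, 1))
    vel2d = np.tile(v, (cfg.reach_rows, 1))
    return HydraulicGrid(depth=depth2d, velocity=vel2d,
                         cell_area=cfg.cell_size ** 2)


def synth_network(cfg: SynthConfig) -> tuple[RiverNetworkGraph, set]:
    """Random dendritic river network with barriers and source cells.

    Reaches are added one at a time, each attaching upstream of a node
    chosen uniformly at random (branching 0 forces a single chain). Edge
    lengths are lognormal around the configured mean; barriers arrive by a
    Poisson process along the edges at the configured density with
    passability 0; source cells are independent Bernoulli draws.
    """
    rng = _rng(cfg.seed, "network")
    sigma = 0.5
    mu = math.log(cfg.mean_reach_length) - sigma ** 2 / 2
    edges = []
    nodes = [0]          # node 0 = outlet
    tips = [0]
    next_node = 1
    for _ in range(cfg.n_reaches):
        if cfg.branching > 0 and rng.random() < cfg.branching:
            parent = nodes[rng.integers(len(nodes))]
        else:
            parent = tips[-1]
        length = float(rng.lognormal(mu, sigma))
        edges.append((next_node, parent, length))
        nodes.append(next_node)
        tips.append(next_node)
        next_node += 1
    # planar coordinates by an upstream random walk (for aerial dispersal)
    coords = {0: (0.0, 0.0)}
    scale = 1e-3  # map metres to kilometres for compact rasters
    for u, v, length in edges:
        ang = rng.uniform(0.25 * np.pi, 0.75 * np.pi)
        x, y0 = coords[v]
        coords[u] = (x + length * scale * math.cos(ang),
                     y0 + length * scale * math.sin(ang))
    barriers = []
    for u, v, length in edges:
        count = rng.poisson(cfg.barrier_density * length / 1000.0)
        for pos in np.sort(rng.uniform(0, length, size=count)):
            barriers.append(Barrier(edge=(u, v), position_m=float(pos),
                                    passability_up=0.0, passability_down=1.0))
    net = RiverNetworkGraph(edges, dx=cfg.dx, barriers=barriers, coords=coords)
    draws = rng.random(len(net.cells))
    sources = {c for c, r in zip(net.cells, draws) if r < cfg.source_rate}
    if not sources:
        sources = {net.cells[0]}
    return net, sources


def synth_substrate(cfg: SynthConfig, degenerate: str | None = None) -> SubstrateComposition:
    """Random substrate composition with configured class concentrations.

    Dirichlet draw with the configured concentration per class (expected
    fractions proportional to concentrations). ``degenerate`` puts all mass
    on a single named class — the pure-sand baseline of a degraded reach.
    """
    classes = list(cfg.substrate_concentration)
    if degenerate is not None:
        if degenerate not in classes:
            raise ValueError(f"unknown substrate class {degenerate!r}")
        return SubstrateComposition({c: 1.0 if c == degenerate else 0.0 for c in classes})
    rng = _rng(cfg.seed, "substrate")
    alphas = np.array([cfg.substrate_concentration[c] for c in classes])
    frac = rng.dirichlet(alphas)
    return SubstrateComposition(dict(zip(classes, frac)))


def synth_regime_data(cfg: SynthConfig, a: float = 6.69, b: float = 0.28,
                      n: int = 14, noise_sd: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic bankfull width vs formative discharge survey, W = a·Q^b·ε.

    Multiplicative lognormal noise with log-sd ``noise_sd``; Q spans the
    range of small-to-mid lowland streams.
    """
    rng = _rng(cfg.seed, "regime")
    q = np.exp(rng.uniform(math.log(0.5), math.log(30.0), size=n))
    w = a * q ** b * np.exp(rng.normal(0, noise_sd, size=n))
    return w, q


# --- illustrative species parameter sets ------------------------------------
# These are plausible expert-style parameterizations for lowland fish and
# macroinvertebrates, constructed for demonstration and testing; they are not
# field-derived preference data.

def example_fish_species() -> dict[str, FuzzySystem]:
    """Two contrasting fish habitat rule bases.

    ``riffle_minnow`` prefers shallow, slowly flowing margins (small-bodied
    cyprinid); ``pool_roach`` prefers deep, slow pool habitat (large-bodied
    cyprinid). Velocity in m/s, depth in m, suitability on [0, 1].
    """
    out = {
        "low": MembershipFunction(0.0, 0.0, 0.1, 0.4),
        "medium": MembershipFunction(0.2, 0.45, 0.55, 0.8),
        "high": MembershipFunction(0.6, 0.9, 1.0, 1.0),
    }
    v_classes = {
        "slow": MembershipFunction(0.0, 0.0, 0.15, 0.35),
        "moderate": MembershipFunction(0.15, 0.35, 0.55, 0.8),
        "fast": MembershipFunction(0.55, 0.8, 5.0, 5.0),
    }
    d_classes = {
        "shallow": MembershipFunction(0.0, 0.0, 0.25, 0.5),
        "intermediate": MembershipFunction(0.25, 0.5, 0.9, 1.3),
        "deep": MembershipFunction(0.9, 1.3, 10.0, 10.0),
    }
    variables = {"velocity": v_classes, "depth": d_classes}

    def rules(table):
        return [Rule({"velocity": v, "depth": d}, s) for (v, d), s in table.items()]

    minnow = FuzzySystem(variables, out, rules({
        ("slow", "shallow"): "high",
        ("slow", "intermediate"): "medium",
        ("slow", "deep"): "low",
        ("moderate", "shallow"): "medium",
        ("moderate", "intermediate"): "medium",
        ("moderate", "deep"): "low",
        ("fast", "shallow"): "low",
        ("fast", "intermediate"): "low",
        ("fast", "deep"): "low",
    }))
    roach = FuzzySystem(variables, out, rules({
        ("slow", "shallow"): "low",
        ("slow", "intermediate"): "medium",
        ("slow", "deep"): "high",
        ("moderate", "shallow"): "low",
        ("moderate", "intermediate"): "medium",
        ("moderate", "deep"): "medium",
        ("fast", "shallow"): "low",
        ("fast", "intermediate"): "low",
        ("fast", "deep"): "low",
    }))
    return {"riffle_minnow": minnow, "pool_roach": roach}


def example_invert_species() -> dict[str, dict]:
    """Two contrasting macroinvertebrate parameter sets.

    ``sand_mayfly`` is a burrowing psammophile (high densities on sand);
    ``gravel_caddis`` is a rheophilic lithophile tied to gravel and coarse
    organic substrate. Each entry carries substrate densities (ind/m²) and a
    nitrate dose–response curve (mg/l N).
    """
    return {
        "sand_mayfly": {
            "preference": SubstratePreference("sand_mayfly", {
                "sand": 120.0, "silt": 30.0, "fine_gravel": 20.0,
                "macrophytes": 10.0, "wood": 5.0, "cpom": 15.0,
            }),
            "dose_response": [DoseResponse("nitrate_mg_l",
                                           values=[1.0, 3.0, 8.0],
                                           factors=[1.0, 0.9, 0.5])],
        },
        "gravel_caddis": {
            "preference": SubstratePreference("gravel_caddis", {
                "sand": 5.0, "silt": 0.0, "fine_gravel": 150.0,
                "macrophytes": 20.0, "wood": 60.0, "cpom": 40.0,
            }),
            "dose_response": [DoseResponse("nitrate_mg_l",
                                           values=[1.0, 3.0, 8.0],
                                           factors=[1.0, 0.8, 0.3])],
        },
    }


def example_reference_ranges() -> ReferenceRange:
    """Natural substrate cover ranges of a lowland sand-bed river type.

    Sand dominates, with minor gravel (the classic 5–20% band), organic and
    woody substrate present.
    """
    return ReferenceRange({
        "sand": (0.40, 0.80),
        "silt": (0.00, 0.15),
        "fine_gravel": (0.05, 0.20),
        "macrophytes": (0.05, 0.20),
        "wood": (0.02, 0.10),
        "cpom": (0.02, 0.15),
    })
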