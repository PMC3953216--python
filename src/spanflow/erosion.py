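"""Hybrid soil-loss production function and sediment-concentration summaries.

On gentle slopes annual soil loss follows the Revised Universal Soil Loss
Equation, A = R*K*LS*C*P (mass/area/year).  Where the slope exceeds a
threshold (default 20%, strict) — too steep for the empirical equation to
be defensible — a discrete Bayesian network over soil, precipitation and
vegetation evidence takes over, and the combined result is a single
seamless per-cell distribution layer: a point mass at the deterministic
value on the gentle branch, the full posterior on the steep branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes import BayesNet, DistributionLayer, NodeDef, apply_bn
from .errors import DomainError, UndefinedRatioError
from .raster import RasterLayer

__all__ = [
    "RusleFactors",
    "rusle",
    "hybrid_erosion",
    "sediment_concentration",
    "concentration_ratio",
    "example_steep_slope_net",
]


@dataclass
class RusleFactors:
    """The five multiplicative soil-loss factor layers plus the slope
    threshold (percent) above which the equation is not applied.

    R: rainfall erosivity; K: soil erodibility; LS: slope length-steepness;
    C: cover management; P: support practice.  Factor derivation from
    primary data is out of scope — factors are inputs.
    """

    R: RasterLayer
    K: RasterLayer
    LS: RasterLayer
    C: RasterLayer
    P: RasterLayer

    slope_threshold: float = 20.0

    def __post_init__(self) -> None:
        layers = (self.R, self.K, self.LS, self.C, self.P)
        shapes = {l.spec.shape for l in layers}
        if len(shapes) != 1:
            raise DomainError("factor layers must be aligned to one grid")
        for name, layer in zip("R K LS C P".split(), layers):
            if np.any(layer.values[layer.valid_mask] < 0):
                raise DomainError(f"factor {name} has negative values")
        if not self.slope_threshold > 0:
            raise DomainError("slope_threshold must be positive")

    @property
    def layers(self) -> tuple[RasterLayer, ...]:
        return (self.R, self.K, self.LS, self.C, self.P)


def rusle(factors: RusleFactors) -> RasterLayer:
    """Annual soil loss A = R*K*LS*C*P per cell (mass/area/year).

    A cell is nodata when any factor is nodata there.
    """
    spec = factors.R.spec
    product = np.ones(spec.shape)
    valid = np.ones(spec.shape, dtype=bool)
    for layer in factors.layers:
        product *= layer.filled(0.0)
        valid &= layer.valid_mask
    product[~valid] = spec.nodata
    return RasterLayer(spec, product, semantics="soil_loss", units="t/ha/yr")


def hybrid_erosion(factors: RusleFactors, slope: RasterLayer,
                   steep_net: BayesNet,
                   steep_evidence: dict[str, RasterLayer],
                   steep_discretizers: dict[str, np.ndarray],
                   steep_target: str = "erosion_class") -> DistributionLayer:
    """Seamless erosion distribution layer switching on slope.

    Cells with slope <= threshold (strict comparison: the boundary cell is
    deterministic) carry a point mass at the RUSLE value; steeper cells
    carry the network posterior.  A cell lacking both model inputs is
    nodata.
    """
    spec = slope.spec
    det = rusle(factors)
    post = apply_bn(steep_net, steep_evidence, steep_discretizers, steep_target,
                    spec=spec)
    states = post.states
    k = len(states)
    node = steep_net.nodes[steep_target]
    if node.midpoints is None:
        raise DomainError("steep-slope target node needs numeric midpoints")
    base_mids = np.asarray(node.midpoints, dtype=float)

    steep = slope.valid_mask & (slope.values > factors.slope_threshold)
    gentle = slope.valid_mask & ~steep & det.valid_mask
    valid = steep | gentle

    probs = post.probs.copy()
    mids = np.broadcast_to(base_mids, spec.shape + (k,)).copy()
    # gentle branch: point mass on the state nearest the deterministic
    # value, with the cell midpoint overridden to the exact value
    g_vals = det.values
    nearest = np.argmin(np.abs(g_vals[..., None] - base_mids), axis=-1)
    gi, gj = np.nonzero(gentle)
    probs[gi, gj, :] = 0.0
    probs[gi, gj, nearest[gi, gj]] = 1.0
    mids[gi, gj, nearest[gi, gj]] = g_vals[gi, gj]
    probs[~valid] = 1.0 / k  # placeholder under the nodata mask
    return DistributionLayer(spec, states, probs, midpoints=mids,
                             valid_mask=valid, semantics="erosion",
                             units=det.units)


def sediment_concentration(sediment_delivered: float,
                           water_delivered: float) -> float:
    """Sediment concentration: total delivered mass over total delivered
    water volume (kg/m3 per year for kg and m3 inputs)."""
    if water_delivered <= 0:
        raise UndefinedRatioError("no delivered water; concentration undefined")
    return sediment_delivered / water_delivered


def concentration_ratio(a: float, b: float) -> float:
    """How many times higher concentration ``a`` is than ``b``."""
    if b <= 0:
        raise UndefinedRatioError("reference concentration is zero")
    return a / b


def example_steep_slope_net() -> tuple[BayesNet, dict[str, np.ndarray]]:
    """A small illustrative steep-slope erosion network and its evidence
    discretizers.

    Structure: soil_class, precipitation_class and vegetation_cover are
    independent drivers of erosion_class.  The conditional tables encode
    the obvious qualitative behaviour (erodible soil, heavy rain and bare
    ground raise erosion) and are illustrative defaults that users replace
    with locally trained tables.  Erosion-class midpoints are in t/ha/yr.
    """
    nodes = {
        "soil_class": NodeDef(("stable", "erodible")),
        "precipitation_class": NodeDef(("low", "high")),
        "vegetation_cover": NodeDef(("dense", "sparse")),
        "erosion_class": NodeDef(("low", "moderate", "high"),
                                 midpoints=(5.0, 50.0, 200.0)),
    }
    parents = {
        "soil_class": (),
        "precipitation_class": (),
        "vegetation_cover": (),
        "erosion_class": ("soil_class", "precipitation_class", "vegetation_cover"),
    }
    cpt = np.empty((2, 2, 2, 3))
    cpt[0, 0, 0] = (0.90, 0.08, 0.02)
    cpt[0, 0, 1] = (0.70, 0.22, 0.08)
    cpt[0, 1, 0] = (0.70, 0.22, 0.08)
    cpt[0, 1, 1] = (0.40, 0.40, 0.20)
    cpt[1, 0, 0] = (0.60, 0.30, 0.10)
    cpt[1, 0, 1] = (0.30, 0.40, 0.30)
    cpt[1, 1, 0] = (0.30, 0.40, 0.30)
    cpt[1, 1, 1] = (0.05, 0.25, 0.70)
    cpts = {
        "soil_class": np.array([0.6, 0.4]),
        "precipitation_class": np.array([0.5, 0.5]),
        "vegetation_cover": np.array([0.5, 0.5]),
        "erosion_class": cpt,
    }
    discretizers = {
        "soil_class": np.array([0.0, 0.5, 1.0]),
        "precipitation_class": np.array([0.0, 1500.0, 1e9]),  # mm/yr
        "vegetation_cover": np.array([0.0, 0.5, 1.0]),        # bare fraction
    }
    return BayesNet(nodes, parents, cpts), discretizers
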