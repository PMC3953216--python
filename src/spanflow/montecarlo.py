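"""Monte-Carlo propagation of probabilistic source/sink/use layers through
the flow simulator.

Each draw samples every uncertain cell independently from its discrete
distribution, runs the full two-pass flow simulation, and accumulates
running per-cell means and variances (Welford) for every requested output
map.  One master seed drives everything: per-draw generators come from
``numpy.random.SeedSequence(seed).spawn``, so runs are reproducible across
platforms.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bayes import DistributionLayer
from .errors import DomainError
from .raster import RasterLayer
from .span import BenefitSpec, RouterSpec, SpanOutputs, SpanProblem, run_span

__all__ = ["McConfig", "McResult", "sample_layer", "propagate",
           "propagate_analytic_global_mix"]

DEFAULT_OUTPUTS = ("actual_source", "actual_sink", "actual_use", "actual_flow",
                   "possible_use", "blocked_use")


@dataclass(frozen=True)
class McConfig:
    """Monte-Carlo run settings."""

    n_draws: int
    seed: int
    outputs_requested: tuple[str, ...] = DEFAULT_OUTPUTS
    time_budget_s: float | None = None

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise DomainError("n_draws must be >= 1")
        for name in self.outputs_requested:
            if name not in SpanOutputs.MAP_NAMES:
                raise DomainError(f"unknown output map {name!r}")


@dataclass
class McResult:
    """Per-output mean and coefficient-of-variation maps plus a run log."""

    means: dict[str, RasterLayer]
    cvs: dict[str, RasterLayer]
    log: dict = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return bool(self.log.get("valid", True))


def sample_layer(dl: DistributionLayer, rng: np.random.Generator) -> RasterLayer:
    """Draw one deterministic raster from a numeric distribution layer.

    Each cell is independently set to one of its state midpoints with the
    cell's probabilities; nodata cells stay nodata.  The same generator
    state always yields the same draw.
    """
    if dl.midpoints is None:
        raise DomainError("sampling requires numeric state midpoints")
    cum = np.cumsum(dl.probs, axis=-1)
    u = rng.random(dl.spec.shape)
    idx = np.sum(u[..., None] > cum, axis=-1)
    idx = np.minimum(idx, dl.n_states - 1)
    mids = dl.cell_midpoints()
    ii, jj = np.meshgrid(np.arange(dl.spec.n_rows), np.arange(dl.spec.n_cols),
                         indexing="ij")
    vals = mids[ii, jj, idx]
    vals = np.where(dl.valid_mask, vals, dl.spec.nodata)
    return RasterLayer(dl.spec, vals, dl.semantics, dl.units)


def _as_distribution(layer) -> DistributionLayer:
    if isinstance(layer, DistributionLayer):
        return layer
    return DistributionLayer.point_mass(layer)


def propagate(source_dl, sink_dl, use_dl, benefit: BenefitSpec,
              router: RouterSpec, cfg: McConfig) -> McResult:
    """Propagate input uncertainty through the flow model.

    Accepts distribution layers or deterministic rasters (treated as point
    masses) for source, sink and use.  Returns per-cell mean and CV over
    draws for each requested output map.  If a wall-clock budget is set and
    exceeded, the run stops early and the partial result is flagged
    invalid.
    """
    dls = [_as_distribution(l) for l in (source_dl, sink_dl, use_dl)]
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_draws)
    spec = dls[0].spec

    count = 0
    mean: dict[str, np.ndarray] = {}
    m2: dict[str, np.ndarray] = {}
    t0 = time.monotonic()
    aborted = False
    for d in range(cfg.n_draws):
        if cfg.time_budget_s is not None and time.monotonic() - t0 > cfg.time_budget_s:
            aborted = True
            break
        rng = np.random.default_rng(streams[d])
        src, snk, use = (sample_layer(dl, rng) for dl in dls)
        problem = SpanProblem(src, snk, use, benefit, router)
        outputs = run_span(problem)
        count += 1
        for name in cfg.outputs_requested:
            vals = outputs.as_dict()[name].values
            if name not in mean:
                mean[name] = np.zeros(spec.shape)
                m2[name] = np.zeros(spec.shape)
            delta = vals - mean[name]
            mean[name] += delta / count
            m2[name] += delta * (vals - mean[name])

    means, cvs = {}, {}
    for name in mean:
        var = m2[name] / count if count > 0 else np.zeros(spec.shape)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.sqrt(var) / np.abs(mean[name])
        cv[(mean[name] == 0) & (var == 0)] = 0.0
        cv[(mean[name] == 0) & (var > 0)] = spec.nodata
        means[name] = RasterLayer(spec, mean[name], name + "_mean")
        cvs[name] = RasterLayer(spec, cv, name + "_cv")
    log = {
        "seed": cfg.seed,
        "n_draws": cfg.n_draws,
        "draws_completed": count,
        "valid": not aborted,
        "elapsed_s": time.monotonic() - t0,
    }
    return McResult(means, cvs, log)


def propagate_analytic_global_mix(source_dl, sink_dl, use: RasterLayer
                                  ) -> tuple[RasterLayer, RasterLayer]:
    """Closed-form mean and CV of delivered use for the well-mixed router.

    Valid in the linear regime — total sink below total source and demand
    nowhere capping its pool share — where delivered use at cell i is
    ``d_i / D * (sum S - sum K)``, linear in the independent cell draws.
    Then the mean and variance of the pool are sums of cell means and
    variances.  A warning is issued when the regime does not hold at the
    mean.  Elsewhere Monte Carlo is authoritative.
    """
    src = _as_distribution(source_dl)
    snk = _as_distribution(sink_dl)
    spec = src.spec

    def moments(dl: DistributionLayer):
        mids = dl.cell_midpoints()
        m = np.einsum("ijk,ijk->ij", dl.probs, mids)
        v = np.einsum("ijk,ijk->ij", dl.probs, (mids - m[..., None]) ** 2)
        m = np.where(dl.valid_mask, m, 0.0)
        v = np.where(dl.valid_mask, v, 0.0)
        return m, v

    ms, vs = moments(src)
    mk, vk = moments(snk)
    pool_mean = float(ms.sum() - mk.sum())
    pool_var = float(vs.sum() + vk.sum())
    if pool_mean < 0:
        warnings.warn("total sink exceeds total source at the mean; the "
                      "linear approximation is invalid", stacklevel=2)
    demand = use.filled(0.0)
    tot_d = demand.sum()
    if tot_d <= 0:
        raise DomainError("no demand; nothing to allocate")
    share = demand / tot_d
    if np.any(share * pool_mean > demand + 1e-12):
        warnings.warn("demand caps bind at the mean; the linear "
                      "approximation is invalid", stacklevel=2)
    mean = share * pool_mean
    sd = share * np.sqrt(pool_var)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), 0.0)
    return (RasterLayer(spec, mean, "actual_use_mean", use.units),
            RasterLayer(spec, cv, "actual_use_cv"))
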