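"""Probabilistic sensitivity analysis.

Parameters are sampled from their declared distributions (beta for
probabilities and utilities, gamma for costs, both fitted by the method of
moments from the declared mean and standard error), the tree is re-evaluated
per draw, and the draw-level outcomes are summarised as a cost-effectiveness
plane with a confidence ellipse and as cost-effectiveness acceptability
curves (CEAC).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .engine import DecisionModel
from .errors import ModelError
from .tree_model import ParameterSet, validate_tree

logger = logging.getLogger(__name__)

#: consecutive invalid draws tolerated before giving up
_MAX_REJECTS_PER_DRAW = 1000


def beta_from_moments(mean: float, se: float) -> Tuple[float, float]:
    """Beta shape parameters (alpha, beta) matching the given mean and standard error."""
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ValueError(f"beta moments infeasible: se^2 = {var:.6g} >= mean(1-mean) = "
                         f"{mean * (1 - mean):.6g}")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> Tuple[float, float]:
    """Gamma (shape, scale) matching the given mean and standard error."""
    if mean <= 0 or se <= 0:
        raise ValueError("gamma moments require positive mean and se")
    shape = (mean / se) ** 2
    return shape, se * se / mean


@dataclass
class Sampler:
    """Draws parameter vectors for the parameter set it was built from.

    Parameters are sampled in sorted-name order so the random stream does not
    depend on how the configuration file orders them.
    """

    entries: List[Tuple[str, Callable[[np.random.Generator], float]]]
    params: ParameterSet

    @property
    def names(self) -> List[str]:
        return [name for name, _ in self.entries]

    def sample(self, rng: np.random.Generator) -> Dict[str, float]:
        return {name: draw(rng) for name, draw in self.entries}

    def sample_params(self, rng: np.random.Generator) -> ParameterSet:
        return self.params.with_base(self.sample(rng))


def _fixed(value: float) -> Callable[[np.random.Generator], float]:
    return lambda rng: value


def build_sampler(params: ParameterSet) -> Sampler:
    """Per-parameter samplers by method of moments.

    Parameters without a distribution spec, with family ``fixed``, or with a
    zero standard error are degenerate at their base value.
    """
    entries: List[Tuple[str, Callable[[np.random.Generator], float]]] = []
    for name in sorted(params):
        p = params[name]
        spec = p.dist
        if spec is None or spec.family == "fixed" or (spec.se is not None and spec.se == 0.0):
            entries.append((name, _fixed(p.base if spec is None or spec.mean is None
                                         else spec.mean)))
            continue
        mean, se = spec.mean, spec.se
        if spec.family == "beta":
            try:
                a, b = beta_from_moments(mean, se)
            except ValueError as exc:
                raise ModelError(f"parameter '{name}': {exc}") from exc
            entries.append((name, lambda rng, a=a, b=b: rng.beta(a, b)))
        elif spec.family == "gamma":
            shape, scale = gamma_from_moments(mean, se)
            entries.append((name, lambda rng, k=shape, s=scale: rng.gamma(k, s)))
        elif spec.family == "uniform":
            half = math.sqrt(3.0) * se
            lo, hi = mean - half, mean + half
            entries.append((name, lambda rng, lo=lo, hi=hi: rng.uniform(lo, hi)))
        else:  # pragma: no cover - families are validated upstream
            raise ModelError(f"parameter '{name}': unknown family {spec.family}")
    return Sampler(entries, params)


@dataclass
class PSASampleSet:
    """Per-draw per-strategy outcomes with the seed that produced them."""

    draws: int
    seed: int
    data: pd.DataFrame  # columns: draw, strategy, cost, effect
    rejections: int = 0

    @property
    def strategies(self) -> List[str]:
        return list(self.data["strategy"].unique())

    def pivot(self, value: str) -> pd.DataFrame:
        return self.data.pivot(index="draw", columns="strategy", values=value)


def run_psa(model: DecisionModel, sampler: Sampler, draws: int, seed: int) -> PSASampleSet:
    """Evaluate the tree under ``draws`` sampled parameter vectors.

    Sampled vectors that fail model validation (e.g. explicit branch
    probabilities leaving no room for the complement) are rejected and
    resampled; the rejection count is logged and reported.
    """
    if draws < 1:
        raise ValueError("draws must be at least 1")
    rng = np.random.default_rng(seed)
    rows: List[Tuple[int, str, float, float]] = []
    rejections = 0
    for draw in range(draws):
        for _attempt in range(_MAX_REJECTS_PER_DRAW):
            try:
                trial = sampler.sample_params(rng)
            except ModelError:
                rejections += 1
                continue
            report = validate_tree(model.tree, trial)
            if report.ok:
                break
            rejections += 1
        else:
            raise ModelError(
                f"draw {draw}: {_MAX_REJECTS_PER_DRAW} consecutive sampled vectors "
                "failed validation"
            )
        for o in model.evaluate(trial):
            rows.append((draw, o.strategy, o.cost, o.effect))
    logger.info("PSA: %d draws, seed %d, %d rejected vectors", draws, seed, rejections)
    data = pd.DataFrame(rows, columns=["draw", "strategy", "cost", "effect"])
    return PSASampleSet(draws=draws, seed=seed, data=data, rejections=rejections)


@dataclass
class CEACCurve:
    """Probability each strategy has the highest NMB, per WTP grid point."""

    wtp: np.ndarray
    probabilities: pd.DataFrame  # index: wtp, columns: strategies

    def probability(self, strategy: str, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp)))
        return float(self.probabilities.iloc[idx][strategy])


def ceac(samples: PSASampleSet, wtp_grid: Sequence[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curves.

    At each WTP the probability is the fraction of draws in which the strategy
    attains the strictly highest NMB; draws with ties split their weight
    equally among the tied strategies, so probabilities sum to one exactly.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if (grid < 0).any():
        raise ValueError("wtp_grid values must be non-negative")
    costs = samples.pivot("cost")
    effects = samples.pivot("effect")
    strategies = list(costs.columns)
    c = costs.to_numpy()
    e = effects.to_numpy()
    probs = np.empty((grid.size, len(strategies)))
    for i, lam in enumerate(grid):
        nmb = lam * e - c
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs[i] = weights.mean(axis=0)
    frame = pd.DataFrame(probs, index=pd.Index(grid, name="wtp"), columns=strategies)
    return CEACCurve(wtp=grid, probabilities=frame)


@dataclass
class Ellipse:
    """Confidence ellipse of the incremental (effect, cost) cloud.

    Fitted as a bivariate normal: semi-axes are sqrt(chi²₂(level) · eigenvalues)
    of the sample covariance, oriented along its eigenvectors.
    """

    center: Tuple[float, float]
    semi_axes: Tuple[float, float]
    orientation: float  # radians, major axis against the effect axis
    level: float
    covariance: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse (Mahalanobis test)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        if self.degenerate:
            return (np.abs(pts) < 1e-12).all(axis=1)
        inv = np.linalg.inv(self.covariance)
        d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return d2 <= stats.chi2.ppf(self.level, df=2)


def ce_plane(samples: PSASampleSet, reference: str, comparator: str,
             level: float = 0.95) -> Tuple[pd.DataFrame, Optional[Ellipse]]:
    """Incremental (Δeffect, Δcost) per draw plus the confidence ellipse.

    Fewer than 3 draws yield no ellipse; a zero-variance cloud yields a
    degenerate ellipse reported as a point (with a warning).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    costs = samples.pivot("cost")
    effects = samples.pivot("effect")
    for s in (reference, comparator):
        if s not in costs.columns:
            raise ModelError(f"unknown strategy '{s}'")
    cloud = pd.DataFrame(
        {
            "delta_effect": effects[comparator] - effects[reference],
            "delta_cost": costs[comparator] - costs[reference],
        }
    ).reset_index()
    if len(cloud) < 3:
        return cloud, None
    xy = cloud[["delta_effect", "delta_cost"]].to_numpy()
    center = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False, ddof=1)
    if not np.all(np.isfinite(cov)) or np.allclose(cov, 0.0, atol=1e-24):
        warnings.warn("zero-variance incremental cloud; ellipse degenerates to a point",
                      stacklevel=2)
        return cloud, Ellipse((float(center[0]), float(center[1])), (0.0, 0.0), 0.0,
                              level, covariance=cov, degenerate=True)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    k = stats.chi2.ppf(level, df=2)
    semi = np.sqrt(np.maximum(eigvals, 0.0) * k)
    angle = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
    return cloud, Ellipse((float(center[0]), float(center[1])),
                          (float(semi[0]), float(semi[1])), angle, level, covariance=cov)
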