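"""Instar-number inference from head-capsule-width distributions.

Stage 1 of the analysis: the classic head-width frequency-distribution
method.  Because head capsules do not grow within an instar, the widths
of a mixed-age brood form a multimodal distribution with one mode per
instar.  This module estimates that distribution by Gaussian-kernel
density estimation and counts its distinct peaks, decomposes it into a
finite normal mixture by expectation–maximization, selects the number
of components by BIC, and anchors the candidate solutions against the
developmentally identifiable extremes (mature embryos ≡ first instar,
prepupae ≡ last instar).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.special import logsumexp

from .errors import (
    AnchoringConflictError,
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from .morphdata import SpecimenTable, Stage

_LOG_2PI = math.log(2.0 * math.pi)

#: Variance floor (mm): the measurement quantization step; prevents
#: component collapse onto repeated quantized values.
SIGMA_FLOOR = 1e-3
WEIGHT_FLOOR = 1e-6
MIN_OBSERVATIONS = 10


@dataclass(frozen=True)
class DensityEstimate:
    """Gaussian-KDE of the width distribution on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class PeakSet:
    """Distinct peaks of a density estimate, in increasing location order."""

    locations: np.ndarray
    prominences: np.ndarray
    density: DensityEstimate

    @property
    def count(self) -> int:
        return int(len(self.locations))


@dataclass(frozen=True)
class MixtureModel:
    """Fitted K-component univariate normal mixture (components sorted by mean)."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    log_likelihood_path: np.ndarray = field(repr=False, default=None)

    def n_params(self) -> int:
        return 3 * self.k - 1

    def bic(self, n: int) -> float:
        return -2.0 * self.log_likelihood + self.n_params() * math.log(n)

    def _log_joint(self, x: np.ndarray) -> np.ndarray:
        """log(w_k · N(x | μ_k, σ_k)) as an (n, K) array."""
        x = np.asarray(x, dtype=float)[:, None]
        mu = self.means[None, :]
        sd = self.sds[None, :]
        return (
            np.log(self.weights)[None, :]
            - np.log(sd)
            - 0.5 * _LOG_2PI
            - 0.5 * ((x - mu) / sd) ** 2
        )

    def pdf(self, x) -> np.ndarray:
        return np.exp(logsumexp(self._log_joint(np.atleast_1d(x)), axis=1))


@dataclass(frozen=True)
class AnchorSet:
    """Observed head-width ranges of the developmentally identified extremes."""

    embryo_interval: Optional[tuple[float, float]] = None
    prepupa_interval: Optional[tuple[float, float]] = None

    def __post_init__(self):
        for iv in (self.embryo_interval, self.prepupa_interval):
            if iv is not None and iv[0] > iv[1]:
                raise ValidationError(f"anchor interval {iv} has min > max")


@dataclass(frozen=True)
class Assignment:
    """Per-observation instar labels (1-based) with posterior probabilities."""

    labels: np.ndarray
    posteriors: np.ndarray
    outlier: np.ndarray  # beyond 4σ from every component mean


@dataclass(frozen=True)
class SelectionResult:
    """BIC model-selection sweep over K = 1..k_max."""

    k: int
    models: tuple[MixtureModel, ...]
    bics: np.ndarray
    disqualified: tuple[Optional[str], ...]

    @property
    def model(self) -> MixtureModel:
        return self.models[self.k - 1]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": [m.k for m in self.models],
                "log_likelihood": [m.log_likelihood for m in self.models],
                "n_params": [m.n_params() for m in self.models],
                "bic": self.bics,
                "converged": [m.converged for m in self.models],
                "disqualified": [d if d else "" for d in self.disqualified],
            }
        )


def silverman_bandwidth(widths: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9·min(sd, IQR/1.34)·n^(−1/5)."""
    x = np.asarray(widths, dtype=float)
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = max(abs(float(np.mean(x))), 1.0) * 1e-3
    return 0.9 * scale * x.size ** (-0.2)


def _check_widths(widths) -> np.ndarray:
    x = np.asarray(widths, dtype=float).ravel()
    if x.size and (np.any(~np.isfinite(x)) or np.any(x <= 0)):
        raise ValidationError("widths must be positive finite values")
    return x


def count_modes(
    widths,
    bandwidth: Optional[float] = None,
    min_prominence: float = 0.05,
) -> PeakSet:
    """Count distinct peaks of the head-width density.

    A Gaussian KDE is evaluated on a 512-point grid spanning
    [min − 3h, max + 3h]; a peak is a local maximum whose prominence
    exceeds ``min_prominence`` × the maximum density.  Each distinct
    peak is read as one instar.
    """
    x = _check_widths(widths)
    if x.size < MIN_OBSERVATIONS:
        raise InsufficientDataError(
            f"peak counting needs >= {MIN_OBSERVATIONS} observations, got {x.size}"
        )
    if bandwidth is not None and bandwidth <= 0:
        raise ValidationError("bandwidth must be positive")
    h = bandwidth if bandwidth is not None else silverman_bandwidth(x)
    grid = np.linspace(x.min() - 3.0 * h, x.max() + 3.0 * h, 512)
    z = (grid[:, None] - x[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * math.sqrt(2.0 * math.pi))
    idx, props = find_peaks(density, prominence=min_prominence * density.max())
    return PeakSet(
        locations=grid[idx],
        prominences=props["prominences"],
        density=DensityEstimate(grid=grid, density=density, bandwidth=h),
    )


def _initial_means(
    x: np.ndarray,
    k: int,
    bandwidth: Optional[float],
    min_prominence: float,
) -> np.ndarray:
    """Peak locations, padded/truncated to K via quantile spacing."""
    locs: list[float] = []
    proms: list[float] = []
    if x.size >= MIN_OBSERVATIONS:
        peaks = count_modes(x, bandwidth=bandwidth, min_prominence=min_prominence)
        locs = list(peaks.locations)
        proms = list(peaks.prominences)
    if len(locs) > k:
        keep = np.argsort(proms)[::-1][:k]
        locs = sorted(np.asarray(locs)[keep])
    elif len(locs) < k:
        quantiles = list(np.quantile(x, (np.arange(k) + 0.5) / k))
        while len(locs) < k and quantiles:
            best = max(
                quantiles,
                key=lambda q: min((abs(q - m) for m in locs), default=np.inf),
            )
            quantiles.remove(best)
            locs.append(best)
        # degenerate data could still leave too few starting points
        while len(locs) < k:
            locs.append(locs[-1] if locs else float(np.mean(x)))
    return np.sort(np.asarray(locs, dtype=float))


def fit_mixture_em(
    widths,
    k: int,
    init: Optional[Sequence[float]] = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    sigma_floor: float = SIGMA_FLOOR,
    bandwidth: Optional[float] = None,
    min_prominence: float = 0.05,
) -> MixtureModel:
    """Fit a K-component univariate normal mixture by EM.

    Initialization defaults to the KDE peak locations (padded or
    truncated to K by quantile spacing).  Iterates until the relative
    log-likelihood change drops below ``tol`` or ``max_iter`` is
    reached; the log-likelihood is checked to be non-decreasing at
    every iteration.  A component whose weight falls below 1e-6 or
    whose σ hits the floor marks the fit as not converged rather than
    crashing.  Components are returned sorted by mean.  ``seed`` keeps
    the signature deterministic-by-contract; the default initialization
    itself is deterministic.
    """
    x = _check_widths(widths)
    if k < 1:
        raise ValidationError(f"K must be >= 1, got {k}")
    if x.size == 0:
        raise InsufficientDataError("cannot fit a mixture to an empty sample")
    if np.unique(x).size < k:
        raise DegenerateDataError(
            f"K={k} exceeds the number of distinct values ({np.unique(x).size})"
        )

    n = x.size
    if init is not None:
        mu = np.sort(np.asarray(init, dtype=float))
        if mu.size != k:
            raise ValidationError(f"init must supply exactly K={k} means, got {mu.size}")
    else:
        mu = _initial_means(x, k, bandwidth, min_prominence)
    sd_all = float(np.std(x))
    sigma = np.full(k, max(sd_all / k, sigma_floor))
    w = np.full(k, 1.0 / k)

    ll_old = -np.inf
    ll_path: list[float] = []
    degenerate = False
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_joint = (
            np.log(w)[None, :]
            - np.log(sigma)[None, :]
            - 0.5 * _LOG_2PI
            - 0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
        )
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        if not degenerate and ll < ll_old - 1e-8 * max(1.0, abs(ll_old)):
            raise RuntimeError(
                f"EM log-likelihood decreased ({ll_old} -> {ll}); this is a bug"
            )
        ll_path.append(ll)
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * max(1.0, abs(ll_old)):
            converged = True
            break
        ll_old = ll

        resp = np.exp(log_joint - log_norm[:, None])
        nk = resp.sum(axis=0)
        nk_safe = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk_safe
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk_safe
        sigma = np.sqrt(var)
        if np.any(sigma < sigma_floor) or np.any(w < WEIGHT_FLOOR):
            degenerate = True
        sigma = np.maximum(sigma, sigma_floor)
        w = np.maximum(w, WEIGHT_FLOOR)
        w = w / w.sum()

    order = np.argsort(mu)
    return MixtureModel(
        k=k,
        means=mu[order],
        sds=sigma[order],
        weights=w[order],
        log_likelihood=ll_path[-1],
        n_iterations=n_iter,
        converged=converged and not degenerate,
        log_likelihood_path=np.asarray(ll_path),
    )


def build_anchors(table: SpecimenTable) -> AnchorSet:
    """Head-width min–max intervals of embryos and prepupae, where present."""
    embryo = table.head_widths(stages=[Stage.EMBRYO])
    prepupa = table.head_widths(stages=[Stage.PREPUPA])
    return AnchorSet(
        embryo_interval=(float(embryo.min()), float(embryo.max())) if embryo.size else None,
        prepupa_interval=(float(prepupa.min()), float(prepupa.max())) if prepupa.size else None,
    )


def _anchor_violation(model: MixtureModel, anchors: AnchorSet) -> Optional[str]:
    """Why a candidate conflicts with the anchors, or None if compatible.

    The smallest component must sit within the embryo head-width
    interval widened by 2σ̂ of that component, and the largest within
    the prepupa interval likewise.
    """
    if anchors.embryo_interval is not None:
        lo, hi = anchors.embryo_interval
        mu, sd = model.means[0], model.sds[0]
        if not (lo - 2.0 * sd <= mu <= hi + 2.0 * sd):
            return (
                f"smallest mean {mu:.4f} outside embryo interval "
                f"[{lo:.4f}, {hi:.4f}] ± 2σ ({sd:.4f})"
            )
    if anchors.prepupa_interval is not None:
        lo, hi = anchors.prepupa_interval
        mu, sd = model.means[-1], model.sds[-1]
        if not (lo - 2.0 * sd <= mu <= hi + 2.0 * sd):
            return (
                f"largest mean {mu:.4f} outside prepupa interval "
                f"[{lo:.4f}, {hi:.4f}] ± 2σ ({sd:.4f})"
            )
    return None


def select_instar_number(
    widths,
    k_max: int = 6,
    anchors: Optional[AnchorSet] = None,
    **em_options,
) -> SelectionResult:
    """Fit K = 1..k_max mixtures and select K by BIC.

    BIC = −2·logL + p·ln(n) with p = 3K − 1.  When anchors are given,
    candidates whose extreme component means conflict with the
    embryo/prepupa intervals (± 2σ̂) are disqualified before selection.
    """
    if k_max < 1:
        raise ValidationError(f"k_max must be >= 1, got {k_max}")
    x = _check_widths(widths)
    n = x.size
    models = []
    reasons: list[Optional[str]] = []
    for k in range(1, k_max + 1):
        try:
            m = fit_mixture_em(x, k, **em_options)
        except DegenerateDataError as exc:
            # stop the sweep: larger K is degenerate too
            if not models:
                raise
            break
        models.append(m)
        reasons.append(_anchor_violation(m, anchors) if anchors is not None else None)
    bics = np.array([m.bic(n) for m in models])
    qualified = [i for i, r in enumerate(reasons) if r is None]
    if not qualified:
        detail = "; ".join(f"K={m.k}: {r}" for m, r in zip(models, reasons))
        raise AnchoringConflictError(
            f"every candidate K conflicts with the anchors ({detail})"
        )
    best = min(qualified, key=lambda i: bics[i])
    return SelectionResult(
        k=models[best].k,
        models=tuple(models),
        bics=bics,
        disqualified=tuple(reasons),
    )


def assign_instars(widths, model: MixtureModel) -> Assignment:
    """Label each width with its maximum-posterior component (1-based).

    Exact posterior ties break toward the lower instar.  Observations
    farther than 4σ from every component mean are flagged as outliers
    but still labeled.
    """
    x = _check_widths(widths)
    if x.size == 0:
        raise ValidationError("cannot assign instars to an empty sample")
    log_joint = model._log_joint(x)
    log_norm = logsumexp(log_joint, axis=1)
    posteriors = np.exp(log_joint - log_norm[:, None])
    labels = np.argmax(posteriors, axis=1) + 1  # argmax takes the first max: lower instar
    z = np.abs(x[:, None] - model.means[None, :]) / model.sds[None, :]
    outlier = np.all(z > 4.0, axis=1)
    return Assignment(labels=labels, posteriors=posteriors, outlier=outlier)
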