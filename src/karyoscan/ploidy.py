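"""Per-chromosome ploidy inference from allele-frequency distributions and depth.

Two independent lines of evidence are combined:

* the shape of the alternate-allele frequency distribution over a
  chromosome's heterozygous sites — unimodal around 1/2 for two copies,
  bimodal around 1/3 and 2/3 when one copy of three carries the allele;
* mean coverage depth normalized against the genome-wide baseline — a
  three-copy chromosome runs at 1.5x the two-copy baseline.

Frequencies live on (0,1) and are truncated by the caller's minimum
variant frequency (0.2) and its mirror (0.8), so the component family is
a truncated Beta: ignoring the truncation would bias the 1/3 mode upward.
Fixed-mean models (one component at 1/2; two symmetric components at 1/3
and 2/3) are compared by BIC and decide the label; free-mean fits are
reported alongside but never drive the label.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .errors import ParameterError

BALANCED = "balanced-1:1"
BIMODAL = "bimodal-1:2"
COMPOSITE = "composite"
UNCALLABLE = "uncallable"

_LOG_KAPPA_BOUNDS = (math.log(2.0), math.log(1e8))


@dataclass
class ChromosomeProfile:
    """Per-chromosome aggregate: length, mean depth per read set, sites."""

    chrom: str
    length: int
    depths: dict[str, float] = field(default_factory=dict)
    sites: list = field(default_factory=list)

    def __post_init__(self):
        if self.length <= 0:
            raise ParameterError(f"{self.chrom}: length must be positive")
        if any(d < 0 for d in self.depths.values()):
            raise ParameterError(f"{self.chrom}: negative depth")

    @property
    def density_per_kb(self) -> float:
        return len(self.sites) / (self.length / 1000.0)


@dataclass
class MixtureConfig:
    """Settings for the allele-frequency distribution classifier.

    The truncation bounds default to the caller's minimum variant
    frequency and its mirror; sites outside are discarded before
    fitting.  ``composite_trigger`` is the fraction of a chromosome's
    sites lying in skewed segments above which the distribution is
    labelled composite rather than balanced/bimodal.
    """

    lower: float = 0.2
    upper: float = 0.8
    min_sites: int = 20
    composite_trigger: float = 0.2

    def __post_init__(self):
        if not (0 < self.lower < self.upper < 1):
            raise ParameterError("need 0 < lower < upper < 1")
        if self.min_sites < 1:
            raise ParameterError("min_sites must be >= 1")


@dataclass
class PloidyCall:
    """Outcome of classifying one chromosome's frequency distribution."""

    chrom: str | None
    status: str  # "ok" | "uncallable"
    label: str | None = None
    component_means: tuple[float, ...] = ()   # label-model (fixed) means
    component_weights: tuple[float, ...] = ()
    free_means: tuple[float, ...] = ()        # free-mean fit, reported only
    free_weights: tuple[float, ...] = ()
    bic: dict[str, float] = field(default_factory=dict)
    n_sites: int = 0

    @property
    def means_pct(self) -> tuple[float, ...]:
        return tuple(100.0 * m for m in self.component_means)

    @property
    def free_means_pct(self) -> tuple[float, ...]:
        return tuple(100.0 * m for m in self.free_means)


def trunc_beta_logpdf(
    x: np.ndarray, mean: float, kappa: float, lower: float, upper: float
) -> np.ndarray:
    """Log-density of a Beta(mean*kappa, (1-mean)*kappa) truncated to [lower, upper]."""
    a, b = mean * kappa, (1.0 - mean) * kappa
    mass = float(special.betainc(a, b, upper) - special.betainc(a, b, lower))
    if mass <= 0 or not np.isfinite(mass):
        return np.full_like(np.asarray(x, dtype=float), -np.inf)
    x = np.asarray(x, dtype=float)
    logpdf = (
        special.xlogy(a - 1.0, x)
        + special.xlog1py(b - 1.0, -x)
        - special.betaln(a, b)
    )
    return logpdf - math.log(mass)


def _mix_loglik(
    f: np.ndarray, means: Sequence[float], weights: Sequence[float], kappa: float,
    lower: float, upper: float,
) -> float:
    parts = np.stack(
        [math.log(w) + trunc_beta_logpdf(f, m, kappa, lower, upper) if w > 0
         else np.full(len(f), -np.inf)
         for m, w in zip(means, weights)]
    )
    ll = float(np.logaddexp.reduce(parts, axis=0).sum())
    return ll if np.isfinite(ll) else -np.inf


def _fit_single(f, mean, lower, upper, fit_mean=False):
    """MLE of (mean,) kappa for a single truncated-Beta component."""
    if not fit_mean:
        res = optimize.minimize_scalar(
            lambda t: -_mix_loglik(f, [mean], [1.0], math.exp(t), lower, upper),
            bounds=_LOG_KAPPA_BOUNDS, method="bounded",
        )
        return (mean,), math.exp(res.x), -res.fun, 1
    m0 = float(np.clip(f.mean(), lower + 0.02, upper - 0.02))
    res = optimize.minimize(
        lambda p: -_mix_loglik(
            f, [np.clip(p[0], lower + 1e-3, upper - 1e-3)], [1.0],
            math.exp(np.clip(p[1], *_LOG_KAPPA_BOUNDS)), lower, upper),
        x0=[m0, math.log(200.0)], method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 300},
    )
    m = float(np.clip(res.x[0], lower + 1e-3, upper - 1e-3))
    kappa = math.exp(float(np.clip(res.x[1], *_LOG_KAPPA_BOUNDS)))
    return (m,), kappa, -res.fun, 2


def _fit_pair(f, low_mean, lower, upper, fit_mean=False):
    """MLE for the symmetric two-component mixture (means m and 1-m)."""

    def neg(p):
        if fit_mean:
            m = float(np.clip(p[0], lower + 1e-3, 0.5 - 1e-3))
            t, lw = p[1], p[2]
        else:
            m = low_mean
            t, lw = p[0], p[1]
        kappa = math.exp(float(np.clip(t, *_LOG_KAPPA_BOUNDS)))
        w = 1.0 / (1.0 + math.exp(-float(np.clip(lw, -8, 8))))
        return -_mix_loglik(f, [m, 1.0 - m], [w, 1.0 - w], kappa, lower, upper)

    below = float((f < 0.5).mean())
    w0 = math.log(max(below, 0.02) / max(1.0 - below, 0.02))
    x0 = ([1 / 3, math.log(200.0), w0] if fit_mean else [math.log(200.0), w0])
    res = optimize.minimize(
        neg, x0=x0, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
    )
    if fit_mean:
        m = float(np.clip(res.x[0], lower + 1e-3, 0.5 - 1e-3))
        t, lw = res.x[1], res.x[2]
        n_par = 3
    else:
        m, (t, lw), n_par = low_mean, res.x, 2
    kappa = math.exp(float(np.clip(t, *_LOG_KAPPA_BOUNDS)))
    w = 1.0 / (1.0 + math.exp(-float(np.clip(lw, -8, 8))))
    return (m, 1.0 - m), (w, 1.0 - w), kappa, -res.fun, n_par


def _bic(loglik: float, n_params: int, n: int) -> float:
    return n_params * math.log(n) - 2.0 * loglik


def classify_afd(
    sites,
    config: MixtureConfig | None = None,
    skewed_fraction: float | None = None,
    chrom: str | None = None,
) -> PloidyCall:
    """Classify a chromosome's allele-frequency distribution.

    ``sites`` is an array of frequencies or a sequence of objects with a
    ``frequency`` attribute.  Fits the one-component (mean 1/2) and
    symmetric two-component (means 1/3, 2/3) truncated-Beta models,
    selects by BIC, and labels composite when ``skewed_fraction``
    exceeds the configured trigger.  Too few sites inside the truncation
    bounds yields an ``uncallable`` call, not an exception.
    """
    config = config or MixtureConfig()
    f = np.asarray(
        [s.frequency for s in sites] if sites is not None and len(sites) and hasattr(
            next(iter(sites)), "frequency") else sites,
        dtype=float,
    )
    f = f[(f >= config.lower) & (f <= config.upper)]
    if len(f) < config.min_sites:
        return PloidyCall(chrom, UNCALLABLE, n_sites=len(f))
    n = len(f)

    means1, _k1, ll1, p1 = _fit_single(f, 0.5, config.lower, config.upper)
    means2, w2, _k2, ll2, p2 = _fit_pair(f, 1 / 3, config.lower, config.upper)
    bic = {"balanced": _bic(ll1, p1, n), "bimodal": _bic(ll2, p2, n)}

    fm1, _kf1, llf1, pf1 = _fit_single(f, 0.5, config.lower, config.upper, fit_mean=True)
    fm2, fw2, _kf2, llf2, pf2 = _fit_pair(f, 1 / 3, config.lower, config.upper, fit_mean=True)
    bic["balanced-free"] = _bic(llf1, pf1, n)
    bic["bimodal-free"] = _bic(llf2, pf2, n)

    if bic["balanced"] <= bic["bimodal"]:
        label, comp_means, comp_w = BALANCED, means1, (1.0,)
        free_means, free_w = fm1, (1.0,)
    else:
        label, comp_means, comp_w = BIMODAL, means2, w2
        free_means, free_w = fm2, fw2
    if skewed_fraction is not None and skewed_fraction > config.composite_trigger:
        label = COMPOSITE
    return PloidyCall(
        chrom, "ok", label, tuple(comp_means), tuple(comp_w),
        tuple(free_means), tuple(free_w), bic, n,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def depth_copy_number(
    mean_depths: Mapping[str, float],
    candidate_copies: Sequence[int] = (1, 2, 3, 4),
) -> tuple[pd.DataFrame, float]:
    """Normalize per-chromosome mean depths into copy-number estimates.

    Baseline = median of the per-chromosome means (robust to a single
    aneuploid outlier); fractional copy = 2 * depth / baseline, rounded
    half-away-from-zero for the integer call.  Copies outside
    ``candidate_copies`` are reported as unresolved (NA).  Returns the
    per-chromosome table and the baseline.
    """
    if len(mean_depths) < 2:
        raise ParameterError("need at least two chromosomes for a baseline")
    depths = {c: float(d) for c, d in mean_depths.items()}
    baseline = float(np.median(list(depths.values())))
    if baseline <= 0:
        raise ParameterError("zero depth baseline")
    rows = []
    for chrom, d in depths.items():
        ratio = d / baseline
        frac = 2.0 * ratio
        copies = _round_half_away(frac)
        rows.append((chrom, d, ratio, frac, copies if copies in candidate_copies else pd.NA))
    table = pd.DataFrame(rows, columns=["chrom", "depth", "ratio", "fractional", "copies"])
    return table, baseline


_MODEL_COPIES = {BALANCED: 2, BIMODAL: 3}


def karyotype(
    calls: Mapping[str, PloidyCall], depth_table: pd.DataFrame
) -> pd.DataFrame:
    """Combine distribution calls and depth estimates into final copy numbers.

    Concordant evidence yields the call outright; discordant chromosomes
    are flagged with both values.  A composite distribution (skewed
    segments) never overrides depth, and an unresolved depth copy leaves
    the chromosome unresolved.
    """
    rows = []
    for rec in depth_table.itertuples(index=False):
        call = calls.get(rec.chrom)
        label = call.label if call is not None and call.status == "ok" else UNCALLABLE
        model_copies = _MODEL_COPIES.get(label)
        depth_copies = rec.copies
        if depth_copies is pd.NA or depth_copies is None:
            final, flag = pd.NA, "unresolved"
        elif model_copies is None:
            final, flag = depth_copies, ("" if label == COMPOSITE else "no-afd-call")
        elif model_copies == depth_copies:
            final, flag = depth_copies, ""
        else:
            final, flag = depth_copies, "discordant"
        rows.append((rec.chrom, label, model_copies, rec.ratio, rec.fractional,
                     depth_copies, final, flag))
    return pd.DataFrame(
        rows,
        columns=["chrom", "afd_label", "afd_copies", "depth_ratio", "fractional",
                 "depth_copies", "final_copies", "flag"],
    )


@dataclass(frozen=True)
class OrganelleCopies:
    fractional: float
    rounded: int


def organelle_copy_number(
    organelle_depth: float, nuclear_baseline: float, baseline_copies: int = 2
) -> OrganelleCopies:
    """Cellular organelle-genome copies from the depth ratio to the nuclear baseline.

    copies = baseline_copies * organelle_depth / nuclear_baseline.
    """
    if nuclear_baseline <= 0:
        raise ParameterError("nuclear baseline depth must be positive")
    if organelle_depth <= 0:
        raise ParameterError("organelle depth must be positive")
    frac = baseline_copies * organelle_depth / nuclear_baseline
    return OrganelleCopies(frac, _round_half_away(frac))
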