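"""Phenotype statistics for a Drosophila mutant-allele study.

Covers the quantitative genetics side of the analysis:

* cuticle scoring — dead embryos are placed in ordinal categories 0-5
  (0 wildtype, 1 head-skeleton defects, 2 failed head involution, 3 plus
  cuticle holes, 4 failed head involution and dorsal closure, 5 fragmented
  cuticle) and averaged per genotype;
* Mendelian lethality expectations for het x het crosses and for
  germline-clone (maternal/zygotic) crosses;
* relative viability of balanced stocks from progeny counts;
* junctional-intensity quantification: per-image line/circle pixel
  intensities, background subtraction, and the first-order (delta-method)
  variance of the ratio of the two group means:

      Var[X/Y] ~= Var[X]/mu_Y^2 + mu_X^2 Var[Y]/mu_Y^4
                  - 2 mu_X Cov[X,Y]/mu_Y^3

  with Cov[X,Y] = 0 for unpaired groups (distinct embryos).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

CUTICLE_CATEGORIES = tuple(range(6))


@dataclass
class CuticleTable:
    """Category counts of scored cuticles for one genotype."""

    genotype: str
    counts: dict[int, int]

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(CUTICLE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown cuticle categories {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative category count")
        self.counts = {k: int(self.counts.get(k, 0)) for k in CUTICLE_CATEGORIES}

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def cuticle_score(table: CuticleTable) -> dict:
    """Average cuticle score and category distribution for one genotype.

    The distribution sums to 1 and is suitable for 100%-cumulative-bar
    rendering.
    """
    n = table.n
    if n == 0:
        raise ValueError(f"no scored cuticles for {table.genotype!r}")
    mean = sum(k * c for k, c in table.counts.items()) / n
    dist = {k: table.counts[k] / n for k in CUTICLE_CATEGORIES}
    return {"mean_score": mean, "distribution": dist, "n": n}


class CrossPreset(str, enum.Enum):
    HET_X_HET_ZYGOTIC = "het_x_het_zygotic"
    GERMLINE_CLONE_X_HET = "germline_clone_x_het"


@dataclass(frozen=True)
class CrossModel:
    """Mendelian cross with per-genotype viability fractions.

    ``het_x_het_zygotic``: 1/4 homozygous mutant, 1/2 heterozygous, 1/4
    wildtype progeny. ``germline_clone_x_het``: all progeny lack maternal
    product; half receive a paternal wildtype allele (viability =
    ``zygotic_rescue``), half are maternal/zygotic mutants (viability =
    ``homozygote_viability``).
    """

    preset: CrossPreset = CrossPreset.HET_X_HET_ZYGOTIC
    homozygote_viability: float = 0.0
    heterozygote_viability: float = 1.0
    zygotic_rescue: float = 1.0

    def __post_init__(self) -> None:
        for name in ("homozygote_viability", "heterozygote_viability",
                     "zygotic_rescue"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def expected_lethality(model: CrossModel) -> float:
    """Expected percentage of embryos dying under the cross model."""
    preset = CrossPreset(model.preset)
    if preset is CrossPreset.HET_X_HET_ZYGOTIC:
        death = (0.25 * (1.0 - model.homozygote_viability)
                 + 0.5 * (1.0 - model.heterozygote_viability))
    else:
        death = (0.5 * (1.0 - model.homozygote_viability)
                 + 0.5 * (1.0 - model.zygotic_rescue))
    return 100.0 * death


def relative_viability(n_non_balancer: int, n_balancer: int,
                       denominator: str = "total") -> float:
    """Relative viability of a mutation-bearing chromosome over a balancer.

    ``denominator="total"`` (default): 100 * non_balancer / (non_balancer +
    balancer), i.e. the observed fraction of non-balancer progeny.
    ``denominator="balancer"``: 100 * non_balancer / balancer, i.e. recovery
    relative to balancer sibs.
    """
    if n_balancer < 0 or n_non_balancer < 0:
        raise ValueError("counts must be non-negative")
    if n_balancer == 0 and n_non_balancer == 0:
        raise ValueError("no progeny counted")
    if denominator == "total":
        return 100.0 * n_non_balancer / (n_non_balancer + n_balancer)
    if denominator == "balancer":
        if n_balancer == 0:
            raise ValueError("balancer count is zero")
        return 100.0 * n_non_balancer / n_balancer
    raise ValueError(f"unknown denominator {denominator!r}")


class IntensityGroup(str, enum.Enum):
    GFP_NEGATIVE = "gfp_negative"  # mutant group, numerator X
    GFP_POSITIVE = "gfp_positive"  # control group, denominator Y


@dataclass
class IntensitySample:
    """Per-image junction (line) and background (circle) pixel intensities."""

    embryo_id: str
    group: IntensityGroup
    line_values: list[float]
    circle_values: list[float]

    def __post_init__(self) -> None:
        if not self.line_values or not self.circle_values:
            raise ValueError("line/circle value lists must be non-empty")
        if min(self.line_values) < 0 or min(self.circle_values) < 0:
            raise ValueError("intensities must be >= 0")


def junctional_intensity(sample: IntensitySample) -> float:
    """Background-subtracted junctional intensity of one image:
    mean(lines) - mean(circles). May be negative (reported, not clamped)."""
    return float(np.mean(sample.line_values) - np.mean(sample.circle_values))


@dataclass
class RatioEstimate:
    ratio: float
    ratio_pct: float
    variance: float
    sd: float
    mu_x: float
    mu_y: float
    var_x: float
    var_y: float
    cov_xy: float


def delta_ratio(x: list[float], y: list[float],
                paired: bool = False) -> RatioEstimate:
    """Ratio of group means with its first-order Taylor-expansion variance.

    ``x`` and ``y`` are the per-image background-subtracted intensities of
    the two groups. Sample variances/covariance use ddof=1; the covariance
    term is dropped (0) unless ``paired``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if paired and x.size != y.size:
        raise ValueError("paired groups must have equal length")
    mu_x, mu_y = float(x.mean()), float(y.mean())
    if mu_y == 0:
        raise ZeroDivisionError("denominator group mean is zero")
    var_x = float(x.var(ddof=1))
    var_y = float(y.var(ddof=1))
    cov = float(np.cov(x, y, ddof=1)[0, 1]) if paired else 0.0
    variance = (var_x / mu_y ** 2
                + mu_x ** 2 * var_y / mu_y ** 4
                - 2.0 * mu_x * cov / mu_y ** 3)
    ratio = mu_x / mu_y
    return RatioEstimate(
        ratio=ratio, ratio_pct=100.0 * ratio,
        variance=variance, sd=math.sqrt(max(variance, 0.0)),
        mu_x=mu_x, mu_y=mu_y, var_x=var_x, var_y=var_y, cov_xy=cov,
    )
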