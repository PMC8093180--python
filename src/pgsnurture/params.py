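"""Structural parameters and PGS scaling conventions.

The models are parameterised by the haplotypic-PGS effect ``delta``, the
haplotypic latent-genetic-score effect ``a``, the vertical-transmission path
``f``, the assortative-mating copath coefficient ``mu`` (or, more intuitively,
the spousal phenotypic correlation ``r_mate = mu * V_Y``), and the residual
variance ``V_eps``.  The constants ``k`` and ``j`` are the base-population
variances of the haplotypic observed and latent genetic scores; they are not
estimated but fixed by the user's choice of PGS scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Scaling(str, Enum):
    """How the polygenic score is scaled, which fixes the constant ``k``.

    * ``base_standardized`` — the full PGS has unit variance in the base
      population (before AM/VT): ``k = 1/2``.  Only possible when the base
      population is observable (simulated data) or there is no AM.
    * ``full_pgs_standardized_now`` — the full PGS ``T + NT`` has unit
      variance in the current generation: ``k = 1/2 - 2g``.
    * ``haplotypic_half_now`` — each haplotypic PGS has variance 1/2 in the
      current generation: ``k = 1/2 - g``.

    The latent constant ``j`` is defined analogously from ``h``.
    """

    base_standardized = "base_standardized"
    full_pgs_standardized_now = "full_pgs_standardized_now"
    haplotypic_half_now = "haplotypic_half_now"


_SCALING_ALIASES = {
    "base": Scaling.base_standardized,
    "full": Scaling.full_pgs_standardized_now,
    "haplo": Scaling.haplotypic_half_now,
}


def as_scaling(value: "Scaling | str") -> Scaling:
    if isinstance(value, Scaling):
        return value
    if value in _SCALING_ALIASES:
        return _SCALING_ALIASES[value]
    return Scaling(value)


def base_constants(scaling: "Scaling | str", g: float = 0.0, h: float = 0.0) -> tuple[float, float]:
    """Base-population haplotypic score variances (k, j) for a scaling choice.

    Parameters
    ----------
    scaling : Scaling or str
        Scaling convention (aliases ``base``/``full``/``haplo`` accepted).
    g, h : float
        AM-induced (co)variance of the haplotypic PGS / LGS, ``>= 0``.

    Returns
    -------
    (k, j) : tuple of float

    Raises
    ------
    ValueError
        If the implied ``k`` or ``j`` is non-positive, i.e. AM is too strong
        for the chosen scaling to be coherent.
    """
    if g < 0 or h < 0:
        raise ValueError(f"g and h must be non-negative, got g={g}, h={h}")
    s = as_scaling(scaling)
    if s is Scaling.base_standardized:
        k, j = 0.5, 0.5
    elif s is Scaling.full_pgs_standardized_now:
        k, j = 0.5 - 2.0 * g, 0.5 - 2.0 * h
    else:
        k, j = 0.5 - g, 0.5 - h
    if k <= 0 or j <= 0:
        raise ValueError(
            f"scaling {s.value!r} with g={g}, h={h} implies k={k}, j={j} <= 0; "
            "AM is too strong for this scaling convention"
        )
    return k, j


@dataclass
class ModelParams:
    """Free structural parameters of the parental-effects models.

    ``mu`` and ``r_mate`` are two parameterisations of the same AM strength;
    supply at most one.  ``mu`` is the copath coefficient
    ``cov(Y_p, Y_m) / V_Y^2`` — neither the spousal covariance nor the spousal
    correlation — while ``r_mate = mu * V_Y`` is the spousal correlation and
    is what users typically know.  When ``r_mate`` is given, ``mu`` is solved
    for inside the equilibrium fixed point.
    """

    delta: float
    f: float = 0.0
    a: float = 0.0
    mu: float | None = None
    r_mate: float | None = None
    V_eps: float = 1.0
    scaling: Scaling = field(default=Scaling.base_standardized)

    def __post_init__(self) -> None:
        self.scaling = as_scaling(self.scaling)
        if self.V_eps <= 0:
            raise ValueError(f"V_eps must be positive, got {self.V_eps}")
        if abs(self.f) >= 1:
            raise ValueError(f"|f| must be < 1, got f={self.f}")
        if self.mu is not None and self.r_mate is not None:
            raise ValueError("supply either mu or r_mate, not both")
        if self.r_mate is not None and not -1 < self.r_mate < 1:
            raise ValueError(f"r_mate must lie in (-1, 1), got {self.r_mate}")

    @property
    def am_strength(self) -> float:
        """Either mu or r_mate, 0.0 when neither is set (no AM)."""
        if self.mu is not None:
            return self.mu
        if self.r_mate is not None:
            return self.r_mate
        return 0.0

    def has_am(self) -> bool:
        return self.am_strength != 0.0
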