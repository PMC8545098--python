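"""Physical model of DNA buoyant density in a CsCl gradient.

DNA banded in a CsCl equilibrium gradient settles at a buoyant density
(BD) set by its base composition and isotopic composition.  This module
provides the deterministic pieces of that picture: the GC/label → BD
relation, the fraction layout of a harvested gradient, diffusion
broadening of a DNA fragment's band, and the expected read-depth profile
a contig contributes across fractions — including the natural-abundance
("null") profile used downstream to control for GC content.

Conventions
-----------
Fractions are numbered 1..N from the *heavy* (dense) end of the
gradient, so BD midpoints strictly decrease with fraction id.  All
densities are in g ml⁻¹, lengths in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

# Schildkraut-type linear BD model: BD(GC) = 1.660 + 0.098·GC, with a
# full-label (100 atom% excess) shift of 0.036 g/ml scaled linearly by
# the atom-fraction excess of the DNA.
BD_INTERCEPT = 1.660
BD_GC_SLOPE = 0.098
BD_LABEL_SHIFT = 0.036

#: Maximum attainable atom-fraction excess: 99 atom% substrate minus
#: ~1.1% natural abundance of ¹³C.
MAX_ATOM_EXCESS = 0.989

DEFAULT_SIGMA0 = 0.005  # band sd (g/ml) of a 10 kb fragment
DEFAULT_L0 = 10_000  # reference fragment length (bp)


class GradientDomainError(ValueError):
    """An input fell outside the physical domain of the gradient model."""


@dataclass(frozen=True)
class LabelState:
    """Isotopic state of one population's DNA.

    Parameters
    ----------
    atom_excess:
        ¹³C atom fraction above natural abundance, in [0, 0.989].
    labeled_fraction:
        Proportion ``w`` of the population that is labelled, in [0, 1].
    """

    atom_excess: float = 0.0
    labeled_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.atom_excess <= MAX_ATOM_EXCESS:
            raise GradientDomainError(
                f"atom_excess must be in [0, {MAX_ATOM_EXCESS}], got {self.atom_excess}"
            )
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise GradientDomainError(
                f"labeled_fraction must be in [0, 1], got {self.labeled_fraction}"
            )

    @property
    def mean_bd_shift(self) -> float:
        """Mean BD shift of the population mixture relative to unlabelled DNA."""
        return BD_LABEL_SHIFT * self.atom_excess * self.labeled_fraction


@dataclass(frozen=True)
class BdMixture:
    """Mixture of Gaussian BD bands: list of (mean BD, sd, weight)."""

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise GradientDomainError("mixture needs at least one component")
        weights = [w for _, _, w in self.components]
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise GradientDomainError("weights must be >= 0 and sum to 1")
        if any(sd <= 0 for _, sd, _ in self.components):
            raise GradientDomainError("component sd must be > 0")

    @property
    def mean_bd(self) -> float:
        return sum(m * w for m, _, w in self.components)


@dataclass(frozen=True)
class FractionLayout:
    """Geometry of a fractionated CsCl gradient.

    ``bd_mid[i]`` is the BD midpoint of fraction id ``i+1``; midpoints
    strictly decrease (fraction 1 is the heavy end).  ``sequenced_window``
    is the contiguous range of fraction ids that were actually sequenced.
    """

    n_fractions: int
    bd_mid: tuple[float, ...]
    bd_step: float  # negative toward lighter fractions
    sequenced_window: tuple[int, ...]
    anchor_fractions: tuple[int, int] = (6, 13)
    anchor_bds: tuple[float, float] = (1.749, 1.717)

    def __post_init__(self) -> None:
        if len(self.bd_mid) != self.n_fractions:
            raise GradientDomainError("bd_mid length must equal n_fractions")
        diffs = np.diff(self.bd_mid)
        if not np.all(diffs < 0):
            raise GradientDomainError("bd_mid must be strictly decreasing")
        if abs(self.bd_step) <= 0:
            raise GradientDomainError("|bd_step| must be > 0")
        w = self.sequenced_window
        if not w or any(f < 1 or f > self.n_fractions for f in w):
            raise GradientDomainError("sequenced_window must lie within fraction ids")
        if list(w) != list(range(w[0], w[-1] + 1)):
            raise GradientDomainError("sequenced_window must be contiguous")

    def bd_of(self, fraction_id: int) -> float:
        return self.bd_mid[fraction_id - 1]

    @property
    def window_size(self) -> int:
        return len(self.sequenced_window)

    @property
    def window_slice(self) -> slice:
        return slice(self.sequenced_window[0] - 1, self.sequenced_window[-1])

    # -- serialization (pipeline config) -------------------------------
    def to_dict(self) -> dict:
        return {
            "n_fractions": self.n_fractions,
            "anchor_fractions": list(self.anchor_fractions),
            "anchor_bds": list(self.anchor_bds),
            "sequenced_window": [self.sequenced_window[0], self.sequenced_window[-1]],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FractionLayout":
        a, b = d["anchor_fractions"]
        bd_a, bd_b = d["anchor_bds"]
        lo, hi = d["sequenced_window"]
        return build_layout(
            anchor_a=(a, bd_a),
            anchor_b=(b, bd_b),
            n_fractions=d["n_fractions"],
            sequenced_window=range(lo, hi + 1),
        )


def buoyant_density(gc: float, atom_excess: float = 0.0) -> float:
    """Equilibrium buoyant density of DNA with the given GC content and label.

    BD = 1.660 + 0.098·GC + 0.036·excess, strictly increasing in both.
    """
    if not 0.0 <= gc <= 1.0:
        raise GradientDomainError(f"gc must be in [0, 1], got {gc}")
    if not 0.0 <= atom_excess <= 1.0:
        raise GradientDomainError(f"atom_excess must be in [0, 1], got {atom_excess}")
    return BD_INTERCEPT + BD_GC_SLOPE * gc + BD_LABEL_SHIFT * atom_excess


def fragment_sigma(length: float, sigma0: float = DEFAULT_SIGMA0, l0: float = DEFAULT_L0) -> float:
    """Diffusion broadening of a fragment's band: σ(L) = σ₀·√(L₀/L).

    Shorter fragments diffuse more and band more broadly; only the
    relative width matters to downstream classification.
    """
    if length <= 0:
        raise GradientDomainError(f"length must be > 0, got {length}")
    return sigma0 * np.sqrt(l0 / length)


def build_layout(
    anchor_a: tuple[int, float] = (6, 1.749),
    anchor_b: tuple[int, float] = (13, 1.717),
    n_fractions: int = 35,
    sequenced_window: range | tuple[int, ...] | None = None,
) -> FractionLayout:
    """Linear fraction layout through two (fraction, BD) anchors.

    Defaults reproduce a 35-fraction gradient whose sequenced window runs
    from F6 (1.749 g ml⁻¹) to F13 (1.717 g ml⁻¹); fractions outside the
    anchors are extrapolated on the same line.
    """
    fa, bda = anchor_a
    fb, bdb = anchor_b
    if fa == fb:
        raise GradientDomainError("anchor fractions must differ")
    step = (bdb - bda) / (fb - fa)
    ids = np.arange(1, n_fractions + 1)
    bd_mid = bda + (ids - fa) * step
    if sequenced_window is None:
        sequenced_window = range(min(fa, fb), max(fa, fb) + 1)
    return FractionLayout(
        n_fractions=n_fractions,
        bd_mid=tuple(bd_mid.tolist()),
        bd_step=step,
        sequenced_window=tuple(sequenced_window),
        anchor_fractions=(fa, fb),
        anchor_bds=(bda, bdb),
    )


def bd_mixture(
    gc: float,
    length: float,
    label: LabelState,
    sigma0: float = DEFAULT_SIGMA0,
    l0: float = DEFAULT_L0,
) -> BdMixture:
    """Two-component BD mixture for a partially labelled population.

    An unlabelled band at BD(gc, 0) with weight 1−w and a labelled band
    at BD(gc, excess) with weight w; zero-weight components are dropped.
    """
    sd = fragment_sigma(length, sigma0=sigma0, l0=l0)
    w = label.labeled_fraction
    comps = []
    if w < 1.0:
        comps.append((buoyant_density(gc, 0.0), sd, 1.0 - w))
    if w > 0.0:
        comps.append((buoyant_density(gc, label.atom_excess), sd, w))
    return BdMixture(components=tuple(comps))


def _fraction_edges(layout: FractionLayout) -> np.ndarray:
    """BD interval edges, heavy to light; terminal edges open to ±∞."""
    mid = np.asarray(layout.bd_mid)
    half = abs(layout.bd_step) / 2.0
    upper = mid + half
    lower = mid - half
    upper[0] = np.inf  # pellet/meniscus pooling at the gradient ends
    lower[-1] = -np.inf
    return lower, upper


def expected_profile(mixture: BdMixture, layout: FractionLayout) -> np.ndarray:
    """Expected relative depth of the mixture in every fraction of the layout.

    Each component's Gaussian band is integrated over each fraction's BD
    interval; mass beyond the terminal fraction boundaries accumulates in
    the terminal fractions, so the profile sums to exactly 1.
    """
    lower, upper = _fraction_edges(layout)
    p = np.zeros(layout.n_fractions)
    for mean, sd, weight in mixture.components:
        p += weight * (norm.cdf(upper, mean, sd) - norm.cdf(lower, mean, sd))
    return p


def simulate_null_profile(
    gc: float,
    length: float,
    layout: FractionLayout,
    sigma0: float = DEFAULT_SIGMA0,
    l0: float = DEFAULT_L0,
) -> np.ndarray:
    """Deterministic profile the contig would show at natural ¹³C abundance.

    This is the GC-controlled null against which observed gradient
    profiles are compared: identical GC and length, zero atom excess,
    no noise.
    """
    mix = bd_mixture(gc, length, LabelState(0.0, 0.0), sigma0=sigma0, l0=l0)
    return expected_profile(mix, layout)
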