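"""Pairwise similarity of 3D patterns and the combined GScore.

Every cross-structure pair of patterns gets four partial similarities, each
a multiset-overlap (or magnitude-ratio) percentage:

    SDist = |Dist_A n Dist_B| / max(|Dist_A|, |Dist_B|) * 100
    SNbE  = min(|NbE_A|, |NbE_B|) / max(|NbE_A|, |NbE_B|) * 100
    STsp  = |Tsp_A n Tsp_B| / max(|Tsp_A|, |Tsp_B|) * 100
    SSc   = |Sc_A n Sc_B| / max(|Sc_A|, |Sc_B|) * 100

and the combined score is the weighted mean

    GScore = (SDist*Dp + SNbE*Cp + STsp*Tp + SSc*Sp) / 100

with the four weights summing to 100 % (default 25 % each).  GScore = 100
means indistinguishable descriptor sets; 0 means no shared feature.  The
score quantifies similarity — it does not decide it; thresholding is the
caller's policy (results filtering conventionally uses a strict > 50 %).

Intersections are multiset intersections: the normalizers n(n-1)/2 and n
count tokens with multiplicity, so duplicates must be preserved or
repetitive patterns would be over-rewarded.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .descriptors import DescriptorSet

log = logging.getLogger(__name__)


class EmptyDescriptorError(ValueError):
    """Similarity of an empty token multiset is undefined."""


@dataclass(frozen=True)
class Weights:
    """Relative contributions (percent) of the four partial similarities."""

    dp: float = 25.0  # distance
    cp: float = 25.0  # non-bonded energy
    tp: float = 25.0  # perimeter
    sp: float = 25.0  # sequence component

    def __post_init__(self):
        for name, w in zip(("Dp", "Cp", "Tp", "Sp"), self.as_tuple()):
            if not 0.0 <= w <= 100.0:
                raise ValueError(f"weight {name} must be in [0, 100], got {w}")
        total = sum(self.as_tuple())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"weights must sum to 100, got {total}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.dp, self.cp, self.tp, self.sp)


@dataclass(frozen=True)
class PairScore:
    """Scores of one cross-structure pattern pair (all percentages)."""

    structure_a: str
    pattern_a: str
    structure_b: str
    pattern_b: str
    sdist: float
    snbe: float
    stsp: float
    ssc: float
    gscore: float


def _overlap(a: Counter, b: Counter) -> float:
    """Multiset-intersection cardinality over the larger cardinality, x100."""
    size_a, size_b = sum(a.values()), sum(b.values())
    if size_a == 0 or size_b == 0:
        raise EmptyDescriptorError("similarity of an empty descriptor is undefined")
    inter = sum((a & b).values())
    return 100.0 * inter / max(size_a, size_b)


def sdist(dist_a: Counter, dist_b: Counter) -> float:
    """Distance-token similarity."""
    return _overlap(dist_a, dist_b)


def snbe(nbe_a: float, nbe_b: float) -> float:
    """Energy-magnitude similarity.

    The ratio min(|a|,|b|)/max(|a|,|b|) is 0/0 when both energies vanish;
    two zero energies are identical, so that limit is defined as 100 (and
    zero against non-zero as 0).
    """
    a, b = abs(nbe_a), abs(nbe_b)
    hi = max(a, b)
    if hi == 0.0:
        return 100.0
    # ratio first: equal magnitudes give exactly 1.0, hence exactly 100
    return 100.0 * (min(a, b) / hi)


def stsp(tsp_a: Counter, tsp_b: Counter) -> float:
    """Perimeter-token similarity."""
    return _overlap(tsp_a, tsp_b)


def ssc(sc_a: Counter, sc_b: Counter) -> float:
    """Sequence-component (physicochemical category) similarity."""
    return _overlap(sc_a, sc_b)


def gscore(partials: tuple[float, float, float, float], weights: Weights) -> float:
    """Weighted mean of (SDist, SNbE, STsp, SSc) with weights/100."""
    d, c, t, s = partials
    return (d * weights.dp + c * weights.cp + t * weights.tp + s * weights.sp) / 100.0


def score_pair(a: DescriptorSet, b: DescriptorSet, weights: Weights) -> PairScore:
    """All four partials plus GScore for one pattern pair."""
    parts = (
        sdist(a.dist, b.dist),
        snbe(a.nbe, b.nbe),
        stsp(a.tsp, b.tsp),
        ssc(a.sc, b.sc),
    )
    return PairScore(
        structure_a=a.structure_id,
        pattern_a=a.pattern_ref,
        structure_b=b.structure_id,
        pattern_b=b.pattern_ref,
        sdist=parts[0],
        snbe=parts[1],
        stsp=parts[2],
        ssc=parts[3],
        gscore=gscore(parts, weights),
    )


@dataclass
class ComparisonResult:
    """Outcome of an all-vs-all comparison."""

    total_pairs: int
    retained: list[PairScore] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)


def _anchor_key(label: str):
    # "Atom459" -> 459; falls back to the raw label for odd inputs
    try:
        return (0, int(label.removeprefix("Atom")))
    except ValueError:
        return (1, label)


def compare_all(
    descs_a: list[DescriptorSet],
    descs_b: list[DescriptorSet],
    weights: Weights | None = None,
    threshold: float = 50.0,
) -> ComparisonResult:
    """Score every cross pair; keep those with GScore strictly above the
    threshold, sorted by GScore descending (ties by anchor labels).

    The evaluation order is immaterial: output content and ordering are
    identical regardless of how the loop is executed.
    """
    weights = weights or Weights()
    if not descs_a or not descs_b:
        side = "A" if not descs_a else "B"
        return ComparisonResult(
            total_pairs=0,
            diagnostics=[f"no patterns on side {side}; nothing to compare"],
        )
    retained = []
    for a in descs_a:
        for b in descs_b:
            ps = score_pair(a, b, weights)
            if ps.gscore > threshold:
                retained.append(ps)
    retained.sort(
        key=lambda p: (-p.gscore, _anchor_key(p.pattern_a), _anchor_key(p.pattern_b))
    )
    total = len(descs_a) * len(descs_b)
    diags = []
    if not retained:
        diags.append(
            f"no pair of {total} evaluated exceeded the GScore threshold {threshold:g} %"
        )
    return ComparisonResult(total_pairs=total, retained=retained, diagnostics=diags)
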