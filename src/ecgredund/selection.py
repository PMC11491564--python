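"""Standard 12-lead geometry and redundancy-driven lead selection.

The 12 standard leads are scalar projections of the cardiac dipole: the six
limb leads lie in the frontal plane, the six precordial leads approximately
in the transverse plane.  The geometry table below uses the conventional
textbook projection angles; it is data, not hard-wired logic, and can be
replaced wholesale by callers modelling a different electrode layout.

Selection strategies:

* fixed subsets of 8/6/3/1 leads derived on the PTB-XL corpus (shipped as
  constants — their derivation depends on that corpus' statistics);
* ranking candidate orthogonal lead pairs by two-channel set redundancy;
* the most representative single lead = argmax of channel redundancy;
* a generic minimum-set-redundancy subset search (exhaustive or greedy).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

from .errors import ContractError, UndefinedValueError
from .infotheory import BinnedChannels, channel_redundancy, set_redundancy

Plane = Literal["frontal", "transverse"]

#: cap on the number of subsets the exhaustive search will enumerate
EXHAUSTIVE_CAP = 5000


@dataclass(frozen=True)
class LeadGeometry:
    """Projection direction of one standard lead: plane + in-plane angle."""

    lead: str
    plane: Plane
    angle_deg: float

    def __post_init__(self) -> None:
        if not (-180.0 < self.angle_deg <= 180.0):
            raise ContractError(f"angle_deg must lie in (-180, 180], got {self.angle_deg}")


#: Conventional projection angles of the 12 standard leads.  Frontal-plane
#: angles follow the hexaxial reference system (lead I = 0 deg, positive
#: clockwise toward aVF at +90 deg); transverse-plane angles place V6 along
#: the x-axis with V1 most anterior.
STANDARD_GEOMETRY: dict[str, LeadGeometry] = {
    g.lead: g
    for g in (
        LeadGeometry("I", "frontal", 0.0),
        LeadGeometry("II", "frontal", 60.0),
        LeadGeometry("III", "frontal", 120.0),
        LeadGeometry("aVR", "frontal", -150.0),
        LeadGeometry("aVL", "frontal", -30.0),
        LeadGeometry("aVF", "frontal", 90.0),
        LeadGeometry("V1", "transverse", 115.0),
        LeadGeometry("V2", "transverse", 95.0),
        LeadGeometry("V3", "transverse", 75.0),
        LeadGeometry("V4", "transverse", 60.0),
        LeadGeometry("V5", "transverse", 30.0),
        LeadGeometry("V6", "transverse", 0.0),
    )
}

STANDARD_12_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")
LIMB_LEADS = STANDARD_12_LEADS[:6]
PRECORDIAL_LEADS = STANDARD_12_LEADS[6:]
#: the 8 leads carrying all the linear information of the 12 (the 4 removed
#: augmented/limb leads are exact linear combinations of I and II)
INDEPENDENT_8_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: fixed reduced-lead subsets (derived on the PTB-XL corpus)
FIXED_SUBSETS: dict[str, tuple[str, ...]] = {
    "eight": INDEPENDENT_8_LEADS,
    "six": ("II", "aVL", "V1", "V3", "V5", "V6"),
    "three": ("aVR", "III", "V2"),
    "one": ("V6",),
}

#: the three orthogonal frontal-plane lead pairs
ORTHOGONAL_FRONTAL_PAIRS = (("I", "aVF"), ("II", "aVL"), ("III", "aVR"))


@dataclass(frozen=True)
class SubsetScore:
    """A candidate lead subset with its set-redundancy score."""

    leads: tuple[str, ...]
    set_R: float
    mode: str = "exhaustive"


def absolute_angle(
    lead_a: str, lead_b: str, geometry: dict[str, LeadGeometry] | None = None
) -> float:
    """Smallest absolute angle between two lead directions, in [0, 90] degrees.

    A lead and its reversal carry the same projection axis, so differences
    are folded modulo 180 and then into [0, 90].  Both leads must lie in the
    same plane; cross-plane angles are not comparable in this 2-D geometry.
    """
    geometry = geometry or STANDARD_GEOMETRY
    try:
        ga, gb = geometry[lead_a], geometry[lead_b]
    except KeyError as exc:
        raise ContractError(f"unknown lead {exc.args[0]!r}") from None
    if ga.plane != gb.plane:
        raise ContractError(
            f"cannot compare angles across planes: {lead_a} is {ga.plane}, {lead_b} is {gb.plane}"
        )
    d = abs(ga.angle_deg - gb.angle_deg) % 180.0
    return min(d, 180.0 - d)


def fixed_subset(name: str) -> tuple[str, ...]:
    """Return one of the fixed reduced-lead subsets: eight, six, three, one."""
    try:
        return FIXED_SUBSETS[name]
    except KeyError:
        raise ContractError(
            f"unknown fixed subset {name!r}; choose from {sorted(FIXED_SUBSETS)}"
        ) from None


def rank_orthogonal_pairs(
    channels: BinnedChannels,
    pairs: Sequence[tuple[str, str]] = ORTHOGONAL_FRONTAL_PAIRS,
) -> list[SubsetScore]:
    """Score each candidate lead pair by two-channel set redundancy.

    Returns scores sorted ascending (least redundant first); the sort is
    stable so ties keep input order.
    """
    scores = [
        SubsetScore(tuple(pair), set_redundancy(channels, list(pair)), mode="pair")
        for pair in pairs
    ]
    return sorted(scores, key=lambda s: s.set_R)


def most_representative_lead(channels: BinnedChannels) -> str:
    """Lead whose channel redundancy against the rest is highest.

    The winner is the channel most predictable from the others, i.e. the one
    that best summarizes the whole set.  Ties break by channel order.
    """
    best_name, best_r = None, -1.0
    for i, name in enumerate(channels.channel_names):
        try:
            r = channel_redundancy(channels, i)
        except UndefinedValueError:
            raise UndefinedValueError(
                f"most_representative_lead undefined: channel {name!r} is constant"
            ) from None
        if r > best_r:
            best_name, best_r = name, r
    assert best_name is not None
    return best_name


def search_min_redundancy_subset(
    channels: BinnedChannels,
    k: int,
    mode: Literal["exhaustive", "greedy"] = "exhaustive",
) -> SubsetScore:
    """Find a k-lead subset minimizing set redundancy.

    exhaustive
        Scores all C(n, k) subsets (capped at 5000; use greedy beyond) and
        returns the minimum; ties go to the lexicographically first index
        tuple.
    greedy
        Starts from the pair with minimum set redundancy, then repeatedly
        adds the channel that keeps the growing set's redundancy lowest.
        Never better than exhaustive, but O(n^2 + n*k) scorings.
    """
    n = channels.n_channels
    if not 1 <= k <= n:
        raise ContractError(f"k must be in [1, {n}], got {k}")
    names = channels.channel_names

    if k == 1:
        # every singleton has R = 0; first channel by the tie rule
        return SubsetScore((names[0],), 0.0, mode=mode)

    if mode == "exhaustive":
        from math import comb

        if comb(n, k) > EXHAUSTIVE_CAP:
            raise ContractError(
                f"C({n},{k}) = {comb(n, k)} subsets exceeds the exhaustive cap "
                f"({EXHAUSTIVE_CAP}); use mode='greedy'"
            )
        best_idx, best_r = None, float("inf")
        for idx in combinations(range(n), k):
            r = set_redundancy(channels, list(idx))
            if r < best_r:  # strict < keeps the lexicographically first tie
                best_idx, best_r = idx, r
        assert best_idx is not None
        return SubsetScore(tuple(names[i] for i in best_idx), best_r, mode="exhaustive")

    if mode == "greedy":
        best_pair, best_r = None, float("inf")
        for idx in combinations(range(n), 2):
            r = set_redundancy(channels, list(idx))
            if r < best_r:
                best_pair, best_r = list(idx), r
        assert best_pair is not None
        current = best_pair
        while len(current) < k:
            best_add, best_r = None, float("inf")
            for j in range(n):
                if j in current:
                    continue
                r = set_redundancy(channels, current + [j])
                if r < best_r:
                    best_add, best_r = j, r
            current.append(best_add)
        if len(current) == 2 and k == 2:
            pass  # best_r already the pair score
        return SubsetScore(
            tuple(names[i] for i in current),
            set_redundancy(channels, current),
            mode="greedy",
        )

    raise ContractError(f"unknown mode {mode!r}; choose 'exhaustive' or 'greedy'")
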