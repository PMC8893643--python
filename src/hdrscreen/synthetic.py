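"""Synthetic knock-in experiments and conversion events.

Emulates the structure of a pooled CRISPR/Cas9 knock-in screen in
*Aedes aegypti*: injected G0 survivors are crossed in cages ("pools") of
about 20 founders; a pool is scored positive when at least one founder
transmits a detectable (fluorescent) integration to the G1. Separately,
canonical HDR events are given SDSA-style gene-conversion tracts over
recoded homology arms: each event is non-converted, unidirectional (5'
or 3') or bidirectional, and each converted side extends a geometric
(memoryless per-base) distance from the cut, over marker SNPs that keep
a ~50 bp SNP-free window adjacent to the DSB.

Everything is deterministic under a fixed seed; generated tables are the
ground truth against which the estimators in :mod:`hdrscreen.pooling`
and :mod:`hdrscreen.tracts` are validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tracts import CallState, ConversionCallSet, Direction, SNPMap

__all__ = [
    "SimDesign",
    "TractModel",
    "SNPMapSpec",
    "SimulatedConversion",
    "generate_snp_map",
    "simulate_experiment",
    "simulate_conversion_events",
]

_BASES = ("A", "C", "G", "T")


def _check_prob(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {x}")


@dataclass(frozen=True)
class SimDesign:
    """Design of a simulated pooled screen.

    ``p_individual`` is the probability that one G0 founder produces at
    least one detectable transgenic G1 (the underlying individual
    integration rate the screen tries to bound). ``events_per_founder``
    optionally lets a transgenic founder carry several independent
    insertions; pool positivity is unaffected by it (default 1).
    """

    n_constructs: int = 1
    pools_per_construct: int = 13
    founders_per_pool: int = 20
    p_individual: float = 0.05
    detection_prob: float = 1.0
    seed: int = 0
    events_per_founder: int = 1

    def __post_init__(self) -> None:
        for name in ("n_constructs", "pools_per_construct",
                     "founders_per_pool", "events_per_founder"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        _check_prob("p_individual", self.p_individual)
        _check_prob("detection_prob", self.detection_prob)


@dataclass(frozen=True)
class TractModel:
    """Mixture model for SDSA conversion tracts.

    An event is bidirectional with probability ``p_bidirectional``,
    non-converting with ``p_nonconversion``, otherwise unidirectional
    (5' side with conditional probability ``p_uni_5p``). Each converted
    side extends a Geometric(1/mean_tract_bp) number of bases from the
    DSB (memoryless per-base extension), truncated at ``arm_extent_bp``.
    ``mean_tract_bp=math.inf`` forces full-arm tracts (a limit used in
    tests).
    """

    p_bidirectional: float = 0.2
    p_nonconversion: float = 0.2
    p_uni_5p: float = 0.5
    mean_tract_bp: float = 150.0
    arm_extent_bp: int = 2000

    def __post_init__(self) -> None:
        _check_prob("p_bidirectional", self.p_bidirectional)
        _check_prob("p_nonconversion", self.p_nonconversion)
        _check_prob("p_uni_5p", self.p_uni_5p)
        if self.p_bidirectional + self.p_nonconversion > 1.0 + 1e-12:
            raise ValueError("p_bidirectional + p_nonconversion must be <= 1")
        if not (self.mean_tract_bp >= 1.0):
            raise ValueError("mean_tract_bp must be >= 1 (bp)")
        if self.arm_extent_bp < 1:
            raise ValueError("arm_extent_bp must be >= 1")

    @property
    def p_unidirectional(self) -> float:
        return 1.0 - self.p_bidirectional - self.p_nonconversion


@dataclass(frozen=True)
class SNPMapSpec:
    """Spec for a synthetic marker-SNP map.

    ``guard_bp`` reproduces the uninterrupted perfect-homology window
    adjacent to the cut site: no marker is placed within that distance
    of the DSB on either arm.
    """

    n_snps_5p: int = 25
    n_snps_3p: int = 25
    guard_bp: int = 50
    arm_len_bp: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps_5p < 0 or self.n_snps_3p < 0:
            raise ValueError("SNP counts must be >= 0")
        if self.guard_bp < 0 or self.arm_len_bp < 1:
            raise ValueError("guard_bp >= 0 and arm_len_bp >= 1 required")
        if (self.n_snps_5p or self.n_snps_3p) \
                and self.guard_bp >= self.arm_len_bp:
            raise ValueError(
                "guard_bp >= arm_len_bp leaves no placeable SNP positions")
        placeable = self.arm_len_bp - self.guard_bp
        if max(self.n_snps_5p, self.n_snps_3p) > placeable:
            raise ValueError(
                f"cannot place {max(self.n_snps_5p, self.n_snps_3p)} SNPs in "
                f"{placeable} placeable positions per arm")


def generate_snp_map(spec: SNPMapSpec) -> SNPMap:
    """Draw marker SNPs uniformly over each arm outside the guard window.

    Offsets are unique and at least ``guard_bp`` from the DSB in
    magnitude, at most ``arm_len_bp``; reference and donor bases differ
    at every marker. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    positions = np.arange(max(spec.guard_bp, 1), spec.arm_len_bp + 1)
    offs_5p = -rng.choice(positions, size=spec.n_snps_5p, replace=False)
    offs_3p = rng.choice(positions, size=spec.n_snps_3p, replace=False)
    offsets = np.sort(np.concatenate([offs_5p, offs_3p]))
    ref = rng.choice(_BASES, size=len(offsets))
    shift = rng.integers(1, 4, size=len(offsets))
    donor = [_BASES[(_BASES.index(r) + s) % 4] for r, s in zip(ref, shift)]
    return SNPMap(offsets=tuple(int(o) for o in offsets),
                  ref_base=tuple(ref), donor_base=tuple(donor))


def simulate_experiment(design: SimDesign,
                        construct_ids: Sequence[str] | None = None
                        ) -> pd.DataFrame:
    """Simulate pooled G0 crosses and G1 screening.

    Per pool, each founder integrates independently with
    ``p_individual`` and, if transgenic, is detected with
    ``detection_prob``; the pool is positive iff any founder is both.
    Returns a tidy pool-level table with columns construct, donor_type,
    pool_id, n_founders, n_transgenic (ground truth), positive and
    g0_survivors_total (= pools x founders per construct: every survivor
    joins a pool in simulation).
    """
    rng = np.random.default_rng(design.seed)
    if construct_ids is None:
        construct_ids = [f"sim-{i + 1:03d}" for i in range(design.n_constructs)]
    elif len(construct_ids) != design.n_constructs:
        raise ValueError("construct_ids length must equal n_constructs")
    total = design.pools_per_construct * design.founders_per_pool
    rows = []
    for construct in construct_ids:
        for j in range(design.pools_per_construct):
            transgenic = rng.random(design.founders_per_pool) < design.p_individual
            detected = transgenic & (rng.random(design.founders_per_pool)
                                     < design.detection_prob)
            rows.append({
                "construct": construct,
                "donor_type": "simulated",
                "pool_id": f"{construct}-pool-{j + 1:02d}",
                "n_founders": design.founders_per_pool,
                "n_transgenic": int(transgenic.sum()),
                "positive": bool(detected.any()),
                "g0_survivors_total": total,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimulatedConversion:
    """A simulated event: the observable call set plus its ground truth."""

    calls: ConversionCallSet
    true_direction: Direction
    true_tract_5p: int
    true_tract_3p: int


def _tract_length(rng: np.random.Generator, model: TractModel) -> int:
    if math.isinf(model.mean_tract_bp):
        return model.arm_extent_bp
    length = int(rng.geometric(1.0 / model.mean_tract_bp))
    return min(length, model.arm_extent_bp)


def simulate_conversion_events(n_events: int, model: TractModel,
                               snp_map: SNPMap, seed: int = 0
                               ) -> list[SimulatedConversion]:
    """Simulate SDSA-style conversion events over a marker map.

    Each event draws a direction class from the model mixture, then a
    geometric tract length per converted side; a marker is donor-state
    iff its offset lies inside the tract interval anchored at the DSB,
    so simulated tracts are continuous by construction. The sequenced
    span covers the whole map plus the maximal tract extent.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng = np.random.default_rng(seed)
    classes = (Direction.NON_CONVERSION, Direction.UNI_5P,
               Direction.UNI_3P, Direction.BIDIRECTIONAL)
    p_uni = model.p_unidirectional
    probs = (model.p_nonconversion, p_uni * model.p_uni_5p,
             p_uni * (1.0 - model.p_uni_5p), model.p_bidirectional)
    lo = min((min(snp_map.offsets, default=0), -model.arm_extent_bp))
    hi = max((max(snp_map.offsets, default=0), model.arm_extent_bp))
    out = []
    for i in range(n_events):
        direction = classes[rng.choice(4, p=probs)]
        len_5p = _tract_length(rng, model) if direction in (
            Direction.UNI_5P, Direction.BIDIRECTIONAL) else 0
        len_3p = _tract_length(rng, model) if direction in (
            Direction.UNI_3P, Direction.BIDIRECTIONAL) else 0
        calls = {o: (CallState.DONOR if (-len_5p <= o <= len_3p)
                     else CallState.WILDTYPE)
                 for o in snp_map.offsets}
        out.append(SimulatedConversion(
            calls=ConversionCallSet(event_id=f"sim-ev-{i + 1:05d}",
                                    calls=calls, sequenced_span=(lo, hi)),
            true_direction=direction,
            true_tract_5p=len_5p,
            true_tract_3p=len_3p,
        ))
    return out
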