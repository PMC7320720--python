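"""Deterministic synthetic genomes, variants and adversarial cases.

Stands in, at desk scale, for a real genome with its variant catalogue: an
i.i.d. random backbone with planted features — exact repeats (multi
slots), inverted repeats (singletons, because the reverse complement of an
interior word occurs on the plus strand), over-abundant words (excluded
slots) and N-runs — each recorded with its coordinates and the slot status
its interior words must take.  Variant positions are drawn from a
clustered process by default, because variants in real genomes cluster
and multi-variant reads are the challenging case a Poisson spacing almost
never produces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqio import SequenceRecord
from .urbench import VariantSpec, revcomp

__all__ = [
    "Feature",
    "FixtureSpec",
    "PlantedFeature",
    "make_genome",
    "make_variants",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Feature:
    """A feature to plant: kind in {repeat, inverted_repeat, n_run,
    overabundant_word}; ``length`` is the unit length and ``copies`` the
    number of planted copies (ignored for n_run)."""

    kind: str
    length: int
    copies: int = 2

    def __post_init__(self) -> None:
        kinds = {"repeat", "inverted_repeat", "n_run", "overabundant_word"}
        if self.kind not in kinds:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.length < 1 or self.copies < 1:
            raise ValueError("length and copies must be positive")

    @property
    def total_span(self) -> int:
        if self.kind == "n_run":
            return self.length
        if self.kind == "inverted_repeat":
            return 2 * self.length
        return self.copies * self.length


@dataclass(frozen=True)
class FixtureSpec:
    length: int
    features: tuple[Feature, ...] = ()
    seed: int = 0
    name: str = "chr1"
    margin: int = 60  # clear backbone kept between planted features

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        d = json.loads(text)
        feats = tuple(Feature(**f) for f in d.pop("features", []))
        return cls(features=feats, **d)


@dataclass(frozen=True)
class PlantedFeature:
    """Where a feature landed and what its interior words should look like
    in the index (expected_status uses abundance-threshold t semantics)."""

    kind: str
    starts: tuple[int, ...]
    length: int
    expected_status: str


def make_genome(
    spec: FixtureSpec, t: int = 32
) -> tuple[SequenceRecord, list[PlantedFeature]]:
    """Generate the genome and its truth annotation.

    Features are placed left to right with ``margin`` backbone between
    them; an infeasible spec (features do not fit) is an error.
    ``expected_status`` assumes the feature unit is longer than the word
    length so interior words exist.
    """
    rng = np.random.default_rng(spec.seed)
    seq = rng.choice(_BASES, size=spec.length)
    needed = sum(f.total_span + spec.margin for f in spec.features) + spec.margin
    if needed > spec.length:
        raise ValueError(
            f"features need {needed} bases but genome length is {spec.length}"
        )
    truth = []
    cursor = spec.margin
    for feat in spec.features:
        if feat.kind == "n_run":
            seq[cursor : cursor + feat.length] = "N"
            truth.append(
                PlantedFeature("n_run", (cursor,), feat.length, "absent")
            )
            cursor += feat.length + spec.margin
            continue
        unit = rng.choice(_BASES, size=feat.length)
        starts = []
        if feat.kind == "inverted_repeat":
            seq[cursor : cursor + feat.length] = unit
            starts.append(cursor)
            cursor += feat.length + spec.margin
            rc = np.array(list(revcomp("".join(unit))))
            seq[cursor : cursor + feat.length] = rc
            starts.append(cursor)
            cursor += feat.length + spec.margin
            status = "singleton"
        else:
            copies = feat.copies
            for _ in range(copies):
                seq[cursor : cursor + feat.length] = unit
                starts.append(cursor)
                cursor += feat.length + spec.margin
            if feat.kind == "overabundant_word" or copies > t:
                status = "excluded" if copies > t else "multi"
            else:
                status = "multi"
        truth.append(PlantedFeature(feat.kind, tuple(starts), feat.length, status))
    return SequenceRecord(spec.name, "".join(seq)), truth


def make_variants(
    genome: SequenceRecord,
    density: float,
    snp_indel_ratio: float = 9.0,
    clustering: bool = True,
    seed: int = 0,
    max_indel: int = 3,
    phased_fraction: float = 0.8,
    cluster_size: float = 3.0,
    cluster_span: float = 200.0,
) -> list[VariantSpec]:
    """Draw a clustered (or plain geometric) variant set over a genome.

    With clustering, cluster centres arrive as a Poisson process and each
    centre holds a Poisson(cluster_size - 1) + 1 variants spread
    geometrically (mean spacing ``cluster_span / cluster_size``), so reads
    spanning several variants are common at realistic densities.  SNPs and
    indels are drawn at ``snp_indel_ratio``:1; indel lengths are uniform
    in [1, max_indel].
    """
    if not (0 < density <= 0.05):
        raise ValueError("density must be in (0, 0.05]")
    rng = np.random.default_rng(seed)
    n = len(genome.sequence)
    positions: list[int] = []
    if clustering:
        mean_cluster = max(cluster_size, 1.0)
        centre_rate = density / mean_cluster
        pos = 0.0
        while True:
            pos += rng.exponential(1.0 / centre_rate)
            if pos >= n:
                break
            k = 1 + rng.poisson(mean_cluster - 1.0)
            p = int(pos)
            spacing = max(cluster_span / mean_cluster, 2.0)
            for _ in range(k):
                if 0 <= p < n:
                    positions.append(p)
                p += 1 + int(rng.geometric(1.0 / spacing))
    else:
        pos = 0
        while True:
            pos += int(rng.geometric(density))
            if pos >= n:
                break
            positions.append(pos)

    variants: list[VariantSpec] = []
    last_end = -2
    for p in sorted(set(positions)):
        if p <= last_end + 1:
            continue
        ref_base = genome.sequence[p]
        if ref_base == "N":
            continue
        is_snp = rng.random() < snp_indel_ratio / (snp_indel_ratio + 1.0)
        phased = bool(rng.random() < phased_fraction)
        hap = int(rng.integers(0, 2))
        if is_snp:
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            variants.append(
                VariantSpec(genome.name, p + 1, ref_base, alt, hap, phased)
            )
            last_end = p
        else:
            ilen = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5 and p + ilen + 1 < n:  # deletion
                ref = genome.sequence[p : p + ilen + 1]
                if "N" in ref:
                    continue
                variants.append(
                    VariantSpec(genome.name, p + 1, ref, ref_base, hap, phased)
                )
                last_end = p + ilen
            else:  # insertion
                ins = "".join(rng.choice(_BASES, size=ilen))
                variants.append(
                    VariantSpec(
                        genome.name, p + 1, ref_base, ref_base + ins, hap, phased
                    )
                )
                last_end = p
    return variants
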