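"""Exact and stochastic Mendelian transmission for *C. elegans*-style genetics.

The nematode *Caenorhabditis elegans* has five autosomes (I--V) and an X
chromosome.  XX animals are self-fertile hermaphrodites; XO animals are male
and hemizygous at every X-linked locus.  This module models diploid genotypes
over an arbitrary set of named loci, meiosis with recombination, hermaphrodite
selfing and male outcrosses, and exact enumeration of offspring genotype
distributions -- the brute-force oracle against which the stochastic simulator
is tested.

Map distances are given in centimorgans (cM).  By default 1 cM is treated as a
1% recombination fraction capped at 0.5 (the convention used for the small
distances that matter in two-point mapping); Haldane's map function is
available as an option.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping

import numpy as np

CHROMOSOMES = ("I", "II", "III", "IV", "V", "X")
WILD = "+"
ABSENT_X = "O"  # the empty paternal slot of a hemizygous male X locus

HERMAPHRODITE = "hermaphrodite"
MALE = "male"

#: hard cap on segregating loci for exact enumeration (2**12 gamete patterns)
MAX_SEGREGATING_LOCI = 12


class GeneticsError(ValueError):
    """Structurally invalid genotype, cross, or parameter."""


class CapacityError(GeneticsError):
    """Exact enumeration requested for too many segregating loci."""


def recombination_fraction(distance_cM: float, map_function: str = "linear") -> float:
    """Convert a map distance in cM to a recombination fraction theta.

    ``linear``  -- theta = d/100 capped at 0.5 (cM read directly as percent
    recombination; exact at small distances).
    ``haldane`` -- theta = (1 - exp(-2d/100))/2 (no-interference map function).
    """
    if distance_cM < 0:
        raise GeneticsError(f"negative map distance: {distance_cM}")
    if map_function == "linear":
        return min(distance_cM / 100.0, 0.5)
    if map_function == "haldane":
        return 0.5 * (1.0 - math.exp(-2.0 * distance_cM / 100.0))
    raise GeneticsError(f"unknown map function: {map_function!r}")


@dataclass(frozen=True)
class Locus:
    """A named locus with a chromosome, a map position (cM), and a dominance
    mode that is only meaningful for phenotype-bearing loci."""

    name: str
    chromosome: str
    position: float = 0.0
    dominance: str = "recessive"

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise GeneticsError(
                f"locus {self.name!r}: chromosome must be one of {CHROMOSOMES}, "
                f"got {self.chromosome!r}"
            )
        if not (math.isfinite(self.position) and self.position >= 0):
            raise GeneticsError(f"locus {self.name!r}: position must be finite and >= 0")
        if self.dominance not in ("recessive", "dominant"):
            raise GeneticsError(f"locus {self.name!r}: bad dominance {self.dominance!r}")


def make_locus_map(loci: Iterable[Locus]) -> dict[str, Locus]:
    """Index loci by name, enforcing uniqueness."""
    out: dict[str, Locus] = {}
    for locus in loci:
        if locus.name in out:
            raise GeneticsError(f"duplicate locus name {locus.name!r}")
        out[locus.name] = locus
    return out


@dataclass
class Genotype:
    """Diploid allele state: ordered (maternal, paternal) pair per locus.

    Alleles are strings; ``"+"`` is wild type and anything else is a mutant
    allele identifier.  In males the paternal slot of every X-linked locus
    holds the explicit absent marker ``"O"``.
    """

    loci: dict[str, Locus]
    alleles: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        missing = set(self.loci) - set(self.alleles)
        extra = set(self.alleles) - set(self.loci)
        if missing or extra:
            raise GeneticsError(f"allele/locus mismatch: missing={missing} extra={extra}")

    def validate(self, sex: str) -> None:
        for name, locus in self.loci.items():
            mat, pat = self.alleles[name]
            if mat == ABSENT_X:
                raise GeneticsError(f"{name}: maternal slot may not be absent")
            if locus.chromosome == "X":
                if sex == MALE and pat != ABSENT_X:
                    raise GeneticsError(f"male must be hemizygous at X locus {name}")
                if sex == HERMAPHRODITE and pat == ABSENT_X:
                    raise GeneticsError(f"hermaphrodite must carry two X alleles at {name}")
            elif pat == ABSENT_X:
                raise GeneticsError(f"autosomal locus {name} may not have an absent slot")

    def dosage(self, name: str) -> int:
        """Number of mutant (non-wild, non-absent) alleles at a locus."""
        return sum(1 for a in self.alleles[name] if a not in (WILD, ABSENT_X))

    def is_carrier(self, name: str) -> bool:
        return self.dosage(name) > 0

    def is_homozygous_mutant(self, name: str) -> bool:
        mat, pat = self.alleles[name]
        if pat == ABSENT_X:  # hemizygous males express any X allele
            return mat != WILD
        return mat != WILD and pat != WILD

    def expresses(self, name: str) -> bool:
        """Whether the phenotype of a mutant allele at this locus shows,
        given the locus dominance (hemizygous X alleles always show)."""
        if self.loci[name].dominance == "dominant":
            return self.is_carrier(name)
        return self.is_homozygous_mutant(name)

    def swapped_haplotypes(self) -> "Genotype":
        """Exchange the maternal and paternal haplotypes (phase relabeling)."""
        return Genotype(self.loci, {n: (p, m) for n, (m, p) in self.alleles.items()})


def genotype_from_haplotypes(
    loci: Mapping[str, Locus],
    maternal: Mapping[str, str],
    paternal: Mapping[str, str],
) -> Genotype:
    alleles = {name: (maternal.get(name, WILD), paternal.get(name, WILD)) for name in loci}
    return Genotype(dict(loci), alleles)


@dataclass
class Individual:
    sex: str
    genotype: Genotype
    generation: str = ""

    def __post_init__(self) -> None:
        if self.sex not in (HERMAPHRODITE, MALE):
            raise GeneticsError(f"bad sex {self.sex!r}")
        self.genotype.validate(self.sex)

    def make_gamete(self, rng: np.random.Generator, map_function: str = "linear"):
        return make_gamete(self, rng, map_function)


@dataclass
class Gamete:
    """A haploid allele assignment.  ``carries_x`` is False only for the
    nullo-X sperm of a male (X-locus entries then hold the absent marker)."""

    alleles: dict[str, str]
    carries_x: bool = True


@dataclass
class CrossSpec:
    """A selfing (father=None) or a hermaphrodite x male outcross."""

    mother: Individual
    father: Individual | None = None
    offspring_count: int = 1
    generation: str = ""

    def __post_init__(self) -> None:
        if self.mother.sex != HERMAPHRODITE:
            raise GeneticsError("mother must be a hermaphrodite")
        if self.father is not None and self.father.sex != MALE:
            raise GeneticsError("father must be a male (or None for selfing)")
        if self.offspring_count <= 0:
            raise GeneticsError("offspring_count must be positive")
        if self.father is not None and self.father.genotype.loci != self.mother.genotype.loci:
            raise GeneticsError("parents must share one genetic map")

    @property
    def selfing(self) -> bool:
        return self.father is None


@dataclass
class PhenotypeRule:
    """Total predicates over genotypes: an escape-from-arrest call plus a set
    of visible marker predicates (e.g. Bli, Rol, Unc, Dpy, Vab shown iff
    homozygous mutant)."""

    escapes_arrest: Callable[[Genotype], bool]
    visible_markers: dict[str, Callable[[Genotype], bool]] = field(default_factory=dict)

    def classify(self, genotype: Genotype) -> str:
        label = "escape" if self.escapes_arrest(genotype) else "arrest"
        shown = sorted(name for name, pred in self.visible_markers.items() if pred(genotype))
        if shown:
            label += "+" + "+".join(shown)
        return label


def _chromosome_groups(loci: Mapping[str, Locus]) -> dict[str, list[Locus]]:
    groups: dict[str, list[Locus]] = {}
    for locus in loci.values():
        groups.setdefault(locus.chromosome, []).append(locus)
    for group in groups.values():
        group.sort(key=lambda l: (l.position, l.name))
    return groups


def make_gamete(parent: Individual, rng: np.random.Generator, map_function: str = "linear") -> Gamete:
    """Sample one meiotic product.

    Heterozygous loci transmit either allele with probability 1/2; loci on
    different chromosomes assort independently; adjacent loci on one
    chromosome co-segregate parentally with probability 1 - theta.  A male's
    gamete carries his single X with probability 1/2 and is otherwise nullo-X.
    """
    genotype = parent.genotype
    alleles: dict[str, str] = {}
    carries_x = True
    groups = _chromosome_groups(genotype.loci)
    if parent.sex == MALE and "X" not in groups:
        # X carriage decides offspring sex even when no X locus is tracked
        carries_x = bool(rng.random() < 0.5)
    for chrom, group in groups.items():
        if chrom == "X" and parent.sex == MALE:
            if rng.random() < 0.5:
                for locus in group:
                    alleles[locus.name] = genotype.alleles[locus.name][0]
            else:
                carries_x = False
                for locus in group:
                    alleles[locus.name] = ABSENT_X
            continue
        strand = int(rng.random() < 0.5)
        prev_pos = None
        for locus in group:
            if prev_pos is not None:
                theta = recombination_fraction(locus.position - prev_pos, map_function)
                if rng.random() < theta:
                    strand ^= 1
            alleles[locus.name] = genotype.alleles[locus.name][strand]
            prev_pos = locus.position
    return Gamete(alleles, carries_x)


def _combine(mother_gamete: Gamete, father_gamete: Gamete, loci: dict[str, Locus],
             selfing: bool) -> tuple[str, Genotype]:
    sex = HERMAPHRODITE if (selfing or father_gamete.carries_x) else MALE
    alleles = {
        name: (mother_gamete.alleles.get(name, WILD), father_gamete.alleles.get(name, WILD))
        for name in loci
    }
    return sex, Genotype(loci, alleles)


def cross(spec: CrossSpec, rng: np.random.Generator, map_function: str = "linear") -> list[Individual]:
    """Simulate a brood.

    Offspring combine one maternal and one paternal gamete.  In an outcross,
    offspring receiving a paternal X are hermaphrodites and nullo-X offspring
    are males (about half each); selfing yields hermaphrodites only (X
    nondisjunction is ignored).
    """
    loci = spec.mother.genotype.loci
    out: list[Individual] = []
    for _ in range(spec.offspring_count):
        oocyte = make_gamete(spec.mother, rng, map_function)
        sperm = make_gamete(spec.mother if spec.selfing else spec.father, rng, map_function)
        sex, genotype = _combine(oocyte, sperm, loci, spec.selfing)
        out.append(Individual(sex, genotype, spec.generation))
    return out


# ---------------------------------------------------------------------------
# Exact enumeration (the oracle)
# ---------------------------------------------------------------------------

def _segment_thetas(group: list[Locus], map_function: str) -> list[float]:
    return [
        recombination_fraction(b.position - a.position, map_function)
        for a, b in zip(group, group[1:])
    ]


def _combined_theta(thetas: Iterable[float]) -> float:
    """Probability of an odd number of strand switches across consecutive map
    segments: (1 - prod(1 - 2 theta_i)) / 2.  Marginalizes loci that do not
    segregate, consistently with the per-segment simulation chain."""
    prod = 1.0
    for theta in thetas:
        prod *= 1.0 - 2.0 * theta
    return 0.5 * (1.0 - prod)


def gamete_distribution(parent: Individual, map_function: str = "linear") -> list[tuple[Gamete, float]]:
    """Exact distribution over the parent's gametes.

    Guarded: at most ``MAX_SEGREGATING_LOCI`` heterozygous loci.
    """
    genotype = parent.genotype
    groups = _chromosome_groups(genotype.loci)
    n_seg = sum(
        1
        for name, (mat, pat) in genotype.alleles.items()
        if mat != pat and not (parent.sex == MALE and genotype.loci[name].chromosome == "X")
    )
    if parent.sex == MALE and any(l.chromosome == "X" for l in genotype.loci.values()):
        n_seg += 1
    if n_seg > MAX_SEGREGATING_LOCI:
        raise CapacityError(f"{n_seg} segregating loci exceeds enumeration cap")

    per_chrom: list[list[tuple[dict[str, str], float, bool]]] = []
    if parent.sex == MALE and "X" not in groups:
        per_chrom.append([({}, 0.5, True), ({}, 0.5, False)])
    for chrom, group in groups.items():
        if chrom == "X" and parent.sex == MALE:
            with_x = {l.name: genotype.alleles[l.name][0] for l in group}
            nullo = {l.name: ABSENT_X for l in group}
            per_chrom.append([(with_x, 0.5, True), (nullo, 0.5, False)])
            continue
        thetas = _segment_thetas(group, map_function)
        het = [i for i, l in enumerate(group) if genotype.alleles[l.name][0] != genotype.alleles[l.name][1]]
        fixed = {
            l.name: genotype.alleles[l.name][0]
            for i, l in enumerate(group)
            if i not in het
        }
        if not het:
            per_chrom.append([(fixed, 1.0, True)])
            continue
        # switch probabilities between consecutive heterozygous loci
        link = [
            _combined_theta(thetas[a:b]) for a, b in zip(het, het[1:])
        ]
        options: list[tuple[dict[str, str], float, bool]] = []
        for pattern in itertools.product((0, 1), repeat=len(het)):
            prob = 0.5
            for k, (c0, c1) in enumerate(zip(pattern, pattern[1:])):
                prob *= link[k] if c0 != c1 else 1.0 - link[k]
            alleles = dict(fixed)
            for c, i in zip(pattern, het):
                name = group[i].name
                alleles[name] = genotype.alleles[name][c]
            options.append((alleles, prob, True))
        per_chrom.append(options)

    gametes: list[tuple[Gamete, float]] = []
    for combo in itertools.product(*per_chrom):
        alleles: dict[str, str] = {}
        prob = 1.0
        carries_x = True
        for part, p, cx in combo:
            alleles.update(part)
            prob *= p
            carries_x = carries_x and cx
        gametes.append((Gamete(alleles, carries_x), prob))
    return gametes


GenotypeClass = tuple[tuple[str, tuple[str, str]], ...]


def _class_key(sex: str, genotype: Genotype, unordered: bool) -> tuple[str, GenotypeClass]:
    items = []
    for name in sorted(genotype.alleles):
        pair = genotype.alleles[name]
        if unordered:
            pair = tuple(sorted(pair))
        items.append((name, pair))
    return sex, tuple(items)


def genotype_from_class(loci: Mapping[str, Locus], key: GenotypeClass) -> Genotype:
    return Genotype(dict(loci), {name: tuple(pair) for name, pair in key})


def enumerate_offspring_distribution(
    spec: CrossSpec,
    map_function: str = "linear",
    unordered: bool = True,
) -> dict[tuple[str, GenotypeClass], float]:
    """Exact offspring distribution: mapping (sex, genotype class) -> probability.

    Genotype classes are unordered by default (A/a and a/A pooled, the usual
    Mendelian-ratio convention); pass ``unordered=False`` to keep phase, which
    is what multi-generation pedigree arithmetic needs.
    """
    loci = spec.mother.genotype.loci
    maternal = gamete_distribution(spec.mother, map_function)
    paternal = maternal if spec.selfing else gamete_distribution(spec.father, map_function)
    dist: dict[tuple[str, GenotypeClass], float] = {}
    for (gm, pm) in maternal:
        for (gp, pp) in paternal:
            sex, genotype = _combine(gm, gp, loci, spec.selfing)
            key = _class_key(sex, genotype, unordered)
            dist[key] = dist.get(key, 0.0) + pm * pp
    return dist


def conditional_distribution(
    dist: Mapping[tuple[str, GenotypeClass], float],
    predicate: Callable[[str, Genotype], bool],
    loci: Mapping[str, Locus],
) -> dict[tuple[str, GenotypeClass], float]:
    """Restrict an enumerated distribution to classes satisfying a predicate
    and renormalize (exact selection step for pedigree arithmetic)."""
    kept = {
        key: p
        for key, p in dist.items()
        if predicate(key[0], genotype_from_class(loci, key[1]))
    }
    total = sum(kept.values())
    if total <= 0:
        raise GeneticsError("conditioning event has probability zero")
    return {key: p / total for key, p in kept.items()}


def phenotype_frequencies(
    spec: CrossSpec,
    rule: PhenotypeRule,
    map_function: str = "linear",
) -> dict[str, dict[str, float]]:
    """Exact phenotype distribution per sex class: {sex: {label: probability}}.

    The image of :func:`enumerate_offspring_distribution` under the rule,
    normalized within each sex so each inner mapping sums to 1.
    """
    loci = spec.mother.genotype.loci
    dist = enumerate_offspring_distribution(spec, map_function, unordered=True)
    by_sex: dict[str, dict[str, float]] = {}
    for (sex, key), p in dist.items():
        label = rule.classify(genotype_from_class(loci, key))
        by_sex.setdefault(sex, {})[label] = by_sex.get(sex, {}).get(label, 0.0) + p
    for sex, labels in by_sex.items():
        total = sum(labels.values())
        by_sex[sex] = {label: p / total for label, p in labels.items()}
    return by_sex
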