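"""EMS mutagenesis and forward-screen simulation.

Models the two designs used to hunt suppressors of an *eat-5* feeding defect:

* an **F2 selection** -- mutagenized P0 hermaphrodites self, F1 self in mass
  culture, and a large pool of F2 is plated on restrictive food where only
  suppressed animals grow; and
* an **F1 clonal screen** -- single F1 animals are plated, one per plate, and
  a plate is scored as suppressed when the F1 carries a suppressor allele
  (a recessive suppressor still segregates expressing homozygotes among its
  self progeny on the plate).  At most one isolate is kept per F1 line.

Mutagenesis is parameterized by ``f``, the probability that a given suppressor
gene is hit per mutagenized haploid genome.  Because an F1 receives two
mutagenized genomes, the F1 carrier frequency is 1-(1-f)^2 ~ 2f, and the
suppressed-F2 frequency under the selection is ~ f/2 for a recessive
suppressor (a carrier F1 throws 1/4 homozygotes).

The module also implements the two-cross backcross round used to clean the
isolated strains, and its dilution arithmetic: per round, unlinked autosomal
background mutations are diluted fourfold and X-linked ones twofold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mendel import (
    ABSENT_X,
    CHROMOSOMES,
    HERMAPHRODITE,
    MALE,
    WILD,
    CrossSpec,
    Gamete,
    GeneticsError,
    Genotype,
    Individual,
    Locus,
    conditional_distribution,
    cross,
    enumerate_offspring_distribution,
    genotype_from_class,
    make_gamete,
    make_locus_map,
)

F2_SELECTION = "f2_selection"
F1_CLONAL_SCREEN = "f1_clonal_screen"


@dataclass
class MutagenesisModel:
    """Per-haploid-genome mutation model.

    ``f`` is the probability of hitting a given suppressor gene per
    mutagenized haploid genome (at most one new allele per gene per genome --
    Bernoulli, not Poisson; indistinguishable at realistic f <= 1e-3).
    ``background_rate`` is the Poisson mean of neutral background mutations
    per haploid genome, each placed at a uniformly random map position.
    """

    gene_set: list[Locus]
    f: float
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise GeneticsError(f"f must be in [0, 1], got {self.f}")
        if self.background_rate < 0:
            raise GeneticsError("background_rate must be >= 0")


@dataclass
class ScreenDesign:
    kind: str
    F1: int
    F2: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in (F2_SELECTION, F1_CLONAL_SCREEN):
            raise GeneticsError(f"unknown screen kind {self.kind!r}")
        if self.F1 <= 0:
            raise GeneticsError("F1 must be a positive integer")
        if self.kind == F2_SELECTION:
            if self.F2 is None or self.F2 <= 0:
                raise GeneticsError("F2 selection requires a positive F2 count")


@dataclass
class ScreenResult:
    """Counts produced by a simulated (or transcribed) screen.

    ``n`` is the number of suppressor isolates per gene, ``n_i`` the number of
    independent mutational events among those isolates (n_i <= n: in the F2
    selection many suppressed F2 can descend from one mutagenized gamete).
    ``lines`` is a per-line/per-isolate table.
    """

    design: ScreenDesign
    n: dict[str, int]
    n_i: dict[str, int]
    lines: pd.DataFrame
    true_f: float | None = None

    @property
    def F1(self) -> int:
        return self.design.F1

    @property
    def F2(self) -> int | None:
        return self.design.F2

    def summary(self) -> dict:
        return {
            "kind": self.design.kind,
            "F1": self.design.F1,
            "F2": self.design.F2,
            "n": dict(self.n),
            "n_i": dict(self.n_i),
        }


class MutagenizedIndividual(Individual):
    """An individual whose transmitted gametes acquire fresh mutations.

    Each gamete independently gains a new suppressor allele in each gene of
    the model with probability ``f`` and a Poisson(background_rate) number of
    neutral background mutations at random map positions.  Background
    mutations are materialized as new loci named ``bg<k>``.
    """

    def __init__(self, sex: str, genotype: Genotype, model: MutagenesisModel,
                 generation: str = "P0") -> None:
        missing = [g.name for g in model.gene_set if g.name not in genotype.loci]
        if missing:
            raise GeneticsError(f"genotype lacks suppressor loci {missing}")
        super().__init__(sex, genotype, generation)
        self.model = model
        self._bg_counter = itertools.count(1)
        self._event_counter = itertools.count(1)

    def make_gamete(self, rng: np.random.Generator, map_function: str = "linear") -> Gamete:
        gamete = make_gamete(self, rng, map_function)
        for gene in self.model.gene_set:
            if rng.random() < self.model.f:
                gamete.alleles[gene.name] = f"{gene.name}:e{next(self._event_counter)}"
        n_bg = rng.poisson(self.model.background_rate)
        for _ in range(n_bg):
            name = f"bg{next(self._bg_counter)}"
            chrom = CHROMOSOMES[rng.integers(len(CHROMOSOMES))]
            gamete.alleles[name] = f"{name}:m"
            gamete.extra_loci = getattr(gamete, "extra_loci", {})
            gamete.extra_loci[name] = Locus(name, chrom, float(rng.uniform(0, 100)))
        return gamete


def mutagenize_gametes(parent: Individual, model: MutagenesisModel,
                       rng: np.random.Generator | None = None) -> MutagenizedIndividual:
    """Wrap a P0 so that every gamete it transmits is freshly mutagenized."""
    return MutagenizedIndividual(parent.sex, parent.genotype, model, parent.generation or "P0")


def produce_f1(parent: MutagenizedIndividual, n: int, rng: np.random.Generator,
               map_function: str = "linear") -> list[Individual]:
    """Self a mutagenized P0: each F1 unites two independently mutagenized
    gametes (hence carrier frequency ~ 2f per gene)."""
    if n <= 0:
        raise GeneticsError("n must be positive")
    out = []
    base_loci = parent.genotype.loci
    for _ in range(n):
        oocyte = parent.make_gamete(rng, map_function)
        sperm = parent.make_gamete(rng, map_function)
        loci = dict(base_loci)
        loci.update(getattr(oocyte, "extra_loci", {}))
        loci.update(getattr(sperm, "extra_loci", {}))
        alleles = {
            name: (oocyte.alleles.get(name, WILD), sperm.alleles.get(name, WILD))
            for name in loci
        }
        out.append(Individual(HERMAPHRODITE, Genotype(loci, alleles), "F1"))
    return out


# ---------------------------------------------------------------------------
# Analytic checkpoints (enumeration composed with the mutagenesis probability)
# ---------------------------------------------------------------------------

def expected_f1_carrier_fraction(f: float) -> float:
    """P(an F1 carries >= 1 allele of a given gene) = 1-(1-f)^2 (~ 2f)."""
    if not 0 <= f <= 1:
        raise GeneticsError("f must be in [0, 1]")
    return 1.0 - (1.0 - f) ** 2


def expected_suppressed_f2_fraction(f: float, dominance: str = "recessive") -> float:
    """Exact suppressed-F2 fraction in the selection, by composing the F1
    genotype probabilities with exact selfing enumeration.

    For a heterozygous F1, selfing yields an expressing F2 with probability
    1/4 (recessive) or 3/4 (dominant); a biallelic F1 (probability f^2)
    yields only expressing F2.  First order in f: f/2 (recessive) or
    3f/2 (dominant).
    """
    gene = Locus("sup", "II", 0.0, dominance)
    loci = make_locus_map([gene])
    het = Individual(HERMAPHRODITE, Genotype(dict(loci), {"sup": (WILD, "m1")}))
    dist = enumerate_offspring_distribution(CrossSpec(het, offspring_count=1))
    p_express_het = sum(
        p for (sex, key), p in dist.items()
        if genotype_from_class(loci, key).expresses("sup")
    )
    p_het = 2 * f * (1 - f)
    p_biallelic = f * f
    return p_het * p_express_het + p_biallelic * 1.0


# ---------------------------------------------------------------------------
# Screen simulators (vectorized: only counts and event identities matter)
# ---------------------------------------------------------------------------

def run_f1_clonal_screen(design: ScreenDesign, model: MutagenesisModel,
                         rule=None, rng: np.random.Generator | None = None,
                         detection_sensitivity: float = 1.0) -> ScreenResult:
    """Simulate the clonal screen: one F1 per plate; a plate is suppressed iff
    the F1 carries a suppressor allele in any gene; one isolate per F1 line.

    Effective genomes for this design: G = 2*F1 (each F1 contributes two
    mutagenized haploid genomes).  ``detection_sensitivity`` < 1 models
    imperfect recovery of suppressor-bearing plates (default: perfect).
    """
    if design.kind != F1_CLONAL_SCREEN:
        raise GeneticsError("design kind must be f1_clonal_screen")
    if rng is None:
        raise GeneticsError("an rng is required")
    genes = [g.name for g in model.gene_set]
    # hits[i, j] = number of mutant alleles of gene j carried by F1 line i (0..2)
    hits = rng.binomial(2, model.f, size=(design.F1, len(genes)))
    detected = hits.sum(axis=1) > 0
    if detection_sensitivity < 1.0:
        detected &= rng.random(design.F1) < detection_sensitivity
    rows = []
    n: dict[str, int] = {g: 0 for g in genes}
    n_i: dict[str, int] = {g: 0 for g in genes}
    for i in np.flatnonzero(detected):
        for j, gene in enumerate(genes):
            if hits[i, j] > 0:
                # one allele sequenced per kept line even if both genomes were hit
                rows.append({"line_id": f"F1-{i}", "gene": gene,
                             "event_id": f"{gene}@F1-{i}", "suppressed": True})
                n[gene] += 1
                n_i[gene] += 1  # clonal lines derive from distinct gametes
    lines = pd.DataFrame(rows, columns=["line_id", "gene", "event_id", "suppressed"])
    return ScreenResult(design, n, n_i, lines, true_f=model.f)


def run_f2_selection(design: ScreenDesign, model: MutagenesisModel,
                     rule=None, rng: np.random.Generator | None = None,
                     false_positive_rate: float = 0.0) -> ScreenResult:
    """Simulate the F2 selection.

    F1 carrier states are drawn per gene; the plated F2 pool is spread evenly
    over F1 parents, and each F2 of a carrier F1 expresses the suppressor per
    its dominance (1/4 recessive, 3/4 dominant; biallelic F1 -> all F2).
    Isolates are suppressed F2s; independent events are the distinct
    mutagenized-gamete origins among them.  ``false_positive_rate`` lets
    non-suppressed F2 escape arrest spuriously (default 0).
    """
    if design.kind != F2_SELECTION:
        raise GeneticsError("design kind must be f2_selection")
    if rng is None:
        raise GeneticsError("an rng is required")
    per_f1 = np.full(design.F1, design.F2 // design.F1, dtype=np.int64)
    per_f1[: design.F2 % design.F1] += 1  # even allocation of the F2 pool
    rows = []
    n: dict[str, int] = {}
    n_i: dict[str, int] = {}
    for gene in model.gene_set:
        hits = rng.binomial(2, model.f, size=design.F1)
        p_express = {1: (0.25 if gene.dominance == "recessive" else 0.75), 2: 1.0}
        count = 0
        events = 0
        for i in np.flatnonzero(hits):
            k = rng.binomial(per_f1[i], p_express[min(hits[i], 2)])
            if k > 0:
                event = f"{gene.name}@F1-{i}"
                events += 1
                count += int(k)
                rows.append({"line_id": f"F1-{i}", "gene": gene.name,
                             "event_id": event, "suppressed": True,
                             "n_suppressed_f2": int(k)})
        n[gene.name] = count
        n_i[gene.name] = events
    if false_positive_rate > 0:
        extra = rng.binomial(design.F2, false_positive_rate)
        if extra:
            rows.append({"line_id": "spurious", "gene": "none",
                         "event_id": "none", "suppressed": True,
                         "n_suppressed_f2": int(extra)})
    lines = pd.DataFrame(
        rows, columns=["line_id", "gene", "event_id", "suppressed", "n_suppressed_f2"]
    )
    return ScreenResult(design, n, n_i, lines, true_f=model.f)


# ---------------------------------------------------------------------------
# Backcrossing
# ---------------------------------------------------------------------------

def _strain_loci(suppressor: Locus, background: list[Locus]) -> dict[str, Locus]:
    return make_locus_map([suppressor, *background])


def backcross_strain(suppressor: Locus, background: list[Locus]) -> Individual:
    """The homozygous suppressed strain entering a backcross round: sef/sef
    plus homozygous tagged background mutations."""
    loci = _strain_loci(suppressor, background)
    alleles = {name: ("m", "m") for name in loci}
    return Individual(HERMAPHRODITE, Genotype(dict(loci), alleles), "strain")


def _tester(loci: dict[str, Locus], sex: str) -> Individual:
    alleles = {}
    for name, locus in loci.items():
        pat = ABSENT_X if (sex == MALE and locus.chromosome == "X") else WILD
        alleles[name] = (WILD, pat)
    return Individual(sex, Genotype(dict(loci), alleles), "tester")


def expected_backcross_dilution(suppressor: Locus, background: Locus,
                                map_function: str = "linear") -> float:
    """Exact per-round dilution factor for one background mutation, by staged
    enumeration of the two-cross scheme plus re-homozygosing.

    A round is: (1) strain hermaphrodite x clean male, pick a suppressor-
    carrying male; (2) that male x clean hermaphrodite, pick a suppressor-
    carrying hermaphrodite; then self and select a suppressor homozygote (the
    state the next round starts from).  The factor is the ratio of expected
    background-allele dosage per suppressor-homozygous animal before (2) vs
    after.  Unlinked autosomal: 4; X-linked: 2; fully linked (theta = 0): 1.
    """
    strain = backcross_strain(suppressor, [background])
    loci = strain.genotype.loci
    sup = suppressor.name
    bg = background.name

    # cross 1: strain hermaphrodite x clean male; pick sup-carrying male
    d1 = enumerate_offspring_distribution(
        CrossSpec(strain, _tester(loci, MALE)), map_function, unordered=False)
    d1 = conditional_distribution(
        d1, lambda sex, g: sex == MALE and g.is_carrier(sup), loci)

    # cross 2: that male x clean hermaphrodite; pick sup-carrying hermaphrodite
    d2: dict = {}
    for (sex, key), p1 in d1.items():
        male = Individual(MALE, genotype_from_class(loci, key))
        sub = enumerate_offspring_distribution(
            CrossSpec(_tester(loci, HERMAPHRODITE), male), map_function, unordered=False)
        for k2, p2 in sub.items():
            d2[k2] = d2.get(k2, 0.0) + p1 * p2
    d2 = conditional_distribution(
        d2, lambda sex, g: sex == HERMAPHRODITE and g.is_carrier(sup), loci)

    # re-homozygose: self each selected hermaphrodite, keep sup homozygotes
    d3: dict = {}
    for (sex, key), p2 in d2.items():
        herm = Individual(HERMAPHRODITE, genotype_from_class(loci, key))
        sub = enumerate_offspring_distribution(
            CrossSpec(herm), map_function, unordered=False)
        for k3, p3 in sub.items():
            d3[k3] = d3.get(k3, 0.0) + p2 * p3
    d3 = conditional_distribution(
        d3, lambda sex, g: g.is_homozygous_mutant(sup), loci)

    dosage_after = sum(
        p * genotype_from_class(loci, key).dosage(bg) for (sex, key), p in d3.items()
    )
    dosage_before = 2.0
    if dosage_after <= 0:
        return float("inf")
    return dosage_before / dosage_after


def simulate_backcross_round(strain: Individual, tester_male: Individual | None,
                             suppressor_name: str, rng: np.random.Generator,
                             map_function: str = "linear",
                             brood: int = 40, max_tries: int = 2000):
    """Monte Carlo version of one backcross round on a single pedigree.

    Returns ``(final_individual, dosage_before, dosage_after)`` where dosages
    are per-background-locus mutant allele counts of the suppressor-homozygous
    animal that starts the next round.
    """
    if not strain.genotype.is_carrier(suppressor_name):
        raise GeneticsError("strain must carry the suppressor")
    loci = strain.genotype.loci
    bg_names = [n for n in loci if n != suppressor_name]
    before = {n: strain.genotype.dosage(n) for n in bg_names}
    if tester_male is None:
        tester_male = _tester(loci, MALE)

    def pick(spec: CrossSpec, want) -> Individual:
        for _ in range(max_tries):
            for child in cross(replace_count(spec, brood), rng, map_function):
                if want(child):
                    return child
        raise GeneticsError("selection failed: no qualifying offspring")

    def replace_count(spec: CrossSpec, count: int) -> CrossSpec:
        return CrossSpec(spec.mother, spec.father, count, spec.generation)

    male = pick(
        CrossSpec(strain, tester_male),
        lambda c: c.sex == MALE and c.genotype.is_carrier(suppressor_name),
    )
    herm = pick(
        CrossSpec(_tester(loci, HERMAPHRODITE), male),
        lambda c: c.sex == HERMAPHRODITE and c.genotype.is_carrier(suppressor_name),
    )
    final = pick(
        CrossSpec(herm),
        lambda c: c.genotype.is_homozygous_mutant(suppressor_name),
    )
    after = {n: final.genotype.dosage(n) for n in bg_names}
    return final, before, after
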