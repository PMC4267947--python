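"""Two-point mapping from marker-thrower counts.

The mapping cross: males heterozygous for the focal mutation and (in
repulsion) for one visible marker per chromosome are mated to unmarked
hermaphrodites, and cross-progeny hermaphrodites are singled.  Lines that
throw the focal phenotype ("informative" lines) received the focal mutation
from their father; whether such a line also throws a given visible marker
reveals linkage:

* an unlinked marker rides along with probability 1/2 (the father is
  marker/+, independent assortment);
* a marker in repulsion on the focal chromosome rides along only via a
  recombinant paternal gamete, i.e. with probability theta.

A marker with significantly fewer throwers than the 1/2 expectation is
therefore linked.  Zero (or few) throwers among n informative lines yields a
one-sided Clopper--Pearson upper bound on theta, reported in cM as 100*theta.

X-linkage is detected from backcross behavior instead: a focal mutation on
the X of an F1 male transmits to *all* of his cross-progeny hermaphrodites
(they all receive his single X) rather than half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mendel import (
    HERMAPHRODITE,
    MALE,
    WILD,
    ABSENT_X,
    CrossSpec,
    GeneticsError,
    Genotype,
    Individual,
    Locus,
    enumerate_offspring_distribution,
    genotype_from_class,
    make_locus_map,
)

AUTOSOMAL = "autosomal"
X_LINKED = "X-linked"
INCONCLUSIVE = "inconclusive"

LINKED = "linked"
UNLINKED = "unlinked"


@dataclass
class MappingCounts:
    """Line tallies from a mapping cross.

    ``throwers`` counts, per marker, the informative (focal-bearing) lines
    that threw that marker's phenotype.  ``marker_chromosomes`` (optional)
    lets linkage calls be turned into a chromosome assignment.
    """

    total_lines: int
    uninformative_lines: int
    arrested_lines: int
    informative_lines: int
    throwers: dict[str, int]
    marker_chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.uninformative_lines + self.arrested_lines + self.informative_lines != self.total_lines:
            raise GeneticsError("uninformative + arrested + informative must equal total")
        for marker, k in self.throwers.items():
            if not 0 <= k <= self.informative_lines:
                raise GeneticsError(f"marker {marker!r}: thrower count out of range")


@dataclass
class MappingResult:
    per_marker: pd.DataFrame          # marker, throwers, fraction, p, p_adj, call, theta_u, cM_u
    assigned_marker: str | None
    assigned_chromosome: str | None
    alpha: float
    confidence: float


def expected_thrower_fraction(marker: Locus, focal: Locus, theta: float,
                              map_function: str = "linear") -> float:
    """Probability that an informative line throws the marker, derived by
    exact enumeration of the mapping cross (not hard-coded).

    The father carries marker and focal mutation in repulsion; informative
    lines are hermaphrodite cross-progeny that received the focal mutation.
    Different chromosomes -> 1/2; same chromosome in repulsion -> theta.
    """
    if not 0.0 <= theta <= 0.5:
        raise GeneticsError("theta must be in [0, 0.5]")
    if marker.name == focal.name:
        raise GeneticsError("marker and focal locus must differ")
    if marker.chromosome == focal.chromosome:
        # place the loci theta apart on their shared chromosome
        distance = 100.0 * theta if map_function == "linear" else (
            50.0 * np.log(1.0 / (1.0 - 2.0 * theta)) if theta < 0.5 else 1e6
        )
        marker = Locus(marker.name, marker.chromosome, 0.0, marker.dominance)
        focal = Locus(focal.name, focal.chromosome, distance, focal.dominance)
    loci = make_locus_map([marker, focal])
    # father: marker from one parent, focal from the other (repulsion)
    pat_x = marker.chromosome == "X"
    father = Individual(MALE, Genotype(dict(loci), {
        marker.name: ("M", ABSENT_X if pat_x else WILD),
        focal.name: (WILD, "m") if focal.chromosome != "X" else ("m", ABSENT_X),
    }))
    mother = Individual(HERMAPHRODITE, Genotype(dict(loci), {
        name: (WILD, WILD) for name in loci
    }))
    dist = enumerate_offspring_distribution(CrossSpec(mother, father), map_function)
    informative = {
        key: p for key, p in dist.items()
        if key[0] == HERMAPHRODITE and genotype_from_class(loci, key[1]).is_carrier(focal.name)
    }
    total = sum(informative.values())
    if total <= 0:
        raise GeneticsError("cross yields no informative hermaphrodites")
    throwing = sum(
        p for key, p in informative.items()
        if genotype_from_class(loci, key[1]).is_carrier(marker.name)
    )
    return throwing / total


def recomb_upper_bound(recombinants: int, informative: int,
                       confidence: float = 0.95) -> tuple[float, float]:
    """One-sided Clopper--Pearson upper limit on the per-line marker-carrying
    probability theta, and its cM equivalent (100*theta).

    For 0 recombinants this is 1 - (1-confidence)^(1/n); e.g. 0/16 at 95%
    gives theta_U ~ 0.171, i.e. the focal locus lies within ~17 cM of the
    marker.
    """
    if informative <= 0 or not 0 <= recombinants <= informative:
        raise GeneticsError("need 0 <= recombinants <= informative, informative > 0")
    if not 0.0 < confidence < 1.0:
        raise GeneticsError("confidence must be in (0, 1)")
    if recombinants == informative:
        theta_u = 1.0
    else:
        theta_u = float(stats.beta.ppf(confidence, recombinants + 1,
                                       informative - recombinants))
    return theta_u, 100.0 * theta_u


def linkage_calls(counts: MappingCounts, alpha: float = 0.05,
                  confidence: float = 0.95) -> MappingResult:
    """Per-marker linkage screening plus a chromosome assignment.

    Screening: exact two-sided binomial test of each marker's thrower count
    against the unlinked expectation 1/2, Bonferroni-corrected over the
    markers tested; a significantly *depressed* count is called linked.

    Assignment: the chromosome of the marker with the smallest one-sided
    depletion p-value, assigned when that p-value is below ``alpha``
    (unadjusted -- a point estimate of location, not a familywise claim);
    ties or no depleted marker leave the assignment empty.  Linked markers
    also get a Clopper--Pearson upper bound on theta.
    """
    n = counts.informative_lines
    if n <= 0:
        raise GeneticsError("need informative lines to call linkage")
    if not 0.0 < alpha < 1.0:
        raise GeneticsError("alpha must be in (0, 1)")
    markers = sorted(counts.throwers)
    m = len(markers)
    rows = []
    for marker in markers:
        k = counts.throwers[marker]
        p_two = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
        p_low = stats.binomtest(k, n, 0.5, alternative="less").pvalue
        p_adj = min(1.0, m * p_two)
        if p_adj < alpha and k < n / 2:
            call = LINKED
        else:
            call = UNLINKED
        theta_u, cm_u = (np.nan, np.nan)
        if k < n / 2:
            theta_u, cm_u = recomb_upper_bound(k, n, confidence)
            theta_u = min(theta_u, 0.5)
            cm_u = min(cm_u, 50.0)
        rows.append({
            "marker": marker, "throwers": k, "informative": n,
            "fraction": k / n, "p_two_sided": p_two, "p_one_sided_low": p_low,
            "p_adjusted": p_adj, "call": call,
            "theta_upper": theta_u, "cM_upper": cm_u,
        })
    table = pd.DataFrame(rows)
    assigned_marker = assigned_chrom = None
    depleted = table[table["throwers"] < n / 2]
    if len(depleted):
        best = depleted.loc[depleted["p_one_sided_low"].idxmin()]
        is_tie = (depleted["p_one_sided_low"] == best["p_one_sided_low"]).sum() > 1
        if best["p_one_sided_low"] < alpha and not is_tie:
            assigned_marker = str(best["marker"])
            assigned_chrom = counts.marker_chromosomes.get(assigned_marker)
    return MappingResult(table, assigned_marker, assigned_chrom, alpha, confidence)


def simulate_mapping_experiment(focal: Locus, markers: dict[str, Locus],
                                rng: np.random.Generator,
                                n_informative: int = 16,
                                exclude: set[str] | None = None,
                                map_function: str = "linear") -> MappingCounts:
    """Simulate the mapping cross and tally marker throwers.

    Fathers heterozygous for every marker (maternally) and for the focal
    mutation (paternally, i.e. in repulsion to any same-chromosome marker)
    are mated to unmarked hermaphrodites; hermaphrodite progeny carrying the
    focal mutation are collected until ``n_informative`` lines are singled.
    A line throws a marker iff it carries the marker allele (a heterozygous
    line segregates visible homozygotes among its self progeny).

    ``exclude`` drops markers from the tally (e.g. the marker linked to a
    shared background mutation, whose throwers are uninformative).
    """
    if focal.name in markers:
        raise GeneticsError("focal locus duplicates a marker name")
    exclude = exclude or set()
    loci = make_locus_map([*markers.values(), focal])
    father_alleles: dict[str, tuple[str, str]] = {}
    for name, locus in markers.items():
        father_alleles[name] = ("M", ABSENT_X if locus.chromosome == "X" else WILD)
    father_alleles[focal.name] = (
        ("m", ABSENT_X) if focal.chromosome == "X" else (WILD, "m"))
    father = Individual(MALE, Genotype(dict(loci), father_alleles))
    mother = Individual(HERMAPHRODITE, Genotype(dict(loci), {
        name: (WILD, WILD) for name in loci}))
    informative: list[Individual] = []
    total = 0
    for _ in range(200):  # brood batches until enough informative lines
        from .mendel import cross  # local import avoids a cycle at module load

        for child in cross(CrossSpec(mother, father, 50), rng, map_function):
            total += 1
            if child.sex == HERMAPHRODITE and child.genotype.is_carrier(focal.name):
                informative.append(child)
                if len(informative) == n_informative:
                    break
        if len(informative) == n_informative:
            break
    if len(informative) < n_informative:
        raise GeneticsError("cross failed to yield enough informative lines")
    tested = [m for m in markers if m not in exclude and markers[m].chromosome != "X"]
    throwers = {
        m: sum(1 for line in informative if line.genotype.is_carrier(m))
        for m in tested
    }
    return MappingCounts(
        total_lines=n_informative, uninformative_lines=0, arrested_lines=0,
        informative_lines=n_informative, throwers=throwers,
        marker_chromosomes={m: markers[m].chromosome for m in tested},
    )


def xlinkage_from_backcross(carrier_fraction: float, n: int,
                            alpha: float = 0.05) -> str:
    """Classify a suppressor as autosomal or X-linked from the fraction of
    suppressor-carrying hermaphrodites among backcross progeny.

    Autosomal fathers transmit to half their cross progeny; an X-linked
    mutation in an F1 male transmits to *all* cross-progeny hermaphrodites.
    The autosomal model is rejected by a one-sided exact binomial test for
    an excess of carriers over 1/2 (excess toward 1 is the X signal); the
    X-linked model is rejected by any non-carrier (under it the carrier
    probability is exactly 1).  The single non-rejected model is returned,
    otherwise ``inconclusive``.
    """
    if n <= 0:
        raise GeneticsError("n must be positive")
    if not 0.0 <= carrier_fraction <= 1.0:
        raise GeneticsError("carrier_fraction must be in [0, 1]")
    k = round(carrier_fraction * n)
    p_excess = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
    reject_autosomal = p_excess < alpha
    reject_xlinked = k < n
    if reject_autosomal and not reject_xlinked:
        return X_LINKED
    if reject_xlinked and not reject_autosomal:
        return AUTOSOMAL
    return INCONCLUSIVE
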