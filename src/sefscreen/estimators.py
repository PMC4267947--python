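"""Screen-yield and transgene-rescue statistics.

Two estimators of the per-genome mutation frequency ``f`` of a suppressor
gene:

* combined-design estimate  f_hat = n / (2*F1 + F2/2), where n is the total
  number of isolates recovered from an F1 clonal screen of F1 lines plus an
  F2 selection over F2 plated animals; and
* independent-event estimate  f_hat = n_i / G, preferred when sequencing has
  resolved the isolates into n_i independent mutational events, with G the
  effective number of mutagenized haploid genomes interrogated by the design.

Effective genomes: G = 2*F1 for the clonal screen (each F1 carries two
mutagenized genomes).  For the F2 selection the suppressed-F2 frequency is
f/2 for a recessive suppressor, so G = F2/2; for a dominant suppressor 3/4 of
carrier-F1 progeny express, giving G = 3*F2/2.  (The selection G here is a
reconstruction from those segregation frequencies, not a transcription of any
published worksheet.)  Since isolates are rare events over many genomes, the
uncertainty attached to f_hat is an exact (Garwood) Poisson interval for the
event count at exposure G.

Transgene rescue: non-integrated extrachromosomal arrays transmit to only a
fraction t of progeny, so rescue is read out as the odds ratio

    r = odds(fraction transgenic among escapers on restrictive food)
        / odds(transmission rate on permissive food)
      = f(1-t) / (t(1-f)),

with a delta-method standard error sem_r = r * sqrt(1/(N_D f(1-f)) +
1/(N_H t(1-t))).  r ~ 1 means the transgene does not change escape; r << 1
means transgenic animals escape arrest less often, i.e. the transgene rescues
the suppressor mutation and restores arrest.  Significance is a Pearson
chi-square test of independence on the 2x2 food-by-transgenic table, with a
Bonferroni correction over the m lines tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen import F1_CLONAL_SCREEN, F2_SELECTION, GeneticsError, ScreenDesign


@dataclass
class ScreenCounts:
    n: int = 0
    n_i: int = 0
    F1: int = 0
    F2: int = 0

    def __post_init__(self) -> None:
        if min(self.n, self.n_i, self.F1, self.F2) < 0:
            raise GeneticsError("all screen counts must be >= 0")
        if self.n_i > self.n:
            raise GeneticsError("independent events n_i cannot exceed isolates n")


@dataclass
class FrequencyEstimate:
    f_hat: float
    G: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.f_hat < 0 or not (self.ci_low <= self.f_hat <= self.ci_high):
            raise GeneticsError("inconsistent frequency estimate / interval")


@dataclass
class RescueAssay:
    """Counts from one transgenic line: N_D animals reached L4 on restrictive
    food (DA837), k_D of them transgenic; N_H on permissive food (HB101),
    k_H transgenic.  ``m`` is the number of lines tested (Bonferroni)."""

    N_D: int
    k_D: int
    N_H: int
    k_H: int
    m: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.k_D <= self.N_D and 0 <= self.k_H <= self.N_H):
            raise GeneticsError("need 0 <= k <= N on both foods")
        if self.m < 1:
            raise GeneticsError("m must be >= 1")


@dataclass
class RescueEstimate:
    t: float              # transmission rate (fraction transgenic, permissive)
    f: float              # fraction transgenic among escapers, restrictive
    r: float              # relative escape from arrest, odds(f)/odds(t)
    sem_r: float
    chi2: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class AlleleSignature:
    """An isolate plus the set of tightly linked EMS-signature (GC->AT)
    variant labels that travel with its suppressor allele.  Isolates sharing
    an identical signature derive from one mutational event."""

    isolate: str
    variants: frozenset[str]

    def __post_init__(self) -> None:
        if not self.variants:
            raise GeneticsError(f"isolate {self.isolate!r}: empty variant signature")


# ---------------------------------------------------------------------------
# Mutation frequency
# ---------------------------------------------------------------------------

def effective_genomes(design: ScreenDesign, dominance: str = "recessive") -> float:
    """Effective number of mutagenized haploid genomes interrogated.

    Clonal screen: 2*F1 regardless of dominance.  F2 selection: F2/2
    (recessive) or 3*F2/2 (dominant), so that E[isolates] = f*G.
    """
    if design.kind == F1_CLONAL_SCREEN:
        return 2.0 * design.F1
    if design.F2 is None:
        raise GeneticsError("F2 selection requires an F2 count")
    if dominance == "recessive":
        return design.F2 / 2.0
    if dominance == "dominant":
        return 3.0 * design.F2 / 2.0
    raise GeneticsError(f"bad dominance {dominance!r}")


def poisson_interval(count: int, exposure: float, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson rate count/exposure."""
    if exposure <= 0:
        raise GeneticsError("exposure must be positive")
    alpha = 1.0 - confidence
    low = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2.0
    high = stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2.0
    return low / exposure, high / exposure


def estimate_f_combined(n: int, F1: int, F2: int, confidence: float = 0.95) -> FrequencyEstimate:
    """f_hat = n / (2*F1 + F2/2) over the combined clonal-screen + selection
    exposure, with an exact Poisson interval (recessive suppressors)."""
    if min(n, F1, F2) < 0:
        raise GeneticsError("counts must be >= 0")
    G = 2.0 * F1 + F2 / 2.0
    if G <= 0:
        raise GeneticsError("zero combined exposure (2*F1 + F2/2)")
    low, high = poisson_interval(n, G, confidence)
    return FrequencyEstimate(n / G, G, low, high)


def estimate_f_independent(n_i: int, G: float, confidence: float = 0.95) -> FrequencyEstimate:
    """f_hat = n_i / G from independent mutational events over effective
    genomes G (the better estimate when alleles have been sequenced)."""
    if n_i < 0:
        raise GeneticsError("n_i must be >= 0")
    if G <= 0:
        raise GeneticsError("G must be positive")
    low, high = poisson_interval(n_i, G, confidence)
    return FrequencyEstimate(n_i / G, G, low, high)


def count_independent_events(signatures: Sequence[AlleleSignature]) -> int:
    """Number of independent mutational events among isolates: isolates with
    identical linked-variant signatures are collapsed into one event.
    Deterministic, order-independent, idempotent."""
    if not signatures:
        raise GeneticsError("need at least one allele signature")
    return len({sig.variants for sig in signatures})


# ---------------------------------------------------------------------------
# Transgene rescue
# ---------------------------------------------------------------------------

def transmission_rate(k_H: int, N_H: int) -> tuple[float, float]:
    """Array transmission rate t = k_H/N_H with its binomial standard error."""
    if N_H <= 0:
        raise GeneticsError("N_H must be positive")
    if not 0 <= k_H <= N_H:
        raise GeneticsError("need 0 <= k_H <= N_H")
    t = k_H / N_H
    se = math.sqrt(t * (1.0 - t) / N_H)
    return t, se


def rescue_ratio(assay: RescueAssay, orientation: str = "escape",
                 continuity_correction: bool = False) -> RescueEstimate:
    """Relative escape from arrest r with delta-method SEM and the 2x2
    chi-square test (see module docstring).

    ``orientation="escape"`` (default) reports odds(f)/odds(t), so r << 1
    means rescue; ``orientation="reciprocal"`` reports the inverse.
    Boundary fractions (k = 0 or k = N) are refused unless
    ``continuity_correction`` adds Haldane--Anscombe +0.5 to every cell.
    """
    k_D, N_D, k_H, N_H = assay.k_D, assay.N_D, assay.k_H, assay.N_H
    if continuity_correction:
        k_D, N_D, k_H, N_H = k_D + 0.5, N_D + 1.0, k_H + 0.5, N_H + 1.0
    f = k_D / N_D
    t = k_H / N_H
    if not (0.0 < f < 1.0 and 0.0 < t < 1.0):
        raise GeneticsError(
            "degenerate assay: a transgenic fraction sits on the 0/1 boundary; "
            "pass continuity_correction=True for a Haldane-Anscombe estimate"
        )
    r = (f * (1.0 - t)) / (t * (1.0 - f))
    if orientation == "reciprocal":
        r = 1.0 / r
    elif orientation != "escape":
        raise GeneticsError(f"bad orientation {orientation!r}")
    sem_r = r * math.sqrt(
        1.0 / (N_D * f * (1.0 - f)) + 1.0 / (N_H * t * (1.0 - t))
    )
    chi2, p_raw, p_adj = rescue_significance(assay)
    return RescueEstimate(t=t, f=f, r=r, sem_r=sem_r, chi2=chi2,
                          p_raw=p_raw, p_adjusted=p_adj)


def rescue_significance(assay: RescueAssay, yates: bool = False) -> tuple[float, float, float]:
    """Pearson chi-square test of independence (1 df, no continuity
    correction by default) on the food x transgenic 2x2 table, Bonferroni-
    adjusted over the assay's m lines."""
    table = np.array([
        [assay.k_D, assay.N_D - assay.k_D],
        [assay.k_H, assay.N_H - assay.k_H],
    ], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise GeneticsError("chi-square test needs all 2x2 margins > 0")
    res = stats.chi2_contingency(table, correction=yates)
    chi2, p_raw = float(res.statistic), float(res.pvalue)
    return chi2, p_raw, min(1.0, assay.m * p_raw)


# ---------------------------------------------------------------------------
# Tabular interfaces
# ---------------------------------------------------------------------------

def rescue_table(assays: dict[str, RescueAssay], **kwargs) -> pd.DataFrame:
    """One row of estimates per transgenic line (TSV-ready)."""
    rows = []
    for line_id, assay in assays.items():
        est = rescue_ratio(assay, **kwargs)
        rows.append({
            "line_id": line_id, "t": est.t, "f": est.f, "r": est.r,
            "sem_r": est.sem_r, "chi2": est.chi2,
            "p_raw": est.p_raw, "p_adjusted": est.p_adjusted,
        })
    return pd.DataFrame(rows)


def assays_from_tidy(counts: pd.DataFrame, m: int | None = None) -> dict[str, RescueAssay]:
    """Build assays from a tidy table with columns line_id, food
    ('DA837'/'HB101'), n_transgenic, n_total."""
    required = {"line_id", "food", "n_transgenic", "n_total"}
    if not required <= set(counts.columns):
        raise GeneticsError(f"counts table needs columns {sorted(required)}")
    out: dict[str, RescueAssay] = {}
    lines = counts["line_id"].unique()
    m_eff = m if m is not None else len(lines)
    for line_id in lines:
        sub = counts[counts["line_id"] == line_id].set_index("food")
        try:
            da, hb = sub.loc["DA837"], sub.loc["HB101"]
        except KeyError as err:
            raise GeneticsError(f"line {line_id!r}: missing food {err}") from None
        out[str(line_id)] = RescueAssay(
            N_D=int(da["n_total"]), k_D=int(da["n_transgenic"]),
            N_H=int(hb["n_total"]), k_H=int(hb["n_transgenic"]), m=m_eff,
        )
    return out
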