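"""Seeded generators for every input the pipeline consumes.

Everything here is synthetic: simulated screens, transgenic rescue assays,
per-worm pump-rate tables and growth observations, plus the standard marker
map used by the mapping cross.  Defaults mirror the study conditions the
estimators were built for -- a clonal screen of 5128 F1 plates (10,256
mutagenized genomes), an F2 selection of ~34,000 plated F2 (~17,000 effective
genomes for a recessive suppressor), per-gene mutation frequencies of order
5e-4, and broods of a few hundred for rescue assays.  The array transmission
rate defaults to t = 0.5, a placeholder typical of extrachromosomal arrays,
not a measured value.

All generators take a :class:`numpy.random.Generator`; identical seed and
config give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import RescueAssay
from .mendel import GeneticsError, Locus
from .screen import (
    F1_CLONAL_SCREEN,
    F2_SELECTION,
    MutagenesisModel,
    ScreenDesign,
    ScreenResult,
    run_f1_clonal_screen,
    run_f2_selection,
)


def standard_suppressor_genes() -> list[Locus]:
    """A small synthetic suppressor gene set on distinct chromosomes
    (chromosome/position choices are fixture conventions, not measurements)."""
    return [
        Locus("sef-A", "I", 20.0, "recessive"),
        Locus("sef-B", "III", 10.0, "recessive"),
        Locus("sef-C", "V", 5.0, "recessive"),
    ]


def da438_marker_map(eat5_bli4_cM: float = 1.0) -> dict[str, Locus]:
    """The multiply marked mapping-strain loci: one visible marker per
    chromosome, plus the focal-linked marker on I.

    The distance between the selected locus on I and its linked marker is not
    a measured value; it defaults to 1 cM and is configurable.
    """
    return {
        locus.name: locus
        for locus in [
            Locus("eat-5", "I", 0.0, "recessive"),
            Locus("bli-4", "I", eat5_bli4_cM, "recessive"),
            Locus("rol-6", "II", 0.0, "recessive"),
            Locus("vab-7", "III", 0.0, "recessive"),
            Locus("unc-31", "IV", 0.0, "recessive"),
            Locus("dpy-11", "V", 0.0, "recessive"),
            Locus("lon-2", "X", 0.0, "recessive"),
        ]
    }


@dataclass
class RescueParams:
    """Generator settings for one synthetic rescue assay.

    ``t``: array transmission rate; ``e_t``/``e_n``: escape-from-arrest
    probability of transgenic / non-transgenic animals on restrictive food
    (their ratio e_t/e_n is the quantity the odds-ratio statistic estimates);
    brood sizes are total progeny scored per food.
    """

    t: float = 0.5
    e_t: float = 0.4
    e_n: float = 0.8
    brood_da: int = 500
    brood_hb: int = 500
    m: int = 1

    def __post_init__(self) -> None:
        for name in ("t", "e_t", "e_n"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneticsError(f"{name} must be in [0, 1]")
        if self.brood_da <= 0 or self.brood_hb <= 0:
            raise GeneticsError("brood sizes must be positive")


@dataclass
class ScreenParams:
    f: float = 5e-4
    F1: int = 5128
    F2: int = 34000
    dominance: str = "recessive"
    background_rate: float = 0.0


@dataclass
class PumpParams:
    """Per-genotype truncated-normal pump-rate settings (pumps/min)."""

    means: dict[str, float] = field(default_factory=lambda: {
        "wt": 120.0, "a": 60.0, "b": 60.0, "double": 60.0})
    sd: float = 15.0
    n: int = 12

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise GeneticsError("sd must be positive")
        if self.n < 2:
            raise GeneticsError("need n >= 2 worms per genotype")
        if any(m < 0 for m in self.means.values()):
            raise GeneticsError("pump-rate means must be >= 0")


@dataclass
class SyntheticConfig:
    seed: int = 0
    screen: ScreenParams = field(default_factory=ScreenParams)
    rescue: RescueParams = field(default_factory=RescueParams)
    pump: PumpParams = field(default_factory=PumpParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            screen=ScreenParams(**raw.get("screen", {})),
            rescue=RescueParams(**raw.get("rescue", {})),
            pump=PumpParams(**raw.get("pump", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def generate_rescue_assay(params: RescueParams, rng: np.random.Generator) -> RescueAssay:
    """Simulate the two-food escape experiment.

    Permissive food: every animal grows; k_H ~ Binomial(N_H, t).  Restrictive
    food: each of the brood is transgenic with probability t and escapes
    arrest with probability e_t (transgenic) or e_n (non-transgenic); only
    escapers are counted, so N_D is itself random.  The odds ratio
    odds(f)/odds(t) recovered from these counts estimates e_t/e_n.
    """
    n_h = int(params.brood_hb)
    k_h = int(rng.binomial(n_h, params.t))
    n_trans = int(rng.binomial(params.brood_da, params.t))
    k_d = int(rng.binomial(n_trans, params.e_t))
    nontrans_escapers = int(rng.binomial(params.brood_da - n_trans, params.e_n))
    n_d = k_d + nontrans_escapers
    if n_d == 0:
        raise GeneticsError("no escapers on restrictive food; enlarge the brood")
    return RescueAssay(N_D=n_d, k_D=k_d, N_H=n_h, k_H=k_h, m=params.m)


def generate_screen_fixture(params: ScreenParams, rng: np.random.Generator,
                            out_dir: str | Path | None = None,
                            genes: list[Locus] | None = None,
                            ) -> dict[str, ScreenResult]:
    """Simulate both screen designs with one mutagenesis model; optionally
    write line-level TSVs and a JSON summary (records the true f)."""
    if genes is None:
        genes = standard_suppressor_genes()
        if params.dominance == "dominant":
            genes = [Locus(g.name, g.chromosome, g.position, "dominant") for g in genes]
    model = MutagenesisModel(genes, params.f, params.background_rate)
    results = {
        "clonal_screen": run_f1_clonal_screen(
            ScreenDesign(F1_CLONAL_SCREEN, F1=params.F1), model, rng=rng),
        "selection": run_f2_selection(
            ScreenDesign(F2_SELECTION, F1=params.F1, F2=params.F2), model, rng=rng),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary = {"true_f": params.f}
        for name, res in results.items():
            res.lines.to_csv(out / f"{name}_lines.tsv", sep="\t", index=False)
            summary[name] = res.summary()
        (out / "screen_summary.json").write_text(json.dumps(summary, indent=2))
    return results


def generate_pump_fixture(params: PumpParams, rng: np.random.Generator,
                          path: str | Path | None = None) -> pd.DataFrame:
    """Per-worm pump rates from a truncated-at-zero normal per genotype, in
    tidy form with the two-factor labels the factorial analysis expects."""
    factors = {
        "wt": ("+", "+"), "a": ("mut", "+"), "b": ("+", "mut"), "double": ("mut", "mut"),
    }
    rows = []
    for genotype, mean in params.means.items():
        draws = rng.normal(mean, params.sd, size=params.n)
        while (draws < 0).any():  # truncate at zero by redrawing
            bad = draws < 0
            draws[bad] = rng.normal(mean, params.sd, size=int(bad.sum()))
        fa, fb = factors.get(genotype, (genotype, genotype))
        for i, rate in enumerate(draws):
            rows.append({"worm_id": f"{genotype}-{i}", "genotype": genotype,
                         "factor_a": fa, "factor_b": fb,
                         "pumps_per_min": float(rate)})
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df


def generate_growth_fixture(brood_sizes: dict[str, float], baseline_days: float,
                            rng: np.random.Generator, cv: float = 0.1,
                            n: int = 5) -> pd.DataFrame:
    """Per-plate exhaustion times consistent with the log-brood-size growth
    model: E[days] for a strain scales as ln(B_ref)/ln(B) times the baseline,
    with lognormal plate-to-plate noise of coefficient of variation ``cv``."""
    if baseline_days <= 0 or cv <= 0 or n < 1:
        raise GeneticsError("baseline_days, cv must be positive; n >= 1")
    ref = max(brood_sizes.values())
    rows = []
    sigma = np.sqrt(np.log(1 + cv**2))
    for strain, brood in brood_sizes.items():
        if brood <= 1:
            raise GeneticsError("brood sizes must exceed 1")
        mean_days = baseline_days * np.log(ref) / np.log(brood)
        days = mean_days * rng.lognormal(-sigma**2 / 2, sigma, size=n)
        for i, d in enumerate(days):
            rows.append({"strain": strain, "plate": i,
                         "days_to_exhaustion": float(d),
                         "growth_rate": float(1.0 / d)})
    return pd.DataFrame(rows)
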