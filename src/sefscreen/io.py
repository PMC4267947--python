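"""Reading genetic maps and cross specs; writing offspring tables.

Document format (YAML or JSON):

    loci:
      - {name: sef, chromosome: II, position: 10.0, dominance: recessive}
    parents:
      mother: {sex: hermaphrodite, alleles: {sef: ["+", "m"]}}
      father: {sex: male, alleles: {sef: ["m", "+"]}}
    offspring_count: 100

Omit ``father`` for a selfing.  Offspring tables are TSV: one row per
individual with id, sex, generation, and one ``maternal/paternal`` allele
column per locus.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .mendel import (
    CrossSpec,
    GeneticsError,
    Genotype,
    Individual,
    Locus,
    make_locus_map,
)


def _load_document(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_genetic_map(source: str | Path | Mapping) -> dict[str, Locus]:
    """Read a locus map from a YAML/JSON file or an already-parsed mapping."""
    doc = source if isinstance(source, Mapping) else _load_document(source)
    entries = doc.get("loci")
    if not entries:
        raise GeneticsError("document has no 'loci' entry")
    return make_locus_map(
        Locus(e["name"], e["chromosome"], float(e.get("position", 0.0)),
              e.get("dominance", "recessive"))
        for e in entries
    )


def individual_from_doc(doc: Mapping, loci: dict[str, Locus],
                        generation: str = "") -> Individual:
    alleles = {
        name: tuple(doc.get("alleles", {}).get(name, ("+", "+")))
        for name in loci
    }
    return Individual(doc.get("sex", "hermaphrodite"),
                      Genotype(dict(loci), alleles),
                      doc.get("generation", generation))


def load_cross_spec(source: str | Path | Mapping) -> CrossSpec:
    """Read a full cross specification (map + parents + brood size)."""
    doc = source if isinstance(source, Mapping) else _load_document(source)
    loci = load_genetic_map(doc)
    parents = doc.get("parents", {})
    if "mother" not in parents:
        raise GeneticsError("cross document needs parents.mother")
    mother = individual_from_doc(parents["mother"], loci, "P0")
    father = (individual_from_doc(parents["father"], loci, "P0")
              if "father" in parents else None)
    return CrossSpec(mother, father,
                     int(doc.get("offspring_count", 1)),
                     doc.get("generation", "F1"))


def offspring_table(individuals: Iterable[Individual]) -> pd.DataFrame:
    rows = []
    for i, ind in enumerate(individuals):
        row = {"id": i, "sex": ind.sex, "generation": ind.generation}
        for name in sorted(ind.genotype.alleles):
            mat, pat = ind.genotype.alleles[name]
            row[name] = f"{mat}/{pat}"
        rows.append(row)
    return pd.DataFrame(rows)


def write_individuals_tsv(path: str | Path, individuals: Iterable[Individual]) -> None:
    offspring_table(individuals).to_csv(path, sep="\t", index=False)
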