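"""Line-oriented text serialization of populations.

Format: comment header carrying ``L`` and the clock, then one cell *class*
per line::

    count<TAB>phenotype<TAB>lineage<TAB>k_in<TAB>k_out<TAB>bitstring

Identical cells are aggregated into counted classes and lines are sorted
(bitstring, phenotype, lineage, rates) so that serialized populations are
byte-diffable across runs.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import numpy as np

from .core import Phenotype, Population, SimulationParams

__all__ = ["write_population", "read_population", "population_to_text",
           "population_from_text"]

_MAGIC = "#competence-evo population v1"


def population_to_text(pop: Population) -> str:
    classes: Counter = Counter()
    for i in pop.live_indices():
        key = (
            "".join("1" if b else "0" for b in pop.genomes[i]),
            int(pop.phen[i]),
            int(pop.lineage[i]),
            repr(float(pop.kin[i])),
            repr(float(pop.kout[i])),
        )
        classes[key] += 1
    lines = [_MAGIC, f"#L={pop.L}\tt={pop.t!r}"]
    for key in sorted(classes):
        bits, phen, lineage, kin, kout = key
        lines.append(f"{classes[key]}\t{phen}\t{lineage}\t{kin}\t{kout}\t{bits}")
    return "\n".join(lines) + "\n"


def population_from_text(text: str, params: SimulationParams) -> Population:
    lines = text.splitlines()
    if not lines or lines[0] != _MAGIC:
        raise ValueError("not a competence-evo population file")
    header = dict(
        kv.split("=", 1) for kv in lines[1].lstrip("#").split("\t")
    )
    L = int(header["L"])
    if L != params.L:
        raise ValueError(f"file has L={L} but params.L={params.L}")
    t = float(header["t"])
    pop = Population(params)
    for line in lines[2:]:
        if not line or line.startswith("#"):
            continue
        count, phen, lineage, kin, kout, bits = line.split("\t")
        if len(bits) != L:
            raise ValueError(f"genome length {len(bits)} does not match L={L}")
        alleles = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
        for _ in range(int(count)):
            pop.add_cell(alleles, Phenotype(int(phen)), int(lineage),
                         float(kin), float(kout))
    pop.t = t
    return pop


def write_population(pop: Population, path) -> None:
    Path(path).write_text(population_to_text(pop))


def read_population(path, params: SimulationParams) -> Population:
    return population_from_text(Path(path).read_text(), params)
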