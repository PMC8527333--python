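"""Epistasis-based dependence calls and the three-way consensus intersection.

A gene is up-regulated "in an ATFS-1-dependent manner" when it is up in a
mitoUPR-activating mutant (e.g. nuo-6) but not in the corresponding
atfs-1-null double mutant (nuo-6;atfs-1): a plain set difference of the two
up-lists.  The high-confidence target signature is the genes shared by all
three activating conditions — nuo-6 (dependent), spg-7 RNAi (dependent), and
both constitutively active atfs-1 alleles (et15 AND et17).

All operations assume alias-normalized inputs; only up-regulated lists enter
the consensus (down-regulation is ignored).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import GeneSet


@dataclass(frozen=True)
class ConsensusResult:
    """Three-way consensus plus per-input bookkeeping."""

    consensus: GeneSet
    per_input_sizes: dict[str, int]
    provenance: tuple[str, str, str]

    def __post_init__(self):
        for name, size in self.per_input_sizes.items():
            if size < len(self.consensus):
                raise ValueError(
                    f"input {name!r} ({size}) smaller than consensus ({len(self.consensus)})"
                )


def derive_dependent_set(up_in_mutant: GeneSet, up_in_double: GeneSet) -> GeneSet:
    """Genes up in the mutant but not in the atfs-1-null double mutant."""
    genes = up_in_mutant.genes - up_in_double.genes
    return GeneSet(
        name=f"{up_in_mutant.name}_dependent",
        genes=genes,
        condition=f"{up_in_mutant.condition or up_in_mutant.name}_dependent",
        source=f"{up_in_mutant.source} \\ {up_in_double.source}",
    )


def intersect_pair(a: GeneSet, b: GeneSet) -> GeneSet:
    """Genes shared by two sets (e.g. up in both et15 and et17)."""
    return GeneSet(
        name=f"{a.name}&{b.name}",
        genes=a.genes & b.genes,
        condition=f"{a.condition}&{b.condition}".strip("&"),
        source=f"{a.source} & {b.source}",
    )


def intersect_consensus(a: GeneSet, b: GeneSet, c: GeneSet) -> ConsensusResult:
    """Three-way intersection defining the high-confidence signature."""
    consensus = GeneSet(
        name="consensus",
        genes=a.genes & b.genes & c.genes,
        condition="consensus",
        source=f"{a.name} & {b.name} & {c.name}",
    )
    return ConsensusResult(
        consensus=consensus,
        per_input_sizes={a.name: len(a), b.name: len(b), c.name: len(c)},
        provenance=(a.name, b.name, c.name),
    )
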