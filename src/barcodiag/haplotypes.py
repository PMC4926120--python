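"""Haplotype collapsing: group identical aligned sequences per species.

The default identity rule is a strict exact match over the full aligned
length.  With ``exclude_ambiguous_columns=True`` every column in which any
record carries a gap or ambiguity code is masked before comparison (the
behaviour of popular polymorphism software when sites with gaps/missing data
are excluded).  Identical sequences labelled with different species are kept
as separate haplotypes, with a warning — species labels are trusted input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import DistanceError
from .seqio import Alignment, SeqRecord

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass
class Haplotype:
    representative: str          # id of the first member in input order
    members: list[str]
    species: str

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeTable:
    haplotypes: list[Haplotype] = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def species_counts(self) -> dict[str, int]:
        """species -> number of distinct haplotypes."""
        out: dict[str, int] = {}
        for h in self.haplotypes:
            out[h.species] = out.get(h.species, 0) + 1
        return out

    def to_tsv(self) -> str:
        lines = ["representative\tspecies\tcount\tmembers"]
        for h in self.haplotypes:
            lines.append(f"{h.representative}\t{h.species}\t{h.count}\t{','.join(h.members)}")
        return "\n".join(lines) + "\n"

    def representatives(self, aln: Alignment) -> list[SeqRecord]:
        by_id = {r.id: r for r in aln}
        return [by_id[h.representative] for h in self.haplotypes]


def collapse_haplotypes(
    aln: Alignment,
    species_of: Optional[Mapping[str, str]] = None,
    exclude_ambiguous_columns: bool = False,
) -> HaplotypeTable:
    """Collapse an alignment into haplotypes, grouped per species.

    Haplotype members partition the input ids; the representative is the first
    member in input order.  The same sequence occurring under two species
    labels yields two haplotypes (warned, never merged).
    """
    species_of = species_of if species_of is not None else aln.species_map()
    for rec in aln:
        if rec.id not in species_of:
            raise DistanceError(f"record {rec.id!r} has no species assignment")

    if exclude_ambiguous_columns:
        keep = [
            i for i in range(aln.length)
            if all(r.sequence[i] in _UNAMBIGUOUS for r in aln)
        ]
        key_of = {r.id: "".join(r.sequence[i] for i in keep) for r in aln}
    else:
        key_of = {r.id: r.sequence for r in aln}

    table = HaplotypeTable()
    index: dict[tuple[str, str], Haplotype] = {}
    seq_species: dict[str, set[str]] = {}
    for rec in aln:
        sp = species_of[rec.id]
        key = (sp, key_of[rec.id])
        if key in index:
            index[key].members.append(rec.id)
        else:
            hap = Haplotype(representative=rec.id, members=[rec.id], species=sp)
            index[key] = hap
            table.haplotypes.append(hap)
        seq_species.setdefault(key_of[rec.id], set()).add(sp)
    shared = {s for s, sps in seq_species.items() if len(sps) > 1}
    if shared:
        warnings.warn(
            f"{len(shared)} identical sequence(s) occur under multiple species labels; "
            "kept as separate haplotypes per species"
        )
    return table
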