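"""In-silico PCR: binding-site search, amplicon prediction, specificity grids.

A primer binds where an ungapped window of the template matches it with at
most ``max_mismatch`` mismatches and zero mismatches in the 3'-terminal
``three_prime_window`` bases (extension by the polymerase requires a matched
3' end; mismatches there are precisely what makes species-specific primers
specific).  IUPAC codes in the primer match their base sets and are never
counted as mismatches when the template base is in the set.  No
thermodynamic annealing model is applied at this stage — mismatch counts
only.

An amplicon arises from every plus-strand forward site paired with every
minus-strand reverse site downstream of it, with the product length measured
over the outermost primer bases (``rev_end - fwd_start + 1``).  The
species x primer-pair grid summarises which pairs amplify which species, the
computational mirror of a specificity gel panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

from .errors import DesignError
from .seqio import (
    Alignment,
    IUPAC_SETS,
    PrimerRecord,
    SeqRecord,
    reverse_complement,
)


@dataclass
class BindingSite:
    """One predicted primer binding site on a template."""

    template_id: str
    strand: str                 # "+" or "-"
    start: int                  # 1-based inclusive, plus-strand coordinates
    end: int
    mismatches: int
    three_prime_exact: bool = True


@dataclass
class Amplicon:
    """A predicted PCR product."""

    template_id: str
    start: int                  # outermost forward-primer base
    end: int                    # outermost reverse-primer base
    forward_site: BindingSite
    reverse_site: BindingSite

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _matches(primer_base: str, template_base: str) -> bool:
    return template_base in IUPAC_SETS.get(primer_base, set())


def _scan(pattern: str, template: str, max_mismatch: int,
          three_prime_at_right: bool, window: int) -> list[tuple[int, int]]:
    """(0-based start, mismatches) for windows matching an oriented pattern.

    ``three_prime_at_right`` says which end of the plus-strand window the
    primer's 3' terminus maps to; that terminal ``window`` must match exactly.
    """
    L = len(pattern)
    hits = []
    if three_prime_at_right:
        anchor = range(L - window, L)
    else:
        anchor = range(0, window)
    for start in range(0, len(template) - L + 1):
        seg = template[start:start + L]
        if any(not _matches(pattern[i], seg[i]) for i in anchor):
            continue
        mm = sum(not _matches(p, t) for p, t in zip(pattern, seg))
        if mm <= max_mismatch:
            hits.append((start, mm))
    return hits


def find_binding_sites(
    primer: Union[PrimerRecord, str],
    template: Union[SeqRecord, str],
    max_mismatch: int = 2,
    three_prime_window: int = 3,
) -> list[BindingSite]:
    """All binding sites of a primer on both strands of a template.

    Plus-strand sites have the primer reading 5'->3' along the template
    (3' end at the site's right edge); minus-strand sites match the reverse
    complement (3' end at the left edge).
    """
    pseq = primer.sequence if isinstance(primer, PrimerRecord) else primer.upper()
    pname = primer.name if isinstance(primer, PrimerRecord) else "primer"
    tid = template.id if isinstance(template, SeqRecord) else "template"
    tseq = (template.sequence if isinstance(template, SeqRecord) else template).upper()
    if len(pseq) > len(tseq):
        raise DesignError(f"primer {pname!r} longer than template {tid!r}")
    sites = []
    for start, mm in _scan(pseq, tseq, max_mismatch, True, three_prime_window):
        sites.append(BindingSite(
            template_id=tid, strand="+", start=start + 1,
            end=start + len(pseq), mismatches=mm,
        ))
    rc = reverse_complement(pseq)
    for start, mm in _scan(rc, tseq, max_mismatch, False, three_prime_window):
        sites.append(BindingSite(
            template_id=tid, strand="-", start=start + 1,
            end=start + len(pseq), mismatches=mm,
        ))
    return sites


def predict_amplicons(
    pair: tuple[PrimerRecord, PrimerRecord],
    library: Union[Alignment, Sequence[SeqRecord]],
    product_range: tuple[int, int] = (50, 2000),
    max_mismatch: int = 2,
    three_prime_window: int = 3,
) -> list[Amplicon]:
    """Amplicons of a (forward, reverse) pair across a sequence library.

    Every plus-strand forward site combined with every minus-strand reverse
    site starting downstream yields a product when its length is in bounds.
    """
    forward, reverse = pair
    lo, hi = product_range
    amplicons = []
    records = library.records if isinstance(library, Alignment) else list(library)
    for rec in records:
        if len(forward.sequence) > len(rec.sequence) or len(reverse.sequence) > len(rec.sequence):
            continue
        f_sites = [
            s for s in find_binding_sites(forward, rec, max_mismatch, three_prime_window)
            if s.strand == "+"
        ]
        r_sites = [
            s for s in find_binding_sites(reverse, rec, max_mismatch, three_prime_window)
            if s.strand == "-"
        ]
        for fs in f_sites:
            for rs in r_sites:
                if fs.start < rs.start and lo <= rs.end - fs.start + 1 <= hi:
                    amplicons.append(Amplicon(
                        template_id=rec.id, start=fs.start, end=rs.end,
                        forward_site=fs, reverse_site=rs,
                    ))
    return amplicons


@dataclass
class SpecificityMatrix:
    """Species x primer-pair detection grid."""

    species: list[str]
    pair_names: list[str]
    target_of: dict[str, Optional[str]]                    # pair -> intended species
    grid: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    def amplified(self, species: str, pair_name: str) -> bool:
        return bool(self.grid.get((species, pair_name)))

    def products(self, species: str, pair_name: str) -> list[int]:
        return self.grid.get((species, pair_name), [])

    def is_specific(self, pair_name: str) -> bool:
        """True iff the pair amplifies its target species and no other."""
        target = self.target_of.get(pair_name)
        if target is None or target not in self.species:
            return False
        return all(
            self.amplified(sp, pair_name) == (sp == target)
            for sp in self.species
        )

    @property
    def diagonal(self) -> bool:
        """True iff every pair is specific for its own target."""
        return all(self.is_specific(p) for p in self.pair_names)

    def virtual_gel(self) -> str:
        """Plain-text lane table: one row per species, one column per pair.

        A cell shows predicted product sizes (a "band") or "-" for no
        amplification.
        """
        width = max([len(s) for s in self.species] + [7])
        header = "species".ljust(width) + "".join(
            f"  {name:>14}" for name in self.pair_names
        )
        lines = [header]
        for sp in self.species:
            cells = []
            for name in self.pair_names:
                prods = self.products(sp, name)
                cells.append(",".join(str(p) for p in prods) if prods else "-")
            lines.append(sp.ljust(width) + "".join(f"  {c:>14}" for c in cells))
        return "\n".join(lines) + "\n"

    def to_tsv(self) -> str:
        lines = ["species\t" + "\t".join(self.pair_names)]
        for sp in self.species:
            cells = [
                ",".join(str(p) for p in self.products(sp, name)) or "-"
                for name in self.pair_names
            ]
            lines.append(sp + "\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def specificity_matrix(
    pairs: Sequence,
    library: Union[Alignment, Sequence[SeqRecord]],
    species_of: Optional[Mapping[str, str]] = None,
    product_range: tuple[int, int] = (50, 2000),
    max_mismatch: int = 2,
    three_prime_window: int = 3,
) -> SpecificityMatrix:
    """Populate the species x primer-pair grid by in-silico PCR.

    ``pairs`` may contain (forward, reverse) tuples or design candidates with
    ``forward``/``reverse``/``target_species`` attributes; the intended target
    falls back to the species encoded in the primer names.
    """
    records = library.records if isinstance(library, Alignment) else list(library)
    if species_of is None:
        species_of = {r.id: r.species for r in records}
    species = sorted({species_of[r.id] for r in records})
    names, targets = [], {}
    matrix = SpecificityMatrix(species=species, pair_names=names, target_of=targets)
    for pair in pairs:
        if hasattr(pair, "forward"):
            fwd, rev = pair.forward, pair.reverse
            target = pair.target_species
        else:
            fwd, rev = pair
            target = fwd.species if fwd.species == rev.species else None
        name = f"{fwd.name}+{rev.name}"
        names.append(name)
        targets[name] = target
        for amp in predict_amplicons(
            (fwd, rev), records, product_range, max_mismatch, three_prime_window
        ):
            sp = species_of[amp.template_id]
            matrix.grid.setdefault((sp, name), []).append(amp.length)
    return matrix


def site_carrier_template(
    forward: PrimerRecord,
    reverse: PrimerRecord,
    length: int = 658,
    template_id: str = "carrier",
    fill: str = "A",
) -> SeqRecord:
    """Synthetic template carrying exactly one binding site per primer at its
    declared plus-strand coordinates (reverse primer planted as its reverse
    complement), with a constant background elsewhere.

    Useful for validating product-length arithmetic by running in-silico PCR
    against a template known to contain the declared sites and nothing else.
    """
    if forward.footprint is None or reverse.footprint is None:
        raise DesignError(
            f"pair {forward.name}/{reverse.name}: declared coordinates required"
        )
    f_start, f_end = forward.footprint
    r_start, r_end = reverse.footprint
    if f_end >= r_start:
        raise DesignError("primer footprints overlap or reverse is upstream")
    length = max(length, r_end)
    seq = [fill] * length
    seq[f_start - 1:f_end] = list(forward.sequence)
    seq[r_start - 1:r_end] = list(reverse_complement(reverse.sequence))
    return SeqRecord(id=template_id, species="", sequence="".join(seq))


def amplicons_to_bed(amplicons: Sequence[Amplicon], pair_name: str) -> str:
    """BED-like export: template, 0-based start, half-open end, name, length, strand."""
    lines = []
    for a in amplicons:
        lines.append(f"{a.template_id}\t{a.start - 1}\t{a.end}\t{pair_name}\t{a.length}\t+")
    return "\n".join(lines) + ("\n" if lines else "")
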