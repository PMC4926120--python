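"""Oligo arithmetic and thermodynamics.

GC content, the Wallace rule, nearest-neighbour melting temperature, duplex
free energies, and exhaustive hairpin/dimer screening at primer lengths.

The nearest-neighbour model uses the unified DNA parameter set (the table
shipped with Biopython's melting-temperature module), with the entropic salt
correction applied for monovalent cations and

    Tm = dH / (dS + R ln(C_T / 4)) - 273.15

for non-self-complementary duplexes at total strand concentration ``C_T``.
Structure screening is an exhaustive ungapped register scan: every alignment
register of one oligo against the reverse of the other (or of an oligo
against itself, or a stem against a downstream stem for hairpins) is scored
by summing stack free energies over contiguous complementary runs.  No
suboptimal-folding ensemble is computed; at 18-30 nt this matches common
primer-design-tool practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from Bio.SeqUtils import MeltingTemp as _mt

from .errors import DesignError
from .seqio import PrimerRecord, ProbeRecord

R_GAS = 1.987  # cal / (mol K)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class ThermoParams:
    """Thermodynamic context for Tm and dG calculations.

    ``nn_table`` maps dinucleotide stacks (and initiation terms) to
    (dH kcal/mol, dS cal/mol/K).  ``salt`` is the monovalent cation
    concentration in M; ``c_t`` the total oligo concentration in M;
    ``temperature`` the evaluation temperature for dG in Celsius.
    """

    nn_table: dict = field(default_factory=lambda: dict(_mt.DNA_NN3))
    salt: float = 0.05
    c_t: float = 2.5e-7
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if self.salt <= 0 or self.c_t <= 0:
            raise DesignError("salt and oligo concentrations must be positive")

    def stack_dg(self, stack: str) -> float:
        """Free energy (kcal/mol) of one dinucleotide stack at ``temperature``."""
        dh, ds = self.nn_table[stack]
        return dh - (self.temperature + 273.15) * ds / 1000.0


DEFAULT_PARAMS = ThermoParams()

#: Conditions typical of probe-based qPCR master mixes: about 0.25 M
#: monovalent-equivalent salt (the Mg2+ contribution folded into a single
#: monovalent term) and 0.2 uM per primer (C_T/4).
QPCR_PARAMS = ThermoParams(salt=0.25, c_t=8e-7)


def _plain_seq(oligo: Union[str, PrimerRecord, ProbeRecord]) -> str:
    seq = oligo if isinstance(oligo, str) else oligo.sequence
    seq = seq.upper()
    if not seq:
        raise DesignError("empty oligo sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise DesignError(f"ambiguity codes not allowed here: {sorted(bad)}")
    return seq


def gc_content(oligo: Union[str, PrimerRecord, ProbeRecord]) -> float:
    """Percent G+C of an unambiguous oligo."""
    seq = _plain_seq(oligo)
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq)


def at_content(oligo: Union[str, PrimerRecord, ProbeRecord]) -> float:
    """Percent A+T; complements :func:`gc_content` to 100."""
    return 100.0 - gc_content(oligo)


def tm_wallace(oligo: Union[str, PrimerRecord, ProbeRecord]) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees C."""
    seq = _plain_seq(oligo)
    at = sum(seq.count(b) for b in "AT")
    return 2.0 * at + 4.0 * (len(seq) - at)


def tm_nn(
    oligo: Union[str, PrimerRecord, ProbeRecord],
    params: Optional[ThermoParams] = None,
) -> float:
    """Nearest-neighbour melting temperature in Celsius.

    Requires length >= 8 (shorter oligos are dominated by end effects and the
    NN estimate is not meaningful).
    """
    params = params or DEFAULT_PARAMS
    seq = _plain_seq(oligo)
    if len(seq) < 8:
        raise DesignError(f"oligo too short for NN Tm ({len(seq)} < 8 nt)")
    # dnac1 in nM chosen so Biopython's effective concentration equals C_T / 4
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=params.nn_table,
            dnac1=params.c_t * 1e9 / 4.0,
            dnac2=0.0,
            Na=params.salt * 1e3,
            saltcorr=5,
            selfcomp=False,
        )
    )


# ---------------------------------------------------------------------------
# Duplex / structure screening
# ---------------------------------------------------------------------------

@dataclass
class StructureHit:
    """A predicted secondary-structure interaction.

    ``positions`` are 0-based start indices of the paired run: for dimers
    ``(start_in_a, start_in_b)`` with b indexed 5'->3'; for hairpins
    ``(stem5_start, stem3_start)`` within the single oligo.
    """

    kind: str                 # "hairpin" | "self-dimer" | "cross-dimer"
    positions: tuple[int, int]
    length: int               # paired run length, >= 3
    dg: float                 # kcal/mol at params.temperature


def _run_dg(seq_a: str, params: ThermoParams) -> float:
    """dG of a fully paired run given its top strand, stacks plus initiation."""
    total = 0.0
    for i in range(len(seq_a) - 1):
        a, b = seq_a[i], seq_a[i + 1]
        stack = f"{a}{b}/{_COMPLEMENT[a]}{_COMPLEMENT[b]}"
        if stack not in params.nn_table:
            # table stores each stack in one orientation; read the other strand
            stack = f"{_COMPLEMENT[b]}{_COMPLEMENT[a]}/{b}{a}"
        total += params.stack_dg(stack)
    for end in (seq_a[0], seq_a[-1]):
        key = "init_A/T" if end in "AT" else "init_G/C"
        if key in params.nn_table:
            total += params.stack_dg(key)
    return total


def duplex_dg(
    a: Union[str, PrimerRecord, ProbeRecord],
    b: Union[str, PrimerRecord, ProbeRecord],
    register: int,
    params: Optional[ThermoParams] = None,
    min_run: int = 3,
) -> float:
    """Free energy of the best complementary run of a vs b at one register.

    ``register`` offsets a (5'->3') against b read 3'->5': position ``i`` of a
    pairs with position ``register + i`` of reversed b.  Returns 0.0 when no
    complementary run of at least ``min_run`` bases exists.
    """
    params = params or DEFAULT_PARAMS
    sa, sb = _plain_seq(a), _plain_seq(b)
    rb = sb[::-1]
    best = 0.0
    run_start = None
    i = 0
    while i <= len(sa):
        j = register + i
        paired = (
            i < len(sa) and 0 <= j < len(rb)
            and _COMPLEMENT[sa[i]] == rb[j]
        )
        if paired and run_start is None:
            run_start = i
        elif not paired and run_start is not None:
            run_len = i - run_start
            if run_len >= min_run:
                best = min(best, _run_dg(sa[run_start:i], params))
            run_start = None
        i += 1
    return best


def dimer_screen(
    a: Union[str, PrimerRecord, ProbeRecord],
    b: Optional[Union[str, PrimerRecord, ProbeRecord]] = None,
    params: Optional[ThermoParams] = None,
    min_run: int = 3,
    dg_floor: float = 3.0,
) -> list[StructureHit]:
    """All dimer interactions with |dG| at or above ``dg_floor``, worst first.

    With ``b`` omitted the oligo is screened against itself (self-dimer).
    """
    params = params or DEFAULT_PARAMS
    kind = "self-dimer" if b is None else "cross-dimer"
    sa = _plain_seq(a)
    sb = sa if b is None else _plain_seq(b)
    rb = sb[::-1]
    hits: list[StructureHit] = []
    for register in range(-(len(sa) - 1), len(rb)):
        run_start = None
        i = max(0, -register)
        end = min(len(sa), len(rb) - register)
        for i2 in range(i, end + 1):
            j = register + i2
            paired = i2 < end and _COMPLEMENT[sa[i2]] == rb[j]
            if paired and run_start is None:
                run_start = i2
            elif not paired and run_start is not None:
                run_len = i2 - run_start
                if run_len >= min_run:
                    dg = _run_dg(sa[run_start:i2], params)
                    if abs(dg) >= dg_floor and dg < 0:
                        # start in b, 5'->3' indexing
                        b_start = len(sb) - 1 - (register + i2 - 1)
                        hits.append(StructureHit(
                            kind=kind, positions=(run_start, b_start),
                            length=run_len, dg=dg,
                        ))
                run_start = None
    hits.sort(key=lambda h: h.dg)
    return hits


def hairpin_screen(
    oligo: Union[str, PrimerRecord, ProbeRecord],
    min_stem: int = 4,
    min_loop: int = 3,
    params: Optional[ThermoParams] = None,
    dg_floor: float = 3.0,
) -> list[StructureHit]:
    """All hairpin stems of at least ``min_stem`` paired bases, worst first.

    A stem pairs ``seq[s1 : s1+L]`` with the reverse complement of
    ``seq[s2 : s2+L]`` separated by a loop of at least ``min_loop`` bases.
    Only maximal stems (not extendable on either side) are reported.
    """
    params = params or DEFAULT_PARAMS
    seq = _plain_seq(oligo)
    n = len(seq)
    hits: list[StructureHit] = []
    for s1 in range(n):
        for s2 in range(n - 1, s1 + 2 * min_stem + min_loop - 2, -1):
            # stem pairs seq[s1+k] with seq[s2-k], walking inward
            length = 0
            while (
                _COMPLEMENT[seq[s1 + length]] == seq[s2 - length]
                and (s2 - (length + 1)) - (s1 + (length + 1)) + 1 >= min_loop
            ):
                length += 1
            if length >= min_stem:
                # maximal stems only: skip if extendable outward
                if s1 > 0 and s2 + 1 < n and _COMPLEMENT[seq[s1 - 1]] == seq[s2 + 1]:
                    continue
                stem = seq[s1:s1 + length]
                dg = _run_dg(stem, params)
                if abs(dg) >= dg_floor and dg < 0:
                    hits.append(StructureHit(
                        kind="hairpin", positions=(s1, s2 - length + 1),
                        length=length, dg=dg,
                    ))
    hits.sort(key=lambda h: h.dg)
    return hits


def worst_structure_dg(
    oligo: Union[str, PrimerRecord, ProbeRecord],
    partner: Optional[Union[str, PrimerRecord, ProbeRecord]] = None,
    params: Optional[ThermoParams] = None,
    min_stem: int = 4,
) -> float:
    """Most negative dG among self-dimer, hairpin and (optional) cross-dimer
    hits; 0.0 when no structure is found."""
    params = params or DEFAULT_PARAMS
    dgs = [0.0]
    dgs += [h.dg for h in dimer_screen(oligo, params=params)]
    dgs += [h.dg for h in hairpin_screen(oligo, min_stem=min_stem, params=params)]
    if partner is not None:
        dgs += [h.dg for h in dimer_screen(oligo, partner, params=params)]
    return min(dgs)
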