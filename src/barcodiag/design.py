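"""Species-specific primer and TaqMan assay design and evaluation.

Design starts from *diagnostic positions*: alignment columns where the target
species is fixed for one base that no other species carries.  A primer whose
3' region covers such a column amplifies the target but mismatches every
other species at its extension end, which is what makes endpoint PCR or
TaqMan qPCR species-specific.

Three rule lists are implemented as explicit criterion reports:

* endpoint primers, SP1-SP8: length 18-30; worst structure |dG| < 9 kcal/mol;
  a diagnostic base in the 3'-terminal window; no distinct hairpin; GC 30-70%;
  footprint covers a diagnostic position; false-priming score < 100; Tm inside
  the annealing window.
* hydrolysis probes, PR1-PR7: length 18-30; C content >= G content (else use
  the reverse complement); GC 30-80%; no 5'-G (a G next to the reporter
  quenches it); no GGGG run (other 4-runs warn); probe close to the forward
  primer; no strong probe-primer cross-dimer.
* qPCR primer pairs, QP1-QP6: lengths within 4 nt of each other and each
  18-30; GC 40-60%; no 3'-terminal A; no GGGG run; 3' end not closing with
  three G/C; no strong cross-dimer.

Criteria are evaluated as a report, not a silent filter: published assays can
and do violate individual rules, and the evaluator's job is to surface that.
Criteria that need library context (SP3, SP6, SP7) report status "skipped"
when evaluated without one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

from .errors import DesignError
from .seqio import (
    Alignment,
    PrimerRecord,
    ProbeRecord,
    reverse_complement,
)
from . import thermo

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass
class DesignConfig:
    """All evaluation thresholds in one place."""

    primer_length: tuple[int, int] = (18, 30)
    dg_limit: float = 9.0                    # |dG| kcal/mol, structures
    three_prime_window: int = 5              # nt, SP3 diagnostic-base window
    min_stem: int = 4                        # hairpin stem for SP4
    gc_range: tuple[float, float] = (30.0, 70.0)
    false_priming_limit: float = 100.0       # SP7: must be strictly below
    tm_window: tuple[float, float] = (45.0, 65.0)
    probe_gc_range: tuple[float, float] = (30.0, 80.0)
    probe_max_gap: int = 15                  # nt, probe 5' to forward-primer 3'
    qpcr_gc_range: tuple[float, float] = (40.0, 60.0)
    qpcr_max_len_diff: int = 4
    product_range: tuple[int, int] = (100, 600)
    max_tm_diff: float = 5.0


DEFAULT_CONFIG = DesignConfig()


@dataclass
class Criterion:
    id: str
    description: str
    measured: object
    passed: Optional[bool]       # None = skipped (context unavailable)
    hard: bool = True


@dataclass
class CriterionReport:
    """Ordered per-criterion evaluation of one oligo or pair."""

    subject: str
    criteria: list[Criterion] = field(default_factory=list)

    def add(self, cid: str, description: str, measured, passed, hard=True) -> None:
        if any(c.id == cid for c in self.criteria):
            raise DesignError(f"criterion {cid} added twice for {self.subject}")
        self.criteria.append(Criterion(cid, description, measured, passed, hard))

    def __getitem__(self, cid: str) -> Criterion:
        for c in self.criteria:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def overall(self) -> bool:
        """True iff every evaluated hard criterion passed."""
        return all(c.passed for c in self.criteria if c.hard and c.passed is not None)

    @property
    def n_passed(self) -> int:
        return sum(1 for c in self.criteria if c.passed)

    def to_tsv(self) -> str:
        lines = ["id\tdescription\tmeasured\tpassed"]
        for c in self.criteria:
            status = {True: "pass", False: "FAIL", None: "skipped"}[c.passed]
            lines.append(f"{c.id}\t{c.description}\t{c.measured}\t{status}")
        return "\n".join(lines) + "\n"


@dataclass
class CandidatePair:
    """A coordinate-compatible forward/reverse primer pair for one species."""

    forward: PrimerRecord
    reverse: PrimerRecord
    target_species: Optional[str]
    product_length: int
    tm_difference: float
    forward_report: Optional[CriterionReport] = None
    reverse_report: Optional[CriterionReport] = None

    @property
    def name(self) -> str:
        return f"{self.forward.name}+{self.reverse.name}"

    @property
    def overall(self) -> bool:
        reports = [r for r in (self.forward_report, self.reverse_report) if r]
        return bool(reports) and all(r.overall for r in reports)


@dataclass
class TaqManSet:
    """A qPCR primer pair plus a hydrolysis probe inside the amplicon."""

    forward: PrimerRecord
    reverse: PrimerRecord
    probe: ProbeRecord
    target_species: Optional[str]
    product_length: int
    probe_gap: Optional[int] = None        # nt between fwd 3' end and probe 5'
    pair_report: Optional[CriterionReport] = None
    probe_report: Optional[CriterionReport] = None

    @property
    def overall(self) -> bool:
        reports = [r for r in (self.pair_report, self.probe_report) if r]
        return bool(reports) and all(r.overall for r in reports)


# ---------------------------------------------------------------------------
# Diagnostic positions
# ---------------------------------------------------------------------------

def diagnostic_positions(
    aln: Alignment,
    species_of: Optional[Mapping[str, str]] = None,
    target: str = "",
) -> list[tuple[int, str]]:
    """Columns (1-based) where ``target`` is fixed for a base absent from all
    other species, with that base."""
    species_of = species_of if species_of is not None else aln.species_map()
    target_rows = [r for r in aln if species_of.get(r.id, r.species) == target]
    other_rows = [r for r in aln if species_of.get(r.id, r.species) != target]
    if not target_rows:
        raise DesignError(f"target species {target!r} absent from alignment")
    out: list[tuple[int, str]] = []
    for pos in range(1, aln.length + 1):
        t_bases = {r.sequence[pos - 1] for r in target_rows}
        if len(t_bases) != 1:
            continue
        base = t_bases.pop()
        if base not in _UNAMBIGUOUS:
            continue
        o_bases = {r.sequence[pos - 1] for r in other_rows}
        if base not in o_bases:
            out.append((pos, base))
    return out


# ---------------------------------------------------------------------------
# Primer mapping and false priming
# ---------------------------------------------------------------------------

def map_primer(p: PrimerRecord, template: str) -> tuple[int, int]:
    """Plus-strand footprint (1-based inclusive) of a primer on a template.

    Uses declared coordinates when available, else an exact search of the
    primer (forward) or its reverse complement (reverse orientation).
    """
    if p.footprint is not None:
        return p.footprint
    probe = p.sequence if p.orientation == "forward" else reverse_complement(p.sequence)
    idx = template.upper().find(probe)
    if idx < 0:
        raise DesignError(f"primer {p.name!r} not found on template")
    return idx + 1, idx + len(probe)


def false_priming_score(
    p: PrimerRecord,
    library: Alignment,
    intended: Optional[tuple[int, int]] = None,
    target: Optional[str] = None,
    species_of: Optional[Mapping[str, str]] = None,
    three_prime_anchor: int = 3,
) -> float:
    """100 x best ungapped identity of the primer at any unintended
    same-orientation site, counting only windows whose 3'-terminal
    ``three_prime_anchor`` bases match exactly.

    The intended site is exempt only on sequences of the target species: a
    perfect hit at the same coordinates on another species *is* false
    priming.  A score below 100 means no perfect unintended priming site.
    """
    probe = p.sequence if p.orientation == "forward" else reverse_complement(p.sequence)
    L = len(probe)
    # in footprint coordinates, the primer 3' anchor sits at the right end for
    # forward primers and at the left end for reverse primers
    if p.orientation == "forward":
        anchor = range(L - three_prime_anchor, L)
    else:
        anchor = range(0, three_prime_anchor)
    species_of = species_of if species_of is not None else library.species_map()
    best = 0.0
    for rec in library:
        seq = rec.sequence
        on_target = target is None or species_of.get(rec.id, rec.species) == target
        for start in range(0, len(seq) - L + 1):
            if intended and start + 1 == intended[0] and on_target:
                continue
            window = seq[start:start + L]
            if any(window[i] != probe[i] for i in anchor):
                continue
            ident = sum(a == b for a, b in zip(window, probe)) / L
            best = max(best, 100.0 * ident)
    return best


# ---------------------------------------------------------------------------
# Endpoint-PCR primer criteria (SP1-SP8)
# ---------------------------------------------------------------------------

def evaluate_primer(
    p: PrimerRecord,
    library: Optional[Alignment] = None,
    species_of: Optional[Mapping[str, str]] = None,
    target: Optional[str] = None,
    template: Optional[str] = None,
    config: DesignConfig = DEFAULT_CONFIG,
    params: Optional[thermo.ThermoParams] = None,
) -> CriterionReport:
    """Evaluate one endpoint-PCR primer against the eight specificity rules.

    ``library``/``target`` provide the context for the diagnostic-base and
    false-priming criteria; without them SP3, SP6 and SP7 are reported as
    skipped.  ``template`` (a target-species sequence) is used to map a primer
    without declared coordinates.
    """
    report = CriterionReport(subject=p.name)
    lo, hi = config.primer_length
    report.add("SP1", f"length in [{lo},{hi}]", len(p), lo <= len(p) <= hi)

    worst = thermo.worst_structure_dg(p, params=params, min_stem=config.min_stem)
    report.add("SP2", f"|structure dG| < {config.dg_limit} kcal/mol",
               round(worst, 2), abs(worst) < config.dg_limit)

    footprint = p.footprint
    diag: list[tuple[int, str]] = []
    have_context = library is not None and bool(target)
    if have_context:
        species_of = species_of if species_of is not None else library.species_map()
        diag = diagnostic_positions(library, species_of, target)
        if footprint is None:
            tmpl = template
            if tmpl is None:
                tmpl = next(
                    r.sequence for r in library
                    if species_of.get(r.id, r.species) == target
                )
            try:
                footprint = map_primer(p, tmpl)
            except DesignError:
                footprint = None

    if have_context and footprint is not None:
        start, end = footprint
        if p.orientation == "forward":
            window = range(end - config.three_prime_window + 1, end + 1)
        else:
            window = range(start, start + config.three_prime_window)
        diag_pos = {pos for pos, _ in diag}
        n_3p = sum(1 for pos in window if pos in diag_pos)
        report.add("SP3", "diagnostic base in 3' window", n_3p, n_3p >= 1)
    else:
        report.add("SP3", "diagnostic base in 3' window", None, None)

    hairpins = thermo.hairpin_screen(p, min_stem=config.min_stem, params=params)
    report.add("SP4", "no distinct hairpin", len(hairpins), len(hairpins) == 0)

    gc = thermo.gc_content(p)
    glo, ghi = config.gc_range
    report.add("SP5", f"GC% in [{glo:g},{ghi:g}]", round(gc, 1), glo <= gc <= ghi)

    if have_context and footprint is not None:
        diag_pos = {pos for pos, _ in diag}
        n_cov = sum(1 for pos in range(footprint[0], footprint[1] + 1) if pos in diag_pos)
        report.add("SP6", "footprint covers a diagnostic position", n_cov, n_cov >= 1)
    else:
        report.add("SP6", "footprint covers a diagnostic position", None, None)

    if library is not None:
        score = false_priming_score(
            p, library, intended=footprint,
            target=target or None, species_of=species_of,
        )
        report.add("SP7", "false-priming score < 100", round(score, 1),
                   score < config.false_priming_limit)
    else:
        report.add("SP7", "false-priming score < 100", None, None)

    tm = thermo.tm_nn(p, params=params)
    tlo, thi = config.tm_window
    report.add("SP8", f"Tm in [{tlo:g},{thi:g}] C", round(tm, 1), tlo <= tm <= thi)
    return report


def transfer_coordinates(p: PrimerRecord, ref: PrimerRecord) -> PrimerRecord:
    """Infer declared coordinates for ``p`` from an exact substring match
    inside a coordinate-bearing reference primer of the same orientation.

    Useful when one assay's oligo is a truncation of another's (e.g. a qPCR
    primer nested in an endpoint primer): the reference's plus-strand
    footprint fixes where the substring sits on the template.
    """
    if ref.footprint is None:
        raise DesignError(f"reference primer {ref.name!r} has no coordinates")
    k = ref.sequence.find(p.sequence)
    if k < 0:
        raise DesignError(f"{p.name!r} is not a substring of {ref.name!r}")
    if ref.orientation == "forward":
        start = ref.declared_start + k
    else:
        # a reverse primer's 5' end sits at the plus-strand END of its footprint
        start = ref.declared_start + (len(ref.sequence) - k - len(p.sequence))
    return PrimerRecord(
        name=p.name, sequence=p.sequence, orientation=ref.orientation,
        declared_start=start, declared_length=len(p.sequence),
        declared_tm=p.declared_tm, declared_product=p.declared_product,
    )


def product_length(forward: PrimerRecord, reverse: PrimerRecord) -> int:
    """Amplicon length from name-declared coordinates:
    ``rev_start + rev_len - fwd_start`` (1-based inclusive convention)."""
    if forward.declared_start is None or reverse.declared_start is None:
        raise DesignError(
            f"pair {forward.name}/{reverse.name}: missing declared coordinates"
        )
    return reverse.declared_start + len(reverse.sequence) - forward.declared_start


def pair_primers(
    forwards: Sequence[PrimerRecord],
    reverses: Sequence[PrimerRecord],
    config: DesignConfig = DEFAULT_CONFIG,
    params: Optional[thermo.ThermoParams] = None,
) -> list[CandidatePair]:
    """All coordinate-compatible pairs within the product and Tm windows,
    sorted by (criteria passed, |Tm difference|)."""
    pairs: list[CandidatePair] = []
    for f, r in itertools.product(forwards, reverses):
        if f.declared_start is None or r.declared_start is None:
            continue
        if not f.declared_start < r.declared_start:
            continue
        length = product_length(f, r)
        lo, hi = config.product_range
        if not lo <= length <= hi:
            continue
        tm_diff = abs(thermo.tm_nn(f, params) - thermo.tm_nn(r, params))
        if tm_diff > config.max_tm_diff:
            continue
        pairs.append(CandidatePair(
            forward=f, reverse=r,
            target_species=f.species if f.species == r.species else None,
            product_length=length, tm_difference=tm_diff,
        ))

    def _key(cp: CandidatePair):
        n = sum(r.n_passed for r in (cp.forward_report, cp.reverse_report) if r)
        return (-n, cp.tm_difference)

    pairs.sort(key=_key)
    return pairs


# ---------------------------------------------------------------------------
# TaqMan probe criteria (PR1-PR7)
# ---------------------------------------------------------------------------

def _has_run(seq: str, base: str, n: int = 4) -> bool:
    return base * n in seq


def evaluate_probe(
    pr: ProbeRecord,
    forward: Optional[PrimerRecord] = None,
    reverse: Optional[PrimerRecord] = None,
    probe_gap: Optional[int] = None,
    config: DesignConfig = DEFAULT_CONFIG,
    params: Optional[thermo.ThermoParams] = None,
) -> CriterionReport:
    """Evaluate a hydrolysis probe against the seven probe rules.

    ``probe_gap`` is the distance in nt from the forward primer's 3' end to
    the probe's 5' end; PR6 is skipped when it is unknown.  PR7 is skipped
    when no primers are given.
    """
    report = CriterionReport(subject=pr.name)
    seq = pr.sequence
    lo, hi = config.primer_length
    report.add("PR1", f"length in [{lo},{hi}]", len(seq), lo <= len(seq) <= hi)

    c, g = seq.count("C"), seq.count("G")
    report.add("PR2", "C count >= G count (else use reverse complement)",
               f"C={c},G={g}", c >= g)

    gc = thermo.gc_content(seq)
    glo, ghi = config.probe_gc_range
    report.add("PR3", f"GC% in [{glo:g},{ghi:g}]", round(gc, 1), glo <= gc <= ghi)

    report.add("PR4", "no G at the 5' end (reporter quenching)",
               seq[0], seq[0] != "G")

    runs = [b for b in "ACGT" if _has_run(seq, b)]
    # only a G-quadruplet is a hard failure; other 4-runs are soft warnings
    report.add("PR5", "no GGGG run", ",".join(runs) or "none",
               not _has_run(seq, "G"), hard=True)
    if runs and "G" not in runs:
        report.add("PR5w", "4-base run of A/C/T (soft warning)",
                   ",".join(runs), False, hard=False)

    if probe_gap is not None:
        report.add("PR6", f"probe within {config.probe_max_gap} nt of forward primer",
                   probe_gap, 0 <= probe_gap <= config.probe_max_gap)
    else:
        report.add("PR6", f"probe within {config.probe_max_gap} nt of forward primer",
                   None, None)

    if forward is not None or reverse is not None:
        worst = 0.0
        for primer in (forward, reverse):
            if primer is not None:
                worst = min(worst, thermo.worst_structure_dg(pr, primer, params=params,
                                                             min_stem=config.min_stem))
        report.add("PR7", f"no probe/primer structure with |dG| >= {config.dg_limit}",
                   round(worst, 2), abs(worst) < config.dg_limit)
    else:
        report.add("PR7", f"no probe/primer structure with |dG| >= {config.dg_limit}",
                   None, None)
    return report


# ---------------------------------------------------------------------------
# qPCR primer-pair criteria (QP1-QP6)
# ---------------------------------------------------------------------------

def evaluate_qpcr_pair(
    f: PrimerRecord,
    r: PrimerRecord,
    config: DesignConfig = DEFAULT_CONFIG,
    params: Optional[thermo.ThermoParams] = None,
) -> CriterionReport:
    """Evaluate a qPCR primer pair against the six real-time rules."""
    report = CriterionReport(subject=f"{f.name}/{r.name}")
    lo, hi = config.primer_length
    diff = abs(len(f) - len(r))
    report.add(
        "QP1",
        f"length difference <= {config.qpcr_max_len_diff}, each in [{lo},{hi}]",
        f"{len(f)}/{len(r)}",
        diff <= config.qpcr_max_len_diff and all(lo <= len(p) <= hi for p in (f, r)),
    )
    glo, ghi = config.qpcr_gc_range
    gcs = (thermo.gc_content(f), thermo.gc_content(r))
    report.add("QP2", f"GC% in [{glo:g},{ghi:g}]",
               f"{gcs[0]:.1f}/{gcs[1]:.1f}", all(glo <= gc <= ghi for gc in gcs))
    ends = (f.sequence[-1], r.sequence[-1])
    report.add("QP3", "no A as the 3'-terminal base", "/".join(ends),
               all(e != "A" for e in ends))
    runs = [p.name for p in (f, r) if _has_run(p.sequence, "G")]
    report.add("QP4", "no GGGG run", ",".join(runs) or "none", not runs)
    tails = (f.sequence[-3:], r.sequence[-3:])
    gc_tails = [t for t in tails if all(b in "GC" for b in t)]
    report.add("QP5", "3' end does not close with three G/C", "/".join(tails),
               not gc_tails)
    worst = thermo.worst_structure_dg(f, r, params=params, min_stem=config.min_stem)
    report.add("QP6", f"no cross-dimer with |dG| >= {config.dg_limit}",
               round(worst, 2), abs(worst) < config.dg_limit)
    return report


# ---------------------------------------------------------------------------
# End-to-end assay design
# ---------------------------------------------------------------------------

def _consensus(records: list) -> str:
    """Strict consensus of the target species; N where not fixed."""
    length = len(records[0].sequence)
    out = []
    for i in range(length):
        bases = {r.sequence[i] for r in records}
        out.append(bases.pop() if len(bases) == 1 else "N")
    return "".join(out)


def _enumerate_primers(
    template: str,
    diag: list[tuple[int, str]],
    orientation: str,
    target_tag: str,
    config: DesignConfig,
) -> list[PrimerRecord]:
    """Candidate primers whose 3'-terminal base is a diagnostic position."""
    out: list[tuple[int, PrimerRecord]] = []
    lo, hi = config.primer_length
    # anchor forward candidates from the 5' end but reverse candidates from
    # the 3' end, so capped candidate lists still span long products
    if orientation == "reverse":
        diag = list(reversed(diag))
    for pos, _base in diag:
        for length in range(lo, hi + 1):
            if orientation == "forward":
                start, end = pos - length + 1, pos
            else:
                start, end = pos, pos + length - 1
            if start < 1 or end > len(template):
                continue
            window = template[start - 1:end]
            if any(c not in _UNAMBIGUOUS for c in window):
                continue
            seq = window if orientation == "forward" else reverse_complement(window)
            name = f"{target_tag}{start}{'F' if orientation == 'forward' else 'R'}{length}"
            out.append((pos, PrimerRecord(name=name, sequence=seq, orientation=orientation)))
    return out


def design_assay(
    aln: Alignment,
    species_of: Optional[Mapping[str, str]] = None,
    target: str = "",
    mode: str = "endpoint",
    config: DesignConfig = DEFAULT_CONFIG,
    params: Optional[thermo.ThermoParams] = None,
    max_candidates_per_side: int = 40,
) -> list:
    """Design species-specific assays for ``target`` against the library.

    Enumerates primer windows ending on diagnostic positions, evaluates every
    candidate against SP1-SP8, pairs passing candidates within the product
    and Tm windows, and in ``taqman`` mode places a probe between the
    primers, preferring the strand with more C than G and a 5' base other
    than G.  Returns ranked :class:`CandidatePair` or :class:`TaqManSet`
    objects whose reports all pass; an empty list is a valid outcome.
    """
    species_of = species_of if species_of is not None else aln.species_map()
    if mode not in ("endpoint", "taqman"):
        raise DesignError(f"unknown design mode {mode!r}")
    target_rows = [r for r in aln if species_of.get(r.id, r.species) == target]
    if not target_rows:
        raise DesignError(f"target species {target!r} absent from alignment")
    if len({species_of.get(r.id, r.species) for r in aln}) < 2:
        raise DesignError("library must contain at least one non-target species")
    diag = diagnostic_positions(aln, species_of, target)
    if not diag:
        return []
    template = _consensus(target_rows)
    tag = "".join(w[0] for w in target.replace("_", " ").split())[:3] or "sp"

    all_candidates = {
        orientation: _enumerate_primers(template, diag, orientation, tag, config)
        for orientation in ("forward", "reverse")
    }

    def _evaluate_side(orientation: str, cap: Optional[int]) -> list:
        evaluated = []
        per_site: dict[int, int] = {}
        seen: set[str] = set()
        for site, p in all_candidates[orientation]:
            if p.name in seen:
                continue
            if per_site.get(site, 0) >= 2:   # at most 2 oligos per anchor site
                continue
            seen.add(p.name)
            report = evaluate_primer(
                p, library=aln, species_of=species_of, target=target,
                template=template, config=config, params=params,
            )
            if report.overall:
                evaluated.append((p, report))
                per_site[site] = per_site.get(site, 0) + 1
            if cap is not None and len(evaluated) >= cap:
                break
        return evaluated

    def _paired(candidates: dict) -> list[CandidatePair]:
        reports = {p.name: rep for side in candidates.values() for p, rep in side}
        paired = pair_primers(
            [p for p, _ in candidates["forward"]],
            [p for p, _ in candidates["reverse"]],
            config=config, params=params,
        )
        for cp in paired:
            cp.forward_report = reports[cp.forward.name]
            cp.reverse_report = reports[cp.reverse.name]
            cp.target_species = target
        return [cp for cp in paired if cp.overall]

    candidates = {
        o: _evaluate_side(o, max_candidates_per_side) for o in ("forward", "reverse")
    }
    pairs = _paired(candidates)
    if not pairs:
        # capped, end-anchored candidate lists can miss the product window;
        # fall back to evaluating every enumerated candidate
        candidates = {o: _evaluate_side(o, None) for o in ("forward", "reverse")}
        pairs = _paired(candidates)
    if mode == "endpoint":
        return pairs

    sets: list[TaqManSet] = []
    for cp in pairs:
        qp_report = evaluate_qpcr_pair(cp.forward, cp.reverse, config=config, params=params)
        if not qp_report.overall:
            continue
        placed = _place_probe(cp, template, config, params)
        if placed is None:
            continue
        probe, gap, probe_report = placed
        sets.append(TaqManSet(
            forward=cp.forward, reverse=cp.reverse, probe=probe,
            target_species=target, product_length=cp.product_length,
            probe_gap=gap, pair_report=qp_report, probe_report=probe_report,
        ))
    return sets


def _place_probe(
    cp: CandidatePair,
    template: str,
    config: DesignConfig,
    params: Optional[thermo.ThermoParams],
) -> Optional[tuple[ProbeRecord, int, CriterionReport]]:
    """Best probe window strictly between the primers, nearest to the forward
    primer first; None when no window passes PR1-PR7."""
    f_start, f_end = map_primer(cp.forward, template)
    r_start, _ = map_primer(cp.reverse, template)
    lo, hi = config.primer_length
    for gap in range(0, config.probe_max_gap + 1):
        start = f_end + 1 + gap
        for length in range(lo, hi + 1):
            end = start + length - 1
            if end >= r_start:
                break
            window = template[start - 1:end]
            if any(c not in _UNAMBIGUOUS for c in window):
                continue
            # prefer the strand with C >= G; try the plus strand first
            for seq in (window, reverse_complement(window)):
                probe = ProbeRecord(name=f"{cp.forward.name}_probe", sequence=seq)
                report = evaluate_probe(
                    probe, forward=cp.forward, reverse=cp.reverse,
                    probe_gap=gap, config=config, params=params,
                )
                if report.overall:
                    return probe, gap, report
    return None


def designs_to_tsv(designs: Sequence[Union[CandidatePair, TaqManSet]]) -> str:
    """Export designs in the published table layout
    (name, sequence, bp, Tm, product length)."""
    lines = ["name\tsequence\tbp\ttm\tproduct"]
    for d in designs:
        rows = [(d.forward, d.product_length), (d.reverse, None)]
        for oligo, product in rows:
            tm = thermo.tm_nn(oligo)
            lines.append(
                f"{oligo.name}\t{oligo.sequence}\t{len(oligo)}\t{tm:.1f}"
                f"\t{product if product is not None else ''}"
            )
        if isinstance(d, TaqManSet):
            lines.append(
                f"{d.probe.name}\t{d.probe.reporter}-{d.probe.sequence}-{d.probe.quencher}"
                f"\t{len(d.probe)}\t\t"
            )
    return "\n".join(lines) + "\n"
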