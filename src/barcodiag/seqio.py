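"""Sequence and oligo-table input/output.

Defines the toolkit's core containers (:class:`SeqRecord`, :class:`Alignment`,
:class:`PrimerRecord`, :class:`ProbeRecord`), FASTA reading/writing with a
species-label convention, tab-separated primer/probe tables in the published
layout (name, sequence, length, Tm, product), and the packaged reference
oligo sets for the six stored-product *Tribolium* flour-beetle species.

Coordinate convention used throughout the package: 1-based, inclusive, on the
plus strand of the reference barcode.  A primer name following the encoding
``<prefix><start><F|R><length>`` (e.g. ``Tde25F20``) declares the plus-strand
start of its binding footprint and its own length, so the product length of a
pair is ``rev_start + rev_len - fwd_start``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Optional, Union

from Bio import SeqIO as _BioSeqIO

from .errors import (
    AlignmentError,
    DuplicateIdError,
    EmptyInputError,
    InvalidSequenceError,
    OligoTableError,
)

#: IUPAC DNA alphabet: the four bases, ambiguity codes, and the gap character.
IUPAC_DNA = set("ACGTRYSWKMBDHVN-")

#: Map from IUPAC code to the set of unambiguous bases it stands for.
IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

#: Universal COI barcoding primers (Folmer set) used to amplify the 658-bp
#: barcode region; exposed as metadata for in-silico screens.
UNIVERSAL_PRIMERS = {
    "LCO1490": "GGTCAACAAATCATAAAGATATTGG",
    "HCO2198": "TAAACTTCAGGGTGACCAAAAAATCA",
}

_NAME_ENCODING = re.compile(r"^(?P<prefix>[A-Za-z]+?)(?P<start>\d+)(?P<ori>[FR])(?P<len>\d+)$")
_PROBE_SEQ = re.compile(r"^(?P<reporter>[A-Za-z0-9]+)-(?P<seq>[ACGTacgt]+)-(?P<quencher>[A-Za-z0-9]+)$")

#: Oligo-name prefix -> species, for the packaged reference sets.
SPECIES_PREFIXES = {
    "Tde": "T_destructor",
    "Tbr": "T_brevicornis",
    "Tma": "T_madens",
    "Tfr": "T_freemani",
    "Tca": "T_castaneum",
    "Tco": "T_confusum",
    "To": "T_confusum",  # the published confusum probe is named "ToP"
}


@dataclass
class SeqRecord:
    """A labelled DNA sequence.

    Parameters
    ----------
    id:
        Unique identifier within a collection.
    species:
        Species label; may be empty for classification queries.
    sequence:
        Uppercase IUPAC DNA, ``-`` allowed for alignment gaps.
    """

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InvalidSequenceError("record id must be non-empty")
        if not self.sequence:
            raise InvalidSequenceError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise InvalidSequenceError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class Alignment:
    """An ordered collection of equal-length :class:`SeqRecord` objects."""

    def __init__(self, records: Iterable[SeqRecord]):
        self.records = list(records)
        if not self.records:
            raise EmptyInputError("alignment requires at least one record")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"records have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DuplicateIdError(f"duplicate record ids: {sorted(dupes)}")
        self.length = lengths.pop()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> SeqRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def species_map(self) -> dict[str, str]:
        """id -> species for every record carrying a label."""
        return {r.id: r.species for r in self.records}

    def column(self, pos: int) -> str:
        """Alignment column at 1-based position ``pos``, pooled over records."""
        if not 1 <= pos <= self.length:
            raise AlignmentError(f"column {pos} outside 1..{self.length}")
        return "".join(r.sequence[pos - 1] for r in self.records)


@dataclass
class PrimerRecord:
    """A PCR primer, written 5'->3'.

    ``declared_*`` fields mirror a published table row; ``declared_start`` /
    ``declared_length`` also parse automatically from names following the
    ``<prefix><start><F|R><length>`` encoding.
    """

    name: str
    sequence: str
    orientation: str = "forward"
    declared_start: Optional[int] = None
    declared_length: Optional[int] = None
    declared_tm: Optional[float] = None
    declared_product: Optional[int] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - (IUPAC_DNA - {"-"})
        if bad:
            raise InvalidSequenceError(f"primer {self.name!r}: bad characters {sorted(bad)}")
        m = _NAME_ENCODING.match(self.name)
        if m:
            self.orientation = "forward" if m.group("ori") == "F" else "reverse"
            enc_len = int(m.group("len"))
            if enc_len != len(self.sequence):
                raise OligoTableError(
                    f"primer {self.name!r}: name encodes length {enc_len} "
                    f"but sequence has {len(self.sequence)} nt"
                )
            self.declared_start = int(m.group("start"))
            self.declared_length = enc_len
        if self.orientation not in ("forward", "reverse"):
            raise OligoTableError(f"primer {self.name!r}: bad orientation {self.orientation!r}")
        if self.declared_length is not None and self.declared_length != len(self.sequence):
            raise OligoTableError(
                f"primer {self.name!r}: declared length {self.declared_length} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def species(self) -> Optional[str]:
        for prefix, sp in SPECIES_PREFIXES.items():
            if self.name.startswith(prefix):
                return sp
        return None

    @property
    def footprint(self) -> Optional[tuple[int, int]]:
        """(start, end) plus-strand 1-based inclusive binding coordinates."""
        if self.declared_start is None:
            return None
        return self.declared_start, self.declared_start + len(self.sequence) - 1


@dataclass
class ProbeRecord:
    """A dual-labelled hydrolysis (TaqMan) probe, written 5'->3'."""

    name: str
    sequence: str
    reporter: str = "FAM"
    quencher: str = "BHQ"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise InvalidSequenceError(f"probe {self.name!r}: bad characters {sorted(bad)}")
        if not self.reporter or not self.quencher:
            raise OligoTableError(f"probe {self.name!r}: reporter/quencher must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def species(self) -> Optional[str]:
        for prefix, sp in SPECIES_PREFIXES.items():
            if self.name.startswith(prefix):
                return sp
        return None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_header(record_id: str, description: str) -> tuple[str, str]:
    """Split a FASTA header into (id, species).

    Two conventions are accepted: ``>id species=<label>`` and ``>id|<label>``.
    A header with neither yields an empty species label.
    """
    if "|" in record_id:
        rid, _, species = record_id.partition("|")
        return rid, species
    m = re.search(r"species=(\S+)", description)
    return record_id, m.group(1) if m else ""


def read_fasta(source: Union[str, Path, IO[str]]) -> list[SeqRecord]:
    """Read labelled barcode sequences from FASTA.

    Sequences are uppercased; gap characters are retained.  Raises a named
    error for an empty file, duplicate ids, or non-IUPAC characters (the
    message names the offending record).
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(source, "fasta"):
        rid, species = _parse_header(rec.id, rec.description)
        if rid in seen:
            raise DuplicateIdError(f"duplicate record id {rid!r}")
        seen.add(rid)
        records.append(SeqRecord(id=rid, species=species, sequence=str(rec.seq)))
    if not records:
        raise EmptyInputError("no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], dest: Union[str, Path, IO[str]]) -> None:
    """Write records as FASTA with ``species=`` labels (round-trips read_fasta)."""
    def _dump(handle: IO[str]) -> None:
        for r in records:
            header = f">{r.id} species={r.species}" if r.species else f">{r.id}"
            handle.write(header + "\n")
            for i in range(0, len(r.sequence), 70):
                handle.write(r.sequence[i:i + 70] + "\n")

    if hasattr(dest, "write"):
        _dump(dest)  # type: ignore[arg-type]
    else:
        with open(dest, "w") as fh:
            _dump(fh)


def read_alignment(source: Union[str, Path, IO[str]]) -> Alignment:
    """Read a FASTA file that must form an alignment (equal lengths)."""
    return Alignment(read_fasta(source))


# ---------------------------------------------------------------------------
# Oligo tables
# ---------------------------------------------------------------------------

def _parse_oligo_row(fields: list[str], lineno: int):
    if len(fields) < 4:
        raise OligoTableError(f"line {lineno}: expected >=4 tab-separated fields")
    name, seq, length_s, tm_s = fields[:4]
    product_s = fields[4] if len(fields) > 4 and fields[4].strip() else None
    try:
        declared_len = int(length_s)
    except ValueError as exc:
        raise OligoTableError(f"line {lineno} ({name}): bad length {length_s!r}") from exc
    tm = float(tm_s) if tm_s.strip() else None
    product = int(product_s) if product_s else None

    probe_match = _PROBE_SEQ.match(seq)
    if probe_match:
        probe = ProbeRecord(
            name=name,
            sequence=probe_match.group("seq"),
            reporter=probe_match.group("reporter"),
            quencher=probe_match.group("quencher"),
        )
        if declared_len != len(probe.sequence):
            raise OligoTableError(
                f"line {lineno} ({name}): declared length {declared_len} "
                f"!= sequence length {len(probe.sequence)}"
            )
        return probe
    orientation = "reverse" if name.rstrip("0123456789").endswith("R") else "forward"
    if declared_len != len(seq):
        raise OligoTableError(
            f"line {lineno} ({name}): declared length {declared_len} "
            f"!= sequence length {len(seq)}"
        )
    return PrimerRecord(
        name=name,
        sequence=seq,
        orientation=orientation,
        declared_length=declared_len,
        declared_tm=tm,
        declared_product=product,
    )


def read_oligo_table(path: Union[str, Path, IO[str]]) -> list[Union[PrimerRecord, ProbeRecord]]:
    """Read a tab-separated oligo table in the published layout.

    Columns: name, sequence (5'->3'), length, Tm, [product length].  Probe rows
    are recognised by a ``REPORTER-SEQUENCE-QUENCHER`` sequence field.  A header
    line is detected and skipped.  Rows whose declared length disagrees with
    the sequence raise :class:`OligoTableError`.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()  # type: ignore[union-attr]
    else:
        lines = Path(path).read_text().splitlines()
    oligos = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if lineno == 1 and fields[0].strip().lower() == "name":
            continue
        oligos.append(_parse_oligo_row(fields, lineno))
    if not oligos:
        raise EmptyInputError("oligo table contains no rows")
    return oligos


def write_oligo_table(oligos: Iterable[Union[PrimerRecord, ProbeRecord]],
                      dest: Union[str, Path, IO[str]]) -> None:
    """Write oligos in the same tab-separated layout read_oligo_table reads."""
    rows = ["name\tsequence\tbp\ttm\tproduct"]
    for o in oligos:
        if isinstance(o, ProbeRecord):
            seq = f"{o.reporter}-{o.sequence}-{o.quencher}"
            tm = ""
            product = ""
        else:
            seq = o.sequence
            tm = "" if o.declared_tm is None else f"{o.declared_tm:g}"
            product = "" if o.declared_product is None else str(o.declared_product)
        rows.append(f"{o.name}\t{seq}\t{len(o.sequence)}\t{tm}\t{product}")
    text = "\n".join(rows) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)  # type: ignore[union-attr]
    else:
        Path(dest).write_text(text)


def _packaged_table(filename: str):
    ref = resources.files("barcodiag").joinpath("data", filename)
    with ref.open("r") as fh:
        return read_oligo_table(fh)


def reference_specific_primers() -> list[PrimerRecord]:
    """The six published species-specific endpoint-PCR primer pairs (12 primers).

    Names encode plus-strand binding coordinates on the 658-bp barcode
    (e.g. ``Tde25F20`` binds 25-44).
    """
    return _packaged_table("specific_primers.tsv")  # type: ignore[return-value]


def reference_taqman_sets() -> list[Union[PrimerRecord, ProbeRecord]]:
    """The six published TaqMan sets: 12 qPCR primers and 6 probes (FAM/BHQ)."""
    return _packaged_table("taqman_sets.tsv")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    comp = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")
    return seq.upper().translate(comp)[::-1]
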