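"""Kimura 2-parameter distances and barcode-library divergence statistics.

The K2P model distinguishes transitions (A<->G, C<->T; proportion ``P`` of
compared sites) from transversions (proportion ``Q``) and estimates the
substitutions-per-site distance

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Sites where either sequence carries a gap or an ambiguity code are excluded
pairwise (MEGA-style pairwise deletion; complete deletion available via a
flag).  When a log argument is non-positive the pair is flagged *saturated*
and reported as a missing value rather than raising, so heavily diverged user
data degrades gracefully.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import DistanceError
from .seqio import Alignment, SeqRecord

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_UNAMBIGUOUS = frozenset("ACGT")


@dataclass
class K2PResult:
    """Outcome of a single pairwise K2P comparison.

    ``P``/``Q`` are transition/transversion proportions over the ``n_sites``
    compared sites; ``d`` is in substitutions/site and is ``nan`` when the
    estimate is saturated.
    """

    P: float
    Q: float
    n_sites: int
    d: float
    saturated: bool = False


def _as_seq(x: Union[SeqRecord, str]) -> str:
    return x.sequence if isinstance(x, SeqRecord) else x.upper()


def k2p_distance(a: Union[SeqRecord, str], b: Union[SeqRecord, str]) -> K2PResult:
    """K2P distance between two aligned sequences (pairwise deletion).

    Raises :class:`DistanceError` on unequal lengths or when no site is
    comparable after excluding gaps/ambiguities.
    """
    sa, sb = _as_seq(a), _as_seq(b)
    if len(sa) != len(sb):
        raise DistanceError(f"unequal sequence lengths {len(sa)} != {len(sb)}")
    n = ts = tv = 0
    for ca, cb in zip(sa, sb):
        if ca not in _UNAMBIGUOUS or cb not in _UNAMBIGUOUS:
            continue
        n += 1
        if ca == cb:
            continue
        if (ca in PURINES) == (cb in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise DistanceError("no comparable sites after excluding gaps/ambiguities")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(P=P, Q=Q, n_sites=n, d=float("nan"), saturated=True)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P=P, Q=Q, n_sites=n, d=d, saturated=False)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels.

    Saturated pairs are stored as ``nan``.  ``values`` has a zero diagonal.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DistanceError(f"matrix shape {self.values.shape} != ({n}, {n})")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError as exc:
            raise DistanceError(f"unknown label {label!r}") from exc

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) values, row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels), values=self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        """PHYLIP square distance format (labels padded to >=10 characters)."""
        lines = [f"    {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            cells = "  ".join(f"{v:.6f}" for v in row)
            lines.append(f"{lab:<10}  {cells}")
        return "\n".join(lines) + "\n"

    def to_tsv(self) -> str:
        return self.to_dataframe().to_csv(sep="\t", float_format="%.6f")


def pairwise_matrix(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """All-pairs K2P matrix.

    ``deletion="complete"`` first drops every column containing a gap or
    ambiguity in any record; ``"pairwise"`` (default) excludes such sites per
    pair.  Saturated pairs become ``nan`` with a warning naming the pair.
    """
    if len(aln) < 2:
        raise DistanceError("need at least 2 records for a distance matrix")
    records = aln.records
    if deletion == "complete":
        keep = [
            i for i in range(aln.length)
            if all(r.sequence[i] in _UNAMBIGUOUS for r in records)
        ]
        seqs = ["".join(r.sequence[i] for i in keep) for r in records]
        if not keep:
            raise DistanceError("complete deletion removed all columns")
    elif deletion == "pairwise":
        seqs = [r.sequence for r in records]
    else:
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = len(records)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = k2p_distance(seqs[i], seqs[j])
            if res.saturated:
                warnings.warn(
                    f"saturated K2P distance for pair ({records[i].id}, {records[j].id});"
                    " recorded as missing"
                )
            values[i, j] = values[j, i] = res.d
    return DistanceMatrix(labels=[r.id for r in records], values=values)


# ---------------------------------------------------------------------------
# Divergence summary
# ---------------------------------------------------------------------------

@dataclass
class _Stats:
    average: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None


def _stats(vals: list[float]) -> _Stats:
    vals = [v for v in vals if not math.isnan(v)]
    if not vals:
        return _Stats()
    return _Stats(average=float(np.mean(vals)), min=float(np.min(vals)), max=float(np.max(vals)))


@dataclass
class DivergenceSummary:
    """Per-species intra/inter divergence statistics, in percent.

    ``intra[sp]`` is empty (all ``None``) for single-sequence species.  The
    ``overall`` pair pools all within-species and all between-species values.
    """

    intra: dict[str, _Stats] = field(default_factory=dict)
    inter: dict[str, _Stats] = field(default_factory=dict)
    overall_intra: _Stats = field(default_factory=_Stats)
    overall_inter: _Stats = field(default_factory=_Stats)

    def to_dataframe(self) -> pd.DataFrame:
        rows = {}
        for sp in self.intra:
            i, e = self.intra[sp], self.inter[sp]
            rows[sp] = [i.average, i.min, i.max, e.average, e.min, e.max]
        oi, oe = self.overall_intra, self.overall_inter
        rows["All"] = [oi.average, oi.min, oi.max, oe.average, oe.min, oe.max]
        return pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["intra_avg", "intra_min", "intra_max",
                     "inter_avg", "inter_min", "inter_max"],
        )

    def to_tsv(self) -> str:
        df = self.to_dataframe().round(2)
        return df.to_csv(sep="\t")


def divergence_summary(m: DistanceMatrix, species_of: Mapping[str, str]) -> DivergenceSummary:
    """Intra/inter-specific divergence table (percent) from a K2P matrix.

    Every matrix label must have a species.  Saturated (missing) pairs are
    skipped with a warning.
    """
    for lab in m.labels:
        if lab not in species_of or not species_of[lab]:
            raise DistanceError(f"label {lab!r} has no species assignment")
    species = sorted({species_of[l] for l in m.labels})
    intra_vals: dict[str, list[float]] = {sp: [] for sp in species}
    inter_vals: dict[str, list[float]] = {sp: [] for sp in species}
    n_nan = 0
    for i in range(len(m.labels)):
        for j in range(i + 1, len(m.labels)):
            d = m.values[i, j]
            if math.isnan(d):
                n_nan += 1
                continue
            pct = 100.0 * d
            si, sj = species_of[m.labels[i]], species_of[m.labels[j]]
            if si == sj:
                intra_vals[si].append(pct)
            else:
                inter_vals[si].append(pct)
                inter_vals[sj].append(pct)
    if n_nan:
        warnings.warn(f"{n_nan} saturated pair(s) skipped in divergence summary")
    summary = DivergenceSummary()
    all_intra: list[float] = []
    all_inter: list[float] = []
    for sp in species:
        summary.intra[sp] = _stats(intra_vals[sp])
        summary.inter[sp] = _stats(inter_vals[sp])
        all_intra.extend(intra_vals[sp])
    # pooled inter values: each unordered between-species pair once
    for i in range(len(m.labels)):
        for j in range(i + 1, len(m.labels)):
            d = m.values[i, j]
            if math.isnan(d):
                continue
            if species_of[m.labels[i]] != species_of[m.labels[j]]:
                all_inter.append(100.0 * d)
    summary.overall_intra = _stats(all_intra)
    summary.overall_inter = _stats(all_inter)
    return summary


def base_composition(aln: Alignment) -> dict[str, float]:
    """Percent A/C/G/T (and A+T) pooled over all unambiguous, non-gap sites."""
    counts = {b: 0 for b in "ACGT"}
    for rec in aln:
        for c in rec.sequence:
            if c in counts:
                counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise DistanceError("alignment contains no unambiguous bases")
    pct = {b: 100.0 * counts[b] / total for b in "ACGT"}
    pct["AT"] = pct["A"] + pct["T"]
    return pct


# ---------------------------------------------------------------------------
# Nearest-neighbour classification
# ---------------------------------------------------------------------------

@dataclass
class Classification:
    """Result of classifying a query against a barcode library."""

    species: str                      # assigned species, "ambiguous" or "no-match"
    best_distance: float              # substitutions/site to the nearest record
    best_id: str
    runner_up_species: Optional[str] = None
    runner_up_distance: Optional[float] = None


def classify_query(
    q: Union[SeqRecord, str],
    library: Alignment,
    species_of: Optional[Mapping[str, str]] = None,
    threshold_pct: float = 2.0,
    margin_pct: float = 0.1,
) -> Classification:
    """Nearest-neighbour species assignment with a distance threshold.

    The query is assigned its nearest record's species when the best distance
    is at most ``threshold_pct`` percent; "ambiguous" when a second species
    lies within ``margin_pct`` (absolute percent) of the best; "no-match"
    otherwise.  The 2% default reflects the common barcode practice of a
    threshold roughly an order of magnitude above mean intraspecific
    divergence.
    """
    species_of = species_of if species_of is not None else library.species_map()
    qs = _as_seq(q)
    if len(qs) != library.length:
        raise DistanceError(
            f"query length {len(qs)} != library alignment length {library.length}"
        )
    best: dict[str, tuple[float, str]] = {}
    for rec in library:
        res = k2p_distance(qs, rec.sequence)
        # a saturated estimate means "far beyond any plausible match"
        d_val = float("inf") if res.saturated else res.d
        sp = species_of.get(rec.id, rec.species)
        if sp not in best or d_val < best[sp][0]:
            best[sp] = (d_val, rec.id)
    if not best:
        raise DistanceError("no comparable library records")
    ranked = sorted(best.items(), key=lambda kv: kv[1][0])
    (sp1, (d1, id1)) = ranked[0]
    runner = ranked[1] if len(ranked) > 1 else None
    result = Classification(
        species=sp1, best_distance=d1, best_id=id1,
        runner_up_species=runner[0] if runner else None,
        runner_up_distance=runner[1][0] if runner else None,
    )
    if 100.0 * d1 > threshold_pct:
        result.species = "no-match"
    elif runner and 100.0 * (runner[1][0] - d1) <= margin_pct:
        result.species = "ambiguous"
    return result
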