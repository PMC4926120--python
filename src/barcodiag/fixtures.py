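"""Synthetic barcode-library simulator with ground truth.

Generates aligned COI-like libraries that emulate the divergence structure of
a stored-product beetle barcode study: a handful of species whose
intraspecific K2P distances stay below about 2% while interspecific
distances sit above 16%, base composition AT-rich (about 61% A+T) as in
insect mitochondrial genes, and species-unique "diagnostic" bases planted in
known windows so primer-design code can be tested against ground truth.

Substitutions are placed by count rather than per-site Bernoulli draws so
the realised divergences are controlled: the distances, not the mutation
process, are the object under test downstream.  Transition:transversion
choice follows a kappa ratio (default 2: a transition is twice as likely as
each class of transversion).  No indels are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .distances import k2p_distance
from .errors import BarcodiagError
from .seqio import Alignment, SeqRecord

#: Ancestral base frequencies: AT-rich, matching insect mitochondrial COI.
BASE_FREQS = {"A": 0.3004, "C": 0.2245, "G": 0.1622, "T": 0.3129}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


@dataclass
class SimSpec:
    """Parameters of one simulated library.

    ``intra`` and ``inter`` are target K2P divergences (proportions):
    conspecific sequences stay at or below ``intra``; between-species
    distances land near ``inter``.  ``n_diag_windows`` windows of
    ``diag_width`` consecutive species-unique bases are planted per species.
    ``seed`` is mandatory for reproducibility.
    """

    n_species: int = 6
    n_per_species: Union[int, Sequence[int]] = 4
    length: int = 658
    intra: float = 0.01
    inter: float = 0.19
    kappa: float = 2.0
    n_diag_windows: int = 2
    diag_width: int = 12
    seed: Optional[int] = None

    def counts(self) -> list[int]:
        if isinstance(self.n_per_species, int):
            return [self.n_per_species] * self.n_species
        counts = list(self.n_per_species)
        if len(counts) != self.n_species:
            raise BarcodiagError("n_per_species length must equal n_species")
        return counts

    def validate(self) -> None:
        if self.seed is None:
            raise BarcodiagError("SimSpec.seed is mandatory")
        if not 0 <= self.intra < self.inter <= 0.75:
            raise BarcodiagError(
                f"need 0 <= intra < inter <= 0.75, got {self.intra}, {self.inter}"
            )
        if self.n_species < 1 or self.length < 1:
            raise BarcodiagError("n_species and length must be positive")
        need = self.n_species * self.n_diag_windows * (self.diag_width + 1)
        if need > self.length:
            raise BarcodiagError(
                f"cannot place {self.n_diag_windows} x {self.diag_width} nt windows "
                f"per species in {self.length} nt"
            )


@dataclass
class SimulatedLibrary:
    """A simulated alignment plus its generating ground truth."""

    alignment: Alignment
    species_of: dict[str, str]
    diagnostic_positions: dict[str, list[int]]   # species -> 1-based columns
    spec: SimSpec

    def species_names(self) -> list[str]:
        return sorted(set(self.species_of.values()))

    def ground_truth_tsv(self) -> str:
        lines = ["id\tspecies"]
        for rec in self.alignment:
            lines.append(f"{rec.id}\t{self.species_of[rec.id]}")
        return "\n".join(lines) + "\n"


def mutate_at_rate(
    seq: str,
    rate: float,
    kappa: float = 2.0,
    rng: Union[int, np.random.Generator, None] = None,
    forbidden: Sequence[int] = (),
) -> str:
    """Mutate ``round(rate * len(seq))`` positions, sampled without
    replacement outside ``forbidden`` (0-based), each changed to a different
    base with transition:transversion odds ``kappa : 1`` (per-target odds
    kappa : 1 : 1)."""
    if not 0 <= rate < 1:
        raise BarcodiagError(f"rate must be in [0, 1), got {rate}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_mut = round(rate * len(seq))
    allowed = [i for i in range(len(seq)) if i not in set(forbidden)]
    if n_mut > len(allowed):
        raise BarcodiagError(
            f"cannot place {n_mut} substitutions in {len(allowed)} available positions"
        )
    positions = rng.choice(len(allowed), size=n_mut, replace=False)
    chars = list(seq)
    for p in positions:
        i = allowed[p]
        base = chars[i]
        targets = [_TRANSITION[base], *_TRANSVERSIONS[base]]
        weights = np.array([kappa, 1.0, 1.0])
        chars[i] = targets[rng.choice(3, p=weights / weights.sum())]
    return "".join(chars)


def _random_ancestor(length: int, rng: np.random.Generator) -> str:
    bases = list(BASE_FREQS)
    probs = np.array([BASE_FREQS[b] for b in bases])
    return "".join(rng.choice(bases, size=length, p=probs))


def simulate_library(spec: SimSpec) -> SimulatedLibrary:
    """Simulate an aligned library under ``spec``; deterministic per seed.

    One random AT-rich ancestor is mutated into per-species founders at half
    the interspecific target each (pairwise founder divergence then lands
    near the target); species-unique bases are planted in reserved diagnostic
    windows; individuals receive intraspecific-level substitutions avoiding
    planted sites.  Realised divergences are checked against the targets
    (within about 20%) and the library is resampled up to 10 times before
    raising.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    last_err = None
    for _attempt in range(10):
        try:
            return _simulate_once(spec, rng)
        except BarcodiagError as err:     # realised divergence off target
            last_err = err
    raise BarcodiagError(f"simulation failed after 10 attempts: {last_err}")


def _simulate_once(spec: SimSpec, rng: np.random.Generator) -> SimulatedLibrary:
    counts = spec.counts()
    ancestor = _random_ancestor(spec.length, rng)

    # reserve disjoint diagnostic windows, evenly spread over the sequence
    windows: dict[int, list[tuple[int, int]]] = {}
    total_windows = spec.n_species * spec.n_diag_windows
    stride = spec.length // max(total_windows, 1)
    w = 0
    for s in range(spec.n_species):
        windows[s] = []
        for _ in range(spec.n_diag_windows):
            start = w * stride
            windows[s].append((start, start + spec.diag_width))
            w += 1
    planted = {s: [i for a, b in ws for i in range(a, b)] for s, ws in windows.items()}
    all_planted = sorted(i for ws in planted.values() for i in ws)

    # Calibrate the founder mutation rate so pairwise inter-species K2P lands
    # near the target: planted windows already contribute 2*n_diag*width/L
    # differing sites per pair, and the K2P target is first converted to a raw
    # differing fraction (Jukes-Cantor-style multiple-hit inversion), then the
    # per-founder rate r solves 2r - 1.375 r^2 = remaining fraction (the
    # quadratic term accounts for two independent mutations colliding).
    p_target = 0.75 * (1.0 - np.exp(-4.0 * spec.inter / 3.0))
    f_planted = 2.0 * spec.n_diag_windows * spec.diag_width / spec.length
    p_mut = max(p_target - f_planted, 0.0)
    rate = (2.0 - np.sqrt(max(4.0 - 5.5 * p_mut, 0.0))) / 2.75

    founders = []
    for s in range(spec.n_species):
        founder = mutate_at_rate(
            ancestor, rate, spec.kappa, rng, forbidden=all_planted
        )
        founders.append(list(founder))
    # plant species-unique bases: in species s's windows, species s gets a
    # base that every other founder lacks at that column
    for s in range(spec.n_species):
        for i in planted[s]:
            others = {founders[t][i] for t in range(spec.n_species) if t != s}
            choices = [b for b in "ACGT" if b not in others]
            if not choices:       # all four bases taken; force others to agree
                shared = founders[(s + 1) % spec.n_species][i]
                for t in range(spec.n_species):
                    if t != s:
                        founders[t][i] = shared
                choices = [b for b in "ACGT" if b != shared]
            founders[s][i] = choices[rng.integers(len(choices))]

    records = []
    species_of = {}
    for s in range(spec.n_species):
        name = f"sp{s + 1:02d}"
        founder = "".join(founders[s])
        for k in range(counts[s]):
            rate = 0.0 if spec.intra == 0 else float(rng.uniform(0, spec.intra / 2.0))
            seq = mutate_at_rate(founder, rate, spec.kappa, rng, forbidden=all_planted)
            rid = f"{name}_{k + 1:02d}"
            records.append(SeqRecord(id=rid, species=name, sequence=seq))
            species_of[rid] = name

    library = SimulatedLibrary(
        alignment=Alignment(records),
        species_of=species_of,
        diagnostic_positions={
            f"sp{s + 1:02d}": [i + 1 for i in planted[s]] for s in range(spec.n_species)
        },
        spec=spec,
    )
    _check_divergences(library)
    return library


def _check_divergences(lib: SimulatedLibrary) -> None:
    spec = lib.spec
    records = lib.alignment.records
    intra_max = 0.0
    inter_vals = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            d = k2p_distance(records[i], records[j]).d
            if lib.species_of[records[i].id] == lib.species_of[records[j].id]:
                intra_max = max(intra_max, d)
            else:
                inter_vals.append(d)
    if spec.intra > 0 and intra_max > 1.2 * spec.intra:
        raise BarcodiagError(f"realised intra max {intra_max:.4f} exceeds target band")
    if inter_vals:
        lo, hi = min(inter_vals), max(inter_vals)
        if lo < 0.8 * spec.inter or hi > 1.25 * spec.inter:
            raise BarcodiagError(
                f"realised inter range [{lo:.3f}, {hi:.3f}] outside target band "
                f"around {spec.inter}"
            )
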