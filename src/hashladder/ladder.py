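"""Hash-ladder specifications.

A hash ladder is a mixture of polyadenylated single-stranded DNA oligos
("hash species") spiked into a nuclei prep at known, distinct amounts. Each
species carries a unique 10-base barcode at the start of read 2. Because
every nucleus takes up hash molecules roughly in proportion to their
concentration in the mix, the ladder acts as a per-cell internal dilution
standard: comparing observed per-species UMI counts with the expected number
of molecules per nucleus yields a per-cell calibration curve.

This module holds the ladder description itself: species, barcodes, amounts,
and the conversion from spiked amount to expected molecules per nucleus.
Amounts are stored in picomoles; ``expected_molecules_per_cell`` divides the
absolute molecule count in the mix by the number of starting nuclei for the
condition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import edlib
import numpy as np

__all__ = [
    "AVOGADRO",
    "PMOL",
    "FMOL",
    "AMOL",
    "HashSpecies",
    "LadderSpec",
    "make_serial_ladder",
    "expected_molecules_per_cell",
    "random_barcodes",
    "read_ladder_tsv",
    "write_ladder_tsv",
]

AVOGADRO = 6.02214076e23

#: unit multipliers relative to picomoles
PMOL = 1.0
FMOL = 1e-3
AMOL = 1e-6

_BARCODE_LEN = 10
_ALPHABET = "ACGT"

LADDER = "ladder"
SAMPLE_ID = "sample_id"


@dataclass(frozen=True)
class HashSpecies:
    """One hash oligo species.

    Parameters
    ----------
    species_id : str
        Short unique identifier.
    barcode : str
        10-base DNA barcode (the first 10 bp of read 2).
    concentration_pmol : float
        Absolute amount of this species in the spike-in mix for one
        condition, in picomoles. Must be > 0 for ladder-role species.
    role : str
        Either ``"ladder"`` (part of the dilution series) or
        ``"sample_id"`` (marks the condition a nucleus came from).
    """

    species_id: str
    barcode: str
    concentration_pmol: float
    role: str = LADDER

    def __post_init__(self) -> None:
        if len(self.barcode) != _BARCODE_LEN or any(
            b not in _ALPHABET for b in self.barcode
        ):
            raise ValueError(
                f"barcode must be {_BARCODE_LEN} bases over ACGT, got {self.barcode!r}"
            )
        if self.role not in (LADDER, SAMPLE_ID):
            raise ValueError(f"role must be 'ladder' or 'sample_id', got {self.role!r}")
        if self.role == LADDER and not self.concentration_pmol > 0:
            raise ValueError("ladder species need concentration > 0")


@dataclass
class LadderSpec:
    """An ordered collection of hash species plus the cell count they serve.

    ``n_cells_per_condition`` is the number of starting nuclei that share the
    spike mix; expected molecules per nucleus scale inversely with it.
    """

    species: list[HashSpecies]
    n_cells_per_condition: int = 100_000
    description: str = ""

    def __post_init__(self) -> None:
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("species_id values must be unique")
        concs = [s.concentration_pmol for s in self.ladder_species]
        if len(set(concs)) != len(concs):
            raise ValueError("ladder species must have distinct concentrations")
        if self.n_cells_per_condition <= 0:
            raise ValueError("n_cells_per_condition must be positive")

    @property
    def ladder_species(self) -> list[HashSpecies]:
        return [s for s in self.species if s.role == LADDER]

    @property
    def id_species(self) -> list[HashSpecies]:
        return [s for s in self.species if s.role == SAMPLE_ID]

    @property
    def barcode_map(self) -> dict[str, str]:
        """barcode -> species_id over all species."""
        return {s.barcode: s.species_id for s in self.species}

    def with_id_species(self, id_species: list[HashSpecies]) -> "LadderSpec":
        return replace(self, species=list(self.species) + list(id_species))


def _min_pairwise_distance(barcodes: list[str]) -> int:
    best = _BARCODE_LEN
    for i in range(len(barcodes)):
        for j in range(i + 1, len(barcodes)):
            d = edlib.align(barcodes[i], barcodes[j], task="distance")["editDistance"]
            best = min(best, d)
    return best


def random_barcodes(
    n: int,
    seed: int | np.random.Generator,
    min_distance: int = 5,
    max_tries: int = 10_000,
) -> list[str]:
    """Draw ``n`` random 10-mers with pairwise Levenshtein distance >= min_distance.

    Deterministic for a fixed seed. Raises ``RuntimeError`` if the distance
    constraint cannot be met within a bounded number of rejection-sampling
    tries (only plausible for very large ``n`` or ``min_distance``).
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not generate {n} barcodes at pairwise distance "
                f">= {min_distance} in {max_tries} tries"
            )
        cand = "".join(rng.choice(list(_ALPHABET), size=_BARCODE_LEN))
        ok = all(
            edlib.align(cand, b, task="distance")["editDistance"] >= min_distance
            for b in out
        )
        if ok:
            out.append(cand)
    return out


def make_serial_ladder(
    n_species: int,
    base_concentration: float,
    fold: float = 2.0,
    barcodes: list[str] | None = None,
    n_cells_per_condition: int = 100_000,
    seed: int = 0,
    description: str = "",
) -> LadderSpec:
    """Build a geometric (serial-dilution) hash ladder.

    Species ``k`` (k = 0..n_species-1) gets ``base_concentration * fold**k``
    picomoles. An eight-species two-fold ladder at base 0.1 spans
    0.1-12.8 pmol. If ``barcodes`` is omitted, random barcodes with pairwise
    Levenshtein distance >= 5 are generated from ``seed`` so that
    distance-2 matching is unambiguous.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if base_concentration <= 0:
        raise ValueError("base_concentration must be > 0")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if barcodes is None:
        barcodes = random_barcodes(n_species, seed=seed)
    else:
        if len(barcodes) != n_species:
            raise ValueError("barcodes length must equal n_species")
    species = [
        HashSpecies(
            species_id=f"L{k:02d}",
            barcode=barcodes[k],
            concentration_pmol=base_concentration * fold**k,
        )
        for k in range(n_species)
    ]
    return LadderSpec(
        species=species,
        n_cells_per_condition=n_cells_per_condition,
        description=description or f"{n_species}-species {fold:g}-fold serial ladder",
    )


def ladder_from_concentrations(
    concentrations_pmol: list[float],
    barcodes: list[str] | None = None,
    n_cells_per_condition: int = 100_000,
    seed: int = 0,
    description: str = "",
) -> LadderSpec:
    """Build a ladder from an explicit concentration list (need not be geometric)."""
    n = len(concentrations_pmol)
    if barcodes is None:
        barcodes = random_barcodes(n, seed=seed)
    species = [
        HashSpecies(f"L{k:02d}", barcodes[k], concentrations_pmol[k])
        for k in range(n)
    ]
    return LadderSpec(species, n_cells_per_condition, description)


def expected_molecules_per_cell(spec: LadderSpec) -> dict[str, float]:
    """Expected molecule count per nucleus for each ladder species.

    amount (mol) * N_A / n_cells_per_condition — the number of molecules in
    the spike mix divided by the number of starting nuclei.
    """
    if spec.n_cells_per_condition <= 0:
        raise ValueError("n_cells_per_condition must be positive")
    return {
        s.species_id: s.concentration_pmol * 1e-12 * AVOGADRO / spec.n_cells_per_condition
        for s in spec.ladder_species
    }


_TSV_HEADER = ["species_id", "barcode", "concentration_pmol_per_1e6_nuclei", "role"]


def write_ladder_tsv(spec: LadderSpec, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TSV_HEADER)
        for s in spec.species:
            w.writerow([s.species_id, s.barcode, repr(float(s.concentration_pmol)), s.role])
        # n_cells travels as a comment-free footer row would break round-trip;
        # keep it in a sibling key line instead
        w.writerow(["#n_cells_per_condition", "", repr(spec.n_cells_per_condition), ""])


def read_ladder_tsv(path) -> LadderSpec:
    species: list[HashSpecies] = []
    n_cells = 100_000
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected ladder TSV header: {header}")
        for row in r:
            if not row or not row[0]:
                continue
            if row[0] == "#n_cells_per_condition":
                n_cells = int(float(row[2]))
                continue
            species.append(HashSpecies(row[0], row[1], float(row[2]), row[3]))
    return LadderSpec(species, n_cells_per_condition=n_cells)
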