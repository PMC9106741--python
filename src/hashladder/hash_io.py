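"""Hash read parsing, UMI counting, matrix IO, and knee filtering.

Read 2 of a hash read carries the 10-base species barcode in positions 1-10
(1-based) followed by poly(A) starting at position 12; position 11 is
ignored. Reads are assigned to a species by Levenshtein matching against the
barcode whitelist (distance <= 2 by default, ambiguous ties discarded),
optionally required to show a trailing poly(A) in positions 12-16, and then
collapsed by (cell, species, UMI) so counts are molecules, not reads.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "HashCountMatrix",
    "RejectionTally",
    "match_barcode",
    "has_trailing_polyA",
    "count_hashes",
    "knee_threshold",
    "read_mtx",
    "write_mtx",
    "NO_MATCH",
    "AMBIGUOUS",
]

NO_MATCH = "no_match"
AMBIGUOUS = "ambiguous"


class HashCountMatrix:
    """cell x hash-species UMI count matrix (sparse).

    Ladder species and sample-ID species may live in the same matrix; use
    :meth:`subset_species` to split them for calibration vs. demultiplexing.
    """

    def __init__(self, cells, species, counts):
        cells = list(cells)
        species = list(species)
        if len(set(cells)) != len(cells):
            raise ValueError("duplicate cell barcodes")
        if len(set(species)) != len(species):
            raise ValueError("duplicate species ids")
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(cells), len(species)):
            raise ValueError("counts shape does not match cells x species")
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        self.cells = cells
        self.species = species
        self.counts = counts
        self._cell_index = {c: i for i, c in enumerate(cells)}
        self._species_index = {s: j for j, s in enumerate(species)}

    @property
    def shape(self):
        return self.counts.shape

    def total_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def row(self, cell_barcode: str) -> np.ndarray:
        return np.asarray(
            self.counts[self._cell_index[cell_barcode]].todense()
        ).ravel()

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def subset_species(self, keep) -> "HashCountMatrix":
        idx = [self._species_index[s] for s in keep]
        return HashCountMatrix(self.cells, list(keep), self.counts[:, idx])

    def subset_cells(self, keep) -> "HashCountMatrix":
        idx = [self._cell_index[c] for c in keep]
        return HashCountMatrix(list(keep), self.species, self.counts[idx, :])

    def nonzeros(self):
        """Yield (cell_barcode, species_id, count) over non-zero entries."""
        coo = self.counts.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            yield self.cells[i], self.species[j], int(v)

    @classmethod
    def from_triplets(cls, triplets, cells=None, species=None):
        """Build from (cell, species, count) triplets."""
        triplets = list(triplets)
        if cells is None:
            cells = sorted({t[0] for t in triplets})
        if species is None:
            species = sorted({t[1] for t in triplets})
        ci = {c: i for i, c in enumerate(cells)}
        sj = {s: j for j, s in enumerate(species)}
        rows, cols, data = [], [], []
        for c, s, v in triplets:
            rows.append(ci[c])
            cols.append(sj[s])
            data.append(v)
        m = sp.coo_matrix(
            (data, (rows, cols)), shape=(len(cells), len(species)), dtype=np.int64
        ).tocsr()
        m.sum_duplicates()
        return cls(cells, species, m)


def match_barcode(query: str, whitelist: dict[str, str], max_dist: int = 2) -> str:
    """Assign a 10-base query to the unique nearest whitelist barcode.

    Returns the species_id of the single whitelist entry at minimal
    Levenshtein distance <= ``max_dist``; ``AMBIGUOUS`` when two or more tie
    at the minimum; ``NO_MATCH`` when nothing is within range.
    """
    if not whitelist:
        raise ValueError("whitelist must be non-empty")
    best_d = max_dist + 1
    best_id = NO_MATCH
    n_best = 0
    for barcode, species_id in whitelist.items():
        d = edlib.align(query, barcode, task="distance")["editDistance"]
        if d < best_d:
            best_d, best_id, n_best = d, species_id, 1
        elif d == best_d:
            n_best += 1
    if best_d > max_dist:
        return NO_MATCH
    return best_id if n_best == 1 else AMBIGUOUS


def has_trailing_polyA(
    read2: str, start: int = 12, end: int = 16, max_mismatch: int = 0
) -> bool:
    """True iff the 1-based inclusive window [start, end] is poly(A).

    Up to ``max_mismatch`` non-A bases are tolerated. Reads shorter than the
    window simply return False (rejected upstream).
    """
    if len(read2) < end:
        return False
    window = read2[start - 1 : end]
    mismatches = sum(1 for b in window if b != "A")
    return mismatches <= max_mismatch


@dataclass
class RejectionTally:
    no_match: int = 0
    ambiguous: int = 0
    no_polyA: int = 0
    malformed: int = 0
    retained: int = 0

    @property
    def total(self) -> int:
        return self.no_match + self.ambiguous + self.no_polyA + self.malformed + self.retained


def count_hashes(
    records,
    whitelist: dict[str, str],
    max_dist: int = 2,
    polyA_required: bool = True,
    polyA_max_mismatch: int = 0,
) -> tuple[HashCountMatrix, RejectionTally]:
    """Collapse hash reads to per-(cell, species) UMI counts.

    ``records`` is an iterable of (cell_barcode, umi, read2) tuples (or a
    path handled by :func:`read_hash_reads_tsv` upstream). Duplicate
    (cell, species, UMI) triples count once. Raises if more than half the
    records are malformed.
    """
    if not whitelist:
        raise ValueError("whitelist must be non-empty")
    tally = RejectionTally()
    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        try:
            cell, umi, read2 = rec[0], rec[1], rec[2]
            if not cell or not umi or len(read2) < 10:
                raise ValueError
        except (ValueError, IndexError, TypeError):
            tally.malformed += 1
            continue
        if polyA_required and not has_trailing_polyA(
            read2, max_mismatch=polyA_max_mismatch
        ):
            tally.no_polyA += 1
            continue
        hit = match_barcode(read2[:10], whitelist, max_dist=max_dist)
        if hit == NO_MATCH:
            tally.no_match += 1
            continue
        if hit == AMBIGUOUS:
            tally.ambiguous += 1
            continue
        tally.retained += 1
        seen.add((cell, hit, umi))
    if tally.total and tally.malformed > 0.5 * tally.total:
        raise ValueError(
            f"{tally.malformed}/{tally.total} records malformed; aborting"
        )
    species = sorted(set(whitelist.values()))
    triplets = {}
    for cell, sp_id, _umi in seen:
        triplets[(cell, sp_id)] = triplets.get((cell, sp_id), 0) + 1
    matrix = HashCountMatrix.from_triplets(
        [(c, s, v) for (c, s), v in triplets.items()],
        species=species,
    )
    return matrix, tally


def read_hash_reads_tsv(path):
    """Yield (cell_barcode, umi, read2) from a TSV with that header."""
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header[:3] != ["cell_barcode", "umi", "read2"]:
            raise ValueError(f"unexpected hash read TSV header: {header}")
        for row in r:
            yield tuple(row[:3])


def knee_threshold(total_umis_per_barcode, override: float | None = None) -> float:
    """UMI cutoff separating cell-containing barcodes from debris.

    Barcodes are ranked by total UMIs; on the (log10 rank, log10 total)
    curve the threshold is the total at the point of maximum perpendicular
    distance from the chord joining the curve's endpoints. ``override``
    reproduces a manually chosen per-experiment cutoff.
    """
    totals = np.asarray(total_umis_per_barcode, dtype=float)
    totals = totals[totals >= 1]
    if override is not None:
        return float(override)
    if totals.size < 10:
        raise ValueError("need at least 10 barcodes with >= 1 UMI")
    srt = np.sort(totals)[::-1]
    if srt[0] == srt[-1]:
        warnings.warn("all barcode totals equal; knee undefined, returning that total")
        return float(srt[0])
    x = np.log10(np.arange(1, srt.size + 1))
    y = np.log10(srt)
    # perpendicular distance from chord between endpoints
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    knee = int(np.argmax(dist))
    return float(srt[knee])


def write_mtx(path_prefix, matrix, row_names, col_names) -> None:
    """Write a sparse integer matrix as <prefix>.mtx + <prefix>.rows.txt / .cols.txt."""
    m = sp.coo_matrix(matrix)
    if m.shape != (len(row_names), len(col_names)):
        raise ValueError("matrix shape does not match name lists")
    mmwrite(f"{path_prefix}.mtx", m, field="integer")
    with open(f"{path_prefix}.rows.txt", "w") as fh:
        fh.write("\n".join(map(str, row_names)) + ("\n" if len(row_names) else ""))
    with open(f"{path_prefix}.cols.txt", "w") as fh:
        fh.write("\n".join(map(str, col_names)) + ("\n" if len(col_names) else ""))


def read_mtx(path_prefix):
    """Read a matrix written by :func:`write_mtx`; returns (csr, rows, cols)."""
    m = mmread(f"{path_prefix}.mtx").tocsr()
    with open(f"{path_prefix}.rows.txt") as fh:
        rows = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    with open(f"{path_prefix}.cols.txt") as fh:
        cols = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if m.shape != (len(rows), len(cols)):
        raise ValueError(
            f"matrix dims {m.shape} disagree with name files ({len(rows)}, {len(cols)})"
        )
    if not np.issubdtype(m.dtype, np.integer):
        if not np.allclose(m.data, np.round(m.data)):
            raise ValueError("matrix entries are not integers")
        m = m.astype(np.int64)
    return m, rows, cols
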