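"""Front-ends that turn real-world data into sample paths.

FASTA nucleotide records become 64-state codon paths; 2-D coordinate
trajectories become grid-cell paths; self-transitions can be collapsed so
that dwell times do not dominate the counts; per-document count matrices can
be summed (with an optional zeroed diagonal) when individual documents are
too sparse to count alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from Bio import SeqIO

from .empirics import FrequencyMatrix
from .paths import SamplePath, read_path, write_path  # noqa: F401  (re-export)

__all__ = [
    "CODON_STATES",
    "codon_index",
    "codon_string",
    "read_fasta_codons",
    "remove_self_transitions",
    "GridSpec",
    "grid_bin_trajectory",
    "sum_frequency_matrices",
    "read_path",
    "write_path",
]

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}
CODON_STATES = 64


def codon_index(triplet: str) -> int:
    """Map a codon to ``16 a1 + 4 a2 + a3`` under the order A < C < G < T.

    AAA is 0 and TTT is 63.  Raises on any non-ACGT symbol (U counts as T).
    """
    t = triplet.upper().replace("U", "T")
    if len(t) != 3 or any(b not in _BASE for b in t):
        raise ValueError(f"not an unambiguous codon: {triplet!r}")
    return 16 * _BASE[t[0]] + 4 * _BASE[t[1]] + _BASE[t[2]]


def codon_string(index: int) -> str:
    """Inverse of :func:`codon_index`."""
    if not 0 <= index < 64:
        raise ValueError("codon index must lie in [0, 64)")
    bases = "ACGT"
    return bases[index // 16] + bases[(index // 4) % 4] + bases[index % 4]


def _codons_of(seq: str, frame: int):
    """Yield (codon index or None) for each triplet; None marks a skip."""
    s = seq.upper().replace("U", "T")
    for start in range(frame, len(s) - 2, 3):
        triplet = s[start : start + 3]
        if all(b in _BASE for b in triplet):
            yield 16 * _BASE[triplet[0]] + 4 * _BASE[triplet[1]] + _BASE[triplet[2]]
        else:
            yield None


def read_fasta_codons(fasta, frame: int = 0) -> SamplePath:
    """Read FASTA records as one 64-state codon path.

    Non-overlapping triplets are taken from the ``frame`` offset of each
    record; a trailing partial triplet is dropped.  Triplets containing an
    ambiguity code are skipped and insert a segment break, as does every
    record boundary, so no transition is ever fabricated across either.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1, or 2")
    states: list[int] = []
    breaks: list[int] = []

    def add_break():
        if states and (not breaks or breaks[-1] != len(states)):
            breaks.append(len(states))

    n_records = 0
    for record in SeqIO.parse(fasta, "fasta"):
        n_records += 1
        add_break()
        for codon in _codons_of(str(record.seq), frame):
            if codon is None:
                add_break()
            else:
                states.append(codon)
    if n_records == 0:
        raise ValueError("no FASTA records found")
    if not states:
        raise ValueError("no complete unambiguous codons in input")
    breaks = [b for b in breaks if 0 < b < len(states)]
    return SamplePath(np.asarray(states, dtype=np.int64), n=CODON_STATES,
                      breaks=tuple(breaks))


def remove_self_transitions(path: SamplePath) -> SamplePath:
    """Collapse consecutive duplicate states within each segment.

    Idempotent; segment breaks are preserved (a duplicate across a break is
    kept, since no transition is observed there anyway).
    """
    states: list[int] = []
    breaks: list[int] = []
    for seg in path.segments():
        if states:
            breaks.append(len(states))
        keep = np.ones(seg.size, dtype=bool)
        keep[1:] = seg[1:] != seg[:-1]
        states.extend(seg[keep].tolist())
    return SamplePath(np.asarray(states, dtype=np.int64), n=path.n,
                      breaks=tuple(b for b in breaks if 0 < b < len(states)))


@dataclass(frozen=True)
class GridSpec:
    """A square binning grid: origin, cell width, and bounding box.

    ``bbox = (xmin, ymin, xmax, ymax)`` in the same units as the coordinates;
    points outside it are treated as outliers and dropped.
    """

    origin: tuple
    width: float
    bbox: tuple

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("cell width must be positive")
        xmin, ymin, xmax, ymax = self.bbox
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("bounding box is empty")

    def cell(self, x: float, y: float) -> tuple[int, int]:
        x0, y0 = self.origin
        return (int(np.floor((x - x0) / self.width)),
                int(np.floor((y - y0) / self.width)))

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bbox
        return xmin <= x <= xmax and ymin <= y <= ymax


def grid_bin_trajectory(coords, grid: GridSpec, return_cells: bool = False):
    """Bin a 2-D trajectory onto the grid, dropping out-of-box outliers.

    Occupied cells are numbered by first appearance.  Each dropped point
    inserts a segment break, so no transition is counted across the gap.
    Translation-consistent: shifting coordinates and origin together leaves
    the path unchanged.
    """
    states: list[int] = []
    breaks: list[int] = []
    cells: dict[tuple, int] = {}
    gap = False
    for x, y in coords:
        if not grid.contains(x, y):
            gap = True
            continue
        cell = grid.cell(x, y)
        if cell not in cells:
            cells[cell] = len(cells)
        if gap and states:
            breaks.append(len(states))
        gap = False
        states.append(cells[cell])
    if not states:
        raise ValueError("no in-box coordinates to bin")
    path = SamplePath(np.asarray(states, dtype=np.int64), n=len(cells),
                      breaks=tuple(breaks))
    if return_cells:
        return path, cells
    return path


def sum_frequency_matrices(matrices, zero_diagonal: bool = False) -> FrequencyMatrix:
    """Entrywise sum of per-document count matrices.

    With ``zero_diagonal`` the diagonal of the sum is set to zero
    (self-transitions carry no clustering information and bias toward
    homophilic clusters).
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to sum")
    n = matrices[0].n
    if any(m.n != n for m in matrices):
        raise ValueError("all matrices must share the same state space")
    total = sum((m.counts for m in matrices), sp.csr_matrix((n, n), dtype=np.int64))
    total = sp.csr_matrix(total)
    if zero_diagonal:
        total = sp.csr_matrix(total - sp.diags(total.diagonal(), dtype=np.int64))
        total.eliminate_zeros()
    return FrequencyMatrix(counts=total.astype(np.int64),
                           source_length=sum(m.source_length for m in matrices))
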