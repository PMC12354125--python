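"""Sample paths of discrete observation sequences.

A :class:`SamplePath` holds a finite sequence ``X_1, ..., X_l`` of state
indices in ``[0, n)`` together with optional *segment breaks*.  A break at
position ``b`` means that no transition is observed between ``X_b`` and
``X_{b+1}`` (0-based: between ``states[b-1]`` and ``states[b]``); breaks arise
when independent records (FASTA entries, animal tracks, documents) are
concatenated into one observation sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SamplePath", "read_path", "write_path"]


@dataclass(frozen=True)
class SamplePath:
    """A finite observation sequence over the state space ``[0, n)``.

    Parameters
    ----------
    states : array-like of int
        The observed states, length ``l >= 1``.
    n : int
        Size of the state space; every entry must lie in ``[0, n)``.
    breaks : sequence of int, optional
        Positions ``b`` (``1 <= b < l``) such that the pair
        ``(states[b-1], states[b])`` is *not* an observed transition.
    """

    states: np.ndarray
    n: int
    breaks: tuple = field(default_factory=tuple)

    def __post_init__(self):
        states = np.asarray(self.states, dtype=np.int64)
        if states.ndim != 1 or states.size < 1:
            raise ValueError("a sample path needs at least one observation")
        if states.min() < 0 or states.max() >= self.n:
            raise ValueError(f"state indices must lie in [0, {self.n})")
        breaks = tuple(sorted(set(int(b) for b in self.breaks)))
        for b in breaks:
            if not 1 <= b < states.size:
                raise ValueError(f"break position {b} outside (0, {states.size})")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "breaks", breaks)

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def n_transitions(self) -> int:
        """Number of usable transitions: ``l - 1 - #breaks``."""
        return len(self) - 1 - len(self.breaks)

    def transition_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(origins, destinations)`` of all within-segment transitions."""
        if len(self) < 2:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        mask = np.ones(len(self) - 1, dtype=bool)
        for b in self.breaks:
            mask[b - 1] = False
        return self.states[:-1][mask], self.states[1:][mask]

    def segments(self) -> list[np.ndarray]:
        """Split the path into its contiguous segments."""
        cuts = [0, *self.breaks, len(self)]
        return [self.states[cuts[i]:cuts[i + 1]] for i in range(len(cuts) - 1)]

    def map_states(self, labels: np.ndarray, m: int) -> "SamplePath":
        """Apply a state relabelling (e.g. a cluster assignment) to the path."""
        labels = np.asarray(labels, dtype=np.int64)
        return SamplePath(labels[self.states], n=m, breaks=self.breaks)


def write_path(path: SamplePath, file, comment: str | None = None) -> None:
    """Write a path as plain text: one 0-based integer per line.

    Lines starting with ``#`` are comments; a blank line marks a segment
    break.  ``write_path`` followed by :func:`read_path` is the identity.
    """
    own = isinstance(file, (str, bytes))
    fh = open(file, "w") if own else file
    try:
        fh.write(f"# n={path.n} length={len(path)} breaks={len(path.breaks)}\n")
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        breaks = set(path.breaks)
        for t, s in enumerate(path.states):
            if t in breaks:
                fh.write("\n")
            fh.write(f"{int(s)}\n")
    finally:
        if own:
            fh.close()


def read_path(file, n: int | None = None) -> SamplePath:
    """Read a path written by :func:`write_path`.

    ``n`` defaults to the value recorded in the header comment, falling back
    to ``max(state) + 1``.
    """
    own = isinstance(file, (str, bytes))
    fh = open(file) if own else file
    states: list[int] = []
    breaks: list[int] = []
    header_n = None
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                if header_n is None and "n=" in line:
                    try:
                        header_n = int(line.split("n=")[1].split()[0])
                    except (ValueError, IndexError):
                        pass
                continue
            if line == "":
                if states:
                    breaks.append(len(states))
                continue
            try:
                states.append(int(line))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer token {line!r}") from exc
    finally:
        if own:
            fh.close()
    if not states:
        raise ValueError("empty path: file contains no states")
    breaks = [b for b in breaks if b < len(states)]
    if n is None:
        n = header_n if header_n is not None else max(states) + 1
    return SamplePath(np.asarray(states, dtype=np.int64), n=n, breaks=tuple(breaks))
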