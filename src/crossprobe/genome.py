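"""In-memory genome container with FASTA I/O.

Sequences are held as uppercase strings over {A,C,G,T,N} (other IUPAC
codes are preserved but every non-ACGT character is treated as ambiguous
downstream).  Desk-scale genomes fit comfortably in memory; FASTA reading
goes through pyfaidx so real assemblies load the same way.
"""

from __future__ import annotations

import os
from typing import Dict, Iterator, Mapping

import numpy as np
from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTNRYacgtnry", "TGCANYRtgcanyr")

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement over the extended alphabet (N/R/Y preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """A set of named chromosome sequences with 0-based half-open access."""

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs: Dict[str, str] = {name: s.upper() for name, s in seqs.items()}
        self._encoded: Dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        fa = Fasta(str(path), rebuild=True, as_raw=True)
        try:
            return cls({name: str(fa[name][:]) for name in fa.keys()})
        finally:
            fa.close()

    # -- access -----------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def chrom_len(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def total_len(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice; out-of-bounds coordinates are an error."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        s = self._seqs[chrom]
        if not (0 <= start <= end <= len(s)):
            raise ValueError(
                f"coordinates [{start}, {end}) outside {chrom} (len {len(s)})"
            )
        return s[start:end]

    def encoded(self, chrom: str) -> np.ndarray:
        """Chromosome as a uint8 byte array, cached (aligner fast path)."""
        if chrom not in self._encoded:
            self._encoded[chrom] = np.frombuffer(
                self._seqs[chrom].encode("ascii"), dtype=np.uint8
            )
        return self._encoded[chrom]

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())

    # -- mutation (returns copies; genomes are treated as immutable) ------

    def with_replacements(self, edits: Mapping[str, Mapping[int, str]]) -> "Genome":
        """New genome with per-chromosome {position: base/segment} substitutions.

        A multi-character value replaces ``len(value)`` reference bases starting
        at the position; an empty string deletes nothing (ignored).
        """
        seqs = dict(self._seqs)
        for chrom, ed in edits.items():
            s = list(seqs[chrom])
            for pos in sorted(ed):
                seg = ed[pos].upper()
                s[pos : pos + len(seg)] = list(seg)
            seqs[chrom] = "".join(s)
        return Genome(seqs)

    # -- I/O ---------------------------------------------------------------

    def write_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
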