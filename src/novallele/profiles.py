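"""Mutation counts and position-wise mutation-frequency profiles.

For a group of sequences assigned to one germline allele, the profile
records, for each sequence-wide mutation count bin, the fraction of that
bin's sequences mutated at each IMGT position 1-312.  These
(bin, frequency) points are what the detection fits operate on: a
position that is germline-polymorphic appears mutated in (nearly) every
sequence regardless of the bin, while somatic hypermutation produces
frequencies that grow with the sequence-wide count.

Positions where the germline has an IMGT gap (``.``) are excluded from
counting and fitting; ``N`` and indel characters never count as
mutations (they are masked, like an ``N``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .germline import V_REGION_END, V_REGION_START

# A/C/G/T -> 0..3; everything else (gaps, N, IUPAC codes, padding) -> 255.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def encode_sequences(
    sequences: Iterable[str], length: int = V_REGION_END
) -> np.ndarray:
    """Encode gapped sequences to a ``(n, length)`` uint8 matrix.

    Sequences are right-padded (with non-nucleotide code 255) or
    truncated to ``length``.
    """
    seqs = list(sequences)
    buf = bytearray()
    for s in seqs:
        b = s.encode("ascii")[:length]
        buf += b + b"." * (length - len(b))
    arr = np.frombuffer(bytes(buf), dtype=np.uint8).reshape(len(seqs), length)
    return _CODE[arr]


def mismatch_matrix(observed: np.ndarray, germline: np.ndarray) -> np.ndarray:
    """Boolean matrix: position counted as mutated vs the germline.

    Only positions where both characters are A/C/G/T can be mutations.
    """
    valid = (observed < 4) & (germline < 4)
    return valid & (observed != germline)


def sequence_mutation_count(
    observed: str,
    germline: str,
    start: int = V_REGION_START,
    end: int = V_REGION_END,
) -> int:
    """Number of positions in ``[start, end]`` where both sequences are
    unambiguous nucleotides and differ.  A sequence shorter than ``end``
    is compared over its available positions."""
    length = end
    obs = encode_sequences([observed], length)[0, start - 1 :]
    germ = encode_sequences([germline], length)[0, start - 1 :]
    return int(mismatch_matrix(obs[None, :], germ).sum())


def mutation_count_histogram(counts: Sequence[int]) -> dict[int, int]:
    """Histogram of sequence-wide mutation counts for a group."""
    values, freqs = np.unique(np.asarray(counts, dtype=int), return_counts=True)
    return {int(v): int(f) for v, f in zip(values, freqs)}


@dataclass(frozen=True)
class PositionFrequencyTable:
    """Per-bin, per-position mutation frequencies for one allele group.

    ``freqs[i, p]`` is the fraction of sequences in bin ``bins[i]``
    (sequence-wide mutation count) mutated at IMGT position ``p + 1``;
    frequencies are defined only for occupied bins.  ``germline_sites``
    flags positions where the germline is an unambiguous nucleotide.
    """

    bins: np.ndarray  # occupied sequence-wide mutation counts, ascending
    occupancy: np.ndarray  # sequences per bin
    freqs: np.ndarray  # (n_bins, 312) fractions in [0, 1]
    germline_sites: np.ndarray  # (312,) bool

    def frequency(self, bin_count: int, position: int) -> float:
        """Mutation frequency at a 1-based IMGT position in one bin."""
        i = int(np.searchsorted(self.bins, bin_count))
        if i >= len(self.bins) or self.bins[i] != bin_count:
            raise KeyError(f"bin {bin_count} not occupied")
        return float(self.freqs[i, position - 1])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (bin, occupancy, position, frequency)."""
        n_pos = self.freqs.shape[1]
        return pd.DataFrame(
            {
                "mutation_count": np.repeat(self.bins, n_pos),
                "occupancy": np.repeat(self.occupancy, n_pos),
                "position": np.tile(np.arange(1, n_pos + 1), len(self.bins)),
                "frequency": self.freqs.ravel(),
            }
        )


def build_profile(
    observed: Sequence[str] | np.ndarray,
    germline: str,
) -> tuple[dict[int, int], PositionFrequencyTable]:
    """Histogram and position-frequency table for one allele group.

    ``observed`` may be raw gapped strings or an already-encoded uint8
    matrix from :func:`encode_sequences`.
    """
    if isinstance(observed, np.ndarray):
        codes = observed
    else:
        if len(observed) == 0:
            raise ValueError("group must be nonempty")
        codes = encode_sequences(observed)
    germ = encode_sequences([germline])[0]
    mm = mismatch_matrix(codes, germ)
    counts = mm.sum(axis=1)
    bins, occupancy = np.unique(counts, return_counts=True)
    freqs = np.empty((len(bins), mm.shape[1]), dtype=float)
    for i, b in enumerate(bins):
        freqs[i] = mm[counts == b].mean(axis=0)
    hist = {int(b): int(n) for b, n in zip(bins, occupancy)}
    table = PositionFrequencyTable(
        bins=bins.astype(int),
        occupancy=occupancy.astype(int),
        freqs=freqs,
        germline_sites=germ < 4,
    )
    return hist, table
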