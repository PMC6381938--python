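"""Distances between inferred genotypes.

The distance between two genotypes is a weighted average over genes
present in both of the per-gene Jaccard distance (one minus shared over
total distinct alleles); the weight of a gene is the mean of the two
calls' certainty values.  Certainty defaults to the log10 Bayes factor
clipped to [0, cap] — raw Bayes factors overflow floating point at the
magnitudes the model produces (log10 K above 100), so the literal mean
of two Bayes factors is only usable for small K and is provided as the
``'raw-k'`` weighting.  Frequency-method calls (no K) get unit weight.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype import Genotype


def gene_jaccard(a: set[str] | frozenset[str], b: set[str] | frozenset[str]) -> float:
    """Jaccard distance ``1 - |a & b| / |a | b|`` between allele sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("allele sets must be nonempty")
    return 1.0 - len(a & b) / len(a | b)


def _gene_weight(genotype: Genotype, gene: str, weighting: str, cap: float) -> float:
    call = genotype.calls[gene]
    if call.log_k is None:
        return 1.0
    if weighting == "log-k":
        return float(min(max(call.log_k, 0.0), cap))
    if weighting == "raw-k":
        return float(min(10.0 ** min(call.log_k, 300.0), 10.0**cap))
    raise ValueError(f"unknown weighting {weighting!r}")


def genotype_distance(
    a: Genotype,
    b: Genotype,
    weighting: str = "log-k",
    cap: float = 100.0,
) -> float:
    """Certainty-weighted mean per-gene Jaccard distance in [0, 1].

    Genes appearing in only one genotype are excluded; no shared genes
    is an error.  If every weight is zero the genes are averaged with
    equal weight.
    """
    shared = sorted(set(a.calls) & set(b.calls))
    if not shared:
        raise ValueError(f"no shared genes between {a.subject} and {b.subject}")
    dists = np.array([gene_jaccard(a.alleles(g), b.alleles(g)) for g in shared])
    weights = np.array(
        [
            0.5 * (_gene_weight(a, g, weighting, cap) + _gene_weight(b, g, weighting, cap))
            for g in shared
        ]
    )
    if weights.sum() == 0.0:
        weights = np.ones_like(weights)
    return float(np.average(dists, weights=weights))


def distance_matrix(
    genotypes: Sequence[Genotype],
    weighting: str = "log-k",
    cap: float = 100.0,
) -> pd.DataFrame:
    """Symmetric, zero-diagonal distance matrix labeled by subject."""
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    labels = [g.subject for g in genotypes]
    n = len(genotypes)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = genotype_distance(genotypes[i], genotypes[j], weighting, cap)
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def write_distance_matrix(
    matrix: pd.DataFrame, path: str | Path, header_comments: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        matrix.to_csv(fh, sep="\t", index_label="subject")
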