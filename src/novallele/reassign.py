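"""Nearest-germline reassignment and iterative sparse-database inference.

After novel alleles are added to the database, every sequence is
reassigned to the database allele(s) minimizing Hamming distance over
IMGT positions 1-312 (``.`` and ``N`` ignored).  Starting from a sparse
database (as little as one allele per gene family), detection and
reassignment alternate until no new alleles are accepted; acceptance
between iterations requires a candidate to enter the iteration's
frequency-method genotype, so spurious candidates cannot accumulate.
The database grows strictly while the loop continues and is bounded by
the number of distinct candidate sequences, so the loop terminates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .detect import DetectionConfig, detect_novel_alleles
from .germline import GermlineAllele, GermlineDatabase, parse_allele_name
from .genotype import (
    FREQUENCY_CUTOFF,
    Genotype,
    frequency_genotype,
    infer_genotype,
    unmutated_support,
)
from .profiles import V_REGION_END, encode_sequences
from .repertoire import Repertoire

logger = logging.getLogger(__name__)


def hamming(a: str, b: str, start: int = 1, end: int = V_REGION_END) -> int:
    """Hamming distance over ``[start, end]``; positions where either
    character is not A/C/G/T (gaps, N) are ignored."""
    ca = encode_sequences([a], end)[0, start - 1 :]
    cb = encode_sequences([b], end)[0, start - 1 :]
    valid = (ca < 4) & (cb < 4)
    return int((valid & (ca != cb)).sum())


def _distance_table(
    codes: np.ndarray, germ_codes: np.ndarray, chunk: int = 2048
) -> np.ndarray:
    """(n_records, n_alleles) Hamming distances, chunked to bound memory."""
    n, m = len(codes), len(germ_codes)
    out = np.empty((n, m), dtype=np.int32)
    for lo in range(0, n, chunk):
        block = codes[lo : lo + chunk]  # (c, 312)
        valid = (block[:, None, :] < 4) & (germ_codes[None, :, :] < 4)
        mm = valid & (block[:, None, :] != germ_codes[None, :, :])
        out[lo : lo + chunk] = mm.sum(axis=2)
    return out


def reassign_all(rep: Repertoire, db: GermlineDatabase) -> Repertoire:
    """Assign each record its nearest database allele(s).

    Ties retain every tied name, comma-joined in alphabetical order (the
    first is used for grouping downstream).  Results land in the
    ``v_call_genotyped`` column; ``v_call`` is untouched.
    """
    if len(db) == 0:
        raise ValueError("germline database is empty")
    names = np.array(db.names())
    order = np.argsort(names)
    names = names[order]
    germ_codes = encode_sequences([a.gapped_sequence for a in db])[order]
    codes = encode_sequences(rep.data["sequence_alignment"].tolist())
    dist = _distance_table(codes, germ_codes)
    dmin = dist.min(axis=1)
    tied = dist == dmin[:, None]
    calls = [",".join(names[row]) for row in tied]
    n_ties = int((tied.sum(axis=1) > 1).sum())
    if n_ties:
        logger.info("reassign_all: %d records tied between alleles", n_ties)
    out = rep.copy()
    out.data["v_call_genotyped"] = calls
    out.provenance.append(f"reassign_all(db={len(db)} alleles)")
    return out


def sparse_seed_database(rep: Repertoire, db: GermlineDatabase) -> GermlineDatabase:
    """One allele per family: the most frequently assigned one.

    Emulates the sparse-database condition used to test iterative
    inference.  Assignment frequencies come from the repertoire's
    current calls; ties break by name.
    """
    counts = rep.grouping_call.value_counts()
    best: dict[str, tuple[int, str]] = {}
    for name, n in counts.items():
        if name not in db:
            continue
        fam = db[name].name.family
        held = best.get(fam)
        if held is None or (-n, name) < (-held[0], held[1]):
            best[fam] = (int(n), name)
    return GermlineDatabase(db[name] for _, name in best.values())


@dataclass(frozen=True)
class IterationState:
    """Record of one detection/reassignment iteration."""

    iteration: int
    n_candidates: int
    accepted: tuple[str, ...]
    db_size: int


@dataclass
class IterativeResult:
    database: GermlineDatabase
    genotype: Genotype
    repertoire: Repertoire
    history: list[IterationState]
    converged: bool


def iterative_inference(
    rep: Repertoire,
    sparse_db: GermlineDatabase,
    cfg: DetectionConfig = DetectionConfig(),
    max_iter: int = 10,
    genotype_method: str = "frequency",
    cutoff: float = FREQUENCY_CUTOFF,
    subject: str = "subject",
) -> IterativeResult:
    """Alternate detection, acceptance and reassignment to convergence.

    Each iteration detects candidates against the current database,
    provisionally reassigns the repertoire to database+candidates, and
    accepts the candidates that enter the frequency-method genotype
    (cumulative 7/8 rule) of that assignment.  Accepted alleles join the
    database and the repertoire is reassigned; the loop stops when an
    iteration accepts nothing (or at ``max_iter``, with a warning).
    """
    db = sparse_db.copy()
    current = reassign_all(rep, db)
    history: list[IterationState] = []
    converged = False
    for it in range(1, max_iter + 1):
        candidates = detect_novel_alleles(current, db, cfg)
        accepted: list[str] = []
        if candidates:
            trial_db = db.copy()
            added = {}
            for cand in candidates:
                allele = GermlineAllele(
                    parse_allele_name(cand.candidate_name), cand.candidate_sequence
                )
                if trial_db.add(allele):
                    added[cand.candidate_name] = allele
            if added:
                trial_rep = reassign_all(rep, trial_db)
                support = unmutated_support(trial_rep, trial_db)
                in_genotype = {
                    a
                    for counts in support.values()
                    for a in frequency_genotype(counts, cutoff).alleles
                }
                for name, allele in added.items():
                    if name in in_genotype:
                        db.add(allele)
                        accepted.append(name)
        history.append(
            IterationState(
                iteration=it,
                n_candidates=len(candidates),
                accepted=tuple(accepted),
                db_size=len(db),
            )
        )
        if not accepted:
            converged = True
            break
        current = reassign_all(rep, db)
    else:
        logger.warning("iterative_inference: not converged after %d iterations", max_iter)

    genotype = infer_genotype(
        current, db, method=genotype_method, subject=subject, cutoff=cutoff
    )
    return IterativeResult(
        database=db,
        genotype=genotype,
        repertoire=current,
        history=history,
        converged=converged,
    )
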