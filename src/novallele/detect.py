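"""Novel V-allele detection by dynamic mutation-window fitting.

For each group of sequences assigned to one germline allele, the
sequence-wide mutation-count histogram positions one analysis window per
prominent count: the primary window starts at the most frequent positive
mutation count ``m`` and ends at ``m + 9``, and any other positive count
with at least 1/8 of the most frequent count's sequences starts an
additional window.  Inside a window, an ordinary least-squares line is
fitted per IMGT position through the (mutation count, mutation
frequency) points of the occupied bins; a position is called polymorphic
when the fit predicts a frequency above 0.125 at a count one less than
the window start.  All polymorphic positions of one window are
substituted into the base allele to form a single novel-allele
candidate, which must be supported by at least one exactly-matching
("apparently unmutated") sequence and, by default, by sequences spanning
more than one (J gene, junction length) combination so that a single
expanded clone cannot masquerade as an allele.

The dynamic window placement is what allows alleles any number of
polymorphisms away from the nearest database allele to be found: a group
derived from an allele ``n`` SNPs away piles up at mutation count ``n``,
and the window anchored there sees the ``n`` polymorphic positions at
frequency ~1 in every bin.  With ``m = 1`` the procedure reduces to the
original fixed-window method (`legacy_mode` reproduces that method: a
window from ``min(L, 5)`` to 10 evaluated at the y-intercept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .germline import (
    GermlineAllele,
    GermlineDatabase,
    Polymorphism,
    V_REGION_END,
    apply_polymorphisms,
    compose_novel_name,
)
from .profiles import (
    PositionFrequencyTable,
    build_profile,
    encode_sequences,
    mismatch_matrix,
)
from .repertoire import Repertoire

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MutationWindow:
    """Range of sequence-wide mutation counts analyzed for one fit.

    ``evaluation_x`` is the mutation count at which the fitted line is
    evaluated against the frequency threshold; for an updated-algorithm
    window it is one less than the window start.
    """

    start: int
    end: int
    evaluation_x: int

    @classmethod
    def updated(cls, start: int, width: int = 9) -> "MutationWindow":
        if start < 1:
            raise ValueError("window start must be >= 1")
        return cls(start=start, end=start + width, evaluation_x=start - 1)


@dataclass(frozen=True)
class PositionEvidence:
    """Linear-fit verdict for one IMGT position inside one window."""

    position: int  # 1-based
    fitted_slope: float
    predicted_frequency: float  # at window.evaluation_x
    occupied_bins_used: int
    verdict: str  # 'polymorphic' | 'not_polymorphic' | 'insufficient_data'


@dataclass(frozen=True)
class NovelAlleleCandidate:
    """A proposed germline: base allele with substituted positions."""

    base_allele: GermlineAllele
    polymorphisms: tuple[Polymorphism, ...]
    candidate_sequence: str
    candidate_name: str
    supporting_unmutated_count: int
    window: MutationWindow
    evidence: tuple[PositionEvidence, ...]

    @property
    def v_region(self) -> str:
        return self.candidate_sequence[:V_REGION_END]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the detection procedure.

    The frequency threshold (0.125), window width (9) and secondary
    window ratio (1/8) are the method's published constants; the
    remaining floors guard the fits against sparsely occupied bins.
    """

    y_threshold: float = 0.125
    window_width: int = 9
    secondary_window_ratio: float = 1 / 8
    min_group_size: int = 50
    min_seqs_per_bin: int = 10
    min_occupied_bins: int = 3
    legacy_mode: bool = False
    clonality_guard: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.y_threshold < 1:
            raise ValueError("y_threshold must be in (0, 1)")
        if not 0 < self.secondary_window_ratio < 1:
            raise ValueError("secondary_window_ratio must be in (0, 1)")
        if self.window_width < 1 or self.min_seqs_per_bin < 1:
            raise ValueError("widths and floors must be >= 1")


def find_windows(
    hist: Mapping[int, int], cfg: DetectionConfig = DetectionConfig()
) -> list[MutationWindow]:
    """Mutation windows implied by a mutation-count histogram.

    The primary window starts at the most frequent positive mutation
    count ``m``; every other positive count with at least
    ``secondary_window_ratio`` (default 1/8) of ``m``'s sequences —
    above or below ``m`` — starts an additional window.  Returned sorted
    by start, duplicates removed.  No positive counts -> empty list.
    """
    positive = {c: n for c, n in hist.items() if c > 0 and n > 0}
    if not positive:
        return []
    top = max(positive.values())
    m = min(c for c, n in positive.items() if n == top)
    starts = {m} | {
        c for c, n in positive.items() if n >= top * cfg.secondary_window_ratio
    }
    return [MutationWindow.updated(s, cfg.window_width) for s in sorted(starts)]


def legacy_window(hist: Mapping[int, int]) -> MutationWindow | None:
    """Window of the original fixed-window method.

    Lower bound ``min(L, 5)`` with ``L`` the most frequent positive
    mutation count among sequences with at most 10 mutations; upper
    bound 10; evaluation at the y-intercept (x = 0).
    """
    eligible = {c: n for c, n in hist.items() if 0 < c <= 10 and n > 0}
    if not eligible:
        return None
    top = max(eligible.values())
    L = min(c for c, n in eligible.items() if n == top)
    return MutationWindow(start=min(L, 5), end=10, evaluation_x=0)


def _window_fit(
    table: PositionFrequencyTable,
    window: MutationWindow,
    cfg: DetectionConfig,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized OLS over all positions for one window.

    Returns (predicted frequency at evaluation_x, slope, bins used);
    arrays are NaN when fewer than ``min_occupied_bins`` qualify.

    In legacy mode every integer count in the fixed window enters the
    fit, empty bins contributing zero frequency.  This zero-filling is
    what structurally limits the original method to alleles at most five
    polymorphisms away: a group derived from a more distant allele
    leaves the low bins of the [min(L, 5), 10] window empty, and those
    zero points pull the y-intercept below the threshold.
    """
    if cfg.legacy_mode:
        xs = np.arange(window.start, window.end + 1)
        n_pos = table.freqs.shape[1]
        y = np.zeros((len(xs), n_pos))
        for i, b in enumerate(table.bins):
            if window.start <= b <= window.end:
                y[b - window.start] = table.freqs[i]
        x = xs.astype(float)
        xc = x - x.mean()
        slope = (xc[:, None] * (y - y.mean(axis=0))).sum(axis=0) / float((xc**2).sum())
        pred = y.mean(axis=0) + slope * (window.evaluation_x - x.mean())
        return pred, slope, len(xs)
    sel = (
        (table.bins >= window.start)
        & (table.bins <= window.end)
        & (table.occupancy >= cfg.min_seqs_per_bin)
    )
    n_bins = int(sel.sum())
    n_pos = table.freqs.shape[1]
    if n_bins < cfg.min_occupied_bins:
        nan = np.full(n_pos, np.nan)
        return nan, nan.copy(), n_bins
    x = table.bins[sel].astype(float)
    y = table.freqs[sel]  # (n_bins, 312)
    xc = x - x.mean()
    denom = float((xc**2).sum())
    if denom == 0.0:  # unreachable with >= 2 distinct bins; kept for safety
        slope = np.zeros(n_pos)
    else:
        slope = (xc[:, None] * (y - y.mean(axis=0))).sum(axis=0) / denom
    pred = y.mean(axis=0) + slope * (window.evaluation_x - x.mean())
    return pred, slope, n_bins


def fit_position(
    table: PositionFrequencyTable,
    position: int,
    window: MutationWindow,
    cfg: DetectionConfig = DetectionConfig(),
) -> PositionEvidence:
    """Fit one IMGT position (1-based) inside a window.

    Verdicts encode the degenerate cases: ``insufficient_data`` when
    fewer than ``min_occupied_bins`` occupied bins qualify.
    """
    if not 1 <= position <= table.freqs.shape[1]:
        raise ValueError(f"position {position} outside 1-{table.freqs.shape[1]}")
    if not table.germline_sites[position - 1]:
        raise ValueError(f"position {position} is a germline gap")
    pred, slope, n_bins = _window_fit(table, window, cfg)
    p = pred[position - 1]
    if np.isnan(p):
        return PositionEvidence(position, float("nan"), float("nan"), n_bins, "insufficient_data")
    verdict = "polymorphic" if p > cfg.y_threshold else "not_polymorphic"
    return PositionEvidence(position, float(slope[position - 1]), float(p), n_bins, verdict)


def _group_arrays(
    group: Repertoire | pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = group.data if isinstance(group, Repertoire) else group
    codes = encode_sequences(df["sequence_alignment"].tolist())
    j = df["j_call"].to_numpy() if "j_call" in df else np.full(len(df), "")
    jl = (
        df["junction_length"].astype(str).to_numpy()
        if "junction_length" in df
        else np.full(len(df), "")
    )
    return codes, j, jl


def detect_for_allele(
    group: Repertoire | pd.DataFrame | np.ndarray,
    base: GermlineAllele,
    cfg: DetectionConfig = DetectionConfig(),
    db: GermlineDatabase | None = None,
    j_calls: np.ndarray | None = None,
    junction_lengths: np.ndarray | None = None,
) -> list[NovelAlleleCandidate]:
    """Detect novel-allele candidates among sequences assigned to ``base``.

    ``group`` is a repertoire (or data frame) of records assigned to the
    base allele, or an already-encoded uint8 matrix (then ``j_calls`` /
    ``junction_lengths`` supply the clonality-guard fields).  One
    candidate is emitted per window that yields polymorphic positions;
    candidates identical to an existing database entry over IMGT
    positions 1-312, without exact-match support, or (with the clonality
    guard) supported by a single (J, junction length) combination are
    discarded.
    """
    if isinstance(group, np.ndarray):
        codes = group
        j = j_calls if j_calls is not None else np.full(len(codes), "")
        jl = junction_lengths if junction_lengths is not None else np.full(len(codes), "")
    else:
        codes, j, jl = _group_arrays(group)
    if len(codes) < cfg.min_group_size:
        logger.info(
            "group for %s too small (%d < %d); skipping",
            base.full_name,
            len(codes),
            cfg.min_group_size,
        )
        return []

    germ = encode_sequences([base.gapped_sequence])[0]
    mm = mismatch_matrix(codes, germ)
    counts = mm.sum(axis=1)
    bins, occ = np.unique(counts, return_counts=True)
    hist = {int(b): int(n) for b, n in zip(bins, occ)}
    freqs = np.empty((len(bins), mm.shape[1]))
    for i, b in enumerate(bins):
        freqs[i] = mm[counts == b].mean(axis=0)
    table = PositionFrequencyTable(
        bins=bins.astype(int),
        occupancy=occ.astype(int),
        freqs=freqs,
        germline_sites=germ < 4,
    )

    if cfg.legacy_mode:
        w = legacy_window(hist)
        windows = [w] if w is not None else []
    else:
        windows = find_windows(hist, cfg)

    out: list[NovelAlleleCandidate] = []
    for window in windows:
        pred, slope, n_bins = _window_fit(table, window, cfg)
        if n_bins < cfg.min_occupied_bins:
            continue
        poly_mask = (pred > cfg.y_threshold) & table.germline_sites
        positions = np.flatnonzero(poly_mask) + 1
        if positions.size == 0:
            continue

        in_window = (counts >= window.start) & (counts <= window.end)
        wcodes = codes[in_window]
        polymorphisms: list[Polymorphism] = []
        for pos in positions:
            col = wcodes[:, pos - 1]
            tallies = np.bincount(col[(col < 4) & (col != germ[pos - 1])], minlength=4)
            if tallies.sum() == 0:
                continue  # predicted polymorphic but no alternate base observed
            best = int(np.argmax(tallies))  # argmax tie -> lexicographic A<C<G<T
            if (tallies == tallies[best]).sum() > 1:
                logger.warning(
                    "%s position %d: modal alternate base tied; choosing %s",
                    base.full_name,
                    pos,
                    "ACGT"[best],
                )
            polymorphisms.append(
                Polymorphism(int(pos), base.nucleotide_at(int(pos)), "ACGT"[best])
            )
        if not polymorphisms:
            continue

        candidate_seq = apply_polymorphisms(base.gapped_sequence, polymorphisms)
        if db is not None and db.find_by_sequence(candidate_seq) is not None:
            continue  # already a known allele

        cand = encode_sequences([candidate_seq])[0]
        support_mask = mismatch_matrix(codes, cand).sum(axis=1) == 0
        support = int(support_mask.sum())
        if support == 0:
            continue
        if cfg.clonality_guard:
            combos = {(a, b) for a, b in zip(j[support_mask], jl[support_mask])}
            if len(combos) < 2:
                logger.info(
                    "candidate from %s window %d suppressed by clonality guard",
                    base.full_name,
                    window.start,
                )
                continue

        evidence = tuple(
            PositionEvidence(
                p.position,
                float(slope[p.position - 1]),
                float(pred[p.position - 1]),
                n_bins,
                "polymorphic",
            )
            for p in polymorphisms
        )
        out.append(
            NovelAlleleCandidate(
                base_allele=base,
                polymorphisms=tuple(polymorphisms),
                candidate_sequence=candidate_seq,
                candidate_name=compose_novel_name(base, polymorphisms),
                supporting_unmutated_count=support,
                window=window,
                evidence=evidence,
            )
        )
    return out


def detect_novel_alleles(
    rep: Repertoire,
    db: GermlineDatabase,
    cfg: DetectionConfig = DetectionConfig(),
) -> list[NovelAlleleCandidate]:
    """Run detection over every allele group of a repertoire.

    Groups are formed on the first allele of the current call
    (``v_call_genotyped`` when present, else ``v_call``).  Candidates
    implying the same sequence from different base alleles are
    deduplicated, keeping the best-supported one.
    """
    by_seq: dict[str, NovelAlleleCandidate] = {}
    groups = rep.data.groupby(rep.grouping_call, sort=True)
    for allele_name, group_df in groups:
        if allele_name not in db:
            logger.info("skipping group %s: not in germline database", allele_name)
            continue
        for cand in detect_for_allele(group_df, db[allele_name], cfg, db=db):
            key = cand.v_region
            held = by_seq.get(key)
            if held is None or cand.supporting_unmutated_count > held.supporting_unmutated_count:
                by_seq[key] = cand
    return sorted(by_seq.values(), key=lambda c: c.candidate_name)


def candidates_to_frame(candidates: Sequence[NovelAlleleCandidate]) -> pd.DataFrame:
    """Evidence table: one row per candidate (for the ``detect`` CLI)."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "candidate_name": c.candidate_name,
                "base_allele": c.base_allele.full_name,
                "polymorphisms": ",".join(str(p) for p in c.polymorphisms),
                "window_start": c.window.start,
                "window_end": c.window.end,
                "evaluation_x": c.window.evaluation_x,
                "supporting_unmutated": c.supporting_unmutated_count,
                "predicted_frequencies": ",".join(
                    f"{e.position}:{e.predicted_frequency:.4f}" for e in c.evidence
                ),
            }
        )
    return pd.DataFrame(rows)
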