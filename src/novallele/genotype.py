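"""Per-gene genotype inference from apparently-unmutated sequences.

Two methods are provided.  The *frequency* method includes, per gene,
the minimal set of alleles (in descending count order) explaining at
least 7/8 of the apparently-unmutated sequences.  The *Bayesian* method
selects among seven allele-usage models for the counts of the top four
alleles, X = (x1, x2, x3, x4):

    HH  = (1, 0, 0, 0)          homozygous
    HD1 = (0.5, 0.5, 0, 0)      heterozygous, balanced
    HD2 = (0.67, 0.33, 0, 0)    heterozygous, 2:1 (one locus duplicated)
    HD3 = (0.75, 0.25, 0, 0)    heterozygous, 3:1
    HT1 = (1/3, 1/3, 1/3, 0)    three alleles, balanced
    HT2 = (0.5, 0.25, 0.25, 0)  three alleles, 2:1:1
    HQ  = (0.25, 0.25, 0.25, 0.25)  four alleles (duplicated, both
                                    loci heterozygous)

Each model vector H is perturbed by epsilon = (1,1,1,1)/100 and
renormalized to the probability simplex (a multinomial parameter must
sum to one); the posterior ordinate of theta = (H + eps)/sum under a
uniform Dirichlet(1,1,1,1) prior is

    p(theta | X) = Multinomial(X | theta) * Dirichlet(theta; 1)
                   / DirichletMultinomial(X; 1),

reported in log10.  Model families (1-, 2-, 3-, 4-allele) aggregate
their variants by summation, and the genotype call is the family with
the highest posterior, with certainty log10 K = the log posterior gap to
the runner-up family.  Values are floored at -1000, the scale at which
the corresponding probability underflows double precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .germline import GermlineDatabase, V_REGION_END, parse_allele_name
from .profiles import encode_sequences, mismatch_matrix
from .repertoire import Repertoire

logger = logging.getLogger(__name__)

LN10 = float(np.log(10.0))

FREQUENCY_CUTOFF = 7 / 8


@dataclass(frozen=True)
class ModelVector:
    """One allele-usage model: family label, variant label, theta0."""

    family: str  # '1', '2', '3' or '4' (allele count)
    label: str
    theta0: tuple[float, float, float, float]


MODEL_VECTORS: tuple[ModelVector, ...] = (
    ModelVector("1", "HH", (1.0, 0.0, 0.0, 0.0)),
    ModelVector("2", "HD1", (0.5, 0.5, 0.0, 0.0)),
    ModelVector("2", "HD2", (0.67, 0.33, 0.0, 0.0)),
    ModelVector("2", "HD3", (0.75, 0.25, 0.0, 0.0)),
    ModelVector("3", "HT1", (1 / 3, 1 / 3, 1 / 3, 0.0)),
    ModelVector("3", "HT2", (0.5, 0.25, 0.25, 0.0)),
    ModelVector("4", "HQ", (0.25, 0.25, 0.25, 0.25)),
)

FAMILIES = ("1", "2", "3", "4")


@dataclass(frozen=True)
class BayesConfig:
    """Parameters of the Bayesian gene call.

    ``model_priors`` maps variant label to a prior weight (flat weight 1
    by default; the weights multiply the posterior ordinates and an
    overall scale cancels in every reported ratio).  ``family_mode``
    selects how variants aggregate into their family: ``'sum'``
    (Bayesian model averaging, default) or ``'max'``.
    """

    epsilon: tuple[float, float, float, float] = (0.01, 0.01, 0.01, 0.01)
    model_priors: Mapping[str, float] = field(
        default_factory=lambda: {m.label: 1.0 for m in MODEL_VECTORS}
    )
    log_floor: float = -1000.0
    family_mode: str = "sum"

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.epsilon):
            raise ValueError("epsilon components must be > 0")
        if self.family_mode not in ("sum", "max"):
            raise ValueError("family_mode must be 'sum' or 'max'")


@dataclass(frozen=True)
class AlleleCounts:
    """Apparently-unmutated sequence support per allele of one gene.

    ``alleles``/``counts`` hold every observed allele in descending
    count order (ties broken by allele name); ``X`` is the top-four
    count vector, zero-padded, used by the Bayesian model.
    """

    gene: str
    alleles: tuple[str, ...]
    counts: tuple[int, ...]

    @property
    def X(self) -> np.ndarray:
        x = np.zeros(4, dtype=float)
        top = self.counts[:4]
        x[: len(top)] = top
        return x

    @property
    def total(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class GenotypeCall:
    """Alleles called for one gene, with method tag and certainty."""

    gene: str
    alleles: tuple[str, ...]
    method: str  # 'frequency' | 'bayesian'
    counts: AlleleCounts
    log_k: float | None = None  # log10 Bayes factor (bayesian only)
    family_log10: Mapping[str, float] | None = None
    variant_posteriors: Mapping[str, float] | None = None


@dataclass
class Genotype:
    """Per-gene genotype of one subject."""

    subject: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def alleles(self, gene: str) -> set[str]:
        return set(self.calls[gene].alleles)

    def genes(self) -> list[str]:
        return sorted(self.calls)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.genes():
            c = self.calls[gene]
            row = {
                "gene": gene,
                "alleles": ",".join(c.alleles),
                "counts": ",".join(str(n) for n in c.counts.counts),
                "total": c.counts.total,
                "method": c.method,
                "log_k": "" if c.log_k is None else f"{c.log_k:.4f}",
            }
            if c.family_log10:
                for fam in FAMILIES:
                    row[f"log10_family_{fam}"] = f"{c.family_log10[fam]:.4f}"
            rows.append(row)
        return pd.DataFrame(rows)


def unmutated_support(
    rep: Repertoire, db: GermlineDatabase
) -> dict[str, AlleleCounts]:
    """Count apparently-unmutated sequences per allele, grouped by gene.

    A sequence supports its assigned allele (first of the current call)
    when it has zero mismatches to that germline over IMGT positions
    1-312.  Genes with no unmutated support are excluded with a warning.
    """
    assigned = rep.grouping_call
    support: dict[str, int] = {}
    seen_genes: set[str] = set()
    for allele_name, group in rep.data.groupby(assigned, sort=True):
        if allele_name not in db:
            continue
        seen_genes.add(db[allele_name].name.gene)
        germ = encode_sequences([db[allele_name].gapped_sequence])[0]
        codes = encode_sequences(group["sequence_alignment"].tolist())
        n_unmutated = int((mismatch_matrix(codes, germ).sum(axis=1) == 0).sum())
        if n_unmutated:
            support[allele_name] = n_unmutated

    by_gene: dict[str, list[tuple[str, int]]] = {}
    for allele_name, n in support.items():
        gene = db[allele_name].name.gene
        by_gene.setdefault(gene, []).append((allele_name, n))
    for gene in seen_genes - set(by_gene):
        logger.warning("gene %s has no apparently-unmutated support; excluded", gene)

    out: dict[str, AlleleCounts] = {}
    for gene, pairs in sorted(by_gene.items()):
        pairs.sort(key=lambda p: (-p[1], p[0]))  # descending count, then name
        out[gene] = AlleleCounts(
            gene=gene,
            alleles=tuple(a for a, _ in pairs),
            counts=tuple(n for _, n in pairs),
        )
    return out


def frequency_genotype(
    counts: AlleleCounts, cutoff: float = FREQUENCY_CUTOFF
) -> GenotypeCall:
    """Minimal prefix of alleles explaining at least ``cutoff`` of the
    apparently-unmutated sequences (descending count order)."""
    total = counts.total
    if total <= 0:
        raise ValueError(f"gene {counts.gene}: no unmutated support")
    cum = 0
    included: list[str] = []
    for allele, n in zip(counts.alleles, counts.counts):
        included.append(allele)
        cum += n
        if cum / total >= cutoff:
            break
    return GenotypeCall(
        gene=counts.gene, alleles=tuple(included), method="frequency", counts=counts
    )


def _log10_variant_ordinates(X: np.ndarray, cfg: BayesConfig) -> np.ndarray:
    """log10 posterior ordinate of theta_v = (H_v + eps)/sum for each
    variant, including the prior weight; common Dirichlet(1,1,1,1)
    prior and Dirichlet-multinomial normalization."""
    X = np.asarray(X, dtype=float)
    eps = np.asarray(cfg.epsilon, dtype=float)
    alpha = np.ones(4)
    # Dirichlet-multinomial marginal and Dirichlet prior density (both
    # without the multinomial coefficient, which cancels).
    ln_marginal = (
        gammaln(alpha.sum())
        - gammaln(alpha).sum()
        + gammaln(alpha + X).sum()
        - gammaln(alpha.sum() + X.sum())
    )
    ln_prior_density = float(gammaln(4.0))  # uniform simplex density = Gamma(4)
    out = np.empty(len(MODEL_VECTORS))
    for i, mv in enumerate(MODEL_VECTORS):
        theta = np.asarray(mv.theta0) + eps
        theta = theta / theta.sum()
        ln_lik = float(np.sum(X * np.log(theta)))
        weight = float(cfg.model_priors.get(mv.label, 1.0))
        out[i] = (ln_lik + ln_prior_density - ln_marginal + np.log(weight)) / LN10
    return out


def model_log_posterior(
    X: Sequence[float], cfg: BayesConfig = BayesConfig()
) -> dict[str, float]:
    """Normalized log10 posterior probability of each model variant.

    Probabilities sum to one across the seven variants; values are
    floored at ``cfg.log_floor``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape != (4,) or (X < 0).any():
        raise ValueError("X must be four non-negative counts")
    if X.sum() == 0:
        raise ValueError("all-zero counts: no data to genotype")
    ordinates = _log10_variant_ordinates(X, cfg)
    norm = logsumexp(ordinates * LN10) / LN10
    return {
        mv.label: float(max(v - norm, cfg.log_floor))
        for mv, v in zip(MODEL_VECTORS, ordinates)
    }


def family_log10_posteriors(
    X: Sequence[float], cfg: BayesConfig = BayesConfig()
) -> dict[str, float]:
    """log10 posterior ordinate aggregated per model family.

    This is the certainty scale on which per-family values are reported
    (the ordinates are densities, so the winning family's value need not
    be near zero); differences between families equal log10 Bayes
    factors.  Values are floored at ``cfg.log_floor``.
    """
    X = np.asarray(X, dtype=float)
    if X.sum() == 0:
        raise ValueError("all-zero counts: no data to genotype")
    ordinates = _log10_variant_ordinates(X, cfg)
    out = {}
    for fam in FAMILIES:
        members = np.array(
            [v for mv, v in zip(MODEL_VECTORS, ordinates) if mv.family == fam]
        )
        if cfg.family_mode == "sum":
            val = logsumexp(members * LN10) / LN10
        else:
            val = members.max()
        out[fam] = float(max(val, cfg.log_floor))
    return out


def bayesian_gene_call(
    counts: AlleleCounts, cfg: BayesConfig = BayesConfig()
) -> GenotypeCall:
    """Call the allele-count family with the highest posterior.

    The genotype contains the top ``n`` counted alleles, ``n`` being the
    winning family's allele count (capped at the number of observed
    alleles); log10 K is the posterior gap between the top two families.
    """
    fam_log10 = family_log10_posteriors(counts.X, cfg)
    ranked = sorted(fam_log10.items(), key=lambda kv: -kv[1])
    best_fam, best_val = ranked[0]
    log_k = best_val - ranked[1][1]
    n_alleles = min(int(best_fam), len(counts.alleles))
    return GenotypeCall(
        gene=counts.gene,
        alleles=tuple(counts.alleles[:n_alleles]),
        method="bayesian",
        counts=counts,
        log_k=float(log_k),
        family_log10=fam_log10,
        variant_posteriors={
            k: 10.0**v for k, v in model_log_posterior(counts.X, cfg).items()
        },
    )


def infer_genotype(
    rep: Repertoire,
    db: GermlineDatabase,
    method: str = "bayesian",
    subject: str = "subject",
    cfg: BayesConfig = BayesConfig(),
    cutoff: float = FREQUENCY_CUTOFF,
    original_db: GermlineDatabase | None = None,
) -> Genotype:
    """Infer the per-gene genotype of a repertoire.

    Novel-allele candidates must already be merged into ``db`` and the
    records carry their final calls.  Alleles absent from
    ``original_db`` (when given) are logged as novel.
    """
    if method not in ("frequency", "bayesian"):
        raise ValueError(f"unknown method {method!r}")
    genotype = Genotype(subject=subject)
    for gene, counts in unmutated_support(rep, db).items():
        if method == "frequency":
            call = frequency_genotype(counts, cutoff)
        else:
            call = bayesian_gene_call(counts, cfg)
        genotype.calls[gene] = call
        if original_db is not None:
            for allele in call.alleles:
                if allele not in original_db:
                    logger.info("genotype %s: novel allele %s", subject, allele)
    return genotype


def write_genotype(genotype: Genotype, path, header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        genotype.to_frame().to_csv(fh, sep="\t", index=False)


def read_genotype(path, subject: str | None = None) -> Genotype:
    """Read a genotype TSV written by :func:`write_genotype`."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    name = subject if subject is not None else str(path)
    genotype = Genotype(subject=name)
    for row in df.itertuples(index=False):
        alleles = tuple(row.alleles.split(","))
        numbers = tuple(int(x) for x in row.counts.split(","))
        # the counts column may cover more alleles than were called
        counts = AlleleCounts(
            gene=row.gene,
            alleles=alleles + tuple(f"uncalled{i}" for i in range(len(numbers) - len(alleles))),
            counts=numbers[: max(len(numbers), len(alleles))],
        )
        genotype.calls[row.gene] = GenotypeCall(
            gene=row.gene,
            alleles=tuple(row.alleles.split(",")),
            method=row.method,
            counts=counts,
            log_k=float(row.log_k) if row.log_k else None,
        )
    return genotype
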