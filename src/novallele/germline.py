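"""IMGT-gapped germline V-allele databases.

Germline V sequences are stored in the IMGT unique numbering: position
``i`` (1-based) of the gapped string is IMGT position ``i``, with ``.``
marking numbering gaps.  The analyzed V region spans IMGT positions
1-312.  Novel alleles discovered from repertoire data are named by
appending substitution suffixes to the base allele name, e.g.
``IGHV1-2*02_T163C`` for a T->C change at IMGT position 163 relative to
``IGHV1-2*02``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: First and last IMGT position of the analyzed V region.
V_REGION_START = 1
V_REGION_END = 312

#: Characters allowed in a gapped germline sequence.
SEQUENCE_ALPHABET = frozenset("ACGTN.")

NUCLEOTIDES = "ACGT"


class AlleleNameError(ValueError):
    """Raised when an allele-name string does not match the name grammar."""


class GermlineDatabaseError(ValueError):
    """Raised on inconsistent germline-database content."""


@dataclass(frozen=True, order=True)
class Polymorphism:
    """A single nucleotide substitution at an IMGT position.

    ``from_nt`` is the nucleotide of the base (reference) allele and
    ``to_nt`` the nucleotide of the derived allele.
    """

    position: int
    from_nt: str
    to_nt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise AlleleNameError(f"position must be >= 1, got {self.position}")
        for nt in (self.from_nt, self.to_nt):
            if nt not in NUCLEOTIDES:
                raise AlleleNameError(f"invalid nucleotide {nt!r}")
        if self.from_nt == self.to_nt:
            raise AlleleNameError(
                f"self-substitution {self.from_nt}{self.position}{self.to_nt}"
            )

    def __str__(self) -> str:
        return f"{self.from_nt}{self.position}{self.to_nt}"


_NAME_RE = re.compile(
    r"^(?P<gene>[A-Za-z0-9().\/-]+)"
    r"\*(?P<allele>[A-Za-z0-9.]+?)"
    r"(?P<suffix>(?:_[ACGT]\d+[ACGT])*)$"
)
_SNP_RE = re.compile(r"_([ACGT])(\d+)([ACGT])")
_FAMILY_RE = re.compile(r"^(?P<family>[A-Za-z]+\d+)")


@dataclass(frozen=True)
class AlleleName:
    """Parsed V-allele name: gene, allele number and substitution suffix.

    Composing the fields back (``str(name)``) reproduces the original
    string exactly.
    """

    gene: str
    allele: str
    snp_suffix: tuple[Polymorphism, ...] = ()

    @property
    def family(self) -> str:
        """Gene family, e.g. ``IGHV1`` for gene ``IGHV1-69``."""
        head = self.gene.split("-")[0]
        m = _FAMILY_RE.match(head)
        return m.group("family") if m else head

    @property
    def base_name(self) -> str:
        """Name without the substitution suffix."""
        return f"{self.gene}*{self.allele}"

    @property
    def is_novel(self) -> bool:
        return bool(self.snp_suffix)

    def __str__(self) -> str:
        suffix = "".join(f"_{p}" for p in self.snp_suffix)
        return f"{self.base_name}{suffix}"


def parse_allele_name(raw: str) -> AlleleName:
    """Parse an allele-name string such as ``IGHV3-64*05_A210C_G265C``.

    Raises :class:`AlleleNameError` naming the offending token if the
    string does not match the grammar ``GENE*ALLELE[_<NT><POS><NT>]*``.
    """
    if not isinstance(raw, str) or not raw:
        raise AlleleNameError("empty allele name")
    m = _NAME_RE.match(raw)
    if m is None:
        if "*" not in raw:
            raise AlleleNameError(f"missing '*' separator in allele name {raw!r}")
        gene, _, rest = raw.partition("*")
        token = rest if rest else gene
        raise AlleleNameError(f"malformed allele name {raw!r} (offending token {token!r})")
    snps = tuple(
        Polymorphism(int(pos), f, t) for f, pos, t in _SNP_RE.findall(m.group("suffix"))
    )
    positions = [p.position for p in snps]
    if positions != sorted(set(positions)):
        raise AlleleNameError(
            f"substitution positions must be strictly increasing in {raw!r}"
        )
    return AlleleName(gene=m.group("gene"), allele=m.group("allele"), snp_suffix=snps)


@dataclass(frozen=True)
class GermlineAllele:
    """A named, IMGT-gapped germline V sequence."""

    name: AlleleName
    gapped_sequence: str

    def __post_init__(self) -> None:
        seq = self.gapped_sequence.upper()
        object.__setattr__(self, "gapped_sequence", seq)
        if not seq:
            raise GermlineDatabaseError(f"{self.name}: empty sequence")
        bad = set(seq) - SEQUENCE_ALPHABET
        if bad:
            raise GermlineDatabaseError(
                f"{self.name}: invalid characters {sorted(bad)} in sequence"
            )

    @property
    def full_name(self) -> str:
        return str(self.name)

    @property
    def v_region(self) -> str:
        """Gapped sequence over IMGT positions 1-312 (as available)."""
        return self.gapped_sequence[:V_REGION_END]

    def nucleotide_at(self, position: int) -> str:
        """Character at a 1-based IMGT position ('.' for numbering gaps)."""
        if not 1 <= position <= len(self.gapped_sequence):
            raise IndexError(f"position {position} outside sequence of {self.name}")
        return self.gapped_sequence[position - 1]


AlleleLike = Union[str, AlleleName, GermlineAllele]


def _as_name(base: AlleleLike) -> AlleleName:
    if isinstance(base, GermlineAllele):
        return base.name
    if isinstance(base, AlleleName):
        return base
    return parse_allele_name(base)


def compose_novel_name(
    base: AlleleLike,
    polymorphisms: Sequence[Polymorphism | tuple[int, str, str]],
) -> str:
    """Name a novel allele as the base name plus substitution suffixes.

    Substitutions are expressed relative to the suffix-free origin of the
    base name, so naming is canonical under iteration: a change that
    reverts an existing suffix entry removes it, and a change on top of
    one collapses into a single entry.  If ``base`` is a
    :class:`GermlineAllele`, each ``from_nt`` is checked against the base
    sequence.
    """
    if not polymorphisms:
        raise AlleleNameError("polymorphism list must be nonempty")
    name = _as_name(base)
    polys = [p if isinstance(p, Polymorphism) else Polymorphism(*p) for p in polymorphisms]
    seen: set[int] = set()
    for p in polys:
        if not V_REGION_START <= p.position <= V_REGION_END:
            raise AlleleNameError(f"position {p.position} outside V region 1-{V_REGION_END}")
        if p.position in seen:
            raise AlleleNameError(f"duplicate substitution position {p.position}")
        seen.add(p.position)
        if isinstance(base, GermlineAllele):
            have = base.nucleotide_at(p.position)
            if have != p.from_nt:
                raise GermlineDatabaseError(
                    f"{name}: from_nt {p.from_nt} does not match base "
                    f"nucleotide {have} at position {p.position}"
                )
    merged: dict[int, Polymorphism] = {p.position: p for p in name.snp_suffix}
    for p in polys:
        if p.position in merged:
            origin = merged[p.position].from_nt
            if origin == p.to_nt:
                del merged[p.position]  # reversion to the suffix-free origin
            else:
                merged[p.position] = Polymorphism(p.position, origin, p.to_nt)
        else:
            merged[p.position] = p
    suffix = tuple(merged[pos] for pos in sorted(merged))
    return str(AlleleName(gene=name.gene, allele=name.allele, snp_suffix=suffix))


def apply_polymorphisms(sequence: str, polymorphisms: Iterable[Polymorphism]) -> str:
    """Substitute ``to_nt`` at each polymorphism position (1-based)."""
    chars = list(sequence)
    for p in polymorphisms:
        chars[p.position - 1] = p.to_nt
    return "".join(chars)


class GermlineDatabase:
    """Ordered mapping from full allele-name string to :class:`GermlineAllele`.

    Names are unique; two entries may not share an identical gapped
    sequence over IMGT positions 1-312 (later duplicates are skipped
    with a warning, keeping the first).
    """

    def __init__(self, alleles: Iterable[GermlineAllele] = ()) -> None:
        self._records: dict[str, GermlineAllele] = {}
        self._by_sequence: dict[str, str] = {}
        for allele in alleles:
            self.add(allele)

    def add(self, allele: GermlineAllele) -> bool:
        """Add an allele; return False if skipped as a duplicate sequence."""
        key = allele.full_name
        if key in self._records:
            raise GermlineDatabaseError(f"duplicate allele name {key}")
        core = allele.v_region
        if core in self._by_sequence:
            logger.warning(
                "germline %s has the same V-region sequence as %s; keeping the first",
                key,
                self._by_sequence[core],
            )
            return False
        self._records[key] = allele
        self._by_sequence[core] = key
        return True

    def remove(self, name: str) -> GermlineAllele:
        allele = self._records.pop(name)
        self._by_sequence.pop(allele.v_region, None)
        return allele

    def rename(self, old: str, new: str) -> None:
        """Replace a (typically temporary novel) allele name.

        The new name must parse; the sequence is unchanged.
        """
        allele = self._records[old]
        if new in self._records:
            raise GermlineDatabaseError(f"name {new} already present")
        renamed = GermlineAllele(parse_allele_name(new), allele.gapped_sequence)
        self.remove(old)
        self.add(renamed)

    def find_by_sequence(self, gapped_sequence: str) -> str | None:
        """Name of the entry matching the sequence over positions 1-312."""
        return self._by_sequence.get(gapped_sequence.upper()[:V_REGION_END])

    def genes(self) -> set[str]:
        return {a.name.gene for a in self}

    def by_gene(self) -> dict[str, list[GermlineAllele]]:
        out: dict[str, list[GermlineAllele]] = {}
        for allele in self:
            out.setdefault(allele.name.gene, []).append(allele)
        return out

    def by_family(self) -> dict[str, list[GermlineAllele]]:
        out: dict[str, list[GermlineAllele]] = {}
        for allele in self:
            out.setdefault(allele.name.family, []).append(allele)
        return out

    def copy(self) -> "GermlineDatabase":
        return GermlineDatabase(self)

    def names(self) -> list[str]:
        return list(self._records)

    def __getitem__(self, name: str) -> GermlineAllele:
        return self._records[name]

    def __contains__(self, name: object) -> bool:
        return name in self._records

    def __iter__(self) -> Iterator[GermlineAllele]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GermlineDatabase):
            return NotImplemented
        return [(a.full_name, a.gapped_sequence) for a in self] == [
            (a.full_name, a.gapped_sequence) for a in other
        ]


def _header_name(record: SeqRecord) -> str:
    # First token before '|' or whitespace; tolerates IMGT multi-field headers.
    return re.split(r"[|\s]", record.description or record.id)[0]


def read_germline_fasta(path: str | Path) -> GermlineDatabase:
    """Load an IMGT-gapped germline FASTA into a :class:`GermlineDatabase`.

    Sequences are upper-cased.  Duplicate names or non-alphabet
    characters are errors naming the offending record.
    """
    db = GermlineDatabase()
    lengths: set[int] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        name = _header_name(record)
        seq = str(record.seq).upper()
        bad = set(seq) - SEQUENCE_ALPHABET
        if bad:
            raise GermlineDatabaseError(
                f"record {name}: invalid characters {sorted(bad)}"
            )
        if name in db:
            raise GermlineDatabaseError(f"duplicate allele name {name} in {path}")
        db.add(GermlineAllele(parse_allele_name(name), seq))
        lengths.add(len(seq))
    if len(lengths) > 1:
        logger.warning(
            "gapped sequence lengths differ across %s: %s", path, sorted(lengths)
        )
    return db


def write_germline_fasta(db: GermlineDatabase, path: str | Path) -> None:
    """Write the database as gapped FASTA, preserving record order."""
    records = [
        SeqRecord(Seq(a.gapped_sequence), id=a.full_name, description="") for a in db
    ]
    SeqIO.write(records, str(path), "fasta-2line")
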