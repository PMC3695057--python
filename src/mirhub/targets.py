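"""Seed-based miRNA target prediction over 3'UTR sequences.

A target site is defined by Watson-Crick complementarity between a 3'UTR
and the miRNA seed (mature-sequence nucleotides 2-7/2-8), using the
standard site taxonomy:

========  =====================================================
8mer      match to positions 2-8 plus an A opposite position 1
7mer-m8   match to positions 2-8
7mer-A1   match to positions 2-7 plus an A opposite position 1
6mer      match to positions 2-7
========  =====================================================

Each matched locus is assigned its single strongest requested type
(8mer > 7mer-m8 > 7mer-A1 > 6mer) so one locus is never double-counted.
Conservation filtering is deliberately not implemented; sites are matched
on the given mRNA 5'->3' sequence only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .expression import GeneSet
from .io import read_fasta, write_fasta
from .seq import canonicalize, revcomp, validate_dna

log = logging.getLogger(__name__)

#: Site types in decreasing order of specificity.
SITE_HIERARCHY = ("8mer", "7mer-m8", "7mer-A1", "6mer")

#: Canonical default site set; 6mer is available but off by default.
DEFAULT_SITE_TYPES = frozenset({"8mer", "7mer-m8", "7mer-A1"})


@dataclass(frozen=True)
class MiRNASequence:
    """A mature miRNA sequence, stored 5'->3' in the DNA alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", canonicalize(self.sequence))
        if len(self.sequence) < 8:
            raise ValueError(f"miRNA {self.id!r}: mature sequence shorter than 8 nt")
        validate_dna(self.sequence, allow_n=True, context=f"miRNA {self.id!r}")

    @property
    def seed6(self) -> str:
        """Seed nucleotides 2-7 of the mature sequence."""
        return self.sequence[1:7]

    @property
    def seed7(self) -> str:
        """Seed nucleotides 2-8 of the mature sequence."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class SeedSite:
    """One predicted site: 0-based start within the UTR (5'->3' mRNA)."""

    gene_id: str | None
    start: int
    site_type: str
    word: str

    @property
    def end(self) -> int:
        return self.start + len(self.word)


@dataclass
class UTRSet:
    """Mapping of gene ID to 3'UTR sequence (5'->3', DNA alphabet)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for gene_id, seq in self.sequences.items():
            seq = canonicalize(seq)
            if not seq:
                raise ValueError(f"empty UTR for gene {gene_id!r}")
            validate_dna(seq, allow_n=True, context=f"UTR of {gene_id!r}")
            clean[gene_id] = seq
        self.sequences = clean

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.sequences

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)

    def length_of(self, gene_id: str) -> int:
        return len(self.sequences[gene_id])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "UTRSet":
        return cls(read_fasta(path))

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(self.sequences, path)


def load_mirnas(path: str | Path) -> dict[str, MiRNASequence]:
    """Load mature miRNA sequences from FASTA into ``{id: MiRNASequence}``."""
    return {name: MiRNASequence(name, seq) for name, seq in read_fasta(path).items()}


def site_words(mirna: MiRNASequence) -> dict[str, str]:
    """The mRNA word (5'->3', DNA alphabet) matched by each site type.

    8mer = revcomp(nt 2-8) + 'A'; 7mer-m8 = revcomp(nt 2-8);
    7mer-A1 = revcomp(nt 2-7) + 'A'; 6mer = revcomp(nt 2-7).
    """
    if "N" in mirna.seed7:
        raise ValueError(f"ambiguous base in seed region of miRNA {mirna.id!r}")
    core = revcomp(mirna.seed6)
    m8 = revcomp(mirna.seed7)
    return {
        "8mer": m8 + "A",
        "7mer-m8": m8,
        "7mer-A1": core + "A",
        "6mer": core,
    }


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return
        yield idx
        start = idx + 1


def find_seed_sites(
    mirna: MiRNASequence,
    utr: str,
    *,
    site_types: frozenset[str] | set[str] = DEFAULT_SITE_TYPES,
    allow_overlap: bool = True,
    gene_id: str | None = None,
) -> list[SeedSite]:
    """All seed-match sites of the requested types in one UTR.

    Loci are anchored on occurrences of the 6mer core; each locus is
    reported once, as the strongest requested type it supports. With
    ``allow_overlap=False`` sites overlapping an earlier-kept site (by
    start) are dropped.
    """
    unknown = set(site_types) - set(SITE_HIERARCHY)
    if unknown:
        raise ValueError(f"unknown site types: {sorted(unknown)}")
    utr = canonicalize(utr)
    if not utr:
        raise ValueError("empty UTR sequence")
    words = site_words(mirna)
    core = words["6mer"]
    m8_base = words["7mer-m8"][0]
    sites: list[SeedSite] = []
    for pos in _find_all(utr, core):
        has_m8 = pos >= 1 and utr[pos - 1] == m8_base
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        supported = {
            "8mer": has_m8 and has_a1,
            "7mer-m8": has_m8,
            "7mer-A1": has_a1,
            "6mer": True,
        }
        for site_type in SITE_HIERARCHY:
            if site_type in site_types and supported[site_type]:
                start = pos - 1 if site_type in ("8mer", "7mer-m8") else pos
                sites.append(SeedSite(gene_id, start, site_type, words[site_type]))
                break
    sites.sort(key=lambda s: (s.start, s.site_type))
    if not allow_overlap:
        kept: list[SeedSite] = []
        last_end = -1
        for site in sites:
            if site.start >= last_end:
                kept.append(site)
                last_end = site.end
        sites = kept
    return sites


def predict_targets(
    mirna: MiRNASequence,
    utrs: UTRSet,
    *,
    site_types: frozenset[str] | set[str] = DEFAULT_SITE_TYPES,
) -> GeneSet:
    """Genes whose UTR carries at least one site of an included type."""
    members: dict[str, str | None] = {}
    for gene_id, seq in utrs.sequences.items():
        if find_seed_sites(mirna, seq, site_types=site_types, gene_id=gene_id):
            members[gene_id] = None
    return GeneSet(f"targets:{mirna.id}", members)


def site_table(
    mirna: MiRNASequence,
    utrs: UTRSet,
    *,
    site_types: frozenset[str] | set[str] = DEFAULT_SITE_TYPES,
) -> list[SeedSite]:
    """Flat list of all sites for one miRNA across a UTR set."""
    out: list[SeedSite] = []
    for gene_id, seq in utrs.sequences.items():
        out.extend(find_seed_sites(mirna, seq, site_types=site_types, gene_id=gene_id))
    return out


def write_site_table(sites: list[SeedSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tsite_type\tword\n")
        for site in sites:
            fh.write(f"{site.gene_id}\t{site.start}\t{site.site_type}\t{site.word}\n")
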