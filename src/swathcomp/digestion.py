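"""In-silico tryptic digestion and the cross-species conserved-peptide index.

Label-free intensities of *different* peptide sequences are not comparable:
ionization efficiency varies by orders of magnitude between sequences. The
same sequence measured in different samples, however, behaves identically,
which is why a cross-species comparison must be restricted to peptides whose
amino-acid sequence is present in the proteome database of every species
compared. This module provides:

* :func:`digest_sequence` — tryptic digestion with missed cleavages,
* :func:`build_conserved_index` — which peptide occurs in which species,
* :func:`count_observable_peptides` — the iBAQ denominator (number of
  theoretically observable fully-tryptic peptides of a protein).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Cleave after K/R unless the next residue is proline (classical trypsin rule).
TRYPSIN_BLOCKED_BY_PROLINE = "trypsin_blocked_by_proline"
#: Cleave after every K/R regardless of the following residue.
TRYPSIN_P = "trypsin_p"

_ENZYME_RULES = (TRYPSIN_BLOCKED_BY_PROLINE, TRYPSIN_P)


@dataclass(frozen=True)
class ProteinEntry:
    """One database entry: accession, gene symbol and amino-acid sequence."""

    accession: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for accession {self.accession!r}")
        if not self.sequence.isupper():
            raise ValueError(f"sequence for {self.accession!r} must be uppercase")
        if not self.gene:
            raise ValueError(f"empty gene symbol for accession {self.accession!r}")


@dataclass
class Proteome:
    """A per-species protein database."""

    species: str
    entries: list[ProteinEntry]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class DigestParams:
    """Parameters of the in-silico digestion used for identification and
    conservation testing.

    Defaults mirror a typical database-search configuration: minimum peptide
    length 6 with at most two missed cleavages, trypsin blocked by proline.
    """

    enzyme_rule: str = TRYPSIN_BLOCKED_BY_PROLINE
    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int | None = None

    def __post_init__(self) -> None:
        if self.enzyme_rule not in _ENZYME_RULES:
            raise ValueError(
                f"unknown enzyme rule {self.enzyme_rule!r}; expected one of {_ENZYME_RULES}"
            )
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_length is not None and self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")


@dataclass(frozen=True)
class IbaqParams:
    """Bounds defining a "theoretically observable" tryptic peptide for iBAQ.

    The iBAQ abundance of a protein is its summed intensity divided by the
    number of fully-tryptic peptides it could in principle yield within a
    detectable length window (default 7-30 residues, no missed cleavages).
    """

    min_length: int = 7
    max_length: int = 30
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


class DigestedPeptide(NamedTuple):
    sequence: str
    missed_cleavages: int
    start: int


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    for pos, residue in enumerate(sequence):
        if not ("A" <= residue <= "Z"):
            raise ValueError(
                f"invalid residue {residue!r} at position {pos}: "
                "sequence must be uppercase alphabetic"
            )


def cleavage_sites(sequence: str, enzyme_rule: str = TRYPSIN_BLOCKED_BY_PROLINE) -> list[int]:
    """0-based positions *after* which trypsin cleaves (internal sites only)."""
    last = len(sequence) - 1
    sites = []
    for i, residue in enumerate(sequence):
        if residue in "KR" and i < last:
            if enzyme_rule == TRYPSIN_P or sequence[i + 1] != "P":
                sites.append(i + 1)
    return sites


def digest_sequence(sequence: str, params: DigestParams = DigestParams()) -> list[DigestedPeptide]:
    """Tryptic digest of ``sequence`` allowing missed cleavages.

    Returns peptides as ``(sequence, missed_cleavage_count, start)`` with
    0-based start positions, ordered by start position (then end). Peptides
    outside ``[min_length, max_length]`` are dropped.
    """
    _validate_sequence(sequence)
    bounds = [0] + cleavage_sites(sequence, params.enzyme_rule) + [len(sequence)]
    n_frag = len(bounds) - 1
    peptides: list[DigestedPeptide] = []
    for i in range(n_frag):
        for j in range(i, min(i + params.max_missed_cleavages + 1, n_frag)):
            pep = sequence[bounds[i] : bounds[j + 1]]
            if len(pep) < params.min_length:
                continue
            if params.max_length is not None and len(pep) > params.max_length:
                # longer joins only get longer; stop extending this start
                break
            peptides.append(DigestedPeptide(pep, j - i, bounds[i]))
    return peptides


def count_observable_peptides(sequence: str, ibaq: IbaqParams = IbaqParams()) -> int:
    """Number of distinct fully-tryptic peptides of ``sequence`` within the
    iBAQ length window. May be 0; callers must guard the iBAQ division."""
    params = DigestParams(
        max_missed_cleavages=ibaq.missed_cleavages,
        min_length=ibaq.min_length,
        max_length=ibaq.max_length,
    )
    return len({p.sequence for p in digest_sequence(sequence, params)})


@dataclass
class ConservedIndex:
    """Which tryptic peptide occurs in which species' database.

    ``peptide_species`` maps a peptide sequence to the set of species in whose
    digest it occurs; ``peptide_genes`` maps it to the gene symbols carrying it
    per species. A peptide is *conserved* across a species subset iff it is
    recorded for every species in that subset.
    """

    species: tuple[str, ...]
    peptide_species: dict[str, set[str]] = field(default_factory=dict)
    peptide_genes: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    params: DigestParams = DigestParams()

    def species_of(self, peptide: str) -> frozenset[str]:
        return frozenset(self.peptide_species.get(peptide, ()))

    def genes_of(self, peptide: str, species: str) -> frozenset[str]:
        return frozenset(self.peptide_genes.get(peptide, {}).get(species, ()))

    def is_conserved(self, peptide: str, species_subset: Iterable[str]) -> bool:
        subset = list(species_subset)
        if not subset:
            raise ValueError("species_subset must be non-empty")
        unknown = set(subset) - set(self.species)
        if unknown:
            raise ValueError(f"unknown species in subset: {sorted(unknown)}")
        present = self.peptide_species.get(peptide)
        if present is None:
            return False
        return all(sp in present for sp in subset)


def build_conserved_index(
    proteomes: Sequence[Proteome], params: DigestParams = DigestParams()
) -> ConservedIndex:
    """Digest every proteome and index peptide occurrence per species."""
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes to build a conserved index")
    species = [p.species for p in proteomes]
    if len(set(species)) != len(species):
        raise ValueError(f"duplicate species identifiers: {species}")
    index = ConservedIndex(species=tuple(species), params=params)
    for proteome in proteomes:
        for entry in proteome.entries:
            for pep in digest_sequence(entry.sequence, params):
                index.peptide_species.setdefault(pep.sequence, set()).add(proteome.species)
                index.peptide_genes.setdefault(pep.sequence, {}).setdefault(
                    proteome.species, set()
                ).add(entry.gene)
    logger.info(
        "conserved index: %d distinct peptides over %d species",
        len(index.peptide_species),
        len(species),
    )
    return index


def is_conserved(peptide: str, index: ConservedIndex, species_subset: Iterable[str]) -> bool:
    """Functional alias for :meth:`ConservedIndex.is_conserved`."""
    return index.is_conserved(peptide, species_subset)


_GN_RE = re.compile(r"\bGN=(\S+)")


def read_fasta_proteome(path: str | Path, species: str) -> Proteome:
    """Read a protein FASTA with UniProt-style headers.

    Accepts ``>sp|ACC|NAME ... GN=GENE`` and the simpler ``>ACC GN=GENE``.
    The gene symbol comes from the ``GN=`` field; when absent, the accession
    is used and a warning logged.
    """
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        ident = record.id
        parts = ident.split("|")
        accession = parts[1] if len(parts) >= 3 else parts[0]
        match = _GN_RE.search(record.description)
        if match:
            gene = match.group(1)
        else:
            gene = accession
            logger.warning(
                "no GN= field in FASTA header for %s; using accession as gene symbol",
                accession,
            )
        entries.append(ProteinEntry(accession, gene, str(record.seq).upper()))
    if not entries:
        raise ValueError(f"no FASTA records found in {path}")
    return Proteome(species=species, entries=entries)
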