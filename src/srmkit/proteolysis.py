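"""In-silico tryptic digestion of proteome FASTA files.

Generates fully tryptic peptides (cleavage C-terminal to K/R, suppressed
before proline by default) with bounded missed cleavages, and annotates each
peptide with its monoisotopic mass and mean Hopp-Woods hydrophilicity.
Peptides are filtered by residue count and by a mass window before entering
the downstream catalog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from pyteomics import mass as _pmass

log = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic residue masses (Da), restricted to the 20 standard letters.
MONO_RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES
}

WATER_MONO = 18.010565  # Da, monoisotopic H2O

#: Hopp-Woods hydrophilicity scale (positive = hydrophilic).
HOPP_WOODS: dict[str, float] = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}


@dataclass(frozen=True)
class ProteinEntry:
    """A single proteome entry parsed from FASTA."""

    accession: str
    description: str
    sequence: str

    @property
    def is_standard(self) -> bool:
        return bool(self.sequence) and set(self.sequence) <= STANDARD_RESIDUES


@dataclass(frozen=True)
class DigestParams:
    """Digestion filter settings.

    Defaults follow the common targeted-assay design convention:
    400-6000 Da mass window, >=5 residues, up to 3 missed cleavages,
    trypsin cleaving after K/R but not before P.
    """

    min_mass: float = 400.0
    max_mass: float = 6000.0
    min_length: int = 5
    max_missed_cleavages: int = 3
    cleave_residues: frozenset[str] = frozenset("KR")
    no_cleave_before: frozenset[str] = frozenset("P")

    def __post_init__(self) -> None:
        if self.min_mass >= self.max_mass:
            raise ValueError("min_mass must be < max_mass")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")


@dataclass
class PeptideRecord:
    """A digested peptide with provenance and physicochemical annotations."""

    sequence: str
    parent_accessions: set[str] = field(default_factory=set)
    missed_cleavages: int = 0
    mono_mass: float = 0.0
    hydrophobicity: float = 0.0
    n_term_tryptic: bool = True
    c_term_tryptic: bool = True


def mono_mass(sequence: str) -> float:
    """Monoisotopic peptide mass: residue masses plus one water."""
    if not sequence:
        raise ValueError("empty sequence has no peptide mass")
    try:
        return sum(MONO_RESIDUE_MASS[aa] for aa in sequence) + WATER_MONO
    except KeyError as exc:
        raise ValueError(f"nonstandard residue {exc.args[0]!r} in {sequence!r}") from exc


def hopp_woods(sequence: str) -> float:
    """Mean Hopp-Woods hydrophilicity over the peptide's residues."""
    if not sequence:
        raise ValueError("empty sequence has no hydrophobicity")
    try:
        return sum(HOPP_WOODS[aa] for aa in sequence) / len(sequence)
    except KeyError as exc:
        raise ValueError(f"nonstandard residue {exc.args[0]!r} in {sequence!r}") from exc


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a protein FASTA file into ProteinEntry records.

    The accession is the header token up to the first whitespace; sequences
    are upper-cased with wrapped lines concatenated. Records with empty
    sequences raise; an empty file returns an empty list with a warning.
    """
    entries: list[ProteinEntry] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().strip("*")
        if not rec.id:
            raise ValueError(f"{path}: record with empty header")
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        entries.append(ProteinEntry(rec.id, rec.description, seq))
    if not entries:
        log.warning("no FASTA records found in %s", path)
    return entries


def cleavage_sites(sequence: str, params: DigestParams) -> list[int]:
    """0-based positions after which trypsin cuts, plus the two termini.

    Returned as sorted cut indices in [0, len]; a peptide spans two cuts.
    """
    cuts = [0]
    n = len(sequence)
    for i, aa in enumerate(sequence[:-1]):
        if aa in params.cleave_residues and sequence[i + 1] not in params.no_cleave_before:
            cuts.append(i + 1)
    cuts.append(n)
    return sorted(set(cuts))


def count_missed_cleavages(sequence: str, params: DigestParams = DigestParams()) -> int:
    """Internal uncut K/R sites within a peptide (C-terminal residue excluded)."""
    return sum(
        1
        for i, aa in enumerate(sequence[:-1])
        if aa in params.cleave_residues and sequence[i + 1] not in params.no_cleave_before
    )


def digest(protein: ProteinEntry, params: DigestParams = DigestParams()) -> list[PeptideRecord]:
    """Fully tryptic digestion of one protein with missed cleavages.

    Every peptide bounded by two cleavage sites (protein termini count as
    sites) with at most ``max_missed_cleavages`` internal uncut sites is
    generated, then filtered by length and by the monoisotopic mass window.
    """
    if not protein.is_standard:
        raise ValueError(
            f"protein {protein.accession!r} contains nonstandard residues; "
            "sanitize or exclude it before digestion"
        )
    seq = protein.sequence
    cuts = cleavage_sites(seq, params)
    out: list[PeptideRecord] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + params.max_missed_cleavages, len(cuts))):
            pep = seq[cuts[a]:cuts[b]]
            if len(pep) < params.min_length:
                continue
            m = mono_mass(pep)
            if not (params.min_mass <= m <= params.max_mass):
                continue
            out.append(
                PeptideRecord(
                    sequence=pep,
                    parent_accessions={protein.accession},
                    missed_cleavages=b - a - 1,
                    mono_mass=m,
                    hydrophobicity=hopp_woods(pep),
                    n_term_tryptic=True,
                    c_term_tryptic=True,
                )
            )
    return out


def digest_proteome(
    proteins: Iterable[ProteinEntry], params: DigestParams = DigestParams()
) -> dict[str, PeptideRecord]:
    """Digest a proteome into a catalog of unique peptide sequences.

    Records with nonstandard residues are excluded and logged. Identical
    sequences from different proteins are merged, with parent accessions
    unioned; the missed-cleavage count is a property of the sequence and is
    identical across parents.
    """
    catalog: dict[str, PeptideRecord] = {}
    n_excluded = 0
    for prot in proteins:
        if not prot.is_standard:
            n_excluded += 1
            log.warning(
                "excluding %s from digestion: nonstandard residues %s",
                prot.accession,
                sorted(set(prot.sequence) - STANDARD_RESIDUES),
            )
            continue
        for rec in digest(prot, params):
            existing = catalog.get(rec.sequence)
            if existing is None:
                catalog[rec.sequence] = rec
            else:
                existing.parent_accessions |= rec.parent_accessions
    if n_excluded:
        log.warning("%d protein(s) excluded for nonstandard residues", n_excluded)
    return catalog


def write_catalog(catalog: dict[str, PeptideRecord], path: str | Path) -> None:
    """Write a peptide catalog as TSV."""
    cols = (
        "sequence\tparents\tmissed_cleavages\tmono_mass\t"
        "hydrophobicity\tnterm_tryptic\tcterm_tryptic\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for seq in sorted(catalog):
            r = catalog[seq]
            fh.write(
                f"{r.sequence}\t{','.join(sorted(r.parent_accessions))}\t"
                f"{r.missed_cleavages}\t{r.mono_mass:.6f}\t{r.hydrophobicity:.4f}\t"
                f"{int(r.n_term_tryptic)}\t{int(r.c_term_tryptic)}\n"
            )


def read_catalog(path: str | Path) -> dict[str, PeptideRecord]:
    """Read a peptide catalog TSV written by :func:`write_catalog`."""
    catalog: dict[str, PeptideRecord] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence\t"):
            raise ValueError(f"{path}: not a peptide catalog TSV")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            catalog[f[0]] = PeptideRecord(
                sequence=f[0],
                parent_accessions=set(f[1].split(",")) if f[1] else set(),
                missed_cleavages=int(f[2]),
                mono_mass=float(f[3]),
                hydrophobicity=float(f[4]),
                n_term_tryptic=bool(int(f[5])),
                c_term_tryptic=bool(int(f[6])),
            )
    return catalog


def catalog_summary(catalog: dict[str, PeptideRecord]) -> dict[str, float]:
    """Headline counts for a digestion run."""
    return {
        "n_peptides": len(catalog),
        "n_parents": len({a for r in catalog.values() for a in r.parent_accessions}),
        "mean_length": (
            sum(len(s) for s in catalog) / len(catalog) if catalog else 0.0
        ),
    }
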