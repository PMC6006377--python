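"""Peptide taxonomic specificity via lowest-common-ancestor assignment.

A peptide shared verbatim between two proteomes cannot discriminate the two
species, so assay design must drop it. For peptides observed across many
taxa, the deepest taxonomic rank at which all carrying organisms agree (the
LCA) measures how specific the peptide is. All lookups are offline: the
caller supplies a lineage table and a peptide->taxa occurrence map as TSVs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

#: Reporting ranks, shallow to deep. Input lineages may carry intermediate
#: ranks; those participate in LCA depth comparison via their position in the
#: lineage, but profiles are tallied on whatever rank names the table uses.
CANONICAL_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class TaxonLineage:
    """Ordered (rank, name) pairs from the root down to the taxon itself."""

    taxon_id: str
    ranked: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ranks = [r for r, _ in self.ranked]
        if len(ranks) != len(set(ranks)):
            raise ValueError(f"duplicate rank in lineage of {self.taxon_id}")


@dataclass(frozen=True)
class SpecificityCall:
    peptide: str
    lca_rank: str
    lca_name: str
    discriminatory: bool


def read_lineages(path: str | Path) -> dict[str, TaxonLineage]:
    """Read a lineage TSV with columns taxon_id, rank, name (one row per rank).

    Rows for one taxon must appear in shallow-to-deep order.
    """
    acc: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("taxon_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns, got {len(parts)}")
            tid, rank, name = parts
            acc.setdefault(tid, []).append((rank, name))
    return {tid: TaxonLineage(tid, tuple(rows)) for tid, rows in acc.items()}


def read_peptide_taxon_map(path: str | Path) -> dict[str, set[str]]:
    """Read a peptide->taxon occurrence TSV with columns peptide, taxon_id."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("peptide\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def _normalize(seq: str, equate_il: bool) -> str:
    return seq.replace("L", "I") if equate_il else seq


def shared_peptides(
    catalog_a: Iterable[str],
    catalog_b: Iterable[str],
    equate_il: bool = False,
) -> set[str]:
    """Peptide sequences present in both catalogs.

    With ``equate_il=True`` isoleucine and leucine are treated as identical
    (they are isobaric and indistinguishable by mass alone); the returned
    sequences are then in I-normalized form.
    """
    a = {_normalize(s, equate_il) for s in catalog_a}
    b = {_normalize(s, equate_il) for s in catalog_b}
    return a & b


def lca_of_taxa(
    taxa: Iterable[str], lineages: Mapping[str, TaxonLineage]
) -> tuple[str, str]:
    """Deepest (rank, name) on which all the given taxa's lineages agree.

    Returns ("root", "root") when the lineages disagree already at the
    shallowest rank.
    """
    taxa = list(taxa)
    if not taxa:
        raise ValueError("empty taxon set has no LCA")
    try:
        paths = [lineages[t].ranked for t in taxa]
    except KeyError as exc:
        raise KeyError(f"taxon {exc.args[0]!r} missing from lineage table") from exc
    lca = ("root", "root")
    for depth in range(min(len(p) for p in paths)):
        level = {p[depth] for p in paths}
        if len(level) != 1:
            break
        lca = next(iter(level))
    return lca


def lca_assign(
    peptide: str,
    peptide_taxa: Mapping[str, set[str]],
    lineages: Mapping[str, TaxonLineage],
    target_clade: str,
) -> SpecificityCall:
    """Assign a peptide its LCA rank and a discriminatory flag.

    A peptide is discriminatory for ``target_clade`` when its LCA lies at or
    below that clade, i.e. every organism carrying the sequence is inside the
    clade. A peptide absent from the occurrence map yields an "unknown" call.
    """
    taxa = peptide_taxa.get(peptide)
    if not taxa:
        return SpecificityCall(peptide, "unknown", "unknown", False)
    paths = [lineages[t].ranked for t in taxa]
    agreed: list[tuple[str, str]] = []
    for depth in range(min(len(p) for p in paths)):
        level = {p[depth] for p in paths}
        if len(level) != 1:
            break
        agreed.append(next(iter(level)))
    if not agreed:
        return SpecificityCall(peptide, "root", "root", False)
    rank, name = agreed[-1]
    discriminatory = any(n == target_clade for _, n in agreed)
    return SpecificityCall(peptide, rank, name, discriminatory)


def specificity_profile(calls: Iterable[SpecificityCall]) -> dict[str, int]:
    """Tally of specificity calls per LCA rank."""
    return dict(Counter(c.lca_rank for c in calls))


def write_specificity(calls: Iterable[SpecificityCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tlca_rank\tlca_name\tdiscriminatory\n")
        for c in calls:
            fh.write(f"{c.peptide}\t{c.lca_rank}\t{c.lca_name}\t{int(c.discriminatory)}\n")
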