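"""Build SRM transition lists from candidate peptides and a spectral library.

A transition is one (peptide precursor, fragment ion) pair monitored on the
triple quadrupole. Fragments observed reproducibly across library technical
replicates are scored by relative intensity; peptides with enough quality
fragments are kept, capped at a fixed number of transitions per peptide and
peptides per protein, and the final list is split across method files so a
single instrument run stays within its duty cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .proteolysis import MONO_RESIDUE_MASS, WATER_MONO

log = logging.getLogger(__name__)

PROTON_MONO = 1.007276  # Da


@dataclass(frozen=True)
class Fragment:
    ion_type: str  # "b" or "y"
    ordinal: int
    charge: int
    mz: float
    rel_intensity: float = 0.0


@dataclass
class LibraryEntry:
    """One peptide precursor's fragment evidence from a spectral library."""

    peptide: str
    precursor_charge: int
    fragments: list[Fragment]
    replicates_detected: Mapping[tuple[str, int, int], int]  # fragment key -> count


@dataclass(frozen=True)
class Transition:
    protein: str
    peptide: str
    precursor_charge: int
    ion_type: str
    ordinal: int
    fragment_charge: int
    mz: float
    quality: float


@dataclass
class AssayDefinition:
    """The scheduled assay: transitions grouped per peptide with caps recorded."""

    transitions: list[Transition] = field(default_factory=list)
    method_file: dict[tuple[str, int], int] = field(default_factory=dict)  # (peptide, z) -> file idx
    not_schedulable: list[str] = field(default_factory=list)
    transitions_per_peptide: int = 4
    peptides_per_protein: int = 3
    min_quality_transitions: int = 3

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.transitions:
            rows.append(
                {
                    "protein": t.protein,
                    "peptide": t.peptide,
                    "precursor_charge": t.precursor_charge,
                    "precursor_mz": precursor_mz(t.peptide, t.precursor_charge),
                    "ion_type": t.ion_type,
                    "ordinal": t.ordinal,
                    "fragment_charge": t.fragment_charge,
                    "fragment_mz": t.mz,
                    "quality": t.quality,
                    "method_file": self.method_file[(t.peptide, t.precursor_charge)],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "protein", "peptide", "precursor_charge", "precursor_mz",
                "ion_type", "ordinal", "fragment_charge", "fragment_mz",
                "quality", "method_file",
            ],
        )


def precursor_mz(peptide: str, charge: int) -> float:
    neutral = sum(MONO_RESIDUE_MASS[aa] for aa in peptide) + WATER_MONO
    return (neutral + charge * PROTON_MONO) / charge


def theoretical_fragments(
    peptide: str, precursor_charge: int = 2, max_fragment_charge: int = 1
) -> list[Fragment]:
    """Theoretical b/y fragment ions for a peptide.

    b_k is the sum of the first k residue masses; y_k the sum of the last k
    plus water. m/z = (neutral + z * proton) / z. Ordinals run 1..n-1.
    """
    if len(peptide) < 2:
        raise ValueError("peptide must have at least 2 residues to fragment")
    if precursor_charge < 1 or max_fragment_charge < 1:
        raise ValueError("charges must be >= 1")
    masses = [MONO_RESIDUE_MASS[aa] for aa in peptide]
    n = len(peptide)
    out: list[Fragment] = []
    prefix = 0.0
    suffix = [0.0] * (n + 1)
    for k in range(1, n + 1):
        suffix[k] = suffix[k - 1] + masses[n - k]
    for k in range(1, n):
        prefix += masses[k - 1]
        for z in range(1, max_fragment_charge + 1):
            out.append(Fragment("b", k, z, (prefix + z * PROTON_MONO) / z))
            out.append(Fragment("y", k, z, (suffix[k] + WATER_MONO + z * PROTON_MONO) / z))
    return out


def _tie_key(frag: Fragment) -> tuple:
    # deterministic tie-break: higher m/z, then y before b, then lower ordinal
    return (-frag.mz, 0 if frag.ion_type == "y" else 1, frag.ordinal)


def score_transition_quality(entry: LibraryEntry, min_replicates: int = 2) -> dict[tuple[str, int, int], float]:
    """Rank-based quality scores for a library entry's fragments.

    Fragments detected in fewer than ``min_replicates`` technical replicates
    score 0 (not schedulable). Qualifying fragments are ranked by relative
    intensity (descending) with a deterministic tie-break on (higher m/z,
    y before b, lower ordinal); the top fragment of an entry with F
    qualifying fragments scores F, the bottom scores 1.
    """
    qualifying = [
        f
        for f in entry.fragments
        if entry.replicates_detected.get((f.ion_type, f.ordinal, f.charge), 0) >= min_replicates
    ]
    ordered = sorted(qualifying, key=lambda f: (-f.rel_intensity, *_tie_key(f)))
    scores: dict[tuple[str, int, int], float] = {
        (f.ion_type, f.ordinal, f.charge): 0.0 for f in entry.fragments
    }
    nq = len(ordered)
    for i, f in enumerate(ordered):
        scores[(f.ion_type, f.ordinal, f.charge)] = float(nq - i)
    return scores


def read_library(path: str | Path) -> list[LibraryEntry]:
    """Read a spectral-library TSV export.

    Columns: peptide, precursor_charge, ion_type, ordinal, fragment_charge,
    mz, rel_intensity, replicates_detected.
    """
    df = pd.read_csv(path, sep="\t")
    required = {
        "peptide", "precursor_charge", "ion_type", "ordinal",
        "fragment_charge", "mz", "rel_intensity", "replicates_detected",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: library TSV missing columns {sorted(missing)}")
    entries = []
    for (pep, z), grp in df.groupby(["peptide", "precursor_charge"]):
        frags = []
        reps = {}
        for row in grp.itertuples():
            key = (row.ion_type, int(row.ordinal), int(row.fragment_charge))
            frags.append(Fragment(row.ion_type, int(row.ordinal), int(row.fragment_charge),
                                  float(row.mz), float(row.rel_intensity)))
            reps[key] = int(row.replicates_detected)
        entries.append(LibraryEntry(pep, int(z), frags, reps))
    return entries


def _split_method_files(peptide_sizes: list[tuple[tuple[str, int], int]], n_files: int) -> dict[tuple[str, int], int]:
    """Greedy longest-processing-time balance of peptides across method files.

    A peptide's transitions are never split across files (they must be
    co-acquired to quantify the peptide), so file sizes are balanced to
    within one peptide's transition count.
    """
    loads = [0] * n_files
    assign: dict[tuple[str, int], int] = {}
    for key, size in sorted(peptide_sizes, key=lambda kv: (-kv[1], kv[0])):
        idx = min(range(n_files), key=lambda i: (loads[i], i))
        assign[key] = idx
        loads[idx] += size
    return assign


def build_assay(
    candidates: Iterable[str],
    library: Sequence[LibraryEntry],
    protein_of: Mapping[str, str],
    min_quality_transitions: int = 3,
    transitions_per_peptide: int = 4,
    peptides_per_protein: int = 3,
    min_replicates: int = 2,
    n_method_files: int = 2,
) -> AssayDefinition:
    """Assemble the final transition list under the selection caps.

    Candidate peptides with a library entry and at least
    ``min_quality_transitions`` reproducible fragments are kept; each
    contributes its top ``transitions_per_peptide`` fragments by quality.
    Within a protein, only the ``peptides_per_protein`` peptides with the
    highest summed transition quality are retained. Candidates without a
    usable library entry are listed as not schedulable, never silently
    dropped.
    """
    candidates = set(candidates)
    by_pep: dict[str, list[LibraryEntry]] = {}
    for e in library:
        by_pep.setdefault(e.peptide, []).append(e)

    per_protein: dict[str, list[tuple[float, str, int, list[Transition]]]] = {}
    not_schedulable = sorted(candidates - set(by_pep))
    for pep in sorted(candidates & set(by_pep)):
        prot = protein_of.get(pep, "unknown")
        best: tuple[float, str, int, list[Transition]] | None = None
        for entry in by_pep[pep]:
            scores = score_transition_quality(entry, min_replicates)
            scored = [
                (scores[(f.ion_type, f.ordinal, f.charge)], f) for f in entry.fragments
            ]
            qualifying = [(q, f) for q, f in scored if q > 0]
            if len(qualifying) < min_quality_transitions:
                continue
            top = sorted(qualifying, key=lambda qf: (-qf[0], *_tie_key(qf[1])))
            top = top[:transitions_per_peptide]
            trans = [
                Transition(prot, pep, entry.precursor_charge, f.ion_type,
                           f.ordinal, f.charge, f.mz, q)
                for q, f in top
            ]
            total = sum(q for q, _ in top)
            if best is None or total > best[0]:
                best = (total, pep, entry.precursor_charge, trans)
        if best is None:
            not_schedulable.append(pep)
        else:
            per_protein.setdefault(prot, []).append(best)

    assay = AssayDefinition(
        transitions_per_peptide=transitions_per_peptide,
        peptides_per_protein=peptides_per_protein,
        min_quality_transitions=min_quality_transitions,
    )
    kept: list[tuple[tuple[str, int], list[Transition]]] = []
    for prot in sorted(per_protein):
        ranked = sorted(per_protein[prot], key=lambda b: (-b[0], b[1]))
        for total, pep, z, trans in ranked[:peptides_per_protein]:
            kept.append(((pep, z), trans))
        for total, pep, z, trans in ranked[peptides_per_protein:]:
            log.info("peptide %s dropped by per-protein cap on %s", pep, prot)

    sizes = [(key, len(trans)) for key, trans in kept]
    assay.method_file = _split_method_files(sizes, n_method_files)
    for key, trans in kept:
        assay.transitions.extend(trans)
    assay.not_schedulable = sorted(set(not_schedulable))
    return assay
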