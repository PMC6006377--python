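import numpy as np
import pandas as pd
import pytest

from srmkit.proteolysis import DigestParams
from srmkit.simulate import SimulationConfig, make_design


@pytest.fixture
def default_params():
    return DigestParams()


@pytest.fixture
def design():
    return make_design()


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=42)


@pytest.fixture
def toy_psm_table():
    """Five proteins with engineered peptide counts and tryptic termini.

    PA: 3 peptides, tryptic -> kept. PB: 1 peptide -> dropped (min_peptides).
    PC: 2 peptides, all termini 0 -> dropped. PD: 2 peptides, one tryptic
    -> kept. PE: 2 peptides but prob_pass False -> dropped upstream.
    """
    rows = []

    def add(prot, pep, tt, ok=True, sample="62:1|rep1", dil="62:1", rep=1, sc=4):
        rows.append(
            {"sample": sample, "replicate": rep, "dilution_label": dil,
             "protein": prot, "peptide": pep, "spectral_count": sc,
             "tryptic_termini": tt, "prob_pass": ok}
        )

    for pep in ("AAK", "CCK", "DDR"):
        add("PA", pep, 2)
    add("PB", "EEK", 2)
    add("PC", "FFK", 0)
    add("PC", "GGK", 0)
    add("PD", "HHK", 1)
    add("PD", "IIK", 0)
    add("PE", "LLK", 2, ok=False)
    add("PE", "MMK", 2, ok=False)
    return pd.DataFrame(rows)


@pytest.fixture
def toy_lineages(tmp_path):
    """Toy lineage table: two Rhodobacteraceae, one other bacterium, one diatom."""
    rows = [
        # Ruegeria pomeroyi
        ("rpom", [("kingdom", "Bacteria"), ("phylum", "Proteobacteria"),
                  ("class", "Alphaproteobacteria"), ("order", "Rhodobacterales"),
                  ("family", "Rhodobacteraceae"), ("genus", "Ruegeria"),
                  ("species", "Ruegeria pomeroyi")]),
        ("phaeo", [("kingdom", "Bacteria"), ("phylum", "Proteobacteria"),
                   ("class", "Alphaproteobacteria"), ("order", "Rhodobacterales"),
                   ("family", "Rhodobacteraceae"), ("genus", "Phaeobacter"),
                   ("species", "Phaeobacter inhibens")]),
        ("ecoli", [("kingdom", "Bacteria"), ("phylum", "Proteobacteria"),
                   ("class", "Gammaproteobacteria"), ("order", "Enterobacterales"),
                   ("family", "Enterobacteriaceae"), ("genus", "Escherichia"),
                   ("species", "Escherichia coli")]),
        ("thaps", [("kingdom", "Chromista"), ("phylum", "Bacillariophyta"),
                   ("class", "Coscinodiscophyceae"), ("order", "Thalassiosirales"),
                   ("family", "Thalassiosiraceae"), ("genus", "Thalassiosira"),
                   ("species", "Thalassiosira pseudonana")]),
    ]
    path = tmp_path / "lineages.tsv"
    with open(path, "w") as fh:
        fh.write("taxon_id\trank\tname\n")
        for tid, lineage in rows:
            for rank, name in lineage:
                fh.write(f"{tid}\t{rank}\t{name}\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(7)
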