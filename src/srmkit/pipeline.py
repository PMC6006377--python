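"""End-to-end pipeline orchestration with provenance manifests.

Chains the stages digest -> specificity -> discover -> assay -> evaluate on
user data, or runs the fully synthetic test bed (simulate -> all stages).
Every run directory gets a manifest recording parameters, seeds and SHA-256
digests of the stage outputs, so a rerun with the same configuration can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assay import build_assay, read_library
from .discovery import (
    average_technical_replicates,
    axis_loadings,
    bray_curtis_matrix,
    filter_inferences,
    nmds_scores,
    nsaf,
    select_candidates,
)
from .proteolysis import DigestParams, digest_proteome, read_fasta, write_catalog
from .simulate import (
    SimulationConfig,
    gen_proteomes,
    make_design,
    make_library,
    simulate_dda,
    simulate_srm,
    write_fasta,
)
from .srm import fit_normalization, normalize, screen_transitions, write_report

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters for a full synthetic-to-evaluation pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    digest: DigestParams = field(default_factory=DigestParams)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    min_peptides: int = 2
    loading_threshold: float = 0.99
    n_perm: int = 1000
    min_quality_transitions: int = 3
    transitions_per_peptide: int = 4
    peptides_per_protein: int = 3
    qc_n: int = 8
    qc_cv_max: float = 40.0
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        digest = DigestParams(**raw.pop("digest", {}))
        sim = SimulationConfig(**raw.pop("sim", {}))
        return cls(digest=digest, sim=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run simulate -> digest -> specificity -> discover -> assay -> evaluate.

    Returns the run directory. Any stage failure propagates with the stage
    name; outputs of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(**{**asdict(config.sim), "seed": config.seed})
    stage = "simulate"
    try:
        design = make_design(per_cell_ratio=sim.per_cell_ratio)
        bact, phyto, planted = gen_proteomes(sim)
        write_fasta(bact, out / "bact.fasta")
        write_fasta(phyto, out / "phyto.fasta")
        (out / "planted_shared.tsv").write_text("\n".join(planted) + "\n")
        psm = simulate_dda(design, bact, phyto, sim)
        psm.to_csv(out / "psm.tsv", sep="\t", index=False)

        stage = "digest"
        cat_b = digest_proteome(read_fasta(out / "bact.fasta"), config.digest)
        cat_p = digest_proteome(read_fasta(out / "phyto.fasta"), config.digest)
        write_catalog(cat_b, out / "catalog_bact.tsv")
        write_catalog(cat_p, out / "catalog_phyto.tsv")

        stage = "specificity"
        from .taxonomy import shared_peptides

        shared = shared_peptides(cat_b, cat_p)
        (out / "shared_peptides.tsv").write_text("\n".join(sorted(shared)) + "\n")

        stage = "discover"
        psm_f = filter_inferences(psm, min_peptides=config.min_peptides)
        bact_psm = psm_f[psm_f["species"] == "bact"] if "species" in psm_f else psm_f
        avg = average_technical_replicates(bact_psm)
        lengths = {p.accession: len(p.sequence) for p in bact + phyto}
        mat = nsaf(avg, lengths)
        dism = bray_curtis_matrix(mat)
        scores = nmds_scores(dism, seed=config.seed)
        loadings = axis_loadings(mat, scores["axis1"], n_perm=config.n_perm, seed=config.seed)
        cands = select_candidates(
            bact_psm, loadings, shared,
            loading_threshold=config.loading_threshold,
        )
        cands.to_frame().to_csv(out / "candidates.tsv", sep="\t", index=False)

        stage = "assay"
        lib = make_library(sorted(cands.peptides), sim)
        lib.to_csv(out / "library.tsv", sep="\t", index=False)
        protein_of = (
            bact_psm.drop_duplicates("peptide").set_index("peptide")["protein"].to_dict()
        )
        assay = build_assay(
            cands.peptides,
            read_library(out / "library.tsv"),
            protein_of,
            min_quality_transitions=config.min_quality_transitions,
            transitions_per_peptide=config.transitions_per_peptide,
            peptides_per_protein=config.peptides_per_protein,
        )
        assay.to_frame().to_csv(out / "assay.tsv", sep="\t", index=False)

        stage = "evaluate"
        quant, truth = simulate_srm(design, sim)
        quant.to_csv(out / "quant.csv", index=False)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        model = fit_normalization(quant, n_qc=config.qc_n, cv_threshold=config.qc_cv_max)
        normed = normalize(quant, model)
        report = screen_transitions(normed, alpha=config.alpha)
        write_report(report, out / "report")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "srmkit_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            "digest": asdict(config.digest)
            | {
                "cleave_residues": sorted(config.digest.cleave_residues),
                "no_cleave_before": sorted(config.digest.no_cleave_before),
            },
            "sim": asdict(sim),
            "qc_n": config.qc_n,
            "qc_cv_max": config.qc_cv_max,
            "alpha": config.alpha,
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
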