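"""Spectral-count statistics and candidate selection from DDA results.

Operates on long-format PSM tables (one row per sample x protein x peptide
with a spectral count), providing protein-inference filtering, NSAF
abundance normalization, Bray-Curtis / non-metric MDS ordination support,
permutation tests (axis loadings, ANOSIM), and selection of candidate
peptides for targeted assays by three criteria: ubiquity across dilutions
and replicates, uniqueness to low-dilution samples, and driving the
ordination separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.stats import rankdata
from sklearn.manifold import MDS

log = logging.getLogger(__name__)

PSM_COLUMNS = (
    "sample",
    "replicate",
    "dilution_label",
    "protein",
    "peptide",
    "spectral_count",
    "tryptic_termini",
)


@dataclass
class CandidateSet:
    """Peptides selected for targeted assays, with their selection reasons."""

    reasons: dict[str, set[str]] = field(default_factory=dict)
    excluded_shared: set[str] = field(default_factory=set)

    @property
    def peptides(self) -> set[str]:
        return set(self.reasons)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"peptide": p, "reasons": ",".join(sorted(rs))}
            for p, rs in sorted(self.reasons.items())
        ]
        return pd.DataFrame(rows, columns=["peptide", "reasons"])


def validate_psm_table(table: pd.DataFrame) -> None:
    missing = [c for c in PSM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"PSM table missing columns: {missing}")
    if (table["spectral_count"] < 1).any():
        raise ValueError("spectral counts must be >= 1")


def filter_inferences(
    table: pd.DataFrame,
    min_peptides: int = 2,
    require_prob_pass: bool = True,
) -> pd.DataFrame:
    """Apply protein-inference acceptance filters to a PSM table.

    A protein is retained when it has at least ``min_peptides`` distinct
    peptide sequences, at least one of which has one or more tryptic termini.
    Upstream search-engine probability filtering is represented by an
    optional boolean ``prob_pass`` column; rows failing it are dropped first.
    """
    validate_psm_table(table)
    df = table
    if require_prob_pass and "prob_pass" in df.columns:
        df = df[df["prob_pass"].astype(bool)]
    grp = df.groupby("protein")
    n_pep = grp["peptide"].nunique()
    has_tryptic = grp["tryptic_termini"].max() >= 1
    keep = n_pep.index[(n_pep >= min_peptides) & has_tryptic]
    return df[df["protein"].isin(keep)].copy()


def average_technical_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean spectral count across technical replicates of the same sample."""
    keys = ["sample", "dilution_label", "protein", "peptide"]
    out = table.groupby(keys, as_index=False)["spectral_count"].mean()
    if "tryptic_termini" in table.columns:
        tt = table.groupby(keys, as_index=False)["tryptic_termini"].max()
        out = out.merge(tt, on=keys)
    return out


def nsaf(table: pd.DataFrame, lengths: Mapping[str, int]) -> pd.DataFrame:
    """Normalized spectral abundance factor matrix (proteins x samples).

    NSAF_i = (S_i / L_i) / sum_j (S_j / L_j) within each sample, where S is
    the protein's summed spectral count and L its residue length. Columns of
    the returned matrix each sum to 1.
    """
    counts = (
        table.groupby(["protein", "sample"])["spectral_count"].sum().unstack(fill_value=0)
    )
    missing = [p for p in counts.index if p not in lengths]
    if missing:
        raise KeyError(f"no length for protein(s): {missing[:5]}")
    lens = np.array([lengths[p] for p in counts.index], dtype=float)
    saf = counts.to_numpy(dtype=float) / lens[:, None]
    colsum = saf.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("a sample has zero total spectral abundance")
    return pd.DataFrame(saf / colsum, index=counts.index, columns=counts.columns)


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be nonnegative")
    if x.sum() + y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_braycurtis(x, y))


def bray_curtis_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between sample columns."""
    cols = list(matrix.columns)
    n = len(cols)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(matrix.iloc[:, i], matrix.iloc[:, j])
    return pd.DataFrame(d, index=cols, columns=cols)


def nmds_scores(dissimilarity: pd.DataFrame, seed: int = 0, n_components: int = 2) -> pd.DataFrame:
    """Non-metric MDS embedding of a sample dissimilarity matrix.

    Delegated to scikit-learn's SMACOF-based non-metric MDS (Kruskal
    stress-1 minimization); the seed pins the embedding.
    """
    mds = MDS(
        n_components=n_components,
        metric_mds=False,
        dissimilarity="precomputed",
        random_state=seed,
        normalized_stress="auto",
        n_init=4,
    )
    coords = mds.fit_transform(dissimilarity.to_numpy())
    return pd.DataFrame(
        coords,
        index=dissimilarity.index,
        columns=[f"axis{i + 1}" for i in range(n_components)],
    )


def axis_loadings(
    matrix: pd.DataFrame,
    axis_scores: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-protein loading on an ordination axis with a permutation p-value.

    The loading is the Pearson correlation between a protein's abundances
    across samples and the samples' axis coordinates. Significance is a
    two-sided permutation test on |loading|:
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm), so the smallest
    attainable p is 1/(1 + n_perm). Constant protein rows are reported with
    missing loading and p.
    """
    scores = axis_scores.reindex(matrix.columns).to_numpy(dtype=float)
    if np.isnan(scores).any():
        raise ValueError("axis_scores missing for some samples")
    x = matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    sc = scores - scores.mean()
    sc_norm = np.sqrt((sc**2).sum())
    xc = x - x.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((xc**2).sum(axis=1))
    constant = x_norm == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r_obs = (xc @ sc) / (x_norm * sc_norm)
    exceed = np.zeros(x.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(sc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r_perm = (xc @ perm) / (x_norm * sc_norm)
        exceed += np.abs(r_perm) >= np.abs(r_obs) - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    r_obs[constant] = np.nan
    pvals[constant] = np.nan
    return pd.DataFrame({"loading": r_obs, "p_value": pvals}, index=matrix.index)


def anosim(
    dissimilarities: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Analysis of similarities on a sample dissimilarity matrix.

    R = (mean rank of between-group dissimilarities - mean rank of
    within-group dissimilarities) / (M/2) with M = n(n-1)/2 pairs and
    midranks for ties; R is in [-1, 1]. The p-value permutes group labels:
    p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    """
    labels = pd.Series(groups).reindex(dissimilarities.index)
    if labels.isna().any():
        raise ValueError("group label missing for some samples")
    if labels.nunique() < 2:
        raise ValueError("ANOSIM needs at least two groups")
    d = dissimilarities.to_numpy(dtype=float)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    m = n * (n - 1) / 2

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        if not within.any() or within.all():
            raise ValueError("ANOSIM needs both within- and between-group pairs")
        return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2))

    lab = labels.to_numpy()
    r_obs = r_stat(lab)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(lab)) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1.0 + count) / (1.0 + n_perm)


def select_candidates(
    table: pd.DataFrame,
    loadings: pd.DataFrame,
    shared: set[str],
    protein_peptides: Mapping[str, Iterable[str]] | None = None,
    low_dilutions: Sequence[str] = (),
    loading_threshold: float = 0.99,
    p_threshold: float | None = None,
) -> CandidateSet:
    """Select targeted-assay candidate peptides by three criteria.

    1. *ubiquitous*: detected in every dilution and every replicate;
    2. *unique-to-low-dilution*: detected only in the named low-dilution
       samples (where the target species is hardest to see);
    3. *ordination-driver*: peptides of proteins whose axis loading exceeds
       ``loading_threshold`` with permutation p at or below ``p_threshold``
       (default: the minimum attainable p among the supplied loadings).

    Peptides in the cross-proteome ``shared`` set are excluded regardless of
    the criteria they meet.
    """
    validate_psm_table(table)
    reasons: dict[str, set[str]] = {}

    dilutions = set(table["dilution_label"].unique())
    pairs = table[["dilution_label", "replicate"]].drop_duplicates()
    n_pairs = len(pairs)
    per_pep = table.groupby("peptide")[["dilution_label", "replicate"]].apply(
        lambda g: len(g.drop_duplicates())
    )
    for pep in per_pep.index[per_pep == n_pairs]:
        reasons.setdefault(pep, set()).add("ubiquitous")

    if low_dilutions:
        low = set(low_dilutions)
        if not low <= dilutions:
            log.warning("low dilutions %s not all present in table", sorted(low - dilutions))
        seen_in = table.groupby("peptide")["dilution_label"].agg(set)
        for pep, seen in seen_in.items():
            if seen and seen <= low:
                reasons.setdefault(pep, set()).add("unique-to-low-dilution")

    if len(loadings):
        valid = loadings.dropna(subset=["loading", "p_value"])
        if p_threshold is None and len(valid):
            p_threshold = float(valid["p_value"].min()) + 1e-12
        drivers = valid.index[
            (valid["loading"] > loading_threshold) & (valid["p_value"] <= p_threshold)
        ]
        pep_of = protein_peptides
        if pep_of is None:
            pep_of = table.groupby("protein")["peptide"].agg(set).to_dict()
        for prot in drivers:
            for pep in pep_of.get(prot, ()):
                reasons.setdefault(pep, set()).add("ordination-driver")

    excluded = {p for p in reasons if p in shared}
    for p in excluded:
        del reasons[p]
    if not reasons:
        log.warning("no candidate peptides selected")
    return CandidateSet(reasons=reasons, excluded_shared=excluded)
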