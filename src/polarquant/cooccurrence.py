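"""Gene co-occurrence profiling over genome presence/absence matrices.

Genes whose phylogenetic profile (the boolean vector of which genomes carry a
homolog) resembles that of a reference gene are candidate functional partners.
The default similarity is the Jaccard index, which ignores genomes where both
genes are absent — appropriate when the genes of interest occur in only a
small slice of a large genome panel. The phi coefficient is available as an
alternative that does credit shared absences.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PresenceAbsenceMatrix",
    "ProfileSimilarity",
    "load_matrix",
    "profile_similarity",
    "cooccurrence_table",
]

TAXON_COLUMNS = ("genome", "phylum", "class", "order")


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Boolean genomes x genes table plus per-genome taxon metadata.

    ``values`` is indexed by genome name with one boolean column per gene;
    ``taxa`` carries (genome, phylum, class, order), same index.
    """

    values: pd.DataFrame
    taxa: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate genome names")
        if pd.Index(self.values.columns).duplicated().any():
            raise ValueError("duplicate gene names")
        if not self.values.dtypes.map(lambda d: d == bool).all():
            raise ValueError("matrix values must be boolean")
        if not self.values.index.equals(self.taxa.index):
            raise ValueError("taxa index must match matrix index")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genomes(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path) -> None:
        out = self.taxa.copy()
        for g in self.values.columns:
            out[g] = self.values[g].astype(int)
        out.insert(0, "genome", out.index)
        out.to_csv(path, sep="\t", index=False)


def load_matrix(path) -> PresenceAbsenceMatrix:
    """Parse a TSV with taxon columns (genome, phylum, class, order) followed
    by one 0/1 column per gene. Ragged rows, duplicates and non-binary values
    are rejected with the offending line/name."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed matrix TSV: {exc}") from exc
    missing = [c for c in TAXON_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"matrix TSV missing taxon columns {missing}")
    gene_cols = [c for c in df.columns if c not in TAXON_COLUMNS]
    if not gene_cols:
        raise ValueError("matrix TSV has no gene columns")
    if df["genome"].duplicated().any():
        dup = df["genome"][df["genome"].duplicated()].iloc[0]
        raise ValueError(f"duplicate genome name: {dup}")
    values = {}
    for g in gene_cols:
        col = df[g]
        bad = ~col.isin(["0", "1"])
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
            raise ValueError(f"non-0/1 value {col[bad].iloc[0]!r} for gene {g} at line {line}")
        values[g] = col.astype(int).astype(bool).to_numpy()
    idx = pd.Index(df["genome"], name="genome")
    taxa = df[list(TAXON_COLUMNS[1:])].set_index(idx)
    return PresenceAbsenceMatrix(values=pd.DataFrame(values, index=idx), taxa=taxa)


@dataclass(frozen=True)
class ProfileSimilarity:
    """Similarity of one gene's profile to the reference gene's profile."""

    gene: str
    score: float
    both_present: int
    only_reference: int
    only_gene: int
    both_absent: int


def _score(a: np.ndarray, b: np.ndarray, metric: str) -> tuple[float, int, int, int, int]:
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    if metric == "jaccard":
        denom = n11 + n10 + n01
        score = n11 / denom if denom else 0.0
    elif metric == "phi":
        denom = np.sqrt(float(n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
        score = (n11 * n00 - n10 * n01) / denom if denom else 0.0
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return float(score), n11, n10, n01, n00


def profile_similarity(matrix: PresenceAbsenceMatrix, reference_gene: str,
                       metric: str = "jaccard") -> list[ProfileSimilarity]:
    """Rank all other genes by profile similarity to ``reference_gene``.

    Descending score, ties broken alphabetically; the reference is excluded.
    """
    if reference_gene not in matrix.values.columns:
        raise KeyError(f"reference gene {reference_gene!r} not in matrix")
    ref = matrix.values[reference_gene].to_numpy()
    out = []
    for gene in matrix.genes:
        if gene == reference_gene:
            continue
        score, n11, n10, n01, n00 = _score(ref, matrix.values[gene].to_numpy(), metric)
        out.append(ProfileSimilarity(gene=gene, score=score, both_present=n11,
                                     only_reference=n10, only_gene=n01, both_absent=n00))
    out.sort(key=lambda r: (-r.score, r.gene))
    return out


def cooccurrence_table(matrix: PresenceAbsenceMatrix, gene_subset=None,
                       metric: str = "jaccard") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise similarity matrix plus per-taxon presence fractions.

    Returns (scores, taxon_summary): ``scores`` is symmetric with unit
    diagonal over ``gene_subset`` (default: all genes); ``taxon_summary`` is
    long-format (level, taxon, gene, fraction_present) grouped at the phylum,
    class and order levels.
    """
    genes = list(gene_subset) if gene_subset is not None else matrix.genes
    unknown = [g for g in genes if g not in matrix.values.columns]
    if unknown:
        raise KeyError(f"genes not in matrix: {unknown}")
    n = len(genes)
    scores = np.ones((n, n))
    for i in range(n):
        a = matrix.values[genes[i]].to_numpy()
        for j in range(i + 1, n):
            s, *_ = _score(a, matrix.values[genes[j]].to_numpy(), metric)
            scores[i, j] = scores[j, i] = s
    score_df = pd.DataFrame(scores, index=genes, columns=genes)

    rows = []
    for level in ("phylum", "class", "order"):
        grouped = matrix.values[genes].groupby(matrix.taxa[level])
        frac = grouped.mean()
        for taxon, row in frac.iterrows():
            for gene in genes:
                rows.append({"level": level, "taxon": taxon, "gene": gene,
                             "fraction_present": float(row[gene])})
    return score_df, pd.DataFrame(rows)
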