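"""In-memory containers for gene x sample and gene x gene data.

``TEMatrix`` holds strictly positive translation-efficiency estimates
(genes in rows, samples in columns).  ``CovariationMatrix`` holds a
symmetric matrix of proportionality scores in [-1, 1] with unit
diagonal — the substrate from which covariation networks are built.

Both round-trip through TSV: matrices as a header row of labels plus one
row per gene, and covariation scores additionally through a long-format
edge table ``(gene_a, gene_b, score)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["TEMatrix", "CovariationMatrix"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} identifiers must be unique")


@dataclass
class TEMatrix:
    """Gene x sample matrix of strictly positive translation efficiencies."""

    gene_ids: list[str]
    samples: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.samples = list(map(str, self.samples))
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TE values must be finite")
        if np.any(self.values <= 0):
            raise ValueError("TE values must be strictly positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.samples)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TEMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class CovariationMatrix:
    """Symmetric gene x gene matrix of scores in [-1, 1], unit diagonal."""

    gene_ids: list[str]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.scores = np.asarray(self.scores, dtype=float)
        _check_unique(self.gene_ids, "gene")
        n = len(self.gene_ids)
        if self.scores.shape != (n, n):
            raise ValueError(f"scores must be {n}x{n}, got {self.scores.shape}")
        if n == 0:
            raise ValueError("empty covariation matrix")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("scores must be exactly symmetric")
        if np.nanmax(np.abs(self.scores)) > 1 + 1e-9:
            raise ValueError("scores must lie in [-1, 1]")
        if not np.allclose(np.diag(self.scores), 1.0):
            raise ValueError("diagonal must be 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, genes: Iterable[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in genes], dtype=int)

    def subset(self, genes: Sequence[str]) -> "CovariationMatrix":
        idx = self.index_of(genes)
        return CovariationMatrix(list(genes), self.scores[np.ix_(idx, idx)])

    def overlap(self, other: "CovariationMatrix") -> list[str]:
        present = set(other.gene_ids)
        return [g for g in self.gene_ids if g in present]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.gene_ids, columns=self.gene_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CovariationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("matrix TSV must have identical row and column gene ids")
        scores = df.to_numpy(dtype=float)
        scores = (scores + scores.T) / 2.0  # tolerate formatting round-off
        np.fill_diagonal(scores, 1.0)
        return cls(list(df.index), scores)

    def to_long(self, path: str | Path) -> None:
        """Write the upper triangle as a (gene_a, gene_b, score) edge table."""
        iu = np.triu_indices(self.n_genes, k=1)
        genes = np.asarray(self.gene_ids)
        pd.DataFrame(
            {"gene_a": genes[iu[0]], "gene_b": genes[iu[1]], "score": self.scores[iu]}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long(cls, path: str | Path) -> "CovariationMatrix":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        genes = sorted(set(df["gene_a"].astype(str)) | set(df["gene_b"].astype(str)))
        pos = {g: i for i, g in enumerate(genes)}
        scores = np.zeros((len(genes), len(genes)))
        ia = df["gene_a"].astype(str).map(pos).to_numpy()
        ib = df["gene_b"].astype(str).map(pos).to_numpy()
        scores[ia, ib] = df["score"].to_numpy(dtype=float)
        scores[ib, ia] = scores[ia, ib]
        np.fill_diagonal(scores, 1.0)
        return cls(genes, scores)

    @classmethod
    def read(cls, path: str | Path) -> "CovariationMatrix":
        """Read either dialect: square TSV matrix or long edge table."""
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        if [c.lower() for c in header[:3]] == ["gene_a", "gene_b", "score"]:
            return cls.from_long(path)
        return cls.from_tsv(path)
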