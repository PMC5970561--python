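"""Co-expression network construction from a log2 fold-change matrix.

The input is a genes x conditions matrix of log2(treatment/control)
expression fold changes.  Pairwise Pearson correlation is computed over
the conditions each gene pair shares (pairwise-complete observations),
and an undirected CoEx edge links every pair whose correlation magnitude
reaches the strength threshold (default |r| >= 0.7, both signs admitted).
Pairs with fewer than ``min_overlap`` shared observations, or with zero
variance in either profile, have undefined correlation and never form
edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import DataType, EvidenceEdge, IntegratedNetwork

__all__ = [
    "ExpressionMatrix",
    "pearson_similarity",
    "build_coex_network",
    "correlation_histogram",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.7
DEFAULT_MIN_OVERLAP = 3


@dataclass
class ExpressionMatrix:
    """Genes x conditions matrix of log2 fold changes; NaN marks missing."""

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.condition_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "ExpressionMatrix":
        """Read a TSV with gene ids in the first column, condition ids in the header."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g", na_rep="")


def pearson_similarity(m: ExpressionMatrix, min_overlap: int = DEFAULT_MIN_OVERLAP) -> pd.DataFrame:
    """Gene x gene Pearson correlation with pairwise-complete observations.

    Entries are NaN (undefined) for pairs sharing fewer than
    ``min_overlap`` non-missing conditions or where either profile has
    zero variance over the shared conditions.
    """
    if m.n_conditions < 2:
        raise ValueError("need at least 2 conditions to correlate")
    if min_overlap < 2:
        raise ValueError("min_overlap must be >= 2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing rows
        degenerate = [g for g, row in zip(m.gene_ids, m.values) if np.nanstd(row) == 0]
    if degenerate:
        log.warning(
            "%d gene(s) with zero expression variance excluded from edges: %s",
            len(degenerate),
            ", ".join(degenerate[:5]) + ("..." if len(degenerate) > 5 else ""),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        # conditions are observations -> correlate columns of the transpose
        sim = m.to_frame().T.corr(method="pearson", min_periods=min_overlap)
    return sim


def build_coex_network(
    m: ExpressionMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> IntegratedNetwork:
    """Build the CoEx network: an edge per gene pair with defined |r| >= threshold.

    The signed correlation is kept on each edge (``pearson_r``); the
    threshold used is recorded in the edge metadata.  Genes left without
    any edge are omitted from the node set.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    sim = pearson_similarity(m, min_overlap=min_overlap)
    r = sim.to_numpy()
    ids = list(sim.index)
    net = IntegratedNetwork(provenance=["coex"])
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = ~np.isnan(r[iu, ju]) & (np.abs(r[iu, ju]) >= threshold)
    for i, j in zip(iu[mask], ju[mask]):
        net.add_edge(
            EvidenceEdge(
                ids[i],
                ids[j],
                DataType.COEX,
                pearson_r=float(np.clip(r[i, j], -1.0, 1.0)),
                meta={"threshold": format(threshold, ".10g")},
            )
        )
    return net


def correlation_histogram(
    m: ExpressionMatrix,
    bins: int = 20,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Histogram of all defined off-diagonal correlations (each pair once).

    Mirrors the threshold-picking aid of co-expression plugins: the
    count distribution over r in [-1, 1] shows how many edges each
    threshold would admit.  Returns columns ``bin_left``, ``bin_right``,
    ``count``; the counts sum to the number of defined pairs.
    """
    sim = pearson_similarity(m, min_overlap=min_overlap).to_numpy()
    iu, ju = np.triu_indices(sim.shape[0], k=1)
    vals = sim[iu, ju]
    vals = vals[~np.isnan(vals)]
    counts, edges = np.histogram(np.clip(vals, -1, 1), bins=bins, range=(-1.0, 1.0))
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
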