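"""Chromatin-informed selection constraints from Hi-C contact maps.

Genes colocalized in the nucleus (e.g. within a transcription factory)
are often coregulated, so measuring several of them is redundant.  A
gene-by-gene contact-frequency matrix is converted to a dissimilarity,
clustered hierarchically with the cut chosen by silhouette score, and
the clusters become at-most-one-gene-per-cluster constraints for the
sensor-selection solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .selection import ConstraintSet

__all__ = [
    "ContactMatrix",
    "GeneClustering",
    "cluster_genes",
    "make_constraints",
    "read_contacts",
    "write_clustering",
]


@dataclass
class ContactMatrix:
    """Symmetric non-negative gene-by-gene contact frequencies."""

    contacts: np.ndarray
    genes: Sequence[str]
    coordinates: pd.DataFrame | None = None  # chrom/start/end, 0-based half-open

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=float)
        n = self.contacts.shape[0]
        if self.contacts.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if np.max(np.abs(self.contacts - self.contacts.T)) > 1e-9 * max(
                1.0, np.max(np.abs(self.contacts))):
            raise ValueError("contact matrix must be symmetric")
        if np.any(self.contacts < 0):
            raise ValueError("contact frequencies must be non-negative")
        self.genes = [str(g) for g in self.genes]
        if len(self.genes) != n:
            raise ValueError("gene list length must match matrix size")

    @property
    def n_genes(self) -> int:
        return self.contacts.shape[0]


@dataclass
class GeneClustering:
    """A gene -> cluster-id assignment with its selection diagnostics."""

    labels: dict[str, int]
    n_clusters: int
    silhouette: float
    linkage_method: str = "average"
    transform: str = "1-c/cmax"
    silhouette_by_k: dict[int, float] = field(default_factory=dict)


def contact_dissimilarity(contacts: ContactMatrix,
                          transform: str = "1-c/cmax") -> np.ndarray:
    """Monotone contact -> dissimilarity transforms (zero diagonal)."""
    c = contacts.contacts
    cmax = c.max()
    if transform == "1-c/cmax":
        d = 1.0 - c / cmax if cmax > 0 else np.ones_like(c)
    elif transform == "inverse":
        d = 1.0 / (1.0 + c)
    elif transform == "log":
        d = np.log1p(cmax) - np.log1p(c)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


def cluster_genes(contacts: ContactMatrix,
                  k_range: tuple[int, int] | Sequence[int] = (2, 10),
                  linkage_method: str = "average",
                  transform: str = "1-c/cmax") -> GeneClustering:
    """Hierarchical clustering of the contact map with the cut chosen by
    silhouette score.

    The dissimilarity d = 1 - c/c_max (configurable) feeds average-
    linkage clustering; each candidate cluster count k in ``k_range`` is
    scored with the silhouette on the same dissimilarity and the best k
    wins (ties go to the smallest k).
    """
    n = contacts.n_genes
    if n < 3:
        raise ValueError("clustering needs at least 3 genes")
    if isinstance(k_range, tuple) and len(k_range) == 2:
        ks = range(k_range[0], k_range[1] + 1)
    else:
        ks = list(k_range)
    ks = [k for k in ks if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range contains no feasible cluster count")
    D = contact_dissimilarity(contacts, transform)
    best_k, best_s, best_labels = None, -np.inf, None
    by_k: dict[int, float] = {}
    for k in ks:
        agg = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                      linkage=linkage_method)
        labels = agg.fit_predict(D) + 1
        if len(np.unique(labels)) < 2:
            continue
        s = float(silhouette_score(D, labels, metric="precomputed"))
        by_k[k] = s
        if s > best_s + 1e-12:
            best_k, best_s, best_labels = k, s, labels
    if best_labels is None:
        raise ValueError("no cut in k_range produced >= 2 clusters")
    return GeneClustering(
        labels={g: int(l) for g, l in zip(contacts.genes, best_labels)},
        n_clusters=int(len(np.unique(best_labels))),
        silhouette=best_s,
        linkage_method=linkage_method,
        transform=transform,
        silhouette_by_k=by_k,
    )


def make_constraints(clustering: GeneClustering,
                     budget: int | Sequence[int] | None = None,
                     forbidden: Sequence[str] = ()) -> ConstraintSet:
    """At-most-one-gene-per-cluster constraints for the selection
    solvers; genes outside the clustering stay unconstrained."""
    return ConstraintSet(budget=budget, cluster_map=dict(clustering.labels),
                         forbidden=frozenset(forbidden))


# ---------------------------------------------------------------------------
# file formats


def read_contacts(path: str | Path) -> ContactMatrix:
    """Square CSV/TSV with gene ids as both header row and first column."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("contact matrix row and column gene ids differ")
    return ContactMatrix(df.to_numpy(dtype=float), [str(g) for g in df.index])


def write_contacts(contacts: ContactMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    pd.DataFrame(contacts.contacts, index=contacts.genes,
                 columns=contacts.genes).to_csv(path, sep=sep,
                                                float_format="%.17g")


def write_clustering(clustering: GeneClustering, path: str | Path) -> None:
    """Two-column TSV (gene, cluster)."""
    with open(path, "w") as fh:
        fh.write("gene\tcluster\n")
        for g, l in clustering.labels.items():
            fh.write(f"{g}\t{l}\n")


def read_clustering(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return {str(g): int(c) for g, c in zip(df["gene"], df["cluster"])}
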