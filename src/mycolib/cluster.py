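"""OTU clustering at a fixed identity threshold, and reference-based naming.

Genotypes are grouped into operational taxonomic units (OTUs) at 97%
pairwise identity by default.  Single linkage mirrors the overlap semantics
of contig assembly (two genotypes share an OTU iff they are connected by a
path of pairwise identities at or above the threshold); a greedy
abundance-ordered centroid mode is available for comparison.

Naming follows the similarity-rank convention of clone-library surveys:
an OTU whose representative matches a reference at >=97% identity takes that
reference's species name; at 90-97% it takes the genus ("Genus sp.N");
below 90% it takes the family-or-order label ("Family N").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import DisjointSet
from sklearn.base import BaseEstimator

from .align import _seq_to_array, pairwise_identity
from .qc import GenotypeTable
from .reference import ReferenceDB

SPECIES_THRESHOLD = 0.97
GENUS_THRESHOLD = 0.90


def identity_matrix(sequences: list[str]) -> np.ndarray:
    """Dense pairwise alignment-identity matrix (no shortcuts; small n)."""
    n = len(sequences)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(sequences[i], sequences[j])
    return mat


def _candidate_pairs(
    sequences: list[str], threshold: float, margin: float
) -> list[tuple[int, int]]:
    """Pairs that could reach the identity threshold.

    Equal-length pairs are screened by vectorised Hamming identity: with
    substitution-only divergence the ungapped alignment is optimal, so pairs
    whose Hamming identity falls below ``threshold - margin`` cannot reach
    the threshold and are dropped without a full alignment.  Length-differing
    pairs are always aligned.
    """
    n = len(sequences)
    lengths = np.array([len(s) for s in sequences])
    pairs: list[tuple[int, int]] = []
    for length in np.unique(lengths):
        idx = np.nonzero(lengths == length)[0]
        if len(idx) < 2:
            continue
        mat = np.stack([_seq_to_array(sequences[i]) for i in idx])
        # chunked pairwise Hamming to bound memory
        for a in range(len(idx)):
            diffs = (mat[a + 1 :] != mat[a]).sum(axis=1)
            ham_ident = 1.0 - diffs / length
            for off in np.nonzero(ham_ident >= threshold - margin)[0]:
                pairs.append((int(idx[a]), int(idx[a + 1 + off])))
    for i in range(n):
        for j in range(i + 1, n):
            if lengths[i] != lengths[j]:
                pairs.append((i, j))
    return pairs


class OTUClusterer(BaseEstimator):
    """Cluster sequences into OTUs at an identity threshold.

    Parameters
    ----------
    threshold : float in (0, 1]
        Minimum pairwise identity for two sequences to be linked (default
        0.97).
    linkage : {"single", "greedy"}
        "single": connected components of the >=threshold identity graph.
        "greedy": abundance-ordered centroid clustering; each sequence joins
        the first existing centroid it matches, else founds a new one.
    prefilter_margin : float
        Safety margin of the Hamming prefilter for equal-length pairs; set
        to 1.0 to force a full alignment for every pair.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster label per input sequence, numbered by decreasing cluster
        abundance (ties: lexicographically smallest member sequence).
    representative_ : list of int
        Index of the representative (most abundant member, ties broken
        lexicographically by sequence) per cluster.
    """

    def __init__(
        self,
        threshold: float = 0.97,
        linkage: str = "single",
        prefilter_margin: float = 0.03,
    ):
        self.threshold = threshold
        self.linkage = linkage
        self.prefilter_margin = prefilter_margin

    def _validate(self):
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in (0, 1], got {self.threshold}")
        if self.linkage not in ("single", "greedy"):
            raise ValueError(f"unknown linkage {self.linkage!r}")

    def fit(self, X: list[str], y=None, abundances: list[int] | None = None):
        """Cluster sequences; ``abundances`` are clone counts (default 1)."""
        self._validate()
        sequences = list(X)
        if any(not s for s in sequences):
            raise ValueError("empty sequence in input")
        ab = np.ones(len(sequences)) if abundances is None else np.asarray(abundances)
        if self.linkage == "single":
            raw = self._fit_single(sequences)
        else:
            raw = self._fit_greedy(sequences, ab)
        self.labels_, self.representative_ = self._canonicalise(sequences, ab, raw)
        self.n_clusters_ = len(self.representative_)
        return self

    def fit_predict(self, X, y=None, abundances=None) -> np.ndarray:
        return self.fit(X, abundances=abundances).labels_

    def _identity(self, a: str, b: str) -> float:
        return pairwise_identity(a, b)

    def _fit_single(self, sequences: list[str]) -> np.ndarray:
        ds = DisjointSet(range(len(sequences)))
        pairs = _candidate_pairs(sequences, self.threshold, self.prefilter_margin)
        for i, j in pairs:
            if ds.connected(i, j):
                continue
            if self._identity(sequences[i], sequences[j]) >= self.threshold:
                ds.merge(i, j)
        labels = np.empty(len(sequences), dtype=int)
        for lab, subset in enumerate(ds.subsets()):
            for i in subset:
                labels[i] = lab
        return labels

    def _fit_greedy(self, sequences: list[str], ab: np.ndarray) -> np.ndarray:
        order = sorted(range(len(sequences)), key=lambda i: (-ab[i], sequences[i]))
        centroids: list[int] = []
        labels = np.empty(len(sequences), dtype=int)
        for i in order:
            for lab, c in enumerate(centroids):
                same_len = len(sequences[c]) == len(sequences[i])
                if same_len:
                    ham = 1.0 - (
                        (_seq_to_array(sequences[c]) != _seq_to_array(sequences[i])).sum()
                        / len(sequences[i])
                    )
                    if ham < self.threshold - self.prefilter_margin:
                        continue
                if self._identity(sequences[c], sequences[i]) >= self.threshold:
                    labels[i] = lab
                    break
            else:
                labels[i] = len(centroids)
                centroids.append(i)
        return labels

    @staticmethod
    def _canonicalise(
        sequences: list[str], ab: np.ndarray, raw: np.ndarray
    ) -> tuple[np.ndarray, list[int]]:
        """Renumber clusters by (-total abundance, smallest member sequence)
        and pick representatives, so output is input-order invariant."""
        clusters: dict[int, list[int]] = {}
        for i, lab in enumerate(raw):
            clusters.setdefault(int(lab), []).append(i)
        keyed = []
        for members in clusters.values():
            total = ab[members].sum()
            rep = min(members, key=lambda i: (-ab[i], sequences[i]))
            key = (-total, min(sequences[i] for i in members))
            keyed.append((key, members, rep))
        keyed.sort(key=lambda t: t[0])
        labels = np.empty(len(sequences), dtype=int)
        reps = []
        for new_lab, (_, members, rep) in enumerate(keyed):
            for i in members:
                labels[i] = new_lab
            reps.append(rep)
        return labels, reps


@dataclass
class OTUTable:
    """OTU assignments and the OTU x root-system incidence matrix."""

    assignments: pd.DataFrame  # otu_id, members, representative, name, rank, ...
    incidence: pd.DataFrame  # OTU x root-system 0/1
    clone_counts: pd.DataFrame  # OTU x root-system clone counts
    genotype_otu: pd.Series  # genotype_id -> otu_id

    @property
    def n_otus(self) -> int:
        return len(self.assignments)

    def singleton_fraction(self) -> float:
        """Fraction of OTUs observed in exactly one root system."""
        return float((self.incidence.sum(axis=1) == 1).mean())


def rank_for_identity(identity: float) -> str:
    if identity >= SPECIES_THRESHOLD:
        return "species"
    if identity >= GENUS_THRESHOLD:
        return "genus"
    return "family_or_order"


def assign_names(
    representatives: list[str], reference_db: ReferenceDB | None
) -> pd.DataFrame:
    """Name each OTU from its best reference match.

    Species-rank OTUs take the species label (suffixed 1, 2, ... when several
    OTUs share it); genus-rank OTUs become "<genus> sp.N"; family-rank OTUs
    become "<family> N"; numbering is deterministic in OTU order.  With no
    reference panel every OTU is "Unknown" at family_or_order rank.
    """
    rows = []
    for seq in representatives:
        if reference_db is None:
            rows.append(
                {"base": "Unknown", "rank": "family_or_order", "best_identity": np.nan}
            )
            continue
        ref, ident = reference_db.best_match(seq, "full")
        rank = rank_for_identity(ident)
        base = {"species": ref["species"], "genus": ref["genus"], "family_or_order": ref["family"]}[rank]
        rows.append({"base": base, "rank": rank, "best_identity": ident})
    df = pd.DataFrame(rows)
    counters: dict[tuple[str, str], int] = {}
    names = []
    base_counts = df.groupby(["rank", "base"])["base"].transform("count")
    for (_, row), n_same in zip(df.iterrows(), base_counts):
        key = (row["rank"], row["base"])
        counters[key] = counters.get(key, 0) + 1
        n = counters[key]
        if row["rank"] == "species":
            names.append(row["base"] if n_same == 1 else f"{row['base']} {n}")
        elif row["rank"] == "genus":
            names.append(f"{row['base']} sp.{n}")
        else:
            names.append(f"{row['base']} {n}")
    df["name"] = names
    return df[["name", "rank", "best_identity"]]


def cluster_otus(
    genotypes: GenotypeTable,
    reference_db: ReferenceDB | None = None,
    threshold: float = 0.97,
    linkage: str = "single",
) -> OTUTable:
    """Cluster a genotype table into a named OTU table with incidence."""
    seqs = genotypes.sequences()
    counts = genotypes.table["n_clones"].to_numpy()
    clusterer = OTUClusterer(threshold=threshold, linkage=linkage)
    labels = clusterer.fit_predict(seqs, abundances=counts)

    otu_ids = [f"OTU{k + 1:03d}" for k in range(clusterer.n_clusters_)]
    gids = list(genotypes.table["genotype_id"])
    genotype_otu = pd.Series(
        [otu_ids[lab] for lab in labels], index=gids, name="otu_id"
    )
    clone_counts = genotypes.counts.groupby(genotype_otu).sum()
    clone_counts = clone_counts.reindex(otu_ids)
    incidence = (clone_counts > 0).astype(int)

    reps = [seqs[i] for i in clusterer.representative_]
    named = assign_names(reps, reference_db)
    assignments = pd.DataFrame(
        {
            "otu_id": otu_ids,
            "members": [
                ",".join(g for g, lab in zip(gids, labels) if otu_ids[lab] == oid)
                for oid in otu_ids
            ],
            "representative": [gids[i] for i in clusterer.representative_],
            "name": named["name"],
            "rank": named["rank"],
            "best_identity": named["best_identity"],
            "n_clones": clone_counts.sum(axis=1).to_numpy(),
            "n_root_systems": incidence.sum(axis=1).to_numpy(),
        }
    )
    return OTUTable(assignments, incidence, clone_counts, genotype_otu)
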