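"""Target gene selection from a pangenome presence/absence matrix.

Pangenome construction (e.g. Roary) is upstream; this module consumes its
gene_presence_absence output (Rtab dialect: clusters x genomes of 0/1, or a
long-format cluster,genome,gene_id table) and applies the core-gene
prevalence threshold: a cluster is targeted when it is present in at least
``min_genomes`` genomes of the species. Paralogs (several members of one
cluster in one genome) count once: presence is per genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import CdsFeature


@dataclass
class PresenceAbsenceMatrix:
    cluster_ids: list[str]
    genome_ids: list[str]
    presence: np.ndarray  # (clusters, genomes) of {0,1}

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if self.presence.shape != (len(self.cluster_ids), len(self.genome_ids)):
            raise ValueError("presence matrix shape does not match ID lists")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0/1")
        if len(set(self.cluster_ids)) != len(self.cluster_ids):
            raise ValueError("duplicate cluster IDs")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("duplicate genome IDs")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def prevalence(self) -> pd.Series:
        return pd.Series(self.presence.sum(axis=1), index=self.cluster_ids)


@dataclass
class TargetSet:
    """Clusters passing the prevalence filter, optionally mapped to
    reference CDS intervals."""

    species_id: str
    clusters: list[str]
    min_genomes: int
    features_by_cluster: dict = field(default_factory=dict)  # cluster -> [CdsFeature]
    unmapped_clusters: list = field(default_factory=list)

    def features(self) -> list[CdsFeature]:
        out = []
        for cl in self.clusters:
            out.extend(self.features_by_cluster.get(cl, []))
        return out


def read_rtab(path) -> PresenceAbsenceMatrix:
    """Read the Roary Rtab dialect: tab-separated, clusters x genomes.

    Counts >1 (paralogs) are collapsed to presence=1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    presence = (df.to_numpy(dtype=float) > 0).astype(np.int8)
    return PresenceAbsenceMatrix(
        cluster_ids=[str(c) for c in df.index],
        genome_ids=[str(g) for g in df.columns],
        presence=presence,
    )


def read_long_format(path) -> tuple[PresenceAbsenceMatrix, pd.DataFrame]:
    """Read a long-format cluster,genome,gene_id CSV.

    Returns the collapsed presence/absence matrix and the raw table (which
    doubles as the cluster -> gene mapping input).
    """
    df = pd.read_csv(path)
    required = {"cluster", "genome", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"long-format table requires columns {sorted(required)}")
    clusters = sorted(df["cluster"].astype(str).unique())
    genomes = sorted(df["genome"].astype(str).unique())
    ci = {c: i for i, c in enumerate(clusters)}
    gi = {g: i for i, g in enumerate(genomes)}
    presence = np.zeros((len(clusters), len(genomes)), dtype=np.int8)
    for cl, gn in zip(df["cluster"].astype(str), df["genome"].astype(str)):
        presence[ci[cl], gi[gn]] = 1
    return PresenceAbsenceMatrix(clusters, genomes, presence), df


def select_core_targets(
    matrix: PresenceAbsenceMatrix, min_genomes: int, species_id: str = ""
) -> TargetSet:
    """Select clusters present in at least ``min_genomes`` genomes.

    Deterministic: clusters are returned sorted by cluster_id.
    """
    if not (1 <= min_genomes <= matrix.n_genomes):
        raise ValueError(
            f"min_genomes must be in [1, {matrix.n_genomes}], got {min_genomes}"
        )
    prev = matrix.prevalence()
    selected = sorted(prev.index[prev >= min_genomes])
    return TargetSet(species_id=species_id, clusters=selected, min_genomes=min_genomes)


def map_targets_to_reference(
    targets: TargetSet,
    reference_cds: list[CdsFeature],
    cluster_to_gene: pd.DataFrame,
    reference_genome_id: str | None = None,
) -> TargetSet:
    """Attach reference CDS intervals to selected clusters.

    ``cluster_to_gene`` needs columns cluster, gene_id (and optionally
    genome, used to restrict the mapping to the design reference). Clusters
    without any reference gene are listed in ``unmapped_clusters``, never
    silently dropped; a cluster mapping to several reference genes keeps all
    intervals.
    """
    table = cluster_to_gene
    if reference_genome_id is not None and "genome" in table.columns:
        table = table[table["genome"].astype(str) == str(reference_genome_id)]
    by_gene = {}
    for f in reference_cds:
        by_gene.setdefault(f.gene_id, []).append(f)
    mapping = {}
    for cl, sub in table.groupby(table["cluster"].astype(str)):
        feats = []
        for gid in sorted(sub["gene_id"].astype(str).unique()):
            feats.extend(by_gene.get(gid, []))
        if feats:
            mapping[cl] = feats
    features_by_cluster = {}
    unmapped = []
    for cl in targets.clusters:
        if cl in mapping:
            features_by_cluster[cl] = mapping[cl]
        else:
            unmapped.append(cl)
    return TargetSet(
        species_id=targets.species_id,
        clusters=list(targets.clusters),
        min_genomes=targets.min_genomes,
        features_by_cluster=features_by_cluster,
        unmapped_clusters=unmapped,
    )
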