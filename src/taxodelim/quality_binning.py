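"""Genome quality filtering and ANI-based species binning.

Genomes below 80% completeness or above 5% contamination are discarded.
The survivors are collapsed into species-level genome bins by
average-linkage hierarchical clustering on ANI distance (100 − ANI),
cut at the conventional 95% ANI species threshold; each bin is represented
by its most complete member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .metrics import GenomeRecord, canonical_pair

#: Distance assigned to pairs whose ANI could not be computed: such pairs
#: are more divergent than the species level by construction.
_MISSING_DISTANCE = 100.0


@dataclass
class SpeciesBin:
    """A species-level genome bin: members clustered at >= threshold ANI,
    represented by the most complete member (ties broken by id)."""

    bin_id: str
    members: list[str]
    representative: str


def filter_quality(records: list[GenomeRecord],
                   min_completeness: float = 0.80,
                   max_contamination: float = 0.05) -> list[GenomeRecord]:
    """Keep genomes with completeness >= *min_completeness* and
    contamination <= *max_contamination*; boundary values are kept."""
    return [r for r in records
            if r.completeness >= min_completeness
            and r.contamination <= max_contamination]


def bin_species(ani_table: pd.DataFrame, records: list[GenomeRecord],
                threshold: float = 95.0) -> list[SpeciesBin]:
    """Collapse genomes into species bins at an ANI cut-off.

    Average-linkage agglomerative clustering on distance ``100 - ANI``
    (missing ANI = distance 100), cut at ``100 - threshold``.  Invariant to
    input row order: genomes are processed in sorted id order.
    """
    ids = sorted(r.genome_id for r in records)
    if not ids:
        return []
    if len(ids) == 1:
        return select_representatives([(ids, None)], records)  # type: ignore[arg-type]

    lut: dict[tuple[str, str], float] = {}
    if ani_table is not None and len(ani_table):
        g1 = ani_table.iloc[:, 0].astype(str).to_numpy()
        g2 = ani_table.iloc[:, 1].astype(str).to_numpy()
        vals = ani_table.iloc[:, 2].astype(float).to_numpy()
        known = set(ids)
        for a, b, v in zip(g1, g2, vals):
            if a in known and b in known and not np.isnan(v):
                lut[canonical_pair(a, b)] = v

    n = len(ids)
    dist = np.full((n, n), _MISSING_DISTANCE)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            ani = lut.get((ids[i], ids[j]))
            if ani is not None:
                dist[i, j] = dist[j, i] = max(0.0, 100.0 - ani)

    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=100.0 - threshold, criterion="distance")

    groups: dict[int, list[str]] = {}
    for gid, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(gid)
    # deterministic bin order: by smallest member id
    ordered = sorted(groups.values(), key=lambda members: min(members))
    return select_representatives([(members, None) for members in ordered], records)


def select_representatives(raw_bins: list[tuple[list[str], object]],
                           records: list[GenomeRecord]) -> list[SpeciesBin]:
    """Pick the most complete member of each bin as its representative;
    ties broken by lexicographic genome id."""
    completeness = {r.genome_id: r.completeness for r in records}
    bins: list[SpeciesBin] = []
    for k, (members, _) in enumerate(raw_bins):
        members = sorted(members)
        rep = min(members, key=lambda g: (-completeness[g], g))
        bins.append(SpeciesBin(bin_id=f"bin{k + 1:05d}", members=members,
                               representative=rep))
    return bins


def bins_to_frame(bins: list[SpeciesBin]) -> pd.DataFrame:
    rows = [(b.bin_id, g, g == b.representative)
            for b in bins for g in b.members]
    return pd.DataFrame(rows, columns=["bin_id", "genome_id", "is_representative"])
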