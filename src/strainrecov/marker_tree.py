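"""Marker-gene cross-check of strain calls: PID distances and neighbor joining.

Independently of the genome-wide similarity score, strain identity can be
checked phylogenetically: reconstruct per-sample marker-gene sequences by
substituting each sample's SNVs into configured reference sub-regions,
compute pairwise percent-identity (PID) distances, and build a
neighbor-joining tree. Samples carrying the same strain should form a tight
clade; a replacement strain should branch apart. ``tree_wss_concordance``
quantifies the agreement between the tree and the relatedness calls.

Markers here are configured reference sub-regions (default ten 500 bp
regions spread evenly along the genome) rather than an external marker-gene
database; the inferential shape — align markers, distance, NJ — is the same.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .errors import ConfigError
from .synthetic_cohort import Reference
from .variant_io import SampleVariantProfile
from .wss_core import RelatednessCall

GAP = "-"


@dataclass(frozen=True)
class MarkerAlignment:
    """Equal-length per-sample marker sequences for one species."""

    species_id: str
    sequences: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ConfigError("aligned sequences must all have equal length")

    def sample_ids(self) -> list[str]:
        return list(self.sequences)


@dataclass
class StrainTree:
    """An unrooted NJ tree over samples, serializable to Newick."""

    tree: TreeNode
    negative_branches: int = 0

    def to_newick(self) -> str:
        return str(self.tree).strip()

    def tip_distances(self) -> tuple[list[str], np.ndarray]:
        """Patristic (path-length) distances between all tips."""
        dm = self.tree.tip_tip_distances()
        return list(dm.ids), dm.data


def make_marker_regions(
    genome_length: int, n_regions: int = 10, region_length: int = 500
) -> list[tuple[int, int]]:
    """Evenly spaced, non-overlapping half-open marker regions."""
    if n_regions * region_length > genome_length:
        raise ConfigError("marker regions do not fit in the genome")
    stride = genome_length // n_regions
    return [(i * stride, i * stride + region_length) for i in range(n_regions)]


def extract_marker_sequences(
    profile: SampleVariantProfile,
    reference: Reference | str,
    marker_regions: Sequence[tuple[int, int]],
    min_depth: int = 1,
) -> tuple[str, int]:
    """Reference sequence over the marker regions with sample SNVs substituted.

    Returns the concatenated marker sequence and the count of SNV loci whose
    depth fell below ``min_depth`` (these keep the reference base).
    """
    seq = reference.sequence if isinstance(reference, Reference) else reference
    for start, end in marker_regions:
        if not 0 <= start < end <= len(seq):
            raise ConfigError(f"marker region ({start}, {end}) outside genome")
    by_pos = {c.position: c for c in profile.calls}
    pieces: list[str] = []
    n_masked = 0
    for start, end in marker_regions:
        chars = list(seq[start:end])
        for pos in range(start, end):
            call = by_pos.get(pos)
            if call is None:
                continue
            if call.depth < min_depth:
                n_masked += 1
                continue
            chars[pos - start] = call.alt_allele
        pieces.append("".join(chars))
    return "".join(pieces), n_masked


def build_alignment(
    profiles: Sequence[SampleVariantProfile],
    reference: Reference,
    marker_regions: Sequence[tuple[int, int]] | None = None,
    min_depth: int = 1,
) -> MarkerAlignment:
    """Marker alignment over several samples of one species.

    With SNV-only profiles the extracted sequences are gap-free and equal
    length, so no realignment step is needed.
    """
    if marker_regions is None:
        marker_regions = make_marker_regions(reference.genome_length)
    sequences = {
        p.sample_id: extract_marker_sequences(p, reference, marker_regions, min_depth)[0]
        for p in profiles
    }
    return MarkerAlignment(reference.species_id, sequences)


def pid_distance(a: str, b: str, gap: str = GAP) -> float:
    """1 − fractional identity over columns where neither sequence has a gap."""
    if len(a) != len(b):
        raise ConfigError("sequences must have equal length")
    compared = matches = 0
    for x, y in zip(a, b):
        if x == gap or y == gap:
            continue
        compared += 1
        matches += x == y
    if compared == 0:
        raise ConfigError("no comparable (gap-free) columns between sequences")
    return 1.0 - matches / compared


def distance_matrix(alignment: MarkerAlignment) -> tuple[list[str], np.ndarray]:
    ids = alignment.sample_ids()
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pid_distance(
            alignment.sequences[ids[i]], alignment.sequences[ids[j]]
        )
    return ids, d


def nj_tree(d: np.ndarray, ids: Sequence[str]) -> StrainTree:
    """Canonical Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the smallest (row, column) index pair
    in row-major order; negative branch lengths are clamped to zero and
    counted. Exact topology recovery on additive matrices is the defining
    guarantee and is enforced by the test suite.
    """
    d = np.asarray(d, dtype=float)
    n = len(ids)
    if d.shape != (n, n):
        raise ConfigError("distance matrix shape does not match ids")
    if n < 3:
        raise ConfigError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ConfigError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ConfigError("distance matrix diagonal must be zero")

    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in ids]
    D = d.copy()
    negative = 0

    def clamp(x: float) -> float:
        nonlocal negative
        if x < 0:
            negative += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin scans row-major, so the first minimum is the smallest (i, j)
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        parent = TreeNode(children=[child_i, child_j])
        row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.zeros((m - 1, m - 1))
        D_new[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D_new[-1, : m - 2] = D_new[: m - 2, -1] = row[keep]
        D = D_new
        nodes = [nodes[k] for k in keep] + [parent]

    # final three nodes: closed-form three-point branch lengths
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    for node, length in zip(nodes, lengths):
        node.length = clamp(length)
    root = TreeNode(children=nodes)
    return StrainTree(root, negative)


def tree_wss_concordance(
    tree: StrainTree,
    calls: np.ndarray,
    sample_ids: Sequence[str],
) -> float:
    """Fraction of defined sample pairs where tree distance agrees with the call.

    A pair is concordant when RELATED and its patristic distance is at or
    below the cohort median, or UNRELATED and at or above it (ties count as
    concordant either way, which keeps the degenerate single-strain cohort —
    all distances zero — fully concordant). INDETERMINATE pairs are skipped.
    """
    tip_ids, dmat = tree.tip_distances()
    index = {s: i for i, s in enumerate(tip_ids)}
    missing = [s for s in sample_ids if s not in index]
    if len(missing) == len(sample_ids):
        raise ConfigError("tree and call matrix share no samples")
    pairs = []
    for i, j in itertools.combinations(range(len(sample_ids)), 2):
        call = calls[i, j]
        # equality, not identity: numpy object arrays may hold the str values
        if call is None or call == RelatednessCall.INDETERMINATE:
            continue
        a, b = sample_ids[i], sample_ids[j]
        if a not in index or b not in index:
            continue
        pairs.append((call, dmat[index[a], index[b]]))
    if not pairs:
        raise ConfigError("no defined pairs to assess concordance")
    median = float(np.median([d for _, d in pairs]))
    concordant = sum(
        1
        for call, dist in pairs
        if (call == RelatednessCall.RELATED and dist <= median)
        or (call == RelatednessCall.UNRELATED and dist >= median)
    )
    return concordant / len(pairs)


def simulate_additive_distances(
    n_taxa: int, rng: np.random.Generator, min_branch: float = 0.05, max_branch: float = 1.0
) -> tuple[list[str], np.ndarray, str]:
    """Random binary tree with positive branch lengths and its exact distances.

    Returns (taxon ids, additive distance matrix, true-tree Newick); useful
    for exercising the NJ guarantee of exact recovery on additive inputs.
    """
    if n_taxa < 4:
        raise ConfigError("need at least 4 taxa for a non-trivial unrooted topology")
    ids = [f"t{i}" for i in range(n_taxa)]
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop larger index first
        nodes.pop(j), nodes.pop(i)
        a.length = float(rng.uniform(min_branch, max_branch))
        b.length = float(rng.uniform(min_branch, max_branch))
        nodes.append(TreeNode(children=[a, b]))
    for node in nodes:
        node.length = float(rng.uniform(min_branch, max_branch))
    tree = TreeNode(children=nodes)
    dm = tree.tip_tip_distances()
    order = [list(dm.ids).index(i) for i in ids]
    return ids, dm.data[np.ix_(order, order)], str(tree).strip()
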