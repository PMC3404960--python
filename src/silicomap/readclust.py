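"""Cluster enriched-library reads from two lines into per-locus groups.

Reads carrying the same genomic feature (an SSR tract or a transposon
junction) are grouped by flanking-sequence identity.  The feature interval
is excised before alignment, so a 10-repeat and a 12-repeat allele of one
locus — or a TE-present and TE-absent haplotype — still show near-identical
flanks and land in one cluster.  Candidate pairs are pre-filtered by shared
canonical k-mers, then verified with a global (Needleman–Wunsch) alignment
of the concatenated flanks; identity is matches over aligned columns, with
gaps counting as columns.  Clusters are single-linkage connected components
with deterministic ids and strand-normalized members.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from silicomap.ssrscan import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AnnotatedRead:
    """A read with an optional feature annotation.

    ``feature`` is ``None`` (no annotation; ignored by clustering), or a
    half-open interval ``(start, end)`` covering the SSR tract or the TE
    segment.  ``payload`` carries the feature observation used downstream:
    for SSR a ``(motif_class, repeat_count)`` tuple, for TE the string
    ``"TE"``.
    """

    read_id: str
    line: str
    seq: str
    feature: tuple[int, int] | None = None
    payload: object = None


@dataclass
class SeqCluster:
    """Reads from both lines grouped as one putative genomic locus."""

    cluster_id: str
    members_by_line: dict[str, list[str]]
    observations_by_line: dict[str, list]
    left_flank: str
    right_flank: str
    member_ids: list[str] = field(default_factory=list)


def _canonical_kmer(kmer: str) -> str:
    return min(kmer, revcomp(kmer))


def flank_fingerprints(seq: str, feature: tuple[int, int], k: int = 15) -> set[str]:
    """Canonical (strand-minimal) k-mers of the flanks around ``feature``.

    K-mers overlapping the feature interval are excluded; a flank shorter
    than ``k`` contributes nothing.
    """
    s, e = feature
    keys: set[str] = set()
    for flank in (seq[:s], seq[e:]):
        for i in range(len(flank) - k + 1):
            keys.add(_canonical_kmer(flank[i : i + k]))
    return keys


def _excised(read: AnnotatedRead) -> str:
    s, e = read.feature
    return read.seq[:s] + read.seq[e:]


def flank_identity(a: str, b: str) -> tuple[float, int, bool]:
    """Global-alignment identity between two flank strings.

    Aligns ``a`` against ``b`` and against the reverse complement of ``b``;
    returns ``(identity, aligned_columns, flipped)`` for the better of the
    two orientations.  Identity = matching columns / aligned columns, gaps
    counting as columns.
    """
    best = (-1.0, 0, False)
    for flipped, target in ((False, b), (True, revcomp(b))):
        res = edlib.align(a, target, mode="NW", task="path")
        cols = 0
        matches = 0
        for num, op in _CIGAR_RE.findall(res["cigar"] or ""):
            num = int(num)
            cols += num
            if op == "=":
                matches += num
        ident = matches / cols if cols else 1.0
        if ident > best[0]:
            best = (ident, cols, flipped)
    return best


class _ParityUnionFind:
    """Union-find tracking relative strand (parity) to the root."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.parity = [0] * n  # strand relative to parent chain root

    def find(self, x: int) -> tuple[int, int]:
        if self.parent[x] == x:
            return x, 0
        root, p = self.find(self.parent[x])
        self.parent[x] = root
        self.parity[x] ^= p
        return root, self.parity[x]

    def union(self, x: int, y: int, rel: int) -> None:
        rx, px = self.find(x)
        ry, py = self.find(y)
        if rx == ry:
            return
        # attach ry under rx such that parity(y) - parity(x) == rel
        self.parent[ry] = rx
        self.parity[ry] = px ^ py ^ rel


def cluster_reads(
    reads: list[AnnotatedRead],
    min_identity: float = 0.95,
    k: int = 15,
    min_shared_kmers: int = 3,
    min_aligned_cols: int = 40,
) -> list[SeqCluster]:
    """Single-linkage clustering of feature-annotated reads.

    Pairs sharing at least ``min_shared_kmers`` flank fingerprints are
    aligned over their excised flanks; pairs reaching ``min_identity`` over
    at least ``min_aligned_cols`` columns are connected.  Reads without a
    feature annotation are ignored.  Cluster ids are ``C`` + the smallest
    member read id; members are reported on the representative's strand.

    Output is independent of the input read order.
    """
    if not 0.5 < min_identity <= 1.0:
        raise ValueError(f"min_identity must be in (0.5, 1], got {min_identity}")
    annotated = sorted((r for r in reads if r.feature is not None), key=lambda r: r.read_id)
    n = len(annotated)
    fps = [flank_fingerprints(r.seq, r.feature, k) for r in annotated]

    index: dict[str, list[int]] = {}
    for i, keys in enumerate(fps):
        for key in keys:
            index.setdefault(key, []).append(i)
    pair_counts: dict[tuple[int, int], int] = {}
    for hits in index.values():
        if len(hits) < 2 or len(hits) > 200:
            continue
        for ai in range(len(hits)):
            for bi in range(ai + 1, len(hits)):
                pair = (hits[ai], hits[bi])
                pair_counts[pair] = pair_counts.get(pair, 0) + 1

    uf = _ParityUnionFind(n)
    excised = [_excised(r) for r in annotated]
    for (i, j), shared in sorted(pair_counts.items()):
        if shared < min_shared_kmers:
            continue
        ident, cols, flipped = flank_identity(excised[i], excised[j])
        if cols >= min_aligned_cols and ident >= min_identity:
            uf.union(i, j, 1 if flipped else 0)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        root, _ = uf.find(i)
        groups.setdefault(root, []).append(i)

    clusters = []
    for members in groups.values():
        members.sort(key=lambda i: annotated[i].read_id)
        rep = members[0]
        _, rep_parity = uf.find(rep)
        rep_read = annotated[rep]
        s, e = rep_read.feature
        by_line: dict[str, list[str]] = {}
        obs: dict[str, list] = {}
        ids = []
        for i in members:
            r = annotated[i]
            by_line.setdefault(r.line, []).append(r.read_id)
            obs.setdefault(r.line, []).append(r.payload)
            ids.append(r.read_id)
        clusters.append(
            SeqCluster(
                cluster_id=f"C{rep_read.read_id}",
                members_by_line=by_line,
                observations_by_line=obs,
                left_flank=rep_read.seq[:s],
                right_flank=rep_read.seq[e:],
                member_ids=ids,
            )
        )
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters
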