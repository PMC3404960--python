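"""Classify read clusters into polymorphic / monomorphic / single-line marker candidates.

This is the in-silico polymorphism call at the heart of the pipeline: an SSR
cluster is *polymorphic* when the two lines' consensus repeat counts of the
shared motif differ, *monomorphic* when they agree, and *single_line* when
only one line contributed reads.  A transposon (MITE) insertion site is
polymorphic — i.e. a cultivar-specific insertion — when junction reads come
from exactly one line.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd
from Bio import Align

from silicomap.readclust import SeqCluster
from silicomap.ssrscan import revcomp

POLYMORPHIC = "polymorphic"
MONOMORPHIC = "monomorphic"
SINGLE_LINE = "single_line"
CONFLICTED = "conflicted"


@dataclass
class MarkerCandidate:
    """A classified SSR or TE locus, ready for primer design."""

    candidate_id: str
    cluster_id: str
    marker_type: str            # "SSR" or "TE"
    klass: str                  # polymorphic / monomorphic / single_line / conflicted
    motif: str | None           # SSR canonical motif class (None for TE)
    observations_by_line: dict  # line -> repeat counts (SSR) or TE presence (TE)
    template: str               # sequence for primer design
    feature_interval: tuple[int, int] | None = None


def _majority(values: list) -> object | None:
    """Majority vote; ``None`` on a tie for the top count."""
    counts = Counter(values).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return None
    return counts[0][0]


def classify_ssr_cluster(cluster: SeqCluster, min_reads_per_line: int = 1) -> MarkerCandidate:
    """Classify an SSR cluster by per-line consensus repeat count.

    The consensus within each line is the majority repeat count over that
    line's reads (ties make the cluster ``conflicted``).  Clusters whose
    members disagree on the canonical motif class are also ``conflicted``.
    A line with fewer than ``min_reads_per_line`` reads counts as absent.
    """
    per_line = {
        line: obs
        for line, obs in cluster.observations_by_line.items()
        if len(obs) >= min_reads_per_line
    }
    motifs = {m for obs in per_line.values() for (m, _c) in obs}
    if len(motifs) > 1:
        klass, motif, consensus = CONFLICTED, None, {}
    else:
        motif = motifs.pop() if motifs else None
        consensus = {}
        tie = False
        for line, obs in per_line.items():
            c = _majority([cnt for (_m, cnt) in obs])
            if c is None:
                tie = True
            consensus[line] = c
        if len(consensus) == 1:
            # a within-line tie cannot change a single-line call
            klass = SINGLE_LINE
        elif tie:
            klass = CONFLICTED
        elif len(set(consensus.values())) > 1:
            klass = POLYMORPHIC
        else:
            klass = MONOMORPHIC
    # template: representative flanks around the representative tract
    rep_count = next(iter(consensus.values()), 0) or 0
    tract = (motif or "") * rep_count
    template = cluster.left_flank + tract + cluster.right_flank
    interval = (len(cluster.left_flank), len(cluster.left_flank) + len(tract))
    return MarkerCandidate(
        candidate_id=f"SSR_{cluster.cluster_id}",
        cluster_id=cluster.cluster_id,
        marker_type="SSR",
        klass=klass,
        motif=motif,
        observations_by_line={ln: sorted(c for (_m, c) in obs) for ln, obs in per_line.items()},
        template=template,
        feature_interval=interval,
    )


_TE_ALIGNER = Align.PairwiseAligner(
    mode="local", match_score=2, mismatch_score=-3,
    open_gap_score=-5, extend_gap_score=-2,
)


def detect_te(read_seq: str, te_consensus: str, min_len: int = 30, min_identity: float = 0.80):
    """Locate a transposon segment in a read by local alignment to the consensus.

    Both strands of the read are tried.  A hit requires an aligned length of
    at least ``min_len`` columns at identity >= ``min_identity`` (matches
    over aligned columns, gaps included).  Returns ``None`` for no hit, else
    a dict with the TE interval on the read (original orientation), the
    flank intervals that remain genomic, and the alignment identity.
    """
    if not te_consensus:
        raise ValueError("te_consensus must be non-empty")
    best = None
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        try:
            aln = _TE_ALIGNER.align(seq, te_consensus)[0]
        except (IndexError, ValueError):
            continue
        cols = 0
        matches = 0
        for (qs, qe), (ts, te_) in zip(*aln.aligned):
            # aligned blocks are gap-free; count matches within
            block_q = seq[qs:qe]
            block_t = te_consensus[ts:te_]
            matches += sum(1 for x, y in zip(block_q, block_t) if x == y)
            cols += qe - qs
        # gap columns between blocks
        qblocks, tblocks = aln.aligned
        for b in range(1, len(qblocks)):
            cols += max(qblocks[b][0] - qblocks[b - 1][1], tblocks[b][0] - tblocks[b - 1][1])
        if cols == 0:
            continue
        ident = matches / cols
        qstart, qend = qblocks[0][0], qblocks[-1][1]
        if cols >= min_len and ident >= min_identity:
            if best is None or ident * cols > best["score"]:
                if strand == "-":
                    qstart, qend = len(read_seq) - qend, len(read_seq) - qstart
                best = {
                    "te_interval": (int(qstart), int(qend)),
                    "left_flank": (0, int(qstart)),
                    "right_flank": (int(qend), len(read_seq)),
                    "identity": ident,
                    "aligned_cols": cols,
                    "strand": strand,
                    "score": ident * cols,
                }
    return best


def classify_te_cluster(cluster: SeqCluster) -> MarkerCandidate:
    """Classify a cluster of TE-junction reads.

    Cultivar-specific (``polymorphic``) when all members come from one line;
    ``monomorphic`` when both lines contributed junction reads.
    """
    lines = [ln for ln, ids in cluster.members_by_line.items() if ids]
    if not lines:
        raise ValueError("empty cluster")
    klass = POLYMORPHIC if len(lines) == 1 else MONOMORPHIC
    rep = cluster.left_flank + cluster.right_flank
    return MarkerCandidate(
        candidate_id=f"TE_{cluster.cluster_id}",
        cluster_id=cluster.cluster_id,
        marker_type="TE",
        klass=klass,
        motif=None,
        observations_by_line={ln: True for ln in lines},
        template=rep,
        feature_interval=(len(cluster.left_flank), len(cluster.left_flank)),
    )


def round_half_up_pct(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, rounding half away from zero (as printed tables do)."""
    if denominator == 0:
        return 0.0
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def screen_report(candidates: list[MarkerCandidate]) -> pd.DataFrame:
    """Summary counts and percentages per marker type and class.

    One row per (marker type, class) with columns ``count`` and ``pct``
    (percentage of that marker type's total, one decimal, half-up), plus a
    ``total`` row per type.
    """
    rows = []
    by_type: dict[str, list[MarkerCandidate]] = {}
    for c in candidates:
        by_type.setdefault(c.marker_type, []).append(c)
    for mtype in sorted(by_type):
        group = by_type[mtype]
        total = len(group)
        counts = Counter(c.klass for c in group)
        for klass in (POLYMORPHIC, MONOMORPHIC, SINGLE_LINE, CONFLICTED):
            if counts.get(klass, 0) or klass != CONFLICTED:
                rows.append(
                    {
                        "marker_type": mtype,
                        "class": klass,
                        "count": counts.get(klass, 0),
                        "pct": round_half_up_pct(counts.get(klass, 0), total),
                    }
                )
        rows.append({"marker_type": mtype, "class": "total", "count": total, "pct": 100.0})
    return pd.DataFrame(rows, columns=["marker_type", "class", "count", "pct"])
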