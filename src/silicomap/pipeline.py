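"""End-to-end marker-discovery pipeline and recovery metrics.

Ties the per-read stages together — feature annotation (SSR tract or TE
junction), clustering, classification — and scores the classifications
against simulation ground truth for recovery experiments.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from silicomap import markerscreen, readclust, ssrscan
from silicomap.io import RunConfig
from silicomap.markerscreen import MarkerCandidate, POLYMORPHIC
from silicomap.readclust import AnnotatedRead, SeqCluster
from silicomap.simdata import SimRead, SimTruth


def annotate_features(
    reads: list[SimRead],
    cfg: RunConfig | None = None,
    te_consensus: str | None = None,
) -> list[AnnotatedRead]:
    """Annotate each read with its SSR tract or TE junction (if any).

    The longest SSR tract wins when a read has several; reads without an
    SSR tract are probed for the TE consensus when one is supplied.
    """
    cfg = cfg or RunConfig()
    out = []
    for r in reads:
        feature = None
        payload = None
        tracts = ssrscan.find_tracts(r.seq, cfg.min_repeats(), seq_id=r.read_id)
        if tracts:
            t = max(tracts, key=lambda t: t.tract_len)
            feature, payload = (t.start, t.end), (t.motif, t.repeat_count)
        elif te_consensus:
            hit = markerscreen.detect_te(r.seq, te_consensus, cfg.te_min_len, cfg.te_min_identity)
            if hit:
                feature, payload = hit["te_interval"], "TE"
        out.append(AnnotatedRead(r.read_id, r.line, r.seq, feature, payload))
    return out


def discover_markers(
    reads: list[SimRead],
    cfg: RunConfig | None = None,
    te_consensus: str | None = None,
) -> tuple[list[MarkerCandidate], list[SeqCluster]]:
    """Annotate, cluster and classify reads into marker candidates."""
    cfg = cfg or RunConfig()
    annotated = annotate_features(reads, cfg, te_consensus)
    clusters = readclust.cluster_reads(
        annotated,
        cfg.cluster_min_identity,
        cfg.cluster_kmer,
        cfg.cluster_min_shared_kmers,
        cfg.cluster_min_aligned_cols,
    )
    candidates = []
    for c in clusters:
        obs = next(iter(c.observations_by_line.values()), [])
        if obs and obs[0] == "TE":
            candidates.append(markerscreen.classify_te_cluster(c))
        else:
            candidates.append(markerscreen.classify_ssr_cluster(c, cfg.min_reads_per_line))
    return candidates, clusters


@dataclass
class RecoveryScore:
    """Confusion counts of the polymorphic call against simulation truth."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


def _majority_candidate(reads, candidates, clusters):
    """Map each truth locus to the classification of the cluster holding most of its reads."""
    cand_by_cluster = {c.cluster_id: c for c in candidates}
    cluster_of_read = {}
    for cl in clusters:
        for rid in cl.member_ids:
            cluster_of_read[rid] = cl.cluster_id
    by_locus = defaultdict(list)
    for r in reads:
        parts = r.read_id.split("|")
        if len(parts) >= 2:
            by_locus[parts[1]].append(r.read_id)
    out = {}
    for locus, rids in by_locus.items():
        hits = Counter(cluster_of_read[rid] for rid in rids if rid in cluster_of_read)
        if hits:
            out[locus] = cand_by_cluster[hits.most_common(1)[0][0]]
    return out


def score_ssr_recovery(reads, truth: SimTruth, candidates, clusters) -> RecoveryScore:
    """Sensitivity/specificity of the SSR polymorphic call vs ground truth.

    Each truth locus is judged by the cluster containing the majority of
    its reads; a truth locus whose reads all failed annotation counts as a
    miss (false negative if polymorphic, true negative otherwise).
    """
    calls = _majority_candidate(reads, candidates, clusters)
    score = RecoveryScore()
    for t in truth.ssr_loci:
        cand = calls.get(t.locus_id)
        called = bool(cand and cand.marker_type == "SSR" and cand.klass == POLYMORPHIC)
        if t.polymorphic and called:
            score.tp += 1
        elif t.polymorphic:
            score.fn += 1
        elif called:
            score.fp += 1
        else:
            score.tn += 1
    return score


def score_te_recovery(reads, truth: SimTruth, candidates, clusters) -> tuple[float, RecoveryScore]:
    """Called cultivar-specific fraction and confusion counts for TE sites."""
    calls = _majority_candidate(reads, candidates, clusters)
    score = RecoveryScore()
    n_called_specific = 0
    n_scored = 0
    for t in truth.te_sites:
        cand = calls.get(t.site_id)
        if cand is None:
            continue
        n_scored += 1
        called = cand.marker_type == "TE" and cand.klass == POLYMORPHIC
        n_called_specific += called
        if t.line_specific and called:
            score.tp += 1
        elif t.line_specific:
            score.fn += 1
        elif called:
            score.fp += 1
        else:
            score.tn += 1
    frac = n_called_specific / n_scored if n_scored else float("nan")
    return frac, score
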