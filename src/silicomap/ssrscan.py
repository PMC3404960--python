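"""Detection of perfect microsatellite (SSR) tracts and motif canonicalization.

An SSR tract is a maximal perfect tandem run of a short primitive motif
(unit length 2–4 by default).  Because the same genomic repeat can be read
in either orientation and in any phase, motifs are tallied by *canonical
class*: the lexicographically smallest string over all cyclic rotations of
the motif and of its reverse complement, so e.g. TC, CT, GA and AG all
belong to class "CT".
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: minimum repeat counts per unit length, keyed by unit length
DEFAULT_MIN_REPEATS = {2: 6, 3: 5, 4: 5}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not a whole-number repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


@dataclass(frozen=True)
class RepeatTract:
    """A located, canonicalized SSR run inside one sequence.

    ``start``/``end`` are 0-based half-open; ``observed_motif`` is the unit
    as read (leftmost phase); ``motif`` is its canonical class.
    """

    seq_id: str
    start: int
    end: int
    motif: str
    observed_motif: str
    repeat_count: int

    @property
    def tract_len(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.tract_len != self.repeat_count * len(self.observed_motif):
            raise ValueError("tract length inconsistent with repeat count")


def canonical_motif(motif: str) -> str:
    """Canonical class of a repeat motif.

    A motif class is the set of all cyclic rotations of the motif and of its
    reverse complement.  The representative follows the naming convention of
    the SSR-marker literature (classes "(CT)n", "(AC)n", ...): the
    lexicographically smallest rotation of the pyrimidine-richer strand
    (more C/T than its complement); if both strands tie, the smallest
    rotation overall.  So TC, CT, GA and AG all canonicalize to "CT", and
    AC, CA, GT, TG to "AC".  Idempotent, and invariant under rotation and
    reverse complement of the argument.

    Raises
    ------
    ValueError
        If the motif is outside length 2–6, contains non-ACGT characters,
        or is itself a repetition of a shorter unit (non-primitive).
    """
    if not 2 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 2-6, got {motif!r}")
    if any(c not in "ACGT" for c in motif):
        raise ValueError(f"motif must be ACGT only, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = revcomp(motif)
    pyr = sum(1 for c in motif if c in "CT")
    pyr_rc = sum(1 for c in rc if c in "CT")
    if pyr > pyr_rc:
        strands = [motif]
    elif pyr_rc > pyr:
        strands = [rc]
    else:
        strands = [motif, rc]
    return min(s[i:] + s[:i] for s in strands for i in range(len(s)))


def find_tracts(seq: str, min_repeats: dict[int, int] | None = None, seq_id: str = "") -> list[RepeatTract]:
    """All maximal perfect SSR tracts in ``seq``.

    Scans every unit length in ``min_repeats`` (default di=6, tri=5,
    tetra=5), keeps maximal runs with a primitive unit meeting the repeat
    threshold for that length, merges phase-shifted reports of one run into
    a single (leftmost) tract, and resolves overlaps between different runs
    in favour of the longer tract (ties: smaller start).  ``N`` never
    matches.  Returned tracts are sorted by start.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    n = len(seq)
    candidates: list[RepeatTract] = []
    for k, min_count in sorted(min_repeats.items()):
        i = 0
        while i + 2 * k <= n:
            unit = seq[i : i + k]
            if "N" in unit or any(c not in "ACGT" for c in unit):
                i += 1
                continue
            # extend the periodic region: positions t with seq[t] == seq[t+k]
            j = i
            while j + k < n and seq[j] == seq[j + k] and seq[j + k] in "ACGT":
                j += 1
            # periodic region is [i, j + k); whole copies from the left phase
            region_len = j + k - i
            count = region_len // k
            if count >= 2:
                if is_primitive(unit) and count >= min_count:
                    end = i + count * k
                    candidates.append(
                        RepeatTract(seq_id, i, end, canonical_motif(unit), unit, count)
                    )
                # skip past the periodic region: any tract starting inside it
                # with this unit length is a phase of the same run
                i = j + 1
            else:
                i += 1
    # overlap resolution: longer tract wins, ties by smaller start
    candidates.sort(key=lambda t: (-t.tract_len, t.start))
    kept: list[RepeatTract] = []
    for t in candidates:
        if all(t.end <= u.start or t.start >= u.end for u in kept):
            kept.append(t)
    kept.sort(key=lambda t: t.start)
    return kept


def tally_motif_classes(tracts: list[RepeatTract]) -> pd.DataFrame:
    """Tally canonical motif classes.

    Returns a DataFrame indexed by class with columns ``count`` and
    ``fraction``, ordered by descending count then lexicographic class.
    Empty input yields an empty table.
    """
    if not tracts:
        return pd.DataFrame(columns=["count", "fraction"])
    counts: dict[str, int] = {}
    for t in tracts:
        counts[t.motif] = counts.get(t.motif, 0) + 1
    total = len(tracts)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["motif", "count"]).set_index("motif")
    df["fraction"] = df["count"] / total
    return df
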