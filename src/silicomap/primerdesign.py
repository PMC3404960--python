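"""PCR primer-pair selection on marker-candidate flanks.

A self-contained picker in the spirit of Primer3: candidate windows of
18–27 bases are enumerated in the left and right flanks of the target
feature (the right primer being the reverse complement of its template
window), filtered on melting temperature, GC content, homopolymer runs,
3'-end complementarity and product size, and ranked by a weighted penalty.

Melting temperatures use the unified nearest-neighbor thermodynamic
parameters (Allawi & SantaLucia 1997) with a salt-corrected entropy at
fixed default conditions — 50 mM monovalent cation, 250 nM primer — so
reported Tm values are reproducible across runs and machines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from silicomap.ssrscan import revcomp

# Unified NN parameters: (dH kcal/mol, dS cal/(mol K)) per stacked pair,
# read 5'->3' on the top strand.
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
    # complements
    "TT": (-7.9, -22.2), "TG": (-8.5, -22.7), "AC": (-8.4, -22.4),
    "AG": (-7.8, -21.0), "TC": (-8.2, -22.2), "CC": (-8.0, -19.9),
}
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}

_R = 1.987  # cal/(mol K)
MONOVALENT_M = 0.05   # 50 mM Na+
PRIMER_M = 250e-9     # 250 nM primer, assumed in excess over template

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def melting_temp(seq: str) -> float:
    """Nearest-neighbor melting temperature (°C) of a primer.

    Duplex of ``seq`` with its perfect complement under the fixed default
    conditions above; entropy is salt-corrected by 0.368·(N−1)·ln[Na+].
    Symmetric under reverse complement.
    """
    if not 10 <= len(seq) <= 36:
        raise ValueError(f"primer length must be 10-36, got {len(seq)}")
    if any(c not in "ACGT" for c in seq):
        raise ValueError(f"ambiguity codes not supported: {seq!r}")
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        h, s = _INIT[end]
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(MONOVALENT_M)
    return 1000.0 * dh / (ds + _R * math.log(PRIMER_M)) - 273.15


def gc_fraction(seq: str) -> float:
    return sum(1 for c in seq if c in "GC") / len(seq) if seq else 0.0


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        best = max(best, run)
    return best


def _three_prime_comp_run(a: str, b: str) -> int:
    """Longest exact-complement run anchored at the 3' end of ``a`` against any window of ``b``.

    Used for both self- (a==b) and cross-complementarity: a 3' suffix of
    ``a`` that is the reverse complement of some substring of ``b`` can
    prime extension.  Returns the longest such suffix length.
    """
    longest = 0
    for L in range(1, min(len(a), len(b)) + 1):
        suffix = a[-L:]
        if revcomp(suffix) in b:
            longest = L
        else:
            break
    return longest


@dataclass
class PrimerPair:
    """A left/right primer pair on a candidate template.

    ``left`` is on the template strand; ``right`` is the reverse complement
    of its template window.  Positions are 0-based on the template; product
    length is ``right_end − left_start``.
    """

    left: str
    right: str
    left_start: int
    right_start: int          # start of the right primer's template window
    left_tm: float
    right_tm: float
    left_gc: float
    right_gc: float
    product_length: int
    penalty: float
    left_internal: bool = False   # drawn from the TE consensus interior
    right_internal: bool = False


@dataclass
class PrimerConstraints:
    """All numeric constraints of the picker; defaults mirror common Primer3 practice."""

    min_len: int = 18
    max_len: int = 27
    opt_len: int = 20
    min_tm: float = 57.0
    max_tm: float = 63.0
    opt_tm: float = 60.0
    min_gc: float = 0.30
    max_gc: float = 0.70
    opt_gc: float = 0.50
    max_homopolymer: int = 4
    max_3p_comp: int = 4
    product_range: tuple[int, int] = (80, 400)
    w_len: float = 0.5
    w_tm: float = 1.0
    w_gc: float = 5.0
    w_tm_diff: float = 0.5
    rejections: dict = field(default_factory=dict)


def _candidate_windows(region: str, offset: int, cons: PrimerConstraints, rejections: dict):
    """Feasible single-primer windows in ``region`` (template coordinates via ``offset``)."""
    out = []
    for L in range(cons.min_len, cons.max_len + 1):
        for i in range(len(region) - L + 1):
            w = region[i : i + L]
            if any(c not in "ACGT" for c in w):
                rejections["non_acgt"] = rejections.get("non_acgt", 0) + 1
                continue
            gc = gc_fraction(w)
            if not cons.min_gc <= gc <= cons.max_gc:
                rejections["gc"] = rejections.get("gc", 0) + 1
                continue
            if max_homopolymer(w) > cons.max_homopolymer:
                rejections["homopolymer"] = rejections.get("homopolymer", 0) + 1
                continue
            tm = melting_temp(w)
            if not cons.min_tm <= tm <= cons.max_tm:
                rejections["tm"] = rejections.get("tm", 0) + 1
                continue
            out.append((offset + i, w, tm, gc))
    return out


def design_primers(
    template: str,
    target: tuple[int, int],
    constraints: PrimerConstraints | None = None,
    te_interior: tuple[int, int] | None = None,
    max_pairs: int = 10,
) -> list[PrimerPair]:
    """Enumerate, filter and rank primer pairs flanking ``target``.

    The left primer lies entirely left of ``target``, the right primer
    (reverse-complemented) entirely right of it.  For TE candidates lacking
    a usable flank, ``te_interior`` — the template interval occupied by the
    transposon consensus — supplies fallback windows from the element's
    interior so the pair still spans one junction.

    Returns up to ``max_pairs`` pairs ranked by penalty (ties: leftmost
    left primer, then shortest product).  An empty list means no feasible
    pair; per-filter rejection counts accumulate in
    ``constraints.rejections``.
    """
    if len(template) < 60:
        raise ValueError("template must be at least 60 bases")
    s, e = target
    if not (0 <= s <= e <= len(template)):
        raise ValueError("target interval outside template")
    cons = constraints or PrimerConstraints()
    rej = cons.rejections

    left_windows = _candidate_windows(template[:s], 0, cons, rej)
    left_internal = False
    if not left_windows and te_interior is not None:
        ts, te_ = te_interior
        margin = (te_ - ts) // 4
        left_windows = _candidate_windows(template[ts : ts + (te_ - ts) // 2], ts, cons, rej)
        left_internal = True

    right_region = template[e:]
    right_windows_fwd = _candidate_windows(right_region, e, cons, rej)
    right_internal = False
    if not right_windows_fwd and te_interior is not None:
        ts, te_ = te_interior
        right_windows_fwd = _candidate_windows(template[ts + (te_ - ts) // 2 : te_], ts + (te_ - ts) // 2, cons, rej)
        right_internal = True

    pairs = []
    for rstart, rw, rtm, rgc in right_windows_fwd:
        right_seq = revcomp(rw)
        for lstart, lw, ltm, lgc in left_windows:
            product = (rstart + len(rw)) - lstart
            lo, hi = cons.product_range
            if not lo <= product <= hi:
                rej["product_size"] = rej.get("product_size", 0) + 1
                continue
            if (
                _three_prime_comp_run(lw, lw) > cons.max_3p_comp
                or _three_prime_comp_run(right_seq, right_seq) > cons.max_3p_comp
                or _three_prime_comp_run(lw, right_seq) > cons.max_3p_comp
                or _three_prime_comp_run(right_seq, lw) > cons.max_3p_comp
            ):
                rej["dimer"] = rej.get("dimer", 0) + 1
                continue
            penalty = (
                cons.w_len * (abs(len(lw) - cons.opt_len) + abs(len(rw) - cons.opt_len))
                + cons.w_tm * (abs(ltm - cons.opt_tm) + abs(rtm - cons.opt_tm))
                + cons.w_gc * (abs(lgc - cons.opt_gc) + abs(rgc - cons.opt_gc))
                + cons.w_tm_diff * abs(ltm - rtm)
            )
            pairs.append(
                PrimerPair(
                    left=lw, right=right_seq,
                    left_start=lstart, right_start=rstart,
                    left_tm=ltm, right_tm=rtm, left_gc=lgc, right_gc=rgc,
                    product_length=product, penalty=penalty,
                    left_internal=left_internal, right_internal=right_internal,
                )
            )
    pairs.sort(key=lambda p: (p.penalty, p.left_start, p.product_length))
    return pairs[:max_pairs]
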