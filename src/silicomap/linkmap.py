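"""F2 linkage-map construction: segregation tests, EM recombination fractions,
LOD grouping, SARF ordering and Haldane distances.

Genotype codes follow the usual F2 convention: ``a`` (P1 homozygote), ``h``
(heterozygote), ``b`` (P2 homozygote) for codominant loci; ``c`` (not-a,
i.e. h-or-b) and ``d`` (not-b) for dominant loci; ``-`` for missing.  The
recombination fraction between two loci is the maximum-likelihood estimate
under the standard F2 two-locus multinomial (coupling phase, no
interference), obtained by EM over the latent per-gamete recombination
events; this handles every codominant/dominant code combination uniformly,
including the coupling/repulsion mixture of the double-heterozygote class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

MISSING = "-"
#: compatible genotype sets (count of P2 alleles) per code
CODE_SETS = {"a": (0,), "h": (1,), "b": (2,), "c": (1, 2), "d": (0, 1)}

# ---------------------------------------------------------------------------
# Haldane mapping function


def haldane_cM(r):
    """Map distance in cM from recombination fraction: d = −50·ln(1−2r).

    ``r`` at or above 0.5 yields ``inf`` (unlinked loci have no finite
    distance).  Accepts scalars or arrays.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("recombination fraction must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(r_arr >= 0.5, np.inf, -50.0 * np.log1p(-2.0 * np.minimum(r_arr, 0.5)))
    return float(d) if np.isscalar(r) else d


def haldane_r(d):
    """Inverse Haldane: r = (1 − e^(−d/50))/2 for a distance in cM."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-d_arr / 50.0))
    return float(r) if np.isscalar(d) else r


# ---------------------------------------------------------------------------
# Genotype matrix

#: the canonical in-memory genotype container is a pandas DataFrame of code
#: strings, individuals as rows and loci as columns
GenotypeMatrix = pd.DataFrame


def validate_genotypes(gm: pd.DataFrame) -> pd.DataFrame:
    """Check a genotype matrix: legal codes only, no mixed codominant/dominant locus.

    Returns the matrix unchanged; raises ``ValueError`` naming the first
    offending locus.
    """
    for locus in gm.columns:
        try:
            locus_type(gm[locus])
        except ValueError as exc:
            raise ValueError(f"locus {locus!r}: {exc}") from None
    return gm


# ---------------------------------------------------------------------------
# Segregation tests


def locus_type(column: pd.Series) -> str:
    """``codominant`` or ``dominant_ac`` / ``dominant_bd`` from the codes present."""
    codes = set(column) - {MISSING}
    bad = codes - set(CODE_SETS)
    if bad:
        raise ValueError(f"illegal genotype codes {sorted(bad)}")
    if "c" in codes and "d" in codes:
        raise ValueError("mixed dominant codes c and d in one locus")
    if "c" in codes:
        if codes - {"a", "c"}:
            raise ValueError(f"mixed codominant/dominant codes {sorted(codes)}")
        return "dominant_ac"
    if "d" in codes:
        if codes - {"b", "d"}:
            raise ValueError(f"mixed codominant/dominant codes {sorted(codes)}")
        return "dominant_bd"
    return "codominant"


def segregation_chisq(column: pd.Series) -> tuple[float, float, int]:
    """Chi-square goodness of fit to the Mendelian F2 ratio.

    Codominant loci are tested against 1:2:1 (df=2), dominant loci against
    3:1 (df=1), with no continuity correction.  Returns ``(chi2, p, df)``.
    """
    obs_codes = column[column != MISSING]
    if len(obs_codes) < 2:
        raise ValueError("need at least 2 non-missing observations")
    ltype = locus_type(column)
    n = len(obs_codes)
    counts = obs_codes.value_counts()
    if ltype == "codominant":
        obs = [counts.get(c, 0) for c in "ahb"]
        exp = [n / 4, n / 2, n / 4]
    elif ltype == "dominant_ac":
        obs = [counts.get("c", 0), counts.get("a", 0)]
        exp = [3 * n / 4, n / 4]
    else:
        obs = [counts.get("d", 0), counts.get("b", 0)]
        exp = [3 * n / 4, n / 4]
    chi2, p = stats.chisquare(obs, exp)
    return float(chi2), float(p), len(obs) - 1


# ---------------------------------------------------------------------------
# Two-point recombination by EM

# gametes in coupling phase: (allele at locus 1, allele at locus 2);
# parental gametes (0,0) and (1,1), recombinant (0,1) and (1,0)
_GAMETES = [(0, 0), (0, 1), (1, 0), (1, 1)]
_RECOMB = [0, 1, 1, 0]

# unordered gamete-pair configurations: (i, j, multiplicity, n_recomb, gA, gB)
_CONFIGS = []
for _i in range(4):
    for _j in range(_i, 4):
        _CONFIGS.append(
            (
                _i,
                _j,
                2 if _i < _j else 1,
                _RECOMB[_i] + _RECOMB[_j],
                _GAMETES[_i][0] + _GAMETES[_j][0],
                _GAMETES[_i][1] + _GAMETES[_j][1],
            )
        )
_N_CONF = len(_CONFIGS)
_CONF_MULT = np.array([c[2] for c in _CONFIGS], dtype=float)
_CONF_REC = np.array([c[3] for c in _CONFIGS], dtype=float)
# exponents: prob of config = mult * ((1-r)/2)^(4 - nrec... per gamete) —
# each gamete contributes (1-r)/2 if parental, r/2 if recombinant
_CONF_NREC = _CONF_REC                      # recombinant gametes per config
_CONF_NPAR = 2 - _CONF_REC                  # parental gametes per config


def _config_probs(r: float) -> np.ndarray:
    return _CONF_MULT * ((1 - r) / 2) ** _CONF_NPAR * (r / 2) ** _CONF_NREC


def _class_masks(code1: str, code2: str) -> np.ndarray:
    s1, s2 = CODE_SETS[code1], CODE_SETS[code2]
    return np.array([(c[4] in s1) and (c[5] in s2) for c in _CONFIGS])


@dataclass
class TwoPointResult:
    """Two-point linkage estimate for a locus pair."""

    locus1: str
    locus2: str
    r: float
    lod: float
    n_informative: int
    non_identifiable: bool = False


def _observed_classes(col1: pd.Series, col2: pd.Series):
    mask = (col1 != MISSING) & (col2 != MISSING)
    pairs = list(zip(col1[mask], col2[mask]))
    classes: dict[tuple[str, str], int] = {}
    for p in pairs:
        classes[p] = classes.get(p, 0) + 1
    return classes, int(mask.sum())


def two_point_loglik(classes: dict[tuple[str, str], int], r) -> float | np.ndarray:
    """Multinomial log-likelihood (natural log) of observed code-pair counts at ``r``.

    ``r`` may be a scalar or an array (for grid evaluation)."""
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    probs = (
        _CONF_MULT[None, :]
        * ((1 - r_arr[:, None]) / 2) ** _CONF_NPAR[None, :]
        * (r_arr[:, None] / 2) ** _CONF_NREC[None, :]
    )
    ll = np.zeros(len(r_arr))
    for (c1, c2), n in classes.items():
        mask = _class_masks(c1, c2)
        p = probs[:, mask].sum(axis=1)
        ll += n * np.log(np.maximum(p, 1e-300))
    return float(ll[0]) if np.isscalar(r) else ll


def estimate_rf_f2(
    col1: pd.Series,
    col2: pd.Series,
    tol: float = 1e-6,
    max_iter: int = 2000,
    locus1: str | None = None,
    locus2: str | None = None,
) -> TwoPointResult:
    """Maximum-likelihood recombination fraction between two F2 loci by EM.

    The E-step imputes the expected number of recombinant gametes per
    individual given the current ``r`` (the double heterozygote mixes the
    0-recombinant coupling and 2-recombinant repulsion configurations); the
    M-step sets ``r`` to expected recombinant gametes over total gametes.
    Iterated until the change in ``r`` falls below ``tol``; ``r`` is
    clamped to [0, 0.5].  LOD compares the likelihood at the estimate with
    free recombination (r = 0.5).
    """
    t1, t2 = locus_type(col1), locus_type(col2)
    for col, name in ((col1, "locus1"), (col2, "locus2")):
        if len(set(col) - {MISSING}) < 2:
            raise ValueError(f"{name} is monomorphic")
    classes, n = _observed_classes(col1, col2)
    if n < 10:
        raise ValueError(f"need >= 10 individuals non-missing at both loci, got {n}")
    non_ident = {t1, t2} == {"dominant_ac", "dominant_bd"}

    masks = {pair: _class_masks(*pair) for pair in classes}
    r = 0.25
    for _ in range(max_iter):
        q = _config_probs(r)
        total_rec = 0.0
        for pair, count in classes.items():
            qm = q * masks[pair]
            denom = qm.sum()
            if denom <= 0:
                continue
            total_rec += count * (qm * _CONF_REC).sum() / denom
        r_new = min(max(total_rec / (2 * n), 0.0), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    lod = (two_point_loglik(classes, r) - two_point_loglik(classes, 0.5)) / math.log(10)
    return TwoPointResult(
        locus1=locus1 or getattr(col1, "name", "") or "locus1",
        locus2=locus2 or getattr(col2, "name", "") or "locus2",
        r=float(r),
        lod=max(float(lod), 0.0),
        n_informative=n,
        non_identifiable=non_ident,
    )


def two_point_all(gm: pd.DataFrame, min_informative: int = 10) -> list[TwoPointResult]:
    """Two-point estimates for every locus pair of a genotype matrix.

    Pairs failing preconditions (monomorphic column, too few joint
    observations) are skipped.
    """
    results = []
    for l1, l2 in combinations(gm.columns, 2):
        try:
            results.append(estimate_rf_f2(gm[l1], gm[l2], locus1=l1, locus2=l2))
        except ValueError:
            continue
    return results


# ---------------------------------------------------------------------------
# Grouping and ordering


def group_loci(
    results: list[TwoPointResult],
    lod_threshold: float = 4.0,
    max_rf: float = 0.30,
    all_loci: list[str] | None = None,
) -> list[list[str]]:
    """Single-linkage linkage groups.

    Loci are connected when LOD >= ``lod_threshold`` and r <= ``max_rf``;
    groups are the connected components, each sorted, ordered by size then
    first locus.
    """
    if lod_threshold <= 0:
        raise ValueError("lod_threshold must be positive")
    loci = set(all_loci or [])
    for tp in results:
        loci.update((tp.locus1, tp.locus2))
    parent = {loc: loc for loc in loci}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for tp in results:
        if tp.lod >= lod_threshold and tp.r <= max_rf:
            ra, rb = find(tp.locus1), find(tp.locus2)
            if ra != rb:
                parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for loc in loci:
        groups.setdefault(find(loc), []).append(loc)
    out = [sorted(g) for g in groups.values()]
    out.sort(key=lambda g: (-len(g), g[0]))
    return out


def group_sweep(results, thresholds=range(4, 11), max_rf: float = 0.30) -> dict[int, list[list[str]]]:
    """Partitions for a sweep of LOD grouping thresholds (default 4..10)."""
    return {t: group_loci(results, lod_threshold=t, max_rf=max_rf) for t in thresholds}


def _sarf(order: list[str], rf: pd.DataFrame) -> float:
    return float(sum(rf.loc[a, b] for a, b in zip(order, order[1:])))


def order_group(group: list[str], results: list[TwoPointResult]) -> tuple[list[str], list[float]]:
    """Order loci within one linkage group and assign cM positions.

    Initial order by greedy chain extension from the pair with smallest
    r̂ (each remaining locus appended at whichever chain end adds the least
    recombination), then 2-opt segment reversals minimizing SARF — the sum
    of adjacent recombination fractions — to a local optimum.  Positions
    are cumulative Haldane distances of adjacent r̂.  Orientation is
    normalized so the lexicographically smaller terminal locus comes first.
    """
    if len(group) < 2:
        raise ValueError("group must have >= 2 loci")
    rf = pd.DataFrame(np.full((len(group), len(group)), 0.5), index=group, columns=group)
    seen = False
    for tp in results:
        if tp.locus1 in rf.index and tp.locus2 in rf.index:
            rf.loc[tp.locus1, tp.locus2] = tp.r
            rf.loc[tp.locus2, tp.locus1] = tp.r
            seen = True
    np.fill_diagonal(rf.values, 0.0)
    if not seen:
        raise ValueError("no pairwise estimates available for this group")

    if len(group) == 2:
        order = sorted(group)
    else:
        # greedy chain from the tightest pair
        best_pair = min(
            ((a, b) for a, b in combinations(group, 2)),
            key=lambda p: (rf.loc[p[0], p[1]], p),
        )
        chain = list(best_pair)
        remaining = [loc for loc in group if loc not in chain]
        while remaining:
            best = None
            for loc in remaining:
                for end, anchor in ((0, chain[0]), (1, chain[-1])):
                    cost = rf.loc[anchor, loc]
                    key = (cost, loc, end)
                    if best is None or key < best:
                        best = key
            _, loc, end = best
            remaining.remove(loc)
            if end == 0:
                chain.insert(0, loc)
            else:
                chain.append(loc)
        # 2-opt: reverse internal segments while SARF improves
        improved = True
        while improved:
            improved = False
            current = _sarf(chain, rf)
            for i in range(len(chain) - 1):
                for j in range(i + 2, len(chain) + 1):
                    cand = chain[:i] + chain[i:j][::-1] + chain[j:]
                    if _sarf(cand, rf) < current - 1e-12:
                        chain = cand
                        improved = True
                        current = _sarf(chain, rf)
        order = chain
    if order[-1] < order[0]:
        order = order[::-1]
    adj = np.array([rf.loc[a, b] for a, b in zip(order, order[1:])])
    dists = haldane_cM(np.minimum(adj, 0.499))
    positions = [0.0] + list(np.cumsum(dists))
    return order, positions


# ---------------------------------------------------------------------------
# Map assembly and reporting


@dataclass
class LinkageMap:
    """Ordered linkage groups with cM positions and per-locus segregation stats."""

    groups: dict[str, list[tuple[str, float]]]
    segregation: pd.DataFrame = field(default_factory=pd.DataFrame)
    # segregation columns: locus, chi2, p, df, distorted

    def locus_position(self, locus: str) -> tuple[str, float]:
        for name, loci in self.groups.items():
            for loc, pos in loci:
                if loc == locus:
                    return name, pos
        raise KeyError(locus)


def build_map(
    gm: pd.DataFrame,
    lod_threshold: float = 4.0,
    max_rf: float = 0.30,
    distortion_alpha: float = 0.05,
) -> tuple[LinkageMap, list[TwoPointResult]]:
    """Full pipeline: two-point estimates → LOD grouping → per-group ordering.

    Single-locus groups are kept (position 0).  Returns the map and the
    two-point results it was built from.
    """
    results = two_point_all(gm)
    partition = group_loci(results, lod_threshold, max_rf, all_loci=list(gm.columns))
    groups = {}
    for gi, members in enumerate(partition, start=1):
        name = f"LG{gi:02d}"
        if len(members) == 1:
            groups[name] = [(members[0], 0.0)]
        else:
            order, positions = order_group(members, results)
            groups[name] = list(zip(order, positions))
    seg_rows = []
    for locus in gm.columns:
        try:
            chi2, p, df = segregation_chisq(gm[locus])
        except ValueError:
            chi2, p, df = np.nan, np.nan, 0
        seg_rows.append(
            {"locus": locus, "chi2": chi2, "p": p, "df": df, "distorted": bool(p < distortion_alpha)}
        )
    seg = pd.DataFrame(seg_rows).set_index("locus")
    return LinkageMap(groups=groups, segregation=seg), results


def map_report(linkage_map: LinkageMap) -> pd.DataFrame:
    """Per-group summary: length (cM), locus count, marker density, distortion %.

    Density is cM per marker *interval* — group length divided by
    (loci − 1) — and is blank (NaN) for single-locus groups.  Distortion %
    is the percentage of loci with segregation p < 0.05, one decimal.
    """
    from silicomap.markerscreen import round_half_up_pct

    rows = []
    seg = linkage_map.segregation
    for name, loci in linkage_map.groups.items():
        length = loci[-1][1] if loci else 0.0
        n = len(loci)
        density = round(length / (n - 1), 1) if n > 1 else np.nan
        if len(seg):
            distorted = sum(bool(seg.loc[loc, "distorted"]) for loc, _ in loci if loc in seg.index)
        else:
            distorted = 0
        rows.append(
            {
                "group": name,
                "length_cM": round(length, 1),
                "n_loci": n,
                "density_cM_per_interval": density,
                "distortion_pct": round_half_up_pct(distorted, n),
            }
        )
    return pd.DataFrame(rows, columns=["group", "length_cM", "n_loci", "density_cM_per_interval", "distortion_pct"])
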