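"""QTL detection on an F2 linkage map.

Two complementary searches:

* :func:`hk_scan` — Haley–Knott interval mapping: at each test position
  the QTL genotype probabilities are computed conditionally on the nearest
  non-missing flanking markers (Haldane transition probabilities, no
  interference) and the phenotype is regressed on the additive score
  x_a = P(QQ) − P(qq) and dominance score x_d = P(Qq).  LOD =
  (n/2)·log10(RSS0/RSS1).  Genome-wide significance comes from
  :func:`permutation_threshold`.
* :func:`gmm_search` — exhaustive genotype-matrix association for
  epistatic traits: every single locus and unordered locus pair partitions
  the individuals by joint genotype and a one-way ANOVA tests phenotype
  differences among the groups; combinations are ranked by p then F.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

from silicomap.linkmap import CODE_SETS, MISSING, LinkageMap, haldane_r

_QTL_CODES = ("a", "h", "b")


def _conditional_qtl_probs(
    code_left: str | None,
    code_right: str | None,
    r_left: float,
    r_right: float,
) -> tuple[float, float, float]:
    """P(QTL genotype = 0/1/2 P2 alleles) given flanking marker codes.

    Enumerates ordered gamete configurations (allele at left marker, at the
    QTL, at the right marker, per gamete) with Haldane transition
    probabilities and conditions on the observed marker genotypes; dominant
    codes condition on the compatible genotype set.  A ``None`` code means
    no informative marker on that side.
    """
    s_left = CODE_SETS.get(code_left) if code_left else None
    s_right = CODE_SETS.get(code_right) if code_right else None

    def t(x, y, r):
        return 1.0 - r if x == y else r

    probs = [0.0, 0.0, 0.0]
    for g1 in product((0, 1), repeat=3):
        for g2 in product((0, 1), repeat=3):
            if s_left is not None and (g1[0] + g2[0]) not in s_left:
                continue
            if s_right is not None and (g1[2] + g2[2]) not in s_right:
                continue
            w = 1.0
            for g in (g1, g2):
                w *= 0.25 * t(g[0], g[1], r_left) * t(g[1], g[2], r_right)
            probs[g1[1] + g2[1]] += w
    total = sum(probs)
    if total <= 0:
        return (0.25, 0.5, 0.25)
    return tuple(p / total for p in probs)


def _scan_designs(
    genotypes: pd.DataFrame,
    linkage_map: LinkageMap,
    step_cM: float = 1.0,
):
    """Design matrices [1, x_a, x_d] for every test position of the scan.

    Returns ``(positions, designs)`` where positions is a list of
    ``(group, cM)`` and designs a list of (n × 3) arrays.  Per individual,
    the nearest non-missing flanking markers are used; positions landing on
    an informative codominant marker collapse to its indicator scores.
    """
    n = len(genotypes)
    positions = []
    designs = []
    cache: dict[tuple, tuple[float, float]] = {}
    for gname, loci in linkage_map.groups.items():
        if not loci:
            continue
        marker_ids = [loc for loc, _ in loci]
        marker_pos = np.array([pos for _, pos in loci])
        present = [m for m in marker_ids if m in genotypes.columns]
        if not present:
            continue
        length = marker_pos[-1]
        steps = list(np.arange(0.0, length, step_cM)) + [float(length)]
        codes = genotypes[marker_ids].to_numpy()
        for pos in steps:
            X = np.ones((n, 3))
            for i in range(n):
                li = None
                for j in range(len(marker_ids) - 1, -1, -1):
                    if marker_pos[j] <= pos + 1e-9 and codes[i, j] != MISSING:
                        li = j
                        break
                ri = None
                for j in range(len(marker_ids)):
                    if marker_pos[j] >= pos - 1e-9 and codes[i, j] != MISSING:
                        ri = j
                        break
                if li is not None and ri is not None and li == ri:
                    ri = li  # on an informative marker
                cl = codes[i, li] if li is not None else None
                cr = codes[i, ri] if ri is not None else None
                rl = haldane_r(pos - marker_pos[li]) if li is not None else 0.5
                rr = haldane_r(marker_pos[ri] - pos) if ri is not None else 0.5
                key = (cl, cr, round(rl, 9), round(rr, 9))
                if key not in cache:
                    p0, p1, p2 = _conditional_qtl_probs(cl, cr, rl, rr)
                    cache[key] = (p2 - p0, p1)
                X[i, 1], X[i, 2] = cache[key]
            positions.append((gname, float(pos)))
            designs.append(X)
    return positions, designs


@dataclass
class QtlScanResult:
    """Interval-mapping profile with optional threshold and declared peaks."""

    profile: pd.DataFrame   # columns: group, position_cM, lod, a, d, pve
    threshold: float | None = None
    peaks: list = field(default_factory=list)

    def find_peaks(self, threshold: float, drop: float = 1.0) -> list[dict]:
        """Per-group maxima above ``threshold`` with a LOD-drop support interval."""
        peaks = []
        for gname, sub in self.profile.groupby("group", sort=False):
            sub = sub.reset_index(drop=True)
            if sub["lod"].max() < threshold:
                continue
            k = int(sub["lod"].idxmax())
            peak_lod = sub.loc[k, "lod"]
            lo = k
            while lo > 0 and sub.loc[lo - 1, "lod"] >= peak_lod - drop:
                lo -= 1
            hi = k
            while hi < len(sub) - 1 and sub.loc[hi + 1, "lod"] >= peak_lod - drop:
                hi += 1
            peaks.append(
                {
                    "group": gname,
                    "position_cM": float(sub.loc[k, "position_cM"]),
                    "lod": float(peak_lod),
                    "a": float(sub.loc[k, "a"]),
                    "d": float(sub.loc[k, "d"]),
                    "pve": float(sub.loc[k, "pve"]),
                    "support_cM": (float(sub.loc[lo, "position_cM"]), float(sub.loc[hi, "position_cM"])),
                }
            )
        self.peaks = peaks
        self.threshold = threshold
        return peaks


def _fit_position(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(LOD, a, d, pve) for one design matrix against phenotype y."""
    n = len(y)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    coef, _res, _rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss1 = float(resid @ resid)
    rss1 = max(rss1, 1e-300)
    lod = (n / 2.0) * np.log10(max(rss0, 1e-300) / rss1)
    pve = 1.0 - rss1 / rss0 if rss0 > 0 else 0.0
    return max(lod, 0.0), float(coef[1]), float(coef[2]), max(min(pve, 1.0), 0.0)


def hk_scan(
    genotypes: pd.DataFrame,
    linkage_map: LinkageMap,
    phenotype: pd.Series,
    step_cM: float = 1.0,
    cofactors: list[str] | None = None,
) -> QtlScanResult:
    """Haley–Knott interval mapping over the whole map.

    ``cofactors`` optionally names marker loci whose additive/dominance
    indicator scores are residualized out of the phenotype before scanning
    (a fixed-cofactor hook, not full composite interval mapping).
    """
    y = pd.to_numeric(phenotype.reindex(genotypes.index), errors="coerce")
    keep = y.notna()
    y = y[keep].to_numpy(dtype=float)
    gm = genotypes.loc[keep.index[keep]]
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    if cofactors:
        C = [np.ones(len(y))]
        amap = {"a": -1.0, "h": 0.0, "b": 1.0, "c": 0.5, "d": -0.5, MISSING: 0.0}
        dmap = {"a": 0.0, "h": 1.0, "b": 0.0, "c": 2 / 3, "d": 2 / 3, MISSING: 0.5}
        for m in cofactors:
            C.append(gm[m].map(amap).to_numpy(dtype=float))
            C.append(gm[m].map(dmap).to_numpy(dtype=float))
        C = np.column_stack(C)
        coef, *_ = np.linalg.lstsq(C, y, rcond=None)
        y = y - C @ coef + y.mean()
    positions, designs = _scan_designs(gm, linkage_map, step_cM)
    rows = []
    for (gname, pos), X in zip(positions, designs):
        lod, a, d, pve = _fit_position(X, y)
        rows.append({"group": gname, "position_cM": pos, "lod": lod, "a": a, "d": d, "pve": pve})
    return QtlScanResult(profile=pd.DataFrame(rows))


def permutation_threshold(
    genotypes: pd.DataFrame,
    linkage_map: LinkageMap,
    phenotype: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    step_cM: float = 1.0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    Phenotype labels are permuted ``n_perm`` times; the genome-wide maximum
    LOD of each permutation is recorded and the empirical (1 − alpha)
    quantile (linear interpolation, 'type 7') is returned.  Seeded and
    reproducible.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = pd.to_numeric(phenotype.reindex(genotypes.index), errors="coerce")
    keep = y.notna()
    y = y[keep].to_numpy(dtype=float)
    gm = genotypes.loc[keep.index[keep]]
    n = len(y)
    rng = np.random.default_rng(seed)
    _positions, designs = _scan_designs(gm, linkage_map, step_cM)
    # orthonormal bases of each design's column space (rank-aware; a
    # degenerate design must not inflate the projection): RSS1 = |y|^2 - |Q^T y|^2
    qs = []
    for X in designs:
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        qs.append(U[:, s > s[0] * 1e-10])
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)  # n × n_perm
    col_means = perms.mean(axis=0)
    rss0 = ((perms - col_means) ** 2).sum(axis=0)
    yty = (perms**2).sum(axis=0)
    max_lod = np.zeros(n_perm)
    for Q in qs:
        proj = Q.T @ perms                      # 3 × n_perm
        rss1 = np.maximum(yty - (proj**2).sum(axis=0), 1e-300)
        lod = (n / 2.0) * np.log10(np.maximum(rss0, 1e-300) / rss1)
        np.maximum(max_lod, lod, out=max_lod)
    return float(np.quantile(max_lod, 1.0 - alpha))


@dataclass
class ComboResult:
    """ANOVA of phenotype across joint-genotype groups of a locus combination."""

    loci: tuple[str, ...]
    groups: dict            # joint genotype string -> (n, mean)
    F: float
    p: float
    r2: float
    n: int


def gmm_search(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    max_combo: int = 2,
    min_samples: int = 1,
) -> list[ComboResult]:
    """Exhaustive single-locus and locus-pair genotype-combination association.

    Individuals missing at any locus of a combination are dropped; joint-
    genotype groups with fewer than ``min_samples`` members are dropped;
    combinations with fewer than two remaining groups or no residual
    degrees of freedom are skipped.  Results are ranked by p, then by
    descending F.
    """
    if max_combo not in (1, 2):
        raise ValueError("max_combo must be 1 or 2")
    y = pd.to_numeric(phenotype.reindex(genotypes.index), errors="coerce")
    combos = [(c,) for c in genotypes.columns]
    if max_combo == 2:
        combos += list(combinations(genotypes.columns, 2))
    results = []
    for loci in combos:
        sub = genotypes[list(loci)]
        mask = y.notna() & (sub != MISSING).all(axis=1)
        if mask.sum() < 2:
            continue
        yv = y[mask].to_numpy(dtype=float)
        labels = sub[mask].agg("/".join, axis=1)
        frame = pd.DataFrame({"y": yv, "g": labels.to_numpy()})
        sizes = frame.groupby("g")["y"].agg(["size", "mean"])
        keepg = sizes.index[sizes["size"] >= min_samples]
        frame = frame[frame["g"].isin(keepg)]
        k = frame["g"].nunique()
        ntot = len(frame)
        if k < 2 or ntot - k < 1:
            continue
        grand = frame["y"].mean()
        by = frame.groupby("g")["y"]
        ssb = float((by.size() * (by.mean() - grand) ** 2).sum())
        sst = float(((frame["y"] - grand) ** 2).sum())
        ssw = max(sst - ssb, 0.0)
        if sst <= 0:
            continue
        if ssw <= 1e-300:
            F, p = np.inf, 0.0
        else:
            F = (ssb / (k - 1)) / (ssw / (ntot - k))
            p = float(stats.f.sf(F, k - 1, ntot - k))
        results.append(
            ComboResult(
                loci=tuple(loci),
                groups={g: (int(s), float(m)) for g, (s, m) in sizes.loc[keepg].iterrows()},
                F=float(F),
                p=p,
                r2=ssb / sst,
                n=ntot,
            )
        )
    results.sort(key=lambda cr: (cr.p, -cr.F, cr.loci))
    return results
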