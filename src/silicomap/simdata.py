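"""Seeded generators for all pipeline inputs, with ground truth for recovery tests.

Three generators cover the two workflow stages:

* :func:`simulate_two_line_reads` — reads from SSR- and MITE-enriched
  libraries of two inbred lines.  Each SSR locus has unique flanks (no two
  loci share a 20-mer), a motif drawn from a weighted pool and per-line
  repeat counts that differ at a configurable fraction of loci; each TE
  site is either shared or line-specific.  Reads carry i.i.d. substitution
  errors.
* :func:`simulate_f2` — F2 genotypes from a true linkage map, by Markov
  meiosis without crossover interference (Haldane model), with optional
  viability-based segregation distortion and missing data.
* :func:`simulate_phenotypes` — quantitative traits as sums of additive and
  dominance QTL effects plus Gaussian noise, and a two-locus
  double-recessive (epistatic) trait in which only individuals homozygous
  for the designated allele at *both* loci express the high phenotype class
  (the oleic/linoleic-ratio pattern controlled by the two seed FAD2 genes).

Every generator is fully determined by its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from silicomap.linkmap import haldane_r

BASES = np.array(list("ACGT"))

#: default MITE-like consensus used when the caller supplies none: a short
#: element with terminal inverted repeats, generated once from a fixed seed.
def default_te_consensus(length: int = 180, tir_len: int = 24, seed: int = 20050520) -> str:
    rng = np.random.default_rng(seed)
    core = "".join(rng.choice(BASES, size=length - 2 * tir_len))
    tir = "".join(rng.choice(BASES, size=tir_len))
    comp = str.maketrans("ACGT", "TGCA")
    return tir + core + tir.translate(comp)[::-1]


@dataclass
class SimConfig:
    """Study-condition parameters for the two-line read generator.

    Defaults are the conditions the recovery experiments run under: 200 SSR
    loci with 30% polymorphic between the lines, 100 TE sites with 43%
    line-specific insertions, 4 reads per line per locus and a 0.5%
    substitution error rate (a stand-in for Sanger-read error).
    """

    n_ssr_loci: int = 200
    frac_polymorphic: float = 0.30
    motif_pool: tuple = (("CT", 0.45), ("AC", 0.30), ("AAG", 0.15), ("AAAT", 0.10))
    repeat_count_range: tuple[int, int] = (8, 20)
    flank_len: int = 150
    n_te_sites: int = 100
    frac_te_line_specific: float = 0.43
    read_error_rate: float = 0.005
    indel_rate: float = 0.0
    reads_per_locus_per_line: int = 4
    line_names: tuple[str, str] = ("line1", "line2")
    te_consensus: str | None = None
    seed: int = 0

    def validate(self, min_detect_repeats: int = 6) -> None:
        for name in ("frac_polymorphic", "frac_te_line_specific", "read_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for motif, _w in self.motif_pool:
            if any(c not in "ACGT" for c in motif):
                raise ValueError(f"motif {motif!r} contains non-ACGT characters")
        lo, hi = self.repeat_count_range
        if lo < 2 or hi < lo:
            raise ValueError(f"bad repeat_count_range {self.repeat_count_range}")
        if self.flank_len < 2 * 36:
            raise ValueError("flank_len must be at least twice the maximum primer length")
        if lo < min_detect_repeats:
            import warnings

            warnings.warn(
                f"repeat_count_range low end {lo} is below the detection minimum "
                f"{min_detect_repeats}; short tracts may be missed",
                stacklevel=2,
            )


@dataclass
class SsrLocusTruth:
    locus_id: str
    left_flank: str
    right_flank: str
    motif: str
    repeat_counts: dict          # line -> repeat count
    polymorphic: bool


@dataclass
class TeSiteTruth:
    site_id: str
    left_flank: str
    right_flank: str
    presence: dict               # line -> bool
    line_specific: bool


@dataclass
class SimTruth:
    """Ground truth for everything a simulation produced."""

    ssr_loci: list = field(default_factory=list)
    te_sites: list = field(default_factory=list)
    map_groups: dict = field(default_factory=dict)   # group -> [(locus, cM)]
    qtl_effects: list = field(default_factory=list)  # dicts with locus/position, a, d
    epistatic_pair: tuple | None = None
    distortion_loci: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "ssr_loci": [asdict(x) for x in self.ssr_loci],
            "te_sites": [asdict(x) for x in self.te_sites],
            "map_groups": self.map_groups,
            "qtl_effects": self.qtl_effects,
            "epistatic_pair": self.epistatic_pair,
            "distortion_loci": self.distortion_loci,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimRead:
    read_id: str
    line: str
    seq: str


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _unique_flank(rng, n, used_kmers: set, k: int = 20, max_tries: int = 50) -> str:
    """Draw a uniform flank none of whose k-mers has been used by another locus."""
    for _ in range(max_tries):
        s = _rand_seq(rng, n)
        kmers = {s[i : i + k] for i in range(len(s) - k + 1)}
        if not kmers & used_kmers:
            used_kmers |= kmers
            return s
    raise RuntimeError("could not draw a flank unique at the 20-mer level")


def _add_errors(rng, seq: str, sub_rate: float, indel_rate: float = 0.0) -> str:
    if sub_rate <= 0 and indel_rate <= 0:
        return seq
    out = []
    arr = list(seq)
    n = len(arr)
    sub_mask = rng.random(n) < sub_rate
    for i, c in enumerate(arr):
        if indel_rate > 0 and rng.random() < indel_rate / 2:
            continue  # deletion
        base = c
        if sub_mask[i]:
            choices = [b for b in "ACGT" if b != c]
            base = choices[rng.integers(3)]
        out.append(base)
        if indel_rate > 0 and rng.random() < indel_rate / 2:
            out.append(str(rng.choice(BASES)))
    return "".join(out)


def simulate_two_line_reads(cfg: SimConfig) -> tuple[list[SimRead], SimTruth]:
    """Generate SSR-library and TE-library reads for two lines plus ground truth.

    Polymorphic SSR loci carry different repeat counts of the same motif in
    the two lines (offset 1–3 repeats); TE sites emit junction reads only
    from lines carrying the insertion.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = SimTruth()
    reads: list[SimRead] = []
    used_kmers: set[str] = set()
    motifs = [m for m, _ in cfg.motif_pool]
    weights = np.array([w for _, w in cfg.motif_pool], dtype=float)
    weights /= weights.sum()
    lo, hi = cfg.repeat_count_range
    l1, l2 = cfg.line_names

    n_poly = int(round(cfg.frac_polymorphic * cfg.n_ssr_loci))
    poly_flags = np.zeros(cfg.n_ssr_loci, dtype=bool)
    poly_flags[rng.choice(cfg.n_ssr_loci, size=n_poly, replace=False)] = True

    for i in range(cfg.n_ssr_loci):
        locus = f"S{i:04d}"
        left = _unique_flank(rng, cfg.flank_len, used_kmers)
        right = _unique_flank(rng, cfg.flank_len, used_kmers)
        motif = motifs[rng.choice(len(motifs), p=weights)]
        c1 = int(rng.integers(lo, hi + 1))
        if poly_flags[i]:
            delta = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 or c1 - 3 < lo else -1)
            c2 = min(max(c1 + delta, lo), hi + 3)
            if c2 == c1:
                c2 = c1 + 1
        else:
            c2 = c1
        counts = {l1: c1, l2: c2}
        truth.ssr_loci.append(
            SsrLocusTruth(locus, left, right, motif, counts, bool(poly_flags[i]))
        )
        for line in (l1, l2):
            haplotype = left + motif * counts[line] + right
            for ridx in range(cfg.reads_per_locus_per_line):
                seq = _add_errors(rng, haplotype, cfg.read_error_rate, cfg.indel_rate)
                reads.append(SimRead(f"{line}|{locus}|{ridx}", line, seq))

    te = cfg.te_consensus or default_te_consensus()
    n_specific = int(round(cfg.frac_te_line_specific * cfg.n_te_sites))
    spec_flags = np.zeros(cfg.n_te_sites, dtype=bool)
    if cfg.n_te_sites:
        spec_flags[rng.choice(cfg.n_te_sites, size=n_specific, replace=False)] = True
    for i in range(cfg.n_te_sites):
        site = f"T{i:04d}"
        left = _unique_flank(rng, cfg.flank_len, used_kmers)
        right = _unique_flank(rng, cfg.flank_len, used_kmers)
        if spec_flags[i]:
            carrier = l1 if rng.random() < 0.5 else l2
            presence = {l1: carrier == l1, l2: carrier == l2}
        else:
            presence = {l1: True, l2: True}
        truth.te_sites.append(TeSiteTruth(site, left, right, presence, bool(spec_flags[i])))
        for line in (l1, l2):
            if not presence[line]:
                continue
            haplotype = left + te + right
            for ridx in range(cfg.reads_per_locus_per_line):
                seq = _add_errors(rng, haplotype, cfg.read_error_rate, cfg.indel_rate)
                reads.append(SimRead(f"{line}|{site}|{ridx}", line, seq))
    return reads, truth


def make_truth_map(
    n_groups: int = 2,
    loci_per_group: int = 15,
    spacing_cM: float = 10.0,
    prefix: str = "M",
) -> dict[str, list[tuple[str, float]]]:
    """Evenly spaced true map: ``{group: [(locus, position_cM), ...]}``."""
    groups = {}
    idx = 0
    for g in range(1, n_groups + 1):
        name = f"G{g}"
        groups[name] = [
            (f"{prefix}{idx + j:03d}", j * spacing_cM) for j in range(loci_per_group)
        ]
        idx += loci_per_group
    return groups


def simulate_f2(
    truth_map: dict[str, list[tuple[str, float]]],
    n_individuals: int,
    distortion: dict[str, dict[str, float]] | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    dominant_loci: dict[str, str] | None = None,
) -> pd.DataFrame:
    """F2 genotypes from a true map by no-interference (Haldane) meiosis.

    Each gamete is a Markov walk along each group: the allele at the first
    locus is uniform, and switches between adjacent loci with probability
    ``r`` = inverse-Haldane of the cM interval.  Genotype codes: ``a`` (P1
    homozygote), ``h`` (heterozygote), ``b`` (P2 homozygote); loci listed
    in ``dominant_loci`` are collapsed to dominant codes (``"c"``: a-masked
    → codes a vs c; ``"d"``: b-masked → codes b vs d).  ``distortion`` maps
    locus → viability weight per genotype code, applied by rejection
    sampling.  Missing cells are coded ``-``.

    Returns a DataFrame (individuals × loci) with string codes.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    for group, loci in truth_map.items():
        pos = [p for _, p in loci]
        if any(p < 0 for p in pos) or any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"positions in group {group} must be non-negative and increasing")
    rng = np.random.default_rng(seed)
    locus_ids = [loc for loci in truth_map.values() for loc, _ in loci]
    rows = []
    accepted = 0
    while accepted < n_individuals:
        genotype: dict[str, int] = {}
        for loci in truth_map.values():
            pos = np.array([p for _, p in loci])
            rs = haldane_r(np.diff(pos))
            for gamete in range(2):
                allele = int(rng.random() < 0.5)
                for j, (loc, _p) in enumerate(loci):
                    if j > 0 and rng.random() < rs[j - 1]:
                        allele = 1 - allele
                    genotype[loc] = genotype.get(loc, 0) + allele
        codes = {loc: "ahb"[g] for loc, g in genotype.items()}
        if distortion:
            w = 1.0
            for loc, weights in distortion.items():
                w *= weights.get(codes[loc], 1.0)
            if rng.random() > w:
                continue
        accepted += 1
        rows.append([codes[loc] for loc in locus_ids])
    gm = pd.DataFrame(rows, columns=locus_ids, index=[f"F2_{i:03d}" for i in range(n_individuals)])
    if dominant_loci:
        for loc, mode in dominant_loci.items():
            if mode == "c":       # P2 allele dominant: h and b indistinguishable
                gm[loc] = gm[loc].map({"a": "a", "h": "c", "b": "c"})
            elif mode == "d":     # P1 allele dominant: a and h indistinguishable
                gm[loc] = gm[loc].map({"a": "d", "h": "d", "b": "b"})
            else:
                raise ValueError(f"dominant mode must be 'c' or 'd', got {mode!r}")
    if missing_rate > 0:
        mask = rng.random(gm.shape) < missing_rate
        gm = gm.mask(pd.DataFrame(mask, index=gm.index, columns=gm.columns), "-")
    return gm


_X_ADD = {"a": -1.0, "h": 0.0, "b": 1.0}
_X_DOM = {"a": 0.0, "h": 1.0, "b": 0.0}


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    qtl_model: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotypes for an F2 genotype matrix.

    ``qtl_model`` keys:

    * ``"qtls"`` — list of ``{"locus", "a", "d"}``; the trait is
      Σ(a·x_a + d·x_d) + N(0, σ²), with x_a ∈ {−1,0,+1} and x_d ∈ {0,1}
      (x_a = +1 for the P2 homozygote).
    * ``"sigma"`` — Gaussian noise s.d. (default 1.0).
    * ``"epistatic_pair"`` — optional ``(locusA, locusB)``; adds a second
      trait that is high (mean ``high_mean``) only for individuals
      homozygous ``b`` at both loci and low (mean ``low_mean``) otherwise,
      the double-recessive pattern of the seed O/L ratio.

    Returns a DataFrame indexed like ``genotypes`` with columns ``trait``
    and, if requested, ``epistatic_trait``.
    """
    rng = np.random.default_rng(seed)
    sigma = qtl_model.get("sigma", 1.0)
    out = pd.DataFrame(index=genotypes.index)
    qtls = qtl_model.get("qtls", [])
    for q in qtls:
        if q["locus"] not in genotypes.columns:
            raise ValueError(f"QTL locus {q['locus']!r} not in genotype matrix")
    if qtls:
        y = np.zeros(len(genotypes))
        for q in qtls:
            col = genotypes[q["locus"]]
            y += q.get("a", 0.0) * col.map(_X_ADD).fillna(0.0).to_numpy()
            y += q.get("d", 0.0) * col.map(_X_DOM).fillna(0.0).to_numpy()
        y += rng.normal(0.0, sigma, size=len(genotypes))
        out["trait"] = y
    pair = qtl_model.get("epistatic_pair")
    if pair is not None:
        la, lb = pair
        for loc in (la, lb):
            if loc not in genotypes.columns:
                raise ValueError(f"epistatic locus {loc!r} not in genotype matrix")
        high_mean = qtl_model.get("high_mean", 40.0)
        low_mean = qtl_model.get("low_mean", 1.0)
        eps_sigma = qtl_model.get("eps_sigma", 0.15)
        both_bb = (genotypes[la] == "b") & (genotypes[lb] == "b")
        mu = np.where(both_bb, high_mean, low_mean)
        noise = rng.normal(0.0, 1.0, size=len(genotypes)) * np.where(both_bb, high_mean, low_mean) * eps_sigma
        out["epistatic_trait"] = mu + noise
    return out
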