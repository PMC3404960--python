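"""File formats and run configuration.

Reads travel as FASTA with the id convention ``<line>|<locus>|<readIdx>``
(the line label is optional); genotype and phenotype tables, marker-
candidate lists and linkage maps travel as CSV/TSV with a header row.
Genotype cells are restricted to the F2 code alphabet ``a h b c d -``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from silicomap.linkmap import CODE_SETS, MISSING, LinkageMap
from silicomap.markerscreen import MarkerCandidate
from silicomap.simdata import SimRead

_IUPAC = set("ACGTRYSWKMBDHVN")
VALID_CODES = set(CODE_SETS) | {MISSING}


class FormatError(ValueError):
    """A file failed validation; message names the offending location."""


def read_fasta(path) -> list[SimRead]:
    """Parse FASTA into reads, extracting the line label from ``line|...`` ids.

    Duplicate ids and non-IUPAC characters raise :class:`FormatError` with
    the offending record and line number.
    """
    reads = []
    seen = set()
    line_no = 0
    id_lines = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            if raw.startswith(">"):
                id_lines[raw[1:].split()[0] if raw[1:].split() else ""] = i
    for rec in SeqIO.parse(str(path), "fasta"):
        line_no = id_lines.get(rec.id, 0)
        if rec.id in seen:
            raise FormatError(f"{path}:{line_no}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise FormatError(
                f"{path}:{line_no}: record {rec.id!r} has non-IUPAC characters {sorted(bad)}"
            )
        line = rec.id.split("|")[0] if "|" in rec.id else None
        reads.append(SimRead(read_id=rec.id, line=line, seq=seq))
    return reads


def write_fasta(reads, path) -> None:
    """Write reads as FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(r.seq), id=r.read_id, description="") for r in reads
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_genotypes(path, sep: str | None = None) -> pd.DataFrame:
    """Genotype matrix CSV/TSV: first column individual id, one column per locus.

    Cells outside the code alphabet raise :class:`FormatError` naming the
    row and column.
    """
    sep = sep or ("\t" if str(path).endswith((".tsv", ".txt")) else ",")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    for col in df.columns:
        bad = df.index[~df[col].fillna(MISSING).isin(VALID_CODES)]
        if len(bad):
            cell = df.loc[bad[0], col]
            raise FormatError(
                f"{path}: illegal genotype code {cell!r} at row {bad[0]!r}, column {col!r}"
            )
    return df.fillna(MISSING)


def write_genotypes(gm: pd.DataFrame, path, sep: str | None = None) -> None:
    sep = sep or ("\t" if str(path).endswith((".tsv", ".txt")) else ",")
    gm.to_csv(path, sep=sep, index_label="individual")


def read_phenotypes(path, sep: str | None = None) -> pd.DataFrame:
    """Phenotype table: first column individual id, numeric trait columns."""
    sep = sep or ("\t" if str(path).endswith((".tsv", ".txt")) else ",")
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df


def write_phenotypes(ph: pd.DataFrame, path, sep: str | None = None) -> None:
    sep = sep or ("\t" if str(path).endswith((".tsv", ".txt")) else ",")
    ph.to_csv(path, sep=sep, index_label="individual")


def write_map(linkage_map: LinkageMap, path) -> None:
    """Linkage map as TSV: group, locus, position_cM, chi2, p, distorted."""
    rows = []
    seg = linkage_map.segregation
    for gname, loci in linkage_map.groups.items():
        for locus, pos in loci:
            if len(seg) and locus in seg.index:
                chi2, p, dist = seg.loc[locus, "chi2"], seg.loc[locus, "p"], seg.loc[locus, "distorted"]
            else:
                chi2, p, dist = float("nan"), float("nan"), False
            rows.append(
                {"group": gname, "locus": locus, "position_cM": round(float(pos), 3),
                 "chi2": chi2, "p": p, "distorted": bool(dist)}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_map(path) -> LinkageMap:
    df = pd.read_csv(path, sep="\t")
    groups: dict[str, list[tuple[str, float]]] = {}
    for _, row in df.iterrows():
        groups.setdefault(row["group"], []).append((row["locus"], float(row["position_cM"])))
    seg = df.set_index("locus")[["chi2", "p", "distorted"]]
    seg["df"] = 0
    return LinkageMap(groups=groups, segregation=seg)


def write_candidates(candidates: list[MarkerCandidate], path, primers: dict | None = None) -> None:
    """Candidate table as TSV; optional ``primers`` maps candidate id → PrimerPair."""
    rows = []
    for c in candidates:
        lines = sorted(c.observations_by_line)
        obs = {ln: c.observations_by_line[ln] for ln in lines}
        row = {
            "id": c.candidate_id,
            "type": c.marker_type,
            "class": c.klass,
            "motif": c.motif or "",
            "counts_line1": ";".join(map(str, obs.get(lines[0], []))) if lines else "",
            "counts_line2": ";".join(map(str, obs.get(lines[1], []))) if len(lines) > 1 else "",
        }
        pp = (primers or {}).get(c.candidate_id)
        row.update(
            {
                "primer_left": pp.left if pp else "",
                "primer_right": pp.right if pp else "",
                "left_tm": round(pp.left_tm, 2) if pp else "",
                "right_tm": round(pp.right_tm, 2) if pp else "",
                "product_length": pp.product_length if pp else "",
            }
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Every tunable default of the pipeline in one validated document."""

    seed: int = 0
    # ssrscan
    min_repeats_di: int = 6
    min_repeats_tri: int = 5
    min_repeats_tetra: int = 5
    # readclust
    cluster_min_identity: float = 0.95
    cluster_kmer: int = 15
    cluster_min_shared_kmers: int = 3
    cluster_min_aligned_cols: int = 40
    # markerscreen
    min_reads_per_line: int = 1
    te_min_len: int = 30
    te_min_identity: float = 0.80
    # primerdesign
    primer_min_len: int = 18
    primer_max_len: int = 27
    primer_min_tm: float = 57.0
    primer_max_tm: float = 63.0
    primer_min_gc: float = 0.30
    primer_max_gc: float = 0.70
    product_min: int = 80
    product_max: int = 400
    # linkmap
    lod_threshold: float = 4.0
    max_rf: float = 0.30
    distortion_alpha: float = 0.05
    # qtlscan
    step_cM: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    gmm_max_combo: int = 2
    gmm_min_samples: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    def min_repeats(self) -> dict[int, int]:
        return {2: self.min_repeats_di, 3: self.min_repeats_tri, 4: self.min_repeats_tetra}
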