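"""Readers, writers and validated containers for every table the pipeline touches.

Conventions used throughout the package:

* genomic coordinates are 1-based and intervals are inclusive on both ends
  (VCF convention); a position ``p`` is within ``w`` bp of ``[a, b]`` iff
  ``max(a - p, p - b, 0) <= w``;
* abundance matrices are on log2 scale natively (a flag on read applies the
  transform); missing values are permitted and handled downstream;
* phosphosite identifiers use ``GENE_SiteResiduePosition`` (e.g. ``UFL1_S462``).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("asorescue")

GENOTYPES = ("proband", "control")
TREATMENTS = ("ASO_S", "ASO_T", "untreated")

MISSING = -1  # allele-count code for an uncalled genotype


class FormatError(ValueError):
    """Raised when an input table violates its format contract."""


# ---------------------------------------------------------------------------
# abundance matrices and sample design
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Features x samples matrix of log2 intensities (proteins or phosphosites).

    ``values`` is indexed by feature id with one column per sample; missing
    entries are NaN. Feature and sample ids must be unique and every present
    value finite.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        bad = np.isinf(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-finite abundance at feature {idx[i]!r}, sample {cols[j]!r}"
            )


@dataclass
class SampleDesign:
    """Per-sample genotype / treatment / replicate assignment.

    ``table`` is indexed by sample id with columns ``genotype``, ``treatment``
    and ``replicate`` (and optionally ``batch``). An *arm* is a
    ``(genotype, treatment)`` pair.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"genotype", "treatment", "replicate"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"design missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"duplicate sample id in design: {dup!r}")
        bad_g = set(t["genotype"]) - set(GENOTYPES)
        if bad_g:
            raise FormatError(f"unknown genotype label(s): {sorted(bad_g)}")
        bad_t = set(t["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise FormatError(f"unknown treatment label(s): {sorted(bad_t)}")
        if (t["replicate"].astype(int) < 1).any():
            raise FormatError("replicate indices must be positive integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def arm_samples(self, genotype: str, treatment: str) -> list[str]:
        t = self.table
        mask = (t["genotype"] == genotype) & (t["treatment"] == treatment)
        return list(t.index[mask])

    def arms(self) -> list[tuple[str, str]]:
        pairs = self.table[["genotype", "treatment"]].drop_duplicates()
        return [tuple(r) for r in pairs.itertuples(index=False)]


def read_abundance(
    path: str | Path,
    design_path: str | Path,
    *,
    sep: str | None = None,
    log2_transform: bool = False,
) -> tuple[AbundanceTable, SampleDesign]:
    """Read a feature x sample abundance matrix plus its sample-design table.

    The first column of the matrix file holds feature ids; every remaining
    column is one sample. ``log2_transform=True`` declares the file to be on
    raw intensity scale and applies log2 on read (zeros become missing).
    Samples present in the matrix but absent from the design are an error.
    """
    path = Path(path)
    sep_m = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep_m, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate feature id: {dup!r} in {path.name}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(
                f"non-numeric value at feature {row!r}, sample {col!r} in {path.name}"
            )
        df[col] = coerced
    if log2_transform:
        arr = df.to_numpy(dtype=float)
        nonpos = arr <= 0
        if nonpos.any():
            n = int(nonpos.sum())
            logger.warning("log2 transform: %d non-positive cells set to missing", n)
            arr = np.where(nonpos, np.nan, arr)
        df = pd.DataFrame(np.log2(arr), index=df.index, columns=df.columns)
    design = read_design(design_path, sep=sep)
    unknown = [s for s in df.columns if s not in design.table.index]
    if unknown:
        raise FormatError(f"samples absent from design: {unknown}")
    return AbundanceTable(df), design


def read_design(path: str | Path, *, sep: str | None = None) -> SampleDesign:
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sniff_sep(path))
    if "sample" not in df.columns:
        raise FormatError(f"design {path.name} needs a 'sample' column")
    return SampleDesign(df.set_index("sample"))


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """term id -> (description, member genes); members unique within a term."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {term!r} has no members")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {term!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, term: str) -> tuple[str, ...]:
        return self.sets[term][1]

    def description(self, term: str) -> str:
        return self.sets[term][0]

    def items(self):
        return self.sets.items()


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``term<TAB>description<TAB>member...`` per line.

    Duplicate members within a term are collapsed with a warning; terms with
    an empty member list are rejected (dropped) with a warning.
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"unreadable GMT line {lineno}: {line[:60]!r}")
            term, desc, *members = parts
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) != len(members):
                logger.warning("term %s: %d duplicate members collapsed",
                               term, len(members) - len(uniq))
            if not uniq:
                logger.warning("term %s rejected: empty member list", term)
                continue
            if term in sets:
                raise FormatError(f"duplicate term {term!r} at line {lineno}")
            sets[term] = (desc, tuple(uniq))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection.sets):
            desc, members = collection.sets[term]
            fh.write("\t".join([term, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# genotypes, pedigree
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Ordered biallelic markers x individuals with allele counts and GQ.

    ``markers`` has columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt`` and
    is strictly increasing by (chrom, pos). ``geno`` holds alt-allele counts
    (0 hom-ref, 1 het, 2 hom-alt, -1 missing); ``gq`` the genotype qualities.
    Both arrays are (n_markers, n_individuals).
    """

    markers: pd.DataFrame
    individuals: list[str]
    geno: np.ndarray
    gq: np.ndarray

    def __post_init__(self) -> None:
        m = self.markers
        for col in ("chrom", "pos", "ref", "alt"):
            if col not in m.columns:
                raise FormatError(f"markers missing column {col!r}")
        keys = list(zip(m["chrom"], m["pos"]))
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise FormatError("markers not strictly increasing by (chrom, pos)")
        n_m, n_i = self.geno.shape
        if n_m != len(m) or n_i != len(self.individuals):
            raise FormatError("genotype array shape does not match markers/individuals")
        if self.gq.shape != self.geno.shape:
            raise FormatError("GQ array shape does not match genotype array")
        if not np.isin(self.geno, [MISSING, 0, 1, 2]).all():
            raise FormatError("allele counts must be in {0,1,2} or missing")
        if (self.gq < 0).any():
            raise FormatError("GQ must be non-negative")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def column(self, individual: str) -> np.ndarray:
        return self.geno[:, self.individuals.index(individual)]

    def gq_column(self, individual: str) -> np.ndarray:
        return self.gq[:, self.individuals.index(individual)]

    def marker_index(self, chrom: str, pos: int) -> int:
        m = self.markers
        hit = np.flatnonzero((m["chrom"] == chrom) & (m["pos"] == pos))
        if len(hit) == 0:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return int(hit[0])


@dataclass
class PedigreeSpec:
    """PED-style family structure: per individual parents, sex and status."""

    table: pd.DataFrame  # index: individual id; columns father, mother, sex, affected

    def __post_init__(self) -> None:
        t = self.table
        for col in ("father", "mother", "sex", "affected"):
            if col not in t.columns:
                raise FormatError(f"pedigree missing column {col!r}")
        ids = set(t.index)
        for col in ("father", "mother"):
            for iid, parent in t[col].items():
                if parent is not None and not _is_na(parent) and parent not in ids:
                    raise FormatError(f"{iid}: unknown {col} id {parent!r}")
        bad = set(t["affected"]) - {"yes", "no", "unknown"}
        if bad:
            raise FormatError(f"affected status must be yes/no/unknown, got {bad}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        t = self.table
        for start in t.index:
            seen = {start}
            frontier = [start]
            while frontier:
                nxt = []
                for iid in frontier:
                    for col in ("father", "mother"):
                        p = t.at[iid, col]
                        if p is None or _is_na(p):
                            continue
                        if p == start:
                            raise FormatError(f"{start} is its own ancestor")
                        if p not in seen:
                            seen.add(p)
                            nxt.append(p)
                frontier = nxt

    @property
    def individuals(self) -> list[str]:
        return list(self.table.index)

    def affected(self) -> list[str]:
        return list(self.table.index[self.table["affected"] == "yes"])

    def unaffected(self) -> list[str]:
        return list(self.table.index[self.table["affected"] == "no"])

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        f = self.table.at[iid, "father"]
        m = self.table.at[iid, "mother"]
        return (None if _is_na(f) else f, None if _is_na(m) else m)

    def siblings(self, iid: str) -> list[str]:
        f, m = self.parents(iid)
        if f is None and m is None:
            return []
        out = []
        for other in self.table.index:
            if other == iid:
                continue
            if self.parents(other) == (f, m):
                out.append(other)
        return out


def _is_na(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or x in ("", "0", ".")


def read_pedigree(path: str | Path) -> PedigreeSpec:
    """Read a PED-like file: fam, id, father, mother, sex, affected(1/2/0)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"pedigree line {lineno}: expected 6 columns")
            _, iid, father, mother, sex, status = parts[:6]
            affected = {"2": "yes", "1": "no", "0": "unknown"}.get(status)
            if affected is None:
                raise FormatError(f"pedigree line {lineno}: bad status {status!r}")
            rows.append(
                dict(id=iid,
                     father=None if father in ("0", ".") else father,
                     mother=None if mother in ("0", ".") else mother,
                     sex={"1": "male", "2": "female"}.get(sex, "unknown"),
                     affected=affected)
            )
    df = pd.DataFrame(rows).set_index("id")
    return PedigreeSpec(df)


def read_genotypes(
    path: str | Path, pedigree_path: str | Path
) -> tuple[GenotypeMatrix, PedigreeSpec]:
    """Read genotypes (VCF or TSV dialect) plus the matching pedigree.

    VCF records must carry GT and GQ FORMAT fields; multiallelic records are
    skipped with a logged count. The TSV dialect has columns chrom, pos, ref,
    alt and then one ``GT:GQ`` column per individual. Individuals present in
    the genotype file but absent from the pedigree are an error.
    """
    pedigree = read_pedigree(pedigree_path)
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        gm = read_vcf(path)
    else:
        gm = _read_genotype_tsv(path)
    missing = [i for i in gm.individuals if i not in set(pedigree.individuals)]
    if missing:
        raise FormatError(f"individuals absent from pedigree: {missing}")
    return gm, pedigree


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (plain or bgzipped) VCF into a GenotypeMatrix via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    markers, genos, gqs = [], [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        markers.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0,1,2; 3 = unknown
        gt = np.where(gt == 3, MISSING, gt)
        genos.append(gt)
        gq = rec.format("GQ")
        if gq is None:
            gqs.append(np.zeros(len(individuals)))
        else:
            gqs.append(np.asarray(gq, dtype=float).reshape(-1))
    if skipped:
        logger.info("skipped %d multiallelic record(s)", skipped)
    mk = pd.DataFrame(markers, columns=["chrom", "pos", "ref", "alt"])
    _require_sorted(mk)
    return GenotypeMatrix(mk, individuals,
                          np.asarray(genos, dtype=np.int8).reshape(len(mk), -1),
                          np.asarray(gqs, dtype=float).reshape(len(mk), -1))


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fixed = ["chrom", "pos", "ref", "alt"]
    for col in fixed:
        if col not in df.columns:
            raise FormatError(f"genotype TSV missing column {col!r}")
    individuals = [c for c in df.columns if c not in fixed]
    geno = np.full((len(df), len(individuals)), MISSING, dtype=np.int8)
    gq = np.zeros((len(df), len(individuals)), dtype=float)
    code = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": MISSING}
    for j, ind in enumerate(individuals):
        for i, cell in enumerate(df[ind]):
            gt, _, q = str(cell).partition(":")
            if gt not in code:
                raise FormatError(f"bad GT {gt!r} at row {i + 1}, individual {ind}")
            geno[i, j] = code[gt]
            gq[i, j] = float(q) if q else 0.0
    mk = df[fixed].copy()
    _require_sorted(mk)
    return GenotypeMatrix(mk, individuals, geno, gq)


def _require_sorted(markers: pd.DataFrame) -> None:
    keys = list(zip(markers["chrom"], markers["pos"]))
    if any(b <= a for a, b in zip(keys, keys[1:])):
        raise FormatError("genotype records are not sorted by (chrom, pos)")


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = gm.markers.copy()
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j, ind in enumerate(gm.individuals):
        df[ind] = [
            f"{code[int(g)]}:{_fmt_num(q)}" for g, q in zip(gm.geno[:, j], gm.gq[:, j])
        ]
    df.to_csv(path, sep="\t", index=False)


def write_pedigree(ped: PedigreeSpec, path: str | Path, fam: str = "FAM") -> None:
    sex_code = {"male": "1", "female": "2"}
    status_code = {"yes": "2", "no": "1", "unknown": "0"}
    with open(path, "w") as fh:
        for iid, row in ped.table.iterrows():
            fh.write(" ".join([
                fam, str(iid),
                row["father"] if not _is_na(row["father"]) else "0",
                row["mother"] if not _is_na(row["mother"]) else "0",
                sex_code.get(row["sex"], "0"),
                status_code[row["affected"]],
            ]) + "\n")


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


@dataclass
class CtTable:
    """Long-format qPCR Ct measurements plus per-sample group labels.

    ``data`` columns: sample, assay, role (target/reference), rep, ct.
    ``groups`` maps sample -> proband/control; ``treatments`` is optional.
    """

    data: pd.DataFrame
    groups: Mapping[str, str]
    treatments: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = self.data
        required = {"sample", "assay", "role", "rep", "ct"}
        missing = required - set(d.columns)
        if missing:
            raise FormatError(f"Ct table missing columns: {sorted(missing)}")
        if (d["ct"] <= 0).any():
            raise FormatError("Ct values must be positive")
        bad = set(d["role"]) - {"target", "reference"}
        if bad:
            raise FormatError(f"assay role must be target/reference, got {bad}")
        refs = sorted(d.loc[d["role"] == "reference", "assay"].unique())
        for sample in d["sample"].unique():
            have = set(d.loc[d["sample"] == sample, "assay"])
            for r in refs:
                if r not in have:
                    raise FormatError(
                        f"sample {sample!r} lacks reference assay {r!r}"
                    )
        unlabelled = set(d["sample"]) - set(self.groups)
        if unlabelled:
            raise FormatError(f"samples without group label: {sorted(unlabelled)}")

    @property
    def reference_assays(self) -> list[str]:
        d = self.data
        return sorted(d.loc[d["role"] == "reference", "assay"].unique())

    @property
    def target_assays(self) -> list[str]:
        d = self.data
        return sorted(d.loc[d["role"] == "target", "assay"].unique())


def read_ct(path: str | Path) -> CtTable:
    """Read a long-format Ct TSV with columns sample, assay, role, rep, ct,
    group (and optionally treatment)."""
    df = pd.read_csv(path, sep=_sniff_sep(Path(path)))
    if "group" not in df.columns:
        raise FormatError("Ct file needs a 'group' column")
    groups = dict(df.groupby("sample")["group"].first())
    treatments = {}
    if "treatment" in df.columns:
        treatments = dict(df.groupby("sample")["treatment"].first())
    data = df[["sample", "assay", "role", "rep", "ct"]].copy()
    return CtTable(data, groups, treatments)


def write_ct(table: CtTable, path: str | Path) -> None:
    df = table.data.copy()
    df["group"] = df["sample"].map(dict(table.groups))
    if table.treatments:
        df["treatment"] = df["sample"].map(dict(table.treatments))
    write_table(df, path)


# ---------------------------------------------------------------------------
# splice-outlier intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutlierInterval:
    """One aberrant-splicing (or other outlier) interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    kind: str = "splice-outlier"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"interval start {self.start} > end {self.end}")


def distance_to_interval(pos: int, start: int, end: int) -> int:
    """Distance from a position to a 1-based inclusive interval (0 if inside)."""
    return max(start - pos, pos - end, 0)


def read_outliers(path: str | Path) -> list[OutlierInterval]:
    df = pd.read_csv(path, sep=_sniff_sep(Path(path)), dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        score = getattr(row, "score", None)
        if score is not None and pd.isna(score):
            score = None
        out.append(OutlierInterval(str(row.chrom), int(row.start), int(row.end),
                                   getattr(row, "kind", "splice-outlier"), score))
    return out


def write_outliers(intervals: Sequence[OutlierInterval], path: str | Path) -> None:
    df = pd.DataFrame(
        [(iv.chrom, iv.start, iv.end, iv.kind,
          "" if iv.score is None else iv.score) for iv in intervals],
        columns=["chrom", "start", "end", "kind", "score"],
    )
    write_table(df, path)


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, *, index: bool = False,
                sort: bool = True) -> None:
    """Byte-stable TSV writer: sorted rows, floats at 6 significant digits."""
    out = df.reset_index() if index else df.copy()
    if sort and len(out):
        out = out.sort_values(list(out.columns), kind="mergesort")
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, out.columns)) + "\n")
        for row in out.itertuples(index=False):
            fh.write("\t".join(_fmt_num(v) for v in row) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _fmt_num(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    if isinstance(v, (bool, np.bool_)):
        return "True" if v else "False"
    if isinstance(v, (float, np.floating)):
        if float(v).is_integer() and abs(v) < 1e15:
            return str(int(v))
        return f"{v:.6g}"
    return str(v)


def _sniff_sep(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    return "\t"


def read_xlsx_table(
    path: str | Path,
    column_map: Mapping[str, str],
    *,
    sheet: str | int = 0,
    skiprows: int = 0,
) -> pd.DataFrame:
    """Convenience reader for supplementary XLSX tables.

    ``column_map`` maps source column headers to the pipeline's canonical
    names (e.g. ``{"Gene names": "feature", "Logfold": "log2FC"}``); only
    mapped columns are returned. Layouts of third-party workbooks vary, hence
    the explicit mapping rather than guessed headers.
    """
    df = pd.read_excel(path, sheet_name=sheet, skiprows=skiprows, engine="openpyxl")
    missing = [c for c in column_map if c not in df.columns]
    if missing:
        raise FormatError(f"XLSX {Path(path).name} lacks mapped columns: {missing}")
    out = df[list(column_map)].rename(columns=dict(column_map))
    return out
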