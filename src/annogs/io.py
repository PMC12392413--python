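"""Data model and on-disk formats for genotypes, phenotypes and annotations.

Conventions
-----------
* Genotype codes are allele-dosage integers in {0, 1, 2} with 0 = homozygous
  for the **major** allele of the loaded cohort (so a code counts copies of
  the minor allele).  Missing genotypes are a load error: the library expects
  imputation to have happened upstream.
* SNP positions are 1-based internally (matching names like ``chr10:23833431``);
  interval files on disk are BED-style 0-based half-open.  A SNP at 1-based
  position ``pos`` falls in interval ``[start, end)`` iff
  ``start <= pos - 1 < end``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SnpTable",
    "GenotypeMatrix",
    "PhenotypeVector",
    "AnnotationBundle",
    "ImpactScores",
    "read_genotypes",
    "read_snp_table",
    "read_phenotype",
    "read_annotation_bundle",
    "read_impact_scores",
    "write_genotypes",
    "write_snp_table",
    "write_phenotype",
    "write_annotation_bundle",
    "write_impact_scores",
    "assign_snp_to_elements",
    "merge_intervals",
]

CATEGORIES = ("coding", "noncoding")


class AnnotationError(ValueError):
    """Raised when cross-references between tables are inconsistent."""


@dataclass
class SnpTable:
    """Per-SNP metadata: id, position, alleles and coding/noncoding category."""

    frame: pd.DataFrame  # columns: snp_id, chrom, pos, ref_allele, alt_allele,
    #                                category, nonsynonymous_flag

    REQUIRED = (
        "snp_id",
        "chrom",
        "pos",
        "ref_allele",
        "alt_allele",
        "category",
        "nonsynonymous_flag",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"SnpTable missing columns: {missing}")
        f = self.frame
        if f["snp_id"].duplicated().any():
            dup = f.loc[f["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_ids: {dup[:5]}")
        if (f["pos"] < 1).any():
            raise ValueError("SNP positions must be >= 1")
        bad = set(f["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown SNP categories: {sorted(bad)}")
        self.frame = f.reset_index(drop=True)

    @property
    def snp_ids(self) -> list[str]:
        return self.frame["snp_id"].tolist()

    @property
    def n_snps(self) -> int:
        return len(self.frame)

    def subset(self, snp_ids: list[str]) -> "SnpTable":
        keep = self.frame.set_index("snp_id").loc[list(snp_ids)].reset_index()
        return SnpTable(keep)

    def ids_in_category(self, category: str) -> list[str]:
        return self.frame.loc[self.frame["category"] == category, "snp_id"].tolist()


@dataclass
class GenotypeMatrix:
    """n x p allele-dosage matrix plus sample ids and SNP metadata."""

    samples: list[str]
    snps: SnpTable
    codes: np.ndarray  # (n, p) int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        n, p = self.codes.shape
        if n != len(self.samples):
            raise ValueError("sample count does not match genotype rows")
        if p != self.snps.n_snps:
            raise ValueError("SNP count does not match genotype columns")
        if not np.isin(self.codes, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(self.codes, (0, 1, 2)))[0]
            sid = self.snps.snp_ids[bad[1]]
            raise ValueError(
                f"genotype code outside {{0,1,2}} at sample {self.samples[bad[0]]}, "
                f"SNP {sid} (missing genotypes must be imputed upstream)"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.snps.n_snps

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snps.snp_ids.index(snp_id)
        return self.codes[:, j]

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = {s: j for j, s in enumerate(self.snps.snp_ids)}
        cols = [idx[s] for s in snp_ids]
        return GenotypeMatrix(self.samples, self.snps.subset(snp_ids), self.codes[:, cols])


@dataclass
class PhenotypeVector:
    trait: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AnnotationBundle:
    """SNP -> element -> gene -> term -> metaterm annotation graph.

    ``element_intervals`` and ``gene_intervals`` are DataFrames with columns
    (chrom, start, end, label/gene_id), 0-based half-open.  Maps are plain
    dicts; ``element_to_gene`` maps one element label to a list of gene ids.
    """

    element_intervals: pd.DataFrame
    snp_to_element: dict[str, str]
    gene_intervals: pd.DataFrame
    element_to_gene: dict[str, list[str]]
    snp_to_gene: dict[str, str]
    gene_term_scores: pd.DataFrame  # genes x terms
    term_metaterm_weights: pd.DataFrame  # terms x metaterms
    conserved_gene_flags: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    signature_gene_flags: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))

    @property
    def elements(self) -> list[str]:
        return self.element_intervals["label"].tolist()

    @property
    def genes(self) -> list[str]:
        return self.gene_intervals["gene_id"].tolist()

    @property
    def terms(self) -> list[str]:
        return self.gene_term_scores.columns.tolist()

    @property
    def metaterms(self) -> list[str]:
        return self.term_metaterm_weights.columns.tolist()

    def validate(self, snps: SnpTable | None = None) -> None:
        """Raise :class:`AnnotationError` listing every dangling reference."""
        problems: list[str] = []
        elements = set(self.elements)
        genes = set(self.genes)
        bad_el = [e for e in set(self.snp_to_element.values()) if e not in elements]
        if bad_el:
            problems.append(f"snp_to_element references unknown elements: {sorted(bad_el)[:5]}")
        bad_src = [e for e in self.element_to_gene if e not in elements]
        if bad_src:
            problems.append(f"element_to_gene references unknown elements: {sorted(bad_src)[:5]}")
        bad_tg = sorted({g for gs in self.element_to_gene.values() for g in gs if g not in genes})
        if bad_tg:
            problems.append(f"element_to_gene references unknown genes: {bad_tg[:5]}")
        bad_g = [g for g in set(self.snp_to_gene.values()) if g not in genes]
        if bad_g:
            problems.append(f"snp_to_gene references unknown genes: {sorted(bad_g)[:5]}")
        if snps is not None:
            known = set(snps.snp_ids)
            bad_s = sorted(
                (set(self.snp_to_element) | set(self.snp_to_gene)) - known
            )
            if bad_s:
                problems.append(f"maps reference unknown SNPs: {bad_s[:5]}")
        for name, mat in (
            ("gene_term_scores", self.gene_term_scores),
            ("term_metaterm_weights", self.term_metaterm_weights),
        ):
            if len(mat) and not np.isfinite(mat.to_numpy(dtype=float)).all():
                problems.append(f"{name} contains non-finite values")
        score_genes = set(self.gene_term_scores.index)
        extra = sorted(score_genes - genes)
        if extra:
            problems.append(f"gene_term_scores rows for unknown genes: {extra[:5]}")
        if len(self.gene_term_scores.columns) and len(self.term_metaterm_weights):
            t_terms = set(self.term_metaterm_weights.index)
            missing_t = sorted(t_terms - set(self.gene_term_scores.columns))
            if missing_t:
                problems.append(
                    f"term_metaterm_weights rows for unknown terms: {missing_t[:5]}"
                )
        if problems:
            raise AnnotationError("; ".join(problems))


@dataclass
class ImpactScores:
    """Allele-level functional impact scores.

    ``noncoding_access`` holds predicted chromatin accessibility per allele of
    each noncoding SNP, ``coding_mfe`` normalized RNA minimum-free-energy
    scores per allele of each coding SNP; all in [0, 1].  ``peak_threshold``
    is the accessibility level above which an allele is considered to sit in
    an open-chromatin peak.
    """

    noncoding_access: pd.DataFrame  # index snp_id; columns ref_score, alt_score
    coding_mfe: pd.DataFrame  # index snp_id; columns ref_score, alt_score
    peak_threshold: float = 0.147

    def __post_init__(self) -> None:
        for name, df in (("noncoding_access", self.noncoding_access),
                         ("coding_mfe", self.coding_mfe)):
            if len(df):
                vals = df[["ref_score", "alt_score"]].to_numpy(dtype=float)
                if not np.isfinite(vals).all() or vals.min() < 0 or vals.max() > 1:
                    raise ValueError(f"{name} scores must lie in [0, 1]")

    def validate_coverage(self, snps: SnpTable) -> None:
        nc = set(snps.ids_in_category("noncoding"))
        co = set(snps.ids_in_category("coding"))
        miss_nc = sorted(nc - set(self.noncoding_access.index))
        miss_co = sorted(co - set(self.coding_mfe.index))
        problems = []
        if miss_nc:
            problems.append(f"noncoding SNPs without accessibility scores: {miss_nc[:5]}")
        if miss_co:
            problems.append(f"coding SNPs without MFE scores: {miss_co[:5]}")
        if problems:
            raise AnnotationError("; ".join(problems))

    def delta(self, snp_id: str) -> float:
        for df in (self.noncoding_access, self.coding_mfe):
            if snp_id in df.index:
                return float(abs(df.at[snp_id, "alt_score"] - df.at[snp_id, "ref_score"]))
        raise KeyError(snp_id)


# ---------------------------------------------------------------------------
# interval handling


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent 0-based half-open intervals per chromosome.

    The merged interval keeps the ``+``-joined labels of its constituents so
    the result is still addressable.
    """
    out = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None or row.start > cur[1]:
                if cur is not None:
                    out.append((chrom, cur[0], cur[1], "+".join(cur[2])))
                cur = [row.start, row.end, [row.label]]
            else:
                cur[1] = max(cur[1], row.end)
                cur[2].append(row.label)
        if cur is not None:
            out.append((chrom, cur[0], cur[1], "+".join(cur[2])))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "label"])


def assign_snp_to_elements(snps: SnpTable, intervals: pd.DataFrame) -> dict[str, str]:
    """Map each noncoding SNP to the merged element interval containing it.

    Intervals are merged first so containment is unique; SNPs falling in no
    interval are simply absent from the returned map.
    """
    merged = merge_intervals(intervals)
    mapping: dict[str, str] = {}
    frame = snps.frame
    for chrom, grp in merged.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        labels = grp["label"].tolist()
        sub = frame[(frame["chrom"] == chrom) & (frame["category"] == "noncoding")]
        if not len(sub):
            continue
        pos0 = sub["pos"].to_numpy() - 1  # to 0-based
        k = np.searchsorted(starts, pos0, side="right") - 1
        inside = (k >= 0) & (pos0 < ends[np.clip(k, 0, len(ends) - 1)])
        for sid, ki, ok in zip(sub["snp_id"], k, inside):
            if ok:
                mapping[sid] = labels[ki]
    return mapping


# ---------------------------------------------------------------------------
# readers


def read_snp_table(path: str | Path) -> SnpTable:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    frame["nonsynonymous_flag"] = frame["nonsynonymous_flag"].astype(bool)
    return SnpTable(frame)


def _snp_table_from_ids(snp_ids: list[str]) -> SnpTable:
    """Build a minimal SnpTable from ``chrom:pos`` style column names."""
    rows = []
    for sid in snp_ids:
        m = re.match(r"^(.+):(\d+)$", sid)
        chrom, pos = (m.group(1), int(m.group(2))) if m else ("unknown", 1)
        rows.append((sid, chrom, pos, "A", "C", "noncoding", False))
    return SnpTable(pd.DataFrame(rows, columns=list(SnpTable.REQUIRED)))


def read_genotypes(
    path: str | Path,
    format: str = "tsv_matrix",
    snps: SnpTable | None = None,
) -> GenotypeMatrix:
    """Load a genotype matrix from a TSV matrix or a (biallelic-SNP) VCF.

    TSV: header row of snp_ids, first column the sample id.  VCF: genotypes
    are re-oriented so a code counts minor-allele copies in this cohort
    (frequency ties broken toward REF = major).  A missing genotype is an
    error naming the offending SNP.
    """
    path = Path(path)
    if format == "tsv_matrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if frame.isna().any().any():
            col = frame.columns[frame.isna().any()][0]
            raise ValueError(f"missing genotype for SNP {col}; imputation is out of scope")
        table = snps if snps is not None else _snp_table_from_ids(list(frame.columns))
        order = np.lexsort(
            (table.frame["pos"].to_numpy(), table.frame["chrom"].to_numpy())
        )
        table = SnpTable(table.frame.iloc[order])
        frame = frame[table.snp_ids]
        return GenotypeMatrix(list(frame.index.astype(str)), table, frame.to_numpy())
    if format == "vcf":
        return _read_vcf(path, snps)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path, snps: SnpTable | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta = {} if snps is None else snps.frame.set_index("snp_id").to_dict("index")
    rows, records = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"non-biallelic record at {var.CHROM}:{var.POS}; only biallelic SNPs supported"
            )
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        gts = np.array([g[:2] for g in var.genotypes])
        if (gts < 0).any():
            raise ValueError(f"missing genotype at SNP {sid}; imputation is out of scope")
        alt_count = gts.sum(axis=1)
        alt_freq = alt_count.mean() / 2.0
        # code counts minor-allele copies; ties go toward REF being major
        codes = alt_count if alt_freq <= 0.5 else 2 - alt_count
        m = meta.get(sid, {})
        rows.append(
            (
                sid,
                str(var.CHROM),
                int(var.POS),
                var.REF,
                var.ALT[0],
                m.get("category", "noncoding"),
                bool(m.get("nonsynonymous_flag", False)),
            )
        )
        records.append(codes)
    frame = pd.DataFrame(rows, columns=list(SnpTable.REQUIRED))
    codes = np.array(records).T if records else np.zeros((len(samples), 0), dtype=int)
    order = np.lexsort((frame["pos"].to_numpy(), frame["chrom"].to_numpy()))
    return GenotypeMatrix(samples, SnpTable(frame.iloc[order]), codes[:, order])


def read_phenotype(path: str | Path) -> PhenotypeVector:
    frame = pd.read_csv(path, sep="\t")
    trait = frame.columns[1]
    return PhenotypeVector(trait, frame[trait].to_numpy(dtype=float))


def _read_map(path: Path, value_list: bool = False) -> dict:
    if not path.exists():
        return {}
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if value_list:
        out: dict[str, list[str]] = {}
        for k, v in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
            out.setdefault(k, []).append(v)
        return out
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def read_annotation_bundle(directory: str | Path, snps: SnpTable | None = None) -> AnnotationBundle:
    """Read a bundle directory written by :func:`write_annotation_bundle`."""
    d = Path(directory)

    def bed(name: str, label_col: str) -> pd.DataFrame:
        p = d / name
        if not p.exists() or p.stat().st_size == 0:
            return pd.DataFrame(columns=["chrom", "start", "end", label_col])
        frame = pd.read_csv(p, sep="\t", header=None,
                            names=["chrom", "start", "end", label_col],
                            dtype={"chrom": str})
        return frame

    def matrix(name: str) -> pd.DataFrame:
        p = d / name
        if not p.exists() or p.stat().st_size == 0:
            return pd.DataFrame()
        return pd.read_csv(p, sep="\t", index_col=0)

    flags = matrix("gene_flags.tsv")
    conserved = flags["conserved"].astype(bool) if "conserved" in flags else pd.Series(dtype=bool)
    signature = flags["signature"].astype(bool) if "signature" in flags else pd.Series(dtype=bool)
    bundle = AnnotationBundle(
        element_intervals=bed("elements.bed", "label"),
        snp_to_element=_read_map(d / "snp_to_element.tsv"),
        gene_intervals=bed("genes.bed", "gene_id"),
        element_to_gene=_read_map(d / "element_to_gene.tsv", value_list=True),
        snp_to_gene=_read_map(d / "snp_to_gene.tsv"),
        gene_term_scores=matrix("gene_term_scores.tsv"),
        term_metaterm_weights=matrix("term_metaterm_weights.tsv"),
        conserved_gene_flags=conserved,
        signature_gene_flags=signature,
    )
    bundle.validate(snps)
    return bundle


def read_impact_scores(directory: str | Path) -> ImpactScores:
    d = Path(directory)

    def scores(name: str) -> pd.DataFrame:
        p = d / name
        if not p.exists() or p.stat().st_size == 0:
            return pd.DataFrame(columns=["ref_score", "alt_score"])
        return pd.read_csv(p, sep="\t", index_col=0)

    threshold = 0.147
    meta = d / "impact_meta.tsv"
    if meta.exists():
        for line in meta.read_text().splitlines():
            if line.startswith("peak_threshold"):
                threshold = float(line.split("\t")[1])
    return ImpactScores(scores("noncoding_access.tsv"), scores("coding_mfe.tsv"), threshold)


# ---------------------------------------------------------------------------
# writers


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(gm.codes, index=pd.Index(gm.samples, name="sample"),
                         columns=gm.snps.snp_ids)
    frame.to_csv(path, sep="\t")


def write_snp_table(snps: SnpTable, path: str | Path) -> None:
    snps.frame.to_csv(path, sep="\t", index=False)


def write_phenotype(ph: PhenotypeVector, samples: list[str], path: str | Path) -> None:
    pd.DataFrame({"sample": samples, ph.trait: ph.values}).to_csv(path, sep="\t", index=False)


def _write_map(mapping: dict, path: Path, cols: tuple[str, str]) -> None:
    rows = []
    for k, v in mapping.items():
        if isinstance(v, list):
            rows += [(k, vi) for vi in v]
        else:
            rows.append((k, v))
    pd.DataFrame(rows, columns=list(cols)).to_csv(path, sep="\t", index=False)


def write_annotation_bundle(bundle: AnnotationBundle, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.element_intervals.to_csv(d / "elements.bed", sep="\t", header=False, index=False)
    bundle.gene_intervals.to_csv(d / "genes.bed", sep="\t", header=False, index=False)
    _write_map(bundle.snp_to_element, d / "snp_to_element.tsv", ("snp_id", "element"))
    _write_map(bundle.element_to_gene, d / "element_to_gene.tsv", ("element", "gene_id"))
    _write_map(bundle.snp_to_gene, d / "snp_to_gene.tsv", ("snp_id", "gene_id"))
    bundle.gene_term_scores.to_csv(d / "gene_term_scores.tsv", sep="\t")
    bundle.term_metaterm_weights.to_csv(d / "term_metaterm_weights.tsv", sep="\t")
    flags = pd.DataFrame(
        {
            "conserved": bundle.conserved_gene_flags.astype(bool),
            "signature": bundle.signature_gene_flags.astype(bool),
        }
    )
    flags.index.name = "gene_id"
    flags.to_csv(d / "gene_flags.tsv", sep="\t")


def write_impact_scores(impacts: ImpactScores, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    impacts.noncoding_access.rename_axis("snp_id").to_csv(d / "noncoding_access.tsv", sep="\t")
    impacts.coding_mfe.rename_axis("snp_id").to_csv(d / "coding_mfe.tsv", sep="\t")
    (d / "impact_meta.tsv").write_text(f"peak_threshold\t{impacts.peak_threshold}\n")
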