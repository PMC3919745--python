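"""Pedigree, marker-map and genotype I/O.

Reads PLINK-style text formats (PED/FAM, 4- or 6-column MAP) and multi-sample
VCF into a single internal dialect: genotypes are coded 0 (hom-ref), 1 (het),
2 (hom-alt) against a declared reference allele per marker, with -1 for
missing.  Analysis-group assignment (the "expected carrier" group vs the
unaffected pool) also lives here because it is a property of the pedigree's
phenotypes, not of any one analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

SEX_CODES = {"1": "male", "2": "female"}
AFFECTION_CODES = {"1": "unaffected", "2": "affected"}


class PedigreeError(ValueError):
    """Structural or format problem in pedigree input."""


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class Individual:
    """One pedigree member.

    A founder has both parent ids equal to ``None``; a PED parent code of
    ``0`` is read as missing, so individuals with unknown parents are treated
    as founders.
    """

    id: str
    father_id: str | None
    mother_id: str | None
    sex: str = "unknown"            # male / female / unknown
    affection: str = "unknown"      # affected / unaffected / unknown
    antibody_status: str = "unknown"  # positive / negative / unknown
    genotyped: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A directed family graph; consanguineous loops are allowed.

    Invariants checked on construction: unique ids, resolvable parent
    references, and no individual is its own ancestor (the parent relation is
    acyclic even though the marriage graph may contain loops).
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise FormatError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self.individuals.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.individuals:
                    raise PedigreeError(
                        f"individual {ind.id!r} references unknown parent {pid!r}"
                    )
        self.generations()  # raises on ancestry cycles

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals.values())

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[iid]

    def founders(self) -> list[Individual]:
        return [i for i in self if i.is_founder]

    def genotyped_ids(self) -> list[str]:
        return [i.id for i in self if i.genotyped]

    def mark_genotyped(self, ids: Iterable[str]) -> None:
        for iid in ids:
            if iid not in self.individuals:
                raise PedigreeError(f"cannot mark unknown individual {iid!r}")
            self.individuals[iid].genotyped = True

    def generations(self) -> dict[str, int]:
        """Generation index per individual (founders = 0, child = 1 + max parent).

        Raises :class:`PedigreeError` if an individual is its own ancestor.
        """
        depth: dict[str, int] = {}
        state: dict[str, int] = {}  # 0 = visiting, 1 = done

        def visit(iid: str, stack: list[str]) -> int:
            if iid in depth:
                return depth[iid]
            if state.get(iid) == 0:
                raise PedigreeError(
                    f"ancestry cycle involving {iid!r}: {' -> '.join(stack)}"
                )
            state[iid] = 0
            ind = self.individuals[iid]
            parents = [p for p in (ind.father_id, ind.mother_id) if p is not None]
            d = 0 if not parents else 1 + max(visit(p, stack + [iid]) for p in parents)
            depth[iid] = d
            state[iid] = 1
            return d

        for iid in self.individuals:
            visit(iid, [])
        return depth

    def has_loops(self) -> bool:
        """True if any mating pair shares a pedigree ancestor (consanguinity)."""
        ancestors: dict[str, set[str]] = {}

        def anc(iid: str) -> set[str]:
            if iid not in ancestors:
                ind = self.individuals[iid]
                s: set[str] = set()
                for p in (ind.father_id, ind.mother_id):
                    if p is not None:
                        s.add(p)
                        s |= anc(p)
                ancestors[iid] = s
            return ancestors[iid]

        pairs = {
            (i.father_id, i.mother_id)
            for i in self
            if i.father_id is not None and i.mother_id is not None
        }
        return any(anc(f) & anc(m) for f, m in pairs)


@dataclass
class MarkerMap:
    """Ordered biallelic marker map (1-based physical positions)."""

    table: pd.DataFrame  # columns: chrom, pos, id, ref, alt
    build_label: str = "unknown"

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "id", "ref", "alt"]
        missing_cols = [c for c in required if c not in self.table.columns]
        if missing_cols:
            raise FormatError(f"marker map missing columns {missing_cols}")
        self.table = self.table.reset_index(drop=True)
        for chrom, grp in self.table.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise FormatError(
                    f"marker positions not strictly increasing on chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def positions(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos"].to_numpy()

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Row indices of the markers on one chromosome, in map order."""
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())

    @classmethod
    def uniform(
        cls,
        chrom: str = "1",
        length_bp: int = 30_000_000,
        spacing_bp: int = 50_000,
        start_bp: int = 1,
        build_label: str = "synthetic",
    ) -> "MarkerMap":
        """Evenly spaced biallelic markers along one chromosome."""
        pos = np.arange(start_bp, start_bp + length_bp + 1, spacing_bp, dtype=np.int64)
        table = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "id": [f"{chrom}:{p}" for p in pos],
                "ref": "A",
                "alt": "G",
            }
        )
        return cls(table, build_label=build_label)


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype matrix in 0/1/2 coding, -1 missing."""

    samples: list[str]
    marker_map: MarkerMap
    values: np.ndarray  # shape (n_samples, n_markers), dtype int8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.samples), len(self.marker_map)):
            raise FormatError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.marker_map)} markers"
            )
        bad = ~np.isin(self.values, [MISSING, 0, 1, 2])
        if bad.any():
            raise FormatError("genotype values outside {-1, 0, 1, 2}")
        self._index = {s: i for i, s in enumerate(self.samples)}

    def row(self, sample: str) -> np.ndarray:
        return self.values[self._index[sample]]

    def rows(self, sample_ids: Iterable[str]) -> np.ndarray:
        return self.values[[self._index[s] for s in sample_ids]]

    def monomorphic_mask(self) -> np.ndarray:
        """Markers where at most one allele is observed among non-missing calls."""
        has_ref = ((self.values == 0) | (self.values == 1)).any(axis=0)
        has_alt = ((self.values == 2) | (self.values == 1)).any(axis=0)
        return ~(has_ref & has_alt)

    def drop_monomorphic(self) -> "GenotypeMatrix":
        keep = ~self.monomorphic_mask()
        return self.subset_markers(np.flatnonzero(keep))

    def subset_markers(self, indices: np.ndarray) -> "GenotypeMatrix":
        table = self.marker_map.table.iloc[indices].reset_index(drop=True)
        mm = MarkerMap(table, build_label=self.marker_map.build_label)
        return GenotypeMatrix(list(self.samples), mm, self.values[:, indices])


@dataclass
class AnalysisGroups:
    """The 'expected carrier' group vs the unaffected pool.

    ``carriers_expected`` holds the members assumed to carry the risk
    haplotype: the affected cases, plus (optionally) unaffected members whose
    serology argues for pre-clinical disease and is grounds for
    reclassification into the case group.
    """

    carriers_expected: set[str]
    unaffected_pool: set[str]
    rationale: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.carriers_expected & self.unaffected_pool:
            raise PedigreeError("analysis groups overlap")


def _parse_parent(code: str) -> str | None:
    return None if code in ("0", "", ".") else code


def read_pedigree(ped_path: str | Path, phenotype_path: str | Path | None = None) -> Pedigree:
    """Read a PED/FAM file (first 6 columns) into a validated :class:`Pedigree`.

    If the file carries genotype columns (PED rather than FAM), individuals
    with at least one non-missing genotype call are marked ``genotyped``.
    ``phenotype_path`` may point to a TSV with columns ``id`` and
    ``antibody_status`` (and optionally ``affection``) to supplement the
    6-column phenotype code.
    """
    ped_path = Path(ped_path)
    individuals: list[Individual] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or line.startswith("#"):
                continue
            if len(fields) < 6:
                raise FormatError(f"{ped_path}:{lineno}: fewer than 6 columns")
            _fid, iid, pat, mat, sex, pheno = fields[:6]
            alleles = fields[6:]
            genotyped = any(a != "0" for a in alleles)
            individuals.append(
                Individual(
                    id=iid,
                    father_id=_parse_parent(pat),
                    mother_id=_parse_parent(mat),
                    sex=SEX_CODES.get(sex, "unknown"),
                    affection=AFFECTION_CODES.get(pheno, "unknown"),
                    genotyped=genotyped,
                )
            )
    pedigree = Pedigree(individuals)
    if phenotype_path is not None:
        pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
        if "id" not in pheno.columns:
            raise FormatError("phenotype file needs an 'id' column")
        for _, row in pheno.iterrows():
            iid = row["id"]
            if iid not in pedigree.individuals:
                raise PedigreeError(f"phenotype file references unknown id {iid!r}")
            ind = pedigree.individuals[iid]
            if "antibody_status" in pheno.columns and pd.notna(row.get("antibody_status")):
                ind.antibody_status = str(row["antibody_status"])
            if "affection" in pheno.columns and pd.notna(row.get("affection")):
                ind.affection = str(row["affection"])
    return pedigree


def _read_map(map_path: Path) -> MarkerMap:
    raw = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    if raw.shape[1] == 6:
        table = pd.DataFrame(
            {
                "chrom": raw[0],
                "pos": raw[3].astype(np.int64),
                "id": raw[1],
                "ref": raw[4],
                "alt": raw[5],
            }
        )
    elif raw.shape[1] == 4:
        table = pd.DataFrame(
            {
                "chrom": raw[0],
                "pos": raw[3].astype(np.int64),
                "id": raw[1],
                "ref": "",  # declared after allele inference from PED
                "alt": "",
            }
        )
    else:
        raise FormatError(f"{map_path}: expected 4 or 6 columns, got {raw.shape[1]}")
    return MarkerMap(table)


def _infer_ref_alt(a1: np.ndarray, a2: np.ndarray) -> tuple[str, str]:
    """Major allele as ref; ties broken lexicographically."""
    alleles, counts = np.unique(
        np.concatenate([a1[a1 != "0"], a2[a2 != "0"]]), return_counts=True
    )
    if len(alleles) == 0:
        return "A", "G"
    if len(alleles) > 2:
        raise FormatError(f"more than two alleles observed: {list(alleles)}")
    order = np.lexsort((alleles, -counts))
    ref = str(alleles[order[0]])
    alt = str(alleles[order[1]]) if len(alleles) == 2 else ("G" if ref != "G" else "A")
    return ref, alt


def _read_ped_genotypes(prefix: Path) -> tuple[MarkerMap, GenotypeMatrix]:
    mm = _read_map(prefix.with_suffix(".map"))
    rows: list[list[str]] = []
    samples: list[str] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            samples.append(fields[1])
            alleles = fields[6:]
            if len(alleles) != 2 * len(mm):
                raise FormatError(
                    f"sample {fields[1]}: {len(alleles)} allele columns, "
                    f"expected {2 * len(mm)}"
                )
            rows.append(alleles)
    allele_arr = np.array(rows, dtype="U8").reshape(len(samples), len(mm), 2)
    table = mm.table.copy()
    values = np.empty((len(samples), len(mm)), dtype=np.int8)
    for j in range(len(mm)):
        a1 = allele_arr[:, j, 0]
        a2 = allele_arr[:, j, 1]
        ref, alt = table.at[j, "ref"], table.at[j, "alt"]
        if ref == "":
            ref, alt = _infer_ref_alt(a1, a2)
            table.at[j, "ref"], table.at[j, "alt"] = ref, alt
        dose = np.where(
            (a1 == "0") | (a2 == "0"),
            MISSING,
            (a1 == alt).astype(int) + (a2 == alt).astype(int),
        )
        unknown = ~np.isin(a1, [ref, alt, "0"]) | ~np.isin(a2, [ref, alt, "0"])
        if unknown.any():
            raise FormatError(
                f"marker {table.at[j, 'id']}: allele outside declared {{{ref},{alt}}}"
            )
        values[:, j] = dose
    mm = MarkerMap(table, build_label=mm.build_label)
    return mm, GenotypeMatrix(samples, mm, values)


def _read_vcf_genotypes(path: Path) -> tuple[MarkerMap, GenotypeMatrix]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    geno_cols = []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        calls = np.full(len(samples), MISSING, dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a = g[:-1]  # trailing element is phase flag
            if len(a) != 2 or min(a) < 0:
                continue  # half-calls and missing -> missing
            calls[i] = int(a[0] > 0) + int(a[1] > 0)
        records.append((str(var.CHROM), int(var.POS), var.ID or f"{var.CHROM}:{var.POS}",
                        var.REF, var.ALT[0]))
        geno_cols.append(calls)
    if n_multiallelic:
        log.info("dropped %d multi-allelic records from %s", n_multiallelic, path)
    table = pd.DataFrame(records, columns=["chrom", "pos", "id", "ref", "alt"])
    mm = MarkerMap(table)
    values = (
        np.stack(geno_cols, axis=1) if geno_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return mm, GenotypeMatrix(samples, mm, values)


def read_genotypes(path: str | Path, fmt: str = "vcf") -> tuple[MarkerMap, GenotypeMatrix]:
    """Read genotypes from a VCF file or a PED/MAP prefix.

    ``fmt='ped'`` expects ``path`` to be a prefix resolving to ``path.ped`` and
    ``path.map``.  Multi-allelic VCF records are dropped (count logged);
    half-calls are read as missing.
    """
    path = Path(path)
    if fmt == "vcf":
        return _read_vcf_genotypes(path)
    if fmt == "ped":
        return _read_ped_genotypes(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def check_sample_overlap(pedigree: Pedigree, matrix: GenotypeMatrix) -> list[str]:
    """Samples present in the matrix but absent from the pedigree (rejected)."""
    unknown = [s for s in matrix.samples if s not in pedigree.individuals]
    if unknown:
        raise PedigreeError(f"samples not in pedigree: {unknown}")
    return unknown


def assign_groups(
    pedigree: Pedigree, reclassify_antibody_positive: bool = True
) -> AnalysisGroups:
    """Partition genotyped, phenotyped members into analysis groups.

    Affected members form the expected-carrier group; with
    ``reclassify_antibody_positive`` an antibody-positive unaffected member is
    moved into that group on serologic grounds (antibodies can precede overt
    disease by years).  The remaining unaffected members form the pool used to
    refine IBD stretches.  Genotyped members with unknown phenotype belong to
    neither group.
    """
    carriers: set[str] = set()
    pool: set[str] = set()
    rationale: dict[str, str] = {}
    for ind in pedigree:
        if not ind.genotyped or ind.affection == "unknown":
            continue
        if ind.affection == "affected":
            carriers.add(ind.id)
            rationale[ind.id] = "affected"
        elif reclassify_antibody_positive and ind.antibody_status == "positive":
            carriers.add(ind.id)
            rationale[ind.id] = "unaffected, antibody-positive (reclassified)"
        else:
            pool.add(ind.id)
            rationale[ind.id] = "unaffected"
    if not carriers:
        raise PedigreeError("no members in the expected-carrier group")
    return AnalysisGroups(carriers, pool, rationale)


def write_ped(
    matrix: GenotypeMatrix,
    pedigree: Pedigree | None,
    prefix: str | Path,
    phenotypes: Mapping[str, str] | None = None,
) -> tuple[Path, Path]:
    """Write PED + 6-column MAP files for a genotype matrix.

    Returns the (ped, map) paths.  Round-trips bit-identically at genotype
    level through :func:`read_genotypes`.
    """
    prefix = Path(prefix)
    table = matrix.marker_map.table
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for _, m in table.iterrows():
            fh.write(f"{m['chrom']}\t{m['id']}\t0\t{m['pos']}\t{m['ref']}\t{m['alt']}\n")
    ped_path = prefix.with_suffix(".ped")
    ref = table["ref"].to_numpy()
    alt = table["alt"].to_numpy()
    pheno_code = {"affected": "2", "unaffected": "1", "unknown": "0"}
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    with open(ped_path, "w") as fh:
        for si, sample in enumerate(matrix.samples):
            if pedigree is not None and sample in pedigree.individuals:
                ind = pedigree.individuals[sample]
                # parents outside the written sample set are coded missing
                sample_set = set(matrix.samples)
                pat = ind.father_id if ind.father_id in sample_set else "0"
                mat = ind.mother_id if ind.mother_id in sample_set else "0"
                sex = sex_code[ind.sex]
                aff = ind.affection
            else:
                pat = mat = "0"
                sex = "0"
                aff = "unknown"
            if phenotypes is not None and sample in phenotypes:
                aff = phenotypes[sample]
            g = matrix.values[si]
            a1 = np.where(g == MISSING, "0", np.where(g >= 1, alt, ref))
            a2 = np.where(g == MISSING, "0", np.where(g == 2, alt, ref))
            cols = ["FAM1", sample, pat, mat, sex, pheno_code[aff]]
            cols += [x for pair in zip(a1, a2) for x in pair]
            fh.write(" ".join(cols) + "\n")
    return ped_path, map_path


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> Path:
    """Write the matrix as an uncompressed VCFv4.2 file."""
    path = Path(path)
    table = matrix.marker_map.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in matrix.marker_map.chroms:
            length = int(matrix.marker_map.positions(chrom).max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        gt_str = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for j, m in table.iterrows():
            calls = "\t".join(gt_str[int(v)] for v in matrix.values[:, j])
            fh.write(
                f"{m['chrom']}\t{m['pos']}\t{m['id']}\t{m['ref']}\t{m['alt']}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )
    return path
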