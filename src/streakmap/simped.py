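"""Gene-dropping simulator with a planted ancestral risk haplotype.

Forward-simulates allele transmission through a fixed (possibly looped)
pedigree: founder haplotypes are drawn marker-by-marker from given allele
frequencies (linkage equilibrium), offspring haplotypes follow Mendelian
transmission with crossovers as a Poisson process at a fixed per-bp rate (no
interference), and a risk mutation is planted on one designated founder
haplotype.  Haplotype *descent* is tracked explicitly (each founder haplotype
carries a unique label), so the true carrier set and the unbroken shared
segment around the planted locus are known exactly — this is the ground
truth every mapping test is scored against.

Phenotypes follow a dominant single-locus model: planted-haplotype carriers
are affected with probability ``penetrance`` (default 0.50), non-carriers
with ``phenocopy_rate``.  Optionally one unaffected carrier is flagged
antibody-positive to mirror serology-based reclassification into the case
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .pedio import (
    MISSING,
    AnalysisGroups,
    GenotypeMatrix,
    Individual,
    MarkerMap,
    Pedigree,
    write_ped,
    write_vcf,
)


@dataclass
class SimConfig:
    pedigree: Pedigree
    marker_map: MarkerMap
    founder_allele_freqs: float | np.ndarray = 0.5  # alt-allele frequency per marker
    planted_locus: tuple[str, int] | None = None    # defaults to map midpoint
    ancestral_founder_id: str | None = None         # defaults to first founder
    haplotype_index: int = 0
    recomb_rate_per_bp: float = 1e-8
    penetrance: float = 0.50
    phenocopy_rate: float = 0.0
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    flag_antibody_positive_carrier: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("penetrance", "phenocopy_rate", "genotype_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.ancestral_founder_id is None:
            self.ancestral_founder_id = self.pedigree.founders()[0].id
        elif not self.pedigree[self.ancestral_founder_id].is_founder:
            raise ValueError(
                f"{self.ancestral_founder_id!r} is not a founder of the pedigree"
            )
        if self.haplotype_index not in (0, 1):
            raise ValueError("haplotype_index must be 0 or 1")
        table = self.marker_map.table
        if self.planted_locus is None:
            mid = len(table) // 2
            self.planted_locus = (str(table.at[mid, "chrom"]), int(table.at[mid, "pos"]))
        chrom, pos = self.planted_locus
        cpos = self.marker_map.positions(chrom)
        if len(cpos) == 0 or not (cpos[0] <= pos <= cpos[-1]):
            raise ValueError(f"planted locus {chrom}:{pos} outside the marker map")


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    true_haplotype_carriers: set[str]
    phenotypes: dict[str, str]            # id -> affected/unaffected (all members)
    antibody: dict[str, str]              # id -> positive/negative/unknown
    transmission_record: dict[tuple[str, str], dict[str, tuple[int, list[float]]]]
    haplotype_labels: dict[str, tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=dict)
    planted_marker_index: int = 0
    planted_label: int = 0
    pedigree: Pedigree | None = field(repr=False, default=None)
    config: SimConfig | None = field(repr=False, default=None)

    def phenotyped_pedigree(self) -> Pedigree:
        """A copy of the pedigree carrying the simulated phenotypes."""
        inds = []
        for ind in self.pedigree:
            inds.append(
                Individual(
                    id=ind.id,
                    father_id=ind.father_id,
                    mother_id=ind.mother_id,
                    sex=ind.sex,
                    affection=self.phenotypes[ind.id],
                    antibody_status=self.antibody.get(ind.id, "unknown"),
                    genotyped=ind.id in self.genotypes.samples,
                )
            )
        return Pedigree(inds)

    def shared_planted_segment(self) -> tuple[int, int]:
        """Marker-index extent (on the planted chromosome, inclusive) over
        which *every* true carrier still carries the planted haplotype —
        the unbroken IBD segment the streak scan should recover."""
        cfg = self.config
        chrom = cfg.planted_locus[0]
        idx = cfg.marker_map.chrom_index(chrom)
        local_planted = int(np.flatnonzero(idx == self.planted_marker_index)[0])
        lo, hi = 0, len(idx) - 1
        for iid in self.true_haplotype_carriers:
            h0, h1 = self.haplotype_labels[iid]
            has = (h0[idx] == self.planted_label) | (h1[idx] == self.planted_label)
            j = local_planted
            a = j
            while a > 0 and has[a - 1]:
                a -= 1
            b = j
            while b < len(idx) - 1 and has[b + 1]:
                b += 1
            lo, hi = max(lo, a), min(hi, b)
        return lo, hi


def _topological_order(pedigree: Pedigree) -> list[Individual]:
    depth = pedigree.generations()
    return sorted(pedigree, key=lambda i: depth[i.id])


def gene_drop(config: SimConfig) -> SimResult:
    """Drop genes through the pedigree; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    mm = config.marker_map
    n_markers = len(mm)
    freqs = np.broadcast_to(
        np.asarray(config.founder_allele_freqs, dtype=float), (n_markers,)
    )
    pedigree = config.pedigree
    founders = pedigree.founders()

    # founder haplotypes: unique descent labels, alleles in linkage equilibrium
    founder_label = {f.id: (2 * i, 2 * i + 1) for i, f in enumerate(founders)}
    n_haps = 2 * len(founders)
    founder_alleles = (rng.random((n_haps, n_markers)) < freqs).astype(np.int8)

    chrom_planted, pos_planted = config.planted_locus
    idx_c = mm.chrom_index(chrom_planted)
    pos_c = mm.table["pos"].to_numpy()[idx_c]
    planted_idx = int(idx_c[np.argmin(np.abs(pos_c - pos_planted))])
    planted_label = founder_label[config.ancestral_founder_id][config.haplotype_index]
    founder_alleles[planted_label, planted_idx] = 1

    chrom_blocks = [
        (chrom, mm.chrom_index(chrom), mm.positions(chrom)) for chrom in mm.chroms
    ]

    def gamete(h0: np.ndarray, h1: np.ndarray):
        labels = np.empty(n_markers, dtype=np.int64)
        record: dict[str, tuple[int, list[float]]] = {}
        for chrom, idx, pos in chrom_blocks:
            length = float(pos[-1] - pos[0])
            n_x = rng.poisson(config.recomb_rate_per_bp * length)
            xpos = np.sort(rng.uniform(pos[0], pos[-1], n_x)) if n_x else np.empty(0)
            start = int(rng.integers(2))
            phase = (start + np.searchsorted(xpos, pos)) % 2
            labels[idx] = np.where(phase == 0, h0[idx], h1[idx])
            record[chrom] = (start, [float(x) for x in xpos])
        return labels, record

    hap: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    transmission: dict[tuple[str, str], dict[str, tuple[int, list[float]]]] = {}
    for ind in _topological_order(pedigree):
        if ind.is_founder:
            l0, l1 = founder_label[ind.id]
            hap[ind.id] = (
                np.full(n_markers, l0, dtype=np.int64),
                np.full(n_markers, l1, dtype=np.int64),
            )
        else:
            if ind.father_id is None or ind.mother_id is None:
                raise ValueError(
                    f"{ind.id!r} has exactly one known parent; gene dropping "
                    "needs both parents or neither"
                )
            pat, rec_p = gamete(*hap[ind.father_id])
            mat, rec_m = gamete(*hap[ind.mother_id])
            hap[ind.id] = (pat, mat)
            transmission[(ind.id, "paternal")] = rec_p
            transmission[(ind.id, "maternal")] = rec_m

    carriers = {
        iid
        for iid, (h0, h1) in hap.items()
        if h0[planted_idx] == planted_label or h1[planted_idx] == planted_label
    }

    phenotypes: dict[str, str] = {}
    for ind in pedigree:
        p = config.penetrance if ind.id in carriers else config.phenocopy_rate
        phenotypes[ind.id] = "affected" if rng.random() < p else "unaffected"

    genotyped = pedigree.genotyped_ids() or [i.id for i in pedigree]
    values = np.empty((len(genotyped), n_markers), dtype=np.int8)
    for r, iid in enumerate(genotyped):
        h0, h1 = hap[iid]
        values[r] = founder_alleles[h0, np.arange(n_markers)] + founder_alleles[
            h1, np.arange(n_markers)
        ]

    if config.genotype_error_rate > 0:
        err = rng.random(values.shape) < config.genotype_error_rate
        # flip to a uniformly chosen *different* genotype value
        bump = rng.integers(1, 3, size=values.shape)
        values = np.where(err, (values + bump) % 3, values).astype(np.int8)
    if config.missing_rate > 0:
        values[rng.random(values.shape) < config.missing_rate] = MISSING

    antibody: dict[str, str] = {
        iid: "negative" for iid in genotyped
    }
    if config.flag_antibody_positive_carrier:
        eligible = sorted(
            iid for iid in genotyped
            if iid in carriers and phenotypes[iid] == "unaffected"
        )
        if eligible:
            antibody[str(rng.choice(eligible))] = "positive"

    matrix = GenotypeMatrix(genotyped, mm, values)
    return SimResult(
        genotypes=matrix,
        true_haplotype_carriers=carriers,
        phenotypes=phenotypes,
        antibody=antibody,
        transmission_record=transmission,
        haplotype_labels=hap,
        planted_marker_index=planted_idx,
        planted_label=planted_label,
        pedigree=pedigree,
        config=config,
    )


def write_sim(result: SimResult, fmt: str, prefix: str | Path) -> list[Path]:
    """Write simulated genotypes (PED+MAP or VCF) plus a truth TSV sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "ped":
        ped, mp = write_ped(
            result.genotypes,
            result.phenotyped_pedigree(),
            prefix,
            phenotypes=result.phenotypes,
        )
        written += [ped, mp]
    elif fmt == "vcf":
        written.append(write_vcf(result.genotypes, prefix.with_suffix(".vcf")))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    truth = prefix.with_suffix(".truth.tsv")
    cfg = result.config
    with open(truth, "w") as fh:
        fh.write("# record\tid\tdetail\n")
        chrom, pos = cfg.planted_locus
        fh.write(f"planted_locus\t{chrom}:{pos}\tmarker_index={result.planted_marker_index}\n")
        for iid in sorted(result.true_haplotype_carriers):
            fh.write(f"carrier\t{iid}\t.\n")
        for iid, pheno in sorted(result.phenotypes.items()):
            fh.write(f"phenotype\t{iid}\t{pheno}\n")
        for (iid, side), rec in sorted(result.transmission_record.items()):
            for chrom, (start, xpos) in rec.items():
                xs = ",".join(f"{x:.0f}" for x in xpos) or "."
                fh.write(f"crossovers\t{iid}\t{side}:{chrom}:start={start}:{xs}\n")
    written.append(truth)
    return written


def study_pedigree() -> tuple[Pedigree, AnalysisGroups]:
    """The packaged 4-generation consanguineous study pedigree.

    49 members across 4 generations, 8 affected; 24 genotyped members
    comprising 5 affected cases (II:12, III:3, III:17, IV:5, IV:9), one
    strongly antibody-positive unaffected subject (III:2, reclassified into
    the expected-carrier group), and 18 antibody-negative unaffected members.
    Five third-generation marriages are between first cousins, giving the
    looped structure typical of a consanguineous family.  The exact mating
    structure of the source family is known only from a drawing; this
    topology is an approximation that reproduces every published count and
    the listed member identifiers.
    """
    genotyped = {
        "II:5", "II:6", "II:12",
        "III:1", "III:2", "III:3", "III:4", "III:5", "III:6", "III:9",
        "III:11", "III:12", "III:13", "III:14", "III:17", "III:19", "III:20",
        "IV:1", "IV:2", "IV:3", "IV:4", "IV:5", "IV:7", "IV:9",
    }
    affected = {"II:12", "III:3", "III:17", "IV:5", "IV:9",  # genotyped cases
                "II:4", "II:8", "III:16"}                     # deceased/unsampled
    antibody_positive_ids = {"III:2"}

    def ind(iid, father=None, mother=None, sex="unknown"):
        aff = "affected" if iid in affected else "unaffected"
        ab = "positive" if iid in antibody_positive_ids else (
            "negative" if iid in genotyped else "unknown"
        )
        return Individual(
            id=iid, father_id=father, mother_id=mother, sex=sex,
            affection=aff, antibody_status=ab, genotyped=iid in genotyped,
        )

    members: list[Individual] = [ind("I:1", sex="male"), ind("I:2", sex="female")]
    # generation II: six children of I:1 x I:2 (even ids) and their spouses
    for k in (2, 4, 6, 8, 10, 12):
        members.append(ind(f"II:{k}", "I:1", "I:2", sex="male" if k % 4 == 0 else "female"))
    for k in (1, 3, 5, 7, 9, 11):
        members.append(ind(f"II:{k}", sex="female" if (k + 1) % 4 == 0 else "male"))
    # generation III: all are children of generation-II couples
    couples_iii = {
        ("II:1", "II:2"): ["III:2", "III:5", "III:11", "III:16"],
        ("II:3", "II:4"): ["III:3", "III:6", "III:12", "III:17"],
        ("II:5", "II:6"): ["III:7", "III:9", "III:13", "III:18"],
        ("II:7", "II:8"): ["III:8", "III:10", "III:14", "III:19"],
        ("II:9", "II:10"): ["III:15", "III:20"],
        ("II:11", "II:12"): ["III:1", "III:4"],
    }
    sex_iii = {  # members of each gen-III couple need opposite sexes
        "III:2": "female", "III:3": "male", "III:9": "female", "III:10": "male",
        "III:13": "female", "III:14": "male", "III:17": "female", "III:18": "male",
        "III:4": "female", "III:5": "male",
    }
    for (p1, p2), kids in couples_iii.items():
        father, mother = (p1, p2) if members_sex(members, p1) == "male" else (p2, p1)
        for kid in kids:
            members.append(ind(kid, father, mother, sex=sex_iii.get(kid, "unknown")))
    # generation IV: five first-cousin marriages among generation III
    couples_iv = {
        ("III:3", "III:2"): ["IV:1", "IV:5", "IV:9"],
        ("III:10", "III:9"): ["IV:2", "IV:6", "IV:10"],
        ("III:14", "III:13"): ["IV:3", "IV:7", "IV:11"],
        ("III:18", "III:17"): ["IV:4", "IV:8", "IV:12"],
        ("III:5", "III:4"): ["IV:13", "IV:14", "IV:15"],
    }
    for (father, mother), kids in couples_iv.items():
        for kid in kids:
            members.append(ind(kid, father, mother))
    pedigree = Pedigree(members)
    assert len(pedigree) == 49
    groups = AnalysisGroups(
        carriers_expected={"II:12", "III:3", "III:17", "IV:5", "IV:9", "III:2"},
        unaffected_pool=genotyped - {"II:12", "III:3", "III:17", "IV:5", "IV:9", "III:2"},
        rationale={"III:2": "unaffected, antibody-positive (reclassified)"},
    )
    return pedigree, groups


def members_sex(members: list[Individual], iid: str) -> str:
    for m in members:
        if m.id == iid:
            return m.sex
    raise KeyError(iid)


def study_sim_config(
    seed: int = 0,
    penetrance: float = 1.0,
    chrom_length_bp: int = 30_000_000,
    marker_spacing_bp: int = 50_000,
    founder_alt_freq: float = 0.5,
    flag_antibody_positive_carrier: bool = False,
    **kwargs,
) -> SimConfig:
    """Study-pedigree simulation with the default genome-scale-down map:
    one 30 Mbp chromosome at 50 kbp marker spacing, risk haplotype planted
    mid-chromosome on founder I:1."""
    pedigree, _ = study_pedigree()
    mm = MarkerMap.uniform(
        chrom="2", length_bp=chrom_length_bp, spacing_bp=marker_spacing_bp
    )
    mid = mm.table.at[len(mm) // 2, "pos"]
    return SimConfig(
        pedigree=pedigree,
        marker_map=mm,
        founder_allele_freqs=founder_alt_freq,
        planted_locus=("2", int(mid)),
        ancestral_founder_id="I:1",
        haplotype_index=0,
        penetrance=penetrance,
        flag_antibody_positive_carrier=flag_antibody_positive_carrier,
        seed=seed,
        **kwargs,
    )
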