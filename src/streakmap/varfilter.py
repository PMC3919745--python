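"""Rare-pathogenic-variant filtering and intersection with IBD stretches.

Implements the four-step exome candidate filter: (i) a likely-pathogenic
consequence class; (ii) not registered in population databases at
non-reference allele frequency >= 0.01; (iii) for indels, not within +/-5 bp
of a known variant; (iv) at least one non-reference allele observed in every
sequenced case.  Rejections are labeled with the first failing criterion.
Survivors are intersected with the IBD stretches and ranked by segregation
evidence (mid-P) in validation genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .pedio import AnalysisGroups, GenotypeMatrix
from .segstats import (
    ContingencyTable2x2,
    MidPResult,
    midp_fisher,
    segregation_table,
)
from .streak import IBDStretch

PATHOGENIC_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift_indel", "splice_acceptor", "splice_donor"}
)

# first-fail rejection labels, in criterion order
REASON_CONSEQUENCE = "consequence"
REASON_DB_FREQUENCY = "db_frequency"
REASON_INDEL_PROXIMITY = "indel_proximity"
REASON_CARRIER_SUPPORT = "carrier_support"


@dataclass
class CandidateVariant:
    """An annotated variant call with per-individual carrier status."""

    chrom: str
    pos_bp: int
    ref: str
    alt: str
    kind: str  # snv | indel
    consequence: str
    db_frequencies: dict[str, float] = field(default_factory=dict)
    carrier_calls: dict[str, str] = field(default_factory=dict)  # carries_alt/no_alt/missing

    def __post_init__(self) -> None:
        if self.pos_bp <= 0:
            raise ValueError("position must be positive (1-based)")
        if self.ref == self.alt:
            raise ValueError("alt allele equals ref")
        for src, f in self.db_frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} for {src} outside [0,1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos_bp, self.ref, self.alt)


@dataclass
class FilterConfig:
    max_db_frequency: float = 0.01
    indel_proximity_bp: int = 5
    required_carrier_ids: frozenset[str] = frozenset()
    pathogenic_classes: frozenset[str] = PATHOGENIC_CLASSES
    # frequency-less known sites fail criterion (ii) only on exact site match
    reject_frequencyless_known_sites: bool = True

    def __post_init__(self) -> None:
        if self.indel_proximity_bp < 0:
            raise ValueError("indel proximity must be >= 0")


def _first_fail(
    v: CandidateVariant,
    known_sites: Mapping[str, set[tuple[str, int]]],
    cfg: FilterConfig,
) -> str | None:
    # (i) likely-pathogenic consequence class
    if v.consequence not in cfg.pathogenic_classes:
        return REASON_CONSEQUENCE
    # (ii) registered in a database at frequency >= threshold; the maximum
    # frequency across sources governs.  A site present in a frequency-less
    # database rejects only on exact position match (configurable).
    if v.db_frequencies and max(v.db_frequencies.values()) >= cfg.max_db_frequency:
        return REASON_DB_FREQUENCY
    if cfg.reject_frequencyless_known_sites:
        for src, sites in known_sites.items():
            if src in v.db_frequencies:
                continue  # frequency already consulted for this source
            if (v.chrom, v.pos_bp) in sites:
                return REASON_DB_FREQUENCY
    # (iii) indels near known variants (leftmost-coordinate distance)
    if v.kind == "indel":
        for sites in known_sites.values():
            for delta in range(-cfg.indel_proximity_bp, cfg.indel_proximity_bp + 1):
                if (v.chrom, v.pos_bp + delta) in sites:
                    return REASON_INDEL_PROXIMITY
    # (iv) alt allele observed in every required (sequenced) case
    for iid in sorted(cfg.required_carrier_ids):
        if iid not in v.carrier_calls:
            raise ValueError(f"required carrier {iid!r} missing from calls")
    for iid in sorted(cfg.required_carrier_ids):
        if v.carrier_calls[iid] != "carries_alt":
            return REASON_CARRIER_SUPPORT
    return None


def filter_candidates(
    variants: Sequence[CandidateVariant],
    known_sites: Mapping[str, set[tuple[str, int]]],
    config: FilterConfig | None = None,
) -> tuple[list[CandidateVariant], dict[tuple, str]]:
    """Apply criteria (i)-(iv); returns (retained, rejection reason per key).

    Each rejected variant carries exactly one label: the first criterion it
    fails, in the order consequence, database frequency, indel proximity,
    carrier support.
    """
    cfg = config or FilterConfig()
    retained: list[CandidateVariant] = []
    reasons: dict[tuple, str] = {}
    for v in variants:
        reason = _first_fail(v, known_sites, cfg)
        if reason is None:
            retained.append(v)
        else:
            reasons[v.key] = reason
    return retained, reasons


def intersect_stretches(
    variants: Sequence[CandidateVariant],
    stretches: Sequence[IBDStretch],
    variant_build: str | None = None,
    stretch_build: str | None = None,
) -> list[CandidateVariant]:
    """Variants whose start position lies inside any IBD stretch (1-based
    inclusive on both sides)."""
    if (
        variant_build is not None
        and stretch_build is not None
        and variant_build != stretch_build
    ):
        raise ValueError(
            f"genome build mismatch: variants {variant_build!r} vs "
            f"stretches {stretch_build!r}"
        )
    trees: dict[str, IntervalTree] = {}
    for st in stretches:
        trees.setdefault(st.chrom, IntervalTree()).addi(st.start_bp, st.end_bp + 1)
    return [
        v for v in variants if v.chrom in trees and trees[v.chrom].overlaps(v.pos_bp)
    ]


@dataclass
class RankedVariant:
    variant: CandidateVariant
    table: ContingencyTable2x2
    midp: MidPResult


def rank_by_segregation(
    variants: Sequence[CandidateVariant],
    validation: GenotypeMatrix | Mapping[tuple, set[str]],
    groups: AnalysisGroups,
) -> list[RankedVariant]:
    """Order variants by segregation evidence (ascending two-sided mid-P).

    ``validation`` supplies per-variant carrier sets from the validation
    genotyping: either a GenotypeMatrix whose marker map contains a marker at
    each variant's position (carrier = any non-reference allele) or a mapping
    from variant key to carrier id set.  Ties keep input order (stable sort).
    """
    ranked: list[RankedVariant] = []
    for v in variants:
        if isinstance(validation, GenotypeMatrix):
            carriers = _carriers_from_matrix(v, validation)
        else:
            carriers = set(validation[v.key])
        table = segregation_table(carriers, groups)
        ranked.append(RankedVariant(v, table, midp_fisher(table)))
    ranked.sort(key=lambda r: r.midp.p_mid_two_sided)
    return ranked


def _carriers_from_matrix(v: CandidateVariant, matrix: GenotypeMatrix) -> set[str]:
    table = matrix.marker_map.table
    hit = table.index[(table["chrom"] == v.chrom) & (table["pos"] == v.pos_bp)]
    if len(hit) == 0:
        raise ValueError(f"no validation genotypes at {v.chrom}:{v.pos_bp}")
    j = int(hit[0])
    col = matrix.values[:, j]
    return {s for s, g in zip(matrix.samples, col) if g in (1, 2)}


def read_candidates_vcf(
    path: str,
    consequence_key: str = "CSQ_CLASS",
    frequency_keys: Mapping[str, str] | None = None,
) -> list[CandidateVariant]:
    """Read annotated candidate variants from a VCF.

    ``consequence_key`` names the INFO field holding the consequence class;
    ``frequency_keys`` maps database source name to the INFO field with its
    non-reference allele frequency (e.g. ``{"1000G": "AF_1KG"}``).  Carrier
    calls come from the sample genotypes.
    """
    from cyvcf2 import VCF

    frequency_keys = frequency_keys or {}
    out: list[CandidateVariant] = []
    vcf = VCF(path)
    samples = list(vcf.samples)
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        kind = "snv" if len(var.REF) == 1 and len(var.ALT[0]) == 1 else "indel"
        freqs = {}
        for source, key in frequency_keys.items():
            val = var.INFO.get(key)
            if val is not None:
                freqs[source] = float(val)
        calls: dict[str, str] = {}
        for i, g in enumerate(var.genotypes):
            a = g[:-1]
            if len(a) != 2 or min(a) < 0:
                calls[samples[i]] = "missing"
            else:
                calls[samples[i]] = "carries_alt" if max(a) > 0 else "no_alt"
        out.append(
            CandidateVariant(
                chrom=str(var.CHROM),
                pos_bp=int(var.POS),
                ref=var.REF,
                alt=var.ALT[0],
                kind=kind,
                consequence=str(var.INFO.get(consequence_key, "other")),
                db_frequencies=freqs,
                carrier_calls=calls,
            )
        )
    return out


def read_known_sites(path: str) -> set[tuple[str, int]]:
    """Known-variant sites from a 2+ column TSV (chrom, pos[, ...]) or VCF."""
    sites: set[tuple[str, int]] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            sites.add((f[0], int(f[1])))
    return sites


def write_filter_report(
    variants: Sequence[CandidateVariant],
    reasons: Mapping[tuple, str],
    path: str,
) -> None:
    """TSV report: one row per input variant with retained/rejection status."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tkind\tconsequence\tstatus\n")
        for v in variants:
            status = reasons.get(v.key, "retained")
            fh.write(
                f"{v.chrom}\t{v.pos_bp}\t{v.ref}\t{v.alt}\t{v.kind}\t"
                f"{v.consequence}\t{status}\n"
            )
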