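"""SNP-streak identity-by-descent mapping.

The mapping rule: members assumed to carry a risk mutation on one ancestral
haplotype each hold at least one copy of that haplotype, so at markers inside
the shared segment the carrier set can never exhibit *both* homozygote
classes — at least one allele is carried by every member.  A 1-Mbp window is
called IBD-compatible when at most one marker in it violates the rule, and
compatible windows merging to >= 2 Mbp form an IBD stretch.  Works for any
inheritance mode without a penetrance model; a recessive variant (all members
homozygous for the same allele — classical homozygosity mapping) shares the
same window machinery.

Refinement uses the unaffected members: a stretch's ancestral haplotype is
imputed present in an unaffected subject when adding that subject to the
carrier set leaves the stretch compatible, and stretches are confined by
consecutively restricting how many unaffected subjects may harbor them.
Significance of ending up with such a stretch at all is assessed by
re-running the whole pipeline over random "affected" subsets of the pedigree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pedio import MISSING, GenotypeMatrix, MarkerMap

log = logging.getLogger(__name__)


@dataclass
class StreakConfig:
    """Parameters of the windowed streak scan.

    window_span_bp
        Width of the sliding window (default 1 Mbp).
    min_stretch_bp
        Minimum span of merged compatible windows to call a stretch
        (default 2 Mbp).
    max_exceptions_per_window
        Number of rule-violating markers tolerated per window (default 1;
        absorbs isolated genotyping errors).
    ld_prune_r2
        r-squared threshold for pre-scan LD pruning (default 0.9).
    missing_policy
        'compatible' (default): a missing call imposes no constraint.
        'incompatible': any missing call breaks the window rule.
    window_step
        'per_marker' (default) anchors a window start at every marker;
        'fixed_bp' uses a regular grid of step_bp.
    """

    window_span_bp: int = 1_000_000
    min_stretch_bp: int = 2_000_000
    max_exceptions_per_window: int = 1
    ld_prune_r2: float = 0.9
    missing_policy: str = "compatible"
    window_step: str = "per_marker"
    step_bp: int = 100_000

    def __post_init__(self) -> None:
        if self.window_span_bp > self.min_stretch_bp:
            raise ValueError("window_span_bp must be <= min_stretch_bp")
        if self.max_exceptions_per_window < 0:
            raise ValueError("max_exceptions_per_window must be >= 0")
        if self.missing_policy not in ("compatible", "incompatible"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        if self.window_step not in ("per_marker", "fixed_bp"):
            raise ValueError(f"unknown window_step {self.window_step!r}")


@dataclass
class WindowCall:
    """Compatibility call for one window placement."""

    chrom: str
    start_bp: int
    end_bp: int
    first_marker: int  # indices into the chromosome's marker order
    last_marker: int
    n_incompatible: int
    compatible: bool


@dataclass
class IBDStretch:
    """A run of compatible windows spanning at least min_stretch_bp.

    Coordinates are the marker-supported extent (first to last marker of the
    merged compatible windows), 1-based inclusive.
    """

    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int
    mode: str = "dominant_streak"  # or "recessive_homozygosity"
    unaffected_presence: dict[str, bool] = field(default_factory=dict)
    first_marker: int = 0  # indices within the chromosome's marker order
    last_marker: int = 0

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, chrom: str, pos_bp: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos_bp <= self.end_bp


@dataclass
class RefinementTrace:
    """Surviving stretches at each consecutive presence-count threshold k."""

    presence_counts: list[int]
    steps: list[tuple[int, list[IBDStretch]]]

    def survivors_at(self, k: int) -> list[IBDStretch]:
        for kk, surv in self.steps:
            if kk == k:
                return surv
        raise KeyError(f"threshold {k} not in trace")

    @property
    def final(self) -> list[IBDStretch]:
        return self.steps[-1][1]


@dataclass
class PermutationResult:
    n_iterations: int
    n_affected_drawn: int
    presence_threshold_k: int
    n_success: int
    p_value: float
    seed: int


def marker_compatible(
    genotypes: Sequence[int], missing_policy: str = "compatible"
) -> bool:
    """Streak rule at one marker: the carrier set may not contain both
    homozygote classes.

    Under 'compatible' a missing genotype imposes no constraint; under
    'incompatible' any missing genotype fails the marker.
    """
    g = np.asarray(genotypes)
    if g.size == 0:
        raise ValueError("empty carrier set")
    if missing_policy == "incompatible" and (g == MISSING).any():
        return False
    return not (((g == 0).any()) and ((g == 2).any()))


def _incompatible_mask(sub: np.ndarray, missing_policy: str, mode: str) -> np.ndarray:
    """Boolean per-marker rule violations for a carrier submatrix (rows=carriers)."""
    has_ref_hom = (sub == 0).any(axis=0)
    has_alt_hom = (sub == 2).any(axis=0)
    if mode == "dominant_streak":
        incompat = has_ref_hom & has_alt_hom
    elif mode == "recessive_homozygosity":
        # all non-missing genotypes must be the same homozygote
        has_het = (sub == 1).any(axis=0)
        incompat = has_het | (has_ref_hom & has_alt_hom)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if missing_policy == "incompatible":
        incompat = incompat | (sub == MISSING).any(axis=0)
    return incompat


def _window_bounds(
    pos: np.ndarray, cfg: StreakConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window (start_bp, first_marker, last_marker) arrays for one chromosome.

    Windows with no markers are omitted (non-calls).
    """
    if cfg.window_step == "per_marker":
        starts = pos.copy()
    else:
        grid = np.arange(pos[0], pos[-1] + 1, cfg.step_bp, dtype=np.int64)
        starts = grid
    ends = starts + cfg.window_span_bp - 1
    first = np.searchsorted(pos, starts, side="left")
    last = np.searchsorted(pos, ends, side="right") - 1
    keep = last >= first
    return starts[keep], first[keep], last[keep]


def _window_incompat_counts(
    incompat: np.ndarray, first: np.ndarray, last: np.ndarray
) -> np.ndarray:
    csum = np.concatenate([[0], np.cumsum(incompat)])
    return csum[last + 1] - csum[first]


def scan_windows(
    matrix: GenotypeMatrix,
    marker_map: MarkerMap,
    carrier_ids: Sequence[str],
    config: StreakConfig | None = None,
    mode: str = "dominant_streak",
) -> list[WindowCall]:
    """Call IBD compatibility for every window placement, genome-wide.

    A window is compatible when the number of rule-violating markers it
    contains is at most ``max_exceptions_per_window``.
    """
    cfg = config or StreakConfig()
    if len(carrier_ids) == 0:
        raise ValueError("empty carrier set")
    if len(carrier_ids) < 2:
        warnings.warn(
            "carrier set of size 1: every marker is trivially compatible",
            stacklevel=2,
        )
    sub_all = matrix.rows(carrier_ids)
    calls: list[WindowCall] = []
    for chrom in marker_map.chroms:
        idx = marker_map.chrom_index(chrom)
        pos = marker_map.table["pos"].to_numpy()[idx]
        incompat = _incompatible_mask(sub_all[:, idx], cfg.missing_policy, mode)
        starts, first, last = _window_bounds(pos, cfg)
        counts = _window_incompat_counts(incompat, first, last)
        for s, f, l, c in zip(starts, first, last, counts):
            calls.append(
                WindowCall(
                    chrom=chrom,
                    start_bp=int(s),
                    end_bp=int(s) + cfg.window_span_bp - 1,
                    first_marker=int(f),
                    last_marker=int(l),
                    n_incompatible=int(c),
                    compatible=bool(c <= cfg.max_exceptions_per_window),
                )
            )
    return calls


def _merge_compatible(
    starts: np.ndarray,
    first: np.ndarray,
    last: np.ndarray,
    ok: np.ndarray,
    span: int,
) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent compatible windows into (first, last) marker runs."""
    runs: list[tuple[int, int]] = []
    cur_f = cur_l = None
    cur_end = None
    for s, f, l, good in zip(starts, first, last, ok):
        if not good:
            continue
        e = s + span - 1
        if cur_end is not None and s <= cur_end + 1:
            cur_l = max(cur_l, l)
            cur_end = max(cur_end, e)
        else:
            if cur_f is not None:
                runs.append((cur_f, cur_l))
            cur_f, cur_l, cur_end = f, l, e
    if cur_f is not None:
        runs.append((cur_f, cur_l))
    return runs


def call_stretches(
    window_calls: Sequence[WindowCall],
    marker_map: MarkerMap,
    config: StreakConfig | None = None,
    mode: str = "dominant_streak",
) -> list[IBDStretch]:
    """Merge compatible windows into maximal IBD stretches of >= min_stretch_bp.

    Stretch coordinates are the first-to-last marker of the merged windows.
    """
    cfg = config or StreakConfig()
    stretches: list[IBDStretch] = []
    by_chrom: dict[str, list[WindowCall]] = {}
    for w in window_calls:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, calls in by_chrom.items():
        calls.sort(key=lambda w: w.start_bp)
        pos = marker_map.positions(chrom)
        starts = np.array([w.start_bp for w in calls])
        first = np.array([w.first_marker for w in calls])
        last = np.array([w.last_marker for w in calls])
        ok = np.array([w.compatible for w in calls])
        for f, l in _merge_compatible(starts, first, last, ok, cfg.window_span_bp):
            start_bp, end_bp = int(pos[f]), int(pos[l])
            if end_bp - start_bp + 1 >= cfg.min_stretch_bp:
                stretches.append(
                    IBDStretch(
                        chrom=chrom,
                        start_bp=start_bp,
                        end_bp=end_bp,
                        n_markers=int(l - f + 1),
                        mode=mode,
                        first_marker=int(f),
                        last_marker=int(l),
                    )
                )
    return stretches


def scan_stretches(
    matrix: GenotypeMatrix,
    marker_map: MarkerMap,
    carrier_ids: Sequence[str],
    config: StreakConfig | None = None,
    mode: str = "dominant_streak",
) -> list[IBDStretch]:
    """Convenience: scan windows then call stretches."""
    cfg = config or StreakConfig()
    calls = scan_windows(matrix, marker_map, carrier_ids, cfg, mode)
    return call_stretches(calls, marker_map, cfg, mode)


def recessive_scan(
    matrix: GenotypeMatrix,
    marker_map: MarkerMap,
    carrier_ids: Sequence[str],
    config: StreakConfig | None = None,
) -> list[IBDStretch]:
    """Homozygosity mapping: all carriers homozygous for the same allele.

    Every recessive stretch is also compatible under the dominant streak rule.
    """
    return scan_stretches(
        matrix, marker_map, carrier_ids, config, mode="recessive_homozygosity"
    )


def _extent_compatible(
    sub: np.ndarray,
    pos: np.ndarray,
    cfg: StreakConfig,
    mode: str,
    strict: bool,
) -> bool:
    """Window rule over a restricted marker extent for an extended carrier set.

    strict=True: every window placement within the extent must be compatible.
    strict=False: some merged run of compatible windows spanning
    >= min_stretch_bp must remain.
    """
    incompat = _incompatible_mask(sub, cfg.missing_policy, mode)
    starts, first, last = _window_bounds(pos, cfg)
    # clip windows at the extent's last marker (the extent IS the region)
    counts = _window_incompat_counts(incompat, first, last)
    ok = counts <= cfg.max_exceptions_per_window
    if strict:
        return bool(ok.all())
    runs = _merge_compatible(starts, first, last, ok, cfg.window_span_bp)
    return any(pos[l] - pos[f] + 1 >= cfg.min_stretch_bp for f, l in runs)


def impute_presence(
    stretch: IBDStretch,
    matrix: GenotypeMatrix,
    carrier_ids: Sequence[str],
    subject_id: str,
    config: StreakConfig | None = None,
    strict: bool = True,
) -> bool:
    """Impute presence of the stretch's ancestral haplotype in one subject.

    True iff re-running the window rule over the stretch's extent with the
    carrier set extended by the subject leaves the stretch compatible: under
    the default strict reading the entire original extent must stay
    compatible; with ``strict=False`` it suffices that a sub-stretch of at
    least ``min_stretch_bp`` remains.
    """
    cfg = config or StreakConfig()
    if subject_id in carrier_ids:
        raise ValueError(f"subject {subject_id!r} is already in the carrier set")
    if subject_id not in matrix.samples:
        raise ValueError(f"subject {subject_id!r} is not genotyped")
    idx = matrix.marker_map.chrom_index(stretch.chrom)
    pos = matrix.marker_map.table["pos"].to_numpy()[idx]
    in_extent = (pos >= stretch.start_bp) & (pos <= stretch.end_bp)
    sub = matrix.rows(list(carrier_ids) + [subject_id])[:, idx[in_extent]]
    return _extent_compatible(sub, pos[in_extent], cfg, stretch.mode, strict)


def presence_counts(
    stretches: Sequence[IBDStretch],
    matrix: GenotypeMatrix,
    carrier_ids: Sequence[str],
    unaffected_pool: Iterable[str],
    config: StreakConfig | None = None,
    strict: bool = True,
) -> list[int]:
    """Per-stretch count of pool subjects imputed to harbor the haplotype.

    Fills each stretch's ``unaffected_presence`` map as a side effect.
    """
    cfg = config or StreakConfig()
    pool = list(unaffected_pool)
    counts = []
    for st in stretches:
        n = 0
        for sid in pool:
            present = impute_presence(st, matrix, carrier_ids, sid, cfg, strict)
            st.unaffected_presence[sid] = present
            n += present
        counts.append(n)
    return counts


def refine(
    stretches: Sequence[IBDStretch],
    matrix: GenotypeMatrix,
    carrier_ids: Sequence[str],
    unaffected_pool: Iterable[str],
    config: StreakConfig | None = None,
    strict: bool = True,
) -> RefinementTrace:
    """Confine stretches by consecutively restricting unaffected sharing.

    For each stretch, count the pool subjects imputed to harbor its haplotype;
    then walk the threshold k down from the pool size, keeping at each step
    the stretches harbored by at most k pool subjects, stopping at the first k
    with at most one survivor (or k=0).  The causal region is expected to be
    shared by fewer unaffected members than regions shared merely by descent.
    """
    cfg = config or StreakConfig()
    pool = list(unaffected_pool)
    counts = presence_counts(stretches, matrix, carrier_ids, pool, cfg, strict)
    steps: list[tuple[int, list[IBDStretch]]] = []
    for k in range(len(pool), -1, -1):
        survivors = [st for st, c in zip(stretches, counts) if c <= k]
        steps.append((k, survivors))
        if len(survivors) <= 1:
            break
    return RefinementTrace(presence_counts=counts, steps=steps)


def subset_has_confined_stretch(
    matrix: GenotypeMatrix,
    marker_map: MarkerMap,
    carrier_ids: Sequence[str],
    other_ids: Sequence[str],
    threshold_k: int,
    config: StreakConfig | None = None,
    strict: bool = True,
) -> bool:
    """Full pipeline for one carrier subset: does any stretch end up harbored
    by at most ``threshold_k`` of the remaining members?"""
    cfg = config or StreakConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stretches = scan_stretches(matrix, marker_map, carrier_ids, cfg)
    if not stretches:
        return False
    counts = presence_counts(stretches, matrix, carrier_ids, other_ids, cfg, strict)
    return any(c <= threshold_k for c in counts)


def permutation_test(
    matrix: GenotypeMatrix,
    marker_map: MarkerMap,
    pedigree_member_ids: Sequence[str],
    n_affected: int,
    threshold_k: int,
    B: int = 10_000,
    seed: int = 0,
    config: StreakConfig | None = None,
    strict: bool = True,
) -> PermutationResult:
    """Subset-permutation significance of observing a confined IBD stretch.

    Each iteration draws ``n_affected`` members uniformly without replacement,
    re-runs the scan with them as the carrier set, and scores success when at
    least one resulting stretch is harbored by at most ``threshold_k`` of the
    remaining members.  p is reported as the plain fraction n_success / B.
    """
    cfg = config or StreakConfig()
    members = list(pedigree_member_ids)
    if n_affected + 1 > len(members):
        raise ValueError("n_affected leaves no members to test presence in")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n_success = 0
    member_arr = np.array(members)
    cache: dict[frozenset, bool] = {}
    for _ in range(B):
        drawn_idx = rng.choice(len(members), size=n_affected, replace=False)
        drawn = frozenset(member_arr[drawn_idx])
        if drawn not in cache:
            others = [m for m in members if m not in drawn]
            cache[drawn] = subset_has_confined_stretch(
                matrix, marker_map, sorted(drawn), others, threshold_k, cfg, strict
            )
        n_success += cache[drawn]
    return PermutationResult(
        n_iterations=B,
        n_affected_drawn=n_affected,
        presence_threshold_k=threshold_k,
        n_success=n_success,
        p_value=n_success / B,
        seed=seed,
    )


def pairwise_r2_from_panel(
    matrix: GenotypeMatrix, window_bp: int = 1_000_000
) -> dict[tuple[str, str], float]:
    """Pairwise dosage r-squared between markers within a bp window, computed
    from a reference genotype panel.  Missing genotypes are pairwise-dropped."""
    out: dict[tuple[str, str], float] = {}
    table = matrix.marker_map.table
    ids = table["id"].to_numpy()
    for chrom in matrix.marker_map.chroms:
        idx = matrix.marker_map.chrom_index(chrom)
        pos = table["pos"].to_numpy()[idx]
        vals = matrix.values[:, idx].astype(float)
        vals[vals == MISSING] = np.nan
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if pos[b] - pos[a] > window_bp:
                    break
                x, y = vals[:, a], vals[:, b]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 2:
                    continue
                xs, ys = x[ok], y[ok]
                if xs.std() == 0 or ys.std() == 0:
                    continue
                r = np.corrcoef(xs, ys)[0, 1]
                out[(str(ids[idx[a]]), str(ids[idx[b]]))] = float(r * r)
    return out


def ld_prune(
    matrix_or_map: GenotypeMatrix | MarkerMap,
    pairwise_r2: Mapping[tuple[str, str], float],
    threshold: float = 0.9,
) -> list[int]:
    """Greedy left-to-right LD prune.

    Walking markers in map order, a marker is dropped when its r-squared with
    any already-retained marker reaches the threshold.  Returns the indices of
    retained markers.  An empty r-squared source keeps everything (logged).
    """
    marker_map = (
        matrix_or_map.marker_map
        if isinstance(matrix_or_map, GenotypeMatrix)
        else matrix_or_map
    )
    if not pairwise_r2:
        log.info("ld_prune: empty r2 source, keeping all %d markers", len(marker_map))
        return list(range(len(marker_map)))
    partners: dict[str, dict[str, float]] = {}
    for (a, b), r2 in pairwise_r2.items():
        partners.setdefault(a, {})[b] = r2
        partners.setdefault(b, {})[a] = r2
    ids = marker_map.table["id"].to_numpy()
    kept: list[int] = []
    kept_ids: set[str] = set()
    for j, mid in enumerate(ids):
        linked = partners.get(str(mid), {})
        if any(k in kept_ids and r2 >= threshold for k, r2 in linked.items()):
            continue
        kept.append(j)
        kept_ids.add(str(mid))
    return kept
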