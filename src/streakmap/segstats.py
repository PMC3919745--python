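"""Segregation statistics: mid-P Fisher exact test and penetrance estimate.

The mid-P variant of Fisher's exact test counts only half the probability of
the observed table (and of any table exactly as probable), which removes much
of the conservatism the discreteness of the hypergeometric null imposes on
the standard exact test.  Two-sidedness follows the "tables no more probable
than observed" construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .pedio import AnalysisGroups


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier-by-group counts.

    Rows are the analysis groups (expected carriers vs unaffected pool),
    columns are variant carrier yes/no::

        a b   (expected-carrier group: carriers, non-carriers)
        c d   (unaffected pool:        carriers, non-carriers)
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class MidPResult:
    p_mid_two_sided: float
    p_fisher_two_sided: float
    method_note: str = (
        "two-sided by the 'tables no more probable than observed' criterion; "
        "mid-P counts half the mass of tables exactly as probable as observed"
    )


# relative tolerance for probability ties in the enumeration
TIE_REL_TOL = 1e-12


def _support_log_masses(table: ContingencyTable2x2) -> tuple[np.ndarray, np.ndarray]:
    r1, _r2, c1, _c2 = table.margins
    n = table.n
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = hypergeom.logpmf(support, n, c1, r1)
    return support, logp


def midp_fisher(table: ContingencyTable2x2) -> MidPResult:
    """Two-sided mid-P Fisher exact test by full hypergeometric enumeration.

    With margins fixed, every admissible table's probability is enumerated;
    the mid-P sums the mass of tables strictly less probable than the observed
    one plus half the mass of tables exactly as probable (the observed table
    included).  Probability ties are compared within a relative tolerance.
    The standard two-sided Fisher p (full observed mass) is reported
    alongside.
    """
    r1, r2, c1, c2 = table.margins
    if 0 in (r1, r2, c1, c2):
        raise ValueError("zero margin: exact test undefined")
    support, logp = _support_log_masses(table)
    obs_logp = float(logp[support == table.a][0])
    # relative tie tolerance on probabilities ~ absolute tolerance on logs
    tol = np.log1p(TIE_REL_TOL)
    equal = np.abs(logp - obs_logp) <= tol
    less = (logp < obs_logp) & ~equal
    masses = np.exp(logp)
    p_less = float(masses[less].sum())
    p_equal = float(masses[equal].sum())
    p_mid = min(1.0, p_less + 0.5 * p_equal)
    p_fisher = min(1.0, p_less + p_equal)
    return MidPResult(p_mid_two_sided=p_mid, p_fisher_two_sided=p_fisher)


def midp_fisher_one_sided(table: ContingencyTable2x2, alternative: str = "greater") -> float:
    """One-sided mid-P (enrichment of carriers in the first group by default)."""
    r1, r2, c1, c2 = table.margins
    if 0 in (r1, r2, c1, c2):
        raise ValueError("zero margin: exact test undefined")
    support, logp = _support_log_masses(table)
    masses = np.exp(logp)
    obs = table.a
    if alternative == "greater":
        tail = support > obs
    elif alternative == "less":
        tail = support < obs
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(1.0, masses[tail].sum() + 0.5 * masses[support == obs].sum()))


def segregation_table(
    variant_carriers: set[str], groups: AnalysisGroups
) -> ContingencyTable2x2:
    """Cross-tabulate variant carrier status by analysis group."""
    g1, g2 = groups.carriers_expected, groups.unaffected_pool
    if g1 & g2:
        raise ValueError("analysis groups overlap")
    a = len(variant_carriers & g1)
    c = len(variant_carriers & g2)
    return ContingencyTable2x2(a=a, b=len(g1) - a, c=c, d=len(g2) - c)


def penetrance_estimate(table: ContingencyTable2x2) -> float:
    """Fraction of all carriers that are in the affected/expected-carrier group.

    For a dominant-model family this is the naive penetrance of the variant.
    """
    total_carriers = table.a + table.c
    if total_carriers == 0:
        raise ValueError("no carriers: penetrance undefined")
    return table.a / total_carriers


def round_sig(p: float, sig_figs: int = 2) -> float:
    """Round to significant figures (reporting convention for tables)."""
    if p == 0:
        return 0.0
    from math import floor, log10

    return round(p, -int(floor(log10(abs(p)))) + (sig_figs - 1))
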