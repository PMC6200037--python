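"""Gene-trait matching: exact association tests between gene-family
presence/absence and a binary growth phenotype.

Each family is summarized as a 2x2 table over strains::

                     grows    does not grow
    family present     a           c
    family absent      b           d

and tested with the two-sided Fisher exact test, followed by
Benjamini-Hochberg step-up correction across families. A strain is
growth-positive when the arithmetic mean of its OD600 replicates is
1.0 or higher (boundary inclusive).

Two-sided convention: the point-probability ("minimum likelihood")
method — the p-value sums the hypergeometric probabilities of every
table with the same margins whose point probability does not exceed the
observed table's. Probabilities are computed in exact rational
arithmetic, so ties are resolved exactly and no continuity correction or
pseudo-count enters anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import PresenceAbsenceMatrix

GROWTH_OD_THRESHOLD = 1.0


def phenotype_from_od(od_replicates: Sequence[float]) -> bool:
    """Growth-positive iff the mean OD600 is 1.0 or higher."""
    if len(od_replicates) == 0:
        raise ValueError("need at least one OD replicate")
    return float(np.mean(od_replicates)) >= GROWTH_OD_THRESHOLD


def load_phenotypes(path) -> dict[str, bool]:
    """Read a phenotype TSV into strain -> growth.

    Accepts either a ``growth`` column (0/1) or OD replicate columns
    (``od_rep*``), in which case the mean-OD threshold rule is applied.
    A ``growth`` column, when present alongside replicates, must agree
    with the rule.
    """
    df = pd.read_csv(path, sep="\t")
    if "strain" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs a 'strain' column")
    od_cols = [c for c in df.columns if c.startswith("od_rep")]
    out: dict[str, bool] = {}
    for _, row in df.iterrows():
        strain = str(row["strain"])
        if od_cols:
            growth = phenotype_from_od([float(row[c]) for c in od_cols])
            if "growth" in df.columns and bool(int(row["growth"])) != growth:
                raise ValueError(
                    f"{path}: growth flag for {strain} contradicts the "
                    f"mean-OD >= {GROWTH_OD_THRESHOLD} rule")
        elif "growth" in df.columns:
            growth = bool(int(row["growth"]))
        else:
            raise ValueError(f"{path}: need od_rep* or growth columns")
        out[strain] = growth
    return out


@dataclass
class AssociationResult:
    """One family's 2x2 counts and test results."""

    family_id: str
    a: int  # carriers among growers
    b: int  # non-carriers among growers
    c: int  # carriers among non-growers
    d: int  # non-carriers among non-growers
    p_raw: float
    p_adj: float
    significant: bool


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table, exact arithmetic.

    With all margins fixed, sums the hypergeometric point probabilities of
    every table whose point probability is <= the observed table's.
    Rational arithmetic makes tie comparisons exact; an all-zero table
    returns 1.0.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1 = a + b  # growers
    c1 = a + c  # carriers
    denom = comb(n, c1)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    p_obs = Fraction(comb(r1, a) * comb(n - r1, c1 - a), denom)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        pk = Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        if pk <= p_obs:
            total += pk
    return float(min(total, Fraction(1)))


def bh_adjust(p_values: Sequence[float], m_override: int | None = None
              ) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the ascending sort, capped at
    1 and mapped back. ``m_override`` substitutes the number of tests m
    (it must be >= the number of p-values), allowing a worked example to
    be adjusted as if it sat at the top ranks of a larger family of tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m_override is None else int(m_override)
    if m < len(p):
        raise ValueError("m_override must be >= the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def match_traits(matrix: PresenceAbsenceMatrix,
                 phenotypes: Mapping[str, bool],
                 alpha: float = 0.05,
                 m_override: int | None = None) -> list[AssociationResult]:
    """Test every family for association with the growth phenotype.

    Results are sorted by (p_raw, family_id); ``significant`` means
    BH-adjusted p strictly below ``alpha``. Raises if any matrix strain
    lacks a phenotype.
    """
    missing = [s for s in matrix.strains if s not in phenotypes]
    if missing:
        raise ValueError(f"phenotype missing for strains: {missing}")
    growth = np.array([phenotypes[s] for s in matrix.strains], dtype=bool)
    n_grow = int(growth.sum())
    n_nogrow = len(matrix.strains) - n_grow

    tables = []
    for j, fam in enumerate(matrix.families):
        present = matrix.values[:, j]
        a = int((present & growth).sum())
        c = int((present & ~growth).sum())
        tables.append((fam, a, n_grow - a, c, n_nogrow - c))
    p_raw = np.array([fisher_exact_two_sided(a, b, c, d)
                      for _, a, b, c, d in tables])
    p_adj = bh_adjust(p_raw, m_override=m_override)
    results = [
        AssociationResult(fam, a, b, c, d, float(pr), float(pa), bool(pa < alpha))
        for (fam, a, b, c, d), pr, pa in zip(tables, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.family_id))
    return results


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.family_id, r.a, r.b, r.c, r.d, r.p_raw, r.p_adj, int(r.significant))
         for r in results],
        columns=["family_id", "a", "b", "c", "d", "p_raw", "p_adj", "significant"])
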