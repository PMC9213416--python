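"""Phenotypic correlations, the free-oestradiol calculation and
leave-one-out grouping of disease subtypes.

Phenotypic correlations are Pearson correlations on complete pairs with a
Fisher-z normal test (binary traits go through the same machinery, i.e.
point-biserial).  Free oestradiol is the fraction of serum oestradiol not
bound by SHBG or albumin; the published formula is evaluated literally as
printed (see the note on :func:`free_estradiol_mass_action` for a standard
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypicCorrelation",
    "FreeEstradiolRecord",
    "LooGrouping",
    "phenotypic_correlation",
    "free_estradiol",
    "free_estradiol_mass_action",
    "loo_groupings",
    "loo_rg_grid",
]

#: association-constant terms of the printed free-oestradiol formula
N_E2_ALBUMIN_COEF = 0.64e9
N_SHBG_COEF = 5.55e4


@dataclass
class PhenotypicCorrelation:
    trait_x: str
    trait_y: str
    r: float
    se: float  # on the r scale, (1 - r^2)/sqrt(n - 3)
    se_z: float  # on the Fisher-z scale, 1/sqrt(n - 3)
    p_value: float
    n: int


@dataclass
class FreeEstradiolRecord:
    E2: float
    SHBG: float
    albumin: float
    N_E2: float
    N_SHBG: float
    N_TOTAL: float
    cFO: float


@dataclass
class LooGrouping:
    subtypes: list[str]
    held_out: str
    grouped_status: np.ndarray  # union of the remaining subtypes


def phenotypic_correlation(x, y, names=("x", "y")) -> PhenotypicCorrelation:
    """Pearson r on complete pairs with a Fisher-z two-tailed normal test."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a variable")
    r = float(np.corrcoef(x, y)[0, 1])
    se_z = 1.0 / np.sqrt(n - 3)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        z = np.arctanh(r)
        p = float(2.0 * stats.norm.sf(abs(z) / se_z))
    return PhenotypicCorrelation(
        trait_x=names[0], trait_y=names[1], r=r,
        se=float((1 - r**2) / np.sqrt(n - 3)), se_z=float(se_z),
        p_value=p, n=n,
    )


def free_estradiol(E2, SHBG, albumin) -> FreeEstradiolRecord:
    """Calculated free oestradiol, literal published form:

        cFO = (E2 - N_TOTAL) / (N_SHBG - (E2 + N_E2))

    with N_E2 = 0.64e9 * albumin + 1, N_SHBG = 5.55e4 * SHBG and
    N_TOTAL = N_SHBG + N_E2.  Units pass through unconverted.  The
    denominator structure is kept exactly as printed even though it is
    dimensionally inconsistent with the mass-action free-hormone literature;
    see :func:`free_estradiol_mass_action` for the standard alternative.
    """
    E2, SHBG, albumin = float(E2), float(SHBG), float(albumin)
    if E2 < 0 or SHBG < 0 or albumin < 0:
        raise ValueError("inputs must be non-negative")
    n_e2 = N_E2_ALBUMIN_COEF * albumin + 1.0
    n_shbg = N_SHBG_COEF * SHBG
    n_total = n_shbg + n_e2
    denom = n_shbg - (E2 + n_e2)
    if denom == 0:
        raise ZeroDivisionError("free-oestradiol denominator is zero")
    return FreeEstradiolRecord(
        E2=E2, SHBG=SHBG, albumin=albumin,
        N_E2=n_e2, N_SHBG=n_shbg, N_TOTAL=n_total,
        cFO=(E2 - n_total) / denom,
    )


def free_estradiol_mass_action(E2_total, SHBG, albumin, K_shbg=3.14e8, K_alb=4.21e4):
    """Standard mass-action free-fraction quadratic (off by default in any
    pipeline output; provided for comparison with :func:`free_estradiol`).

    Solves K_shbg F^2 + (1 + K_shbg (SHBG - E2_total) + K_alb albumin) F -
    E2_total = 0 for the free concentration F, all in molar units.
    """
    a = K_shbg * (1.0 + K_alb * albumin)
    b = 1.0 + K_alb * albumin + K_shbg * (SHBG - E2_total)
    c = -float(E2_total)
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("no real free concentration")
    return (-b + np.sqrt(disc)) / (2 * a)


def loo_groupings(subtypes: list[str], statuses: pd.DataFrame) -> list[LooGrouping]:
    """One fold per subtype: the grouped phenotype excluding it.

    ``statuses`` holds one 0/1 (NaN = not at risk) column per subtype.
    """
    if len(subtypes) < 2:
        raise ValueError("need at least two subtypes")
    if len(set(subtypes)) != len(subtypes):
        raise ValueError("duplicate subtype names")
    folds = []
    for held in subtypes:
        rest = [s for s in subtypes if s != held]
        grouped = (statuses[rest] == 1).any(axis=1).astype(int).to_numpy()
        folds.append(LooGrouping(subtypes=rest, held_out=held, grouped_status=grouped))
    return folds


def loo_rg_grid(
    subtypes: list[str],
    statuses: pd.DataFrame,
    rg_func,
) -> pd.DataFrame:
    """Assemble the leave-one-out genetic-correlation grid.

    ``rg_func(status_a, status_b) -> (rg, se) or raises`` computes the
    genetic correlation between two binary phenotypes (cross-trait LD-score
    regression or bivariate GREML); non-estimable cells carry the failure
    reason instead of a value.
    """
    folds = loo_groupings(subtypes, statuses)
    full = (statuses[subtypes] == 1).any(axis=1).astype(int).to_numpy()
    rows = []
    labels = ["grouped (all subtypes)"] + [f"grouped excluding {f.held_out}" for f in folds]
    groups = [full] + [f.grouped_status for f in folds]
    excluded = [None] + [f.held_out for f in folds]
    for lab, grp, excl in zip(labels, groups, excluded):
        row: dict = {"grouping": lab}
        for s in subtypes:
            if s == excl:
                row[s] = np.nan
                continue
            try:
                rg, se = rg_func(statuses[s].to_numpy(), grp)
                row[s] = f"{rg:.4f} ({se:.4f})" if rg is not None else "NE"
            except Exception as exc:  # non-estimable cell, keep the reason
                row[s] = f"NE: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
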